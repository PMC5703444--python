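"""File formats: pedigree/phenotype/summary-stat TSV, GT-only VCF, truth JSON.

All artifacts are plain text.  Genotypes travel as VCF v4.2 with a
single FORMAT field (GT) and biallelic records; dosages are counts of
the ALT allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PEDIGREE_COLUMNS = [
    "family_id",
    "person_id",
    "zygosity",
    "role",
    "sex",
    "age_t1",
    "age_t2",
]


@dataclass
class VariantTable:
    """Biallelic variants with per-person ALT-allele dosages.

    ``dosages`` is (n_variants, n_persons) float with NaN for missing
    calls; ``variants`` carries id/chrom/pos/ref/alt (pos is 1-based).
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    persons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.variants), len(self.persons)):
            raise ValueError("dosage matrix shape does not match variants x persons")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad & ~np.isnan(self.dosages)):
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    def person_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def alt_frequency(self) -> np.ndarray:
        """Observed ALT allele frequency per variant (missing ignored)."""
        return np.nanmean(self.dosages, axis=1) / 2.0

    def subset(self, variant_mask=None, person_mask=None) -> "VariantTable":
        v = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask)
        p = np.ones(self.n_persons, bool) if person_mask is None else np.asarray(person_mask)
        return VariantTable(
            variants=self.variants.loc[v].reset_index(drop=True),
            dosages=self.dosages[np.ix_(v, p)],
            persons=[s for s, keep in zip(self.persons, p) if keep],
        )


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    pedigree.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", na_values="NA")
    missing = set(PEDIGREE_COLUMNS) - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree file lacks columns: {sorted(missing)}")
    return ped


def write_phenotypes(path, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P"]


def write_sumstats(path, stats: pd.DataFrame) -> None:
    stats.to_csv(path, sep="\t", index=False, columns=SUMSTAT_COLUMNS)


def read_sumstats(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t")
    missing = set(SUMSTAT_COLUMNS) - set(stats.columns)
    if missing:
        raise ValueError(f"summary-statistics file lacks columns: {sorted(missing)}")
    return stats


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(path, table: VariantTable) -> None:
    """Write a GT-only VCF v4.2 (hard genotype calls; `./.` for missing)."""
    cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + list(table.persons))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(cols + "\n")
        for i, row in enumerate(table.variants.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d) else _GT_CODE[float(round(d))]
                for d in table.dosages[i]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path) -> VariantTable:
    """Read a GT-only VCF into a :class:`VariantTable` (biallelic records only)."""
    meta_rows = []
    dosage_rows = []
    persons: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                persons = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[:5]
            if "," in alt:
                raise ValueError(f"multiallelic record not supported: {vid}")
            meta_rows.append((vid, chrom, int(pos), ref, alt))
            row = np.empty(len(fields) - 9)
            for j, gt in enumerate(fields[9:]):
                gt = gt.split(":")[0]
                if "." in gt:
                    row[j] = np.nan
                else:
                    row[j] = sum(int(a) for a in gt.replace("|", "/").split("/"))
            dosage_rows.append(row)
    variants = pd.DataFrame(meta_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(persons)))
    return VariantTable(variants=variants, dosages=dosages, persons=persons)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
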