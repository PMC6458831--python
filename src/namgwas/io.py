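"""Plain TSV readers/writers and cross-file validation.

All pipeline artefacts are header-carrying tab-separated tables so every
intermediate can be inspected, diffed and round-tripped: genotypes
(line_id, family, one column per SNP), map (snp_id, chromosome,
position), long-format PSA series (cart_id, day, psa), per-cart harvest
and trait tables, BLUE/heritability tables and QTL reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genmap import GeneticMap, CHROMOSOMES
from .population import Genotypes


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", **kwargs)


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    def add(self, message: str) -> None:
        self.violations.append(message)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.violations)


def validate_inputs(genotype_tsv, map_tsv, phenotype_tsv=None) -> ValidationReport:
    """Check dosage domain, map sorting and ID cross-references.

    Returns a report listing one message per violation; empty when clean.
    """
    report = ValidationReport()
    try:
        geno_raw = pd.read_csv(genotype_tsv, sep="\t", index_col="line_id",
                               na_values="NA")
    except Exception as exc:  # noqa: BLE001 - report, do not crash
        report.add(f"genotype file unreadable: {exc}")
        return report
    try:
        map_raw = pd.read_csv(map_tsv, sep="\t")
    except Exception as exc:  # noqa: BLE001
        report.add(f"map file unreadable: {exc}")
        return report

    if "family" not in geno_raw.columns:
        report.add("genotype file lacks a 'family' column")
        snp_cols = list(geno_raw.columns)
    else:
        snp_cols = [c for c in geno_raw.columns if c != "family"]
    for col in snp_cols:
        vals = pd.to_numeric(geno_raw[col], errors="coerce")
        bad = geno_raw[col].notna() & ~vals.isin([0, 1, 2])
        for line in geno_raw.index[bad]:
            report.add(f"dosage out of domain at line {line}, SNP {col}: "
                       f"{geno_raw.at[line, col]!r}")

    for col in ("snp_id", "chromosome", "position"):
        if col not in map_raw.columns:
            report.add(f"map file lacks column '{col}'")
            return report
    if map_raw["snp_id"].duplicated().any():
        report.add("duplicate snp_id in map")
    unknown = set(map_raw["chromosome"]) - set(CHROMOSOMES)
    if unknown:
        report.add(f"unknown chromosomes in map: {sorted(unknown)}")
    for chrom, grp in map_raw.groupby("chromosome"):
        if not grp["position"].is_monotonic_increasing:
            report.add(f"map positions not sorted on {chrom}")

    missing_in_map = set(snp_cols) - set(map_raw["snp_id"])
    for snp in sorted(missing_in_map):
        report.add(f"SNP {snp} in genotype file absent from map")

    if phenotype_tsv is not None:
        try:
            pheno = pd.read_csv(phenotype_tsv, sep="\t", na_values="NA")
        except Exception as exc:  # noqa: BLE001
            report.add(f"phenotype file unreadable: {exc}")
            return report
        for col in ("cart_id", "day", "psa"):
            if col not in pheno.columns:
                report.add(f"phenotype file lacks column '{col}'")
        if "psa" in pheno.columns:
            neg = pheno["psa"] < 0
            if neg.any():
                report.add(f"{int(neg.sum())} negative PSA values")
        if "day" in pheno.columns:
            out = ~pheno["day"].between(32, 59)
            if out.any():
                report.add(f"{int(out.sum())} PSA days outside [32, 59]")
    return report


def read_genotypes(path) -> Genotypes:
    return Genotypes.read_tsv(path)


def read_map(path) -> GeneticMap:
    return GeneticMap.read_tsv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
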