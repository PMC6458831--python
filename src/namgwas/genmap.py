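"""Genetic maps on the seven barley chromosomes (1H..7H), in centiMorgan.

A map is held as a :class:`pandas.DataFrame` with columns ``snp_id``,
``chromosome`` and ``position`` (cM), sorted by chromosome then position.
The :class:`GeneticMap` wrapper validates the invariants once on
construction and provides per-chromosome views, Haldane recombination
fractions and TSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHROMOSOMES = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")


def haldane_c(d_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction between loci ``d_cM`` centiMorgan apart.

    Haldane's map function (no crossover interference):
    ``c = (1 - exp(-2 d / 100)) / 2``.
    """
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distances must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass(frozen=True)
class GeneticMap:
    """Validated SNP map: unique ids, sorted positions, non-empty chromosomes."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"snp_id", "chromosome", "position"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"map table missing columns: {sorted(missing)}")
        if t["snp_id"].duplicated().any():
            raise ValueError("snp_id values must be unique")
        if (t["position"] < 0).any():
            raise ValueError("cM positions must be non-negative")
        unknown = set(t["chromosome"]) - set(CHROMOSOMES)
        if unknown:
            raise ValueError(f"unknown chromosome labels: {sorted(unknown)}")
        if len(t) == 0:
            raise ValueError("empty map")
        for chrom, grp in t.groupby("chromosome", observed=True):
            if not grp["position"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on {chrom}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return [c for c in CHROMOSOMES if c in set(self.table["chromosome"])]

    def chromosome_slice(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self.chromosome_slice(chrom)["position"].to_numpy(dtype=float)

    def adjacent_recomb_fractions(self, chrom: str) -> np.ndarray:
        """Haldane recombination fractions between consecutive markers."""
        pos = self.positions(chrom)
        return haldane_c(np.diff(pos))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chromosome": str})
        return cls(t)


def simulate_map(
    n_snps_per_chrom: int | dict[str, int],
    chrom_lengths: float | dict[str, float] = 150.0,
    seed: int | np.random.Generator = 0,
) -> GeneticMap:
    """Draw a uniform random marker map over the 7 barley chromosomes.

    Parameters
    ----------
    n_snps_per_chrom
        Marker count per chromosome, either one integer for all or a dict
        keyed by chromosome label. Must be positive.
    chrom_lengths
        Chromosome length(s) in cM; positions are uniform on [0, length].
    seed
        Integer seed or a :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(seed)
    if not isinstance(n_snps_per_chrom, dict):
        n_snps_per_chrom = {c: int(n_snps_per_chrom) for c in CHROMOSOMES}
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = {c: float(chrom_lengths) for c in CHROMOSOMES}
    rows = []
    for chrom in CHROMOSOMES:
        n = int(n_snps_per_chrom.get(chrom, 0))
        length = float(chrom_lengths.get(chrom, 0.0))
        if n <= 0:
            raise ValueError(f"n_snps_per_chrom must be positive (chromosome {chrom})")
        if length <= 0:
            raise ValueError(f"chrom_lengths must be positive (chromosome {chrom})")
        pos = np.sort(rng.uniform(0.0, length, size=n))
        width = max(4, len(str(n)))
        for i, p in enumerate(pos):
            rows.append((f"{chrom}_{i + 1:0{width}d}", chrom, p))
    return GeneticMap(pd.DataFrame(rows, columns=["snp_id", "chromosome", "position"]))
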