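"""BC1S3 nested association mapping population simulator.

The emulated population follows the HEB-25 design: 25 wild barley donors
each crossed once to a common recurrent (elite) parent, the F1 backcrossed
to the recurrent parent, and the BC1 selfed for three generations with
independent meioses. Genotypes are coded identity-by-state as the wild
allele dosage per marker: 0 = homozygous recurrent, 1 = heterozygous,
2 = homozygous wild.

Meiosis uses Haldane's map function (no interference): the transmitted
haplotype is a Markov chain along each chromosome whose switch probability
between adjacent markers is the Haldane recombination fraction.

Per-locus expectations under this pedigree (wild allele ``A``):
the BC1 is ``Aa`` with probability 1/2, so after three selfings
``P(het) = 1/2 * (1/2)^3 = 1/16``, ``P(hom wild) = 7/32``,
``P(hom recurrent) = 23/32`` and the wild allele frequency is 1/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap

RECURRENT_ID = "BARKE"
CHECK_ID = "NAVIGATOR"
RECURRENT_FAMILY = "RECURRENT"
CHECK_FAMILY = "CHECK"

FAMILY_LABELS = tuple(f"F{i:02d}" for i in range(1, 26))


@dataclass
class Genotypes:
    """Wild-allele dosage matrix (lines x SNPs) with family labels.

    ``dosage`` is a float DataFrame (values 0/1/2 or NaN for missing),
    indexed by line id with one column per SNP; ``family`` maps each line
    to its donor family (F01..F25) or to CHECK / RECURRENT.
    """

    dosage: pd.DataFrame = field(repr=False)
    family: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.dosage.index.equals(self.family.index):
            raise ValueError("dosage and family must share the same line index")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        self.dosage.index.name = "line_id"
        self.family.index.name = "line_id"
        self.family.name = "family"

    @property
    def line_ids(self) -> np.ndarray:
        return self.dosage.index.to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.dosage.columns.to_numpy()

    def nam_lines(self) -> pd.Index:
        """Lines belonging to a donor family (checks/recurrent excluded)."""
        keep = ~self.family.isin([CHECK_FAMILY, RECURRENT_FAMILY])
        return self.family.index[keep]

    def subset_lines(self, lines) -> "Genotypes":
        return Genotypes(self.dosage.loc[lines], self.family.loc[lines])

    def subset_snps(self, snps) -> "Genotypes":
        return Genotypes(self.dosage.loc[:, snps], self.family)

    def write_tsv(self, path) -> None:
        out = self.dosage.copy()
        out.insert(0, "family", self.family)
        out.index.name = "line_id"
        out.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def read_tsv(cls, path) -> "Genotypes":
        t = pd.read_csv(path, sep="\t", index_col="line_id", na_values="NA")
        fam = t.pop("family").astype(str)
        return cls(t.astype(float), fam)


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, c: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorised gametes for one chromosome.

    ``hap_a``/``hap_b`` are (n, m) parental haplotypes; ``c`` the (m-1,)
    Haldane recombination fractions between adjacent markers. The phase
    starts 50:50 and switches independently between markers.
    """
    n, m = hap_a.shape
    phase = np.empty((n, m), dtype=bool)
    phase[:, 0] = rng.random(n) < 0.5
    if m > 1:
        switches = rng.random((n, m - 1)) < c[None, :]
        # cumulative xor along markers gives the phase path
        phase[:, 1:] = phase[:, [0]] ^ (np.cumsum(switches, axis=1) % 2).astype(bool)
    return np.where(phase, hap_b, hap_a)


def simulate_bc1s3_family(
    genetic_map: GeneticMap,
    n_lines: int,
    donor_id: str,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
) -> Genotypes:
    """Simulate one BC1S3 family as wild-allele dosages.

    The donor is assumed fixed for the wild allele at every marker, so the
    F1 is fully heterozygous. Each line descends from its own BC1
    individual (independent F1 gamete), then three selfing meioses.
    ``missing_rate`` masks dosages at random to exercise missing-data paths.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if len(genetic_map) == 0:
        raise ValueError("empty map")
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom in genetic_map.chromosomes:
        m = len(genetic_map.chromosome_slice(chrom))
        c = genetic_map.adjacent_recomb_fractions(chrom)
        ones = np.ones((n_lines, m), dtype=np.int8)
        zeros = np.zeros((n_lines, m), dtype=np.int8)
        # BC1: gamete of the fully heterozygous F1 plus a recurrent gamete
        hap1 = _meiosis(ones, zeros, c, rng)
        hap2 = zeros
        for _ in range(3):  # S1..S3, independent meioses per gamete
            new1 = _meiosis(hap1, hap2, c, rng)
            new2 = _meiosis(hap1, hap2, c, rng)
            hap1, hap2 = new1, new2
        blocks.append(hap1 + hap2)
    dosage = np.concatenate(blocks, axis=1).astype(float)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan
    line_ids = [f"{donor_id}_{i + 1:04d}" for i in range(n_lines)]
    frame = pd.DataFrame(dosage, index=line_ids, columns=genetic_map.snp_ids)
    family = pd.Series(donor_id, index=frame.index, name="family")
    return Genotypes(frame, family)


def simulate_population(
    genetic_map: GeneticMap,
    family_sizes,
    seed: int | np.random.Generator = 0,
    allow_any_family_count: bool = False,
    missing_rate: float = 0.0,
) -> Genotypes:
    """Simulate the full NAM population plus recurrent-parent and check lines.

    ``family_sizes`` gives the number of lines per donor family; the
    standard population has 25 families (override with
    ``allow_any_family_count`` for small tests). The recurrent parent is an
    all-zero dosage line; the check is genetically identical to it but kept
    as a distinct line id, mirroring a replicated elite control line.
    """
    family_sizes = list(family_sizes)
    if len(family_sizes) != 25 and not allow_any_family_count:
        raise ValueError("expected 25 families (set allow_any_family_count for tests)")
    rng = np.random.default_rng(seed)
    parts = []
    for i, n in enumerate(family_sizes):
        fam = f"F{i + 1:02d}"
        parts.append(
            simulate_bc1s3_family(genetic_map, int(n), fam, rng, missing_rate)
        )
    dosage = pd.concat([p.dosage for p in parts], axis=0)
    family = pd.concat([p.family for p in parts], axis=0)
    zero = pd.DataFrame(
        np.zeros((2, len(genetic_map))), index=[RECURRENT_ID, CHECK_ID],
        columns=genetic_map.snp_ids,
    )
    dosage = pd.concat([dosage, zero], axis=0)
    family = pd.concat(
        [family, pd.Series({RECURRENT_ID: RECURRENT_FAMILY, CHECK_ID: CHECK_FAMILY})]
    )
    family.name = "family"
    return Genotypes(dosage, family)


def draw_family_sizes(
    n_families: int = 25,
    low: int = 23,
    high: int = 61,
    seed: int | np.random.Generator = 0,
) -> list[int]:
    """Family sizes uniform on [low, high], matching the 23-61 line range."""
    rng = np.random.default_rng(seed)
    return [int(v) for v in rng.integers(low, high + 1, size=n_families)]
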