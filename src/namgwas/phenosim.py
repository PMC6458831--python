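"""Trait architectures, logistic growth curves and plant-level simulation.

The simulator emits the data the downstream stages consume: a daily
projected shoot area (PSA, kilopixels) series per cart for days 32..59
after planting, and a harvest table (fresh/dry weight, height, tiller
number, water added, developmental score, image-derived proxies).

A single latent "size" genetic value per line (QTL effects are additive in
wild-allele dosage and may differ by donor family) shifts the asymptote of
a logistic growth curve. Drought, imposed from day 32, multiplies the
asymptote and growth rate by factors < 1; the defaults reduce final-day
shoot area by roughly half relative to control. Spatial structure
(Smarthouse shift, linear lane/position trends, a smooth field, a shared
main-plot deviation and Smarthouse-by-treatment residual spread) is added
to the PSA series as a per-cart constant, so it propagates into every
derived trait exactly as the stage-1 spatial model assumes. Harvest traits
are deterministic functions of final-day PSA plus trait-specific noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .population import Genotypes, FAMILY_LABELS, CHECK_FAMILY, RECURRENT_FAMILY

DAYS = tuple(range(32, 60))  # imaging days after planting
AGR_INTERVALS = {"AGR32": (32, 40), "AGR42": (42, 50), "AGR52": (52, 59)}
RGR_INTERVALS = {"RGR32": (32, 40), "RGR42": (42, 50), "RGR52": (52, 59)}


@dataclass
class TraitArchitecture:
    """Ground-truth additive genetic architecture for one latent trait.

    ``qtl`` maps a SNP id to either a single per-dosage effect (all
    families) or a dict of per-family effects in trait units per wild
    allele. ``family_effect_sd`` adds a polygenic family deviation.
    """

    qtl: dict = field(default_factory=dict)
    intercept: float = 0.0
    residual_sd: float = 0.0
    family_effect_sd: float = 0.0

    def effects_for(self, snp_id: str, families) -> pd.Series:
        eff = self.qtl[snp_id]
        if isinstance(eff, dict):
            out = pd.Series({f: float(eff.get(f, 0.0)) for f in families})
        else:
            out = pd.Series(float(eff), index=list(families))
        if not np.isfinite(out.to_numpy()).all():
            raise ValueError(f"non-finite effect for {snp_id}")
        return out


def simulate_genetic_values(
    geno: Genotypes,
    architecture: TraitArchitecture,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-line genetic values: intercept + QTL dosage effects + family deviation.

    Returns a DataFrame indexed by line id with columns ``family``,
    ``genetic_value`` and ``family_deviation`` (the deviation is included
    in the value). Checks and the recurrent parent get deviation 0.
    """
    missing = set(architecture.qtl) - set(geno.snp_ids)
    if missing:
        raise ValueError(f"architecture SNPs not in genotype matrix: {sorted(missing)}")
    for snp, eff in architecture.qtl.items():
        if isinstance(eff, dict):
            unknown = set(eff) - set(geno.family.unique())
            if unknown:
                raise ValueError(f"unknown families in architecture: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    fams = geno.family
    value = np.full(len(fams), float(architecture.intercept))
    for snp in architecture.qtl:
        dosage = geno.dosage[snp].fillna(0.0).to_numpy()
        eff = architecture.effects_for(snp, fams.unique())
        value += eff.loc[fams].to_numpy() * dosage
    fam_dev = pd.Series(0.0, index=fams.index)
    if architecture.family_effect_sd > 0:
        nam_fams = [f for f in fams.unique() if f not in (CHECK_FAMILY, RECURRENT_FAMILY)]
        devs = pd.Series(
            rng.normal(0.0, architecture.family_effect_sd, len(nam_fams)),
            index=nam_fams,
        )
        fam_dev = fams.map(devs).fillna(0.0)
    value = value + fam_dev.to_numpy()
    return pd.DataFrame(
        {"family": fams, "genetic_value": value, "family_deviation": fam_dev},
        index=fams.index,
    )


@dataclass
class GrowthModel:
    """Logistic shoot-area growth with drought multipliers from day 32.

    PSA(t) = K / (1 + exp(-r (t - t0))) in kilopixels; under drought both
    K and r are multiplied by factors in (0, 1]. The per-line genetic
    value shifts K additively. Defaults give a control final-day area
    near 200 kPix and a drought/control final ratio near 0.5.
    """

    K: float = 200.0          # asymptote, kPix
    r: float = 0.25           # growth rate, 1/day
    t0: float = 45.0          # inflection day
    drought_k_mult: float = 0.50
    drought_r_mult: float = 0.95
    noise_sd: float = 3.0     # daily observation noise, kPix

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0:
            raise ValueError("K and r must be positive")
        for m in (self.drought_k_mult, self.drought_r_mult):
            if not 0 < m <= 1:
                raise ValueError("drought multipliers must be in (0, 1]")

    def curve(self, days, genetic_value: float = 0.0,
              treatment: str = "control") -> np.ndarray:
        days = np.asarray(days, dtype=float)
        k = max(self.K + genetic_value, 1e-9)
        r = self.r
        if treatment == "drought":
            k *= self.drought_k_mult
            r *= self.drought_r_mult
        return k / (1.0 + np.exp(-r * (days - self.t0)))


def simulate_psa_series(
    genetic_value: float,
    treatment: str,
    growth: GrowthModel,
    days=DAYS,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One plant's daily PSA: logistic closed form plus noise, clipped at 0."""
    days = np.asarray(days, dtype=int)
    if days.min() < 32 or days.max() > 59:
        raise ValueError("imaging days must lie in [32, 59]")
    rng = np.random.default_rng(seed)
    psa = growth.curve(days, genetic_value, treatment)
    if growth.noise_sd > 0:
        psa = psa + rng.normal(0.0, growth.noise_sd, len(days))
    return pd.DataFrame({"day": days, "psa": np.clip(psa, 0.0, None)})


@dataclass
class SimulationTruth:
    """Everything needed to recompute the simulated expectation of any plant."""

    architecture: TraitArchitecture = field(default_factory=TraitArchitecture)
    growth: GrowthModel = field(default_factory=GrowthModel)
    smarthouse_effect: dict = field(default_factory=lambda: {"NE": 6.0, "NW": 0.0})
    lane_coef: dict = field(default_factory=lambda: {"NE": 0.6, "NW": 0.4})
    mainposn_coef: dict = field(default_factory=lambda: {"NE": -0.5, "NW": 0.3})
    spatial_field_amp: float = 3.0
    mainplot_sd: float = 2.0
    # residual spread of the per-cart deviation, by Smarthouse x treatment
    residual_sd: dict = field(default_factory=lambda: {
        ("NE", "control"): 6.0, ("NE", "drought"): 4.0,
        ("NW", "control"): 5.0, ("NW", "drought"): 3.5,
    })
    year_effect: float = 0.0
    # harvest-trait construction: trait = base + slope * PSA(59) + noise
    harvest: dict = field(default_factory=lambda: {
        "FW": (0.0, 0.55, 2.0),    # (base, per-kPix slope, noise sd) [g]
        "DW": (0.0, 0.0385, 0.25),  # g (dry fraction 7% of FW slope)
        "HEI": (30.0, 0.15, 1.5),  # cm
        "TN": (2.0, 0.06, 1.0),    # count
    })
    water: dict = field(default_factory=lambda: {
        # g of irrigation water: base + per-kPix slope + noise sd
        "control": (6000.0, 15.0, 150.0),
        "drought": (1500.0, 10.0, 100.0),
    })
    cha_per_kpix_day: float = 0.12   # convex-hull-area integral proxy
    cl_per_kpix_day: float = 0.012   # caliper-length integral proxy
    zadoks_advanced_rate: float = 0.1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residual_sd"] = {f"{h}:{t}": v for (h, t), v in self.residual_sd.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        d = dict(d)
        if "architecture" in d:
            d["architecture"] = TraitArchitecture(**d["architecture"])
        if "growth" in d:
            d["growth"] = GrowthModel(**d["growth"])
        if "residual_sd" in d:
            d["residual_sd"] = {
                tuple(k.split(":")): v for k, v in d["residual_sd"].items()
            }
        if "harvest" in d:
            d["harvest"] = {k: tuple(v) for k, v in d["harvest"].items()}
        if "water" in d:
            d["water"] = {k: tuple(v) for k, v in d["water"].items()}
        return cls(**d)


def _smooth_field(layout: pd.DataFrame, amp: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth two-dimensional trend per Smarthouse (low-order sinusoids)."""
    out = np.zeros(len(layout))
    if amp == 0:
        return out
    for house, grp in layout.groupby("smarthouse"):
        phase = rng.uniform(0, 2 * np.pi, size=2)
        lane = grp["cLane"].to_numpy()
        pos = grp["cMainPosn"].to_numpy()
        lane_span = max(lane.max() - lane.min(), 1.0)
        pos_span = max(pos.max() - pos.min(), 1.0)
        out[grp.index.to_numpy()] = amp * (
            np.sin(2 * np.pi * lane / lane_span + phase[0])
            + np.cos(2 * np.pi * pos / pos_span + phase[1])
        ) / 2.0
    return out


def simulate_experiment(
    population: Genotypes,
    layout: pd.DataFrame,
    truth: SimulationTruth,
    seed: int | np.random.Generator = 0,
    days=DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the plant-level dataset for one laid-out experiment.

    Returns ``(psa_long, harvest)``: a long table (cart_id, day, psa) and a
    one-row-per-cart harvest table with FW, DW, HEI, TN, CHA, CL, water
    added, Zadoks score and the design columns carried along.
    """
    missing = set(layout["genotype"]) - set(population.line_ids)
    if missing:
        raise ValueError(f"layout genotypes absent from population: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    layout = layout.reset_index(drop=True)
    gvals = simulate_genetic_values(population, truth.architecture, rng)

    field_dev = _smooth_field(layout, truth.spatial_field_amp, rng)
    mp_ids = layout["main_plot_id"].unique()
    mp_dev = pd.Series(
        rng.normal(0.0, truth.mainplot_sd, len(mp_ids)) if truth.mainplot_sd > 0
        else np.zeros(len(mp_ids)), index=mp_ids)

    days = np.asarray(days, dtype=int)
    psa_rows = []
    harvest_rows = []
    for i, row in layout.iterrows():
        gv = float(gvals.loc[row["genotype"], "genetic_value"])
        house, trt = row["smarthouse"], row["treatment"]
        spatial = (
            truth.year_effect
            + truth.smarthouse_effect.get(house, 0.0)
            + truth.lane_coef.get(house, 0.0) * row["cLane"]
            + truth.mainposn_coef.get(house, 0.0) * row["cMainPosn"]
            + field_dev[i]
            + mp_dev[row["main_plot_id"]]
        )
        res_sd = truth.residual_sd.get((house, trt), 0.0)
        cart_dev = spatial + (rng.normal(0.0, res_sd) if res_sd > 0 else 0.0)
        clean = truth.growth.curve(days, gv, trt)
        psa = clean + cart_dev
        if truth.growth.noise_sd > 0:
            psa = psa + rng.normal(0.0, truth.growth.noise_sd, len(days))
        psa = np.clip(psa, 0.0, None)
        for d, v in zip(days, psa):
            psa_rows.append((row["cart_id"], int(d), float(v)))

        final = clean[-1] + cart_dev
        record = dict(row)
        for trait, (base, slope, sd) in truth.harvest.items():
            v = base + slope * final + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            record[trait] = float(max(v, 0.0))
        if "TN" in record:
            record["TN"] = int(round(record["TN"]))
        wb, ws, wsd = truth.water[trt]
        water = wb + ws * final + (rng.normal(0.0, wsd) if wsd > 0 else 0.0)
        record["water_g"] = float(max(water, 1.0))
        psa_sum = float(np.sum(psa))
        record["CHA"] = truth.cha_per_kpix_day * psa_sum
        record["CL"] = truth.cl_per_kpix_day * psa_sum
        advanced = rng.random() < truth.zadoks_advanced_rate
        record["zadoks"] = int(33 + (rng.integers(6, 17) if advanced else 0))
        harvest_rows.append(record)

    psa_long = pd.DataFrame(psa_rows, columns=["cart_id", "day", "psa"])
    harvest = pd.DataFrame(harvest_rows)
    return psa_long, harvest
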