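"""Two-stage spatially adjusted analysis of the phenomics trials.

Stage 1 fits, per trait and year, the split-plot spatial mixed model

    y = mu + Smarthouse + S:cLane + S:cMainPosn + Checks + Genotypes
        + Treatment + C:T + G:T [+ S:cZadoks]          (fixed)
        + spl(S:cLane) + spl(S:cMainPosn) + mainplot    (random)

with a separate residual variance for every Smarthouse-by-treatment
combination. Random curved trends are natural cubic smoothing-spline
bases over the lane and main-plot-position grids, scaled so the implied
roughness penalty on the spline coefficients is the identity. Model
reduction follows REML ratio tests for the variance components (boundary
chi-square mixture, alpha = 0.05; the main-plot variance is always kept)
and Wald F tests for the fixed linear trends and the Zadoks covariate
slope. The reduced model yields spatially adjusted BLUEs per
genotype-by-treatment cell.

A companion genotype-random fit provides the generalised (Cullis)
heritability H2 = 1 - vbar_delta / (2 sigma2_g), with vbar_delta the mean
variance of pairwise genotype BLUP differences.

Stage 2 combines the per-year BLUEs for one treatment across years with
genotype fixed and year random; replicated check and recurrent lines
connect the otherwise disjoint yearly line sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedmodel import MixedModel, RandomBlock, reml_lrt, reml_lrt_boundary
from .population import CHECK_ID, RECURRENT_ID

ALPHA = 0.05
ZADOKS_CENTRE = 33.0


# -- spline basis ----------------------------------------------------------

def natural_spline_penalty(knots: np.ndarray) -> np.ndarray:
    """Green-Silverman roughness penalty matrix for a natural cubic spline.

    For values ``f`` at the knots, ``f' K f`` equals the integrated squared
    second derivative of the natural cubic interpolant.
    """
    g = np.asarray(knots, dtype=float)
    K = len(g)
    if K < 3:
        raise ValueError("need at least 3 knots")
    h = np.diff(g)
    D = np.zeros((K - 2, K))
    W = np.zeros((K - 2, K - 2))
    for i in range(K - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < K - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def spline_random_basis(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mixed-model spline basis at the unique grid of ``values``.

    Returns ``(knots, Zk)`` where ``Zk`` (K x K-2) maps iid random
    coefficients ``u`` to knot values ``f = Zk u`` with roughness
    ``f' K f = u' u`` (so a single variance component is the right prior).
    """
    knots = np.unique(np.asarray(values, dtype=float))
    pen = natural_spline_penalty(knots)
    w, U = np.linalg.eigh(pen)
    keep = w > 1e-10 * w.max()
    return knots, U[:, keep] / np.sqrt(w[keep])


# -- model specification ---------------------------------------------------

@dataclass
class StageOneDesign:
    """Assembled design matrices plus bookkeeping for one trait-year."""

    y: np.ndarray
    X: np.ndarray
    column_names: list
    blocks: list
    resid_groups: np.ndarray
    group_labels: list
    data: pd.DataFrame = field(repr=False)
    term_columns: dict = field(default_factory=dict)


def _line_type(row) -> str:
    if row["is_check"]:
        return "check"
    if row["is_recurrent"]:
        return "recurrent"
    return "test"


def build_design_matrices(
    data: pd.DataFrame,
    trait: str,
    include_zadoks: bool = False,
    spline_lane: bool = True,
    spline_posn: bool = True,
) -> StageOneDesign:
    """Build stage-1 fixed/random design matrices for one trait.

    ``data`` is a derived trait table (one row per cart) carrying the
    design columns. Rows with a missing trait value are dropped listwise.
    Reference levels are alphabetical: control treatment, first NAM
    genotype, "test" line class; centred covariates are re-centred on the
    retained rows.
    """
    d = data.loc[np.isfinite(data[trait].astype(float))].reset_index(drop=True)
    if len(d) == 0:
        raise ValueError(f"no finite observations for {trait}")
    y = d[trait].to_numpy(dtype=float)
    houses = sorted(d["smarthouse"].unique())
    d = d.copy()
    for cov in ("cLane", "cMainPosn"):
        d[cov] = d[cov] - d.groupby("smarthouse")[cov].transform("mean")
    line_type = d.apply(_line_type, axis=1)
    nam_genos = sorted(d.loc[line_type == "test", "genotype"].unique())

    cols, names = [], []
    term_columns: dict[str, list[str]] = {}

    def add(name, col, term):
        cols.append(np.asarray(col, dtype=float))
        names.append(name)
        term_columns.setdefault(term, []).append(name)

    add("mu", np.ones(len(d)), "mu")
    for h in houses[1:]:
        add(f"S[{h}]", (d["smarthouse"] == h).astype(float), "S")
    for h in houses:
        ind = (d["smarthouse"] == h).to_numpy(dtype=float)
        add(f"S[{h}]:cLane", ind * d["cLane"].to_numpy(), "S:cLane")
        add(f"S[{h}]:cMainPosn", ind * d["cMainPosn"].to_numpy(), "S:cMainPosn")
    for cls in ("check", "recurrent"):
        if (line_type == cls).any():
            add(f"C[{cls}]", (line_type == cls).astype(float), "C")
    for g in nam_genos[1:]:
        add(f"G[{g}]", (d["genotype"] == g).astype(float), "G")
    trt = (d["treatment"] == "drought").to_numpy(dtype=float)
    add("T[drought]", trt, "T")
    for cls in ("check", "recurrent"):
        if (line_type == cls).any():
            add(f"C[{cls}]:T[drought]", (line_type == cls).to_numpy() * trt, "C:T")
    for g in nam_genos[1:]:
        add(f"G[{g}]:T[drought]", (d["genotype"] == g).to_numpy() * trt, "G:T")
    if include_zadoks:
        if "zadoks" not in d.columns:
            raise ValueError("zadoks column required")
        cz = d["zadoks"].to_numpy(dtype=float) - ZADOKS_CENTRE
        for h in houses:
            ind = (d["smarthouse"] == h).to_numpy(dtype=float)
            add(f"S[{h}]:cZadoks", ind * cz, "S:cZadoks")
    X = np.column_stack(cols)

    blocks = []
    for flag, cov, bname in ((spline_lane, "cLane", "spl(S:cLane)"),
                             (spline_posn, "cMainPosn", "spl(S:cMainPosn)")):
        if not flag:
            continue
        parts = []
        for h in houses:
            sub = d["smarthouse"] == h
            vals = d.loc[sub, cov].to_numpy(dtype=float)
            if len(np.unique(vals)) < 3:
                continue
            knots, Zk = spline_random_basis(vals)
            idx = np.searchsorted(knots, vals)
            Zh = np.zeros((len(d), Zk.shape[1]))
            Zh[np.flatnonzero(sub.to_numpy())] = Zk[idx]
            parts.append(Zh)
        if parts:
            blocks.append(RandomBlock(bname, np.concatenate(parts, axis=1)))
    mp_levels, mp_idx = np.unique(d["main_plot_id"], return_inverse=True)
    Zmp = np.zeros((len(d), len(mp_levels)))
    Zmp[np.arange(len(d)), mp_idx] = 1.0
    blocks.append(RandomBlock("mainplot", Zmp, list(mp_levels)))

    group_labels = sorted(
        {(h, t) for h, t in zip(d["smarthouse"], d["treatment"])})
    lab_to_code = {lab: i for i, lab in enumerate(group_labels)}
    groups = np.array([lab_to_code[(h, t)]
                       for h, t in zip(d["smarthouse"], d["treatment"])])
    return StageOneDesign(y, X, names, blocks, groups, group_labels, d,
                          term_columns)


# -- fitting and reduction -------------------------------------------------

@dataclass
class StageOneFit:
    model: MixedModel
    design: StageOneDesign
    tests: list = field(default_factory=list)


def fit_stage_one(design: StageOneDesign) -> StageOneFit:
    m = MixedModel(design.y, design.X, design.blocks, design.resid_groups,
                   design.column_names).fit()
    return StageOneFit(m, design)


def reduce_model(fit: StageOneFit, alpha: float = ALPHA) -> StageOneFit:
    """REML-ratio / Wald-F model reduction of a fitted stage-1 model.

    Spline variances are tested one at a time with the boundary-corrected
    chi-square mixture; the heteroscedastic residual structure with a
    standard chi-square on g-1 df; dropped curved trends trigger a Wald F
    test of the matching fixed linear trend (and the Zadoks slope is Wald
    tested when present). The main-plot variance is never tested.
    """
    design = fit.design
    model = fit.model
    tests = list(fit.tests)
    dropped_splines = []
    for bname in ("spl(S:cLane)", "spl(S:cMainPosn)"):
        if bname not in {b.name for b in model.blocks}:
            continue
        reduced = model.drop_block(bname).fit()
        p = reml_lrt_boundary(model.loglik_, reduced.loglik_)
        keep = p < alpha
        tests.append({"term": bname, "kind": "reml_lrt_boundary",
                      "p": p, "kept": keep})
        if not keep:
            model = reduced
            dropped_splines.append(bname)
    if len(set(model.group_levels)) > 1:
        homo = model.with_groups(np.zeros(model.n, dtype=int)).fit()
        df = len(model.group_levels) - 1
        p = reml_lrt(model.loglik_, homo.loglik_, df)
        keep = p < alpha
        tests.append({"term": "heteroscedastic_residuals", "kind": "reml_lrt",
                      "p": p, "kept": keep})
        if not keep:
            model = homo
    trend_term = {"spl(S:cLane)": "S:cLane", "spl(S:cMainPosn)": "S:cMainPosn"}
    for bname in dropped_splines:
        term = trend_term[bname]
        cols = design.term_columns.get(term, [])
        _, _, _, p = model.wald_f(cols)
        tests.append({"term": term, "kind": "wald_f", "p": p, "kept": p < alpha})
    if "S:cZadoks" in design.term_columns:
        cols = design.term_columns["S:cZadoks"]
        _, _, _, p = model.wald_f(cols)
        tests.append({"term": "S:cZadoks", "kind": "wald_f", "p": p,
                      "kept": p < alpha})
    return StageOneFit(model, design, tests)


def extract_blues(fit: StageOneFit, year=None) -> pd.DataFrame:
    """Estimated marginal means per genotype-by-treatment cell.

    Means are taken at centred spatial covariates 0, Zadoks 33, averaging
    equally over Smarthouses (treatment-weighted population marginal
    means). Inestimable cells are returned as missing.
    """
    design = fit.design
    model = fit.model
    d = design.data
    names = design.column_names
    col_idx = {n: i for i, n in enumerate(names)}
    houses = sorted(d["smarthouse"].unique())
    line_type = d.apply(_line_type, axis=1)
    rows = []
    cells = d[["genotype", "treatment"]].drop_duplicates()
    for _, cell in cells.iterrows():
        g, t = cell["genotype"], cell["treatment"]
        cls = line_type[(d["genotype"] == g)].iloc[0]
        L = np.zeros(len(names))
        L[col_idx["mu"]] = 1.0
        for h in houses[1:]:
            L[col_idx[f"S[{h}]"]] = 1.0 / len(houses)
        if cls != "test":
            L[col_idx[f"C[{cls}]"]] = 1.0
        elif f"G[{g}]" in col_idx:
            L[col_idx[f"G[{g}]"]] = 1.0
        if t == "drought":
            L[col_idx["T[drought]"]] = 1.0
            if cls != "test" and f"C[{cls}]:T[drought]" in col_idx:
                L[col_idx[f"C[{cls}]:T[drought]"]] = 1.0
            elif cls == "test" and f"G[{g}]:T[drought]" in col_idx:
                L[col_idx[f"G[{g}]:T[drought]"]] = 1.0
        if model.is_estimable(L):
            est, se = model.predict(L[None, :])
            rows.append({"genotype": g, "treatment": t, "blue": float(est[0]),
                         "se": float(se[0])})
        else:
            rows.append({"genotype": g, "treatment": t, "blue": float("nan"),
                         "se": float("nan")})
    out = pd.DataFrame(rows)
    if year is not None:
        out["year"] = year
    return out


# -- heritability ----------------------------------------------------------

@dataclass
class HeritabilityResult:
    trait: str
    treatment: str
    h2: float
    sigma2_g: float
    vbar_delta: float
    h2_unclipped: float


def cullis_h2(data: pd.DataFrame, trait: str, treatment: str,
              spline_trends: bool = False) -> HeritabilityResult:
    """Generalised heritability from a genotype-random fit of one treatment.

    The per-treatment model keeps the Smarthouse effects and linear
    spatial trends fixed, takes genotypes random, and allows per-
    Smarthouse residual variances. vbar_delta is the mean variance of
    pairwise genotype BLUP differences from the mixed-model-equation
    prediction-error-variance matrix.
    """
    d = data.loc[(data["treatment"] == treatment)
                 & np.isfinite(data[trait].astype(float))].reset_index(drop=True)
    if len(d) == 0:
        raise ValueError("no data for this treatment")
    houses = sorted(d["smarthouse"].unique())
    d = d.copy()
    for cov in ("cLane", "cMainPosn"):
        d[cov] = d[cov] - d.groupby("smarthouse")[cov].transform("mean")
    cols = [np.ones(len(d))]
    names = ["mu"]
    for h in houses[1:]:
        cols.append((d["smarthouse"] == h).astype(float).to_numpy())
        names.append(f"S[{h}]")
    for h in houses:
        ind = (d["smarthouse"] == h).to_numpy(dtype=float)
        cols.append(ind * d["cLane"].to_numpy())
        names.append(f"S[{h}]:cLane")
        cols.append(ind * d["cMainPosn"].to_numpy())
        names.append(f"S[{h}]:cMainPosn")
    X = np.column_stack(cols)
    genos, gidx = np.unique(d["genotype"], return_inverse=True)
    Zg = np.zeros((len(d), len(genos)))
    Zg[np.arange(len(d)), gidx] = 1.0
    blocks = [RandomBlock("genotype", Zg, list(genos))]
    if spline_trends:
        for cov, bname in (("cLane", "spl(S:cLane)"),
                           ("cMainPosn", "spl(S:cMainPosn)")):
            vals = d[cov].to_numpy(dtype=float)
            if len(np.unique(vals)) >= 3:
                knots, Zk = spline_random_basis(vals)
                blocks.append(RandomBlock(bname, Zk[np.searchsorted(knots, vals)]))
    house_code = {h: i for i, h in enumerate(houses)}
    groups = np.array([house_code[h] for h in d["smarthouse"]])
    m = MixedModel(d[trait].to_numpy(dtype=float), X, blocks, groups, names).fit()
    sg2 = m.block_variances_["genotype"]
    if sg2 <= 1e-10:
        return HeritabilityResult(trait, treatment, 0.0, 0.0, float("nan"), 0.0)
    P = m.pev("genotype")
    t = P.shape[0]
    diag = np.diag(P)
    mean_off = (P.sum() - diag.sum()) / (t * (t - 1))
    vbar = 2.0 * diag.mean() - 2.0 * mean_off
    h2_raw = 1.0 - vbar / (2.0 * sg2)
    h2 = float(np.clip(h2_raw, 0.0, 1.0))
    if h2 != h2_raw:
        warnings.warn(f"Cullis H2 clipped from {h2_raw:.4f}")
    return HeritabilityResult(trait, treatment, h2, float(sg2), float(vbar),
                              float(h2_raw))


# -- stage 2: across-year combination -------------------------------------

def _years_connected(blues: pd.DataFrame) -> bool:
    years = sorted(blues["year"].unique())
    parent = {y: y for y in years}

    def find(y):
        while parent[y] != y:
            parent[y] = parent[parent[y]]
            y = parent[y]
        return y

    for _, grp in blues.groupby("genotype"):
        ys = sorted(grp["year"].unique())
        for a in ys[1:]:
            ra, rb = find(a), find(ys[0])
            if ra != rb:
                parent[ra] = rb
    return len({find(y) for y in years}) == 1


def combine_years(blues: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Across-year genotype BLUEs for one treatment (genotype fixed,
    year random).

    Input needs columns genotype, treatment, year, blue. With a single
    year the input is returned unchanged; a disconnected year design
    (no genotype shared between years) warns and passes through.
    """
    d = blues.loc[(blues["treatment"] == treatment)
                  & np.isfinite(blues["blue"].astype(float))].copy()
    years = sorted(d["year"].unique())
    if len(years) <= 1:
        out = d[["genotype", "treatment", "blue", "se"]].copy()
        return out.reset_index(drop=True)
    if not _years_connected(d):
        warnings.warn("years share no genotypes; returning unadjusted BLUEs")
        out = (d.groupby("genotype", as_index=False)
                .agg(blue=("blue", "mean"), se=("se", "mean")))
        out["treatment"] = treatment
        return out[["genotype", "treatment", "blue", "se"]]
    genos, gidx = np.unique(d["genotype"], return_inverse=True)
    X = np.zeros((len(d), len(genos)))
    X[np.arange(len(d)), gidx] = 1.0
    yrs, yidx = np.unique(d["year"], return_inverse=True)
    Z = np.zeros((len(d), len(yrs)))
    Z[np.arange(len(d)), yidx] = 1.0
    m = MixedModel(d["blue"].to_numpy(dtype=float), X,
                   [RandomBlock("year", Z, list(yrs))],
                   column_names=[f"G[{g}]" for g in genos]).fit()
    L = np.eye(len(genos))
    est, se = m.predict(L)
    return pd.DataFrame({"genotype": genos, "treatment": treatment,
                         "blue": est, "se": se})
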