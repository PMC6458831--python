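"""Cross-validated multi-parent GWAS with stepwise cofactor selection.

The association model regresses the genotype BLUEs for one trait and
treatment on wild-allele dosage (identity-by-state coding, treated as
quantitative):

    y = mu + X_snp b_snp + cofactors + e

Population structure and genetic background are controlled through the
cofactors themselves: bidirectional stepwise selection over all SNPs,
entering or leaving on the marginal F-test at p < 0.001. To stabilise
detection, selection is repeated on the training 4/5 of a 5-fold split,
20 times with reshuffled folds; a SNP (or 5-cM map window) detected in at
least 20 of the 100 runs is a putative QTL. Parent-specific (per donor
family) substitution effects and leave-one-out variance-explained shares
are then estimated for the putative QTL set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from sklearn.model_selection import KFold

from .genmap import GeneticMap
from .population import Genotypes, CHECK_FAMILY, RECURRENT_FAMILY


@dataclass
class GwasConfig:
    maf_threshold: float = 0.01
    alpha: float = 0.001          # enter/leave marginal-F p-value
    folds: int = 5
    repeats: int = 20
    detection_threshold: int = 20  # of folds * repeats runs
    window_cM: float = 5.0
    seed: int = 0
    max_steps: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("need folds >= 2 and repeats >= 1")
        if self.detection_threshold > self.folds * self.repeats:
            raise ValueError("detection threshold exceeds number of runs")

    @property
    def n_runs(self) -> int:
        return self.folds * self.repeats


def minor_allele_frequencies(geno: Genotypes, nam_only: bool = True) -> pd.Series:
    """min(p, 1-p) of the wild allele over non-missing (NAM) lines."""
    d = geno.dosage
    if nam_only:
        d = d.loc[geno.nam_lines()]
    p = d.mean(axis=0, skipna=True) / 2.0
    return pd.concat([p, 1.0 - p], axis=1).min(axis=1)


def maf_filter(geno: Genotypes, threshold: float = 0.01) -> Genotypes:
    """Keep SNPs with minor allele frequency strictly above ``threshold``.

    Frequencies are computed over non-missing NAM lines; SNPs with no
    calls at all are dropped with a warning.
    """
    d = geno.dosage.loc[geno.nam_lines()]
    all_missing = d.isna().all(axis=0)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing SNPs")
    maf = minor_allele_frequencies(geno)
    keep = geno.dosage.columns[(maf > threshold) & ~all_missing]
    return geno.subset_snps(keep)


def impute_dosage(geno: Genotypes) -> pd.DataFrame:
    """Mean-impute missing dosages within family (regression use only)."""
    d = geno.dosage.copy()
    if not d.isna().any().any():
        return d
    filled = d.groupby(geno.family).transform(lambda g: g.fillna(g.mean()))
    return filled.fillna(d.mean())


# -- single-SNP model ------------------------------------------------------

def fit_model_a(y: np.ndarray, snp: np.ndarray,
                cofactors: np.ndarray | None = None) -> dict:
    """OLS of y on one quantitative SNP dosage given cofactor columns.

    Returns coefficient, marginal F p-value for the SNP, model R2 and a
    collinearity flag (collinear SNPs get p = 1).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    base = np.ones((n, 1)) if cofactors is None else np.column_stack(
        [np.ones(n), cofactors])
    X = np.column_stack([base, snp])
    if n <= X.shape[1]:
        raise ValueError("more parameters than observations")
    Qb, _ = np.linalg.qr(base)
    r_y = y - Qb @ (Qb.T @ y)
    r_s = snp - Qb @ (Qb.T @ snp)
    sxx = float(r_s @ r_s)
    syy = float(r_y @ r_y)
    if sxx <= 1e-10 * max(float(snp @ snp), 1.0):
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - syy / tss if tss > 0 else 0.0
        return {"coef": 0.0, "p": 1.0, "r2": r2, "collinear": True}
    b = float(r_s @ r_y) / sxx
    rss = syy - b * b * sxx
    df = n - base.shape[1] - 1
    F = (b * b * sxx) / (rss / df) if rss > 0 else np.inf
    p = float(f_dist.sf(F, 1, df))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return {"coef": b, "p": p, "r2": r2, "collinear": False}


# -- stepwise selection ----------------------------------------------------

def _tie_break_order(genetic_map: GeneticMap, snp_ids) -> dict:
    """Deterministic ordering key per SNP: (chromosome, cM, snp_id)."""
    t = genetic_map.table.set_index("snp_id")
    order = {}
    for s in snp_ids:
        if s in t.index:
            order[s] = (str(t.at[s, "chromosome"]), float(t.at[s, "position"]), str(s))
        else:
            order[s] = ("ZZ", np.inf, str(s))
    return order


def _marginal_p_included(y, G_sel):
    """Marginal (drop-one) F p-values for every included SNP via full OLS."""
    n = len(y)
    X = np.column_stack([np.ones(n), G_sel])
    p_cols = X.shape[1]
    if n <= p_cols:
        return np.ones(G_sel.shape[1])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - rank
    XtX_inv = np.linalg.pinv(X.T @ X)
    se2 = np.maximum(np.diag(XtX_inv)[1:] * rss / df, 0.0)
    out = np.ones(G_sel.shape[1])
    ok = se2 > 0
    t2 = np.zeros_like(se2)
    t2[ok] = beta[1:][ok] ** 2 / se2[ok]
    out[ok] = f_dist.sf(t2[ok], 1, df)
    return out


def select_cofactors(y: np.ndarray, G: pd.DataFrame, genetic_map: GeneticMap,
                     alpha: float = 0.001, max_steps: int = 200) -> list[str]:
    """Bidirectional stepwise SNP selection on the marginal F criterion.

    Repeatedly adds the most significant excluded SNP while its marginal
    p-value given the current set is below ``alpha``, then drops any
    included SNP whose marginal p-value has risen to ``alpha`` or above.
    Ties break deterministically on (p, chromosome, cM, snp_id). Returns
    the selected SNP ids in selection order.
    """
    y = np.asarray(y, dtype=float)
    snp_ids = list(G.columns)
    Gm = G.to_numpy(dtype=float)
    n = len(y)
    order = _tie_break_order(genetic_map, snp_ids)
    selected: list[str] = []
    sel_idx: list[int] = []
    for _ in range(max_steps):
        # marginal F of excluded SNPs given [1, selected]
        base = np.column_stack([np.ones(n)] + ([Gm[:, sel_idx]] if sel_idx else []))
        if n <= base.shape[1] + 1:
            break
        Qb, _ = np.linalg.qr(base)
        r_y = y - Qb @ (Qb.T @ y)
        excluded = [j for j in range(Gm.shape[1]) if j not in set(sel_idx)]
        if not excluded:
            break
        Ge = Gm[:, excluded]
        Re = Ge - Qb @ (Qb.T @ Ge)
        sxx = np.einsum("ij,ij->j", Re, Re)
        sxy = Re.T @ r_y
        syy = float(r_y @ r_y)
        df = n - base.shape[1] - 1
        scale = np.maximum(np.einsum("ij,ij->j", Ge, Ge), 1.0)
        valid = sxx > 1e-10 * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            ess = np.where(valid, sxy ** 2 / np.where(valid, sxx, 1.0), 0.0)
            rss = np.maximum(syy - ess, 0.0)
            F = np.where(rss > 0, ess / (rss / df), np.inf)
        pvals = np.where(valid, f_dist.sf(F, 1, df), 1.0)
        best = None
        for k, j in enumerate(excluded):
            if pvals[k] < alpha:
                key = (pvals[k],) + order[snp_ids[j]]
                if best is None or key < best[0]:
                    best = (key, j)
        if best is None:
            break
        sel_idx.append(best[1])
        selected.append(snp_ids[best[1]])
        # backward: drop included SNPs no longer significant
        changed = True
        while changed and len(sel_idx) > 1:
            changed = False
            pin = _marginal_p_included(y, Gm[:, sel_idx])
            worst = None
            for k, j in enumerate(sel_idx):
                if pin[k] >= alpha:
                    key = (-pin[k],) + order[snp_ids[j]]
                    if worst is None or key < worst[0]:
                        worst = (key, k)
            if worst is not None:
                k = worst[1]
                del sel_idx[k], selected[k]
                changed = True
    return selected


# -- cross-validated scan --------------------------------------------------

@dataclass
class ScanResult:
    config: GwasConfig
    detection_counts: pd.Series          # per SNP, out of n_runs
    window_counts: pd.DataFrame          # per (chromosome, window start)
    run_selections: list = field(repr=False, default_factory=list)
    test_r2: list = field(default_factory=list)

    def putative_qtl(self) -> pd.Series:
        c = self.detection_counts
        return c[c >= self.config.detection_threshold].sort_values(ascending=False)


def cross_validated_scan(y: pd.Series, geno: Genotypes,
                         genetic_map: GeneticMap,
                         config: GwasConfig | None = None) -> ScanResult:
    """Repeated k-fold stepwise scans and SNP/window detection counts.

    ``y`` is indexed by line id (NAM lines only are used); folds partition
    the lines, selection runs on each training split, and a run's test
    fold yields a held-out predictive R2 (reported, not used for calling).
    """
    config = config or GwasConfig()
    lines = [ln for ln in y.index if ln in set(geno.nam_lines())]
    y = y.loc[lines].astype(float)
    y = y[np.isfinite(y)]
    lines = list(y.index)
    G = impute_dosage(geno.subset_lines(lines))
    if len(lines) < config.folds:
        raise ValueError("fewer lines than folds")
    mapt = genetic_map.table.set_index("snp_id")
    counts = pd.Series(0, index=G.columns, dtype=int)
    run_selections = []
    test_r2 = []
    rng = np.random.default_rng(config.seed)
    for rep in range(config.repeats):
        kf = KFold(n_splits=config.folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        for fold, (tr, te) in enumerate(kf.split(G)):
            if len(tr) <= 2:
                raise ValueError("training fold too small for regression")
            ytr = y.iloc[tr].to_numpy()
            sel = select_cofactors(ytr, G.iloc[tr], genetic_map,
                                   alpha=config.alpha,
                                   max_steps=config.max_steps)
            run_selections.append({"repeat": rep, "fold": fold, "snps": sel})
            counts[sel] += 1
            if sel:
                Xtr = np.column_stack([np.ones(len(tr)), G.iloc[tr][sel]])
                beta, *_ = np.linalg.lstsq(Xtr, ytr, rcond=None)
                Xte = np.column_stack([np.ones(len(te)), G.iloc[te][sel]])
                yte = y.iloc[te].to_numpy()
                ss = float(np.sum((yte - yte.mean()) ** 2))
                r2 = 1.0 - float(np.sum((yte - Xte @ beta) ** 2)) / ss if ss > 0 else 0.0
            else:
                r2 = 0.0
            test_r2.append(r2)
    # per-window counts: a run detects a window if any selected SNP falls in it
    win = config.window_cM
    rows = []
    win_hits: dict[tuple, int] = {}
    for rec in run_selections:
        seen = set()
        for s in rec["snps"]:
            if s in mapt.index:
                chrom = mapt.at[s, "chromosome"]
                w = int(np.floor(float(mapt.at[s, "position"]) / win))
                seen.add((chrom, w))
        for key in seen:
            win_hits[key] = win_hits.get(key, 0) + 1
    for (chrom, w), c in sorted(win_hits.items()):
        rows.append({"chromosome": chrom, "window_start_cM": w * win,
                     "window_end_cM": (w + 1) * win, "count": c})
    window_counts = pd.DataFrame(
        rows, columns=["chromosome", "window_start_cM", "window_end_cM", "count"])
    return ScanResult(config, counts, window_counts, run_selections, test_r2)


# -- effects and variance explained ---------------------------------------

def _family_nested_design(G: pd.DataFrame, families: pd.Series,
                          qtl: list[str]) -> tuple[np.ndarray, list]:
    cols, labels = [np.ones(len(G))], [("mu", None, None)]
    fams = [f for f in sorted(families.unique())
            if f not in (CHECK_FAMILY, RECURRENT_FAMILY)]
    for s in qtl:
        dosage = G[s].to_numpy(dtype=float)
        for f in fams:
            ind = (families == f).to_numpy()
            col = dosage * ind
            if np.nanvar(col[ind]) > 1e-12:
                cols.append(col)
                labels.append(("effect", s, f))
    return np.column_stack(cols), labels


def estimate_parent_effects(y: pd.Series, geno: Genotypes, qtl: list[str],
                            cv_splits=None) -> pd.DataFrame:
    """Per-family wild-homozygote substitution effects for each putative QTL.

    A joint regression of the phenotype on family-nested dosage terms for
    all putative QTL; the reported effect per family is twice the nested
    slope (wild homozygote versus recurrent homozygote). With
    ``cv_splits`` (an iterable of training index arrays) estimates are
    averaged over the training runs; otherwise the full data are used.
    Families with no dosage variation at a QTL are missing; families
    whose column is collinear in the joint fit are flagged.
    """
    lines = [ln for ln in y.index if ln in set(geno.nam_lines())]
    y = y.loc[lines].astype(float)
    G = impute_dosage(geno.subset_lines(lines))
    fams = geno.family.loc[lines]
    X, labels = _family_nested_design(G, fams, qtl)
    rank = np.linalg.matrix_rank(X)
    flagged = rank < X.shape[1]
    splits = list(cv_splits) if cv_splits is not None else [np.arange(len(y))]
    acc = np.zeros(X.shape[1])
    nfit = 0
    for tr in splits:
        beta, *_ = np.linalg.lstsq(X[tr], y.to_numpy()[tr], rcond=None)
        acc += beta
        nfit += 1
    beta = acc / nfit
    rows = []
    for b, (kind, snp, fam) in zip(beta, labels):
        if kind == "effect":
            rows.append({"snp_id": snp, "family": fam, "effect": 2.0 * b,
                         "collinear_fit": flagged})
    out = pd.DataFrame(rows, columns=["snp_id", "family", "effect",
                                      "collinear_fit"])
    return out


def variance_explained(y: pd.Series, geno: Genotypes,
                       qtl: list[str]) -> tuple[float, pd.Series]:
    """Total R2 of the joint QTL dosage model and leave-one-out shares.

    The per-QTL share is the decrease in R2 when that QTL is removed from
    the joint model (the adopted partition; shares of correlated QTL sum
    to at most the total).
    """
    lines = [ln for ln in y.index if ln in set(geno.nam_lines())]
    yv = y.loc[lines].astype(float).to_numpy()
    G = impute_dosage(geno.subset_lines(lines))

    def r2_of(snps):
        if not snps:
            return 0.0
        X = np.column_stack([np.ones(len(yv)), G[snps].to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        rss = float(np.sum((yv - X @ beta) ** 2))
        tss = float(np.sum((yv - yv.mean()) ** 2))
        return 1.0 - rss / tss if tss > 0 else 0.0

    total = r2_of(list(qtl))
    shares = pd.Series(
        {s: max(total - r2_of([t for t in qtl if t != s]), 0.0) for s in qtl})
    return total, shares
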