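"""Split-plot Smarthouse layout generation.

A Smarthouse is divided into ``zones`` blocks, each a grid of ``lanes``
(north-south) by ``positions`` (east-west) conveyor carts. Two consecutive
carts along a lane form a *main plot*; the two water treatments are
randomised to the two carts within each main plot (the split). Main plots
therefore occupy east-west *columns* 1..positions/2; at the default
6 zones x 4 lanes x 22 positions a Smarthouse holds 24 x 11 = 264 main
plots (528 carts).

Main plots carry either an unreplicated test line, a replicated check
line, or the recurrent parent. Check main plots follow the blocked
row-and-column quotas of the emulated experiment: exactly
``n_check_mainplots_per_zone`` per zone (default 6, hence 36 per
Smarthouse) and 3 or 4 per column. Recurrent-parent main plots are spread
over distinct zones and columns. This is a seeded constrained
randomisation honouring those quotas, not a re-implementation of the
row-column design optimiser originally used; the quotas are what the
downstream spatial model relies on.

Centred covariates used by the stage-1 model are emitted per cart:
``cLane`` (global lane index centred within Smarthouse) and ``cMainPosn``
(east-west midpoint of the main-plot cart pair, centred).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .population import CHECK_ID, RECURRENT_ID

TREATMENTS = ("control", "drought")

DESIGN_COLUMNS = [
    "cart_id", "smarthouse", "zone", "lane", "position", "main_plot_id",
    "column", "treatment", "genotype", "is_check", "is_recurrent",
    "cMainPosn", "cLane",
]


def _check_count_matrix(zones: int, columns: int, per_zone: int,
                        rng: np.random.Generator, lanes: int) -> np.ndarray:
    """Zone x column counts of check main plots.

    Row sums equal ``per_zone``; column sums are as equal as possible
    (3 or 4 at the default 6x11 with 6 per zone); no cell exceeds the
    number of lanes. Sampled by sequential weighted draws with retry.
    """
    if per_zone == 0:
        return np.zeros((zones, columns), dtype=int)
    total = zones * per_zone
    base, extra = divmod(total, columns)
    col_targets = np.full(columns, base)
    col_targets[rng.choice(columns, size=extra, replace=False)] += 1
    for _ in range(2000):
        counts = np.zeros((zones, columns), dtype=int)
        remaining = col_targets.copy()
        ok = True
        for z in range(zones):
            avail = np.flatnonzero(remaining > 0)
            if len(avail) < per_zone:
                ok = False
                break
            # prefer columns with the most unmet demand to stay feasible
            w = remaining[avail].astype(float)
            picked = rng.choice(avail, size=per_zone, replace=False,
                                p=w / w.sum())
            counts[z, picked] += 1
            remaining[picked] -= 1
        if ok and remaining.sum() == 0 and counts.max() <= lanes:
            return counts
    raise RuntimeError("could not satisfy check quotas for this grid")


def generate_smarthouse(
    lines,
    smarthouse: str = "NE",
    zones: int = 6,
    lanes: int = 4,
    positions: int = 22,
    n_check_mainplots_per_zone: int = 6,
    n_recurrent_mainplots: int = 5,
    seed: int | np.random.Generator = 0,
    fill_with_recurrent: bool = True,
) -> pd.DataFrame:
    """Generate one Smarthouse layout as a design table (one row per cart)."""
    if positions % 2 != 0:
        raise ValueError("positions must be even (carts pair into main plots)")
    rng = np.random.default_rng(seed)
    columns = positions // 2
    n_mainplots = zones * lanes * columns
    n_checks = zones * n_check_mainplots_per_zone
    if n_checks + n_recurrent_mainplots > n_mainplots:
        raise ValueError("check/recurrent quota exceeds grid capacity")
    lines = list(lines)
    capacity = n_mainplots - n_checks - n_recurrent_mainplots
    if len(lines) > capacity:
        raise ValueError(
            f"{len(lines)} lines exceed the {capacity} available main plots"
        )

    check_counts = _check_count_matrix(
        zones, columns, n_check_mainplots_per_zone, rng, lanes)

    # main plot slot = (zone, lane, column); allocate checks per cell
    genotype = {}
    for z in range(zones):
        for col in range(columns):
            k = check_counts[z, col]
            if k:
                for lane in rng.choice(lanes, size=k, replace=False):
                    genotype[(z + 1, lane + 1, col + 1)] = CHECK_ID

    # recurrent parent main plots: distinct zones and columns where possible
    rec_zones = rng.permutation(zones)[: n_recurrent_mainplots] if (
        n_recurrent_mainplots <= zones) else rng.integers(0, zones, n_recurrent_mainplots)
    rec_cols = rng.permutation(columns)[: n_recurrent_mainplots] if (
        n_recurrent_mainplots <= columns) else rng.integers(0, columns, n_recurrent_mainplots)
    for z, col in zip(rec_zones, rec_cols):
        free = [ln for ln in range(lanes) if (z + 1, ln + 1, col + 1) not in genotype]
        if not free:  # cell full of checks; pick any free slot in the zone
            free_slots = [(z + 1, ln + 1, c + 1) for ln in range(lanes)
                          for c in range(columns)
                          if (z + 1, ln + 1, c + 1) not in genotype]
            slot = free_slots[rng.integers(len(free_slots))]
        else:
            slot = (z + 1, int(rng.choice(free)) + 1, col + 1)
        genotype[slot] = RECURRENT_ID

    free_slots = [(z + 1, ln + 1, c + 1) for z in range(zones)
                  for ln in range(lanes) for c in range(columns)
                  if (z + 1, ln + 1, c + 1) not in genotype]
    order = rng.permutation(len(free_slots))
    shuffled_lines = [lines[i] for i in rng.permutation(len(lines))]
    for i, slot_idx in enumerate(order):
        slot = free_slots[slot_idx]
        if i < len(shuffled_lines):
            genotype[slot] = shuffled_lines[i]
        elif fill_with_recurrent:
            genotype[slot] = RECURRENT_ID
        else:
            genotype[slot] = None

    mean_lane = (zones * lanes + 1) / 2.0
    mean_pos = (positions + 1) / 2.0
    rows = []
    for z in range(1, zones + 1):
        for lane in range(1, lanes + 1):
            for col in range(1, columns + 1):
                geno = genotype[(z, lane, col)]
                if geno is None:
                    continue
                mp_id = f"{smarthouse}_Z{z}_L{lane}_C{col:02d}"
                trt_order = rng.permutation(TREATMENTS)
                global_lane = (z - 1) * lanes + lane
                pos_pair = (2 * col - 1, 2 * col)
                c_main = (pos_pair[0] + pos_pair[1]) / 2.0 - mean_pos
                for cart_in_pair, pos in enumerate(pos_pair):
                    rows.append({
                        "cart_id": f"{mp_id}_P{pos:02d}",
                        "smarthouse": smarthouse,
                        "zone": z,
                        "lane": lane,
                        "position": pos,
                        "main_plot_id": mp_id,
                        "column": col,
                        "treatment": trt_order[cart_in_pair],
                        "genotype": geno,
                        "is_check": geno == CHECK_ID,
                        "is_recurrent": geno == RECURRENT_ID,
                        "cMainPosn": c_main,
                        "cLane": global_lane - mean_lane,
                    })
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def generate_year(lines, seed: int | np.random.Generator = 0,
                  **smarthouse_kwargs) -> dict[str, pd.DataFrame]:
    """Split a year's lines over the NE and NW Smarthouses and lay both out.

    The NE house takes the larger half (224 of 447 at default capacity);
    the recurrent-parent quota in each house flexes between 4 and 5 so the
    remaining main plots exactly fit the lines where possible.
    """
    rng = np.random.default_rng(seed)
    lines = list(lines)
    zones = smarthouse_kwargs.get("zones", 6)
    lanes = smarthouse_kwargs.get("lanes", 4)
    positions = smarthouse_kwargs.get("positions", 22)
    per_zone = smarthouse_kwargs.get("n_check_mainplots_per_zone", 6)
    n_mainplots = zones * lanes * (positions // 2)
    n_checks = zones * per_zone
    cap4 = n_mainplots - n_checks - 4  # capacity with 4 recurrent plots
    if len(lines) > 2 * cap4:
        raise ValueError(f"too many lines for one year (max {2 * cap4})")
    n_ne = min(cap4, math.ceil(len(lines) / 2))
    ne_lines, nw_lines = lines[:n_ne], lines[n_ne:]
    layouts = {}
    for house, house_lines in (("NE", ne_lines), ("NW", nw_lines)):
        kwargs = dict(smarthouse_kwargs)
        if "n_recurrent_mainplots" not in kwargs:
            n_rec = 5 if len(house_lines) <= n_mainplots - n_checks - 5 else 4
            kwargs["n_recurrent_mainplots"] = n_rec
        layouts[house] = generate_smarthouse(
            house_lines, smarthouse=house, seed=rng, **kwargs)
    return layouts


def validate_layout(layout: pd.DataFrame) -> list[str]:
    """Return a list of invariant violations (empty when clean)."""
    problems = []
    for mp, grp in layout.groupby("main_plot_id"):
        if len(grp) != 2 or set(grp["treatment"]) != set(TREATMENTS):
            problems.append(f"main plot {mp} lacks one cart per treatment")
    for house, grp in layout.groupby("smarthouse"):
        for cov in ("cMainPosn", "cLane"):
            if abs(grp[cov].mean()) > 1e-8:
                problems.append(f"{cov} not centred in {house}")
    nam = layout[~(layout["is_check"] | layout["is_recurrent"])]
    counts = nam.groupby("genotype")["main_plot_id"].nunique()
    repeated = counts[counts > 1]
    for geno in repeated.index:
        problems.append(f"test line {geno} replicated")
    return problems
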