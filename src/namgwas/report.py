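"""Post-GWAS aggregation: QTL grouping, treatment classification and
candidate-gene matching on the centiMorgan map.

QTL calls within a grouping window (default 4 cM, single linkage along
each chromosome) merge into one region; regions found in both treatments
are treatment-common, others treatment-specific; genes within the match
window of a region interval are candidates. Region positions are
reported as the detection-count-weighted mean cM of the member calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_WINDOW_CM = 4.0


@dataclass
class QtlRegion:
    chromosome: str
    cm_start: float
    cm_end: float
    snps: list
    detection_count: int          # maximum over members
    position: float               # detection-weighted mean cM
    trait: str | None = None
    treatments: set = field(default_factory=set)

    def distance_to(self, other: "QtlRegion") -> float:
        if self.chromosome != other.chromosome:
            return float("inf")
        if self.cm_end < other.cm_start:
            return other.cm_start - self.cm_end
        if other.cm_end < self.cm_start:
            return self.cm_start - other.cm_end
        return 0.0


def group_qtl(calls: pd.DataFrame, window_cM: float = GROUP_WINDOW_CM) -> list[QtlRegion]:
    """Single-linkage grouping of mapped QTL calls along each chromosome.

    ``calls`` needs columns snp_id, chromosome, position, detection_count
    and optionally trait/treatment. Consecutive calls at most ``window_cM``
    apart merge; groups never span chromosomes.
    """
    regions: list[QtlRegion] = []
    if len(calls) == 0:
        return regions
    for chrom, grp in calls.groupby("chromosome", sort=True):
        grp = grp.sort_values(["position", "snp_id"])
        current: list[pd.Series] = []
        for _, row in grp.iterrows():
            if current and row["position"] - current[-1]["position"] > window_cM:
                regions.append(_make_region(chrom, current))
                current = []
            current.append(row)
        if current:
            regions.append(_make_region(chrom, current))
    return regions


def _make_region(chrom, members) -> QtlRegion:
    pos = np.array([m["position"] for m in members], dtype=float)
    cnt = np.array([m.get("detection_count", 1) for m in members], dtype=float)
    w = cnt if cnt.sum() > 0 else np.ones_like(cnt)
    trait = members[0].get("trait")
    treatments = {m["treatment"] for m in members if "treatment" in m and
                  pd.notna(m.get("treatment"))}
    return QtlRegion(
        chromosome=str(chrom), cm_start=float(pos.min()), cm_end=float(pos.max()),
        snps=[m["snp_id"] for m in members],
        detection_count=int(cnt.max()),
        position=float(np.average(pos, weights=w)),
        trait=trait, treatments=treatments,
    )


def classify_by_treatment(control_regions: list[QtlRegion],
                          drought_regions: list[QtlRegion],
                          window_cM: float = GROUP_WINDOW_CM) -> pd.DataFrame:
    """Label regions common to both treatments or treatment-specific.

    Regions from the two treatments overlapping within the grouping
    window count as one common QTL.
    """
    rows = []
    matched_d = set()
    for r in control_regions:
        partner = None
        for j, s in enumerate(drought_regions):
            if j not in matched_d and r.distance_to(s) <= window_cM:
                partner = j
                break
        if partner is not None:
            matched_d.add(partner)
            s = drought_regions[partner]
            rows.append({"chromosome": r.chromosome,
                         "position": (r.position + s.position) / 2.0,
                         "label": "common"})
        else:
            rows.append({"chromosome": r.chromosome, "position": r.position,
                         "label": "control-specific"})
    for j, s in enumerate(drought_regions):
        if j not in matched_d:
            rows.append({"chromosome": s.chromosome, "position": s.position,
                         "label": "drought-specific"})
    return pd.DataFrame(rows, columns=["chromosome", "position", "label"])


def match_candidates(regions: list[QtlRegion], genes: pd.DataFrame,
                     window_cM: float = GROUP_WINDOW_CM) -> pd.DataFrame:
    """Genes within ``window_cM`` of a region interval on the same chromosome.

    ``genes`` needs columns gene, chromosome, position (cM). The distance
    is from the gene to the nearest edge of the region interval,
    inclusive at the boundary.
    """
    rows = []
    for i, r in enumerate(regions):
        sub = genes[genes["chromosome"] == r.chromosome]
        for _, g in sub.iterrows():
            p = float(g["position"])
            dist = max(r.cm_start - p, p - r.cm_end, 0.0)
            if dist <= window_cM:
                rows.append({"region": i, "chromosome": r.chromosome,
                             "region_position": r.position,
                             "gene": g["gene"], "gene_position": p,
                             "distance_cM": dist})
    return pd.DataFrame(rows, columns=["region", "chromosome",
                                       "region_position", "gene",
                                       "gene_position", "distance_cM"])


def multi_trait_summary(regions_by_trait: dict[str, list[QtlRegion]],
                        window_cM: float = GROUP_WINDOW_CM) -> pd.DataFrame:
    """Cross-trait single-linkage grouping with trait multiplicity.

    Regions from all traits are pooled per chromosome and merged when at
    most ``window_cM`` apart; each merged region reports how many
    distinct traits it carries.
    """
    pooled = []
    for trait, regions in regions_by_trait.items():
        for r in regions:
            pooled.append((r.chromosome, r.cm_start, r.cm_end, r.position, trait))
    rows = []
    frame = pd.DataFrame(pooled, columns=["chromosome", "start", "end",
                                          "position", "trait"])
    for chrom, grp in frame.groupby("chromosome", sort=True):
        grp = grp.sort_values("start")
        cluster = []
        cluster_end = -np.inf
        for _, row in grp.iterrows():
            if cluster and row["start"] - cluster_end > window_cM:
                rows.append(_summarise_cluster(chrom, cluster))
                cluster = []
                cluster_end = -np.inf
            cluster.append(row)
            cluster_end = max(cluster_end, row["end"])
        if cluster:
            rows.append(_summarise_cluster(chrom, cluster))
    return pd.DataFrame(rows, columns=["chromosome", "cm_start", "cm_end",
                                       "traits", "multiplicity"])


def _summarise_cluster(chrom, cluster) -> dict:
    traits = sorted({r["trait"] for r in cluster})
    return {"chromosome": str(chrom),
            "cm_start": float(min(r["start"] for r in cluster)),
            "cm_end": float(max(r["end"] for r in cluster)),
            "traits": ",".join(traits), "multiplicity": len(traits)}


def regions_to_frame(regions: list[QtlRegion]) -> pd.DataFrame:
    rows = [{"chromosome": r.chromosome, "cm_start": r.cm_start,
             "cm_end": r.cm_end, "position": r.position,
             "detection_count": r.detection_count,
             "n_snps": len(r.snps), "snps": ";".join(map(str, r.snps)),
             "trait": r.trait,
             "treatments": ",".join(sorted(map(str, r.treatments)))}
            for r in regions]
    return pd.DataFrame(rows)
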