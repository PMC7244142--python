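"""Genomic context of mapped loci on a reference genome.

Given locus intervals (BED, 0-based half-open) and annotated features
(CDS, transposable elements, 5'/3' UTRs), this stage reports the nearest
feature per locus (bedtools-closest semantics: distance 0 on overlap,
else the gap between the nearest interval ends), per-chromosome locus
densities with the count-vs-length correlation, and a test of whether
locus spacing is compatible with a homogeneous Poisson placement
(exponential inter-locus gaps).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_CLASS_ORDER = ("CDS", "TE", "UTR5", "UTR3")


def nearest_feature(
    loci: pd.DataFrame, features: pd.DataFrame
) -> pd.DataFrame:
    """Closest annotated feature per locus.

    ``loci`` needs columns chrom/start/end/name, ``features`` columns
    chrom/start/end/feature_class. Returns one row per locus with the
    globally closest feature class and signed distance, plus per-class
    absolute distances (NaN when the class is absent from the
    chromosome). Ties break toward the smaller feature start, then
    feature-class order. Loci on chromosomes without features get class
    ``none``.
    """
    by_chrom: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for chrom, sub in features.groupby("chrom"):
        per_class = {}
        for cls, csub in sub.groupby("feature_class"):
            arr = csub.sort_values(["start", "end"])
            per_class[cls] = (
                arr["start"].to_numpy(int),
                arr["end"].to_numpy(int),
            )
        by_chrom[str(chrom)] = per_class

    rows = []
    for loc in loci.itertuples():
        per_class_dist: dict[str, float] = {c: np.nan for c in FEATURE_CLASS_ORDER}
        best = None  # ((abs_dist, feature_start, class_rank), signed, cls)
        chrom_feats = by_chrom.get(loc.chrom, {})
        for cls, (starts, ends) in chrom_feats.items():
            signed = np.where(
                ends <= loc.start,
                -(loc.start - ends),
                np.where(starts >= loc.end, starts - loc.end, 0),
            )
            dist = np.abs(signed)
            j = int(np.lexsort((starts, dist))[0])  # min dist, tie: min start
            per_class_dist[cls] = int(dist[j])
            key = (int(dist[j]), int(starts[j]), FEATURE_CLASS_ORDER.index(cls))
            if best is None or key < best[0]:
                best = (key, int(signed[j]), cls)
        if best is None:
            rows.append(
                {
                    "locus": loc.name,
                    "chrom": loc.chrom,
                    "closest_class": "none",
                    "distance": np.nan,
                    **{f"dist_{c}": per_class_dist[c] for c in FEATURE_CLASS_ORDER},
                }
            )
        else:
            rows.append(
                {
                    "locus": loc.name,
                    "chrom": loc.chrom,
                    "closest_class": best[2],
                    "distance": best[1],
                    **{f"dist_{c}": per_class_dist[c] for c in FEATURE_CLASS_ORDER},
                }
            )
    return pd.DataFrame(rows)


def locus_density(
    loci: pd.DataFrame, chrom_sizes: dict[str, int]
) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome locus counts and densities (loci per Mb), plus the
    Pearson correlation (r, r^2) of count vs chromosome length.

    Chromosomes with no loci count as zero. The correlation is NaN when
    fewer than 2 chromosomes or zero variance (e.g. no loci anywhere).
    """
    if any(v <= 0 for v in chrom_sizes.values()):
        raise ValueError("zero-length chromosome")
    counts = loci.groupby("chrom").size()
    rows = []
    for chrom in sorted(chrom_sizes):
        n = int(counts.get(chrom, 0))
        size = chrom_sizes[chrom]
        rows.append(
            {
                "chrom": chrom,
                "n_loci": n,
                "size_bp": size,
                "loci_per_mb": n / (size / 1e6),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        raise ValueError("correlation needs >= 2 chromosomes")
    x = table["size_bp"].to_numpy(float)
    y = table["n_loci"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return table, float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return table, r, r * r


def spacing_randomness_test(
    loci: pd.DataFrame, chrom_sizes: dict[str, int], min_gaps: int = 30
) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of locus spacing against a homogeneous
    Poisson placement.

    Gaps between consecutive locus midpoints are computed per
    chromosome, rescaled by the per-chromosome density (so they are
    Exp(1) under the null), pooled, and tested against the standard
    exponential. Returns (KS statistic, p).
    """
    scaled = []
    for chrom, sub in loci.groupby("chrom"):
        if chrom not in chrom_sizes:
            continue
        mids = np.sort((sub["start"].to_numpy(float) + sub["end"].to_numpy(float)) / 2.0)
        if len(mids) < 2:
            continue
        gaps = np.diff(mids)
        rate = len(mids) / chrom_sizes[chrom]
        scaled.append(gaps * rate)
    if not scaled:
        raise ValueError("no inter-locus gaps available")
    pooled = np.concatenate(scaled)
    if len(pooled) < min_gaps:
        raise ValueError(
            f"only {len(pooled)} inter-locus gaps; need >= {min_gaps}"
        )
    res = stats.kstest(pooled, "expon")
    return float(res.statistic), float(res.pvalue)
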