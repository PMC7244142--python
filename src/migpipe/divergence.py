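"""Zone-based genomic-distance divergence analysis.

For every locus and every sample pair sharing it, the uncorrected
pairwise p-distance is computed over unambiguous shared sites; all
records are pooled (no per-pair averaging) and labeled intra- or
inter-zone under a 2-, 4- or 6-zone biogeographic configuration.
Group summaries, a two-way ANOVA (factors: distance type and zone,
type-II sums of squares with interaction) and Tukey HSD pairwise
comparisons quantify continental-vs-insular divergence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import ZONE_VOCAB, LocusAlignment, SampleRecord

_UNAMBIGUOUS = frozenset(b"ACGT")


@dataclass
class ZoneConfig:
    """One zone configuration: label vocabulary plus the species map.

    ``zone_map`` maps sample/species ids to the set of zones they occur
    in. ``exclude_multizone``: when True (the 2-zone treatment), records
    involving a species assigned to several zones are labeled
    ``excluded``; when False the pair is intra-zone whenever the zone
    sets intersect.
    """

    name: str
    zone_map: dict[str, frozenset[str]] = field(default_factory=dict)
    exclude_multizone: bool = True

    def __post_init__(self) -> None:
        if self.name not in ZONE_VOCAB:
            raise ValueError(f"unknown configuration {self.name!r}")
        vocab = set(ZONE_VOCAB[self.name])
        for sp, zones in self.zone_map.items():
            bad = set(zones) - vocab
            if bad:
                raise ValueError(f"{sp}: labels {sorted(bad)} not in {self.name}")

    @classmethod
    def from_samples(
        cls, name: str, samples: list[SampleRecord], exclude_multizone: bool = True
    ) -> "ZoneConfig":
        zone_map = {
            s.sample_id: s.zones.get(name, frozenset()) for s in samples
        }
        return cls(name, zone_map, exclude_multizone)


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Uncorrected p-distance over shared unambiguous sites.

    Sites where either sequence carries a gap, N or any IUPAC ambiguity
    code are excluded. Returns ``(distance, n_shared_sites)``;
    ``(nan, 0)`` when no site is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    ok_a = np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8))
    ok_b = np.isin(b, np.frombuffer(b"ACGT", dtype=np.uint8))
    shared = ok_a & ok_b
    n = int(shared.sum())
    if n == 0:
        return float("nan"), 0
    diff = int((a[shared] != b[shared]).sum())
    return diff / n, n


def pool_pairwise_distances(
    loci: list[LocusAlignment], samples: list[str] | None = None
) -> pd.DataFrame:
    """One record per (locus, unordered sample pair) sharing the locus.

    Records with zero comparable sites are dropped (their count is
    recoverable as the difference from the combinatorial total).
    Columns: locus, sample_a, sample_b, distance, shared_sites.
    """
    rows = []
    for loc in loci:
        present = loc.samples()
        if samples is not None:
            present = [s for s in present if s in samples]
        for a, b in combinations(present, 2):
            d, n = p_distance(loc.sequences[a], loc.sequences[b])
            if n >= 1:
                rows.append((loc.locus_id, a, b, d, n))
    df = pd.DataFrame(
        rows, columns=["locus", "sample_a", "sample_b", "distance", "shared_sites"]
    )
    return df


def label_zone_pairs(records: pd.DataFrame, config: ZoneConfig) -> pd.DataFrame:
    """Label each record intra/inter/excluded under one configuration.

    intra: the two species share at least one zone (and neither is
    multi-zone when the exclusion policy applies); inter: disjoint zone
    sets; excluded: a multi-zone species under the exclusion policy, or
    a species with no zone assignment.
    """
    missing = sorted(
        {s for s in pd.concat([records["sample_a"], records["sample_b"]]).unique()}
        - set(config.zone_map)
    )
    if missing:
        raise ValueError(f"species missing from zone map: {missing}")
    labels = []
    for rec in records.itertuples():
        za = config.zone_map[rec.sample_a]
        zb = config.zone_map[rec.sample_b]
        if not za or not zb:
            labels.append("excluded")
        elif config.exclude_multizone and (len(za) > 1 or len(zb) > 1):
            labels.append("excluded")
        elif za & zb:
            labels.append("intra")
        else:
            labels.append("inter")
    out = records.copy()
    out["distance_type"] = labels
    return out


def expand_records_by_zone(labeled: pd.DataFrame, config: ZoneConfig) -> pd.DataFrame:
    """Long format for the per-zone analysis: a record enters zone Z's
    panel when at least one of its species occurs in Z; within the panel
    it is intra if both do, inter otherwise. Excluded records are
    dropped."""
    rows = []
    usable = labeled[labeled["distance_type"] != "excluded"]
    for rec in usable.itertuples():
        za = config.zone_map[rec.sample_a]
        zb = config.zone_map[rec.sample_b]
        for zone in sorted(za | zb):
            dtype = "intra" if zone in za and zone in zb else "inter"
            rows.append((rec.locus, rec.sample_a, rec.sample_b, rec.distance, zone, dtype))
    return pd.DataFrame(
        rows,
        columns=["locus", "sample_a", "sample_b", "distance", "zone", "distance_type"],
    )


def group_summaries(expanded: pd.DataFrame, n_bins: int = 40) -> pd.DataFrame:
    """Medians, quartiles, counts and density histograms per
    (zone, distance type) group; empty groups report NaN summaries."""
    rows = []
    zones = sorted(expanded["zone"].unique())
    edges = np.linspace(0.0, max(float(expanded["distance"].max()), 1e-9), n_bins + 1)
    for zone in zones:
        for dtype in ("intra", "inter"):
            grp = expanded[
                (expanded["zone"] == zone) & (expanded["distance_type"] == dtype)
            ]["distance"]
            if len(grp) == 0:
                rows.append(
                    {
                        "zone": zone,
                        "distance_type": dtype,
                        "n": 0,
                        "median": np.nan,
                        "q1": np.nan,
                        "q3": np.nan,
                        "density": None,
                    }
                )
                continue
            hist, _ = np.histogram(grp, bins=edges, density=True)
            rows.append(
                {
                    "zone": zone,
                    "distance_type": dtype,
                    "n": int(len(grp)),
                    "median": float(grp.median()),
                    "q1": float(grp.quantile(0.25)),
                    "q3": float(grp.quantile(0.75)),
                    "density": hist.tolist(),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    table: pd.DataFrame  # per-term df, sum_sq, F, PR(>F); Residual row last

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table.index if t != "Residual"]

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])


def two_way_anova(expanded: pd.DataFrame) -> AnovaResult:
    """Two-way ANOVA of distance on distance type and zone.

    Type-II sums of squares (the records are unbalanced) with the
    interaction term included. Expects the long format of
    :func:`expand_records_by_zone` (columns distance, distance_type,
    zone)."""
    for factor in ("distance_type", "zone"):
        if expanded[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    # the interaction is estimable only when every (type, zone) cell is
    # occupied; with empty cells (e.g. a single-species zone has no
    # intra-zone pairs) fall back to the additive model
    cells = expanded.groupby(["distance_type", "zone"]).size()
    full_rank = len(cells) == (
        expanded["distance_type"].nunique() * expanded["zone"].nunique()
    )
    formula = (
        "distance ~ C(distance_type) * C(zone)"
        if full_rank
        else "distance ~ C(distance_type) + C(zone)"
    )
    model = smf.ols(formula, data=expanded).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [
        idx.replace("C(distance_type)", "distance_type").replace("C(zone)", "zone")
        for idx in table.index
    ]
    return AnovaResult(table)


def tukey_hsd(
    expanded: pd.DataFrame, factor: str = "zone", alpha: float = 0.01
) -> pd.DataFrame:
    """All pairwise group comparisons with studentized-range adjusted
    p-values; ``significant`` flags adjusted p below ``alpha`` (the
    0.01 reporting threshold). Groups with fewer than 2 records are
    skipped with a note."""
    counts = expanded.groupby(factor)["distance"].count()
    usable = counts[counts >= 2].index
    skipped = sorted(set(counts.index) - set(usable))
    sub = expanded[expanded[factor].isin(usable)]
    if sub[factor].nunique() < 2:
        raise ValueError("Tukey HSD needs at least 2 groups with n >= 2")
    res = pairwise_tukeyhsd(sub["distance"], sub[factor], alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    frame = frame.rename(columns={"p-adj": "p_adj", "reject": "significant"})
    frame["p_adj"] = res.pvalues
    frame["significant"] = frame["p_adj"] < alpha
    frame.attrs["skipped_groups"] = skipped
    return frame
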