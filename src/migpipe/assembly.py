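"""Orthologous-locus assembly and the filter cascade.

The stage mirrors a reduced-representation assembler run without a
restriction overhang: quality-filter reads, cluster within each sample,
jointly estimate per-sample heterozygosity and sequencing error under a
diploid site model, call IUPAC consensus sequences, cluster consensus
sequences across samples into candidate loci, and apply the filter
cascade (depth >= 5; <= 2 alleles; <= 5 N and <= 8 heterozygous sites
per consensus; <= 40 indels per locus; locus present in >= min_taxa
samples, default 4).

Per-sample consensus failures (low depth, excess N, excess het) drop
that sample from its candidate locus; a locus showing more than
``max_alleles_per_locus`` resolved alleles in any sample, or more than
``max_indels_per_locus`` alignment indels, is removed outright; a locus
left with fewer than ``min_taxa`` samples is removed as low_taxa. A
removed locus may carry several reasons, so per-reason counts are
non-exclusive (flagged in the report).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from ._align import align_to_reference, gapped_identity, identity_ungapped
from ._util import PAIR_TO_IUPAC
from .core import LocusAlignment, Read, ReadSet

FILTER_REASONS = (
    "low_taxa",
    "excess_alleles",
    "excess_N",
    "excess_het",
    "excess_indels",
    "low_depth",
)

STAT_COLUMNS = [
    "reads_raw",
    "reads_passed_filter",
    "clusters_total",
    "clusters_hidepth",
    "hetero_est",
    "error_est",
    "reads_consens",
    "loci_in_assembly",
]

_BASES = "ACGT"
_HOMO = [(i,) for i in range(4)]
_HET = [(i, j) for i in range(4) for j in range(i + 1, 4)]


@dataclass
class AssemblyParams:
    """Filter-cascade parameters (defaults follow the study settings)."""

    min_depth: int = 5
    max_alleles_per_locus: int = 2
    max_n_per_consensus: int = 5
    max_het_sites_per_consensus: int = 8
    max_indels_per_locus: int = 40
    min_taxa: int = 4
    within_sample_identity: float = 0.85
    across_sample_identity: float = 0.85
    max_low_quality_bases: int = 50
    low_quality_threshold: int = 20

    def __post_init__(self) -> None:
        counts = (
            self.min_depth,
            self.max_alleles_per_locus,
            self.max_n_per_consensus,
            self.max_het_sites_per_consensus,
            self.max_indels_per_locus,
            self.min_taxa,
            self.max_low_quality_bases,
            self.low_quality_threshold,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all count parameters must be >= 0")
        for ident in (self.within_sample_identity, self.across_sample_identity):
            if not 0.5 < ident <= 1.0:
                raise ValueError("identity thresholds must lie in (0.5, 1]")


@dataclass
class Cluster:
    """Within-sample read cluster (putative locus in one sample)."""

    sample_id: str
    centroid: str
    reads: list[Read] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.reads)

    def matrix(self) -> np.ndarray:
        """Reads as an int matrix, end-trimmed to the shortest member.

        Bases are encoded 0-3 (ACGT); anything else is -1 and ignored by
        the caller.
        """
        n = min(len(r.sequence) for r in self.reads)
        enc = np.full((len(self.reads), n), -1, dtype=np.int8)
        for i, r in enumerate(self.reads):
            arr = np.frombuffer(r.sequence[:n].encode(), dtype=np.uint8)
            for code, base in enumerate(_BASES):
                enc[i][arr == ord(base)] = code
        return enc


@dataclass
class ConsensusSequence:
    sample_id: str
    cluster_index: int
    sequence: str
    depth: int
    het_sites: int
    n_sites: int
    n_alleles: int
    rejection: str | None = None  # consensus-level reason, if any


@dataclass
class FilterReport:
    input_loci: int
    removal_counts: dict[str, int]
    retained: int
    removed: int
    reasons_non_exclusive: bool = True

    def __post_init__(self) -> None:
        if self.retained + self.removed != self.input_loci:
            raise ValueError("retained + removed loci must equal input loci")


# ---------------------------------------------------------------------------
# Read quality filtering


def quality_filter_reads(
    readset: ReadSet, params: AssemblyParams
) -> tuple[ReadSet, dict[str, int]]:
    """Drop reads with more than ``max_low_quality_bases`` bases below the
    Phred ``low_quality_threshold``."""
    kept = []
    for read in readset.reads:
        if read.qualities is None or len(read.qualities) == 0:
            raise ValueError(f"read {read.name}: missing base qualities")
        n_low = sum(q < params.low_quality_threshold for q in read.qualities)
        if n_low <= params.max_low_quality_bases:
            kept.append(read)
    counts = {"reads_raw": len(readset.reads), "reads_passed_filter": len(kept)}
    return ReadSet(readset.sample_id, kept), counts


# ---------------------------------------------------------------------------
# Within-sample clustering


def cluster_within_sample(
    readset: ReadSet, identity: float = 0.85
) -> list[Cluster]:
    """Greedy centroid clustering of one sample's reads.

    Unique sequences are visited by decreasing abundance, ties broken
    lexicographically; each joins the first existing centroid whose
    5'-anchored ungapped identity over the overlap reaches the
    threshold, else founds a new cluster. Deterministic.
    """
    by_seq: dict[str, list[Read]] = {}
    for read in readset.reads:
        by_seq.setdefault(read.sequence, []).append(read)
    order = sorted(by_seq, key=lambda s: (-len(by_seq[s]), s))

    clusters: list[Cluster] = []
    for seq in order:
        placed = False
        for cl in clusters:
            if identity_ungapped(seq, cl.centroid) >= identity:
                cl.reads.extend(by_seq[seq])
                placed = True
                break
        if not placed:
            clusters.append(Cluster(readset.sample_id, seq, list(by_seq[seq])))
    return clusters


# ---------------------------------------------------------------------------
# Joint heterozygosity / error estimation


def _site_patterns(clusters: list[Cluster], min_depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Collapse all sites of sufficiently deep clusters into unique sorted
    base-count patterns with multiplicities."""
    patterns: dict[tuple[int, ...], int] = {}
    for cl in clusters:
        if cl.depth < min_depth:
            continue
        mat = cl.matrix()
        counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # 4 x L
        counts = np.sort(counts, axis=0)[::-1]  # descending
        for col in counts.T:
            key = tuple(int(v) for v in col)
            patterns[key] = patterns.get(key, 0) + 1
    if not patterns:
        raise ValueError("no cluster reaches the minimum depth")
    keys = np.array(sorted(patterns), dtype=float)
    weights = np.array([patterns[tuple(int(v) for v in k)] for k in keys], dtype=float)
    return keys, weights


def _pattern_loglik(h: float, eps: float, counts: np.ndarray, weights: np.ndarray) -> float:
    """Log-likelihood of site base-count patterns under the diploid model.

    A site is heterozygous with probability h (two true bases at 50:50)
    else homozygous; a read base is miscalled with probability eps,
    uniformly to the three other bases. Multinomial coefficients are
    constant in (h, eps) and omitted.
    """
    n = counts  # P x 4, sorted descending
    total = n.sum(axis=1, keepdims=True)
    log_e3 = np.log(eps / 3.0)
    # homozygous: correct base prob 1-eps; sum over the 4 base identities
    homo_terms = n * np.log1p(-eps) + (total - n) * log_e3  # P x 4
    log_homo = logsumexp(homo_terms, axis=1) - np.log(4.0)
    # heterozygous: the two true bases each read with prob 0.5 - eps/3
    q = 0.5 - eps / 3.0
    pair_sums = np.stack([n[:, i] + n[:, j] for i, j in _HET], axis=1)  # P x 6
    het_terms = pair_sums * np.log(q) + (total - pair_sums) * log_e3
    log_het = logsumexp(het_terms, axis=1) - np.log(6.0)
    site_ll = logsumexp(
        np.stack([np.log1p(-h) + log_homo, np.log(h) + log_het]), axis=0
    )
    return float((weights * site_ll).sum())


def estimate_het_error(
    clusters: list[Cluster], min_depth: int = 5
) -> tuple[float, float]:
    """Joint ML estimates (hetero_est, error_est) over deep clusters.

    Maximizes the diploid-site-model likelihood over (h, eps) in (0, 1)^2
    by bounded quasi-Newton from several fixed starts.
    """
    counts, weights = _site_patterns(clusters, min_depth)
    lo = 1e-9

    def neg_ll(x):
        return -_pattern_loglik(x[0], x[1], counts, weights)

    best = None
    for h0, e0 in ((0.01, 0.005), (0.001, 0.001), (0.05, 0.02)):
        res = optimize.minimize(
            neg_ll,
            x0=[h0, e0],
            method="L-BFGS-B",
            bounds=[(lo, 0.5), (lo, 0.5)],
        )
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(best.x[1])


# ---------------------------------------------------------------------------
# Consensus calling


def _genotype_log_posteriors(
    base_counts: np.ndarray, h: float, eps: float
) -> np.ndarray:
    """Log posterior (up to a constant) of the 10 genotypes at each site.

    ``base_counts`` is 4 x L. Rows of the result: 4 homozygous genotypes
    then the 6 heterozygous pairs in ``_HET`` order.
    """
    h = min(max(h, 1e-9), 0.5)
    eps = min(max(eps, 1e-9), 0.5)
    total = base_counts.sum(axis=0, keepdims=True)  # 1 x L
    log_e3 = np.log(eps / 3.0)
    homo = (
        base_counts * np.log1p(-eps)
        + (total - base_counts) * log_e3
        + np.log((1.0 - h) / 4.0)
    )  # 4 x L
    q = 0.5 - eps / 3.0
    pair_counts = np.stack(
        [base_counts[i] + base_counts[j] for i, j in _HET]
    )  # 6 x L
    het = (
        pair_counts * np.log(q)
        + (total - pair_counts) * log_e3
        + np.log(h / 6.0)
    )
    return np.vstack([homo, het])


def call_consensus(
    cluster: Cluster,
    hetero_est: float,
    error_est: float,
    params: AssemblyParams,
    cluster_index: int = 0,
    min_posterior: float = 0.5,
) -> ConsensusSequence:
    """Call an IUPAC consensus for one cluster under the (h, eps) model.

    Per site the maximum-posterior genotype is chosen among the 4
    homozygous and 6 heterozygous states; a site whose best genotype
    holds less than ``min_posterior`` of the posterior mass is called N.
    The returned record carries a consensus-level ``rejection`` reason
    (``low_depth``, ``excess_N`` or ``excess_het``) when a threshold is
    exceeded; allele counting feeds the locus-level allele filter.
    """
    depth = cluster.depth
    if depth < params.min_depth:
        return ConsensusSequence(
            cluster.sample_id, cluster_index, "", depth, 0, 0, 0, rejection="low_depth"
        )
    mat = cluster.matrix()
    base_counts = np.stack([(mat == b).sum(axis=0) for b in range(4)]).astype(float)
    logpost = _genotype_log_posteriors(base_counts, hetero_est, error_est)
    norm = logsumexp(logpost, axis=0)
    post = np.exp(logpost - norm)
    best = post.argmax(axis=0)
    best_p = post.max(axis=0)

    chars = []
    het_positions = []
    n_sites = 0
    for pos, (g, p) in enumerate(zip(best, best_p)):
        if p < min_posterior:
            chars.append("N")
            n_sites += 1
        elif g < 4:
            chars.append(_BASES[g])
        else:
            i, j = _HET[g - 4]
            chars.append(PAIR_TO_IUPAC[frozenset((_BASES[i], _BASES[j]))])
            het_positions.append(pos)
    sequence = "".join(chars)
    het_count = len(het_positions)
    n_alleles = _count_alleles(mat, het_positions, depth)

    rejection = None
    if n_sites > params.max_n_per_consensus:
        rejection = "excess_N"
    elif het_count > params.max_het_sites_per_consensus:
        rejection = "excess_het"
    return ConsensusSequence(
        cluster.sample_id,
        cluster_index,
        sequence,
        depth,
        het_count,
        n_sites,
        n_alleles,
        rejection=rejection,
    )


def _count_alleles(mat: np.ndarray, het_positions: list[int], depth: int) -> int:
    """Resolved allele count: distinct read haplotypes across the
    heterozygous sites, keeping haplotypes seen in at least
    max(2, 10% of depth) reads (singletons are treated as errors)."""
    if not het_positions:
        return 1
    sub = mat[:, het_positions]
    sub = sub[(sub >= 0).all(axis=1)]
    if len(sub) == 0:
        return 1
    haplos, counts = np.unique(sub, axis=0, return_counts=True)
    threshold = max(2, int(np.ceil(0.1 * depth)))
    return max(1, int((counts >= threshold).sum()))


# ---------------------------------------------------------------------------
# Across-sample clustering


@dataclass
class CandidateLocus:
    """One across-sample cluster before locus-level filtering."""

    locus_id: str
    members: list[ConsensusSequence]
    aligned: dict[str, str]  # sample_id -> sequence projected on centroid
    n_indels: int


def cluster_across_samples(
    consensi: list[ConsensusSequence], params: AssemblyParams
) -> list[CandidateLocus]:
    """Greedy centroid clustering of per-sample consensus sequences.

    Candidates are visited by decreasing depth then lexicographic
    sequence; each joins the first centroid reaching
    ``across_sample_identity`` under unit-cost global alignment, else
    founds a new locus. Members are projected onto centroid coordinates
    (gapped); a sample contributing several consensus sequences to one
    locus keeps only its deepest.
    """
    if len({c.sample_id for c in consensi}) < 2:
        raise ValueError("across-sample clustering needs consensus from >= 2 samples")
    order = sorted(
        [c for c in consensi if c.sequence],
        key=lambda c: (-c.depth, c.sequence),
    )
    centroids: list[str] = []
    groups: list[list[ConsensusSequence]] = []
    for cons in order:
        placed = False
        for k, cent in enumerate(centroids):
            ident, _ = gapped_identity(cons.sequence, cent)
            if ident >= params.across_sample_identity:
                groups[k].append(cons)
                placed = True
                break
        if not placed:
            centroids.append(cons.sequence)
            groups.append([cons])

    loci: list[CandidateLocus] = []
    for k, (cent, members) in enumerate(zip(centroids, groups)):
        best_by_sample: dict[str, ConsensusSequence] = {}
        for m in members:
            prev = best_by_sample.get(m.sample_id)
            if prev is None or m.depth > prev.depth:
                best_by_sample[m.sample_id] = m
        aligned = {}
        total_indels = 0
        for sample_id, m in sorted(best_by_sample.items()):
            proj, n_ind, _ = align_to_reference(m.sequence, cent)
            aligned[sample_id] = proj
            total_indels += n_ind
        loci.append(
            CandidateLocus(
                locus_id=f"locus_{k + 1:04d}",
                members=sorted(best_by_sample.values(), key=lambda m: m.sample_id),
                aligned=aligned,
                n_indels=total_indels,
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Locus-level filter cascade


def filter_loci(
    candidates: list[CandidateLocus], params: AssemblyParams
) -> tuple[list[LocusAlignment], FilterReport, dict[str, list[str]]]:
    """Apply the locus-level filter cascade.

    Members whose consensus was rejected (low depth, excess N, excess
    het) are dropped from their locus and the reason tagged on it. A
    locus with any member showing more than ``max_alleles_per_locus``
    resolved alleles, or with more than ``max_indels_per_locus`` total
    alignment indels, is removed outright; a locus left with fewer than
    ``min_taxa`` members is removed as low_taxa. Removal reasons are
    non-exclusive.
    """
    retained: list[LocusAlignment] = []
    reasons_by_locus: dict[str, list[str]] = {}
    counts = {r: 0 for r in FILTER_REASONS}
    removed = 0
    for cand in candidates:
        tags: list[str] = []
        keep_members = []
        for m in cand.members:
            if m.rejection is not None:
                if m.rejection not in tags:
                    tags.append(m.rejection)
            else:
                keep_members.append(m)
        fatal: list[str] = []
        if any(m.n_alleles > params.max_alleles_per_locus for m in keep_members):
            fatal.append("excess_alleles")
        if cand.n_indels > params.max_indels_per_locus:
            fatal.append("excess_indels")
        if len(keep_members) < params.min_taxa:
            fatal.append("low_taxa")
        if fatal:
            removed += 1
            reasons = tags + fatal if "low_taxa" in fatal else fatal
            reasons_by_locus[cand.locus_id] = reasons
            for r in reasons:
                counts[r] += 1
        else:
            retained.append(
                LocusAlignment(
                    cand.locus_id,
                    {m.sample_id: cand.aligned[m.sample_id] for m in keep_members},
                )
            )
    report = FilterReport(
        input_loci=len(candidates),
        removal_counts=counts,
        retained=len(retained),
        removed=removed,
    )
    return retained, report, reasons_by_locus


def filter_min_taxa(
    loci: list[LocusAlignment], min_taxa: int = 4
) -> tuple[list[LocusAlignment], FilterReport]:
    """Standalone min-taxa filter: keep loci found in >= ``min_taxa`` samples."""
    retained = [loc for loc in loci if loc.n_samples >= min_taxa]
    counts = {r: 0 for r in FILTER_REASONS}
    counts["low_taxa"] = len(loci) - len(retained)
    return retained, FilterReport(
        input_loci=len(loci),
        removal_counts=counts,
        retained=len(retained),
        removed=len(loci) - len(retained),
    )


# ---------------------------------------------------------------------------
# Whole-stage driver and per-sample statistics


@dataclass
class AssemblyResult:
    loci: list[LocusAlignment]
    report: FilterReport
    stats: pd.DataFrame
    reasons_by_locus: dict[str, list[str]]
    het_error: dict[str, tuple[float, float]]


def assemble_dataset(
    readsets: dict[str, ReadSet], params: AssemblyParams | None = None
) -> AssemblyResult:
    """Run the full assembly stage on per-sample read sets."""
    params = params or AssemblyParams()
    per_sample: dict[str, dict] = {}
    all_consensi: list[ConsensusSequence] = []
    het_error: dict[str, tuple[float, float]] = {}
    for sample_id in sorted(readsets):
        filtered, counts = quality_filter_reads(readsets[sample_id], params)
        clusters = cluster_within_sample(filtered, params.within_sample_identity)
        try:
            h, e = estimate_het_error(clusters, params.min_depth)
        except ValueError:
            h, e = float("nan"), float("nan")
        het_error[sample_id] = (h, e)
        consensi = [
            call_consensus(cl, h, e, params, cluster_index=i)
            for i, cl in enumerate(clusters)
        ]
        all_consensi.extend(consensi)
        per_sample[sample_id] = {
            "counts": counts,
            "clusters": clusters,
            "consensi": consensi,
        }

    candidates = cluster_across_samples(
        [c for c in all_consensi if c.sequence], params
    )
    loci, report, reasons = filter_loci(candidates, params)
    stats = compute_assembly_stats(per_sample, loci, het_error, params)
    return AssemblyResult(loci, report, stats, reasons, het_error)


def compute_assembly_stats(
    per_sample: dict[str, dict],
    retained_loci: list[LocusAlignment],
    het_error: dict[str, tuple[float, float]],
    params: AssemblyParams,
) -> pd.DataFrame:
    """One row per sample: raw/filtered reads, cluster counts, estimates,
    reads assembled into accepted consensus, and final loci containing
    the sample."""
    rows = {}
    loci_by_sample: dict[str, int] = {}
    for loc in retained_loci:
        for s in loc.sequences:
            loci_by_sample[s] = loci_by_sample.get(s, 0) + 1
    for sample_id, parts in per_sample.items():
        clusters = parts["clusters"]
        consensi = parts["consensi"]
        accepted = {
            c.cluster_index for c in consensi if c.rejection is None and c.sequence
        }
        rows[sample_id] = {
            "reads_raw": parts["counts"]["reads_raw"],
            "reads_passed_filter": parts["counts"]["reads_passed_filter"],
            "clusters_total": len(clusters),
            "clusters_hidepth": sum(c.depth >= params.min_depth for c in clusters),
            "hetero_est": het_error[sample_id][0],
            "error_est": het_error[sample_id][1],
            "reads_consens": sum(
                cl.depth for i, cl in enumerate(clusters) if i in accepted
            ),
            "loci_in_assembly": loci_by_sample.get(sample_id, 0),
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=STAT_COLUMNS).sort_index()


# ---------------------------------------------------------------------------
# Group comparisons and correlogram


def compare_groups(
    stats_table: pd.DataFrame,
    grouping: pd.Series | dict[str, str],
    test: str = "mannwhitney",
) -> pd.DataFrame:
    """Per-statistic comparison of two sample groups.

    Reports group means and a two-sided Mann-Whitney U p-value (or
    Welch's t with ``test='welch'``); raw p-values, no multiplicity
    correction.
    """
    groups = pd.Series(grouping)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    a_ids = groups[groups == labels[0]].index
    b_ids = groups[groups == labels[1]].index
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs at least 3 samples")
    rows = []
    for col in stats_table.columns:
        a = stats_table.loc[stats_table.index.intersection(a_ids), col].dropna()
        b = stats_table.loc[stats_table.index.intersection(b_ids), col].dropna()
        if test == "mannwhitney":
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        elif test == "welch":
            res = stats.ttest_ind(a, b, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "statistic_name": col,
                f"mean_{labels[0]}": a.mean(),
                f"mean_{labels[1]}": b.mean(),
                "test_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("statistic_name")


def correlogram(stats_df: pd.DataFrame, ages: pd.Series | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations over the assembly statistics (plus
    specimen age when given); zero-variance columns yield NaN."""
    if len(stats_df) < 4:
        raise ValueError("correlogram needs at least 4 samples")
    df = stats_df.copy()
    if ages is not None:
        df["age"] = pd.Series(ages)
    return df.corr(method="pearson")
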