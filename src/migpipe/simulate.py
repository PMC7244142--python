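"""Synthetic MIGseq data with known truth.

Emulates the statistical structure the downstream analysis assumes: a
dated (ultrametric) species tree from a pure-birth process; short
SSR-anchored amplicon loci (300-800 bp) evolved under Jukes-Cantor;
sequencing reads either in ``amplicon`` mode (PCR products, damage-free)
or ``genomic`` mode (terminal C>T / G>A deamination decaying
exponentially with distance from the fragment end); locus dropout
logistic in specimen age and preservation type; and biogeographic zone
labels under 2/4/6-zone configurations, either clade-structured (so
intra-zone divergences run smaller than inter-zone ones) or randomly
permuted (a null).

Every operation takes an explicit seed or Generator and is fully
deterministic given it. Truth tables retain everything needed to score
downstream stages without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import ints_to_seq, seq_to_ints, stage_rng
from .core import ZONE_VOCAB, LocusAlignment, Read, ReadSet, SampleRecord


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Rates are per site per Ma; ages in Ma; dropout coefficients act on
    the logit of the per-(sample, locus) retention probability.
    """

    n_species: int = 12
    birth_rate: float = 0.1
    root_age: float = 45.0
    n_loci: int = 60
    locus_length_range: tuple[int, int] = (300, 800)
    subst_rate: float = 0.001
    p0_ct: float = 0.3
    p0_ga: float = 0.3
    damage_decay: float = 0.4
    dropout_intercept: float = 30.0  # keep probability ~1 by default
    dropout_age_coef: float = 0.0  # paper-style null: recovery not driven by age
    dropout_herbarium_coef: float = 0.0
    read_depth: int = 12
    error_rate: float = 0.001
    mode: str = "amplicon"
    reference_year: int = 2020
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.locus_length_range
        if lo > hi or lo <= 0:
            raise ValueError("locus_length_range must satisfy 0 < low <= high")
        for name in ("birth_rate", "subst_rate", "damage_decay", "read_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p0_ct", "p0_ga", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mode not in ("genomic", "amplicon"):
            raise ValueError("mode must be 'genomic' or 'amplicon'")


@dataclass
class TruthTables:
    """Ground truth for scoring downstream stages."""

    tree: dendropy.Tree
    loci: list[LocusAlignment]
    presence: pd.DataFrame  # samples x loci, observed (post-dropout)
    presence_truth: pd.DataFrame  # samples x loci, pre-dropout
    ssr_flanks: dict[str, tuple[str, str]] = field(default_factory=dict)
    read_truth: pd.DataFrame | None = None  # read -> sample, locus, strand
    damage_events: pd.DataFrame | None = None  # read, position, change


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    samples: list[SampleRecord]
    readsets: dict[str, ReadSet]
    truth: TruthTables


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Species tree


def simulate_species_tree(
    n_species: int, birth_rate: float, root_age: float, seed
) -> dendropy.Tree:
    """Pure-birth tree conditioned on tip count and root age.

    A Yule process is run forward from the root split until ``n_species``
    lineages exist, plus one final exponential waiting stretch; all split
    times are then rescaled so the root sits at ``root_age`` Ma. Node ages
    (Ma before present, tips at 0) are stored on ``node.age`` and edge
    lengths are age differences, so the tree is exactly ultrametric.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    if birth_rate <= 0 or root_age <= 0:
        raise ValueError("birth_rate and root_age must be positive")
    rng = _as_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    root = tree.seed_node
    root.split_time = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active.pop(int(idx))
        node.split_time = t
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    total = t + rng.exponential(1.0 / (birth_rate * len(active)))

    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxon_ns.new_taxon(label=f"sp{i + 1:02d}")
        leaf.age = 0.0
    scale = root_age / total
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.age = root_age - node.split_time * scale
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    return tree


# ---------------------------------------------------------------------------
# Locus evolution (Jukes-Cantor)

_SSR_MOTIFS = ("AC", "AG", "AT", "CT", "GT", "GA")


def _jc_mutate(parent: np.ndarray, t: float, rate: float, rng) -> np.ndarray:
    """One Jukes-Cantor branch: each site substitutes with the JC
    closed-form probability (3/4)(1 - exp(-4/3 mu t)), uniformly to one
    of the three other bases."""
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * t))
    child = parent.copy()
    hit = rng.random(parent.shape) < p
    n_hit = int(hit.sum())
    if n_hit:
        child[hit] = (child[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return child


def evolve_loci(
    tree: dendropy.Tree, config: SimulationConfig, seed
) -> tuple[list[LocusAlignment], dict[str, tuple[str, str]]]:
    """Evolve ``config.n_loci`` loci along the tree under Jukes-Cantor.

    Returns the per-tip alignments (one sequence per species, equal
    length within a locus) and the fixed SSR primer-motif pair flanking
    each locus, recorded for the truth tables. Tip sequences are the
    locus cores; flanks are conserved PCR anchors and do not evolve.
    """
    if config.subst_rate < 0:
        raise ValueError("substitution rate must be >= 0")
    lo, hi = config.locus_length_range
    if lo == hi == 0:
        raise ValueError("zero-length locus range")
    rng = _as_rng(seed)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    loci: list[LocusAlignment] = []
    flanks: dict[str, tuple[str, str]] = {}
    for k in range(config.n_loci):
        locus_id = f"L{k + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seqs: dict[str, str] = {}
        root_seq = rng.integers(0, 4, size=length).astype(np.int8)
        stack = [(tree.seed_node, root_seq)]
        while stack:
            node, seq = stack.pop()
            for child in node.child_nodes():
                child_seq = _jc_mutate(seq, child.edge.length, config.subst_rate, rng)
                if child.is_leaf():
                    seqs[child.taxon.label] = ints_to_seq(child_seq)
                else:
                    stack.append((child, child_seq))
        loci.append(LocusAlignment(locus_id, {t: seqs[t] for t in tips}))
        left = _SSR_MOTIFS[int(rng.integers(len(_SSR_MOTIFS)))] * 5
        right = _SSR_MOTIFS[int(rng.integers(len(_SSR_MOTIFS)))] * 5
        flanks[locus_id] = (left, right)
    return loci, flanks


# ---------------------------------------------------------------------------
# Dropout


def apply_dropout(
    presence_truth: pd.DataFrame,
    samples: list[SampleRecord],
    coefficients: tuple[float, float, float],
    seed,
    reference_year: int = 2020,
) -> pd.DataFrame:
    """Thin the true presence matrix by logistic dropout.

    Each (sample, locus) cell is kept independently with probability
    ``expit(intercept + age_coef * age_years + herb_coef * is_herbarium)``.
    With all coefficients at 0 and a large intercept the observed matrix
    equals the truth (the no-age-effect null).
    """
    intercept, age_coef, herb_coef = (float(c) for c in coefficients)
    for c in (intercept, age_coef, herb_coef):
        if not np.isfinite(c):
            raise ValueError("dropout coefficients must be finite")
    rng = _as_rng(seed)
    by_id = {s.sample_id: s for s in samples}
    observed = presence_truth.copy()
    for sample_id in presence_truth.index:
        s = by_id[sample_id]
        eta = intercept + age_coef * s.age_years(reference_year) + herb_coef * int(
            s.is_herbarium
        )
        keep_p = expit(eta)
        keep = rng.random(presence_truth.shape[1]) < keep_p
        observed.loc[sample_id] = presence_truth.loc[sample_id].to_numpy() * keep
    return observed


# ---------------------------------------------------------------------------
# Reads


def simulate_reads(
    locus_seq: str,
    depth: int,
    error_rate: float,
    damage_params: tuple[float, float, float],
    mode: str,
    seed,
    read_prefix: str = "read",
    base_quality: int = 40,
) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate full-length amplicon reads from one locus sequence.

    ``genomic`` mode injects C>T at 5' offsets i (0-based) with
    probability p0_ct * exp(-decay * i) and G>A at 3' offsets j from the
    read end with probability p0_ga * exp(-decay * j) — the canonical
    terminal-deamination profile. ``amplicon`` mode injects none (PCR
    copies are damage-free). Uniform per-base sequencing error applies in
    both modes. Returns the reads and a truth table with one row per
    injected damage event (read, position, change).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if mode not in ("genomic", "amplicon"):
        raise ValueError("mode must be 'genomic' or 'amplicon'")
    p0_ct, p0_ga, decay = damage_params
    rng = _as_rng(seed)
    template = seq_to_ints(locus_seq)
    length = len(template)
    mat = np.tile(template, (depth, 1))

    events: list[tuple[str, int, str]] = []
    names = [f"{read_prefix}_{i}" for i in range(depth)]
    if mode == "genomic":
        offsets = np.arange(length)
        p5 = p0_ct * np.exp(-decay * offsets)
        p3 = p0_ga * np.exp(-decay * offsets[::-1])
        is_c = template == 1  # C
        is_g = template == 2  # G
        hit5 = (rng.random((depth, length)) < p5[None, :]) & is_c[None, :]
        hit3 = (rng.random((depth, length)) < p3[None, :]) & is_g[None, :]
        mat[hit5] = 3  # C -> T
        mat[hit3] = 0  # G -> A
        for r, pos in zip(*np.nonzero(hit5)):
            events.append((names[r], int(pos), "C>T"))
        for r, pos in zip(*np.nonzero(hit3)):
            events.append((names[r], int(pos), "G>A"))

    if error_rate > 0:
        err = rng.random((depth, length)) < error_rate
        n_err = int(err.sum())
        if n_err:
            mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4

    reads = [
        Read(names[i], ints_to_seq(mat[i]), [base_quality] * length)
        for i in range(depth)
    ]
    truth = pd.DataFrame(events, columns=["read", "position", "change"])
    return ReadSet(read_prefix, reads), truth


# ---------------------------------------------------------------------------
# Zones


def assign_zones(
    tree: dendropy.Tree, zone_labels: tuple[str, ...] | list[str], scheme: str, seed
) -> dict[str, str]:
    """Assign each species (tip) to one zone.

    ``clade-structured`` cuts the tree at its oldest internal nodes into
    as many clades as zones, assigning whole clades to zones — so true
    intra-zone path lengths are stochastically smaller than inter-zone
    ones. ``random`` permutes that assignment's labels across species,
    the matched null.
    """
    labels = list(zone_labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 zones")
    if scheme not in ("clade-structured", "random"):
        raise ValueError("scheme must be 'clade-structured' or 'random'")
    rng = _as_rng(seed)

    groups = [tree.seed_node]
    while len(groups) < len(labels):
        internal = [g for g in groups if not g.is_leaf()]
        if not internal:
            break
        oldest = max(internal, key=lambda n: n.age)
        groups.remove(oldest)
        groups.extend(oldest.child_nodes())
    if len(groups) < len(labels):
        raise ValueError("tree has too few tips for the requested zone count")

    assignment: dict[str, str] = {}
    for label, group in zip(labels, groups):
        for leaf in group.leaf_iter():
            assignment[leaf.taxon.label] = label

    if scheme == "random":
        species = sorted(assignment)
        shuffled = rng.permutation([assignment[s] for s in species])
        assignment = {s: z for s, z in zip(species, shuffled)}
    return assignment


# ---------------------------------------------------------------------------
# End-to-end dataset


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic study: tree, loci, samples, reads, truth."""
    rng_tree = stage_rng(config.seed, "simulate/tree")
    rng_loci = stage_rng(config.seed, "simulate/loci")
    rng_samples = stage_rng(config.seed, "simulate/samples")
    rng_drop = stage_rng(config.seed, "simulate/dropout")
    rng_reads = stage_rng(config.seed, "simulate/reads")
    rng_zones = stage_rng(config.seed, "simulate/zones")

    tree = simulate_species_tree(
        config.n_species, config.birth_rate, config.root_age, rng_tree
    )
    loci, flanks = evolve_loci(tree, config, rng_loci)
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]

    zone_maps = {}
    for cfg_name, labels in ZONE_VOCAB.items():
        if len(labels) <= config.n_species:
            zone_maps[cfg_name] = assign_zones(
                tree, labels, "clade-structured", rng_zones
            )

    samples: list[SampleRecord] = []
    for i, sp in enumerate(species):
        herbarium = i % 2 == 0
        if herbarium:
            year = int(rng_samples.integers(1909, 2004))
        else:
            year = int(rng_samples.integers(2013, 2019))
        zones = {
            cfg: frozenset([zone_maps[cfg][sp]]) for cfg in zone_maps
        }
        samples.append(
            SampleRecord(
                sample_id=sp,
                species=f"L.{sp}",
                preservation="herbarium" if herbarium else "silica",
                collection_year=year,
                zones=zones,
            )
        )

    locus_ids = [loc.locus_id for loc in loci]
    presence_truth = pd.DataFrame(
        1, index=species, columns=locus_ids, dtype=int
    )
    presence = apply_dropout(
        presence_truth,
        samples,
        (
            config.dropout_intercept,
            config.dropout_age_coef,
            config.dropout_herbarium_coef,
        ),
        rng_drop,
        reference_year=config.reference_year,
    )

    readsets: dict[str, ReadSet] = {}
    read_rows = []
    damage_frames = []
    for sp in species:
        reads: list[Read] = []
        for loc in loci:
            if not presence.at[sp, loc.locus_id]:
                continue
            prefix = f"{sp}|{loc.locus_id}"
            rs, dmg = simulate_reads(
                loc.sequences[sp],
                config.read_depth,
                config.error_rate,
                (config.p0_ct, config.p0_ga, config.damage_decay),
                config.mode,
                rng_reads,
                read_prefix=prefix,
            )
            reads.extend(rs.reads)
            for r in rs.reads:
                read_rows.append((r.name, sp, loc.locus_id, "+"))
            if len(dmg):
                damage_frames.append(dmg)
        readsets[sp] = ReadSet(sp, reads)

    truth = TruthTables(
        tree=tree,
        loci=loci,
        presence=presence,
        presence_truth=presence_truth,
        ssr_flanks=flanks,
        read_truth=pd.DataFrame(
            read_rows, columns=["read", "sample", "locus", "strand"]
        ),
        damage_events=(
            pd.concat(damage_frames, ignore_index=True)
            if damage_frames
            else pd.DataFrame(columns=["read", "position", "change"])
        ),
    )
    return SimulatedDataset(config=config, samples=samples, readsets=readsets, truth=truth)


def make_filter_cascade_fixture(seed: int = 0):
    """Constructed 20-candidate-locus fixture for the filter cascade.

    Fourteen clean loci pass every filter; six trip, between them, each
    rejection reason exactly once at the stage where it applies:
    a low-depth member, an excess-N member and an excess-het member each
    leave their locus below the taxon minimum; one locus shows three
    resolved alleles; one exceeds the indel budget; one is simply too
    sparsely sampled. Returns ``(candidates, expected_removal_counts,
    expected_retained)``.
    """
    from .assembly import CandidateLocus, ConsensusSequence

    rng = _as_rng(seed)
    samples = [f"s{i}" for i in range(1, 7)]

    def seq(length=60):
        return ints_to_seq(rng.integers(0, 4, size=length).astype(np.int8))

    def cons(sample, sequence, depth=10, rejection=None, n_alleles=1,
             het=0, n_sites=0):
        return ConsensusSequence(sample, 0, sequence, depth, het, n_sites,
                                 n_alleles, rejection=rejection)

    candidates = []

    def locus(lid, members, n_indels=0):
        aligned = {m.sample_id: m.sequence for m in members}
        candidates.append(
            CandidateLocus(lid, list(members), aligned, n_indels)
        )

    for k in range(14):  # clean loci
        s = seq()
        locus(f"clean_{k:02d}", [cons(sid, s) for sid in samples[:5]])
    s = seq()
    locus("trip_low_depth", [cons(samples[0], s, depth=4, rejection="low_depth")]
          + [cons(sid, s) for sid in samples[1:4]])
    s = seq()
    locus("trip_excess_N", [cons(samples[0], s, rejection="excess_N", n_sites=6)]
          + [cons(sid, s) for sid in samples[1:4]])
    s = seq()
    locus("trip_excess_het", [cons(samples[0], s, rejection="excess_het", het=9)]
          + [cons(sid, s) for sid in samples[1:4]])
    s = seq()
    locus("trip_excess_alleles",
          [cons(samples[0], s, n_alleles=3)]
          + [cons(sid, s) for sid in samples[1:5]])
    s = seq()
    locus("trip_excess_indels", [cons(sid, s) for sid in samples[:5]],
          n_indels=50)
    s = seq()
    locus("trip_low_taxa", [cons(sid, s) for sid in samples[:3]])

    expected_counts = {
        "low_taxa": 4,
        "excess_alleles": 1,
        "excess_N": 1,
        "excess_het": 1,
        "excess_indels": 1,
        "low_depth": 1,
    }
    return candidates, expected_counts, 14


def simulate_phylogram(
    tree: dendropy.Tree,
    rate: float,
    n_sites: float,
    seed,
    rate_sigma: float = 0.0,
    poisson: bool = True,
    autocorrelated: bool = False,
    clade_shift_factor: float | None = None,
) -> tuple[dendropy.Tree, dict[int, float]]:
    """Phylogram (branch lengths in subst/site) from a dated tree.

    With ``rate_sigma`` = 0 every branch evolves at ``rate`` (strict
    clock). Otherwise rates vary lognormally with log-sd ``rate_sigma``:
    independently per branch by default, or as a geometric random walk
    from parent to child branch with ``autocorrelated=True``.
    ``clade_shift_factor`` multiplies the rate throughout the larger
    basal clade — a lineage-effect rate shift, the classic strong
    heterogeneity scenario. Branch length is
    Poisson(rate * t * n_sites) / n_sites substitutions per site (the
    exact expectation with ``poisson=False``). Returns the phylogram
    and the true per-branch rates keyed by preorder branch index.
    """
    rng = _as_rng(seed)
    phylo = tree.clone(depth=1)
    shifted: set[int] = set()
    if clade_shift_factor is not None:
        kids = phylo.seed_node.child_nodes()
        fast = max(kids, key=lambda c: len(list(c.leaf_iter())))
        shifted = {id(n) for n in fast.preorder_iter()}
    true_rates: dict[int, float] = {}
    parent_rate: dict[int, float] = {}
    k = 0
    for node in phylo.preorder_node_iter():
        if node.parent_node is None:
            parent_rate[id(node)] = rate
            continue
        t = node.edge.length
        if rate_sigma <= 0:
            r = rate
        elif autocorrelated:
            base = parent_rate[id(node.parent_node)]
            r = base * float(
                np.exp(rng.normal(-0.5 * rate_sigma**2, rate_sigma))
            )
        else:
            r = rate * float(
                np.exp(rng.normal(-0.5 * rate_sigma**2, rate_sigma))
            )
        parent_rate[id(node)] = r  # walk operates on the unshifted rate
        if id(node) in shifted:
            r = r * clade_shift_factor
        mu = r * t * n_sites
        if poisson:
            x = float(rng.poisson(mu))
        else:
            x = mu
        node.edge.length = x / n_sites
        true_rates[k] = r
        k += 1
    return phylo, true_rates


def with_overrides(config: SimulationConfig, **kwargs) -> SimulationConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
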