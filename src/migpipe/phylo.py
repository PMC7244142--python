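"""Presence-absence phylogenetics and SNP export.

The retained loci define a binary samples x loci matrix (1 = the sample
has a consensus in that locus). Gains and losses of amplifiable loci are
treated as characters: a mismatch-proportion (or Jaccard) distance feeds
a Saitou-Nei neighbor-joining tree, with nodal support from resampling
loci columns with replacement (Felsenstein bootstrap, default 1000
replicates). Variable alignment columns are additionally exported as a
concatenated SNP matrix (PHYLIP/FASTA) for external maximum-likelihood
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .core import LocusAlignment

_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Presence-absence matrix and distances


def build_presence_matrix(
    loci: list[LocusAlignment], samples: list[str]
) -> pd.DataFrame:
    """Binary samples x loci matrix; warns on all-zero rows."""
    mat = pd.DataFrame(0, index=list(samples), columns=[l.locus_id for l in loci], dtype=int)
    for loc in loci:
        for s in loc.sequences:
            if s in mat.index:
                mat.at[s, loc.locus_id] = 1
    empty = mat.index[mat.sum(axis=1) == 0].tolist()
    if empty:
        import warnings

        warnings.warn(f"samples with no retained locus: {empty}", stacklevel=2)
    return mat


def binary_distance(matrix: pd.DataFrame, metric: str = "mismatch") -> pd.DataFrame:
    """Pairwise distance on presence-absence rows.

    ``mismatch``: Hamming count over the number of loci (treats shared
    absence as agreement); ``jaccard``: 1 - |intersection| / |union|
    over presences (0 for two empty rows).
    """
    x = matrix.to_numpy(dtype=bool)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if metric == "mismatch":
        d = np.zeros((n, n))
        for i in range(n):
            d[i] = (x[i] ^ x).mean(axis=1)
    elif metric == "jaccard":
        inter = x.astype(int) @ x.T.astype(int)
        sums = x.sum(axis=1)
        union = sums[:, None] + sums[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        np.fill_diagonal(d, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(distance: pd.DataFrame, taxon_namespace=None) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion
    ``Q_ij = (n-2) d_ij - r_i - r_j``; branch lengths follow the
    standard two-point formulas. Negative branch lengths are clamped to
    zero with the deficit transferred to the sister branch. Ties break
    toward the lowest-index pair in current scan order, so the result is
    deterministic. Returns an unrooted tree (the seed node is the final
    join and has three children for n >= 3).
    """
    labels = list(distance.index)
    d = distance.to_numpy(dtype=float).copy()
    if d.shape[0] != d.shape[1] or len(labels) < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    np.fill_diagonal(d, 0.0)

    tns = taxon_namespace or dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node()
        taxon = tns.get_taxon(lab) or tns.new_taxon(lab)
        node.taxon = taxon
        nodes.append(node)

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n - 1):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((n - 1, n - 1))
        d2[: n - 2, : n - 2] = d[np.ix_(keep, keep)]
        d2[n - 2, : n - 2] = dnew[keep]
        d2[: n - 2, n - 2] = dnew[keep]
        d2[n - 2, n - 2] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    a, b = nodes
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    a.add_child(b)
    b.edge.length = max(d[0, 1], 0.0)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = a
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap supports


def _bipartitions(tree: dendropy.Tree, bit_of: dict[str, int], full: int) -> set[int]:
    """Non-trivial bipartitions as canonical bitmasks of the smaller side
    (ties to the side containing taxon bit 0 complement)."""
    out: set[int] = set()
    masks: dict[int, int] = {}

    def mask_of(node) -> int:
        m = 0
        for child in node.child_nodes():
            m |= masks[id(child)]
        if node.taxon is not None and not node.child_nodes():
            m = 1 << bit_of[node.taxon.label]
        masks[id(node)] = m
        return m

    for node in tree.postorder_node_iter():
        mask_of(node)
    n_taxa = full.bit_count()
    for node in tree.preorder_node_iter():
        m = masks[id(node)]
        size = m.bit_count()
        if size < 2 or size > n_taxa - 2:
            continue
        canon = min(m, full ^ m)
        out.add(canon)
    return out


def bootstrap_support(
    matrix: pd.DataFrame,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    metric: str = "mismatch",
) -> dendropy.Tree:
    """NJ tree from the presence matrix with bootstrap supports.

    Loci columns are resampled with replacement ``n_reps`` times; each
    replicate's NJ tree is built and the support of every internal
    bipartition of the reference tree is the percentage of replicates
    containing it. Supports are stored on internal node labels and
    ``node.support``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = nj_tree(binary_distance(matrix, metric))
    labels = list(matrix.index)
    bit_of = {lab: i for i, lab in enumerate(labels)}
    full = (1 << len(labels)) - 1
    ref_bips = _bipartitions(ref, bit_of, full)
    hits = {b: 0 for b in ref_bips}
    n_loci = matrix.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_loci, size=n_loci)
        boot = matrix.iloc[:, cols]
        btree = nj_tree(binary_distance(boot, metric))
        for b in _bipartitions(btree, bit_of, full):
            if b in hits:
                hits[b] += 1

    masks: dict[int, int] = {}
    for node in ref.postorder_node_iter():
        if node.taxon is not None and not node.child_nodes():
            masks[id(node)] = 1 << bit_of[node.taxon.label]
        else:
            masks[id(node)] = sum(masks[id(c)] for c in node.child_nodes())
    n_taxa = len(labels)
    for node in ref.preorder_node_iter():
        m = masks[id(node)]
        size = m.bit_count()
        if 2 <= size <= n_taxa - 2:
            canon = min(m, full ^ m)
            if canon in hits:
                support = 100.0 * hits[canon] / n_reps
                node.support = support
                node.label = f"{support:g}"
    return ref


# ---------------------------------------------------------------------------
# SNP extraction


@dataclass
class SnpMatrix:
    """Concatenated variable columns over all loci.

    ``matrix``: samples x SNP columns (IUPAC characters, 'N' for samples
    missing the locus); ``sources``: per column (locus_id, position).
    """

    matrix: pd.DataFrame
    sources: list[tuple[str, int]]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def to_fasta(self) -> str:
        lines = []
        for sample in self.matrix.index:
            lines.append(f">{sample}")
            lines.append("".join(self.matrix.loc[sample]))
        return "\n".join(lines) + "\n"

    def to_phylip(self) -> str:
        n, m = self.matrix.shape
        lines = [f"{n} {m}"]
        for sample in self.matrix.index:
            lines.append(f"{sample}  {''.join(self.matrix.loc[sample])}")
        return "\n".join(lines) + "\n"


def extract_snps(
    loci: list[LocusAlignment], samples: list[str] | None = None
) -> SnpMatrix:
    """Variable columns across loci.

    A column is a SNP iff at least two distinct unambiguous bases (ACGT)
    occur among the non-missing samples. Heterozygous IUPAC codes are
    carried through as-is; samples lacking the locus get 'N' for all its
    columns.
    """
    if samples is None:
        samples = sorted({s for loc in loci for s in loc.sequences})
    columns: dict[str, list[str]] = {s: [] for s in samples}
    sources: list[tuple[str, int]] = []
    for loc in loci:
        present = [s for s in samples if s in loc.sequences]
        if not present:
            continue
        arr = np.array([list(loc.sequences[s]) for s in present])
        for pos in range(arr.shape[1]):
            states = {c for c in arr[:, pos] if c in _ACGT}
            if len(states) >= 2:
                for s in samples:
                    columns[s].append(
                        loc.sequences[s][pos] if s in loc.sequences else "N"
                    )
                sources.append((loc.locus_id, pos))
    mat = pd.DataFrame(
        {s: "".join(columns[s]) for s in samples}, index=["seq"]
    ).T["seq"].apply(list)
    frame = pd.DataFrame(mat.tolist(), index=samples) if sources else pd.DataFrame(index=samples)
    return SnpMatrix(frame, sources)
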