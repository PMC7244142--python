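"""Pairwise alignment helpers used by clustering and damage scoring."""

from __future__ import annotations

import numpy as np

try:
    import edlib
except ImportError:  # pragma: no cover
    edlib = None


def identity_ungapped(a: str, b: str) -> float:
    """5'-anchored ungapped identity over the overlap of two sequences.

    Amplicon reads share their SSR primer anchor, so comparing from the
    5' end over ``min(len(a), len(b))`` positions is the natural
    within-sample comparison.
    """
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    xa = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    xb = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return float((xa == xb).mean())


def align_to_reference(query: str, ref: str) -> tuple[str, int, float]:
    """Globally align ``query`` to ``ref`` and project onto ref coordinates.

    Returns ``(projected, n_indels, identity)`` where ``projected`` has
    exactly ``len(ref)`` characters: reference deletions become ``-``,
    query insertions are dropped; ``n_indels`` counts inserted plus
    deleted bases; identity is matches over alignment columns.
    """
    if query == ref:
        return query, 0, 1.0
    if edlib is None or len(query) == len(ref):
        # same-length fast path: column-wise comparison, no indels
        if len(query) == len(ref):
            ident = identity_ungapped(query, ref)
            return query, 0, ident
        raise RuntimeError("edlib required for gapped alignment")
    res = edlib.align(query, ref, mode="NW", task="path")
    cigar = res["cigar"]
    out = []
    qi = ri = 0
    matches = 0
    n_indels = 0
    ncols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        ncols += n
        if ch == "=":
            out.append(query[qi : qi + n])
            matches += n
            qi += n
            ri += n
        elif ch == "X":
            out.append(query[qi : qi + n])
            qi += n
            ri += n
        elif ch == "I":  # bases present in query only
            n_indels += n
            qi += n
        elif ch == "D":  # bases present in ref only
            n_indels += n
            out.append("-" * n)
            ri += n
    projected = "".join(out)
    return projected, n_indels, matches / max(ncols, 1)


def gapped_identity(a: str, b: str) -> tuple[float, int]:
    """Identity and indel count under unit-cost global alignment."""
    if a == b:
        return 1.0, 0
    if len(a) == len(b):
        return identity_ungapped(a, b), 0
    if edlib is None:
        raise RuntimeError("edlib required for gapped alignment")
    res = edlib.align(a, b, mode="NW", task="distance")
    dist = res["editDistance"]
    return 1.0 - dist / max(len(a), len(b)), abs(len(a) - len(b))
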