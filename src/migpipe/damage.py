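"""Post-assembly DNA-damage scoring.

Reads are compared against the consensus locus they derive from and
position-specific misincorporations are profiled: C>T at the 5' end and
G>A at the 3' end, the signature of post-mortem cytosine deamination
concentrated at fragment extremities. PCR-generated amplicon loci should
show a flat profile (the amplification steps copy over damage-free
primer-anchored templates); genomic fragments show terminal enrichment
decaying into the read.

A terminal-vs-interior two-proportion exact test turns the visual
profile check into a decision: pooled misincorporation frequency over
terminal offsets 1..k against offsets >= ``interior_from``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._align import align_to_reference
from .core import Read, ReadSet

_C, _G, _T, _A = "C", "G", "T", "A"


@dataclass
class SubstitutionCalls:
    """Per-aligned-column records for one read set vs consensus.

    Arrays are parallel: consensus base, read base, 1-based distance
    from the 5' read end, 1-based distance from the 3' read end.
    Unassignable reads (alignment identity < 0.5) are counted, not kept.
    """

    cons_base: np.ndarray
    read_base: np.ndarray
    offset5: np.ndarray
    offset3: np.ndarray
    n_reads: int = 0
    n_unassigned: int = 0


@dataclass
class DamageProfile:
    """Position-indexed misincorporation counts near the read ends."""

    window: int
    ct5_opportunities: np.ndarray  # consensus C at 5' offset 1..w
    ct5_observations: np.ndarray  # of those, read T
    ga3_opportunities: np.ndarray  # consensus G at 3' offset 1..w
    ga3_observations: np.ndarray

    @property
    def ct5_frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.ct5_opportunities > 0,
                self.ct5_observations / np.maximum(self.ct5_opportunities, 1),
                0.0,
            )

    @property
    def ga3_frequency(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.ga3_opportunities > 0,
                self.ga3_observations / np.maximum(self.ga3_opportunities, 1),
                0.0,
            )

    def to_frame(self) -> pd.DataFrame:
        offs = np.arange(1, self.window + 1)
        five = pd.DataFrame(
            {
                "end": "5p",
                "offset": offs,
                "opportunities": self.ct5_opportunities,
                "observations": self.ct5_observations,
                "frequency": self.ct5_frequency,
            }
        )
        three = pd.DataFrame(
            {
                "end": "3p",
                "offset": offs,
                "opportunities": self.ga3_opportunities,
                "observations": self.ga3_observations,
                "frequency": self.ga3_frequency,
            }
        )
        return pd.concat([five, three], ignore_index=True)


def align_read_to_consensus(
    read: Read | str, consensus: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """Align one read to its consensus; return per-column arrays
    (consensus base, read base, 5' offset, 3' offset), or None when the
    alignment identity falls below 0.5 (read flagged unassigned)."""
    seq = read.sequence if isinstance(read, Read) else read
    if not seq or not consensus:
        raise ValueError("read and consensus must be non-empty")
    projected, _, identity = align_to_reference(seq, consensus)
    if identity < 0.5:
        return None
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    rd = np.frombuffer(projected.encode(), dtype=np.uint8)
    keep = rd != ord("-")
    cons = cons[keep]
    rd = rd[keep]
    n = len(rd)
    off5 = np.arange(1, n + 1)
    off3 = off5[::-1].copy()
    return cons, rd, off5, off3


def collect_substitution_calls(
    readset: ReadSet | list[Read], consensus_by_read
) -> SubstitutionCalls:
    """Align every read against its assigned consensus.

    ``consensus_by_read`` is either a mapping from read name to consensus
    sequence or a single consensus string applied to all reads.
    """
    reads = readset.reads if isinstance(readset, ReadSet) else readset
    cons_parts, read_parts, off5_parts, off3_parts = [], [], [], []
    n_unassigned = 0
    for read in reads:
        consensus = (
            consensus_by_read
            if isinstance(consensus_by_read, str)
            else consensus_by_read[read.name]
        )
        result = align_read_to_consensus(read, consensus)
        if result is None:
            n_unassigned += 1
            continue
        c, r, o5, o3 = result
        cons_parts.append(c)
        read_parts.append(r)
        off5_parts.append(o5)
        off3_parts.append(o3)
    if not cons_parts:
        empty = np.array([], dtype=np.uint8)
        return SubstitutionCalls(empty, empty, empty.astype(int), empty.astype(int),
                                 n_reads=0, n_unassigned=n_unassigned)
    return SubstitutionCalls(
        np.concatenate(cons_parts),
        np.concatenate(read_parts),
        np.concatenate(off5_parts),
        np.concatenate(off3_parts),
        n_reads=len(reads) - n_unassigned,
        n_unassigned=n_unassigned,
    )


def merge_calls(parts: list[SubstitutionCalls]) -> SubstitutionCalls:
    """Pool substitution calls across read sets / loci."""
    parts = [p for p in parts if len(p.cons_base)]
    if not parts:
        raise ValueError("no calls to merge")
    return SubstitutionCalls(
        np.concatenate([p.cons_base for p in parts]),
        np.concatenate([p.read_base for p in parts]),
        np.concatenate([p.offset5 for p in parts]),
        np.concatenate([p.offset3 for p in parts]),
        n_reads=sum(p.n_reads for p in parts),
        n_unassigned=sum(p.n_unassigned for p in parts),
    )


def misincorporation_profile(calls: SubstitutionCalls, window: int = 25) -> DamageProfile:
    """Aggregate C>T (5') and G>A (3') counts per offset 1..window."""
    if calls.n_reads < 1:
        raise ValueError("no assigned reads to profile")
    ct_opp = np.zeros(window, dtype=int)
    ct_obs = np.zeros(window, dtype=int)
    ga_opp = np.zeros(window, dtype=int)
    ga_obs = np.zeros(window, dtype=int)

    in5 = calls.offset5 <= window
    is_c = calls.cons_base == ord(_C)
    sel = in5 & is_c
    np.add.at(ct_opp, calls.offset5[sel] - 1, 1)
    sel_t = sel & (calls.read_base == ord(_T))
    np.add.at(ct_obs, calls.offset5[sel_t] - 1, 1)

    in3 = calls.offset3 <= window
    is_g = calls.cons_base == ord(_G)
    sel = in3 & is_g
    np.add.at(ga_opp, calls.offset3[sel] - 1, 1)
    sel_a = sel & (calls.read_base == ord(_A))
    np.add.at(ga_obs, calls.offset3[sel_a] - 1, 1)

    return DamageProfile(window, ct_opp, ct_obs, ga_opp, ga_obs)


def terminal_damage_test(
    profile: DamageProfile, terminal_k: int = 3, interior_from: int = 11
) -> tuple[float, float]:
    """Terminal-vs-interior misincorporation test.

    Pools C>T and G>A counts over terminal offsets 1..k and interior
    offsets >= ``interior_from`` (up to the profile window) and compares
    the two proportions with Fisher's exact test. Returns
    (rate ratio, two-sided p). The ratio is terminal frequency over
    interior frequency (inf when the interior is clean but the terminal
    is not; 1.0 when both are clean).
    """
    k, start = terminal_k, interior_from - 1
    term_opp = int(profile.ct5_opportunities[:k].sum() + profile.ga3_opportunities[:k].sum())
    term_obs = int(profile.ct5_observations[:k].sum() + profile.ga3_observations[:k].sum())
    int_opp = int(
        profile.ct5_opportunities[start:].sum() + profile.ga3_opportunities[start:].sum()
    )
    int_obs = int(
        profile.ct5_observations[start:].sum() + profile.ga3_observations[start:].sum()
    )
    if term_opp < 30 or int_opp < 30:
        raise ValueError(
            "fewer than 30 opportunities in the terminal or interior window; "
            "increase read depth or the number of profiled reads"
        )
    table = [[term_obs, term_opp - term_obs], [int_obs, int_opp - int_obs]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    f_term = term_obs / term_opp
    f_int = int_obs / int_opp
    if f_int == 0:
        ratio = 1.0 if f_term == 0 else float("inf")
    else:
        ratio = f_term / f_int
    return float(ratio), float(p)
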