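"""Shared helpers: seeded random streams and sequence/array conversions."""

from __future__ import annotations

import zlib

import numpy as np

# Nucleotide integer encoding used throughout the simulators and callers.
BASES = "ACGT"
BASE_TO_INT = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES = set("ACGTURYSWKMBDHVN")
ALIGNMENT_CHARS = IUPAC_CODES | {"-"}

# Unordered base pair -> IUPAC ambiguity code (heterozygote calls).
PAIR_TO_IUPAC = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for a pipeline stage.

    Streams are derived from ``(master_seed, crc32(stage))`` so that running
    stages in a different order, or skipping one, never changes another
    stage's draws.
    """
    if master_seed < 0:
        raise ValueError("master_seed must be >= 0")
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return np.random.default_rng(ss)


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode an ACGT string as an int8 array (non-ACGT mapped to -1)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_TO_INT.items():
        out[arr == ord(base)] = code
    return out


def ints_to_seq(arr: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lookup[arr].tobytes().decode()


def validate_sequence(seq: str, *, allow_gaps: bool = False, name: str = "") -> None:
    """Raise ValueError naming the first offending character position."""
    allowed = ALIGNMENT_CHARS if allow_gaps else IUPAC_CODES
    for pos, ch in enumerate(seq):
        if ch.upper() not in allowed:
            where = f" in record '{name}'" if name else ""
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {pos + 1}{where}"
            )
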