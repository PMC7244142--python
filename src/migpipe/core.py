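"""Domain containers shared across pipeline stages.

The pipeline moves four kinds of object between stages: sequencing reads
(:class:`Read` / :class:`ReadSet`), per-specimen metadata
(:class:`SampleRecord`), assembled orthologous loci
(:class:`LocusAlignment`) and phylogenies (``dendropy.Tree``, handled in
:mod:`migpipe.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

PRESERVATION_TYPES = ("herbarium", "silica")

ZONE_VOCAB = {
    "zones2": ("continent", "island"),
    "zones4": ("I", "II", "III", "IV"),
    "zones6": ("I", "II", "IIIa", "IIIb", "IIIc", "IV"),
}


@dataclass
class Read:
    """One sequencing read with Sanger-scaled Phred qualities."""

    name: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.name}: sequence/quality length mismatch")


@dataclass
class ReadSet:
    """Reads belonging to one sample."""

    sample_id: str
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class SampleRecord:
    """Per-specimen metadata row.

    ``zones`` maps a configuration name (``zones2``/``zones4``/``zones6``)
    to the frozenset of zone labels the species occurs in. A species
    spanning several zones in a configuration carries them all; a missing
    assignment is an empty set and the record is excluded from zone
    analyses (with a warning at read time).
    """

    sample_id: str
    species: str
    preservation: str
    collection_year: int
    zones: dict[str, frozenset[str]] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.preservation not in PRESERVATION_TYPES:
            raise ValueError(
                f"sample {self.sample_id}: unknown preservation "
                f"{self.preservation!r} (expected one of {PRESERVATION_TYPES})"
            )
        for config, labels in self.zones.items():
            vocab = ZONE_VOCAB.get(config)
            if vocab is None:
                raise ValueError(f"unknown zone configuration {config!r}")
            bad = set(labels) - set(vocab)
            if bad:
                raise ValueError(
                    f"sample {self.sample_id}: zone labels {sorted(bad)} "
                    f"not in {config} vocabulary {vocab}"
                )

    @property
    def is_herbarium(self) -> bool:
        return self.preservation == "herbarium"

    def age_years(self, reference_year: int = 2020) -> int:
        return reference_year - self.collection_year


@dataclass
class LocusAlignment:
    """One orthologous locus: aligned per-sample consensus sequences."""

    locus_id: str
    sequences: dict[str, str]  # sample_id -> aligned sequence (equal length)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"locus {self.locus_id}: unequal sequence lengths")

    @property
    def n_samples(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def samples(self) -> list[str]:
        return sorted(self.sequences)
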