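"""Readers and writers for the on-disk formats the pipeline exchanges.

FASTA/FASTQ go through Biopython, trees through dendropy; the tabular
formats (metadata TSV, BED, GFF3, chromosome sizes) through pandas. All
writers are deterministic: identical inputs give byte-identical output.
Coordinates are converted at the boundary: BED is 0-based half-open,
GFF3 1-based closed; internally everything is 0-based half-open.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import validate_sequence
from .core import ZONE_VOCAB, LocusAlignment, Read, ReadSet, SampleRecord

METADATA_COLUMNS = [
    "sample_id",
    "species",
    "preservation",
    "collection_year",
    "zone2",
    "zone4",
    "zone6",
]

FEATURE_CLASSES = ("CDS", "TE", "UTR5", "UTR3")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, sequence), ...]`` in file order.

    Raises ``ValueError`` on duplicate identifiers (naming the duplicate),
    on empty sequences, and on non-IUPAC characters (with position).
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        validate_sequence(seq, allow_gaps=True, name=rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_locus_fasta(path: str | Path) -> LocusAlignment:
    """Read one locus alignment file (record ids are sample ids)."""
    records = read_fasta(path)
    return LocusAlignment(Path(path).stem, dict(records))


def write_locus_fasta(path: str | Path, locus: LocusAlignment) -> None:
    write_fasta(path, [(s, locus.sequences[s]) for s in locus.samples()])


def read_fastq(path: str | Path, sample_id: str | None = None) -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
        )
    return ReadSet(sample_id or Path(path).stem, reads)


def write_fastq(path: str | Path, readset: ReadSet) -> None:
    with open(path, "w") as fh:
        for r in readset.reads:
            rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(text_or_path: str | Path) -> dendropy.Tree:
    """Parse Newick into a dendropy tree.

    Internal node labels are interpreted as support values. Malformed input
    (unbalanced parentheses, duplicate tip labels) raises ``ValueError``.
    """
    text = str(text_or_path)
    if "(" not in text:  # looks like a path, not newick
        text = Path(text_or_path).read_text()
    if text.count("(") != text.count(")"):
        raise ValueError(
            f"unbalanced parentheses in Newick (offset {_paren_offset(text)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels in Newick: {sorted(dupes)}")
    for node in tree.internal_nodes():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def _paren_offset(text: str) -> int:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    return len(text)


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at full precision (%.12g)."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g",
        ).strip()
        + "\n"
    )


# ---------------------------------------------------------------------------
# Sample metadata TSV


def _parse_zone_field(value, config: str, sample_id: str) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    labels = frozenset(str(value).split("+"))
    vocab = ZONE_VOCAB[config]
    bad = labels - set(vocab)
    if bad:
        raise ValueError(
            f"sample {sample_id}: zone label(s) {sorted(bad)} not in {config} "
            f"vocabulary {vocab}"
        )
    return labels


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV.

    Required columns: sample_id, species, preservation, collection_year,
    zone2, zone4, zone6. Multi-zone species list labels joined by '+'
    (e.g. ``continent+island``). A missing zone code leaves that
    configuration's set empty; the record is excluded from zone analyses
    and a warning is emitted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        zones = {
            "zones2": _parse_zone_field(row["zone2"], "zones2", row["sample_id"]),
            "zones4": _parse_zone_field(row["zone4"], "zones4", row["sample_id"]),
            "zones6": _parse_zone_field(row["zone6"], "zones6", row["sample_id"]),
        }
        empty = [k for k, v in zones.items() if not v]
        if empty:
            warnings.warn(
                f"sample {row['sample_id']}: missing zone code for {empty}; "
                "excluded from those zone analyses",
                stacklevel=2,
            )
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                species=row["species"],
                preservation=row["preservation"],
                collection_year=int(row["collection_year"]),
                zones=zones,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s) in metadata: {dupes}")
    return records


def write_metadata(path: str | Path, records: list[SampleRecord]) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "species": r.species,
                "preservation": r.preservation,
                "collection_year": r.collection_year,
                "zone2": "+".join(sorted(r.zones.get("zones2", ()))),
                "zone4": "+".join(sorted(r.zones.get("zones4", ()))),
                "zone6": "+".join(sorted(r.zones.get("zones6", ()))),
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intervals: BED, GFF3, chromosome sizes


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file: columns chrom, start, end (0-based half-open), name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} has fewer than 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0],
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "name": df[3] if df.shape[1] > 3 else [f"iv{i}" for i in range(len(df))],
        }
    )
    bad = out[out.start >= out.end]
    if len(bad):
        raise ValueError(
            f"BED file {path}: start >= end at line {bad.index[0] + 1}"
        )
    return out


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path: str | Path, feature_classes=FEATURE_CLASSES) -> pd.DataFrame:
    """Read GFF3 features into 0-based half-open intervals.

    The GFF3 ``type`` column is mapped to the feature classes used in the
    genome-context analysis: CDS, TE (types containing 'transposable' or
    'TE'), UTR5 ('five_prime_UTR'), UTR3 ('three_prime_UTR'). Other types
    are dropped.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
        dtype=str,
    )
    type_map = {
        "CDS": "CDS",
        "five_prime_UTR": "UTR5",
        "three_prime_UTR": "UTR3",
        "transposable_element": "TE",
        "TE": "TE",
    }
    df["feature_class"] = df["type"].map(type_map)
    df = df.dropna(subset=["feature_class"])
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].astype(int).to_numpy() - 1,  # to 0-based
            "end": df["end"].astype(int).to_numpy(),
            "feature_class": df["feature_class"].to_numpy(),
        }
    )
    out = out[out["feature_class"].isin(feature_classes)].reset_index(drop=True)
    if (out.start < 0).any() or (out.start >= out.end).any():
        raise ValueError(f"GFF3 file {path}: invalid coordinates after conversion")
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype=str)
    sizes = {row.chrom: int(row.size) for row in df.itertuples()}
    if any(v <= 0 for v in sizes.values()):
        raise ValueError(f"non-positive chromosome size in {path}")
    return sizes


# ---------------------------------------------------------------------------
# JSON stage reports


def write_json_report(path: str | Path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, sort_keys=True, indent=2)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
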