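"""Readers and writers for the formats the toolkit consumes and produces.

Genomic coordinates follow the BED convention everywhere at I/O boundaries:
0-based, half-open intervals.  Dyad-relative pattern coordinates (signed
integers centred on the nucleosome dyad) appear only inside pattern tables
and are documented in :mod:`npskit.pattern_core`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_STRANDS = frozenset({"+", "-", "."})
SEQUENCE_ALPHABET = frozenset("ACGTN")

PATTERN_TABLE_COLUMNS = ("condition", "label", "position", "frequency")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Coordinate of the 5' end (last base for minus-strand intervals)."""
        return self.start if self.strand in ("+", ".") else self.end - 1

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class SequenceSet:
    """A set of equal-length DNA sequences aligned by their 5' ends."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if not self.sequences:
            raise ValueError("empty sequence set")
        widths = {len(s) for s in self.sequences}
        if len(widths) != 1:
            raise ValueError(
                f"sequences are not uniform in width (lengths seen: {sorted(widths)})"
            )
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - SEQUENCE_ALPHABET
            if bad:
                raise ValueError(
                    f"record {sid!r} contains invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def width(self) -> int:
        return len(self.sequences[0])


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a multi-record FASTA of uniform-width sequences.

    Sequences are uppercased; `N` is allowed.  Raises ``ValueError`` for an
    empty file, an empty record, invalid characters (naming the record), or
    non-uniform sequence lengths.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"malformed FASTA: record {record.id!r} is empty")
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"malformed FASTA: record {record.id!r} contains {sorted(bad)}"
            )
        ids.append(record.id)
        seqs.append(seq)
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(tuple(ids), tuple(seqs))


def write_fasta(seqset: SequenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(seqset.ids, seqset.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed_reads(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file of aligned reads into genomic intervals.

    Lines with ``start >= end`` or malformed fields are rejected with the
    offending line number.  ``track``/``browser`` lines and comments are
    skipped.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[int | float] | None = None,
) -> None:
    """Write intervals as BED6 (name/score default to ``.``/0)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph into a frame (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
    df = df.astype({"start": int, "end": int, "value": float})
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: empty interval on data row {bad}")
    return df.reset_index(drop=True)


def write_bedgraph(chrom: str, start: int, values: np.ndarray, path: str | Path) -> None:
    """Write a per-base value vector as a run-length-collapsed bedGraph."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(values)) + 1
        edges = np.concatenate(([0], boundaries, [values.size]))
        for a, b in zip(edges[:-1], edges[1:]):
            v = values[a]
            fh.write(f"{chrom}\t{start + a}\t{start + b}\t{v:g}\n")


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS table TSV with columns chrom, tss, strand, gene_id.

    The TSS coordinate is 0-based (the first transcribed base).
    """
    df = pd.read_csv(path, sep="\t")
    rename = {"tss_position": "tss", "position": "tss", "gene": "gene_id"}
    df = df.rename(columns=rename)
    required = {"chrom", "tss", "strand", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    df = df.astype({"tss": int})
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError("TSS strand must be '+' or '-'")
    return df[["chrom", "tss", "strand", "gene_id"]]


class PatternTable:
    """Long-format table of positional patterns: one frequency per
    (condition, label, dyad-relative position).

    Invariants enforced on construction: (condition, label, position) keys
    unique; positions form a contiguous integer range per (condition, label).
    """

    def __init__(self, frame: pd.DataFrame, meta: dict | None = None):
        missing = set(PATTERN_TABLE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"pattern table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(PATTERN_TABLE_COLUMNS)].copy()
        frame["position"] = frame["position"].astype(int)
        frame["frequency"] = frame["frequency"].astype(float)
        dup = frame.duplicated(subset=["condition", "label", "position"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValueError(
                "duplicate pattern entry for "
                f"({row['condition']}, {row['label']}, {row['position']})"
            )
        for (cond, label), grp in frame.groupby(["condition", "label"], sort=False):
            pos = np.sort(grp["position"].to_numpy())
            if not np.array_equal(pos, np.arange(pos[0], pos[0] + pos.size)):
                raise ValueError(
                    f"positions for ({cond}, {label}) are not contiguous"
                )
        self._frame = frame.sort_values(
            ["condition", "label", "position"], kind="stable"
        ).reset_index(drop=True)
        self.meta = dict(meta or {})

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self._frame["condition"]))

    def labels(self, condition: str | None = None) -> list[str]:
        frame = self._frame
        if condition is not None:
            frame = frame[frame["condition"] == condition]
        return list(dict.fromkeys(frame["label"]))

    def get(self, condition: str, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (positions, frequencies) for one condition/label, sorted."""
        sel = self._frame[
            (self._frame["condition"] == condition) & (self._frame["label"] == label)
        ]
        if sel.empty:
            raise KeyError(f"no pattern for ({condition}, {label})")
        return sel["position"].to_numpy(), sel["frequency"].to_numpy()

    def equals(self, other: "PatternTable", tol: float = 1e-9) -> bool:
        a, b = self._frame, other._frame
        if len(a) != len(b):
            return False
        keys = ["condition", "label", "position"]
        if not a[keys].reset_index(drop=True).equals(b[keys].reset_index(drop=True)):
            return False
        return bool(
            np.all(np.abs(a["frequency"].to_numpy() - b["frequency"].to_numpy()) <= tol)
        )

    def __len__(self) -> int:
        return len(self._frame)


def read_pattern_table(path: str | Path) -> PatternTable:
    """Read a tab-separated pattern table (header required)."""
    frame = pd.read_csv(path, sep="\t")
    return PatternTable(frame)


def write_pattern_table(table: PatternTable, path: str | Path) -> None:
    """Write a pattern table as TSV; round-trips within 1e-9 per frequency."""
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
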