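"""Classification of individual sequences by reference NPS patterns.

Each sequence is converted into 16 binary occurrence strings (one per
dinucleotide).  Every string with more than 12 occurrences is slid against
every reference pattern in a 146 bp window, and the single maximal positive
Pearson correlation over all (dinucleotide, reference, offset) triples
labels the sequence with that reference's class (WW1/WW2/SS1/SS2/RR1/RR2/
YY1/YY2).  Exact ties are resolved uniformly at random under a recorded
seed; sequences with no eligible string or no positive correlation are
"unassigned".
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import GenomicInterval, SequenceSet
from .pattern_core import DINUCLEOTIDES, PositionalPattern, _dinucleotide_codes

CLASS_LABELS = ("WW1", "WW2", "SS1", "SS2", "RR1", "RR2", "YY1", "YY2")

_TIE_TOL = 1e-12


@dataclass
class PatternLibrary:
    """Reference patterns, one per class label, all of equal window width."""

    entries: dict[str, PositionalPattern]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty pattern library")
        widths = {len(p) for p in self.entries.values()}
        if len(widths) != 1:
            raise ValueError("library patterns differ in width")

    @property
    def width(self) -> int:
        return len(next(iter(self.entries.values())))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PatternAssignment:
    """Best-matching pattern class for one sequence."""

    sequence_id: str
    class_label: str  # one of the library labels or "unassigned"
    best_dinucleotide: str | None
    offset: int | None
    correlation: float | None
    seed_used: int

    @property
    def assigned(self) -> bool:
        return self.class_label != "unassigned"


def binary_strings(seq: str) -> dict[str, np.ndarray]:
    """16 binary occurrence vectors of a sequence (positions ``1..len-1``).

    Vector ``d`` has 1 at (0-based) index ``i`` iff bases ``(i, i+1)`` are
    exactly ``d``; any dinucleotide touching an N is 0 in all 16 vectors.
    """
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 bp")
    seqset = SequenceSet(("x",), (seq.upper(),))
    from .pattern_core import encode_sequences

    codes = _dinucleotide_codes(encode_sequences(seqset))[0]
    return {
        d: (codes == k).astype(np.uint8) for k, d in enumerate(DINUCLEOTIDES)
    }


def sliding_correlation(
    binary_vector: np.ndarray,
    pattern: PositionalPattern | np.ndarray,
    window: int = 146,
) -> np.ndarray:
    """Pearson correlation of a reference pattern against every placement of
    a 146 bp window on a binary occurrence vector.

    Returns one value per window start offset; offsets where the binary
    sub-vector is constant are NaN (Pearson undefined, skipped).
    """
    freq = pattern.freq if isinstance(pattern, PositionalPattern) else np.asarray(pattern)
    npos = window - 1
    if freq.size != npos:
        raise ValueError(
            f"pattern has {freq.size} positions, expected {npos} for a "
            f"{window} bp window"
        )
    vec = np.asarray(binary_vector, dtype=float)
    if vec.size < npos:
        raise ValueError(
            f"binary vector of length {vec.size} is shorter than {npos}"
        )
    windows = sliding_window_view(vec, npos)
    p = freq - freq.mean()
    sp = freq.std()
    mw = windows.mean(axis=1)
    sw = windows.std(axis=1)
    cov = windows @ p / npos
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sw * sp)
    r[sw == 0] = np.nan
    if sp == 0:
        r[:] = np.nan
    return r


def _sequence_rng(seed: int, sequence_id: str) -> np.random.Generator:
    # Keyed on (seed, id) so assignment is invariant to sequence order.
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sequence_id.encode())])
    )


def assign_pattern(
    seq: str,
    library: PatternLibrary,
    min_occurrences: int = 12,
    seed: int = 0,
    sequence_id: str = "",
) -> PatternAssignment:
    """Assign one sequence to its best-correlating library pattern class.

    Only binary strings with more than ``min_occurrences`` occurrences of
    their dinucleotide are considered.  The strictly maximal positive
    correlation over all (dinucleotide, library entry, offset) triples
    wins; ties within 1e-12 are broken uniformly at random by a generator
    keyed on ``(seed, sequence_id)``.
    """
    if len(seq) < 147:
        raise ValueError("sequence shorter than 147 bp cannot be mapped")
    vectors = binary_strings(seq)
    candidates: list[tuple[float, str, str, int]] = []
    best_r = 0.0
    for dinuc, vec in vectors.items():
        if int(vec.sum()) <= min_occurrences:
            continue
        for label, pattern in library.entries.items():
            r = sliding_correlation(vec, pattern, window=library.width + 1)
            finite = np.isfinite(r)
            if not finite.any():
                continue
            rmax = np.nanmax(r)
            if rmax <= 0 or rmax < best_r - _TIE_TOL:
                continue
            for o in np.flatnonzero(finite & (r >= rmax - _TIE_TOL)):
                candidates.append((float(r[o]), label, dinuc, int(o)))
            best_r = max(best_r, float(rmax))
    candidates = [c for c in candidates if c[0] >= best_r - _TIE_TOL]
    if not candidates:
        return PatternAssignment(sequence_id, "unassigned", None, None, None, seed)
    candidates.sort(key=lambda c: (c[1], c[2], c[3]))
    if len(candidates) == 1:
        r, label, dinuc, offset = candidates[0]
    else:
        rng = _sequence_rng(seed, sequence_id)
        r, label, dinuc, offset = candidates[int(rng.integers(len(candidates)))]
    return PatternAssignment(sequence_id, label, dinuc, offset, r, seed)


def assign_all(
    seqset: SequenceSet,
    library: PatternLibrary,
    min_occurrences: int = 12,
    seed: int = 0,
) -> list[PatternAssignment]:
    return [
        assign_pattern(
            seq, library, min_occurrences=min_occurrences, seed=seed, sequence_id=sid
        )
        for sid, seq in zip(seqset.ids, seqset.sequences)
    ]


def _largest_remainder_percent(counts: np.ndarray, decimals: int = 2) -> np.ndarray:
    """Percentages rounded to ``decimals`` that sum exactly to 100."""
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts, dtype=float)
    scale = 10**decimals
    raw = counts / total * 100 * scale
    floors = np.floor(raw)
    shortfall = int(round(100 * scale - floors.sum()))
    order = np.argsort(-(raw - floors), kind="stable")
    floors[order[:shortfall]] += 1
    return floors / scale


def proportion_table(
    assignments: Sequence[PatternAssignment],
    groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group percentage and count tables of assigned pattern classes.

    ``groups`` maps sequence id to group name (e.g. promoter / gene body /
    random).  Percentages are over assigned sequences only and are rounded
    to 2 decimals with a largest-remainder correction so each row sums to
    exactly 100; unassigned sequences appear as a count column.  Empty
    groups are omitted with a warning.
    """
    class_labels = sorted(
        {a.class_label for a in assignments if a.assigned}
    ) or list(CLASS_LABELS)
    group_names = list(dict.fromkeys(groups.values()))
    pct_rows, cnt_rows, kept = [], [], []
    for g in group_names:
        members = [a for a in assignments if groups.get(a.sequence_id) == g]
        if not members:
            warnings.warn(f"group {g!r} has no sequences; omitted")
            continue
        counts = np.array(
            [sum(a.class_label == c for a in members) for c in class_labels],
            dtype=float,
        )
        unassigned = sum(not a.assigned for a in members)
        pct_rows.append(_largest_remainder_percent(counts))
        cnt_rows.append(list(counts.astype(int)) + [unassigned])
        kept.append(g)
    pct = pd.DataFrame(pct_rows, index=kept, columns=class_labels)
    pct["Total"] = pct.sum(axis=1)
    cnt = pd.DataFrame(cnt_rows, index=kept, columns=class_labels + ["unassigned"])
    return pct, cnt


def event_windows(
    events: Iterable[tuple[str, int, str]],
    up: int = 20,
    down: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Sequence windows around single-bp occupancy-change events.

    Each event ``(chrom, position, strand)`` yields the interval from
    ``up`` bp upstream through ``down`` bp downstream of the event base
    (221 bp by default), mirrored on the minus strand.  Windows are clipped
    at contig bounds with a warning.
    """
    out: list[GenomicInterval] = []
    for chrom, pos, strand in events:
        if strand == "-":
            start, end = pos - down, pos + up + 1
        else:
            start, end = pos - up, pos + down + 1
        if start < 0:
            warnings.warn(f"event window at {chrom}:{pos} clipped at contig start")
            start = 0
        if chrom_sizes is not None and end > chrom_sizes[chrom]:
            warnings.warn(f"event window at {chrom}:{pos} clipped at contig end")
            end = chrom_sizes[chrom]
        out.append(GenomicInterval(chrom, start, end, strand))
    return out


def library_from_table(table, class_to_condition_label: Mapping[str, tuple[str, str]]):
    """Build a library from a pattern table.

    ``class_to_condition_label`` maps each class label to the (condition,
    label) pair in the table supplying its reference pattern.
    """
    from .pattern_core import pattern_from_table

    entries = {
        cls: pattern_from_table(table, cond, lab)
        for cls, (cond, lab) in class_to_condition_label.items()
    }
    return PatternLibrary(entries)


def default_library() -> PatternLibrary:
    """Default 8-class library built from the packaged synthetic condition
    fixtures: class 1 from the human CD4+-like condition, class 2 from the
    apoptotic-like (phase-flipped) condition."""
    from .simulate import load_fixture_patterns

    cd4 = load_fixture_patterns("human_cd4")
    apo = load_fixture_patterns("human_apoptotic")
    from .pattern_core import pattern_from_table

    entries: dict[str, PositionalPattern] = {}
    for comp in ("WW", "SS", "RR", "YY"):
        entries[comp + "1"] = pattern_from_table(cd4, "human_cd4", comp)
        entries[comp + "2"] = pattern_from_table(apo, "human_apoptotic", comp)
    return PatternLibrary(entries)
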