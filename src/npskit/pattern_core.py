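"""Positional dinucleotide frequency patterns of nucleosomal DNA.

The central objects are *positional patterns*: for a batch of aligned
nucleosomal DNA sequences, the frequency of a given dinucleotide at every
position along the alignment.  In nucleosome-bound DNA these frequencies
oscillate with the double-helix period (~10 bp) and are two-fold
pseudo-symmetric about the dyad, the central base pair of the wrapped DNA.
This module computes raw patterns, localizes the dyad by forward versus
reverse-complement strand correlation, symmetrizes patterns about the dyad,
forms composite WW/SS (weak/strong) and RR/YY (purine/pyrimidine) patterns,
and measures their periodicity with an FFT periodogram.

Coordinate conventions
----------------------
A dinucleotide is addressed by the 1-based index ``i`` of its 5' base, so a
width-``W`` sequence has dinucleotide positions ``1 .. W-1``.  A nucleosome
window is 146 bp wide (145 dinucleotide positions); within a window placed
at start offset ``o`` the dyad-relative coordinate of position ``i`` is
``c = i - (o + 73)``, giving ``c in -72 .. +72`` and mirror ``m(c) = -c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .io_formats import PatternTable, SequenceSet

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

#: Composite class membership.  W = A/T (weak), S = C/G (strong),
#: R = A/G (purine), Y = C/T (pyrimidine).
COMPOSITE_MEMBERS: dict[str, tuple[str, ...]] = {
    "WW": ("AA", "AT", "TA", "TT"),
    "SS": ("CC", "CG", "GC", "GG"),
    "RR": ("AA", "AG", "GA", "GG"),
    "YY": ("CC", "CT", "TC", "TT"),
}

DEFAULT_WINDOW = 146  # bp spanned by the pattern window
DYAD_INDEX = 73  # 1-based dinucleotide position of the dyad within the window

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def revcomp_dinucleotide(dinuc: str) -> str:
    return COMPLEMENT[dinuc[1]] + COMPLEMENT[dinuc[0]]


@dataclass
class PositionalPattern:
    """Per-position frequency of one dinucleotide or composite class.

    ``coords`` are contiguous integers: absolute positions ``1..W-1`` for a
    raw full-width pattern, or dyad-relative coordinates after windowing.
    """

    label: str
    coords: np.ndarray
    freq: np.ndarray
    condition: str = ""
    n_sequences: int | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.coords.shape != self.freq.shape:
            raise ValueError("coords and freq differ in shape")
        if self.coords.size == 0:
            raise ValueError("empty pattern")
        if not np.array_equal(
            self.coords, np.arange(self.coords[0], self.coords[0] + self.coords.size)
        ):
            raise ValueError("pattern coordinates must be contiguous integers")

    def __len__(self) -> int:
        return self.coords.size


@dataclass
class OccurrenceMatrix:
    """Binary occurrence matrix of one dinucleotide.

    ``matrix[s, i]`` is 1.0 if the dinucleotide occupies bases ``(i+1, i+2)``
    (1-based) of sequence ``s``, 0.0 otherwise, and NaN where an N base
    intrudes (missing observation).
    """

    dinucleotide: str
    matrix: np.ndarray

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[1]


@dataclass
class DyadScan:
    """Result of the strand-symmetry sliding-correlation dyad search."""

    offsets: np.ndarray
    correlations: dict[str, np.ndarray]
    argmax: dict[str, int]
    max_correlation: dict[str, float]
    consensus_offset: int
    needs_review: bool


def encode_sequences(seqset: SequenceSet) -> np.ndarray:
    """Encode sequences as an int8 matrix, A..T -> 0..3, N -> -1."""
    buf = np.frombuffer(
        "".join(seqset.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqset), seqset.width)
    return _ENCODE[buf]


def _dinucleotide_codes(encoded: np.ndarray) -> np.ndarray:
    """Per-position dinucleotide code 0..15; -1 where an N intrudes."""
    a, b = encoded[:, :-1], encoded[:, 1:]
    codes = 4 * a + b
    codes[(a < 0) | (b < 0)] = -1
    return codes


def occurrence_matrix(seqset: SequenceSet, dinucleotide: str) -> OccurrenceMatrix:
    """Binary occurrence matrix of ``dinucleotide`` over a uniform-width set."""
    if dinucleotide not in DINUCLEOTIDES:
        raise ValueError(f"not a dinucleotide over ACGT: {dinucleotide!r}")
    if seqset.width < 2:
        raise ValueError("sequences must be at least 2 bp wide")
    codes = _dinucleotide_codes(encode_sequences(seqset))
    code = DINUCLEOTIDES.index(dinucleotide)
    mat = (codes == code).astype(float)
    mat[codes < 0] = np.nan
    return OccurrenceMatrix(dinucleotide, mat)


def positional_frequency(
    occ: OccurrenceMatrix, condition: str = ""
) -> PositionalPattern:
    """Column means of an occurrence matrix over non-missing entries.

    A column with no observations (all N) yields NaN frequency.
    """
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nanmean(occ.matrix, axis=0)
    coords = np.arange(1, occ.n_positions + 1)
    return PositionalPattern(
        occ.dinucleotide,
        coords,
        freq,
        condition=condition,
        n_sequences=occ.n_sequences,
        state="raw",
    )


def pattern_set(
    seqset: SequenceSet, condition: str = ""
) -> dict[str, PositionalPattern]:
    """All 16 raw dinucleotide patterns of a sequence set (one pass)."""
    if seqset.width < 2:
        raise ValueError("sequences must be at least 2 bp wide")
    codes = _dinucleotide_codes(encode_sequences(seqset))
    observed = (codes >= 0).sum(axis=0).astype(float)
    observed[observed == 0] = np.nan
    coords = np.arange(1, seqset.width)
    out: dict[str, PositionalPattern] = {}
    for code, dinuc in enumerate(DINUCLEOTIDES):
        counts = (codes == code).sum(axis=0)
        out[dinuc] = PositionalPattern(
            dinuc,
            coords,
            counts / observed,
            condition=condition,
            n_sequences=len(seqset),
            state="raw",
        )
    return out


def _require_full_set(pset: Mapping[str, PositionalPattern]) -> None:
    missing = [d for d in DINUCLEOTIDES if d not in pset]
    if missing:
        raise ValueError(f"incomplete pattern set; missing {missing}")
    widths = {len(p) for p in pset.values()}
    if len(widths) != 1:
        raise ValueError("patterns in the set differ in width")


def reverse_strand_pattern(
    pset: Mapping[str, PositionalPattern]
) -> dict[str, PositionalPattern]:
    """Patterns as seen from the reverse-complementary strand.

    For a width-``W`` alignment, ``f_rev(d, i) = f(rc(d), W - i)`` with
    1-based dinucleotide positions ``i`` in ``1 .. W-1``; equivalently each
    reverse-complement partner's profile is reversed in place.
    """
    _require_full_set(pset)
    out: dict[str, PositionalPattern] = {}
    for dinuc in DINUCLEOTIDES:
        src = pset[revcomp_dinucleotide(dinuc)]
        out[dinuc] = replace(
            src, label=dinuc, coords=src.coords.copy(), freq=src.freq[::-1].copy()
        )
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN if undefined (constant input or <2 pairs)."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def locate_dyad(
    seqset: SequenceSet, window: int = DEFAULT_WINDOW
) -> DyadScan:
    """Localize the dyad by sliding strand-symmetry correlation.

    At every window start offset, each dinucleotide's forward profile within
    the window is correlated (Pearson) with the reverse-complement strand
    profile of the same window.  At the true dyad-centred placement the two
    strands agree and the correlation is maximal.  The consensus offset is
    the correlation-weighted median of the per-dinucleotide argmax offsets
    (only dinucleotides with a positive maximum contribute).  The result is
    flagged ``needs_review`` when fewer than 4 dinucleotides contribute or
    any contributing argmax disagrees with the consensus by more than 5 bp
    -- dyad localization is not always clear-cut and deserves inspection.
    """
    if seqset.width < window:
        raise ValueError(
            f"sequence width {seqset.width} is smaller than the window {window}"
        )
    pset = pattern_set(seqset)
    npos = window - 1
    offsets = np.arange(seqset.width - window + 1)
    correlations: dict[str, np.ndarray] = {}
    argmax: dict[str, int] = {}
    maxcorr: dict[str, float] = {}
    for dinuc in DINUCLEOTIDES:
        fwd_full = pset[dinuc].freq
        rc_full = pset[revcomp_dinucleotide(dinuc)].freq
        cc = np.full(offsets.size, np.nan)
        for k, o in enumerate(offsets):
            fwd = fwd_full[o : o + npos]
            rev = rc_full[o : o + npos][::-1]
            cc[k] = _pearson(fwd, rev)
        correlations[dinuc] = cc
        if np.all(np.isnan(cc)):
            continue
        best = int(np.nanargmax(cc))
        argmax[dinuc] = int(offsets[best])
        maxcorr[dinuc] = float(cc[best])
    if not argmax:
        raise ValueError("no offset with a computable strand-symmetry correlation")
    contrib = [d for d, r in maxcorr.items() if r > 0]
    if contrib:
        values = np.array([argmax[d] for d in contrib], dtype=float)
        weights = np.array([maxcorr[d] for d in contrib])
        consensus = int(round(_weighted_median(values, weights)))
    else:
        consensus = int(min(argmax.values()))
    needs_review = len(contrib) < 4 or any(
        abs(argmax[d] - consensus) > 5 for d in contrib
    )
    return DyadScan(offsets, correlations, argmax, maxcorr, consensus, needs_review)


def symmetrize(
    pset: Mapping[str, PositionalPattern],
    dyad_offset: int | None = None,
    window: int = DEFAULT_WINDOW,
) -> dict[str, PositionalPattern]:
    """Symmetrize a full dinucleotide pattern set about the dyad.

    With ``dyad_offset`` given, the window starting at that offset is first
    extracted from full-width raw patterns and assigned dyad-relative
    coordinates ``c = i - (dyad_offset + 73)``.  With ``dyad_offset=None``
    the patterns must already be on coordinates symmetric about 0.  Then

        f_sym(d, c) = ( f(d, c) + f(rc(d), -c) ) / 2

    which makes every pattern satisfy the two-fold dyad symmetry
    ``f_sym(d, c) = f_sym(rc(d), -c)`` exactly.  Idempotent.
    """
    _require_full_set(pset)
    windowed: dict[str, PositionalPattern] = {}
    if dyad_offset is not None:
        half = window // 2
        npos = window - 1
        for dinuc, pat in pset.items():
            start_pos = dyad_offset + 1  # 1-based first dinucleotide of the window
            idx0 = np.searchsorted(pat.coords, start_pos)
            if (
                idx0 >= len(pat)
                or pat.coords[idx0] != start_pos
                or idx0 + npos > len(pat)
            ):
                raise ValueError(
                    f"window at offset {dyad_offset} does not fit pattern {dinuc}"
                )
            coords = np.arange(-(half - 1), half)
            windowed[dinuc] = replace(
                pat, coords=coords, freq=pat.freq[idx0 : idx0 + npos].copy()
            )
    else:
        for dinuc, pat in pset.items():
            if pat.coords[0] != -pat.coords[-1]:
                raise ValueError(
                    "pattern coordinates are not symmetric about 0; "
                    "pass dyad_offset to extract a dyad-centred window"
                )
            windowed[dinuc] = replace(pat, coords=pat.coords.copy(), freq=pat.freq.copy())
    out: dict[str, PositionalPattern] = {}
    for dinuc, pat in windowed.items():
        partner = windowed[revcomp_dinucleotide(dinuc)]
        out[dinuc] = replace(
            pat, freq=0.5 * (pat.freq + partner.freq[::-1]), state="symmetrized"
        )
    return out


def composite_pattern(
    pset: Mapping[str, PositionalPattern], composite: str
) -> PositionalPattern:
    """Position-wise sum of a composite class's four member patterns."""
    if composite not in COMPOSITE_MEMBERS:
        raise ValueError(f"unknown composite class {composite!r}")
    members = COMPOSITE_MEMBERS[composite]
    missing = [d for d in members if d not in pset]
    if missing:
        raise ValueError(f"composite {composite} missing member patterns {missing}")
    base = pset[members[0]]
    freq = np.zeros_like(base.freq)
    for d in members:
        if not np.array_equal(pset[d].coords, base.coords):
            raise ValueError("member patterns are on different coordinates")
        freq = freq + pset[d].freq
    return replace(base, label=composite, coords=base.coords.copy(), freq=freq)


def normalize_pattern(pattern: PositionalPattern) -> PositionalPattern:
    """Z-transform a pattern (mean 0, SD 1; all zeros if constant)."""
    freq = pattern.freq
    ok = ~np.isnan(freq)
    mu = freq[ok].mean()
    sd = freq[ok].std()
    constant = np.ptp(freq[ok]) == 0  # exactly flat, not merely tiny-variance
    out = np.zeros_like(freq) if constant else (freq - mu) / sd
    out = np.where(ok, out, np.nan)
    return replace(pattern, coords=pattern.coords.copy(), freq=out, state="normalized")


def smooth_pattern(pattern: PositionalPattern, window: int = 3) -> PositionalPattern:
    """Centred moving average; edges average over available positions only."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(pattern) < window:
        raise ValueError("pattern shorter than the smoothing window")
    half = window // 2
    freq = pattern.freq
    out = np.empty_like(freq)
    for i in range(freq.size):
        lo, hi = max(0, i - half), min(freq.size, i + half + 1)
        out[i] = np.nanmean(freq[lo:hi])
    return replace(pattern, coords=pattern.coords.copy(), freq=out, state="smoothed")


def periodogram(
    pattern: PositionalPattern,
    period_range: tuple[float, float] = (5.0, 20.0),
    n_pad: int = 2048,
) -> tuple[np.ndarray, np.ndarray, float]:
    """FFT periodogram of a positional pattern.

    The mean-subtracted frequency vector is zero-padded to at least
    ``n_pad`` points (default 2048, giving ~0.05 bp period resolution near
    10 bp) and the squared magnitude of its DFT is reported.  Returns
    ``(periods, power, dominant_period)`` where the dominant period is the
    reciprocal frequency of maximal power within ``period_range``.

    Raises ``ValueError`` for patterns shorter than 16 positions or with no
    power in the range (constant input).
    """
    if len(pattern) < 16:
        raise ValueError("pattern too short for a periodogram (< 16 positions)")
    x = pattern.freq.astype(float)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    x = x - x.mean()
    n = max(n_pad, x.size)
    spec = np.fft.rfft(x, n=n)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        periods = 1.0 / freqs
    lo, hi = period_range
    in_range = (periods >= lo) & (periods <= hi)
    if not np.any(in_range) or np.all(power[in_range] == 0):
        raise ValueError("no spectral power within the period range")
    k = np.flatnonzero(in_range)[np.argmax(power[in_range])]
    return periods[in_range], power[in_range], float(periods[k])


def table_from_patterns(patterns: Iterable[PositionalPattern]) -> PatternTable:
    """Assemble positional patterns into a long-format :class:`PatternTable`."""
    import pandas as pd

    rows = []
    for pat in patterns:
        for c, f in zip(pat.coords, pat.freq):
            rows.append((pat.condition, pat.label, int(c), float(f)))
    frame = pd.DataFrame(rows, columns=["condition", "label", "position", "frequency"])
    return PatternTable(frame)


def pattern_from_table(
    table: PatternTable, condition: str, label: str, state: str = "raw"
) -> PositionalPattern:
    positions, freq = table.get(condition, label)
    return PositionalPattern(
        label, positions, freq, condition=condition, state=state
    )
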