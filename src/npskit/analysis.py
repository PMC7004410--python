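"""Peak analytics of positional patterns: extrema indicator tracks,
coinciding-peak hubs, superhelix location (SHL) zone assignment, and
cross-condition pattern correlation and clustering.

SHL zones index the positions along nucleosomal DNA in helical turns from
the dyad (SHL 0), alternating between minor- and major-groove contacts with
the histone octamer.  The default zone table is a synthetic reconstruction
generated from a 10.2 bp helical period (zone k centred at 10.2*k bp,
half-width 2.55 bp), since the published zone extents derive from a
crystal-structure cartoon rather than a formula; users can supply their
own table.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import wilcoxon

from .pattern_core import PositionalPattern


@dataclass
class IndicatorTrack:
    """Per-position extrema indicator: +1 maxima, -1 minima, 0 elsewhere."""

    label: str
    coords: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.coords.shape != self.values.shape:
            raise ValueError("coords and values differ in shape")
        if not np.all(np.isin(self.values, (-1, 0, 1))):
            raise ValueError("indicator values must be in {-1, 0, +1}")

    def peak_coords(self) -> np.ndarray:
        return self.coords[self.values == 1]

    def valley_coords(self) -> np.ndarray:
        return self.coords[self.values == -1]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix between condition patterns."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")


def _extrema_runs(values: np.ndarray, sign: int) -> list[int]:
    """Leftmost indices of strict local extrema (plateau-aware)."""
    v = sign * values
    n = v.size
    found: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < n - 1 and v[i - 1] < v[i] and v[j + 1] < v[i]:
            found.append(i)
        i = j + 1
    return found


def _prominence(values: np.ndarray, peak: int) -> float:
    """Topographic prominence of a local maximum of ``values``."""
    h = values[peak]
    bases = []
    for step in (-1, 1):
        i = peak
        lowest = h
        while 0 <= i < values.size and values[i] <= h:
            lowest = min(lowest, values[i])
            i += step
        bases.append(lowest)
    return float(h - max(bases))


def extrema_indicator(
    pattern: PositionalPattern, min_prominence: float = 0.0
) -> IndicatorTrack:
    """Transform a pattern into a unit indicator track of its extrema.

    +1 marks local maxima and -1 local minima (strictly greater/less than
    both neighbours; a plateau contributes its leftmost point; endpoints
    are never extrema).  Extrema with topographic prominence below
    ``min_prominence`` are suppressed.  Smoothing the pattern first is
    recommended to avoid single-position noise peaks.
    """
    if len(pattern) < 3:
        raise ValueError("pattern too short for extrema detection")
    values = np.where(np.isnan(pattern.freq), np.nanmean(pattern.freq), pattern.freq)
    track = np.zeros(values.size, dtype=np.int8)
    for i in _extrema_runs(values, +1):
        if _prominence(values, i) >= min_prominence:
            track[i] = 1
    for i in _extrema_runs(values, -1):
        if _prominence(-values, i) >= min_prominence:
            track[i] = -1
    return IndicatorTrack(pattern.label, pattern.coords.copy(), track)


def find_hubs(
    tracks: Sequence[IndicatorTrack],
    majority_frac: float = 0.5,
    tol: int = 1,
) -> list[int]:
    """Coordinates where a majority of tracks have coinciding peaks.

    A coordinate ``c`` is a hub candidate iff more than
    ``majority_frac * len(tracks)`` tracks have a +1 within ``[c-tol,
    c+tol]``.  Overlapping candidates (within ``2*tol`` of each other) are
    merged to the candidate with the highest count; ties go to the smallest
    ``|c|``, then the smallest ``c``.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    coords = tracks[0].coords
    for t in tracks[1:]:
        if not np.array_equal(t.coords, coords):
            raise ValueError("tracks are on mismatched coordinates")
    counts = np.zeros(coords.size, dtype=int)
    exact = np.zeros(coords.size, dtype=int)
    for t in tracks:
        peaks = t.values == 1
        exact += peaks
        near = np.zeros(coords.size, dtype=bool)
        for shift in range(-tol, tol + 1):
            if shift == 0:
                near |= peaks
            elif shift > 0:
                near[shift:] |= peaks[:-shift]
            else:
                near[:shift] |= peaks[-shift:]
        counts += near
    threshold = majority_frac * len(tracks)
    candidate_idx = np.flatnonzero(counts > threshold)
    hubs: list[int] = []
    group: list[int] = []
    for idx in candidate_idx:
        if group and coords[idx] - coords[group[-1]] > 2 * tol:
            hubs.append(_best_candidate(group, coords, counts, exact))
            group = []
        group.append(idx)
    if group:
        hubs.append(_best_candidate(group, coords, counts, exact))
    return sorted(hubs)


def _best_candidate(
    group: list[int], coords: np.ndarray, counts: np.ndarray, exact: np.ndarray
) -> int:
    # highest tolerant count wins; ties prefer a position where peaks
    # actually sit, then the coordinate closest to the dyad
    key = lambda i: (-counts[i], -exact[i], abs(int(coords[i])), int(coords[i]))
    return int(coords[min(group, key=key)])


def default_shl_zone_table(
    period: float = 10.2, half_width: float = 2.55, max_zone: float = 7.0
) -> pd.DataFrame:
    """Synthetic SHL zone table: zone k centred at ``k * period`` bp.

    Zones run from -max_zone to +max_zone in steps of 0.5.  Integer zones
    are labelled major-groove and half-integer zones minor-groove, matching
    the groove parity of the WW/SS peak placements this table is used to
    read out; it is a reconstruction, not a crystallographic measurement.
    """
    zones = np.round(np.arange(-max_zone, max_zone + 0.25, 0.5), 1)
    rows = [
        {
            "zone": z,
            "center": z * period,
            "half_width": half_width,
            "groove": "major" if float(z).is_integer() else "minor",
        }
        for z in zones
    ]
    return pd.DataFrame(rows)


def assign_shl_zone(
    coord: float, zone_table: pd.DataFrame | None = None
) -> float | None:
    """Zone label whose interval [center-hw, center+hw] contains ``coord``.

    Returns ``None`` ("unzoned") when the coordinate falls outside every
    zone.  Coordinates on a shared boundary go to the nearer zone centre.
    """
    if zone_table is None:
        zone_table = default_shl_zone_table()
    centers = zone_table["center"].to_numpy(float)
    hw = zone_table["half_width"].to_numpy(float)
    inside = np.abs(coord - centers) <= hw
    if not inside.any():
        return None
    idx = np.flatnonzero(inside)
    best = idx[np.argmin(np.abs(coord - centers[idx]))]
    return float(zone_table["zone"].iloc[best])


def zone_peak_counts(
    tracks_by_group: Mapping[str, Sequence[IndicatorTrack]],
    zone_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count peak sites per SHL zone for each group of indicator tracks.

    A peak site is a distinct coordinate at which at least one of the
    group's tracks has a +1.  Unzoned sites are dropped.  Returns a frame
    indexed by zone with one column per group.
    """
    if zone_table is None:
        zone_table = default_shl_zone_table()
    zones = list(zone_table["zone"])
    out = pd.DataFrame(0, index=pd.Index(zones, name="zone"), columns=list(tracks_by_group))
    for group, tracks in tracks_by_group.items():
        sites = sorted({int(c) for t in tracks for c in t.peak_coords()})
        for c in sites:
            z = assign_shl_zone(c, zone_table)
            if z is not None:
                out.loc[z, group] += 1
    return out


def compare_zone_counts(
    counts_a: pd.Series | np.ndarray,
    counts_b: pd.Series | np.ndarray,
    alternative: str = "two-sided",
) -> float:
    """Paired Wilcoxon signed-rank test between two groups' per-zone counts.

    Pairs with zero difference are dropped; the exact null distribution is
    used for up to 25 informative pairs.  Raises ``ValueError`` when fewer
    than 2 non-zero paired differences remain (the test is undefined, e.g.
    for identical groups).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must be over the same zone set")
    diffs = a - b
    n_nonzero = int(np.sum(diffs != 0))
    if n_nonzero < 2:
        raise ValueError(
            "fewer than 2 non-zero paired differences; signed-rank p undefined"
        )
    method = "exact" if n_nonzero <= 25 else "auto"
    res = wilcoxon(a, b, zero_method="wilcox", alternative=alternative, method=method)
    return float(res.pvalue)


def pattern_correlation_matrix(
    patterns: Mapping[str, PositionalPattern], min_overlap: int = 50
) -> CorrelationMatrix:
    """Pair-wise Pearson correlation between one label's patterns across
    conditions, on the intersection of their coordinate ranges."""
    labels = list(patterns)
    if len(labels) < 2:
        raise ValueError("need at least 2 conditions")
    lo = max(int(p.coords[0]) for p in patterns.values())
    hi = min(int(p.coords[-1]) for p in patterns.values())
    if hi - lo + 1 < min_overlap:
        raise ValueError(
            f"coordinate overlap {max(0, hi - lo + 1)} < required {min_overlap}"
        )
    mat = np.empty((len(labels), hi - lo + 1))
    for i, name in enumerate(labels):
        p = patterns[name]
        start = lo - int(p.coords[0])
        row = p.freq[start : start + hi - lo + 1]
        if np.nanstd(row) == 0:
            raise ValueError(f"pattern for condition {name!r} is constant")
        mat[i] = np.where(np.isnan(row), np.nanmean(row), row)
    values = np.corrcoef(mat)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(labels, values)


def cluster_patterns(matrix: CorrelationMatrix) -> tuple[np.ndarray, str]:
    """Complete-linkage hierarchical clustering on distance d = 1 - r.

    Anti-correlated patterns are maximally distant (d = 2), which separates
    pattern from anti-pattern conditions.  Returns the SciPy linkage matrix
    and a newick rendering of the dendrogram.
    """
    from skbio.tree import TreeNode

    n = len(matrix.labels)
    dist = 1.0 - matrix.values
    condensed = dist[np.triu_indices(n, k=1)]
    condensed = np.maximum(condensed, 0.0)
    link = linkage(condensed, method="complete")
    tree = TreeNode.from_linkage_matrix(link, matrix.labels)
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return link, buf.getvalue().strip()
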