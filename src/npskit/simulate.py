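"""Synthetic nucleosomal-DNA sequence sets and MNase-like read coverage.

Two generators provide inputs with the statistical structure the pipeline
assumes:

* :func:`generate_patterned_sequences` samples fixed-width sequence sets in
  which the aggregate occurrence probability of a chosen composite
  dinucleotide class (WW, SS, RR or YY) oscillates sinusoidally along the
  dyad-relative coordinate with a ~10.2 bp period.  A phase shift of pi
  turns a pattern into its anti-pattern (peak placement flipped).  The
  profile is mirror-symmetric about the planted dyad.

* :func:`generate_coverage_reads` plants nucleosomes at given dyad
  positions and emits Poisson-distributed 99 bp reads whose 5' starts
  jitter normally around ``dyad - 73``, producing the Gaussian-like
  coverage peaks the calling module consumes.

:func:`load_fixture_patterns` builds small per-condition pattern tables
(human CD4+, human apoptotic, mouse control/resilient/susceptible, yeast).
These are synthetic stand-ins generated from the planted-sinusoid model --
phase 0 for the CD4+/mouse conditions, phase pi (anti-pattern) for the
apoptotic/yeast conditions, genome G+C content per organism -- not
transcriptions of published pattern tables.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calling import CoverageProfile, coverage_from_reads
from .io_formats import GenomicInterval, SequenceSet
from .pattern_core import (
    BASES,
    COMPOSITE_MEMBERS,
    composite_pattern,
    pattern_set,
    symmetrize,
    table_from_patterns,
)

#: Bases belonging to each composite class's "first letter" alphabet.
CLASS_BASES = {"WW": "AT", "SS": "CG", "RR": "AG", "YY": "CT"}


@dataclass
class PlantedSignalSpec:
    """Specification of a planted periodic dinucleotide-class signal.

    The aggregate probability of the favoured class's dinucleotides at
    dyad-relative coordinate ``c`` is
    ``p(c) = p0 + amplitude * cos(2*pi*|c| / period + phase)`` where ``p0``
    is the squared total probability of the class's bases under
    ``base_composition`` (A, C, G, T order).  ``|c|`` keeps the profile
    mirror-symmetric about the dyad for any phase; for phase 0 or pi it
    coincides with the plain cosine.
    """

    n_sequences: int
    width: int = 147
    period: float = 10.2
    phase: float = 0.0
    amplitude: float = 0.1
    signal_class: str = "WW"
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    dyad_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")
        if self.signal_class not in CLASS_BASES:
            raise ValueError(f"unknown signal class {self.signal_class!r}")
        if not 0 <= self.amplitude <= 0.5:
            raise ValueError("amplitude must be in [0, 0.5]")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1) > 1e-9:
            raise ValueError("base_composition must be 4 probabilities summing to 1")


@dataclass
class PlantedCoverageSpec:
    """Specification of planted nucleosome read pileups on one contig."""

    nucleosome_positions: Sequence[int]
    mean_depth: float
    read_length: int = 99
    positional_jitter_sd: float = 0.0
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if self.read_length < 30:
            raise ValueError("read length must be at least 30 bp")


def _base_probability_profile(spec: PlantedSignalSpec) -> np.ndarray:
    """Per-position base probabilities (width x 4) realizing the planted
    class-probability sinusoid.

    Bases are drawn independently per position with the favoured class's
    per-base weight ``q(c) = sqrt(p(c))``, so the realized dinucleotide
    class frequency at coordinate ``c`` is ``q(c - 1/2) * q(c + 1/2) ~
    p(c)`` (the half-base lag is negligible at a 10 bp period).
    """
    comp = np.asarray(spec.base_composition, dtype=float)
    class_mask = np.array([b in CLASS_BASES[spec.signal_class] for b in BASES])
    w0 = comp[class_mask].sum()
    if w0 in (0.0, 1.0):
        raise ValueError("base composition gives the signal class weight 0 or 1")
    p0 = w0**2
    j = np.arange(1, spec.width + 1)
    c = j - (spec.dyad_offset + 73.5)
    p = p0 + spec.amplitude * np.cos(
        2 * np.pi * np.abs(c) / spec.period + spec.phase
    )
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(
            "amplitude pushes the class probability outside [0, 1]; reduce the "
            "amplitude or enrich the base composition for the signal class"
        )
    q = np.sqrt(p)
    probs = np.empty((spec.width, 4))
    probs[:, class_mask] = comp[class_mask] * (q / w0)[:, None]
    probs[:, ~class_mask] = comp[~class_mask] * ((1 - q) / (1 - w0))[:, None]
    return probs


def generate_patterned_sequences(spec: PlantedSignalSpec) -> SequenceSet:
    """Sample a sequence set with the planted periodic class signal.

    Bit-reproducible under ``spec.seed``.
    """
    probs = _base_probability_profile(spec)
    cum = np.cumsum(probs, axis=1)
    rng = np.random.default_rng(spec.seed)
    u = rng.random((spec.n_sequences, spec.width))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    letters = np.array(list(BASES))
    seqs = ["".join(row) for row in letters[codes]]
    ids = [f"synth_{i + 1:05d}" for i in range(spec.n_sequences)]
    return SequenceSet(tuple(ids), tuple(seqs))


def generate_coverage_reads(
    spec: PlantedCoverageSpec, chrom_length: int
) -> tuple[list[GenomicInterval], CoverageProfile]:
    """Plant nucleosome read pileups and derive their coverage profile.

    Per nucleosome, ``Poisson(mean_depth)`` reads are emitted whose 5'
    starts are ``round(Normal(position - 73, jitter))`` (clipped inside the
    contig) with the configured read length on the plus strand.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[GenomicInterval] = []
    for pos in spec.nucleosome_positions:
        if not 0 <= pos < chrom_length:
            raise ValueError(f"nucleosome position {pos} outside the contig")
        n = rng.poisson(spec.mean_depth)
        starts = np.rint(
            rng.normal(pos - 73, spec.positional_jitter_sd, size=n)
        ).astype(int)
        starts = np.clip(starts, 0, chrom_length - spec.read_length)
        reads.extend(
            GenomicInterval(spec.chrom, int(s), int(s) + spec.read_length, "+")
            for s in starts
        )
    if not reads:
        raise ValueError("no reads generated; increase mean_depth")
    reads.sort()
    return reads, coverage_from_reads(reads, chrom_length)


def _composition_from_gc(gc: float) -> tuple[float, float, float, float]:
    return ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)


#: Study-condition stand-ins.  CD4+/mouse conditions carry the phase-0
#: pattern, apoptotic/yeast the phase-pi anti-pattern; G+C content follows
#: the hg19 (40.4%) and mm9 (38.3%) genome values, yeast ~38%.  Each
#: condition is a mixture of a WW-planted and an RR-planted subset, because
#: nucleosomal DNA carries both the canonical WW/SS signal and the weaker
#: RR/YY signal.
FIXTURE_CONDITIONS: dict[str, dict] = {
    "human_cd4": dict(gc=0.404, ww_amp=0.18, rr_amp=0.12, phase=0.0, seed=1101),
    "human_apoptotic": dict(gc=0.415, ww_amp=0.17, rr_amp=0.12, phase=math.pi, seed=1103),
    "mouse_control": dict(gc=0.383, ww_amp=0.20, rr_amp=0.13, phase=0.0, seed=1105),
    "mouse_resilient": dict(gc=0.383, ww_amp=0.19, rr_amp=0.12, phase=0.0, seed=1107),
    "mouse_susceptible": dict(gc=0.383, ww_amp=0.21, rr_amp=0.13, phase=0.0, seed=1109),
    "yeast": dict(gc=0.380, ww_amp=0.22, rr_amp=0.11, phase=math.pi, seed=1111),
}

_FIXTURE_N_WW = 2000
_FIXTURE_N_RR = 1000
_FIXTURE_WIDTH = 146


def _build_condition_patterns(name: str):
    params = FIXTURE_CONDITIONS[name]
    comp = _composition_from_gc(params["gc"])
    subsets = []
    for cls, amp, seed_off in (
        ("WW", params["ww_amp"], 0),
        ("RR", params["rr_amp"], 1),
    ):
        spec = PlantedSignalSpec(
            n_sequences=_FIXTURE_N_WW if cls == "WW" else _FIXTURE_N_RR,
            width=_FIXTURE_WIDTH,
            period=10.2,
            phase=params["phase"],
            amplitude=amp,
            signal_class=cls,
            base_composition=comp,
            dyad_offset=0,
            seed=params["seed"] + seed_off,
        )
        subsets.append(generate_patterned_sequences(spec))
    ids = subsets[0].ids + tuple(f"rr_{i}" for i in subsets[1].ids)
    pooled = SequenceSet(ids, subsets[0].sequences + subsets[1].sequences)
    pset = pattern_set(pooled, condition=name)
    sym = symmetrize(pset, dyad_offset=0)
    patterns = list(sym.values())
    patterns += [composite_pattern(sym, comp_cls) for comp_cls in COMPOSITE_MEMBERS]
    return patterns


@functools.lru_cache(maxsize=None)
def load_fixture_patterns(name: str):
    """Pattern table for one packaged synthetic study condition.

    The table holds all 16 symmetrized dinucleotide patterns plus the WW,
    SS, RR and YY composites on dyad-relative coordinates -72..+72.
    Deterministic: repeated loads return identical tables.
    """
    if name not in FIXTURE_CONDITIONS:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURE_CONDITIONS)}"
        )
    table = table_from_patterns(_build_condition_patterns(name))
    table.meta.update(
        source="synthetic stand-in generated by npskit.simulate",
        model="planted-sinusoid mixture (WW + RR classes), period 10.2 bp",
        condition=name,
        **FIXTURE_CONDITIONS[name],
    )
    return table
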