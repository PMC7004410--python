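# Methods

## Coordinate conventions

Genomic intervals are BED-style: 0-based, half-open.  A dinucleotide is
addressed by the 1-based position of its 5' base, so a width-*W* alignment
has dinucleotide positions 1..*W*−1.  The nucleosome window is 146 bp
(145 dinucleotide positions); within a window starting at offset *o* the
dyad-relative coordinate is *c* = *i* − (*o* + 73), giving *c* ∈ −72..+72
with mirror m(*c*) = −*c*.  This integer-symmetric convention is why the
window is 146 bp rather than the 147 bp of fully wrapped DNA: 145 odd
positions centre exactly on the dyad.

Sequences may contain N.  A dinucleotide touching an N is a *missing*
observation, not a zero: it is excluded from the denominator of the
positional frequency at that position, so N bases do not bias frequencies
downward.

## Nucleosome calling

Per-base coverage is the read-membership pileup.  Smoothing uses a
Gaussian kernel spanning 70 bp (σ = window/6, so ±3σ sits inside the
window), renormalized at the profile edges; 70 bp is the window suited to
mononucleosomal MNase data.  Summits are strict local maxima (plateaus
report their leftmost base — an arbitrary but deterministic tie-break)
with height at least max(10, ⌈2.5 × mean coverage⌉); the floor of 10
corresponds to 2.5× a genome-wide mean depth of 4.  Supporting reads must
overlap the summit with at least 30 bp on each side.  Each selected read
is extended 20 bp upstream of its 5' end and 100 bp downstream of its 3'
end so the interval flanks the 146 bp nucleosome and its dyad from both
sides; the shorter upstream flank is expected to capture the MNase
cleavage site that marks the nucleosome start.

**Phasing score.**  "Well phased" is operationalized as the number of
supporting reads sharing the modal 5' start.  The call's sequence
interval is the extension of one modal-5'-start read, so extracted
sequences stay aligned by the experimental 5' end.  Per gene, the first
best-phased nucleosome is the call with maximal phasing score among
summits within (TSS, TSS + 1000] downstream (strand-aware); ties go to
the smaller TSS distance, then the smaller coordinate.  Minus-strand
sequences are reverse-complemented on extraction so position 1 is always
TSS-proximal.

## Dyad localization

At the dyad-centred placement the dinucleotide profiles seen from the two
strands agree, so for every window offset and every dinucleotide *d* we
correlate the forward profile with the reverse-complement strand profile
(f_rc(d) reversed within the window).  Windows in which either profile is
constant are excluded (Pearson undefined) rather than scored 0.  The
consensus offset is the correlation-weighted median of the
per-dinucleotide argmax offsets, restricted to dinucleotides with a
positive maximum.  Because localization is not always clear-cut, the scan
carries a `needs_review` flag — raised when fewer than 4 dinucleotides
contribute or any contributing argmax is more than 5 bp from the
consensus — instead of requiring interactive verification.

A caveat established during validation: a *pure cosine* profile is
mirror-symmetric about every half-period multiple, so on such synthetic
input the scan is inherently ambiguous modulo ~5 bp.  Real patterns (and
the recovery tests here, which plant phase π/2 and hence a slope
discontinuity at the dyad) have a distinguished symmetry point and are
recovered exactly.

## Symmetrization, composites, spectra

Symmetrization averages each pattern with its reverse-complement
partner's mirror, f_sym(d, c) = ½[f(d, c) + f(rc(d), −c)], which enforces
the dyad symmetry exactly and is idempotent.  Composites are position-wise
sums: WW = AA+AT+TA+TT, SS = CC+CG+GC+GG, RR = AA+AG+GA+GG,
YY = CC+CT+TC+TT.  Because WW and SS are closed under reverse complement,
their symmetrized composites are self-mirror; RR and YY map onto each
other (RR(c) = YY(−c)).

Normalization is the z-transform (exactly flat patterns map to zeros);
Pearson comparisons are invariant to it, so the choice does not affect
correlation results.  Smoothing is a centred moving average (default
window 3) with shrinking edge windows.  The default processing order is
symmetrize → normalize → smooth.  The periodogram zero-pads the
mean-subtracted profile to 2048 points (~0.05 bp period resolution near
10 bp, enough to separate 10.1 from 10.4) and reports the period of
maximal power within 5–20 bp; a constant profile has no dominant period
and raises an error.

## Peak analytics

Indicator tracks mark strict local maxima (+1) and minima (−1) with a
configurable topographic-prominence floor; endpoints and plateau
non-leading positions are 0.  A hub is a coordinate at which more than
`majority_frac` (default 0.5) of the tracks have a peak within ±`tol`
(default 1 bp); overlapping candidates merge to the best-supported
coordinate (ties prefer exact peak positions, then proximity to the
dyad).  Whether published hub analyses used smoothed or raw profiles is
not stated; smoothing first is recommended and is what the CLI does.

The SHL zone table is a synthetic reconstruction: zone *k* (k = −7..+7 in
half steps) is centred at 10.2·*k* bp with half-width 2.55 bp, integer
zones labelled major-groove and half-integer minor-groove.  Published
zone extents derive from crystal-structure roll-angle cartoons, so the
table is configurable and users with a structural map should supply their
own.  Per-zone peak-site counts (distinct coordinates with any track's
+1) are compared between groups with the *paired* Wilcoxon signed-rank
test — the counts are paired per zone — with zero differences dropped and
the exact null distribution for ≤ 25 informative pairs.

Cross-condition comparison uses Pearson correlation on the intersection
of coordinate ranges (≥ 50 positions required) and complete-linkage
clustering on d = 1 − r, so anti-correlated (anti-pattern) conditions are
maximally distant; dendrograms are exported as newick.

## Sequence classification

Each sequence yields 16 binary occurrence strings.  Strings with more
than 12 occurrences (strictly > 12, read literally) are slid under every
reference pattern in a 146 bp window; the single maximal positive Pearson
correlation over all (dinucleotide, reference, offset) triples assigns
the class.  Correlations equal within 1e−12 are ties, resolved uniformly
at random by a generator keyed on (seed, sequence id) — deterministic,
and invariant to the order sequences are processed in.  Sequences with no
eligible string or no positive correlation are "unassigned"; proportion
tables report percentages over assigned sequences (largest-remainder
rounding to 2 decimals so each row totals exactly 100) with unassigned
counts alongside.

The default 8-class library is built from the packaged synthetic
condition tables (class 1 = CD4+-like composites, class 2 =
apoptotic-like, i.e. phase-flipped).  Users can supply any pattern table
as a library.

A structural caveat for synthetic validation: with sinusoidal references,
WW1 and SS2 (likewise SS1 and WW2) are phase-identical up to sign of the
mean — the anti-pattern relation itself — and a long sequence lets the
sliding window re-phase an anti-pattern onto a pattern.  Classification
between such twins is therefore only meaningful for references with
non-sinusoidal shape (as real patterns have).  The planted-recovery tests
accordingly use short sequences (150 bp, ≤ 5 window placements, anchoring
phase) and libraries without phase-twins; under those conditions planted
classes are recovered with ≤ 20% (measured 1–3%) cross-class confusion.

## Synthetic data

`generate_patterned_sequences` samples bases independently per position
with the favoured class's per-base weight q(c) = √p(c), where
p(c) = p₀ + A·cos(2π|c|/T + φ), p₀ the squared class base probability
under the chosen composition, T the period (default 10.2 bp) and A the
amplitude (error if p leaves [0, 1]).  The realized class dinucleotide
frequency is q(c−½)q(c+½) ≈ p(c); |c| keeps the profile mirror-symmetric
about the planted dyad for every phase.  Anti-patterns are φ = π.  What
this emulates: the aggregate periodic signal, its dyad symmetry, and
pattern/anti-pattern phase opposition.  What it does not: sequence
autocorrelation beyond one base, amplitude envelopes, MNase digestion
bias, linker/NDR structure, or the coexistence of more than two signal
classes — so passing recovery tests demonstrates correctness of the
machinery, not performance on real chromatin.

`generate_coverage_reads` plants Poisson(mean depth) reads per nucleosome
with 5' starts Normal(dyad − 73, jitter), read length 99 bp (typical
paired MNase-seq read length).  Note the resulting pileup peaks at the
*read centre*, dyad − 73 + (L−1)/2, which is the reference point the
summit-recovery checks use.

**Packaged condition fixtures.**  `load_fixture_patterns` builds six
synthetic condition tables (human_cd4, human_apoptotic, mouse_control,
mouse_resilient, mouse_susceptible, yeast) at load time from fixed seeds:
each is a pooled mixture of 2000 WW-planted and 1000 RR-planted 146 bp
sequences (nucleosomal DNA carries both signals), period 10.2 bp, with
phase 0 for the CD4+/mouse conditions and phase π for the
apoptotic/yeast anti-pattern conditions, base composition from the
organisms' genomic G+C (40.4% human, 38.3% mouse, 38% yeast), and
per-condition amplitudes in 0.17–0.22.  They are labelled synthetic in
their metadata; conclusions drawn from them concern the pipeline, not
biological samples.

## Problem sizes

Validation runs use n = 1000–2000 sequences for pattern-level recovery,
150 sequences per class for classification, ~11 planted nucleosomes at
mean depth 25 for calling, chosen so realized sampling noise sits well
below the planted amplitudes while the whole suite completes in seconds.

## Known limitations

* Dyad localization assumes the batch shares one dominant nucleosome
  register; mixtures of registers blur the correlation maximum (the
  `needs_review` flag fires, but no deconvolution is attempted).
* The classifier follows the literal per-dinucleotide procedure — member
  strings of a composite class are not pooled — so rare dinucleotides in
  short windows are often ineligible (> 12 occurrences required).
* The SHL zone table is a periodic idealization; zone-level conclusions
  inherit its boundaries.
* BAM input is out of scope: convert alignments to BED first.
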