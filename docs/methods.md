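# Methods

This note documents the modelling and numerical choices behind
`hhtseizure`: what each stage computes, where the literature leaves the
details open and what this implementation chose, what the synthetic
generator does and does not emulate, and what the test suite does and
does not establish.

## Signal model and preprocessing

Input is a 6-channel iEEG record (three focal channels near the seizure
onset zone, three extrafocal), sampled at 256 Hz (512 Hz inputs are
decimated by 2 with scipy's zero-phase anti-alias decimator so a 30 s
window is always 7680 samples). Artifact intervals annotated by a
reviewer are honoured by *dropping every analysis window that intersects
one* rather than excising samples: splicing non-adjacent samples creates
step discontinuities that EMD would dutifully decompose into spurious
high-frequency modes. Artifact exclusion precedes filtering; the order
is a convention (the notch is linear and time-invariant, so the order
only matters at artifact boundaries, which are dropped anyway).

The power-line notch is a second-order IIR notch at 50 Hz with quality
factor 30, applied forward-backward (`filtfilt`) for zero phase. The
passband response is flat to well under 1% RMS, so the filter is
idempotent in the passband (tested to 2%).

Windows are half-open [t, t+30) s, anchored at the record start and
advancing 15 s (50% overlap). An artifact-free record of T seconds
yields ⌊(T−30)/15⌋+1 windows.

## Empirical mode decomposition

The sifting literature fixes the idea but not the constants. Choices
here:

* **Envelopes**: natural cubic splines through the strict local extrema
  (plateau centres count once). Two extrema are mirror-reflected about
  each record end before spline fitting, which curbs the end swings that
  otherwise leak energy into the first IMFs.
* **Sift stop**: a Cauchy-type criterion — the iteration stops when
  ‖m‖²/‖h‖² < 0.2, where m is the envelope mean being subtracted and h
  the current component — with a hard cap of 100 sift iterations per
  IMF. The 0.2 threshold is the classic choice.
* **Decomposition stop**: at most 12 IMFs, or a residue with fewer than
  2 maxima or 2 minima (monotone-like).
* The residue is updated by exact subtraction of each extracted IMF, so
  the reconstruction identity x = Σ g_i + r_N holds to machine
  precision by construction (asserted at 1e-9 over 200 random signals).

The envelope kernel (extrema scan, tridiagonal natural-spline solve,
evaluation) is numba-compiled; a SciPy reference implementation of the
identical algorithm is kept and cross-checked in the tests. A 30 s
6-channel window decomposes in ~15 ms on one core, which is what makes
the synthetic end-to-end runs cheap enough for routine testing.

## Hilbert spectrum and features

Each IMF's analytic signal (scipy `hilbert`) gives amplitude G_i(t) and
unwrapped phase θ(t); instantaneous frequency is the central-difference
derivative dθ/dt/2π (one-sided at the edges). Samples whose IF falls
outside [0, 128.5) Hz — differentiation artifacts — are masked out of
the spectrum rather than clamped, so they contribute to no band and not
to the marginal energy.

The spectrum grid uses 0.5 Hz bins over 0–128.5 Hz at sample-rate time
resolution. Energy is deposited additively as squared amplitude: the
stored bin value is the square root of the accumulated G², so the
squared-mass identity Σ values² = Σ_i Σ_t G_i(t)² holds exactly even
when two IMFs hit the same bin. (Amplitude-additive accumulation would
break that identity; the band features integrate (H)², so the
energy-additive reading is the consistent one.)

The ten clinical bands are tiled half-open with no gaps: δ=[0.5,4),
θ=[4,8), α1=[8,10), α2=[10,13), β1=[13,18), β2=[18,31), γ1=[31,41),
γ2=[41,51), γ3=[51,91), γ4=[91,128.5). The conventional integer band
labels leave gaps (3–4 Hz, 7–8 Hz, …); instantaneous frequency is a
continuous variable, and leaving the gaps open would silently discard
energy. Mass below 0.5 Hz counts toward the channel total E_Tot only,
so Σ_j E_j ≤ E_Tot with equality when no mass lies below 0.5 Hz.

Per channel: E_Tot, ten E_j, ten ratios E_j/E_Tot (0/0 → 0 by
convention), ten groupiness factors GF_j = population-σ/mean of the
band's instantaneous-energy series (0 when the mean is 0) — 31 features,
186 per 6-channel window, in a fixed channel-major order
(`ch{k}_etot`, `ch{k}_E_{band}`, `ch{k}_ratio_{band}`, `ch{k}_GF_{band}`).
All integrals are sums on the grid with Δt = one sample period.

For the pipeline the band energies are computed directly from the IMF
analytic traces (each sample's G² goes to the band containing its 0.5 Hz
IF bin) without materializing the dense grid; the tests assert this fast
path equals the dense-spectrum route bin-for-bin.

## Feature selection (CFS)

Correlation is symmetrical uncertainty SU = 2·I(a;b)/(H(a)+H(b)) on
supervised MDL-discretized features (recursive entropy-minimizing binary
cuts accepted under the Fayyad–Irani MDL rule; a feature with no
accepted cut is uninformative, SU = 0). Subset merit is
k·r̄_cf / √(k + k(k−1)·r̄_ff). Search is forward best-first from the
empty set with a patience of 5 consecutive non-improving expansions —
the common default of the ecosystem this method comes from — with merit
ties broken toward the lower feature index, so selection is
deterministic and seed-free. On every ≤12-feature instance tried, the
best-first optimum equals the exhaustive-search optimum (asserted in the
tests).

## Bayesian-network classifier

Attributes (the selected features) are discretized with the same MDL
procedure, cuts learned on training data only. The default structure is
naive (class-only parents); `structure="k2-1parent"` optionally gives
each attribute at most one earlier attribute as an extra parent when a
BIC-penalized likelihood score improves, keeping the graph acyclic by
construction. CPTs use additive smoothing α = 0.5, priors are the
honest class frequencies — the heavy interictal/preictal imbalance is
deliberately not resampled away, since the decision threshold operates
on the posterior scale. Posteriors are computed in log space;
normalization and the naive factorization are asserted algebraically in
the tests.

## Decisions, alarms, and scoring

Window posteriors (15 s cadence) are averaged over non-overlapping 5-min
blocks anchored at the record start; a block with no surviving windows
(artifact gaps) emits no decision, a partial block averages what it has.
A block is preictal when its mean ≥ threshold; the comparison is closed
(≥) — with the default 0.25 operating point a block alarms when at
least half its windows average 50% preictal probability. Each preictal
block start is a raw alarm; raw alarms within SPH+SOP (40 min) of a
cluster's first alarm join that cluster.

Scoring: a preictal record is a true positive iff some raw alarm a has
onset − a ∈ [SPH, SPH+SOP]; latency is onset − a for the earliest
qualifying alarm. On interictal records the false-positive count is the
number of clusters, and time in warning is the union of [a, a+SPH+SOP)
over raw alarms clipped to the record — counting clusters but unioning
raw-alarm warning intervals is the only bookkeeping consistent with
both conventions used in the field's reporting. The FP% denominator is
the evaluated interictal time.

## Chance predictor

The comparison predictor is a Poisson process matched in proportion of
time in warning ρ_w: λ_w = −ln(1−ρ_w)/(SPH+SOP) and

    S_nc = 1 − exp(−λ_w(SPH+SOP) + (1 − e^{−λ_w·SPH})).

This composition is implemented exactly as written — including the
second term inside the exponent — because it is the form whose values
this package is validated against; it differs from other chance-predictor
variants in the literature, and the difference is documented rather than
"corrected". S_nc is strictly increasing in ρ_w (the exponent's
ρ-derivative is negative since SPH·e^{−λ·SPH} < SPH+SOP). Significance
of n of N predicted seizures is the one-sided binomial tail
P = 1 − Σ_{k<n} C(N,k) S_nc^k (1−S_nc)^{N−k}; n = 0 gives P = 1. The
tail is asserted equal (1e-12) to brute-force enumeration over all 2^N
outcome sequences for N ≤ 12. When a run spends essentially all
interictal time in warning, ρ_w is clamped just below 1, which drives
S_nc → 1 and P → 1 — the correct degenerate limit for an alarm that is
always on.

## Synthetic data: what it emulates and what it does not

Each channel is a sum over the ten bands of an AM sinusoid at the band's
centre frequency — amplitude table × slowly varying envelope (low-pass
Gaussian noise, 0.2 Hz bandwidth, depth 0.3, clipped non-negative) —
plus 1/f background noise (2 µV RMS). The baseline band amplitudes
(30, 20, 12, 10, 8, 6, 4, 3, 2, 1.5 µV from δ to γ4) follow the broadly
1/f amplitude profile of intracranial recordings. In the preictal state
the four γ-band amplitudes of the three focal channels are multiplied
by `gamma_boost` (default 2), emulating the empirical finding that
focal-channel gamma energies carry most of the discriminative
information; `gamma_boost=1` produces an exchangeable null. The
background level was chosen so that a boost of 2 separates focal γ4
window energies by more than 3 pooled standard deviations — a planted
effect that a working pipeline must find and a broken one must not
invent in the null.

This generator reproduces the *feature-level* statistical structure the
classifier exploits, not iEEG morphology: no spikes, no ictal
waveforms, no nonstationary background drift, no inter-channel
correlation, no artifacts (tests that need artifacts annotate them
synthetically). Passing the end-to-end tests therefore shows the
pipeline machinery is correct and recovers a planted preictal
signature above chance; it says nothing about performance on clinical
recordings, which are access-restricted.

Patient datasets follow the leave-one-seizure-out layout: N preictal
records (default 40 min, onset at the record end) and M ≥ N interictal
files (durations drawn from N(58.58, 6.97²) min, truncated at 10 min),
apportioned round-robin over the N test sets so no file appears on both
sides of a split — contiguous (highly correlated) recordings never
straddle train and test. Leakage is re-checked at model construction
and each split's training matrix is content-hashed for audit.

## Problem sizes used in the tests

The end-to-end recovery test runs the full pipeline on a gamma-boost
patient with 4 seizures (40-min preictal records) and 8 half-hour
interictal files (~4 h) — large enough for every stage to operate at
its production window counts while keeping the suite's runtime in
minutes. The ten-seed negative control runs a compact configuration
(3 seizures, 20-min preictal, 3 × 20-min interictal) per seed; its
conclusion — that the null pipeline does not beat the chance predictor
— is insensitive to the record lengths because the failure mode it
guards against (posteriors tracking the class prior) scales with
proportions, not durations.

## Known limitations

* EMD is the plain single-channel variant: no ensemble EMD, no noise-
  assisted or multivariate extensions, no streaming decomposition.
* Mode mixing is real: nearby carriers (frequency ratio ≳ 0.6) share an
  IMF, and band energies then apportion by instantaneous frequency, so
  planted narrowband effects bleed slightly into adjacent bands (the
  tests account for this).
* The discretization-based classifier gives piecewise-constant
  posteriors; records whose features sit entirely in one bin yield
  posteriors equal to the class prior.
* The chance-predictor formula is used in its published composition
  (see above); comparisons with other implementations of the Poisson
  chance predictor must account for the variant form.
* Evaluation assumes one onset per preictal record and seizure-free
  interictal records; multi-seizure records must be split upstream.
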