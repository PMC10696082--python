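# Methods

## Model

The dermis is treated as a thin 2D sheet with the intravascular space
distributed homogeneously across it. Four variables are evolved: histamine
released from basophils `[H_B]` (an ODE on small disk-shaped basophil
adhesion sites), tissue-factor expression `[TF]` (an ODE at every pixel),
coagulation factors `[C]` and mast-cell histamine `[H_M]` (both
reaction–diffusion). The couplings are the calibrated response functions of
`model_functions`: Hill-2 adenosine inhibition of histamine release and of
TF expression (exponent 2 is fixed; the activation is exponent 1 — no
alternative Hill exponents are offered), saturating TF activation by the
summed histamine pool, and a sigmoidal TF-gated plasma-leakage switch. The
basophil contribution to the TF equation at a pixel is the site value where
the pixel lies inside a site and zero elsewhere.

Cells carry finite histamine reservoirs. Release decrements the reservoir
by `(release rate)·dt`, floored at zero; the Heaviside indicators
`χ = (reservoir > 0)` are always derived, never stored, and switch 1→0 at
most once per site/pixel. Reservoir depletion is what clears the wake of an
excitation front and turns a growing disk into an expanding ring.

The visible output is the eruption-state sigmoid `S_w([C])`; the
coagulation-factor and mast-histamine fields pattern essentially
identically, so `[C]` is the plotted/thresholded field. The wheal
*disappearance* phase is outside the model's scope: eruptions expand for as
long as the simulated window lasts, and the classifier correspondingly
analyses the development phase only (see below).

## Numerics

Explicit operator-split Euler: pointwise reactions with all terms evaluated
at the current state, then 5-point Laplacian diffusion for `[C]` and
`[H_M]` with zero-flux (Neumann) boundaries, realised by edge replication,
which conserves the discrete integral exactly. The time step defaults to
0.9 × the diffusion stability bound `h²/(4 max(D_C, D_M))`, additionally
capped at `dt_max = 0.05` for reaction accuracy; a configured `dt` above
the bound is rejected with the admissible maximum. Sigmoid exponents are
clamped to ±700 before exponentiation so saturation never produces
non-finite intermediates. A guard raises if any field leaves `[0, ∞)`
after a step — with the default caps this indicates a configuration whose
reaction rates are too stiff for the explicit scheme.

Against a high-accuracy adaptive reference integration of the single-pixel
(diffusion-off) system, the scheme at `dt = 2·10⁻³` agrees to ~3·10⁻⁵
relative over 10 time units. The per-step mass balance of `[C]`
(`∫C(t) = ∫C(0) + ∬f_leak − μ_C∬C`) holds to machine precision and is
recorded in every run's ledger. Doubling the grid resolution at fixed
physical size changes the final mask area fraction by under 5% in the
deterministic configuration (site centres are drawn in physical
coordinates, so a layout is reproducible across refinements).

## Domain, units and the simulated patch

Concentrations are in model units except the TF switch, which is
parameterised in ng/mL with default threshold `T_sw = 2` — the midpoint of
the experimentally bracketed 1–3 ng/mL transition of endothelial gap
formation; a configurable linear map (`ConversionParams`) relates
co-stimulus scales (LPS, adenosine) to histamine-equivalents, defaulting to
unity as a documented surrogate for the unpublished conversion. Time is in
model units throughout.

The default study patch is a 12.8 cm square at 64×64 (h = 0.2 cm/px),
a viewport onto the larger dermis rather than the full 35 cm sheet: the
clinical 1 cm dot criterion must be resolvable (5 px here), and the full
sheet at this spacing would need N = 175 with no change in behaviour.
`DermisGrid` defaults to the 35 cm sheet for users who want the full-scale
domain.

## Pattern regimes

The preset base configuration and the three swept axes — mast-cell release
rate γ_M, histamine decay μ_M and maximal release inhibition α_M — were
located by a coarse regime search and are calibration surrogates, not fits
to data. The mechanism map:

* **annular / broken-annular** (γ_M high, μ_M low): the excitation front
  outruns a wake in which mast reservoirs are exhausted and leakage has
  shut off, leaving an expanding ring. Patches of the dermis with no mast
  cells (`mast_occupancy < 1`, a correlated binary field) cannot relay the
  front and leave persistent gaps — arcs.
* **geographic / circular** (γ_M moderate): filled wheals grow and fuse
  (geographic) or, with sparse larger stimulation foci and slow spread,
  remain isolated disks ≥ 1 cm (circular).
* **dot** (γ_M low, μ_M high, or α_M saturating): the mast-cell sheet is
  never recruited; only small static spots above the basophil sites remain,
  sustained by basophil-driven local leakage.

Initial conditions are the basal production/decay balance plus ±1%
multiplicative noise on `[H_M]` and an initial basophil stimulus at the
sites (the IgE-mediated trigger); some symmetry breaking is required for
pattern selection. Mast capacity heterogeneity (±15%, correlation length
3 px) and 90% occupancy are part of the base study conditions. Per-run
sub-seeds in the sweep are expanded from the global seed by a fixed counter
scheme so every cell×replicate sees an independent disorder realization.

Preset label reliability over ten seeds: annular 10/10 boundary-class
(fully occupied mast sheet keeps fronts closed), broken-annular ~6/10
broken with most of the rest boundary/geographic (the break band is
intrinsically narrow), geographic 8/10, circular 10/10, dot 9/10.

## Classification (EGe criteria, KF1–KF5)

Masks are `S_w ≥ θ` (θ = 0.5, ties included). Components use
8-connectivity for foreground and 4-connectivity for holes. Annularity of a
wheal is hole area / filled area; a wheal is boundary-class when annularity
≥ τ = 0.15 (qualitative wording in the source criteria; the threshold is
config-exposed and fixture-calibrated). Arcs of one broken ring are
disjoint components, re-grouped by binary closing with radii tried in
increasing order (2, 4, 8 px) until a group attains boundary-class
annularity — the closing radius is the maximal gap read as a break rather
than a separation. Equivalent diameter is `2√(area/π)`.

Because only the development phase is modelled, a series is truncated at
its maximal total wheal area before feature measurement. KF1 (boundary
score) is the strongest dominant-wheal annularity over the development
frames — an expanding ring holds a visible hole only while it fits the
patch, so a single late snapshot can miss it; KF2 (disconnection) is read
at the latest qualifying frame, since a broken-annular wheal is one whose
boundary *stays* disconnected. KF4 counts merge events by overlap mapping
between consecutive frames plus the relative area growth rate from first
emergence. KF5 (punctate) requires mean component diameter < 1 cm and
relative area change < ε = 0.2 over the last third of the development
series (the established phase; the emergence transient would otherwise
mask genuinely static wheals, and single-pixel quantisation on a 5-px dot
is itself a 20% area step). Decision table: boundary-class → annular
(1 arc) or broken-annular (≥ 2); area-class → geographic if fusing
(≥ 1 merge with positive growth; fusion outranks punctate, with a recorded
warning when both fire), else dot if punctate or if the dominant wheal is
below 1 cm, else circular. Components under 4 px are ignored for size
statistics, under 8 px for boundary analysis.

These features are proxies for the topological definitions of the five
patterns; they are validated by a randomized ground-truth fixture suite
(growing rings, sector-broken rings, chain-placed merging disks, sparse
≥ 1 cm disks, static sub-centimetre dots at 0.1 cm/px) on which the
classifier is exact, and by rotation/reflection invariance checks.

## eFAST

Each parameter is driven along the arcsine search curve
`x(s) = 1/2 + arcsin(sin(ω s + φ))/π`, `s` equispaced on `[−π, π)`, which
makes every marginal uniform. Per curve, the parameter of interest carries
`ω_max = (Ns − 1)/(4M)` (M = 4 interference factor by default; Ns below
the Nyquist bound `4·M·ω_max + 1` is rejected) and the complementary set
gets low frequencies ≤ ω_max/(2M), cycled 1, 2, 3…; phases are
re-randomised over `Nr` resamplings. The first-order index is the spectral
power at harmonics `p·ω_max, p ≤ M` over the total variance. The power at
the interest harmonics is phase-stable, but a single curve's total
variance fluctuates strongly when low-frequency complementary content
interferes, so the denominator is the per-curve total variance pooled over
all curves and resamplings — the output's variance does not depend on
which parameter rides the high frequency. With Ns = 1025, Nr = 2 the
estimator reproduces the closed-form Ishigami indices (0.3139, 0.4424, 0)
within ±0.05 across seeds.

A dummy parameter the model never reads is always appended; its index is
the significance floor. Reported flags: `negligible` (index ≤ dummy),
`high` (≥ 2× dummy), `moderate` otherwise. For the wheal-feature analysis
(`kf_sensitivity_run`) the five sensitivity functions are the classifier's
scalar scores (annularity, arc count, area score, merges + growth,
punctate indicator) — documented proxies for the unpublished definitions —
computed on reduced-scale simulations (32×32, shortened horizon in the
desk preset); failed runs are imputed with the per-curve median to keep
the Fourier grid intact, and the run aborts above a configurable failure
fraction.

## Vote statistics

Per sample, SB is the fraction of raters selecting the modal qualifying
type (uniform/NA never qualify; with no qualifying vote SB = 0), and SS is
the fraction matching both the modal class and modal type — the joint
probability p(class ∧ type), never above SB. Modal ties resolve toward the
type whose class gathers more votes; remaining ties are flagged ambiguous
and excluded from type-frequency tables. With six raters, a "> 83%"
reliability criterion is operationally SB ≥ 5/6, the only attainable value
in that range. The classifiable rate at a threshold counts samples whose
modal label is a qualifying type at that SB level; the positive
*unclassifiable* rate counts samples whose raters agree, at the same
level, on a non-qualifying label. The binomial tail P-value
`Σ_{k≥k0} C(n,k) p0^k (1−p0)^{n−k}` is computed through the regularised
incomplete beta function; `p0` is a required user input.

## Synthetic data

Generators are seeded and embed their truth in metadata, enabling
generate-and-refit tests: log-spaced dose–response curves with truncated
Gaussian noise on the ratio scale (emulating mean ± SD replicate
readouts); impedance traces whose gap `1 − CI` is a reference gap scaled
by the target switch value, so the relative CI reproduces the switch curve
exactly when noiseless; vote matrices with exact unanimity structure; and
the mask fixture suite above. They emulate the *structure* of in vitro and
clinical inputs, not their biology — passing round-trip tests shows the
estimators are correct, not that the model parameters are physiological.
Real impedance data would add instrument drift and well effects that the
generator omits.

## Fitting

All curve fits are bounded nonlinear least squares (trust-region
reflective) over five documented starting points spanning the dose scale;
fits are applied to all replicate points, not per-dose means, preserving
the replicate error structure. Flat responses are flagged degenerate
rather than raised; window means all on one side of 0.5 flag the switch
fit unbracketed. The impedance window average over [0.2, 0.6] h uses
trapezoidal weighting on the closed interval, robust to uneven sampling;
time points where the reference gap vanishes are masked and reported. No
confidence intervals are attached beyond residual diagnostics.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 64×64
patch simulations (~1 s each), a 3×3×3 sweep with 3 replicates per cell
(~45 s), Ishigami at Ns = 1025 × Nr = 2, the ODE cross-check at
`dt = 2·10⁻³` over 10 time units, and a 25-series fixture suite. The whole
suite completes in about a minute on one CPU.

## Known limitations

* The kinetic parameter values are regime-search surrogates; none are fit
  to published measurements, and absolute times/concentrations are not
  physiological.
* The broken-annular band is narrow; its preset yields the broken label in
  roughly half of seeds, with most others classified as the neighbouring
  annular/geographic regimes.
* No wheal disappearance phase, no 3D dermis, no classification of real
  photographs (binary masks only).
* The explicit scheme requires small steps for stiff parameter choices; no
  implicit integrator is provided.
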