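# Methods

## The measurement model

An HPLC-DAD run records a full UV-Vis spectrum at every elution time, so
each injected sample yields a matrix (time × wavelength) and a set of K
samples yields a three-way array `X` of shape I × J × K. `tricalib`
assumes the trilinear (PARAFAC) model

    x_ijk = Σ_n  a_in · b_jn · c_kn  +  e_ijk ,      n = 1 … N

where column `a_n` is the elution profile of species n (identical shape
in every sample), `b_n` its UV spectrum, and `c_kn` its relative amount
in sample k. This is Beer's law lifted to second-order data: signals of
co-eluting species add, and each species' profile/spectrum pair is the
same in every sample up to the concentration scale. The model is *not*
valid when retention times shift between runs, when peaks change shape
with load, or when the detector saturates — none of which the package
attempts to correct.

Under mild conditions (Kruskal's condition, comfortably met when no two
species share both their elution profile and their spectrum) the
decomposition is essentially unique — up to permutation, sign and scale
of components. That uniqueness is the entire point: the C-column of an
analyte is proportional to its true concentration across samples *even
when unknown species are present in some samples only*, so calibration
standards and unknowns can be decomposed jointly and the unknowns
quantified in the presence of an uncalibrated background (the
second-order advantage).

Indeterminacies are fixed by convention: columns of A and B are scaled
to unit Euclidean norm with all magnitude carried in C, signs are chosen
so each profile's largest element is positive, and the permutation is
resolved by `align_factors`, which matches fitted spectra to reference
spectra of the analytes (greedy on |Pearson r|, ties broken by
reference order then column order) and orders leftover (interferent)
components by decreasing C-column norm.

## Decomposition engines

**PARAFAC-ALS** minimizes Σ e²_ijk by alternating exact least-squares
updates of A, B and C on the mode unfoldings (Khatri-Rao normal
equations). Modes listed in `FitOptions.nonnegative` are updated by
row-wise nonnegative least squares on the Gram-reduced system (Cholesky
of the N × N Gram matrix, then NNLS per row), so the objective is
non-increasing sweep by sweep in both the constrained and the
unconstrained case.

*Nonnegativity default.* All three modes are constrained by default.
Negative elution intensities, absorbances and concentrations are
physically meaningless here, and the constraint on C is also what keeps
the deterministic SVD-started ALS out of two-factor degeneracies: with
C free, pairs of nearly collinear components with huge opposite-signed
scores can form and the fit creeps for thousands of sweeps at a
suboptimal plateau. Pass `nonnegative=()` for the unconstrained model
(the rank module always does this itself).

*Convergence.* Sweeps stop when the relative change of the residual sum
of squares falls below `tol` (default 1e-6, the conventional ALS rule)
or when the residual reaches 1e-20 of the total sum of squares (exact
fit to machine precision). `max_iter` defaults to 2000. The threshold
is deliberately on the SSR, not on the percentage of fit: the same
numeric threshold applied to fit-percent changes halts inside ALS
swamps far from the optimum.

*Initialization.* `init="svd"` (default) uses the leading left singular
vectors of the first two unfoldings — element-wise magnitudes when the
corresponding mode is nonnegativity-constrained, since a signed
singular vector can be zeroed wholesale by the first NNLS sweep — and a
least-squares C. `init="random"` draws seed-determined factors;
`n_starts > 1` adds random restarts and keeps the best fit. A loading
column whose norm collapses below 1e-12 triggers one random
re-initialization; a second collapse raises.

**SWATLD** alternates self-weighted updates in which each factor row is
the average of two diagonal extractions of the data projected onto the
other two modes, weighted by those modes' squared column norms. It is
not monotone in the least-squares objective but typically converges in
one to two dozen sweeps (versus one to several hundred for ALS on the
same data) and degrades gracefully when `n_components` exceeds the true
chemical rank: surplus columns absorb noise without distorting the true
ones. Requested nonnegativity is applied as a terminal projection of
the affected modes rather than inside the sweeps — hard clipping inside
the self-weighted iteration corrupts its fixed point (observed as an
analyte's elution column collapsing outright), while terminal
excursions below zero on trilinear data are of order 1e-3 of a
unit-norm column.

## Chemical rank

`corcondia` computes the least-squares Tucker core G of the data given
the fixed fitted loadings (mode-wise pseudo-inverses, cutoff 1e-10;
numerically collinear loadings raise rather than return a misleading
number) and scores how superdiagonal it is:

    CORCONDIA = 100 · (1 − Σ (g_def − t_def)² / N),

with T the N × N × N identity array. A valid trilinear model reproduces
T exactly; surplus components leave large off-superdiagonal structure
and the score collapses, often to large negative values. For N = 1 the
ALS stationarity condition forces the scalar core to 1, so 100 is
returned in closed form. `scan_components` fits *unconstrained* models
(the diagnostic's standard setting) over a candidate range and picks
the largest N whose core consistency stays at or above 50% — the
conventional collapse threshold. Two caveats, both observed in testing:
on *exactly* trilinear data an overfactored fit goes numerically
collinear and the diagnostic raises instead of collapsing (the scan
records the error and the candidate does not qualify), and on pure
noise the two-component core can look deceptively superdiagonal — the
fit percentage, also recorded in the scan, is the quantity that exposes
the absence of trilinear structure there.

## Calibration and scoring

For each analyte the proportionality `score = k · concentration` is
fitted through the origin on the calibration samples (k = y·s / y·y);
unknowns are predicted as `score / k`. Regression through the origin is
what the single-coefficient formulation implies; no intercept, no
weighting. Per-sample recovery is 100 · predicted/added; accuracy over
the prediction set is RMSEP = √(Σ(y − ŷ)²/m). The report table rounds
recoveries to 1 decimal, mean ± sd to integer percent (sd with the m−1
denominator), RMSEP to 2 significant figures, all half-up — matching
the layout conventions of determination tables in the application
literature.

A second route, `direct_prediction`, estimates scores from a single
sample matrix as diag(A⁺ X_un (Bᵀ)⁺). It requires every species in
X_un to be represented in A and B and is provided as a cross-check; on
noiseless data the two routes agree to better than 1e-6 relative.

## Figures of merit

With unit-norm A and B covering all N modelled species,

    SEN_n = k_n · ([(AᵀA)⁻¹]_nn [(BᵀB)⁻¹]_nn)^(−1/2),
    SEL_n = SEN_n / k_n ∈ (0, 1],
    LOD_n = 3.3 · s0_n,

the net-analyte-signal sensitivity, selectivity and detection limit.
s0 is the sample standard deviation of the concentration estimated for
the blank samples, which are carried through the *same* joint
decomposition and converted by the same k (route recorded in the
report). Three blanks, as in a typical study design, make s0 a very
noisy estimate; the LOD ordering test therefore pools 20 simulated
blanks and uses the unconstrained fit, because zero-clipped blank
scores from a nonnegative fit bias s0 toward zero.

## The synthetic-data generator

`simulate` replaces the instrument: each species is a Gaussian elution
peak (unit maximum; optional exponential tailing, off by default) and a
sum of Gaussian UV bands (unit norm). A sample slab is the trilinear
combination plus an optional constant baseline and iid additive
Gaussian noise with sd expressed as a fraction of the maximum noiseless
signal. Blanks contain baseline and noise only. One `numpy` Generator
seeded by a single integer drives every draw, so a seed fully
determines the dataset.

`paperlike_dataset` encodes the emulated determination study: 10
calibration standards containing only vancomycin and cephalexin
(levels staggered over 5–40 mg/mL so the concentration vectors are
linearly independent), 6 prediction samples spiked at the published
added levels (vancomycin 15.15–30.30, cephalexin 10.18–30.54 mg/mL)
plus 1–2 uncalibrated "plasma" interferents at 8–20 mg/mL, and 3
blanks, on a 0–5 min / 151-point × 200–380 nm / 91-point grid. Elution
centers are 2.00, 2.30 (σ = 0.25 min) for the analytes with the first
interferent at 2.15 (σ = 0.35) — elution cosines up to 0.92, i.e.
severely incomplete chromatographic separation — while the spectra
remain distinguishable (analyte–interferent cosines 0.81/0.57;
cephalexin's spectrum is deliberately the most distinct in shape, so it
is the more selective analyte, mirroring the qualitative ordering
reported for this drug pair). Defaults: noise sd 0.5% of maximum
signal, baseline 0 (the blank-subtraction path is exercised with
nonzero baselines in tests). The published study reports neither its
noise magnitude nor the plasma rank, so these are the package's
realism choices, fixed once.

What passing on this generator does *not* show: robustness to
retention-time warping, heteroscedastic detector noise, peak-shape
nonlinearity, or plasma backgrounds whose spectra are nearly collinear
with an analyte — a regime in which no trilinear method can succeed and
which the generator can produce only if configured to.

## Problem sizes and determinism

Default grids (151 × 91 × 19) decompose in well under a second per
model on one CPU; the test suite and the acceptance script use cubes
between 8 × 6 × 5 (brute-force nonlinear-least-squares cross-check)
and 151 × 91 × 19, with the rank scans on a reduced 100 × 60 grid.
Every stochastic test fixes its seeds; the CLI writes a manifest with
config snapshot, seeds and per-output SHA-256 checksums, and re-running
a manifest's config reproduces the outputs bit for bit.
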