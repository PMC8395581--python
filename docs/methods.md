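# Methods

## Signal model and preprocessing

A trial is a channels × samples matrix (14 × 512 under the default
conditions: 14 electrodes, 128 Hz, 4 s). Preprocessing applies, in order:
a 5th-order Butterworth band-pass run forward-backward (`sosfiltfilt`, so
the effective order doubles and the group delay cancels) over 8–30 Hz,
covering the mu and beta sensorimotor rhythms; an optional artifact-removal
hook that defaults to pass-through (EOG/EMG removal is delegated to
external tooling and deliberately out of scope); common average
referencing, which subtracts the instantaneous cross-channel mean; and,
immediately before decomposition only, a mirror extension that triples the
signal by reflecting it at both ends. Boundary artefacts of the
decomposition then land in the reflected copies and are cut away by
cropping the middle third of every component. The zero-phase filter keeps
its library default odd-reflection padding; the explicit mirror extension
exists solely for the decomposition. Which sub-window of a trial holds
imagery is dataset-dependent, so the full supplied trial is analysed by
default with an optional `[t_start, t_end)` crop.

## Local mean decomposition

LMD peels a signal x(t) into product functions h_j(t) plus a residual,
x = Σ_j h_j + u, each PF an envelope-modulated oscillation and PF1 the
fastest. One sifting pass estimates, from successive local extrema, a
piecewise-constant local mean (midpoints of adjacent extrema) and local
envelope (half the absolute extrema difference), both smoothed by a
repeated centered moving average; the signal minus the mean, divided by the
envelope, is re-sifted until the envelope flattens to within
`envelope_convergence_tol` of 1 (default 1e-3) or `max_sift_iterations`
(default 30) is hit. The PF is the product of all envelopes with the final
demodulated signal, subtracted exactly from the input, so additive
reconstruction holds to machine precision by construction — this is the
module's primary regression property.

Numerical choices: the smoothing window defaults to half the mean extrema
spacing, odd-forced with a floor of 3; the moving average is reapplied
until no two adjacent smoothed values are equal (dissolving the plateaus of
the step curves), capped at 20 passes; flat extrema runs count once at
their first sample, which makes the decomposition fully deterministic; the
envelope is floored at a relative 1e-10 before division. The outer loop
stops when the residual has fewer than three extrema or at `max_pfs`
(default 8). A signal with fewer than three extrema returns itself as the
residual with zero PFs rather than raising. Instantaneous
amplitude/frequency extraction (Hilbert spectra) is a non-goal.

The pipeline only ever consumes the PFs its selection rule can cite, so
with the default `fixed:1` rule it stops sifting after PF1; the saving is
proportional and changes nothing about PF1 itself, since outer-loop
truncation does not alter earlier PFs.

## Cloud-model PF selection

The backward cloud transform summarizes a sample by Ex (mean),
En = √(π/2) · mean|x − Ex|, and He = √(S − En²) with S the second central
moment (1/n normalization throughout, matching Ex's convention). For
Gaussian data E|x − μ| = σ√(2/π), so En is a consistent estimator of σ and
S − En² → 0; He measures the dispersion of the entropy itself and its
estimator converges at the slow n^(−1/4) rate with a heavy right tail —
tests therefore check its median over independent draws. Finite samples
can make S − En² slightly negative; He is clamped at zero.

Complex, rhythm-bearing PFs have larger En and He than sifting artefacts.
Two selection rules are exposed: `fixed:i` (the standard choice for
band-limited MI data is `fixed:1`) and `top:m`, which ranks PF indices by
(En, He) descending lexicographically, averaged across the supplied
decompositions. Selection is a calibration step run on training data only,
and is global across channels so the reconstructed matrix stays
rectangular: the selected, cropped PFs stack channel-major into an
M × N matrix per trial.

## One-versus-one CSP

Per trial the spatial covariance is trace-normalized (R = XXᵀ/tr XXᵀ) and
averaged per class. For each class pair the composite covariance R1 + R2
is whitened and the whitened R1 eigendecomposed; the filter's rows are the
m eigenvectors with the largest eigenvalues followed by the m with the
smallest (default m = 4, giving 8 × 14 filters on 14 channels), mapped back
through the whitening transform, so each row w satisfies wᵀ(R1+R2)w = 1 and
both class covariances are simultaneously diagonalized. Near-singular
composite covariances are ridge-regularized (1e-10 · trace/M) with a
warning. Row signs are fixed by forcing each row's largest-magnitude entry
positive, for determinism across linear-algebra backends. The three
pairwise filters stack vertically into the global filter, and features are
the normalized log-variances of the projected rows; the normalization
forces Σ_p exp(f_p) = 1 and cancels global trial amplitude, and the
features are used as-is (no additional standardization). Channel weight
scores — column norm over Frobenius norm of a pairwise filter, min-max
rescaled after any cross-subject averaging — quantify which electrodes
drive each discrimination.

## Twin SVM

For classes A (m1 × g) and B (m2 × g), with C = [A; B], H = [K(A,Cᵀ), e]
and G = [K(B,Cᵀ), e], hyperplane 1 minimizes ½‖H u1‖² + c1 eᵀξ subject to
−(G u1) ≥ e − ξ, ξ ≥ 0; hyperplane 2 mirrors it with the same constraint
sign, so both recoveries u_i = ∓(·)⁻¹(·)ᵀ(dual) carry a minus — a pure
convention, since prediction uses |K(xᵀ,Cᵀ)w_i + b_i| / ‖w_i‖ and assigns
the nearer hyperplane's class. The Wolfe duals are box-constrained QPs of
sizes m2 and m1, solved by a projected-Newton active-set iteration with a
projection-arc (backtracking) line search from a deterministic start at
zero, with an L-BFGS-B polish if the KKT residual has not converged; the
(w, b) recovery uses Tikhonov-regularized normal equations with
ε = 1e-7 · trace/dim, which keeps the augmented Gram matrices invertible.
The Gaussian kernel is K(x,y) = exp(−‖x−y‖²/(2λ²)) with λ the tuned width.
Multiclass decisions take the majority over the three pairwise machines;
circular ties break by the smallest summed perpendicular distance, then
sorted label order, so prediction is deterministic. One (c1, c2, λ) triple
is shared across the three binary tasks by default, with a per-pair mode
available.

## Multi-objective grey wolf optimizer

Positions are (c1, c2, λ) triples inside [0.01, 8]² × [0.001, 8]. The
objective vector (all maximized) is the stratified-CV pooled mean accuracy
Σ NC_i / Σ(NC_i + NE_i) plus the three per-class rates CR_i; the same fold
assignment is reused for every evaluation within a run so comparisons are
paired, and evaluations are cached on positions rounded to 1e-6.
Defaults: 12 wolves, 100 iterations, archive 10, grid inflation 0.1,
leader-selection pressure 4, 10 grid divisions per objective dimension.
The archive admits a candidate iff no member dominates it, purges members
it dominates, and on overflow evicts by roulette weighted linearly by grid
cell occupancy; leaders α, β, δ are drawn by roulette over cells with
weight count^(−pressure) (favouring sparse regions), distinct when the
archive allows. Each wolf moves to the mean of three leader-encirclement
candidates (D = |C·X_leader − X|, candidate = X_leader − A·D,
A = 2a·r1 − a, C = 2·r2) with a decaying linearly from 2 to 0 and positions
clipped to the box. The final solution is the archive member with maximal
accuracy, ties broken by the larger worst-class rate, then the smaller
parameter norm — a deterministic reading of the Pareto set.

## Synthetic data

Each trial mixes n_channels latent sources — 8–30 Hz band-pass-filtered
Gaussian noise, ZCA-whitened per trial so the latent sample covariance is
exactly identity — through a class-specific mixing A_c = Q·diag(g_c), with
Q a shared random orthogonal basis and per-class log-gain patterns scaled
by a `discriminability` knob (zero-mean contrasts across classes, so
classes differ in spatial covariance but not overall power trend). Pink
(1/f) channel-independent noise is added at a power ratio set by `snr`
(default 4). The analytic class covariance is then exactly
A_c A_cᵀ + σ²_noise I, which the CSP parameter-recovery tests exploit. An
optional < 4 Hz common drift can be injected to verify front-end
suppression. Defaults mirror the study conditions: 14 channels, 128 Hz,
4 s trials, 20 trials per class, three classes. What the generator does
*not* emulate: volume-conduction forward models, ERD/ERS time-locking
within a trial, non-stationarity across a session, and ocular/muscular
artefacts — so passing tests demonstrate correct recovery of spatial
covariance structure, not robustness to those real-data effects.

## Cross-validation protocols and evaluation

`single` (default) is the classic tune-and-report protocol: PF selection
and CSP filters are fitted inside each training fold, the optimizer tunes
(c1, c2, λ) against the pooled 5-fold objectives, and the chosen triple's
pooled predictions are reported. Because the same folds pick and score the
winner, the estimate is optimistically biased — on null data (identically
distributed classes, 60 trials) the maximum over ~10² correlated
evaluations sits several accuracy points above chance. `nested` tunes
inside each outer training split and scores once on the untouched outer
fold; it is unbiased and is therefore the protocol used whenever a
generalization claim is at stake, such as the chance-level check on the
null preset. Reported metrics: pooled confusion matrix, per-class recall
(identical to CR_i by construction, asserted in tests), column-normalized
precision, and mean accuracy.

## Problem sizes in the test suite

Unit tests run on 2–6 channel toys. The end-to-end checks use the full
14-channel, 20-trials-per-class conditions with a reduced optimizer budget
of 6 wolves and 20 iterations — ample here because the TWSVM objective
surface over three hyperparameters is broad and the desk-scale feature
tables are small; the surrogate-front and archive-invariant checks use the
full published budget (12 wolves, 100 iterations).

## Known limitations

The LMD smoothing window and stopping tolerance are exposed defaults, not
canonical constants; different choices change PF shapes slightly (never
additivity). He's clamp and slow convergence make it a coarse selector on
short signals. The box-QP solver targets the small duals this problem
produces (≲ a few hundred samples); it is not an SMO-style large-scale
solver. The single-level protocol's bias is inherent to its design and is
reported as such rather than corrected.
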