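# Methods

This note documents the models, algorithms and numerical choices behind
`nmrprofile`, in the order the data flows: forward model → synthetic data →
processing → inference → quantification. It also states what the synthetic
benchmark does and does not demonstrate.

## Forward model

A compound signature is a set of clusters of Lorentzian lines. Height is the
apex intensity at unit concentration (1 µM), not the integral, so
concentration scales heights linearly; center and full width at half height
(FWHM) are in ppm. All clusters of a compound share its concentration; each
cluster carries one shift offset δ bounded by a window that brackets zero
(default ±0.025 ppm; pH-sensitive compounds may carry wider windows in a
library file). ppm axes are stored ascending and uniform; interval logic is
half-open `[lo, hi)`. Noise is additive i.i.d. Gaussian on the real channel,
consistent with the squared-error loss used downstream.

Library files are a small XML dialect
(`<library><compound><cluster><peak/>…`) or the equivalent JSON; omitted
windows default to ±0.025 ppm, and reader/writer round-trips are lossless.

## Synthetic data

`simulate.generate_library` draws random but structurally realistic
signatures: 1–4 clusters per compound, 1–4 peaks per cluster spread over
±0.012 ppm (J-coupling-scale splittings), FWHM 0.002–0.005 ppm (1–2.5 Hz at
500 MHz), heights 0.5–3 per µM, centers uniform on 0.5–9.0 ppm avoiding the
water band (4.45–5.15 ppm), windows ±0.025 ppm. Every library includes a DSS
reference singlet at 0 ppm with zero shift freedom (chemically locked); the
shift reference and the concentration reference are the same compound, as in
practice.

Ground truths sample each compound independently present with probability
0.9 and give present compounds log-uniform concentrations — serum-like
5–2000 µM, CSF-like 2–300 µM — emulating the wide dynamic range of biofluid
metabolomes; DSS is always present at 500 µM. Cluster shifts are uniform in
their windows. The observed spectrum is `gain * signal + noise` with a random
receiver gain (log-uniform 0.5–2), so absolute quantification must go through
the reference compound. Noise is calibrated so the median compound detection
threshold lands at a target concentration: 10 µM for both benchmark presets
(a 128-scan acquisition scale). Real CSF acquisitions compensate for dilution
with more scans, pushing thresholds below ~2 µM; the benchmark instead keeps
the 10 µM scale and makes CSF harder through its lower concentration range.

`distort_to_fid` inverts the processing chain: Hilbert reconstruction,
multiplication by `exp(-i(φ0 + φ1(k/N − ½)))`, addition of a smooth random
baseline (low-order cosine mixture, default amplitude 30 noise sigmas), and
inverse FFT. It is the exact inverse of `apply_phase`, so processing with the
known parameters recovers the input to rounding error.

What the generator does **not** emulate: protein background and
macromolecular baselines, residual water resonance, pH-driven shift
correlations across clusters, lineshape distortions (field inhomogeneity,
eddy currents), and library mismatch (the fitted library always matches the
generating one exactly). Benchmarks on this generator therefore measure the
method's performance limit under a correct model — the computer-generated
columns of a validation study — not performance on biological samples.

## Processing

* **FFT conventions.** `fourier_transform` = `fftshift(fft(points))` on an
  ascending ppm axis derived from the dwell time, spectrometer frequency and
  carrier; `spectrum_to_fid` is its exact inverse.
* **Hilbert reconstruction** is a causality projection (zero the acausal half
  of the time signal, double the causal half): the real channel is preserved
  exactly and the implied FID is causal.
* **Automatic phasing.** Isolated peaks are selected on a 4× Fourier-
  interpolated magnitude spectrum (phase-invariant): local maxima ≥ 8σ with
  no comparable neighbor within 3×FWHM. Each peak is fit locally with a
  complex Lorentzian `h(A + iD)e^{iθ}` plus a complex quadratic background;
  θ measures the local phase error and the background absorbs neighbor
  tails. Where the residual indicates an unresolved blend, a two-component
  common-phase model replaces the single line on strong evidence (blends of
  same-phase lines otherwise bias the apparent phase). Peaks with relative
  residual above 0.02 are dropped; the rest are weighted by 1/(q² + 10⁻⁵) —
  the θ error scales with the residual contamination q, not with height. A
  robust consensus line over (θ, position) — candidate lines through all
  well-separated peak pairs scored by a capped cost, then an
  adaptive-cap Gauss–Newton refit — seeds a cross-entropy search (population
  64, elite 10, Gaussian proposal refit, stop at std(φ0) < 10⁻³ rad or 50
  iterations, seeded, incumbent retained). Typical recovery error on the
  synthetic suite is ~0.005 rad in φ0 and ~0.01–0.05 rad in φ1.
* **Noise estimation**: 1.4826·MAD of first differences /√2 over the flattest
  decile of 128 windows; windows are scored on their first half and the
  estimate uses the second halves, so the order-statistics selection does not
  bias the result (naively estimating on the scoring samples biases ~10%
  low).
* **Baseline.** Detection iterates: Whittaker-smooth trend on the current
  baseline set, keep points within 3σ, until stable (≤ 20 iterations); the
  detection trend is 100× stiffer than the modelling smoother so it cannot
  ride up slowly-varying tails of strong peaks. Modelling: Whittaker smoother
  (second-difference penalty, λ = 10⁷ at 32768 points, scaled as the fourth
  power of point density) weighted by the mask, sampled at anchor knots taken
  only from contiguous baseline runs (≥ 16 points), carried through signal
  regions by monotone cubic Hermite (PCHIP) interpolation, which cannot
  overshoot. A single feedback pass re-phases and re-corrects when the
  corrected spectrum still carries substantial negativity. Known limitation:
  in crowded regions with no true baseline stretches the bridged curve can be
  off by 1–2σ, which dominates the error budget of weak compounds there.
* **Referencing** shifts the axis so the tallest ≥10σ peak in [−0.2, 0.2] ppm
  sits at exactly 0 ppm, with parabolic sub-grid apex refinement.
* **Solvent region**: a configurable exclusion interval (default
  4.6–5.0 ppm) is masked from phasing objectives and from profiling.

## Inference

The Gibbs posterior is `log P ∝ −loss/2σ²` with σ the estimated noise level
(the loss is noise-normalized rather than raw SSE). The axis partitions into
regions with constant cluster-influence sets; a cluster's influence interval
is its peak envelope widened by `(FWHM/2)·√(1/ε − 1)` with amplitude cutoff
ε = 10⁻³, plus the shift window. Factors (one per non-empty region) connect
to the shift variables of their clusters and the concentration variables of
the parent compounds.

Inference is Rao-Blackwellized iterative narrowing:

* Shift beliefs start as truncated Gaussians with std = window/2. Per
  iteration K = 256 particles sample the joint shift vector; for each
  particle the concentrations are solved by global nonnegative least squares
  through the Gram matrix of tail-truncated signature columns (Cholesky +
  compiled Lawson–Hanson), which the cluster-overlap sparsity makes cheap.
* Each belief is refit to the elite 25% of particles ranked by the loss
  restricted to *its own* influence region — the factorization at work.
  Ranking by total loss instead gives per-dimension selection intensity
  ~1/√d and stalls beyond ~20 shift dimensions. Beliefs shrink by 0.9 per
  iteration and freeze below the axis spacing; a belief whose region still
  holds residual above a noise/truncation floor after narrowing has locked
  onto the wrong explanation and is re-widened (up to 3 restarts). The
  incumbent best particle rides along in every population, so the best loss
  never increases. Stop when all beliefs are frozen or after 30 iterations.
* The belief mode is then polished deterministically: a conditional scan of
  each shift window (33 points + bisection to 0.03 axis spacings) accepting
  total-loss improvements, a joint 2-D scan for overlapping cluster pairs in
  regions with unexplained residual (rescues identity swaps between
  coincident clusters), and a 3-D scan for mutually-overlapping triples
  (rescues cyclic misassignments). Finally the concentrations are re-solved
  once with full-axis (untruncated) columns: absent compounds otherwise soak
  up the unmodelled tail mass as small spurious concentrations.
* ρ is capped at 2× the ratio of spectrum maximum to signature maximum.
  Ties among equal-loss particles break by particle index (deterministic
  under the seed).

On noise-free 10-compound mixtures (16384 points) the median relative
concentration error is ~10⁻³–10⁻⁴ and every shift lands well within one
axis spacing; one full 51-compound spectrum takes ~15–25 s on one CPU.

## Quantification and evaluation

Relative concentrations are scaled so the reference compound matches its
known concentration. The detection threshold of compound ℳ is
`3σ / max-unit-response(ℳ)`, scaled by a per-compound detectability factor
(default 1; library authors may raise it for compounds experts treat as hard)
and converted to µM through the reference calibration. A compound is a true
positive when truth and estimate both exceed the threshold, a true negative
when both fall below; identification accuracy is (TP + TN)/library size.
Quantification error is the median over co-detected compounds of
`|ρ − ρ̂| / max(ρ, ρ̂)` — symmetric, bounded by [0, 1], and not dominated by
high-concentration compounds; quantification *accuracy* is reported as one
minus this error so both accuracies share a scale.

## Benchmark design and problem sizes

The benchmark (`nmrprofile.benchmark`, driven by `scripts/acceptance.py`)
draws one library per preset and five mixtures from it, synthesizes
undistorted noisy spectra — these are "perfect" spectra that probe the
profiling limit, while the FID distortion path is validated separately by the
processing recovery tests — and scores the full fit + quantification against
the generating truth, excluding the reference compound from the metrics. The
acceptance script uses 32768-point spectra; the test suite uses 16384 points
and fixed seeds, a size at which results are indistinguishable from the full
grid but the whole suite stays within a coffee break.

Two constructions in the noise-free exactness check deserve note: detection
thresholds are evaluated at the nominal calibrated noise level (at an
estimated σ of ~0 the present/absent boundary is degenerate — any
infinitesimal imperfection flips a label), and ground-truth concentrations
are kept clear of each compound's own threshold, so the check isolates
deconvolution exactness from threshold straddling, which is scored separately
in the noisy benchmarks.

## Known limitations

* Lorentzian-only lineshapes; no Voigt/Gaussian components and no J-coupling
  simulation from spin systems.
* The restricted per-region loss differs from the global SSE by the tail
  mass outside the ε = 10⁻³ influence cutoff (~10⁻⁵ relative); the final
  concentration solve removes this bias but per-region diagnostics carry it.
* Baseline correction bridges crowded regions from their flanks; under dense
  multiplet forests the curve can sit 1–2σ off, limiting weak-compound
  accuracy after full FID processing (id ~0.92 on distorted-FID serum cases
  vs ~0.98 on perfect spectra).
* Identity rescue handles coincident pairs and triples; deeper entanglements
  (4+ mutually-coincident clusters) may still converge to a local optimum.
* Posterior uncertainty (credible intervals) is not quantified; diagnostics
  expose belief trajectories and loss traces only.
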