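# nmrprofile

Automated processing and targeted profiling of 1D ¹H NMR spectra of complex
mixtures — the computational core of NMR-based metabolomics. Given a raw free
induction decay (FID) or a frequency-domain spectrum and a library of
compound signatures, the package produces a *metabolic profile*: the list of
library metabolites with their absolute concentrations and present/absent
calls. It is aimed at people building or validating automated quantitative
NMR pipelines (serum, CSF and similar biofluids) and at method developers who
need a fully synthetic, ground-truthed test bed for spectral deconvolution.

## The model

A compound signature ℳ is a set of peak clusters {𝒞}; each cluster is a set
of Lorentzian lines, each parameterized by apex height *h* (response at 1 µM),
center *c* (ppm) and full width at half height *w*. Two variables attach to a
signature in a given spectrum: its concentration ρ_ℳ, which scales all peak
heights linearly, and one chemical-shift offset δ_𝒞 per cluster, bounded by a
per-cluster window (default ±0.025 ppm). A mixture spectrum is the linear
superposition

  s(x) = Σ_ℳ ρ_ℳ Σ_{𝒞∈ℳ} Σ_{p∈𝒞} h_p (w_p/2)² / ((x − c_p − δ_𝒞)² + (w_p/2)²) + ε(x)

with i.i.d. Gaussian noise ε. Profiling inverts this: find the (ρ, δ) that
minimize the sum of squared residuals, equivalently maximize the Gibbs
posterior ℙ(ρ, δ) ∝ exp(−loss/2σ²).

Because a Lorentzian dies off quickly and each δ ranges over a small window,
every cluster influences only a short ppm interval. The axis therefore
partitions into regions with constant cluster-influence sets, the loss
factors over those regions, and the posterior is a factor graph over
concentration and shift variables. Inference is sequential Monte Carlo with
iterative narrowing: each shift carries a truncated-Gaussian belief; per
iteration, particles sample the shift vector, concentrations are solved
conditionally by nonnegative least squares (the model is linear in ρ), and
each belief is refit to the particles that reconstruct its own region best,
shrinking until every belief is narrower than the axis spacing. A
deterministic conditional scan then polishes each shift (and jointly rescues
coincident cluster pairs/triples that a narrowing scheme cannot untangle).
Concentrations are made absolute by scaling against an internal reference
standard (DSS) of known concentration, and each compound gets an SNR-derived
detection threshold (3σ over its unit-concentration apex response).

The spectral processing chain in front of the fitter is fully automatic:
zero-filling, Fourier and Hilbert transformation, automatic zero/first-order
phasing (per-peak local phase measurement + cross-entropy refinement),
baseline detection by iterative thresholding and correction with a Whittaker
smoother plus monotone cubic Hermite interpolation, optional smoothing, and
chemical-shift referencing to the DSS singlet.

A synthetic-data module generates random libraries, ground-truth profiles,
noisy spectra, and distorted FIDs (known phase error and baseline drift) from
the same forward model, so every stage is testable against a known answer.

## Worked example

Simulate a serum-like study case (50 random compounds + DSS, concentrations
log-uniform 5–2000 µM, noise calibrated to ~10 µM detection thresholds, the
FID distorted by a random phase error and baseline drift), then run the full
chain and score it against the generating truth:

```
$ nmrprofile simulate --preset serum --seed 7 --n-points 16384 --outdir case
wrote case (serum-like, seed 7) to case/

$ nmrprofile process --input case/fid.json --output case/processed.json --seed 7
phi0=-0.4074 rad, phi1=+0.1427 rad, offset=+0.00004 ppm, sigma=20.85

$ nmrprofile fit --spectrum case/processed.json --library case/library.json \
      --output case/profile.csv --seed 7
fit converged=False after 30 iterations

$ nmrprofile evaluate --profile case/profile.csv --truth case/truth.json \
      --output case/report.json
id_accuracy=0.920 (tp=32 tn=14 fp=0 fn=4), median_rel_error=0.046285729011905155
```

The `process` line reports the recovered phase correction (the case was
distorted by φ0 = −0.398, φ1 = +0.149 rad), the axis re-referencing offset and
the estimated noise level. The evaluation line is the headline score: 46 of
50 compounds are labelled correctly against the ground truth at their
detection thresholds, and among the co-detected compounds the median relative
concentration error is 4.6%. On undistorted ("perfect") spectra, where only
noise separates the fit from the truth, identification accuracy is typically
0.96–1.00 and the median relative error under 2% (see below). `nmrprofile run
--config run.toml` executes the same chain in one step and writes a manifest
with the seed and input hashes for reproducibility.

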