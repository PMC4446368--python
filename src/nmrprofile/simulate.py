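"""Synthetic libraries, ground-truth profiles, spectra and distorted FIDs.

Emulates computer-generated validation mixtures: compound signatures are drawn
at random, a ground-truth profile samples which compounds occur and at what
concentration, the mixture spectrum is synthesized from the forward model, and
an optional inverse-processing step turns it into a raw FID with known phase
error and baseline distortion so the whole processing chain can be exercised
against a known answer.

Presets
-------
``serum_preset`` — 50 compounds, occurrence 0.9, log-uniform 5–2000 uM,
noise calibrated so median detection thresholds sit near 10 uM (a 128-scan
acquisition).
``csf_preset`` — 48 compounds at lower concentrations (2–300 uM), same
noise calibration: what makes the CSF-like benchmark harder is that its
concentration range sits much closer to the detection thresholds. (Real CSF
acquisitions compensate for dilution with more scans — 1024 rather than
128 — pushing thresholds below 2 uM; model that by lowering
``target_threshold``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from .model import (
    DEFAULT_SHIFT_WINDOW,
    Cluster,
    CompoundSignature,
    InvalidParameterError,
    Peak,
    ProfileAssignment,
    SpectralLibrary,
    Spectrum,
    synthesize_mixture,
)
from .processing import FID, hilbert_reconstruct, phase_ramp, spectrum_to_fid

__all__ = [
    "LibraryParams",
    "GroundTruthCase",
    "generate_library",
    "sample_truth",
    "distort_to_fid",
    "default_axis",
    "noise_sigma_for_threshold",
    "generate_case",
    "serum_preset",
    "csf_preset",
    "REFERENCE_NAME",
    "REFERENCE_CONCENTRATION",
]

#: Name and known concentration (uM) of the chemical-shift / quantity
#: reference singlet (DSS) that every synthetic mixture contains.
REFERENCE_NAME = "DSS"
REFERENCE_CONCENTRATION = 500.0


@dataclass(frozen=True)
class LibraryParams:
    """Bounds for random signature generation.

    Linewidths default to 1–2.5 Hz at 500 MHz (0.002–0.005 ppm); cluster
    centers avoid the water/solvent band around 4.6–5.0 ppm, which profiling
    excludes anyway.
    """

    clusters_range: tuple[int, int] = (1, 4)
    peaks_range: tuple[int, int] = (1, 4)
    center_range: tuple[float, float] = (0.5, 9.0)
    avoid_band: tuple[float, float] = (4.45, 5.15)
    fwhm_range: tuple[float, float] = (0.002, 0.005)
    height_range: tuple[float, float] = (0.5, 3.0)
    multiplet_spread: float = 0.012
    shift_window: float = DEFAULT_SHIFT_WINDOW

    def validate(self) -> None:
        for name in ("clusters_range", "peaks_range", "center_range", "fwhm_range", "height_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidParameterError(f"{name}: lo {lo} > hi {hi}")
        if self.clusters_range[0] < 1 or self.peaks_range[0] < 1:
            raise InvalidParameterError("need at least 1 cluster and 1 peak")


@dataclass
class GroundTruthCase:
    """One fully reproducible synthetic study case."""

    library: SpectralLibrary
    truth: ProfileAssignment
    spectrum: Spectrum
    fid: FID | None
    seed: int
    gain: float = 1.0
    noise_sigma: float = 0.0
    phase: tuple[float, float] = (0.0, 0.0)


def default_axis(n_points: int = 32768, lo: float = -1.0, hi: float = 11.0) -> NDArray:
    """Standard acquisition grid: a 12 ppm sweep centered near the water line,
    endpoint-exclusive so the implied spectral width is exactly ``hi - lo``."""
    return lo + (hi - lo) * np.arange(n_points) / n_points


def _reference_signature() -> CompoundSignature:
    # DSS trimethyl singlet at 0 ppm; chemically locked, so no shift freedom
    return CompoundSignature(
        REFERENCE_NAME,
        (Cluster("DSS:0", (Peak(height=9.0, center=0.0, fwhm=0.0025),), 0.0, 0.0),),
    )


def generate_library(
    n_compounds: int,
    seed: int = 0,
    params: LibraryParams | None = None,
    frequency: float = 500.0,
    biofluid_tag: str = "synthetic",
    include_reference: bool = True,
) -> SpectralLibrary:
    """Draw a random but valid compound library (deterministic given seed)."""
    if n_compounds < 1:
        raise InvalidParameterError("n_compounds must be >= 1")
    p = params or LibraryParams()
    p.validate()
    rng = np.random.default_rng(seed)
    compounds = []
    for i in range(n_compounds):
        n_cl = int(rng.integers(p.clusters_range[0], p.clusters_range[1] + 1))
        clusters = []
        for k in range(n_cl):
            while True:
                center = float(rng.uniform(*p.center_range))
                if not (p.avoid_band[0] <= center <= p.avoid_band[1]):
                    break
            n_pk = int(rng.integers(p.peaks_range[0], p.peaks_range[1] + 1))
            offsets = np.sort(rng.uniform(-p.multiplet_spread, p.multiplet_spread, n_pk))
            if n_pk == 1:
                offsets = np.array([0.0])
            peaks = tuple(
                Peak(
                    height=float(rng.uniform(*p.height_range)),
                    center=center + float(off),
                    fwhm=float(rng.uniform(*p.fwhm_range)),
                )
                for off in offsets
            )
            clusters.append(
                Cluster(f"M{i:03d}:{k}", peaks, -p.shift_window, p.shift_window)
            )
        compounds.append(CompoundSignature(f"M{i:03d}", tuple(clusters)))
    if include_reference:
        compounds.append(_reference_signature())
    return SpectralLibrary(compounds, frequency=frequency, biofluid_tag=biofluid_tag)


def sample_truth(
    lib: SpectralLibrary,
    occurrence_prob: float = 0.9,
    conc_range: tuple[float, float] = (5.0, 2000.0),
    seed: int = 0,
    reference_concentration: float | None = REFERENCE_CONCENTRATION,
) -> ProfileAssignment:
    """Sample a ground-truth profile.

    Each non-reference compound is present independently with
    ``occurrence_prob``; present compounds get a log-uniform concentration in
    ``conc_range``. Every cluster gets a shift drawn uniformly in its window.
    The reference compound, when in the library, is always present at the
    known reference concentration.
    """
    if not (0.0 <= occurrence_prob <= 1.0):
        raise InvalidParameterError("occurrence_prob must be in [0, 1]")
    if conc_range[0] <= 0 or conc_range[0] > conc_range[1]:
        raise InvalidParameterError("conc_range must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    conc: dict[str, float] = {}
    shifts: dict[str, float] = {}
    log_lo, log_hi = np.log(conc_range[0]), np.log(conc_range[1])
    for comp in lib.compounds:
        if comp.name == REFERENCE_NAME and reference_concentration is not None:
            conc[comp.name] = reference_concentration
        elif rng.random() < occurrence_prob:
            conc[comp.name] = float(np.exp(rng.uniform(log_lo, log_hi)))
        for cl in comp.clusters:
            shifts[cl.cluster_id] = float(rng.uniform(cl.shift_lo, cl.shift_hi))
    return ProfileAssignment(conc, shifts)


def noise_sigma_for_threshold(
    lib: SpectralLibrary,
    target_threshold: float,
    k_det: float = 3.0,
) -> float:
    """Noise level at which the *median* compound detection threshold equals
    ``target_threshold`` uM: threshold = k * sigma / max unit intensity."""
    heights = [
        c.max_unit_intensity() for c in lib.compounds if c.name != REFERENCE_NAME
    ]
    return target_threshold * float(np.median(heights)) / k_det


def _default_baseline(axis: NDArray, amplitude: float, seed: int) -> NDArray:
    """A smooth random drift: low-order cosine mixture over the sweep."""
    rng = np.random.default_rng(seed)
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    out = np.zeros_like(axis)
    for m in range(1, 4):
        out += rng.normal(0, 1) * np.cos(np.pi * m * t) + rng.normal(0, 1) * t**m
    peak = np.abs(out).max()
    if peak > 0:
        out *= amplitude / peak
    return out


def distort_to_fid(
    spectrum: Spectrum,
    phi0: float = 0.0,
    phi1: float = 0.0,
    baseline: NDArray | float | None = None,
    seed: int = 0,
) -> FID:
    """Turn a real spectrum into a raw FID with known distortions.

    The imaginary channel is reconstructed by Hilbert transformation, the
    complex spectrum is de-phased by ``exp(-i(phi0 + phi1*(k/N - 1/2)))``
    (the exact inverse of ``apply_phase(phi0, phi1)``), the baseline curve is
    added in the frequency domain, and the result is inverse Fourier
    transformed. ``baseline`` may be a curve, an amplitude for a random smooth
    drift (seeded), or None.
    """
    spec = hilbert_reconstruct(spectrum)
    vals = spec.complex_values()
    n = vals.size
    vals = vals * np.exp(-1j * phase_ramp(n, phi0, phi1))
    if baseline is not None:
        if np.isscalar(baseline):
            baseline = _default_baseline(spectrum.ppm_axis, float(baseline), seed)
        vals = vals + np.asarray(baseline, dtype=float)
    distorted = spec.copy()
    distorted.real = vals.real
    distorted.imag = vals.imag
    return spectrum_to_fid(distorted)


@dataclass(frozen=True)
class CasePreset:
    """Study conditions for one synthetic biofluid."""

    name: str
    n_compounds: int
    occurrence_prob: float
    conc_range: tuple[float, float]
    target_threshold: float
    gain_range: tuple[float, float] = (0.5, 2.0)
    phi0_range: tuple[float, float] = (-0.6, 0.6)
    phi1_range: tuple[float, float] = (-0.4, 0.4)
    baseline_rel: float = 30.0  # drift amplitude in units of noise sigma
    library_params: LibraryParams = field(default_factory=LibraryParams)


serum_preset = CasePreset(
    name="serum-like",
    n_compounds=50,
    occurrence_prob=0.9,
    conc_range=(5.0, 2000.0),
    target_threshold=10.0,
)

csf_preset = CasePreset(
    name="csf-like",
    n_compounds=48,
    occurrence_prob=0.9,
    conc_range=(2.0, 300.0),
    target_threshold=10.0,
)


def generate_case(
    preset: CasePreset,
    seed: int,
    axis: NDArray | None = None,
    library: SpectralLibrary | None = None,
    make_fid: bool = True,
) -> GroundTruthCase:
    """Generate one fully seeded study case from a preset.

    The observed spectrum is ``gain * signal + noise`` (gain emulates receiver
    scaling, so absolute quantification must go through the reference
    compound), optionally wrapped into a distorted FID.
    """
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = default_axis()
    if library is None:
        library = generate_library(
            preset.n_compounds, seed=int(rng.integers(2**31)), params=preset.library_params
        )
    truth = sample_truth(
        library, preset.occurrence_prob, preset.conc_range, seed=int(rng.integers(2**31))
    )
    gain = float(np.exp(rng.uniform(*np.log(preset.gain_range))))
    sigma = gain * noise_sigma_for_threshold(library, preset.target_threshold)
    clean = synthesize_mixture(library, truth, axis)
    noisy = clean.copy()
    noisy.real = gain * clean.real
    spectrum = Spectrum(
        axis,
        noisy.real + rng.normal(0.0, sigma, axis.size),
        frequency=library.frequency,
        noise_sigma=sigma,
    )
    fid = None
    phi0 = phi1 = 0.0
    if make_fid:
        phi0 = float(rng.uniform(*preset.phi0_range))
        phi1 = float(rng.uniform(*preset.phi1_range))
        fid = distort_to_fid(
            spectrum, phi0, phi1,
            baseline=preset.baseline_rel * sigma,
            seed=int(rng.integers(2**31)),
        )
    return GroundTruthCase(
        library, truth, spectrum, fid, seed, gain, sigma, (phi0, phi1)
    )
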