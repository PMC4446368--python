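"""Absolute quantification, SNR-based detection calls, and accuracy metrics.

Profiling yields *relative* concentrations; scaling them so the reference
compound (DSS or TSP, included at known concentration) matches its known value
gives absolute uM. Presence calls use a per-compound detection threshold
proportional to the spectral noise level: a compound whose unit-concentration
signature has apex height h is detectable once ``rho * h`` clears
``k_det * sigma``, scaled by an expert-style per-compound detectability
factor.

A compound is scored a true positive when both the true and estimated
concentrations exceed the detection threshold, a true negative when both fall
below it; identification accuracy is (TP + TN) / library size. Quantification
error is the median over compounds of ``|rho - rho_hat| / max(rho, rho_hat)``,
a symmetric relative measure that is not dominated by high-concentration
compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import InvalidParameterError, SpectralLibrary, Spectrum

__all__ = [
    "QuantificationError",
    "MetabolicProfile",
    "EvaluationReport",
    "absolute_quantify",
    "detection_threshold",
    "build_profile",
    "identification_accuracy",
    "quantification_error",
]


class QuantificationError(RuntimeError):
    """Absolute quantification is impossible (reference compound not fit)."""


@dataclass
class MetabolicProfile:
    """Final per-compound table: absolute concentration (uM), detection
    threshold (uM), presence call, and fitted cluster shifts (ppm)."""

    concentrations: dict[str, float]
    thresholds: dict[str, float]
    detected: dict[str, bool]
    shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, rho in self.concentrations.items():
            if rho < 0:
                raise InvalidParameterError(f"concentration[{name!r}] < 0")
            want = rho >= self.thresholds[name]
            if self.detected[name] != want:
                raise InvalidParameterError(
                    f"{name!r}: detected flag inconsistent with threshold"
                )


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    id_accuracy: float
    median_rel_error: float | None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def absolute_quantify(
    relative_rho: dict[str, float],
    ref_compound: str,
    ref_concentration: float,
) -> dict[str, float]:
    """Scale relative concentrations so the reference compound equals its
    known concentration (uM)."""
    rho_ref = relative_rho.get(ref_compound, 0.0)
    if rho_ref <= 0:
        raise QuantificationError(
            f"reference compound {ref_compound!r} was not found in the fit "
            f"(relative rho = {rho_ref})"
        )
    scale = ref_concentration / rho_ref
    return {name: rho * scale for name, rho in relative_rho.items()}


def detection_threshold(
    spectrum: Spectrum,
    compound,
    calibration: float = 1.0,
    k_det: float = 3.0,
) -> float:
    """Minimum detectable concentration (uM) for one compound.

    ``k_det * sigma`` intensity units divided by the compound's maximum
    unit-concentration response, converted to uM via the reference
    ``calibration`` (uM per relative unit) and scaled by the compound's
    detectability factor.
    """
    sigma = spectrum.noise_sigma
    if sigma is None:
        from .processing import estimate_noise

        sigma = estimate_noise(spectrum)
    h = compound.max_unit_intensity()
    if h <= 0:
        return float("inf")
    return k_det * sigma / h * compound.detectability_factor * calibration


def build_profile(
    spectrum: Spectrum,
    lib: SpectralLibrary,
    relative_rho: dict[str, float],
    shifts: dict[str, float],
    ref_compound: str,
    ref_concentration: float,
    k_det: float = 3.0,
) -> MetabolicProfile:
    """Assemble the final metabolic profile from a relative fit: absolute
    concentrations, per-compound thresholds and presence calls."""
    conc = absolute_quantify(relative_rho, ref_compound, ref_concentration)
    calibration = ref_concentration / relative_rho[ref_compound]
    thresholds = {
        c.name: detection_threshold(spectrum, c, calibration, k_det)
        for c in lib.compounds
    }
    detected = {name: conc.get(name, 0.0) >= thresholds[name] for name in lib.names}
    return MetabolicProfile(
        concentrations={name: conc.get(name, 0.0) for name in lib.names},
        thresholds=thresholds,
        detected=detected,
        shifts=dict(shifts),
    )


def identification_accuracy(
    truth: dict[str, float],
    estimate: dict[str, float],
    thresholds: dict[str, float],
) -> EvaluationReport:
    """Confusion counts over the library and (TP + TN) / library size.

    ``thresholds`` defines the library: every compound must have a threshold;
    truth/estimate entries outside it are an error.
    """
    extra = (set(truth) | set(estimate)) - set(thresholds)
    if extra:
        raise InvalidParameterError(f"compounds without thresholds: {sorted(extra)}")
    tp = fp = tn = fn = 0
    errs: list[float] = []
    for name, thr in thresholds.items():
        t = truth.get(name, 0.0) >= thr
        e = estimate.get(name, 0.0) >= thr
        if t and e:
            tp += 1
            errs.append(_rel_err(truth[name], estimate[name]))
        elif t and not e:
            fn += 1
        elif not t and e:
            fp += 1
        else:
            tn += 1
    n = len(thresholds)
    med = float(np.median(errs)) if errs else None
    return EvaluationReport(tp, fp, tn, fn, (tp + tn) / n if n else 0.0, med)


def _rel_err(a: float, b: float) -> float:
    m = max(a, b)
    return abs(a - b) / m if m > 0 else 0.0


def quantification_error(
    truth: dict[str, float],
    estimate: dict[str, float],
    detected_both: set[str] | None = None,
) -> float | None:
    """Median over compounds of ``|rho - rho_hat| / max(rho, rho_hat)``.

    Computed over ``detected_both`` if given, else over the compounds present
    in both maps with a positive value on either side. Returns None when the
    intersection is empty (undefined, not zero).
    """
    if detected_both is None:
        detected_both = {
            k for k in set(truth) & set(estimate) if max(truth[k], estimate[k]) > 0
        }
    errs = [_rel_err(truth[k], estimate[k]) for k in detected_both]
    return float(np.median(errs)) if errs else None
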