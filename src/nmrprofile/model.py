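"""Compound-signature domain model and the forward (synthesis) model.

A metabolite signature is a set of peak *clusters*; each cluster is a set of
Lorentzian peaks that shift together as a rigid unit by a single chemical-shift
offset bounded by a per-cluster window. A mixture spectrum is the linear
superposition of its compounds' signatures: concentration scales peak heights,
and each cluster's offset translates its peaks.

Conventions
-----------
* ppm axes are stored ascending and uniformly spaced; display may reverse.
* Peak ``height`` is the apex intensity at unit concentration (1 uM), not the
  integral; concentration scales heights linearly.
* All interval logic is half-open ``[lo, hi)`` with 0-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "Peak",
    "Cluster",
    "CompoundSignature",
    "SpectralLibrary",
    "ProfileAssignment",
    "Spectrum",
    "DEFAULT_SHIFT_WINDOW",
    "eval_lorentzian",
    "synthesize_compound",
    "synthesize_mixture",
]

#: Default allowable chemical-shift half-window for a cluster (ppm).
DEFAULT_SHIFT_WINDOW = 0.025


class InvalidParameterError(ValueError):
    """A domain parameter violates its invariant."""


class ShiftWindowError(ValueError):
    """A cluster shift falls outside its allowable window."""


class UnknownCompoundError(KeyError):
    """A profile refers to a compound absent from the library."""


@dataclass(frozen=True)
class Peak:
    """One Lorentzian line: apex ``height`` at unit concentration, ``center``
    in ppm and full width at half height ``fwhm`` in ppm."""

    height: float
    center: float
    fwhm: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise InvalidParameterError(f"peak height must be > 0, got {self.height}")
        if not self.fwhm > 0:
            raise InvalidParameterError(f"peak fwhm must be > 0, got {self.fwhm}")


@dataclass(frozen=True)
class Cluster:
    """A multiplet: peaks that translate together by one offset delta with
    ``shift_lo <= delta <= shift_hi`` (shift_lo <= 0 <= shift_hi)."""

    cluster_id: str
    peaks: tuple[Peak, ...]
    shift_lo: float = -DEFAULT_SHIFT_WINDOW
    shift_hi: float = DEFAULT_SHIFT_WINDOW

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if len(self.peaks) == 0:
            raise InvalidParameterError(f"cluster {self.cluster_id!r} has no peaks")
        if not (self.shift_lo <= 0.0 <= self.shift_hi):
            raise InvalidParameterError(
                f"cluster {self.cluster_id!r}: window [{self.shift_lo}, "
                f"{self.shift_hi}] must bracket 0"
            )

    def contains_shift(self, delta: float) -> bool:
        return self.shift_lo <= delta <= self.shift_hi


@dataclass(frozen=True)
class CompoundSignature:
    """A metabolite's library entry: a named, nonempty set of clusters plus a
    relative detectability factor (>= 0, 1.0 = typical)."""

    name: str
    clusters: tuple[Cluster, ...]
    detectability_factor: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        if len(self.clusters) == 0:
            raise InvalidParameterError(f"compound {self.name!r} has no clusters")
        if self.detectability_factor < 0:
            raise InvalidParameterError(
                f"compound {self.name!r}: detectability_factor must be >= 0"
            )
        ids = [c.cluster_id for c in self.clusters]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError(f"compound {self.name!r}: duplicate cluster ids")

    def max_unit_intensity(self, resolution: float = 1e-4) -> float:
        """Apex of the unit-concentration signature (zero shifts), found on a
        fine grid around each peak center. Used for detection thresholds."""
        best = 0.0
        for cl in self.clusters:
            for pk in cl.peaks:
                x = np.arange(pk.center - 2 * pk.fwhm, pk.center + 2 * pk.fwhm, resolution)
                y = np.zeros_like(x)
                for q in cl.peaks:
                    y += eval_lorentzian(q, 0.0, x)
                best = max(best, float(y.max()))
        return best


@dataclass
class SpectralLibrary:
    """A biofluid-specific set of compound signatures at one spectrometer
    frequency (MHz)."""

    compounds: list[CompoundSignature]
    frequency: float = 500.0
    biofluid_tag: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidParameterError(f"duplicate compound names: {dupes}")
        for c in self.compounds:
            for cl in c.clusters:
                if not (np.isfinite(cl.shift_lo) and np.isfinite(cl.shift_hi)):
                    raise InvalidParameterError(
                        f"non-finite shift window on {c.name}/{cl.cluster_id}"
                    )

    def __len__(self) -> int:
        return len(self.compounds)

    def __getitem__(self, name: str) -> CompoundSignature:
        for c in self.compounds:
            if c.name == name:
                return c
        raise UnknownCompoundError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.compounds)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def clusters(self):
        """Yield (compound, cluster) pairs over the whole library."""
        for c in self.compounds:
            for cl in c.clusters:
                yield c, cl


@dataclass
class ProfileAssignment:
    """An assignment of the inference variables: per-compound concentrations
    rho (uM, >= 0) and per-cluster shift offsets delta (ppm)."""

    concentrations: dict[str, float] = field(default_factory=dict)
    shifts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, rho in self.concentrations.items():
            if rho < 0:
                raise InvalidParameterError(f"rho[{name!r}] = {rho} < 0")

    def validate_against(self, lib: SpectralLibrary) -> None:
        for name in self.concentrations:
            if name not in lib:
                raise UnknownCompoundError(name)
        for comp, cl in lib.clusters():
            d = self.shifts.get(cl.cluster_id)
            if d is not None and not cl.contains_shift(d):
                raise ShiftWindowError(
                    f"shift {d} outside window [{cl.shift_lo}, {cl.shift_hi}] "
                    f"for cluster {cl.cluster_id!r} of {comp.name!r}"
                )


@dataclass
class Spectrum:
    """A frequency-domain spectrum on a uniform ascending ppm axis.

    ``imag`` is present only after Hilbert reconstruction or a complex Fourier
    transform; ``noise_sigma`` is filled in by noise estimation.
    """

    ppm_axis: NDArray[np.floating]
    real: NDArray[np.floating]
    imag: NDArray[np.floating] | None = None
    frequency: float = 500.0
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.real = np.asarray(self.real, dtype=float)
        n = self.ppm_axis.size
        if n < 2:
            raise InvalidParameterError("ppm axis needs at least 2 points")
        d = np.diff(self.ppm_axis)
        if d[0] <= 0 or not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise InvalidParameterError("ppm axis must be uniform and ascending")
        if self.real.shape != self.ppm_axis.shape:
            raise InvalidParameterError("real array length != axis length")
        if self.imag is not None:
            self.imag = np.asarray(self.imag, dtype=float)
            if self.imag.shape != self.ppm_axis.shape:
                raise InvalidParameterError("imag array length != axis length")

    @property
    def n_points(self) -> int:
        return self.ppm_axis.size

    @property
    def spacing(self) -> float:
        return float(self.ppm_axis[1] - self.ppm_axis[0])

    @property
    def is_complex(self) -> bool:
        return self.imag is not None

    def complex_values(self) -> NDArray[np.complexfloating]:
        if self.imag is None:
            raise InvalidParameterError("spectrum has no imaginary channel")
        return self.real + 1j * self.imag

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.ppm_axis.copy(),
            self.real.copy(),
            None if self.imag is None else self.imag.copy(),
            self.frequency,
            self.noise_sigma,
        )


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def eval_lorentzian(peak: Peak, shift: float, x: NDArray) -> NDArray:
    """Evaluate one Lorentzian line on ``x`` (ppm), translated by ``shift``.

    Returns ``h * g^2 / ((x - c - shift)^2 + g^2)`` with ``g = fwhm / 2`` so
    the apex equals ``height`` and the value at one half-width from the center
    equals ``height / 2``.
    """
    if not peak.fwhm > 0:
        raise InvalidParameterError(f"fwhm must be > 0, got {peak.fwhm}")
    g = peak.fwhm / 2.0
    dx = np.asarray(x, dtype=float) - peak.center - shift
    return peak.height * g * g / (dx * dx + g * g)


def synthesize_compound(
    sig: CompoundSignature,
    rho: float,
    shifts: dict[str, float],
    axis: NDArray,
) -> NDArray:
    """Unit signature scaled by concentration: ``rho * sum_clusters sum_peaks
    L(peak, delta_cluster)``.

    ``shifts`` must supply an in-window offset for every cluster of ``sig``.
    """
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    if rho == 0.0:
        return out
    for cl in sig.clusters:
        if cl.cluster_id not in shifts:
            raise ShiftWindowError(
                f"no shift supplied for cluster {cl.cluster_id!r} of {sig.name!r}"
            )
        d = shifts[cl.cluster_id]
        if not cl.contains_shift(d):
            raise ShiftWindowError(
                f"shift {d} outside window [{cl.shift_lo}, {cl.shift_hi}] "
                f"for cluster {cl.cluster_id!r} of {sig.name!r}"
            )
        for pk in cl.peaks:
            out += eval_lorentzian(pk, d, axis)
    out *= rho
    return out


def synthesize_mixture(
    lib: SpectralLibrary,
    assign: ProfileAssignment,
    axis: NDArray,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> Spectrum:
    """Draw a mixture spectrum: pointwise sum of the compound syntheses, plus
    optional i.i.d. zero-mean Gaussian noise on the real channel.

    Compounds absent from ``assign.concentrations`` contribute rho = 0.
    """
    axis = np.asarray(axis, dtype=float)
    assign.validate_against(lib)
    total = np.zeros_like(axis)
    for comp in lib.compounds:
        rho = assign.concentrations.get(comp.name, 0.0)
        if rho == 0.0:
            continue
        shifts = {cl.cluster_id: assign.shifts.get(cl.cluster_id, 0.0) for cl in comp.clusters}
        total += synthesize_compound(comp, rho, shifts, axis)
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        total = total + rng.normal(0.0, noise_sigma, size=axis.size)
    return Spectrum(
        ppm_axis=axis,
        real=total,
        frequency=lib.frequency,
        noise_sigma=noise_sigma if noise_sigma > 0 else None,
    )
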