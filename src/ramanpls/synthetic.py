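"""Synthetic Raman spectrum generator for the polymorph mixture study.

Each pure component (the three carbamazepine crystal forms plus one pooled
excipient blend) is modelled as a sum of Gaussian/Lorentzian bands.  A
tablet spectrum is the mass-fraction-weighted sum of the pure-component
spectra; replicate acquisitions add a multiplicative gain (laser/focus
variation), a per-replicate quadratic baseline, subsampling jitter on the
component weights (the laser spot sees a slightly different local
composition at each point on the tablet surface) and additive noise.

By construction each crystal form owns at least one band no other
component has near it, inside the regions where the real polymorphs are
spectrally distinctive (160-250, 700-800 and 1000-1100 cm^-1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .design import MixtureSample, mass_fractions
from .spectra import AXIS_MAX, AXIS_MIN, Spectrum

logger = logging.getLogger(__name__)

#: Component names, in the fixed order used for weight vectors.
POLYMORPHS = ("CBZ_I", "CBZ_III", "CBZ_DH")
COMPONENTS = POLYMORPHS + ("EXCIPIENT",)

#: Wavenumber regions (cm^-1) in which each polymorph carries a distinctive band.
UNIQUE_REGIONS = ((160.0, 250.0), (700.0, 800.0), (1000.0, 1100.0))

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # fwhm = 2*sqrt(2 ln 2) * sigma


@dataclass(frozen=True)
class Peak:
    """One spectral band: center (cm^-1), fwhm (cm^-1), amplitude, shape."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Evaluate the band on ``axis``; unit height at the center."""
        x = np.asarray(axis, dtype=float) - self.center
        if self.shape == "gaussian":
            sigma = self.fwhm / _GAUSS_FWHM
            return self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        gamma = self.fwhm / 2.0  # lorentzian: fwhm = 2*gamma
        return self.amplitude * gamma**2 / (x**2 + gamma**2)


@dataclass(frozen=True)
class PeakModel:
    """A pure-component spectrum as a list of peaks."""

    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError("a component needs at least one peak")
        for p in self.peaks:
            if not (AXIS_MIN <= p.center <= AXIS_MAX):
                raise ValueError(f"peak center {p.center} outside {AXIS_MIN}-{AXIS_MAX} cm^-1")


@dataclass(frozen=True)
class ComponentLibrary:
    """Peak models for the four components of the tablet."""

    components: dict[str, PeakModel]

    def __post_init__(self) -> None:
        if set(self.components) != set(COMPONENTS):
            raise ValueError(f"library must contain exactly {COMPONENTS}")

    def unique_peaks(self, name: str) -> list[Peak]:
        """Peaks of ``name`` with no other component's band center within one fwhm."""
        own = self.components[name].peaks
        others = [
            p.center
            for other, model in self.components.items()
            if other != name
            for p in model.peaks
        ]
        return [p for p in own if all(abs(p.center - c) > p.fwhm for c in others)]

    def validate(self) -> None:
        """Raise if any polymorph lacks a unique band in a distinctive region."""
        for name in POLYMORPHS:
            uniques = self.unique_peaks(name)
            if not any(
                lo <= p.center <= hi for p in uniques for lo, hi in UNIQUE_REGIONS
            ):
                raise ValueError(
                    f"{name} has no unique peak inside any of the regions {UNIQUE_REGIONS}"
                )


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-to-replicate variability of the simulated acquisitions.

    additive_sd : s.d. of i.i.d. Gaussian noise, intensity units.
    gain_sd : s.d. of the log of the multiplicative gain (mean-1 lognormal).
    baseline_amplitude : scale of the per-replicate quadratic baseline.
    subsample_jitter_sd : relative s.d. of per-replicate component-weight jitter.
    n_replicates : spectra acquired per tablet (10 in the study protocol).
    seed : master seed; every stream is derived from it deterministically.
    """

    additive_sd: float = 0.0
    gain_sd: float = 0.0
    baseline_amplitude: float = 0.0
    subsample_jitter_sd: float = 0.0
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "gain_sd", "baseline_amplitude", "subsample_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


#: Named noise levels.  The study does not report instrument noise figures,
#: so "low" and "paper_like" are plausible settings exposed as configuration.
NOISE_PRESETS: dict[str, dict[str, float]] = {
    "none": dict(additive_sd=0.0, gain_sd=0.0, baseline_amplitude=0.0, subsample_jitter_sd=0.0),
    "low": dict(additive_sd=5e-4, gain_sd=0.01, baseline_amplitude=2e-3, subsample_jitter_sd=0.01),
    "paper_like": dict(additive_sd=2e-3, gain_sd=0.05, baseline_amplitude=8e-3, subsample_jitter_sd=0.04),
}


def noise_preset(name: str, seed: int = 0, n_replicates: int = 10) -> NoiseModel:
    """Build a :class:`NoiseModel` from a named preset."""
    key = name.replace("-", "_")
    if key not in NOISE_PRESETS:
        raise ValueError(f"unknown noise preset {name!r}; choose from {sorted(NOISE_PRESETS)}")
    return NoiseModel(seed=seed, n_replicates=n_replicates, **NOISE_PRESETS[key])


# Anchor bands guaranteed unique to each polymorph, one per distinctive region.
# Spaced >= 30 cm^-1 apart so that fwhm <= 12 keeps them mutually unique.
_ANCHORS: dict[str, tuple[float, ...]] = {
    "CBZ_I": (172.0, 712.0, 1012.0),
    "CBZ_III": (206.0, 752.0, 1052.0),
    "CBZ_DH": (240.0, 792.0, 1092.0),
}
_ANCHOR_EXCLUSION = 26.0  # cm^-1 kept clear around every anchor center


def default_library(seed: int = 0) -> ComponentLibrary:
    """Deterministic random component library satisfying the uniqueness invariant.

    Each polymorph receives its three anchor bands plus 5-12 random bands
    (8-15 total); the excipient blend gets broad, low-amplitude bands spread
    over the axis, emulating the weak Raman response of cellulose-dominated
    excipients relative to the aromatic API.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    forbidden = [c for centers in _ANCHORS.values() for c in centers]
    components: dict[str, PeakModel] = {}
    for name in POLYMORPHS:
        peaks = [
            Peak(center=c, fwhm=float(rng.uniform(7.0, 11.0)),
                 amplitude=float(rng.uniform(0.6, 1.0)),
                 shape="gaussian" if rng.random() < 0.5 else "lorentzian")
            for c in _ANCHORS[name]
        ]
        n_extra = int(rng.integers(5, 13))
        while len(peaks) < 3 + n_extra:
            center = float(rng.uniform(AXIS_MIN + 20.0, AXIS_MAX - 20.0))
            # keep random bands clear of every anchor so anchors stay unique
            if any(abs(center - c) < _ANCHOR_EXCLUSION for c in forbidden):
                continue
            peaks.append(
                Peak(
                    center=center,
                    fwhm=float(rng.uniform(6.0, 20.0)),
                    amplitude=float(rng.uniform(0.1, 0.9)),
                    shape="gaussian" if rng.random() < 0.5 else "lorentzian",
                )
            )
        components[name] = PeakModel(tuple(peaks))

    exc_centers = np.linspace(AXIS_MIN + 250.0, AXIS_MAX - 100.0, 6)
    exc_peaks = tuple(
        Peak(
            center=float(c + rng.uniform(-15.0, 15.0)),
            fwhm=float(rng.uniform(80.0, 200.0)),
            amplitude=float(rng.uniform(0.05, 0.2)),
            shape="gaussian",
        )
        for c in exc_centers
    )
    components["EXCIPIENT"] = PeakModel(exc_peaks)
    lib = ComponentLibrary(components)
    lib.validate()
    return lib


def pure_component_spectrum(model: PeakModel, axis: np.ndarray) -> Spectrum:
    """Evaluate a component's peak model on a wavenumber grid."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be one-dimensional and strictly increasing")
    y = np.zeros_like(axis)
    for p in model.peaks:
        y += p.profile(axis)
    return Spectrum(axis=axis, intensities=y)


def component_weights(sample: MixtureSample) -> np.ndarray:
    """Tablet-mass fractions of (CBZ I, CBZ III, CBZ DH, excipient); sums to 1."""
    f1, f3, fdh, fc = mass_fractions(sample)
    return np.array([f1 * fc, f3 * fc, fdh * fc, 1.0 - fc])


def simulate_replicates(
    sample: MixtureSample,
    lib: ComponentLibrary,
    noise: NoiseModel,
    axis: np.ndarray,
) -> list[Spectrum]:
    """Simulate the replicate Raman acquisitions of one tablet.

    Replicate ``r`` is ``g_r * sum_k (w_k + delta_rk) S_k + b_r + eps_r``
    where ``w`` are the tablet-mass component weights, ``delta`` is
    subsampling jitter (clipped at zero and renormalized so the weights
    remain a composition), ``g_r`` a mean-one lognormal gain, ``b_r`` a
    quadratic baseline and ``eps_r`` i.i.d. Gaussian noise.  Fully
    deterministic given ``noise.seed`` and ``sample.sample_id``.
    """
    axis = np.asarray(axis, dtype=float)
    if axis[0] < AXIS_MIN - 1e-9 or axis[-1] > AXIS_MAX + 1e-9:
        raise ValueError(f"axis must lie within {AXIS_MIN}-{AXIS_MAX} cm^-1")
    pure = np.vstack(
        [pure_component_spectrum(lib.components[name], axis).intensities for name in COMPONENTS]
    )
    w = component_weights(sample)
    rng = np.random.default_rng(np.random.SeedSequence([int(noise.seed), int(sample.sample_id)]))
    u = (axis - axis[0]) / (axis[-1] - axis[0]) * 2.0 - 1.0  # axis scaled to [-1, 1]

    out: list[Spectrum] = []
    for r in range(noise.n_replicates):
        wr = w * (1.0 + rng.normal(0.0, noise.subsample_jitter_sd, size=w.size))
        if np.any(wr < 0):
            logger.info(
                "sample %d replicate %d: jitter produced negative weights; clipped",
                sample.sample_id, r,
            )
            wr = np.clip(wr, 0.0, None)
        total = wr.sum()
        wr = wr / total if total > 0 else w.copy()  # pathological jitter: keep nominal
        gain = math.exp(rng.normal(0.0, noise.gain_sd)) if noise.gain_sd > 0 else 1.0
        coeffs = rng.normal(0.0, 1.0, size=3)
        baseline = noise.baseline_amplitude * (coeffs[0] + coeffs[1] * u + coeffs[2] * u**2)
        eps = rng.normal(0.0, noise.additive_sd, size=axis.size) if noise.additive_sd > 0 else 0.0
        y = gain * (wr @ pure) + baseline + eps
        out.append(
            Spectrum(axis=axis, intensities=y, sample_id=sample.sample_id, replicate_index=r)
        )
    return out
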