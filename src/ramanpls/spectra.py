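"""Spectrum container and the default wavenumber grid.

A :class:`Spectrum` is one Raman trace: a strictly increasing wavenumber
axis (cm^-1) and an intensity vector of the same length, tagged with the
tablet sample it came from and which replicate acquisition it is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Instrument spectral range, cm^-1.
AXIS_MIN = 52.0
AXIS_MAX = 1708.0

#: Default grid spacing, cm^-1 (finer than the 3.5 cm^-1 optical resolution).
AXIS_STEP = 2.0


def default_axis(lo: float = AXIS_MIN, hi: float = AXIS_MAX, step: float = AXIS_STEP) -> np.ndarray:
    """Uniform wavenumber grid ``lo, lo+step, ..., hi`` inclusive (829 points by default)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """One wavenumber-intensity trace with provenance metadata.

    Parameters
    ----------
    axis : array of float
        Wavenumbers in cm^-1, strictly increasing.
    intensities : array of float
        Intensities in arbitrary units, same length as ``axis``, all finite.
    sample_id : int
        Tablet sample the trace belongs to (0 for synthetic/pure traces).
    replicate_index : int
        Acquisition index within the sample (0-based).
    meta : dict
        Free-form metadata (e.g. replicate count after averaging).
    """

    axis: np.ndarray
    intensities: np.ndarray
    sample_id: int = 0
    replicate_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", y)
        if axis.ndim != 1 or y.ndim != 1:
            raise ValueError("axis and intensities must be one-dimensional")
        if axis.shape != y.shape:
            raise ValueError(
                f"axis length {axis.size} != intensities length {y.size}"
            )
        if axis.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(y)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.axis.size)

    def with_intensities(self, y: np.ndarray, **meta) -> "Spectrum":
        """Copy of this spectrum with new intensities (same axis and ids)."""
        return Spectrum(
            axis=self.axis,
            intensities=np.asarray(y, dtype=float),
            sample_id=self.sample_id,
            replicate_index=self.replicate_index,
            meta={**self.meta, **meta},
        )


def check_shared_axis(spectra: list[Spectrum]) -> np.ndarray:
    """Return the common axis of ``spectra`` or raise if they disagree."""
    if not spectra:
        raise ValueError("no spectra given")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if s.axis.shape != axis.shape or not np.allclose(s.axis, axis, rtol=0, atol=1e-9):
            raise ValueError("spectra do not share a common wavenumber axis")
    return axis
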