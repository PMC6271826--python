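"""Spectral preprocessing: replicate averaging, area normalization,
first derivative, interval extraction.

The pipeline order is fixed — average the replicates of a tablet, scale
the average spectrum to unit integrated area (removing overall
signal-intensity differences between measurements), differentiate once
with respect to wavenumber (separating overlapped bands and cancelling
additive baselines), then keep only the selected wavenumber intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, check_shared_axis


@dataclass(frozen=True)
class PreprocessSpec:
    """Preprocessing parameters.

    ``derivative_method`` is either ``"savitzky_golay"`` (default; window 7,
    polynomial order 2 — standard chemometric practice, robust to noise) or
    ``"central_difference"`` (used as an independent oracle in tests).  The
    stage order average -> normalize -> derivative is fixed.
    """

    derivative_method: str = "savitzky_golay"
    sg_window: int = 7
    sg_polyorder: int = 2
    normalization: str = "area"

    def __post_init__(self) -> None:
        if self.derivative_method not in ("savitzky_golay", "central_difference"):
            raise ValueError(f"unknown derivative method {self.derivative_method!r}")
        if self.normalization != "area":
            raise ValueError("only area normalization is supported")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")


def average_replicates(replicates: list[Spectrum]) -> Spectrum:
    """Pointwise mean of the replicate spectra of one tablet.

    All replicates must share the wavenumber axis; the result carries the
    replicate count in its metadata.
    """
    axis = check_shared_axis(replicates)
    mean = np.mean([s.intensities for s in replicates], axis=0)
    return Spectrum(
        axis=axis,
        intensities=mean,
        sample_id=replicates[0].sample_id,
        replicate_index=-1,
        meta={"n_replicates": len(replicates)},
    )


def normalize_area(s: Spectrum) -> Spectrum:
    """Scale a spectrum so its trapezoidal integral over the axis equals 1.

    Invariant to positive rescaling of the input (hence idempotent).  The
    axis may be non-uniform.  A spectrum with (near-)zero integrated area
    cannot be normalized and raises ``ValueError``.
    """
    area = float(np.trapezoid(s.intensities, s.axis))
    abs_area = float(np.trapezoid(np.abs(s.intensities), s.axis))
    if abs_area <= 0 or abs(area) < 1e-15 * max(abs_area, 1.0):
        raise ValueError("cannot area-normalize a zero-area spectrum")
    return s.with_intensities(s.intensities / area, normalized="area")


def first_derivative(s: Spectrum, spec: PreprocessSpec = PreprocessSpec()) -> Spectrum:
    """First derivative with respect to wavenumber (intensity per cm^-1).

    Savitzky-Golay differentiation preserves the spectrum length by fitting
    the edge polynomials on the interior window (``mode="interp"``); the
    central-difference variant uses one-sided differences at the ends.
    """
    n = len(s)
    if spec.derivative_method == "savitzky_golay":
        if n < spec.sg_window:
            raise ValueError(
                f"spectrum has {n} points, fewer than the SG window {spec.sg_window}"
            )
        step = float(np.mean(np.diff(s.axis)))
        dy = savgol_filter(
            s.intensities,
            window_length=spec.sg_window,
            polyorder=spec.sg_polyorder,
            deriv=1,
            delta=step,
            mode="interp",
        )
    else:
        if n < 3:
            raise ValueError("central difference needs at least 3 points")
        dy = np.gradient(s.intensities, s.axis)
    return s.with_intensities(dy, derivative=1)


def extract_intervals(
    s: Spectrum, intervals: list[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate the intensities inside the given wavenumber intervals.

    Bounds are inclusive and in cm^-1; intervals are sorted and must not
    overlap.  Returns ``(features, indices)`` where ``indices`` maps each
    retained feature back to its position on the full axis.
    """
    ordered = sorted((float(lo), float(hi)) for lo, hi in intervals)
    for (lo, hi) in ordered:
        if hi < lo:
            raise ValueError(f"interval ({lo}, {hi}) has hi < lo")
    for (_, hi_prev), (lo_next, _) in zip(ordered, ordered[1:]):
        if lo_next <= hi_prev:
            raise ValueError("intervals overlap after sorting")
    idx_blocks = []
    for lo, hi in ordered:
        mask = (s.axis >= lo - 1e-9) & (s.axis <= hi + 1e-9)
        idx_blocks.append(np.flatnonzero(mask))
    indices = np.concatenate(idx_blocks) if idx_blocks else np.array([], dtype=int)
    if indices.size == 0:
        raise ValueError("no axis points fall inside the given intervals")
    return s.intensities[indices], indices


def preprocess_sample(
    replicates: list[Spectrum],
    spec: PreprocessSpec = PreprocessSpec(),
    intervals: list[tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full per-sample pipeline: average -> normalize -> derivative [-> intervals].

    Returns the feature row and the retained axis indices.
    """
    s = first_derivative(normalize_area(average_replicates(replicates)), spec)
    if intervals is None:
        return s.intensities, np.arange(len(s))
    return extract_intervals(s, intervals)
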