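"""Ternary mixture design of the calibration and validation tablets.

Fifteen lab-made tablets, each 300 mg: 250 mg of a fixed excipient blend
(microcrystalline cellulose, sodium croscarmellose, colloidal silicon
dioxide, magnesium stearate) plus nominally 50 mg of carbamazepine split
between the three crystal forms.  Samples 1-10 form the calibration set,
11-15 the validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXCIPIENT_MASS_MG = 250.0

# (sample_id, role, CBZ I mg, CBZ III mg, CBZ DH mg) for the 15 tablets.
_DESIGN_ROWS: list[tuple[int, str, float, float, float]] = [
    (1, "calibration", 49.4, 0.0, 0.0),
    (2, "calibration", 0.0, 50.0, 0.0),
    (3, "calibration", 0.0, 0.0, 50.8),
    (4, "calibration", 25.3, 25.2, 0.0),
    (5, "calibration", 25.2, 0.0, 24.7),
    (6, "calibration", 0.0, 25.1, 24.9),
    (7, "calibration", 34.3, 8.1, 8.2),
    (8, "calibration", 7.9, 34.3, 8.3),
    (9, "calibration", 8.2, 8.0, 33.9),
    (10, "calibration", 16.4, 16.2, 16.4),
    (11, "validation", 40.2, 5.2, 5.0),
    (12, "validation", 5.1, 40.0, 5.0),
    (13, "validation", 5.1, 5.1, 40.1),
    (14, "validation", 30.0, 10.6, 10.1),
    (15, "validation", 10.2, 29.8, 9.8),
]


@dataclass(frozen=True)
class MixtureSample:
    """One designed tablet: per-polymorph CBZ masses plus the excipient mass."""

    sample_id: int
    role: str  # "calibration" or "validation"
    mass_cbz1: float
    mass_cbz3: float
    mass_cbzdh: float
    mass_excipients: float = EXCIPIENT_MASS_MG

    def __post_init__(self) -> None:
        if self.role not in ("calibration", "validation"):
            raise ValueError(f"unknown role {self.role!r}")
        masses = (self.mass_cbz1, self.mass_cbz3, self.mass_cbzdh)
        if any(m < 0 for m in masses):
            raise ValueError("polymorph masses must be >= 0")
        if self.mass_excipients < 0:
            raise ValueError("excipient mass must be >= 0")

    @property
    def cbz_total(self) -> float:
        """Total carbamazepine mass, mg."""
        return self.mass_cbz1 + self.mass_cbz3 + self.mass_cbzdh

    @property
    def tablet_total(self) -> float:
        """Total tablet mass (CBZ + excipients), mg."""
        return self.cbz_total + self.mass_excipients


@dataclass(frozen=True)
class MixtureDesign:
    """An ordered collection of :class:`MixtureSample` rows."""

    samples: tuple[MixtureSample, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, role: str) -> "MixtureDesign":
        return MixtureDesign(tuple(s for s in self.samples if s.role == role))

    @property
    def calibration(self) -> "MixtureDesign":
        return self.subset("calibration")

    @property
    def validation(self) -> "MixtureDesign":
        return self.subset("validation")

    def sample(self, sample_id: int) -> MixtureSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"no sample with id {sample_id}")

    def responses(self) -> np.ndarray:
        """Y matrix: per-sample polymorph content as % of total CBZ mass."""
        rows = []
        for s in self.samples:
            f1, f3, fdh, _ = mass_fractions(s)
            rows.append([100.0 * f1, 100.0 * f3, 100.0 * fdh])
        return np.array(rows)

    def cbz_tablet_fractions(self) -> np.ndarray:
        """Per-sample CBZ mass fraction of the whole tablet."""
        return np.array([mass_fractions(s)[3] for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "role": [s.role for s in self.samples],
                "cbz1_mg": [s.mass_cbz1 for s in self.samples],
                "cbz3_mg": [s.mass_cbz3 for s in self.samples],
                "cbzdh_mg": [s.mass_cbzdh for s in self.samples],
                "excipients_mg": [s.mass_excipients for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MixtureDesign":
        samples = tuple(
            MixtureSample(
                sample_id=int(r.sample_id),
                role=str(r.role),
                mass_cbz1=float(r.cbz1_mg),
                mass_cbz3=float(r.cbz3_mg),
                mass_cbzdh=float(r.cbzdh_mg),
                mass_excipients=float(r.excipients_mg),
            )
            for r in df.itertuples(index=False)
        )
        return cls(samples)


def make_design() -> MixtureDesign:
    """The 15-tablet ternary design: 10 calibration + 5 validation samples."""
    return MixtureDesign(
        tuple(
            MixtureSample(sample_id=i, role=role, mass_cbz1=m1, mass_cbz3=m3, mass_cbzdh=mdh)
            for i, role, m1, m3, mdh in _DESIGN_ROWS
        )
    )


def mass_fractions(sample: MixtureSample) -> tuple[float, float, float, float]:
    """Polymorph fractions of total CBZ and the CBZ fraction of the tablet.

    Returns
    -------
    (f1, f3, fdh, f_cbz_tablet)
        ``f1 + f3 + fdh == 1`` exactly; ``f_cbz_tablet`` is total CBZ mass
        over total tablet mass (nominally 50/300 = 16.67%).

    Raises
    ------
    ValueError
        If the sample contains no carbamazepine.
    """
    total = sample.cbz_total
    if total <= 0:
        raise ValueError(f"sample {sample.sample_id} has zero total CBZ mass")
    f1 = sample.mass_cbz1 / total
    f3 = sample.mass_cbz3 / total
    fdh = sample.mass_cbzdh / total
    f_cbz_tablet = total / (total + sample.mass_excipients)
    return f1, f3, fdh, f_cbz_tablet
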