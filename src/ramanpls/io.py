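"""Reading and writing spectra, designs and models.

Spectra travel as long-format CSV (sample_id, replicate, wavenumber_cm1,
intensity); the mixture design as a CSV mirroring the printed design
table; fitted models as JSON.  A minimal JCAMP-DX (XYDATA, ``(XY..XY)``
form) writer/reader is provided for single spectra.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import MixtureDesign
from .pls import PlsModel
from .preprocess import PreprocessSpec
from .spectra import Spectrum

SPECTRA_COLUMNS = ["sample_id", "replicate", "wavenumber_cm1", "intensity"]


def write_spectra_csv(spectra: list[Spectrum], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "sample_id": s.sample_id,
                "replicate": s.replicate_index,
                "wavenumber_cm1": s.axis,
                "intensity": s.intensities,
            }
        )
        for s in spectra
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path) -> dict[int, list[Spectrum]]:
    """Load spectra grouped by sample_id; replicates ordered by index."""
    df = pd.read_csv(path)
    missing = set(SPECTRA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV missing columns {sorted(missing)}")
    out: dict[int, list[Spectrum]] = {}
    for (sid, rep), grp in df.groupby(["sample_id", "replicate"], sort=True):
        grp = grp.sort_values("wavenumber_cm1")
        out.setdefault(int(sid), []).append(
            Spectrum(
                axis=grp["wavenumber_cm1"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                sample_id=int(sid),
                replicate_index=int(rep),
            )
        )
    return out


def write_design_csv(design: MixtureDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design_csv(path) -> MixtureDesign:
    return MixtureDesign.from_frame(pd.read_csv(path))


def write_jcamp(spectrum: Spectrum, path, title: str = "synthetic Raman spectrum") -> None:
    """Write one spectrum as a minimal JCAMP-DX file, XYDATA in (XY..XY) form."""
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={len(spectrum)}",
        f"##FIRSTX={spectrum.axis[0]:.6g}",
        f"##LASTX={spectrum.axis[-1]:.6g}",
        "##XYDATA=(XY..XY)",
    ]
    lines += [f"{x:.6f}, {y:.10e}" for x, y in zip(spectrum.axis, spectrum.intensities)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcamp(path, sample_id: int = 0, replicate_index: int = 0) -> Spectrum:
    """Read a spectrum written by :func:`write_jcamp` (XY..XY form only)."""
    xs, ys = [], []
    in_data = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("##XYDATA"):
            in_data = True
            continue
        if line.startswith("##END"):
            break
        if in_data and line and not line.startswith("##"):
            x, y = line.split(",")
            xs.append(float(x))
            ys.append(float(y))
    if not xs:
        raise ValueError(f"no XYDATA found in {path}")
    return Spectrum(
        axis=np.array(xs), intensities=np.array(ys),
        sample_id=sample_id, replicate_index=replicate_index,
    )


def save_model_json(model: PlsModel, path) -> None:
    payload = {
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean.tolist(),
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "x_variance_explained": model.x_variance_explained.tolist(),
        "interval_set": model.interval_set,
        "preprocess": vars(model.preprocess) if model.preprocess is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_model_json(path) -> PlsModel:
    d = json.loads(Path(path).read_text())
    return PlsModel(
        n_lv=int(d["n_lv"]),
        x_mean=np.array(d["x_mean"]),
        y_mean=np.array(d["y_mean"]),
        weights=np.array(d["weights"]),
        x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        x_variance_explained=np.array(d["x_variance_explained"]),
        interval_set=[tuple(iv) for iv in d["interval_set"]] if d["interval_set"] else None,
        preprocess=PreprocessSpec(**d["preprocess"]) if d["preprocess"] else None,
    )
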