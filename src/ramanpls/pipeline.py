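"""End-to-end workflow: generate a synthetic dataset, calibrate the
interval-PLS model on the calibration tablets, validate on the held-back
tablets.

Every stage is config-driven and reproducible: the configuration and the
master seed are serialized alongside every artifact, and a manifest with
SHA-256 checksums accompanies each generated dataset.  Calibration only
ever touches the calibration samples — interval selection and LV choice
never see a validation spectrum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .design import MixtureDesign, make_design, mass_fractions
from .intervals import IntervalSet, forward_select_intervals, partition_axis
from .metrics import ErrorReport, build_report, loo_cross_validate
from .pls import PlsModel, choose_n_lv, explained_x_variance, fit_pls, predict
from .preprocess import PreprocessSpec, extract_intervals, preprocess_sample
from .spectra import default_axis
from .synthetic import default_library, noise_preset, simulate_replicates

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full generate/calibrate/validate run."""

    seed: int = 0
    axis_lo: float = 52.0
    axis_hi: float = 1708.0
    axis_step: float = 2.0
    noise: str = "paper_like"  # preset: none, low, paper_like
    replicates: int = 10
    sg_window: int = 7
    sg_polyorder: int = 2
    derivative_method: str = "savitzky_golay"
    n_intervals: int = 20
    lv_candidates: tuple[int, ...] = tuple(range(1, 11))
    max_intervals: int = 5
    min_improvement: float = 0.02
    write_jcamp: bool = False

    def __post_init__(self) -> None:
        if self.axis_hi <= self.axis_lo:
            raise ValueError("axis_hi must exceed axis_lo")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_intervals < 2:
            raise ValueError("n_intervals must be >= 2")
        self.lv_candidates = tuple(int(k) for k in self.lv_candidates)
        if not self.lv_candidates:
            raise ValueError("lv_candidates must be non-empty")
        # constructing the spec validates window/polyorder/method
        self.preprocess_spec()

    def axis(self) -> np.ndarray:
        return default_axis(self.axis_lo, self.axis_hi, self.axis_step)

    def preprocess_spec(self) -> PreprocessSpec:
        return PreprocessSpec(
            derivative_method=self.derivative_method,
            sg_window=self.sg_window,
            sg_polyorder=self.sg_polyorder,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lv_candidates"] = list(self.lv_candidates)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - self.t0)
            return False

    return _T()


def run_generate(config: RunConfig, out_dir) -> dict:
    """Generate the designed dataset: design CSV, replicate spectra CSV
    (optionally JCAMP), ground-truth fractions and a checksummed manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    axis = config.axis()
    design = make_design()
    lib = default_library(seed=config.seed)
    noise = noise_preset(config.noise, seed=config.seed, n_replicates=config.replicates)

    with _timed("generate"):
        spectra = []
        for sample in design:
            spectra.extend(simulate_replicates(sample, lib, noise, axis))
        rio.write_design_csv(design, out / "design.csv")
        rio.write_spectra_csv(spectra, out / "spectra.csv")
        truth_rows = []
        for sample in design:
            f1, f3, fdh, fc = mass_fractions(sample)
            truth_rows.append(
                dict(sample_id=sample.sample_id, frac_cbz1=f1, frac_cbz3=f3,
                     frac_cbzdh=fdh, f_cbz_tablet=fc)
            )
        import pandas as pd

        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
        if config.write_jcamp:
            jdir = out / "jcamp"
            jdir.mkdir(exist_ok=True)
            for s in spectra:
                rio.write_jcamp(
                    s, jdir / f"sample{s.sample_id:02d}_rep{s.replicate_index:02d}.jdx",
                    title=f"synthetic Raman, sample {s.sample_id} replicate {s.replicate_index}",
                )
    config.to_yaml(out / "config.yaml")
    files = ["design.csv", "spectra.csv", "truth.csv", "config.yaml"]
    manifest = {
        "seed": config.seed,
        "n_spectra": len(spectra),
        "checksums": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _preprocessed_matrix(
    design: MixtureDesign, spectra_by_sample: dict, spec: PreprocessSpec
) -> np.ndarray:
    rows = []
    for sample in design:
        if sample.sample_id not in spectra_by_sample:
            raise ValueError(f"no spectra for sample {sample.sample_id}")
        x, _ = preprocess_sample(spectra_by_sample[sample.sample_id], spec)
        rows.append(x)
    return np.vstack(rows)


@dataclass
class CalibrationResult:
    model: PlsModel
    interval_set: IntervalSet
    chosen_n_lv: int
    rmsecv_curve: np.ndarray
    lv_candidates: tuple[int, ...]
    x_variance_cumulative: np.ndarray
    cv_predictions: dict[int, np.ndarray] = field(default_factory=dict)


def calibrate(
    design: MixtureDesign, spectra_by_sample: dict, config: RunConfig
) -> CalibrationResult:
    """Fit the interval-PLS model on the calibration samples only.

    Pipeline: average -> area-normalize -> first derivative -> equidistant
    partition -> greedy forward interval selection (LOO-scored) -> LV count
    by the cross-validated parsimony rule -> final NIPALS fit on the
    selected intervals.
    """
    cal = design.calibration
    if len(cal) < 3:
        raise ValueError("need at least 3 calibration samples")
    spec = config.preprocess_spec()
    axis = config.axis()

    with _timed("preprocess"):
        cal_spectra = {s.sample_id: spectra_by_sample[s.sample_id] for s in cal}
        X = _preprocessed_matrix(cal, cal_spectra, spec)
        Y = cal.responses()

    with _timed("interval-selection"):
        partition = partition_axis(axis, config.n_intervals)
        iset = forward_select_intervals(
            partition, X, Y, axis,
            lv_candidates=config.lv_candidates,
            max_intervals=config.max_intervals,
            min_improvement=config.min_improvement,
        )

    with _timed("lv-choice"):
        dummy = np.zeros(axis.size)
        from .spectra import Spectrum

        _, idx = extract_intervals(
            Spectrum(axis=axis, intensities=dummy), list(iset.intervals)
        )
        cv, cv_preds = loo_cross_validate(X[:, idx], Y, list(config.lv_candidates))
        n_lv = choose_n_lv(cv)
        cv = cv.with_choice(n_lv)

    with _timed("final-fit"):
        model = fit_pls(
            X[:, idx], Y, n_lv=n_lv,
            interval_set=list(iset.intervals), preprocess=spec,
        )
        _, cum = explained_x_variance(model)

    j = cv.lv_candidates.index(n_lv)
    cv_predictions = {s.sample_id: cv_preds[j, i] for i, s in enumerate(cal)}
    return CalibrationResult(
        model=model,
        interval_set=iset,
        chosen_n_lv=n_lv,
        rmsecv_curve=cv.rmsecv_mean,
        lv_candidates=cv.lv_candidates,
        x_variance_cumulative=cum,
        cv_predictions=cv_predictions,
    )


def run_calibrate(config: RunConfig, data_dir, out_dir=None) -> CalibrationResult:
    """Calibrate from a generated dataset directory; persist model + CV curve."""
    data = Path(data_dir)
    out = Path(out_dir) if out_dir is not None else data
    out.mkdir(parents=True, exist_ok=True)
    design = rio.read_design_csv(data / "design.csv")
    spectra = rio.read_spectra_csv(data / "spectra.csv")
    # stage isolation: drop validation spectra before any computation
    cal_ids = {s.sample_id for s in design.calibration}
    spectra = {sid: reps for sid, reps in spectra.items() if sid in cal_ids}

    result = calibrate(design, spectra, config)

    rio.save_model_json(result.model, out / "model.json")
    import pandas as pd

    pd.DataFrame(
        {"n_lv": list(result.lv_candidates), "rmsecv_mean": result.rmsecv_curve}
    ).to_csv(out / "cv_curve.csv", index=False)
    pd.DataFrame(
        result.interval_set.intervals, columns=["lo_cm1", "hi_cm1"]
    ).to_csv(out / "selected_intervals.csv", index=False)
    # held-out LOO predictions, so the validation report's RMSECV uses them
    (out / "cv_predictions.json").write_text(
        json.dumps(
            {str(k): v.tolist() for k, v in result.cv_predictions.items()},
            sort_keys=True,
        )
        + "\n"
    )
    config.to_yaml(out / "config.yaml")
    return result


def predict_samples(
    design: MixtureDesign, spectra_by_sample: dict, model: PlsModel, config: RunConfig
) -> dict[int, np.ndarray]:
    """Preprocess and predict each sample in ``design`` with a fitted model."""
    spec = model.preprocess if model.preprocess is not None else config.preprocess_spec()
    out = {}
    for sample in design:
        reps = spectra_by_sample[sample.sample_id]
        x, _ = preprocess_sample(reps, spec, intervals=model.interval_set)
        if x.size != model.n_features:
            raise ValueError(
                f"sample {sample.sample_id}: {x.size} features, model expects "
                f"{model.n_features}; check that the wavenumber grid matches"
            )
        out[sample.sample_id] = predict(model, x)
    return out


def run_validate(config: RunConfig, data_dir, model_dir=None, out_dir=None) -> ErrorReport:
    """Predict the validation tablets and write the two-basis error report."""
    data = Path(data_dir)
    mdir = Path(model_dir) if model_dir is not None else data
    out = Path(out_dir) if out_dir is not None else mdir
    out.mkdir(parents=True, exist_ok=True)
    design = rio.read_design_csv(data / "design.csv")
    spectra = rio.read_spectra_csv(data / "spectra.csv")
    model = rio.load_model_json(mdir / "model.json")

    with _timed("validate"):
        cal_pred = predict_samples(design.calibration, spectra, model, config)
        val_pred = predict_samples(design.validation, spectra, model, config)
        cv_pred_path = mdir / "cv_predictions.json"
        cv_predictions = None
        if cv_pred_path.exists():
            loaded = json.loads(cv_pred_path.read_text())
            cv_predictions = {int(k): np.array(v) for k, v in loaded.items()}
        report = build_report(design, cal_pred, val_pred, cv_predictions=cv_predictions)

    report.to_csv(out / "report.csv")
    (out / "report.txt").write_text(report.formatted() + "\n")
    import pandas as pd

    scatter = []
    for subset, preds in (("calibration", cal_pred), ("validation", val_pred)):
        sub = design.subset(subset)
        y = sub.responses()
        for i, s in enumerate(sub):
            for j, name in enumerate(("CBZ_I", "CBZ_III", "CBZ_DH")):
                scatter.append(
                    dict(sample_id=s.sample_id, subset=subset, polymorph=name,
                         real_pct=y[i, j], predicted_pct=float(preds[s.sample_id][j]))
                )
    pd.DataFrame(scatter).to_csv(out / "real_vs_predicted.csv", index=False)
    return report


def run_full(config: RunConfig, work_dir) -> tuple[CalibrationResult, ErrorReport]:
    """generate -> calibrate -> validate in one call (used by the CLI and tests)."""
    work = Path(work_dir)
    run_generate(config, work)
    cal = run_calibrate(config, work)
    report = run_validate(config, work)
    return cal, report
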