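"""Formats, configuration, pipeline orchestration and the command line.

Volumes travel as NIfTI-1: 3D for maps and labels, 4D for echo stacks with
their preparation times in a small JSON sidecar next to the image file.
Phantom volumes use an identity orientation with the voxel spacing on the
affine diagonal; real-data mode trusts input headers and never resamples.

``run_pipeline`` chains the stages simulate -> fit -> split -> train ->
predict -> evaluate.  Every stage persists its outputs in its own
subdirectory with a completion marker, so deleting one stage's directory
re-runs that stage only.  All randomness flows from one root seed through
named per-stage substreams recorded in the run log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import click
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import evaluation, phantom, relaxometry, synthesis
from ._unet import UNet2D
from .phantom import (
    AcquisitionSpec,
    CompartmentLabels,
    DomainShiftSpec,
    PhantomSpec,
    TissueParams,
)
from .relaxometry import EchoSeries, QuantMap
from .synthesis import SynthModelSpec, TrainConfig

logger = logging.getLogger("qmapsynth")


def setup_logging(run_dir: Optional[Path] = None, level: int = logging.INFO) -> None:
    root = logging.getLogger("qmapsynth")
    root.setLevel(level)
    have_stream = any(isinstance(h, logging.StreamHandler) for h in root.handlers)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    if not have_stream:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(fmt)
        root.addHandler(h)
    if run_dir is not None:
        fh = logging.FileHandler(Path(run_dir) / "run.log")
        fh.setFormatter(fmt)
        root.addHandler(fh)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    a = np.eye(4)
    for i, s in enumerate(spacing):
        a[i, i] = s
    return a


def write_map(path: Path, qmap: QuantMap) -> Path:
    """Write a relaxation map as float32 NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(qmap.values_ms.astype(np.float32), _affine(qmap.spacing))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def read_map(path: Path, kind: str) -> QuantMap:
    """Read a 3D NIfTI map; 4D images (echo stacks) are rejected."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got {data.ndim}D")
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    return QuantMap(np.asarray(data, float), kind=kind, spacing=spacing)


def write_labels(path: Path, labels: CompartmentLabels,
                 spacing: Tuple[float, float, float] = (4.0, 0.55, 0.55)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(labels.label_volume.astype(np.int16), _affine(spacing))
    nib.save(img, str(path))
    with open(str(path) + ".labels.json", "w") as f:
        json.dump(labels.label_table, f, indent=1)
    return path


def read_labels(path: Path) -> CompartmentLabels:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    table_path = Path(str(path) + ".labels.json")
    if table_path.exists():
        table = {k: int(v) for k, v in json.load(open(table_path)).items()}
        return CompartmentLabels(data.astype(np.int16), table)
    return CompartmentLabels(data.astype(np.int16))


def write_echoes(path: Path, series: EchoSeries) -> Path:
    """4D NIfTI (slice/row/col/echo on disk) plus a JSON time sidecar."""
    path = Path(path)
    data = np.moveaxis(series.data, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(series.spacing))
    nib.save(img, str(path))
    sidecar = {
        "times_ms": [float(t) for t in series.times_ms],
        "kind": series.kind,
        "noise_sigma_au": series.noise_sigma_au,
    }
    with open(str(path) + ".times.json", "w") as f:
        json.dump(sidecar, f, indent=1)
    return path


def read_echoes(path: Path, times_ms=None, kind: Optional[str] = None) -> EchoSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D echo stack, got {data.ndim}D")
    sidecar_path = Path(str(path) + ".times.json")
    noise = 0.0
    if times_ms is None or kind is None:
        if not sidecar_path.exists():
            raise ValueError(f"{path}: no time sidecar and no times/kind given")
        sc = json.load(open(sidecar_path))
        times_ms = times_ms if times_ms is not None else sc["times_ms"]
        kind = kind or sc["kind"]
        noise = float(sc.get("noise_sigma_au", 0.0))
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    return EchoSeries(
        data=np.moveaxis(np.asarray(data, float), -1, 0),
        times_ms=np.asarray(times_ms, float),
        kind=kind,
        spacing=spacing,
        noise_sigma_au=noise,
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML losslessly."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    model: SynthModelSpec = field(default_factory=SynthModelSpec.tiny)
    train: TrainConfig = field(default_factory=TrainConfig)
    domain_shift: Optional[DomainShiftSpec] = None
    fit_bounds_ms: Tuple[float, float] = relaxometry.FIT_BOUNDS_MS
    fit_s0_threshold_frac: float = 0.05
    seed: int = 0


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(d: dict) -> RunConfig:
    ph = dict(d.get("phantom", {}))
    if "tissue_params" in ph:
        ph["tissue_params"] = {
            k: TissueParams(**v) for k, v in ph["tissue_params"].items()
        }
    if "matrix_size" in ph:
        ph["matrix_size"] = tuple(ph["matrix_size"])
    if "compartment_t1rho_offset_ms" in ph:
        ph["compartment_t1rho_offset_ms"] = tuple(ph["compartment_t1rho_offset_ms"])
    acq = dict(d.get("acquisition", {}))
    for k in ("tsl_times_ms", "te_times_ms"):
        if k in acq:
            acq[k] = tuple(acq[k])
    tr = dict(d.get("train", {}))
    for k in ("split_fractions", "clip_range"):
        if k in tr:
            tr[k] = tuple(tr[k])
    shift = d.get("domain_shift")
    return RunConfig(
        phantom=PhantomSpec(**ph),
        acquisition=AcquisitionSpec(**acq),
        model=SynthModelSpec(**d.get("model", {})),
        train=TrainConfig(**tr),
        domain_shift=DomainShiftSpec(**shift) if shift else None,
        fit_bounds_ms=tuple(d.get("fit_bounds_ms", relaxometry.FIT_BOUNDS_MS)),
        fit_s0_threshold_frac=float(d.get("fit_s0_threshold_frac", 0.05)),
        seed=int(d.get("seed", 0)),
    )


def save_config(config: RunConfig, path: Path) -> Path:
    path = Path(path)
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(config), f, sort_keys=True)
    return path


def load_config(path: Path) -> RunConfig:
    with open(path) as f:
        return config_from_dict(yaml.safe_load(f))


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path_prefix: Path, model: UNet2D, model_spec: SynthModelSpec,
                    train_config: TrainConfig) -> Path:
    path_prefix = Path(path_prefix)
    np.savez(str(path_prefix) + ".npz", **model.state_dict())
    meta = {"model": _to_plain(model_spec), "train": _to_plain(train_config)}
    with open(str(path_prefix) + ".json", "w") as f:
        json.dump(meta, f, indent=1)
    return path_prefix


def load_checkpoint(path_prefix: Path) -> Tuple[UNet2D, SynthModelSpec, TrainConfig]:
    path_prefix = Path(path_prefix)
    meta = json.load(open(str(path_prefix) + ".json"))
    tr = dict(meta["train"])
    for k in ("split_fractions", "clip_range"):
        tr[k] = tuple(tr[k])
    spec = SynthModelSpec(**meta["model"])
    cfg = TrainConfig(**tr)
    model = synthesis.build_model(spec, seed=cfg.seed)
    with np.load(str(path_prefix) + ".npz") as state:
        model.load_state_dict(dict(state))
    return model, spec, cfg


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage_done(stage_dir: Path) -> bool:
    return (stage_dir / ".done").exists()


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / ".done").touch()


def run_pipeline(config: RunConfig, run_dir: Path,
                 stop_after: Optional[str] = None) -> Dict[str, object]:
    """Execute (or resume) the full phantom-to-report pipeline.

    Stage subdirectories: cohort/ maps/ split/ model/ pred/ eval/.  A stage
    with its ``.done`` marker present is skipped, so deleting a stage
    directory re-runs that stage (and later stages read from disk, not from
    memory).  ``stop_after`` ("simulate", "fit", "split", "train",
    "predict") halts the pipeline after that stage.  Returns a summary dict
    of headline numbers and paths (partial if stopped early).
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(run_dir)
    from . import __version__
    logger.info("qmapsynth %s | config hash %s | root seed %d",
                __version__, config_hash(config), config.seed)
    save_config(config, run_dir / "config.yaml")

    ids = [f"S{i + 1:03d}" for i in range(config.phantom.n_subjects)]

    # -- stage 1: simulate -------------------------------------------------
    cohort_dir = run_dir / "cohort"
    if not _stage_done(cohort_dir):
        cohort_dir.mkdir(exist_ok=True)
        cohort = phantom.make_cohort(config.phantom, config.acquisition, ids)
        rows = []
        for subj in cohort:
            sid = subj.truth.subject_id
            write_map(cohort_dir / f"{sid}_t1rho_truth.nii", subj.truth.t1rho_truth)
            write_map(cohort_dir / f"{sid}_t2_truth.nii", subj.truth.t2_truth)
            write_labels(cohort_dir / f"{sid}_labels.nii", subj.truth.labels)
            write_echoes(cohort_dir / f"{sid}_echoes_t1rho.nii", subj.echoes_t1rho)
            write_echoes(cohort_dir / f"{sid}_echoes_t2.nii", subj.echoes_t2)
            rows.append({"subject_id": sid, "seed": config.phantom.seed,
                         "stratum": "in_distribution"})
        pd.DataFrame(rows).to_csv(cohort_dir / "manifest.csv", index=False)
        _mark_done(cohort_dir)
        logger.info("stage simulate: %d subjects written", len(ids))
    else:
        logger.info("stage simulate: resumed from %s", cohort_dir)
    if stop_after == "simulate":
        return {"run_dir": str(run_dir), "stopped_after": "simulate"}

    # -- stage 2: fit ------------------------------------------------------
    maps_dir = run_dir / "maps"
    if not _stage_done(maps_dir):
        maps_dir.mkdir(exist_ok=True)
        for sid in ids:
            for kind, tag in (("T1rho", "t1rho"), ("T2", "t2")):
                series = read_echoes(cohort_dir / f"{sid}_echoes_{tag}.nii")
                fit = relaxometry.fit_monoexponential(
                    series, bounds=config.fit_bounds_ms,
                    s0_threshold_frac=config.fit_s0_threshold_frac)
                write_map(maps_dir / f"{sid}_{tag}_fit.nii", fit.map)
        _mark_done(maps_dir)
        logger.info("stage fit: maps written for %d subjects", len(ids))
    else:
        logger.info("stage fit: resumed")
    if stop_after == "fit":
        return {"run_dir": str(run_dir), "stopped_after": "fit"}

    # -- stage 3: split ----------------------------------------------------
    split_dir = run_dir / "split"
    if not _stage_done(split_dir):
        split_dir.mkdir(exist_ok=True)
        split = synthesis.split_dataset(ids, config.train.split_fractions,
                                        seed=config.seed)
        with open(split_dir / "split.json", "w") as f:
            json.dump(split, f, indent=1)
        _mark_done(split_dir)
    split = json.load(open(split_dir / "split.json"))
    assert set(split["train"]) | set(split["val"]) | set(split["test"]) == set(ids)
    if stop_after == "split":
        return {"run_dir": str(run_dir), "stopped_after": "split", "split": split}

    def load_subject(sid: str):
        t2 = read_map(maps_dir / f"{sid}_t2_fit.nii", "T2")
        t1r = read_map(maps_dir / f"{sid}_t1rho_fit.nii", "T1rho")
        labels = read_labels(cohort_dir / f"{sid}_labels.nii")
        return t2, t1r, labels

    # -- stage 4: train ----------------------------------------------------
    model_dir = run_dir / "model"
    if not _stage_done(model_dir):
        model_dir.mkdir(exist_ok=True)
        def pairs_for(subset):
            out = []
            for sid in subset:
                t2, t1r, labels = load_subject(sid)
                out += synthesis.make_slice_pairs(t2, t1r, labels.cartilage_mask, sid)
            return out
        train_pairs = pairs_for(split["train"])
        val_pairs = pairs_for(split["val"])
        synthesis.assert_split_integrity(
            {k: v for k, v in split.items()}, train_pairs + val_pairs
        )
        model = synthesis.build_model(config.model, seed=config.seed)
        result = synthesis.train(model, train_pairs, val_pairs, config.train)
        save_checkpoint(model_dir / "model", result.model, config.model, config.train)
        result.history.to_csv(model_dir / "history.csv", index=False)
        _mark_done(model_dir)
        logger.info("stage train: best val loss %.3e", result.best_val_loss)
    else:
        logger.info("stage train: resumed")
    if stop_after == "train":
        return {"run_dir": str(run_dir), "stopped_after": "train",
                "split": split,
                "checkpoint": str(model_dir / "model")}

    # -- stage 5: predict --------------------------------------------------
    pred_dir = run_dir / "pred"
    if not _stage_done(pred_dir):
        pred_dir.mkdir(exist_ok=True)
        model, _, train_cfg = load_checkpoint(model_dir / "model")
        for sid in split["test"]:
            t2, _, _ = load_subject(sid)
            pred = synthesis.predict_map(model, t2, train_cfg)
            write_map(pred_dir / f"{sid}_t1rho_pred.nii", pred)
            if config.domain_shift is not None:
                shifted_maps = {}
                for kind, tag in (("T1rho", "t1rho"), ("T2", "t2")):
                    series = read_echoes(cohort_dir / f"{sid}_echoes_{tag}.nii")
                    truth = read_map(cohort_dir / f"{sid}_{tag}_truth.nii", kind)
                    # the relaxation-time offset models the component of a
                    # coil/scanner change that affects the spin-lock
                    # preparation differently from the T2 preparation, so it
                    # applies to the T1rho acquisition only
                    shift = config.domain_shift
                    if kind == "T2":
                        shift = dataclasses.replace(shift, global_offset_ms=0.0)
                    shifted = phantom.apply_domain_shift(series, shift,
                                                         truth_map=truth)
                    fit = relaxometry.fit_monoexponential(
                        shifted, bounds=config.fit_bounds_ms,
                        s0_threshold_frac=config.fit_s0_threshold_frac)
                    shifted_maps[tag] = fit.map
                    write_map(pred_dir / f"{sid}_{tag}_fit_shifted.nii", fit.map)
                pred_s = synthesis.predict_map(model, shifted_maps["t2"], train_cfg)
                write_map(pred_dir / f"{sid}_t1rho_pred_shifted.nii", pred_s)
        _mark_done(pred_dir)
        logger.info("stage predict: %d test subjects", len(split["test"]))
    else:
        logger.info("stage predict: resumed")
    if stop_after == "predict":
        return {"run_dir": str(run_dir), "stopped_after": "predict", "split": split}

    # -- stage 6: evaluate -------------------------------------------------
    eval_dir = run_dir / "eval"
    if not _stage_done(eval_dir):
        eval_dir.mkdir(exist_ok=True)
        preds, truths, labs, strata = {}, {}, {}, {}
        for sid in split["test"]:
            _, t1r, labels = load_subject(sid)
            key = sid
            preds[key] = read_map(pred_dir / f"{sid}_t1rho_pred.nii", "T1rho").values_ms
            truths[key] = relaxometry.clip_map(t1r).values_ms
            labs[key] = labels
            strata[key] = "in_distribution"
            if config.domain_shift is not None:
                key = sid + "__shifted"
                preds[key] = read_map(pred_dir / f"{sid}_t1rho_pred_shifted.nii",
                                      "T1rho").values_ms
                t1r_s = read_map(pred_dir / f"{sid}_t1rho_fit_shifted.nii", "T1rho")
                truths[key] = relaxometry.clip_map(t1r_s).values_ms
                labs[key] = labels
                strata[key] = "shifted"
        metrics, agreement = evaluation.evaluate_cohort(preds, truths, labs, strata)
        metrics.per_subject.to_csv(eval_dir / "per_subject_metrics.csv", index=False)
        metrics.summary.to_csv(eval_dir / "summary_metrics.csv")
        report = {}
        for stratum, ag in agreement.items():
            ag.table.to_csv(eval_dir / f"agreement_units_{stratum}.csv", index=False)
            ba = evaluation.bland_altman(ag.table["truth_mean_ms"].to_numpy(),
                                         ag.table["pred_mean_ms"].to_numpy())
            evaluation.plot_bland_altman(
                ba, eval_dir / f"bland_altman_{stratum}.png", title=stratum)
            evaluation.plot_correlation(
                ag.table["truth_mean_ms"], ag.table["pred_mean_ms"],
                eval_dir / f"correlation_{stratum}.png")
            report[stratum] = {
                "bias_ms": ag.bias_ms,
                "loa_ms": list(ag.loa_ms),
                "pearson_r": ag.pearson_r,
                "dof": ag.dof,
                "p_value": ag.p_value,
                "quantification_error_pct": ag.quantification_error_pct,
                "within_clinical_threshold": ag.within_clinical_threshold,
            }
        with open(eval_dir / "agreement.json", "w") as f:
            json.dump(report, f, indent=1)
        _mark_done(eval_dir)
        logger.info("stage evaluate: reports written to %s", eval_dir)
    else:
        logger.info("stage evaluate: resumed")

    with open(eval_dir / "agreement.json") as f:
        agreement_report = json.load(f)
    summary = pd.read_csv(eval_dir / "summary_metrics.csv")
    return {
        "run_dir": str(run_dir),
        "split": split,
        "agreement": agreement_report,
        "summary_metrics": summary,
    }


# ---------------------------------------------------------------------------
# command line
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Synthetic T1rho map generation from T2 maps: simulate, fit, train,
    predict, evaluate, or run the whole pipeline."""
    setup_logging()


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def simulate(config_path, out_dir):
    """Generate a phantom cohort (truth maps, labels, echo series)."""
    cfg = load_config(config_path) if config_path else RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [f"S{i + 1:03d}" for i in range(cfg.phantom.n_subjects)]
    cohort = phantom.make_cohort(cfg.phantom, cfg.acquisition, ids)
    rows = []
    for subj in cohort:
        sid = subj.truth.subject_id
        write_map(out / f"{sid}_t1rho_truth.nii", subj.truth.t1rho_truth)
        write_map(out / f"{sid}_t2_truth.nii", subj.truth.t2_truth)
        write_labels(out / f"{sid}_labels.nii", subj.truth.labels)
        write_echoes(out / f"{sid}_echoes_t1rho.nii", subj.echoes_t1rho)
        write_echoes(out / f"{sid}_echoes_t2.nii", subj.echoes_t2)
        rows.append({"subject_id": sid, "seed": cfg.phantom.seed})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    save_config(cfg, out / "config.yaml")
    click.echo(f"wrote {len(ids)} subjects to {out}")


@cli.command()
@click.option("--echoes", type=click.Path(exists=True), required=True)
@click.option("--times", type=click.Path(exists=True), default=None,
              help="CSV/YAML list of preparation times (default: sidecar)")
@click.option("--kind", type=click.Choice(["t1rho", "t2"]), default=None)
@click.option("--out", "out_path", type=click.Path(), required=True)
@click.option("--quality", type=click.Path(), default=None,
              help="optional output path for the residual-norm map")
def fit(echoes, times, kind, out_path, quality):
    """Fit a mono-exponential relaxation map from a 4D echo NIfTI."""
    times_ms = None
    if times:
        times_ms = [float(x) for x in
                    pd.read_csv(times, header=None).to_numpy().ravel()]
    kind_map = {"t1rho": "T1rho", "t2": "T2", None: None}
    series = read_echoes(echoes, times_ms=times_ms, kind=kind_map[kind])
    result = relaxometry.fit_monoexponential(series)
    write_map(out_path, result.map)
    if quality:
        write_map(quality, QuantMap(result.residual_map, kind=series.kind,
                                    spacing=series.spacing))
    click.echo(f"fitted {series.kind} map -> {out_path}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "run_dir", type=click.Path(), required=True)
def run(config_path, run_dir):
    """Run (or resume) the full pipeline into a run directory."""
    cfg = load_config(config_path) if config_path else RunConfig()
    result = run_pipeline(cfg, Path(run_dir))
    click.echo(json.dumps(result["agreement"], indent=1))


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "run_dir", type=click.Path(), required=True)
def train(config_path, run_dir):
    """Train the synthesis network (runs simulate/fit/split first if their
    outputs are not already in the run directory)."""
    cfg = load_config(config_path) if config_path else RunConfig()
    result = run_pipeline(cfg, Path(run_dir), stop_after="train")
    click.echo(f"checkpoint: {result['checkpoint']}")


@cli.command()
@click.option("--model", "model_prefix", type=click.Path(), required=True)
@click.option("--t2", "t2_path", type=click.Path(exists=True), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def predict(model_prefix, t2_path, out_path):
    """Synthesize a T1rho map from a T2 map NIfTI."""
    model, _, train_cfg = load_checkpoint(model_prefix)
    t2 = read_map(t2_path, "T2")
    pred = synthesis.predict_map(model, t2, train_cfg)
    write_map(out_path, pred)
    click.echo(f"synthesized T1rho map -> {out_path}")


@cli.command()
@click.option("--pred-dir", type=click.Path(exists=True), required=True)
@click.option("--truth-dir", type=click.Path(exists=True), required=True)
@click.option("--labels-dir", type=click.Path(exists=True), required=True)
@click.option("--strata", type=click.Path(exists=True), default=None,
              help="CSV with subject_id,stratum columns")
@click.option("--out", "out_dir", type=click.Path(), required=True)
def evaluate(pred_dir, truth_dir, labels_dir, strata, out_dir):
    """Evaluate predicted vs. ground-truth T1rho maps.

    Expects {sid}_t1rho_pred.nii in pred-dir, {sid}_t1rho_truth.nii (or
    *_t1rho_fit.nii) in truth-dir, and {sid}_labels.nii in labels-dir.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preds, truths, labs = {}, {}, {}
    for p in sorted(Path(pred_dir).glob("*_t1rho_pred.nii*")):
        sid = p.name.split("_t1rho_pred")[0]
        preds[sid] = read_map(p, "T1rho").values_ms
        tdir = Path(truth_dir)
        tpath = next(
            (c for c in (tdir / f"{sid}_t1rho_truth.nii", tdir / f"{sid}_t1rho_fit.nii")
             if c.exists()), None)
        if tpath is None:
            raise click.ClickException(f"no truth map for subject {sid}")
        truths[sid] = read_map(tpath, "T1rho").values_ms
        labs[sid] = read_labels(Path(labels_dir) / f"{sid}_labels.nii")
    strata_map = None
    if strata:
        df = pd.read_csv(strata)
        strata_map = dict(zip(df["subject_id"], df["stratum"]))
    metrics, agreement = evaluation.evaluate_cohort(preds, truths, labs, strata_map)
    metrics.per_subject.to_csv(out / "per_subject_metrics.csv", index=False)
    metrics.summary.to_csv(out / "summary_metrics.csv")
    for stratum, ag in agreement.items():
        ba = evaluation.bland_altman(ag.table["truth_mean_ms"].to_numpy(),
                                     ag.table["pred_mean_ms"].to_numpy())
        evaluation.plot_bland_altman(ba, out / f"bland_altman_{stratum}.png",
                                     title=stratum)
        evaluation.plot_correlation(ag.table["truth_mean_ms"],
                                    ag.table["pred_mean_ms"],
                                    out / f"correlation_{stratum}.png")
        click.echo(f"[{stratum}] bias {ag.bias_ms:+.3f} ms, "
                   f"LoA ({ag.loa_ms[0]:.3f}, {ag.loa_ms[1]:.3f}) ms, "
                   f"r {ag.pearson_r:.3f}, qerr {ag.quantification_error_pct:.2f}%")


if __name__ == "__main__":
    cli()
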