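"""End-to-end orchestration: simulate -> preprocess -> train -> evaluate.

Every stage is a function usable on its own; :func:`run_pipeline` chains them,
persists patch manifests, checkpoints, prediction CSVs and metric tables, and
writes a machine-readable run manifest (full config + seeds + versions) that
suffices to reproduce the run bit-identically on CPU.
"""

from __future__ import annotations

import json
import platform
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import (PredictionSet, average_vote, image_probability,
                        majority_vote)
from .config import RunConfig, dump_config
from .evaluate import ConfusionTable, auc, kfold_split, metrics
from .model import DualNet, DualNetConfig
from .pce import PceParams, enhance_for_model
from .preprocess import (GrayVolume, LesionAnnotation, PatchRecord,
                         SliceWindowSpec, augment, patches_from_volume,
                         prediction_slices, sample_slices,
                         standardize_orientation)
from .synthdata import PhantomSpec, generate_phantom
from .train import Trainer


@dataclass
class Case:
    """One lesion case: annotation, its Z-window, and the per-slice patches."""

    ann: LesionAnnotation
    window: list[int]
    patches: np.ndarray          # (n_window, 224, 224) grayscale


def build_cases(volumes: dict[str, GrayVolume],
                annotations: list[LesionAnnotation],
                spec: SliceWindowSpec = SliceWindowSpec()) -> list[Case]:
    cases = []
    for ann in annotations:
        records = patches_from_volume(volumes[ann.patient_id], ann, spec)
        _, anns = standardize_orientation(volumes[ann.patient_id], [ann])
        window = sample_slices(volumes[ann.patient_id], anns[0], spec)
        cases.append(Case(ann, window,
                          np.stack([r.patch for r in records])))
    return cases


def enhance_cases(cases: list[Case], mode: str,
                  params: PceParams) -> list[np.ndarray]:
    """PCE (or baseline) enhancement of every slice patch of every case."""
    return [np.stack([enhance_for_model(p, mode, params)
                      for p in case.patches]).astype(np.float32)
            for case in cases]


def split_patients(annotations: list[LesionAnnotation], test_fraction: float,
                   seed: int) -> tuple[set[str], set[str]]:
    """Deterministic class-stratified patient-level train/test split."""
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {0: [], 1: []}
    for ann in sorted(annotations, key=lambda a: a.patient_id):
        by_class[ann.label_int].append(ann.patient_id)
    train, test = set(), set()
    for pids in by_class.values():
        pids = list(dict.fromkeys(pids))
        rng.shuffle(pids)
        n_test = max(1, int(round(test_fraction * len(pids))))
        test.update(pids[:n_test])
        train.update(pids[n_test:])
    return train, test


def _stack_slices(cases, enhanced, augment_seed=None):
    xs, ys, iids = [], [], []
    for case, x in zip(cases, enhanced):
        xs.append(x)
        ys.extend([case.ann.label_int] * len(x))
        iids.extend([case.ann.image_id] * len(x))
    return np.concatenate(xs), np.asarray(ys, dtype=np.float64), iids


def evaluate_cases(model, cases: list[Case], enhanced: list[np.ndarray],
                   m: int, batch_size: int = 32) -> dict:
    """Slice- and image-level evaluation of a trained model on held-out cases.

    Slice-level metrics use every window slice; image-level votes use the
    2m+1 slices symmetric about the center slice.
    """
    from .train import predict_probs

    slice_probs, slice_labels = [], []
    rows = []
    maj, avg, img_probs, img_labels = [], [], [], []
    for case, x in zip(cases, enhanced):
        probs = predict_probs(model, x, batch_size)
        slice_probs.append(probs)
        slice_labels.append(np.full(len(probs), case.ann.label_int))
        for z, p in zip(case.window, probs):
            rows.append({"image_id": case.ann.image_id, "slice_index": z,
                         "prob": p, "label": case.ann.label_int})
        sel = prediction_slices(case.window, case.ann.center_slice, m)
        sel_probs = probs[[case.window.index(z) for z in sel]]
        ps = PredictionSet(case.ann.image_id, sel_probs, case.ann.label_int)
        maj.append(majority_vote(ps))
        avg.append(average_vote(ps))
        img_probs.append(image_probability(ps))
        img_labels.append(case.ann.label_int)

    sp = np.concatenate(slice_probs)
    sl = np.concatenate(slice_labels)
    img_labels = np.asarray(img_labels)
    slice_ct = ConfusionTable.from_predictions(sl, (sp >= 0.5).astype(int))
    maj_ct = ConfusionTable.from_predictions(img_labels, maj)
    avg_ct = ConfusionTable.from_predictions(img_labels, avg)
    result = {
        "slice": {**metrics(slice_ct), "auc": auc(sp, sl)},
        "image_majority": metrics(maj_ct),
        "image_average": metrics(avg_ct),
        "image_auc": auc(img_probs, img_labels),
        "predictions": pd.DataFrame(rows),
        "image_votes": pd.DataFrame({
            "image_id": [c.ann.image_id for c in cases],
            "majority": maj, "average": avg, "prob": img_probs,
            "label": img_labels}),
    }
    return result


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 save_volumes: bool = False) -> dict:
    """Execute all stages in order and persist artifacts under ``out_dir``.

    Returns a dict with the trained model, per-level metric dicts and paths.
    Any stage failure raises with the stage name attached.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    timings = {}
    try:
        t0 = time.time()
        phantom = PhantomSpec(n_patients=config.phantom.n_patients,
                              n_slices=config.phantom.n_slices,
                              height=config.phantom.height,
                              width=config.phantom.width,
                              spacing_xy=config.phantom.spacing_xy,
                              spacing_z=config.phantom.spacing_z,
                              seed=config.seed)
        volumes, annotations = generate_phantom(phantom)
        if save_volumes:
            from .synthdata import save_phantom
            save_phantom(volumes, annotations, out_dir / "phantom")
        timings[stage] = time.time() - t0

        stage = "preprocess"
        t0 = time.time()
        wspec = SliceWindowSpec(config.window.total_slices, config.window.m)
        cases = build_cases(volumes, annotations, wspec)
        volumes.clear()   # free volume memory; patches carry everything needed
        params = PceParams(config.pce.delta_h, config.pce.alpha,
                           config.pce.beta, config.pce.colorize_mode)
        if config.train.augment:
            aug_root = np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
            for ci, case in enumerate(cases):
                for si in range(len(case.patches)):
                    rec = PatchRecord(case.ann.patient_id, case.ann.image_id,
                                      case.window[si], case.patches[si],
                                      case.ann.label_int)
                    case.patches[si] = augment(
                        rec, int((aug_root + ci * 1009 + si) % 2**31)).patch
        enhanced = enhance_cases(cases, config.pce.enabled, params)
        manifest = pd.DataFrame(
            [{"patient_id": c.ann.patient_id, "image_id": c.ann.image_id,
              "slice_index": z, "label": c.ann.label_int}
             for c in cases for z in c.window])
        manifest.to_csv(out_dir / "patch_manifest.csv", index=False)
        timings[stage] = time.time() - t0

        if config.eval_mode == "cv":
            stage = "cross_validate"
            t0 = time.time()
            cv = cross_validate(cases, enhanced, config)
            cv["table"].to_csv(out_dir / "cv_metrics.csv", index=False)
            timings[stage] = time.time() - t0
            (out_dir / "run_manifest.json").write_text(json.dumps({
                "config": dump_config(config), "dbtnet_version": __version__,
                "timings_s": {k: round(v, 2) for k, v in timings.items()},
            }, indent=2))
            return {"cases": cases, "cv": cv, "out_dir": out_dir}

        stage = "train"
        t0 = time.time()
        train_pids, test_pids = split_patients(
            annotations, config.train.test_fraction, config.seed)
        tr_idx = [i for i, c in enumerate(cases)
                  if c.ann.patient_id in train_pids]
        te_idx = [i for i, c in enumerate(cases)
                  if c.ann.patient_id in test_pids]
        x_train, y_train, _ = _stack_slices([cases[i] for i in tr_idx],
                                            [enhanced[i] for i in tr_idx])
        model = DualNet(DualNetConfig(
            shallow=config.model.shallow, deep=config.model.deep,
            proj_dim=config.model.proj_dim, variant=config.model.variant,
            pool_size=config.model.pool_size,
            pretrained=config.model.pretrained, seed=config.seed))
        trainer = Trainer(model, lam=config.loss.lam,
                          sim_reduction=config.loss.sim_reduction,
                          optimizer_name=config.train.optimizer,
                          lr=config.train.learning_rate,
                          batch_size=config.train.batch_size,
                          seed=config.seed)
        history = trainer.fit(x_train, y_train, config.train.epochs,
                              log_path=out_dir / "training_log.csv")
        model.save_checkpoint(out_dir / "checkpoint.npz")
        timings[stage] = time.time() - t0

        stage = "evaluate"
        t0 = time.time()
        result = evaluate_cases(model, [cases[i] for i in te_idx],
                                [enhanced[i] for i in te_idx],
                                config.window.m, config.train.batch_size)
        result["predictions"].to_csv(out_dir / "slice_predictions.csv",
                                     index=False)
        result["image_votes"].to_csv(out_dir / "image_votes.csv", index=False)
        metric_rows = []
        for level in ("slice", "image_majority", "image_average"):
            for name, value in result[level].items():
                metric_rows.append({"level": level, "metric": name,
                                    "value": round(float(value), 6)})
        metric_rows.append({"level": "image", "metric": "auc",
                            "value": round(float(result["image_auc"]), 6)})
        pd.DataFrame(metric_rows).to_csv(out_dir / "metrics.csv", index=False)
        timings[stage] = time.time() - t0

        manifest_doc = {
            "config": dump_config(config),
            "dbtnet_version": __version__,
            "numpy_version": np.__version__,
            "python_version": platform.python_version(),
            "n_train_patients": len(train_pids),
            "n_test_patients": len(test_pids),
            "final_loss": history[-1].total if history else None,
            "timings_s": {k: round(v, 2) for k, v in timings.items()},
        }
        (out_dir / "run_manifest.json").write_text(
            json.dumps(manifest_doc, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {"model": model, "cases": cases, "result": result,
            "history": history, "out_dir": out_dir,
            "train_patients": train_pids, "test_patients": test_pids}


def cross_validate(cases: list[Case], enhanced: list[np.ndarray],
                   config: RunConfig) -> dict:
    """Patient-level stratified k-fold cross-validation.

    Each fold trains a fresh model on the remaining folds' patients and
    evaluates on its own; per-fold metrics are summarized as mean and standard
    deviation (reported to 2 decimals in the table).
    """
    pids = [c.ann.patient_id for c in cases]
    labels = [c.ann.label_int for c in cases]
    folds = kfold_split(pids, labels, k=config.cv_folds, seed=config.seed)
    fold_results = []
    for fold in range(config.cv_folds):
        tr = [i for i, p in enumerate(pids) if folds[p] != fold]
        te = [i for i, p in enumerate(pids) if folds[p] == fold]
        x_train, y_train, _ = _stack_slices([cases[i] for i in tr],
                                            [enhanced[i] for i in tr])
        model = DualNet(DualNetConfig(
            shallow=config.model.shallow, deep=config.model.deep,
            proj_dim=config.model.proj_dim, variant=config.model.variant,
            pool_size=config.model.pool_size, seed=config.seed + fold))
        trainer = Trainer(model, lam=config.loss.lam,
                          sim_reduction=config.loss.sim_reduction,
                          optimizer_name=config.train.optimizer,
                          lr=config.train.learning_rate,
                          batch_size=config.train.batch_size,
                          seed=config.seed + fold)
        trainer.fit(x_train, y_train, config.train.epochs)
        fold_results.append(evaluate_cases(
            model, [cases[i] for i in te], [enhanced[i] for i in te],
            config.window.m, config.train.batch_size))
    rows = []
    for level in ("slice", "image_majority", "image_average"):
        names = fold_results[0][level].keys()
        for name in names:
            vals = np.array([fr[level][name] for fr in fold_results])
            rows.append({"level": level, "metric": name,
                         "mean": round(float(np.nanmean(vals)), 2),
                         "sd": round(float(np.nanstd(vals)), 2)})
    img_auc = np.array([fr["image_auc"] for fr in fold_results])
    rows.append({"level": "image", "metric": "auc",
                 "mean": round(float(img_auc.mean()), 2),
                 "sd": round(float(img_auc.std()), 2)})
    return {"folds": fold_results, "table": pd.DataFrame(rows)}
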