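"""End-to-end orchestration: simulate/extract → features → CV → LSTM → HMM → metrics.

A :class:`PipelineConfig` collects every tunable of the method (wavelet
name, window length T, feature parameters, classifier and HMM settings,
CV layout, and the input manifest).  :func:`run` executes the whole study
into a run directory whose artifacts — per-night feature CSVs, the split
manifest, per-fold HMM JSON, predictions before/after correction, and
metric reports — are all re-derivable from the config plus its seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import dataset as ds
from . import evaluation as ev
from . import hmm as hmm_mod
from .classifier import ClassifierConfig, LstmStageClassifier, predict_night
from .features import FeatureConfig, extract_night_features, feature_names
from .preprocessing import (
    bandpass_filter,
    epoch_recording,
    map_labels,
    read_recording,
    trim_to_sleep_period,
)
from .recording import EpochedRecording
from .synthetic import StageMarkovSpec, generate_night
from .wavelets import WAVELET_FUNCTIONS

logger = logging.getLogger("wavesleep")


class RecordingEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    edf: str
    hypnogram: str
    channel: str = "EEG Fpz-Cz"
    night_id: str = ""


class SyntheticInput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_nights: int = 20
    n_epochs: int = 1080
    self_transition: float = 0.85
    noise_sd: float = 1.0


class InputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["synthetic", "edf"] = "synthetic"
    synthetic: SyntheticInput = Field(default_factory=SyntheticInput)
    recordings: list[RecordingEntry] = Field(default_factory=list)


class ClassifierSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden_size: int = 20
    num_layers: int = 1
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-3
    patience: int = 10


class PipelineConfig(BaseModel):
    """Validated configuration of a full run; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    wavelet: str = "db4"
    levels: int = 4
    T: int = 3
    ae_m: int = 2
    ae_r_mult: float = 0.2
    se_bins: int = 16
    higuchi_t_max: int = 10
    filter_low_hz: float = 0.5
    filter_high_hz: float = 49.0
    classifier: ClassifierSettings = Field(default_factory=ClassifierSettings)
    hmm_smoothing: float = 1.0
    cv_k: int = 10
    val_fraction: float = 0.2
    seed: int = 0
    input: InputConfig = Field(default_factory=InputConfig)

    @field_validator("wavelet")
    @classmethod
    def _known_wavelet(cls, v: str) -> str:
        if v not in WAVELET_FUNCTIONS:
            raise ValueError(f"unknown wavelet {v!r}; choose one of {WAVELET_FUNCTIONS}")
        return v

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            ae_m=self.ae_m,
            ae_r_mult=self.ae_r_mult,
            se_bins=self.se_bins,
            higuchi_t_max=self.higuchi_t_max,
        )


def load_config(path) -> PipelineConfig:
    """Load and schema-validate a YAML config file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return PipelineConfig(**payload)


def _load_nights(config: PipelineConfig) -> list[EpochedRecording]:
    """Materialize the input manifest as epoched, labelled recordings."""
    nights: list[EpochedRecording] = []
    if config.input.kind == "synthetic":
        spec = config.input.synthetic
        p_stay = spec.self_transition
        a = np.full((5, 5), (1.0 - p_stay) / 4.0)
        np.fill_diagonal(a, p_stay)
        markov = StageMarkovSpec(transition_matrix=a, n_epochs=spec.n_epochs)
        from .synthetic import StageSpectralSpec

        spectral = StageSpectralSpec(noise_sd=spec.noise_sd)
        for i in range(spec.n_nights):
            nights.append(
                generate_night(
                    markov=markov,
                    spectral=spectral,
                    seed=config.seed * 10_007 + i,
                    night_id=f"night{i:03d}",
                )
            )
    else:
        if not config.input.recordings:
            raise ValueError("edf input requires a non-empty recordings list")
        for entry in config.input.recordings:
            raw = read_recording(entry.edf, entry.hypnogram, channel=entry.channel)
            raw = bandpass_filter(raw, config.filter_low_hz, config.filter_high_hz)
            codes, keep = map_labels(raw.annotations)
            rec = epoch_recording(
                raw, codes, keep, night_id=entry.night_id or Path(entry.edf).stem
            )
            nights.append(trim_to_sleep_period(rec))
    return nights


def _night_sequences(
    features: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    night_ids: list[str],
    normalizer: ds.Normalizer,
    T: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for nid in night_ids:
        seqs = ds.build_sequences(normalizer.transform(features[nid]), labels[nid],
                                  night_id=nid, T=T)
        out[nid] = ds.sequences_to_arrays(seqs)
    return out


def run(config: PipelineConfig, run_dir) -> dict:
    """Execute the full pipeline; returns the aggregated summary dict."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(run_dir / "run.log")
    logger.addHandler(fh)
    try:
        return _run(config, run_dir, t0)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run(config: PipelineConfig, run_dir: Path, t0: float) -> dict:
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.model_dump()))

    stage = "simulate/extract"
    try:
        nights = _load_nights(config)
        logger.info("loaded %d nights (%.1fs)", len(nights), time.time() - t0)

        stage = "features"
        feat_dir = run_dir / "features"
        feat_dir.mkdir(exist_ok=True)
        fcfg = config.feature_config()
        features: dict[str, np.ndarray] = {}
        labels: dict[str, np.ndarray] = {}
        for rec in nights:
            x = extract_night_features(rec, wavelet=config.wavelet, config=fcfg)
            features[rec.night_id] = x
            labels[rec.night_id] = rec.labels
            df = pd.DataFrame(x, columns=list(feature_names()))
            df.insert(0, "stage", rec.labels)
            df.to_csv(feat_dir / f"{rec.night_id}.csv", index=False)
        logger.info("features extracted (%.1fs)", time.time() - t0)

        stage = "split"
        night_ids = [rec.night_id for rec in nights]
        folds = ds.make_folds(
            night_ids, k=config.cv_k, val_fraction=config.val_fraction, seed=config.seed
        )
        ds.save_folds(folds, run_dir / "folds.json")

        reports_raw, reports_cor = [], []
        cms_raw, cms_cor = [], []
        for fold in folds:
            stage = f"fold {fold.fold_id}"
            fold_dir = run_dir / f"fold{fold.fold_id:02d}"
            fold_dir.mkdir(exist_ok=True)

            norm = ds.Normalizer().fit(
                np.vstack([features[n] for n in fold.train_nights])
            )
            train = _night_sequences(features, labels, fold.train_nights, norm, config.T)
            val = _night_sequences(features, labels, fold.validation_nights, norm, config.T)
            test = _night_sequences(features, labels, fold.test_nights, norm, config.T)

            x_tr = np.concatenate([v[0] for v in train.values()])
            y_tr = np.concatenate([v[1] for v in train.values()])
            x_va = np.concatenate([v[0] for v in val.values()])
            y_va = np.concatenate([v[1] for v in val.values()])

            ccfg = ClassifierConfig(
                input_dim=x_tr.shape[2],
                hidden_size=config.classifier.hidden_size,
                num_layers=config.classifier.num_layers,
                T=config.T,
                epochs=config.classifier.epochs,
                batch_size=config.classifier.batch_size,
                learning_rate=config.classifier.learning_rate,
                patience=config.classifier.patience,
                seed=config.seed * 1000 + fold.fold_id,
            )
            model = LstmStageClassifier(ccfg).fit(x_tr, y_tr, x_va, y_va)
            np.savez(fold_dir / "lstm.npz", *model.get_weights())

            # HMM from validation nights of this same fold's model
            val_true = [val[n][1] for n in fold.validation_nights]
            val_pred = [
                predict_night(model, val[n][0], n).predicted_labels
                for n in fold.validation_nights
            ]
            corrector = hmm_mod.estimate(val_true, val_pred, smoothing=config.hmm_smoothing)
            corrector.to_json(fold_dir / "hmm.json")

            rows = []
            true_all, raw_all, cor_all = [], [], []
            for nid in fold.test_nights:
                pred = predict_night(model, test[nid][0], nid)
                pred = hmm_mod.correct_night(corrector, pred)
                y_true = test[nid][1]
                true_all.append(y_true)
                raw_all.append(pred.predicted_labels)
                cor_all.append(pred.corrected_labels)
                for t, (yt, yr, yc) in enumerate(
                    zip(y_true, pred.predicted_labels, pred.corrected_labels)
                ):
                    rows.append((nid, t, yt, yr, yc))
            pd.DataFrame(
                rows, columns=["night_id", "epoch", "true", "predicted", "corrected"]
            ).to_csv(fold_dir / "predictions.csv", index=False)

            cm_raw = ev.confusion(np.concatenate(true_all), np.concatenate(raw_all))
            cm_cor = ev.confusion(np.concatenate(true_all), np.concatenate(cor_all))
            rep_raw = ev.metrics(cm_raw, fold_id=fold.fold_id)
            rep_cor = ev.metrics(cm_cor, fold_id=fold.fold_id)
            with open(fold_dir / "metrics.json", "w") as fjson:
                json.dump(
                    {"raw": rep_raw.as_dict(), "corrected": rep_cor.as_dict()},
                    fjson,
                    indent=2,
                )
            reports_raw.append(rep_raw)
            reports_cor.append(rep_cor)
            cms_raw.append(cm_raw)
            cms_cor.append(cm_cor)
            logger.info(
                "fold %d: acc %.3f -> %.3f (%.1fs)",
                fold.fold_id, rep_raw.accuracy, rep_cor.accuracy, time.time() - t0,
            )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    summary_raw = ev.aggregate_folds(reports_raw, cms_raw)
    summary_cor = ev.aggregate_folds(reports_cor, cms_cor)
    summary = {
        "raw": {"mean": summary_raw.mean, "std": summary_raw.std},
        "corrected": {"mean": summary_cor.mean, "std": summary_cor.std},
        "n_nights": len(nights),
        "n_epochs": int(sum(len(v) for v in labels.values())),
        "elapsed_seconds": time.time() - t0,
    }
    with open(run_dir / "summary.json", "w") as fjson:
        json.dump(summary, fjson, indent=2)
    np.savetxt(run_dir / "pooled_confusion_raw.csv", summary_raw.pooled.counts,
               fmt="%d", delimiter=",")
    np.savetxt(run_dir / "pooled_confusion_corrected.csv", summary_cor.pooled.counts,
               fmt="%d", delimiter=",")
    return summary
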