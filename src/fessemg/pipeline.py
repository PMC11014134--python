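"""End-to-end reproducible pipeline: simulate -> clean -> image -> train -> evaluate.

A run directory is laid out as::

    run/
      manifest.json            # config, seed, stage status, versions
      recordings.h5            # simulated recordings (+ ground-truth clean)
      manifest_labels.csv      # recording_id, motion, fatigue, seed
      windows_clean.h5         # artifact-suppressed windows
      examples.npz             # stacked per-channel image tensors + labels
      model.npz                # best-validation checkpoint
      history.csv              # per-epoch losses/accuracies
      metrics_*.json/.csv      # network and LDA baseline reports
      confusion_*.csv

Every stage is deterministic given the global seed; ``resume=True`` reuses
stage outputs already on disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as fio
from .evaluation import (confusion_from_predictions, metrics_from_counts,
                         MetricsReport)
from .features import lda_fit, lda_predict, tdf_features, tff_features
from .imaging import window_to_image
from .labels import FATIGUE_LEVELS, MOTIONS
from .model import (LabeledExample, ModelConfig, TrainConfig, build_model,
                    load_checkpoint, predict, save_checkpoint, split_dataset,
                    train)
from .preprocess import remove_fes_artifacts, segment
from .simulate import SimulationConfig, generate_dataset

log = logging.getLogger("fessemg")


@dataclass(frozen=True)
class ImagingConfig:
    method: str = "STFT"
    image_size: int = 32
    colormap: str = "viridis"
    scaling: str = "log"

    def validate(self) -> "ImagingConfig":
        if self.method.upper() not in ("STFT", "CWT", "HHT"):
            raise ValueError(f"unknown imaging method {self.method!r}")
        if self.image_size % 16 != 0:
            raise ValueError("image_size must be divisible by 16 (four 2x pools)")
        return self


@dataclass(frozen=True)
class ArtifactRemovalConfig:
    stim_freq_hz: float = 20.0
    n_harmonics: int = 5
    imf_line_ratio_threshold: float = 0.6
    notch_quality: float = 30.0


@dataclass(frozen=True)
class BaselineConfig:
    wl_form: str = "conventional"
    epsilon: float = 0.0


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for one end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_windows_per_class: int = 200
    artifact_removal: ArtifactRemovalConfig = field(default_factory=ArtifactRemovalConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig.reduced())
    training: TrainConfig = field(default_factory=lambda: TrainConfig(epochs=40))
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        self.simulation.validate()
        self.imaging.validate()
        self.model.validate()
        self.training.validate()
        if self.model.input_size != self.imaging.image_size:
            raise ValueError(
                f"model input_size {self.model.input_size} must equal "
                f"imaging image_size {self.imaging.image_size}"
            )
        if self.n_windows_per_class < 1:
            raise ValueError("n_windows_per_class must be >= 1")
        return self

    def reseeded(self, seed: int) -> "PipelineConfig":
        return replace(
            self, seed=seed,
            simulation=replace(self.simulation, seed=seed),
            model=replace(self.model, seed=seed),
            training=replace(self.training, seed=seed),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["motion_envelopes"] = {
            k: [list(env) for env in v]
            for k, v in d["simulation"]["motion_envelopes"].items()
        }
        return d

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        kw = {}
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            sim.pop("motion_envelopes", None)  # envelope table is code-defined
            if "carrier_support_hz" in sim:
                sim["carrier_support_hz"] = tuple(sim["carrier_support_hz"])
            kw["simulation"] = SimulationConfig(**sim)
        if "artifact_removal" in raw:
            kw["artifact_removal"] = ArtifactRemovalConfig(**raw["artifact_removal"])
        if "imaging" in raw:
            kw["imaging"] = ImagingConfig(**raw["imaging"])
        if "model" in raw:
            m = dict(raw["model"])
            if "fatigue_fc_dims" in m:
                m["fatigue_fc_dims"] = tuple(m["fatigue_fc_dims"])
            kw["model"] = ModelConfig(**m)
        if "training" in raw:
            t = dict(raw["training"])
            if "split" in t:
                t["split"] = tuple(t["split"])
            kw["training"] = TrainConfig(**t)
        if "baseline" in raw:
            kw["baseline"] = BaselineConfig(**raw["baseline"])
        for key in ("n_windows_per_class", "seed", "log_level"):
            if key in raw:
                kw[key] = raw[key]
        cfg = cls(**kw)
        if "seed" in raw:
            cfg = cfg.reseeded(raw["seed"])
        return cfg.validate()


def clean_windows_for_recording(rec, cfg: PipelineConfig):
    """Segment one recording and artifact-clean each per-channel window."""
    ar = cfg.artifact_removal
    wins = segment(rec, window_s=0.5, overlap_fraction=0.0)
    return [remove_fes_artifacts(
        w, stim_freq_hz=ar.stim_freq_hz, n_harmonics=ar.n_harmonics,
        imf_line_ratio_threshold=ar.imf_line_ratio_threshold,
        notch_quality=ar.notch_quality) for w in wins]


def windows_to_example(windows, cfg: PipelineConfig) -> LabeledExample:
    im = cfg.imaging
    imgs = [window_to_image(w, im.method, out_size=(im.image_size, im.image_size),
                            colormap=im.colormap, scaling=im.scaling
                            ).pixels.transpose(2, 0, 1) for w in windows]
    w0 = windows[0]
    return LabeledExample(np.stack(imgs).astype(np.float32),
                          w0.motion_label, w0.fatigue_label, w0.recording_id)


def _metrics(y_true, y_pred, labels) -> MetricsReport:
    return metrics_from_counts(confusion_from_predictions(y_true, y_pred, labels))


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = False) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: simulate -> preprocess (segment + artifact removal) -> images ->
    split -> train network -> fit LDA baselines -> evaluate everything on the
    held-out test split. Deterministic given ``config.seed``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    manifest_path = out / "manifest.json"
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def _stage(name):
        def deco(fn):
            t0 = time.time()
            result = fn()
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
            manifest_path.write_text(json.dumps(manifest, indent=1))
            log.info("stage %s done in %.1f s", name, time.time() - t0)
            return result
        return deco

    # -- simulate ------------------------------------------------------------
    rec_path = out / "recordings.h5"
    if resume and rec_path.exists():
        recordings = fio.load_recordings_hdf5(rec_path)
    else:
        @_stage("simulate")
        def recordings():
            recs = generate_dataset(config.simulation, config.n_windows_per_class)
            fio.save_recordings_hdf5(recs, rec_path)
            fio.save_manifest(recs, out / "manifest_labels.csv")
            return recs
    log.info("simulate: %d recordings", len(recordings))

    # -- preprocess + images --------------------------------------------------
    ex_path = out / "examples.npz"
    win_path = out / "windows_clean.h5"
    if resume and ex_path.exists():
        data = np.load(ex_path, allow_pickle=False)
        examples = [LabeledExample(img, m, f, r) for img, m, f, r in zip(
            data["images"], data["motion"], data["fatigue"], data["recording_id"])]
        tdf_X, tff_X = data["tdf"], data["tff"]
    else:
        @_stage("preprocess_images")
        def _built():
            examples, tdf_rows, tff_rows, all_windows = [], [], [], []
            for rec in recordings:
                wins = clean_windows_for_recording(rec, config)
                all_windows.extend(wins)
                examples.append(windows_to_example(wins, config))
                tdf_rows.append(np.concatenate([
                    tdf_features(w, config.baseline.epsilon,
                                 config.baseline.wl_form).values for w in wins]))
                tff_rows.append(np.concatenate([
                    tff_features(w).values for w in wins]))
            fio.save_windows_hdf5(all_windows, win_path)
            np.savez_compressed(
                ex_path,
                images=np.stack([e.images for e in examples]),
                motion=np.array([e.motion_label for e in examples]),
                fatigue=np.array([e.fatigue_label for e in examples]),
                recording_id=np.array([e.recording_id for e in examples]),
                tdf=np.array(tdf_rows), tff=np.array(tff_rows),
            )
            return examples, np.array(tdf_rows), np.array(tff_rows)
        examples, tdf_X, tff_X = _built
    n_ch = config.simulation.n_channels
    log.info("images: %d examples x %d channels (one image per window-channel)",
             len(examples), n_ch)

    # -- split ----------------------------------------------------------------
    tr, va, te = split_dataset(examples, config.training.split, seed=config.seed)
    pos = {id(e): i for i, e in enumerate(examples)}
    itr = [pos[id(e)] for e in tr]
    iva = [pos[id(e)] for e in va]
    ite = [pos[id(e)] for e in te]

    # -- train network ---------------------------------------------------------
    model_path = out / "model.npz"
    if resume and model_path.exists():
        model = load_checkpoint(model_path)
    else:
        @_stage("train")
        def model():
            net = build_model(config.model)
            net, history = train(net, tr, va, config.training)
            save_checkpoint(net, model_path)
            fio.save_history_csv(history, out / "history.csv")
            return net

    # -- evaluate --------------------------------------------------------------
    @_stage("evaluate")
    def results():
        preds = predict(model, te)
        pm = np.array([p.motion_label for p in preds])
        pf = np.array([p.fatigue_label for p in preds])
        tm = np.array([e.motion_label for e in te])
        tf = np.array([e.fatigue_label for e in te])
        fio.save_predictions([{
            "recording_id": e.recording_id, "motion_true": a, "motion_pred": b,
            "fatigue_true": c, "fatigue_pred": d}
            for e, a, b, c, d in zip(te, tm, pm, tf, pf)], out / "predictions.csv")

        ym = np.array([e.motion_label for e in examples])
        yf = np.array([e.fatigue_label for e in examples])
        fit = itr + iva
        lda_motion = lda_fit(tdf_X[fit], ym[fit])
        lda_fatigue = lda_fit(tff_X[fit], yf[fit])
        lm = lda_predict(lda_motion, tdf_X[ite])
        lf = lda_predict(lda_fatigue, tff_X[ite])

        reports = {
            "net_motion": _metrics(tm, pm, list(MOTIONS)),
            "net_fatigue": _metrics(tf, pf, list(FATIGUE_LEVELS)),
            "lda_motion": _metrics(ym[ite], lm, list(MOTIONS)),
            "lda_fatigue": _metrics(yf[ite], lf, list(FATIGUE_LEVELS)),
        }
        for name, rep in reports.items():
            fio.save_metrics(rep, out / f"metrics_{name}.json",
                             out / f"metrics_{name}.csv")
            fio.save_confusion_csv(
                confusion_from_predictions(
                    tm if name == "net_motion" else
                    tf if name == "net_fatigue" else
                    ym[ite] if name == "lda_motion" else yf[ite],
                    pm if name == "net_motion" else
                    pf if name == "net_fatigue" else
                    lm if name == "lda_motion" else lf,
                    list(MOTIONS) if "motion" in name else list(FATIGUE_LEVELS)),
                out / f"confusion_{name}.csv")
        return {k: v.accuracy for k, v in reports.items()}

    manifest["accuracies_percent"] = results
    manifest_path.write_text(json.dumps(manifest, indent=1))
    log.info("accuracies: %s", results)
    return out
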