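"""End-to-end orchestration: images -> features -> group statistics -> PNN.

``run_pipeline`` drives the full screening analysis over either a directory of
labelled photographs or a generated synthetic cohort, writing a feature CSV, a
group-summary table, the leave-one-out confusion matrix and metrics, and a run
log.  Everything is deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import pnn, stats, synthetic
from .exceptions import ValidationError
from .features import build_feature_table
from .images import GreyImage, RoiSpec, load_image, preprocess

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("mucotex")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """Flat, file-serializable configuration of one pipeline run."""

    mode: str = "synthetic"              # "synthetic" | "directory"
    input_dir: str = ""                  # directory mode: holds images + labels.csv
    output_dir: str = "mucotex_out"
    n_per_class: int = 35                # synthetic mode cohort size
    seed: int = 0
    image_size: int = 300
    roi_top: int = -1                    # -1 = no crop
    roi_left: int = -1
    roi_height: int = 300
    roi_width: int = 300
    highpass_radius: float = 10.0
    equalize_mode: str = "stretch"
    quantize_bits: int = 4
    glcm_distance: int = 5
    wavelet_scale_lo: int = 5
    wavelet_scale_hi: int = 6
    sigma_grid: tuple[float, ...] = pnn.DEFAULT_SIGMA_GRID
    positive_label: str = "lesion"
    report_resubstitution: bool = False

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file; unknown keys are rejected."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValidationError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _parse_value(raw, getattr(cls, key, None), known[key].type)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _parse_value(raw: str, default, typ):
    if isinstance(default, bool) or typ is bool:
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, tuple) or "tuple" in str(typ):
        return tuple(float(x) for x in raw.split(",") if x.strip())
    if isinstance(default, int) or typ is int:
        return int(raw)
    if isinstance(default, float) or typ is float:
        return float(raw)
    return raw


def _load_directory(cfg: PipelineConfig) -> tuple[list, list[str]]:
    root = Path(cfg.input_dir)
    manifest = root / "labels.csv"
    if not manifest.exists():
        raise PipelineError(f"stage 'load': missing manifest {manifest}")
    table = pd.read_csv(manifest)
    images, labels = [], []
    for _, row in table.iterrows():
        path = root / str(row["filename"])
        try:
            images.append(load_image(path))
        except Exception as exc:
            raise PipelineError(f"stage 'load' failed on {path}: {exc}") from exc
        labels.append(str(row["label"]))
    return images, labels


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run preprocess -> features -> statistics -> PNN and write all artifacts.

    Returns a dict with the artifact paths, the group-summary DataFrame, the
    confusion counts and the selected sigma.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("pipeline start; config hash %s", cfg.config_hash())
        cfg.to_file(out / "config.txt")

        if cfg.mode == "synthetic":
            images, labels = synthetic.generate_cohort(
                cfg.n_per_class, seed=cfg.seed, size=cfg.image_size)
            sources = [f"synthetic[{i}]" for i in range(len(images))]
        elif cfg.mode == "directory":
            images, labels = _load_directory(cfg)
            sources = [f"{cfg.input_dir}[{i}]" for i in range(len(images))]
        else:
            raise ValidationError(f"unknown mode {cfg.mode!r}")
        log.info("loaded %d images", len(images))

        roi = None
        if cfg.roi_top >= 0 and cfg.roi_left >= 0:
            roi = RoiSpec(cfg.roi_top, cfg.roi_left, cfg.roi_height, cfg.roi_width)
        processed: list[GreyImage] = []
        for img, src in zip(images, sources):
            try:
                processed.append(preprocess(
                    img, roi=roi, highpass_radius=cfg.highpass_radius,
                    equalize_mode=cfg.equalize_mode, bits=cfg.quantize_bits))
            except Exception as exc:
                raise PipelineError(f"stage 'preprocess' failed on {src}: {exc}") from exc

        try:
            table = build_feature_table(processed, labels,
                                        glcm_distance=cfg.glcm_distance)
        except Exception as exc:
            raise PipelineError(f"stage 'features' failed: {exc}") from exc
        features_csv = out / "features.csv"
        table.to_csv(features_csv, index=False)
        log.info("feature table written: %s", features_csv)

        artifacts = {"features_csv": features_csv, "table": table}
        # group statistics and classification need both classes represented
        counts = table["label"].value_counts()
        if len(counts) == 2 and counts.min() >= 2:
            summary = stats.summarize(table)
            summary.to_csv(out / "summary.csv")
            (out / "summary.txt").write_text(stats.render_summary(summary) + "\n")
            x = table[list(pnn.PNN_FEATURES)].to_numpy(float)
            y = table["label"].to_numpy()
            sigma = pnn.select_sigma(x, y, grid=cfg.sigma_grid,
                                     positive_label=cfg.positive_label)
            cc, sens, spec = pnn.evaluate_loo(x, y, sigma=sigma,
                                              positive_label=cfg.positive_label)
            metrics = {"sigma": sigma, "protocol": "leave-one-out",
                       "tp": cc.tp, "fn": cc.fn, "tn": cc.tn, "fp": cc.fp,
                       "sensitivity": sens, "specificity": spec,
                       **cc.percent_metrics()}
            if cfg.report_resubstitution:
                rc = pnn.evaluate_resubstitution(x, y, sigma=sigma,
                                                 positive_label=cfg.positive_label)
                metrics["resub_sensitivity"] = rc.sensitivity
                metrics["resub_specificity"] = rc.specificity
            pd.DataFrame([metrics]).to_csv(out / "metrics.csv", index=False)
            pd.DataFrame([{"tp": cc.tp, "fn": cc.fn, "tn": cc.tn, "fp": cc.fp}]
                         ).to_csv(out / "confusion.csv", index=False)
            log.info("LOO sensitivity %.1f%% specificity %.1f%% (sigma=%g)",
                     100 * sens, 100 * spec, sigma)
            artifacts.update(summary=summary, confusion=cc, sigma=sigma,
                             metrics=metrics,
                             summary_csv=out / "summary.csv",
                             metrics_csv=out / "metrics.csv",
                             confusion_csv=out / "confusion.csv")
        log.info("pipeline done")
        return artifacts
    finally:
        log.removeHandler(handler)
        handler.close()
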