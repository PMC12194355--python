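"""End-to-end orchestration: simulate -> train -> evaluate, reproducibly.

A :class:`RunConfig` holds every knob of the pipeline in one structured,
YAML-serializable object; all per-phase seeds are derived from its single
global seed (simulate: seed, split: seed+1, training: seed+2, weight
init: seed+3), so one integer reproduces the whole study on one machine.

``run_scaled_study`` runs the full pipeline at a desk-scale problem size
(small images, narrow model) and returns the per-dose evaluation summary
plus the point-source linearity check — the package's headline computation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom
from .dataio import (SplitAssignment, build_pairs, read_grayscale,
                     split_dataset, write_grayscale)
from .errors import ConfigurationError
from .metrics import (EIGHT_BIT, MetricConfig, evaluate_pairs,
                      records_to_frame, summaries_to_frame, summarize_by_dose)
from .model import (ModelConfig, init_parameters, load_checkpoint,
                    save_checkpoint)
from .training import TrainingConfig, denoise, train


@dataclass
class PhantomSettings:
    image_size: tuple[int, int] = (64, 64)
    background_rate: float = 10.0
    bone_rate_scale: float = 5.0


@dataclass
class DatasetSettings:
    n_subjects: int = 8
    regions: tuple[str, ...] = ("pelvis", "thorax")
    fractions: tuple[float, ...] = phantom.LOW_DOSE_FRACTIONS
    split_ratios: tuple[float, float, float] = (0.75, 0.15, 0.10)
    group_by_subject: bool = True
    intensity_mode: str = "per_image_max"


@dataclass
class PathSettings:
    data_dir: str = "data"
    output_dir: str = "outputs"
    checkpoint: str = "outputs/model.npz"
    split_file: str = "outputs/split.json"


@dataclass
class RunConfig:
    seed: int = 0
    phantom: PhantomSettings = field(default_factory=PhantomSettings)
    dataset: DatasetSettings = field(default_factory=DatasetSettings)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    metrics: MetricConfig = field(default_factory=lambda: EIGHT_BIT)

    paths: PathSettings = field(default_factory=PathSettings)

    # per-phase seeds, all derived from the one global seed
    @property
    def simulate_seed(self) -> int:
        return self.seed

    @property
    def split_seed(self) -> int:
        return self.seed + 1

    @property
    def train_seed(self) -> int:
        return self.seed + 2

    @property
    def init_seed(self) -> int:
        return self.seed + 3

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, d):
            if d is None:
                return klass()
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name in d:
                    v = d[f.name]
                    kwargs[f.name] = tuple(v) if isinstance(v, list) else v
            return klass(**kwargs)

        return cls(
            seed=int(raw.get("seed", 0)),
            phantom=build(PhantomSettings, raw.get("phantom")),
            dataset=build(DatasetSettings, raw.get("dataset")),
            model=build(ModelConfig, raw.get("model")),
            training=build(TrainingConfig, raw.get("training")),
            metrics=build(MetricConfig, raw.get("metrics")),
            paths=build(PathSettings, raw.get("paths")))


# --------------------------------------------------------------------------
# pipeline phases

def cmd_simulate(config: RunConfig) -> pd.DataFrame:
    """Generate the paired low/full-dose dataset and its manifest."""
    manifest = phantom.generate_paired_dataset(
        n_subjects=config.dataset.n_subjects,
        regions=list(config.dataset.regions),
        fractions=list(config.dataset.fractions),
        base_seed=config.simulate_seed,
        out_dir=config.paths.data_dir,
        image_size=tuple(config.phantom.image_size),
        background_rate=config.phantom.background_rate,
        bone_rate_scale=config.phantom.bone_rate_scale)
    counts = manifest.groupby(["region", "dose_fraction"]).size()
    print(f"simulate: seed={config.simulate_seed} "
          f"pairs={len(manifest)} -> {config.paths.data_dir}")
    for (region, frac), n in counts.items():
        print(f"  {region} @ {frac:.0%}: {n} pairs")
    return manifest


def cmd_train(config: RunConfig):
    """Build pairs, split, train, persist checkpoint + split + history."""
    manifest_path = Path(config.paths.data_dir) / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path} "
                                "(run simulate first)")
    pairs = build_pairs(manifest_path,
                        intensity_mode=config.dataset.intensity_mode)
    split = split_dataset(pairs, config.dataset.split_ratios,
                          seed=config.split_seed,
                          group_by_subject=config.dataset.group_by_subject)
    by_id = {p.pair_id: p for p in pairs}
    train_pairs = [by_id[i] for i in split.train]
    val_pairs = [by_id[i] for i in split.validation]

    model_cfg = dataclasses.replace(config.model, init_seed=config.init_seed)
    train_cfg = dataclasses.replace(config.training, seed=config.train_seed)
    params = init_parameters(model_cfg)
    params, history = train(params, model_cfg, train_pairs, val_pairs,
                            train_cfg, log_every=50)

    out_dir = Path(config.paths.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    split.to_json(config.paths.split_file)
    save_checkpoint(config.paths.checkpoint, params,
                    train_seed=train_cfg.seed,
                    history={"stop_reason": history.stop_reason,
                             "best_iteration": history.best_iteration,
                             "best_val_loss": history.best_val_loss})
    print(f"train: {len(train_pairs)} train / {len(val_pairs)} val pairs, "
          f"stopped by {history.stop_reason} at best iteration "
          f"{history.best_iteration} (val loss {history.best_val_loss:.5f})")
    return params, history, split


def cmd_evaluate(config: RunConfig, *, identity_denoiser: bool = False):
    """Evaluate the held-out test split; write record + summary CSVs."""
    ckpt = Path(config.paths.checkpoint)
    if not ckpt.exists():
        raise FileNotFoundError(f"checkpoint not found: {ckpt}")
    params, _ = load_checkpoint(ckpt)
    split = SplitAssignment.from_json(config.paths.split_file)
    pairs = build_pairs(Path(config.paths.data_dir) / "manifest.csv",
                        intensity_mode=config.dataset.intensity_mode)
    by_id = {p.pair_id: p for p in pairs}
    test_pairs = [by_id[i] for i in split.test]
    for p in test_pairs:
        assert split.split_of(p.pair_id) == "test"

    denoiser = (lambda imgs: imgs) if identity_denoiser else None
    records = evaluate_pairs(params, test_pairs, config.metrics,
                             denoiser=denoiser)
    summaries = summarize_by_dose(records)
    out_dir = Path(config.paths.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # %.17g keeps the CSV round-trip bit-exact for float64
    records_to_frame(records).to_csv(out_dir / "metrics.csv", index=False,
                                     float_format="%.17g")
    summary_frame = summaries_to_frame(summaries)
    summary_frame.to_csv(out_dir / "summary.csv", index=False,
                         float_format="%.17g")
    print(f"evaluate: {len(records)} test pairs -> {out_dir/'summary.csv'}")
    return records, summaries


def cmd_denoise(config: RunConfig, inputs: list[str | Path],
                out_dir: str | Path):
    """Denoise stored PNGs with the trained checkpoint."""
    params, _ = load_checkpoint(config.paths.checkpoint)
    images = [read_grayscale(p) for p in inputs]
    outputs = denoise(params, params.config, images)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for src, img in zip(inputs, outputs):
        dst = out_dir / f"denoised_{Path(src).name}"
        write_grayscale(dst, img)
        written.append(dst)
    return written


# --------------------------------------------------------------------------
# the scaled-down study

def scaled_study_config(seed: int, work_dir: str | Path, *,
                        n_subjects: int = 40,
                        image_size: tuple[int, int] = (64, 64),
                        max_iterations: int = 500) -> RunConfig:
    """Desk-scale study conditions: full protocol, small images, narrow model.

    40 subjects x 2 regions x 2 views x 7 low-dose fractions = 1120 pairs
    at 64x64. The model uses a single downsampling stage of width 16: with
    images four times smaller (linearly) than the clinical 256x256 matrix,
    one stride-2 stage keeps the latent-to-image compression ratio
    comparable to two stages at full resolution, which a few hundred Adam
    iterations can train on one CPU. 500 iterations, validation every 10.
    """
    work_dir = Path(work_dir)
    return RunConfig(
        seed=seed,
        phantom=PhantomSettings(image_size=image_size),
        dataset=DatasetSettings(n_subjects=n_subjects),
        model=ModelConfig(encoder_widths=(16,), n_downsamples=1,
                          gn_groups=4, attention_reduction=4),
        training=TrainingConfig(max_iterations=max_iterations,
                                validate_every=10),
        paths=PathSettings(data_dir=str(work_dir / "data"),
                           output_dir=str(work_dir / "outputs"),
                           checkpoint=str(work_dir / "outputs" / "model.npz"),
                           split_file=str(work_dir / "outputs" / "split.json")))


def run_scaled_study(seed: int, work_dir: str | Path, **kwargs) -> dict:
    """Simulate, train and evaluate at desk scale; return headline numbers."""
    config = scaled_study_config(seed, work_dir, **kwargs)
    cmd_simulate(config)
    params, history, split = cmd_train(config)
    records, summaries = cmd_evaluate(config)

    point = phantom.simulate_point_source(
        1e6, list(phantom.PROTOCOL_FRACTIONS), seed=config.seed + 17)

    return {"config": config, "history": history, "split": split,
            "records": records, "summaries": summaries,
            "summary_frame": summaries_to_frame(summaries),
            "point_source": point}
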