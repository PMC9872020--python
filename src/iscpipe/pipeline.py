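"""End-to-end orchestration: simulate -> preprocess -> ISC -> annotate ->
ALD -> model, with a single declarative config and stamped stage tables.

The window grid is computed once (in the ISC stage) and passed by reference
to the annotation and ALD stages, so grid alignment holds structurally.
Every output table carries the config hash and seed; identical configs give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import corrca, io, model, movement, preprocess, synthkit, visual

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "isc", "annotate", "ald", "model")


class ConfigError(ValueError):
    """Config validation failure (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serializable round-trip to YAML."""

    # simulation
    n_subjects: int = 8
    n_channels: int = 8
    fs: float = 200.0
    duration: float = 60.0
    n_blocks: int = 2
    clip_lengths: list[float] | None = None
    base_gain: float = 1.0
    movement_gains: dict[str, float] = field(
        default_factory=lambda: {"arm": 0.5, "leg": 0.5, "both": 1.0})
    noise_sd: float = 1.0
    fps: float = 25.0
    seed: int = 0
    groups: dict[str, str] | None = None      # subject -> group; default half/half
    # synthetic keypoints
    jitter_sd: float = 0.5
    move_amp: float = 5.0
    cut_jump: float = 200.0
    frame_height: int = 16
    frame_width: int = 16
    # preprocessing
    hp: float = 1.0
    lp: float = 50.0
    bad_k_sd: float = 4.0
    run_ica: bool = False
    outlier_k_sd: float = 3.0
    outlier_pad_ms: float = 40.0
    outlier_rule: str = "mean_abs_plus_sd"
    skip: float = 5.0
    # CorrCA / ISC
    gamma: float = 0.1
    n_components: int | None = None
    k_sum: int = 3
    window_len: float = 1.5
    hop: float = 0.3
    max_excised_frac: float = 0.5
    # annotation
    theta_low: float = 2.0
    theta_high: float = 50.0
    window_rule_fraction: float = 0.25
    # model
    df_method: str = "satterthwaite"
    posthoc_family: str = "per_panel"
    ald_zscore: bool = False

    def validate(self) -> None:
        if not (self.window_len > self.hop > 0):
            raise ConfigError("need window_len > hop > 0")
        if not (0 < self.hp < self.lp < self.fs / 2):
            raise ConfigError("need 0 < hp < lp < fs/2")
        if not (0 <= self.theta_low < self.theta_high):
            raise ConfigError("need 0 <= theta_low < theta_high")
        if self.k_sum < 1:
            raise ConfigError("k_sum must be >= 1")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ConfigError("df_method must be 'satterthwaite' or 'residual'")
        if self.outlier_rule not in preprocess.OUTLIER_RULES:
            raise ConfigError(f"unknown outlier_rule {self.outlier_rule!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        return io.config_hash(self.to_yaml())

    def synth_config(self) -> synthkit.SynthConfig:
        return synthkit.SynthConfig(
            n_subjects=self.n_subjects, n_channels=self.n_channels, fs=self.fs,
            duration=self.duration, n_blocks=self.n_blocks,
            clip_lengths=list(self.clip_lengths) if self.clip_lengths else None,
            base_gain=self.base_gain, movement_gains=dict(self.movement_gains),
            noise_sd=self.noise_sd, fps=self.fps, seed=self.seed,
        )

    def subject_groups(self, subjects: list[str]) -> dict[str, str]:
        if self.groups:
            return dict(self.groups)
        half = len(subjects) // 2
        return {s: ("children" if i < half else "adults")
                for i, s in enumerate(subjects)}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run all stages in order, writing stamped tables under ``out_dir``.

    A stage failure raises with the stage named; tables written before the
    failure are retained for inspection.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.hash(), "seed": cfg.seed}
    (out / "config.yaml").write_text(cfg.to_yaml())

    state: dict = {}
    for stage in STAGES:
        logger.info("stage: %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out, stamp, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return out


def _stage_simulate(cfg, out, stamp, state):
    scfg = cfg.synth_config()
    rec, gt = synthkit.generate_eeg(scfg)
    track, kp_gt = synthkit.generate_keypoints(
        scfg, cfg.jitter_sd, cfg.move_amp, cfg.cut_jump,
        movement_track=gt.movement_track)
    stack, ald_track = synthkit.generate_frames(
        scfg, cfg.frame_height, cfg.frame_width)
    gt.ald_track = ald_track
    io.write_recording_h5(rec, out / "eeg.h5")
    io.write_recording_matrix(rec, out / "eeg_matrix")
    io.write_keypoints_json(track, out / "keypoints.json")
    io.write_frames(stack, out / "frames.npz", cfg.fps)
    import pandas as pd

    truth = pd.DataFrame({
        "frame": np.arange(len(gt.movement_track)),
        "movement": gt.movement_track,
        "ald": np.r_[np.nan, ald_track],
    })
    io.write_table(truth, out / "ground_truth.tsv", stamp)
    io.write_table(gt.event_log, out / "event_log.tsv", stamp)
    state.update(rec=rec, gt=gt, track=track, stack=stack)


def _stage_preprocess(cfg, out, stamp, state):
    rec, report, mask = preprocess.preprocess(
        state["rec"], hp=cfg.hp, lp=cfg.lp, bad_k_sd=cfg.bad_k_sd,
        run_ica=cfg.run_ica, ica_seed=cfg.seed, outlier_k_sd=cfg.outlier_k_sd,
        outlier_pad_ms=cfg.outlier_pad_ms, outlier_rule=cfg.outlier_rule,
        skip=cfg.skip)
    io.write_recording_h5(rec, out / "eeg_preprocessed.h5")
    io.write_table(report.to_frame(), out / "preprocess_report.tsv", stamp)
    n_zeroed = sum(len(v) for v in report.zeroed_channels.values())
    logger.info("preprocess: %d channels zeroed, %d samples excised",
                n_zeroed, int(mask.sum()))
    state.update(rec=rec, report=report, mask=mask)


def _stage_isc(cfg, out, stamp, state):
    import pandas as pd

    rec, mask = state["rec"], state["mask"]
    pairs = []
    for bid, b0, b1 in rec.layout.block_spans():
        i0, i1 = int(round(b0 * rec.fs)), int(round(b1 * rec.fs))
        block_mask = np.ones(rec.n_samples, dtype=bool)
        block_mask[i0:i1] = mask[i0:i1]
        pairs.append(corrca.compute_covariances(rec, block_mask))
    cov = corrca.average_covariances(pairs)
    filters = corrca.fit_corrca(cov, gamma=cfg.gamma,
                                n_components=cfg.n_components)
    series = corrca.time_resolved_isc(
        rec, filters, cfg.window_len, cfg.hop, cfg.k_sum, mask,
        cfg.max_excised_frac)
    ch = rec.channel_labels
    wide = pd.DataFrame(filters.W, index=ch,
                        columns=[f"W{c+1}" for c in range(filters.n_components)])
    wide[[f"A{c+1}" for c in range(filters.n_components)]] = filters.A
    wide.insert(0, "channel", ch)
    io.write_table(wide, out / "spatial_filters.tsv", stamp)
    io.write_table(pd.DataFrame({"component": np.arange(1, len(filters.rho) + 1),
                                 "rho": filters.rho}),
                   out / "component_correlations.tsv", stamp)
    io.write_table(series.to_frame(), out / "isc_windows.tsv", stamp)
    io.write_table(pd.DataFrame({"subject": series.subjects,
                                 "isc_global": series.global_isc}),
                   out / "isc_global.tsv", stamp)
    logger.info("isc: %d windows retained, %d dropped",
                series.grid.n_windows, len(series.grid.dropped))
    state.update(filters=filters, isc=series, grid=series.grid)


def _stage_annotate(cfg, out, stamp, state):
    rec = state["rec"]
    frame_mask = rec.layout.onset_mask(state["track"].n_frames, cfg.fps, cfg.skip)
    moves = movement.annotate(
        state["track"], state["grid"], cfg.theta_low, cfg.theta_high,
        frame_mask, cfg.window_rule_fraction)
    io.write_table(moves.to_frame(), out / "movement_windows.tsv", stamp)
    state.update(moves=moves, frame_mask=frame_mask)


def _stage_ald(cfg, out, stamp, state):
    rec = state["rec"]
    gray = visual.to_grayscale(state["stack"], already_gray=True)
    per_frame = visual.ald_per_frame(gray, cfg.fps, rec.layout)
    ald = visual.downsample_ald(per_frame, cfg.fps, state["grid"],
                                state["frame_mask"])
    if cfg.ald_zscore:
        v = ald.per_window
        ok = ~np.isnan(v)
        if v[ok].std() > 0:
            ald.per_window = np.where(ok, (v - v[ok].mean()) / v[ok].std(), v)
    io.write_table(ald.to_frame(), out / "ald_windows.tsv", stamp)
    state.update(ald=ald)


def _stage_model(cfg, out, stamp, state):
    groups = cfg.subject_groups(state["isc"].subjects)
    design = model.build_design(state["isc"], state["moves"], state["ald"],
                                groups)
    io.write_table(design, out / "design.tsv", stamp)
    fit = model.fit_engagement_model(design, df_method=cfg.df_method)
    io.write_table(fit.effects, out / "model_effects.tsv", stamp)
    (out / "model_report.txt").write_text(fit.to_text() + "\n")
    post = model.posthoc_wilcoxon(design, family=cfg.posthoc_family)
    io.write_table(post, out / "posthoc.tsv", stamp)
    io.write_table(model.condition_means_table(design),
                   out / "condition_means.tsv", stamp)
    state.update(design=design, fit=fit, posthoc=post)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "isc": _stage_isc,
    "annotate": _stage_annotate,
    "ald": _stage_ald,
    "model": _stage_model,
}


# ---------------------------------------------------------------------------
# Format conversion

_EEG_DIALECTS = {"h5", "matrix"}
_POSE_DIALECTS = {"pose-json", "pose-json-frames"}
_FRAME_DIALECTS = {"npz", "png-dir"}


def convert_io(path: str | Path, from_dialect: str, to_dialect: str,
               out_path: str | Path) -> Path:
    """Convert between recognized dialects of the same family."""
    families = [_EEG_DIALECTS, _POSE_DIALECTS, _FRAME_DIALECTS]
    fam = next((f for f in families if from_dialect in f), None)
    if fam is None:
        raise ConfigError(f"unknown dialect {from_dialect!r}")
    if to_dialect not in fam:
        raise ConfigError(
            f"unknown or incompatible target dialect {to_dialect!r} "
            f"(source family: {sorted(fam)})")
    if fam is _EEG_DIALECTS:
        rec = (io.read_recording_h5(path) if from_dialect == "h5"
               else io.read_recording_matrix(path))
        return (io.write_recording_h5(rec, out_path) if to_dialect == "h5"
                else io.write_recording_matrix(rec, out_path))
    if fam is _POSE_DIALECTS:
        track = io.read_keypoints_json(path)
        return io.write_keypoints_json(
            track, out_path, per_frame=(to_dialect == "pose-json-frames"))
    stack, fps = io.read_frames(path)
    return io.write_frames(stack, out_path, fps)
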