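"""Reusable simulation experiments: synthetic generation through model fit.

These wrap the full analysis path at reduced scale for calibration and
recovery studies (type-I error of the movement effects, power of the
``both`` effect, mixing-vector recovery).
"""

from __future__ import annotations

import numpy as np

from . import corrca, model, movement, synthkit, visual


def default_synth_config(seed: int, movement_gains: dict[str, float],
                         n_subjects: int = 8, n_channels: int = 8,
                         fs: float = 100.0, duration: float = 60.0,
                         base_gain: float = 1.0,
                         noise_sd: float = 1.0) -> synthkit.SynthConfig:
    return synthkit.SynthConfig(
        n_subjects=n_subjects, n_channels=n_channels, fs=fs, duration=duration,
        base_gain=base_gain, movement_gains=dict(movement_gains),
        noise_sd=noise_sd, seed=seed)


def run_isc_replicate(cfg: synthkit.SynthConfig, window_len: float = 1.5,
                      hop: float = 0.3, K: int = 3, gamma: float = 0.1):
    """Generate EEG, fit CorrCA, and window the ISC.

    Returns ``(series, ground_truth, filters)``.  No preprocessing: the
    generator emits clean in-band signals, so this isolates the ISC and
    modeling stages.
    """
    rec, gt = synthkit.generate_eeg(cfg)
    cov = corrca.compute_covariances(rec)
    filters = corrca.fit_corrca(cov, gamma=gamma)
    series = corrca.time_resolved_isc(rec, filters, window_len, hop, K)
    return series, gt, filters


def movement_series_from_truth(gt: synthkit.GroundTruth,
                               grid: corrca.WindowGrid,
                               rule_fraction: float = 0.25
                               ) -> movement.MovementSeries:
    """Window categories from the generator's own per-frame labels."""
    track = gt.movement_track
    arm = np.array([c in ("arm", "both") for c in track])
    leg = np.array([c in ("leg", "both") for c in track])
    arm[0] = leg[0] = False
    return movement.window_categories(arm, leg, gt.fps, grid,
                                      rule_fraction=rule_fraction)


def fit_replicate(seed: int, movement_gains: dict[str, float],
                  df_method: str = "satterthwaite",
                  **cfg_kwargs) -> model.EngagementModelFit:
    """One full replicate: simulate, window ISC, annotate, ALD, fit."""
    cfg = default_synth_config(seed, movement_gains, **cfg_kwargs)
    series, gt, _ = run_isc_replicate(cfg)
    moves = movement_series_from_truth(gt, series.grid)
    stack, _ = synthkit.generate_frames(cfg, height=8, width=8)
    per_frame = visual.ald_per_frame(stack, cfg.fps)
    ald = visual.downsample_ald(per_frame, cfg.fps, series.grid)
    groups = {s: ("children" if i < cfg.n_subjects // 2 else "adults")
              for i, s in enumerate(series.subjects)}
    design = model.build_design(series, moves, ald, groups)
    return model.fit_engagement_model(design, df_method=df_method)
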