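"""Synthetic multi-subject EEG, keypoint tracks and frame stacks with known
ground truth.

Generative model for the EEG:

    X_k(t) = mixing * g(t) * s(t) + eps_k(t)

with ``s(t)`` a shared band-limited (1-15 Hz) latent source, ``eps_k``
independent channel noise per subject, and a time-varying gain

    g(t) = base_gain + movement_gains[category(t)]

driven by a per-frame movement category track in {neither, arm, leg, both}.
All outputs are fully reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .layout import ClipLayout
from .recording import MultiSubjectRecording, default_channel_labels

CATEGORIES = ("neither", "arm", "leg", "both")

ARM_JOINTS = ("l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_wrist", "r_wrist")
LEG_JOINTS = ("l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle")
JOINT_NAMES = ("nose",) + ARM_JOINTS + LEG_JOINTS


@dataclass
class ArtifactSpec:
    """Optional artifact injection, off by default; used by preprocessing tests."""

    blink_rate: float = 0.0          # blinks per second
    blink_amplitude: float = 20.0
    bad_channel: int | None = None   # channel index scaled by bad_channel_scale
    bad_channel_scale: float = 20.0
    spike_rate: float = 0.0          # isolated outlier samples per second per channel
    spike_amplitude: float = 50.0


@dataclass
class SynthConfig:
    n_subjects: int = 8
    n_channels: int = 8
    fs: float = 100.0
    duration: float = 60.0           # seconds per block
    n_blocks: int = 1
    clip_lengths: list[float] | None = None  # per block; must sum to duration
    mixing: np.ndarray | None = None         # channel loadings of the shared source
    base_gain: float = 1.0
    movement_gains: dict[str, float] = field(
        default_factory=lambda: {"arm": 0.5, "leg": 0.5, "both": 1.0}
    )
    noise_sd: float = 1.0
    fps: float = 25.0
    event_length_range: tuple[float, float] = (1.0, 3.0)
    event_probs: dict[str, float] = field(
        default_factory=lambda: {"neither": 0.55, "arm": 0.15, "leg": 0.15, "both": 0.15}
    )
    artifact_spec: ArtifactSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (ISC undefined otherwise)")
        if self.fs <= 0 or self.fps <= 0:
            raise ValueError("fs and fps must be positive")
        if self.base_gain < 0 or any(v < 0 for v in self.movement_gains.values()):
            raise ValueError("gains must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.clip_lengths is None:
            self.clip_lengths = [self.duration]
        if abs(sum(self.clip_lengths) - self.duration) > 1e-9:
            raise ValueError("clip_lengths must sum to duration per block")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.shape != (self.n_channels,):
                raise ValueError("mixing must have length n_channels")

    @property
    def total_duration(self) -> float:
        return self.duration * self.n_blocks

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.total_duration))

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.total_duration))

    def make_layout(self) -> ClipLayout:
        return ClipLayout.from_clip_lengths(self.clip_lengths, self.n_blocks)


@dataclass
class GroundTruth:
    """Everything the generator knows: recovery target for acceptance tests.

    All tracks share the common time base (seconds), convertible to EEG
    samples via fs and to video frames via fps.
    """

    source: np.ndarray                    # latent s(t), per EEG sample
    gain_track: np.ndarray                # g(t), per EEG sample
    movement_track: np.ndarray            # category per video frame (str)
    event_log: pd.DataFrame               # injected artifacts / movement events
    mixing: np.ndarray
    fs: float
    fps: float
    ald_track: np.ndarray | None = None   # true ALD per frame transition


def _movement_schedule(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame categories from a renewal process of labeled segments."""
    n = cfg.n_frames
    track = np.empty(n, dtype=object)
    cats = list(cfg.event_probs)
    probs = np.array([cfg.event_probs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    t = 0
    while t < n:
        length = int(round(rng.uniform(*cfg.event_length_range) * cfg.fps))
        length = max(length, 1)
        cat = rng.choice(cats, p=probs)
        track[t:t + length] = cat
        t += length
    return track.astype(str)


def _bandlimited_source(n: int, fs: float, rng: np.random.Generator,
                        band: tuple[float, float] = (1.0, 15.0)) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    x = rng.standard_normal(n)
    hi = min(band[1], 0.45 * fs)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    s = signal.sosfiltfilt(sos, x)
    sd = s.std()
    return s / sd if sd > 0 else s


def gain_from_movement(cfg: SynthConfig, movement_track: np.ndarray) -> np.ndarray:
    """Per-EEG-sample gain g(t) from the per-frame movement categories."""
    frame_of_sample = np.minimum(
        (np.arange(cfg.n_samples) / cfg.fs * cfg.fps).astype(int),
        len(movement_track) - 1,
    )
    extra = np.array(
        [cfg.movement_gains.get(c, 0.0) for c in movement_track], dtype=float
    )
    return cfg.base_gain + extra[frame_of_sample]


def generate_eeg(cfg: SynthConfig) -> tuple[MultiSubjectRecording, GroundTruth]:
    """Generate aligned multi-subject EEG sharing a gain-modulated latent source."""
    rng = np.random.default_rng(cfg.seed)
    movement_track = _movement_schedule(cfg, rng)
    source = _bandlimited_source(cfg.n_samples, cfg.fs, rng)
    gain = gain_from_movement(cfg, movement_track)

    if cfg.mixing is None:
        mixing = rng.standard_normal(cfg.n_channels)
        mixing /= np.linalg.norm(mixing)
    else:
        mixing = cfg.mixing.copy()

    shared = gain * source
    events: list[dict] = []
    data = {}
    subjects = [f"S{i:02d}" for i in range(cfg.n_subjects)]
    for k, subj in enumerate(subjects):
        noise = cfg.noise_sd * rng.standard_normal((cfg.n_channels, cfg.n_samples))
        x = np.outer(mixing, shared) + noise
        if cfg.artifact_spec is not None:
            x = _inject_artifacts(x, cfg, subj, rng, events)
        data[subj] = x

    # movement segments into the event log for downstream recovery checks
    starts = [0] + list(np.flatnonzero(movement_track[1:] != movement_track[:-1]) + 1)
    for i, s0 in enumerate(starts):
        e0 = starts[i + 1] if i + 1 < len(starts) else len(movement_track)
        events.append({
            "kind": "movement", "subject": "", "channel": -1,
            "start_frame": s0, "end_frame": e0,
            "category": movement_track[s0],
        })
    event_log = pd.DataFrame(
        events, columns=["kind", "subject", "channel", "start_frame",
                         "end_frame", "category", "sample"]
    )

    rec = MultiSubjectRecording(
        subjects=subjects,
        data=data,
        fs=cfg.fs,
        channel_labels=default_channel_labels(cfg.n_channels),
        layout=cfg.make_layout(),
    )
    gt = GroundTruth(
        source=source, gain_track=gain, movement_track=movement_track,
        event_log=event_log, mixing=mixing, fs=cfg.fs, fps=cfg.fps,
    )
    return rec, gt


def _inject_artifacts(x: np.ndarray, cfg: SynthConfig, subj: str,
                      rng: np.random.Generator, events: list[dict]) -> np.ndarray:
    spec = cfg.artifact_spec
    n_ch, n = x.shape
    if spec.blink_rate > 0:
        n_blinks = rng.poisson(spec.blink_rate * cfg.total_duration)
        width = int(round(0.3 * cfg.fs))
        kernel = np.hanning(max(width, 3))
        # frontal-weighted: exponential falloff from channel 0
        weights = np.exp(-np.arange(n_ch) / 2.0)
        for _ in range(n_blinks):
            t0 = rng.integers(0, max(n - width, 1))
            x[:, t0:t0 + width] += (
                spec.blink_amplitude * np.outer(weights, kernel[: n - t0])
            )
            events.append({"kind": "blink", "subject": subj, "channel": -1,
                           "sample": int(t0)})
    if spec.bad_channel is not None:
        x[spec.bad_channel] *= spec.bad_channel_scale
        events.append({"kind": "bad_channel", "subject": subj,
                       "channel": int(spec.bad_channel)})
    if spec.spike_rate > 0:
        for ch in range(n_ch):
            n_spikes = rng.poisson(spec.spike_rate * cfg.total_duration)
            ts = rng.integers(0, n, size=n_spikes)
            for t0 in ts:
                x[ch, t0] += spec.spike_amplitude * rng.choice([-1.0, 1.0])
                events.append({"kind": "spike", "subject": subj,
                               "channel": int(ch), "sample": int(t0)})
    return x


# ---------------------------------------------------------------------------
# Keypoints


def generate_keypoints(
    cfg: SynthConfig,
    jitter_sd: float = 0.5,
    move_amp: float = 5.0,
    cut_jump: float = 200.0,
    movement_track: np.ndarray | None = None,
):
    """Single-person keypoint track with jitter, genuine limb movements and
    scene cuts at clip boundaries.

    Returns ``(KeypointTrack, GroundTruth)`` where the ground truth carries
    the per-frame category labels and the scene-cut frames in the event log.
    """
    from .movement import KeypointTrack

    if jitter_sd < 0 or move_amp < 0 or cut_jump < 0:
        raise ValueError("amplitudes must be >= 0")
    rng = np.random.default_rng(cfg.seed + 1)
    if movement_track is None:
        movement_track = _movement_schedule(cfg, rng)
    n_frames = len(movement_track)

    base = {j: np.array([100.0 + 30.0 * i, 100.0 + 10.0 * i])
            for i, j in enumerate(JOINT_NAMES)}
    pos = {j: np.tile(base[j], (n_frames, 1)) for j in JOINT_NAMES}

    # genuine movements: displace the limb's joints by move_amp each frame,
    # alternating direction so coordinates stay bounded
    for t in range(1, n_frames):
        cat = movement_track[t]
        moving: tuple[str, ...] = ()
        if cat in ("arm", "both"):
            moving += ARM_JOINTS
        if cat in ("leg", "both"):
            moving += LEG_JOINTS
        for j in moving:
            direction = 1.0 if (t // 2) % 2 == 0 else -1.0
            step = direction * move_amp / np.sqrt(2.0)
            pos[j][t:] += np.array([step, step])

    # scene cuts at interior clip boundaries: jump every joint
    layout = cfg.make_layout()
    cut_frames = []
    clip_starts = sorted({s for _, s, _ in layout.clips})
    for s in clip_starts:
        f = int(round(s * cfg.fps))
        if 0 < f < n_frames:
            cut_frames.append(f)
            for j in JOINT_NAMES:
                pos[j][f:] += np.array([cut_jump / np.sqrt(2.0)] * 2)

    jitter = {j: rng.normal(0.0, jitter_sd, size=(n_frames, 2)) for j in JOINT_NAMES}
    frames = []
    for t in range(n_frames):
        person = {
            j: (pos[j][t, 0] + jitter[j][t, 0], pos[j][t, 1] + jitter[j][t, 1], 1.0)
            for j in JOINT_NAMES
        }
        frames.append([person])
    track = KeypointTrack(fps=cfg.fps, frames=frames, joint_names=list(JOINT_NAMES))

    events = [{"kind": "scene_cut", "subject": "", "channel": -1,
               "start_frame": f, "end_frame": f, "category": ""}
              for f in cut_frames]
    starts = [0] + list(np.flatnonzero(movement_track[1:] != movement_track[:-1]) + 1)
    for i, s0 in enumerate(starts):
        e0 = starts[i + 1] if i + 1 < len(starts) else n_frames
        events.append({"kind": "movement", "subject": "", "channel": -1,
                       "start_frame": s0, "end_frame": e0,
                       "category": movement_track[s0]})
    gt = GroundTruth(
        source=np.zeros(0), gain_track=np.zeros(0),
        movement_track=np.asarray(movement_track, dtype=str),
        event_log=pd.DataFrame(events), mixing=np.zeros(0),
        fs=cfg.fs, fps=cfg.fps,
    )
    return track, gt


# ---------------------------------------------------------------------------
# Frames


def generate_frames(
    cfg: SynthConfig, height: int = 16, width: int = 16, rgb: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Grayscale (or RGB) frame stack with its true per-transition ALD.

    Luminance follows a slow random walk with occasional large jumps so the
    ALD track has structure; the returned ``ald_track`` has length
    ``n_frames - 1`` and is the exact mean squared grayscale difference.
    """
    if height < 1 or width < 1:
        raise ValueError("frame dimensions must be >= 1x1")
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_frames
    stack = np.empty((n, height, width))
    frame = rng.uniform(0, 255, size=(height, width))
    stack[0] = frame
    for t in range(1, n):
        step = rng.normal(0, 2.0, size=(height, width))
        if rng.random() < 0.05:  # occasional large jump
            step += rng.normal(0, 30.0, size=(height, width))
        frame = np.clip(frame + step, 0, 255)
        stack[t] = frame
    ald_track = ((np.diff(stack, axis=0)) ** 2).mean(axis=(1, 2))
    if rgb:
        stack = np.repeat(stack[..., None], 3, axis=-1)
    return stack, ald_track
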