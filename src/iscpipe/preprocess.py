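"""EEG preprocessing chain.

Stages, applied in this order: zero-phase band-pass filter, bad-channel
zeroing, ICA eye-artifact removal, outlier zeroing (with a +/- pad), channel
z-scoring, and clip-onset excision.  Excision is a boolean *mask* carried
alongside the data, never a deletion, so every downstream stage shares one
time base.  Every stage preserves the (channels, samples) shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import MultiSubjectRecording

logger = logging.getLogger(__name__)

OUTLIER_RULES = ("mean_abs_plus_sd", "sd_of_abs", "sd_raw")


@dataclass
class PreprocessReport:
    """Audit trail of what each stage removed."""

    zeroed_channels: dict[str, list[int]] = field(default_factory=dict)
    zeroed_sample_fraction: dict[str, np.ndarray] = field(default_factory=dict)
    removed_ica_components: dict[str, list[int]] = field(default_factory=dict)
    ica_converged: dict[str, bool] = field(default_factory=dict)
    excised_mask: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        rows = []
        subjects = (set(self.zeroed_channels) | set(self.zeroed_sample_fraction)
                    | set(self.removed_ica_components))
        for s in sorted(subjects):
            rows.append({
                "subject": s,
                "zeroed_channels": ",".join(map(str, self.zeroed_channels.get(s, []))),
                "removed_ica_components": ",".join(
                    map(str, self.removed_ica_components.get(s, []))),
                "ica_converged": self.ica_converged.get(s, True),
                "mean_zeroed_fraction": float(
                    np.mean(self.zeroed_sample_fraction.get(s, np.zeros(1)))),
            })
        return pd.DataFrame(rows)


def bandpass(rec: MultiSubjectRecording, hp: float = 1.0, lp: float = 50.0,
             order: int = 4) -> MultiSubjectRecording:
    """Zero-phase forward-backward Butterworth band-pass (separate HP and LP)."""
    if not (0 < hp < lp < rec.fs / 2):
        raise ValueError(f"need 0 < hp < lp < fs/2; got hp={hp}, lp={lp}, fs={rec.fs}")
    sos_hp = signal.butter(order, hp, btype="highpass", fs=rec.fs, output="sos")
    sos_lp = signal.butter(order, lp, btype="lowpass", fs=rec.fs, output="sos")
    x = rec.stack()
    x = signal.sosfiltfilt(sos_hp, x, axis=-1)
    x = signal.sosfiltfilt(sos_lp, x, axis=-1)
    return rec.with_data(x)


def bandpass_gain(fs: float, hp: float, lp: float, freq: float,
                  order: int = 4) -> float:
    """Analytic passband gain of the zero-phase cascade at ``freq`` Hz."""
    w = 2 * np.pi * freq / fs
    g = 1.0
    for sos, _ in ((signal.butter(order, hp, btype="highpass", fs=fs,
                                  output="sos"), "hp"),
                   (signal.butter(order, lp, btype="lowpass", fs=fs,
                                  output="sos"), "lp")):
        _, h = signal.sosfreqz(sos, worN=[w])
        g *= abs(h[0]) ** 2  # forward-backward doubles the magnitude response
    return float(g)


def zero_bad_channels(
    rec: MultiSubjectRecording, k_sd: float = 4.0,
    report: PreprocessReport | None = None,
) -> tuple[MultiSubjectRecording, PreprocessReport]:
    """Zero channels whose average power exceeds the across-channel mean
    power by ``k_sd`` standard deviations.  Single pass, per subject.
    """
    if rec.n_channels < 2:
        raise ValueError("need >= 2 channels")
    report = report or PreprocessReport()
    x = rec.stack()
    for i, subj in enumerate(rec.subjects):
        power = (x[i] ** 2).mean(axis=1)
        sd = power.std()
        if sd == 0:
            flagged = np.zeros(rec.n_channels, dtype=bool)
        else:
            flagged = power > power.mean() + k_sd * sd
        idx = np.flatnonzero(flagged)
        x[i, idx, :] = 0.0
        report.zeroed_channels[subj] = idx.tolist()
        if len(idx):
            logger.info("subject %s: zeroed channels %s", subj, idx.tolist())
    return rec.with_data(x), report


def _eog_surrogate(x: np.ndarray, labels: list[str]) -> np.ndarray:
    """Frontal-channel average used to identify ocular ICA components."""
    frontal = [i for i, lab in enumerate(labels) if lab.upper().startswith("FP")]
    if not frontal:
        frontal = [0]
    return x[frontal].mean(axis=0)


def remove_eye_artifacts(
    rec: MultiSubjectRecording,
    n_components: int | None = None,
    corr_threshold: float = 0.7,
    manual_components: dict[str, list[int]] | None = None,
    seed: int = 0,
    max_iter: int = 500,
    report: PreprocessReport | None = None,
) -> tuple[MultiSubjectRecording, PreprocessReport]:
    """Remove ocular components per subject with FastICA.

    Components whose source time-course correlates with a frontal EOG
    surrogate above ``corr_threshold`` (absolute value) are subtracted.
    ``manual_components`` overrides the automatic selection per subject; an
    empty list means identity.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning
    import warnings

    report = report or PreprocessReport()
    x = rec.stack()
    for i, subj in enumerate(rec.subjects):
        manual = None if manual_components is None else manual_components.get(subj)
        if manual is not None and len(manual) == 0:
            report.removed_ica_components[subj] = []
            report.ica_converged[subj] = True
            continue
        active = np.flatnonzero(x[i].std(axis=1) > 0)
        n_comp = n_components or len(active)
        n_comp = min(n_comp, len(active))
        if n_comp == 0:
            report.removed_ica_components[subj] = []
            report.ica_converged[subj] = True
            continue
        ica = FastICA(n_components=n_comp, random_state=seed, max_iter=max_iter,
                      whiten="unit-variance")
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            sources = ica.fit_transform(x[i, active].T)  # (samples, comps)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged = False
                logger.warning(
                    "subject %s: FastICA did not converge (seed=%d, max_iter=%d)",
                    subj, seed, max_iter,
                )
        if manual is not None:
            remove = list(manual)
        else:
            eog = _eog_surrogate(x[i], rec.channel_labels)
            remove = []
            if eog.std() > 0:
                for c in range(n_comp):
                    sc = sources[:, c]
                    if sc.std() == 0:
                        continue
                    r = np.corrcoef(sc, eog)[0, 1]
                    if abs(r) > corr_threshold:
                        remove.append(c)
        if remove:
            cleaned_sources = sources.copy()
            cleaned_sources[:, remove] = 0.0
            recon = ica.inverse_transform(cleaned_sources).T
            x[i, active] = recon
        report.removed_ica_components[subj] = remove
        report.ica_converged[subj] = converged
    return rec.with_data(x), report


def zero_outliers(
    rec: MultiSubjectRecording, k_sd: float = 3.0, pad_ms: float = 40.0,
    rule: str = "mean_abs_plus_sd", report: PreprocessReport | None = None,
) -> tuple[MultiSubjectRecording, PreprocessReport]:
    """Zero outlier samples and everything within ``pad_ms`` on each side.

    The flagging statistics are computed per channel before any zeroing.
    ``rule`` selects the threshold form:

    * ``mean_abs_plus_sd`` (default): |x| > mean(|x|) + k*SD(|x|)
    * ``sd_of_abs``:                  |x| > k*SD(|x|)
    * ``sd_raw``:                     |x| > k*SD(x)
    """
    if pad_ms < 0:
        raise ValueError("pad must be >= 0")
    if rule not in OUTLIER_RULES:
        raise ValueError(f"unknown outlier rule {rule!r}; choose from {OUTLIER_RULES}")
    report = report or PreprocessReport()
    pad = int(round(pad_ms / 1000.0 * rec.fs))
    x = rec.stack()
    n = rec.n_samples
    for i, subj in enumerate(rec.subjects):
        mags = np.abs(x[i])
        if rule == "mean_abs_plus_sd":
            thresh = mags.mean(axis=1) + k_sd * mags.std(axis=1)
        elif rule == "sd_of_abs":
            thresh = k_sd * mags.std(axis=1)
        else:
            thresh = k_sd * x[i].std(axis=1)
        flagged = mags > thresh[:, None]
        zero_mask = np.zeros_like(flagged)
        for ch in range(rec.n_channels):
            idx = np.flatnonzero(flagged[ch])
            for t in idx:
                zero_mask[ch, max(t - pad, 0):min(t + pad + 1, n)] = True
        x[i][zero_mask] = 0.0
        report.zeroed_sample_fraction[subj] = zero_mask.mean(axis=1)
    return rec.with_data(x), report


def zscore(rec: MultiSubjectRecording,
           mask: np.ndarray | None = None) -> MultiSubjectRecording:
    """Z-score each channel of each subject.

    Statistics use only non-excised samples when ``mask`` (True = excised)
    is given; the transform is applied to all samples.  All-zero / zero-SD
    channels are left untouched.
    """
    x = rec.stack()
    keep = slice(None) if mask is None else ~np.asarray(mask, dtype=bool)
    for i in range(rec.n_subjects):
        sub = x[i][:, keep]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        x[i][ok] = (x[i][ok] - mu[ok]) / sd[ok]
    return rec.with_data(x)


def excise_onsets(rec: MultiSubjectRecording,
                  skip: float = 5.0) -> tuple[MultiSubjectRecording, np.ndarray]:
    """Mask (True = excised) covering the first ``skip`` seconds of each clip.

    The data are returned unchanged; excision is applied by the mask in all
    downstream windowing, annotation and covariate computations.
    """
    mask = rec.layout.onset_mask(rec.n_samples, rec.fs, skip)
    return rec, mask


def preprocess(
    rec: MultiSubjectRecording,
    hp: float = 1.0, lp: float = 50.0,
    bad_k_sd: float = 4.0,
    run_ica: bool = True,
    ica_seed: int = 0,
    outlier_k_sd: float = 3.0,
    outlier_pad_ms: float = 40.0,
    outlier_rule: str = "mean_abs_plus_sd",
    skip: float = 5.0,
) -> tuple[MultiSubjectRecording, PreprocessReport, np.ndarray]:
    """Run the full chain in order; returns (recording, report, excision mask)."""
    report = PreprocessReport()
    rec = bandpass(rec, hp, lp)
    rec, report = zero_bad_channels(rec, bad_k_sd, report)
    if run_ica:
        rec, report = remove_eye_artifacts(rec, seed=ica_seed, report=report)
    rec, report = zero_outliers(rec, outlier_k_sd, outlier_pad_ms, outlier_rule,
                                report)
    rec, mask = excise_onsets(rec, skip)
    rec = zscore(rec, mask)
    report.excised_mask = mask
    return rec, report, mask
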