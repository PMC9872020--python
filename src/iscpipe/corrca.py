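"""Correlated component analysis (CorrCA) and intersubject correlation.

CorrCA finds channel-weight vectors ``w`` maximizing the ratio of
between-subject to within-subject covariance, ``(w' Rb w) / (w' Rw w)``,
via the generalized eigenproblem

    Rb w = rho * [(1 - gamma) Rw + gamma * (tr(Rw)/D) I] w

with optional shrinkage ``gamma`` guarding against rank deficiency (e.g.
after bad-channel zeroing).  Subject-level ISC is leave-one-out: for each
subject, the Pearson correlation between their projected time-course and
the mean projected time-course of everyone else, summed over the top-K
components.  Time-resolved ISC repeats this on sliding windows using the
*global* projection vectors, never refitting per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .recording import MultiSubjectRecording

logger = logging.getLogger(__name__)


@dataclass
class CovariancePair:
    """Pooled within- and between-subject channel covariance."""

    Rw: np.ndarray
    Rb: np.ndarray
    n_subjects: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.Rw.shape != self.Rb.shape or self.Rw.shape[0] != self.Rw.shape[1]:
            raise ValueError("Rw and Rb must be square and of equal shape")


@dataclass
class SpatialFilterSet:
    """Projection vectors W, forward model A and component correlations."""

    W: np.ndarray       # (channels, components)
    A: np.ndarray       # (channels, components)
    rho: np.ndarray     # descending
    gamma: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.rho) > 1e-12):
            raise ValueError("rho must be in descending order")

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


@dataclass
class WindowGrid:
    """Sliding-window grid shared by ISC, movement and ALD series.

    ``starts`` are the retained window start times in seconds; ``dropped``
    records starts excluded for excessive excision overlap.
    """

    starts: np.ndarray
    window_len: float
    hop: float
    blocks: np.ndarray          # block id per retained window
    dropped: np.ndarray         # start times of dropped windows

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def samples_per_window(self, fs: float) -> int:
        """Discrete sample count per window at sampling rate ``fs``."""
        return int(round(self.window_len * fs))

    @property
    def overlap_fraction(self) -> float:
        """Fraction of each window shared with the next."""
        return (self.window_len - self.hop) / self.window_len


@dataclass
class ISCSeries:
    """Global and windowed per-subject ISC (sum of top-K components)."""

    subjects: list[str]
    global_isc: np.ndarray          # (subjects,)
    windows: np.ndarray             # (subjects, n_windows)
    grid: WindowGrid
    K: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, s in enumerate(self.subjects):
            for j, t0 in enumerate(self.grid.starts):
                rows.append({"subject": s, "window_start": t0,
                             "block": self.grid.blocks[j],
                             "isc": self.windows[i, j]})
        return pd.DataFrame(rows)


def compute_covariances(rec: MultiSubjectRecording,
                        mask: np.ndarray | None = None) -> CovariancePair:
    """Pooled covariance pair over unmasked samples.

    With per-subject centered data ``X_k``: ``R_kl = X_k X_l' / (n-1)``,
    ``Rw = mean_k R_kk`` and ``Rb = mean_{k != l} R_kl``.
    """
    if rec.n_subjects < 2:
        raise ValueError("ISC requires >= 2 subjects")
    x = rec.stack()
    if mask is not None:
        x = x[:, :, ~np.asarray(mask, dtype=bool)]
    n = x.shape[2]
    if n < 2:
        raise ValueError("need >= 2 unmasked samples")
    x = x - x.mean(axis=2, keepdims=True)
    N = rec.n_subjects
    # R[k, l] = X_k X_l' / (n - 1), all pairs in one einsum
    R = np.einsum("kct,ldt->klcd", x, x) / (n - 1)
    Rw = R[np.arange(N), np.arange(N)].mean(axis=0)
    total = R.sum(axis=(0, 1))
    Rb = (total - R[np.arange(N), np.arange(N)].sum(axis=0)) / (N * (N - 1))
    Rw = (Rw + Rw.T) / 2
    Rb = (Rb + Rb.T) / 2
    return CovariancePair(Rw=Rw, Rb=Rb, n_subjects=N, n_samples=n)


def average_covariances(pairs: list[CovariancePair]) -> CovariancePair:
    """Element-wise mean across stimuli, equal weights."""
    if not pairs:
        raise ValueError("no covariance pairs")
    dims = {p.Rw.shape for p in pairs}
    if len(dims) != 1:
        raise ValueError(f"mixed channel dimensions: {dims}")
    Rw = np.mean([p.Rw for p in pairs], axis=0)
    Rb = np.mean([p.Rb for p in pairs], axis=0)
    return CovariancePair(Rw=Rw, Rb=Rb,
                          n_subjects=pairs[0].n_subjects,
                          n_samples=sum(p.n_samples for p in pairs))


def fit_corrca(cov: CovariancePair, gamma: float = 0.1,
               n_components: int | None = None) -> SpatialFilterSet:
    """Solve the regularized generalized eigenproblem.

    ``rho`` is reported as the raw ratio ``(w' Rb w)/(w' Rw w)`` with the
    *unregularized* Rw; the forward model is ``A = Rw W (W' Rw W)^-1`` with
    a sign convention making the largest-|entry| of each column positive.
    """
    if not (0 <= gamma <= 1):
        raise ValueError("gamma must be in [0, 1]")
    D = cov.Rw.shape[0]
    Rw_reg = (1 - gamma) * cov.Rw + gamma * (np.trace(cov.Rw) / D) * np.eye(D)
    try:
        evals, evecs = linalg.eigh(cov.Rb, Rw_reg)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            f"regularized Rw is not positive definite ({exc}); raise gamma"
        ) from exc
    order = np.argsort(evals)[::-1]
    W = evecs[:, order]
    if n_components is not None:
        W = W[:, :n_components]
    # raw correlation ratio with the unregularized Rw
    num = np.einsum("ck,cd,dk->k", W, cov.Rb, W)
    den = np.einsum("ck,cd,dk->k", W, cov.Rw, W)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    rho = np.clip(rho, -1.0, 1.0)  # numerical noise in null directions
    # forward model; pinv covers rank-deficient Rw (e.g. noise-free toys)
    WRW = W.T @ cov.Rw @ W
    A = cov.Rw @ W @ linalg.pinv(WRW)
    # sign convention: largest-|entry| of each A column positive
    for c in range(A.shape[1]):
        j = np.argmax(np.abs(A[:, c]))
        if A[j, c] < 0:
            A[:, c] *= -1
            W[:, c] *= -1
    # enforce descending rho (ties in eigenvalues can reorder the raw ratio)
    order2 = np.argsort(rho)[::-1]
    return SpatialFilterSet(W=W[:, order2], A=A[:, order2], rho=rho[order2],
                            gamma=gamma)


def brute_force_corrca_2ch(cov: CovariancePair,
                           n_grid: int = 1_000_000) -> tuple[float, np.ndarray]:
    """Independent oracle for 2-channel problems: maximize the correlation
    ratio over ``n_grid`` unit vectors on the half-circle.
    """
    theta = np.linspace(0, np.pi, n_grid, endpoint=False)
    W = np.vstack([np.cos(theta), np.sin(theta)])  # (2, n_grid)
    num = np.einsum("ck,cd,dk->k", W, cov.Rb, W)
    den = np.einsum("ck,cd,dk->k", W, cov.Rw, W)
    ratio = np.where(den > 0, num / den, -np.inf)
    j = int(np.argmax(ratio))
    return float(ratio[j]), W[:, j]


def _project(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(subjects, channels, samples) -> (subjects, components, samples)."""
    return np.einsum("cK,kct->kKt", W, x)


def _loo_correlations(y: np.ndarray) -> np.ndarray:
    """Per-subject, per-component Pearson r against the mean of the others.

    ``y`` is (subjects, components, samples), already mean-removed or not;
    means are removed here.  Zero-variance series contribute r = 0.
    """
    N, K, n = y.shape
    y = y - y.mean(axis=2, keepdims=True)
    total = y.sum(axis=0)  # (K, samples)
    r = np.zeros((N, K))
    for k in range(N):
        others = (total - y[k]) / (N - 1)
        others = others - others.mean(axis=1, keepdims=True)
        for c in range(K):
            a, b = y[k, c], others[c]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                logger.debug("zero-variance projected series (subj %d comp %d)",
                             k, c)
                continue
            r[k, c] = float(np.dot(a, b) / (n * sa * sb))
    return r


def loo_isc(rec: MultiSubjectRecording, filters: SpatialFilterSet, K: int = 3,
            mask: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out per-subject ISC: sum of the top-K component correlations."""
    if K < 1 or K > filters.n_components:
        raise ValueError(f"K={K} outside available components")
    x = rec.stack()
    if mask is not None:
        x = x[:, :, ~np.asarray(mask, dtype=bool)]
    y = _project(x, filters.W[:, :K])
    return _loo_correlations(y).sum(axis=1)


def make_window_grid(rec: MultiSubjectRecording, window_len: float = 1.5,
                     hop: float = 0.3, mask: np.ndarray | None = None,
                     max_excised_frac: float = 0.5) -> WindowGrid:
    """Sliding-window grid per block; windows never span block boundaries.

    Windows whose excised-sample fraction exceeds ``max_excised_frac`` are
    dropped and recorded.
    """
    if not (window_len > hop > 0):
        raise ValueError("need window_len > hop > 0")
    fs = rec.fs
    wlen = int(round(window_len * fs))
    if wlen > rec.n_samples:
        raise ValueError("window longer than recording")
    mask = (np.zeros(rec.n_samples, dtype=bool) if mask is None
            else np.asarray(mask, dtype=bool))
    starts, blocks, dropped = [], [], []
    for bid, b0, b1 in rec.layout.block_spans():
        t = b0
        while t + window_len <= b1 + 1e-9:
            i0 = int(round(t * fs))
            i1 = min(i0 + wlen, rec.n_samples)
            frac = mask[i0:i1].mean() if i1 > i0 else 1.0
            if frac > max_excised_frac:
                dropped.append(t)
            else:
                starts.append(t)
                blocks.append(bid)
            t = round(t + hop, 9)
    return WindowGrid(starts=np.array(starts), window_len=window_len, hop=hop,
                      blocks=np.array(blocks, dtype=object),
                      dropped=np.array(dropped))


def time_resolved_isc(rec: MultiSubjectRecording, filters: SpatialFilterSet,
                      window_len: float = 1.5, hop: float = 0.3, K: int = 3,
                      mask: np.ndarray | None = None,
                      max_excised_frac: float = 0.5,
                      grid: WindowGrid | None = None) -> ISCSeries:
    """Leave-one-out ISC per sliding window, projecting with the global W.

    Per-window means are re-removed inside each window; masked samples are
    excluded from the correlations.
    """
    if K < 1 or K > filters.n_components:
        raise ValueError(f"K={K} outside available components")
    if grid is None:
        grid = make_window_grid(rec, window_len, hop, mask, max_excised_frac)
    fs = rec.fs
    wlen = grid.samples_per_window(fs)
    x = rec.stack()
    y = _project(x, filters.W[:, :K])  # (subjects, K, samples)
    m = (np.zeros(rec.n_samples, dtype=bool) if mask is None
         else np.asarray(mask, dtype=bool))
    windows = np.zeros((rec.n_subjects, grid.n_windows))
    for j, t0 in enumerate(grid.starts):
        i0 = int(round(t0 * fs))
        i1 = min(i0 + wlen, rec.n_samples)
        keep = ~m[i0:i1]
        seg = y[:, :, i0:i1][:, :, keep]
        if seg.shape[2] < 2:
            continue
        windows[:, j] = _loo_correlations(seg).sum(axis=1)
    global_isc = loo_isc(rec, filters, K, mask)
    return ISCSeries(subjects=list(rec.subjects), global_isc=global_isc,
                     windows=windows, grid=grid, K=K)
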