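"""Denoising: discrete-cosine high-pass, confound regression, censoring, QC-FC.

The high-pass is realized as regression on a discrete cosine basis (the
standard 128-s cutoff used for task analyses) rather than an IIR filter:
it is exactly linear, idempotent, and commutes with the other projections.
Frames whose framewise displacement exceeds the threshold (default
0.40 mm, strict inequality) are not deleted but flagged; downstream they
enter the weighted correlation with zero weight so the weight algebra
stays aligned with the task design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import canonical_hrf
from .design import TaskDesign
from .exceptions import InvalidArgumentError

__all__ = [
    "CensorMask",
    "CleanSeries",
    "highpass_filter",
    "regress_confounds",
    "censor_frames",
    "qcfc_diagnostic",
    "session_task_regressors",
    "preprocess_subject",
]

DEFAULT_FD_THRESHOLD_MM = 0.40
DEFAULT_HIGHPASS_HZ = 1.0 / 128.0


@dataclass
class CensorMask:
    """Per-frame keep flags from the framewise-displacement rule."""

    keep: np.ndarray
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())


@dataclass
class CleanSeries:
    """Filtered, confound-regressed node time series plus its censor mask."""

    timeseries: np.ndarray
    mask: CensorMask
    filter_cutoff_hz: float = DEFAULT_HIGHPASS_HZ
    node_labels: list[str] = field(default_factory=list)


def _dct_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II columns with frequency below cutoff (excluding the constant)."""
    order = int(np.floor(2.0 * n * tr * cutoff_hz))
    t = np.arange(n)
    cols = [np.cos(np.pi * (t + 0.5) * k / n) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def highpass_filter(series: np.ndarray, tr: float, cutoff_hz: float = DEFAULT_HIGHPASS_HZ) -> np.ndarray:
    """Remove the mean and all discrete-cosine components below ``cutoff_hz``.

    Operates column-wise on a (frames x nodes) array; a constant column
    maps to (numerically) zero.
    """
    series = np.asarray(series, dtype=float)
    was_1d = series.ndim == 1
    if was_1d:
        series = series[:, None]
    if series.ndim != 2:
        raise InvalidArgumentError(f"series must be 1-D or 2-D, got {series.shape}")
    n = series.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least 2 frames to filter")
    if cutoff_hz <= 0:
        raise InvalidArgumentError(f"cutoff must be > 0, got {cutoff_hz}")
    nyquist = 0.5 / tr
    if cutoff_hz >= nyquist:
        raise InvalidArgumentError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist {nyquist} Hz"
        )
    out = series - series.mean(axis=0, keepdims=True)
    basis = _dct_basis(n, tr, cutoff_hz)
    if basis.shape[1]:
        coef, *_ = np.linalg.lstsq(basis, out, rcond=None)
        out = out - basis @ coef
    return out[:, 0] if was_1d else out


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Project out confound columns (an intercept is always included).

    Residuals are orthogonal to every confound column and have zero mean.
    Rank-deficient confound matrices are rejected with the collinear
    columns named.
    """
    series = np.asarray(series, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    if confounds.ndim == 1:
        confounds = confounds[:, None]
    if series.shape[0] != confounds.shape[0]:
        raise InvalidArgumentError(
            f"frame mismatch: series has {series.shape[0]}, confounds "
            f"{confounds.shape[0]}"
        )
    X = np.column_stack([np.ones(series.shape[0]), confounds])
    # detect collinearity via the QR diagonal
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 1.0
    bad = np.flatnonzero(diag < 1e-10 * scale)
    if bad.size:
        cols = [int(b - 1) for b in bad]  # report in caller's column indexing
        raise InvalidArgumentError(
            f"confound matrix is rank-deficient; collinear columns "
            f"(0-based, -1 = intercept): {cols}"
        )
    coef, *_ = np.linalg.lstsq(X, series, rcond=None)
    return series - X @ coef


def censor_frames(fd_trace: np.ndarray, threshold_mm: float = DEFAULT_FD_THRESHOLD_MM) -> CensorMask:
    """Flag frames with framewise displacement strictly greater than threshold."""
    fd = np.asarray(fd_trace, dtype=float)
    if np.any(fd < 0):
        raise InvalidArgumentError("framewise displacement must be nonnegative")
    return CensorMask(keep=fd <= threshold_mm, threshold_mm=threshold_mm)


def qcfc_diagnostic(
    fc: np.ndarray, mean_fd: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Across-subject correlation between each edge's FC and mean motion.

    ``fc`` is (n_subjects x n_edges); ``mean_fd`` is per-subject mean
    framewise displacement.  Edges with zero across-subject variance are
    reported as NaN with a warning.  Returns the per-edge correlation
    vector and a summary with the median absolute QC-FC association.
    """
    fc = np.asarray(fc, dtype=float)
    mean_fd = np.asarray(mean_fd, dtype=float)
    if fc.ndim != 2:
        raise InvalidArgumentError(f"fc must be 2-D, got shape {fc.shape}")
    n_subj = fc.shape[0]
    if n_subj < 3 or mean_fd.shape[0] != n_subj:
        raise InvalidArgumentError(
            f"QC-FC needs >= 3 subjects with matching motion summaries "
            f"(got {n_subj} subjects, {mean_fd.shape[0]} summaries)"
        )
    fd_c = mean_fd - mean_fd.mean()
    fd_ss = (fd_c**2).sum()
    if fd_ss <= 0:
        raise InvalidArgumentError("mean FD is constant across subjects")
    fc_c = fc - fc.mean(axis=0, keepdims=True)
    fc_ss = (fc_c**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (fc_c * fd_c[:, None]).sum(axis=0) / np.sqrt(fc_ss * fd_ss)
    zero_var = fc_ss <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} edges have zero across-subject FC "
            "variance; their QC-FC correlation is undefined (NaN)",
            stacklevel=2,
        )
        r = np.where(zero_var, np.nan, r)
    summary = {
        "median_abs_qcfc": float(np.nanmedian(np.abs(r))),
        "n_edges": int(fc.shape[1]),
        "n_undefined": int(zero_var.sum()),
        "n_subjects": int(n_subj),
    }
    return r, summary


def session_task_regressors(
    design: TaskDesign, include_task: bool = True
) -> np.ndarray:
    """Per-run intercept columns plus HRF-convolved condition regressors.

    Models constant session offsets and mean task-evoked responses as
    nuisance components; the first run intercept is omitted (absorbed by
    the global intercept of the regression).
    """
    T = design.total_frames
    cols = []
    nf = design.n_frames
    for r in range(1, design.n_runs):
        col = np.zeros(T)
        col[r * nf:(r + 1) * nf] = 1.0
        cols.append(col)
    if include_task:
        from .connectivity import _boxcar  # unrectified task response shape

        hrf = canonical_hrf(design.tr)
        for cond in design.conditions:
            occ = _boxcar(design, cond)
            w = np.empty(T)
            for r in range(design.n_runs):
                seg = occ[r * nf:(r + 1) * nf]
                w[r * nf:(r + 1) * nf] = np.convolve(seg, hrf)[:nf]
            cols.append(w)
    return np.column_stack(cols) if cols else np.empty((T, 0))


def preprocess_subject(
    sample,
    cutoff_hz: float = DEFAULT_HIGHPASS_HZ,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    model_session_task: bool = True,
) -> CleanSeries:
    """Full per-subject denoising: per-run high-pass + confound regression.

    ``sample`` provides ``timeseries``, ``confounds``, ``fd_trace`` and
    ``design`` (a synthetic_data SubjectSample or any duck-typed record).
    Filtering and regression run within each run separately; the censor
    mask is attached for zero-weight propagation, leaving kept-frame
    values untouched by censoring itself.
    """
    design: TaskDesign = sample.design
    series = np.asarray(sample.timeseries, dtype=float)
    confounds = np.asarray(sample.confounds, dtype=float)
    extra = session_task_regressors(design) if model_session_task else None

    nf = design.n_frames
    out = np.empty_like(series)
    for r in range(design.n_runs):
        sl = slice(r * nf, (r + 1) * nf)
        seg = highpass_filter(series[sl], design.tr, cutoff_hz)
        conf = confounds[sl]
        if extra is not None and extra.shape[1]:
            conf = np.column_stack([conf, extra[sl]])
        # within-run, drop any confound columns that the high-pass/intercept
        # already annihilates (e.g. the run-intercept column of this run)
        keepcols = conf.std(axis=0) > 1e-12
        conf = conf[:, keepcols]
        conf = highpass_filter(conf, design.tr, cutoff_hz) if conf.shape[1] else conf
        out[sl] = regress_confounds(seg, conf) if conf.shape[1] else seg
    mask = censor_frames(sample.fd_trace, fd_threshold_mm)
    labels = getattr(sample, "node_labels", None) or [
        f"node{i:02d}" for i in range(series.shape[1])
    ]
    return CleanSeries(timeseries=out, mask=mask, filter_cutoff_hz=cutoff_hz,
                       node_labels=list(labels))
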