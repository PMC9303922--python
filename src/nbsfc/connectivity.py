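"""First-level estimation: condition weights and weighted ROI-to-ROI correlation.

Condition-specific functional connectivity is computed as a weighted
Pearson correlation between every pair of node time series, with per-frame
temporal weights given by the condition's boxcar convolved with a canonical
double-gamma haemodynamic response function (negative lobe rectified to
zero, censored frames zero-weighted).  Correlations are Fisher-transformed
(arctanh) into one symmetric 30 x 30 matrix per subject per condition; the
diagonal is undefined and stored as NaN.

Weights are deliberately not renormalized: the weighted correlation is
invariant to a positive rescaling of the weight vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TaskDesign
from .exceptions import (
    DegenerateConditionError,
    InvalidArgumentError,
    OutOfDomainError,
    ZeroVarianceError,
)

__all__ = [
    "HRFModel",
    "ConditionWeights",
    "RRCMatrix",
    "canonical_hrf",
    "condition_weights",
    "weighted_pearson",
    "fisher_z",
    "build_rrc",
    "edge_pairs",
    "n_edges",
]


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma HRF parameters (seconds).

    Defaults are the conventional canonical set: response peaking at 6 s,
    undershoot at 16 s, unit dispersions, peak-to-undershoot ratio 6,
    kernel support 32 s.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    p_u_ratio: float = 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        if self.length < 16.0:
            raise InvalidArgumentError(
                f"HRF kernel length must be >= 16 s, got {self.length}"
            )


@dataclass
class ConditionWeights:
    """Nonnegative per-frame temporal weights for one condition."""

    w: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise InvalidArgumentError("condition weights must be nonnegative")
        if self.w.sum() <= 0:
            raise DegenerateConditionError(
                f"condition {self.condition!r} has all-zero weights"
            )


@dataclass
class RRCMatrix:
    """Fisher-z weighted correlation matrix for one subject x condition.

    ``z`` is symmetric with NaN on the (undefined) diagonal.
    """

    z: np.ndarray
    subject: str
    condition: str
    node_labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle (i < j) edge values in canonical order."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.z[iu, ju]


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical undirected edge enumeration: upper triangle, row-major."""
    return np.triu_indices(n_nodes, k=1)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def canonical_hrf(tr: float, model: HRFModel | None = None) -> np.ndarray:
    """Double-gamma HRF sampled on the frame grid (peak normalized to 1).

    Positive main lobe followed by a negative undershoot; the sampled
    kernel integrates to a positive value.
    """
    from scipy.stats import gamma

    if tr <= 0:
        raise InvalidArgumentError(f"tr must be > 0, got {tr}")
    model = model or HRFModel()
    t = np.arange(0.0, model.length + 1e-9, tr)
    peak = gamma.pdf(t, a=model.peak_delay / model.peak_disp, scale=model.peak_disp)
    under = gamma.pdf(
        t, a=model.undershoot_delay / model.undershoot_disp,
        scale=model.undershoot_disp,
    )
    h = peak - under / model.p_u_ratio
    return h / h.max()


def _boxcar(design: TaskDesign, condition: str) -> np.ndarray:
    """Fractional occupancy of each frame interval by the condition's events."""
    occ = np.zeros(design.total_frames)
    tr = design.tr
    for ev in design.events:
        if ev.condition != condition:
            continue
        f0 = int(np.floor(ev.onset / tr))
        f1 = int(np.ceil((ev.onset + ev.duration) / tr))
        for f in range(f0, min(f1, design.total_frames)):
            lo = max(ev.onset, f * tr)
            hi = min(ev.onset + ev.duration, (f + 1) * tr)
            occ[f] += max(0.0, hi - lo) / tr
    return occ


def condition_weights(
    design: TaskDesign,
    condition: str,
    hrf: np.ndarray | None = None,
    mask: "np.ndarray | None" = None,
) -> ConditionWeights:
    """HRF-convolved condition boxcar, rectified, censor-aware.

    The boxcar is the per-frame fractional occupancy of the condition's
    events, convolved with ``hrf`` independently within each run (no
    haemodynamic bleed across run boundaries).  Negative values from the
    HRF undershoot are rectified to zero; frames excluded by ``mask``
    (a boolean keep vector or a CensorMask) get weight zero.
    """
    if condition not in design.conditions:
        raise InvalidArgumentError(
            f"condition {condition!r} does not occur in the design "
            f"(has {design.conditions})"
        )
    if hrf is None:
        hrf = canonical_hrf(design.tr)
    hrf = np.asarray(hrf, dtype=float)

    occ = _boxcar(design, condition)
    w = np.empty_like(occ)
    nf = design.n_frames
    for r in range(design.n_runs):
        seg = occ[r * nf:(r + 1) * nf]
        w[r * nf:(r + 1) * nf] = np.convolve(seg, hrf)[:nf]
    w = np.maximum(w, 0.0)

    if mask is not None:
        keep = np.asarray(getattr(mask, "keep", mask), dtype=bool)
        if keep.shape[0] != w.shape[0]:
            raise InvalidArgumentError(
                f"mask length {keep.shape[0]} != n frames {w.shape[0]}"
            )
        w = np.where(keep, w, 0.0)
    if w.sum() <= 0:
        raise DegenerateConditionError(
            f"condition {condition!r} has no usable frames after censoring"
        )
    return ConditionWeights(w=w, condition=condition)


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation with weighted-mean centring.

    r = sum(w (x - mx)(y - my)) / sqrt(sum(w (x-mx)^2) sum(w (y-my)^2))
    with mx, my the w-weighted means.  Weights must be nonnegative with
    positive sum; both variables need positive weighted variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape):
        raise InvalidArgumentError(
            f"shape mismatch: x {x.shape}, y {y.shape}, w {w.shape}"
        )
    if np.any(w < 0):
        raise InvalidArgumentError("weights must be nonnegative")
    sw = w.sum()
    if sw <= 0:
        raise InvalidArgumentError("weights must have positive sum")
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    dx = x - mx
    dy = y - my
    vx = (w * dx * dx).sum()
    vy = (w * dy * dy).sum()
    if vx <= 0 or vy <= 0:
        which = "x" if vx <= 0 else "y"
        raise ZeroVarianceError(f"zero weighted variance in {which}")
    r = (w * dx * dy).sum() / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def fisher_z(r):
    """Fisher variance-stabilizing transform z = arctanh(r); requires |r| < 1."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1.0):
        raise OutOfDomainError(
            f"|r| >= 1 is outside the domain of arctanh (got max |r| = "
            f"{np.max(np.abs(r_arr))})"
        )
    z = np.arctanh(r_arr)
    return float(z) if np.isscalar(r) or r_arr.ndim == 0 else z


def _weighted_corr_matrix(series: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized weighted correlation over all node pairs."""
    sw = w.sum()
    xm = series - (w[:, None] * series).sum(axis=0) / sw
    cov = (w[:, None] * xm).T @ xm
    var = np.diag(cov).copy()
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise ZeroVarianceError(
            f"zero weighted variance at node index {bad[0]} "
            f"(nodes {bad.tolist()})"
        )
    denom = np.sqrt(np.outer(var, var))
    return cov / denom


def build_rrc(
    clean,
    design: TaskDesign,
    conditions: list[str],
    hrf: np.ndarray | None = None,
    subject: str = "",
    node_labels: list[str] | None = None,
) -> dict[str, RRCMatrix]:
    """Weighted, Fisher-transformed RRC matrix for every condition.

    ``clean`` is either a preprocess.CleanSeries (its censor mask zeroes
    the weights) or a raw (frames x nodes) array.  A pair with |r| = 1
    raises OutOfDomainError naming the nodes; silent clipping would
    distort downstream component masses.
    """
    mask = getattr(clean, "mask", None)
    series = np.asarray(getattr(clean, "timeseries", clean), dtype=float)
    if series.ndim != 2:
        raise InvalidArgumentError(f"series must be 2-D, got shape {series.shape}")
    if series.shape[0] != design.total_frames:
        raise InvalidArgumentError(
            f"series has {series.shape[0]} frames, design expects "
            f"{design.total_frames}"
        )
    if hrf is None:
        hrf = canonical_hrf(design.tr)
    nn = series.shape[1]
    labels = node_labels or [f"node{i:02d}" for i in range(nn)]

    out: dict[str, RRCMatrix] = {}
    for cond in conditions:
        try:
            cw = condition_weights(design, cond, hrf=hrf, mask=mask)
        except (DegenerateConditionError, InvalidArgumentError) as exc:
            raise type(exc)(f"subject {subject!r}: {exc}") from exc
        try:
            r = _weighted_corr_matrix(series, cw.w)
        except ZeroVarianceError as exc:
            raise ZeroVarianceError(
                f"subject {subject!r}, condition {cond!r}: {exc}"
            ) from exc
        off = ~np.eye(nn, dtype=bool)
        if np.any(np.abs(r[off]) >= 1.0 - 1e-12):
            iu, ju = np.where((np.abs(r) >= 1.0 - 1e-12) & off)
            raise OutOfDomainError(
                f"subject {subject!r}, condition {cond!r}: |r| = 1 between "
                f"nodes {labels[iu[0]]} and {labels[ju[0]]} (identical or "
                "anti-identical series); cannot Fisher-transform"
            )
        z = np.arctanh(np.where(off, r, 0.0))
        np.fill_diagonal(z, np.nan)
        z = (z + z.T) / 2.0  # enforce exact symmetry against fp noise
        out[cond] = RRCMatrix(z=z, subject=subject, condition=cond,
                              node_labels=list(labels))
    return out


def stack_cohort_z(
    rrc_list: "list[dict[str, RRCMatrix]]",
    conditions: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Stack per-subject RRC maps into condition -> (n_subjects, n_edges)."""
    if not rrc_list:
        raise InvalidArgumentError("empty cohort")
    if conditions is None:
        conditions = list(rrc_list[0].keys())
    out = {}
    for cond in conditions:
        rows = []
        for s, rrc in enumerate(rrc_list):
            if cond not in rrc:
                raise InvalidArgumentError(
                    f"subject index {s} is missing condition {cond!r}"
                )
            rows.append(rrc[cond].edge_vector())
        out[cond] = np.vstack(rows)
    return out
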