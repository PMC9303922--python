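"""Second-level edge-wise GLM: condition contrasts and group t-statistics.

The group model for a within-subject contrast is the one-sample t-test on
per-subject contrast values (for a paired difference this is exactly the
paired t-test): t = mean / (sd / sqrt(n)), df = n - 1, per edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import InvalidArgumentError

__all__ = [
    "ContrastSpec",
    "EdgeStatMap",
    "apply_contrast",
    "edge_tstats",
    "height_threshold",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Named linear contrast over condition labels.

    Difference contrasts (e.g. ``{"self": 1, "stranger": -1}``) must have
    weights summing to zero; at least one weight must be nonzero.
    """

    name: str
    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nz = [w for w in self.weights.values() if w != 0]
        if not nz:
            raise InvalidArgumentError(
                f"contrast {self.name!r} has no nonzero weight"
            )

    @property
    def conditions(self) -> list[str]:
        return [c for c, w in self.weights.items() if w != 0]

    @property
    def is_paired_difference(self) -> bool:
        """True for a two-condition +1/-1 contrast (sign-flip permutable)."""
        nz = sorted(w for w in self.weights.values() if w != 0)
        return nz == [-1, 1] or nz == [-1.0, 1.0]

    def scaled(self, a: float) -> "ContrastSpec":
        return ContrastSpec(
            name=f"{a}*{self.name}",
            weights={c: a * w for c, w in self.weights.items()},
        )


@dataclass
class EdgeStatMap:
    """Per-edge group t-statistics plus the subject-level contrast values.

    ``subject_diffs`` (n_subjects x n_edges) is retained because the
    permutation null and the effect sizes are recomputed from it.
    Degenerate (zero-variance) edges carry t = NaN and are flagged.
    """

    t: np.ndarray
    df: int
    subject_diffs: np.ndarray
    degenerate: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.subject_diffs.shape[0]

    @property
    def n_edge(self) -> int:
        return self.t.shape[0]

    @property
    def n_nodes(self) -> int:
        """Node count implied by the canonical upper-triangle edge order."""
        e = self.n_edge
        n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        if n * (n - 1) // 2 != e:
            raise InvalidArgumentError(
                f"{e} edges is not a complete-graph edge count"
            )
        return n


def apply_contrast(
    z_by_condition: dict, spec: ContrastSpec
) -> np.ndarray:
    """Per-subject, per-edge contrast values sum_c weight_c * z_c.

    ``z_by_condition`` maps condition -> (n_subjects x n_edges) Fisher-z
    arrays (see connectivity.stack_cohort_z).  Linear in its inputs.
    """
    out = None
    shape = None
    for cond in spec.conditions:
        if cond not in z_by_condition:
            raise InvalidArgumentError(
                f"contrast {spec.name!r} needs condition {cond!r}, which is "
                f"missing from the cohort (has {sorted(z_by_condition)})"
            )
        z = np.asarray(z_by_condition[cond], dtype=float)
        if shape is None:
            shape = z.shape
            out = np.zeros(shape)
        elif z.shape != shape:
            raise InvalidArgumentError(
                f"condition {cond!r} has shape {z.shape}, expected {shape}"
            )
        out += spec.weights[cond] * z
    return out


def edge_tstats(subject_diffs: np.ndarray) -> EdgeStatMap:
    """One-sample t per edge on subject contrast values.

    Edges whose across-subject variance is zero are flagged (t = NaN) with
    a warning rather than silently set to zero.
    """
    D = np.asarray(subject_diffs, dtype=float)
    if D.ndim != 2:
        raise InvalidArgumentError(
            f"subject_diffs must be (n_subjects, n_edges), got {D.shape}"
        )
    n = D.shape[0]
    if n < 2:
        raise InvalidArgumentError(f"need >= 2 subjects, got {n}")
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    degenerate = sd <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edges have zero variance across "
            "subjects; they are excluded from inference (t = NaN)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate, np.nan, t)
    return EdgeStatMap(t=t, df=n - 1, subject_diffs=D, degenerate=degenerate)


def height_threshold(df: int, p_uncorrected: float, sided: str = "two") -> float:
    """Critical t for the uncorrected per-edge height threshold.

    Two-sided: P(|T| > t_crit) = p; one-sided: P(T > t_crit) = p.
    """
    if df < 1:
        raise InvalidArgumentError(f"df must be >= 1, got {df}")
    if not (0 < p_uncorrected < 1):
        raise InvalidArgumentError(
            f"p_uncorrected must be in (0, 1), got {p_uncorrected}"
        )
    if sided not in ("one", "two"):
        raise InvalidArgumentError(f"sided must be 'one' or 'two', got {sided!r}")
    tail = p_uncorrected / 2 if sided == "two" else p_uncorrected
    return float(sps.t.ppf(1 - tail, df))
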