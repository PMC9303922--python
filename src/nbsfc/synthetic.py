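"""Synthetic multi-subject ROI time-series cohorts with known ground truth.

Generative model
----------------
Each frame t is an independent Gaussian draw with correlation matrix

    Sigma(t) = (1 - rho0) I + rho0 J  +  e(t) * B,

where rho0 is the baseline inter-node correlation, B places ones on the
ground-truth edge set, and e(t) = sum_c delta_c * alpha_c(t) is the
condition-gated excess correlation.  The gate alpha_c is the bounded
per-frame function with the smallest possible peak (found by linear
programming) that satisfies the exact calibration constraints against
every HRF-convolved condition weight train w_1, ..., w_C:

    <w_c', alpha_c> / sum(w_c') = 1 if c' == c else 0,

In practice the optimal peak is 1, so the largest excess correlation
ever injected on an edge is |delta| itself.

so that the condition-c' weighted correlation on a ground-truth edge has
estimand exactly rho0 + delta_c' and the estimand off the edge set (and
for unaffected conditions) is exactly rho0.  This is what makes long-run
recovery targets closed-form: z(c) - z(c0) -> arctanh(rho0 + delta_c) -
arctanh(rho0) on ground-truth edges.

``noise_sd`` scales the stochastic frame draw itself (the white,
frame-to-frame component of the signal); drift and confound loadings are
additive and exactly removable by the linear preprocessing.  Drawing a
separate additive white-noise term instead would shrink every correlation
by 1/(1 + noise_sd^2) and destroy the analytic calibration.

Per-frame covariances are checked by Cholesky factorization; an
infeasible combination of baseline, deltas and edge topology raises
InvalidArgumentError naming the edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import canonical_hrf, condition_weights
from .design import TaskDesign, generate_design
from .exceptions import InvalidArgumentError

__all__ = [
    "GroundTruthEffect",
    "SubjectSample",
    "Cohort",
    "simulate_subject",
    "generate_cohort",
]


@dataclass
class GroundTruthEffect:
    """A known condition-dependent connectivity effect.

    ``edge_set``: unordered node pairs carrying the effect.
    ``condition_deltas``: condition -> correlation shift on those edges.
    ``baseline_corr``: correlation between every node pair otherwise.
    """

    edge_set: list[tuple[int, int]] = field(default_factory=list)
    condition_deltas: dict[str, float] = field(default_factory=dict)
    baseline_corr: float = 0.1

    def __post_init__(self) -> None:
        if not (-1.0 < self.baseline_corr < 1.0):
            raise InvalidArgumentError(
                f"baseline_corr must be in (-1, 1), got {self.baseline_corr}"
            )
        canon = []
        for i, j in self.edge_set:
            if i == j:
                raise InvalidArgumentError(f"self-edge ({i},{j}) not allowed")
            canon.append((min(i, j), max(i, j)))
        if len(set(canon)) != len(canon):
            raise InvalidArgumentError("duplicate edges in edge_set")
        self.edge_set = canon
        for c, d in self.condition_deltas.items():
            tot = self.baseline_corr + d
            if not (-1.0 < tot < 1.0):
                raise InvalidArgumentError(
                    f"baseline + delta for condition {c!r} is {tot}, "
                    "outside (-1, 1)"
                )

    def node_indices(self) -> list[int]:
        return sorted({n for e in self.edge_set for n in e})

    def is_null(self) -> bool:
        return not self.edge_set or all(
            d == 0 for d in self.condition_deltas.values()
        )


@dataclass
class SubjectSample:
    """One subject's simulated data: series, motion trace, confounds, design."""

    timeseries: np.ndarray
    fd_trace: np.ndarray
    confounds: np.ndarray
    design: TaskDesign
    subject: str = ""
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        T = self.design.total_frames
        for name, arr in (
            ("timeseries", self.timeseries),
            ("fd_trace", self.fd_trace),
            ("confounds", self.confounds),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape[0] != T:
                raise InvalidArgumentError(
                    f"{name} has {a.shape[0]} rows, design expects {T}"
                )
            if np.isnan(a).any():
                raise InvalidArgumentError(f"{name} contains missing values")
        if np.any(np.asarray(self.fd_trace) < 0):
            raise InvalidArgumentError("fd_trace must be nonnegative")


@dataclass
class Cohort:
    """A list of subjects plus the ground truth they were generated from."""

    subjects: list[SubjectSample]
    effect: GroundTruthEffect
    subject_deltas: list[dict[str, float]]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.subjects)


def _condition_gates(
    design: TaskDesign, conditions: list[str]
) -> np.ndarray:
    """Minimum-peak gates alpha_c(t) meeting the calibration constraints.

    Column c of the returned (T x len(conditions)) matrix satisfies
    <w_c', alpha_c> / sum(w_c') = delta_{cc'} over every condition in the
    design, with the smallest possible max |alpha_c| (a linear program).
    In practice the optimum is max |alpha| = 1: the gate sits at 1 across
    the target condition's weight support and swings within [-1, 1]
    elsewhere to cancel the other conditions' integrals, so the peak
    excess correlation injected on an edge is exactly |delta|.
    """
    from scipy.optimize import linprog
    from scipy.sparse import csr_matrix, eye, hstack, vstack

    hrf = canonical_hrf(design.tr)
    all_conds = design.conditions
    W = np.column_stack(
        [condition_weights(design, c, hrf=hrf).w for c in all_conds]
    )
    S = W.sum(axis=0)
    T, C = W.shape
    # variables: alpha (T values) then the peak bound A; minimize A subject
    # to -A <= alpha_t <= A and the C calibration equalities
    cost = np.zeros(T + 1)
    cost[-1] = 1.0
    A_eq = np.hstack([W.T, np.zeros((C, 1))])
    eye_T = eye(T, format="csr")
    minus_one = csr_matrix(-np.ones((T, 1)))
    A_ub = vstack(
        [hstack([eye_T, minus_one]), hstack([-eye_T, minus_one])],
        format="csr",
    )
    b_ub = np.zeros(2 * T)
    gates = np.empty((T, len(conditions)))
    for k, cond in enumerate(conditions):
        b_eq = np.where(np.array(all_conds) == cond, S, 0.0)
        res = linprog(
            cost,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=[(None, None)] * T + [(0, None)],
            method="highs",
        )
        if not res.success:
            raise InvalidArgumentError(
                f"cannot construct a calibration gate for condition "
                f"{cond!r}: {res.message}"
            )
        gates[:, k] = res.x[:T]
    return gates


def _simulate_fd(rng: np.random.Generator, T: int) -> np.ndarray:
    """|AR(1)| base motion plus sparse spikes above the 0.40 mm rule."""
    x = np.empty(T)
    x[0] = rng.normal(0, 0.06)
    for t in range(1, T):
        x[t] = 0.6 * x[t - 1] + rng.normal(0, 0.06)
    fd = np.abs(x)
    spikes = rng.random(T) < 0.03
    fd[spikes] += rng.uniform(0.45, 1.2, size=int(spikes.sum()))
    return fd


def _smooth_confounds(rng: np.random.Generator, T: int, k: int = 6) -> np.ndarray:
    conf = np.empty((T, k))
    conf[0] = rng.normal(0, 1, k)
    for t in range(1, T):
        conf[t] = 0.9 * conf[t - 1] + rng.normal(0, np.sqrt(1 - 0.81), k)
    return conf


def simulate_subject(
    design: TaskDesign,
    effect: GroundTruthEffect,
    noise_sd: float = 1.0,
    drift_amp: float = 1.0,
    seed: int = 0,
    n_nodes: int = 30,
    subject: str = "",
    node_labels: list[str] | None = None,
) -> SubjectSample:
    """Simulate one subject under the gated-covariance model.

    The condition-specific weighted correlation of the returned series (as
    computed by the connectivity module) converges, as run length grows,
    to ``baseline_corr + condition_deltas[c]`` on ground-truth edges under
    condition c's weights and to ``baseline_corr`` elsewhere.
    """
    if noise_sd <= 0:
        raise InvalidArgumentError(f"noise_sd must be > 0, got {noise_sd}")
    for i, j in effect.edge_set:
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise InvalidArgumentError(
                f"effect edge ({i},{j}) outside 0..{n_nodes - 1}"
            )
    rng = np.random.default_rng(seed)
    T = design.total_frames
    rho0 = effect.baseline_corr

    base = np.full((n_nodes, n_nodes), rho0)
    np.fill_diagonal(base, 1.0)

    active = {
        c: d for c, d in effect.condition_deltas.items() if d != 0.0
    } if effect.edge_set else {}
    for c in active:
        if c not in design.conditions:
            raise InvalidArgumentError(
                f"effect condition {c!r} does not occur in the design"
            )

    if active:
        gates = _condition_gates(design, list(active))
        deltas = np.array([active[c] for c in active])
        e_t = gates @ deltas  # excess correlation per frame
    else:
        e_t = np.zeros(T)

    try:
        base_chol = np.linalg.cholesky(base)
    except np.linalg.LinAlgError as exc:
        raise InvalidArgumentError(
            f"baseline correlation {rho0} is not positive definite for "
            f"{n_nodes} nodes"
        ) from exc

    z = rng.standard_normal((T, n_nodes))
    y = np.empty((T, n_nodes))
    hot = np.abs(e_t) > 1e-12
    y[~hot] = z[~hot] @ base_chol.T
    chol_cache: dict[float, np.ndarray] = {}
    for t in np.flatnonzero(hot):
        key = round(float(e_t[t]), 12)
        L = chol_cache.get(key)
        if L is None:
            sig = base.copy()
            for i, j in effect.edge_set:
                sig[i, j] = sig[j, i] = rho0 + e_t[t]
            try:
                L = np.linalg.cholesky(sig)
            except np.linalg.LinAlgError as exc:
                raise InvalidArgumentError(
                    "implied covariance is not positive semidefinite at "
                    f"frame {t} (excess correlation {rho0 + e_t[t]:.3f}) for "
                    f"edge set {effect.edge_set}; reduce deltas or baseline"
                ) from exc
            chol_cache[key] = L
        y[t] = z[t] @ L.T

    y *= noise_sd

    # slow drift below the high-pass cutoff, random phase/frequency per node
    tgrid = np.arange(T) * design.tr
    freqs = rng.uniform(0.002, 0.006, n_nodes)
    phases = rng.uniform(0, 2 * np.pi, n_nodes)
    y += drift_amp * np.cos(2 * np.pi * np.outer(tgrid, freqs) + phases)

    confounds = _smooth_confounds(rng, T)
    loadings = rng.normal(0, 0.2, (confounds.shape[1], n_nodes))
    y += confounds @ loadings

    fd = _simulate_fd(rng, T)
    return SubjectSample(
        timeseries=y,
        fd_trace=fd,
        confounds=confounds,
        design=design,
        subject=subject,
        node_labels=list(node_labels) if node_labels else [],
    )


def generate_cohort(
    n_subjects: int,
    design_params: dict,
    effect: GroundTruthEffect,
    between_subject_sd: float = 0.05,
    seed: int = 0,
    noise_sd: float = 1.0,
    drift_amp: float = 1.0,
    n_nodes: int = 30,
    node_labels: list[str] | None = None,
) -> Cohort:
    """Generate an independent design and subject realization per subject.

    Each subject's nonzero condition deltas are perturbed by a truncated
    (+/- 2 sd) normal with scale ``between_subject_sd``; truncation is
    symmetric, so the population mean equals the nominal delta, and it
    keeps every subject's implied covariance inside the feasible region.
    Zero deltas are left untouched so a delta-0 cohort is an exact null.
    """
    if n_subjects < 2:
        raise InvalidArgumentError(
            f"a group analysis needs >= 2 subjects, got {n_subjects}"
        )
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_subjects)
    subjects = []
    subject_deltas = []
    for s in range(n_subjects):
        sub_rng = np.random.default_rng(child[s])
        design_seed = int(sub_rng.integers(0, 2**31 - 1))
        sim_seed = int(sub_rng.integers(0, 2**31 - 1))
        design = generate_design(seed=design_seed, **design_params)
        deltas = {}
        for c, d in effect.condition_deltas.items():
            if d == 0.0 or between_subject_sd == 0.0:
                deltas[c] = d
            else:
                pert = sub_rng.normal(0, between_subject_sd)
                while abs(pert) > 2 * between_subject_sd:
                    pert = sub_rng.normal(0, between_subject_sd)
                deltas[c] = d + pert
        sub_effect = GroundTruthEffect(
            edge_set=list(effect.edge_set),
            condition_deltas=deltas,
            baseline_corr=effect.baseline_corr,
        )
        subjects.append(
            simulate_subject(
                design,
                sub_effect,
                noise_sd=noise_sd,
                drift_amp=drift_amp,
                seed=sim_seed,
                n_nodes=n_nodes,
                subject=f"sub-{s + 1:02d}",
                node_labels=node_labels,
            )
        )
        subject_deltas.append(deltas)
    return Cohort(
        subjects=subjects, effect=effect, subject_deltas=subject_deltas,
        seed=seed,
    )
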