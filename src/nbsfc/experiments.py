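"""Canned simulation experiments: FWE calibration and effect recovery.

These drive the package's own validation: batches of synthetic cohorts
are pushed through the full pipeline (simulate -> denoise -> weighted
RRC -> edge GLM -> NBS) and summarized.  Desk-scale problem sizes (two
conditions, one run, tens of trials) keep whole batches cheap while
preserving every statistical property the inference relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import atlas
from .connectivity import build_rrc, stack_cohort_z
from .glm import ContrastSpec, EdgeStatMap
from .nbs import NBSResult, run_nbs
from .preprocess import preprocess_subject
from .report import jaccard_edges
from .synthetic import GroundTruthEffect, generate_cohort

TWO_CONDITIONS = ["self", "stranger"]
CONTRAST = ContrastSpec("self_gt_stranger", {"self": 1, "stranger": -1})


def design_params(n_trials: int = 24) -> dict:
    return dict(
        n_trials_per_condition=n_trials,
        conditions=list(TWO_CONDITIONS),
        tr=2.0,
        isi_range=(2.0, 6.0),
        n_runs=1,
    )


def delta_for_z_shift(z_shift: float, baseline: float) -> float:
    """Correlation shift whose Fisher-z difference from baseline is z_shift."""
    return float(np.tanh(np.arctanh(baseline) + z_shift) - baseline)


def star_effect(
    z_shift: float = 0.3, baseline: float = 0.1, condition: str = "self"
) -> GroundTruthEffect:
    """4-edge star on the medial-prefrontal hub at a given z-difference."""
    return GroundTruthEffect(
        edge_set=list(atlas.DEFAULT_STAR_EDGES),
        condition_deltas={condition: delta_for_z_shift(z_shift, baseline)},
        baseline_corr=baseline,
    )


def null_effect(baseline: float = 0.1) -> GroundTruthEffect:
    return GroundTruthEffect(
        edge_set=[], condition_deltas={}, baseline_corr=baseline
    )


def analyze_cohort(
    cohort,
    height_p: float = 0.001,
    n_perms: int = 500,
    statistic_kind: str = "intensity_abs",
    seed: int = 0,
    estimator: str = "plus_one",
) -> NBSResult:
    """Full pipeline on one cohort for the self-vs-stranger contrast."""
    rrc = [
        build_rrc(preprocess_subject(s), s.design, TWO_CONDITIONS,
                  subject=s.subject)
        for s in cohort.subjects
    ]
    z = stack_cohort_z(rrc, TWO_CONDITIONS)
    return run_nbs(
        z,
        CONTRAST,
        height_p=height_p,
        n_perms=n_perms,
        statistic_kind=statistic_kind,
        seed=seed,
        estimator=estimator,
    )


@dataclass
class CalibrationResult:
    n_cohorts: int
    n_significant: int
    alpha: float

    @property
    def fraction(self) -> float:
        return self.n_significant / self.n_cohorts


def null_calibration(
    n_cohorts: int = 200,
    n_subjects: int = 20,
    seed: int = 0,
    n_perms: int = 500,
    height_p: float = 0.001,
    statistic_kind: str = "intensity_abs",
    alpha: float = 0.05,
    n_trials: int = 12,
) -> CalibrationResult:
    """Empirical FWE of the full pipeline on no-effect cohorts.

    Counts cohorts where any component reaches p_fwe <= alpha; under a
    calibrated procedure the fraction is close to alpha.
    """
    ss = np.random.SeedSequence([seed, 101])
    hits = 0
    for k, child in enumerate(ss.spawn(n_cohorts)):
        s1, s2 = (int(x % (2**31 - 1)) for x in child.generate_state(2))
        cohort = generate_cohort(
            n_subjects, design_params(n_trials), null_effect(), seed=s1
        )
        res = analyze_cohort(
            cohort, height_p=height_p, n_perms=n_perms,
            statistic_kind=statistic_kind, seed=s2,
        )
        if any(c.p_fwe[statistic_kind] <= alpha for c in res.components):
            hits += 1
    return CalibrationResult(n_cohorts=n_cohorts, n_significant=hits, alpha=alpha)


@dataclass
class RecoveryResult:
    jaccards: list = field(default_factory=list)
    spurious_flags: list = field(default_factory=list)
    results: list = field(default_factory=list)  # NBSResult per cohort
    truth_pairs: list = field(default_factory=list)

    @property
    def n_cohorts(self) -> int:
        return len(self.jaccards)

    @property
    def fraction_recovered(self) -> float:
        """Fraction of cohorts whose top component has Jaccard >= 0.75."""
        return float(np.mean([j >= 0.75 for j in self.jaccards]))

    @property
    def fraction_spurious(self) -> float:
        return float(np.mean(self.spurious_flags))

    @property
    def stat_maps(self) -> "list[EdgeStatMap]":
        return [r.stats for r in self.results]


def recovery_study(
    n_cohorts: int = 50,
    n_subjects: int = 20,
    seed: int = 0,
    z_shift: float = 0.3,
    between_subject_sd: float = 0.05,
    baseline: float = 0.1,
    n_perms: int = 500,
    height_p: float = 0.001,
    statistic_kind: str = "intensity_abs",
    alpha: float = 0.05,
    n_trials: int = 24,
) -> RecoveryResult:
    """Recovery of an injected 4-edge star across seeded cohorts.

    Per cohort: the top component's edge Jaccard with ground truth, and
    whether any significant component is edge-disjoint from the truth
    (a spurious detection).
    """
    effect = star_effect(z_shift, baseline)
    truth = {tuple(e) for e in effect.edge_set}
    out = RecoveryResult(truth_pairs=sorted(truth))
    ss = np.random.SeedSequence([seed, 202])
    for child in ss.spawn(n_cohorts):
        s1, s2 = (int(x % (2**31 - 1)) for x in child.generate_state(2))
        cohort = generate_cohort(
            n_subjects,
            design_params(n_trials),
            effect,
            between_subject_sd=between_subject_sd,
            seed=s1,
        )
        res = analyze_cohort(
            cohort, height_p=height_p, n_perms=n_perms,
            statistic_kind=statistic_kind, seed=s2,
        )
        top = res.largest
        out.jaccards.append(
            jaccard_edges(top.pairs, out.truth_pairs) if top else 0.0
        )
        spurious = any(
            c.p_fwe[statistic_kind] <= alpha
            and not ({tuple(p) for p in c.pairs.tolist()} & truth)
            for c in res.components
        )
        out.spurious_flags.append(spurious)
        out.results.append(res)
    return out
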