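"""Network-based statistics: suprathreshold components and permutation FWE.

The inference chain per contrast: edge-wise t-map -> height threshold
(uncorrected per-edge p, user-set) -> suprathreshold graph -> connected
components, each summarized by size (edge count), mass_t2 (sum of squared
t) and intensity_abs (sum of |t|) -> permutation null of the maximal
component statistic -> family-wise-error-corrected p per component.

The permutation scheme honours the within-subject constraint: for a
paired difference the condition labels of one subject are either swapped
or not, which is exactly an independent +/-1 sign on that subject's whole
difference vector; the same sign applies to every edge, preserving
inter-edge dependence.  For compound contrasts the condition labels are
permuted within each subject, again identically across edges.  Edge
t-statistics are recomputed in full inside every permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError
from .glm import ContrastSpec, EdgeStatMap, apply_contrast, edge_tstats, height_threshold

__all__ = [
    "SuprathresholdGraph",
    "Component",
    "NullDistribution",
    "NBSResult",
    "threshold_edges",
    "connected_components",
    "permute_within_subject",
    "null_distribution",
    "fwe_pvalue",
    "run_nbs",
    "threshold_sweep",
    "default_p_grid",
]

STAT_KINDS = ("size", "mass_t2", "intensity_abs")


@dataclass
class SuprathresholdGraph:
    """Edges whose statistic exceeds the critical value.

    ``edge_indices`` index the canonical upper-triangle edge enumeration;
    ``pairs`` are the corresponding (i, j) node pairs with i < j.
    """

    edge_indices: np.ndarray
    pairs: np.ndarray  # (k, 2)
    t: np.ndarray
    t_crit: float
    sided: str
    n_nodes: int

    @property
    def node_set(self) -> list[int]:
        return sorted(set(self.pairs.ravel().tolist()))


@dataclass
class Component:
    """A connected set of suprathreshold edges with its summary statistics."""

    edge_indices: np.ndarray
    pairs: np.ndarray
    t: np.ndarray
    p_fwe: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return int(self.edge_indices.shape[0])

    @property
    def mass_t2(self) -> float:
        return float(np.sum(self.t**2))

    @property
    def intensity_abs(self) -> float:
        return float(np.sum(np.abs(self.t)))

    @property
    def sign_profile(self) -> np.ndarray:
        return np.sign(self.t).astype(int)

    def statistic(self, kind: str) -> float:
        if kind == "size":
            return float(self.size)
        if kind == "mass_t2":
            return self.mass_t2
        if kind == "intensity_abs":
            return self.intensity_abs
        raise InvalidArgumentError(f"unknown statistic kind {kind!r}")

    def nodes(self) -> list[int]:
        return sorted(set(self.pairs.ravel().tolist()))


@dataclass
class NullDistribution:
    """Per-permutation maximal component statistic (0 when no component)."""

    max_stat: np.ndarray
    statistic_kind: str
    seed: int

    @property
    def n_perms(self) -> int:
        return int(self.max_stat.shape[0])


@dataclass
class NBSResult:
    """Components with FWE p-values plus the permutation null."""

    components: list
    null: dict  # statistic_kind -> NullDistribution
    contrast: str
    height_p: float
    t_crit: float
    sided: str
    statistic_kind: str
    estimator: str
    n_perms: int
    seed: int
    stats: EdgeStatMap | None = None

    @property
    def largest(self):
        return self.components[0] if self.components else None

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "height_p": self.height_p,
            "t_crit": self.t_crit,
            "sided": self.sided,
            "statistic_kind": self.statistic_kind,
            "estimator": self.estimator,
            "n_perms": self.n_perms,
            "seed": self.seed,
            "components": [
                {
                    "edge_indices": c.edge_indices.tolist(),
                    "pairs": c.pairs.tolist(),
                    "t": c.t.tolist(),
                    "p_fwe": {k: float(v) for k, v in c.p_fwe.items()},
                }
                for c in self.components
            ],
            "null": {
                k: nd.max_stat.tolist() for k, nd in self.null.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "NBSResult":
        comps = [
            Component(
                edge_indices=np.asarray(c["edge_indices"], dtype=int),
                pairs=np.asarray(c["pairs"], dtype=int).reshape(-1, 2),
                t=np.asarray(c["t"], dtype=float),
                p_fwe=dict(c["p_fwe"]),
            )
            for c in d["components"]
        ]
        null = {
            k: NullDistribution(
                max_stat=np.asarray(v, dtype=float),
                statistic_kind=k,
                seed=d["seed"],
            )
            for k, v in d["null"].items()
        }
        return cls(
            components=comps,
            null=null,
            contrast=d["contrast"],
            height_p=d["height_p"],
            t_crit=d["t_crit"],
            sided=d["sided"],
            statistic_kind=d["statistic_kind"],
            estimator=d["estimator"],
            n_perms=d["n_perms"],
            seed=d["seed"],
        )

    @classmethod
    def from_json(cls, s: str) -> "NBSResult":
        return cls.from_dict(json.loads(s))


def _suprathreshold_mask(t: np.ndarray, t_crit: float, sided: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if sided == "two":
            return np.abs(t) > t_crit
        if sided == "one":
            return t > t_crit
    raise InvalidArgumentError(f"sided must be 'one' or 'two', got {sided!r}")


def threshold_edges(
    stats: EdgeStatMap, t_crit: float, sided: str = "two"
) -> SuprathresholdGraph:
    """Retain exactly the edges whose t exceeds the critical value."""
    if t_crit <= 0:
        raise InvalidArgumentError(f"t_crit must be > 0, got {t_crit}")
    mask = _suprathreshold_mask(stats.t, t_crit, sided)
    mask &= ~stats.degenerate
    idx = np.flatnonzero(mask)
    n = stats.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    pairs = np.column_stack([iu[idx], ju[idx]])
    return SuprathresholdGraph(
        edge_indices=idx,
        pairs=pairs,
        t=stats.t[idx],
        t_crit=t_crit,
        sided=sided,
        n_nodes=n,
    )


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        parent = self.parent
        root = parent.setdefault(x, x)
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _component_labels(pairs: np.ndarray) -> np.ndarray:
    """Label each edge by the connected component of its incident nodes."""
    uf = _UnionFind()
    for i, j in pairs:
        uf.union(int(i), int(j))
    roots = np.fromiter((uf.find(int(i)) for i in pairs[:, 0]), dtype=int,
                        count=pairs.shape[0])
    return roots


def connected_components(graph: SuprathresholdGraph) -> list:
    """Partition the suprathreshold edges into maximal connected subgraphs.

    Returned components are sorted by descending mass_t2 (ties broken by
    the smallest canonical edge index, so the partition order is invariant
    to edge enumeration order).
    """
    if graph.edge_indices.size == 0:
        return []
    roots = _component_labels(graph.pairs)
    comps = []
    for root in np.unique(roots):
        sel = roots == root
        comps.append(
            Component(
                edge_indices=graph.edge_indices[sel],
                pairs=graph.pairs[sel],
                t=graph.t[sel],
            )
        )
    comps.sort(key=lambda c: (-c.mass_t2, int(c.edge_indices.min())))
    return comps


def permute_within_subject(
    subject_diffs: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One within-subject label exchange: an independent +/-1 per subject.

    For the paired-difference design, exchanging a subject's two condition
    labels negates that subject's whole difference vector; the same sign
    applies to every edge.
    """
    D = np.asarray(subject_diffs, dtype=float)
    if D.shape[0] < 2:
        raise InvalidArgumentError("need >= 2 subjects to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=D.shape[0])
    return D * signs[:, None]


def _max_component_stats(
    pairs_all: np.ndarray, mask: np.ndarray, t: np.ndarray
) -> dict:
    """Max component statistic of each kind for one thresholded t-map."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return {k: 0.0 for k in STAT_KINDS}
    pairs = pairs_all[idx]
    roots = _component_labels(pairs)
    tt = t[idx]
    out = {"size": 0.0, "mass_t2": 0.0, "intensity_abs": 0.0}
    for root in np.unique(roots):
        sel = roots == root
        out["size"] = max(out["size"], float(sel.sum()))
        out["mass_t2"] = max(out["mass_t2"], float(np.sum(tt[sel] ** 2)))
        out["intensity_abs"] = max(
            out["intensity_abs"], float(np.sum(np.abs(tt[sel])))
        )
    return out


def _perm_tstats_signflip(D: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for many sign-flip permutations at once.

    Sign flips leave each edge's sum of squares unchanged, so only the
    mean varies per permutation: a single matrix product gives all maps.
    """
    n = D.shape[0]
    M = signs @ D / n  # (P, E)
    ss = np.einsum("ij,ij->j", D, D)
    var = (ss[None, :] - n * M**2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return M / np.sqrt(var / n)


def null_distribution(
    subject_diffs: np.ndarray,
    height_p: float = 0.001,
    sided: str = "two",
    n_perms: int = 1000,
    statistic_kind: str = "intensity_abs",
    seed: int = 0,
    signs: np.ndarray | None = None,
    _all_kinds: bool = False,
):
    """Permutation null of the maximal component statistic (sign-flip scheme).

    Per permutation the full chain is recomputed: sign-flip subject
    difference vectors, edge t-statistics, height threshold, connected
    components, maximal statistic (0 when the suprathreshold graph is
    empty).  ``signs`` may be supplied explicitly (n_perms x n_subjects)
    for deterministic checks; otherwise they are drawn from ``seed``.
    """
    if statistic_kind not in STAT_KINDS:
        raise InvalidArgumentError(
            f"statistic_kind must be one of {STAT_KINDS}, got {statistic_kind!r}"
        )
    if n_perms < 1:
        raise InvalidArgumentError(f"n_perms must be >= 1, got {n_perms}")
    D = np.asarray(subject_diffs, dtype=float)
    n, E = D.shape
    if signs is None:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perms, n))
    else:
        signs = np.asarray(signs, dtype=float)
        if signs.shape != (n_perms, n):
            raise InvalidArgumentError(
                f"signs must have shape {(n_perms, n)}, got {signs.shape}"
            )

    sd = D.std(axis=0, ddof=1)
    degenerate = sd <= 0
    t_crit = height_threshold(n - 1, height_p, sided)
    n_nodes = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    iu, ju = np.triu_indices(n_nodes, k=1)
    pairs_all = np.column_stack([iu, ju])

    T = _perm_tstats_signflip(D, signs)
    T[:, degenerate] = 0.0
    supra = _suprathreshold_mask(T, t_crit, sided)

    maxima = {k: np.zeros(n_perms) for k in STAT_KINDS}
    for p in np.flatnonzero(supra.any(axis=1)):
        stats_p = _max_component_stats(pairs_all, supra[p], T[p])
        for k in STAT_KINDS:
            maxima[k][p] = stats_p[k]

    seed_int = int(seed) if np.isscalar(seed) else 0
    nulls = {
        k: NullDistribution(max_stat=maxima[k], statistic_kind=k, seed=seed_int)
        for k in STAT_KINDS
    }
    return nulls if _all_kinds else nulls[statistic_kind]


def _null_distribution_labels(
    z_by_condition: dict,
    spec: ContrastSpec,
    height_p: float,
    sided: str,
    n_perms: int,
    seed: int,
) -> dict:
    """Permutation null for compound contrasts: within-subject label shuffles.

    For every permutation each subject's condition vectors (over the
    conditions the contrast involves) are rearranged by an independent
    random permutation, identical across edges; the contrast and the full
    edge t-map are then recomputed.
    """
    conds = spec.conditions
    weights = np.array([spec.weights[c] for c in conds])
    stack = np.stack([np.asarray(z_by_condition[c], dtype=float) for c in conds])
    C, n, E = stack.shape
    t_crit = height_threshold(n - 1, height_p, sided)
    n_nodes = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    iu, ju = np.triu_indices(n_nodes, k=1)
    pairs_all = np.column_stack([iu, ju])

    rng = np.random.default_rng(seed)
    maxima = {k: np.zeros(n_perms) for k in STAT_KINDS}
    sqn = np.sqrt(n)
    for p in range(n_perms):
        D = np.empty((n, E))
        for s in range(n):
            perm = rng.permutation(C)
            D[s] = weights @ stack[perm, s, :]
        mean = D.mean(axis=0)
        sd = D.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / sqn)
        t = np.where(sd <= 0, 0.0, t)
        mask = _suprathreshold_mask(t, t_crit, sided)
        if mask.any():
            stats_p = _max_component_stats(pairs_all, mask, t)
            for k in STAT_KINDS:
                maxima[k][p] = stats_p[k]
    return {
        k: NullDistribution(max_stat=maxima[k], statistic_kind=k, seed=seed)
        for k in STAT_KINDS
    }


def fwe_pvalue(
    observed_stat: float, null: NullDistribution, estimator: str = "plus_one"
) -> float:
    """FWE p: permutations whose maximal component is as large or larger.

    ``proportion``: #{perm >= obs} / n_perms (can be exactly 0).
    ``plus_one``: (1 + #{perm >= obs}) / (1 + n_perms), floor 1/(n+1).
    Ties count as >=.
    """
    if null.n_perms < 1:
        raise InvalidArgumentError("null distribution is empty")
    count = int(np.sum(null.max_stat >= observed_stat))
    if estimator == "proportion":
        return count / null.n_perms
    if estimator == "plus_one":
        return (1 + count) / (1 + null.n_perms)
    raise InvalidArgumentError(
        f"estimator must be 'proportion' or 'plus_one', got {estimator!r}"
    )


def run_nbs(
    z_by_condition: dict,
    contrast: ContrastSpec,
    height_p: float = 0.001,
    sided: str = "two",
    n_perms: int = 1000,
    statistic_kind: str = "intensity_abs",
    seed: int = 0,
    estimator: str = "plus_one",
    perm_scheme: str = "auto",
) -> NBSResult:
    """End-to-end NBS for one contrast.

    ``perm_scheme``: 'sign_flip' (paired differences), 'label_permute'
    (within-subject condition shuffles, for compound contrasts), or
    'auto' (sign_flip exactly when the contrast is a two-condition
    +1/-1 difference).  Deterministic given ``seed``.
    """
    if statistic_kind not in STAT_KINDS:
        raise InvalidArgumentError(
            f"statistic_kind must be one of {STAT_KINDS}, got {statistic_kind!r}"
        )
    D = apply_contrast(z_by_condition, contrast)
    stats = edge_tstats(D)
    t_crit = height_threshold(stats.df, height_p, sided)
    graph = threshold_edges(stats, t_crit, sided)
    comps = connected_components(graph)

    if perm_scheme == "auto":
        perm_scheme = "sign_flip" if contrast.is_paired_difference else "label_permute"
    if perm_scheme == "sign_flip":
        nulls = null_distribution(
            D, height_p=height_p, sided=sided, n_perms=n_perms,
            statistic_kind=statistic_kind, seed=seed, _all_kinds=True,
        )
    elif perm_scheme == "label_permute":
        nulls = _null_distribution_labels(
            z_by_condition, contrast, height_p, sided, n_perms, seed
        )
    else:
        raise InvalidArgumentError(
            f"perm_scheme must be 'auto', 'sign_flip' or 'label_permute', "
            f"got {perm_scheme!r}"
        )

    for comp in comps:
        comp.p_fwe = {
            k: fwe_pvalue(comp.statistic(k), nulls[k], estimator)
            for k in STAT_KINDS
        }
    comps.sort(
        key=lambda c: (-c.statistic(statistic_kind), int(c.edge_indices.min()))
    )
    return NBSResult(
        components=comps,
        null=nulls,
        contrast=contrast.name,
        height_p=height_p,
        t_crit=t_crit,
        sided=sided,
        statistic_kind=statistic_kind,
        estimator=estimator,
        n_perms=n_perms,
        seed=seed if np.isscalar(seed) else 0,
        stats=stats,
    )


def default_p_grid(start: float = 0.05, stop: float = 0.0001, factor: float = 0.9) -> np.ndarray:
    """Descending height-p grid in 10% multiplicative steps."""
    vals = []
    p = start
    while p >= stop * (1 - 1e-12):
        vals.append(p)
        p *= factor
    return np.asarray(vals)


def threshold_sweep(
    z_by_condition: dict,
    contrast: ContrastSpec,
    p_grid: np.ndarray | None = None,
    alpha_fwe: float = 0.05,
    conservative_cut: float = 0.01,
    **nbs_kwargs,
):
    """NBS at every height threshold of a descending grid.

    Returns (summary table, list of NBSResult).  The table carries one row
    per threshold with the largest component's size, statistics and FWE p,
    and the sweep-level taxonomy: an effect significant only at
    conservative thresholds (height p <= ``conservative_cut``) is
    'focal', only at liberal thresholds 'extended', at both 'combined'.
    """
    import pandas as pd

    if p_grid is None:
        p_grid = default_p_grid()
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size == 0:
        raise InvalidArgumentError("p_grid must be non-empty")
    if np.any((p_grid <= 0) | (p_grid >= 1)):
        raise InvalidArgumentError("p_grid values must lie in (0, 1)")

    results = []
    rows = []
    kind = nbs_kwargs.get("statistic_kind", "intensity_abs")
    for hp in p_grid:
        res = run_nbs(z_by_condition, contrast, height_p=float(hp), **nbs_kwargs)
        top = res.largest
        rows.append(
            {
                "height_p": float(hp),
                "t_crit": res.t_crit,
                "n_supra_edges": int(
                    sum(c.size for c in res.components)
                ),
                "n_components": len(res.components),
                "largest_size": top.size if top else 0,
                "largest_mass_t2": top.mass_t2 if top else 0.0,
                "largest_intensity_abs": top.intensity_abs if top else 0.0,
                "p_fwe": top.p_fwe[kind] if top else 1.0,
                "significant": bool(top and top.p_fwe[kind] <= alpha_fwe),
            }
        )
        results.append(res)
    table = pd.DataFrame(rows)
    cons = table["height_p"] <= conservative_cut
    sig_cons = bool((table["significant"] & cons).any())
    sig_lib = bool((table["significant"] & ~cons).any())
    if sig_cons and sig_lib:
        taxonomy = "combined"
    elif sig_cons:
        taxonomy = "focal"
    elif sig_lib:
        taxonomy = "extended"
    else:
        taxonomy = "none"
    table.attrs["taxonomy"] = taxonomy
    table["taxonomy"] = taxonomy
    return table, results
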