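"""Human-readable summaries of NBS results and recovery metrics."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .effects import ComponentEffect
from .exceptions import InvalidArgumentError
from .nbs import NBSResult

FLOAT_FMT = "%.6g"


def jaccard_edges(pairs_a, pairs_b) -> float:
    """Jaccard index of two undirected edge sets given as (i, j) pairs."""
    a = {tuple(sorted(map(int, e))) for e in pairs_a}
    b = {tuple(sorted(map(int, e))) for e in pairs_b}
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def components_table(result: NBSResult, node_labels: list[str]) -> pd.DataFrame:
    rows = []
    for k, comp in enumerate(result.components, start=1):
        for (i, j), t in zip(comp.pairs, comp.t):
            rows.append(
                {
                    "component_id": k,
                    "node_i": node_labels[i],
                    "node_j": node_labels[j],
                    "t": float(t),
                    "sign": int(np.sign(t)),
                }
            )
    return pd.DataFrame(
        rows, columns=["component_id", "node_i", "node_j", "t", "sign"]
    )


def summary_table(result: NBSResult) -> pd.DataFrame:
    rows = []
    for k, comp in enumerate(result.components, start=1):
        rows.append(
            {
                "component_id": k,
                "size": comp.size,
                "mass_t2": comp.mass_t2,
                "intensity_abs": comp.intensity_abs,
                "p_fwe_size": comp.p_fwe.get("size", np.nan),
                "p_fwe_mass_t2": comp.p_fwe.get("mass_t2", np.nan),
                "p_fwe_intensity_abs": comp.p_fwe.get("intensity_abs", np.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "component_id",
            "size",
            "mass_t2",
            "intensity_abs",
            "p_fwe_size",
            "p_fwe_mass_t2",
            "p_fwe_intensity_abs",
        ],
    )


def null_table(result: NBSResult) -> pd.DataFrame:
    data = {"perm": np.arange(1, result.n_perms + 1)}
    for kind, nd in result.null.items():
        data[f"max_{kind}"] = nd.max_stat
    return pd.DataFrame(data)


def _fmt_component_line(
    result: NBSResult, comp_idx: int, effect: ComponentEffect | None
) -> str:
    comp = result.components[comp_idx]
    kind = result.statistic_kind
    parts = [
        f"component={comp_idx + 1}",
        f"mass={comp.statistic(kind):.2f}",
        f"p-FWE={comp.p_fwe[kind]:.3f}",
        f"size={comp.size}",
    ]
    if effect is not None:
        parts.append(
            f"Cohen's d={effect.d:.2f}, "
            f"90%CI [{effect.ci90[0]:.2f}, {effect.ci90[1]:.2f}]"
        )
    return "; ".join(parts)


def render_report(
    results: list,
    out_dir,
    node_labels: list[str],
    effects: dict | None = None,
    sweep_tables: dict | None = None,
    truth_pairs: list | None = None,
) -> pathlib.Path:
    """Write per-contrast TSVs plus a plain-text summary.

    ``results`` is a list of NBSResult; ``effects`` maps contrast name ->
    list of ComponentEffect aligned with that result's components;
    ``sweep_tables`` maps contrast name -> threshold-sweep DataFrame.
    When ``truth_pairs`` (ground-truth edge pairs) is given, top-component
    recovery metrics are reported.
    """
    if not results:
        raise InvalidArgumentError("results list is empty")
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    effects = effects or {}
    sweep_tables = sweep_tables or {}

    lines = []
    for res in results:
        prefix = out_dir / res.contrast
        components_table(res, node_labels).to_csv(
            f"{prefix}_components.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        summary_table(res).to_csv(
            f"{prefix}_summary.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        null_table(res).to_csv(
            f"{prefix}_null.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        lines.append(
            f"contrast {res.contrast} (height p<{res.height_p:g}, "
            f"t_crit={res.t_crit:.3f}, {res.sided}-sided, "
            f"{res.n_perms} permutations, statistic={res.statistic_kind}, "
            f"estimator={res.estimator})"
        )
        if not res.components:
            lines.append("  no suprathreshold component")
        eff_list = effects.get(res.contrast, [])
        for k in range(len(res.components)):
            eff = eff_list[k] if k < len(eff_list) else None
            lines.append("  " + _fmt_component_line(res, k, eff))
        if truth_pairs is not None and res.largest is not None:
            jac = jaccard_edges(res.largest.pairs, truth_pairs)
            lines.append(
                f"  ground-truth recovery: top-component edge Jaccard="
                f"{jac:.3f} against {len(truth_pairs)} true edges"
            )
        if res.contrast in sweep_tables:
            tab = sweep_tables[res.contrast]
            tab.to_csv(
                f"{prefix}_sweep.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT,
            )
            lines.append(
                f"  threshold sweep: {len(tab)} thresholds, taxonomy="
                f"{tab['taxonomy'].iloc[0]}"
            )
        lines.append("")

    report = out_dir / "report.txt"
    report.write_text("\n".join(lines))
    return report
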