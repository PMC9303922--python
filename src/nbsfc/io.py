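"""Plain-text serialization: TSV tables and the cohort manifest.

All artifacts are tab-separated text with headers (floats written with a
fixed %.10g format so that reruns with the same seed are byte-identical)
plus one YAML manifest per cohort describing per-subject paths and the
ground-truth effect.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .design import TaskDesign, TrialEvent
from .exceptions import InvalidArgumentError
from .preprocess import CensorMask, CleanSeries
from .synthetic import Cohort, GroundTruthEffect, SubjectSample

FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: pathlib.Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_events(design: TaskDesign, path) -> None:
    df = pd.DataFrame(
        [(e.condition, e.onset, e.duration) for e in design.events],
        columns=["condition", "onset", "duration"],
    )
    _write_tsv(df, pathlib.Path(path))


def read_events(path, tr: float, n_frames: int, n_runs: int) -> TaskDesign:
    df = pd.read_csv(path, sep="\t")
    events = [
        TrialEvent(str(r.condition), float(r.onset), float(r.duration))
        for r in df.itertuples()
    ]
    return TaskDesign(events=events, tr=tr, n_frames=n_frames, n_runs=n_runs)


def write_timeseries(series: np.ndarray, node_labels: list[str], path) -> None:
    _write_tsv(pd.DataFrame(series, columns=node_labels), pathlib.Path(path))


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_subject(sample: SubjectSample, subj_dir) -> dict:
    """Write one subject's TSVs; returns the relative path map."""
    subj_dir = pathlib.Path(subj_dir)
    subj_dir.mkdir(parents=True, exist_ok=True)
    labels = sample.node_labels or [
        f"node{i:02d}" for i in range(sample.timeseries.shape[1])
    ]
    write_timeseries(sample.timeseries, labels, subj_dir / "timeseries.tsv")
    write_events(sample.design, subj_dir / "events.tsv")
    _write_tsv(
        pd.DataFrame(
            sample.confounds,
            columns=[f"conf{i:02d}" for i in range(sample.confounds.shape[1])],
        ),
        subj_dir / "confounds.tsv",
    )
    _write_tsv(pd.DataFrame({"fd_mm": sample.fd_trace}), subj_dir / "fd.tsv")
    return {
        "timeseries": "timeseries.tsv",
        "events": "events.tsv",
        "confounds": "confounds.tsv",
        "fd": "fd.tsv",
    }


def write_cohort(cohort: Cohort, out_dir) -> pathlib.Path:
    """Write every subject plus a manifest with the ground truth."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects = []
    for s, sample in enumerate(cohort.subjects):
        name = sample.subject or f"sub-{s + 1:02d}"
        files = write_subject(sample, out_dir / name)
        subjects.append(
            {
                "subject": name,
                "dir": name,
                "files": files,
                "tr": sample.design.tr,
                "n_frames": sample.design.n_frames,
                "n_runs": sample.design.n_runs,
                "true_deltas": {
                    k: float(v) for k, v in cohort.subject_deltas[s].items()
                },
            }
        )
    manifest = {
        "seed": int(cohort.seed),
        "n_subjects": len(cohort.subjects),
        "ground_truth": {
            "edge_set": [[int(i), int(j)] for i, j in cohort.effect.edge_set],
            "condition_deltas": {
                k: float(v) for k, v in cohort.effect.condition_deltas.items()
            },
            "baseline_corr": float(cohort.effect.baseline_corr),
        },
        "subjects": subjects,
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_cohort(out_dir) -> Cohort:
    out_dir = pathlib.Path(out_dir)
    manifest_path = out_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise InvalidArgumentError(f"no cohort manifest at {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    gt = manifest["ground_truth"]
    effect = GroundTruthEffect(
        edge_set=[tuple(e) for e in gt["edge_set"]],
        condition_deltas=dict(gt["condition_deltas"]),
        baseline_corr=gt["baseline_corr"],
    )
    subjects = []
    deltas = []
    for rec in manifest["subjects"]:
        sdir = out_dir / rec["dir"]
        series, labels = read_timeseries(sdir / rec["files"]["timeseries"])
        design = read_events(
            sdir / rec["files"]["events"],
            tr=rec["tr"],
            n_frames=rec["n_frames"],
            n_runs=rec["n_runs"],
        )
        confounds = pd.read_csv(sdir / rec["files"]["confounds"], sep="\t").to_numpy(
            dtype=float
        )
        fd = pd.read_csv(sdir / rec["files"]["fd"], sep="\t")["fd_mm"].to_numpy(
            dtype=float
        )
        subjects.append(
            SubjectSample(
                timeseries=series,
                fd_trace=fd,
                confounds=confounds,
                design=design,
                subject=rec["subject"],
                node_labels=labels,
            )
        )
        deltas.append(dict(rec["true_deltas"]))
    return Cohort(
        subjects=subjects,
        effect=effect,
        subject_deltas=deltas,
        seed=manifest["seed"],
    )


def write_mask(mask: CensorMask, path) -> None:
    _write_tsv(pd.DataFrame({"keep": mask.keep.astype(int)}), pathlib.Path(path))


def read_mask(path, threshold_mm: float = 0.40) -> CensorMask:
    keep = pd.read_csv(path, sep="\t")["keep"].to_numpy(dtype=bool)
    return CensorMask(keep=keep, threshold_mm=threshold_mm)


def write_clean(clean: CleanSeries, subj_dir) -> None:
    subj_dir = pathlib.Path(subj_dir)
    subj_dir.mkdir(parents=True, exist_ok=True)
    write_timeseries(clean.timeseries, clean.node_labels, subj_dir / "clean.tsv")
    write_mask(clean.mask, subj_dir / "mask.tsv")


def read_clean(subj_dir, cutoff_hz: float, threshold_mm: float) -> CleanSeries:
    subj_dir = pathlib.Path(subj_dir)
    series, labels = read_timeseries(subj_dir / "clean.tsv")
    mask = read_mask(subj_dir / "mask.tsv", threshold_mm)
    return CleanSeries(
        timeseries=series, mask=mask, filter_cutoff_hz=cutoff_hz,
        node_labels=labels,
    )


def write_edge_table_long(
    z_by_condition: dict, node_labels: list[str], subject_names: list[str], path
) -> None:
    """Long-format edge table: node_i, node_j, condition, subject, z."""
    n = len(node_labels)
    iu, ju = np.triu_indices(n, k=1)
    frames = []
    for cond, Z in z_by_condition.items():
        for s, name in enumerate(subject_names):
            frames.append(
                pd.DataFrame(
                    {
                        "node_i": [node_labels[i] for i in iu],
                        "node_j": [node_labels[j] for j in ju],
                        "condition": cond,
                        "subject": name,
                        "z": Z[s],
                    }
                )
            )
    _write_tsv(pd.concat(frames, ignore_index=True), pathlib.Path(path))


def read_edge_table_long(path) -> tuple[dict, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t")
    labels_i = list(df["node_i"].unique())
    labels_j = list(df["node_j"].unique())
    node_labels = list(dict.fromkeys(labels_i + labels_j))
    subjects = list(df["subject"].unique())
    n = len(node_labels)
    iu, ju = np.triu_indices(n, k=1)
    key = {(node_labels[i], node_labels[j]): k for k, (i, j) in enumerate(zip(iu, ju))}
    out = {}
    for cond, grp in df.groupby("condition", sort=False):
        Z = np.full((len(subjects), len(iu)), np.nan)
        srank = {s: k for k, s in enumerate(subjects)}
        for r in grp.itertuples():
            Z[srank[r.subject], key[(r.node_i, r.node_j)]] = r.z
        if np.isnan(Z).any():
            raise InvalidArgumentError(
                f"edge table at {path} is missing entries for condition {cond!r}"
            )
        out[str(cond)] = Z
    return out, node_labels, subjects
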