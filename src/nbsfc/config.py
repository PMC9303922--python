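"""Run configuration: YAML schema, validation, defaults."""

from __future__ import annotations

import hashlib
import pathlib
from dataclasses import dataclass, field

import yaml

from .exceptions import InvalidArgumentError
from .glm import ContrastSpec

DEFAULT_CONDITIONS = ["self", "friend", "stranger", "happy", "sad", "neutral"]


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``seed`` is mandatory; every stage derives its randomness from it.
    """

    seed: int
    out_dir: str = "nbsfc_out"
    # cohort
    n_subjects: int = 20
    conditions: list = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    n_trials_per_condition: int = 40
    tr: float = 2.0
    isi_range: tuple = (2.0, 6.0)
    n_runs: int = 2
    baseline_corr: float = 0.1
    effect_edges: list = field(default_factory=list)
    condition_deltas: dict = field(default_factory=dict)
    between_subject_sd: float = 0.05
    noise_sd: float = 1.0
    drift_amp: float = 1.0
    # preprocessing
    highpass_hz: float = 1.0 / 128.0
    fd_threshold_mm: float = 0.40
    model_session_task: bool = True
    # inference
    contrasts: list = field(default_factory=list)  # list[ContrastSpec]
    height_p: float = 0.001
    sweep_grid: list = field(default_factory=list)  # empty -> default grid
    n_perms: int = 1000
    sided: str = "two"
    statistic_kind: str = "intensity_abs"
    estimator: str = "plus_one"
    perm_scheme: str = "auto"
    config_hash: str = ""

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidArgumentError("field 'seed' is mandatory")
        if self.n_subjects < 2:
            raise InvalidArgumentError(
                f"field 'n_subjects' must be >= 2, got {self.n_subjects}"
            )
        if self.sided not in ("one", "two"):
            raise InvalidArgumentError(
                f"field 'sided' must be 'one' or 'two', got {self.sided!r}"
            )
        if self.statistic_kind not in ("size", "mass_t2", "intensity_abs"):
            raise InvalidArgumentError(
                "field 'statistic_kind' must be size|mass_t2|intensity_abs, "
                f"got {self.statistic_kind!r}"
            )
        if self.estimator not in ("proportion", "plus_one"):
            raise InvalidArgumentError(
                "field 'estimator' must be proportion|plus_one, "
                f"got {self.estimator!r}"
            )
        if not (0 < self.height_p < 1):
            raise InvalidArgumentError(
                f"field 'height_p' must be in (0, 1), got {self.height_p}"
            )
        if not self.contrasts:
            self.contrasts = [
                ContrastSpec("self_gt_stranger", {"self": 1, "stranger": -1}),
                ContrastSpec("self_gt_friend", {"self": 1, "friend": -1}),
                ContrastSpec("happy_gt_neutral", {"happy": 1, "neutral": -1}),
                ContrastSpec("sad_gt_neutral", {"sad": 1, "neutral": -1}),
            ]
        for spec in self.contrasts:
            for c in spec.conditions:
                if c not in self.conditions:
                    raise InvalidArgumentError(
                        f"contrast {spec.name!r} references condition {c!r}, "
                        f"not in field 'conditions' {self.conditions}"
                    )

    @property
    def design_params(self) -> dict:
        return {
            "n_trials_per_condition": self.n_trials_per_condition,
            "conditions": list(self.conditions),
            "tr": self.tr,
            "isi_range": tuple(self.isi_range),
            "n_runs": self.n_runs,
        }


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; errors name the offending field."""
    path = pathlib.Path(path)
    if not path.exists():
        raise InvalidArgumentError(f"config file does not exist: {path}")
    raw = path.read_text()
    try:
        data = yaml.safe_load(raw) or {}
    except yaml.YAMLError as exc:
        raise InvalidArgumentError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise InvalidArgumentError("config must be a YAML mapping")
    if "seed" not in data:
        raise InvalidArgumentError("field 'seed' is mandatory in the config")

    contrasts = []
    for item in data.pop("contrasts", []):
        if not isinstance(item, dict) or "name" not in item or "weights" not in item:
            raise InvalidArgumentError(
                "each entry of field 'contrasts' needs 'name' and 'weights'"
            )
        contrasts.append(ContrastSpec(item["name"], dict(item["weights"])))

    effect_edges = [tuple(e) for e in data.pop("effect_edges", [])]
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise InvalidArgumentError(
            f"unknown config fields: {sorted(unknown)}"
        )
    if "isi_range" in data:
        data["isi_range"] = tuple(data["isi_range"])
    cfg = RunConfig(
        contrasts=contrasts, effect_edges=effect_edges, **data
    )
    cfg.config_hash = hashlib.sha256(raw.encode()).hexdigest()[:16]
    return cfg
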