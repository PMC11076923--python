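"""Run configuration: a validated, YAML-loadable set of pipeline settings.

A configuration fully determines a pipeline run: the single master seed
drives every random stream, so two runs with equal configurations produce
identical artifacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from volunteerbias.defaults import (
    DEFAULT_ASSOCIATIONS,
    DEFAULT_MISSINGNESS,
    REFERENCE_RESPONSE_RATE,
    REFERENCE_SAMPLING_FRACTION,
)

_VALID_NORMALIZATIONS = {"mean-one", "sum-n"}
_VALID_FORMULAS = {"inverse-odds", "inverse-probability"}
_VALID_KINDS = {"lpm", "standardized"}


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    ``cohort_path``/``reference_path`` switch the pipeline to file mode
    (harmonized person tables as CSV); when both are ``None`` the synthetic
    study is simulated at ``n_population``.
    """

    seed: int = 0
    n_population: int = 500_000
    cohort_path: str | None = None
    reference_path: str | None = None
    reference_sampling_fraction: float = REFERENCE_SAMPLING_FRACTION
    reference_response_rate: float = REFERENCE_RESPONSE_RATE
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS)
    )
    folds: int = 5
    n_lambdas: int = 14
    lambda_ratio: float = 1e-4
    max_iter: int = 2000
    refit_active_set: bool = True
    normalization: str = "mean-one"
    formula: str = "inverse-odds"
    associations: list[dict] = field(
        default_factory=lambda: [dict(p) for p in DEFAULT_ASSOCIATIONS]
    )
    run_robustness: bool = False
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")
        if (self.cohort_path is None) != (self.reference_path is None):
            raise ValueError(
                "file mode needs both cohort_path and reference_path"
            )
        if self.cohort_path is None and self.n_population < 1000:
            raise ValueError("n_population must be at least 1000")
        if not 0 < self.reference_sampling_fraction < 1:
            raise ValueError("reference_sampling_fraction must lie in (0, 1)")
        if not 0 < self.reference_response_rate <= 1:
            raise ValueError("reference_response_rate must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be at least 2")
        if not 0 < self.lambda_ratio < 1:
            raise ValueError("lambda_ratio must lie in (0, 1)")
        if self.normalization not in _VALID_NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.formula not in _VALID_FORMULAS:
            raise ValueError(f"unknown weight formula {self.formula!r}")
        if not self.associations:
            raise ValueError("at least one association must be configured")
        for pair in self.associations:
            missing = {"outcome", "exposure"} - set(pair)
            if missing:
                raise ValueError(f"association lacks keys {sorted(missing)}: {pair}")
            if pair.get("kind", "lpm") not in _VALID_KINDS:
                raise ValueError(f"unknown association kind in {pair}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys raise, so typos fail loudly instead of silently falling back
    to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration as YAML (round-trips through :func:`load_config`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
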