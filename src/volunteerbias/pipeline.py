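"""End-to-end pipeline: data in, weights + weighted inference + diagnostics out.

Stages
------
1. Acquire a cohort and a reference sample — simulated from the synthetic
   population model, or read from harmonized person-table CSVs.
2. Apply the eligibility filter to both samples.
3. Impute missing model variables by exact-match hot deck (participation
   model only; association estimation uses the observed values).
4. Build the sparse dummy + two-way-interaction design on the stacked
   samples and fit the cross-validated L1-penalized probit of membership
   (cohort = 1, reference = 0).
5. Convert predicted participation probabilities to inverse-probability
   weights for the cohort.
6. Estimate every configured association in the reference, the unweighted
   cohort and the weighted cohort; report bias reduction, effective sample
   sizes and (optionally) leave-one-out robustness.

All artifacts are plain text (CSV / JSON / YAML) and fully determined by the
run configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from volunteerbias.codebook import (
    Codebook,
    filter_eligible,
    read_person_table,
    validate_person_table,
)
from volunteerbias.config import RunConfig, save_config
from volunteerbias.defaults import (
    MODEL_VARIABLES,
    default_codebook,
    default_population_spec,
    default_selection_spec,
)
from volunteerbias.design import build_design_matrix
from volunteerbias.diagnostics import (
    build_ess_report,
    leave_one_out_robustness,
    weight_summary,
)
from volunteerbias.impute import impute_exact_match
from volunteerbias.inference import run_association_batch
from volunteerbias.probit import cross_validate_lambda, lambda_grid, lambda_max, predict_probability
from volunteerbias.synthpop import (
    draw_reference_sample,
    draw_volunteers,
    generate_population,
    inject_missingness,
)
from volunteerbias.weights import WeightSet, compute_ip_weights, oracle_weights


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run (artifacts also on disk)."""

    config: RunConfig
    cohort: pd.DataFrame
    reference: pd.DataFrame
    weights: WeightSet
    associations: pd.DataFrame
    ess: dict
    manifest: dict
    robustness: dict | None = None
    oracle_associations: pd.DataFrame | None = None
    artifacts: dict[str, str] = field(default_factory=dict)


def simulate_inputs(
    config: RunConfig, codebook: Codebook | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (cohort, reference, eligible population) under the defaults.

    The cohort keeps its true participation probability (``true_prob``) so
    oracle weights can be formed; missingness is injected into both observed
    samples at the configured rates.
    """
    cb = codebook or default_codebook()
    pop = generate_population(default_population_spec(config.n_population, config.seed))
    eligible, _ = filter_eligible(pop, cb)
    cohort = draw_volunteers(eligible, default_selection_spec(config.seed))
    reference = draw_reference_sample(
        eligible,
        sampling_fraction=config.reference_sampling_fraction,
        response_rate=config.reference_response_rate,
        seed=config.seed,
    )
    cohort = inject_missingness(cohort, config.missingness, config.seed)
    reference = inject_missingness(reference, config.missingness, config.seed + 1)
    return cohort, reference, eligible


def load_inputs(
    config: RunConfig, codebook: Codebook
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read, validate and eligibility-filter the two person tables."""
    cohort = read_person_table(config.cohort_path, codebook)
    reference = read_person_table(config.reference_path, codebook)
    for tbl, name in ((cohort, "cohort"), (reference, "reference")):
        validate_person_table(tbl, codebook)
        tbl["source"] = name
    cohort, _ = filter_eligible(cohort, codebook)
    reference, _ = filter_eligible(reference, codebook)
    return cohort, reference


def estimate_weights(
    cohort: pd.DataFrame,
    reference: pd.DataFrame,
    codebook: Codebook,
    config: RunConfig,
    model_variables: list[str] | None = None,
):
    """Impute, build the design, cross-validate the probit, form IP weights.

    Returns ``(weights, cv_fit, design, labels, excluded)`` where ``excluded``
    maps person ids dropped at imputation (no exact donor) to a reason.
    """
    model_vars = model_variables or MODEL_VARIABLES
    stacked = pd.concat([cohort, reference], ignore_index=True)
    imputed, excluded = impute_exact_match(stacked, model_vars, config.seed)
    labels = (imputed["source"] == "cohort").to_numpy(dtype=float)
    design = build_design_matrix(imputed, codebook, variables=model_vars)
    grid = lambda_grid(
        lambda_max(design.X, labels),
        n_points=config.n_lambdas,
        ratio=config.lambda_ratio,
    )
    cv = cross_validate_lambda(
        design.X,
        labels,
        grid=grid,
        folds=config.folds,
        seed=config.seed,
        columns=design.columns,
        max_iter=config.max_iter,
        refit_active_set=config.refit_active_set,
    )
    mask = labels > 0.5
    pi, n_clipped = predict_probability(cv.fit, design.X[mask])
    weights = compute_ip_weights(
        design.row_ids[mask],
        pi,
        normalization=config.normalization,
        formula=config.formula,
        provenance={
            "chosen_lambda": cv.chosen_lambda,
            "n_selected": cv.fit.n_selected,
            "n_clipped": int(n_clipped),
            "folds": config.folds,
            "seed": config.seed,
        },
    )
    weights.excluded.update(excluded)
    return weights, cv, design, labels, excluded


def run_pipeline(
    config: RunConfig,
    codebook: Codebook | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline and write artifacts under ``out_dir``.

    Artifacts: ``weights.csv``, ``associations.csv`` (plus
    ``oracle_associations.csv`` in simulate mode), ``ess.json``,
    ``manifest.json``, ``config.yaml`` and, when requested,
    ``robustness.json``.
    """
    t0 = time.time()
    cb = codebook or default_codebook()
    simulated = config.cohort_path is None
    if simulated:
        cohort, reference, _ = simulate_inputs(config, cb)
    else:
        cohort, reference = load_inputs(config, cb)

    weights, cv, design, labels, excluded = estimate_weights(
        cohort, reference, cb, config
    )
    # association estimation uses observed (pre-imputation) values of the
    # persons that actually received a weight
    cohort_w = cohort[cohort["person_id"].isin(weights.person_id)]
    associations = run_association_batch(
        cohort_w, reference, config.associations, weights, cb
    )
    ess_report = build_ess_report(weights, associations)

    oracle_batch = None
    if simulated:
        ow = oracle_weights(cohort_w)
        oracle_batch = run_association_batch(
            cohort_w, reference, config.associations, ow, cb
        )

    robustness = None
    if config.run_robustness:
        robustness = leave_one_out_robustness(
            design,
            labels,
            cohort_w,
            reference,
            config.associations,
            cb,
            associations,
            folds=config.folds,
            seed=config.seed,
            normalization=config.normalization,
            formula=config.formula,
            max_iter=config.max_iter,
        ).to_dict()

    defined = associations[associations["bias_defined"]]
    manifest = {
        "mode": "simulate" if simulated else "file",
        "seed": config.seed,
        "n_cohort": int(len(cohort)),
        "n_reference": int(len(reference)),
        "n_weighted": int(len(weights)),
        "n_excluded_imputation": len(excluded),
        "chosen_lambda": float(cv.chosen_lambda),
        "n_selected_columns": int(cv.fit.n_selected),
        "n_design_columns": int(design.X.shape[1]),
        "kish_fraction": ess_report.kish_fraction,
        "n_associations": int(len(associations)),
        "n_bias_defined": int(len(defined)),
        "mean_bias_reduction": float(defined["bias_reduction"].mean())
        if len(defined)
        else float("nan"),
        "weight_summary": weight_summary(weights),
        "runtime_seconds": round(time.time() - t0, 1),
    }

    result = PipelineResult(
        config=config,
        cohort=cohort,
        reference=reference,
        weights=weights,
        associations=associations,
        ess=ess_report.to_dict(),
        manifest=manifest,
        robustness=robustness,
        oracle_associations=oracle_batch,
    )
    if out_dir is None:
        out_dir = config.out_dir
    if out_dir is not None:
        result.artifacts = write_artifacts(result, Path(out_dir))
    return result


def _jsonify(obj):
    """Recursively make an object strictly JSON-serializable (NaN -> null)."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.generic):
        return _jsonify(obj.item())
    return obj


def write_artifacts(result: PipelineResult, out_dir: Path) -> dict[str, str]:
    """Write all pipeline artifacts as text files; returns name -> path."""
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _path(name: str) -> Path:
        p = out_dir / name
        paths[name] = str(p)
        return p

    result.weights.to_frame().to_csv(_path("weights.csv"), index=False)
    result.associations.to_csv(_path("associations.csv"), index=False)
    if result.oracle_associations is not None:
        result.oracle_associations.to_csv(
            _path("oracle_associations.csv"), index=False
        )
    with open(_path("ess.json"), "w") as fh:
        json.dump(_jsonify(result.ess), fh, indent=2, allow_nan=False)
    with open(_path("manifest.json"), "w") as fh:
        json.dump(_jsonify(result.manifest), fh, indent=2, allow_nan=False)
    if result.robustness is not None:
        with open(_path("robustness.json"), "w") as fh:
            json.dump(_jsonify(result.robustness), fh, indent=2, allow_nan=False)
    save_config(result.config, _path("config.yaml"))
    return paths
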