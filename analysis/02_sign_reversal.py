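#!/usr/bin/env python
"""Sign reversal of the age -> poor-health association, and SD restoration.

Re-simulates the study inputs deterministically (same seed as
01_run_study.py), reads the estimated weights from results/study/weights.csv
and writes two tables:

* results/sign_reversal.csv — the age -> poor-health slope in the eligible
  population, the reference sample, the unweighted cohort and the weighted
  cohort;
* results/sd_restoration.csv — reference / cohort / weighted SDs of the
  variables most concentrated by selection.

Run 01_run_study.py first.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from volunteerbias.codebook import derive_numeric, indicator
from volunteerbias.config import RunConfig
from volunteerbias.defaults import SD_NARROWED_VARIABLES, default_codebook
from volunteerbias.inference import fit_bivariate_lpm, weighted_sd
from volunteerbias.pipeline import simulate_inputs


def main() -> None:
    weights_path = Path("results/study/weights.csv")
    if not weights_path.exists():
        raise SystemExit("results/study/weights.csv not found; run 01_run_study.py first")
    wtab = pd.read_csv(weights_path).set_index("person_id")["weight"]

    cfg = RunConfig(seed=1)
    cb = default_codebook()
    cohort, reference, eligible = simulate_inputs(cfg, cb)
    cohort = cohort[cohort["person_id"].isin(wtab.index)]
    w = wtab.reindex(cohort["person_id"]).to_numpy()

    rows = []
    for sample, table, wts in [
        ("eligible population", eligible, None),
        ("reference sample", reference, None),
        ("cohort (unweighted)", cohort, None),
        ("cohort (weighted)", cohort, w),
    ]:
        y = indicator(table, "health", "poor").to_numpy()
        x = indicator(table, "age_band", "60-69").to_numpy()
        est = fit_bivariate_lpm(y, x, wts)
        rows.append(
            {"sample": sample, "slope": est.beta, "robust_se": est.robust_se,
             "n": est.n_used}
        )
    reversal = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    reversal.to_csv("results/sign_reversal.csv", index=False)
    print(reversal.to_string(index=False))

    sd_rows = []
    for var in SD_NARROWED_VARIABLES:
        ref_vals = derive_numeric(reference, cb, var).dropna().to_numpy()
        coh_vals = derive_numeric(cohort, cb, var).to_numpy()
        ok = np.isfinite(coh_vals)
        sd_rows.append(
            {
                "variable": var,
                "sd_reference": float(np.std(ref_vals, ddof=1)),
                "sd_cohort": float(np.std(coh_vals[ok], ddof=1)),
                "sd_weighted": weighted_sd(coh_vals[ok], w[ok]),
            }
        )
    sd_table = pd.DataFrame(sd_rows)
    sd_table.to_csv("results/sd_restoration.csv", index=False)
    print()
    print(sd_table.to_string(index=False))


if __name__ == "__main__":
    main()
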