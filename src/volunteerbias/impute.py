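"""Exact-matching (hot-deck) imputation of missing categorical values.

For each person with missing model variables, the donor pool consists of
persons from the same source table who are complete on all model variables
and match the recipient exactly on every observed model variable. Each
missing value is filled by a uniform random draw from the donor pool's
values for that variable. Persons without any exact donor are excluded with
reason ``"no exact donor"`` — mirroring how a small number of respondents
can remain unimputable in practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def impute_exact_match(
    table: pd.DataFrame,
    model_vars: list[str],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[object, str]]:
    """Impute missing model variables by exact matching within source.

    Returns the imputed table (excluded persons removed) and a map
    ``person_id -> exclusion reason``.
    """
    missing_cols = [v for v in model_vars if v not in table.columns]
    if missing_cols:
        raise KeyError(f"model variables not in table: {missing_cols}")

    rng = np.random.default_rng(seed)
    out = table.copy()
    excluded: dict[object, str] = {}

    sources = (
        out["source"].unique() if "source" in out.columns else np.array([None])
    )
    drop_idx: list[np.ndarray] = []
    for src in sources:
        part = out if src is None else out[out["source"] == src]
        miss = part[model_vars].isna()
        any_miss = miss.any(axis=1)
        if not any_miss.any():
            continue
        donors = part.loc[~any_miss]
        recipients = part.loc[any_miss]
        if donors.empty:
            for pid in recipients.get("person_id", recipients.index):
                excluded[pid] = "no exact donor"
            drop_idx.append(recipients.index.to_numpy())
            continue

        # group recipients by missingness pattern; donors are indexed once
        # per pattern by their values on the pattern's observed variables
        pattern = miss.loc[any_miss]
        pattern_key = pattern.apply(lambda r: tuple(r.index[r]), axis=1)
        for missing_vars, group in recipients.groupby(pattern_key, sort=False):
            missing_vars = list(missing_vars)
            observed_vars = [v for v in model_vars if v not in missing_vars]
            if observed_vars:
                donor_groups = donors.groupby(
                    [donors[v].astype("object") for v in observed_vars],
                    sort=False,
                ).indices
                rec_keys = list(
                    zip(*(group[v].astype("object") for v in observed_vars))
                )
                if len(observed_vars) == 1:
                    rec_keys = [k[0] for k in rec_keys]
            else:
                donor_groups = {None: np.arange(len(donors))}
                rec_keys = [None] * len(group)

            for (row_label, _), key in zip(group.iterrows(), rec_keys):
                pool_pos = donor_groups.get(key)
                if pool_pos is None or len(pool_pos) == 0:
                    pid = (
                        out.at[row_label, "person_id"]
                        if "person_id" in out.columns
                        else row_label
                    )
                    excluded[pid] = "no exact donor"
                    drop_idx.append(np.array([row_label]))
                    continue
                pool = donors.iloc[pool_pos]
                for var in missing_vars:
                    draw = pool[var].iloc[rng.integers(len(pool))]
                    out.at[row_label, var] = draw

    if drop_idx:
        out = out.drop(index=np.concatenate(drop_idx))
    return out, excluded
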