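"""Non-parametric design matrix: full dummies plus all two-way interactions.

Each categorical variable contributes one binary column per level (full dummy
coding — no reference level is dropped; the L1 penalty downstream handles the
induced collinearity), and every pair of distinct variables contributes one
column per level pair. Within-variable level×level interactions are
structurally zero and omitted. Column order is lexicographic in (variable
order, level order) and therefore deterministic.

The matrix is stored sparse (CSR): each person has exactly one active level
per variable, so a table with k variables has k + k(k-1)/2 nonzeros per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from volunteerbias.codebook import Codebook


def main_column_name(var: str, level: str) -> str:
    return f"main:{var}={level}"


def interaction_column_name(var1: str, l1: str, var2: str, l2: str) -> str:
    return f"int:{var1}={l1}×{var2}={l2}"


def expected_column_count(level_counts: list[int]) -> int:
    """Pre-pruning column count: sum(L_k) + sum_{k<l} L_k * L_l."""
    total = sum(level_counts)
    cross = 0
    for i in range(len(level_counts)):
        for j in range(i + 1, len(level_counts)):
            cross += level_counts[i] * level_counts[j]
    return total + cross


@dataclass
class DesignMatrix:
    """Sparse binary design with stable column names and a pruning log."""

    row_ids: np.ndarray
    columns: list[str]
    X: sparse.csr_matrix
    pruned: list[tuple[str, str]] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def subset_columns(self, keep: np.ndarray) -> "DesignMatrix":
        keep = np.asarray(keep)
        return DesignMatrix(
            row_ids=self.row_ids,
            columns=[self.columns[i] for i in keep],
            X=sparse.csr_matrix(self.X[:, keep]),
            pruned=list(self.pruned),
        )

    def drop_variables(self, variables: set[str]) -> "DesignMatrix":
        """Remove every main and interaction column touching the variables."""

        def touches(name: str) -> bool:
            body = name.split(":", 1)[1]
            terms = body.split("×")
            return any(t.partition("=")[0] in variables for t in terms)

        keep = np.array([i for i, c in enumerate(self.columns) if not touches(c)])
        if len(keep) == len(self.columns):
            return self
        return self.subset_columns(keep)

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet export: (row_id, column_name, 1)."""
        coo = self.X.tocoo()
        return pd.DataFrame(
            {
                "row_id": self.row_ids[coo.row],
                "column_name": [self.columns[j] for j in coo.col],
                "value": np.ones(coo.nnz, dtype=int),
            }
        )


def build_design_matrix(
    table: pd.DataFrame,
    codebook: Codebook,
    variables: list[str] | None = None,
    prune: bool = True,
) -> DesignMatrix:
    """Build the dummy + two-way-interaction design for the model variables.

    Raises if any model variable has missing values: imputation must run
    first (see :func:`volunteerbias.impute.impute_exact_match`).
    """
    names = variables if variables is not None else codebook.names
    codes: dict[str, np.ndarray] = {}
    levels: dict[str, list[str]] = {}
    for name in names:
        var = codebook[name]
        col = table[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            cat = col.cat.set_categories(list(var.levels))
        else:
            cat = pd.Categorical(col.astype("object"), categories=list(var.levels))
            cat = pd.Series(cat)
        code = np.asarray(cat.codes if hasattr(cat, "codes") else cat.cat.codes)
        if (code < 0).any():
            n_bad = int((code < 0).sum())
            raise ValueError(
                f"variable {name!r} has {n_bad} missing/undeclared values; "
                "impute before building the design matrix"
            )
        codes[name] = code
        levels[name] = list(var.levels)

    n = len(table)
    col_names: list[str] = []
    col_rows: list[np.ndarray] = []

    # main effects: one dummy per level, in (variable, level) order
    main_rows: dict[tuple[str, str], np.ndarray] = {}
    for name in names:
        for li, level in enumerate(levels[name]):
            rows = np.nonzero(codes[name] == li)[0]
            main_rows[(name, level)] = rows
            col_names.append(main_column_name(name, level))
            col_rows.append(rows)

    # two-way interactions between distinct variables
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            vi, vj = names[i], names[j]
            # joint code identifies the (level_i, level_j) cell per person
            joint = codes[vi].astype(np.int64) * len(levels[vj]) + codes[vj]
            order = np.argsort(joint, kind="stable")
            sorted_joint = joint[order]
            for li, level_i in enumerate(levels[vi]):
                for lj, level_j in enumerate(levels[vj]):
                    cell = li * len(levels[vj]) + lj
                    lo = np.searchsorted(sorted_joint, cell, side="left")
                    hi = np.searchsorted(sorted_joint, cell, side="right")
                    rows = np.sort(order[lo:hi])
                    col_names.append(
                        interaction_column_name(vi, level_i, vj, level_j)
                    )
                    col_rows.append(rows)

    pruned: list[tuple[str, str]] = []
    if prune:
        keep_names: list[str] = []
        keep_rows: list[np.ndarray] = []
        seen: dict[bytes, str] = {}
        for cname, rows in zip(col_names, col_rows):
            if len(rows) == 0 or len(rows) == n:
                pruned.append((cname, "constant"))
                continue
            key = rows.tobytes()
            if key in seen:
                pruned.append((cname, f"duplicate of {seen[key]}"))
                continue
            seen[key] = cname
            keep_names.append(cname)
            keep_rows.append(rows)
        col_names, col_rows = keep_names, keep_rows

    indptr = np.zeros(len(col_names) + 1, dtype=np.int64)
    for k, rows in enumerate(col_rows):
        indptr[k + 1] = indptr[k] + len(rows)
    indices = (
        np.concatenate(col_rows) if col_rows else np.empty(0, dtype=np.int64)
    )
    data = np.ones(len(indices), dtype=np.float64)
    X = sparse.csc_matrix(
        (data, indices, indptr), shape=(n, len(col_names))
    ).tocsr()

    row_ids = (
        table["person_id"].to_numpy()
        if "person_id" in table.columns
        else np.arange(n)
    )
    return DesignMatrix(row_ids=row_ids, columns=col_names, X=X, pruned=pruned)
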