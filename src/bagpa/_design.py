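"""Shared covariate design-matrix construction."""

from __future__ import annotations

import numpy as np
import pandas as pd


def covariate_matrix(table: pd.DataFrame, covariates, add_intercept: bool = True) -> pd.DataFrame:
    """Numeric design matrix for covariate adjustment.

    Categorical (object/category/bool) columns are dummy-coded with the
    first level dropped; numeric columns pass through.  Raises on
    rank-deficient designs, naming the aliased columns.
    """
    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"const": np.ones(len(table))}, index=table.index))
    for col in covariates:
        s = table[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float).to_frame(col))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        cols = list(X.columns)
        kept: list[str] = []
        for c in cols:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"rank-deficient covariate design; aliased columns: {aliased}")
    return X
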