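"""Nuisance-covariate correction and probe filtering.

Covariate correction fits, per probe, an ordinary least-squares linear
model containing the protected factors (by default diagnosis, region and
their interaction, so that all four diagnosis-by-region cell means survive)
together with the nuisance covariates, and subtracts the fitted nuisance
part. Nuisance columns are mean-centered before subtraction, so the grand
mean is preserved exactly and the operation is idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg

DEFAULT_PROTECTED = ("diagnosis", "region", "diagnosis:region")

_RANK_TOL = 1e-8


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient design; collinear columns: " + ", ".join(self.columns)
        )


def _encode_factor(samples: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    """Dummy-code a factor, first level as reference; interaction terms
    (``a:b``) are products of the parts' reference-coded dummies."""
    if ":" in name:
        left, right = name.split(":", 1)
        mat_l, cols_l = _encode_factor(samples, left)
        mat_r, cols_r = _encode_factor(samples, right)
        cols: list[np.ndarray] = []
        names: list[str] = []
        for i, ci in enumerate(cols_l):
            for j, cj in enumerate(cols_r):
                cols.append(mat_l[:, i] * mat_r[:, j])
                names.append(f"{ci}:{cj}")
        return np.column_stack(cols), names
    series = samples[name].astype(str)
    dummies = pd.get_dummies(series, prefix=name, drop_first=True, dtype=float)
    return dummies.to_numpy(), list(dummies.columns)


def _encode_covariate(samples: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    col = samples[name]
    if col.isna().any():
        raise ValueError(f"missing values in covariate {name!r}; no imputation is done")
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None], [name]
    return _encode_factor(samples, name)


def build_design(
    samples: pd.DataFrame,
    nuisance: list[str],
    protected: tuple[str, ...] = DEFAULT_PROTECTED,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Full design [intercept | protected | nuisance]; returns the matrix,
    column names, and a boolean mask marking the nuisance columns."""
    blocks = [np.ones((len(samples), 1))]
    names = ["intercept"]
    is_nuisance = [False]
    for term in protected:
        for part in term.split(":"):
            if part not in samples.columns:
                raise ValueError(f"protected factor {part!r} not in sample table")
        mat, cols = _encode_factor(samples, term)
        blocks.append(mat)
        names.extend(cols)
        is_nuisance.extend([False] * len(cols))
    for name in nuisance:
        if name not in samples.columns:
            raise ValueError(f"nuisance covariate {name!r} not in sample table")
        mat, cols = _encode_covariate(samples, name)
        blocks.append(mat)
        names.extend(cols)
        is_nuisance.extend([True] * len(cols))
    X = np.hstack(blocks)
    return X, names, np.asarray(is_nuisance)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = _RANK_TOL * max(X.shape) * (diag.max() if diag.size else 1.0)
    bad = diag < tol
    if bad.any():
        raise RankDeficientDesignError([names[piv[i]] for i in np.where(bad)[0]])


def correct_covariates(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    nuisance: list[str],
    protected: tuple[str, ...] = DEFAULT_PROTECTED,
) -> pd.DataFrame:
    """Remove nuisance-covariate variation from log2 expression.

    Per probe, fits OLS on [intercept | protected | nuisance] and returns
    the data minus the fitted contribution of the (mean-centered) nuisance
    columns. Protected effects are untouched; row and column order are
    preserved.
    """
    if list(expr.columns) != list(samples["sample_id"]):
        raise ValueError("expression columns do not match sample table order")
    X, names, nuis_mask = build_design(samples, list(nuisance), protected)
    _check_rank(X, names)
    if not nuis_mask.any():
        return expr.copy()
    # center nuisance columns so subtracting their fit preserves the mean
    Xc = X.copy()
    Xc[:, nuis_mask] -= Xc[:, nuis_mask].mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, expr.to_numpy().T, rcond=None)
    removed = Xc[:, nuis_mask] @ coef[nuis_mask, :]
    out = expr.to_numpy() - removed.T
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def restrict_to_named(
    expr: pd.DataFrame, annot: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only probes with a non-missing gene symbol, order preserved.

    Probes sharing a symbol are all retained; uniqueness matters only when
    counting genes during set extraction.
    """
    symbol = annot.set_index("probe_id")["gene_symbol"]
    missing_probes = expr.index.difference(symbol.index)
    if len(missing_probes):
        raise ValueError(
            f"{len(missing_probes)} probes absent from annotation, e.g. "
            f"{list(missing_probes[:5])}"
        )
    aligned = symbol.reindex(expr.index)
    keep = aligned.notna().to_numpy()
    kept_expr = expr.loc[keep]
    kept_annot = pd.DataFrame(
        {"probe_id": kept_expr.index, "gene_symbol": aligned[keep].to_numpy()}
    )
    return kept_expr, kept_annot
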