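"""Principal variance component analysis (PVCA).

Apportions total expression variance among cohort covariates and residual
(random) variation: probes are centered, the sample-sample covariance is
eigendecomposed, the smallest set of leading principal components whose
cumulative eigenvalue fraction reaches a threshold (default 60%) is
retained, and for each retained PC a linear mixed model with every
covariate as an independent random intercept is fit by EM-REML. Each
covariate's variance proportion is then averaged across PCs with
eigenvalue-fraction weights and normalized to sum to one.

Continuous covariates (age, post-mortem interval, pH, RNA integrity) are
discretized into quantile bins (default quartiles) before entering as
grouping factors, since variance-component estimation requires factors.
Only main effects are modeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ror import matched_differences
from .synth import RESISTANT, VULNERABLE

logger = logging.getLogger(__name__)

CORE_COLUMNS = ("sample_id", "case_id", "region", "diagnosis")


@dataclass(frozen=True)
class PVCAResult:
    proportions: dict[str, float]  # covariate -> share of variance, + "residual"
    n_components: int
    threshold: float

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")


def _as_factor(col: pd.Series, n_bins: int) -> pd.Series | None:
    """Quantile-bin continuous covariates; drop single-level factors."""
    if pd.api.types.is_numeric_dtype(col):
        binned = pd.qcut(col, q=n_bins, duplicates="drop")
        col = binned.astype(str)
    col = col.astype(str)
    if col.nunique() < 2:
        return None
    return col


def _em_reml(
    y: np.ndarray, Zs: list[np.ndarray], max_iter: int = 500, tol: float = 1e-8
) -> np.ndarray | None:
    """EM-REML for y = mu + sum_j Z_j u_j + e with independent random
    intercepts u_j ~ N(0, s_j^2 I). Returns [s_1^2 .. s_m^2, s_e^2] or
    None on non-convergence."""
    n = y.size
    m = len(Zs)
    X = np.ones((n, 1))
    var_y = float(np.var(y, ddof=1))
    if var_y == 0:
        return np.array([0.0] * m + [0.0])
    sig = np.full(m + 1, var_y / (m + 1))
    q = [Z.shape[1] for Z in Zs]
    ZZt = [Z @ Z.T for Z in Zs]
    for _ in range(max_iter):
        V = sig[-1] * np.eye(n)
        for j in range(m):
            V += sig[j] * ZZt[j]
        Vi = np.linalg.inv(V)
        ViX = Vi @ X
        P = Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)
        Py = P @ y
        new = np.empty_like(sig)
        for j in range(m):
            if sig[j] == 0:
                new[j] = 0.0
                continue
            ZtPy = Zs[j].T @ Py
            ZtPZ = Zs[j].T @ P @ Zs[j]
            uu = sig[j] ** 2 * float(ZtPy @ ZtPy)
            trace = sig[j] * q[j] - sig[j] ** 2 * float(np.trace(ZtPZ))
            new[j] = max((uu + trace) / q[j], 0.0)
        ee = sig[-1] ** 2 * float(Py @ Py)
        tre = sig[-1] * n - sig[-1] ** 2 * float(np.trace(P))
        new[-1] = max((ee + tre) / n, 0.0)
        if np.max(np.abs(new - sig)) < tol * (1.0 + new.sum()):
            return new
        sig = new
    return None


def run_pvca(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    var_threshold: float = 0.6,
    n_bins: int = 4,
) -> PVCAResult:
    """Variance-proportion decomposition of an expression matrix.

    ``covariates`` defaults to every non-core column of the sample table.
    ``var_threshold`` is the cumulative eigenvalue fraction the retained
    PCs must reach (in (0, 1]).
    """
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must be in (0, 1]")
    if covariates is None:
        covariates = [c for c in samples.columns if c not in CORE_COLUMNS]

    factors: dict[str, pd.Series] = {}
    for name in covariates:
        fac = _as_factor(samples[name], n_bins)
        if fac is None:
            logger.warning("covariate %r has a single level; excluded", name)
            continue
        factors[name] = fac

    Y = expr.to_numpy()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    n = Yc.shape[1]
    S = (Yc.T @ Yc) / (Yc.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(S)
    eigval = np.clip(eigval[::-1], 0.0, None)
    eigvec = eigvec[:, ::-1]
    frac = eigval / eigval.sum()
    k = int(np.searchsorted(np.cumsum(frac), var_threshold) + 1)
    k = max(1, min(k, n))

    names = list(factors)
    Zs = [pd.get_dummies(factors[nm], dtype=float).to_numpy() for nm in names]
    weights = frac[:k] / frac[:k].sum()
    props = np.zeros(len(names) + 1)
    for i in range(k):
        sig = _em_reml(eigvec[:, i], Zs)
        if sig is None:
            logger.warning("EM-REML did not converge on PC %d; set to residual", i + 1)
            pc_prop = np.array([0.0] * len(names) + [1.0])
        else:
            total = sig.sum()
            pc_prop = sig / total if total > 0 else np.array([0.0] * len(names) + [1.0])
        props += weights[i] * pc_prop
    props = props / props.sum()
    proportions = {nm: float(p) for nm, p in zip(names, props[:-1])}
    proportions["residual"] = float(props[-1])
    return PVCAResult(proportions=proportions, n_components=k,
                      threshold=var_threshold)


def _region_subset(expr, samples, region):
    sub = samples[samples["region"] == region].reset_index(drop=True)
    return expr[sub["sample_id"]], sub


def ratio_dataset(
    expr: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-case interregional ratio matrix (log2 difference) with a
    per-case sample table. Demographic covariates come from the individual;
    per-sample quality covariates (pH, RNA integrity) are kept from both
    regions under suffixed names, so the ratio table carries two more
    covariates than each single-region table; batch is taken from the
    vulnerable-region sample."""
    d, diagnosis = matched_differences(expr, samples)
    vul = samples[samples["region"] == VULNERABLE].set_index("case_id")
    res = samples[samples["region"] == RESISTANT].set_index("case_id")
    cases = list(d.columns)
    table = pd.DataFrame({
        "sample_id": cases,
        "case_id": cases,
        "region": "ratio",
        "diagnosis": diagnosis.loc[cases].to_numpy(),
    })
    covs = [c for c in samples.columns if c not in CORE_COLUMNS]
    for name in covs:
        same = (vul.loc[cases, name].to_numpy() == res.loc[cases, name].to_numpy()).all()
        if name == "batch" or same:
            table[name] = vul.loc[cases, name].to_numpy()
        else:
            table[f"{name}_{VULNERABLE}"] = vul.loc[cases, name].to_numpy()
            table[f"{name}_{RESISTANT}"] = res.loc[cases, name].to_numpy()
    d.columns = cases
    return d, table


def pvca_panel(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    var_threshold: float = 0.6,
    n_bins: int = 4,
) -> dict[str, PVCAResult]:
    """Run PVCA on the vulnerable-region, resistant-region, and
    within-case interregional-ratio views of one matched dataset."""
    panels: dict[str, PVCAResult] = {}
    for region in (VULNERABLE, RESISTANT):
        e, s = _region_subset(expr, samples, region)
        panels[region] = run_pvca(e, s, covariates, var_threshold, n_bins)
    d, ratio_samples = ratio_dataset(expr, samples)
    ratio_covs = None
    if covariates is not None:
        ratio_covs = [c for c in ratio_samples.columns if c not in CORE_COLUMNS
                      and (c in covariates or c.rsplit("_", 1)[0] in covariates)]
    panels["ratio"] = run_pvca(d, ratio_samples, ratio_covs, var_threshold, n_bins)
    return panels
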