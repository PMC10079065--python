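"""Ratio-of-ratios statistics, Priority Scores, and set extraction.

The ratio-of-ratios (RoR) contrast compares the disease fold change in the
vulnerable region with that in the resistant region. On matched data the
within-case interregional difference d = log2(vulnerable) - log2(resistant)
is formed first and a single two-sample (case vs control) test is run on d:

    logRoR = mean(d | case) - mean(d | control)

On unmatched data the algebraically identical rearrangement
logRoR = logFC_vulnerable - logFC_resistant is used, with standard errors
combined in quadrature and Welch-Satterthwaite degrees of freedom.

Positive logRoR marks disease-dependent increases in the vulnerable region
relative to the resistant one; negative logRoR marks increases in the
resistant region relative to the vulnerable one.

The desirability-function Priority Score P compares a probe's magnitude
rank under the region-only contrast (rank_fc, 1 = largest |logFC|) with
its rank under RoR (rank_ror): P = rank_fc / rank_ror, log10 scale, so
log P > 0 marks probes amplified by RoR ("contrasting") and log P < 0
probes dampened by RoR ("parallel"). Set 1 collects the top-limb probes
confirmed contrasting by the RoR test (p < alpha); Set 2 the bottom-limb
probes whose RoR test stays non-significant (p >= alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import diffexp
from .synth import CASE, RESISTANT, VULNERABLE


def matched_differences(
    expr: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-case interregional difference d = vulnerable - resistant.

    Returns (d, diagnosis): d is probe x case, columns in case order of
    first appearance; diagnosis gives each case's label.
    """
    counts = samples.groupby("case_id", sort=False)["region"].agg(
        lambda r: tuple(sorted(r))
    )
    bad = counts[counts != (RESISTANT, VULNERABLE)]
    if len(bad):
        raise ValueError(
            "unmatched cases (need exactly one sample per region): "
            + ", ".join(map(str, bad.index[:10]))
        )
    cases = samples["case_id"].drop_duplicates().tolist()
    by = samples.set_index(["case_id", "region"])["sample_id"]
    vul_cols = [by[(c, VULNERABLE)] for c in cases]
    res_cols = [by[(c, RESISTANT)] for c in cases]
    d = pd.DataFrame(
        expr[vul_cols].to_numpy() - expr[res_cols].to_numpy(),
        index=expr.index,
        columns=cases,
    )
    diagnosis = samples.drop_duplicates("case_id").set_index("case_id")["diagnosis"]
    return d, diagnosis.loc[cases]


def ror_matched(
    d: pd.DataFrame,
    diagnosis: pd.Series,
    params: diffexp.ModerationParams | None = None,
) -> pd.DataFrame:
    """RoR table from matched differences: one moderated two-sample t on d
    between diagnosis groups per probe, BH q over all probes."""
    is_case = (diagnosis.loc[d.columns] == CASE).to_numpy()
    effect, s2, df, se_factor = diffexp.two_group_stats(d.to_numpy(), is_case)
    if params is None:
        params = diffexp.fit_variance_prior(s2, df)
    mod = diffexp.moderated_t(effect, s2, df, params, se_factor)
    out = pd.DataFrame({"probe_id": d.index, "logRoR": effect, "s2": s2,
                        "df_residual": df})
    out = pd.concat([out, mod], axis=1)
    out["q"] = diffexp.bh_adjust(out["p"].to_numpy())
    out.attrs["params"] = params
    return out


def ror_unmatched(fc_vul: pd.DataFrame, fc_res: pd.DataFrame) -> pd.DataFrame:
    """RoR table from two independent region contrasts:
    logRoR = logFC_vul - logFC_res, SEs combined in quadrature,
    Welch-Satterthwaite df on the moderated variances."""
    if list(fc_vul["probe_id"]) != list(fc_res["probe_id"]):
        raise ValueError("contrast tables cover different probe universes")
    logror = fc_vul["logFC"].to_numpy() - fc_res["logFC"].to_numpy()
    se_v = fc_vul["se"].to_numpy()
    se_r = fc_res["se"].to_numpy()
    df_v = fc_vul["df_total"].to_numpy(dtype=float)
    df_r = fc_res["df_total"].to_numpy(dtype=float)
    se2 = se_v**2 + se_r**2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / (se_v**4 / df_v + se_r**4 / df_r)
        t = logror / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame(
        {
            "probe_id": fc_vul["probe_id"].to_numpy(),
            "logRoR": logror,
            "t_mod": t,
            "df_total": df,
            "p": p,
            "se": se,
        }
    )
    out["q"] = diffexp.bh_adjust(p)
    return out


def _magnitude_rank(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest magnitude; ties receive average ranks."""
    return stats.rankdata(-np.abs(values), method="average")


def priority_scores(fc: pd.DataFrame, ror: pd.DataFrame) -> pd.DataFrame:
    """Per-probe Priority Score table, sorted by probe id.

    rank_fc and rank_ror are magnitude ranks of |logFC| and |logRoR|;
    P = rank_fc / rank_ror, logP = log10 P. The output order (probe id) is
    canonical, so the table is invariant to the input probe order.
    """
    if len(fc) == 0 or len(ror) == 0:
        raise ValueError("empty contrast table")
    if set(fc["probe_id"]) != set(ror["probe_id"]):
        raise ValueError("contrast tables cover different probe universes")
    fc = fc.sort_values("probe_id", kind="mergesort")
    ror = ror.sort_values("probe_id", kind="mergesort")
    rank_fc = _magnitude_rank(fc["logFC"].to_numpy())
    rank_ror = _magnitude_rank(ror["logRoR"].to_numpy())
    P = rank_fc / rank_ror
    return pd.DataFrame(
        {
            "probe_id": fc["probe_id"].to_numpy(),
            "rank_fc": rank_fc,
            "rank_ror": rank_ror,
            "P": P,
            "logP": np.log10(P),
        }
    )


@dataclass(frozen=True)
class GeneSetResult:
    """Contrasting (Set 1) and parallel (Set 2) probe and gene lists."""

    set1_probes: tuple[str, ...]
    set2_probes: tuple[str, ...]
    set1_genes: tuple[str, ...]
    set2_genes: tuple[str, ...]
    parameters: dict = field(default_factory=dict)


def extract_sets(
    priority: pd.DataFrame,
    ror: pd.DataFrame,
    annot: pd.DataFrame,
    n_limb: int = 500,
    alpha: float = 0.05,
    p_basis: str = "p",
) -> GeneSetResult:
    """Extract Set 1 and Set 2 from the priority-curve limbs.

    Set 1: the ``n_limb`` probes with the largest logP, kept where the RoR
    test confirms contrast (p < alpha). Set 2: the ``n_limb`` probes with
    the smallest logP, kept where the RoR test stays non-significant
    (p >= alpha). ``p_basis`` selects the raw moderated p ("p", default)
    or the BH-adjusted q ("q") for both filters. Gene lists are the
    distinct annotated symbols of each probe list.
    """
    n = len(priority)
    if n_limb > n // 2:
        raise ValueError(f"n_limb={n_limb} exceeds half the probe universe ({n})")
    if p_basis not in ("p", "q"):
        raise ValueError("p_basis must be 'p' or 'q'")
    pvals = ror.set_index("probe_id")[p_basis]
    # deterministic ordering: logP, then probe id
    ordered = priority.sort_values(
        ["logP", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    top = ordered.head(n_limb)
    bottom = ordered.tail(n_limb)
    set1 = tuple(p for p in top["probe_id"] if pvals[p] < alpha)
    set2 = tuple(p for p in bottom["probe_id"] if pvals[p] >= alpha)
    symbol = annot.set_index("probe_id")["gene_symbol"]

    def genes(probes):
        seen: dict[str, None] = {}
        for pr in probes:
            sym = symbol.get(pr)
            if pd.notna(sym):
                seen.setdefault(sym)
        return tuple(seen)

    return GeneSetResult(
        set1_probes=set1,
        set2_probes=set2,
        set1_genes=genes(set1),
        set2_genes=genes(set2),
        parameters={"n_limb": n_limb, "alpha": alpha, "p_basis": p_basis},
    )
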