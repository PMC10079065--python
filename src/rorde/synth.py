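"""Synthetic matched two-region case-control cohorts with planted signals.

The generator emulates a post-mortem brain expression study in which every
individual contributes one sample from a disease-vulnerable region
(prefrontal cortex) and one from a disease-resistant region (cerebellum),
so that within-case interregional ratios can be formed. Expression values
are already-normalized log2 intensities; per-gene residual variances follow
a scaled inverse chi-square prior (the empirical-Bayes model under which
the moderated t-statistic is exact), and disease effects are planted as
additive log2 shifts in one of five classes:

``contrasting_resistant_up``   up in the resistant region only
``contrasting_vulnerable_up``  up in the vulnerable region only
``parallel_up`` / ``parallel_down``  equal shift in both regions
``null``                       no disease effect

Demographic covariates (age, sex, post-mortem interval, preservation
method) are drawn once per individual and shared by both of their samples;
sample-quality covariates (pH, RNA integrity number) are drawn per sample;
batch is assigned round-robin over samples. Covariate effects on
expression are per-gene random coefficients, except batch, which is a
per-batch offset shared across genes with a per-gene positive scaling —
a low-rank structure that dominates sample-to-sample covariance the way
hybridization batches dominate real microarray data.

All randomness derives from a single integer seed, split hierarchically
by purpose, so e.g. adding a covariate does not perturb the gene noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VULNERABLE = "vulnerable"
RESISTANT = "resistant"
REGIONS = (VULNERABLE, RESISTANT)
CASE = "case"
CONTROL = "control"

PLANTED_CLASSES = (
    "contrasting_resistant_up",
    "contrasting_vulnerable_up",
    "parallel_up",
    "parallel_down",
    "null",
)

# purpose codes for hierarchical RNG splitting
_PURPOSE = {
    "cohort": 11,
    "baseline": 23,
    "sigma": 31,
    "noise": 47,
    "covariate": 59,
}


def _rng(seed: int, purpose: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), _PURPOSE[purpose], int(index)))
    )


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate of the cohort and the scale of its expression effect.

    ``effect_sd`` is the standard deviation, in log2 units, of the additive
    per-level effect (categorical) or of the per-unit slope (continuous,
    natural units: age in years, post-mortem interval in hours).
    ``per_sample`` marks sample-quality covariates drawn independently for
    each sample rather than once per individual.
    """

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] | None = None
    range: tuple[float, float] | None = None
    effect_sd: float = 0.0
    per_sample: bool = False

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(f"categorical covariate {self.name!r} needs >=2 levels")
        else:
            if self.range is None or not self.range[0] < self.range[1]:
                raise ValueError(f"continuous covariate {self.name!r} needs min < max")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")


def default_covariates(n_batches: int = 8) -> list[CovariateSpec]:
    """The seven covariates of the emulated cohort, with effect scales
    chosen so that batch dominates non-random variance while demographic
    and quality covariates contribute visibly but modestly."""
    return [
        CovariateSpec("age", "continuous", range=(60.0, 95.0), effect_sd=0.004),
        CovariateSpec("sex", "categorical", levels=("F", "M"), effect_sd=0.10),
        CovariateSpec("pmi", "continuous", range=(2.0, 30.0), effect_sd=0.006),
        CovariateSpec("ph", "continuous", range=(5.8, 7.2), effect_sd=0.12,
                      per_sample=True),
        CovariateSpec("rin", "continuous", range=(5.0, 9.0), effect_sd=0.05,
                      per_sample=True),
        CovariateSpec("preservation", "categorical", levels=("frozen", "fixed"),
                      effect_sd=0.10),
        CovariateSpec("batch", "categorical",
                      levels=tuple(f"b{i + 1}" for i in range(n_batches)),
                      effect_sd=0.40),
    ]


@dataclass(frozen=True)
class PlantedSpec:
    """Planted disease-effect classes.

    ``delta`` maps class name to the additive log2 effect in
    (vulnerable, resistant) region, applied to case samples only.
    """

    n_per_class: int = 200
    classes: tuple[str, ...] = PLANTED_CLASSES
    delta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "contrasting_resistant_up": (0.0, 1.0),
            "contrasting_vulnerable_up": (1.0, 0.0),
            "parallel_up": (1.0, 1.0),
            "parallel_down": (-1.0, -1.0),
            "null": (0.0, 0.0),
        }
    )

    def __post_init__(self):
        unknown = set(self.classes) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        for cls in self.classes:
            dv, dr = self.delta[cls]
            if cls.startswith("parallel"):
                if dv != dr or dv == 0:
                    raise ValueError(f"{cls}: parallel deltas must be equal and nonzero")
            elif cls == "contrasting_resistant_up":
                if dv != 0 or dr <= 0:
                    raise ValueError(f"{cls}: delta must be (0, +x)")
            elif cls == "contrasting_vulnerable_up":
                if dr != 0 or dv <= 0:
                    raise ValueError(f"{cls}: delta must be (+x, 0)")
            elif cls == "null":
                if (dv, dr) != (0.0, 0.0):
                    raise ValueError("null class must have delta (0, 0)")

    @property
    def n_planted(self) -> int:
        return self.n_per_class * len([c for c in self.classes if c != "null"]) + (
            self.n_per_class if "null" in self.classes else 0
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Scaled-inverse-chi-square prior on per-gene residual variance:
    sigma^2_g ~ s0_sq * d0 / chi2(d0)."""

    d0: float = 4.0
    s0_sq: float = 0.05

    def __post_init__(self):
        if not self.d0 > 0 or not self.s0_sq > 0:
            raise ValueError("d0 and s0_sq must be positive")


def generate_cohort(
    n_case: int,
    n_control: int,
    covariates: Sequence[CovariateSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Matched cohort: one vulnerable- and one resistant-region sample per
    individual, sharing case id, diagnosis, and demographic covariates.

    Returns a sample table with 2*(n_case + n_control) rows and columns
    sample_id, case_id, region, diagnosis, then one column per covariate.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    if covariates is None:
        covariates = default_covariates()
    names = [c.name for c in covariates]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate covariate names in {names}")

    rng = _rng(seed, "cohort")
    n_ind = n_case + n_control
    case_ids = [f"I{i + 1:04d}" for i in range(n_ind)]
    diagnosis = [CASE] * n_case + [CONTROL] * n_control

    rows: list[dict] = []
    for i, cid in enumerate(case_ids):
        for region in REGIONS:
            rows.append(
                {
                    "sample_id": f"{cid}_{region[:3]}",
                    "case_id": cid,
                    "region": region,
                    "diagnosis": diagnosis[i],
                }
            )
    table = pd.DataFrame(rows)

    for cov in covariates:
        if cov.name == "batch":
            # round-robin over individuals, resistant sample shifted by one
            # so batch parity is not confounded with region
            levels = cov.levels
            ind_idx = np.repeat(np.arange(n_ind), 2)
            reg_idx = np.tile([0, 1], n_ind)
            table[cov.name] = [
                levels[(i + r) % len(levels)] for i, r in zip(ind_idx, reg_idx)
            ]
            continue
        n_draw = len(table) if cov.per_sample else n_ind
        if cov.kind == "continuous":
            lo, hi = cov.range
            vals = np.round(rng.uniform(lo, hi, size=n_draw), 3)
        else:
            vals = rng.choice(np.asarray(cov.levels, dtype=object), size=n_draw)
        if cov.per_sample:
            table[cov.name] = vals
        else:
            per_ind = dict(zip(case_ids, vals))
            table[cov.name] = table["case_id"].map(per_ind)
    return table


def _assign_classes(n_genes: int, planted: PlantedSpec) -> np.ndarray:
    n_explicit = planted.n_per_class * len(planted.classes)
    if n_explicit > n_genes:
        raise ValueError(
            f"{n_explicit} planted genes exceed n_genes={n_genes}"
        )
    labels = np.full(n_genes, "null", dtype=object)
    pos = 0
    for cls in planted.classes:
        labels[pos : pos + planted.n_per_class] = cls
        pos += planted.n_per_class
    return labels


def generate_expression(
    samples: pd.DataFrame,
    n_genes: int,
    planted: PlantedSpec | None = None,
    noise: NoiseSpec | None = None,
    covariates: Sequence[CovariateSpec] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a probe x sample log2 expression matrix plus ground truth.

    Model per gene g and sample s:

        y[g,s] = mu_g + r_g * 1[region=vulnerable] + sum_c effect_c(g, s)
                 + delta_{class(g), region(s)} * 1[diagnosis=case] + eps[g,s]

    with eps ~ N(0, sigma^2_g), sigma^2_g ~ s0_sq * d0 / chi2(d0).

    Covariate effects are taken from the expression-effect model described
    in the module docstring; ``covariates`` must list the specs whose
    columns appear in ``samples`` (pass ``[]`` to plant no covariate
    effects). Returns ``(expression, truth)`` where truth records, per
    gene, the class label, the planted (delta_vul, delta_res), sigma_sq,
    and the seed.
    """
    if len(samples) == 0:
        raise ValueError("empty sample table")
    planted = planted or PlantedSpec()
    noise = noise or NoiseSpec()
    if covariates is None:
        covariates = default_covariates()

    n_samples = len(samples)
    probe_ids = [f"P{i + 1:06d}" for i in range(n_genes)]

    labels = _assign_classes(n_genes, planted)
    delta_vul = np.array([planted.delta.get(c, (0.0, 0.0))[0] for c in labels])
    delta_res = np.array([planted.delta.get(c, (0.0, 0.0))[1] for c in labels])

    rng_base = _rng(seed, "baseline")
    mu = rng_base.normal(7.0, 1.0, size=n_genes)
    region_offset = rng_base.normal(0.0, 0.5, size=n_genes)

    sigma_sq = noise.s0_sq * noise.d0 / _rng(seed, "sigma").chisquare(
        noise.d0, size=n_genes
    )

    is_vul = (samples["region"] == VULNERABLE).to_numpy()
    is_case = (samples["diagnosis"] == CASE).to_numpy()

    y = mu[:, None] + np.outer(region_offset, is_vul)
    y += np.where(is_case, 1.0, 0.0) * np.where(
        is_vul, delta_vul[:, None], delta_res[:, None]
    )

    for idx, cov in enumerate(covariates):
        if cov.effect_sd == 0:
            continue
        rng_c = _rng(seed, "covariate", idx)
        vals = samples[cov.name]
        if cov.name == "batch":
            # per-batch offset shared across genes, scaled per gene
            levels = list(cov.levels)
            offsets = rng_c.normal(0.0, cov.effect_sd, size=len(levels))
            scale = rng_c.lognormal(0.0, 0.25, size=n_genes)
            per_sample = np.array([offsets[levels.index(v)] for v in vals])
            y += np.outer(scale, per_sample)
        elif cov.kind == "categorical":
            levels = list(cov.levels)
            beta = rng_c.normal(0.0, cov.effect_sd, size=(n_genes, len(levels)))
            ind = np.array([levels.index(v) for v in vals])
            y += beta[:, ind]
        else:
            x = vals.to_numpy(dtype=float)
            x = x - x.mean()
            beta = rng_c.normal(0.0, cov.effect_sd, size=n_genes)
            y += np.outer(beta * 1.0, x)

    eps = _rng(seed, "noise").normal(0.0, 1.0, size=(n_genes, n_samples))
    y += eps * np.sqrt(sigma_sq)[:, None]

    expr = pd.DataFrame(y, index=pd.Index(probe_ids, name="probe_id"),
                        columns=samples["sample_id"].to_numpy())
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_class": labels,
            "delta_vul": delta_vul,
            "delta_res": delta_res,
            "sigma_sq": sigma_sq,
            "seed": seed,
        }
    )
    return expr, truth


def default_annotation(expr: pd.DataFrame, n_unnamed: int = 0) -> pd.DataFrame:
    """One named gene symbol per probe (synthetic probes map 1:1 to genes);
    optionally leave the last ``n_unnamed`` probes without a symbol."""
    probes = list(expr.index)
    symbols: list[object] = [f"GENE{i + 1:06d}" for i in range(len(probes))]
    for i in range(len(probes) - n_unnamed, len(probes)):
        symbols[i] = pd.NA
    return pd.DataFrame({"probe_id": probes, "gene_symbol": symbols})
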