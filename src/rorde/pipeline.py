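"""End-to-end pipeline: simulate/load -> correct -> (PVCA) -> per-region
contrasts -> RoR -> Priority Scores -> Set 1/Set 2 -> optional enrichment.

Every output file carries a header with the configuration hash, seed and
software version; rerunning with an identical configuration reproduces
byte-identical files. Matched mode (within-case ratios) is the default
and is selected automatically whenever every case has one sample per
region; otherwise the unmatched rearrangement of the RoR statistic is
used, with a logged notice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, _io, diffexp, enrichment, preprocess, pvca, ror, synth
from .synth import RESISTANT, VULNERABLE

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the emulated study where it
    states one (var_threshold 0.6, n_limb 500, alpha 0.05, universe 25,000).
    """

    output_dir: str = "rorde_out"
    seed: int = 0
    # inputs (real-data mode); ignored when simulate=True
    expression: str | None = None
    samples: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None  # GMT of reference sets for enrichment
    # simulation mode
    simulate: bool = False
    n_case: int = 129
    n_control: int = 101
    n_genes: int = 25_000
    n_per_class: int = 200
    delta: float = 1.0
    d0: float = 4.0
    s0_sq: float = 0.05
    # stage parameters
    nuisance: list[str] | None = None  # None -> all covariate columns
    protected: tuple[str, ...] = preprocess.DEFAULT_PROTECTED
    run_pvca: bool = False
    var_threshold: float = 0.6
    n_limb: int = 500
    alpha: float = 0.05
    p_basis: str = "p"
    universe: int = 25_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if "protected" in raw:
            cfg.protected = tuple(raw["protected"])
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _planted_spec(cfg: RunConfig) -> synth.PlantedSpec:
    m = cfg.delta
    return synth.PlantedSpec(
        n_per_class=cfg.n_per_class,
        delta={
            "contrasting_resistant_up": (0.0, m),
            "contrasting_vulnerable_up": (m, 0.0),
            "parallel_up": (m, m),
            "parallel_down": (-m, -m),
            "null": (0.0, 0.0),
        },
    )


def simulate_inputs(cfg: RunConfig):
    """Generate cohort, expression, truth and a 1:1 named annotation."""
    covs = synth.default_covariates()
    samples = synth.generate_cohort(cfg.n_case, cfg.n_control, covs, seed=cfg.seed)
    expr, truth = synth.generate_expression(
        samples,
        cfg.n_genes,
        planted=_planted_spec(cfg),
        noise=synth.NoiseSpec(cfg.d0, cfg.s0_sq),
        covariates=covs,
        seed=cfg.seed,
    )
    annot = synth.default_annotation(expr)
    return expr, samples, annot, truth


def _is_matched(samples) -> bool:
    per_case = samples.groupby("case_id")["region"].agg(lambda r: tuple(sorted(r)))
    return bool((per_case == (RESISTANT, VULNERABLE)).all())


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute all stages; returns a manifest of output artifact paths.

    On stage failure, partially written outputs are removed and the error
    is re-raised with the failing stage named.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config": cfg.digest(), "seed": cfg.seed, "version": __version__}
    manifest: dict[str, str] = {}
    written: list[Path] = []

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path, meta)
        written.append(path)
        manifest[name.split(".")[0]] = str(path)

    stage = "inputs"
    try:
        if cfg.simulate:
            expr, samples, annot, truth = simulate_inputs(cfg)
            emit("expression.tsv", _io.write_expression, expr)
            emit("samples.tsv", lambda df, p, m: _io.write_table(df, p, m), samples)
            emit("annotation.tsv", lambda df, p, m: _io.write_table(df, p, m), annot)
            emit("truth.tsv", lambda df, p, m: _io.write_table(df, p, m), truth)
        else:
            if not (cfg.expression and cfg.samples and cfg.annotation):
                raise ValueError(
                    "real-data mode needs expression, samples and annotation paths"
                )
            expr = _io.read_expression(cfg.expression)
            samples = _io.read_table(cfg.samples)
            annot = _io.read_annotation(cfg.annotation)

        stage = "restrict_to_named"
        expr, annot = preprocess.restrict_to_named(expr, annot)

        stage = "correct_covariates"
        nuisance = cfg.nuisance
        if nuisance is None:
            nuisance = [c for c in samples.columns if c not in pvca.CORE_COLUMNS]
        corrected = preprocess.correct_covariates(
            expr, samples, nuisance, cfg.protected
        )
        emit("corrected.tsv", _io.write_expression, corrected)

        if cfg.run_pvca:
            stage = "pvca"
            rows = []
            for label, data in (("before", expr), ("after", corrected)):
                panel = pvca.pvca_panel(data, samples, var_threshold=cfg.var_threshold)
                for dataset, result in panel.items():
                    for covariate, prop in result.proportions.items():
                        rows.append((label, dataset, covariate, prop))
            import pandas as pd

            emit(
                "pvca.tsv",
                lambda df, p, m: _io.write_table(df, p, m),
                pd.DataFrame(rows, columns=["stage", "dataset", "covariate",
                                            "proportion"]),
            )

        stage = "differential_expression"
        fc_vul = diffexp.region_contrast(corrected, samples, VULNERABLE)
        fc_res = diffexp.region_contrast(corrected, samples, RESISTANT)
        emit("contrast_vulnerable.tsv", lambda df, p, m: _io.write_table(df, p, m),
             fc_vul)
        emit("contrast_resistant.tsv", lambda df, p, m: _io.write_table(df, p, m),
             fc_res)

        stage = "ror"
        if _is_matched(samples):
            d, diagnosis = ror.matched_differences(corrected, samples)
            ror_table = ror.ror_matched(d, diagnosis)
        else:
            logger.info("case ids do not pair across regions; using unmatched RoR")
            ror_table = ror.ror_unmatched(fc_vul, fc_res)
        emit("ror.tsv", lambda df, p, m: _io.write_table(df, p, m), ror_table)

        stage = "priority"
        priority = ror.priority_scores(fc_vul, ror_table)
        emit("priority.tsv", lambda df, p, m: _io.write_table(df, p, m), priority)

        stage = "sets"
        sets = ror.extract_sets(
            priority, ror_table, annot, cfg.n_limb, cfg.alpha, cfg.p_basis
        )
        import pandas as pd

        emit(
            "sets.tsv",
            lambda df, p, m: _io.write_table(df, p, m),
            pd.DataFrame(
                [("set1", pr) for pr in sets.set1_probes]
                + [("set2", pr) for pr in sets.set2_probes],
                columns=["set", "probe_id"],
            ),
        )
        for name, genes in (("set1", sets.set1_genes), ("set2", sets.set2_genes)):
            path = outdir / f"{name}_genes.txt"
            _io.write_gene_list(genes, path)
            written.append(path)
            manifest[f"{name}_genes"] = str(path)
        _io.write_gmt(
            {"set1_contrasting": sets.set1_genes, "set2_parallel": sets.set2_genes},
            outdir / "sets.gmt",
        )
        written.append(outdir / "sets.gmt")
        manifest["sets_gmt"] = str(outdir / "sets.gmt")

        if cfg.gene_sets:
            stage = "enrichment"
            refs = enrichment.genesets_from_gmt(_io.read_gmt(cfg.gene_sets))
            query = [
                enrichment.GeneSet("set1_contrasting", sets.set1_genes, "rorde"),
                enrichment.GeneSet("set2_parallel", sets.set2_genes, "rorde"),
            ]
            table = enrichment.overlap_matrix(query, refs, cfg.universe)
            emit("enrichment.tsv", lambda df, p, m: _io.write_table(df, p, m), table)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"meta": meta, "artifacts": manifest}, fh, indent=2, sort_keys=True)
    manifest["manifest"] = str(outdir / "manifest.json")
    return manifest
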