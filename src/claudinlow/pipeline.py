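"""End-to-end orchestration: simulate/load -> preprocess -> subtype -> DE ->
enrichment -> survival meta-analysis, with a deterministic run manifest.

One pipeline runs per cohort with a final cross-cohort meta-analysis stage,
mirroring per-dataset analyses that feed a single forest plot. The resolved
configuration, the seed, the package version, and a SHA-256 checksum of every
output file are written to ``manifest.json``; identical config + inputs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexp import filter_degs, moderated_t
from .enrichment import permutation_significance, rank_genes
from .io import (
    CL_LABEL,
    ExpressionMatrix,
    LabeledReference,
    load_cl_signature,
    load_toy_gene_sets,
    read_clinical,
    read_expression,
    read_gmt,
    write_expression,
)
from .preprocess import log2_transform, quantile_normalize
from .simulate import GENERATOR_NAME, SimulationConfig, Study, simulate_study
from .subtyping import assign_subtype, build_centroids, ward_cluster
from .survival import cox_fit, forest_table, meta_pool

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the failing stage is named and partial outputs kept."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``inputs`` (paths)
    must be provided. ``inputs`` is a mapping with a ``cohorts`` list of
    ``{name, expression, clinical}`` paths and an optional ``reference`` of
    ``{expression, labels}`` paths.
    """

    outdir: str = "claudinlow_run"
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict | None = None
    log2: bool = False
    pseudocount: float = 1.0
    quantile: bool = True
    subtyping: str = "both"  # centroid | cluster | both
    k: int = 2
    cl_threshold: float = 1.0
    de_mode: str = "results"
    gene_sets: str | None = "builtin:toy"  # GMT path, 'builtin:toy', or None
    n_perm: int = 1000
    meta_model: str = "random"

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'simulate' or 'inputs'")
        if self.subtyping not in ("centroid", "cluster", "both"):
            raise ValueError(f"unknown subtyping mode {self.subtyping!r}")
        if self.de_mode not in ("methods", "results"):
            raise ValueError(f"unknown DE mode {self.de_mode!r}")
        if self.meta_model not in ("fixed", "random"):
            raise ValueError(f"unknown meta model {self.meta_model!r}")
        if self.gene_sets not in (None, "builtin:toy") and not Path(self.gene_sets).exists():
            raise ValueError(f"gene set GMT not found: {self.gene_sets}")
        if self.subtyping in ("centroid", "both") and self.inputs is not None:
            if "reference" not in self.inputs:
                raise ValueError("centroid subtyping requires a reference panel")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig) -> Study:
    from .simulate import Cohort

    inputs = config.inputs
    cohorts = []
    for spec in inputs["cohorts"]:
        expression = read_expression(spec["expression"])
        clinical = read_clinical(spec["clinical"])
        cohorts.append(
            Cohort(
                name=spec["name"],
                expression=expression,
                labels=pd.Series(dtype=object),
                clinical=clinical,
            )
        )
    panel = None
    if "reference" in inputs:
        matrix = read_expression(inputs["reference"]["expression"])
        labels = (
            pd.read_csv(inputs["reference"]["labels"], sep="\t")
            .set_index("sample_id")["label"]
        )
        gene_list = inputs["reference"].get("gene_list") or load_cl_signature().genes
        panel = LabeledReference(matrix, labels, list(gene_list))
    return Study(
        panel=panel,
        panel_labels=panel.labels if panel is not None else pd.Series(dtype=object),
        cohorts=cohorts,
        metadata={"source": "files"},
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signature = load_cl_signature()
    stage_log: list[str] = []
    outputs: list[Path] = []

    def _write_tsv(frame: pd.DataFrame, name: str, index: bool = True) -> Path:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=index)
        outputs.append(path)
        return path

    # -- stage: data -------------------------------------------------------
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            study = simulate_study(sim)
            stage_log.append(
                f"simulate: {sim.n_cohorts} cohorts x {sim.n_samples} samples, "
                f"{sim.n_genes} genes, cl_fraction={sim.cl_fraction}, "
                f"delta={sim.effect_size}, generator={GENERATOR_NAME}"
            )
            for cohort in study.cohorts:
                path = outdir / f"{cohort.name}_expression.tsv"
                write_expression(cohort.expression, path)
                outputs.append(path)
                _write_tsv(cohort.clinical, f"{cohort.name}_clinical.tsv", index=False)
                _write_tsv(cohort.labels.to_frame(), f"{cohort.name}_truth.tsv")
            if study.panel is not None:
                path = outdir / "panel_expression.tsv"
                write_expression(study.panel.matrix, path)
                outputs.append(path)
                _write_tsv(study.panel.labels.to_frame("label"), "panel_labels.tsv")
        else:
            study = _load_inputs(config)
            stage_log.append(f"load: {len(study.cohorts)} cohorts from files")
    except Exception as exc:
        raise PipelineError("data", exc) from exc

    # -- stage: preprocess -------------------------------------------------
    try:
        for cohort in study.cohorts:
            matrix = cohort.expression
            if config.log2:
                matrix = log2_transform(matrix, pseudocount=config.pseudocount)
            if config.quantile:
                matrix = quantile_normalize(matrix)
            cohort.expression = matrix
        panel = study.panel
        if panel is not None and config.quantile:
            panel = LabeledReference(
                quantile_normalize(panel.matrix), panel.labels, panel.gene_list
            )
        stage_log.append(
            f"preprocess: log2={config.log2}, quantile={config.quantile}, per cohort"
        )
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc

    # -- stage: subtype ----------------------------------------------------
    calls_by_cohort: dict[str, pd.Series] = {}
    concordance_rows = []
    try:
        model = None
        if config.subtyping in ("centroid", "both"):
            model = build_centroids(panel, gene_list=signature.genes)
            stage_log.append(
                f"centroids: {len(model.gene_list)} genes kept, "
                f"{len(model.missing_genes)} missing, groups "
                f"CL={model.n_cl}/other={model.n_other}"
            )
        for cohort in study.cohorts:
            centroid_calls = cluster_calls = None
            if model is not None:
                table = assign_subtype(model, cohort.expression)
                _write_tsv(table, f"{cohort.name}_calls_centroid.tsv")
                centroid_calls = table["label"]
            if config.subtyping in ("cluster", "both"):
                result = ward_cluster(
                    cohort.expression,
                    signature,
                    k=config.k,
                    threshold=config.cl_threshold,
                )
                cluster_calls = result.calls
                frame = cluster_calls.to_frame("label")
                frame["cluster"] = result.labels
                frame["cluster_score"] = result.labels.map(result.cluster_scores)
                _write_tsv(frame, f"{cohort.name}_calls_cluster.tsv")
                stage_log.append(
                    f"{cohort.name}: cl_cluster={result.cl_cluster}, scores="
                    + ",".join(
                        f"{c}:{s:.3f}" for c, s in sorted(result.cluster_scores.items())
                    )
                )
            final = cluster_calls if cluster_calls is not None else centroid_calls
            calls_by_cohort[cohort.name] = final
            _write_tsv(final.to_frame("label"), f"{cohort.name}_calls.tsv")
            if centroid_calls is not None and cluster_calls is not None:
                agree = float((centroid_calls == cluster_calls).mean())
                concordance_rows.append(
                    {
                        "cohort": cohort.name,
                        "agreement": agree,
                        "n_cl_centroid": int((centroid_calls == CL_LABEL).sum()),
                        "n_cl_cluster": int((cluster_calls == CL_LABEL).sum()),
                    }
                )
        if concordance_rows:
            _write_tsv(pd.DataFrame(concordance_rows), "concordance.tsv", index=False)
    except Exception as exc:
        raise PipelineError("subtype", exc) from exc

    # -- stage: differential expression + enrichment -----------------------
    try:
        if config.gene_sets == "builtin:toy":
            gene_sets = load_toy_gene_sets()
        elif config.gene_sets is not None:
            gene_sets = read_gmt(config.gene_sets)
        else:
            gene_sets = None
        for cohort in study.cohorts:
            calls = calls_by_cohort[cohort.name]
            n_cl = int((calls == CL_LABEL).sum())
            if n_cl < 2 or len(calls) - n_cl < 2:
                stage_log.append(
                    f"{cohort.name}: DE skipped ({n_cl} CL calls of {len(calls)})"
                )
                continue
            de = moderated_t(cohort.expression, calls)
            _write_tsv(de, f"{cohort.name}_de.tsv")
            degs = filter_degs(de, mode=config.de_mode)
            _write_tsv(degs, f"{cohort.name}_degs.tsv")
            stage_log.append(
                f"{cohort.name}: {len(degs)} DEGs in mode {config.de_mode!r} "
                f"({int((degs['direction'] == 'up').sum())} up)"
            )
            if gene_sets is not None:
                ranked = rank_genes(de)
                records = permutation_significance(
                    ranked, gene_sets, n_perm=config.n_perm, seed=config.seed
                )
                _write_tsv(records, f"{cohort.name}_gsea.tsv", index=False)
    except Exception as exc:
        raise PipelineError("diffexp", exc) from exc

    # -- stage: survival ---------------------------------------------------
    try:
        fits = []
        for cohort in study.cohorts:
            if cohort.clinical is None or cohort.clinical.empty:
                continue
            fits.append(
                cox_fit(cohort.clinical, calls_by_cohort[cohort.name], cohort=cohort.name)
            )
        meta = None
        if fits:
            fits_frame = pd.DataFrame(
                {
                    "cohort": [f.cohort for f in fits],
                    "beta": [f.beta for f in fits],
                    "se": [f.se for f in fits],
                    "hr": [f.hr if f.valid else float("nan") for f in fits],
                    "n": [f.n for f in fits],
                    "n_events": [f.n_events for f in fits],
                    "n_cl": [f.n_cl for f in fits],
                    "valid": [f.valid for f in fits],
                    "note": [f.message for f in fits],
                }
            )
            _write_tsv(fits_frame, "cox_fits.tsv", index=False)
            if any(f.valid for f in fits):
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    meta = meta_pool(fits, model=config.meta_model)
                _write_tsv(forest_table(meta, fits), "forest.tsv", index=False)
                meta_frame = pd.DataFrame(
                    [
                        {
                            "k": meta.k,
                            "beta_fixed": meta.beta_fixed,
                            "se_fixed": meta.se_fixed,
                            "beta_random": meta.beta_random,
                            "se_random": meta.se_random,
                            "tau2": meta.tau2,
                            "q": meta.q_stat,
                            "i2": meta.i2,
                            "hr_fixed": meta.hr("fixed"),
                            "hr_random": meta.hr("random"),
                        }
                    ]
                )
                _write_tsv(meta_frame, "meta.tsv", index=False)
                stage_log.append(
                    f"survival: pooled HR ({config.meta_model}) = "
                    f"{meta.hr():.3f}, CI {meta.ci()[0]:.3f}-{meta.ci()[1]:.3f}, "
                    f"I2={meta.i2:.1f}%"
                )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("survival", exc) from exc

    # -- manifest ----------------------------------------------------------
    log_path = outdir / "stages.log"
    log_path.write_text("\n".join(stage_log) + "\n")
    outputs.append(log_path)
    manifest = {
        "package": "claudinlow",
        "version": __version__,
        "seed": config.seed,
        "generator": GENERATOR_NAME,
        "config": _jsonable(config.to_dict()),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
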