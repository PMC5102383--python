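"""End-to-end pipeline driver: phenotype -> preprocess -> DE -> enrichment.

``run_pipeline`` wires the modules together on files: it reads (or
simulates) the cohort CSV and count TSV, scores and classifies the
phenotype, preprocesses counts, detects age- and youthfulness-
associated genes, optionally runs gene-set enrichment against a GMT
collection, orders genes by hierarchical clustering and samples by
``r_delta`` for the heatmap, and writes every table plus a run log
recording all parameters, the seed, and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, genesets, io, phenotype, preprocess
from .cluster import hierarchical_cluster
from .matrix import ExpressionMatrix


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All pipeline parameters with the analysis' standard defaults."""

    metadata: str | None = None     # cohort CSV; None -> simulate
    counts: str | None = None       # counts TSV; None -> simulate
    gmt: str | None = None          # optional gene-set collection
    outdir: str = "results"
    seed: int = 0
    # phenotype
    sy_top_fraction: float = 0.10
    nonsy_lower_fraction: float = 0.50
    sy_age_min: float = 50.0
    young_age_max: float = 30.0
    # preprocessing
    normalize_target: float = 1e7
    min_mean: float = 2.0
    pseudocount: float = 1.0
    # differential expression
    age_fdr: float = 0.01
    sy_p_cut: float = 0.01
    # enrichment
    min_change: float = 0.3
    set_fdr: float = 0.1

    def validate(self) -> None:
        for name in ("sy_top_fraction", "nonsy_lower_fraction", "age_fdr",
                     "sy_p_cut", "set_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} must be in (0, 1]")
        if self.min_mean < 0 or self.min_change < 0 or self.normalize_target <= 0:
            raise ValueError("thresholds must be non-negative, target positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        """Short digest of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of in-memory results (assignments, DE tables,
    enrichment table, leaf orders, output paths).  Any stage failure
    raises :class:`PipelineError` naming the stage, and removes the
    partially written output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"outdir": outdir}
    tag = f"{config.hash()}_seed{config.seed}"

    try:
        # ---- inputs ---------------------------------------------------
        stage = "inputs"
        if config.metadata is None or config.counts is None:
            from .simulate import SimulationConfig, simulate_study

            sim = SimulationConfig(seed=config.seed)
            cohort, counts, truth = simulate_study(sim)
            io.write_cohort(cohort, outdir / "cohort.csv")
            io.write_expression(counts, outdir / "counts.tsv")
            io.write_ground_truth(truth, outdir)
            results["truth"] = truth
        else:
            cohort = io.read_cohort(config.metadata)
            counts = io.read_expression(config.counts)

        # ---- phenotype ------------------------------------------------
        stage = "phenotype"
        assignments, fit = phenotype.assign_phenotypes(
            cohort,
            sy_top_fraction=config.sy_top_fraction,
            nonsy_lower_fraction=config.nonsy_lower_fraction,
            sy_age_min=config.sy_age_min,
            young_age_max=config.young_age_max,
        )
        assignments.to_csv(outdir / f"assignments_{tag}.csv", index=False)
        results["assignments"] = assignments
        results["delta_fit"] = fit

        # ---- preprocess -----------------------------------------------
        stage = "preprocess"
        common = [s for s in counts.sample_ids if s in set(assignments.index)]
        counts = ExpressionMatrix(counts.values[common], stage=counts.stage)
        batches = cohort.loc[common, "batch"] if "batch" in cohort else None
        m = preprocess.normalize_counts(counts, target=config.normalize_target)
        m = preprocess.filter_expressed(m, min_mean=config.min_mean)
        m = preprocess.log2_transform(m, pseudocount=config.pseudocount)
        if batches is not None and batches.nunique() > 1:
            m, _ = preprocess.batch_adjust(m, batches)
        results["expression"] = m

        ages = assignments.loc[common, "age"].to_numpy()
        classes = assignments.loc[common, "class"].to_numpy()

        # ---- differential expression ----------------------------------
        stage = "de-age"
        up_a, down_a, age_table = diffexpr.detect_age_genes(m, ages, fdr=config.age_fdr)
        age_table.to_csv(outdir / f"age_genes_{tag}.tsv", sep="\t")
        results["age_genes"] = (up_a, down_a, age_table)

        stage = "de-sy"
        up_s, down_s, sy_table = diffexpr.detect_sy_genes(
            m, ages, classes, p_cut=config.sy_p_cut
        )
        sy_table.to_csv(outdir / f"sy_genes_{tag}.tsv", sep="\t")
        results["sy_genes"] = (up_s, down_s, sy_table)

        # ---- enrichment -----------------------------------------------
        if config.gmt is not None:
            stage = "gsea"
            collection = genesets.read_gmt(config.gmt)
            keep = pd.Series(classes, index=common).isin(["SY", "non-SY"])
            sub = ExpressionMatrix(m.values.loc[:, keep.to_numpy()], stage=m.stage)
            resid = diffexpr.residualize_on_age(sub, ages[keep.to_numpy()])
            up, down, universe = genesets.call_changed_genes(
                resid, np.asarray(classes)[keep.to_numpy()],
                min_change=config.min_change,
            )
            enriched = genesets.enrich(
                up, down, universe, collection, fdr=config.set_fdr
            )
            enriched.to_csv(outdir / f"enrichment_{tag}.tsv", sep="\t", index=False)
            results["enrichment"] = enriched

        # ---- heatmap ordering -----------------------------------------
        stage = "cluster"
        de_genes = [*up_s, *down_s]
        if len(de_genes) >= 2:
            dendro = hierarchical_cluster(m.values.loc[de_genes], axis="genes")
            gene_order = dendro.leaf_order
            (outdir / f"gene_dendrogram_{tag}.nwk").write_text(dendro.to_newick() + "\n")
            results["gene_dendrogram"] = dendro
        else:
            gene_order = de_genes
        sample_order = (
            assignments.loc[common]
            .sort_values("r_delta", ascending=False, kind="stable")
            .index.tolist()
        )
        pd.DataFrame({"gene_id": gene_order}).to_csv(
            outdir / f"gene_order_{tag}.tsv", sep="\t", index=False
        )
        pd.DataFrame({"subject_id": sample_order}).to_csv(
            outdir / f"sample_order_{tag}.tsv", sep="\t", index=False
        )
        results["gene_order"] = gene_order
        results["sample_order"] = sample_order

        # ---- run log ---------------------------------------------------
        stage = "log"
        log = {
            "config": {
                k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"
            },
            "config_hash": config.hash(),
            "seed": config.seed,
            "n_subjects": int(len(assignments)),
            "n_genes_tested": int(m.shape[0]),
            "n_age_genes": len(up_a) + len(down_a),
            "n_sy_genes": len(up_s) + len(down_s),
        }
        (outdir / f"run_log_{tag}.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
        results["log"] = log
    except Exception as exc:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for f in outdir.glob(f"*_{tag}.*"):
                f.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return results
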