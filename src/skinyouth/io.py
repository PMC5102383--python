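"""File round-tripping for the pipeline's plain-text formats.

Cohort metadata travels as CSV (one row per subject); expression
matrices as gene x sample TSV with a ``#stage=`` comment line so the
processing stage survives a round trip; ground truth as CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix
from .simulate import GroundTruth


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: missing subject_id column")
    return df.set_index("subject_id", drop=False)


def write_expression(m: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#stage={m.stage}\n")
        m.values.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression(path) -> ExpressionMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    stage = "raw"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#stage="):
            stage = first.strip().split("=", 1)[1]
        else:
            fh.seek(0)
        values = pd.read_csv(fh, sep="\t", index_col="gene_id")
    return ExpressionMatrix(values, stage=stage)


def write_ground_truth(truth: GroundTruth, outdir) -> None:
    outdir = Path(outdir)
    pd.DataFrame(
        {
            "gene_id": list(truth.age_gene_signs) + list(truth.sy_gene_signs),
            "kind": ["age"] * len(truth.age_gene_signs) + ["sy"] * len(truth.sy_gene_signs),
            "sign": list(truth.age_gene_signs.values()) + list(truth.sy_gene_signs.values()),
        }
    ).to_csv(outdir / "truth_genes.csv", index=False)
    pd.DataFrame(
        {
            "subject_id": truth.true_r_delta.index,
            "true_r_delta": truth.true_r_delta.to_numpy(),
            "true_sy": [s in truth.true_sy_subjects for s in truth.true_r_delta.index],
        }
    ).to_csv(outdir / "truth_subjects.csv", index=False)


def read_ground_truth(outdir) -> GroundTruth:
    outdir = Path(outdir)
    genes = pd.read_csv(outdir / "truth_genes.csv")
    subjects = pd.read_csv(outdir / "truth_subjects.csv")
    return GroundTruth(
        age_gene_signs=dict(
            zip(genes.loc[genes["kind"] == "age", "gene_id"],
                genes.loc[genes["kind"] == "age", "sign"])
        ),
        sy_gene_signs=dict(
            zip(genes.loc[genes["kind"] == "sy", "gene_id"],
                genes.loc[genes["kind"] == "sy", "sign"])
        ),
        true_sy_subjects=set(subjects.loc[subjects["true_sy"], "subject_id"]),
        true_r_delta=pd.Series(
            subjects["true_r_delta"].to_numpy(), index=subjects["subject_id"]
        ),
    )
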