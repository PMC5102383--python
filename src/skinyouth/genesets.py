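"""Gene-set over-representation between youthful and non-youthful skin.

Mirrors the Genomica-style workflow: on the age-residualized log2
matrix, call a gene "changed" when the SY-vs-non-SY group-mean
difference exceeds a minimum expression change (0.3 log2 units by
default, inclusive); test each set in a GMT collection for
over-representation of up- and down-changed genes with the one-sided
hypergeometric tail; control the set-level FDR at 0.1 by
Benjamini-Hochberg.  A set-level location comparison (cumulative plots
of per-gene group means with a paired signed-rank test) complements the
over-representation view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diffexpr import bh_adjust
from .matrix import ExpressionMatrix
from .stats import TestResult


class GMTParseError(ValueError):
    pass


class InsufficientSetError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets (MSigDB-style), e.g. hallmark / C2 / C5 / C7."""

    name: str
    sets: dict = field(default_factory=dict)  # set name -> list of gene ids
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Duplicate members within a set are dropped (order-preserving) with a
    warning; a line with fewer than three fields is a parse error.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            set_name, members = fields[0], [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {set_name!r} dropped",
                    stacklevel=2,
                )
            sets[set_name] = unique
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(name=name or str(path), sets=sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, description, *members]) + "\n")


def call_changed_genes(
    m: ExpressionMatrix, classes, min_change: float = 0.3
) -> tuple[set, set, set]:
    """Call up/down changed genes from the residualized matrix.

    For each gene, delta = mean(SY) - mean(non-SY); ``delta >=
    min_change`` is up, ``<= -min_change`` down (boundary inclusive).
    Returns (up set, down set, universe of all tested genes).
    """
    classes = pd.Series(np.asarray(classes, dtype=object), index=m.sample_ids)
    sy = (classes == "SY").to_numpy()
    nonsy = (classes == "non-SY").to_numpy()
    if sy.sum() < 2 or nonsy.sum() < 2:
        raise InsufficientSetError("need >=2 samples in each group")
    Y = m.values.to_numpy(dtype=float)
    diff = Y[:, sy].mean(axis=1) - Y[:, nonsy].mean(axis=1)
    genes = m.gene_ids
    up = set(genes[diff >= min_change])
    down = set(genes[diff <= -min_change])
    return up, down, set(genes)


def hypergeom_tail(overlap: int, universe: int, set_size: int, drawn: int) -> float:
    """Upper-tail P(X >= overlap) for overlap between a set and a draw."""
    return float(sps.hypergeom.sf(overlap - 1, universe, set_size, drawn))


def enrich(
    up: set,
    down: set,
    universe: set,
    collection: GeneSetCollection,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set, per direction.

    Set members are intersected with the universe first; sets disjoint
    from the universe are skipped with a warning.  BH adjustment runs
    across all set x direction tests; rows with adjusted p below
    ``fdr`` are returned ranked by p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (up <= universe and down <= universe):
        raise ValueError("changed genes must be contained in the universe")
    rows = []
    for set_name, members in collection.sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            warnings.warn(f"set {set_name!r} has no members in the universe", stacklevel=2)
            continue
        for direction, changed in (("up", up), ("down", down)):
            overlap = in_universe & changed
            rows.append(
                {
                    "set_name": set_name,
                    "direction": direction,
                    "n_set_in_universe": len(in_universe),
                    "n_changed": len(changed),
                    "n_overlap": len(overlap),
                    "p": hypergeom_tail(
                        len(overlap), len(universe), len(in_universe), len(changed)
                    ),
                    "members": sorted(overlap),
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["fdr"] = bh_adjust(result["p"])
    result = result.sort_values("p", kind="stable").reset_index(drop=True)
    return result[result["fdr"] < fdr].reset_index(drop=True)


def cumulative_set_test(
    m: ExpressionMatrix,
    classes,
    set_members,
    method: str = "signed_rank",
) -> tuple[np.ndarray, np.ndarray, TestResult]:
    """Set-level expression comparison via cumulative distributions.

    For each member gene present in the matrix, computes the group-mean
    expression in SY and in non-SY samples; returns the two sorted
    per-gene mean vectors (the empirical CDF supports) and a two-sided
    paired test on the per-gene differences — Wilcoxon signed-rank by
    default, ``method='ks'`` for a two-sample Kolmogorov-Smirnov
    alternative.  Needs at least 5 member genes in the matrix.
    """
    classes = pd.Series(np.asarray(classes, dtype=object), index=m.sample_ids)
    present = [g for g in set_members if g in set(m.gene_ids)]
    if len(present) < 5:
        raise InsufficientSetError(
            f"only {len(present)} set members present in the matrix (need >=5)"
        )
    sub = m.values.loc[present]
    mean_sy = sub.loc[:, (classes == "SY").to_numpy()].mean(axis=1).to_numpy()
    mean_nonsy = sub.loc[:, (classes == "non-SY").to_numpy()].mean(axis=1).to_numpy()
    diffs = mean_sy - mean_nonsy
    if method == "ks":
        res = sps.ks_2samp(mean_sy, mean_nonsy)
        test = TestResult(float(res.statistic), float(res.pvalue), "ks_2samp")
    else:
        if np.allclose(diffs, 0):
            test = TestResult(0.0, 1.0, "wilcoxon_signed_rank")
        else:
            res = sps.wilcoxon(diffs, alternative="two-sided")
            test = TestResult(float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank")
    return np.sort(mean_sy), np.sort(mean_nonsy), test
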