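"""Expression transforms and gene-set (module) scoring for sorted microglia.

Works on genes × samples matrices of nRPKM-scale expression values.  The
module score of a sample is the average, over the genes of a named set, of
the difference between that sample's log2(nRPKM) value and the across-sample
mean log2(nRPKM) for the gene — so scores of one set always sum to zero
across samples.  Genes undetected (nRPKM = 0) in some samples receive an
imputed log2 value one log2 step below the lowest detected value for that
gene; genes detected in no sample are dropped from the set.  Group
comparisons use two-tailed Welch t tests (unequal variances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "log2_floor",
    "zscore_by_gene",
    "gene_set_score",
    "score_gene_sets",
    "compare_scores",
    "read_gmt",
    "write_gmt",
]

#: Default floor for log2-scale heat-map matrices: max(log2(nRPKM), -4).
LOG2_FLOOR = -4.0


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty list of gene ids (one expression module)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("gene and sample ids must be unique")
    if (matrix.values < 0).any():
        raise ValueError("nRPKM values must be non-negative")
    return matrix


def log2_floor(matrix: pd.DataFrame, floor: float = LOG2_FLOOR) -> pd.DataFrame:
    """Elementwise max(log2(x), floor); zeros map to the floor."""
    _check_matrix(matrix)
    with np.errstate(divide="ignore"):
        out = np.log2(matrix.astype(float))
    return out.clip(lower=floor)


def zscore_by_gene(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each gene row to z scores across samples.

    Uses the sample standard deviation (n − 1 denominator).  Zero-variance
    rows are set to all-zero rather than NaN.  Requires at least two samples.
    """
    if log2_matrix.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    vals = log2_matrix.astype(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    z = vals.sub(mean, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z


def _resolve(matrix: pd.DataFrame, gene_set: GeneSet) -> list[str]:
    present = [g for g in gene_set.genes if g in matrix.index]
    missing = set(gene_set.genes) - set(present)
    if missing:
        logger.warning(
            "gene set %s: %d/%d genes absent from matrix, dropped",
            gene_set.name,
            len(missing),
            len(gene_set.genes),
        )
    if not present:
        raise ValueError(f"gene set {gene_set.name!r}: no gene resolvable against matrix")
    return present


def gene_set_score(
    matrix: pd.DataFrame, gene_set: GeneSet, floor: float | None = None
) -> pd.DataFrame:
    """Per-sample module score of one gene set on an nRPKM matrix.

    For each set gene, samples with nRPKM > 0 contribute log2(nRPKM);
    undetected (zero) entries are imputed at one log2 step below the lowest
    detected log2 value for that gene.  Genes with no detected value in any
    sample are dropped, logged.  The score of sample *s* is the mean over
    set genes of (x_gs − mean_s' x_gs'), hence scores sum to zero across
    samples.  ``floor`` optionally applies max(log2, floor) before scoring
    (off by default; the floor belongs to the heat-map display transform).

    Returns a table indexed by sample with columns ``gene_set``, ``score``,
    ``n_genes_used``, ``n_imputed``.
    """
    _check_matrix(matrix)
    genes = _resolve(matrix, gene_set)
    sub = matrix.loc[genes].astype(float)
    usable = (sub.values > 0).any(axis=1)
    if not usable.all():
        logger.warning(
            "gene set %s: %d genes undetected in all samples, dropped from scoring",
            gene_set.name,
            int((~usable).sum()),
        )
    sub = sub.loc[usable]
    if sub.empty:
        raise ValueError(f"gene set {gene_set.name!r}: no gene detected in any sample")
    detected = sub.values > 0
    with np.errstate(divide="ignore"):
        log2v = np.log2(sub.values, where=detected, out=np.full(sub.shape, np.nan))
    min_detected = np.nanmin(np.where(detected, log2v, np.nan), axis=1)
    imputed_value = min_detected - 1.0
    log2v = np.where(detected, log2v, imputed_value[:, None])
    if floor is not None:
        log2v = np.maximum(log2v, floor)
    centered = log2v - log2v.mean(axis=1, keepdims=True)
    scores = centered.mean(axis=0)
    n_imputed = (~detected).sum(axis=0)
    return pd.DataFrame(
        {
            "gene_set": gene_set.name,
            "score": scores,
            "n_genes_used": sub.shape[0],
            "n_imputed": n_imputed,
        },
        index=pd.Index(matrix.columns, name="sample"),
    )


def score_gene_sets(
    matrix: pd.DataFrame, gene_sets: list[GeneSet], floor: float | None = None
) -> pd.DataFrame:
    """Score several gene sets; concatenated long-format table."""
    return pd.concat(
        [gene_set_score(matrix, gs, floor=floor) for gs in gene_sets]
    ).reset_index()


def compare_scores(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample comparison of module scores between groups.

    Returns the unequal-variance t statistic (with Welch–Satterthwaite
    degrees of freedom) and the two-sided p value.  Both groups need at
    least two samples.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_gene_sets(
    score_table: pd.DataFrame,
    groups: pd.Series,
    adjust: bool = False,
) -> pd.DataFrame:
    """Welch comparisons of every gene set between two groups.

    ``groups`` maps sample id to group label (exactly two labels).  When
    ``adjust`` is set, Benjamini–Hochberg adjusted p values are appended
    (off by default: per-set tests are reported as-is).
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    rows = []
    for name, tab in score_table.groupby("gene_set", sort=True):
        tab = tab.set_index("sample")
        ga = tab.loc[tab.index.intersection(groups[groups == labels[0]].index), "score"]
        gb = tab.loc[tab.index.intersection(groups[groups == labels[1]].index), "score"]
        t, p = compare_scores(ga.values, gb.values)
        rows.append(
            {
                "gene_set": name,
                "group_a": labels[0],
                "group_b": labels[1],
                "mean_a": float(ga.mean()),
                "mean_b": float(gb.mean()),
                "mean_diff": float(gb.mean() - ga.mean()),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if adjust and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets.append(GeneSet(parts[0], tuple(g for g in parts[2:] if g), parts[1]))
    return sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")
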