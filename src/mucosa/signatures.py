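"""Epithelial lineage signature scoring for bulk expression matrices.

Expression is a genes x samples matrix of log2(normalised counts + 1).
Each gene is Z-scored across samples and the signature score of a curated
marker set (absorptive, goblet, stem, ...) for a sample is the mean
Z-scored expression over the set's genes present in the matrix.  A
rank-based single-sample scorer is provided as a documented stand-in for
published single-sample enrichment methods: it depends only on the
within-sample ordering of genes, so it is invariant to any monotone
per-sample transform of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerGeneSet",
    "filter_genes",
    "zscore_genes",
    "signature_score_meanz",
    "signature_score_rank",
    "score_signatures",
    "group_mean_scores",
]


@dataclass(frozen=True)
class MarkerGeneSet:
    """A named marker gene set for one epithelial subset."""

    subset_name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.subset_name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.subset_name!r} has duplicate genes")


def filter_genes(
    matrix: pd.DataFrame,
    min_expression: float = 1.0,
    min_fraction_samples: float = 0.2,
) -> pd.DataFrame:
    """Keep genes exceeding ``min_expression`` in >= a fraction of samples."""
    if min_expression < 0 or min_fraction_samples < 0:
        raise ValueError("thresholds must be >= 0")
    frac = (matrix > min_expression).mean(axis=1)
    kept = matrix.loc[frac >= min_fraction_samples]
    if kept.empty:
        raise ValueError("no genes pass the expression filter")
    return kept


def zscore_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise Z-scores across samples (sample SD, n-1 denominator).

    Zero-variance genes become all-zero rows; their identifiers are kept
    in ``Z.attrs['zero_variance_genes']``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to Z-score across samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    out.attrs["zero_variance_genes"] = list(matrix.index[flat])
    if flat.any():
        logger.info("%d zero-variance genes set to Z = 0", int(flat.sum()))
    return out


def _present_genes(index: pd.Index, gene_set: MarkerGeneSet) -> list[str]:
    present = [g for g in gene_set.genes if g in index]
    if not present:
        raise ValueError(
            f"no marker of set {gene_set.subset_name!r} is present in the matrix"
        )
    missing = len(gene_set.genes) - len(present)
    if missing:
        logger.info(
            "set %s: %d of %d markers absent from matrix",
            gene_set.subset_name, missing, len(gene_set.genes),
        )
    return present


def signature_score_meanz(Z: pd.DataFrame, gene_set: MarkerGeneSet) -> pd.Series:
    """Per-sample mean Z-scored expression over the set's present markers."""
    present = _present_genes(Z.index, gene_set)
    scores = Z.loc[present].mean(axis=0)
    scores.name = gene_set.subset_name
    scores.attrs["n_genes_used"] = len(present)
    return scores


def signature_score_rank(matrix: pd.DataFrame, gene_set: MarkerGeneSet) -> pd.Series:
    """Rank-based single-sample score, rescaled to [-1, 1].

    Genes are mid-ranked within each sample (1 = lowest expression); the
    score is the markers' mean rank mapped linearly so that a set sitting
    uniformly across the ranking scores ~0 and the top-|set| genes score
    the maximum attainable for that set size.
    """
    present = _present_genes(matrix.index, gene_set)
    n_genes = matrix.shape[0]
    if n_genes < 2:
        raise ValueError("need >= 2 genes for rank scoring")
    ranks = np.apply_along_axis(stats.rankdata, 0, matrix.to_numpy(dtype=float))
    ranks = pd.DataFrame(ranks, index=matrix.index, columns=matrix.columns)
    mean_rank = ranks.loc[present].mean(axis=0)
    scores = 2.0 * (mean_rank - (n_genes + 1) / 2.0) / (n_genes - 1)
    scores.name = gene_set.subset_name
    scores.attrs["n_genes_used"] = len(present)
    return scores


def score_signatures(
    matrix: pd.DataFrame,
    gene_sets,
    scorer: str = "meanz",
) -> pd.DataFrame:
    """Tidy per-(sample, subset) score table.

    ``scorer`` is ``"meanz"`` (Z-score the matrix gene-wise, then mean-Z
    per set) or ``"rank"`` (within-sample rank scorer on the raw matrix).
    """
    if scorer == "meanz":
        Z = zscore_genes(matrix)
        score_one = lambda gs: signature_score_meanz(Z, gs)  # noqa: E731
    elif scorer == "rank":
        score_one = lambda gs: signature_score_rank(matrix, gs)  # noqa: E731
    else:
        raise ValueError(f"unknown scorer {scorer!r}")
    frames = []
    for gs in gene_sets:
        s = score_one(gs)
        frames.append(
            pd.DataFrame(
                {
                    "sample": s.index,
                    "subset": gs.subset_name,
                    "score": s.to_numpy(),
                    "n_genes_used": s.attrs["n_genes_used"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def group_mean_scores(scores: pd.DataFrame, treatments: pd.Series) -> pd.DataFrame:
    """Subset x treatment matrix of arithmetic mean scores.

    ``treatments`` maps sample id -> treatment label; every scored sample
    must be labelled.
    """
    treatments = pd.Series(treatments)
    missing = set(scores["sample"]) - set(treatments.index)
    if missing:
        raise ValueError(f"unlabelled samples: {sorted(missing)[:5]}")
    labelled = scores.assign(treatment=scores["sample"].map(treatments))
    return (
        labelled.groupby(["subset", "treatment"], sort=True)["score"]
        .mean()
        .unstack("treatment")
    )
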