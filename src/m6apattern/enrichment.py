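"""Single-sample gene-set enrichment (ssGSEA) and z-score signature means.

ssGSEA quantifies per-sample relative abundance of, e.g., infiltrating
immune-cell populations from their marker gene sets.  Genes are ranked per
sample, integer rank positions are weighted by an exponent ``alpha``, and
the enrichment score is the summed difference between the weighted
in-set and unweighted out-of-set running CDFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentScores:
    scores: pd.DataFrame      # sets x samples
    alpha: float
    normalized: bool

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)


def _sample_es(order: np.ndarray, weights_alpha: np.ndarray, member: np.ndarray) -> float:
    """Enrichment score for one sample.

    ``order`` maps rank position -> gene index (descending expression),
    ``weights_alpha`` holds z^alpha per rank position (z = N, N-1, ..., 1),
    ``member`` is a boolean gene-membership mask.
    """
    in_set = member[order]
    n = order.size
    n_in = int(in_set.sum())
    inc = np.where(in_set, weights_alpha, 0.0)
    p_in = np.cumsum(inc)
    total = p_in[-1]
    p_in = p_in / total
    p_out = np.cumsum(~in_set) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
    per_set: bool = False,
    min_overlap: int = 2,
) -> EnrichmentScores:
    """ssGSEA enrichment scores for every (set, sample) pair.

    Per sample, the N genes are ordered by descending expression (ties
    broken by gene id, so scores are deterministic and invariant to input
    gene order) and weighted z = N..1 by rank position.  The in-set running
    sum uses z^alpha, the out-set running sum is the uniform CDF over
    non-members; their summed difference over all positions is the score.
    With ``normalize`` the whole matrix is rescaled by its global
    max - min range (``per_set`` switches to a per-set range).
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    usable = sets.restrict_to(expr.index, min_overlap=min_overlap)
    if len(usable) == 0:
        raise ValueError("no gene set overlaps the expression matrix")
    n = expr.shape[0]
    for name, members in usable.items():
        if len(members) >= n:
            raise ValueError(
                f"gene set {name!r} covers every gene; out-of-set CDF undefined"
            )

    gene_pos = {g: i for i, g in enumerate(expr.index)}
    member_masks = {}
    for name, members in usable.items():
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        member_masks[name] = mask

    gene_order_key = np.argsort(expr.index.to_numpy())  # for tie-breaking
    tie_rank = np.empty(n, dtype=float)
    tie_rank[gene_order_key] = np.arange(n)
    weights_alpha = (np.arange(n, 0, -1, dtype=float)) ** alpha

    values = expr.to_numpy(dtype=float)
    out = np.empty((len(usable), expr.shape[1]))
    for j in range(expr.shape[1]):
        col = values[:, j]
        # descending expression, ties by lexicographic gene id
        order = np.lexsort((tie_rank, -col))
        for i, name in enumerate(usable.names):
            out[i, j] = _sample_es(order, weights_alpha, member_masks[name])

    scores = pd.DataFrame(out, index=usable.names, columns=expr.columns)
    if normalize:
        if per_set:
            rng_ = scores.max(axis=1) - scores.min(axis=1)
            rng_ = rng_.replace(0.0, 1.0)
            scores = scores.div(rng_, axis=0)
        else:
            span = float(scores.to_numpy().max() - scores.to_numpy().min())
            if span > 0:
                scores = scores / span
    return EnrichmentScores(scores=scores, alpha=alpha, normalized=normalize)


def zscore_signature(expr: pd.DataFrame, genes) -> pd.Series:
    """Per-sample mean of per-gene z-scores over a signature panel.

    Used for stromal/immune pathway panels (EMT, TGF-beta, angiogenesis).
    Zero-variance genes are dropped with a warning; duplicated ids count
    once.
    """
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in expr.index]
    if len(present) < 2:
        raise ValueError("signature shares fewer than 2 genes with the matrix")
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    for g in sub.index[~keep]:
        logger.warning("dropping zero-variance signature gene %r", g)
    if not keep.any():
        raise ValueError("all signature genes have zero variance")
    sub = sub.loc[keep]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z.mean(axis=0).rename("signature_score")


class SSGSEA(TransformerMixin, BaseEstimator):
    """Transformer wrapper: samples x genes in, samples x sets out."""

    def __init__(
        self,
        gene_sets: GeneSetCollection | dict | None = None,
        alpha: float = 0.25,
        normalize: bool = True,
        min_overlap: int = 2,
    ):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize
        self.min_overlap = min_overlap

    def _collection(self) -> GeneSetCollection:
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        if isinstance(self.gene_sets, GeneSetCollection):
            return self.gene_sets
        return GeneSetCollection({k: list(v) for k, v in self.gene_sets.items()})

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("SSGSEA requires a samples x genes DataFrame")
        self.set_names_ = self._collection().restrict_to(
            X.columns, min_overlap=self.min_overlap
        ).names
        return self

    def transform(self, X) -> pd.DataFrame:
        result = ssgsea_scores(
            X.T,
            self._collection(),
            alpha=self.alpha,
            normalize=self.normalize,
            min_overlap=self.min_overlap,
        )
        return result.scores.T
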