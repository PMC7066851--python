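"""The PCA-based m6Ascore and the association statistics run against it.

The score condenses the phenotype-related gene signature into one number
per sample: signature genes are z-scored across samples, the samples x
genes matrix is decomposed by SVD, and the score is the sum of each
sample's first two principal-component projections,
``score_s = PC1_s + PC2_s``.  Restricting to the top two components focuses
the score on the largest block of mutually correlated signature genes and
down-weights genes that do not track the rest of the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    sample_ids: list[str]
    score: pd.Series               # m6Ascore = PC1 + PC2 per sample
    pc1: pd.Series
    pc2: pd.Series
    loadings: pd.DataFrame         # genes x [PC1, PC2]
    var_explained: np.ndarray      # fraction for PC1, PC2
    genes: list[str]
    orientation: dict              # per-component sign record


def compute_m6ascore(
    expr: pd.DataFrame,
    signature_genes,
    orient_to: pd.Series | None = None,
) -> ScoreResult:
    """Per-sample m6Ascore from the signature-gene submatrix.

    Each signature gene is z-scored across samples (correlation-scale PCA,
    robust to heterogeneous platform dynamic ranges); the SVD of the
    samples x genes matrix yields PC1/PC2 projections.  Component signs are
    arbitrary in an SVD, so each is fixed deterministically: the gene with
    the largest-magnitude loading gets a positive loading.  If
    ``orient_to`` (a per-sample reference signature, e.g. a stromal panel
    mean) is given and the score correlates negatively with it, the whole
    decomposition is flipped so that a high score keeps the
    stromal/immune-excluded meaning.
    """
    genes = [g for g in dict.fromkeys(signature_genes) if g in expr.index]
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    dropped = sub.index[sd == 0].tolist()
    for g in dropped:
        logger.warning("dropping zero-variance signature gene %r", g)
    sub = sub.loc[sd > 0]
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 usable (present, non-constant) signature genes")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    X = z.to_numpy().T  # samples x genes, column-centered by construction

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    proj = U[:, :2] * S[:2]
    load = Vt[:2].T
    signs = np.ones(2)
    for c in range(2):
        top = int(np.argmax(np.abs(load[:, c])))
        if load[top, c] < 0:
            signs[c] = -1.0
    proj = proj * signs
    load = load * signs

    samples = list(expr.columns)
    pc1 = pd.Series(proj[:, 0], index=samples, name="PC1")
    pc2 = pd.Series(proj[:, 1], index=samples, name="PC2")
    score = (pc1 + pc2).rename("m6ascore")
    orientation = {"pc_signs": signs.tolist(), "flipped_to_reference": False}

    if orient_to is not None:
        # flip each component so it tracks the reference signature
        # non-negatively; a single global flip cannot reconcile components
        # that load on the reference with opposite signs
        ref = pd.Series(orient_to).loc[samples].to_numpy()
        flips = []
        for c, pc in enumerate((pc1, pc2)):
            rho, _ = spearman_corr(pc.to_numpy(), ref)
            flips.append(rho < 0)
        if flips[0]:
            pc1 = -pc1
        if flips[1]:
            pc2 = -pc2
        load = load * np.where(flips, -1.0, 1.0)
        score = (pc1 + pc2).rename("m6ascore")
        orientation["flipped_to_reference"] = flips

    total_var = np.sum(S**2)
    var_explained = (S[:2] ** 2 / total_var) if total_var > 0 else np.zeros(2)
    return ScoreResult(
        sample_ids=samples,
        score=score,
        pc1=pc1,
        pc2=pc2,
        loadings=pd.DataFrame(load, index=sub.index, columns=["PC1", "PC2"]),
        var_explained=var_explained,
        genes=list(sub.index),
        orientation=orientation,
    )


def dichotomize_score(score: pd.Series | np.ndarray, cutpoint: float):
    """Split into low (score <= cutpoint) and high (score > cutpoint)."""
    values = np.asarray(score, dtype=float)
    if cutpoint < values.min() or cutpoint >= values.max():
        raise ValueError(
            "cutpoint outside the observed score range would create an empty group"
        )
    labels = np.where(values <= cutpoint, "low", "high")
    if isinstance(score, pd.Series):
        return pd.Series(labels, index=score.index, name="score_group")
    return labels


# --------------------------------------------------------------------------
# Association statistics
# --------------------------------------------------------------------------

def spearman_corr(x, y) -> tuple[float, float]:
    """Tie-aware Spearman rho with the t-approximation p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with the chi-square p (k - 1 df)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    parts = [values[groups == lv] for lv in levels]
    if any(len(p_) == 0 for p_ in parts):
        raise ValueError("empty group")
    if np.unique(values).size == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*parts)
    return float(h), float(p)


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Mann-Whitney U for x (exact for small untied samples, otherwise
    normal approximation with tie correction); two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class FisherResult:
    odds_ratio: float
    p: float
    or_defined: bool


def fisher_exact_2x2(table) -> FisherResult:
    """Conditional exact test for a 2x2 count table.

    Two-sided p sums the probabilities of all tables (at fixed margins)
    no more likely than the observed one.  The sample odds ratio is
    ad/bc, with a 0.5 continuity add to every cell when any cell is zero;
    a zero margin makes the OR undefined and forces p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.all(t == np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    a, b, c, d = t.ravel()
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        return FisherResult(odds_ratio=np.nan, p=1.0, or_defined=False)
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    oddsr = (aa * dd) / (bb * cc)
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return FisherResult(odds_ratio=float(oddsr), p=float(p), or_defined=True)


def auc_rank(score, binary_labels) -> float:
    """Rank (Mann-Whitney) AUC: P(score_pos > score_neg) with mid-rank ties."""
    score = np.asarray(score, dtype=float)
    labels = np.asarray(binary_labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


class M6AScorer(TransformerMixin, BaseEstimator):
    """Transformer wrapper: samples x genes in, m6Ascore out.

    ``fit`` learns the z-scoring parameters and PC loadings on the
    signature submatrix; ``transform`` projects (new) samples and returns
    PC1 + PC2.  On the training data this reproduces
    :func:`compute_m6ascore` exactly.
    """

    def __init__(self, signature_genes=None, orient_to=None):
        self.signature_genes = signature_genes
        self.orient_to = orient_to

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("M6AScorer requires a samples x genes DataFrame")
        if self.signature_genes is None:
            raise ValueError("signature_genes must be provided")
        result = compute_m6ascore(
            X.T, self.signature_genes, orient_to=self.orient_to
        )
        self.result_ = result
        self.genes_ = result.genes
        self.center_ = X[self.genes_].mean(axis=0)
        self.scale_ = X[self.genes_].std(axis=0, ddof=1)
        self.loadings_ = result.loadings
        self.var_explained_ = result.var_explained
        return self

    def transform(self, X) -> pd.Series:
        z = (X[self.genes_] - self.center_) / self.scale_
        proj = z.to_numpy() @ self.loadings_.to_numpy()
        return pd.Series(proj.sum(axis=1), index=X.index, name="m6ascore")
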