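"""Tumor mutation burden, per-gene mutation frequency, and pairwise
co-occurrence / mutual-exclusivity tests over a mutation record table."""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .io import NONSILENT_CLASSES, VARIANT_CLASSES
from .degs import bh_adjust
from .scoring import fisher_exact_2x2

logger = logging.getLogger(__name__)


def tmb_per_sample(
    mutations: pd.DataFrame,
    cohort_samples,
    nonsilent_classes=NONSILENT_CLASSES,
) -> pd.Series:
    """Nonsilent mutation count per sample, zero-filled for the cohort.

    TMB is reported as a raw count (not per megabase) because panel sizes
    are unavailable for the formats handled here.
    """
    bad = set(nonsilent_classes) - VARIANT_CLASSES
    if bad:
        raise ValueError(f"unknown variant classes: {sorted(bad)}")
    cohort_samples = list(cohort_samples)
    kept = mutations[mutations["variant_class"].isin(set(nonsilent_classes))]
    counts = kept.groupby("sample").size()
    return (
        counts.reindex(cohort_samples, fill_value=0).astype(int).rename("tmb")
    )


def mutation_frequency(mutations: pd.DataFrame, cohort_samples) -> pd.DataFrame:
    """Per-gene distinct-mutated-sample counts and percent frequency.

    Frequency = mutated samples / cohort size, as a percentage rounded to
    two decimals; sorted by descending frequency (gene id breaks ties).
    """
    cohort_samples = list(cohort_samples)
    if len(cohort_samples) == 0:
        raise ValueError("empty cohort")
    in_cohort = mutations[mutations["sample"].isin(set(cohort_samples))]
    counts = in_cohort.groupby("gene")["sample"].nunique()
    out = pd.DataFrame(
        {
            "n_mutated_samples": counts,
            "frequency_pct": (counts / len(cohort_samples) * 100).round(2),
        }
    )
    # stable sort: descending frequency, gene id breaks ties
    return out.sort_index().sort_values(
        "frequency_pct", ascending=False, kind="mergesort"
    )


def mutated_sample_fraction(
    mutations: pd.DataFrame, cohort_samples, genes=None
) -> float:
    """Percent of cohort samples carrying >= 1 mutation (optionally
    restricted to ``genes``), rounded to two decimals."""
    cohort_samples = list(cohort_samples)
    if len(cohort_samples) == 0:
        raise ValueError("empty cohort")
    recs = mutations[mutations["sample"].isin(set(cohort_samples))]
    if genes is not None:
        recs = recs[recs["gene"].isin(set(genes))]
    n_mut = recs["sample"].nunique()
    return round(n_mut / len(cohort_samples) * 100, 2)


def cooccurrence_tests(
    mutations: pd.DataFrame, cohort_samples, genes
) -> pd.DataFrame:
    """Pairwise mutation co-occurrence / exclusivity Fisher tests.

    For each unordered gene pair, samples are cross-tabulated by
    mutated/not-mutated status; the two-sided Fisher p is BH-adjusted over
    all pairs and the direction called from the odds ratio.
    """
    genes = list(dict.fromkeys(genes))
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    cohort_samples = list(cohort_samples)
    n = len(cohort_samples)
    in_cohort = mutations[mutations["sample"].isin(set(cohort_samples))]
    mutated = {
        g: set(in_cohort.loc[in_cohort["gene"] == g, "sample"]) for g in genes
    }
    rows = []
    for ga, gb in itertools.combinations(genes, 2):
        sa, sb = mutated[ga], mutated[gb]
        both = len(sa & sb)
        a_only = len(sa) - both
        b_only = len(sb) - both
        neither = n - both - a_only - b_only
        res = fisher_exact_2x2([[both, a_only], [b_only, neither]])
        direction = "co-occurrence" if (not res.or_defined or res.odds_ratio > 1) else "exclusivity"
        if not res.or_defined:
            direction = "undefined"
        rows.append(
            (ga, gb, both, a_only, b_only, neither, res.odds_ratio, res.p, direction)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "n_both", "n_a_only", "n_b_only", "n_neither",
            "odds_ratio", "p", "direction",
        ],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
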