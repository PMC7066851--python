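"""Readers, writers and cohort alignment for the tabular formats of the pipeline.

Expression matrices are plain pandas DataFrames, genes on the index and
samples on the columns, holding log2-scale abundances (log2(TPM+1)
convention).  Clinical tables are DataFrames indexed by sample id.  Mutation
tables are record DataFrames with columns ``sample``, ``gene``,
``variant_class``.  Gene sets live in :class:`GeneSetCollection`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled vocabulary for MAF variant classifications.
VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Splice_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Translation_Start_Site",
        "Silent",
        "Other",
    }
)

#: Classes counted as nonsilent for tumor mutation burden.
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "Splice_Site",
        "In_Frame_Ins",
        "In_Frame_Del",
    }
)

_MAF_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


@dataclass
class GeneSetCollection:
    """Named gene sets (immune-cell markers, stromal panels, regulator lists).

    Parameters
    ----------
    sets
        Mapping of set name to an ordered list of unique gene ids.
    provenance
        Free-text record of where the sets came from.
    """

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                # dedupe preserving order
                self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()

    def restrict_to(self, genes, min_overlap: int = 2) -> "GeneSetCollection":
        """Intersect every set with ``genes``; drop sets below ``min_overlap``."""
        universe = set(genes)
        kept: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in universe]
            if len(inter) >= min_overlap:
                kept[name] = inter
            else:
                logger.warning(
                    "dropping gene set %r: only %d of %d genes present "
                    "(minimum overlap %d)",
                    name,
                    len(inter),
                    len(members),
                    min_overlap,
                )
        return GeneSetCollection(kept, provenance=self.provenance)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique ids, finite values."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    values = expr.to_numpy()
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite expression value for gene {expr.index[r]!r}, "
            f"sample {expr.columns[c]!r}"
        )
    return expr


def read_expression_tsv(path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a gene-by-sample expression TSV.

    The header row carries sample ids, the first column gene ids.  Pass
    ``orientation="samples_by_genes"`` for transposed files.  Duplicate gene
    rows are collapsed by their mean; any non-numeric cell is an error naming
    the offending gene and sample.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression table")
    if orientation == "samples_by_genes":
        raw = raw.T
    df = raw.apply(pd.to_numeric, errors="coerce")
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} for gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if df.index.has_duplicates:
        n_before = df.shape[0]
        df = df.groupby(level=0, sort=False).mean()
        logger.info(
            "collapsed %d duplicate gene rows by mean", n_before - df.shape[0]
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene"
    return validate_expression(df)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.6g", index_label="gene")


def fpkm_to_tpm(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Convert per-sample FPKM columns to TPM (each column sums to 1e6)."""
    values = fpkm.to_numpy(dtype=float)
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative FPKM for gene {fpkm.index[r]!r}, sample {fpkm.columns[c]!r}"
        )
    colsums = values.sum(axis=0)
    if (colsums == 0).any():
        bad = fpkm.columns[np.argwhere(colsums == 0)[0, 0]]
        raise ValueError(f"sample {bad!r} has all-zero FPKM; TPM undefined")
    return fpkm / colsums * 1e6


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, then gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if len(genes) < 1:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, collection.provenance or "na", *genes]) + "\n")


def read_clinical_tsv(path, response_col: str | None = None) -> pd.DataFrame:
    """Read a clinical TSV requiring ``sample``, ``os_time``, ``os_event``.

    Extra columns are kept as covariates.  ``os_time`` is overall-survival
    time in months (strictly positive); ``os_event`` is 0/1.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    missing = [c for c in ("sample", "os_time", "os_event") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    df = df.set_index("sample")
    df["os_time"] = pd.to_numeric(df["os_time"])
    bad_t = df.index[df["os_time"] <= 0]
    if len(bad_t):
        raise ValueError(f"non-positive os_time for sample {bad_t[0]!r}")
    events = pd.to_numeric(df["os_event"])
    if not events.isin([0, 1]).all():
        bad = df.index[~events.isin([0, 1])][0]
        raise ValueError(f"os_event must be 0/1; sample {bad!r} violates this")
    df["os_event"] = events.astype(int)
    if response_col is not None and response_col not in df.columns:
        raise FormatError(f"{path}: response column {response_col!r} not found")
    return df


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample", float_format="%.6g")


def response_to_binary(values: pd.Series) -> pd.Series:
    """Map RECIST labels (CR/PR responder, SD/PD non-responder) or 0/1 to int."""
    mapping = {"CR": 1, "PR": 1, "SD": 0, "PD": 0, "0": 0, "1": 1, 0: 0, 1: 1}
    out = values.map(mapping)
    if out.isna().any():
        bad = values[out.isna()].iloc[0]
        raise ValueError(f"unrecognized response label {bad!r}")
    return out.astype(int)


def read_maf_lite(path) -> pd.DataFrame:
    """Read a MAF-lite TSV (three required MAF columns; extras ignored).

    Unknown variant classifications are kept with class ``Other`` and a
    logged warning; duplicate (sample, gene, class) records are permitted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MAF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required MAF columns {missing}")
    out = pd.DataFrame(
        {
            "sample": df["Tumor_Sample_Barcode"],
            "gene": df["Hugo_Symbol"],
            "variant_class": df["Variant_Classification"],
        }
    )
    unknown = ~out["variant_class"].isin(VARIANT_CLASSES)
    if unknown.any():
        for vc in out.loc[unknown, "variant_class"].unique():
            logger.warning("unknown variant classification %r mapped to 'Other'", vc)
        out.loc[unknown, "variant_class"] = "Other"
    return out


def write_maf_lite(mutations: pd.DataFrame, path) -> None:
    pd.DataFrame(
        {
            "Tumor_Sample_Barcode": mutations["sample"],
            "Hugo_Symbol": mutations["gene"],
            "Variant_Classification": mutations["variant_class"],
        }
    ).to_csv(path, sep="\t", index=False)


def align_cohort(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    mutations: pd.DataFrame | None = None,
):
    """Restrict all tables to their common samples, in expression order.

    Mutation tables do not constrain the intersection (a sample without
    mutation records is simply mutation-free); mutation records for samples
    outside the cohort are dropped.
    """
    common = [s for s in expr.columns if s in set(clinical.index)]
    if not common:
        raise ValueError("no samples shared between expression and clinical tables")
    n_drop_e = expr.shape[1] - len(common)
    n_drop_c = clinical.shape[0] - len(common)
    if n_drop_e or n_drop_c:
        logger.info(
            "cohort alignment dropped %d expression and %d clinical samples",
            n_drop_e,
            n_drop_c,
        )
    expr_a = expr.loc[:, common]
    clin_a = clinical.loc[common]
    if mutations is None:
        return expr_a, clin_a, None
    mut_a = mutations[mutations["sample"].isin(set(common))].reset_index(drop=True)
    return expr_a, clin_a, mut_a
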