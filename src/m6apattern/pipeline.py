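"""End-to-end orchestration: cluster -> TME scores -> DEGs -> Cox screen ->
m6Ascore -> cutpoint -> survival/TMB/ICB associations, from one config.

Every stage logs, writes its tabular outputs under the configured output
directory, and records a completed/skipped status in ``report.json``.  All
randomness flows from the single master seed, so a fixed config yields a
byte-identical report.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    align_cohort,
    read_clinical_tsv,
    read_expression_tsv,
    read_gmt,
    read_maf_lite,
)
from .cluster import run_consensus, select_k
from .enrichment import ssgsea_scores, zscore_signature
from .degs import moderated_ttest, deg_overlap
from .survival import (
    cox_fit,
    cox_screen,
    encode_covariates,
    km_estimate,
    logrank_test,
    max_stat_cutpoint,
)
from .scoring import (
    auc_rank,
    compute_m6ascore,
    dichotomize_score,
    fisher_exact_2x2,
    spearman_corr,
)
from .mutations import cooccurrence_tests, mutation_frequency, tmb_per_sample

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    expression: str
    clinical: str
    regulators: str | list[str]
    outdir: str
    markers_gmt: str | None = None
    maf: str | None = None
    response_col: str | None = None
    orient_to: str | None = None
    covariates: list[str] = field(default_factory=lambda: ["age"])
    k_min: int = 2
    k_max: int = 5
    consensus_reps: int = 1000
    p_item: float = 0.8
    deg_alpha: float = 0.001
    cox_alpha: float = 0.05
    minprop: float = 0.1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("expression", "clinical"):
            if not Path(getattr(self, attr)).exists():
                raise FileNotFoundError(f"{attr} path not found: {getattr(self, attr)}")
        for attr in ("markers_gmt", "maf"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr} path not found: {value}")
        if isinstance(self.regulators, str) and not Path(self.regulators).exists():
            raise FileNotFoundError(f"regulators path not found: {self.regulators}")
        if not (2 <= self.k_min < self.k_max + 1):
            raise ValueError("need 2 <= k_min <= k_max")


@dataclass
class ReportBundle:
    report: dict
    outdir: Path

    def __getitem__(self, key):
        return self.report[key]


def _native(obj):
    """Recursively convert numpy scalars/arrays for JSON output."""
    if isinstance(obj, dict):
        return {str(k): _native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_native(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_native(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float):
        return round(obj, 12)
    return obj


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(_native(payload), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis described by ``config``.

    Stages with unmet optional inputs (no MAF, no response column) are
    skipped and recorded as such; any stage error aborts with the stage
    name after persisting the partial report.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": {**asdict(config)},
        "stages": [],
        "seed": config.seed,
    }
    stage_times: dict[str, float] = {}

    def run_stage(name: str, fn, skip_reason: str | None = None):
        if skip_reason is not None:
            logger.info("stage %s skipped: %s", name, skip_reason)
            report["stages"].append({"name": name, "status": "skipped"})
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report stage then abort
            report["stages"].append({"name": name, "status": "failed"})
            _write_json(report, out / "report.json")
            raise PipelineError(name, exc) from exc
        stage_times[name] = time.perf_counter() - t0
        logger.info("stage %s completed in %.2fs", name, stage_times[name])
        report["stages"].append({"name": name, "status": "completed"})
        return result

    # ---- load -------------------------------------------------------------
    def load():
        expr = read_expression_tsv(config.expression)
        clinical = read_clinical_tsv(config.clinical, response_col=config.response_col)
        mutations = read_maf_lite(config.maf) if config.maf else None
        expr, clinical, mutations = align_cohort(expr, clinical, mutations)
        if isinstance(config.regulators, str):
            regulators = [
                line.strip()
                for line in Path(config.regulators).read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
        else:
            regulators = list(config.regulators)
        markers = read_gmt(config.markers_gmt) if config.markers_gmt else None
        return expr, clinical, mutations, regulators, markers

    expr, clinical, mutations, regulators, markers = run_stage("load", load)
    report["n_samples"] = expr.shape[1]
    report["n_genes"] = expr.shape[0]

    # ---- consensus clustering --------------------------------------------
    def cluster():
        runs = []
        for k in range(config.k_min, config.k_max + 1):
            runs.append(
                run_consensus(
                    expr,
                    regulators,
                    k=k,
                    n_resamples=config.consensus_reps,
                    p_item=config.p_item,
                    seed=config.seed + k,
                )
            )
        sel = select_k(runs)
        chosen = next(r for r in runs if r.k == sel.chosen_k)
        labels = pd.Series(chosen.labels, index=expr.columns, name="cluster")
        labels.to_csv(out / "labels.tsv", sep="\t", index_label="sample")
        for r in runs:
            pd.DataFrame(
                r.consensus_matrix, index=expr.columns, columns=expr.columns
            ).to_csv(out / f"consensus_k{r.k}.tsv", sep="\t", float_format="%.6g")
        _write_json(
            {
                "candidate_ks": sel.ks,
                "pac": sel.pac,
                "cdf_area": sel.cdf_area,
                "delta_area": sel.delta_area,
                "chosen_k": sel.chosen_k,
                "rule": sel.rule,
            },
            out / "k_selection.json",
        )
        return sel, labels

    selection, cluster_labels = run_stage("cluster", cluster)
    report["k_selection"] = {
        "chosen_k": selection.chosen_k,
        "pac": {str(k): v for k, v in selection.pac.items()},
    }
    report["cluster_sizes"] = {
        str(k): int(v) for k, v in cluster_labels.value_counts().sort_index().items()
    }

    # ---- TME enrichment ---------------------------------------------------
    def tme():
        scores = ssgsea_scores(expr, markers)
        scores.scores.to_csv(out / "tme_scores.tsv", sep="\t", float_format="%.6g")
        return scores

    tme_scores = run_stage(
        "tme", tme, skip_reason=None if markers is not None else "no marker GMT"
    )
    if tme_scores is not None:
        report["tme"] = {
            "n_sets": len(tme_scores.set_names),
            "set_names": tme_scores.set_names,
        }

    # ---- phenotype-related genes -----------------------------------------
    def degs():
        ks = sorted(cluster_labels.unique())
        tables = {}
        for a, b in itertools.combinations(ks, 2):
            tab = moderated_ttest(
                expr,
                cluster_labels.index[cluster_labels == a],
                cluster_labels.index[cluster_labels == b],
            )
            tables[f"{a}_vs_{b}"] = tab
            tab.to_csv(out / f"deg_{a}_vs_{b}.tsv", sep="\t", float_format="%.6g")
        genes = deg_overlap(tables, alpha=config.deg_alpha)
        (out / "phenotype_genes.txt").write_text(
            "\n".join(genes) + "\n", encoding="utf-8"
        )
        return genes

    phenotype_genes = run_stage("degs", degs)
    report["phenotype_genes"] = {"n": len(phenotype_genes)}

    # ---- prognostic screen ------------------------------------------------
    def screen():
        table = cox_screen(expr, clinical, phenotype_genes, alpha=config.cox_alpha)
        table.to_csv(out / "cox_screen.tsv", sep="\t", float_format="%.6g")
        kept = table.index[table["keep"]].tolist()
        if len(kept) < 2:
            raise ValueError("fewer than 2 prognostic signature genes survived")
        return kept

    signature_genes = run_stage("cox_screen", screen)
    report["cox_screen"] = {
        "n_tested": len(phenotype_genes),
        "n_kept": len(signature_genes),
    }

    # ---- m6Ascore ---------------------------------------------------------
    def score_stage():
        orient = None
        if config.orient_to is not None:
            if markers is None or config.orient_to not in markers:
                raise ValueError(
                    f"orientation set {config.orient_to!r} not in marker GMT"
                )
            orient = zscore_signature(expr, markers[config.orient_to])
        result = compute_m6ascore(expr, signature_genes, orient_to=orient)
        result.score.to_csv(out / "m6ascore.tsv", sep="\t", index_label="sample")
        result.loadings.to_csv(
            out / "pca_loadings.tsv", sep="\t", index_label="gene", float_format="%.6g"
        )
        return result

    score_result = run_stage("m6ascore", score_stage)
    report["m6ascore"] = {
        "n_signature_genes": len(score_result.genes),
        "mean": float(score_result.score.mean()),
        "sd": float(score_result.score.std(ddof=1)),
        "var_explained": score_result.var_explained.tolist(),
        "orientation": score_result.orientation,
    }

    # ---- cutpoint + survival ---------------------------------------------
    def survival_stage():
        times = clinical["os_time"].to_numpy(float)
        events = clinical["os_event"].to_numpy(int)
        cut = max_stat_cutpoint(
            score_result.score.to_numpy(), times, events, minprop=config.minprop
        )
        groups = dichotomize_score(score_result.score, cut.cutpoint)
        groups.to_csv(out / "score_groups.tsv", sep="\t", index_label="sample")
        _write_json(
            {
                "cutpoint": cut.cutpoint,
                "max_stat": cut.max_stat,
                "n_low": cut.n_low,
                "n_high": cut.n_high,
                "minprop": cut.minprop,
            },
            out / "cutpoint.json",
        )
        lr = logrank_test(times, events, groups.to_numpy())
        km_rows = []
        km60 = {}
        for g in ("low", "high"):
            mask = groups.to_numpy() == g
            curve = km_estimate(times[mask], events[mask])
            km60[g] = curve.survival_at(60.0)
            for t, nr, d, s in zip(
                curve.times, curve.at_risk, curve.events, curve.survival
            ):
                km_rows.append((g, t, nr, d, s))
        pd.DataFrame(
            km_rows, columns=["group", "time", "at_risk", "events", "survival"]
        ).to_csv(out / "km.tsv", sep="\t", index=False, float_format="%.6g")

        high = (groups.to_numpy() == "high").astype(float)
        uni = cox_fit(times, events, high, names=["high_vs_low"])
        design = [pd.Series(score_result.score.to_numpy(), index=clinical.index, name="m6ascore")]
        covs = [c for c in config.covariates if c in clinical.columns]
        if covs:
            design.append(encode_covariates(clinical, covs))
        X = pd.concat(design, axis=1)
        multi = cox_fit(times, events, X.to_numpy(), names=list(X.columns))
        multi.summary().to_csv(
            out / "cox_multivariable.tsv", sep="\t", float_format="%.6g"
        )
        return cut, groups, lr, km60, uni, multi

    cut, score_groups, lr, km60, uni_cox, multi_cox = run_stage(
        "survival", survival_stage
    )
    report["cutpoint"] = {
        "value": cut.cutpoint,
        "max_stat": cut.max_stat,
        "n_low": cut.n_low,
        "n_high": cut.n_high,
    }
    report["survival"] = {
        "logrank_chisq": lr.chisq,
        "logrank_p": lr.p,
        "km_survival_60m": km60,
        "hr_high_vs_low": float(uni_cox.hr[0]),
        "hr_ci": [float(uni_cox.ci_lower[0]), float(uni_cox.ci_upper[0])],
        "multivariable": {
            name: {"hr": float(h), "p": float(pv)}
            for name, h, pv in zip(multi_cox.names, multi_cox.hr, multi_cox.p)
        },
    }

    # ---- mutation / TMB ---------------------------------------------------
    def mutation_stage():
        tmb = tmb_per_sample(mutations, clinical.index)
        tmb.to_csv(out / "tmb.tsv", sep="\t", index_label="sample")
        freq = mutation_frequency(mutations, clinical.index)
        freq.to_csv(out / "gene_freq.tsv", sep="\t", index_label="gene")
        rho, p = spearman_corr(score_result.score.to_numpy(), tmb.to_numpy())
        top_genes = freq.head(10).index.tolist()
        cooc = cooccurrence_tests(mutations, clinical.index, top_genes)
        cooc.to_csv(out / "cooccurrence.tsv", sep="\t", index=False, float_format="%.6g")
        high_mask = score_groups == "high"
        return {
            "tmb_spearman_rho": rho,
            "tmb_spearman_p": p,
            "median_tmb_low": float(tmb[~high_mask].median()),
            "median_tmb_high": float(tmb[high_mask].median()),
            "n_cooccurrence_pairs_tested": int(len(cooc)),
        }

    mut_summary = run_stage(
        "mutation",
        mutation_stage,
        skip_reason=None if mutations is not None else "no MAF provided",
    )
    if mut_summary is not None:
        report["tmb"] = mut_summary

    # ---- checkpoint-blockade response ------------------------------------
    def icb_stage():
        resp = clinical[config.response_col].astype(int).to_numpy()
        auc = auc_rank(-score_result.score.to_numpy(), resp)
        low_mask = (score_groups == "low").to_numpy()
        table = [
            [int((resp[low_mask] == 1).sum()), int((resp[low_mask] == 0).sum())],
            [int((resp[~low_mask] == 1).sum()), int((resp[~low_mask] == 0).sum())],
        ]
        fisher = fisher_exact_2x2(table)
        summary = {
            "auc_low_score_vs_response": auc,
            "response_rate_low": float(np.mean(resp[low_mask])),
            "response_rate_high": float(np.mean(resp[~low_mask])),
            "fisher_p": fisher.p,
            "fisher_or": fisher.odds_ratio if fisher.or_defined else None,
        }
        _write_json(summary, out / "associations.json")
        return summary

    icb_summary = run_stage(
        "icb",
        icb_stage,
        skip_reason=None
        if (config.response_col and config.response_col in clinical.columns)
        else "no response column",
    )
    if icb_summary is not None:
        report["icb"] = icb_summary

    _write_json(report, out / "report.json")
    logger.info("stage wall times (s): %s", {k: round(v, 2) for k, v in stage_times.items()})
    return ReportBundle(report=report, outdir=out)
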