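"""End-to-end orchestration of the two analysis stages.

The study flow has a discovery stage (spectral-count differential
comparison of paired PT/LT samples) and a clinicopathological validation
stage (group comparisons, ROC cutoff discovery, liver-RFS survival and Cox
models on a surgical cohort).  This module wires the component modules
together under one config, echoes the config and seed into every report,
and stamps reports with a content hash so reruns are verifiably identical.
No statistics are computed here — every number in a report comes from
``differential``, ``survival`` or ``simulate``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential as diff
from . import simulate as sim
from . import survival as surv
from .errors import ValidationError
from .io import (
    CohortTable,
    SpectralCountMatrix,
    read_annotation_table,
    read_cohort,
    read_count_table,
    lengths_from_fasta,
    write_report,
)

log = logging.getLogger("specount")


@dataclass
class PipelineConfig:
    """One config for both stages; exactly one input source per stage.

    For the discovery stage provide either real input paths
    (``counts_path`` + ``sample_map_path`` + ``lengths_path``/``fasta_path``)
    or a count-simulation config; likewise ``cohort_path`` or a cohort
    simulation config for the validation stage.
    """

    counts_path: str | None = None
    sample_map_path: str | None = None
    lengths_path: str | None = None
    fasta_path: str | None = None
    count_sim: sim.CountSimConfig | None = None

    cohort_path: str | None = None
    cohort_sim: sim.CohortSimConfig | None = None

    f: float = 0.5
    rsc_threshold: float = 1.0
    alpha: float = 0.05
    spi_min: float | None = None
    nsaf_ratio_min: float | None = None
    mode: str = "pooled"

    marker: str = "CNPY2"
    landmark_months: float = 120.0
    ties: str = "efron"
    univariate_alpha: float = 0.05

    seed: int = 0
    out_dir: str = "specount_out"

    def __post_init__(self) -> None:
        if isinstance(self.count_sim, dict):
            self.count_sim = sim.CountSimConfig(**self.count_sim)
        if isinstance(self.cohort_sim, dict):
            self.cohort_sim = sim.CohortSimConfig(**self.cohort_sim)
        has_real = self.counts_path is not None
        if has_real and self.count_sim is not None:
            raise ValidationError(
                "provide real count inputs or a simulation config, not both"
            )
        if self.cohort_path is not None and self.cohort_sim is not None:
            raise ValidationError(
                "provide a real cohort or a simulation config, not both"
            )
        for name, value, lo, hi in (
            ("f", self.f, 0.0, np.inf),
            ("alpha", self.alpha, 0.0, 1.0),
            ("univariate_alpha", self.univariate_alpha, 0.0, 1.0),
        ):
            if not (lo < value <= hi) and not (lo < value < hi):
                raise ValidationError(f"{name}={value} out of range")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _load_discovery_inputs(config: PipelineConfig):
    if config.count_sim is not None:
        cs = dataclasses.replace(config.count_sim, seed=config.seed)
        matrix, ann, truth = sim.simulate_counts(cs)
        return matrix, ann, truth
    if config.counts_path is None or config.sample_map_path is None:
        raise ValidationError("discovery stage needs counts + sample map or a simulation config")
    matrix = read_count_table(config.counts_path, config.sample_map_path)
    if config.fasta_path:
        ann = lengths_from_fasta(config.fasta_path)
    elif config.lengths_path:
        ann = read_annotation_table(config.lengths_path)
    else:
        raise ValidationError("discovery stage needs --lengths or --fasta")
    return matrix, ann, None


def run_discovery(config: PipelineConfig) -> dict:
    """Discovery stage: differential table, Venn summary, selected candidates."""
    matrix, ann, truth = _load_discovery_inputs(config)
    log.info(
        "discovery: %d proteins x %d samples (f=%g, |Rsc|>%g, alpha=%g)",
        matrix.counts.shape[0], matrix.counts.shape[1],
        config.f, config.rsc_threshold, config.alpha,
    )
    table = diff.differential_table(
        matrix, ann, f=config.f, rsc_threshold=config.rsc_threshold,
        alpha=config.alpha, mode=config.mode,
    )
    selected = diff.select_candidates(
        table, rsc_threshold=config.rsc_threshold, alpha=config.alpha,
        spi_min=config.spi_min, nsaf_ratio_min=config.nsaf_ratio_min,
    )
    venn = diff.venn_summary(matrix)
    n_pt = int((selected["direction"] == "PT").sum())
    n_lt = int((selected["direction"] == "LT").sum())
    log.info(
        "discovery funnel: %d identified -> %d selected (%d PT-up, %d LT-up)",
        venn.total, len(selected), n_pt, n_lt,
    )
    result = {
        "differential": table,
        "selected": selected,
        "venn": venn,
        "truth": truth,
        "summary": {
            "venn": {
                "pt_only": venn.pt_only, "lt_only": venn.lt_only,
                "shared": venn.shared, "total": venn.total,
                "percentages": venn.percentages(),
            },
            "n_selected": len(selected),
            "n_selected_pt": n_pt,
            "n_selected_lt": n_lt,
        },
    }
    return result


def group_comparison(cohort: CohortTable) -> pd.DataFrame:
    """Cohort-characteristics comparison across the three metastasis groups.

    Categorical factors use a chi-square test with an exact fallback when
    expected cells are small; continuous factors use Kruskal-Wallis.
    """
    t = cohort.table
    labels = t["group"].to_numpy()
    rows = []

    def cat(name, series):
        tab = pd.crosstab(series, t["group"])
        tab = tab.reindex(columns=["synchronous", "metachronous", "none"], fill_value=0)
        p = surv.contingency_test(tab.to_numpy(), method="auto")
        rows.append((name, "categorical", p))

    def cont(name, series):
        p = surv.rank_test(series.to_numpy(dtype=float), labels, "kruskal_wallis")
        rows.append((name, "continuous", p))

    cat("gender", t["gender"])
    cont("age", t["age"])
    cat("function_type", t["function_type"])
    cat("who_grade", t["who_grade"])
    cont("ki67", t["ki67"])
    cont("mitotic_count", t["mitotic_count"])
    cont("tumor_size_mm", t["tumor_size_mm"])
    cat("lymph_node_metastasis", t["lymph_node_metastasis"])
    cat("vascular_invasion", t["vascular_invasion"])
    cat("lymphatic_invasion", t["lymphatic_invasion"])
    cat("enets_stage", t["enets_stage"])
    for m in cohort.marker_columns:
        cat(m, t[m])
    return pd.DataFrame(rows, columns=["factor", "kind", "p"])


def run_validation(config: PipelineConfig) -> dict:
    """Validation stage: group comparison plus the liver-RFS survival report."""
    if config.cohort_sim is not None:
        cs = dataclasses.replace(config.cohort_sim, seed=config.seed)
        cohort, truth = sim.simulate_cohort(cs)
    elif config.cohort_path is not None:
        cohort, truth = read_cohort(config.cohort_path), None
    else:
        raise ValidationError("validation stage needs a cohort or a simulation config")

    sizes = cohort.group_sizes()
    log.info("validation: %d patients, groups %s", len(cohort.table), sizes)
    comparison = group_comparison(cohort)
    rfs = surv.liver_rfs_analysis(
        cohort, config.marker,
        landmark_months=config.landmark_months,
        ties=config.ties,
        univariate_alpha=config.univariate_alpha,
    )
    log.info(
        "liver RFS: %d analyzed (%d synchronous excluded), multivariate covariates %s",
        rfs.n_analyzed, rfs.n_excluded_synchronous, rfs.multivariate_covariates,
    )
    summary = {
        "group_sizes": sizes,
        "marker": rfs.marker,
        "n_excluded_synchronous": rfs.n_excluded_synchronous,
        "n_analyzed": rfs.n_analyzed,
        "landmark_months": rfs.landmark_months,
        "landmark_survival": {str(k): v for k, v in rfs.landmark_survival.items()},
        "logrank": dataclasses.asdict(rfs.logrank) if rfs.logrank else None,
        "roc": {k: dataclasses.asdict(v) for k, v in rfs.roc.items()},
        "multivariate_covariates": rfs.multivariate_covariates,
        "warnings": rfs.stratum_warnings,
    }
    return {
        "cohort": cohort,
        "truth": truth,
        "comparison": comparison,
        "rfs": rfs,
        "summary": summary,
    }


def _hash_payload(payload: dict) -> str:
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()


def write_stage_report(config: PipelineConfig, stage: str, result: dict) -> dict:
    """Write a stage's tables (TSV) and summary (JSON, with config echo/hash).

    The content hash covers the analysis parameters and results but not the
    output location, so identical runs hash identically wherever written.
    """
    payload = {"config": config.echo(), "stage": stage, **result["summary"]}
    hashed = dict(payload)
    hashed["config"] = {k: v for k, v in payload["config"].items() if k != "out_dir"}
    payload["content_hash"] = _hash_payload(hashed)
    tables = {}
    if stage == "discovery":
        tables["differential"] = result["differential"].reset_index(drop=True)
        tables["selected"] = result["selected"].reset_index(drop=True)
    else:
        tables["group_comparison"] = result["comparison"]
        tables["univariate"] = result["rfs"].univariate.reset_index()
        if result["rfs"].multivariate is not None:
            tables["multivariate"] = result["rfs"].multivariate.summary.reset_index()
    return write_report({**tables, **payload}, config.out_dir, stage)
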