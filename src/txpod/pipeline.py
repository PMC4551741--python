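"""End-to-end convenience pipeline: filter -> gene BMDs -> pathways -> PoD."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import continuous_bmd, pathway_bmd, pod_selection, prefilter
from .io_formats import DoseResponseSet, GeneSetCollection, RunConfig, TxpodError

logger = logging.getLogger("txpod")


@dataclass
class StudyResult:
    platform_tag: str
    tier: str
    gene_stats: pd.DataFrame
    tiers: dict[str, list[str]]
    bmd_results: list[continuous_bmd.BmdResult]
    pathway_summaries: list[pathway_bmd.PathwayBmdSummary] = field(default_factory=list)

    @property
    def gene_bmds(self) -> np.ndarray:
        return np.array([r.bmd for r in self.bmd_results
                         if np.isfinite(r.bmd) and not r.excluded_above_top])


def run_study(
    dset: DoseResponseSet,
    gene_sets: GeneSetCollection | None = None,
    cfg: RunConfig | None = None,
    tier: str | None = None,
    with_bmdl: bool = False,
) -> StudyResult:
    """Apply present calls, the chosen filter tier, gene BMD modeling, and
    (when gene sets are given) pathway aggregation."""
    cfg = cfg or RunConfig()
    tier = tier or cfg.filter_tier
    if dset.value_scale == "counts":
        present = prefilter.present_call_counts(dset)
    else:
        present = pd.Series(True, index=dset.values.index)
    fcfg = prefilter.FilterConfig(tier=tier, alpha=cfg.alpha,
                                  fc_threshold=cfg.fc_threshold)
    stats_df = prefilter.compute_gene_stats(dset, present)
    tiers = prefilter.select_genes(stats_df, fcfg)
    genes = tiers[tier]
    if not genes:
        raise TxpodError(f"no genes pass filter tier {tier!r}")
    results = continuous_bmd.run_gene_bmd(dset, genes, cfg, with_bmdl=with_bmdl)
    summaries = []
    if gene_sets is not None:
        summaries = pathway_bmd.aggregate_pathways(results, gene_sets,
                                                   cfg.min_genes_report)
    return StudyResult(platform_tag=dset.platform_tag, tier=tier,
                       gene_stats=stats_df, tiers=tiers, bmd_results=results,
                       pathway_summaries=summaries)


def pod_reports(result: StudyResult, cfg: RunConfig | None = None,
                moa_set_name: str | None = None) -> list[pod_selection.PodReport]:
    """All PoD strategies that are computable from one study's summaries."""
    cfg = cfg or RunConfig()
    reports: list[pod_selection.PodReport] = []
    try:
        reports.append(pod_selection.pod_lowest_pathway(
            result.pathway_summaries, cfg.min_genes_pod, result.platform_tag))
    except TxpodError as exc:
        logger.warning("lowest-pathway PoD unavailable: %s", exc)
    try:
        reports.extend(pod_selection.pod_distribution_summary(
            result.pathway_summaries, cfg.min_genes_pod,
            platform_tag=result.platform_tag).values())
    except TxpodError as exc:
        logger.warning("distribution PoD unavailable: %s", exc)
    if moa_set_name:
        try:
            reports.append(pod_selection.pod_moa(
                result.pathway_summaries, moa_set_name, cfg.min_genes_pod,
                result.platform_tag))
        except TxpodError as exc:
            logger.warning("MoA PoD unavailable: %s", exc)
    return reports
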