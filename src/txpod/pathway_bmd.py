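"""Aggregate per-gene BMD/BMDL values to gene-set (pathway) summaries.

A pathway summary is emitted when at least ``min_genes`` of its members were
successfully modeled (defined BMD, not excluded above the top dose).  Means
and medians are arithmetic; genes with a BMD but no BMDL contribute to the
BMD statistics only, with the BMDL gene count reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .continuous_bmd import BmdResult
from .io_formats import GeneSetCollection

logger = logging.getLogger("txpod")


@dataclass
class PathwayBmdSummary:
    set_name: str
    n_genes_modeled: int
    bmd_mean: float
    bmd_median: float
    n_genes_bmdl: int
    bmdl_mean: float
    bmdl_median: float
    genes: list[str] = field(default_factory=list, repr=False)
    gene_bmds: list[float] = field(default_factory=list, repr=False)
    gene_bmdls: list[float] = field(default_factory=list, repr=False)


def modeled_gene_bmds(results: list[BmdResult]) -> dict[str, tuple[float, float]]:
    """gene -> (bmd, bmdl) for genes with a usable BMD (case-normalized keys)."""
    out: dict[str, tuple[float, float]] = {}
    for r in results:
        if r.model_name is None or not np.isfinite(r.bmd) or r.excluded_above_top:
            continue
        out[r.gene.upper()] = (r.bmd, r.bmdl)
    return out


def aggregate_pathways(
    results: list[BmdResult],
    sets: GeneSetCollection,
    min_genes: int = 3,
) -> list[PathwayBmdSummary]:
    """Per-set mean/median BMD and BMDL over modeled member genes.

    Gene-symbol matching is case-insensitive; a gene belonging to several
    sets contributes to each independently.
    """
    by_gene = modeled_gene_bmds(results)
    summaries: list[PathwayBmdSummary] = []
    for name, members in sets:
        hits = [(g, *by_gene[g.upper()]) for g in dict.fromkeys(members)
                if g.upper() in by_gene]
        if len(hits) < min_genes:
            continue
        genes = [h[0] for h in hits]
        bmds = np.array([h[1] for h in hits], dtype=float)
        bmdls = np.array([h[2] for h in hits], dtype=float)
        have_l = np.isfinite(bmdls)
        summaries.append(PathwayBmdSummary(
            set_name=name,
            n_genes_modeled=len(hits),
            bmd_mean=float(bmds.mean()),
            bmd_median=float(np.median(bmds)),
            n_genes_bmdl=int(have_l.sum()),
            bmdl_mean=float(bmdls[have_l].mean()) if have_l.any() else float("nan"),
            bmdl_median=float(np.median(bmdls[have_l])) if have_l.any() else float("nan"),
            genes=genes,
            gene_bmds=[float(b) for b in bmds],
            gene_bmdls=[float(b) for b in bmdls],
        ))
    summaries.sort(key=lambda s: (s.bmd_mean, s.set_name))
    logger.info("pathway aggregation: %d of %d sets with >= %d modeled genes",
                len(summaries), len(sets), min_genes)
    return summaries
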