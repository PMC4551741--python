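"""Point-of-departure (PoD) selection from the pathway BMD ensemble.

Four strategies distill the many pathway-level benchmark doses into a single
PoD for risk assessment:

1. lowest pathway — the smallest pathway BMD-mean (most sensitive pathway);
2. cross-validated lowest — the smallest pathway BMD-mean among pathways
   that could also be modeled on at least one other platform;
3. distribution summaries — the mode / mean / median of all pathway
   BMD-means (the mode anchors the PoD to the bulk of the transcriptional
   response; for multimodal ensembles the most sensitive peak is used);
4. mode-of-action pathway — the BMD-mean of a named mechanism-relevant
   pathway.

Only pathways with at least ``min_genes_pod`` (default 4) modeled genes are
eligible.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np

from .io_formats import TxpodError
from .pathway_bmd import PathwayBmdSummary


@dataclass
class PodReport:
    approach: str
    pod_bmd: float
    pod_bmdl: float
    set_name: str | None = None
    platform_tag: str | None = None
    n_pathways_considered: int = 0
    multimodal: bool = False


def _eligible(summaries: list[PathwayBmdSummary],
              min_genes: int) -> list[PathwayBmdSummary]:
    return [s for s in summaries if s.n_genes_modeled >= min_genes]


def _pick_lowest(elig: list[PathwayBmdSummary]) -> PathwayBmdSummary:
    # ties: larger modeled-gene count, then name order
    return min(elig, key=lambda s: (s.bmd_mean, -s.n_genes_modeled, s.set_name))


def pod_lowest_pathway(summaries: list[PathwayBmdSummary],
                       min_genes_pod: int = 4,
                       platform_tag: str | None = None) -> PodReport:
    """Approach 1: the most sensitive eligible pathway."""
    elig = _eligible(summaries, min_genes_pod)
    if not elig:
        raise TxpodError("no pathway with enough modeled genes for a PoD")
    best = _pick_lowest(elig)
    return PodReport("lowest_pathway", best.bmd_mean, best.bmdl_mean,
                     best.set_name, platform_tag, len(elig))


def pod_cross_validated(
    summaries_by_platform: dict[str, list[PathwayBmdSummary]],
    reference: str,
    min_genes_pod: int = 4,
) -> PodReport:
    """Approach 2: most sensitive reference pathway modeled on >= 2 platforms."""
    if len(summaries_by_platform) < 2:
        raise TxpodError("cross-validation needs at least two platforms")
    if reference not in summaries_by_platform:
        raise TxpodError(f"reference platform {reference!r} not supplied")
    ref = _eligible(summaries_by_platform[reference], min_genes_pod)
    others: set[str] = set()
    for plat, summ in summaries_by_platform.items():
        if plat == reference:
            continue
        others |= {s.set_name for s in _eligible(summ, min_genes_pod)}
    validated = [s for s in ref if s.set_name in others]
    if not validated:
        raise TxpodError("no pathway is modeled on a second platform")
    best = _pick_lowest(validated)
    return PodReport("cross_validated_lowest", best.bmd_mean, best.bmdl_mean,
                     best.set_name, reference, len(validated))


def _log_mode(values: np.ndarray, bin_width: float = 0.1) -> tuple[float, bool]:
    """Mode of a log10 histogram with fixed bin width; returns (mode, multimodal).

    Bins within one count of the tallest and separated from it by a valley
    mark multimodality; the lowest-dose peak is then reported.
    """
    logs = np.log10(values)
    lo = np.floor(logs.min() / bin_width) * bin_width
    hi = np.ceil(logs.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(logs, bins=edges)
    top = counts.max()
    peak_bins = [i for i in range(len(counts))
                 if counts[i] >= top - 1 and
                 (i == 0 or counts[i] >= counts[i - 1]) and
                 (i == len(counts) - 1 or counts[i] >= counts[i + 1])]
    multimodal = False
    if len(peak_bins) > 1:
        # require a genuine valley between distinct peaks
        for a, b in zip(peak_bins[:-1], peak_bins[1:]):
            if counts[a:b + 1].min() < min(counts[a], counts[b]):
                multimodal = True
                break
    chosen = peak_bins[0] if multimodal else int(np.argmax(counts))
    mid = 0.5 * (edges[chosen] + edges[chosen + 1])
    # the mode is a location of observed values: keep the bin midpoint
    # inside the data range
    mode = float(np.clip(10.0 ** mid, values.min(), values.max()))
    return mode, multimodal


def pod_distribution_summary(
    summaries: list[PathwayBmdSummary],
    min_genes_pod: int = 4,
    bin_width: float = 0.1,
    platform_tag: str | None = None,
) -> dict[str, PodReport]:
    """Approach 3: mode / mean / median of the pathway BMD-mean distribution."""
    elig = _eligible(summaries, min_genes_pod)
    if len(elig) < 5:
        raise TxpodError("too few eligible pathways for a distribution summary")
    bmds = np.array([s.bmd_mean for s in elig])
    bmdls = np.array([s.bmdl_mean for s in elig])
    ok_l = np.isfinite(bmdls)
    mode_bmd, multimodal = _log_mode(bmds, bin_width)
    mode_bmdl, _ = _log_mode(bmdls[ok_l], bin_width) if ok_l.any() else (float("nan"), False)
    n = len(elig)
    return {
        "mode": PodReport("distribution_mode", mode_bmd, mode_bmdl,
                          None, platform_tag, n, multimodal),
        "mean": PodReport("distribution_mean", float(bmds.mean()),
                          float(bmdls[ok_l].mean()) if ok_l.any() else float("nan"),
                          None, platform_tag, n),
        "median": PodReport("distribution_median", float(np.median(bmds)),
                            float(np.median(bmdls[ok_l])) if ok_l.any() else float("nan"),
                            None, platform_tag, n),
    }


def pod_moa(summaries: list[PathwayBmdSummary], moa_set_name: str,
            min_genes_pod: int = 4,
            platform_tag: str | None = None) -> PodReport:
    """Approach 4: the BMD-mean of a named mode-of-action pathway."""
    by_name = {s.set_name: s for s in summaries}
    if moa_set_name not in by_name:
        near = difflib.get_close_matches(moa_set_name, by_name, n=3, cutoff=0.4)
        hint = f"; similar names: {near}" if near else ""
        raise TxpodError(f"pathway {moa_set_name!r} not found{hint}")
    s = by_name[moa_set_name]
    if s.n_genes_modeled < min_genes_pod:
        raise TxpodError(
            f"pathway {moa_set_name!r} has only {s.n_genes_modeled} modeled "
            f"genes (need {min_genes_pod})")
    return PodReport("moa_pathway", s.bmd_mean, s.bmdl_mean, s.set_name,
                     platform_tag, 1)
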