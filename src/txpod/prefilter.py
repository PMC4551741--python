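"""Present calls, per-gene ANOVA, FDR adjustment, fold changes, filter tiers.

Three pre-filter tiers precede benchmark-dose modeling: ``none`` (all present
genes), ``anova`` (one-way ANOVA p < alpha across dose groups), and ``fdr``
(Benjamini-Hochberg adjusted p < alpha).  A gene is additionally a DEG when
its adjusted p passes and its signed fold change versus control reaches the
threshold (default +/-1.5) at at least one dose.

The differential-expression engine here is classical one-way ANOVA with BH
adjustment.  The moderated statistics some platforms use (shrinkage t /
permutation Fs) are intentionally not reproduced: the downstream BMD/PoD
machinery consumes gene lists, and the classical test is fully specified and
reproducible.  This is the largest simplification in the package; see the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import DoseResponseSet, TxpodError


@dataclass
class FilterConfig:
    tier: str = "anova"
    alpha: float = 0.05
    fc_threshold: float = 1.5
    cpm_threshold: float = 0.5
    min_samples_cpm: int = 3
    background_sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise TxpodError("alpha must be in (0, 1)")
        if min(self.fc_threshold, self.cpm_threshold,
               self.background_sd_multiplier) <= 0:
            raise TxpodError("thresholds must be positive")


def present_call_counts(
    dset: DoseResponseSet, cpm_threshold: float = 0.5, min_samples: int = 3
) -> pd.Series:
    """Detectability filter for count data.

    A gene is present when at least ``min_samples`` samples within at least
    one dose group reach ``cpm_threshold`` counts-per-million (inclusive).
    """
    if dset.value_scale != "counts":
        raise TxpodError("present_call_counts requires a counts-scale dataset")
    lib = dset.values.sum(axis=0)
    if (lib <= 0).any():
        raise TxpodError("library sizes must be positive")
    cpm = dset.values.div(lib, axis=1) * 1e6
    present = pd.Series(False, index=dset.values.index)
    for dose in dset.doses:
        cols = dset.group_columns(dose)
        hits = (cpm[cols] >= cpm_threshold).sum(axis=1)
        present |= hits >= min_samples
    return present


def present_call_intensity(
    dset: DoseResponseSet,
    background_mean: float,
    background_sd: float,
    multiplier: float = 3.0,
) -> pd.Series:
    """Detectability filter for intensity data.

    Signals are compared (on the linear intensity scale) against the
    background mean plus ``multiplier`` background SDs; a gene is present
    when all but one sample of at least one dose group clear the threshold,
    mirroring the "3 of 4" leniency of the counts rule.
    """
    if background_sd < 0:
        raise TxpodError("background_sd must be non-negative")
    threshold = background_mean + multiplier * background_sd
    if dset.value_scale == "log2_intensity":
        # compare on the stored log2 scale (monotone-equivalent, and exact
        # at the boundary)
        signal, cut = dset.values, np.log2(threshold)
    else:
        signal, cut = dset.values, threshold
    present = pd.Series(False, index=dset.values.index)
    for dose in dset.doses:
        cols = dset.group_columns(dose)
        quorum = max(len(cols) - 1, 1)
        hits = (signal[cols] >= cut).sum(axis=1)
        present |= hits >= quorum
    return present


def anova_pvalues(dset: DoseResponseSet) -> pd.Series:
    """Classical one-way ANOVA p across dose groups, per gene.

    Genes with zero between- and within-group variance get p = 1.
    """
    groups = []
    for dose in dset.doses:
        cols = dset.group_columns(dose)
        if len(cols) < 2:
            raise TxpodError(f"dose group {dose:g} has fewer than 2 samples")
        groups.append(dset.log2_values()[cols].to_numpy())
    if len(groups) < 2:
        raise TxpodError("need at least 2 dose groups")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*groups, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # constant genes: F is 0/0 -> NaN; define p = 1
    p[np.isnan(p)] = 1.0
    return pd.Series(p, index=dset.values.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise TxpodError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _signed_fc_from_log2(delta: np.ndarray) -> np.ndarray:
    """Signed fold change: +2^d for d >= 0, -2^(-d) otherwise (-2 = halving)."""
    return np.where(delta >= 0, 2.0 ** delta, -(2.0 ** (-delta)))


def fold_changes(dset: DoseResponseSet) -> pd.DataFrame:
    """Per-gene signed fold change of each dose group versus control.

    Log-scale data use the difference of group means; delta-Ct data use the
    delta-delta-Ct rule (fold change 2^-ddCt).  Both reduce to the same
    signed convention via :func:`DoseResponseSet.log2_values`.
    """
    log2 = dset.log2_values()
    ctrl_cols = dset.group_columns(0.0)
    if not ctrl_cols:
        raise TxpodError("control group absent")
    ctrl_mean = log2[ctrl_cols].mean(axis=1)
    out = {}
    for dose in dset.doses:
        delta = log2[dset.group_columns(dose)].mean(axis=1) - ctrl_mean
        out[dose] = _signed_fc_from_log2(delta.to_numpy())
    return pd.DataFrame(out, index=dset.values.index)


def pairwise_pvalues(dset: DoseResponseSet) -> pd.DataFrame:
    """Per-dose Welch t-test p versus control (bookkeeping for DEG calls)."""
    log2 = dset.log2_values()
    ctrl = log2[dset.group_columns(0.0)].to_numpy()
    out = {}
    for dose in dset.doses:
        if dose == 0.0:
            out[dose] = np.ones(len(log2))
            continue
        grp = log2[dset.group_columns(dose)].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(grp, ctrl, axis=1, equal_var=False).pvalue
        p = np.asarray(p, dtype=float)
        p[np.isnan(p)] = 1.0
        out[dose] = p
    return pd.DataFrame(out, index=log2.index)


def compute_gene_stats(dset: DoseResponseSet, present: pd.Series | None = None
                       ) -> pd.DataFrame:
    """ANOVA p, BH-adjusted p, max |signed FC|, per-dose FCs for present genes."""
    if present is not None:
        dset = dset.subset_genes(list(present.index[present]))
    anova_p = anova_pvalues(dset)
    fdr_p = pd.Series(bh_adjust(anova_p.to_numpy()), index=anova_p.index)
    fc = fold_changes(dset)
    nonzero = [d for d in dset.doses if d > 0]
    max_abs_fc = fc[nonzero].abs().max(axis=1)
    stats_df = pd.DataFrame({
        "anova_p": anova_p,
        "fdr_p": fdr_p,
        "max_abs_fc": max_abs_fc,
    })
    for d in nonzero:
        stats_df[f"fc_{d:g}"] = fc[d]
    return stats_df


def select_genes(stats_df: pd.DataFrame, cfg: FilterConfig) -> dict[str, list[str]]:
    """Gene lists for each filter tier plus the DEG list.

    Tiers are nested by construction: fdr (subset) anova (subset) none.  The
    DEG list is the fdr tier further restricted by the fold-change threshold.
    """
    if cfg.tier not in ("none", "anova", "fdr"):
        raise TxpodError(f"unknown filter tier {cfg.tier!r}")
    all_genes = list(stats_df.index)
    anova_genes = list(stats_df.index[stats_df["anova_p"] < cfg.alpha])
    fdr_genes = list(stats_df.index[(stats_df["fdr_p"] < cfg.alpha)
                                    & (stats_df["anova_p"] < cfg.alpha)])
    degs = list(stats_df.index[
        (stats_df["fdr_p"] < cfg.alpha)
        & (stats_df["anova_p"] < cfg.alpha)
        & (stats_df["max_abs_fc"] >= cfg.fc_threshold)
    ])
    return {"none": all_genes, "anova": anova_genes, "fdr": fdr_genes, "deg": degs}
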