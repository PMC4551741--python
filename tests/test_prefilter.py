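import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txpod import DoseResponseSet, SimConfig, TxpodError, simulate_platform_study
from txpod.prefilter import (
    FilterConfig,
    anova_pvalues,
    bh_adjust,
    compute_gene_stats,
    fold_changes,
    present_call_counts,
    present_call_intensity,
    select_genes,
)


def _counts_dset(matrix, doses, platform="rnaseq"):
    cols = [f"s{i}" for i in range(len(doses))]
    vals = pd.DataFrame(matrix, columns=cols,
                        index=[f"G{i}" for i in range(len(matrix))])
    return DoseResponseSet(platform, vals,
                           pd.Series(doses, index=cols, dtype=float), "counts")


class TestPresentCalls:
    def test_three_of_four_rule(self):
        # G0: cpm 0.6,0.6,0.6,0.1 in control, 0 elsewhere -> present
        # G1: all zero -> absent; G2 fills the library
        lib = 10_000_000
        row0 = [6, 6, 6, 1] + [0] * 12    # ~0.6, 0.6, 0.6, 0.1 cpm in control
        row1 = [0] * 16
        row2 = [lib] * 16
        dset = _counts_dset([row0, row1, row2],
                            np.repeat([0, 2, 4, 8], 4))
        flags = present_call_counts(dset, cpm_threshold=0.5, min_samples=3)
        assert bool(flags["G0"]) is True
        assert bool(flags["G1"]) is False

    def test_boundary_cpm_is_inclusive(self):
        lib = 2_000_000
        # exactly 0.5 cpm in exactly 3 samples of one group
        row0 = [1, 1, 1, 0] + [0] * 12
        row2 = [lib - r for r in row0]
        dset = _counts_dset([row0, row2], np.repeat([0, 2, 4, 8], 4))
        cpm0 = 1 / dset.values.sum(axis=0).iloc[0] * 1e6
        flags = present_call_counts(dset, cpm_threshold=float(cpm0),
                                    min_samples=3)
        assert bool(flags["G0"]) is True

    def test_non_count_scale_rejected(self, tiny_dset):
        with pytest.raises(TxpodError):
            present_call_counts(tiny_dset)

    def test_intensity_thresholds(self):
        cols = [f"s{i}" for i in range(8)]
        doses = pd.Series([0, 0, 2, 2, 4, 4, 8, 8], index=cols, dtype=float)
        bg_mean, bg_sd = 100.0, 10.0
        at_bg = np.log2(np.full(8, bg_mean))
        above = np.log2(np.full(8, bg_mean + 4 * bg_sd))
        at_3sd = np.log2(np.full(8, bg_mean + 3 * bg_sd))
        vals = pd.DataFrame([at_bg, above, at_3sd],
                            index=["Gbg", "Ghigh", "Gedge"], columns=cols)
        dset = DoseResponseSet("microarray", vals, doses, "log2_intensity")
        flags = present_call_intensity(dset, bg_mean, bg_sd, 3.0)
        assert bool(flags["Gbg"]) is False
        assert bool(flags["Ghigh"]) is True
        assert bool(flags["Gedge"]) is True  # inclusive boundary


class TestAnova:
    def test_matches_hand_computed_f(self):
        """Groups (1,2),(3,4),(5,6),(7,8): SSB=40, SSW=2, F=26.667."""
        cols = [f"s{i}" for i in range(8)]
        doses = pd.Series([0, 0, 2, 2, 4, 4, 8, 8], index=cols, dtype=float)
        vals = pd.DataFrame([[1, 2, 3, 4, 5, 6, 7, 8]], index=["G"],
                            columns=cols, dtype=float)
        dset = DoseResponseSet("microarray", vals, doses, "log2_intensity")
        p = anova_pvalues(dset)
        from scipy.stats import f as fdist
        f_hand = (40.0 / 3) / (2.0 / 4)
        p_hand = float(fdist.sf(f_hand, 3, 4))
        assert np.isclose(p["G"], p_hand, rtol=1e-12)

    def test_identical_group_means_give_p_one(self):
        cols = [f"s{i}" for i in range(8)]
        doses = pd.Series([0, 0, 2, 2, 4, 4, 8, 8], index=cols, dtype=float)
        vals = pd.DataFrame([[1, 2, 1, 2, 1, 2, 1, 2]], index=["G"],
                            columns=cols, dtype=float)
        dset = DoseResponseSet("microarray", vals, doses, "log2_intensity")
        assert anova_pvalues(dset)["G"] == pytest.approx(1.0)

    def test_scale_invariance(self, tiny_dset):
        p1 = anova_pvalues(tiny_dset)
        doubled = DoseResponseSet(
            tiny_dset.platform_tag, tiny_dset.values * 2,
            tiny_dset.sample_doses, tiny_dset.value_scale)
        p2 = anova_pvalues(doubled)
        assert np.allclose(p1, p2)

    def test_constant_gene_gets_p_one(self, tiny_dset):
        assert anova_pvalues(tiny_dset)["GB"] == pytest.approx(1.0)

    def test_single_sample_group_rejected_at_construction(self):
        cols = [f"s{i}" for i in range(5)]
        doses = pd.Series([0, 0, 2, 2, 4], index=cols, dtype=float)
        vals = pd.DataFrame([[1, 2, 3, 4, 5]], index=["G"], columns=cols,
                            dtype=float)
        with pytest.raises(TxpodError, match="fewer than 2"):
            DoseResponseSet("microarray", vals, doses, "log2_intensity")


def _bh_bruteforce(p):
    """Step-up definition: adj_(i) = min_{j>=i} min(1, m/j * p_(j))."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m / rank * p[idx])
        adj[idx] = running
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(TxpodError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_bruteforce_definition(self, pvals):
        assert np.allclose(bh_adjust(pvals), _bh_bruteforce(pvals), atol=1e-12)


class TestFoldChanges:
    def test_signed_convention(self):
        cols = [f"s{i}" for i in range(4)]
        doses = pd.Series([0, 0, 4, 4], index=cols, dtype=float)
        vals = pd.DataFrame([[1, 1, 2, 2],      # delta +1 -> FC +2
                             [2, 2, 1, 1],      # delta -1 -> FC -2
                             [3, 3, 3, 3]],     # delta 0 -> FC +1
                            index=["up", "down", "flat"], columns=cols,
                            dtype=float)
        dset = DoseResponseSet("microarray", vals, doses, "log2_intensity")
        fc = fold_changes(dset)
        assert fc.loc["up", 4.0] == pytest.approx(2.0)
        assert fc.loc["down", 4.0] == pytest.approx(-2.0)
        assert fc.loc["flat", 4.0] == pytest.approx(1.0)
        assert np.allclose(fc[0.0], 1.0)  # control vs itself

    def test_delta_ct_rule(self):
        """ddCt = -1 means doubling: FC = +2."""
        cols = [f"s{i}" for i in range(4)]
        doses = pd.Series([0, 0, 4, 4], index=cols, dtype=float)
        vals = pd.DataFrame([[5.0, 5.0, 4.0, 4.0]], index=["G"], columns=cols)
        dset = DoseResponseSet("qpcr", vals, doses, "delta_ct")
        fc = fold_changes(dset)
        assert fc.loc["G", 4.0] == pytest.approx(2.0)


class TestSelectGenes:
    def test_fdr_passing_non_deg(self):
        stats_df = pd.DataFrame(
            {"anova_p": [0.001, 0.001], "fdr_p": [0.04, 0.04],
             "max_abs_fc": [1.6, 1.2]}, index=["deg", "modeled_only"])
        out = select_genes(stats_df, FilterConfig(tier="fdr"))
        assert "deg" in out["deg"] and "modeled_only" not in out["deg"]
        assert set(out["fdr"]) == {"deg", "modeled_only"}

    def test_unknown_tier_rejected(self):
        with pytest.raises(TxpodError):
            FilterConfig(tier="fdr", alpha=2.0)

    def test_nesting_property_on_simulated_study(self, small_rnaseq):
        dset, _ = small_rnaseq
        pres = present_call_counts(dset)
        stats_df = compute_gene_stats(dset, pres)
        out = select_genes(stats_df, FilterConfig(tier="anova"))
        assert set(out["fdr"]) <= set(out["anova"]) <= set(out["none"])
        assert set(out["deg"]) <= set(out["fdr"])

    def test_null_simulation_retains_alpha_fraction(self):
        cfg = SimConfig(n_genes=2000, frac_responders=0.0, noise_sd=0.25,
                        compression_factor=1.0, n_per_dose=(5, 5, 5, 5),
                        seed=42)
        dset, _ = simulate_platform_study(cfg, "microarray")
        stats_df = compute_gene_stats(dset)
        frac = (stats_df["anova_p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065
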