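"""Synthetic multi-platform dose-response studies with known ground truth.

The generator emulates a 21-day rodent oral-gavage design: doses 0/2/4/8
mg/kg/day (mkd), 4-5 biological replicates per dose, and three measurement
platforms — sequencing-like (counts via a Poisson-lognormal model),
microarray-like (log2 intensities with a global fold-change compression
factor, mimicking two-color signal compression), and qPCR-like (normalized
delta-Ct values).

A fraction of genes are true responders whose mean log2-expression follows a
Hill, power, or linear curve in dose.  Each responder's amplitude is anchored
so that its curve crosses the benchmark-response band (``bmr_sd`` residual
standard deviations) exactly at a drawn "true BMD", giving every responder a
closed-form ground-truth benchmark dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import DoseResponseSet, GeneSetCollection, TxpodError

DICT_MODELS = ("hill", "power", "linear")


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the emulated study: 4 doses (0/2/4/8 mkd), n = 4/dose for
    sequencing-like data and n = 5,5,4,5 for microarray-like data, residual
    SD 0.25 on the log2 scale, and a 1.349-SD benchmark response.
    """

    doses: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0)
    n_per_dose: tuple[int, ...] | None = None  # platform default when None
    n_genes: int = 1000
    frac_responders: float = 0.2
    true_model_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # hill, power, linear
    true_bmd_distribution: tuple[float, float] = (0.5, 6.0)  # log-uniform, mkd
    noise_sd: float = 0.25
    bmr_sd: float = 1.349
    compression_factor: float = 0.7
    library_size: float = 2e6
    max_top_log2fc: float = 8.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise TxpodError("n_genes must be >= 1")
        if not 0 <= self.frac_responders <= 1:
            raise TxpodError("frac_responders must be in [0, 1]")
        if self.noise_sd < 0:
            raise TxpodError("noise_sd must be non-negative")
        if abs(sum(self.true_model_mix) - 1.0) > 1e-9:
            raise TxpodError("true_model_mix must sum to 1")
        lo, hi = self.true_bmd_distribution
        if not (0 < lo < hi):
            raise TxpodError("true_bmd_distribution bounds must satisfy 0 < low < high")
        if not 0 < self.compression_factor <= 1:
            raise TxpodError("compression_factor must be in (0, 1]")
        if self.max_top_log2fc <= 0:
            raise TxpodError("max_top_log2fc must be positive")
        if 0.0 not in self.doses:
            raise TxpodError("doses must include control (0)")

    def replicates(self, platform_tag: str) -> tuple[int, ...]:
        if self.n_per_dose is not None:
            return tuple(self.n_per_dose)
        if platform_tag == "microarray":
            return (5, 5, 4, 5)[: len(self.doses)]
        return (4,) * len(self.doses)


@dataclass
class GroundTruth:
    """Per-gene generative truth: responder status, curve, and true BMD."""

    table: pd.DataFrame  # gene-indexed: responder, model, params..., true_bmd

    @property
    def responders(self) -> list[str]:
        return list(self.table.index[self.table["responder"]])

    @property
    def non_responders(self) -> list[str]:
        return list(self.table.index[~self.table["responder"]])

    def true_bmd(self, gene: str) -> float:
        return float(self.table.loc[gene, "true_bmd"])


def _unit_curve(model: str, d: np.ndarray, k: float, n: float, delta: float) -> np.ndarray:
    """Unit-amplitude response shape at dose d (0 at control, increasing)."""
    d = np.asarray(d, dtype=float)
    if model == "hill":
        return d**n / (k**n + d**n)
    if model == "power":
        return d**delta
    if model == "linear":
        return d
    raise TxpodError(f"unknown true model {model!r}")


def _invert_curve(model: str, u: float, k: float, n: float,
                  delta: float) -> float:
    """Closed-form dose at which the unit curve reaches level u."""
    if model == "linear":
        return float(u)
    if model == "power":
        return float(u ** (1.0 / delta))
    if model == "hill":
        if u >= 1.0:
            return float("inf")
        return float(k * (u / (1.0 - u)) ** (1.0 / n))
    raise TxpodError(f"unknown true model {model!r}")


def simulate_platform_study(
    cfg: SimConfig, platform_tag: str
) -> tuple[DoseResponseSet, GroundTruth]:
    """Simulate one platform's study and its gene-level ground truth.

    Responder amplitudes solve ``|mu(true_bmd) - mu(0)| = bmr_sd * noise_sd``
    in closed form, so the recorded true BMD is exact by construction.  With
    ``noise_sd = 0`` the benchmark-response band has zero width and true BMDs
    are recorded as NaN (undefined), but the mean curves are still drawn with
    a fixed reference amplitude so downstream fold-change comparisons remain
    meaningful.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    n_resp = int(round(cfg.frac_responders * cfg.n_genes))
    responder_idx = rng.choice(cfg.n_genes, size=n_resp, replace=False)
    is_resp = np.zeros(cfg.n_genes, dtype=bool)
    is_resp[responder_idx] = True

    model_choice = rng.choice(len(DICT_MODELS), size=cfg.n_genes,
                              p=list(cfg.true_model_mix))
    lo, hi = cfg.true_bmd_distribution
    true_bmd = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_genes))
    hill_k = np.exp(rng.uniform(np.log(1.0), np.log(max(cfg.doses)), size=cfg.n_genes))
    hill_n = rng.uniform(1.0, 4.0, size=cfg.n_genes)
    power_delta = rng.uniform(1.0, 3.0, size=cfg.n_genes)
    direction = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                          size=cfg.n_genes)

    # Amplitude anchoring: the BMR band is bmr_sd * noise_sd wide; with zero
    # noise fall back to a fixed 1-log2-unit response at the drawn true BMD.
    band = cfg.bmr_sd * cfg.noise_sd if cfg.noise_sd > 0 else 1.0

    reps = cfg.replicates(platform_tag)
    if len(reps) != len(cfg.doses):
        raise TxpodError("n_per_dose length must match doses")
    dose_vec = np.repeat(list(cfg.doses), reps)
    sample_names = [
        f"{platform_tag}_d{dose:g}_r{r + 1}"
        for dose, nrep in zip(cfg.doses, reps)
        for r in range(nrep)
    ]

    mean_log2 = np.tile(baseline[:, None], (1, len(dose_vec)))
    records = []
    for gi, gene in enumerate(genes):
        model = DICT_MODELS[model_choice[gi]]
        if not is_resp[gi]:
            records.append((gene, False, "none", np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        u_at_bmd = _unit_curve(model, np.array([true_bmd[gi]]),
                               hill_k[gi], hill_n[gi], power_delta[gi])[0]
        amp = direction[gi] * band / u_at_bmd
        bmd_i = float(true_bmd[gi])
        # cap the top-dose effect at a biologically plausible magnitude; the
        # true BMD is then re-derived from the capped curve in closed form
        u_top = _unit_curve(model, np.array([max(cfg.doses)]),
                            hill_k[gi], hill_n[gi], power_delta[gi])[0]
        if abs(amp) * u_top > cfg.max_top_log2fc:
            amp = direction[gi] * cfg.max_top_log2fc / u_top
            bmd_i = _invert_curve(model, band / abs(amp), hill_k[gi],
                                  hill_n[gi], power_delta[gi])
        mean_log2[gi] += amp * _unit_curve(model, dose_vec, hill_k[gi],
                                           hill_n[gi], power_delta[gi])
        records.append((
            gene, True, model, amp,
            hill_k[gi] if model == "hill" else np.nan,
            hill_n[gi] if model == "hill" else np.nan,
            power_delta[gi] if model == "power" else np.nan,
            bmd_i if cfg.noise_sd > 0 else np.nan,
        ))

    truth = GroundTruth(pd.DataFrame.from_records(
        records,
        columns=["gene", "responder", "model", "amplitude",
                 "hill_k", "hill_n", "power_delta", "true_bmd"],
    ).set_index("gene"))

    if platform_tag == "microarray":
        effects = mean_log2 - baseline[:, None]
        mean_log2 = baseline[:, None] + cfg.compression_factor * effects

    noisy = mean_log2
    if cfg.noise_sd > 0:
        noisy = mean_log2 + rng.normal(0.0, cfg.noise_sd, size=mean_log2.shape)

    if platform_tag == "rnaseq":
        # Poisson-lognormal counts: gene weights from the baseline log2
        # level, scaled by a fixed factor so the expected baseline total per
        # sample equals library_size.  The factor is deliberately NOT
        # renormalized per sample: the pipeline assumes normalized input, so
        # the generator must not introduce the compositional shift that
        # per-sample renormalization would impose on non-responding genes.
        base_total = float((2.0 ** baseline).sum())
        rel = 2.0 ** noisy * (cfg.library_size / base_total)
        values = rng.poisson(rel).astype(int)
        scale = "counts"
    elif platform_tag == "microarray":
        values = noisy
        scale = "log2_intensity"
    elif platform_tag == "qpcr":
        # delta-Ct decreases when expression increases
        values = -noisy
        scale = "delta_ct"
    else:
        raise TxpodError(f"unknown platform_tag {platform_tag!r}")

    dset = DoseResponseSet(
        platform_tag=platform_tag,
        values=pd.DataFrame(values, index=genes, columns=sample_names),
        sample_doses=pd.Series(dose_vec, index=sample_names),
        value_scale=scale,
    )
    return dset, truth


@dataclass
class DichotomousDataset:
    """Quantal incidence data: affected / denominator at each dose."""

    doses: np.ndarray
    affected: np.ndarray
    denominator: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.affected = np.asarray(self.affected, dtype=int)
        self.denominator = np.asarray(self.denominator, dtype=int)
        if not (len(self.doses) == len(self.affected) == len(self.denominator)):
            raise TxpodError("doses, affected, denominator must align")
        if (self.affected < 0).any() or (self.affected > self.denominator).any():
            raise TxpodError("affected counts must lie in [0, denominator]")
        if 0.0 not in self.doses:
            raise TxpodError("dose 0 must be present")

    @property
    def fractions(self) -> np.ndarray:
        return self.affected / self.denominator


def simulate_deg_count_profile(
    total_unique: int, per_dose_counts, doses=(0.0, 2.0, 4.0, 8.0)
) -> DichotomousDataset:
    """Package per-dose DEG counts as a quantal dataset.

    The denominator at every dose is the total number of unique DEGs across
    doses, matching the convention under which the study's printed per-dose
    percentages (e.g. 131/1113 -> 12%) reproduce.
    """
    counts = np.asarray(per_dose_counts, dtype=int)
    if (counts > total_unique).any():
        raise TxpodError("per-dose DEG count exceeds the unique total")
    return DichotomousDataset(
        doses=np.asarray(doses, dtype=float),
        affected=counts,
        denominator=np.full(len(counts), total_unique, dtype=int),
    )


def make_gene_sets(
    truth: GroundTruth,
    n_sets: int,
    genes_per_set: int,
    enrichment: float,
    seed: int = 0,
) -> GeneSetCollection:
    """Draw gene sets with a stated fraction of responders per set."""
    if not 0 <= enrichment <= 1:
        raise TxpodError("enrichment must be in [0, 1]")
    rng = np.random.default_rng(seed)
    responders = truth.responders
    others = truth.non_responders
    n_resp = int(round(enrichment * genes_per_set))
    n_other = genes_per_set - n_resp
    if n_resp > len(responders) or n_other > len(others):
        raise TxpodError("requested set size exceeds the gene pool")
    sets: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        members = list(rng.choice(responders, size=n_resp, replace=False)) + \
                  list(rng.choice(others, size=n_other, replace=False))
        sets[f"Set{i:03d}"] = [str(m) for m in members]
    return GeneSetCollection(sets=sets,
                             descriptions={k: f"simulated (enrichment={enrichment:g})"
                                           for k in sets})


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", float_format="%.6g")


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth(pd.read_csv(path, sep="\t", index_col=0))
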