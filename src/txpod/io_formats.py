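"""Input/output for the dose-response pipeline.

The pipeline exchanges three plain-text formats:

* expression matrices — tab-separated, first column gene symbols, one column
  per sample; the dose of each sample is given either in a second header row
  (``dose=``) or in a two-column sample sheet;
* gene sets — standard GMT (name, description, members...);
* result tables — tab-separated with a header, floats at six significant
  digits.

Doses are administered doses in mg/kg body weight per day (mkd) and are kept
on the natural dose scale throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("txpod")

PLATFORMS = ("rnaseq", "microarray", "qpcr")
VALUE_SCALES = ("log2_intensity", "counts", "log_cpm", "delta_ct")
FILTER_TIERS = ("none", "anova", "fdr")


class TxpodError(ValueError):
    """Raised on malformed inputs or unsatisfiable requests."""


@dataclass
class DoseResponseSet:
    """A platform-tagged gene x sample expression matrix with dose labels.

    ``values`` is a genes-by-samples DataFrame; ``sample_doses`` maps each
    sample (column) to its administered dose.  The control group (dose 0)
    must be present and every dose group must have at least two samples.
    """

    platform_tag: str
    values: pd.DataFrame
    sample_doses: pd.Series
    value_scale: str

    def __post_init__(self) -> None:
        if self.platform_tag not in PLATFORMS:
            raise TxpodError(f"unknown platform_tag {self.platform_tag!r}")
        if self.value_scale not in VALUE_SCALES:
            raise TxpodError(f"unknown value_scale {self.value_scale!r}")
        self.sample_doses = pd.Series(self.sample_doses, dtype=float)
        missing = [s for s in self.values.columns if s not in self.sample_doses.index]
        if missing:
            raise TxpodError(f"samples lack dose annotation: {missing}")
        self.sample_doses = self.sample_doses.loc[list(self.values.columns)]
        if self.values.shape[0] < 1:
            raise TxpodError("matrix has no genes")
        if (self.sample_doses < 0).any():
            raise TxpodError("doses must be non-negative")
        if 0.0 not in set(self.sample_doses):
            raise TxpodError("control group (dose 0) absent")
        counts = self.sample_doses.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise TxpodError(
                f"dose groups with fewer than 2 samples: {sorted(small.index)}"
            )
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TxpodError("non-numeric expression values")
        if self.value_scale == "counts":
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise TxpodError("counts scale requires non-negative integers")

    @property
    def doses(self) -> np.ndarray:
        """Distinct doses, strictly increasing."""
        return np.unique(self.sample_doses.to_numpy())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def dose_vector(self) -> np.ndarray:
        """Per-sample dose, aligned with the matrix columns."""
        return self.sample_doses.to_numpy(dtype=float)

    def group_columns(self, dose: float) -> list[str]:
        return list(self.sample_doses.index[self.sample_doses == dose])

    def subset_genes(self, genes: Sequence[str]) -> "DoseResponseSet":
        return replace(self, values=self.values.loc[list(genes)])

    def log2_values(self) -> pd.DataFrame:
        """The matrix on a log2 expression scale.

        counts -> log2 counts-per-million with a 0.5 pseudocount, using a
        median-of-ratios effective library size so that composition drift
        (a few strongly responding genes dominating the totals) does not
        masquerade as expression change in the majority of genes;
        delta_ct -> negated (expression is proportional to -dCt);
        log2 intensities and log-cpm are returned unchanged.
        """
        if self.value_scale == "counts":
            vals = self.values.to_numpy(dtype=float)
            with np.errstate(divide="ignore"):
                logv = np.log(vals)
            ref = logv.mean(axis=1)  # log geometric mean per gene
            usable = np.isfinite(ref)
            if usable.sum() >= 10:
                ratios = logv[usable] - ref[usable, None]
                size = np.exp(np.median(ratios, axis=0))
            else:
                size = vals.sum(axis=0) / max(vals.sum(axis=0).mean(), 1.0)
            eff_lib = size * vals.sum(axis=0).mean()
            cpm = self.values.div(pd.Series(eff_lib, index=self.values.columns),
                                  axis=1) * 1e6
            return np.log2(cpm + 0.5)
        if self.value_scale == "delta_ct":
            return -self.values
        return self.values


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> ordered member symbols."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not name:
                raise TxpodError("empty set name")
            if not members:
                raise TxpodError(f"gene set {name!r} is empty")
            if any(not g for g in members):
                raise TxpodError(f"gene set {name!r} has empty gene symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class RunConfig:
    """Tunable analysis parameters with the study's published defaults."""

    filter_tier: str = "anova"
    alpha: float = 0.05
    fc_threshold: float = 1.5
    bmr_sd: float = 1.349
    confidence: float = 0.95
    max_iterations: int = 250
    bmr_extra_risk: float = 0.10
    min_genes_report: int = 3
    min_genes_pod: int = 4
    pod_range_low: float = 2.6
    pod_range_high: float = 5.13
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise TxpodError("alpha must be in (0, 1)")
        if self.fc_threshold < 1:
            raise TxpodError("fc_threshold must be >= 1")
        if not 0 < self.confidence < 1:
            raise TxpodError("confidence must be in (0, 1)")
        if not 0 < self.bmr_extra_risk < 1:
            raise TxpodError("bmr_extra_risk must be in (0, 1)")
        for name in ("max_iterations", "min_genes_report", "min_genes_pod"):
            if int(getattr(self, name)) < 1:
                raise TxpodError(f"{name} must be a positive integer")
        if self.filter_tier not in FILTER_TIERS:
            raise TxpodError(f"unknown filter tier {self.filter_tier!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise TxpodError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def read_expression_matrix(
    path: str | Path,
    platform_tag: str,
    value_scale: str,
    sample_sheet: str | Path | None = None,
) -> DoseResponseSet:
    """Read a TSV expression matrix into a :class:`DoseResponseSet`.

    Dose annotation comes either from a second header row whose first cell is
    ``dose=`` (values aligned with the sample columns) or from ``sample_sheet``,
    a two-column TSV of sample identifier and dose.  Duplicate gene symbols
    are collapsed by arithmetic mean on the stored scale (probe averaging).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        second = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if not samples:
        raise TxpodError(f"{path}: no sample columns")
    skiprows: list[int] = []
    doses: pd.Series | None = None
    if second and second[0].strip().lower() in ("dose=", "dose"):
        vals = second[1 : 1 + len(samples)]
        if len(vals) != len(samples):
            raise TxpodError(f"{path}: dose header row length mismatch")
        doses = pd.Series([float(v) for v in vals], index=samples)
        skiprows = [1]
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t", header=None, comment="#")
        if sheet.shape[1] < 2:
            raise TxpodError("sample sheet needs two columns: sample, dose")
        doses = pd.Series(sheet.iloc[:, 1].astype(float).to_numpy(),
                          index=sheet.iloc[:, 0].astype(str))
    if doses is None:
        raise TxpodError(
            f"{path}: no dose annotation (need a 'dose=' header row or a sample sheet)"
        )
    missing = [s for s in samples if s not in doses.index]
    if missing:
        raise TxpodError(f"samples lack dose annotation: {missing}")

    mat = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows)
    mat.index = mat.index.astype(str)
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise TxpodError(f"{path}: non-numeric cell ({exc})") from None
    n_dup = int(mat.index.duplicated().sum())
    if n_dup:
        logger.info("collapsed %d duplicate gene rows by averaging", n_dup)
        mat = mat.groupby(level=0, sort=False).mean()
    return DoseResponseSet(
        platform_tag=platform_tag,
        values=mat,
        sample_doses=doses.loc[samples],
        value_scale=value_scale,
    )


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (one set per line: name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TxpodError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            if name in sets:
                raise TxpodError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m.strip()]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "gene set %r: removed %d duplicate members",
                    name, len(members) - len(deduped),
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_results_table(records, path: str | Path) -> None:
    """Write result records as TSV with floats at 6 significant digits.

    ``records`` may be a DataFrame or an iterable of dataclasses / mappings.
    Column order is deterministic (field order of the first record).
    """
    df = _as_frame(records)
    if df.empty:
        raise TxpodError("refusing to write an empty results table")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if isinstance(rec, Mapping):
            rows.append(dict(rec))
        elif hasattr(rec, "__dataclass_fields__"):
            rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
        else:
            raise TxpodError(f"cannot tabulate record of type {type(rec)!r}")
    return pd.DataFrame(rows)


def write_expression_matrix(dset: DoseResponseSet, path: str | Path) -> None:
    """Write a DoseResponseSet in the two-header-row TSV dialect."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, dset.values.columns)) + "\n")
        fh.write("dose=\t" + "\t".join("%g" % d for d in dset.dose_vector) + "\n")
    dset.values.to_csv(path, sep="\t", header=False, mode="a", float_format="%.6g")


def read_expression_matrix_auto(path: str | Path, platform_tag: str,
                                value_scale: str) -> DoseResponseSet:
    return read_expression_matrix(path, platform_tag, value_scale)
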