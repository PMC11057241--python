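"""Fucci-reporter gating, apoptotic exclusion and dataset construction.

Ground-truth cell-cycle classes come from two Fucci reporter channels:
a red construct (mKO2/mCherry-hCdt1) that accumulates in G1 and a green
one (mAG-hGeminin) that accumulates in S/G2/M.  Hard thresholds on the
per-nucleus mean intensities of the two channels partition nuclei into
four groups: G1 (red only), early S (both), S/G2/M (green only) and
double negative (neither).  Fragmented apoptotic nuclei are removed by a
coefficient-of-variation filter on the DNA channel before sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "FucciGatingConfig",
    "GatedNucleus",
    "DatasetSplit",
    "gate",
    "gate_table",
    "apoptotic_filter",
    "make_binary_labels",
    "sample_and_normalize",
]

#: Cell-cycle classes assignable by gating, in canonical order.
PHASES = ("G1", "earlyS", "SG2M", "DN")

#: Binary one-vs-rest prediction tasks, in canonical order.
TASKS = ("G1", "earlyS", "SG2M")


class ConfigurationError(ValueError):
    """Raised for invalid gating or sampling configuration."""


@dataclass(frozen=True)
class FucciGatingConfig:
    """Thresholds of the Fucci gate for one cell line.

    ``red_threshold`` / ``green_threshold`` are mean-intensity cutoffs in
    raw camera counts; the ">=" side of each cutoff is inclusive.
    ``cv_exclusion_pct`` is the DNA-channel coefficient-of-variation (in
    percent) above which a nucleus is flagged apoptotic; the filter is
    only applied when ``cv_exclusion_enabled`` is set (default for MCF7,
    whose cultures carry substantial dead-cell contamination).
    """

    cell_line: str
    red_threshold: float
    green_threshold: float
    cv_exclusion_pct: float = 70.0
    cv_exclusion_enabled: bool = False

    def __post_init__(self) -> None:
        if self.red_threshold <= 0 or self.green_threshold <= 0:
            raise ConfigurationError("gating thresholds must be positive")
        if self.cv_exclusion_pct <= 0:
            raise ConfigurationError("cv_exclusion_pct must be positive")

    @classmethod
    def for_cell_line(cls, cell_line: str) -> "FucciGatingConfig":
        """Default gate for a supported cell line (``HeLa`` or ``MCF7``)."""
        if cell_line == "HeLa":
            return cls("HeLa", red_threshold=700.0, green_threshold=2500.0,
                       cv_exclusion_enabled=False)
        if cell_line == "MCF7":
            return cls("MCF7", red_threshold=150.0, green_threshold=300.0,
                       cv_exclusion_enabled=True)
        raise ConfigurationError(f"unknown cell line: {cell_line!r}")


@dataclass
class GatedNucleus:
    """One nucleus with its feature vector, Fucci means and assigned class."""

    features: np.ndarray
    red_mean: float
    green_mean: float
    dna_cv: float
    fucci_class: str = field(default="DN")
    excluded: bool = False


def gate(red_mean: float, green_mean: float, config: FucciGatingConfig) -> str:
    """Assign a cell-cycle class from the two Fucci channel means.

    The red/green plane is partitioned exhaustively: every
    ``(red_mean, green_mean)`` pair maps to exactly one of ``PHASES``.
    Both thresholds are inclusive on the ">=" side.
    """
    red_on = red_mean >= config.red_threshold
    green_on = green_mean >= config.green_threshold
    if red_on and not green_on:
        return "G1"
    if red_on and green_on:
        return "earlyS"
    if green_on:
        return "SG2M"
    return "DN"


def gate_table(table: pd.DataFrame, config: FucciGatingConfig,
               red_col: str = "red_mean", green_col: str = "green_mean",
               cv_col: str = "dna_cv") -> pd.DataFrame:
    """Vectorized gate over a nuclei table.

    Adds ``fucci_class``, ``excluded`` and the three one-vs-rest label
    columns (``label_G1``, ``label_earlyS``, ``label_SG2M``).  Double
    negative nuclei are "else" in all three tasks.
    """
    red_on = table[red_col].to_numpy() >= config.red_threshold
    green_on = table[green_col].to_numpy() >= config.green_threshold
    fucci = np.where(red_on & ~green_on, "G1",
                     np.where(red_on & green_on, "earlyS",
                              np.where(green_on, "SG2M", "DN")))
    out = table.copy()
    out["fucci_class"] = fucci
    if config.cv_exclusion_enabled:
        out["excluded"] = out[cv_col].to_numpy() > config.cv_exclusion_pct
    else:
        out["excluded"] = False
    for task in TASKS:
        out[f"label_{task}"] = (fucci == task).astype(int)
    return out


def apoptotic_filter(table: pd.DataFrame, config: FucciGatingConfig,
                     cv_col: str = "dna_cv") -> pd.DataFrame:
    """Drop nuclei whose DNA-channel CV strictly exceeds the cutoff.

    A no-op when ``cv_exclusion_enabled`` is False.  The boundary is
    strict: CV exactly at the cutoff is retained.
    """
    if not config.cv_exclusion_enabled:
        return table
    keep = table[cv_col].to_numpy() <= config.cv_exclusion_pct
    return table.loc[keep].reset_index(drop=True)


def make_binary_labels(fucci_class: str) -> tuple[int, int, int]:
    """One-vs-rest indicators (G1, earlyS, SG2M) for a gated class."""
    if fucci_class not in PHASES:
        raise ValueError(f"unknown fucci class: {fucci_class!r}")
    return tuple(int(fucci_class == task) for task in TASKS)  # type: ignore[return-value]


@dataclass
class DatasetSplit:
    """Disjoint train/validation partition with min-max normalization bounds."""

    train: pd.DataFrame
    validation: pd.DataFrame
    feature_columns: list[str]
    bounds: pd.DataFrame  # index = feature, columns = [min, max]


def sample_and_normalize(table: pd.DataFrame, feature_columns: list[str],
                         n_train: int = 7500, n_val: int = 2500,
                         seed: int = 0,
                         fit_bounds_on: str = "train") -> DatasetSplit:
    """Random disjoint train/validation sample with [0, 1] feature scaling.

    Rows are sampled uniformly without replacement (not stratified).
    Per-feature min/max bounds are fitted on the training rows by default
    (``fit_bounds_on="all"`` uses both partitions); both partitions are
    transformed as ``(x - min) / (max - min)`` and clipped to [0, 1], so
    validation values outside the training range saturate.  Constant
    features map to 0.
    """
    n = len(table)
    if n < n_train + n_val:
        raise ValueError(
            f"need at least {n_train + n_val} rows, got {n}")
    feat = table[feature_columns]
    if feat.isna().any().any() or not np.isfinite(feat.to_numpy(float)).all():
        raise ValueError("feature table contains missing or non-finite values")
    if fit_bounds_on not in ("train", "all"):
        raise ConfigurationError("fit_bounds_on must be 'train' or 'all'")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = table.iloc[perm[:n_train]].reset_index(drop=True)
    val = table.iloc[perm[n_train:n_train + n_val]].reset_index(drop=True)

    ref = train if fit_bounds_on == "train" else pd.concat(
        [train, val], ignore_index=True)
    lo = ref[feature_columns].min(axis=0)
    hi = ref[feature_columns].max(axis=0)
    span = (hi - lo).replace(0.0, np.inf)  # constant features -> 0

    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[feature_columns] = (
            (df[feature_columns] - lo) / span).clip(0.0, 1.0)
        return out

    bounds = pd.DataFrame({"min": lo, "max": hi})
    return DatasetSplit(train=_norm(train), validation=_norm(val),
                        feature_columns=list(feature_columns), bounds=bounds)
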