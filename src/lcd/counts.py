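"""Nuclei-count activity baseline and % Inhibition.

Cell count is the conventional viability readout that phenotypic profiling is
benchmarked against: per-FOV live nuclei counts are Z-transformed against the
DMSO wells of each plate at each timepoint, and a condition is called active
when the 95% percentile-bootstrap confidence interval for the *median* of all
its normalized counts (pooled across wells, plates and replicas, without any
prior aggregation) lies entirely below zero — i.e. the compound measurably
depresses cell count relative to vehicle.

% Inhibition on a well metric (nuclei count or confluency) is
``100 * (mean(metric_DMSO) - metric_compound) / mean(metric_DMSO)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .schema import DMSO, CountTable

__all__ = [
    "CountActivityCall",
    "z_transform_counts",
    "bootstrap_median_ci",
    "call_count_activity",
    "count_activity_matrix",
    "inhibition_effect",
]

_GROUP_KEYS = ["Metadata_plate", "Metadata_timepoint_h"]


class GroupError(ValueError):
    """A (plate, timepoint) group cannot be Z-transformed."""


@dataclass
class CountActivityCall:
    condition: tuple
    ci_low: float
    ci_high: float
    is_active: bool
    n_boot: int
    seed: int


def z_transform_counts(counts: CountTable) -> CountTable:
    """Add a ``nuclei_count_z`` column: per-(plate, timepoint) DMSO Z-score.

    ``z = (count - mean_DMSO) / sd_DMSO`` with the unbiased DMSO sample SD of
    the group; FOV-level records are kept unaggregated.
    """
    df = counts.data.copy()
    values = df["nuclei_count"].to_numpy(dtype=float)
    is_dmso = (df["Metadata_compound"].astype(str) == DMSO).to_numpy()
    z = np.empty(len(df))
    codes, _ = pd.factorize(pd.MultiIndex.from_frame(df[_GROUP_KEYS].reset_index(drop=True)))
    for g in np.unique(codes):
        rows = codes == g
        ref = values[rows & is_dmso]
        key = tuple(df.loc[rows, _GROUP_KEYS].iloc[0])
        if len(ref) < 2:
            raise GroupError(f"group (plate, timepoint)={key} has < 2 DMSO count records")
        sd = ref.std(ddof=1)
        if sd == 0:
            raise GroupError(f"zero DMSO count SD in group (plate, timepoint)={key}")
        z[rows] = (values[rows] - ref.mean()) / sd
    df["nuclei_count_z"] = z
    return CountTable(df)


def bootstrap_median_ci(
    values,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for the median.

    Resamples with replacement ``n_boot`` times and returns the
    (alpha/2, 1-alpha/2) empirical quantiles of the bootstrap medians.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(int(n_boot), len(values)))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.quantile(medians, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def call_count_activity(
    counts: CountTable,
    condition: tuple,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CountActivityCall:
    """Count-based activity call for one (compound, dose, timepoint).

    Pools all FOV-level Z-transformed counts of the condition; active iff the
    CI upper bound is below zero (DMSO sits at z = 0 by construction).
    """
    df = counts.data
    if "nuclei_count_z" not in df.columns:
        raise ValueError("counts must be Z-transformed first (z_transform_counts)")
    compound, dose, tp = condition
    mask = (
        (df["Metadata_compound"] == compound)
        & np.isclose(df["Metadata_dose_uM"].to_numpy(dtype=float), float(dose))
        & np.isclose(df["Metadata_timepoint_h"].to_numpy(dtype=float), float(tp))
    )
    z = df.loc[mask, "nuclei_count_z"].to_numpy(dtype=float)
    if len(z) < 2:
        raise ValueError(f"condition {condition} has fewer than 2 normalized count records")
    rng = child_rng(seed, "count_boot", condition)
    lo, hi = bootstrap_median_ci(z, n_boot=n_boot, alpha=alpha, seed=rng)
    return CountActivityCall(condition, lo, hi, bool(hi < 0), int(n_boot), seed)


def count_activity_matrix(
    counts: CountTable, n_boot: int = 10_000, alpha: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Count-baseline activity calls for every treatment condition."""
    if "nuclei_count_z" not in counts.data.columns:
        counts = z_transform_counts(counts)
    df = counts.data
    treat = df[df["Metadata_compound"] != DMSO]
    conditions = (
        treat[["Metadata_compound", "Metadata_dose_uM", "Metadata_timepoint_h"]]
        .drop_duplicates()
        .to_numpy()
    )
    rows = []
    for compound, dose, tp in conditions:
        call = call_count_activity(
            counts, (compound, float(dose), float(tp)), n_boot=n_boot, alpha=alpha, seed=seed
        )
        rows.append(
            {
                "compound": compound,
                "dose_uM": float(dose),
                "timepoint_h": float(tp),
                "ci_low": call.ci_low,
                "ci_high": call.ci_high,
                "is_active": call.is_active,
            }
        )
    return pd.DataFrame(rows)


def inhibition_effect(compound_metric: float, dmso_metrics) -> float:
    """% Inhibition: ``100 * (mean(DMSO) - compound) / mean(DMSO)``."""
    dmso_metrics = np.asarray(dmso_metrics, dtype=float)
    ref = dmso_metrics.mean()
    if ref == 0:
        raise ValueError("mean DMSO metric is zero; % inhibition undefined")
    return float(100.0 * (ref - float(compound_metric)) / ref)
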