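"""Embedding normalization: MAD+Robustize per measurement, then optional
Harmony-style batch integration over replica / FOV covariates.

A *measurement* is one plate imaged at one timepoint.  Each measurement is
first robust-normalized against its own DMSO wells (subtract the DMSO median,
divide by the Gaussian-consistent scaled MAD), which removes plate- and
timepoint-level shifts.  The Harmony variants then integrate the concatenated
table once, treating experimental replica (and, for the /FOV variant, field
of view) as batch covariates — the residual batch structure that per-plate
robustization cannot see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._harmony import harmonize
from .schema import DMSO, ProfileTable

__all__ = [
    "MAD_CONSISTENCY",
    "NormalizationPlan",
    "GroupError",
    "mad_robustize",
    "harmony_correct",
    "normalize",
]

logger = logging.getLogger(__name__)

#: Gaussian-consistency constant: 1.4826 * MAD estimates the SD of a normal.
MAD_CONSISTENCY = 1.4826

#: Fixed grouping of a "measurement": one plate at one timepoint.
MAD_GROUP_KEYS = ("Metadata_plate", "Metadata_timepoint_h")

_METHODS = {
    "mad": (),
    "mad_harmony": ("replica_id",),
    "mad_harmony_fov": ("replica_id", "fov_id"),
}

_COVARIATE_COLUMNS = {"replica_id": "Metadata_replica", "fov_id": "Metadata_fov"}


class GroupError(ValueError):
    """A (plate, timepoint) group cannot be normalized."""


@dataclass
class NormalizationPlan:
    """Which normalization to run and with what knobs.

    ``method`` is one of "mad", "mad_harmony", "mad_harmony_fov"; the Harmony
    covariates are implied by the method (replica, or replica + FOV).
    """

    method: str = "mad_harmony_fov"
    epsilon: float = 1.0
    mad_consistency: float = MAD_CONSISTENCY
    seed: int = 0
    harmony_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {sorted(_METHODS)}"
            )
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def harmony_covariates(self) -> tuple[str, ...]:
        return _METHODS[self.method]


def mad_robustize(table: ProfileTable, plan: NormalizationPlan | None = None) -> ProfileTable:
    """Center/scale each (plate, timepoint) measurement on its DMSO wells.

    Per group ``g`` and feature ``j``::

        x' = (x - median_DMSO) / (1.4826 * MAD_DMSO)

    A feature whose DMSO MAD is exactly zero within a group is left centered
    but divided by the fallback ``plan.epsilon`` instead (logged, not fatal).
    Row order and metadata are preserved.
    """
    plan = plan or NormalizationPlan(method="mad")
    df = table.data
    X = table.features.copy()
    is_dmso = (df["Metadata_compound"].astype(str) == DMSO).to_numpy()

    codes, _ = pd.factorize(
        pd.MultiIndex.from_frame(df[list(MAD_GROUP_KEYS)].reset_index(drop=True))
    )
    for g in np.unique(codes):
        rows = codes == g
        dmso_rows = rows & is_dmso
        if dmso_rows.sum() < 2:
            key = tuple(df.loc[rows, list(MAD_GROUP_KEYS)].iloc[0])
            raise GroupError(
                f"measurement group (plate, timepoint)={key} has "
                f"{int(dmso_rows.sum())} DMSO records; need >= 2"
            )
        ref = X[dmso_rows]
        med = np.median(ref, axis=0)
        mad = np.median(np.abs(ref - med), axis=0)
        scale = plan.mad_consistency * mad
        degenerate = scale == 0
        if degenerate.any():
            key = tuple(df.loc[rows, list(MAD_GROUP_KEYS)].iloc[0])
            names = [table.feature_names[j] for j in np.flatnonzero(degenerate)[:5]]
            logger.warning(
                "zero DMSO MAD in group %s for %d feature(s) (e.g. %s); "
                "using epsilon fallback",
                key,
                int(degenerate.sum()),
                names,
            )
            scale = np.where(degenerate, plan.epsilon, scale)
        X[rows] = (X[rows] - med) / scale
    return table.with_features(X)


def harmony_correct(
    table: ProfileTable,
    covariates: tuple[str, ...] = ("replica_id", "fov_id"),
    seed: int = 0,
    **harmony_kwargs,
) -> ProfileTable:
    """Integrate batch covariates out of an (already MAD-normalized) table.

    ``covariates`` name metadata levels ("replica_id", "fov_id") treated as
    categorical batch variables; each must have at least two levels.
    Deterministic given ``seed``; metadata untouched.
    """
    if not covariates:
        raise ValueError("need at least one batch covariate")
    label_arrays = []
    for cov in covariates:
        col = _COVARIATE_COLUMNS.get(cov)
        if col is None:
            raise ValueError(f"unknown covariate {cov!r}")
        values = table.data[col].to_numpy()
        if len(np.unique(values)) < 2:
            raise ValueError(f"covariate {cov!r} has a single level; cannot integrate")
        label_arrays.append(values)
    corrected = harmonize(table.features, label_arrays, seed=seed, **harmony_kwargs)
    return table.with_features(corrected)


def normalize(table: ProfileTable, plan: NormalizationPlan) -> ProfileTable:
    """Full normalization pipeline for one table.

    MAD+Robustize every (plate, timepoint) measurement against its DMSO
    wells, then — for the Harmony variants — integrate the concatenated table
    once with the plan's covariates.
    """
    out = mad_robustize(table, plan)
    if plan.harmony_covariates:
        logger.info(
            "running mixture-model batch integration over covariates %s",
            plan.harmony_covariates,
        )
        out = harmony_correct(
            out, plan.harmony_covariates, seed=plan.seed, **plan.harmony_kwargs
        )
    return out
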