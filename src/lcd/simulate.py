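"""Synthetic plate-embedding generator.

Emulates the layout of a multi-replica live-cell brightfield screen: several
384-well plates per experimental replica, each plate holding every compound at
every dose (a fixed number of technical-replicate wells per compound per
plate) plus a block of DMSO vehicle wells, imaged at several timepoints with
several fields of view per well.

Generative model for the feature vector of one FOV record ``r``::

    x_r = e(dose_r, t_r) * emax_c * u_c  +  b_plate  +  b_replica  +  b_fov  +  eps_r

where ``u_c`` is the compound's unit effect direction (a shared MoA direction
plus a small per-compound jitter, so mechanism classes are linearly
recoverable), ``emax_c`` is the compound's maximal effect magnitude, and the
dose-time response is a Hill curve times a linear time ramp::

    e(dose, t) = dose^h / (dose^h + EC50^h) * (t / max_t)   in [0, 1].

Batch offsets are constants drawn once per level from isotropic Gaussians:
one vector per plate id, one per replica, one per (replica, FOV) - the
additive model that mixture-model batch integration assumes.  DMSO records
have the treatment term zeroed.  Live nuclei counts per FOV are
``Poisson(count_base * (1 - count_inhibition_emax * e(dose, t)))``.

Everything is reproducible from a single seed through keyed child streams, so
enlarging one level of the design never shifts the draws of another.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .schema import (
    DMSO,
    METADATA_COLUMNS,
    ROLE_NEGATIVE_CONTROL,
    ROLE_TREATMENT,
    CountTable,
    ProfileTable,
    make_well_id,
)

__all__ = ["GeneratorConfig", "TruthTable", "generate_dataset", "effect_magnitude"]


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Study-design and effect-model parameters for the generator.

    Defaults are a scaled-down rendition of the screen design: ten MoA
    classes, three compounds each, two plates imaged in three complete
    experimental replicas, four doses spanning 0.156-10 uM, five timepoints
    over 20 h, four FOV per well, and 64-dimensional embeddings.
    """

    n_moa: int = 10
    compounds_per_moa: int = 3
    n_plates: int = 2
    n_replicas: int = 3
    wells_per_compound_per_plate: int = 2
    n_dmso_wells_per_plate: int = 40
    n_fov: int = 4
    doses_uM: tuple[float, ...] = (0.156, 0.625, 2.5, 10.0)
    timepoints_h: tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0)
    D: int = 64
    sigma_plate: float = 0.5
    sigma_replica: float = 1.0
    sigma_fov: float = 0.5
    sigma_noise: float = 1.0
    emax_range: tuple[float, float] = (1.0, 8.0)
    ec50_uM: float = 0.6
    hill: float = 2.0
    count_base: float = 120.0
    count_inhibition_emax: float = 0.5
    moa_direction_jitter: float = 0.25
    active_margin: float | None = None  # default sigma_noise / 2
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_moa",
            "compounds_per_moa",
            "n_plates",
            "n_replicas",
            "wells_per_compound_per_plate",
            "n_dmso_wells_per_plate",
            "n_fov",
        ):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.D < 2:
            raise ConfigError("feature dimension D must be >= 2")
        doses = tuple(float(d) for d in self.doses_uM)
        if any(d <= 0 for d in doses) or list(doses) != sorted(doses):
            raise ConfigError("doses must be strictly positive and sorted ascending")
        if any(t <= 0 for t in self.timepoints_h):
            raise ConfigError("timepoints must be strictly positive")
        for name in ("sigma_plate", "sigma_replica", "sigma_fov", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        lo, hi = self.emax_range
        if lo > hi:
            raise ConfigError("emax_range lower bound exceeds upper bound")
        if self.ec50_uM <= 0 or self.hill <= 0:
            raise ConfigError("ec50_uM and hill must be positive")
        if self.count_base <= 0:
            raise ConfigError("count_base must be positive")
        if not 0 <= self.count_inhibition_emax <= 1:
            raise ConfigError("count_inhibition_emax must lie in [0, 1]")

    @property
    def n_compounds(self) -> int:
        return self.n_moa * self.compounds_per_moa

    @property
    def wells_per_plate(self) -> int:
        return (
            self.n_compounds * len(self.doses_uM) * self.wells_per_compound_per_plate
            + self.n_dmso_wells_per_plate
        )

    @property
    def activity_margin(self) -> float:
        """Detectability margin for the ground-truth active flag."""
        return self.sigma_noise / 2 if self.active_margin is None else self.active_margin


@dataclass
class TruthTable:
    """Ground truth behind a generated dataset.

    ``compounds`` has one row per compound (compound, moa, emax);
    ``directions`` holds the matching unit effect directions (n_compounds x D);
    ``conditions`` has one row per (compound, dose, timepoint) with the
    realized effect magnitude ``effect = emax * e(dose, t)`` and the active
    flag ``effect >= margin``.
    """

    compounds: pd.DataFrame
    directions: np.ndarray
    conditions: pd.DataFrame
    margin: float

    def moa_of(self) -> dict[str, str]:
        return dict(zip(self.compounds["compound"], self.compounds["moa"]))


def effect_magnitude(dose_uM: float, timepoint_h: float, config: GeneratorConfig) -> float:
    """Hill dose response times linear time ramp, in [0, 1].

    ``e(dose, t) = dose^h / (dose^h + EC50^h) * t / max(timepoints)``.
    """
    dose = np.asarray(dose_uM, dtype=float)
    t = np.asarray(timepoint_h, dtype=float)
    if np.any(dose <= 0) or np.any(t <= 0):
        raise ValueError("dose and timepoint must be strictly positive")
    h = float(config.hill)
    ec50 = float(config.ec50_uM)
    hillterm = dose**h / (dose**h + ec50**h)
    ramp = t / max(config.timepoints_h)
    out = hillterm * ramp
    return float(out) if out.ndim == 0 else out


def _compound_truth(config: GeneratorConfig):
    """Compound names, MoA labels, unit directions and emax values."""
    moa_labels = [f"MoA{m + 1:02d}" for m in range(config.n_moa)]
    dir_rng = child_rng(config.seed, "moa_directions")
    moa_dirs = dir_rng.standard_normal((config.n_moa, config.D))
    moa_dirs /= np.linalg.norm(moa_dirs, axis=1, keepdims=True)

    rows = []
    directions = np.empty((config.n_compounds, config.D))
    emax_lo, emax_hi = config.emax_range
    i = 0
    for m, moa in enumerate(moa_labels):
        for c in range(config.compounds_per_moa):
            name = f"C{i + 1:03d}"
            jit_rng = child_rng(config.seed, "compound_direction", name)
            jitter = jit_rng.standard_normal(config.D)
            jitter /= np.linalg.norm(jitter)
            u = moa_dirs[m] + config.moa_direction_jitter * jitter
            u /= np.linalg.norm(u)
            emax = child_rng(config.seed, "emax", name).uniform(emax_lo, emax_hi)
            directions[i] = u
            rows.append({"compound": name, "moa": moa, "emax": emax})
            i += 1
    return pd.DataFrame(rows), directions


def _plate_layout(config: GeneratorConfig, replica: str, plate: str) -> pd.DataFrame:
    """Randomized well assignment for one physical plate.

    One row per well: well id, compound, dose (NA for DMSO).  The compound x
    dose x technical-replicate blocks plus the DMSO block are shuffled over
    well positions with a child stream keyed by (replica, plate), emulating
    independent plate randomization per run.
    """
    n_wells = config.wells_per_plate
    if n_wells > 384:
        raise ConfigError(
            f"configured design needs {n_wells} wells per plate; a 384-well plate has 384"
        )
    entries: list[tuple[str, float | None]] = []
    for i in range(config.n_compounds):
        name = f"C{i + 1:03d}"
        for dose in config.doses_uM:
            entries.extend([(name, float(dose))] * config.wells_per_compound_per_plate)
    entries.extend([(DMSO, None)] * config.n_dmso_wells_per_plate)

    rng = child_rng(config.seed, "layout", replica, plate)
    positions = rng.permutation(384)[:n_wells]
    wells = [make_well_id(p // 24 + 1, p % 24 + 1) for p in np.sort(positions)]
    order = rng.permutation(n_wells)
    return pd.DataFrame(
        {
            "Metadata_well": wells,
            "Metadata_compound": [entries[j][0] for j in order],
            "Metadata_dose_uM": [entries[j][1] for j in order],
        }
    )


def generate_dataset(config: GeneratorConfig) -> tuple[ProfileTable, CountTable, TruthTable]:
    """Generate (profiles at FOV granularity, counts, ground truth)."""
    compounds, directions = _compound_truth(config)
    moa_of = dict(zip(compounds["compound"], compounds["moa"]))
    emax_of = dict(zip(compounds["compound"], compounds["emax"]))
    dir_index = {name: i for i, name in enumerate(compounds["compound"])}

    plates = [f"plate{p + 1:02d}" for p in range(config.n_plates)]
    replicas = [f"R{r + 1}" for r in range(config.n_replicas)]

    # batch offsets, one vector per level
    b_plate = {
        p: child_rng(config.seed, "plate_offset", p).normal(0, config.sigma_plate, config.D)
        for p in plates
    }
    b_replica = {
        r: child_rng(config.seed, "replica_offset", r).normal(0, config.sigma_replica, config.D)
        for r in replicas
    }
    b_fov = {
        (r, f): child_rng(config.seed, "fov_offset", r, f).normal(0, config.sigma_fov, config.D)
        for r in replicas
        for f in range(1, config.n_fov + 1)
    }

    frames = []
    for replica, plate in itertools.product(replicas, plates):
        layout = _plate_layout(config, replica, plate)
        base = layout.copy()
        base["Metadata_plate"] = plate
        base["Metadata_replica"] = replica
        expanded = base.merge(
            pd.DataFrame({"Metadata_timepoint_h": list(config.timepoints_h)}), how="cross"
        ).merge(pd.DataFrame({"Metadata_fov": range(1, config.n_fov + 1)}), how="cross")
        frames.append(expanded)
    meta = pd.concat(frames, ignore_index=True)
    meta["Metadata_moa"] = meta["Metadata_compound"].map(moa_of)
    meta["Metadata_role"] = np.where(
        meta["Metadata_compound"] == DMSO, ROLE_NEGATIVE_CONTROL, ROLE_TREATMENT
    )
    meta = meta[list(METADATA_COLUMNS)]

    n = len(meta)
    is_dmso = (meta["Metadata_compound"] == DMSO).to_numpy()
    dose = meta["Metadata_dose_uM"].to_numpy(dtype=float)
    t = meta["Metadata_timepoint_h"].to_numpy(dtype=float)
    e = np.zeros(n)
    if (~is_dmso).any():
        e[~is_dmso] = effect_magnitude(dose[~is_dmso], t[~is_dmso], config)

    emax_row = meta["Metadata_compound"].map(emax_of).fillna(0.0).to_numpy(dtype=float)
    dir_rows = np.zeros((n, config.D))
    treat_idx = np.flatnonzero(~is_dmso)
    if treat_idx.size:
        dir_rows[treat_idx] = directions[
            meta["Metadata_compound"].iloc[treat_idx].map(dir_index).to_numpy()
        ]

    X = (e * emax_row)[:, None] * dir_rows
    X += np.stack([b_plate[p] for p in meta["Metadata_plate"]])
    X += np.stack([b_replica[r] for r in meta["Metadata_replica"]])
    X += np.stack(
        [b_fov[(r, int(f))] for r, f in zip(meta["Metadata_replica"], meta["Metadata_fov"])]
    )
    X += child_rng(config.seed, "noise").normal(0, config.sigma_noise, (n, config.D))

    profile_df = pd.concat(
        [
            meta.reset_index(drop=True),
            pd.DataFrame(X, columns=[f"emb_{j:03d}" for j in range(config.D)]),
        ],
        axis=1,
    )
    profiles = ProfileTable(profile_df, granularity="fov")

    # counts: Poisson thinning of the base rate by the dose-time response
    rate = np.clip(config.count_base * (1.0 - config.count_inhibition_emax * e), 0.0, None)
    counts = child_rng(config.seed, "counts").poisson(rate)
    conf_noise = child_rng(config.seed, "confluency").normal(0, 0.02, n)
    confluency = np.clip(0.55 * rate / config.count_base + conf_noise, 0.0, 1.0)
    count_df = meta.copy().reset_index(drop=True)
    count_df["nuclei_count"] = counts.astype(int)
    count_df["confluency"] = confluency
    count_table = CountTable(count_df)

    # per-condition truth
    cond_rows = []
    margin = config.activity_margin
    for name in compounds["compound"]:
        for d_uM in config.doses_uM:
            for tp in config.timepoints_h:
                eff = emax_of[name] * effect_magnitude(d_uM, tp, config)
                cond_rows.append(
                    {
                        "compound": name,
                        "dose_uM": float(d_uM),
                        "timepoint_h": float(tp),
                        "effect": eff,
                        "is_active": bool(eff >= margin),
                    }
                )
    truth = TruthTable(compounds, directions, pd.DataFrame(cond_rows), margin)
    return profiles, count_table, truth
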