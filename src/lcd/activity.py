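"""Phenotypic activity via mean-average-precision effect size (mAP-ES).

For each treatment condition (compound, dose, timepoint) the retrieval
question is: how distinctly do that condition's well profiles separate from
vehicle (DMSO) wells in embedding space?  One *resample* draws

* a query well of the condition,
* ``n_pos`` wells of the same condition from a different plate AND a
  different experimental replica (the hardest positives: maximal batch
  difference),
* ``n_neg`` DMSO wells from the query's own physical plate (minimal batch
  difference),

ranks positives+negatives by similarity to the query and scores the ranking
with average precision.  Repeating ``n_resamples`` times yields the
condition's mAP *distribution*.  The same resampling with DMSO queries and
DMSO positives yields the *null* distribution, which by construction absorbs
whatever batch structure survives normalization.  Activity is the Cohen's d
effect size between the two distributions (mAP-ES), with a condition called
active when mAP-ES >= 0.8 (the conventional "large effect" cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from .schema import DMSO, ProfileTable

__all__ = [
    "PairScheme",
    "MapDistribution",
    "ActivityCall",
    "InsufficientReplicatesError",
    "average_precision",
    "rank_candidates",
    "sample_map_distribution",
    "sample_null_distribution",
    "cohens_d",
    "call_activity",
    "activity_matrix",
]


class InsufficientReplicatesError(ValueError):
    """No query well has enough cross-plate/cross-replica positives."""


@dataclass(frozen=True)
class PairScheme:
    """Resampling scheme: 3 positives vs 31 same-plate DMSO negatives, 1000x."""

    n_pos: int = 3
    n_neg: int = 31
    n_resamples: int = 1000
    similarity: str = "cosine"
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1 or self.n_resamples < 1:
            raise ValueError("n_pos, n_neg and n_resamples must all be >= 1")
        if self.similarity not in ("cosine", "negative_euclidean"):
            raise ValueError(f"unknown similarity {self.similarity!r}")

    def compatible_with(self, other: "PairScheme") -> bool:
        return (
            self.n_pos == other.n_pos
            and self.n_neg == other.n_neg
            and self.n_resamples == other.n_resamples
            and self.similarity == other.similarity
        )


@dataclass
class MapDistribution:
    """n_resamples average-precision values for one condition (or the null)."""

    condition: tuple | None
    values: np.ndarray
    scheme: PairScheme

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.scheme.n_resamples:
            raise ValueError("values length must equal scheme.n_resamples")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("average precision values must lie in [0, 1]")


@dataclass
class ActivityCall:
    """mAP-ES value and threshold decision for one condition."""

    condition: tuple
    map_es: float
    threshold: float
    is_active: bool
    n_pos: int
    n_neg: int
    n_resamples: int
    seed: int


# ---------------------------------------------------------------------------
# core scoring
# ---------------------------------------------------------------------------


def average_precision(ranked_labels) -> float:
    """Average precision of a binary ranking.

    ``AP = (1/P) * sum over positive ranks k of precision@k`` with
    ``precision@k`` the fraction of positives among the first k items.
    """
    labels = np.asarray(ranked_labels, dtype=float)
    if labels.ndim != 1 or len(labels) == 0:
        raise ValueError("ranked_labels must be a non-empty 1-d binary sequence")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("ranked_labels must be binary")
    P = labels.sum()
    if P == 0:
        raise ValueError("ranking contains no positives")
    precision_at_k = np.cumsum(labels) / np.arange(1, len(labels) + 1)
    return float(precision_at_k[labels == 1].sum() / P)


def _similarities(query: np.ndarray, candidates: np.ndarray, kind: str) -> np.ndarray:
    if kind == "cosine":
        qn = np.linalg.norm(query)
        cn = np.linalg.norm(candidates, axis=1)
        if qn == 0 or (cn == 0).any():
            raise ValueError("cosine similarity undefined for zero-norm vectors")
        return candidates @ query / (cn * qn)
    return -np.linalg.norm(candidates - query, axis=1)


def rank_candidates(
    query: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
    similarity: str = "cosine",
    tie_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Label sequence of positives+negatives sorted by descending similarity.

    Exact similarity ties are broken by a seeded random shuffle applied before
    the stable sort, so tied candidates appear in uniformly random order.
    """
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    query = np.asarray(query, dtype=float)
    cands = np.vstack([positives, negatives])
    labels = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    sims = _similarities(query, cands, similarity)
    rng = tie_rng or np.random.default_rng()
    shuffle = rng.permutation(len(cands))
    order = np.argsort(-sims[shuffle], kind="stable")
    return labels[shuffle][order].astype(int)


def cohens_d(a, b) -> float:
    """Cohen's d with pooled (unbiased) standard deviation: (mean a - mean b)/s_p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("cohens_d requires at least two values per sample")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    diff = a.mean() - b.mean()
    if pooled == 0:
        warnings.warn("zero pooled SD in Cohen's d; returning signed infinity", stacklevel=2)
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


# ---------------------------------------------------------------------------
# resampling machinery
# ---------------------------------------------------------------------------


def _vectorized_ap(
    X: np.ndarray,
    q_idx: np.ndarray,
    cand_idx: np.ndarray,
    n_pos: int,
    similarity: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """AP for each resample row; candidates are [positives | negatives]."""
    if similarity == "cosine":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if (norms == 0).any():
            raise ValueError("cosine similarity undefined for zero-norm vectors")
        V = X / norms
        sims = np.einsum("rcd,rd->rc", V[cand_idx], V[q_idx])
    else:
        diffs = X[cand_idx] - X[q_idx][:, None, :]
        sims = -np.linalg.norm(diffs, axis=2)
    R, C = sims.shape
    labels = np.zeros((R, C))
    labels[:, :n_pos] = 1.0
    # random tie-break: shuffle candidate order per row, then stable sort
    tie_keys = rng.random((R, C))
    shuffle = np.argsort(tie_keys, axis=1)
    sims = np.take_along_axis(sims, shuffle, axis=1)
    labels = np.take_along_axis(labels, shuffle, axis=1)
    order = np.argsort(-sims, axis=1, kind="stable")
    ranked = np.take_along_axis(labels, order, axis=1)
    prec = np.cumsum(ranked, axis=1) / np.arange(1, C + 1)
    return (prec * ranked).sum(axis=1) / n_pos


def _resample_distribution(
    X: np.ndarray,
    query_pool: np.ndarray,
    pos_pools: dict[int, np.ndarray],
    neg_pools: dict[int, np.ndarray],
    scheme: PairScheme,
    rng: np.random.Generator,
    collect_draws: bool = False,
):
    """Draw scheme.n_resamples (query, positives, negatives) sets and score them."""
    R = scheme.n_resamples
    q_idx = rng.choice(query_pool, size=R, replace=True)
    cand_idx = np.empty((R, scheme.n_pos + scheme.n_neg), dtype=int)
    for r in range(R):
        q = int(q_idx[r])
        cand_idx[r, : scheme.n_pos] = rng.choice(pos_pools[q], scheme.n_pos, replace=False)
        cand_idx[r, scheme.n_pos :] = rng.choice(neg_pools[q], scheme.n_neg, replace=False)
    values = _vectorized_ap(X, q_idx, cand_idx, scheme.n_pos, scheme.similarity, rng)
    if collect_draws:
        draws = {
            "query": q_idx,
            "positives": cand_idx[:, : scheme.n_pos],
            "negatives": cand_idx[:, scheme.n_pos :],
        }
        return values, draws
    return values, None


def _pools(
    df: pd.DataFrame,
    member_idx: np.ndarray,
    dmso_idx: np.ndarray,
    scheme: PairScheme,
    exclude_query_from_neg: bool,
):
    """Eligible queries and their positive/negative pools.

    Positives for a query: members from a different plate AND different
    replica.  Negatives: DMSO wells of the query's own physical plate
    (same plate id and same replica).
    """
    plate = df["Metadata_plate"].to_numpy()
    rep = df["Metadata_replica"].to_numpy()
    pos_pools, neg_pools, eligible = {}, {}, []
    short_dmso_plates = []
    for q in member_idx:
        mask = (plate[member_idx] != plate[q]) & (rep[member_idx] != rep[q])
        pool = member_idx[mask]
        pool = pool[pool != q]
        neg = dmso_idx[(plate[dmso_idx] == plate[q]) & (rep[dmso_idx] == rep[q])]
        if exclude_query_from_neg:
            neg = neg[neg != q]
        if len(pool) < scheme.n_pos:
            continue
        if len(neg) < scheme.n_neg:
            short_dmso_plates.append((plate[q], rep[q]))
            continue
        pos_pools[q] = pool
        neg_pools[q] = neg
        eligible.append(q)
    return np.array(eligible, dtype=int), pos_pools, neg_pools, short_dmso_plates


def sample_map_distribution(
    table: ProfileTable,
    condition: tuple,
    scheme: PairScheme,
    collect_draws: bool = False,
):
    """mAP distribution of one (compound, dose, timepoint) condition.

    ``table`` must be at well granularity.  Raises
    :class:`InsufficientReplicatesError` when no query well of the condition
    has ``n_pos`` cross-plate/cross-replica positives; raises ``ValueError``
    naming the plate when a query's plate lacks ``n_neg`` DMSO wells.
    """
    if table.granularity != "well":
        raise ValueError("mAP resampling expects a well-level table")
    compound, dose, timepoint = condition
    df = table.data
    at_tp = np.isclose(df["Metadata_timepoint_h"].to_numpy(dtype=float), float(timepoint))
    member_idx = np.flatnonzero(
        (df["Metadata_compound"].to_numpy() == compound)
        & np.isclose(df["Metadata_dose_uM"].to_numpy(dtype=float), float(dose))
        & at_tp
    )
    dmso_idx = np.flatnonzero((df["Metadata_compound"].to_numpy() == DMSO) & at_tp)
    if len(member_idx) == 0:
        raise ValueError(f"condition {condition} has no wells")

    eligible, pos_pools, neg_pools, short = _pools(
        df, member_idx, dmso_idx, scheme, exclude_query_from_neg=False
    )
    if len(eligible) == 0:
        if short:
            raise ValueError(
                f"plate(s) {sorted(set(short))} hold fewer than {scheme.n_neg} DMSO wells"
            )
        raise InsufficientReplicatesError(
            f"condition {condition}: no query well has {scheme.n_pos} positives from a "
            "different plate and replica"
        )
    rng = child_rng(scheme.seed, "map", condition)
    values, draws = _resample_distribution(
        table.features, eligible, pos_pools, neg_pools, scheme, rng, collect_draws
    )
    dist = MapDistribution(condition, values, scheme)
    return (dist, draws) if collect_draws else dist


def sample_null_distribution(
    table: ProfileTable,
    timepoint: float,
    scheme: PairScheme,
    collect_draws: bool = False,
):
    """DMSO-vs-DMSO null mAP distribution for one timepoint stratum.

    Queries, positives and negatives are all DMSO wells; positives come from
    different plates and replicas, negatives from the query's own plate
    (query excluded).
    """
    if table.granularity != "well":
        raise ValueError("mAP resampling expects a well-level table")
    df = table.data
    at_tp = np.isclose(df["Metadata_timepoint_h"].to_numpy(dtype=float), float(timepoint))
    dmso_idx = np.flatnonzero((df["Metadata_compound"].to_numpy() == DMSO) & at_tp)
    if len(dmso_idx) == 0:
        raise ValueError(f"no DMSO wells at timepoint {timepoint}")
    eligible, pos_pools, neg_pools, short = _pools(
        df, dmso_idx, dmso_idx, scheme, exclude_query_from_neg=True
    )
    if len(eligible) == 0:
        if short:
            raise ValueError(
                f"plate(s) {sorted(set(short))} hold fewer than {scheme.n_neg + 1} DMSO wells"
            )
        raise InsufficientReplicatesError(
            "null distribution needs DMSO wells in >= 2 replicas on >= 2 plates"
        )
    rng = child_rng(scheme.seed, "null", float(timepoint))
    values, draws = _resample_distribution(
        table.features, eligible, pos_pools, neg_pools, scheme, rng, collect_draws
    )
    dist = MapDistribution(None, values, scheme)
    return (dist, draws) if collect_draws else dist


def call_activity(
    compound_dist: MapDistribution,
    null_dist: MapDistribution,
    threshold: float = 0.8,
) -> ActivityCall:
    """Activity decision: mAP-ES = Cohen's d(compound, null), active at >= threshold."""
    if not compound_dist.scheme.compatible_with(null_dist.scheme):
        raise ValueError("compound and null distributions use different pair schemes")
    d = cohens_d(compound_dist.values, null_dist.values)
    scheme = compound_dist.scheme
    return ActivityCall(
        condition=compound_dist.condition,
        map_es=d,
        threshold=threshold,
        is_active=bool(d >= threshold),
        n_pos=scheme.n_pos,
        n_neg=scheme.n_neg,
        n_resamples=scheme.n_resamples,
        seed=scheme.seed,
    )


def activity_matrix(
    table: ProfileTable,
    scheme: PairScheme,
    threshold: float = 0.8,
    truth=None,
) -> tuple[pd.DataFrame, dict]:
    """mAP-ES activity calls for every (compound, dose, timepoint) condition.

    Returns (calls, summary).  ``calls`` has one row per condition with the
    mAP-ES, the decision and a status ("ok" or a skip reason).  When a
    :class:`~lcd.simulate.TruthTable` is given, ``summary`` reports
    sensitivity/specificity against the ground-truth active flags, overall
    and per dose.
    """
    if table.granularity != "well":
        raise ValueError("activity_matrix expects a well-level table")
    df = table.data
    treat = df[df["Metadata_compound"] != DMSO]
    conditions = (
        treat[["Metadata_compound", "Metadata_dose_uM", "Metadata_timepoint_h"]]
        .drop_duplicates()
        .sort_values(["Metadata_compound", "Metadata_dose_uM", "Metadata_timepoint_h"])
        .to_numpy()
    )
    nulls: dict[float, MapDistribution] = {}
    rows = []
    for compound, dose, tp in conditions:
        tp = float(tp)
        if tp not in nulls:
            nulls[tp] = sample_null_distribution(table, tp, scheme)
        cond = (compound, float(dose), tp)
        try:
            dist = sample_map_distribution(table, cond, scheme)
        except InsufficientReplicatesError:
            rows.append(
                {
                    "compound": compound,
                    "dose_uM": float(dose),
                    "timepoint_h": tp,
                    "map_mean": np.nan,
                    "map_es": np.nan,
                    "is_active": False,
                    "status": "insufficient_replicates",
                }
            )
            continue
        call = call_activity(dist, nulls[tp], threshold)
        rows.append(
            {
                "compound": compound,
                "dose_uM": float(dose),
                "timepoint_h": tp,
                "map_mean": float(dist.values.mean()),
                "map_es": call.map_es,
                "is_active": call.is_active,
                "status": "ok",
            }
        )
    calls = pd.DataFrame(rows)
    summary: dict = {
        "threshold": threshold,
        "n_conditions": len(calls),
        "n_evaluated": int((calls["status"] == "ok").sum()),
        "n_active": int(calls["is_active"].sum()),
        "null_means": {tp: float(d.values.mean()) for tp, d in nulls.items()},
    }
    if truth is not None:
        merged = calls.merge(
            truth.conditions,
            left_on=["compound", "dose_uM", "timepoint_h"],
            right_on=["compound", "dose_uM", "timepoint_h"],
            how="left",
            suffixes=("", "_truth"),
        )
        ok = merged["status"] == "ok"
        pos = ok & merged["is_active_truth"].astype(bool)
        neg = ok & ~merged["is_active_truth"].astype(bool)
        summary["sensitivity"] = (
            float(merged.loc[pos, "is_active"].mean()) if pos.any() else np.nan
        )
        summary["specificity"] = (
            float((~merged.loc[neg, "is_active"]).mean()) if neg.any() else np.nan
        )
        by_dose = {}
        for dose, grp in merged[ok].groupby("dose_uM"):
            grp_pos = grp[grp["is_active_truth"].astype(bool)]
            by_dose[float(dose)] = (
                float(grp_pos["is_active"].mean()) if len(grp_pos) else np.nan
            )
        summary["sensitivity_by_dose"] = by_dose
    return calls, summary
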