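"""Mechanism-of-action classification with per-condition linear probes.

One multinomial logistic probe (L2-penalized, features standardized on its
training split) is trained per (dose, timepoint) condition on the well
profiles of compounds called *active* at that condition, with DMSO wells
always included as an explicit class — so a compound whose phenotype is
indistinguishable from vehicle can legitimately be predicted "DMSO".

Per condition, a compound's prediction is the average of the probe's softmax
outputs over that compound's wells.  Predictions are then aggregated
incrementally across doses (ascending, each dose contributing all of its
timepoints) by weighted averaging of the probability rows; the standard
readout is F1-weighted, accuracy, top-3 accuracy and a confusion matrix, and
two classifiers are compared with McNemar's paired test.

Cross-validation splits *by compound* (all wells and conditions of a compound
share a fold), stratified by MoA, so replicate wells never leak across the
train/test boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score
from sklearn.preprocessing import StandardScaler

from ._rng import child_rng
from .schema import DMSO, ProfileTable

__all__ = [
    "LinearProbe",
    "ConditionPredictions",
    "MoAReport",
    "train_probe",
    "predict_conditions",
    "incremental_aggregate",
    "evaluate_moa",
    "assign_folds",
    "cross_validate",
    "fit_condition_probes",
    "mcnemar_test",
]


class SingleClassError(ValueError):
    """Fewer than two classes survive activity filtering."""


@dataclass
class LinearProbe:
    """Standardizer + multinomial logistic model for one (dose, timepoint)."""

    condition: tuple
    class_labels: list[str]
    scaler: StandardScaler
    model: LogisticRegression

    @property
    def weights(self) -> np.ndarray:
        return self.model.coef_

    @property
    def intercepts(self) -> np.ndarray:
        return self.model.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.scaler.mean_.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match probe "
                f"({self.scaler.mean_.shape[0]})"
            )
        return self.model.predict_proba(self.scaler.transform(X))


@dataclass
class ConditionPredictions:
    """Per-compound class-probability rows for one (dose, timepoint)."""

    condition: tuple
    probabilities: pd.DataFrame  # index: compound, columns: class labels

    def __post_init__(self):
        p = self.probabilities.to_numpy(dtype=float)
        if ((p < -1e-12) | (p > 1 + 1e-12)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability rows must sum to 1")


@dataclass
class MoAReport:
    f1_weighted: float
    accuracy: float
    top3_accuracy: float
    confusion_matrix: pd.DataFrame
    per_class_f1: pd.Series


def _condition_slice(table: ProfileTable, dose: float, timepoint: float) -> pd.DataFrame:
    df = table.data
    is_dmso = df["Metadata_compound"] == DMSO
    at_tp = np.isclose(df["Metadata_timepoint_h"].to_numpy(dtype=float), float(timepoint))
    at_dose = np.zeros(len(df), dtype=bool)
    at_dose[~is_dmso.to_numpy()] = np.isclose(
        df.loc[~is_dmso, "Metadata_dose_uM"].to_numpy(dtype=float), float(dose)
    )
    return df[(at_dose | is_dmso.to_numpy()) & at_tp]


def train_probe(
    table: ProfileTable,
    dose: float,
    timepoint: float,
    active_compounds=None,
    compounds=None,
    C: float = 1.0,
    seed: int = 0,
) -> LinearProbe:
    """Fit the linear probe for one (dose, timepoint).

    ``active_compounds`` (if given) restricts treatment training wells to
    compounds called active at this condition; ``compounds`` further restricts
    to a training split (CV fold).  DMSO wells are always included as their
    own class.
    """
    sl = _condition_slice(table, dose, timepoint)
    keep = sl["Metadata_compound"] == DMSO
    treat = ~keep
    if compounds is not None:
        treat &= sl["Metadata_compound"].isin(set(compounds))
    if active_compounds is not None:
        treat &= sl["Metadata_compound"].isin(set(active_compounds))
    sl = sl[keep | treat]
    y = np.where(sl["Metadata_compound"] == DMSO, DMSO, sl["Metadata_moa"])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise SingleClassError(
            f"condition (dose={dose}, t={timepoint}): only {classes} present after filtering"
        )
    X = sl[table.feature_names].to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    model = LogisticRegression(  # default penalty is L2
        C=C,
        max_iter=2000,
        random_state=int(child_rng(seed, "probe", dose, timepoint).integers(2**31)),
    ).fit(scaler.transform(X), y)
    return LinearProbe((float(dose), float(timepoint)), list(model.classes_), scaler, model)


def predict_conditions(
    probe: LinearProbe,
    table: ProfileTable,
    compounds=None,
    class_labels=None,
) -> ConditionPredictions:
    """Per-compound softmax averages for the probe's condition.

    Each compound's probability row is the mean of the probe's softmax
    outputs over that compound's wells at the condition.  ``class_labels``
    aligns the output columns to a global class list (classes the probe never
    saw get probability 0), so rows from different probes can be averaged.
    """
    dose, timepoint = probe.condition
    sl = _condition_slice(table, dose, timepoint)
    sl = sl[sl["Metadata_compound"] != DMSO]
    if compounds is not None:
        sl = sl[sl["Metadata_compound"].isin(set(compounds))]
    X = sl[table.feature_names].to_numpy(dtype=float)
    proba = probe.predict_proba(X)
    frame = pd.DataFrame(proba, columns=probe.class_labels)
    frame["__compound"] = sl["Metadata_compound"].to_numpy()
    rows = frame.groupby("__compound").mean()
    rows.index.name = "compound"
    if class_labels is not None:
        rows = rows.reindex(columns=list(class_labels), fill_value=0.0)
    return ConditionPredictions(probe.condition, rows)


def incremental_aggregate(
    preds: list[ConditionPredictions],
    doses: list[float],
    upto_dose_index: int,
    weights="uniform",
) -> pd.DataFrame:
    """Weighted-average aggregation over all conditions of the first doses.

    Includes every condition whose dose has index <= ``upto_dose_index`` in
    the ascending ``doses`` list (all timepoints of each included dose).
    Returns one row per compound with the aggregated probabilities plus
    ``label`` (argmax) and ``top3`` columns.
    """
    doses = sorted(float(d) for d in doses)
    included = [p for p in preds if float(p.condition[0]) in doses[: upto_dose_index + 1]]
    if not included:
        raise ValueError("no conditions fall within the requested dose range")
    if weights == "uniform":
        w = np.ones(len(included))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(included) or (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative, not all zero, one per condition")
    classes = list(included[0].probabilities.columns)
    compounds = sorted(set().union(*(set(p.probabilities.index) for p in included)))
    num = pd.DataFrame(0.0, index=compounds, columns=classes)
    den = pd.Series(0.0, index=compounds)
    for wi, p in zip(w, included):
        if list(p.probabilities.columns) != classes:
            raise ValueError("condition predictions have mismatched class columns")
        aligned = p.probabilities.reindex(index=compounds)
        present = aligned.notna().all(axis=1)
        num.loc[present] += wi * aligned[present]
        den.loc[present] += wi
    out = num.div(den, axis=0)
    order = np.argsort(-out.to_numpy(), axis=1, kind="stable")
    out["label"] = [classes[i] for i in order[:, 0]]
    out["top3"] = [[classes[i] for i in row[:3]] for row in order]
    out.index.name = "compound"
    return out


def evaluate_moa(predictions: pd.DataFrame, truth: dict[str, str], class_labels=None) -> MoAReport:
    """Score aggregated predictions against compound -> MoA ground truth."""
    compounds = [c for c in predictions.index if c in truth]
    missing = set(predictions.index) - set(compounds)
    if missing:
        raise ValueError(f"compounds without a truth label: {sorted(missing)[:5]}")
    y_true = [truth[c] for c in compounds]
    y_pred = [predictions.loc[c, "label"] for c in compounds]
    if class_labels is None:
        class_labels = sorted(set(y_true) | set(y_pred) | {DMSO})
    unknown = set(y_pred) - set(class_labels)
    if unknown:
        raise ValueError(f"predicted labels outside the class set: {sorted(unknown)}")
    top3 = [predictions.loc[c, "top3"] for c in compounds]
    cm = _sk_confusion(y_true, y_pred, labels=class_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # classes absent from y_true
        f1w = f1_score(y_true, y_pred, labels=class_labels, average="weighted", zero_division=0)
        per_class = f1_score(
            y_true, y_pred, labels=class_labels, average=None, zero_division=0
        )
    acc = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    top3_acc = float(np.mean([t in row for t, row in zip(y_true, top3)]))
    return MoAReport(
        f1_weighted=float(f1w),
        accuracy=acc,
        top3_accuracy=top3_acc,
        confusion_matrix=pd.DataFrame(cm, index=class_labels, columns=class_labels),
        per_class_f1=pd.Series(per_class, index=class_labels),
    )


def assign_folds(compounds: pd.DataFrame, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Compound-level fold assignment, stratified by MoA.

    Shuffles the compounds of each MoA class and deals them round-robin into
    folds; warns (but proceeds best-effort) when a class has fewer than ``k``
    compounds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = child_rng(seed, "folds")
    folds: dict[str, int] = {}
    offset = 0
    small_classes = []
    for moa, grp in compounds.groupby("moa"):
        names = sorted(grp["compound"])
        if len(names) < k:
            small_classes.append(moa)
        names = [names[i] for i in rng.permutation(len(names))]
        for i, name in enumerate(names):
            folds[name] = (i + offset) % k
        offset += len(names)  # rotate start so small classes spread over folds
    if small_classes:
        warnings.warn(
            f"{len(small_classes)} MoA class(es) have fewer than {k} compounds "
            f"(e.g. {small_classes[0]!r}); stratification is best-effort",
            stacklevel=2,
        )
    return folds


def _active_sets(activity_calls: pd.DataFrame | None):
    """condition -> set of active compounds, from an activity_matrix output."""
    if activity_calls is None:
        return None
    active = activity_calls[activity_calls["is_active"]]
    out: dict[tuple, set] = {}
    for _, row in active.iterrows():
        out.setdefault((float(row["dose_uM"]), float(row["timepoint_h"])), set()).add(
            row["compound"]
        )
    return out


def fit_condition_probes(
    table: ProfileTable,
    activity_calls: pd.DataFrame | None = None,
    compounds=None,
    C: float = 1.0,
    seed: int = 0,
) -> dict[tuple, LinearProbe]:
    """One probe per (dose, timepoint) present in the table.

    Conditions where activity filtering leaves only the DMSO class are
    skipped (no probe).
    """
    df = table.data
    treat = df[df["Metadata_compound"] != DMSO]
    conditions = sorted(
        set(
            zip(
                treat["Metadata_dose_uM"].astype(float),
                treat["Metadata_timepoint_h"].astype(float),
            )
        )
    )
    active_sets = _active_sets(activity_calls)
    probes: dict[tuple, LinearProbe] = {}
    for dose, tp in conditions:
        active = None if active_sets is None else active_sets.get((dose, tp), set())
        try:
            probes[(dose, tp)] = train_probe(
                table,
                dose,
                tp,
                active_compounds=active,
                compounds=compounds,
                C=C,
                seed=seed,
            )
        except SingleClassError:
            continue
    return probes


def cross_validate(
    table: ProfileTable,
    activity_calls: pd.DataFrame | None = None,
    k: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[list[ConditionPredictions], list[str]]:
    """Compound-stratified k-fold CV of the per-condition probes.

    Returns out-of-fold :class:`ConditionPredictions` (one per usable
    condition, rows covering every compound via its own test fold) and the
    global class list.  DMSO wells, which are a class rather than evaluated
    compounds, enter every training split.
    """
    df = table.data
    treat = df[df["Metadata_compound"] != DMSO]
    compounds = (
        treat[["Metadata_compound", "Metadata_moa"]]
        .drop_duplicates()
        .rename(columns={"Metadata_compound": "compound", "Metadata_moa": "moa"})
    )
    folds = assign_folds(compounds, k=k, seed=seed)
    class_labels = sorted(set(compounds["moa"])) + [DMSO]
    class_labels = sorted(set(class_labels))
    per_condition: dict[tuple, list[pd.DataFrame]] = {}
    for fold in range(k):
        test_compounds = {c for c, f in folds.items() if f == fold}
        train_compounds = {c for c, f in folds.items() if f != fold}
        probes = fit_condition_probes(
            table, activity_calls, compounds=train_compounds, C=C, seed=seed
        )
        for cond, probe in probes.items():
            preds = predict_conditions(
                probe, table, compounds=test_compounds, class_labels=class_labels
            )
            per_condition.setdefault(cond, []).append(preds.probabilities)
    out = [
        ConditionPredictions(cond, pd.concat(parts).sort_index())
        for cond, parts in sorted(per_condition.items())
    ]
    return out, class_labels


def mcnemar_test(labels_a, labels_b, truth: dict[str, str] | list) -> tuple[float, float]:
    """McNemar's paired test on two classifiers' correctness patterns.

    ``b`` counts compounds a got right and b wrong, ``c`` the reverse.
    Statistic is ``(b - c)^2 / (b + c)`` without continuity correction with a
    chi-square(1) p-value; for ``b + c < 25`` the p-value comes from the
    exact two-sided binomial instead.  ``b + c == 0`` gives (0.0, 1.0).
    """
    labels_a = pd.Series(labels_a)
    labels_b = pd.Series(labels_b)
    if not labels_a.index.equals(labels_b.index):
        raise ValueError("both classifiers must be evaluated on the same compounds")
    if isinstance(truth, dict):
        y = labels_a.index.map(truth)
        if y.isna().any():
            raise ValueError("every evaluated compound needs a truth label")
    else:
        y = pd.Index(truth)
    correct_a = labels_a.to_numpy() == np.asarray(y)
    correct_b = labels_b.to_numpy() == np.asarray(y)
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return 0.0, 1.0
    statistic = (b - c) ** 2 / (b + c)
    if b + c < 25:
        p = float(stats.binomtest(min(b, c), n=b + c, p=0.5).pvalue)
    else:
        p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p
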