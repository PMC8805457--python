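"""Simulated-clinical splitting and event-based evaluation.

The clinical split mimics how a predictor would actually be deployed: the
training and validation pool holds all *other* patients' windows plus the
preictal windows of exactly one seizure of the target patient (with an
equal-size share of the target's interictal windows, nearest in time to
that seizure); every remaining target window is test data.  The pool is
partitioned into 5 folds, 80% train / 20% validation per fold.  Evaluation
is event-based: a test seizure counts as predicted iff at least one alarm
falls inside its preictal horizon, false alarms are alarms in interictal
time, and the false-prediction rate is per interictal hour.  AUC is
computed at window level from the classifier scores by rank statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .aae import AaeParams, train
from .classify import ClassifierConfig, fit_frozen_svm, predict
from .labeling import PREICTAL, WindowSet
from .stft import StftConfig, batch_spectrograms, flatten_batch

logger = logging.getLogger(__name__)

__all__ = ["SplitPlan", "EvalReport", "clinical_split", "score_stream",
           "event_metrics", "window_auc", "loocv_sweep"]

WindowRef = tuple[str, int]          # (patient_id, index into WindowSet)


@dataclass
class SplitPlan:
    """Train/validation/test assignment for one target patient."""

    target_patient: str
    included_target_seizure: int
    train_windows: list[WindowRef]
    val_windows: list[WindowRef]
    test_windows: list[WindowRef]
    fold_assignments: dict[WindowRef, int]
    n_folds: int = 5

    def __post_init__(self):
        pool = set(self.train_windows) | set(self.val_windows)
        if pool & set(self.test_windows):
            raise AssertionError("train/val and test windows overlap")
        if set(self.train_windows) & set(self.val_windows):
            raise AssertionError("train and val windows overlap")
        for pid, _ in self.test_windows:
            if pid != self.target_patient:
                raise AssertionError("non-target window in test set")

    def fold(self, k: int) -> tuple[list[WindowRef], list[WindowRef]]:
        """Train/val references for fold ``k`` of the pooled data."""
        pool = sorted(self.fold_assignments)
        val = [r for r in pool if self.fold_assignments[r] == k]
        tr = [r for r in pool if self.fold_assignments[r] != k]
        return tr, val


@dataclass
class EvalReport:
    """Event-based metrics for one target patient."""

    sensitivity: float
    fpr_per_h: float | None
    auc: float | None
    n_test_seizures: int
    interictal_hours: float
    latencies_s: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity out of [0, 1]")
        if self.fpr_per_h is not None and self.fpr_per_h < 0:
            raise ValueError("fpr_per_h must be >= 0")
        if self.auc is not None and not 0 <= self.auc <= 1:
            raise ValueError("auc out of [0, 1]")


def clinical_split(cohort: dict[str, WindowSet], target: str,
                   seizure_choice: str | int = "first", seed: int = 0,
                   n_folds: int = 5) -> SplitPlan:
    """Build the simulated-clinical split for ``target``.

    ``seizure_choice`` selects which target seizure seeds the training pool:
    ``"first"`` (chronologically first; the clinically realistic default),
    an integer seizure index, or ``"random"`` (seeded).
    """
    if target not in cohort:
        raise KeyError(f"unknown target patient {target!r}")
    tws = cohort[target]
    seizure_ids = sorted({w.seizure_index for w in tws.windows
                          if w.seizure_index is not None})
    if len(seizure_ids) < 2:
        raise ValueError(
            f"target {target} has {len(seizure_ids)} seizures with preictal "
            "windows; need >= 2 so the test set is non-empty")
    rng = np.random.default_rng(seed)
    if seizure_choice == "first":
        chosen = seizure_ids[0]
    elif seizure_choice == "random":
        chosen = int(rng.choice(seizure_ids))
    else:
        chosen = int(seizure_choice)
        if chosen not in seizure_ids:
            raise ValueError(f"seizure index {chosen} not in {seizure_ids}")

    pre_idx = [i for i, w in enumerate(tws.windows)
               if w.seizure_index == chosen]
    inter_idx = [i for i, w in enumerate(tws.windows) if w.label == 0]
    anchor = max(tws.windows[i].t_start_s for i in pre_idx)
    inter_sorted = sorted(inter_idx,
                          key=lambda i: abs(tws.windows[i].t_start_s - anchor))
    matched = sorted(inter_sorted[:len(pre_idx)])

    pool: list[WindowRef] = []
    for pid, ws in cohort.items():
        if pid == target:
            continue
        pool.extend((pid, i) for i in range(len(ws.windows)))
    pool.extend((target, i) for i in pre_idx + matched)
    if len(cohort) == 1:
        logger.warning("single-patient cohort: training pool holds only one "
                       "seizure's windows of the target")

    taken = set(pre_idx) | set(matched)
    test = [(target, i) for i in range(len(tws.windows)) if i not in taken]

    order = rng.permutation(len(pool))
    folds = {pool[i]: int(k % n_folds) for k, i in enumerate(order)}
    train_refs, val_refs = [], []
    for r in pool:
        (val_refs if folds[r] == 0 else train_refs).append(r)
    return SplitPlan(target_patient=target, included_target_seizure=chosen,
                     train_windows=sorted(train_refs),
                     val_windows=sorted(val_refs),
                     test_windows=sorted(test),
                     fold_assignments=folds, n_folds=n_folds)


def score_stream(times_s: np.ndarray, positive: np.ndarray,
                 refractory_s: float = 1800.0) -> list[float]:
    """Collapse time-ordered positive windows into alarm events.

    Each positive window raises an alarm at its start time; further
    positives within the refractory period (default one SPH) are part of
    the same alarm.  Set ``refractory_s=0`` for strict one-alarm-per-window
    scoring.
    """
    times_s = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times_s) < 0):
        raise ValueError("windows must be time-ordered")
    alarms: list[float] = []
    for t, pos in zip(times_s, np.asarray(positive).astype(bool)):
        if pos and (not alarms or t >= alarms[-1] + refractory_s):
            alarms.append(float(t))
    return alarms


def window_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Window-level AUC by rank statistic (ties get mid-ranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def event_metrics(alarms: list[float],
                  preictal_intervals: list[tuple[float, float]],
                  interictal_hours: float,
                  scores: np.ndarray | None = None,
                  labels: np.ndarray | None = None) -> EvalReport:
    """Event-based sensitivity and FPR/h, plus window-level AUC.

    A seizure is predicted iff >= 1 alarm falls in its preictal interval
    ``[onset - SPH, onset)``; any alarm outside every preictal interval is
    a false alarm, rated per interictal hour.
    """
    hits = 0
    latencies = []
    for start, end in preictal_intervals:
        inside = [t for t in alarms if start <= t < end]
        if inside:
            hits += 1
            latencies.append(end - min(inside))
    false_alarms = sum(
        1 for t in alarms
        if not any(s <= t < e for s, e in preictal_intervals))
    n_seiz = len(preictal_intervals)
    sens = hits / n_seiz if n_seiz else 0.0
    fpr = false_alarms / interictal_hours if interictal_hours > 0 else None
    auc = None
    if scores is not None and labels is not None:
        auc = window_auc(scores, labels)
    return EvalReport(sensitivity=sens, fpr_per_h=fpr, auc=auc,
                      n_test_seizures=n_seiz,
                      interictal_hours=interictal_hours,
                      latencies_s=latencies)


# ---------------------------------------------------------------------------
# leave-one-patient-out sweep
# ---------------------------------------------------------------------------

def _features(cohort: dict[str, WindowSet], stft_cfg: StftConfig):
    feats = {}
    for pid, ws in cohort.items():
        X, y = flatten_batch(batch_spectrograms(ws, stft_cfg))
        feats[pid] = (X, y)
    return feats


def evaluate_target(cohort: dict[str, WindowSet], target: str,
                    stft_cfg: StftConfig, aae_params: AaeParams,
                    cls_cfg: ClassifierConfig = ClassifierConfig(),
                    seed: int = 0, features=None,
                    refractory_s: float = 1800.0) -> EvalReport:
    """Train on the clinical split for one target and evaluate its test set."""
    plan = clinical_split(cohort, target, seed=seed)
    if features is None:
        features = _features(cohort, stft_cfg)

    train_refs, val_refs = plan.fold(0)
    by_dom: dict[str, list[int]] = {}
    for pid, i in train_refs:
        by_dom.setdefault(pid, []).append(i)
    data = {pid: (features[pid][0][idx], features[pid][1][idx])
            for pid, idx in by_dom.items()}
    X_val = np.vstack([features[pid][0][[i]] for pid, i in val_refs])
    y_val = np.array([features[pid][1][i] for pid, i in val_refs])

    model = train(data, aae_params, val_data=(X_val, y_val))

    tws = cohort[target]
    test_idx = [i for _, i in plan.test_windows]
    order = np.argsort([tws.windows[i].t_start_s for i in test_idx])
    test_idx = [test_idx[i] for i in order]
    X_test = features[target][0][test_idx]
    y_test = features[target][1][test_idx]
    times = np.array([tws.windows[i].t_start_s for i in test_idx])

    svm = None
    if cls_cfg.mode == "frozen_svm":
        X_tr = np.vstack([d[0] for d in data.values()])
        y_tr = np.concatenate([d[1] for d in data.values()])
        svm = fit_frozen_svm(model, X_tr, y_tr, c_reg=cls_cfg.c_reg)
    scores, pred = predict(model, X_test, cls_cfg, svm=svm)

    alarms = score_stream(times, pred, refractory_s=refractory_s)
    test_seizures = [s for s in
                     {tws.windows[i].seizure_index for i in test_idx
                      if tws.windows[i].seizure_index is not None}]
    pre_ivals = []
    k = -1
    for start, end, kind in tws.intervals:
        if kind == PREICTAL:
            k += 1
            if k in test_seizures:
                pre_ivals.append((start, end))
    window_s = tws.windows[0].data.shape[1] / tws.rate if tws.windows else 5.0
    inter_h = float((y_test == 0).sum()) * window_s / 3600.0
    return event_metrics(alarms, pre_ivals, inter_h, scores=scores,
                         labels=y_test)


def loocv_sweep(cohort: dict[str, WindowSet], stft_cfg: StftConfig,
                aae_params: AaeParams,
                cls_cfg: ClassifierConfig = ClassifierConfig(),
                seed: int = 0, targets: list[str] | None = None,
                refractory_s: float = 1800.0) -> pd.DataFrame:
    """Run the clinical split + training + evaluation once per target.

    Returns one row per target plus an unweighted ``Avg.`` row; per-target
    failures are recorded as NaN rows and the sweep continues.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-patient-out needs >= 2 patients")
    features = _features(cohort, stft_cfg)
    rows = []
    for target in (targets or sorted(cohort)):
        try:
            rep = evaluate_target(cohort, target, stft_cfg, aae_params,
                                  cls_cfg, seed=seed, features=features,
                                  refractory_s=refractory_s)
            rows.append({"target": target, "sensitivity": rep.sensitivity,
                         "fpr_per_h": rep.fpr_per_h, "auc": rep.auc,
                         "n_test_seizures": rep.n_test_seizures,
                         "interictal_hours": rep.interictal_hours})
        except Exception as exc:  # noqa: BLE001 - sweep continues
            logger.error("target %s failed: %s", target, exc)
            rows.append({"target": target, "sensitivity": np.nan,
                         "fpr_per_h": np.nan, "auc": np.nan,
                         "n_test_seizures": 0, "interictal_hours": np.nan})
    df = pd.DataFrame(rows)
    avg = df.drop(columns="target").mean(numeric_only=True)
    df = pd.concat([df, pd.DataFrame([{"target": "Avg.", **avg.to_dict()}])],
                   ignore_index=True)
    return df
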