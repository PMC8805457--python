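"""Preictal / interictal labeling and non-overlapping 5-s windowing.

The binary prediction scheme marks the 30 minutes before each seizure onset
as preictal (the seizure prediction horizon, SPH; the seizure occurrence
period SPO is zero), discards ictal plus a configurable postictal stretch,
and treats all remaining time as interictal.  Each labeled interval is then
tiled left-to-right with non-overlapping fixed-length windows, and the
(usually far larger) interictal class is randomly subsampled to match the
preictal count.

Intervals are half-open ``[start_s, end_s)`` in seconds from recording
start; annotation times are converted to sample indices only at windowing,
using floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Recording

__all__ = [
    "LabelingConfig", "LabeledWindow", "WindowSet",
    "eligible_patient", "label_intervals", "window_segments",
    "balance_classes", "windows_from_recording", "subsample_windows",
]

PREICTAL, INTERICTAL, EXCLUDED = "preictal", "interictal", "excluded"


@dataclass(frozen=True)
class LabelingConfig:
    """SPH/SPO labeling parameters.

    ``sph_minutes`` is the preictal horizon before onset (30 min);
    ``spo_minutes`` a buffer between the horizon end and onset (0 here);
    ``postictal_exclude_minutes`` the stretch after seizure offset dropped
    from the interictal class.
    """

    sph_minutes: float = 30.0
    spo_minutes: float = 0.0
    postictal_exclude_minutes: float = 30.0
    window_s: float = 5.0

    def __post_init__(self):
        if self.sph_minutes <= 0 or self.window_s <= 0 or self.spo_minutes < 0:
            raise ValueError("sph_minutes, window_s > 0 and spo_minutes >= 0")

    @property
    def sph_s(self) -> float:
        return self.sph_minutes * 60.0

    @property
    def spo_s(self) -> float:
        return self.spo_minutes * 60.0

    @property
    def postictal_s(self) -> float:
        return self.postictal_exclude_minutes * 60.0


@dataclass
class LabeledWindow:
    """One fixed-length segment with class label and domain identity."""

    data: np.ndarray            # channels x (window_s * rate)
    label: int                  # 1 = preictal, 0 = interictal
    patient_id: str
    t_start_s: float
    seizure_index: int | None = None   # preictal windows: which seizure

    @property
    def one_hot(self) -> np.ndarray:
        y = np.zeros(2)
        y[self.label] = 1.0
        return y


@dataclass
class WindowSet:
    """Windows from one recording plus enough provenance to split later."""

    windows: list[LabeledWindow]
    rate: float
    patient_id: str
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def counts(self) -> tuple[int, int]:
        pre = sum(w.label == 1 for w in self.windows)
        return pre, len(self.windows) - pre


def eligible_patient(n_seizures_total: int, n_seizures_per_day_max: int) -> bool:
    """Patient filtering rule: at least 2 seizures overall (enough to leave
    test events after seeding one into training) and fewer than 15 on any
    day (beyond that, prediction is uninformative)."""
    if n_seizures_total < 0 or n_seizures_per_day_max < 0:
        raise ValueError("seizure counts must be non-negative")
    return n_seizures_total >= 2 and n_seizures_per_day_max < 15


def label_intervals(rec: Recording, cfg: LabelingConfig = LabelingConfig()
                    ) -> list[tuple[float, float, str]]:
    """Partition ``[0, duration)`` into preictal / interictal / excluded.

    For each seizure k with onset o_k and offset f_k:
    ``[o_k - SPH - SPO, o_k - SPO)`` is preictal, truncated at the recording
    start and at the previous seizure's exclusion end;
    ``[o_k - SPO, f_k + postictal)`` is excluded.  Remaining time is
    interictal.  The returned intervals are sorted and exactly partition the
    recording; empty intervals are dropped.
    """
    dur = rec.duration_s
    marks: list[tuple[float, float, str]] = []
    prev_excl_end = 0.0
    for k, ann in enumerate(rec.annotations):
        pre_end = ann.onset_s - cfg.spo_s
        pre_start = max(pre_end - cfg.sph_s, 0.0, prev_excl_end)
        if pre_end > pre_start:
            marks.append((pre_start, pre_end, PREICTAL))
        excl_start = max(min(pre_end, ann.onset_s), prev_excl_end)
        excl_end = min(ann.offset_s + cfg.postictal_s, dur)
        if excl_end > excl_start:
            marks.append((excl_start, excl_end, EXCLUDED))
        prev_excl_end = max(prev_excl_end, excl_end)
    marks.sort(key=lambda m: m[0])

    out: list[tuple[float, float, str]] = []
    cursor = 0.0
    for start, end, kind in marks:
        if start > cursor:
            out.append((cursor, start, INTERICTAL))
        out.append((start, end, kind))
        cursor = end
    if cursor < dur:
        out.append((cursor, dur, INTERICTAL))
    return out


def window_segments(rec: Recording, intervals, cfg: LabelingConfig = LabelingConfig()
                    ) -> WindowSet:
    """Tile each preictal/interictal interval with non-overlapping windows.

    Windows are anchored at the interval start; the remainder shorter than
    one window at the right edge is discarded.  Excluded intervals yield
    nothing.
    """
    spw = cfg.window_s * rec.rate
    if abs(spw - round(spw)) > 1e-9:
        raise ValueError(
            f"window_s * rate = {spw} is not an integer number of samples")
    spw = int(round(spw))
    windows: list[LabeledWindow] = []
    seizure_idx = -1
    for start, end, kind in intervals:
        if kind == PREICTAL:
            seizure_idx += 1
        if kind == EXCLUDED:
            continue
        n_win = int(np.floor((end - start) / cfg.window_s))
        start_idx = int(np.floor(start * rec.rate))
        for i in range(n_win):
            lo = start_idx + i * spw
            windows.append(LabeledWindow(
                data=rec.signal[:, lo:lo + spw],
                label=1 if kind == PREICTAL else 0,
                patient_id=rec.patient_id,
                t_start_s=start + i * cfg.window_s,
                seizure_index=seizure_idx if kind == PREICTAL else None,
            ))
    return WindowSet(windows=windows, rate=rec.rate,
                     patient_id=rec.patient_id, intervals=list(intervals))


def balance_classes(ws: WindowSet, seed: int) -> WindowSet:
    """Equalize class counts by uniform subsampling of interictal windows.

    All preictal windows are retained; the interictal subsample is drawn
    without replacement, reproducibly from ``seed``.
    """
    pre = [w for w in ws.windows if w.label == 1]
    inter = [w for w in ws.windows if w.label == 0]
    if not pre or not inter:
        raise ValueError("balance_classes requires both classes present")
    if len(inter) < len(pre):
        raise ValueError(
            f"cannot balance: {len(inter)} interictal < {len(pre)} preictal")
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(inter), size=len(pre), replace=False)
    chosen = [inter[i] for i in sorted(keep)]
    windows = sorted(pre + chosen, key=lambda w: w.t_start_s)
    return replace(ws, windows=windows)


def subsample_windows(ws: WindowSet, per_class: int, seed: int) -> WindowSet:
    """Uniformly thin a window set to at most ``per_class`` windows per
    class, preictal windows stratified by seizure so every seizure keeps a
    share.  A run-scale control for desk-scale experiments; reproducible
    from ``seed``."""
    rng = np.random.default_rng(seed)
    pre = [w for w in ws.windows if w.label == 1]
    inter = [w for w in ws.windows if w.label == 0]
    by_seiz: dict[int, list[LabeledWindow]] = {}
    for w in pre:
        by_seiz.setdefault(w.seizure_index, []).append(w)
    keep: list[LabeledWindow] = []
    if by_seiz:
        share = max(1, per_class // len(by_seiz))
        for lst in by_seiz.values():
            idx = rng.choice(len(lst), min(share, len(lst)), replace=False)
            keep.extend(lst[i] for i in sorted(idx))
    if inter:
        idx = rng.choice(len(inter), min(per_class, len(inter)), replace=False)
        keep.extend(inter[i] for i in sorted(idx))
    return replace(ws, windows=sorted(keep, key=lambda w: w.t_start_s))


def windows_from_recording(rec: Recording,
                           cfg: LabelingConfig = LabelingConfig(),
                           balance_seed: int | None = None) -> WindowSet:
    """Convenience pipeline: label, window, optionally balance."""
    ws = window_segments(rec, label_intervals(rec, cfg), cfg)
    if balance_seed is not None:
        ws = balance_classes(ws, balance_seed)
    return ws
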