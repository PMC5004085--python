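"""Activity-type labelling and realistic-criteria failure flags.

A *half-center oscillator* (HCO) instance has both cells bursting in
alternation: at least two complete bursts inside the evaluation window,
regular spikes (within-burst amplitude CV < 0.07), regular period
(CV < 0.05), relative phase within [0.45, 0.55], and at least one synaptic
conductance present.  An HCO is *realistic* (rHCO) when its period lies in
[5, 15] s, spike frequency in [8, 25] Hz and duty cycle in [50, 70] %;
otherwise it is merely *functional* (fHCO).  Synapse-free twins with the
same regularity are *bursters* (realistic or not, period/frequency ranges
only).  All range checks use closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burst_metrics import (
    MIN_INTERBURST_GAP_S,
    MIN_SPIKES_PER_BURST,
    SPIKE_THRESHOLD_MV,
    BurstTrain,
    Characteristics,
    characteristics,
    detect_spikes,
    segment_bursts,
)
from .gridspace import InstanceRecord, ParameterPoint
from .traces import TracePair

PERIOD_RANGE_S = (5.0, 15.0)
FREQ_RANGE_HZ = (8.0, 25.0)
DUTY_RANGE_PCT = (50.0, 70.0)
CV_AMP_MAX = 0.07
CV_PERIOD_MAX = 0.05
PHASE_RANGE = (0.45, 0.55)
EVAL_WINDOW_S = 40.0
PLATEAU_MIN_S = 1.0

#: Table-style names for the seven nonempty subsets of failed criteria.
CATEGORY_NAMES = {
    frozenset({"period"}): "period",
    frozenset({"freq"}): "spike frequency",
    frozenset({"duty"}): "duty cycle",
    frozenset({"period", "freq", "duty"}): "period and spike frequency and duty cycle",
    frozenset({"period", "freq"}): "period and spike frequency",
    frozenset({"period", "duty"}): "period and duty cycle",
    frozenset({"freq", "duty"}): "spike frequency and duty cycle",
}

__all__ = [
    "CriteriaFlags",
    "CellActivity",
    "classify",
    "classify_pair",
    "realistic_flags",
    "summarize_cell",
]


@dataclass(frozen=True)
class CriteriaFlags:
    fail_period: bool
    fail_freq: bool
    fail_duty: bool

    @property
    def category(self) -> str | None:
        failed = set()
        if self.fail_period:
            failed.add("period")
        if self.fail_freq:
            failed.add("freq")
        if self.fail_duty:
            failed.add("duty")
        if not failed:
            return None
        return CATEGORY_NAMES[frozenset(failed)]

    @property
    def mask(self) -> str:
        return ("P" if self.fail_period else "-") + \
               ("F" if self.fail_freq else "-") + \
               ("D" if self.fail_duty else "-")


@dataclass
class CellActivity:
    """Per-cell evidence the classifier needs beyond raw characteristics."""

    n_spikes: int
    chars: Characteristics
    n_bursts_in_window: int
    plateau: bool = False


def _in(value: float | None, lo: float, hi: float) -> bool:
    return value is not None and lo <= value <= hi


def summarize_cell(t: np.ndarray, v: np.ndarray,
                   window: tuple[float, float] | None = None) -> tuple[BurstTrain, CellActivity]:
    """Detect spikes/bursts in one cell and summarise for classification.

    The burst count entering the "two bursts in 40 s" criterion counts
    complete bursts whose middle spikes fall in the final 40 s of the
    window.  Plateau means >= 1 s continuously above threshold containing
    fewer than three spikes.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if window is None:
        window = (float(t[0]), float(t[-1]))
    times, amps = detect_spikes(t, v)
    train = segment_bursts(times, amps, window=window)
    w_start = max(window[0], window[1] - EVAL_WINDOW_S)
    mids = train.middle_spikes
    n_in_window = int(np.sum((mids >= w_start) & (mids <= window[1]))) if len(train) else 0
    plateau = _has_plateau(t, v, times)
    act = CellActivity(
        n_spikes=len(times), chars=_chars_of(train),
        n_bursts_in_window=n_in_window, plateau=plateau,
    )
    return train, act


def _chars_of(train: BurstTrain) -> Characteristics:
    (ch,) = characteristics(train)
    return ch


def _has_plateau(t: np.ndarray, v: np.ndarray, spike_times: np.ndarray) -> bool:
    above = v > SPIKE_THRESHOLD_MV
    if not above.any():
        return False
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(v)]))
    for a, b in zip(starts, ends):
        if t[b - 1] - t[a] >= PLATEAU_MIN_S:
            n_spk = int(np.sum((spike_times >= t[a]) & (spike_times <= t[b - 1])))
            if n_spk < MIN_SPIKES_PER_BURST:
                return True
    return False


def _cell_category(act: CellActivity) -> str:
    if act.n_spikes == 0:
        return "plateau" if act.plateau else "silent"
    if act.plateau and act.n_bursts_in_window < 2:
        return "plateau"
    if act.n_bursts_in_window >= 2:
        return "bursting"
    return "spiking"


def _regular(act: CellActivity) -> bool:
    ch = act.chars
    return (
        ch.cv_amp is not None and ch.cv_amp < CV_AMP_MAX
        and ch.cv_period is not None and ch.cv_period < CV_PERIOD_MAX
    )


def classify(act_A: CellActivity, act_B: CellActivity, point: ParameterPoint) -> str:
    """Assign the instance's activity label (exhaustive; fallback ``other``)."""
    cat_A, cat_B = _cell_category(act_A), _cell_category(act_B)
    if cat_A == cat_B == "silent":
        return "silent"
    if cat_A != cat_B:
        return "asymmetric"
    if cat_A == "plateau":
        return "plateau"
    if cat_A == "spiking":
        return "spiking"
    # both bursting
    isolated = point.x_SynS == 0 and point.x_SynG == 0
    regular = _regular(act_A) and _regular(act_B)
    if isolated:
        if not regular:
            return "other"
        ch = act_A.chars
        if _in(ch.period_s, *PERIOD_RANGE_S) and _in(ch.spike_freq_hz, *FREQ_RANGE_HZ):
            return "realistic_burster"
        return "burster"
    phase = act_B.chars.phase
    phase_ok = phase is not None and (
        PHASE_RANGE[0] <= phase <= PHASE_RANGE[1]
        or PHASE_RANGE[0] <= 1.0 - phase <= PHASE_RANGE[1]
    )
    if not (regular and phase_ok):
        return "asymmetric"
    ch_A, ch_B = act_A.chars, act_B.chars
    if all(
        _in(ch.period_s, *PERIOD_RANGE_S)
        and _in(ch.spike_freq_hz, *FREQ_RANGE_HZ)
        and _in(ch.duty_pct, *DUTY_RANGE_PCT)
        for ch in (ch_A, ch_B)
    ):
        return "rHCO"
    return "fHCO"


def realistic_flags(chars: Characteristics, label: str | None = None) -> CriteriaFlags:
    """Failure flags against the realistic ranges, for HCO-class instances.

    If ``label`` is given it must be an HCO/burster-class label; anything
    else raises, since the physiological ranges only make sense for
    bursting activity.
    """
    if label is not None and label not in {
        "rHCO", "fHCO", "burster", "realistic_burster",
    }:
        raise ValueError(f"realistic criteria undefined for label {label!r}")
    return CriteriaFlags(
        fail_period=not _in(chars.period_s, *PERIOD_RANGE_S),
        fail_freq=not _in(chars.spike_freq_hz, *FREQ_RANGE_HZ),
        fail_duty=not _in(chars.duty_pct, *DUTY_RANGE_PCT),
    )


def classify_pair(pair: TracePair, point: ParameterPoint) -> InstanceRecord:
    """Full pipeline: traces -> spikes -> bursts -> characteristics -> label."""
    window = (float(pair.t[0]), float(pair.t[-1]))
    train_A, act_A = summarize_cell(pair.t, pair.v_A, window)
    train_B, act_B = summarize_cell(pair.t, pair.v_B, window)
    ch_A, ch_B = characteristics(train_A, train_B)
    act_A.chars, act_B.chars = ch_A, ch_B
    label = classify(act_A, act_B, point)
    rec = InstanceRecord(point=point, label=label)
    if label in {"rHCO", "fHCO", "burster", "realistic_burster"}:
        rec.period_s = ch_A.period_s
        rec.spike_freq_hz = ch_A.spike_freq_hz
        rec.duty_pct = ch_A.duty_pct
        rec.phase = ch_B.phase
        rec.cv_period = ch_A.cv_period
        rec.cv_amp = ch_A.cv_amp
        rec.fail_flags = realistic_flags(ch_A).mask
    return rec
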