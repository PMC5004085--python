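"""Spike detection, burst segmentation and burst characteristics.

Conventions used throughout (all documented because boundary behaviour
matters for classification downstream):

* a spike is one contiguous excursion of the voltage strictly above the
  −20 mV threshold; its time is the local maximum, its amplitude the peak;
* a burst needs at least three spikes and ends wherever an inter-spike gap
  reaches 1 s (a gap of exactly 1 s terminates the burst);
* the *middle spike* of an n-spike burst is the one at 0-based index
  ``(n - 1) // 2`` (lower median);
* bursts whose spikes come within one minimum gap of the recording edges
  are treated as possibly truncated and excluded from all statistics;
* the cycle period is the interval between middle spikes of consecutive
  bursts; the duty cycle is mean burst duration over mean period (percent);
* a cell's spike frequency is mean spikes-per-burst over mean burst
  duration (see note on `spike_freq_alt_hz`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPIKE_THRESHOLD_MV = -20.0
MIN_SPIKES_PER_BURST = 3
MIN_INTERBURST_GAP_S = 1.0

__all__ = [
    "SPIKE_THRESHOLD_MV",
    "Burst",
    "BurstTrain",
    "Characteristics",
    "detect_spikes",
    "segment_bursts",
    "characteristics",
]


@dataclass(frozen=True)
class Burst:
    spike_times: np.ndarray
    amplitudes: np.ndarray | None = None

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def duration(self) -> float:
        return float(self.spike_times[-1] - self.spike_times[0])

    @property
    def middle_spike(self) -> float:
        return float(self.spike_times[(self.n_spikes - 1) // 2])

    @property
    def cv_amp(self) -> float:
        """Coefficient of variation of spike amplitudes within the burst."""
        if self.amplitudes is None or len(self.amplitudes) < 2:
            return 0.0
        m = float(np.mean(self.amplitudes))
        if m == 0.0:
            return 0.0
        return abs(float(np.std(self.amplitudes, ddof=1)) / m)


@dataclass
class BurstTrain:
    bursts: list[Burst] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bursts)

    @property
    def middle_spikes(self) -> np.ndarray:
        return np.array([b.middle_spike for b in self.bursts])

    @property
    def durations(self) -> np.ndarray:
        return np.array([b.duration for b in self.bursts])

    @property
    def spike_counts(self) -> np.ndarray:
        return np.array([b.n_spikes for b in self.bursts])


@dataclass
class Characteristics:
    """Burst characteristics of one cell (plus the joint phase if paired).

    ``period_s`` is the mean of ``periods``; both are ``None`` when fewer
    than two complete bursts exist (flagged, not raised).  ``cv_amp`` is the
    maximum over bursts of the within-burst amplitude CV.
    ``spike_freq_alt_hz`` is the mean of per-burst spike frequencies — kept
    alongside the normative mean-count/mean-duration estimate because the
    two differ for unequal bursts.
    """

    n_bursts: int = 0
    periods: np.ndarray | None = None
    period_s: float | None = None
    duty_pct: float | None = None
    spike_freq_hz: float | None = None
    spike_freq_alt_hz: float | None = None
    cv_period: float | None = None
    cv_amp: float | None = None
    phase: float | None = None


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD_MV) -> tuple[np.ndarray, np.ndarray]:
    """Spike times and peak amplitudes from a uniformly sampled trace.

    One spike per contiguous supra-threshold excursion; the spike time is
    the sample of the excursion's maximum.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) != len(v):
        raise ValueError("t and v must have equal length")
    if len(t) > 2:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform time base")
    above = v > threshold
    if not above.any():
        return np.empty(0), np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(v)]))
    times = np.empty(len(starts))
    amps = np.empty(len(starts))
    for i, (a, b) in enumerate(zip(starts, ends)):
        k = a + int(np.argmax(v[a:b]))
        times[i] = t[k]
        amps[i] = v[k]
    return times, amps


def segment_bursts(spike_times: np.ndarray,
                   amplitudes: np.ndarray | None = None,
                   min_spikes: int = MIN_SPIKES_PER_BURST,
                   min_gap: float = MIN_INTERBURST_GAP_S,
                   window: tuple[float, float] | None = None) -> BurstTrain:
    """Group sorted spike times into bursts.

    Maximal runs with inter-spike gaps strictly below ``min_gap``; runs
    with fewer than ``min_spikes`` spikes are discarded.  If ``window`` is
    given, runs whose first (last) spike lies within ``min_gap`` of the
    window start (end) are treated as truncated and discarded.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(spike_times) < 0):
        raise ValueError("spike times must be sorted")
    if amplitudes is not None:
        amplitudes = np.asarray(amplitudes, dtype=float)
    if len(spike_times) == 0:
        return BurstTrain()
    breaks = np.flatnonzero(np.diff(spike_times) >= min_gap) + 1
    runs = np.split(np.arange(len(spike_times)), breaks)
    bursts = []
    for run in runs:
        if len(run) < min_spikes:
            continue
        st = spike_times[run]
        if window is not None:
            t0, t1 = window
            if st[0] < t0 + min_gap or st[-1] > t1 - min_gap:
                continue
        amp = amplitudes[run] if amplitudes is not None else None
        bursts.append(Burst(spike_times=st, amplitudes=amp))
    return BurstTrain(bursts=bursts)


def _phase(train_A: BurstTrain, train_B: BurstTrain) -> float | None:
    """Per-burst phase of B relative to A, averaged over B bursts.

    For each B burst: (B middle − preceding A middle) divided by the
    interval between that A middle and the next A middle.
    """
    mids_A = train_A.middle_spikes
    if len(mids_A) < 2:
        return None
    vals = []
    for mb in train_B.middle_spikes:
        i = int(np.searchsorted(mids_A, mb, side="right")) - 1
        if i < 0 or i + 1 >= len(mids_A):
            continue
        vals.append((mb - mids_A[i]) / (mids_A[i + 1] - mids_A[i]))
    if not vals:
        return None
    return float(np.mean(vals))


def _single_cell(train: BurstTrain) -> Characteristics:
    ch = Characteristics(n_bursts=len(train))
    if len(train) == 0:
        return ch
    durs = train.durations
    counts = train.spike_counts
    ch.cv_amp = max(b.cv_amp for b in train.bursts)
    ch.spike_freq_hz = float(counts.mean() / durs.mean()) if durs.mean() > 0 else None
    with np.errstate(divide="ignore", invalid="ignore"):
        per_burst = np.where(durs > 0, counts / durs, np.nan)
    if np.isfinite(per_burst).any():
        ch.spike_freq_alt_hz = float(np.nanmean(per_burst))
    if len(train) >= 2:
        periods = np.diff(train.middle_spikes)
        ch.periods = periods
        ch.period_s = float(periods.mean())
        ch.cv_period = (
            float(np.std(periods, ddof=1) / periods.mean()) if len(periods) >= 2 else 0.0
        )
        ch.duty_pct = float(100.0 * durs.mean() / periods.mean())
    return ch


def characteristics(train_A: BurstTrain,
                    train_B: BurstTrain | None = None) -> tuple[Characteristics, ...]:
    """Characteristics per cell; the joint phase is stored on cell B's record.

    With fewer than two complete bursts the period (and everything derived
    from it) stays ``None``.
    """
    ch_A = _single_cell(train_A)
    if train_B is None:
        return (ch_A,)
    ch_B = _single_cell(train_B)
    phase = _phase(train_A, train_B)
    ch_B.phase = phase
    ch_A.phase = None if phase is None else phase
    return (ch_A, ch_B)
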