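"""Synthetic trace pairs, a phenomenological grid response, and packaged tables.

Three distinct jobs live here:

* :func:`synthesize_trace_pair` builds two-cell voltage traces with known
  period, duty cycle, spike frequency and phase, so the metrics pipeline
  can be validated by parameter recovery;
* :func:`grid_response` / :func:`make_synthetic_db` map grid points to
  activity labels and burst characteristics through a documented rule set
  whose monotone parameter dependencies mirror what the full conductance
  model shows (more h current -> shorter period, higher spike frequency;
  more CaS, P or SynS -> longer period; more K2 or leak -> shorter period;
  graded transmission -> negligible effect), giving labelled databases with
  analytically known family structure;
* :func:`load_fixtures` returns the packaged census tables (family counts
  per size, missing-member failure categories, period-sensitivity classes)
  used by the robustness arithmetic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .gridspace import (
    GridSpec,
    InstanceRecord,
    ParameterPoint,
    enumerate_grid,
)
from .activity_classifier import (
    DUTY_RANGE_PCT,
    FREQ_RANGE_HZ,
    PERIOD_RANGE_S,
    realistic_flags,
)
from .burst_metrics import Characteristics
from .traces import TracePair

__all__ = [
    "BurstSpec",
    "ResponseModel",
    "FixtureTables",
    "synthesize_trace_pair",
    "grid_response",
    "make_synthetic_db",
    "load_fixtures",
]

#: Half-width of the stereotyped spike waveform (s).
SPIKE_HALF_WIDTH_S = 0.003


@dataclass(frozen=True)
class BurstSpec:
    """Ground-truth description of an alternating-bursting trace pair."""

    period: float = 10.0
    duty: float = 60.0
    spike_freq: float = 15.0
    phase: float = 0.5
    spike_peak: float = 0.0
    burst_base: float = -45.0
    inter_base: float = -60.0
    noise_sd: float = 0.0
    seed: int = 0
    dt: float = 1e-3
    duration: float | None = None

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 < self.duty < 100:
            raise ValueError("duty must be in (0, 100)")
        if self.spike_freq < 0:
            raise ValueError("spike_freq must be >= 0")
        if not 0 <= self.phase < 1:
            raise ValueError("phase must be in [0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def _cell_trace(t: np.ndarray, mids: np.ndarray, spec: BurstSpec) -> tuple[np.ndarray, np.ndarray]:
    burst_dur = spec.duty / 100.0 * spec.period
    v = np.full_like(t, spec.inter_base)
    spike_times: list[float] = []
    n_spikes = int(round(spec.spike_freq * burst_dur))
    half_w = SPIKE_HALF_WIDTH_S
    dt = spec.dt
    for mid in mids:
        a, b = mid - burst_dur / 2.0, mid + burst_dur / 2.0
        ia, ib = np.searchsorted(t, [a, b + dt / 2])
        v[ia:ib] = np.maximum(v[ia:ib], spec.burst_base)
        if n_spikes == 0:
            continue
        if n_spikes == 1:
            times = np.array([mid])
        else:
            times = a + np.arange(n_spikes) * (burst_dur / (n_spikes - 1))
        # snap each spike apex onto the sampling grid so the detected local
        # maximum coincides with the intended time
        times = np.round(times / dt) * dt
        for s in times:
            j0, j1 = np.searchsorted(t, [s - half_w, s + half_w + dt / 2])
            pulse = spec.spike_peak - (np.abs(t[j0:j1] - s) / half_w) * (
                spec.spike_peak - spec.burst_base
            )
            v[j0:j1] = np.maximum(v[j0:j1], pulse)
        spike_times.extend(times.tolist())
    return v, np.array(spike_times)


def synthesize_trace_pair(spec: BurstSpec) -> TracePair:
    """Deterministic (given seed) alternating-bursting trace pair.

    Cell B's burst midpoints lag cell A's by ``phase x period``; each burst
    carries ``round(spike_freq x burst duration)`` evenly spaced spikes
    spanning the burst window.  Raises if the burst window is too short to
    hold three spike waveforms.
    """
    burst_dur = spec.duty / 100.0 * spec.period
    if burst_dur < 3 * 2 * SPIKE_HALF_WIDTH_S:
        raise ValueError(
            "burst window shorter than three spike widths; cannot honor >=3 spikes"
        )
    duration = spec.duration if spec.duration is not None else 7.0 * spec.period
    t = np.arange(0.0, duration + spec.dt / 2, spec.dt)
    n_cycles = int(np.floor(duration / spec.period))
    mids_A = (np.arange(n_cycles) + 0.5) * spec.period
    mids_B = mids_A + spec.phase * spec.period
    half = burst_dur / 2.0
    mids_A = mids_A[(mids_A - half >= 0) & (mids_A + half <= duration)]
    mids_B = mids_B[(mids_B - half >= 0) & (mids_B + half <= duration)]
    v_A, spk_A = _cell_trace(t, mids_A, spec)
    v_B, spk_B = _cell_trace(t, mids_B, spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v_A = v_A + rng.normal(0.0, spec.noise_sd, size=v_A.shape)
        v_B = v_B + rng.normal(0.0, spec.noise_sd, size=v_B.shape)
    return TracePair(t=t, v_A=v_A, v_B=v_B, spikes_A=spk_A, spikes_B=spk_B)


# ---------------------------------------------------------------------------
# phenomenological grid -> activity response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseModel:
    """Rule thresholds and linear coefficients of the synthetic response.

    The bursting-branch period and frequency are linear in the parameter
    fractions around the canonical point (all fractions 1, E_leak −60 mV),
    with signs fixed so the response reproduces the qualitative parameter
    dependencies of the conductance model.  All coefficients are per unit
    fraction (so a +25% grid step moves the period by ``0.25 x base x c``).
    """

    silent_below_xP: float = 0.25
    burster_min_xCaS: float = 0.5
    burster_min_xh: float = 0.25
    spiking_syn_below: float = 0.5
    asym_below_xCaS: float = 0.75
    period_base_s: float = 10.0
    period_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "x_CaS": 0.30, "x_P": 0.50, "x_SynS": 0.25,
            "x_h": -0.35, "x_K2": -0.20, "x_Leak": -0.15,
        }
    )
    period_eleak_coef: float = -0.01
    period_clip_s: tuple[float, float] = (1.0, 40.0)
    freq_base_hz: float = 15.0
    freq_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "x_CaS": 0.30, "x_P": 0.40, "x_h": 0.15,
            "x_K2": -0.10, "x_Leak": -0.15, "x_SynS": -0.05,
        }
    )
    duty_base_pct: float = 60.0
    duty_coef_SynS: float = -10.0
    duty_coef_h: float = 5.0
    duty_clip_pct: tuple[float, float] = (20.0, 90.0)
    cv_period: float = 0.01
    cv_amp: float = 0.02

    def period(self, point: ParameterPoint) -> float:
        s = 1.0 + sum(c * (point.get(p) - 1.0) for p, c in self.period_coefs.items())
        s += self.period_eleak_coef * (point.e_leak + 60.0)
        return float(np.clip(self.period_base_s * s, *self.period_clip_s))

    def freq(self, point: ParameterPoint) -> float:
        s = 1.0 + sum(c * (point.get(p) - 1.0) for p, c in self.freq_coefs.items())
        return float(max(self.freq_base_hz * s, 0.0))

    def duty(self, point: ParameterPoint) -> float:
        d = (
            self.duty_base_pct
            + self.duty_coef_SynS * (point.x_SynS - 1.0)
            + self.duty_coef_h * (point.x_h - 1.0)
        )
        return float(np.clip(d, *self.duty_clip_pct))


def grid_response(point: ParameterPoint, model: ResponseModel | None = None) -> InstanceRecord:
    """Label + characteristics for one grid point under the rule set.

    Rules apply in order: very low persistent-current fraction silences the
    pair; synapse-free twins are bursters when enough slow inward and h
    current is present, otherwise tonic spikers; no K2 produces plateau;
    weak synapses of both kinds produce spiking; low CaS produces
    asymmetric activity; everything else bursts with the linear response,
    and the physiological ranges decide realistic vs merely functional.
    """
    model = model or ResponseModel()
    isolated = point.x_SynS == 0 and point.x_SynG == 0
    if point.x_P < model.silent_below_xP:
        return InstanceRecord(point=point, label="silent")
    if isolated:
        if point.x_CaS >= model.burster_min_xCaS and point.x_h >= model.burster_min_xh:
            return _bursting_record(point, model, isolated=True)
        return InstanceRecord(point=point, label="spiking")
    if point.x_K2 == 0:
        return InstanceRecord(point=point, label="plateau")
    if point.x_SynS < model.spiking_syn_below and point.x_SynG < model.spiking_syn_below:
        return InstanceRecord(point=point, label="spiking")
    if point.x_CaS < model.asym_below_xCaS:
        return InstanceRecord(point=point, label="asymmetric")
    return _bursting_record(point, model, isolated=False)


def _bursting_record(point: ParameterPoint, model: ResponseModel, isolated: bool) -> InstanceRecord:
    period, freq, duty = model.period(point), model.freq(point), model.duty(point)
    chars = Characteristics(
        n_bursts=4, period_s=period, spike_freq_hz=freq, duty_pct=duty,
        cv_period=model.cv_period, cv_amp=model.cv_amp, phase=0.5,
    )
    flags = realistic_flags(chars)
    if isolated:
        realistic = not (flags.fail_period or flags.fail_freq)
        label = "realistic_burster" if realistic else "burster"
    else:
        label = "rHCO" if flags.mask == "---" else "fHCO"
    return InstanceRecord(
        point=point, label=label, period_s=period, spike_freq_hz=freq,
        duty_pct=duty, phase=0.5, cv_period=model.cv_period,
        cv_amp=model.cv_amp, fail_flags=flags.mask,
    )


def make_synthetic_db(spec: GridSpec, model: ResponseModel | None = None,
                      seed: int = 0) -> list[InstanceRecord]:
    """One labelled record per grid point; deterministic given seed.

    The default response has no stochastic component, so the family
    structure of the result is analytically known; ``seed`` is accepted so
    jittered variants remain reproducible.
    """
    model = model or ResponseModel()
    _ = np.random.default_rng(seed)  # reserved for jittered response variants
    return [grid_response(p, model) for p in enumerate_grid(spec)]


# ---------------------------------------------------------------------------
# packaged fixture tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureTables:
    """The packaged census tables.

    ``table1``: families per defining parameter and size — columns
    ``total`` and ``noninterrupted`` (the latter is missing where the
    source leaves one-member entries untabulated).
    ``table2``: missing h-family members with functional bursting, by
    family size and failed physiological criteria.
    ``table3``: h-family period-sensitivity class counts by family size.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame

    def table1_counts(self, parameter: str, size: int) -> tuple[int, int | None]:
        row = self.table1.loc[(parameter, size)]
        non = row["noninterrupted"]
        return int(row["total"]), (None if pd.isna(non) else int(non))

    def group_size(self, parameter: str) -> int:
        sub = self.table1.xs(parameter, level="parameter")
        return int((sub.index * sub["total"]).sum())

    def table2_count(self, size: int, category: str) -> int:
        return int(self.table2.loc[size, category])

    def table3_counts(self, size: int) -> tuple[int, int, int]:
        row = self.table3.loc[size]
        return int(row["high"]), int(row["medium"]), int(row["low"])

    def size_table(self, parameter: str):
        """Family-size counts for one parameter as a ``FamilySizeTable``.

        Untabulated one-member noninterrupted entries follow the
        one-member-families-are-noninterrupted convention (only relevant
        for measures at threshold n = 0).
        """
        from .family_analysis import FamilySizeTable

        sub = self.table1.xs(parameter, level="parameter")
        total = {int(s): int(r["total"]) for s, r in sub.iterrows()}
        nonint = {
            int(s): int(r["total"]) if pd.isna(r["noninterrupted"])
            else int(r["noninterrupted"])
            for s, r in sub.iterrows()
        }
        return FamilySizeTable(total=total, noninterrupted=nonint)


_DATA_FILES = ("table1.tsv", "table2.tsv", "table3.tsv")


def _read_packaged(name: str) -> tuple[str, pd.DataFrame]:
    pkg = resources.files("famscape.data")
    raw = (pkg / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    from io import BytesIO

    return digest, pd.read_csv(BytesIO(raw), sep="\t")


def load_fixtures() -> FixtureTables:
    """Load the packaged tables, verifying their checksums."""
    pkg = resources.files("famscape.data")
    expected = {}
    for line in (pkg / "checksums.sha256").read_text().splitlines():
        digest, name = line.split()
        expected[name] = digest
    frames = {}
    for name in _DATA_FILES:
        digest, df = _read_packaged(name)
        if digest != expected[name]:
            raise ValueError(f"checksum mismatch for packaged fixture {name}")
        frames[name] = df
    t1 = frames["table1.tsv"].set_index(["parameter", "size"]).sort_index()
    t2 = frames["table2.tsv"].set_index("size").sort_index()
    t2.columns = [c.replace("_", " ") for c in t2.columns]
    t3 = frames["table3.tsv"].set_index("size").sort_index()
    return FixtureTables(table1=t1, table2=t2, table3=t3)
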