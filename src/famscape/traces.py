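"""Paired voltage traces and their on-disk containers (HDF5 or TSV)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TracePair", "save_trace_pair", "load_trace_pair"]


@dataclass
class TracePair:
    """Recorded voltage of the two cells on a common, uniform time base.

    ``spikes_A`` / ``spikes_B`` hold spike times (s) within the recording
    window; they may be empty for non-spiking instances.
    """

    t: np.ndarray
    v_A: np.ndarray
    v_B: np.ndarray
    spikes_A: np.ndarray = field(default_factory=lambda: np.empty(0))
    spikes_B: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v_A = np.asarray(self.v_A, dtype=float)
        self.v_B = np.asarray(self.v_B, dtype=float)
        self.spikes_A = np.asarray(self.spikes_A, dtype=float)
        self.spikes_B = np.asarray(self.spikes_B, dtype=float)
        if self.t.ndim != 1 or self.v_A.shape != self.t.shape or self.v_B.shape != self.t.shape:
            raise ValueError("t, v_A, v_B must be 1-D arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time base must be strictly increasing")

    @property
    def dt(self) -> float:
        if len(self.t) < 2:
            raise ValueError("trace too short to define dt")
        return float(self.t[1] - self.t[0])

    def voltage(self, cell: str) -> np.ndarray:
        return {"A": self.v_A, "B": self.v_B}[cell]

    def spikes(self, cell: str) -> np.ndarray:
        return {"A": self.spikes_A, "B": self.spikes_B}[cell]


def save_trace_pair(path, pair: TracePair) -> None:
    """Write a trace pair; ``.h5``/``.hdf5`` selects HDF5, else TSV."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=pair.t)
            f.create_dataset("v_A", data=pair.v_A)
            f.create_dataset("v_B", data=pair.v_B)
            f.create_dataset("spikes_A", data=pair.spikes_A)
            f.create_dataset("spikes_B", data=pair.spikes_B)
    else:
        import pandas as pd

        df = pd.DataFrame({"t_s": pair.t, "v_A_mV": pair.v_A, "v_B_mV": pair.v_B})
        with open(path, "w") as fh:
            fh.write("# famscape-trace v1"
                     f" spikes_A={','.join(f'{s:.17g}' for s in pair.spikes_A)}"
                     f" spikes_B={','.join(f'{s:.17g}' for s in pair.spikes_B)}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def load_trace_pair(path) -> TracePair:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            return TracePair(
                t=f["t"][:], v_A=f["v_A"][:], v_B=f["v_B"][:],
                spikes_A=f["spikes_A"][:], spikes_B=f["spikes_B"][:],
            )
    import pandas as pd

    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# famscape-trace v1"):
            raise ValueError("not a famscape trace file")
        spikes = {"spikes_A": np.empty(0), "spikes_B": np.empty(0)}
        for tok in header.split()[3:]:
            key, _, val = tok.partition("=")
            if key in spikes and val:
                spikes[key] = np.array([float(x) for x in val.split(",")])
        df = pd.read_csv(fh, sep="\t")
    return TracePair(t=df["t_s"].to_numpy(), v_A=df["v_A_mV"].to_numpy(),
                     v_B=df["v_B_mV"].to_numpy(), **spikes)
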