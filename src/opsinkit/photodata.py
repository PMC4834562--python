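"""Containers for voltage-clamped photocurrent traces and their features.

A :class:`PhotoCurrent` holds one recorded (or simulated) trace: time in
ms, current in nA, the light-pulse windows, the stimulating flux and the
clamp voltage.  Derived features — the transient peak, the steady-state
(plateau) current and the on/off phase segmentation — are computed lazily
and are pure functions of the stored arrays, so they survive a
serialization round trip unchanged.

:class:`ProtocolData` groups the traces of one protocol on a complete
(run, flux, voltage) grid, mirroring how characterization experiments are
organized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhotoCurrent",
    "ProtocolData",
    "PlateauResult",
    "find_peak",
    "find_steady_state",
    "segment_phases",
    "align_peaks_to_first_offset",
]

#: Plateau detector configuration (not magic numbers): the plateau estimate
#: averages the final PLATEAU_WINDOW_FRACTION of the on-phase and is accepted
#: only if a straight-line fit over that window has
#: |slope| < PLATEAU_SLOPE_TOL * |mean| / 100 ms.
PLATEAU_WINDOW_FRACTION = 0.10
PLATEAU_SLOPE_TOL = 0.01
PLATEAU_MIN_SAMPLES = 50


@dataclass
class PlateauResult:
    value: float
    at_plateau: bool

    def __float__(self) -> float:
        return self.value


class PhotoCurrent:
    """One voltage-clamped photocurrent trace with pulse annotations.

    Parameters
    ----------
    I : array
        Current in nA.
    t : array or float
        Sample times in ms, strictly increasing; a scalar is taken as a
        uniform time step starting at 0.
    pulses : (n, 2) array-like
        On/off time of each light pulse, ms.
    phi : float
        Stimulating photon flux, photons mm^-2 s^-1.
    V : float or None
        Clamp voltage in mV, or ``None`` for unclamped recordings.
    states : array, optional
        Simulated state-occupancy trajectory (n_samples x n_states).
    """

    def __init__(self, I, t, pulses, phi, V, states=None, state_names=None,
                 smooth_width: int = 0):
        I = np.asarray(I, dtype=float)
        if np.isscalar(t) or np.ndim(t) == 0:
            t = np.arange(I.size) * float(t)
        t = np.asarray(t, dtype=float)
        if t.shape != I.shape or t.ndim != 1:
            raise ValueError("t and I must be 1-D arrays of equal length")
        if I.size == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        pulses = np.atleast_2d(np.asarray(pulses, dtype=float))
        if pulses.shape[1] != 2:
            raise ValueError("pulses must be an n x 2 array of (on, off) times")
        for on, off in pulses:
            if off <= on:
                raise ValueError("pulse off time must exceed on time")
            if on < t[0] - 1e-9 or off > t[-1] + 1e-9:
                raise ValueError("pulse outside the recorded interval")
        order = np.argsort(pulses[:, 0])
        pulses = pulses[order]
        for (a_on, a_off), (b_on, _) in zip(pulses, pulses[1:]):
            if b_on < a_off:
                raise ValueError("pulses overlap")
        self.t = t
        self.I = I
        self.pulses = pulses
        self.phi = float(phi)
        self.V = None if V is None else float(V)
        self.states = None if states is None else np.asarray(states, dtype=float)
        self.state_names = tuple(state_names) if state_names else None
        self.smooth_width = int(smooth_width)
        self._cache: dict = {}

    # -- basic properties ---------------------------------------------------

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_pulses(self) -> int:
        return self.pulses.shape[0]

    def _signal(self) -> np.ndarray:
        if self.smooth_width > 1:
            kernel = np.ones(self.smooth_width) / self.smooth_width
            return np.convolve(self.I, kernel, mode="same")
        return self.I

    # -- derived features (suffixed with _, data-derived) -------------------

    @property
    def peak_(self) -> float:
        """Signed current of maximal magnitude at/after the first pulse onset."""
        return self._peak()[0]

    @property
    def t_peak_(self) -> float:
        return self._peak()[1]

    @property
    def ss_(self) -> float:
        """Plateau (steady-state) current of the first pulse, nA."""
        return self._plateau().value

    @property
    def at_plateau_(self) -> bool:
        return self._plateau().at_plateau

    def _peak(self) -> tuple[float, float]:
        if "peak" not in self._cache:
            self._cache["peak"] = find_peak(self)
        return self._cache["peak"]

    def _plateau(self) -> PlateauResult:
        if "plateau" not in self._cache:
            self._cache["plateau"] = find_steady_state(self)
        return self._cache["plateau"]

    def phases_(self):
        if "phases" not in self._cache:
            self._cache["phases"] = segment_phases(self)
        return self._cache["phases"]

    def peak_in_window(self, t_lo: float, t_hi: float) -> tuple[float, float]:
        """Signed extremum of |I| within [t_lo, t_hi]; ties -> earliest."""
        mask = (self.t >= t_lo - 1e-9) & (self.t <= t_hi + 1e-9)
        if not np.any(mask):
            raise ValueError("window contains no samples")
        sig = self._signal()[mask]
        idx = int(np.argmax(np.abs(sig)))
        return float(sig[idx]), float(self.t[mask][idx])

    # -- I/O ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        data = {"t_ms": self.t, "I_nA": self.I}
        if self.states is not None:
            names = self.state_names or [f"s{i}" for i in range(self.states.shape[1])]
            for i, name in enumerate(names):
                data[name] = self.states[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def meta(self) -> dict:
        return {
            "phi": self.phi,
            "V": self.V,
            "pulses": self.pulses.tolist(),
            "state_names": list(self.state_names) if self.state_names else None,
        }

    @classmethod
    def from_csv(cls, path: str | Path, pulses, phi, V) -> "PhotoCurrent":
        df = pd.read_csv(path, float_precision="round_trip")
        state_cols = [c for c in df.columns if c not in ("t_ms", "I_nA")]
        states = df[state_cols].to_numpy() if state_cols else None
        return cls(df["I_nA"].to_numpy(), df["t_ms"].to_numpy(), pulses, phi, V,
                   states=states, state_names=state_cols or None)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def find_peak(pc: PhotoCurrent) -> tuple[float, float]:
    """Peak current: global extremum of |I| at/after the first pulse onset.

    The sign is preserved (inward currents report negative peaks) so the
    same code serves depolarizing and hyperpolarizing opsins.  Ties go to
    the earliest sample.
    """
    if pc.n_pulses == 0:
        raise ValueError("trace has no pulses")
    mask = pc.t >= pc.pulses[0, 0] - 1e-9
    sig = pc._signal()[mask]
    idx = int(np.argmax(np.abs(sig)))
    return float(sig[idx]), float(pc.t[mask][idx])


def find_steady_state(pc: PhotoCurrent, pulse: int = 0) -> PlateauResult:
    """Plateau current: mean of the final 10% of the on-phase.

    Accepted as a plateau only when a straight-line fit over that window has
    |slope| below 1% of |mean| per 100 ms; otherwise the value is returned
    flagged ``at_plateau=False`` (e.g. pulses too short to desensitize
    fully).  Requires at least 50 on-phase samples.
    """
    on_rng, _ = segment_phases(pc)[pulse]
    n_on = on_rng[1] - on_rng[0]
    if n_on < PLATEAU_MIN_SAMPLES:
        value = float(pc._signal()[on_rng[1] - 1]) if n_on else float("nan")
        return PlateauResult(value, False)
    n_win = max(int(np.ceil(PLATEAU_WINDOW_FRACTION * n_on)), 2)
    sl = slice(on_rng[1] - n_win, on_rng[1])
    t_win = pc.t[sl]
    i_win = pc._signal()[sl]
    mean = float(np.mean(i_win))
    slope = float(np.polyfit(t_win, i_win, 1)[0])  # nA per ms
    ok = abs(slope) < PLATEAU_SLOPE_TOL * abs(mean) / 100.0
    return PlateauResult(mean, ok)


def segment_phases(pc: PhotoCurrent) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Half-open sample-index ranges of each pulse's on- and off-phase.

    The off-range of pulse k runs to pulse k+1's onset or to the end of the
    trace; together the ranges partition the post-onset samples.
    """
    out = []
    n = pc.t.size
    for k, (on, off) in enumerate(pc.pulses):
        i_on = int(np.searchsorted(pc.t, on - 1e-9))
        i_off = int(np.searchsorted(pc.t, off - 1e-9))
        if k + 1 < pc.n_pulses:
            i_end = int(np.searchsorted(pc.t, pc.pulses[k + 1, 0] - 1e-9))
        else:
            i_end = n
        out.append(((i_on, i_off), (i_off, i_end)))
    return out


def align_peaks_to_first_offset(pd_obj: "ProtocolData") -> tuple[np.ndarray, np.ndarray]:
    """Second-pulse peaks of a recovery data set, timed from first-pulse offset.

    Returns ``(t_p, I_p)`` sorted by inter-pulse interval; raises if any
    trial lacks a second pulse.
    """
    t_out, i_out = [], []
    for pc in pd_obj.trials.values():
        if pc.n_pulses < 2:
            raise ValueError("recovery trial needs at least two pulses")
        first_off = pc.pulses[0, 1]
        on2, off2 = pc.pulses[1]
        end = pc.pulses[2, 0] if pc.n_pulses > 2 else pc.t[-1]
        value, t_pk = pc.peak_in_window(on2, end)
        t_out.append(t_pk - first_off)
        i_out.append(value)
    order = np.argsort(t_out)
    return np.asarray(t_out)[order], np.asarray(i_out)[order]


# ---------------------------------------------------------------------------
# Protocol data sets
# ---------------------------------------------------------------------------

class ProtocolData:
    """Photocurrents of one protocol on a (run, flux, voltage) grid."""

    def __init__(self, protocol: str, n_runs: int, phis, Vs):
        self.protocol = protocol
        self.n_runs = int(n_runs)
        self.phis = [float(p) for p in phis]
        self.Vs = [None if v is None else float(v) for v in Vs]
        self.trials: dict[tuple[int, int, int], PhotoCurrent] = {}

    def add_trial(self, pc: PhotoCurrent, run: int, iphi: int, iV: int) -> None:
        if not (0 <= run < self.n_runs and 0 <= iphi < len(self.phis)
                and 0 <= iV < len(self.Vs)):
            raise IndexError("grid position out of range")
        if abs(pc.phi - self.phis[iphi]) > 1e-6 * max(abs(self.phis[iphi]), 1.0):
            raise ValueError("trial flux does not match its grid position")
        if (pc.V is None) != (self.Vs[iV] is None) or (
            pc.V is not None and abs(pc.V - self.Vs[iV]) > 1e-9
        ):
            raise ValueError("trial voltage does not match its grid position")
        self.trials[(run, iphi, iV)] = pc

    def get(self, run: int = 0, iphi: int = 0, iV: int = 0) -> PhotoCurrent:
        return self.trials[(run, iphi, iV)]

    def __iter__(self):
        return iter(sorted(self.trials.items()))

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def complete(self) -> bool:
        expected = self.n_runs * len(self.phis) * len(self.Vs)
        return len(self.trials) == expected

    # -- I/O: directory of CSVs + JSON manifest -----------------------------

    def save(self, directory: str | Path, provenance: dict | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "protocol": self.protocol,
            "n_runs": self.n_runs,
            "phis": self.phis,
            "Vs": self.Vs,
            "trials": [],
        }
        if provenance:
            manifest["provenance"] = provenance
        for (run, iphi, iV), pc in sorted(self.trials.items()):
            fname = f"trial_r{run}_p{iphi}_v{iV}.csv"
            pc.to_csv(directory / fname)
            manifest["trials"].append(
                {"file": fname, "run": run, "iphi": iphi, "iV": iV, **pc.meta()}
            )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "ProtocolData":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        pd_obj = cls(manifest["protocol"], manifest["n_runs"],
                     manifest["phis"], manifest["Vs"])
        for entry in manifest["trials"]:
            pc = PhotoCurrent.from_csv(
                directory / entry["file"], entry["pulses"], entry["phi"], entry["V"]
            )
            pd_obj.add_trial(pc, entry["run"], entry["iphi"], entry["iV"])
        return pd_obj
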