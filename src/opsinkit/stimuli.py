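"""Light-stimulus waveforms and preconfigured voltage-clamp protocols.

A :class:`LightStimulus` is a piecewise flux waveform phi(t) >= 0 built from
non-overlapping segments (constant pulses, ramps, raised-cosine sinusoids or
chirps) on a background flux.  Pulses follow the half-open convention
``[t_on, t_off)``: the onset sample carries the pulse flux, the offset
sample the post-pulse flux.  Segment edges are exposed to the integrator so
discontinuities never fall inside a solver step.

Protocols bundle the stimulation patterns used to characterize an opsin:

* ``step`` — long pulses at several fluxes (flux dependence),
* ``rectifier`` — one flux, several clamp voltages (voltage dependence),
* ``recovery`` — pulse pairs with varying inter-pulse interval (dark recovery),
* ``shortPulse`` — brief pulses of varying duration (activation lag),

plus generic system-analysis stimuli: ``delta``, ``ramp``, ``sinusoid``,
``chirp``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Segment",
    "LightStimulus",
    "ProtocolSpec",
    "PROTOCOL_NAMES",
    "make_protocol",
    "stimulus_for_run",
    "flux_at",
    "irradiance_to_flux",
]

# Planck constant * speed of light, J*m
_HC = 6.62607015e-34 * 2.99792458e8


def irradiance_to_flux(mw_per_mm2, wavelength_nm: float = 470.0):
    """Convert irradiance (mW/mm^2) to photon flux (photons mm^-2 s^-1).

    Needs a wavelength to fix the photon energy ``E = hc/lambda``; the
    default 470 nm matches blue-light stimulation of ChR2.
    """
    e_photon = _HC / (wavelength_nm * 1e-9)
    return np.asarray(mw_per_mm2, dtype=float) * 1e-3 / e_photon


@dataclass
class Segment:
    """One illuminated interval ``[t_on, t_off)`` of a stimulus.

    ``kind`` is one of ``const``, ``ramp``, ``sin``, ``chirp``.  ``params``:

    * const: ``phi``
    * ramp: ``phi_start``, ``phi_end`` (linear in t)
    * sin: ``phi_peak``, ``freq_hz`` — raised cosine
      ``phi_peak/2 * (1 - cos(2 pi f t))``, which is >= 0 everywhere
    * chirp: ``phi_peak``, ``f0_hz``, ``f1_hz`` — raised cosine with
      linearly swept instantaneous frequency
    """

    t_on: float
    t_off: float
    kind: str = "const"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t_off > self.t_on:
            raise ValueError("segment requires t_off > t_on")
        if self.kind not in ("const", "ramp", "sin", "chirp"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    @property
    def width(self) -> float:
        return self.t_off - self.t_on

    def flux(self, t):
        """Flux inside the segment; ``t`` may be scalar or array (ms)."""
        tloc = np.asarray(t, dtype=float) - self.t_on
        p = self.params
        if self.kind == "const":
            out = np.full_like(tloc, p["phi"])
        elif self.kind == "ramp":
            frac = tloc / self.width
            out = p["phi_start"] + (p["phi_end"] - p["phi_start"]) * frac
        elif self.kind == "sin":
            out = 0.5 * p["phi_peak"] * (1.0 - np.cos(2e-3 * np.pi * p["freq_hz"] * tloc))
        else:  # chirp: phase(t) = f0*t + (f1-f0) t^2 / (2T), t in s
            ts = tloc * 1e-3
            T = self.width * 1e-3
            phase = p["f0_hz"] * ts + (p["f1_hz"] - p["f0_hz"]) * ts**2 / (2.0 * T)
            out = 0.5 * p["phi_peak"] * (1.0 - np.cos(2.0 * np.pi * phase))
        return float(out) if out.ndim == 0 else out

    @property
    def is_constant(self) -> bool:
        return self.kind == "const"


@dataclass
class LightStimulus:
    """Piecewise flux waveform with exact discontinuity points."""

    duration: float
    segments: list[Segment] = field(default_factory=list)
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.background < 0:
            raise ValueError("background flux must be >= 0")
        segs = sorted(self.segments, key=lambda s: s.t_on)
        for a, b in zip(segs, segs[1:]):
            if b.t_on < a.t_off:
                raise ValueError("segments overlap")
        for s in segs:
            if s.t_on < 0 or s.t_off > self.duration + 1e-12:
                raise ValueError("segment outside stimulus duration")
        self.segments = segs

    # -- evaluation ---------------------------------------------------------

    def flux_at(self, t):
        """Exact piecewise evaluation; half-open [on, off) convention."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < -1e-12) or np.any(t_arr > self.duration + 1e-12):
            raise ValueError("time outside stimulus duration")
        out = np.full_like(t_arr, self.background, dtype=float)
        for seg in self.segments:
            mask = (t_arr >= seg.t_on) & (t_arr < seg.t_off)
            if np.any(mask):
                out = np.where(mask, seg.flux(np.clip(t_arr, seg.t_on, seg.t_off)), out)
        return float(out) if out.ndim == 0 else out

    def edges(self) -> np.ndarray:
        """Sorted breakpoints (0, every on/off edge, duration)."""
        pts = {0.0, self.duration}
        for s in self.segments:
            pts.add(s.t_on)
            pts.add(s.t_off)
        return np.array(sorted(pts))

    def segment_at(self, t: float) -> Segment | None:
        for s in self.segments:
            if s.t_on <= t < s.t_off:
                return s
        return None

    @property
    def pulses(self) -> np.ndarray:
        """n x 2 array of (t_on, t_off) per segment."""
        if not self.segments:
            return np.zeros((0, 2))
        return np.array([[s.t_on, s.t_off] for s in self.segments])

    @property
    def peak_flux(self) -> float:
        grid = np.linspace(0.0, self.duration, 2001)
        inside = np.nextafter(grid, -np.inf)  # avoid t == duration error
        inside[0] = 0.0
        return float(np.max(self.flux_at(inside)))


def flux_at(stim: LightStimulus, t):
    """Module-level alias of :meth:`LightStimulus.flux_at`."""
    return stim.flux_at(t)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

PROTOCOL_NAMES = (
    "step", "delta", "shortPulse", "recovery", "rectifier",
    "ramp", "sinusoid", "chirp",
)

#: Default high stimulation flux (photons mm^-2 s^-1); top of the ChR2
#: characterization range.
_PHI_HIGH = 2.65e17


@dataclass
class ProtocolSpec:
    """A named stimulation protocol: run dimension x fluxes x voltages."""

    name: str
    fluxes: list[float] = field(default_factory=lambda: [_PHI_HIGH])
    voltages: list[float] = field(default_factory=lambda: [-70.0])
    #: per-run dimension: pulse durations (shortPulse), IPIs (recovery), else [None]
    run_values: list = field(default_factory=lambda: [None])
    delay: float = 25.0          # darkness before the first pulse, ms
    on_duration: float = 500.0   # pulse width for long-pulse protocols, ms
    off_duration: float = 500.0  # recorded darkness after the (last) pulse, ms
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in PROTOCOL_NAMES:
            raise ValueError(f"unknown protocol {self.name!r}")
        if not self.fluxes or not self.voltages:
            raise ValueError("protocol needs at least one flux and one voltage")
        if any(f < 0 for f in self.fluxes):
            raise ValueError("fluxes must be >= 0")
        if self.name == "recovery" and len(self.run_values) < 2:
            raise ValueError("recovery protocol needs >= 2 inter-pulse intervals")
        if self.name == "shortPulse" and any(d <= 0 for d in self.run_values):
            raise ValueError("shortPulse durations must be > 0")

    @property
    def n_runs(self) -> int:
        return len(self.run_values)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ProtocolSpec":
        return cls(**yaml.safe_load(text))


def _defaults(name: str) -> dict:
    if name == "step":
        return dict(
            fluxes=list(irradiance_to_flux([0.1, 0.5, 1, 5, 10, 50, 100])),
            voltages=[-70.0], run_values=[None],
            delay=25.0, on_duration=500.0, off_duration=500.0,
        )
    if name == "rectifier":
        return dict(
            fluxes=[_PHI_HIGH],
            voltages=[-100.0, -70.0, -40.0, -10.0, 20.0, 50.0, 80.0],
            run_values=[None], delay=25.0, on_duration=500.0, off_duration=500.0,
        )
    if name == "recovery":
        return dict(
            fluxes=[_PHI_HIGH], voltages=[-70.0],
            run_values=[500.0, 1000.0, 2500.0, 5000.0, 10000.0],
            delay=25.0, on_duration=250.0, off_duration=250.0,
        )
    if name == "shortPulse":
        return dict(
            fluxes=[_PHI_HIGH], voltages=[-70.0],
            run_values=[0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0],
            delay=5.0, on_duration=0.0, off_duration=100.0,
        )
    if name == "delta":
        return dict(fluxes=[_PHI_HIGH], voltages=[-70.0], run_values=[None],
                    delay=5.0, on_duration=0.0, off_duration=100.0,
                    extra={"dt": 0.1})
    if name == "ramp":
        return dict(fluxes=[_PHI_HIGH], voltages=[-70.0], run_values=[None],
                    delay=25.0, on_duration=500.0, off_duration=250.0,
                    extra={"phi_start": 0.0})
    if name == "sinusoid":
        return dict(fluxes=[_PHI_HIGH], voltages=[-70.0], run_values=[None],
                    delay=25.0, on_duration=1000.0, off_duration=250.0,
                    extra={"freq_hz": 5.0})
    if name == "chirp":
        return dict(fluxes=[_PHI_HIGH], voltages=[-70.0], run_values=[None],
                    delay=25.0, on_duration=2000.0, off_duration=250.0,
                    extra={"f0_hz": 0.5, "f1_hz": 50.0})
    raise ValueError(f"unknown protocol {name!r}")


def make_protocol(name: str, overrides: dict | None = None) -> ProtocolSpec:
    """Build a named protocol with its standard settings, optionally overridden.

    Standard settings: rectifier clamps V in {-100, -70, -40, -10, 20, 50,
    80} mV at one flux; recovery uses inter-pulse intervals {0.5, 1, 2.5, 5,
    10} s at -70 mV; step spans irradiances {0.1, 0.5, 1, 5, 10, 50, 100}
    mW/mm^2 (converted to photon flux at 470 nm); shortPulse uses durations
    {0.5, 1, 2, 3, 5, 8, 10} ms.
    """
    cfg = _defaults(name)
    for key, value in (overrides or {}).items():
        if key in ("fluxes", "voltages", "run_values"):
            # YAML round-trips like "2.65e17" arrive as strings; coerce.
            cfg[key] = [v if v is None else float(v) for v in value]
        elif key in ("delay", "on_duration", "off_duration"):
            cfg[key] = float(value)
        elif key == "extra":
            cfg.setdefault("extra", {}).update(value)
        else:
            cfg.setdefault("extra", {})[key] = value
    return ProtocolSpec(name=name, **cfg)


def stimulus_for_run(spec: ProtocolSpec, run: int, flux: float | None = None,
                     dt: float = 0.1) -> LightStimulus:
    """Deterministic waveform for one run of a protocol.

    ``flux`` defaults to the protocol's first flux; step/rectifier vary flux
    via :func:`engine.run_protocol` instead.  ``dt`` sets the width of the
    one-step ``delta`` pulse.
    """
    if not 0 <= run < spec.n_runs:
        raise IndexError(f"run index {run} out of range for {spec.n_runs} runs")
    phi = spec.fluxes[0] if flux is None else flux
    d = spec.delay
    name = spec.name
    if name in ("step", "rectifier"):
        segs = [Segment(d, d + spec.on_duration, "const", {"phi": phi})]
        total = d + spec.on_duration + spec.off_duration
    elif name == "recovery":
        ipi = float(spec.run_values[run])
        w = spec.on_duration
        segs = [
            Segment(d, d + w, "const", {"phi": phi}),
            Segment(d + w + ipi, d + 2 * w + ipi, "const", {"phi": phi}),
        ]
        total = d + 2 * w + ipi + spec.off_duration
    elif name == "shortPulse":
        w = float(spec.run_values[run])
        segs = [Segment(d, d + w, "const", {"phi": phi})]
        total = d + w + spec.off_duration
    elif name == "delta":
        w = float(spec.extra.get("dt", dt))
        segs = [Segment(d, d + w, "const", {"phi": phi})]
        total = d + w + spec.off_duration
    elif name == "ramp":
        segs = [Segment(d, d + spec.on_duration, "ramp",
                        {"phi_start": spec.extra.get("phi_start", 0.0),
                         "phi_end": phi})]
        total = d + spec.on_duration + spec.off_duration
    elif name == "sinusoid":
        segs = [Segment(d, d + spec.on_duration, "sin",
                        {"phi_peak": phi, "freq_hz": spec.extra.get("freq_hz", 5.0)})]
        total = d + spec.on_duration + spec.off_duration
    elif name == "chirp":
        segs = [Segment(d, d + spec.on_duration, "chirp",
                        {"phi_peak": phi,
                         "f0_hz": spec.extra.get("f0_hz", 0.5),
                         "f1_hz": spec.extra.get("f1_hz", 50.0)})]
        total = d + spec.on_duration + spec.off_duration
    else:  # pragma: no cover
        raise ValueError(f"unknown protocol {name!r}")
    return LightStimulus(duration=total, segments=segs)
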