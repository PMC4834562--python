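"""Markov photocycle models of light-gated ion channels.

Three functional models of the opsin photocycle are implemented, named by
their number of states:

* **3-state** — closed / open / desensitized (C, O, D); single-exponential
  off-phase decay, admits a closed-form solution under constant light.
* **4-state** — two closed and two open states (C1, O1, O2, C2) capturing
  biexponential deactivation and light adaptation.
* **6-state** — adds intermediate (pre-open) states I1, I2 between closed
  and open, producing the short-pulse peak lag seen experimentally.

All models share the conductance factorization

    I = g0 * f_phi(phi, t) * f_v(v) * (v - E)

where ``f_phi`` is the photocycle factor (open-state occupancy, weighted by
the open-state conductance ratio ``gamma`` when there are two open states)
and ``f_v`` is an empirical inward-rectification factor.

Units are fixed module-wide: time in ms, rates in ms^-1, voltage in mV,
conductance in pS, current in nA, photon flux in photons*mm^-2*s^-1.  The
pS*mV -> nA conversion factor 1e-6 lives only in :func:`current`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "OpsinParams",
    "StateOccupancy",
    "RateSet",
    "hill_rate",
    "transition_rates",
    "rate_matrix",
    "ode_rhs",
    "steady_state",
    "analytic_three_state",
    "f_phi",
    "f_v",
    "v1_from_constraint",
    "current",
]

#: Fixed state orderings; part of the public contract (exporters rely on it).
STATE_NAMES = {
    3: ("C", "O", "D"),
    4: ("C1", "O1", "O2", "C2"),
    6: ("C1", "I1", "O1", "O2", "I2", "C2"),
}

# Parameter fields by model order.
_COMMON_FIELDS = ("g0", "phi_m", "p", "q", "Gr0", "E", "v0", "v1")
_FIELDS_3 = _COMMON_FIELDS + ("ka", "kr", "Gd")
_FIELDS_4 = _COMMON_FIELDS + (
    "gamma", "k1", "k2", "kf", "kb", "Gf0", "Gb0", "Gd1", "Gd2",
)
_FIELDS_6 = _FIELDS_4 + ("Go1", "Go2")
PARAM_FIELDS = {3: _FIELDS_3, 4: _FIELDS_4, 6: _FIELDS_6}

#: Fields that must be strictly positive.
_POSITIVE = {
    "g0", "phi_m", "p", "q", "Gr0", "ka", "kr", "Gd",
    "k1", "k2", "kf", "kb", "Gf0", "Gb0", "Gd1", "Gd2", "Go1", "Go2",
}


class ModelConfigError(ValueError):
    """Raised when parameters are inconsistent with the requested model."""


def v1_from_constraint(E: float, v0: float) -> float:
    """Rectification amplitude ``v1`` that normalizes ``f_v(-70 mV) = 1``.

    Closed form: ``v1 = (70 + E) / (exp((70 + E)/v0) - 1)``.  Undefined at
    ``E = -70`` (the normalization point coincides with the reversal
    potential).
    """
    if v0 == 0:
        raise ValueError("v0 must be nonzero")
    u = (70.0 + E) / v0
    if u == 0:
        raise ValueError("v1 constraint undefined for E = -70 mV")
    return (70.0 + E) / math.expm1(u)


@dataclass
class OpsinParams:
    """Parameter record for one photocycle model order (3, 4 or 6).

    Pass ``v1=None`` to tie ``v1`` to the constraint that makes
    ``f_v(-70 mV) = 1`` (the default convention throughout the package);
    supply an explicit value to release it.
    """

    model_order: int
    g0: float = 2.5e4          # conductance scale, pS (defined at v=-70 mV)
    phi_m: float = 3.5e17      # half-saturation flux, photons mm^-2 s^-1
    p: float = 1.0             # activation Hill exponent
    q: float = 1.0             # O1<->O2 (or 3-state recovery) Hill exponent
    Gr0: float = 3.3e-4        # dark recovery rate, ms^-1
    E: float = 0.0             # reversal potential, mV
    v0: float = 43.0           # rectification shape, mV
    v1: float | None = None    # rectification amplitude, mV (None -> Eq. constraint)
    # 3-state only
    ka: float | None = None    # max light-activation coefficient, ms^-1
    kr: float | None = None    # max light-driven recovery coefficient, ms^-1
    Gd: float | None = None    # deactivation rate, ms^-1
    # 4/6-state
    gamma: float | None = None  # open-state conductance ratio g_O2/g_O1
    k1: float | None = None
    k2: float | None = None
    kf: float | None = None
    kb: float | None = None
    Gf0: float | None = None
    Gb0: float | None = None
    Gd1: float | None = None
    Gd2: float | None = None
    # 6-state only
    Go1: float | None = None
    Go2: float | None = None
    v1_constrained: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.model_order not in (3, 4, 6):
            raise ModelConfigError(f"model_order must be 3, 4 or 6, got {self.model_order}")
        if self.v1 is None:
            self.v1 = v1_from_constraint(self.E, self.v0)
            self.v1_constrained = True
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        fields = PARAM_FIELDS[self.model_order]
        for name in fields:
            value = getattr(self, name)
            if value is None:
                raise ModelConfigError(
                    f"{self.model_order}-state model requires parameter {name!r}"
                )
            if name in _POSITIVE and not value > 0:
                raise ModelConfigError(f"parameter {name!r} must be > 0, got {value}")
        for name in PARAM_FIELDS[6]:
            if name not in fields and getattr(self, name) is not None:
                raise ModelConfigError(
                    f"parameter {name!r} is not part of the {self.model_order}-state model"
                )
        if self.v0 == 0:
            raise ModelConfigError("v0 must be nonzero")
        if self.model_order != 3 and not 0.0 <= self.gamma <= 1.0:
            raise ModelConfigError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.v1_constrained:
            ref = v1_from_constraint(self.E, self.v0)
            if abs(self.v1 - ref) > 1e-9 * max(abs(ref), 1.0):
                raise ModelConfigError(
                    f"v1={self.v1} violates the f_v(-70)=1 constraint (expected {ref})"
                )

    # -- convenience --------------------------------------------------------

    @property
    def n_states(self) -> int:
        return self.model_order

    @property
    def state_names(self) -> tuple[str, ...]:
        return STATE_NAMES[self.model_order]

    def ground_state(self) -> "StateOccupancy":
        """Fully dark-adapted state: all occupancy in C (or C1)."""
        values = np.zeros(self.model_order)
        values[0] = 1.0
        return StateOccupancy(self.model_order, values)

    def replace(self, **changes) -> "OpsinParams":
        """Return a copy with fields changed.

        If ``E`` or ``v0`` change on a constrained record, ``v1`` is
        re-derived unless explicitly supplied.
        """
        if self.v1_constrained and "v1" not in changes and (
            "E" in changes or "v0" in changes
        ):
            changes["v1"] = None
        return dataclasses.replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {"model_order": self.model_order}
        for name in PARAM_FIELDS[self.model_order]:
            out[name] = getattr(self, name)
        out["v1_constrained"] = self.v1_constrained
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "OpsinParams":
        data = dict(data)
        order = int(data.pop("model_order"))
        constrained = bool(data.pop("v1_constrained", False))
        known = {k: v for k, v in data.items() if k in PARAM_FIELDS[6]}
        unknown = set(data) - set(known)
        if unknown:
            raise ModelConfigError(f"unknown parameter fields: {sorted(unknown)}")
        if constrained:
            known.pop("v1", None)
        return cls(model_order=order, **known)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_file(cls, path: str | Path) -> "OpsinParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class StateOccupancy:
    """Probability vector over photocycle states (fixed ordering).

    Orderings: 3-state ``(C, O, D)``; 4-state ``(C1, O1, O2, C2)``;
    6-state ``(C1, I1, O1, O2, I2, C2)``.  Values lie in [0, 1] and sum
    to 1 (total occupancy conservation).
    """

    model_order: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        names = STATE_NAMES.get(self.model_order)
        if names is None:
            raise ModelConfigError(f"bad model order {self.model_order}")
        if self.values.shape != (self.model_order,):
            raise ModelConfigError(
                f"expected {self.model_order} occupancies, got shape {self.values.shape}"
            )
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError(f"occupancies outside [0, 1]: {self.values}")
        if abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancies sum to {self.values.sum()}, not 1")

    def __getitem__(self, name: str) -> float:
        return float(self.values[STATE_NAMES[self.model_order].index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STATE_NAMES[self.model_order], map(float, self.values)))


@dataclass
class RateSet:
    """Instantaneous transition rates (ms^-1) evaluated at one flux.

    3-state: Ga, Gd, Gr.  4-state: Ga1, Ga2, Gf, Gb, Gd1, Gd2, Gr0.
    6-state additionally Go1, Go2.
    """

    model_order: int
    Ga: float | None = None
    Gd: float | None = None
    Gr: float | None = None
    Ga1: float | None = None
    Ga2: float | None = None
    Gf: float | None = None
    Gb: float | None = None
    Gd1: float | None = None
    Gd2: float | None = None
    Gr0: float | None = None
    Go1: float | None = None
    Go2: float | None = None

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if name != "model_order" and value is not None and value < 0:
                raise ValueError(f"rate {name} must be >= 0, got {value}")


def hill_rate(phi: float, k: float, phi_m: float, exponent: float,
              baseline: float = 0.0):
    """Light-dependent transition rate: ``k * phi^e / (phi^e + phi_m^e) + baseline``.

    Saturating (Hill) dependence on photon flux ``phi``; monotone
    non-decreasing in ``phi`` and bounded by ``k + baseline``.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise ValueError("flux must be non-negative")
    if not (k > 0 and phi_m > 0 and exponent > 0):
        raise ValueError("k, phi_m and exponent must be > 0")
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    # (phi_m/phi)^e form avoids overflow for large flux * exponent.
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(phi > 0, (phi_m / np.maximum(phi, 1e-300)) ** exponent, np.inf)
    value = k / (1.0 + ratio) + baseline
    return float(value) if value.ndim == 0 else value


def transition_rates(params: OpsinParams, phi: float) -> RateSet:
    """Evaluate every transition rate of ``params``' model at flux ``phi``."""
    if phi < 0:
        raise ValueError("flux must be non-negative")
    n = params.model_order
    if n == 3:
        return RateSet(
            3,
            Ga=hill_rate(phi, params.ka, params.phi_m, params.p),
            Gd=params.Gd,
            Gr=hill_rate(phi, params.kr, params.phi_m, params.q, params.Gr0),
        )
    rates = RateSet(
        n,
        Ga1=hill_rate(phi, params.k1, params.phi_m, params.p),
        Ga2=hill_rate(phi, params.k2, params.phi_m, params.p),
        Gf=hill_rate(phi, params.kf, params.phi_m, params.q, params.Gf0),
        Gb=hill_rate(phi, params.kb, params.phi_m, params.q, params.Gb0),
        Gd1=params.Gd1,
        Gd2=params.Gd2,
        Gr0=params.Gr0,
    )
    if n == 6:
        rates.Go1 = params.Go1
        rates.Go2 = params.Go2
    return rates


def rate_matrix(rates: RateSet) -> np.ndarray:
    """Generator matrix Q with ``d(state)/dt = Q @ state``.

    Columns sum to zero (conservation of total occupancy).
    """
    n = rates.model_order
    if n == 3:
        Ga, Gd, Gr = rates.Ga, rates.Gd, rates.Gr
        return np.array([
            [-Ga, 0.0, Gr],
            [Ga, -Gd, 0.0],
            [0.0, Gd, -Gr],
        ])
    Ga1, Ga2, Gf, Gb = rates.Ga1, rates.Ga2, rates.Gf, rates.Gb
    Gd1, Gd2, Gr0 = rates.Gd1, rates.Gd2, rates.Gr0
    if n == 4:
        # (C1, O1, O2, C2)
        return np.array([
            [-Ga1, Gd1, 0.0, Gr0],
            [Ga1, -(Gd1 + Gf), Gb, 0.0],
            [0.0, Gf, -(Gd2 + Gb), Ga2],
            [0.0, 0.0, Gd2, -(Gr0 + Ga2)],
        ])
    Go1, Go2 = rates.Go1, rates.Go2
    # (C1, I1, O1, O2, I2, C2)
    return np.array([
        [-Ga1, 0.0, Gd1, 0.0, 0.0, Gr0],
        [Ga1, -Go1, 0.0, 0.0, 0.0, 0.0],
        [0.0, Go1, -(Gd1 + Gf), Gb, 0.0, 0.0],
        [0.0, 0.0, Gf, -(Gd2 + Gb), Go2, 0.0],
        [0.0, 0.0, 0.0, 0.0, -Go2, Ga2],
        [0.0, 0.0, 0.0, Gd2, 0.0, -(Gr0 + Ga2)],
    ])


def ode_rhs(state: StateOccupancy, rates: RateSet) -> np.ndarray:
    """Time derivatives of the occupancies (the Markov master equation)."""
    if state.model_order != rates.model_order:
        raise ModelConfigError("state and rates belong to different model orders")
    return rate_matrix(rates) @ state.values


class SingularSteadyStateError(RuntimeError):
    """The rate matrix has a non-unique steady state (reducible chain)."""


def steady_state(params: OpsinParams, phi: float) -> StateOccupancy:
    """Unique stationary occupancy of the photocycle at constant flux.

    Computed as the one-dimensional null space of the generator matrix,
    normalized to sum 1.  Raises :class:`SingularSteadyStateError` when the
    chain is reducible (e.g. ``phi = 0`` with no dark recovery), in which
    case the stationary distribution is not unique.
    """
    from scipy.linalg import null_space

    Q = rate_matrix(transition_rates(params, phi))
    ns = null_space(Q, rcond=1e-10)
    if ns.shape[1] != 1:
        raise SingularSteadyStateError(
            f"steady state not unique (null space dimension {ns.shape[1]})"
        )
    v = ns[:, 0]
    v = v / v.sum()
    v = np.clip(v, 0.0, 1.0)
    v = v / v.sum()
    return StateOccupancy(params.model_order, v)


def f_phi(state: StateOccupancy, gamma: float = 0.0) -> float:
    """Photocycle conductance factor: O (3-state) or O1 + gamma*O2."""
    if state.model_order == 3:
        return state["O"]
    return state["O1"] + gamma * state["O2"]


# Switch to the series branch when |v - E| < _FV_SERIES_FRAC * |v0|; keeps
# the removable singularity at v = E free of catastrophic cancellation.
_FV_SERIES_FRAC = 1e-3


def f_v(v, E: float, v0: float, v1: float):
    """Empirical voltage-rectification factor.

    ``f_v = (v1/(v-E)) * (1 - exp(-(v-E)/v0))``, with the removable
    singularity at ``v = E`` evaluated by series expansion (limit
    ``v1/v0``).  When ``v1`` comes from the f_v(-70)=1 constraint this
    factor equals 1 at -70 mV by construction.
    """
    if v0 == 0:
        raise ValueError("v0 must be nonzero")
    v = np.asarray(v, dtype=float)
    u = (v - E) / v0
    near = np.abs(v - E) < _FV_SERIES_FRAC * abs(v0)
    # (1 - exp(-u))/u = 1 - u/2 + u^2/6 + O(u^3)
    series = 1.0 - u / 2.0 + u * u / 6.0
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = -np.expm1(-u) / np.where(near, 1.0, u)
    value = (v1 / v0) * np.where(near, series, exact)
    return float(value) if value.ndim == 0 else value


#: pS * mV -> nA
_PS_MV_TO_NA = 1e-6


def current(params: OpsinParams, state: StateOccupancy, v: float):
    """Photocurrent ``I = g0 * f_phi * f_v * (v - E)`` in nA.

    Negative (inward) for ``v < E`` whenever the channel is open.
    """
    gamma = 0.0 if params.model_order == 3 else params.gamma
    return (
        params.g0
        * f_phi(state, gamma)
        * f_v(v, params.E, params.v0, params.v1)
        * (v - params.E)
        * _PS_MV_TO_NA
    )


def current_from_fphi(params: OpsinParams, fphi, v: float):
    """Vectorized photocurrent from precomputed photocycle-factor values."""
    return (
        params.g0
        * np.asarray(fphi, dtype=float)
        * f_v(v, params.E, params.v0, params.v1)
        * (v - params.E)
        * _PS_MV_TO_NA
    )


@dataclass
class AnalyticResult:
    """Trajectory from the closed-form 3-state solution."""

    times: np.ndarray
    states: np.ndarray          # shape (len(times), 3), columns (C, O, D)
    degenerate: bool = False    # True if the eigenvalue-degenerate fallback ran

    def occupancy(self, i: int) -> StateOccupancy:
        return StateOccupancy(3, self.states[i])


def analytic_three_state(
    params: OpsinParams,
    phi: float,
    state0: StateOccupancy,
    times: Sequence[float],
) -> AnalyticResult:
    """Closed-form 3-state trajectory under constant flux.

    Using conservation ``C + O + D = 1`` the system reduces to two linear
    ODEs in (C, O):

        C' = -(Ga + Gr) C - Gr O + Gr
        O' =  Ga C - Gd O

    whose solution is the affine fixed point plus two exponential modes with
    rates given by the eigenvalues of the 2x2 matrix.  Repeated eigenvalues
    (measure-zero parameter sets) fall back to numerical integration and are
    flagged on the result.
    """
    if params.model_order != 3:
        raise ModelConfigError("analytic solution exists for the 3-state model only")
    if state0.model_order != 3:
        raise ModelConfigError("state0 must be a 3-state occupancy")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0):
        raise ValueError("times must be an ordered 1-D array")

    r = transition_rates(params, phi)
    A = np.array([
        [-(r.Ga + r.Gr), -r.Gr],
        [r.Ga, -r.Gd],
    ])
    b = np.array([r.Gr, 0.0])
    x0 = state0.values[:2]

    lam, V = np.linalg.eig(A)
    scale = max(np.max(np.abs(lam)), 1e-30)
    if abs(lam[0] - lam[1]) < 1e-9 * scale or np.iscomplexobj(lam) and np.any(
        np.abs(lam.imag) > 1e-12 * scale
    ):
        # Defective/complex pair: integrate numerically instead.
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, x: A @ x + b, (times[0], times[-1]) if len(times) > 1 else
            (times[0], times[0] + 1e-9), x0,
            t_eval=times, rtol=1e-10, atol=1e-12, method="LSODA",
        )
        co = sol.y.T
        states = np.column_stack([co, 1.0 - co.sum(axis=1)])
        return AnalyticResult(times, states, degenerate=True)

    lam = lam.real
    V = V.real
    # Affine fixed point A x_ss + b = 0 (A invertible when eigenvalues distinct
    # and nonzero; a zero eigenvalue means a line of fixed points -> solve via lstsq).
    if np.min(np.abs(lam)) < 1e-14 * scale:
        x_ss, *_ = np.linalg.lstsq(A, -b, rcond=None)
    else:
        x_ss = np.linalg.solve(A, -b)
    c = np.linalg.solve(V, x0 - x_ss)
    # x(t) = x_ss + V @ (c * exp(lam * (t - t0)))
    dt = times - times[0]
    modes = c[:, None] * np.exp(np.outer(lam, dt))
    co = (x_ss[:, None] + V @ modes).T
    states = np.column_stack([co, 1.0 - co.sum(axis=1)])
    return AnalyticResult(times, states, degenerate=False)
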