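"""Synthetic photocurrent generation for fitting verification.

The module's reason to exist is the round trip: generate noiseless
photocurrents from a known parameter set with the forward models, run the
staged fitting pipeline on them, and compare the recovered parameters with
the generating ones.  Optional additive Gaussian noise supports robustness
testing (real recordings additionally contain drift, capacitive transients
and filtering, which are not emulated).

Ships the wild-type ChR2 parameter fixtures: the 6-state set is the
experimentally derived one; the 3- and 4-state sets are package defaults
for a ChR2-like channel (synthetic, not experimentally anchored — see
docstrings).
"""

from __future__ import annotations

import numpy as np

from .engine import run_protocol
from .kinetics import OpsinParams
from .photodata import PhotoCurrent, ProtocolData
from .stimuli import ProtocolSpec, make_protocol

__all__ = [
    "chr2_fixture",
    "chr2_initial_guess",
    "verification_fluxes",
    "generate",
    "verification_dataset",
]

#: Span of the six-trace ChR2 flux-dependence characterization set,
#: photons mm^-2 s^-1 (two orders of magnitude).
PHI_LO = 2.21e15
PHI_HI = 2.65e17


def verification_fluxes(n: int = 6) -> np.ndarray:
    """Log-spaced fluxes spanning the ChR2 characterization range."""
    return np.geomspace(PHI_LO, PHI_HI, n)


# Wild-type ChR2, 6-state model, experimentally derived values.
_CHR2_6 = dict(
    g0=2.76e4,
    gamma=8.33e-16,
    phi_m=5.07e17,
    k1=18.5,
    k2=3.75,
    p=0.982,
    Gf0=0.0365,
    kf=0.121,
    Gb0=0.0146,
    kb=0.133,
    q=1.45,
    Go1=1.93,
    Go2=2.65,
    Gd1=0.108,
    Gd2=0.0111,
    Gr0=0.00033,
    E=0.0,
    v0=43.0,
    v1=17.1,
)

# Standard initial guesses used when fitting the 6-state model to ChR2-like
# data (round-number starting points, deliberately off the true values).
_CHR2_6_INIT = dict(
    g0=2.5e4,
    gamma=0.05,
    phi_m=3.5e17,
    k1=10.0,
    k2=3.0,
    p=1.0,
    Gf0=0.04,
    kf=0.1,
    Gb0=0.02,
    kb=0.15,
    q=1.0,
    Go1=2.0,
    Go2=2.0,
    Gd1=0.1,
    Gd2=0.01,
    Gr0=0.00033,
    E=0.0,
    v0=43.0,
    v1=17.1,
)


def chr2_fixture(model_order: int) -> OpsinParams:
    """ChR2 parameter set for the requested model order.

    The 6-state record is the experimentally derived wild-type ChR2 set.
    The 4-state record reuses its kinetic fields (the 4-state model is the
    fast-activation limit of the 6-state one), and the 3-state record is a
    synthetic package default for a ChR2-like channel; neither of the
    reduced records is experimentally anchored.
    """
    if model_order == 6:
        return OpsinParams(model_order=6, **{k: v for k, v in _CHR2_6.items()
                                             if k != "v1"})
    if model_order == 4:
        fields = {k: v for k, v in _CHR2_6.items()
                  if k not in ("Go1", "Go2", "v1")}
        return OpsinParams(model_order=4, **fields)
    if model_order == 3:
        # Synthetic ChR2-like 3-state defaults: single open state, Gd chosen
        # near the amplitude-weighted mean of the 6-state dark decay rates.
        return OpsinParams(
            model_order=3,
            g0=2.2e4, phi_m=1.32e16, ka=5.0, kr=0.28, p=0.793, q=0.793,
            Gd=0.09, Gr0=3.3e-4, E=0.0, v0=43.0,
        )
    raise ValueError(f"model_order must be 3, 4 or 6, got {model_order}")


def chr2_initial_guess(model_order: int) -> OpsinParams:
    """Round-number starting parameters for fitting ChR2-like data."""
    if model_order == 6:
        return OpsinParams(model_order=6, **{k: v for k, v in _CHR2_6_INIT.items()
                                             if k != "v1"})
    if model_order == 4:
        fields = {k: v for k, v in _CHR2_6_INIT.items()
                  if k not in ("Go1", "Go2", "v1")}
        return OpsinParams(model_order=4, **fields)
    if model_order == 3:
        return OpsinParams(
            model_order=3,
            g0=2.0e4, phi_m=1e16, ka=3.0, kr=0.2, p=1.0, q=1.0,
            Gd=0.1, Gr0=3.3e-4, E=0.0, v0=43.0,
        )
    raise ValueError(f"model_order must be 3, 4 or 6, got {model_order}")


def generate(
    params: OpsinParams,
    spec: ProtocolSpec,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float | None = None,
) -> ProtocolData:
    """Forward-simulate a protocol, optionally adding Gaussian current noise.

    ``noise_sd`` is the standard deviation in nA of i.i.d. additive noise on
    the current only (state trajectories stay noiseless).  A seed is
    required whenever ``noise_sd > 0`` so generated data are reproducible;
    with ``noise_sd = 0`` the output is bit-identical to the engine's.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    data = run_protocol(params, spec, dt=dt)
    if noise_sd == 0.0:
        return data
    rng = np.random.default_rng(seed)
    noisy = ProtocolData(data.protocol, data.n_runs, data.phis, data.Vs)
    for key, pc in sorted(data.trials.items()):
        I = pc.I + rng.normal(0.0, noise_sd, size=pc.I.shape)
        noisy.add_trial(
            PhotoCurrent(I, pc.t, pc.pulses, pc.phi, pc.V,
                         states=pc.states, state_names=pc.state_names),
            *key,
        )
    return noisy


def verification_dataset(
    params: OpsinParams | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_fluxes: int = 6,
    n_short: int = 4,
) -> dict[str, ProtocolData]:
    """The four-protocol synthetic characterization data set.

    Protocols: ``step`` at ``n_fluxes`` log-spaced fluxes spanning the ChR2
    range, ``rectifier`` (7 voltages), ``recovery`` (5 IPIs) and
    ``shortPulse`` (``n_short`` durations <= 3 ms plus longer controls).
    Defaults to noiseless data from the 6-state ChR2 fixture.
    """
    if params is None:
        params = chr2_fixture(6)
    fluxes = list(verification_fluxes(n_fluxes))
    step = make_protocol("step", {"fluxes": fluxes})
    rectifier = make_protocol("rectifier", {"fluxes": [PHI_HI]})
    recovery = make_protocol("recovery", {"fluxes": [PHI_HI]})
    durations = [0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0][: max(n_short, 2)]
    short = make_protocol("shortPulse", {"fluxes": [PHI_HI],
                                         "run_values": durations})
    dataset = {}
    for name, spec in [("step", step), ("rectifier", rectifier),
                       ("recovery", recovery), ("shortPulse", short)]:
        dataset[name] = generate(params, spec, noise_sd=noise_sd, seed=seed)
    return dataset
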