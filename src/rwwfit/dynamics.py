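"""Two-population reduced Wong-Wang neural mass dynamics on a connectome.

Each region i carries excitatory and inhibitory synaptic gating variables
(E_i, I_i) obeying

    dE_i/dt = -E_i/tau_E + (1 - E_i) * gamma * R_i^E + sigma * xi_i^E
    dI_i/dt = -I_i/tau_I + R_i^I + sigma * xi_i^I

with population firing rates given by the sigmoidal current-to-rate transfer
R = (a*I - b) / (1 - exp(-d*(a*I - b))) and input currents squashed through a
tanh to keep them in a biologically plausible range:

    I_i^E = tanh(W_E*I0 + g_EE*E_i + g*sum_j L_ij E_j - g_IE*I_i) + I_ext
    I_i^I = tanh(W_I*I0 + g_EI*E_i + lambda*g*sum_j L_ij E_j)

where L = D - C is the coupling Laplacian of the normalized structural
connectome (a config flag can substitute the plain adjacency C for L).
Integration is Euler-Maruyama; after each stochastic step E is clamped to
[0, 1] and I to [0, inf), with clamp events counted.

All state operations broadcast over a leading batch axis, so a whole cohort
(or a set of fitting seeds) can be simulated in one vectorized loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .connectome import CouplingLaplacian, laplacian_from_adjacency
from .constants import BiophysicalConstants
from .params import GainParameters

__all__ = [
    "firing_rate",
    "firing_rate_derivative",
    "input_currents",
    "drift",
    "integrate",
    "NeuralState",
    "NeuralTrajectory",
]

CouplingMode = Literal["laplacian", "adjacency"]

_EXP_CLIP = 500.0  # exponent clip; transfer argument d*(a*I-b) stays far below this
_SMALL = 1e-7


def firing_rate(current, a: float, b: float, d: float):
    """Sigmoidal current-to-rate transfer phi(u) = u / (1 - exp(-d*u)), u = a*current - b.

    The removable singularity at u = 0 is evaluated by its series limit 1/d.
    Overflow-safe for arbitrarily large |u|; strictly positive for finite input.
    """
    if a <= 0 or d <= 0:
        raise ValueError("transfer parameters a and d must be > 0")
    u = a * np.asarray(current, dtype=float) - b
    x = np.clip(d * u, -_EXP_CLIP, _EXP_CLIP)
    den = -np.expm1(-x)  # 1 - exp(-d*u)
    small = np.abs(x) < _SMALL
    safe_den = np.where(small, 1.0, den)
    # series around u=0: phi = 1/d + u/2 + d u^2/12 + ...
    out = np.where(small, 1.0 / d + u / 2.0, u / safe_den)
    return out if out.ndim else float(out)


def firing_rate_derivative(current, a: float, b: float, d: float):
    """d(firing_rate)/d(current) — exact derivative of the transfer function.

    With u = a*current - b and s = 1 - exp(-d*u):
    dphi/du = 1/s - u*d*exp(-d*u)/s^2, limiting to 1/2 + d*u/6 near u = 0;
    the returned value includes the chain factor a.
    """
    u = a * np.asarray(current, dtype=float) - b
    x = np.clip(d * u, -_EXP_CLIP, _EXP_CLIP)
    ex = np.exp(-x)
    s = -np.expm1(-x)
    small = np.abs(x) < _SMALL
    safe_s = np.where(small, 1.0, s)
    dphi = np.where(small, 0.5 + d * u / 6.0, 1.0 / safe_s - u * d * ex / safe_s**2)
    out = a * dphi
    return out if out.ndim else float(out)


def _coupling_matrix(
    gains: GainParameters,
    lap: CouplingLaplacian | np.ndarray | None,
    coupling_mode: CouplingMode,
) -> np.ndarray:
    """Resolve the N x N coupling operator (CM rebuilds it from sc_mod)."""
    if gains.variant == "cm":
        C = gains.sc_mod
        return laplacian_from_adjacency(C) if coupling_mode == "laplacian" else C
    if lap is None:
        raise ValueError("GM/LM require an explicit coupling Laplacian")
    if isinstance(lap, CouplingLaplacian):
        return lap.matrix
    return np.asarray(lap, dtype=float)


def _as_state(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim == 0:
        raise ValueError("state must be at least a length-N vector")
    return a


def network_input(E: np.ndarray, M: np.ndarray) -> np.ndarray:
    """sum_j M_ij E_j with broadcasting over leading batch axes of E and M."""
    if M.ndim == 2:
        return E @ M.T
    return np.einsum("...ij,...j->...i", M, E)


def input_currents(
    E,
    I,
    gains: GainParameters,
    consts: BiophysicalConstants,
    lap: CouplingLaplacian | np.ndarray | None = None,
    coupling_mode: CouplingMode = "laplacian",
) -> tuple[np.ndarray, np.ndarray]:
    """tanh-squashed excitatory and inhibitory input currents (I^E, I^I).

    Both squashed components lie strictly inside (-1, 1); I_ext is added to
    the excitatory current after squashing.
    """
    E, I = _as_state(E), _as_state(I)
    for name, v in (("E", E), ("I", I)):
        if not np.all(np.isfinite(v)):
            idx = np.argwhere(~np.isfinite(v))[0]
            raise FloatingPointError(f"non-finite {name} state at node index {tuple(idx)}")
    M = _coupling_matrix(gains, lap, coupling_mode)
    cE = network_input(E, M)
    x_e = consts.w_e * consts.i0 + gains.g_ee * E + gains.g * cE - gains.g_ie * I
    x_i = consts.w_i * consts.i0 + gains.g_ei * E + consts.lambda_ffi * gains.g * cE
    return np.tanh(x_e) + consts.i_ext, np.tanh(x_i)


def drift(
    E,
    I,
    gains: GainParameters,
    consts: BiophysicalConstants,
    lap: CouplingLaplacian | np.ndarray | None = None,
    coupling_mode: CouplingMode = "laplacian",
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic part (dE, dI) of the state equations."""
    ie, ii = input_currents(E, I, gains, consts, lap, coupling_mode)
    r_e = firing_rate(ie, consts.a_e, consts.b_e, consts.d_e)
    r_i = firing_rate(ii, consts.a_i, consts.b_i, consts.d_i)
    E, I = np.asarray(E, float), np.asarray(I, float)
    dE = -E / consts.tau_e + (1.0 - E) * consts.gamma * r_e
    dI = -I / consts.tau_i + r_i
    return dE, dI


@dataclass
class NeuralState:
    """Excitatory/inhibitory gating vectors at one instant (batchable)."""

    E: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        self.E = _as_state(self.E)
        self.I = _as_state(self.I)
        if self.E.shape != self.I.shape:
            raise ValueError("E and I must share a shape")


@dataclass
class NeuralTrajectory:
    """Time-ordered gating states at integration resolution.

    ``E`` and ``I`` have shape (n_steps+1, ..., N) including the initial
    state; ``clamp_events`` counts post-step projections of E to [0,1] and I
    to [0, inf).
    """

    dt: float
    E: np.ndarray
    I: np.ndarray
    seed: int | None = None
    clamp_events: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.E.shape[0] - 1

    def final_state(self) -> NeuralState:
        return NeuralState(self.E[-1].copy(), self.I[-1].copy())


def integrate(
    initial: NeuralState,
    gains: GainParameters,
    consts: BiophysicalConstants,
    lap: CouplingLaplacian | np.ndarray | None,
    dt: float,
    n_steps: int,
    seed: int | np.random.Generator | None = None,
    coupling_mode: CouplingMode = "laplacian",
    record: bool = True,
) -> NeuralTrajectory:
    """Euler-Maruyama integration of the stochastic state equations.

    Per step: state += drift*dt + sigma*sqrt(dt)*xi with fresh standard-normal
    xi per node and population, reproducible from ``seed``; E is clamped to
    [0, 1] and I to [0, inf) afterwards (events counted). With sigma = 0 this
    reduces exactly to deterministic Euler and the seed is irrelevant.
    With ``record=False`` only the final state is kept (E/I have length 1+1).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    E = np.array(initial.E, dtype=float, copy=True)
    I = np.array(initial.I, dtype=float, copy=True)
    M = _coupling_matrix(gains, lap, coupling_mode)
    noisy = consts.sigma > 0
    amp = consts.sigma * np.sqrt(dt)
    if record:
        Es = np.empty((n_steps + 1,) + E.shape)
        Is = np.empty_like(Es)
        Es[0], Is[0] = E, I
    clamps = 0
    for t in range(n_steps):
        cE = network_input(E, M)
        x_e = consts.w_e * consts.i0 + gains.g_ee * E + gains.g * cE - gains.g_ie * I
        x_i = consts.w_i * consts.i0 + gains.g_ei * E + consts.lambda_ffi * gains.g * cE
        r_e = firing_rate(np.tanh(x_e) + consts.i_ext, consts.a_e, consts.b_e, consts.d_e)
        r_i = firing_rate(np.tanh(x_i), consts.a_i, consts.b_i, consts.d_i)
        E = E + dt * (-E / consts.tau_e + (1.0 - E) * consts.gamma * r_e)
        I = I + dt * (-I / consts.tau_i + r_i)
        if noisy:
            E = E + amp * rng.standard_normal(E.shape)
            I = I + amp * rng.standard_normal(I.shape)
        out_of_range = int(np.count_nonzero(E < 0) + np.count_nonzero(E > 1)
                           + np.count_nonzero(I < 0))
        if out_of_range:
            clamps += out_of_range
            np.clip(E, 0.0, 1.0, out=E)
            np.clip(I, 0.0, None, out=I)
        if not (np.all(np.isfinite(E)) and np.all(np.isfinite(I))):
            raise FloatingPointError(f"non-finite state at integration step {t}")
        if record:
            Es[t + 1], Is[t + 1] = E, I
    if not record:
        Es = np.stack([np.asarray(initial.E, float), E])
        Is = np.stack([np.asarray(initial.I, float), I])
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return NeuralTrajectory(
        dt=dt, E=Es, I=Is, seed=seed_val, clamp_events=clamps,
        meta={"coupling_mode": coupling_mode},
    )
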