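"""Differentiable whole-brain simulator: forward pass with caching and a
hand-derived reverse-mode adjoint (backpropagation through time).

The computational graph spanned per optimization epoch is

    gains (+ modifiable SC)  ->  Euler-Maruyama neural steps
                             ->  Balloon-Windkessel steps
                             ->  BOLD samples at TR resolution
                             ->  per-node z-scoring and FC (Pearson) matrix
                             ->  correlation with the target FC (the loss).

``simulate_epoch`` runs the forward pass on batched states of shape (B, N)
(B independent subjects/seeds, N regions) and caches the per-step states;
``backward`` walks the graph in reverse, propagating adjoints through the
clamp masks, the tanh current squash, the sigmoidal transfer function, the
balloon equations and the coupling operator, and accumulates exact gradients
with respect to the four synaptic gains and (for the connectivity variant)
the modifiable adjacency. The additive noise is independent of the
parameters, so gradients flow through the drift only; stochasticity enters
solely through the cached states. The step loops are JIT-compiled
(:mod:`rwwfit._kernels`); all derivative expressions are closed-form and the
test-suite checks them against central finite differences of the full
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._kernels import backward_kernel, forward_kernel
from .connectome import laplacian_from_adjacency
from .constants import BiophysicalConstants, HemodynamicConstants

__all__ = ["ParamArrays", "SimState", "EpochCache", "simulate_epoch", "backward",
           "fc_loss_head"]

CouplingMode = Literal["laplacian", "adjacency"]
_EPS_VAR = 1e-12


@dataclass
class ParamArrays:
    """Batched trainable parameters.

    ``g`` has shape (B, 1); ``g_ei``/``g_ie``/``g_ee`` have shape (B, 1)
    (global) or (B, N) (per-node, LM); ``C`` is the modifiable normalized
    adjacency (B, N, N) for the CM and None otherwise.
    """

    g: np.ndarray
    g_ei: np.ndarray
    g_ie: np.ndarray
    g_ee: np.ndarray
    C: np.ndarray | None = None

    def gain_items(self):
        return (("g", self.g), ("g_ei", self.g_ei), ("g_ie", self.g_ie),
                ("g_ee", self.g_ee))


@dataclass
class SimState:
    """Full per-step simulator state: neural (E, I) + hemodynamic (s, f, v, q)."""

    E: np.ndarray
    I: np.ndarray
    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def initial(cls, shape, e0: float = 0.1, i0_state: float = 0.1) -> "SimState":
        z = np.zeros(shape)
        return cls(np.full(shape, e0), np.full(shape, i0_state),
                   z.copy(), np.ones(shape), np.ones(shape), np.ones(shape))

    def copy(self) -> "SimState":
        return SimState(*(x.copy() for x in (self.E, self.I, self.s, self.f,
                                             self.v, self.q)))


@dataclass
class EpochCache:
    """Everything the backward pass needs: per-step states and clamp masks."""

    states: list[np.ndarray]   # 6 arrays (n_steps+1, B, N): E, I, s, f, v, q
    mask_e: np.ndarray         # (n_steps, B, N) uint8
    mask_i: np.ndarray
    params: ParamArrays
    gains_bn: tuple[np.ndarray, ...]   # gains broadcast to (B, N) for the kernels
    M: np.ndarray              # coupling operator (B, N, N) as used
    dt: float
    sample_every: int
    consts: BiophysicalConstants
    hc: HemodynamicConstants
    coupling_mode: CouplingMode
    clamp_events: int


def _resolve_coupling(params: ParamArrays, L, coupling_mode: CouplingMode,
                      B: int, N: int) -> np.ndarray:
    if params.C is not None:
        M = (laplacian_from_adjacency(params.C) if coupling_mode == "laplacian"
             else params.C)
    else:
        if L is None:
            raise ValueError("GM/LM require a precomputed coupling operator")
        M = np.asarray(L, dtype=float)
    if M.ndim == 2:
        M = np.broadcast_to(M, (B, N, N))
    return np.ascontiguousarray(M, dtype=np.float64)


def _consts_args(c: BiophysicalConstants, hc: HemodynamicConstants):
    return (c.tau_e, c.tau_i, c.gamma, c.a_e, c.b_e, c.d_e, c.a_i, c.b_i,
            c.d_i, c.i0, c.w_e, c.w_i, c.i_ext, c.lambda_ffi,
            hc.kappa, hc.gamma_h, hc.tau_h, hc.alpha, hc.rho, hc.v0,
            hc.k1, hc.k2, hc.k3)


def simulate_epoch(
    state: SimState,
    params: ParamArrays,
    consts: BiophysicalConstants,
    hc: HemodynamicConstants,
    L: np.ndarray | None,
    dt: float,
    n_steps: int,
    sample_every: int,
    rng: np.random.Generator | None = None,
    sigma: float | None = None,
    coupling_mode: CouplingMode = "laplacian",
    with_cache: bool = True,
) -> tuple[np.ndarray, SimState, EpochCache | None]:
    """Forward-simulate one epoch; returns (bold (B, T, N), final state, cache).

    The hemodynamic step at step t is driven by the neural state at the start
    of step t; BOLD is read out every ``sample_every`` neural steps. With
    ``sigma`` > 0 fresh Gaussian noise is drawn from ``rng`` (E noise then I
    noise per step, matching :func:`rwwfit.dynamics.integrate`).
    """
    sigma = consts.sigma if sigma is None else sigma
    if sigma > 0 and rng is None:
        raise ValueError("stochastic simulation needs an rng")
    B, N = state.E.shape
    M = _resolve_coupling(params, L, coupling_mode, B, N)
    gains_bn = tuple(
        np.ascontiguousarray(np.broadcast_to(gv, (B, N)), dtype=np.float64)
        for _, gv in params.gain_items()
    )
    if sigma > 0:
        noise = rng.standard_normal((n_steps, 2, B, N))
    else:
        noise = np.empty((0, 2, B, N))
    E = np.ascontiguousarray(state.E, dtype=np.float64).copy()
    I = np.ascontiguousarray(state.I, dtype=np.float64).copy()
    s = np.ascontiguousarray(state.s, dtype=np.float64).copy()
    f = np.ascontiguousarray(state.f, dtype=np.float64).copy()
    v = np.ascontiguousarray(state.v, dtype=np.float64).copy()
    q = np.ascontiguousarray(state.q, dtype=np.float64).copy()
    n_rec = n_steps + 1 if with_cache else 1
    store = [np.empty((n_rec, B, N)) for _ in range(6)]
    n_mask = n_steps if with_cache else 1
    mask_e = np.empty((n_mask, B, N), dtype=np.uint8)
    mask_i = np.empty((n_mask, B, N), dtype=np.uint8)
    n_samples = n_steps // sample_every
    bold = np.empty((B, n_samples, N))
    clamps = forward_kernel(
        E, I, s, f, v, q, *gains_bn, M, noise, sigma * np.sqrt(dt),
        dt, n_steps, sample_every, *_consts_args(consts, hc),
        bold, *store, mask_e, mask_i, with_cache,
    )
    if not (np.all(np.isfinite(E)) and np.all(np.isfinite(bold))):
        raise FloatingPointError("non-finite state during epoch simulation")
    final = SimState(E, I, s, f, v, q)
    cache = None
    if with_cache:
        cache = EpochCache(states=store, mask_e=mask_e, mask_i=mask_i,
                           params=params, gains_bn=gains_bn, M=M, dt=dt,
                           sample_every=sample_every, consts=consts, hc=hc,
                           coupling_mode=coupling_mode, clamp_events=int(clamps))
    return bold, final, cache


def _reduce_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a (B, N) gradient down to a broadcastable parameter shape."""
    if grad.shape == shape:
        return grad
    out = grad
    for ax in range(len(shape)):
        if shape[ax] == 1 and out.shape[ax] != 1:
            out = out.sum(axis=ax, keepdims=True)
    return out


def backward(cache: EpochCache, d_bold: np.ndarray) -> dict[str, np.ndarray]:
    """Reverse sweep: gradients of the loss w.r.t. gains (and C for the CM).

    ``d_bold`` is dLoss/dBOLD of shape (B, T, N). Returns a dict with entries
    ``g``, ``g_ei``, ``g_ie``, ``g_ee`` shaped like the parameters, and ``C``
    of shape (B, N, N) when the cache carries a modifiable adjacency.
    """
    p = cache.params
    B, N = cache.states[0].shape[1:]
    n_steps = cache.states[0].shape[0] - 1
    gr_bn = [np.zeros((B, N)) for _ in range(4)]
    want_gc = p.C is not None
    gr_C = np.zeros((B, N, N)) if want_gc else np.zeros((B, 0, 0))
    backward_kernel(
        np.ascontiguousarray(d_bold), *cache.gains_bn, cache.M,
        cache.dt, n_steps, cache.sample_every,
        *_consts_args(cache.consts, cache.hc),
        *cache.states, cache.mask_e, cache.mask_i,
        gr_bn[0], gr_bn[1], gr_bn[2], gr_bn[3], gr_C,
        want_gc, cache.coupling_mode == "laplacian",
    )
    out = {
        name: _reduce_to(gr, getattr(p, name).shape)
        for (name, _), gr in zip(p.gain_items(), gr_bn)
    }
    if want_gc:
        out["C"] = gr_C
    return out


def fc_loss_head(
    bold: np.ndarray,
    target_fc: np.ndarray,
    eps: float = _EPS_VAR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FC correlation loss head with its gradient w.r.t. the BOLD series.

    For each batch element: z-score the (T, N) BOLD per node, form the
    Pearson FC matrix, and correlate its strictly-upper triangle with the
    target's. Returns (r per batch, simulated FC (B, N, N), dLoss/dBOLD)
    where the loss is -sum_b r_b.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 2:
        bold = bold[None]
    B, T, N = bold.shape
    if T < 2:
        raise ValueError("need at least 2 BOLD samples to form an FC matrix")
    target = np.asarray(target_fc, dtype=float)
    if target.ndim == 2:
        target = np.broadcast_to(target, (B, N, N))
    mu = bold.mean(axis=1, keepdims=True)
    ctr = bold - mu
    sd = np.sqrt((ctr**2).mean(axis=1, keepdims=True) + eps)
    Z = ctr / sd
    fc = np.einsum("bti,btj->bij", Z, Z) / T
    iu, ju = np.triu_indices(N, 1)
    x = fc[:, iu, ju]
    y = target[:, iu, ju]
    xt = x - x.mean(axis=1, keepdims=True)
    yt = y - y.mean(axis=1, keepdims=True)
    Sx = (xt**2).sum(axis=1)
    Sy = (yt**2).sum(axis=1)
    Sxy = (xt * yt).sum(axis=1)
    denom = np.sqrt(np.maximum(Sx * Sy, 1e-300))
    r = Sxy / denom
    # dr/dx then chain through the FC build and the z-scoring
    dr_dx = yt / denom[:, None] - (r / np.maximum(Sx, 1e-300))[:, None] * xt
    G = np.zeros((B, N, N))
    G[:, iu, ju] = -dr_dx  # loss = -sum r
    Gs = G + np.transpose(G, (0, 2, 1))
    dZ = np.einsum("btj,bjk->btk", Z, Gs) / T
    d_bold = (dZ - dZ.mean(axis=1, keepdims=True)
              - Z * (dZ * Z).mean(axis=1, keepdims=True)) / sd
    fc_out = fc.copy()
    fc_out[:, np.arange(N), np.arange(N)] = 1.0
    return r, fc_out, d_bold
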