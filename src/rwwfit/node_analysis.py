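"""Fixed-point and linear-stability analysis of the isolated two-dimensional
node and of the coupled network.

With the long-range coupling removed and noise off, each region reduces to a
planar system in (E, I). Its fixed points are located by Newton iterations
seeded from a grid over [0, 1] x [0, I_max] using the analytic Jacobian, each
root is labeled stable iff both Jacobian eigenvalues have negative real
parts, and the node is classified as monostable (exactly one stable fixed
point), bistable (two or more) or ``no_stable_fp``.

At the network level, a fixed point of the full 2N-dimensional deterministic
system is located (relaxation followed by a root solve with the analytically
assembled 2N x 2N Jacobian) and the stability margin is reported as
m = -max Re eig(J): m > 0 linearly stable, m = 0 critical, m < 0 unstable.

An independent brute-force oracle (:func:`grid_scan_fixed_points`) localizes
roots by a dense sign-change scan polished with a MINPACK solver; the test
suite holds the Newton solver to agreement with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import fsolve

from .connectome import CouplingLaplacian
from .constants import BiophysicalConstants
from .dynamics import firing_rate, firing_rate_derivative, network_input
from .params import GainParameters

__all__ = [
    "NodeRegime",
    "StabilityMargin",
    "node_drift",
    "node_jacobian",
    "find_fixed_points",
    "grid_scan_fixed_points",
    "classify_cohort",
    "network_stability_margin",
]

_MERGE_TOL = 1e-6


@dataclass
class NodeRegime:
    """Fixed points of one isolated node with stability labels and regime."""

    fixed_points: list[tuple[float, float]]
    stable: list[bool]
    regime: str  # monostable | bistable | no_stable_fp

    @property
    def n_stable(self) -> int:
        return int(sum(self.stable))


@dataclass
class StabilityMargin:
    """Network linear-stability margin m = -max Re eig(J) at a fixed point."""

    m: float
    fixed_point: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def _node_gains(gains: GainParameters | dict, node: int | None = None) -> tuple[float, float, float]:
    """Node-local (g_ei, g_ie, g_ee) triple from a parameter set."""
    if isinstance(gains, dict):
        vals = [gains[k] for k in ("g_ei", "g_ie", "g_ee")]
    else:
        vals = [gains.g_ei, gains.g_ie, gains.g_ee]
    out = []
    for v in vals:
        a = np.atleast_1d(np.asarray(v, dtype=float))
        out.append(float(a[node] if (a.size > 1 and node is not None) else a.flat[0]))
    return tuple(out)  # type: ignore[return-value]


def node_drift(E, I, g_ei: float, g_ie: float, g_ee: float,
               consts: BiophysicalConstants) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic planar drift of the isolated node (coupling = 0)."""
    c = consts
    x_e = c.w_e * c.i0 + g_ee * np.asarray(E, float) - g_ie * np.asarray(I, float)
    x_i = c.w_i * c.i0 + g_ei * np.asarray(E, float)
    r_e = firing_rate(np.tanh(x_e) + c.i_ext, c.a_e, c.b_e, c.d_e)
    r_i = firing_rate(np.tanh(x_i), c.a_i, c.b_i, c.d_i)
    f1 = -np.asarray(E, float) / c.tau_e + (1.0 - np.asarray(E, float)) * c.gamma * r_e
    f2 = -np.asarray(I, float) / c.tau_i + r_i
    return f1, f2


def node_jacobian(E: float, I: float, g_ei: float, g_ie: float, g_ee: float,
                  consts: BiophysicalConstants) -> np.ndarray:
    """Analytic 2x2 Jacobian of the isolated-node drift at (E, I)."""
    c = consts
    x_e = c.w_e * c.i0 + g_ee * E - g_ie * I
    x_i = c.w_i * c.i0 + g_ei * E
    t_e, t_i = np.tanh(x_e), np.tanh(x_i)
    i_e = t_e + c.i_ext
    r_e = firing_rate(i_e, c.a_e, c.b_e, c.d_e)
    dphi_e = firing_rate_derivative(i_e, c.a_e, c.b_e, c.d_e) * (1.0 - t_e**2)
    dphi_i = firing_rate_derivative(t_i, c.a_i, c.b_i, c.d_i) * (1.0 - t_i**2)
    j11 = -1.0 / c.tau_e - c.gamma * r_e + (1.0 - E) * c.gamma * dphi_e * g_ee
    j12 = -(1.0 - E) * c.gamma * dphi_e * g_ie
    j21 = dphi_i * g_ei
    j22 = -1.0 / c.tau_i
    return np.array([[j11, j12], [j21, j22]])


def default_i_max(consts: BiophysicalConstants) -> float:
    """Seeding-grid upper bound on I: twice the largest tau_I * R_I scale."""
    r_max = firing_rate(1.0, consts.a_i, consts.b_i, consts.d_i)
    return 2.0 * consts.tau_i * r_max


def _dedupe(roots: list[np.ndarray], tol: float = _MERGE_TOL) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for r in roots:
        if not any(np.max(np.abs(r - o)) < tol for o in out):
            out.append(r)
    return out


def find_fixed_points(
    gains: GainParameters | dict,
    consts: BiophysicalConstants | None = None,
    node: int | None = None,
    grid: int = 12,
    i_max: float | None = None,
    max_iter: int = 80,
    tol: float = 1e-12,
) -> NodeRegime:
    """Newton-based root finding of the isolated node, seeded from a grid.

    Seeds span (E, I) in [0, 1] x [0, i_max]; duplicate roots are merged
    within 1e-6 and roots outside the physical region (with small slack) are
    discarded. Raises if no seed converges — a solver failure, distinguishable
    from a verified no-stable-fixed-point regime (which has roots, all
    unstable).
    """
    consts = consts or BiophysicalConstants()
    g_ei, g_ie, g_ee = _node_gains(gains, node)
    i_max = default_i_max(consts) if i_max is None else i_max
    roots: list[np.ndarray] = []
    for e0 in np.linspace(0.0, 1.0, grid):
        for i0 in np.linspace(0.0, i_max, grid):
            x = np.array([e0, i0])
            for _ in range(max_iter):
                f1, f2 = node_drift(x[0], x[1], g_ei, g_ie, g_ee, consts)
                F = np.array([float(f1), float(f2)])
                if np.max(np.abs(F)) < tol:
                    break
                J = node_jacobian(x[0], x[1], g_ei, g_ie, g_ee, consts)
                try:
                    step = np.linalg.solve(J, F)
                except np.linalg.LinAlgError:
                    break
                x = x - step
                if not np.all(np.isfinite(x)):
                    break
            else:
                continue
            if not np.all(np.isfinite(x)):
                continue
            if -1e-6 <= x[0] <= 1.0 + 1e-6 and -1e-6 <= x[1] <= 2.0 * i_max:
                f1, f2 = node_drift(x[0], x[1], g_ei, g_ie, g_ee, consts)
                if max(abs(float(f1)), abs(float(f2))) < 1e-8:
                    roots.append(x)
    roots = _dedupe(roots)
    if not roots:
        raise RuntimeError("Newton failed to locate any fixed point from all seeds")
    stable = []
    for r in roots:
        eig = np.linalg.eigvals(node_jacobian(r[0], r[1], g_ei, g_ie, g_ee, consts))
        stable.append(bool(np.all(eig.real < 0)))
    n_st = sum(stable)
    regime = "monostable" if n_st == 1 else ("bistable" if n_st >= 2 else "no_stable_fp")
    order = np.argsort([r[0] for r in roots])
    return NodeRegime(
        fixed_points=[(float(roots[i][0]), float(roots[i][1])) for i in order],
        stable=[stable[i] for i in order],
        regime=regime,
    )


def grid_scan_fixed_points(
    gains: GainParameters | dict,
    consts: BiophysicalConstants | None = None,
    node: int | None = None,
    resolution: int = 400,
    i_max: float | None = None,
) -> list[tuple[float, float]]:
    """Brute-force root localization: dense sign-change scan + MINPACK polish.

    Evaluates both drift components on a ``resolution x resolution`` grid,
    flags cells where each component changes sign across the cell corners,
    and refines each candidate cell center with ``scipy.optimize.fsolve``.
    Serves as the independent oracle for :func:`find_fixed_points`.
    """
    consts = consts or BiophysicalConstants()
    g_ei, g_ie, g_ee = _node_gains(gains, node)
    i_max = default_i_max(consts) if i_max is None else i_max
    es = np.linspace(0.0, 1.0, resolution + 1)
    is_ = np.linspace(0.0, i_max, resolution + 1)
    EE, II = np.meshgrid(es, is_, indexing="ij")
    F1, F2 = node_drift(EE, II, g_ei, g_ie, g_ee, consts)
    s1, s2 = np.sign(F1), np.sign(F2)

    def _changes(s):
        corners = np.stack([s[:-1, :-1], s[1:, :-1], s[:-1, 1:], s[1:, 1:]])
        return (corners.min(axis=0) < 0) & (corners.max(axis=0) > 0)

    cand = np.argwhere(_changes(s1) & _changes(s2))
    roots: list[np.ndarray] = []
    for ci, cj in cand:
        x0 = np.array([(es[ci] + es[ci + 1]) / 2, (is_[cj] + is_[cj + 1]) / 2])
        sol, info, ier, _ = fsolve(
            lambda x: np.array(node_drift(x[0], x[1], g_ei, g_ie, g_ee, consts),
                               dtype=float).ravel(),
            x0, full_output=True,
        )
        if ier == 1 and np.max(np.abs(info["fvec"])) < 1e-9:
            roots.append(sol)
    roots = _dedupe(roots, tol=1e-5)
    return sorted([(float(r[0]), float(r[1])) for r in roots])


def classify_cohort(
    cohort_gains: list,
    consts: BiophysicalConstants | None = None,
    n_nodes: int | None = None,
) -> dict:
    """Per-subject regime fractions and cohort medians.

    ``cohort_gains`` is a list of per-subject :class:`GainParameters` (or
    dicts); per-node gain vectors are classified node by node, scalars apply
    to every node (``n_nodes`` then sets the node count, default 1).
    """
    consts = consts or BiophysicalConstants()
    regimes = ("monostable", "bistable", "no_stable_fp")
    per_subject = []
    for gains in cohort_gains:
        g_ei = np.atleast_1d(np.asarray(
            gains["g_ei"] if isinstance(gains, dict) else gains.g_ei, dtype=float))
        n = g_ei.size if g_ei.size > 1 else (n_nodes or 1)
        counts = dict.fromkeys(regimes, 0)
        cache: dict[tuple, str] = {}
        for node in range(n):
            key = _node_gains(gains, node)
            if key not in cache:
                cache[key] = find_fixed_points(gains, consts, node=node).regime
            counts[cache[key]] += 1
        per_subject.append({k: counts[k] / n for k in regimes})
    medians = {k: float(np.median([s[k] for s in per_subject])) for k in regimes}
    return {"per_subject": per_subject, "median": medians}


def _network_drift_and_jacobian(
    E: np.ndarray, I: np.ndarray,
    gains: GainParameters, consts: BiophysicalConstants, M: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    c = consts
    N = E.shape[0]
    g = float(np.atleast_1d(gains.g)[0])
    g_ei = np.broadcast_to(np.atleast_1d(gains.g_ei), (N,)).astype(float)
    g_ie = np.broadcast_to(np.atleast_1d(gains.g_ie), (N,)).astype(float)
    g_ee = np.broadcast_to(np.atleast_1d(gains.g_ee), (N,)).astype(float)
    cE = network_input(E, M)
    x_e = c.w_e * c.i0 + g_ee * E + g * cE - g_ie * I
    x_i = c.w_i * c.i0 + g_ei * E + c.lambda_ffi * g * cE
    t_e, t_i = np.tanh(x_e), np.tanh(x_i)
    i_e = t_e + c.i_ext
    r_e = firing_rate(i_e, c.a_e, c.b_e, c.d_e)
    r_i = firing_rate(t_i, c.a_i, c.b_i, c.d_i)
    f1 = -E / c.tau_e + (1.0 - E) * c.gamma * r_e
    f2 = -I / c.tau_i + r_i
    dphi_e = firing_rate_derivative(i_e, c.a_e, c.b_e, c.d_e) * (1.0 - t_e**2)
    dphi_i = firing_rate_derivative(t_i, c.a_i, c.b_i, c.d_i) * (1.0 - t_i**2)
    dxe_dE = np.diag(g_ee) + g * M
    dxi_dE = np.diag(g_ei) + c.lambda_ffi * g * M
    pre_e = ((1.0 - E) * c.gamma * dphi_e)[:, None]
    J11 = pre_e * dxe_dE + np.diag(-1.0 / c.tau_e - c.gamma * r_e)
    J12 = np.diag(-(1.0 - E) * c.gamma * dphi_e * g_ie)
    J21 = dphi_i[:, None] * dxi_dE
    J22 = np.diag(np.full(N, -1.0 / c.tau_i))
    J = np.block([[J11, J12], [J21, J22]])
    return np.concatenate([f1, f2]), J


def network_stability_margin(
    gains: GainParameters,
    consts: BiophysicalConstants | None = None,
    lap: CouplingLaplacian | np.ndarray | None = None,
    coupling_mode: str = "laplacian",
    relax_time: float = 20.0,
    dt: float = 0.001,
    max_iter: int = 100,
) -> StabilityMargin:
    """Locate a deterministic network fixed point and its stability margin.

    The noiseless system is relaxed from a mid-range state for ``relax_time``
    seconds, then polished by Newton with the analytic 2N x 2N Jacobian;
    the margin is m = -max Re eig(J) at the located point (m > 0 iff
    linearly stable). The fixed point found is the one reached from the
    relaxed state — for multistable networks this is the margin of the
    attractor the warmed-up simulation actually occupies.
    """
    consts = (consts or BiophysicalConstants()).replace(sigma=0.0)
    if gains.variant == "cm":
        from .connectome import laplacian_from_adjacency

        M = (laplacian_from_adjacency(gains.sc_mod) if coupling_mode == "laplacian"
             else gains.sc_mod)
    else:
        if lap is None:
            raise ValueError("GM/LM margin needs the coupling Laplacian")
        M = lap.matrix if isinstance(lap, CouplingLaplacian) else np.asarray(lap, float)
    N = M.shape[0]
    E = np.full(N, 0.2)
    I = np.full(N, 0.1)
    n_steps = int(round(relax_time / dt))
    for _ in range(n_steps):
        f1, f2 = _network_drift_only(E, I, gains, consts, M)
        E = np.clip(E + dt * f1, 0.0, 1.0)
        I = np.maximum(I + dt * f2, 0.0)
    x = np.concatenate([E, I])
    for _ in range(max_iter):
        F, J = _network_drift_and_jacobian(x[:N], x[N:], gains, consts, M)
        if np.max(np.abs(F)) < 1e-12:
            break
        try:
            x = x - np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            break
    F, J = _network_drift_and_jacobian(x[:N], x[N:], gains, consts, M)
    if np.max(np.abs(F)) > 1e-8:
        raise RuntimeError("failed to converge to a network fixed point")
    eig = np.linalg.eigvals(J)
    return StabilityMargin(
        m=float(-np.max(eig.real)),
        fixed_point=x,
        meta={"residual": float(np.max(np.abs(F))), "n_nodes": N},
    )


def _network_drift_only(E, I, gains, consts, M):
    c = consts
    g = float(np.atleast_1d(gains.g)[0])
    cE = network_input(E, M)
    x_e = c.w_e * c.i0 + np.asarray(gains.g_ee) * E + g * cE - np.asarray(gains.g_ie) * I
    x_i = c.w_i * c.i0 + np.asarray(gains.g_ei) * E + c.lambda_ffi * g * cE
    r_e = firing_rate(np.tanh(x_e) + c.i_ext, c.a_e, c.b_e, c.d_e)
    r_i = firing_rate(np.tanh(x_i), c.a_i, c.b_i, c.d_i)
    return (-E / c.tau_e + (1.0 - E) * c.gamma * r_e, -I / c.tau_i + r_i)
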