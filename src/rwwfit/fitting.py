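"""Gradient-based fitting of the whole-brain model to an empirical FC target.

Per optimization epoch the simulator generates ``epoch_trs`` repetition times
of BOLD, continuing from the state carried over from the previous epoch (a
warm-up phase of un-optimized simulation precedes the first epoch, so each
epoch needs no fresh transient). The loss is the negative Pearson correlation
between the upper triangles of simulated and target FC, plus a variant
penalty:

* GM — none;
* LM — ``lambda_lm`` times the across-node variance of each per-node gain
  vector (keeps regional gains from drifting apart);
* CM — ``lambda_cm * ||SC_mod - SC_emp||^2`` over the upper triangle, with
  ``SC_mod`` clamped element-wise to [0, 1] after every optimizer step;
  symmetry and the zero diagonal are inherited from the upper-triangular
  parametrization.

Gains are optimized as unconstrained latents mapped through softplus (which
keeps them positive without projections); ADAM with an exponential
learning-rate decay performs the updates. Everything is reproducible from the
config seed, and fits over several subjects (or restarts) run batched through
one vectorized simulator loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .adjoint import ParamArrays, SimState, backward, fc_loss_head, simulate_epoch
from .connectome import StructuralConnectome, laplacian_from_adjacency, normalize_sc
from .constants import BiophysicalConstants, HemodynamicConstants
from .fc_metrics import FCMatrix, fc_fit as _fc_fit_metric, sc_anchor_correlation
from .params import DEFAULT_GAINS, GainParameters, count_free_parameters  # noqa: F401

__all__ = [
    "FitConfig",
    "FitResult",
    "Adam",
    "loss",
    "warmup",
    "fit",
    "fit_cohort",
    "count_free_parameters",
]

_ALL_GAINS = ("g", "g_ei", "g_ie", "g_ee")


@dataclass
class FitConfig:
    """Everything that defines one optimization run (echoed into results)."""

    variant: str = "gm"
    epochs: int = 500
    warmup_epochs: int = 20
    epoch_trs: int = 50          # TRs of simulated BOLD per epoch
    tr: float = 2.0              # repetition time (s)
    dt: float = 0.005            # integration step (s) used during fitting
    learning_rate: float = 0.05
    lr_decay: float = 0.995      # exponential decay factor per epoch
    lambda_cm: float = 0.5       # SC-anchoring weight (CM)
    lambda_lm: float = 0.05      # across-node dispersion weight (LM)
    sigma: float = 0.01          # state-noise SD during fitting
    seed: int = 0
    eval_trs: int = 150          # length of the final evaluation simulation
    coupling_mode: str = "laplacian"
    trainable: tuple[str, ...] | None = None   # subset of gains to optimize
    init_gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    e0: float = 0.1              # initial excitatory gating before warm-up
    i0_state: float = 0.1        # initial inhibitory gating before warm-up

    def __post_init__(self) -> None:
        self.variant = self.variant.lower()
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")
        if self.lambda_cm < 0 or self.lambda_lm < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.epoch_trs < 2:
            raise ValueError("epoch duration must cover at least 2 TRs")
        k = self.tr / self.dt
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"tr={self.tr} must be an integer multiple of dt={self.dt}")
        if self.trainable is not None:
            bad = set(self.trainable) - {*_ALL_GAINS, "sc_mod"}
            if bad:
                raise ValueError(f"unknown trainable parameters: {sorted(bad)}")

    @property
    def steps_per_tr(self) -> int:
        return int(round(self.tr / self.dt))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trainable"] = list(self.trainable) if self.trainable else None
        return d


@dataclass
class FitResult:
    """Outcome of one subject's fit."""

    final_params: GainParameters
    loss_trace: list[dict]
    final_fc: FCMatrix
    clamp_events: int
    config: dict
    sc_anchor_r: float | None = None

    @property
    def final_fc_fit(self) -> float:
        return self.loss_trace[-1]["fc_fit"] if self.loss_trace else float("nan")


class Adam(object):
    """Plain ADAM with bias correction, operating on a dict of arrays."""

    def __init__(self, params: dict[str, np.ndarray],
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _softplus_inv(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return np.where(y > 30, y, np.log(np.expm1(np.maximum(y, 1e-12))))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def loss(
    sim_fc,
    target_fc,
    params: GainParameters,
    sc_emp: np.ndarray | None = None,
    config: FitConfig | None = None,
) -> float:
    """Scalar training loss: -fc_fit plus the variant's penalty term."""
    config = config or FitConfig(variant=params.variant)
    base = -_fc_fit_metric(sim_fc, target_fc)
    if params.variant == "cm":
        if sc_emp is None:
            raise ValueError("CM loss needs the empirical SC")
        n = params.sc_mod.shape[0]
        iu, ju = np.triu_indices(n, 1)
        diff = params.sc_mod[iu, ju] - np.asarray(sc_emp, float)[iu, ju]
        base += config.lambda_cm * float(diff @ diff)
    elif params.variant == "lm":
        for name in ("g_ei", "g_ie", "g_ee"):
            base += config.lambda_lm * float(np.var(np.asarray(getattr(params, name))))
    return base


# ---------------------------------------------------------------------------
# batched fitting engine


def _init_param_arrays(config: FitConfig, B: int, N: int,
                       C_emp: np.ndarray) -> tuple[ParamArrays, dict, np.ndarray | None]:
    """Latent-space initialization; returns (decoded params, latents, U for CM)."""
    init = {**DEFAULT_GAINS, **config.init_gains}
    latents: dict[str, np.ndarray] = {}
    for name in _ALL_GAINS:
        shape = (B, N) if (config.variant == "lm" and name != "g") else (B, 1)
        latents[name] = np.full(shape, float(_softplus_inv(init[name])))
    U = None
    if config.variant == "cm":
        iu, ju = np.triu_indices(N, 1)
        U = C_emp[:, iu, ju].copy()
    return _decode(latents, U, N), latents, U


def _decode(latents: dict, U: np.ndarray | None, N: int) -> ParamArrays:
    gains = {k: _softplus(v) for k, v in latents.items()}
    C = None
    if U is not None:
        B = U.shape[0]
        C = np.zeros((B, N, N))
        iu, ju = np.triu_indices(N, 1)
        C[:, iu, ju] = U
        C += np.transpose(C, (0, 2, 1))
    return ParamArrays(C=C, **gains)


def warmup(
    sc: StructuralConnectome | np.ndarray,
    params: GainParameters | ParamArrays,
    config: FitConfig,
    consts: BiophysicalConstants | None = None,
    hc: HemodynamicConstants | None = None,
    rng: np.random.Generator | None = None,
) -> SimState:
    """Simulate ``warmup_epochs`` epochs of activity without parameter updates.

    Starts from the fixed initial state of the config and returns the terminal
    neural + hemodynamic state used to seed the optimization epochs. With
    ``warmup_epochs = 0`` the initial state is returned unchanged.
    """
    consts = consts or BiophysicalConstants()
    hc = hc or HemodynamicConstants()
    C = sc.weights if isinstance(sc, StructuralConnectome) else np.asarray(sc, float)
    if C.ndim == 2:
        C = C[None]
    B, N = C.shape[0], C.shape[-1]
    if isinstance(params, GainParameters):
        pa = _param_arrays_from_gains(params, B, N)
    else:
        pa = params
    L = None
    if pa.C is None:
        L = (laplacian_from_adjacency(C) if config.coupling_mode == "laplacian" else C)
        if L.shape[0] == 1:
            L = L[0]
    state = SimState.initial((B, N), config.e0, config.i0_state)
    n_steps = config.warmup_epochs * config.epoch_trs * config.steps_per_tr
    if n_steps == 0:
        return state
    rng = rng or np.random.default_rng(config.seed)
    _, state, _ = simulate_epoch(
        state, pa, consts, hc, L, config.dt, n_steps, sample_every=n_steps,
        rng=rng, sigma=config.sigma, coupling_mode=config.coupling_mode,
        with_cache=False,
    )
    return state


def _param_arrays_from_gains(gp: GainParameters, B: int, N: int) -> ParamArrays:
    def _shape(v):
        a = np.atleast_1d(np.asarray(v, dtype=float))
        if a.size == 1:
            return np.full((B, 1), float(a.flat[0]))
        return np.broadcast_to(a, (B, N)).copy()

    C = None
    if gp.variant == "cm":
        C = np.broadcast_to(gp.sc_mod, (B, N, N)).copy()
    return ParamArrays(g=_shape(gp.g), g_ei=_shape(gp.g_ei),
                       g_ie=_shape(gp.g_ie), g_ee=_shape(gp.g_ee), C=C)


def _fit_batched(
    C_emp: np.ndarray,
    targets: np.ndarray,
    config: FitConfig,
    consts: BiophysicalConstants | None = None,
    hc: HemodynamicConstants | None = None,
) -> dict:
    """Fit one variant to B subjects at once; see :func:`fit` for semantics.

    ``C_emp`` (B, N, N) holds normalized adjacencies, ``targets`` (B, N, N)
    the empirical FC matrices. Returns raw batched outputs; :func:`fit` and
    :func:`fit_cohort` slice them into per-subject :class:`FitResult`.
    """
    consts = (consts or BiophysicalConstants()).replace(sigma=config.sigma)
    hc = hc or HemodynamicConstants()
    C_emp = np.asarray(C_emp, dtype=float)
    if C_emp.ndim == 2:
        C_emp = C_emp[None]
    B, N = C_emp.shape[0], C_emp.shape[-1]
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 2:
        targets = np.broadcast_to(targets, (B, N, N))
    rng = np.random.default_rng(config.seed)
    iu, ju = np.triu_indices(N, 1)
    U_emp = C_emp[:, iu, ju]

    params, latents, U = _init_param_arrays(config, B, N, C_emp)
    trainable = list(config.trainable) if config.trainable is not None else \
        list(_ALL_GAINS) + (["sc_mod"] if config.variant == "cm" else [])
    opt_vars: dict[str, np.ndarray] = {k: latents[k] for k in trainable if k != "sc_mod"}
    if "sc_mod" in trainable and U is not None:
        opt_vars["sc_mod"] = U
    optimizer = Adam(opt_vars)

    L = None
    if config.variant != "cm":
        L = (laplacian_from_adjacency(C_emp) if config.coupling_mode == "laplacian"
             else C_emp)
    k = config.steps_per_tr
    steps_per_epoch = config.epoch_trs * k

    state = warmup(C_emp, params, config, consts, hc, rng=rng)
    lr = config.learning_rate
    trace: list[dict] = []
    clamp_total = 0
    for epoch in range(config.epochs):
        params = _decode(latents, U, N)
        bold, state, cache = simulate_epoch(
            state, params, consts, hc, L, config.dt, steps_per_epoch, k,
            rng=rng, sigma=config.sigma, coupling_mode=config.coupling_mode,
        )
        clamp_total += cache.clamp_events
        r, _fc, d_bold = fc_loss_head(bold, targets)
        grads = backward(cache, d_bold)
        loss_b = -r
        # penalties
        if config.variant == "cm":
            dU = U - U_emp
            loss_b = loss_b + config.lambda_cm * np.sum(dU * dU, axis=1)
            grad_U = grads["C"][:, iu, ju] + grads["C"][:, ju, iu] \
                + 2.0 * config.lambda_cm * dU
        elif config.variant == "lm":
            for name in ("g_ei", "g_ie", "g_ee"):
                vec = params.__dict__[name]
                dev = vec - vec.mean(axis=1, keepdims=True)
                loss_b = loss_b + config.lambda_lm * np.mean(dev * dev, axis=1)
                grads[name] = grads[name] + config.lambda_lm * 2.0 * dev / N
        step_grads: dict[str, np.ndarray] = {}
        for name in trainable:
            if name == "sc_mod":
                step_grads["sc_mod"] = grad_U
            else:
                step_grads[name] = grads[name] * _sigmoid(latents[name])
        optimizer.step(opt_vars, step_grads, lr)
        if U is not None:
            np.clip(U, 0.0, 1.0, out=U)
        if not np.all(np.isfinite(loss_b)):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        row = {"epoch": epoch, "loss": loss_b.copy(), "fc_fit": r.copy(),
               "lr": lr, "clamp_events": cache.clamp_events}
        if U is not None:
            row["sc_mod_min"] = float(U.min())
            row["sc_mod_max"] = float(U.max())
        trace.append(row)
        lr *= config.lr_decay

    params = _decode(latents, U, N)
    # final evaluation simulation with the fitted parameters
    eval_steps = config.eval_trs * k
    bold, state, _ = simulate_epoch(
        state, params, consts, hc, L, config.dt, eval_steps, k,
        rng=rng, sigma=config.sigma, coupling_mode=config.coupling_mode,
        with_cache=False,
    )
    _r, fc_sim, _ = fc_loss_head(bold, targets)
    return {
        "params": params,
        "latents": latents,
        "U": U,
        "fc": fc_sim,
        "eval_fc_fit": _r,
        "trace": trace,
        "clamp_events": clamp_total,
        "C_emp": C_emp,
        "n_nodes": N,
        "n_batch": B,
    }


def _slice_result(raw: dict, b: int, config: FitConfig) -> FitResult:
    p, N = raw["params"], raw["n_nodes"]
    variant = config.variant

    def _gain(name):
        arr = getattr(p, name)[b]
        return float(arr[0]) if arr.shape[-1] == 1 else arr.copy()

    sc_mod = p.C[b].copy() if p.C is not None else None
    gains = GainParameters(variant=variant, g=_gain("g"), g_ei=_gain("g_ei"),
                           g_ie=_gain("g_ie"), g_ee=_gain("g_ee"), sc_mod=sc_mod)
    trace = [
        {"epoch": row["epoch"], "loss": float(row["loss"][b]),
         "fc_fit": float(row["fc_fit"][b]), "lr": row["lr"],
         **{k: row[k] for k in ("sc_mod_min", "sc_mod_max") if k in row}}
        for row in raw["trace"]
    ]
    anchor = None
    if sc_mod is not None:
        anchor = sc_anchor_correlation(sc_mod, raw["C_emp"][b])
    fc_vals = raw["fc"][b]
    return FitResult(
        final_params=gains,
        loss_trace=trace,
        final_fc=FCMatrix(np.clip(fc_vals, -1, 1)),
        clamp_events=raw["clamp_events"],
        config=config.to_dict(),
        sc_anchor_r=anchor,
    )


def fit(
    sc_emp: StructuralConnectome,
    target_fc: FCMatrix | np.ndarray,
    config: FitConfig,
    consts: BiophysicalConstants | None = None,
    hc: HemodynamicConstants | None = None,
    normalized: bool | None = None,
) -> FitResult:
    """Fit the configured variant to one subject's empirical FC.

    ``sc_emp`` may be raw streamline counts (it is then log-transformed and
    unit-normalized first) or already normalized — detected from the weight
    range unless ``normalized`` is passed explicitly.
    """
    if normalized is None:
        normalized = sc_emp.weights.max() <= 1.0
    sc_n = sc_emp if normalized else normalize_sc(sc_emp)
    tgt = target_fc.values if isinstance(target_fc, FCMatrix) else np.asarray(target_fc)
    raw = _fit_batched(sc_n.weights[None], tgt[None], config, consts, hc)
    return _slice_result(raw, 0, config)


def fit_cohort(
    scs: Sequence[StructuralConnectome],
    target_fcs: Sequence[FCMatrix | np.ndarray],
    config: FitConfig,
    consts: BiophysicalConstants | None = None,
    hc: HemodynamicConstants | None = None,
) -> list[FitResult]:
    """Fit every subject of a cohort in one batched simulator loop.

    Subjects share the config (including the seed stream) but have
    independent parameters, connectomes and targets; results are identical in
    distribution to per-subject fits while amortizing the integration loop.
    """
    C = np.stack([
        (sc if sc.weights.max() <= 1.0 else normalize_sc(sc)).weights for sc in scs
    ])
    T = np.stack([
        fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, float)
        for fc in target_fcs
    ])
    if C.shape[0] != T.shape[0]:
        raise ValueError("need one target FC per subject")
    raw = _fit_batched(C, T, config, consts, hc)
    return [_slice_result(raw, b, config) for b in range(C.shape[0])]
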