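"""Balloon-Windkessel hemodynamic forward model: neural gating -> BOLD.

Per region, the excitatory gating variable E drives a vasodilatory signal s,
blood inflow f, venous volume v and deoxyhemoglobin content q:

    ds/dt = E - kappa*s - gamma_h*(f - 1)
    df/dt = s
    tau_h * dv/dt = f - v**(1/alpha)
    tau_h * dq/dt = f*(1 - (1-rho)**(1/f))/rho - v**(1/alpha - 1)*q

and the BOLD signal is read out as

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).

The baseline state (s, f, v, q) = (0, 1, 1, 1) is a fixed point under zero
neural input and yields y = 0. Hemodynamics are applied independently per
node (permutation-equivariant) at the neural integration step, then decimated
to the repetition time (TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import HemodynamicConstants
from .dynamics import NeuralTrajectory

__all__ = ["HemodynamicState", "BoldRecord", "bold_from_neural", "read_bold", "write_bold"]


@dataclass
class HemodynamicState:
    """Vasodilatory signal s, inflow f, volume v, deoxyhemoglobin q (per node)."""

    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.s, self.f, self.v, self.q = (
            np.asarray(x, dtype=float) for x in (self.s, self.f, self.v, self.q)
        )
        if np.any(self.f <= 0) or np.any(self.v <= 0) or np.any(self.q <= 0):
            raise ValueError("f, v and q must stay > 0")

    @classmethod
    def baseline(cls, shape) -> "HemodynamicState":
        return cls(np.zeros(shape), np.ones(shape), np.ones(shape), np.ones(shape))


@dataclass
class BoldRecord:
    """Region x time BOLD series sampled at repetition-time resolution."""

    tr: float
    series: np.ndarray  # (T, ..., N); leading time axis
    subject_id: str = ""
    labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.series.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.series.shape[-1]


def hemo_step(
    state: HemodynamicState,
    E: np.ndarray,
    dt: float,
    hc: HemodynamicConstants,
) -> HemodynamicState:
    """One explicit Euler step of the balloon equations driven by E."""
    s, f, v, q = state.s, state.f, state.v, state.q
    v1a = v ** (1.0 / hc.alpha)
    ef = -np.expm1(np.log1p(-hc.rho) / f)  # 1 - (1-rho)**(1/f)
    s_n = s + dt * (E - hc.kappa * s - hc.gamma_h * (f - 1.0))
    f_n = f + dt * s
    v_n = v + (dt / hc.tau_h) * (f - v1a)
    q_n = q + (dt / hc.tau_h) * (f * ef / hc.rho - v1a * q / v)
    return HemodynamicState(s_n, f_n, v_n, q_n)


def bold_readout(state: HemodynamicState, hc: HemodynamicConstants) -> np.ndarray:
    """Instantaneous BOLD signal from the volume/deoxyhemoglobin state."""
    v, q = state.v, state.q
    return hc.v0 * (hc.k1 * (1.0 - q) + hc.k2 * (1.0 - q / v) + hc.k3 * (1.0 - v))


def bold_from_neural(
    traj: NeuralTrajectory,
    tr: float,
    hc: HemodynamicConstants | None = None,
    initial: HemodynamicState | None = None,
    subject_id: str = "",
    return_state: bool = False,
):
    """Integrate the balloon model over a neural trajectory and sample at TR.

    ``tr`` must be an integer multiple of the neural integration step. The
    hemodynamics are integrated with deterministic Euler at the neural dt,
    driven by the excitatory gating E at each step start, and the BOLD signal
    is recorded every tr seconds (after the step completing each TR interval).
    Raises if v or q become non-positive, naming the offending time index.
    """
    hc = hc or HemodynamicConstants()
    dt = traj.dt
    k = tr / dt
    if abs(k - round(k)) > 1e-9:
        raise ValueError(f"tr={tr} must be an integer multiple of dt={dt}")
    k = int(round(k))
    n_steps = traj.n_steps
    state = initial or HemodynamicState.baseline(traj.E[0].shape)
    samples = []
    for t in range(n_steps):
        state = hemo_step(state, traj.E[t], dt, hc)
        if np.any(state.v <= 0) or np.any(state.q <= 0):
            raise FloatingPointError(
                f"balloon state v/q reached <= 0 at time index {t} (t={t * dt:.3f}s)"
            )
        if (t + 1) % k == 0:
            samples.append(bold_readout(state, hc))
    series = np.stack(samples) if samples else np.empty((0,) + traj.E[0].shape)
    rec = BoldRecord(tr=tr, series=series, subject_id=subject_id,
                     meta={"dt": dt, "hemodynamics": hc.to_dict()})
    return (rec, state) if return_state else rec


# ---------------------------------------------------------------------------
# text I/O: T x N delimited series with a header of region labels


def write_bold(path: str | Path, rec: BoldRecord, delimiter: str = "\t") -> None:
    import json

    path = Path(path)
    n = rec.n_nodes
    labels = rec.labels or [f"region_{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(delimiter.join(labels) + "\n")
        for row in rec.series.reshape(rec.n_samples, n):
            fh.write(delimiter.join(f"{v:.10g}" for v in row) + "\n")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump({"tr": rec.tr, "subject_id": rec.subject_id, **rec.meta}, fh, indent=2)


def read_bold(path: str | Path, tr: float | None = None) -> BoldRecord:
    import json

    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        delim = "," if "," in header else None
        labels = [t.strip() for t in header.split(delim)]
        series = np.loadtxt(fh, delimiter=delim, ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    if tr is None:
        tr = float(meta.get("tr", 1.0))
    return BoldRecord(tr=tr, series=series, labels=labels,
                      subject_id=str(meta.get("subject_id", "")), meta=meta)
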