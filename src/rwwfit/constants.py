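"""Fixed biophysical constants of the two-population reduced Wong-Wang model
and of the Balloon-Windkessel hemodynamic forward model.

The neural constants follow the canonical two-state derivation of the model
(Deco-lineage values); the hemodynamic constants are the standard resting-state
set. Every value can be overridden via the dataclass constructors or a config
mapping, and the values in force are echoed into all provenance output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class BiophysicalConstants:
    """Fixed parameters of the excitatory/inhibitory neural-mass node.

    Units: times in seconds, currents in nA, rates in Hz. ``sigma`` is the
    standard deviation of the additive white state noise (per sqrt(s));
    ``i_ext`` is external stimulation (0 at rest); ``lambda_ffi`` switches
    long-range feedforward inhibition (0 disables it).
    """

    tau_e: float = 0.1
    tau_i: float = 0.01
    gamma: float = 0.641
    a_e: float = 310.0
    b_e: float = 125.0
    d_e: float = 0.16
    a_i: float = 615.0
    b_i: float = 177.0
    d_i: float = 0.087
    i0: float = 0.382
    w_e: float = 1.0
    w_i: float = 0.7
    sigma: float = 0.01
    i_ext: float = 0.0
    lambda_ffi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_i", "a_e", "a_i", "d_e", "d_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.lambda_ffi <= 1.0:
            raise ValueError(f"lambda_ffi must lie in [0, 1], got {self.lambda_ffi}")

    def replace(self, **kw: Any) -> "BiophysicalConstants":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "BiophysicalConstants":
        return cls(**dict(d))


@dataclass(frozen=True)
class HemodynamicConstants:
    """Balloon-Windkessel parameters (canonical resting-state values).

    kappa: signal decay rate (1/s); gamma_h: flow-dependent elimination (1/s);
    tau_h: hemodynamic transit time (s); alpha: Grubb's vessel stiffness
    exponent; rho: resting oxygen extraction fraction; v0: resting venous
    blood volume fraction; k1..k3: BOLD signal weights (k1 = 7*rho,
    k3 = 2*rho - 0.2 at 1.5T convention).
    """

    kappa: float = 0.65
    gamma_h: float = 0.41
    tau_h: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    v0: float = 0.02
    k1: float = 7 * 0.34
    k2: float = 2.0
    k3: float = 2 * 0.34 - 0.2

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_h", "tau_h", "alpha", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie in (0, 1), got {self.rho}")

    def replace(self, **kw: Any) -> "HemodynamicConstants":
        return replace(self, **kw)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "HemodynamicConstants":
        return cls(**dict(d))
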