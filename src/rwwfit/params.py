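"""Trainable gain parameters of the three model variants.

The model exposes four synaptic gains: the long-range global coupling ``g``
(g = G * g_EI in the underlying notation), the within-node
excitatory-to-inhibitory gain ``g_EI`` (= J_nmda), the inhibitory-to-excitatory
feedback gain ``g_IE`` (= J_i) and the recurrent excitatory gain ``g_EE``
(= w+ * g_EI).

Variants:

* GM (globalized): the classical 4-parameter model; all gains scalar.
* LM (localized): ``g`` stays global while g_EI, g_IE, g_EE vary per node,
  giving 1 + 3N free parameters.
* CM (connectivity): scalar gains as in GM plus a trainable symmetric
  modification of the SC upper triangle in [0, 1], giving 4 + N(N-1)/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

VARIANTS = ("gm", "lm", "cm")

#: default initial gain values (scaled from the canonical parameterization;
#: the study does not state its initial values)
DEFAULT_GAINS = {"g": 0.5, "g_ei": 0.15, "g_ie": 1.0, "g_ee": 0.21}


def count_free_parameters(variant: str, n_nodes: int) -> int:
    """Number of optimized parameters for a variant at a given parcellation.

    GM -> 4; LM -> 1 + 3N; CM -> 4 + N(N-1)/2. For the 219-node cortical
    parcellation used in the reference analysis this gives 4, 658 and 23,875.
    """
    variant = variant.lower()
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2, got {n_nodes}")
    if variant == "gm":
        return 4
    if variant == "lm":
        return 1 + 3 * n_nodes
    if variant == "cm":
        return 4 + n_nodes * (n_nodes - 1) // 2
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


@dataclass
class GainParameters:
    """Trainable gain set; scalars for GM/CM, per-node vectors for LM.

    ``sc_mod`` is the CM's modifiable normalized adjacency (symmetric, zero
    diagonal, entries in [0, 1]); it is None for GM/LM.
    """

    variant: str
    g: float | np.ndarray
    g_ei: float | np.ndarray
    g_ie: float | np.ndarray
    g_ee: float | np.ndarray
    sc_mod: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variant = self.variant.lower()
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("g", "g_ei", "g_ie", "g_ee"):
            val = np.asarray(getattr(self, name), dtype=float)
            if np.any(val <= 0):
                raise ValueError(f"gain {name} must be > 0")
            setattr(self, name, float(val) if val.ndim == 0 else val)
        if self.variant == "lm":
            n = np.asarray(self.g_ei).shape
            for name in ("g_ei", "g_ie", "g_ee"):
                if np.asarray(getattr(self, name)).shape != n:
                    raise ValueError("LM per-node gain vectors must share one length")
        if self.variant == "cm":
            if self.sc_mod is None:
                raise ValueError("CM requires sc_mod")
            m = np.asarray(self.sc_mod, dtype=float)
            if not np.allclose(m, m.T, atol=1e-8):
                raise ValueError("sc_mod must be symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError("sc_mod diagonal must be zero")
            if m.min() < 0 or m.max() > 1:
                raise ValueError("sc_mod entries must lie in [0, 1]")
            self.sc_mod = (m + m.T) / 2.0
        elif self.sc_mod is not None:
            raise ValueError(f"sc_mod is only valid for the CM, not {self.variant}")

    @property
    def n_nodes(self) -> int | None:
        if self.variant == "lm":
            return int(np.asarray(self.g_ei).shape[0])
        if self.variant == "cm":
            return int(self.sc_mod.shape[0])
        return None

    @classmethod
    def defaults(
        cls,
        variant: str = "gm",
        n_nodes: int | None = None,
        sc_mod: np.ndarray | None = None,
    ) -> "GainParameters":
        """Canonical starting gains for a variant (LM broadcasts per node)."""
        variant = variant.lower()
        d = dict(DEFAULT_GAINS)
        if variant == "lm":
            if n_nodes is None:
                raise ValueError("LM defaults need n_nodes")
            for k in ("g_ei", "g_ie", "g_ee"):
                d[k] = np.full(n_nodes, d[k])
        if variant == "cm" and sc_mod is None:
            raise ValueError("CM defaults need the empirical normalized SC as sc_mod")
        return cls(variant=variant, sc_mod=sc_mod if variant == "cm" else None, **d)

    def to_dict(self) -> dict:
        out: dict = {"variant": self.variant}
        for name in ("g", "g_ei", "g_ie", "g_ee"):
            v = getattr(self, name)
            out[name] = v.tolist() if isinstance(v, np.ndarray) else v
        if self.sc_mod is not None:
            out["sc_mod"] = self.sc_mod.tolist()
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "GainParameters":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("g_ei", "g_ie", "g_ee", "g", "sc_mod"):
            if isinstance(d.get(k), list):
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)
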