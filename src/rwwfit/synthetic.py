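"""Synthetic cohorts for end-to-end testing without any data download.

The generator emulates the structure of a resting-state modelling study:

* sparse symmetric structural connectomes with heavy-tailed (lognormal)
  streamline weights, built as a random spanning tree (guaranteeing
  connectedness) plus random extra edges up to a target density;
* a cohort sharing a template connectome with per-subject multiplicative
  edge jitter — mimicking the high between-subject anatomical correlation of
  real cohorts, which is what makes FC fingerprinting non-trivial;
* ground-truth gain parameters drawn around the canonical defaults with
  between-subject jitter (per-node for the localized variant, per-edge
  coupling modifications for the connectivity variant);
* "empirical" target FC matrices produced by the forward model itself, with
  optional observation noise added on Fisher-z transformed off-diagonals and
  projected back to a symmetric positive semidefinite correlation matrix;
* phenotypes with configurable planted linear loadings on chosen gains.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjoint import ParamArrays, SimState, fc_loss_head, simulate_epoch
from .connectome import StructuralConnectome, laplacian_from_adjacency, normalize_sc
from .constants import BiophysicalConstants, HemodynamicConstants
from .fc_metrics import FCMatrix
from .hemodynamics import BoldRecord
from .params import DEFAULT_GAINS, GainParameters
from .phenotype_stats import PhenotypeTable

__all__ = ["SyntheticSubject", "SyntheticCohort", "generate_sc", "generate_cohort"]


@dataclass
class SyntheticSubject:
    subject_id: str
    sc: StructuralConnectome            # normalized (log1p + unit max), in [0, 1]
    sc_raw: StructuralConnectome        # raw streamline counts
    gains: GainParameters               # ground truth
    fc: FCMatrix                        # target FC (forward model + noise)
    bold: BoldRecord | None = None


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    phenotypes: PhenotypeTable
    seed: int
    config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def scs(self) -> list[StructuralConnectome]:
        return [s.sc for s in self.subjects]

    @property
    def fcs(self) -> list[FCMatrix]:
        return [s.fc for s in self.subjects]


def generate_sc(
    n_nodes: int,
    density: float = 0.35,
    seed: int | np.random.Generator | None = None,
    weight_mu: float = 3.0,
    weight_sigma: float = 1.0,
) -> StructuralConnectome:
    """Random connected SC with lognormal (heavy-tailed) streamline weights.

    A random spanning tree guarantees connectedness; extra edges are added
    uniformly at random until the requested fraction of all possible edges is
    reached. ``density=1`` yields the complete graph.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(n_nodes)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    w = np.zeros((n, n))
    order = rng.permutation(n)
    edges = set()
    for idx in range(1, n):  # random attachment spanning tree
        child = order[idx]
        parent = order[rng.integers(0, idx)]
        edges.add((min(child, parent), max(child, parent)))
    iu, ju = np.triu_indices(n, 1)
    target_edges = max(len(edges), int(round(density * len(iu))))
    candidates = [(int(a), int(b)) for a, b in zip(iu, ju) if (a, b) not in edges]
    rng.shuffle(candidates)
    for e in candidates[: target_edges - len(edges)]:
        edges.add(e)
    for a, b in edges:
        w[a, b] = w[b, a] = np.round(rng.lognormal(weight_mu, weight_sigma)) + 1.0
    return StructuralConnectome(w, meta={"density": density})


def _project_correlation(fc: np.ndarray) -> np.ndarray:
    """Nearest-ish valid correlation matrix: eigenvalue clip + diagonal rescale."""
    a = (fc + fc.T) / 2.0
    np.fill_diagonal(a, 1.0)
    vals, vecs = np.linalg.eigh(a)
    if vals.min() < 1e-10:
        vals = np.clip(vals, 1e-10, None)
        a = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
    a = np.clip((a + a.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return a


def _add_fc_noise(fc: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Observation noise on Fisher-z off-diagonals, then back-transform + project."""
    if noise_sd == 0:
        return _project_correlation(fc)
    n = fc.shape[0]
    iu, ju = np.triu_indices(n, 1)
    z = np.arctanh(np.clip(fc[iu, ju], -1 + 1e-9, 1 - 1e-9))
    z = z + rng.normal(0.0, noise_sd, z.shape)
    noisy = np.eye(n)
    noisy[iu, ju] = np.tanh(z)
    noisy = noisy + noisy.T - np.eye(n)
    return _project_correlation(noisy)


_PHENOTYPE_BASE = {
    "age": (35.0, 12.0), "bmi": (24.0, 3.5), "yos": (13.0, 3.0), "iq": (100.0, 15.0),
}


def _gain_summary(gains: GainParameters, name: str) -> float:
    if name == "sc_mod":
        iu, ju = np.triu_indices(gains.sc_mod.shape[0], 1)
        return float(gains.sc_mod[iu, ju].mean())
    return float(np.mean(np.asarray(getattr(gains, name), dtype=float)))


def generate_cohort(
    n_subjects: int,
    n_nodes: int,
    variant: str = "gm",
    noise_sd: float = 0.1,
    seed: int = 0,
    n_trs: int = 150,
    tr: float = 2.0,
    dt: float = 0.005,
    sigma: float = 0.01,
    density: float = 0.35,
    sc_jitter: float = 0.15,
    cm_jitter: float = 0.25,
    gain_jitter: float = 0.1,
    warmup_trs: int = 20,
    planted_loadings: dict | None = None,
    coupling_mode: str = "laplacian",
    keep_bold: bool = False,
    consts: BiophysicalConstants | None = None,
    hc: HemodynamicConstants | None = None,
) -> SyntheticCohort:
    """Generate a full synthetic cohort (SCs, gains, target FCs, phenotypes).

    ``variant`` selects where the ground-truth individuality lives: ``gm``
    jitters the four global gains per subject; ``lm`` additionally jitters
    the three local gains per node; ``cm`` jitters the coupling edges
    (sc_mod) around each subject's anatomical SC. ``planted_loadings`` maps a
    phenotype name to ``(gain_name, loading)``: the phenotype then loads
    linearly (with the stated standardized coefficient) on the z-scored
    between-subject summary of that gain, the remainder being Gaussian noise.
    ``noise_sd`` is the observation noise on Fisher-z FC off-diagonals.
    """
    variant = variant.lower()
    rng = np.random.default_rng(seed)
    consts = (consts or BiophysicalConstants()).replace(sigma=sigma)
    hc = hc or HemodynamicConstants()
    template = generate_sc(n_nodes, density=density, seed=rng)
    mask = template.weights > 0

    subjects_raw, subjects_norm, gains_list = [], [], []
    for _ in range(n_subjects):
        w = template.weights.copy()
        jit = np.exp(rng.normal(0.0, sc_jitter, w.shape))
        jit = np.triu(jit, 1)
        jit = jit + jit.T
        w[mask] = np.round(w[mask] * jit[mask]) + 1.0
        raw = StructuralConnectome(w)
        subjects_raw.append(raw)
        subjects_norm.append(normalize_sc(raw))

    def _jit(base: float, shape=None) -> float | np.ndarray:
        draw = rng.normal(0.0, gain_jitter, shape) if shape else rng.normal(0.0, gain_jitter)
        return base * np.exp(draw)

    for b in range(n_subjects):
        g = _jit(DEFAULT_GAINS["g"])
        if variant == "lm":
            gains = GainParameters(
                "lm", g=g, g_ei=_jit(DEFAULT_GAINS["g_ei"], (n_nodes,)),
                g_ie=_jit(DEFAULT_GAINS["g_ie"], (n_nodes,)),
                g_ee=_jit(DEFAULT_GAINS["g_ee"], (n_nodes,)))
        elif variant == "cm":
            base = subjects_norm[b].weights
            pert = base * np.exp(np.triu(rng.normal(0.0, cm_jitter, base.shape), 1))
            pert = np.triu(pert, 1)
            sc_mod = np.clip(pert + pert.T, 0.0, 1.0)
            gains = GainParameters(
                "cm", g=g, g_ei=_jit(DEFAULT_GAINS["g_ei"]),
                g_ie=_jit(DEFAULT_GAINS["g_ie"]), g_ee=_jit(DEFAULT_GAINS["g_ee"]),
                sc_mod=sc_mod)
        else:
            gains = GainParameters(
                "gm", g=g, g_ei=_jit(DEFAULT_GAINS["g_ei"]),
                g_ie=_jit(DEFAULT_GAINS["g_ie"]), g_ee=_jit(DEFAULT_GAINS["g_ee"]))
        gains_list.append(gains)

    # batched forward simulation of the whole cohort
    B, N = n_subjects, n_nodes

    def _arr(name):
        vals = [np.atleast_1d(np.asarray(getattr(g, name), dtype=float)) for g in gains_list]
        width = max(v.size for v in vals)
        return np.stack([np.broadcast_to(v, (width,)) for v in vals])

    C_model = (np.stack([g.sc_mod for g in gains_list]) if variant == "cm" else None)
    pa = ParamArrays(g=_arr("g"), g_ei=_arr("g_ei"), g_ie=_arr("g_ie"),
                     g_ee=_arr("g_ee"), C=C_model)
    if C_model is None:
        C_anat = np.stack([s.weights for s in subjects_norm])
        L = laplacian_from_adjacency(C_anat) if coupling_mode == "laplacian" else C_anat
    else:
        L = None
    k = int(round(tr / dt))
    state = SimState.initial((B, N))
    if warmup_trs > 0:
        _, state, _ = simulate_epoch(
            state, pa, consts, hc, L, dt, warmup_trs * k, sample_every=warmup_trs * k,
            rng=rng, sigma=sigma, coupling_mode=coupling_mode, with_cache=False)
    bold, state, _ = simulate_epoch(
        state, pa, consts, hc, L, dt, n_trs * k, sample_every=k,
        rng=rng, sigma=sigma, coupling_mode=coupling_mode, with_cache=False)
    _, fc_clean, _ = fc_loss_head(bold, np.broadcast_to(np.eye(N), (B, N, N)))

    subjects = []
    for b in range(n_subjects):
        fc_vals = _add_fc_noise(fc_clean[b], noise_sd, rng)
        rec = None
        if keep_bold:
            rec = BoldRecord(tr=tr, series=bold[b], subject_id=f"sub-{b:03d}")
        subjects.append(SyntheticSubject(
            subject_id=f"sub-{b:03d}", sc=subjects_norm[b], sc_raw=subjects_raw[b],
            gains=gains_list[b], fc=FCMatrix(fc_vals, subject_id=f"sub-{b:03d}"),
            bold=rec))

    # phenotypes with planted loadings on gain summaries
    planted = {} if planted_loadings is None else dict(planted_loadings)
    pheno = {
        "subject_id": [s.subject_id for s in subjects],
        "timepoint": [1] * n_subjects,
        "gender": rng.choice(["f", "m"], n_subjects).tolist(),
        "site": rng.choice(["site_a", "site_b"], n_subjects).tolist(),
    }
    for name, (mu, sd) in _PHENOTYPE_BASE.items():
        if name in planted:
            gain_name, loading = planted[name]
            summ = np.array([_gain_summary(g, gain_name) for g in gains_list])
            zs = (summ - summ.mean()) / (summ.std() if summ.std() > 0 else 1.0)
            vals = mu + sd * (loading * zs
                              + np.sqrt(max(1.0 - loading**2, 0.0))
                              * rng.standard_normal(n_subjects))
        else:
            vals = rng.normal(mu, sd, n_subjects)
        pheno[name] = vals
    table = PhenotypeTable(pd.DataFrame(pheno))
    config = {
        "n_subjects": n_subjects, "n_nodes": n_nodes, "variant": variant,
        "noise_sd": noise_sd, "n_trs": n_trs, "tr": tr, "dt": dt, "sigma": sigma,
        "density": density, "sc_jitter": sc_jitter, "cm_jitter": cm_jitter,
        "gain_jitter": gain_jitter,
        "warmup_trs": warmup_trs, "planted": {k: list(v) for k, v in planted.items()},
        "coupling_mode": coupling_mode,
    }
    return SyntheticCohort(subjects=subjects, phenotypes=table, seed=seed, config=config)
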