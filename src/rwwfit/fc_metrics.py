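"""Functional-connectivity metrics: FC computation, goodness-of-fit,
explained variance, cohort baselines, SC anchoring, and subject
identification (FC fingerprinting).

Goodness-of-fit between two FC matrices is the Pearson correlation of their
strictly-upper triangles (the diagonal is excluded); explained variance is
100 * r^2. Fingerprinting ranks, for each subject's simulated FC, all
empirical FCs by this correlation and scores the fraction of subjects whose
own empirical FC lands in the top k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import BoldRecord

__all__ = [
    "FCMatrix",
    "IdentificationReport",
    "compute_fc",
    "fc_fit",
    "explained_variance",
    "mean_fc_baseline",
    "sc_anchor_correlation",
    "identify_subjects",
    "chance_topk",
]


@dataclass
class FCMatrix:
    """Symmetric correlation matrix with unit diagonal, entries in [-1, 1]."""

    values: np.ndarray
    labels: list[str] | None = None
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"FC must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("FC must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("FC diagonal must be 1")
        if v.min() < -1 - 1e-8 or v.max() > 1 + 1e-8:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.values, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n_nodes, 1)
        return self.values[iu, ju]


@dataclass
class IdentificationReport:
    """Fingerprinting outcome: per-subject rank of the true match and top-k rates."""

    n_subjects: int
    top1: float
    top3: float
    top5: float
    rank_list: list[int]
    tie_warnings: int = 0

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "top1": self.top1,
            "top3": self.top3,
            "top5": self.top5,
            "rank_list": list(self.rank_list),
            "tie_warnings": self.tie_warnings,
        }


def _as_values(fc) -> np.ndarray:
    return fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)


def compute_fc(bold: BoldRecord | np.ndarray) -> FCMatrix:
    """Pairwise Pearson correlation of regional BOLD series across time.

    Raises if any region's series is constant (its correlations are
    undefined), naming the region.
    """
    series = bold.series if isinstance(bold, BoldRecord) else np.asarray(bold, float)
    if series.ndim != 2:
        raise ValueError("BOLD series must be a T x N matrix")
    T, _n = series.shape
    if T < 2:
        raise ValueError("need at least 2 time points for FC")
    sd = series.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.nonzero(sd == 0)[0][0])
        labels = getattr(bold, "labels", None)
        name = labels[bad] if labels else f"region {bad}"
        raise ValueError(f"constant BOLD series for {name}; correlation undefined")
    vals = np.corrcoef(series, rowvar=False)
    np.fill_diagonal(vals, 1.0)
    return FCMatrix(
        np.clip(vals, -1, 1),
        labels=getattr(bold, "labels", None),
        subject_id=getattr(bold, "subject_id", ""),
    )


def fc_fit(sim: FCMatrix | np.ndarray, emp: FCMatrix | np.ndarray) -> float:
    """Pearson r between the strictly-upper triangles of two FC matrices."""
    a, b = _as_values(sim), _as_values(emp)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("FC goodness-of-fit needs at least 3 nodes")
    iu, ju = np.triu_indices(n, 1)
    return float(np.corrcoef(a[iu, ju], b[iu, ju])[0, 1])


def explained_variance(sim, emp) -> float:
    """Squared upper-triangle Pearson correlation, as a percentage."""
    r = fc_fit(sim, emp)
    return 100.0 * r * r


def mean_fc_baseline(fcs: list) -> tuple[FCMatrix, list[float]]:
    """Cohort-mean FC and each subject's explained variance against it.

    The mean is entrywise over subjects with the diagonal reset to 1 (the
    diagonal is excluded from upper-triangle metrics regardless).
    """
    if len(fcs) < 2:
        raise ValueError("mean-FC baseline needs at least 2 subjects")
    mats = [_as_values(fc) for fc in fcs]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all FC matrices must share dimensions")
    mean = np.mean(mats, axis=0)
    np.fill_diagonal(mean, 1.0)
    mean_fc = FCMatrix(np.clip(mean, -1, 1))
    return mean_fc, [explained_variance(mean_fc, m) for m in mats]


def sc_anchor_correlation(sc_mod: np.ndarray, sc_emp: np.ndarray) -> float:
    """Edgewise Pearson r between modified and empirical SC upper triangles."""
    a, b = np.asarray(sc_mod, float), np.asarray(sc_emp, float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    iu, ju = np.triu_indices(a.shape[0], 1)
    return float(np.corrcoef(a[iu, ju], b[iu, ju])[0, 1])


def _upper_stack(fcs: list) -> np.ndarray:
    mats = [_as_values(fc) for fc in fcs]
    n = mats[0].shape[0]
    iu, ju = np.triu_indices(n, 1)
    return np.stack([m[iu, ju] for m in mats])


def identify_subjects(sims: list, emps: list) -> IdentificationReport:
    """Match each simulated FC against every empirical FC by upper-triangle r.

    Subject order must be aligned between the lists. For subject i the rank
    of the true match is 1 + (number of empirical FCs correlating strictly
    better than subject i's own) + (ties held by lower-indexed subjects);
    ties are therefore broken deterministically by subject index. Emits a
    warning count when duplicate empirical matrices make ties inevitable.
    """
    if len(sims) != len(emps):
        raise ValueError("sims and emps must have equal length")
    n = len(sims)
    if n < 1:
        raise ValueError("empty cohort")
    S = _upper_stack(sims)
    Emp = _upper_stack(emps)
    Sz = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    Ez = (Emp - Emp.mean(1, keepdims=True)) / Emp.std(1, keepdims=True)
    R = Sz @ Ez.T / S.shape[1]  # R[i, j] = r(sim_i, emp_j)
    ties = 0
    ranks = []
    for i in range(n):
        row = R[i]
        true_r = row[i]
        better = int(np.sum(row > true_r))
        tied = np.nonzero(row == true_r)[0]
        if len(tied) > 1:
            ties += 1
        rank = 1 + better + int(np.sum(tied < i))
        ranks.append(rank)
    ranks_arr = np.asarray(ranks)
    return IdentificationReport(
        n_subjects=n,
        top1=float(np.mean(ranks_arr <= 1)),
        top3=float(np.mean(ranks_arr <= 3)),
        top5=float(np.mean(ranks_arr <= 5)),
        rank_list=ranks,
        tie_warnings=ties,
    )


def chance_topk(k: int, n: int) -> float:
    """Chance level (in %) of the true subject landing in the top k of n."""
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    return 100.0 * k / n
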