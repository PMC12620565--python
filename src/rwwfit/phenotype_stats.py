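"""Univariate association statistics between fitted model parameters (or FC
edges) and phenotypes.

For each feature, a continuous target (age, BMI, years of schooling, IQ) is
modeled by OLS of the z-scored target on the z-scored feature plus covariates
of no interest; the binary target (gender) is modeled by ANOVA with the same
covariates, with effect size reported as partial eta-squared. P values are
corrected across features by the Benjamini-Yekutieli FDR procedure at
q < 0.05, effect sizes of the strongest feature carry stratified BCa
bootstrap confidence intervals, and the predictive value of that feature is
summarized by a deconfounded logistic AUROC (binary targets) or MAE / MAD /
Spearman / Pearson of a single-predictor regression (continuous targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "PhenotypeTable",
    "AssociationResult",
    "ols_effect",
    "anova_partial_eta2",
    "fdr_by",
    "deconfound",
    "auroc_from_residuals",
    "bca_ci",
    "mass_univariate",
]

CONTINUOUS_TARGETS = ("age", "bmi", "yos", "iq")
BINARY_TARGETS = ("gender",)


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes: subject id, gender, age, BMI, YoS, IQ, site.

    One row per sample; a subject may appear at several timepoints but each
    (subject, timepoint) pair at most once.
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "gender", "age", "bmi", "yos", "iq", "site")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        key_cols = ["subject_id"]
        if "timepoint" in self.data.columns:
            key_cols.append("timepoint")
        if self.data.duplicated(subset=key_cols).any():
            raise ValueError("duplicated subject-timepoint rows in phenotype table")

    def __len__(self) -> int:
        return len(self.data)

    def first_timepoint(self) -> "PhenotypeTable":
        """One row per subject (earliest timepoint) — leakage guard for ML export."""
        df = self.data
        if "timepoint" in df.columns:
            df = df.sort_values("timepoint").drop_duplicates("subject_id")
        else:
            df = df.drop_duplicates("subject_id")
        return PhenotypeTable(df.reset_index(drop=True))

    @classmethod
    def read_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class AssociationResult:
    """One feature-target association with corrected p and effect size CI."""

    predictor: str
    target: str
    p_uncorrected: float
    p_corrected: float
    effect_size: float
    effect_kind: str  # "standardized_beta" | "partial_eta2"
    effect_ci: tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    return np.column_stack([np.ones(n), cov])


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def ols_effect(
    target: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Standardized beta and two-sided p of a predictor in a covariate-adjusted OLS.

    Target and predictor are z-scored before the fit, so the coefficient is
    the standardized beta (invariant to affine rescaling of either raw
    variable).
    """
    y = _zscore(target)
    x = _zscore(predictor)
    X = np.column_stack([_design(covariates, len(y)), x])
    res = sm.OLS(y, X).fit()
    return float(res.params[-1]), float(res.pvalues[-1])


def anova_partial_eta2(
    target_group: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial eta-squared and F-test p of a binary group factor.

    eta^2_p = SS_group / (SS_group + SS_residual) from the covariate-adjusted
    model, with SS_group the reduction in residual sum of squares when the
    group factor enters a model already containing the covariates.
    """
    y = np.asarray(outcome, dtype=float)
    grp = np.asarray(target_group)
    codes = pd.factorize(grp)[0].astype(float)
    if len(np.unique(codes)) != 2:
        raise ValueError("target_group must be binary")
    X0 = _design(covariates, len(y))
    X1 = np.column_stack([X0, codes])
    r0 = sm.OLS(y, X0).fit()
    r1 = sm.OLS(y, X1).fit()
    ss_group = float(r0.ssr - r1.ssr)
    ss_res = float(r1.ssr)
    if ss_group + ss_res == 0:
        return 0.0, 1.0
    eta2 = ss_group / (ss_group + ss_res)
    df_res = int(r1.df_resid)
    if ss_res == 0:
        return 1.0, 0.0
    F = (ss_group / 1.0) / (ss_res / df_res)
    p = float(stats.f.sf(F, 1, df_res))
    return float(eta2), p


def fdr_by(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up FDR: corrected p values and rejection mask.

    Uses the harmonic-sum correction c(m) = sum_{i<=m} 1/i; corrected p
    values are monotone and capped at 1 (so p_corrected >= p_uncorrected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_corr, _, _ = multipletests(p, alpha=q, method="fdr_by")
    return p_corr, reject


def deconfound(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of OLS of ``values`` on covariates plus intercept.

    The residuals are orthogonal to every covariate column (and centered).
    """
    y = np.asarray(values, dtype=float)
    X = _design(covariates, len(y))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def auroc_from_residuals(residual_predictor: np.ndarray, group_labels: np.ndarray) -> float:
    """AUROC of a logistic fit on one deconfounded predictor.

    Equals the Mann-Whitney concordance of the predictor scores because the
    single-predictor logistic map is monotone.
    """
    x = np.asarray(residual_predictor, dtype=float)[:, None]
    y = pd.factorize(np.asarray(group_labels))[0]
    if len(np.unique(y)) != 2:
        raise ValueError("group_labels must be binary")
    clf = LogisticRegression(solver="lbfgs").fit(x, y)
    probs = clf.predict_proba(x)[:, 1]
    return float(roc_auc_score(y, probs))


def bca_ci(
    statistic,
    data,
    n_boot: int = 2000,
    seed: int | None = None,
    stratify_by: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI, with group stratification.

    ``data`` is an array (or tuple of aligned arrays) resampled by row index;
    ``statistic`` maps the resampled data to a scalar. With ``stratify_by``,
    resampling is done within each stratum, preserving group sizes. The bias
    correction z0 comes from the fraction of bootstrap estimates below the
    point estimate; the acceleration from the jackknife skewness. Degenerate
    bootstrap distributions collapse to the point estimate (c, c).
    """
    arrays = data if isinstance(data, (tuple, list)) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must share length")
    rng = np.random.default_rng(seed)

    def _stat(idx):
        return float(statistic(*(a[idx] for a in arrays)))

    theta_hat = _stat(np.arange(n))
    if stratify_by is not None:
        strata = [np.nonzero(np.asarray(stratify_by) == g)[0]
                  for g in pd.unique(np.asarray(stratify_by))]
    else:
        strata = [np.arange(n)]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([s[rng.integers(0, len(s), len(s))] for s in strata])
        boots[b] = _stat(idx)
    if np.allclose(boots, boots[0]):
        return theta_hat, theta_hat
    # bias correction
    prop = np.mean(boots < theta_hat) + 0.5 * np.mean(boots == theta_hat)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(prop)
    # jackknife acceleration
    jack = np.empty(n)
    all_idx = np.arange(n)
    for i in range(n):
        jack[i] = _stat(np.delete(all_idx, i))
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    out = []
    for z_alpha in (stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)):
        adj = z0 + (z0 + z_alpha) / (1.0 - a * (z0 + z_alpha))
        out.append(float(np.quantile(boots, stats.norm.cdf(adj))))
    return out[0], out[1]


def _covariate_matrix(pheno: pd.DataFrame, exclude: str) -> np.ndarray | None:
    """age, gender, site covariates, minus the target itself."""
    cols = []
    if exclude != "age":
        cols.append(np.asarray(pheno["age"], dtype=float))
    if exclude != "gender":
        cols.append(pd.factorize(pheno["gender"])[0].astype(float))
    if exclude != "site":
        cols.append(pd.factorize(pheno["site"])[0].astype(float))
    return np.column_stack(cols) if cols else None


def mass_univariate(
    features: np.ndarray | pd.DataFrame,
    phenotypes: PhenotypeTable,
    q: float = 0.05,
    targets: tuple[str, ...] = BINARY_TARGETS + CONTINUOUS_TARGETS,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, list[AssociationResult]]:
    """Feature-by-feature association screening for every target.

    Per target: each feature enters its own covariate-adjusted model (ANOVA
    for gender, OLS for continuous targets; covariates age / gender / site
    minus the target itself); BY-FDR corrects across features within the
    target. The strongest feature additionally gets a stratified BCa CI on
    its effect size and single-predictor prediction summaries: deconfounded
    logistic AUROC for gender; MAE, MAD, Spearman and Pearson of a
    single-predictor regression on the deconfounded target otherwise.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"feature_{j}" for j in range(X.shape[1])]
    df = phenotypes.data
    if len(df) != X.shape[0]:
        raise ValueError("features and phenotypes must have equal row counts")
    results: dict[str, list[AssociationResult]] = {}
    for target in targets:
        cov = _covariate_matrix(df, exclude=target)
        rows: list[AssociationResult] = []
        for j in range(X.shape[1]):
            feat = X[:, j]
            if target in BINARY_TARGETS:
                eff, p = anova_partial_eta2(df[target].to_numpy(), feat, cov)
                kind = "partial_eta2"
            else:
                eff, p = ols_effect(df[target].to_numpy(dtype=float), feat, cov)
                kind = "standardized_beta"
            rows.append(AssociationResult(
                predictor=names[j], target=target, p_uncorrected=p,
                p_corrected=np.nan, effect_size=eff, effect_kind=kind))
        p_corr, reject = fdr_by(np.array([r.p_uncorrected for r in rows]), q=q)
        for r, pc, rej in zip(rows, p_corr, reject):
            r.p_corrected = float(pc)
            r.extras["rejected"] = bool(rej)
        best = int(np.argmax([abs(r.effect_size) for r in rows]))
        rbest = rows[best]
        feat = X[:, best]
        y = df[target].to_numpy()
        strat = pd.factorize(df[target])[0] if target in BINARY_TARGETS else None
        if target in BINARY_TARGETS:
            rbest.effect_ci = bca_ci(
                lambda f, g: anova_partial_eta2(g, f, None)[0],
                (feat, y), n_boot=n_boot, seed=seed, stratify_by=strat)
            resid = deconfound(feat, cov)
            rbest.extras["auroc"] = auroc_from_residuals(resid, y)
        else:
            yv = y.astype(float)
            rbest.effect_ci = bca_ci(
                lambda f, t: ols_effect(t, f, None)[0],
                (feat, yv), n_boot=n_boot, seed=seed)
            y_dec = deconfound(yv, cov) + yv.mean()
            Xp = np.column_stack([np.ones(len(feat)), feat])
            beta, *_ = np.linalg.lstsq(Xp, y_dec, rcond=None)
            pred = Xp @ beta
            err = y_dec - pred
            rbest.extras.update({
                "mae": float(np.mean(np.abs(err))),
                "mad": float(np.median(np.abs(err - np.median(err)))),
                "spearman": float(stats.spearmanr(pred, y_dec).statistic),
                "pearson": float(stats.pearsonr(pred, y_dec).statistic),
            })
        results[target] = rows
    return results


def association_frame(results: dict[str, list[AssociationResult]]) -> pd.DataFrame:
    """Flatten mass-univariate results into a tidy table (CSV-ready)."""
    recs = []
    for target, rows in results.items():
        for r in rows:
            recs.append({
                "target": target, "predictor": r.predictor,
                "p_uncorrected": r.p_uncorrected, "p_corrected": r.p_corrected,
                "effect_size": r.effect_size, "effect_kind": r.effect_kind,
                "ci_low": r.effect_ci[0] if r.effect_ci else np.nan,
                "ci_high": r.effect_ci[1] if r.effect_ci else np.nan,
                **{k: v for k, v in r.extras.items() if np.isscalar(v)},
            })
    return pd.DataFrame.from_records(recs)
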