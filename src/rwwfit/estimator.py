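"""scikit-learn style estimator facade over the fitting engine.

``WholeBrainModel`` follows the sklearn estimator contract (constructor
stores hyperparameters verbatim, ``fit`` validates and sets trailing-
underscore attributes, ``get_params``/``set_params`` work with model
selection tools), so it composes with ``GridSearchCV``-style machinery when
the FC target is treated as the regression target.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .connectome import StructuralConnectome, normalize_sc
from .constants import BiophysicalConstants, HemodynamicConstants
from .fc_metrics import FCMatrix, fc_fit
from .fitting import FitConfig, fit as _fit_fn
from .params import DEFAULT_GAINS

__all__ = ["WholeBrainModel"]


class WholeBrainModel(BaseEstimator):
    """Connectome-based neural-mass model fitted to an FC target by gradient descent.

    Parameters mirror :class:`rwwfit.fitting.FitConfig`. ``fit(X, y)`` takes
    the subject's structural connectome as ``X`` (N x N weights, raw counts
    or normalized) and the empirical FC matrix as ``y``.

    Attributes set by ``fit`` (sklearn convention, trailing underscore):

    - ``gains_`` — fitted :class:`rwwfit.params.GainParameters`;
    - ``sc_mod_`` — fitted modifiable SC (CM only, else None);
    - ``loss_trace_`` — per-epoch loss / fc_fit records;
    - ``fc_`` — FC of the final evaluation simulation;
    - ``fc_fit_`` — its upper-triangle correlation with the target;
    - ``n_features_in_`` — number of regions N.
    """

    def __init__(
        self,
        variant: str = "gm",
        epochs: int = 500,
        warmup_epochs: int = 20,
        epoch_trs: int = 50,
        tr: float = 2.0,
        dt: float = 0.005,
        learning_rate: float = 0.05,
        lr_decay: float = 0.995,
        lambda_cm: float = 0.5,
        lambda_lm: float = 0.05,
        sigma: float = 0.01,
        eval_trs: int = 150,
        coupling_mode: str = "laplacian",
        trainable: tuple | None = None,
        init_gains: dict | None = None,
        random_state: int = 0,
    ):
        self.variant = variant
        self.epochs = epochs
        self.warmup_epochs = warmup_epochs
        self.epoch_trs = epoch_trs
        self.tr = tr
        self.dt = dt
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.lambda_cm = lambda_cm
        self.lambda_lm = lambda_lm
        self.sigma = sigma
        self.eval_trs = eval_trs
        self.coupling_mode = coupling_mode
        self.trainable = trainable
        self.init_gains = init_gains
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            variant=self.variant, epochs=self.epochs,
            warmup_epochs=self.warmup_epochs, epoch_trs=self.epoch_trs,
            tr=self.tr, dt=self.dt, learning_rate=self.learning_rate,
            lr_decay=self.lr_decay, lambda_cm=self.lambda_cm,
            lambda_lm=self.lambda_lm, sigma=self.sigma, seed=self.random_state,
            eval_trs=self.eval_trs, coupling_mode=self.coupling_mode,
            trainable=tuple(self.trainable) if self.trainable else None,
            init_gains=dict(self.init_gains or DEFAULT_GAINS),
        )

    def fit(self, X, y, consts: BiophysicalConstants | None = None,
            hc: HemodynamicConstants | None = None):
        sc = X if isinstance(X, StructuralConnectome) else StructuralConnectome(np.asarray(X, float))
        if sc.weights.max() > 1.0:
            sc = normalize_sc(sc)
        target = y if isinstance(y, FCMatrix) else FCMatrix(np.asarray(y, float))
        result = _fit_fn(sc, target, self._config(), consts=consts, hc=hc,
                         normalized=True)
        self.gains_ = result.final_params
        self.sc_mod_ = result.final_params.sc_mod
        self.loss_trace_ = result.loss_trace
        self.fc_ = result.final_fc
        self.fc_fit_ = fc_fit(result.final_fc, target)
        self.clamp_events_ = result.clamp_events
        self.sc_anchor_r_ = result.sc_anchor_r
        self.result_ = result
        self.n_features_in_ = sc.n_nodes
        return self

    def predict(self, X=None) -> np.ndarray:
        """Simulated FC of the fitted model (the final evaluation run)."""
        self._check_fitted()
        return self.fc_.values

    def score(self, X=None, y=None) -> float:
        """Upper-triangle Pearson r between the fitted FC and ``y``.

        With ``y=None`` the fit target's score recorded during ``fit`` is
        returned.
        """
        self._check_fitted()
        if y is None:
            return self.fc_fit_
        return fc_fit(self.fc_, y if isinstance(y, FCMatrix) else np.asarray(y))

    def _check_fitted(self) -> None:
        if not hasattr(self, "gains_"):
            raise AttributeError("this WholeBrainModel instance is not fitted yet")
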