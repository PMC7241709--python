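"""Scikit-learn-style estimators wrapping the ASO-tuned ANFIS.

:class:`ASOANFISRegressor` is the core model: a Takagi-Sugeno fuzzy rule
system whose bell memberships and linear consequents are tuned jointly by
atom search optimisation against a hold-out validation RMSE.
:class:`ASOANFISClassifier` stacks one indicator-target regressor per class
(one-vs-rest) and predicts by argmax, which is how a fuzzy regressor yields
a thematic map.  Both follow the sklearn estimator contract (get_params /
set_params, fitted attributes with trailing underscores) and compose with
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .anfis import AnfisConfig, predict_batch
from .aso import fit_asoanfis_arrays
from .evaluation import split_holdout

__all__ = ["ASOANFISRegressor", "ASOANFISClassifier"]


class ASOANFISRegressor(RegressorMixin, BaseEstimator):
    """ASO-tuned adaptive neuro-fuzzy regressor.

    Parameters
    ----------
    n_rules : number of fuzzy rules (= clusters) in the rule base.
    n_atoms, n_iterations : population size and iteration budget of the
        atom search.
    validation_fraction : share of the training rows held out internally as
        the optimisation target when no explicit validation set is passed
        to :meth:`fit`.
    mode : ASO dynamics, ``"adaptive"`` (default) or ``"literal"``.
    random_state : seed for the split, the warm start and the search.

    Attributes
    ----------
    params_ : fitted :class:`~asoanfis.anfis.AnfisParameters`.
    history_ : best validation RMSE per search iteration (non-increasing).
    n_features_in_ : number of input features seen during fit.
    """

    def __init__(
        self,
        n_rules: int = 5,
        n_atoms: int = 30,
        n_iterations: int = 200,
        validation_fraction: float = 0.3,
        mode: str = "adaptive",
        stop_threshold: float | None = None,
        polish: str = "deep",
        n_hops: int = 20,
        random_state: int | None = None,
    ):
        self.n_rules = n_rules
        self.n_atoms = n_atoms
        self.n_iterations = n_iterations
        self.validation_fraction = validation_fraction
        self.mode = mode
        self.stop_threshold = stop_threshold
        self.polish = polish
        self.n_hops = n_hops
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(X, y, y_numeric=True)
        if X_val is None:
            split = split_holdout(len(y), 1.0 - self.validation_fraction, self.random_state)
            X_tr, y_tr = X[split.train_idx], y[split.train_idx]
            X_va, y_va = X[split.val_idx], y[split.val_idx]
        else:
            X_tr, y_tr = X, y
            X_va = check_array(X_val)
            y_va = np.asarray(y_val, float)
        cfg = AnfisConfig(n_features=X.shape[1], n_rules=self.n_rules)
        self.params_, self.history_ = fit_asoanfis_arrays(
            X_tr,
            y_tr,
            X_va,
            y_va,
            anfis_cfg=cfg,
            n_atoms=self.n_atoms,
            n_iterations=self.n_iterations,
            seed=self.random_state,
            mode=self.mode,
            stop_threshold=self.stop_threshold,
            polish=self.polish,
            n_hops=self.n_hops,
        )
        self.config_ = cfg
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return predict_batch(X, self.params_, self.config_)


class ASOANFISClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-rest ANFIS classification by indicator regression.

    One :class:`ASOANFISRegressor` is fitted per class on a 0/1 indicator
    target; prediction takes the class whose regressor scores highest, ties
    resolved toward the lowest class code.
    """

    def __init__(
        self,
        n_rules: int = 3,
        n_atoms: int = 20,
        n_iterations: int = 60,
        validation_fraction: float = 0.3,
        polish: str = "light",
        random_state: int | None = None,
    ):
        self.n_rules = n_rules
        self.n_atoms = n_atoms
        self.n_iterations = n_iterations
        self.validation_fraction = validation_fraction
        self.polish = polish
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        self.estimators_ = []
        for ci, cls in enumerate(self.classes_):
            reg = ASOANFISRegressor(
                n_rules=self.n_rules,
                n_atoms=self.n_atoms,
                n_iterations=self.n_iterations,
                validation_fraction=self.validation_fraction,
                polish=self.polish,
                random_state=None if self.random_state is None else self.random_state + ci,
            )
            reg.fit(X, (y == cls).astype(float))
            self.estimators_.append(reg)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        return np.column_stack([est.predict(X) for est in self.estimators_])

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]  # argmax -> lowest on ties
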