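"""Least-squares reconstruction of the 12 standard leads from 3 patch leads.

The personalized linear model is ``Y = α·X + β`` with α a 12×3 coefficient
matrix and β a 12-vector of intercepts, fitted per subject on the training
half of a short simultaneous recording and applied sample-by-sample.  It is
exact when the body acts as a linear, quasi-stationary volume conductor.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, MultiOutputMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .records import MultiLeadRecord, STANDARD_LEADS


class LinearLeadTransform(MultiOutputMixin, RegressorMixin, BaseEstimator):
    """Per-lead affine map from patch samples to target-lead samples.

    Parameters
    ----------
    ridge : float, default 0.0
        Optional Tikhonov penalty on α (0 reproduces plain least squares).

    Attributes
    ----------
    coef_ : ndarray (n_targets, n_inputs)
        The transformation matrix α.
    intercept_ : ndarray (n_targets,)
        The affine term β in μV.
    n_samples_ : int
        Number of training samples.

    Each target lead is an independent regression; stacking them reproduces
    the single multivariate least-squares optimum.  Rank-deficient designs
    get the minimum-norm solution (with a warning) rather than an error.
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, p = X.shape
        if n < p + 1:
            raise ValueError(f"need at least {p + 1} samples, got {n}")
        if np.ptp(X, axis=0).max() == 0.0:
            raise ValueError("all patch channels are constant")
        # centered solve keeps the intercept exact and the design well-scaled
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc = X - x_mean
        Yc = Y - y_mean
        if self.ridge > 0.0:
            A = Xc.T @ Xc + self.ridge * np.eye(p)
            coef = np.linalg.solve(A, Xc.T @ Yc).T
        else:
            coef, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
            coef = coef.T
            if rank < p:
                import warnings
                warnings.warn("rank-deficient patch design; "
                              "minimum-norm least-squares solution returned",
                              RuntimeWarning)
        self.coef_ = coef
        self.intercept_ = y_mean - coef @ x_mean
        self.n_samples_ = n
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        out = X @ self.coef_.T + self.intercept_
        return out[:, 0] if out.shape[1] == 1 else out


def fit_transform_matrix(train_patch: MultiLeadRecord,
                         train_target: MultiLeadRecord,
                         ridge: float = 0.0) -> LinearLeadTransform:
    """Fit α, β on a training segment of a paired recording."""
    model = LinearLeadTransform(ridge=ridge)
    model.fit(train_patch.data, train_target.data)
    model.lead_names_ = tuple(train_target.lead_names)
    model.subject_ = train_target.subject
    return model


def apply_transform(model: LinearLeadTransform,
                    patch: MultiLeadRecord) -> MultiLeadRecord:
    """Reconstruct the 12 target leads for a patch record, sample by sample."""
    check_is_fitted(model, "coef_")
    if patch.n_leads != model.n_features_in_:
        raise ValueError(f"model expects {model.n_features_in_} patch leads, "
                         f"record has {patch.n_leads}")
    data = model.predict(patch.data)
    if data.ndim == 1:
        data = data[:, None]
    names = getattr(model, "lead_names_", STANDARD_LEADS[:data.shape[1]])
    return MultiLeadRecord(lead_names=names, fs=patch.fs, data=data,
                           subject=patch.subject)


def transform_to_json(model: LinearLeadTransform) -> str:
    check_is_fitted(model, "coef_")
    names = getattr(model, "lead_names_", STANDARD_LEADS)
    d = {
        "schema": "patchlead.transform.v1",
        "subject": getattr(model, "subject_", ""),
        "n_samples": int(model.n_samples_),
        "alpha": {name: [float(v) for v in row]
                  for name, row in zip(names, model.coef_)},
        "beta": {name: float(b)
                 for name, b in zip(names, model.intercept_)},
    }
    return json.dumps(d, indent=1, sort_keys=True)


def transform_from_json(text: str) -> LinearLeadTransform:
    d = json.loads(text)
    names = tuple(d["alpha"].keys())
    # preserve standard ordering when all 12 leads are present
    if set(names) == set(STANDARD_LEADS):
        names = STANDARD_LEADS
    model = LinearLeadTransform()
    model.coef_ = np.array([d["alpha"][n] for n in names])
    model.intercept_ = np.array([d["beta"][n] for n in names])
    model.n_samples_ = int(d["n_samples"])
    model.n_features_in_ = model.coef_.shape[1]
    model.lead_names_ = names
    model.subject_ = d.get("subject", "")
    return model
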