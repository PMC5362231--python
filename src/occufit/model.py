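"""Zero-inflated occupancy likelihood with logistic links, fitted by ML.

The site likelihood is ``Pr(y | z=1) * psi + I(y == 0) * (1 - psi)`` where
``Pr(y | z=1)`` is a product of Bernoulli visit terms and the indicator
adds mass for the all-zero history at unoccupied sites.  Occupancy and
detection probabilities are logit-linear in site and visit covariates
respectively.  Fitting uses quasi-Newton minimisation with an analytic
gradient, dispersed restarts, and a finite-difference Hessian for the
covariance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .prep import DetectionDataset

__all__ = [
    "ModelSpec",
    "FitResult",
    "UnfittableYearError",
    "site_likelihood",
    "negative_log_likelihood",
    "fit_model_c",
    "predict_psi",
    "predict_p",
    "aic_compare",
    "delta_method_se_psi",
]

BOUNDARY_LOGIT = 10.0


class UnfittableYearError(ValueError):
    """Raised when a dataset has no target detections at all."""


@dataclass(frozen=True)
class ModelSpec:
    """Covariate terms for occupancy and detection; intercepts are implicit."""

    occupancy_terms: tuple = ()
    detection_terms: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "occupancy_terms", tuple(self.occupancy_terms))
        object.__setattr__(self, "detection_terms", tuple(self.detection_terms))

    def validate(self, dataset: DetectionDataset) -> None:
        available = set(dataset.occupancy_covariate_names)
        for term in self.occupancy_terms:
            if term not in available:
                raise ValueError(f"occupancy term {term!r} not in dataset")
        for term in self.detection_terms:
            if term not in dataset.visit_covariates:
                raise ValueError(f"detection term {term!r} not in dataset")

    @property
    def n_params(self) -> int:
        return 2 + len(self.occupancy_terms) + len(self.detection_terms)


@dataclass
class FitResult:
    """Maximum-likelihood fit of the zero-inflated occupancy model."""

    spec: ModelSpec
    beta: np.ndarray
    alpha: np.ndarray
    vcov: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_sites: int
    dataset: DetectionDataset
    vcov_degenerate: bool = False
    boundary: bool = False
    n_starts_used: int = 1
    label: str = ""

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha])

    @property
    def n_params(self) -> int:
        return self.beta.size + self.alpha.size

    @property
    def coef_names(self) -> list:
        return (
            ["psi:(Intercept)"]
            + [f"psi:{t}" for t in self.spec.occupancy_terms]
            + ["p:(Intercept)"]
            + [f"p:{t}" for t in self.spec.detection_terms]
        )

    def to_dict(self) -> dict:
        return {
            "coef_names": self.coef_names,
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "n_sites": self.n_sites,
            "vcov_degenerate": self.vcov_degenerate,
            "boundary": self.boundary,
            "occupancy_terms": list(self.spec.occupancy_terms),
            "detection_terms": list(self.spec.detection_terms),
            "standardisation": self.dataset.standardisation,
        }


def site_likelihood(y_i, psi_i: float, p_i) -> float:
    """Likelihood contribution of one site's history.

    ``Pr(y | z=1) * psi + (1 - psi)`` if the history is all zero, else
    ``Pr(y | z=1) * psi``.  NaN entries in ``y_i`` are treated as missing
    visits and skipped.
    """
    y = np.asarray(y_i, dtype=float)
    p = np.broadcast_to(np.asarray(p_i, dtype=float), y.shape)
    mask = ~np.isnan(y)
    y, p = y[mask], p[mask]
    pr_given_occupied = float(np.prod(np.where(y == 1, p, 1.0 - p)))
    all_zero = not np.any(y == 1)
    return pr_given_occupied * psi_i + (1.0 - psi_i) * all_zero


def _designs(dataset: DetectionDataset, spec: ModelSpec):
    S, T = dataset.y.shape
    ko = 1 + len(spec.occupancy_terms)
    X = np.ones((S, ko))
    if spec.occupancy_terms:
        idx = [dataset.occupancy_covariate_names.index(t) for t in spec.occupancy_terms]
        X[:, 1:] = dataset.W[:, idx]
    kd = 1 + len(spec.detection_terms)
    V = np.ones((S, T, kd))
    for j, term in enumerate(spec.detection_terms, start=1):
        V[:, :, j] = dataset.visit_covariates[term]
    return X, V


def _nll_grad(theta, X, V, y, mask, y0, allzero):
    """Negative log-likelihood and gradient; log-space throughout."""
    ko = X.shape[1]
    beta, alpha = theta[:ko], theta[ko:]
    eta_o = X @ beta
    log_psi = log_expit(eta_o)
    log_1mpsi = log_expit(-eta_o)

    eta_d = V @ alpha
    # per-site log Pr(y | z=1); masked visits contribute nothing
    log_terms = np.where(y0 == 1.0, log_expit(eta_d), log_expit(-eta_d))
    log_a = np.sum(np.where(mask, log_terms, 0.0), axis=1)

    occ_branch = log_psi + log_a
    with np.errstate(invalid="ignore"):
        log_l = np.where(
            allzero, np.logaddexp(occ_branch, log_1mpsi), occ_branch
        )
    nll = -float(np.sum(log_l))

    psi = expit(eta_o)
    r = np.exp(occ_branch - log_l)  # posterior Pr(z=1 | y)
    g_beta = -X.T @ (r - psi)
    p = expit(eta_d)
    resid = np.where(mask, y0 - p, 0.0) * r[:, None]
    g_alpha = -np.einsum("st,stk->k", resid, V)
    return nll, np.concatenate([g_beta, g_alpha])


def _prepare_arrays(dataset: DetectionDataset, spec: ModelSpec, drop_empty=True):
    y = dataset.y
    mask = ~np.isnan(y)
    X, V = _designs(dataset, spec)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite occupancy covariates")
    if not np.all(np.isfinite(np.where(mask[:, :, None], V, 0.0))):
        raise ValueError("non-finite detection covariates on observed visits")
    if drop_empty:
        has_visits = mask.any(axis=1)
        y, mask, X, V = y[has_visits], mask[has_visits], X[has_visits], V[has_visits]
    V = np.where(mask[:, :, None], V, 0.0)  # NaN padding poisons 0*NaN products
    y0 = np.where(mask, y, 0.0)
    allzero = ~np.any(y0 == 1.0, axis=1)
    return X, V, y, mask, y0, allzero


def negative_log_likelihood(
    theta, dataset: DetectionDataset, spec: ModelSpec | None = None
) -> float:
    """Joint negative log-likelihood over sites (sites with no visits excluded)."""
    spec = spec or ModelSpec()
    spec.validate(dataset)
    X, V, y, mask, y0, allzero = _prepare_arrays(dataset, spec)
    return _nll_grad(np.asarray(theta, dtype=float), X, V, y, mask, y0, allzero)[0]


def _start_points(ko, kd, n_starts, rng):
    starts = [np.zeros(ko + kd)]
    intercept_grid = np.array([-2.0, 0.0, 2.0])
    for _ in range(n_starts - 1):
        theta = np.empty(ko + kd)
        theta[0] = rng.choice(intercept_grid)
        theta[ko] = rng.choice(intercept_grid)
        slopes = rng.normal(0.0, 0.5, ko + kd - 2)
        theta[1:ko] = slopes[: ko - 1]
        theta[ko + 1 :] = slopes[ko - 1 :]
        starts.append(theta)
    return starts


def _hessian(fun_grad, theta):
    """Central-difference Hessian from the analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    h = 1e-5 * (1.0 + np.abs(theta))
    for i in range(k):
        step = np.zeros(k)
        step[i] = h[i]
        g_plus = fun_grad(theta + step)[1]
        g_minus = fun_grad(theta - step)[1]
        H[:, i] = (g_plus - g_minus) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def fit_model_c(
    dataset: DetectionDataset,
    spec: ModelSpec | None = None,
    n_starts: int = 5,
    seed: int = 0,
    max_escalations: int = 2,
) -> FitResult:
    """Fit the occupancy model by maximum likelihood with dispersed restarts.

    The first start is the zero vector; further starts draw intercepts from
    {-2, 0, 2} and slopes from N(0, 0.5).  If no start converges the number
    of starts is doubled, up to ``max_escalations`` times.  The covariance
    is the inverse observed information (pseudo-inverse, with the
    ``vcov_degenerate`` flag, when the Hessian is singular).
    """
    spec = spec or ModelSpec()
    spec.validate(dataset)
    X, V, y, mask, y0, allzero = _prepare_arrays(dataset, spec)
    if X.shape[0] == 0:
        raise UnfittableYearError("no sites with visits")
    if bool(np.all(allzero)):
        raise UnfittableYearError(
            "no detections of the target in this dataset; the year cannot be fitted"
        )

    def fun_grad(theta):
        return _nll_grad(theta, X, V, y, mask, y0, allzero)

    rng = np.random.default_rng(seed)
    ko, kd = X.shape[1], V.shape[2]
    best = None
    attempts = n_starts
    n_used = 0
    for _ in range(max_escalations + 1):
        for theta0 in _start_points(ko, kd, attempts, rng):
            n_used += 1
            res = minimize(
                fun_grad,
                theta0,
                jac=True,
                method="L-BFGS-B",
                options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
            )
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is not None:
            break
        attempts *= 2

    converged = best is not None
    if not converged:  # fall back to the best failed attempt for diagnostics
        res = minimize(
            fun_grad, np.zeros(ko + kd), jac=True, method="L-BFGS-B",
            options={"ftol": 1e-12, "maxiter": 500},
        )
        best = res
        warnings.warn("all optimisation starts failed to converge", stacklevel=2)

    theta = best.x
    H = _hessian(fun_grad, theta)
    degenerate = False
    try:
        vcov = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        degenerate = True
        warnings.warn("singular Hessian: covariance from pseudo-inverse", stacklevel=2)

    loglik = -float(best.fun)
    k_params = theta.size
    return FitResult(
        spec=spec,
        beta=theta[:ko].copy(),
        alpha=theta[ko:].copy(),
        vcov=vcov,
        loglik=loglik,
        aic=2.0 * k_params - 2.0 * loglik,
        converged=converged,
        n_sites=X.shape[0],
        dataset=dataset,
        vcov_degenerate=degenerate,
        boundary=bool(np.any(np.abs(theta) > BOUNDARY_LOGIT)),
        n_starts_used=n_used,
    )


def _occupancy_design_new(fit: FitResult, W_new) -> np.ndarray:
    terms = fit.spec.occupancy_terms
    if isinstance(W_new, pd.DataFrame):
        missing = [t for t in terms if t not in W_new.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        W = W_new[list(terms)].to_numpy(dtype=float)
    else:
        W = np.asarray(W_new, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        if W.shape[1] != len(terms):
            raise ValueError(
                f"expected {len(terms)} covariate column(s), got {W.shape[1]}"
            )
    return np.column_stack([np.ones(W.shape[0]), W]) if terms else np.ones((len(W), 1))


def predict_psi(fit: FitResult, W_new, return_linear: bool = False):
    """Predicted occupancy probabilities for new sites.

    ``W_new`` must already be standardised with the fit's constants; pass
    an empty (S, 0) array or a DataFrame for intercept-only models.
    """
    X = _occupancy_design_new(fit, W_new)
    eta = X @ fit.beta
    psi = expit(eta)
    return (psi, eta) if return_linear else psi


def predict_p(fit: FitResult, visit_covariates: dict | None = None, shape=None):
    """Predicted detection probabilities from visit-level covariates."""
    terms = fit.spec.detection_terms
    if terms:
        if visit_covariates is None:
            raise ValueError("visit covariates required")
        missing = [t for t in terms if t not in visit_covariates]
        if missing:
            raise ValueError(f"missing visit covariate(s): {missing}")
        first = np.asarray(visit_covariates[terms[0]], dtype=float)
        eta = np.full(first.shape, fit.alpha[0])
        for j, t in enumerate(terms, start=1):
            eta = eta + fit.alpha[j] * np.asarray(visit_covariates[t], dtype=float)
    else:
        out_shape = shape if shape is not None else (1,)
        eta = np.full(out_shape, fit.alpha[0])
    return expit(eta)


def aic_compare(fits: list) -> pd.DataFrame:
    """Rank fits of the same dataset by AIC (ascending, with delta AIC)."""
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].dataset
    for f in fits[1:]:
        same = f.dataset is ref or (
            f.dataset.y.shape == ref.y.shape
            and np.array_equal(f.dataset.y, ref.y, equal_nan=True)
        )
        if not same:
            raise ValueError("fits compare different datasets")
    rows = [
        {
            "label": f.label or "+".join(f.spec.occupancy_terms + f.spec.detection_terms) or "intercepts",
            "k": f.n_params,
            "loglik": f.loglik,
            "aic": f.aic,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


def delta_method_se_psi(fit: FitResult, W_new) -> np.ndarray:
    """Delta-method standard errors of predicted occupancy probabilities.

    ``se(psi_hat) = psi_hat (1 - psi_hat) sqrt(x' Sigma_beta x)`` per site.
    """
    X = _occupancy_design_new(fit, W_new)
    ko = fit.beta.size
    sigma_beta = fit.vcov[:ko, :ko]
    var_eta = np.einsum("ij,jk,ik->i", X, sigma_beta, X)
    psi = expit(X @ fit.beta)
    return psi * (1.0 - psi) * np.sqrt(np.clip(var_eta, 0.0, None))
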