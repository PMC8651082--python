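"""Single-season, single-species occupancy model.

The model separates a detection into two latent processes: a site is
occupied with probability psi, and an occupied site yields a detection in
each of its K replicate surveys independently with probability p.  For a
detection history y_i with d_i = sum_k y_ik detections,

    L_i = psi_i * p_i^{d_i} * (1 - p_i)^{K - d_i}            if d_i > 0
    L_i = psi_i * (1 - p_i)^K + (1 - psi_i)                  if d_i = 0

so an all-zero history is ambiguous between true absence and K missed
detections — exactly the ambiguity the model quantifies.  Both parameters
sit on logit-linked linear predictors of site covariates and are estimated
by direct maximum likelihood; models are compared by AIC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .history import DetectionHistory, design_matrix

BOUNDARY_TOL = 1e-6
Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class OccuModelSpec:
    """Covariate terms for occupancy (psi) and detection (p)."""

    psi_terms: str = "1"
    p_terms: str = "1"

    def __str__(self) -> str:
        return f"p ~ {self.p_terms}, psi ~ {self.psi_terms}"


_SPEC_RE = re.compile(r"^\s*(p|psi|Ψ)\s*~\s*(.+?)\s*$", re.IGNORECASE)


def parse_model_spec(text: str) -> OccuModelSpec:
    """Parse ``"p ~ 1, psi ~ ecosystem"`` (accepts the Greek Psi too)."""
    parts = [s for s in text.split(",") if s.strip()]
    psi_terms = p_terms = None
    for part in parts:
        m = _SPEC_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse model component {part!r}")
        lhs = m.group(1).lower()
        if lhs == "p":
            p_terms = m.group(2)
        else:
            psi_terms = m.group(2)
    if psi_terms is None or p_terms is None:
        raise ValueError(f"model spec {text!r} must define both p and psi")
    return OccuModelSpec(psi_terms=psi_terms, p_terms=p_terms)


def site_log_likelihood(history, psi: float, p: float) -> float:
    """Log-probability of one site's detection history.

    ``history`` is the 0/1 vector over the K surveys; ``psi`` and ``p``
    must lie strictly inside (0, 1) except that the exact endpoints are
    accepted (useful for degenerate checks).
    """
    y = np.asarray(history)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("detection history entries must be 0 or 1")
    k = y.size
    d = int(y.sum())
    psi = float(psi)
    p = float(p)
    if d > 0:
        return float(np.log(psi) + d * np.log(p) + (k - d) * np.log1p(-p))
    return float(np.log(psi * (1.0 - p) ** k + (1.0 - psi)))


def naive_occupancy(history: DetectionHistory | np.ndarray) -> float:
    """Fraction of sites with at least one detection.

    Underestimates psi whenever detection is imperfect: its expectation is
    psi * (1 - (1-p)^K) < psi for p < 1.
    """
    y = history.y if isinstance(history, DetectionHistory) else np.asarray(history)
    if y.shape[0] == 0:
        raise ValueError("need at least one site")
    return float((y.sum(axis=1) > 0).mean())


@dataclass
class OccuFit:
    """Maximum-likelihood fit of one single-species occupancy model."""

    spec: OccuModelSpec
    coefs: np.ndarray  # psi block then p block, logit scale
    coef_names: list[str]
    n_psi: int  # number of psi-design columns
    cov: np.ndarray
    loglik: float
    n_params: int
    n_sites: int
    n_surveys: int
    converged: bool
    boundary: bool
    warnings: list[str] = field(default_factory=list)
    ecosystem_levels: tuple[str, ...] | None = None
    psi_terms: str = "1"
    p_terms: str = "1"

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def beta(self) -> np.ndarray:
        """Occupancy coefficients."""
        return self.coefs[: self.n_psi]

    @property
    def alpha(self) -> np.ndarray:
        """Detection coefficients."""
        return self.coefs[self.n_psi :]

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, np.inf))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.coef_names,
                "estimate": self.coefs,
                "se": self.se(),
            }
        )


def _unpack(theta: np.ndarray, x: np.ndarray, w: np.ndarray):
    npsi = x.shape[1]
    eta_psi = x @ theta[:npsi]
    eta_p = w @ theta[npsi:]
    return expit(eta_psi), expit(eta_p)


def _nll_and_grad(theta: np.ndarray, x: np.ndarray, w: np.ndarray, d: np.ndarray, k: int):
    npsi = x.shape[1]
    psi = expit(x @ theta[:npsi])
    p = expit(w @ theta[npsi:])
    psi = np.clip(psi, 1e-300, 1.0 - 1e-16)
    p = np.clip(p, 1e-300, 1.0 - 1e-16)
    pos = d > 0
    ll = np.empty_like(psi)
    ga = np.empty_like(psi)  # d loglik / d eta_psi
    gb = np.empty_like(psi)  # d loglik / d eta_p
    # detected sites: occupied for certain
    ll[pos] = np.log(psi[pos]) + d[pos] * np.log(p[pos]) + (k - d[pos]) * np.log1p(-p[pos])
    ga[pos] = 1.0 - psi[pos]
    gb[pos] = d[pos] - k * p[pos]
    # all-zero sites: mixture of absence and K missed detections
    z = ~pos
    qk = (1.0 - p[z]) ** k
    lz = psi[z] * qk + (1.0 - psi[z])
    ll[z] = np.log(lz)
    ga[z] = psi[z] * (1.0 - psi[z]) * (qk - 1.0) / lz
    gb[z] = -k * psi[z] * (1.0 - p[z]) ** (k - 1) * p[z] * (1.0 - p[z]) / lz
    grad = np.concatenate([x.T @ ga, w.T @ gb])
    return -float(ll.sum()), -grad


def _check_full_rank(mat: np.ndarray, names: list[str], which: str) -> None:
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError(f"{which} design matrix is rank-deficient; columns: {names}")


def fit(
    history: DetectionHistory,
    site_table: pd.DataFrame | None,
    spec: OccuModelSpec | str = OccuModelSpec(),
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 500,
) -> OccuFit:
    """Fit the occupancy model by multi-start quasi-Newton MLE.

    Starts are the zero vector plus ``n_starts - 1`` seeded N(0, 0.5)
    perturbations; the best converged optimum wins.  Standard errors come
    from the inverse observed information (numerical Hessian at the
    optimum); a pseudo-inverse with a warning is used when near-singular.
    """
    if isinstance(spec, str):
        spec = parse_model_spec(spec)
    if history.n_sites < 1:
        raise ValueError("need at least one site")
    if site_table is None:
        site_table = pd.DataFrame(index=range(history.n_sites))
    x, xnames, levels = design_matrix(site_table, spec.psi_terms)
    w, wnames, levels_p = design_matrix(site_table, spec.p_terms, ecosystem_levels=levels)
    if levels is None:
        levels = levels_p
    _check_full_rank(x, xnames, "occupancy (psi)")
    _check_full_rank(w, wnames, "detection (p)")

    d = history.y.sum(axis=1).astype(float)
    k = history.n_surveys
    nparam = x.shape[1] + w.shape[1]
    rng = np.random.default_rng(seed)
    starts = [np.zeros(nparam)]
    starts += [rng.normal(scale=0.5, size=nparam) for _ in range(max(0, n_starts - 1))]

    best = None
    for s0 in starts:
        res = minimize(
            _nll_and_grad,
            s0,
            args=(x, w, d, k),
            jac=True,
            method="BFGS",
            options={"maxiter": maxiter, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimization failed from every start")

    theta = best.x
    # BFGS can report precision loss at a genuine optimum; judge convergence
    # by the score itself
    grad_norm = float(np.abs(_nll_and_grad(theta, x, w, d, k)[1]).max())
    converged = bool(best.success) or grad_norm < 1e-4 * max(1.0, abs(best.fun))
    warnings: list[str] = []
    hess = approx_hess(theta, lambda t: _nll_and_grad(t, x, w, d, k)[0])
    try:
        cov = np.linalg.inv(hess)
        if not np.isfinite(cov).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        warnings.append("observed information near-singular; covariance is a pseudo-inverse")

    psi_hat, p_hat = _unpack(theta, x, w)
    boundary = bool(
        (np.minimum(psi_hat, 1 - psi_hat) < BOUNDARY_TOL).any()
        or (np.minimum(p_hat, 1 - p_hat) < BOUNDARY_TOL).any()
    )
    if k == 1:
        warnings.append(
            "K=1 surveys: only the product psi*p is identifiable; "
            "individual estimates are arbitrary along that ridge"
        )
    if (d == 0).all():
        warnings.append("species never detected at any site; psi and p are not identifiable")

    return OccuFit(
        spec=spec,
        coefs=theta,
        coef_names=[f"psi:{n}" for n in xnames] + [f"p:{n}" for n in wnames],
        n_psi=x.shape[1],
        cov=cov,
        loglik=-best.fun,
        n_params=nparam,
        n_sites=history.n_sites,
        n_surveys=k,
        converged=converged,
        boundary=boundary,
        warnings=warnings,
        ecosystem_levels=levels,
        psi_terms=spec.psi_terms,
        p_terms=spec.p_terms,
    )


def aic(fit: OccuFit) -> float:
    return fit.aic


def delta_aic(fits: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Model-comparison table: AIC ascending, ties in input order."""
    if labels is None:
        labels = [str(f.spec) for f in fits]
    df = pd.DataFrame(
        {
            "model": labels,
            "n_params": [f.n_params for f in fits],
            "AIC": [f.aic for f in fits],
        }
    )
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    return df.sort_values("AIC", kind="stable").reset_index(drop=True)


def _predict_linear(
    fit: OccuFit, site_table: pd.DataFrame, terms: str, block: slice
) -> tuple[np.ndarray, np.ndarray]:
    x, _, _ = design_matrix(site_table, terms, ecosystem_levels=fit.ecosystem_levels)
    coefs = fit.coefs[block]
    cov = fit.cov[block, block]
    eta = x @ coefs
    var = np.einsum("ij,jk,ik->i", x, cov, x)
    return eta, np.sqrt(np.clip(var, 0.0, np.inf))


def predict_occupancy(fit: OccuFit, new_site_table: pd.DataFrame) -> pd.DataFrame:
    """Per-site psi-hat with a 95% Wald interval.

    The interval is computed on the linear predictor and mapped through the
    inverse logit, so it always lies inside (0, 1) and contains the point
    estimate.
    """
    eta, se = _predict_linear(fit, new_site_table, fit.psi_terms, slice(0, fit.n_psi))
    return pd.DataFrame(
        {
            "estimate": expit(eta),
            "lower": expit(eta - Z95 * se),
            "upper": expit(eta + Z95 * se),
        },
        index=new_site_table.index,
    )


def predict_detection(fit: OccuFit, new_site_table: pd.DataFrame) -> pd.DataFrame:
    """Per-site p-hat with a 95% Wald interval (see predict_occupancy)."""
    eta, se = _predict_linear(
        fit, new_site_table, fit.p_terms, slice(fit.n_psi, fit.n_params)
    )
    return pd.DataFrame(
        {
            "estimate": expit(eta),
            "lower": expit(eta - Z95 * se),
            "upper": expit(eta + Z95 * se),
        },
        index=new_site_table.index,
    )
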