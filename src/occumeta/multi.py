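"""Two-species co-occurrence occupancy model (multivariate Bernoulli).

The joint latent state (z1, z2) of the two functions at a site follows a
log-linear multivariate Bernoulli with natural parameters f1, f2 and an
interaction f12:

    P(z1, z2) ∝ exp(z1*f1 + z2*f2 + z1*z2*f12)

so f12 > 0 means the functions co-occur more often than independence
predicts, and f12 = 0 factorizes the joint distribution.  Each natural
parameter carries its own covariate design; detection is intercept-only
per species.  The observed-data likelihood marginalizes each site's pair
of detection histories over the four latent states.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from statsmodels.tools.numdiff import approx_hess

from .history import DetectionHistory, design_matrix
from .single import BOUNDARY_TOL, Z95

QUASI_SEPARATION_F12 = 10.0


@dataclass(frozen=True)
class StateProbs:
    """Joint occupancy probabilities of the four latent states."""

    psi00: float
    psi10: float
    psi01: float
    psi11: float

    def __post_init__(self) -> None:
        total = self.psi00 + self.psi10 + self.psi01 + self.psi11
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state probabilities sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.psi00, self.psi10, self.psi01, self.psi11])

    def marginal(self, species: int) -> float:
        """Marginal occupancy P(z_species = 1)."""
        if species == 1:
            return self.psi10 + self.psi11
        if species == 2:
            return self.psi01 + self.psi11
        raise ValueError("species must be 1 or 2")


def state_probs(f1: float, f2: float, f12: float) -> StateProbs:
    """Normalize the log-linear weights (1, e^f1, e^f2, e^{f1+f2+f12}).

    Uses max-subtraction so very large natural parameters cannot overflow.
    """
    lw = np.array([0.0, f1, f2, f1 + f2 + f12], dtype=float)
    lw -= lw.max()
    w = np.exp(lw)
    w /= w.sum()
    return StateProbs(*w)


def conditional_occupancy(states: StateProbs, target: int, given_present: bool) -> float:
    """P(target species present | other species present or absent)."""
    if target == 1:
        num = states.psi11 if given_present else states.psi10
        den = (states.psi11 + states.psi01) if given_present else (states.psi10 + states.psi00)
    elif target == 2:
        num = states.psi11 if given_present else states.psi01
        den = (states.psi11 + states.psi10) if given_present else (states.psi01 + states.psi00)
    else:
        raise ValueError("target must be 1 or 2")
    if den < 1e-12:
        raise ValueError("conditioning event has probability below 1e-12")
    return num / den


def multi_site_log_likelihood(y1, y2, states: StateProbs, p1: float, p2: float) -> float:
    """Log-probability of one site's paired detection histories.

    Marginalizes over the four latent states; an absent species contributes
    an indicator that its history is all-zero.
    """
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    if y1.size != y2.size:
        raise ValueError("the two histories must have the same number of surveys")
    k = y1.size
    d1, d2 = int(y1.sum()), int(y2.sum())

    def det(d: int, p: float, present: bool) -> float:
        if present:
            return p**d * (1.0 - p) ** (k - d)
        return 1.0 if d == 0 else 0.0

    psis = states.as_array()
    total = 0.0
    for idx, (z1, z2) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
        total += psis[idx] * det(d1, p1, bool(z1)) * det(d2, p2, bool(z2))
    return float(np.log(total))


@dataclass(frozen=True)
class MultiModelSpec:
    """Covariate terms for the three natural parameters.

    Detection is intercept-only per species and not part of the spec.
    """

    f1_terms: str = "1"
    f2_terms: str = "1"
    f12_terms: str = "1"
    species_names: tuple[str, str] = ("mcr", "pmo")

    def __str__(self) -> str:
        s1, s2 = self.species_names
        return (
            f"psi[{s1}] ~ {self.f1_terms}, psi[{s2}] ~ {self.f2_terms}, "
            f"psi[{s1}:{s2}] ~ {self.f12_terms}"
        )


_MULTI_RE = re.compile(r"(psi|Ψ)\s*\[\s*([^\]]+?)\s*\]\s*~\s*([^,]+)", re.IGNORECASE)


def parse_multi_spec(text: str) -> MultiModelSpec:
    """Parse ``"psi[1] ~ ecosystem, psi[2] ~ latitude, psi[12] ~ 1"``.

    Tags may be numeric (1, 2, 12) or names (mcr, pmo, mcr:pmo); the tag
    containing ``:`` or equal to ``12`` is the interaction, the others are
    taken in order of appearance.
    """
    matches = _MULTI_RE.findall(text)
    if len(matches) != 3:
        raise ValueError(f"expected three psi[...] ~ terms components in {text!r}")
    f12 = None
    singles: list[tuple[str, str]] = []
    for _, tag, terms in matches:
        tag = tag.strip()
        if ":" in tag or tag == "12":
            f12 = terms.strip()
        else:
            singles.append((tag, terms.strip()))
    if f12 is None or len(singles) != 2:
        raise ValueError(f"could not identify the interaction component in {text!r}")
    names = tuple(t if not t.isdigit() else f"species{t}" for t, _ in singles)
    return MultiModelSpec(singles[0][1], singles[1][1], f12, names)  # type: ignore[arg-type]


@dataclass
class MultiFit:
    """Maximum-likelihood fit of the two-species occupancy model."""

    spec: MultiModelSpec
    coefs: np.ndarray  # f1 block, f2 block, f12 block, logit p1, logit p2
    coef_names: list[str]
    blocks: dict  # name -> slice into coefs
    cov: np.ndarray
    loglik: float
    n_params: int
    n_sites: int
    n_surveys: int
    converged: bool
    boundary: bool
    warnings: list[str] = field(default_factory=list)
    ecosystem_levels: tuple[str, ...] | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def p1(self) -> float:
        return float(expit(self.coefs[self.blocks["p1"]])[0])

    @property
    def p2(self) -> float:
        return float(expit(self.coefs[self.blocks["p2"]])[0])

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, np.inf))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.coef_names, "estimate": self.coefs, "se": self.se()}
        )

    def natural_params(self, site_table: pd.DataFrame) -> np.ndarray:
        """Per-site (f1, f2, f12) at the fitted coefficients."""
        return _natural_params(self, self.coefs, site_table)


def _natural_params(fit: MultiFit, theta: np.ndarray, site_table: pd.DataFrame) -> np.ndarray:
    cols = []
    for name, terms in (("f1", fit.spec.f1_terms), ("f2", fit.spec.f2_terms), ("f12", fit.spec.f12_terms)):
        block = theta[fit.blocks[name]]
        if block.size == 0:  # f12 fixed at zero
            cols.append(np.zeros(len(site_table)))
            continue
        x, _, _ = design_matrix(site_table, terms, ecosystem_levels=fit.ecosystem_levels)
        cols.append(x @ block)
    return np.column_stack(cols)


def _log_state_probs(f: np.ndarray) -> np.ndarray:
    """Row-wise log state probabilities from per-site (f1, f2, f12)."""
    lw = np.column_stack(
        [np.zeros(len(f)), f[:, 0], f[:, 1], f[:, 0] + f[:, 1] + f[:, 2]]
    )
    return lw - logsumexp(lw, axis=1, keepdims=True)


def _nll_multi(
    theta: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    x12: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    k: int,
    slices: dict,
) -> float:
    f = np.column_stack(
        [x1 @ theta[slices["f1"]], x2 @ theta[slices["f2"]], x12 @ theta[slices["f12"]]]
    )
    lpsi = _log_state_probs(f)
    p1 = float(expit(theta[slices["p1"]])[0])
    p2 = float(expit(theta[slices["p2"]])[0])
    p1 = min(max(p1, 1e-12), 1 - 1e-12)
    p2 = min(max(p2, 1e-12), 1 - 1e-12)

    def ldet(d: np.ndarray, p: float) -> np.ndarray:
        return d * np.log(p) + (k - d) * np.log1p(-p)

    neg_inf = -np.inf
    l1_pres, l2_pres = ldet(d1, p1), ldet(d2, p2)
    l1_abs = np.where(d1 == 0, 0.0, neg_inf)
    l2_abs = np.where(d2 == 0, 0.0, neg_inf)
    terms = np.column_stack(
        [
            lpsi[:, 0] + l1_abs + l2_abs,
            lpsi[:, 1] + l1_pres + l2_abs,
            lpsi[:, 2] + l1_abs + l2_pres,
            lpsi[:, 3] + l1_pres + l2_pres,
        ]
    )
    ll = logsumexp(terms, axis=1)
    return -float(ll.sum())


def fit_multi(
    history1: DetectionHistory,
    history2: DetectionHistory,
    site_table: pd.DataFrame | None,
    spec: MultiModelSpec | str = MultiModelSpec(),
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 2000,
    fix_f12_zero: bool = False,
) -> MultiFit:
    """Joint MLE over the three natural-parameter blocks and two detection
    intercepts, by multi-start quasi-Newton optimization.

    With ``fix_f12_zero`` the interaction is pinned at 0, forcing the two
    species independent — useful as the null against which co-occurrence
    is judged."""
    if isinstance(spec, str):
        spec = parse_multi_spec(spec)
    if history1.site_ids != history2.site_ids:
        raise ValueError("the two panels must share the same sites in the same order")
    if history1.n_surveys != history2.n_surveys:
        raise ValueError("panels must have the same number of surveys")
    n = history1.n_sites
    if site_table is None:
        site_table = pd.DataFrame(index=range(n))

    designs = {}
    names_all: list[str] = []
    levels = None
    for name, terms in (("f1", spec.f1_terms), ("f2", spec.f2_terms), ("f12", spec.f12_terms)):
        if name == "f12" and fix_f12_zero:
            designs[name] = np.zeros((n, 0))
            continue
        x, xnames, lv = design_matrix(site_table, terms, ecosystem_levels=levels)
        if levels is None:
            levels = lv
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"{name} design matrix is rank-deficient; columns: {xnames}")
        designs[name] = x
        names_all += [f"{name}:{c}" for c in xnames]

    slices = {}
    start = 0
    for name in ("f1", "f2", "f12"):
        width = designs[name].shape[1]
        slices[name] = slice(start, start + width)
        start += width
    slices["p1"] = slice(start, start + 1)
    slices["p2"] = slice(start + 1, start + 2)
    names_all += ["p1:(Intercept)", "p2:(Intercept)"]
    nparam = start + 2

    d1 = history1.y.sum(axis=1).astype(float)
    d2 = history2.y.sum(axis=1).astype(float)
    k = history1.n_surveys
    args = (designs["f1"], designs["f2"], designs["f12"], d1, d2, k, slices)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(nparam)]
    starts += [rng.normal(scale=0.5, size=nparam) for _ in range(max(0, n_starts - 1))]
    best = None
    for s0 in starts:
        res = minimize(
            _nll_multi, s0, args=args, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("optimization failed from every start")

    theta = best.x
    from scipy.optimize import approx_fprime

    grad_norm = float(np.abs(approx_fprime(theta, _nll_multi, 1e-7, *args)).max())
    converged = bool(best.success) or grad_norm < 1e-3 * max(1.0, abs(best.fun))
    warnings: list[str] = []
    hess = approx_hess(theta, _nll_multi, args=args)
    try:
        cov = np.linalg.inv(hess)
        if not np.isfinite(cov).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        warnings.append("observed information near-singular; covariance is a pseudo-inverse")

    f = np.column_stack(
        [designs["f1"] @ theta[slices["f1"]], designs["f2"] @ theta[slices["f2"]], designs["f12"] @ theta[slices["f12"]]]
    )
    psis = np.exp(_log_state_probs(f))
    p_hat = expit(theta[start:])
    boundary = bool(
        (psis < BOUNDARY_TOL).any() or (np.minimum(p_hat, 1 - p_hat) < BOUNDARY_TOL).any()
    )
    if np.abs(f[:, 2]).max() > QUASI_SEPARATION_F12:
        warnings.append(
            f"|f12| exceeds {QUASI_SEPARATION_F12}: possible quasi-separation of co-occurrence"
        )

    return MultiFit(
        spec=spec,
        coefs=theta,
        coef_names=names_all,
        blocks=slices,
        cov=cov,
        loglik=-best.fun,
        n_params=nparam,
        n_sites=n,
        n_surveys=k,
        converged=converged,
        boundary=boundary,
        warnings=warnings,
        ecosystem_levels=levels,
    )


def predict_conditional_curves(
    fit: MultiFit,
    grid: pd.DataFrame,
    target: int = 1,
    n_boot: int = 1000,
    method: str = "bootstrap",
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Conditional occupancy of one species along a covariate grid.

    For every grid row and each conditioning state (other species present /
    absent), returns the point estimate and, unless ``n_boot == 0`` (or the
    delta method is selected), a parametric-bootstrap interval from
    ``n_boot`` draws of the coefficient vector's normal approximation.  The
    delta-method alternative propagates the variance on the logit scale, so
    either interval stays inside (0, 1).
    """
    if method not in ("bootstrap", "delta"):
        raise ValueError("method must be 'bootstrap' or 'delta'")
    f = _natural_params(fit, fit.coefs, grid)
    rows = []
    alpha = 1.0 - level
    zq = Z95 if abs(level - 0.95) < 1e-9 else None

    boot_thetas = None
    if method == "bootstrap" and n_boot > 0:
        rng = np.random.default_rng(seed)
        cov = (fit.cov + fit.cov.T) / 2.0
        boot_thetas = rng.multivariate_normal(fit.coefs, cov, size=n_boot, method="svd")
        boot_f = [ _natural_params(fit, th, grid) for th in boot_thetas ]

    for i in range(len(grid)):
        states = state_probs(*f[i])
        for given in (True, False):
            est = conditional_occupancy(states, target, given)
            row = {
                "grid_index": grid.index[i],
                "condition": "present" if given else "absent",
                "estimate": est,
            }
            if method == "bootstrap" and n_boot > 0:
                draws = np.array(
                    [
                        conditional_occupancy(state_probs(*bf[i]), target, given)
                        for bf in boot_f
                    ]
                )
                row["lower"] = float(np.quantile(draws, alpha / 2))
                row["upper"] = float(np.quantile(draws, 1 - alpha / 2))
            elif method == "delta":
                se_l = _delta_se_logit(fit, grid.iloc[[i]], target, given)
                z = zq if zq is not None else -_norm_ppf(alpha / 2)
                eta = logit(min(max(est, 1e-12), 1 - 1e-12))
                row["lower"] = float(expit(eta - z * se_l))
                row["upper"] = float(expit(eta + z * se_l))
            rows.append(row)
    out = pd.DataFrame(rows)
    for c in grid.columns:
        out[c] = np.repeat(grid[c].to_numpy(), 2)
    return out


def _norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(q))


def _delta_se_logit(fit: MultiFit, one_row: pd.DataFrame, target: int, given: bool) -> float:
    """Numeric-gradient delta-method SE of logit(conditional occupancy)."""

    def g(theta: np.ndarray) -> float:
        fr = _natural_params(fit, theta, one_row)[0]
        est = conditional_occupancy(state_probs(*fr), target, given)
        return float(logit(min(max(est, 1e-12), 1 - 1e-12)))

    eps = 1e-5
    grad = np.zeros(fit.n_params)
    base = fit.coefs
    for j in range(fit.n_params):
        up = base.copy()
        dn = base.copy()
        up[j] += eps
        dn[j] -= eps
        grad[j] = (g(up) - g(dn)) / (2 * eps)
    var = float(grad @ fit.cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def delta_aic_multi(fits: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Two-species model-comparison table, AIC ascending."""
    if labels is None:
        labels = [str(f.spec) for f in fits]
    df = pd.DataFrame(
        {"model": labels, "n_params": [f.n_params for f in fits], "AIC": [f.aic for f in fits]}
    )
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    return df.sort_values("AIC", kind="stable").reset_index(drop=True)
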