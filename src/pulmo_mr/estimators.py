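"""Stage 3: causal-effect estimators for a harmonized instrument set.

Implements the Wald ratio, inverse-variance-weighted (fixed and
multiplicative random effects), profile maximum likelihood, weighted
median with parametric bootstrap, MR-Egger regression, the robust
adjusted profile score (RAPS) with additive overdispersion, and
multivariable IVW.  All causal effects are on the log-odds scale per
exposure unit.

First-order weights (1/se_out^2) are used for IVW and the weighted
median; the heterogeneity diagnostics in :mod:`pulmo_mr.diagnostics`
use modified second-order weights instead.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize, stats

from .containers import HarmonizedSet, MRResult

Z95 = stats.norm.ppf(0.975)


def _result(method, theta, se, j, p=None, **aux) -> MRResult:
    if p is None:
        p = 2 * stats.norm.sf(abs(theta) / se) if se > 0 else 0.0
    return MRResult(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        p=float(p),
        n_instruments=int(j),
        **aux,
    )


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MRResult:
    """Single-instrument ratio estimate with the first-order delta SE."""
    if beta_exp == 0:
        raise ZeroDivisionError("exposure effect is zero; Wald ratio undefined")
    theta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _result("wald", theta, se, 1)


def _first_order_q(bx, by, sy, theta) -> float:
    w = bx**2 / sy**2
    ratios = by / bx
    return float(np.sum(w * (ratios - theta) ** 2))


def ivw(hset: HarmonizedSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate with first-order weights.

    With multiplicative random effects the SE is inflated by
    ``max(1, sqrt(Q1 / (J - 1)))`` where Q1 is first-order Cochran's Q at
    the estimate.  A single instrument falls back to the Wald ratio.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j == 1:
        return wald_ratio(bx[0], sx[0], by[0], sy[0])
    if j < 2:
        raise ValueError("IVW needs at least two instruments")

    w = bx**2 / sy**2
    theta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se_fe = float(np.sum(w) ** -0.5)
    phi = 1.0
    se = se_fe
    if random_effects:
        q1 = _first_order_q(bx, by, sy, theta)
        phi = max(1.0, np.sqrt(q1 / (j - 1)))
        se = se_fe * phi
    return _result("ivw_re" if random_effects else "ivw_fe", theta, se, j,
                   heterogeneity_scale=float(phi))


def maximum_likelihood(hset: HarmonizedSet) -> MRResult:
    """Profile maximum likelihood over the causal effect.

    Each instrument's true exposure effect is a nuisance parameter with
    the closed-form profile
    ``b_j(theta) = (bx/sx^2 + theta*by/sy^2) / (1/sx^2 + theta^2/sy^2)``;
    the resulting 1-D profile log-likelihood is maximized by Brent search
    over a bracket spanning the ratio range, and the SE comes from the
    numerical observed information at the optimum.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 2:
        raise ValueError("ML needs at least two instruments")
    sx = np.maximum(sx, 1e-10)
    sy = np.maximum(sy, 1e-10)

    def negloglik(theta: float) -> float:
        b = (bx / sx**2 + theta * by / sy**2) / (1 / sx**2 + theta**2 / sy**2)
        return float(
            np.sum((bx - b) ** 2 / (2 * sx**2) + (by - theta * b) ** 2 / (2 * sy**2))
        )

    ratios = by / np.where(bx == 0, np.nan, bx)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        raise ValueError("no usable instruments")
    spread = max(np.ptp(ratios), 1e-3)
    lo = float(ratios.min() - 5 * spread)
    hi = float(ratios.max() + 5 * spread)

    res = optimize.minimize_scalar(negloglik, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError("profile-likelihood optimization failed to converge")
    theta = float(res.x)

    h = max(1e-6, 1e-6 * abs(theta))
    info = (negloglik(theta + h) - 2 * negloglik(theta) + negloglik(theta - h)) / h**2
    if info <= 0:
        # fall back to a wider stencil for flat curvature
        h *= 100
        info = (negloglik(theta + h) - 2 * negloglik(theta) + negloglik(theta - h)) / h**2
    se = float(1 / np.sqrt(info)) if info > 0 else float("inf")
    return _result("ml", theta, se, j)


def weighted_median(hset: HarmonizedSet, n_bootstrap: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the instrument ratios.

    Consistent when at least half of the instrument weight comes from
    valid instruments.  The point estimate interpolates the weighted
    cumulative distribution of ordered ratios at probability 0.5; the SE
    is the standard deviation of a parametric bootstrap that resamples
    the summary effects from their sampling normals.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 3:
        raise ValueError("weighted median needs at least three instruments")

    theta = _weighted_median_point(by / bx, bx**2 / sy**2)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bxs = bx + sx * rng.standard_normal(j)
        bys = by + sy * rng.standard_normal(j)
        bxs = np.where(bxs == 0, 1e-12, bxs)
        boots[b] = _weighted_median_point(bys / bxs, bxs**2 / sy**2)
    se = float(boots.std(ddof=1))
    return _result("wm", theta, se, j, n_bootstrap=n_bootstrap)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    # cumulative midpoint of each instrument's weight mass
    p = np.cumsum(w) - w / 2
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def mr_egger(hset: HarmonizedSet, force_zero_intercept: bool = False) -> MRResult:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Instruments are jointly sign-oriented so every exposure effect is
    non-negative (required for the intercept to be interpretable), then
    the outcome effects are regressed on the exposure effects with
    weights 1/se_out^2.  Both SEs carry the multiplicative
    random-effects inflation ``max(1, sqrt(Q_E / (J - 2)))``.  The slope
    p-value uses the t distribution with J-2 df; the intercept test is
    the usual z-test for directional pleiotropy.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 3:
        raise ValueError("MR-Egger needs at least three instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise ValueError("all exposure effects equal; Egger slope unidentified")

    w = 1 / sy**2
    if force_zero_intercept:
        theta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        resid = by - theta * bx
        q = float(np.sum(w * resid**2))
        phi = max(1.0, np.sqrt(q / (j - 1)))
        se = float(np.sqrt(1 / np.sum(w * bx**2)) * phi)
        return _result("egger_through_origin", theta, se, j,
                       heterogeneity_scale=float(phi))

    X = np.column_stack([np.ones(j), bx])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    xtwy = X.T @ W @ by
    coef = np.linalg.solve(xtwx, xtwy)
    b0, theta = float(coef[0]), float(coef[1])
    resid = by - X @ coef
    q_e = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(q_e / (j - 2)))
    cov = np.linalg.inv(xtwx) * phi**2
    se_b0, se_theta = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    p_slope = 2 * stats.t.sf(abs(theta) / se_theta, j - 2) if se_theta > 0 else 0.0
    p_b0 = 2 * stats.norm.sf(abs(b0) / se_b0) if se_b0 > 0 else 0.0
    return _result(
        "egger", theta, se_theta, j, p=p_slope,
        heterogeneity_scale=float(phi),
        egger_intercept=b0, egger_intercept_se=se_b0, egger_intercept_p=float(p_b0),
    )


# --- MR-RAPS ---------------------------------------------------------------

HUBER_K = 1.345


def _huber_rho(r: np.ndarray, k: float = HUBER_K) -> np.ndarray:
    a = np.abs(r)
    return np.where(a <= k, r**2 / 2, k * a - k**2 / 2)


def _huber_psi(r: np.ndarray, k: float = HUBER_K) -> np.ndarray:
    return np.clip(r, -k, k)


def _expected_rho(loss: str, k: float = HUBER_K) -> float:
    if loss == "squared":
        return 0.5
    val, _ = integrate.quad(lambda z: _huber_rho(np.array([z]), k)[0] * stats.norm.pdf(z),
                            -np.inf, np.inf)
    return float(val)


def mr_raps(
    hset: HarmonizedSet,
    loss: str = "huber",
    overdispersion: bool = True,
    max_iter: int = 200,
) -> MRResult:
    """Robust adjusted profile score estimator.

    Standardized residuals
    ``r_j = (by - theta*bx) / sqrt(sy^2 + theta^2 sx^2 + tau^2)`` enter a
    robust loss (Huber k=1.345 by default); theta minimizes the summed
    loss while the additive overdispersion tau^2 is tuned so the mean
    loss matches its standard-normal expectation, modelling balanced
    (mean-zero) systematic pleiotropy as additive.  tau^2 driven
    negative is clamped to zero.  The SE is a sandwich estimate from the
    robust score.
    """
    bx, sx, by, sy = hset.arrays()
    j = bx.size
    if j < 3:
        raise ValueError("RAPS needs at least three instruments")
    if loss not in ("huber", "squared"):
        raise ValueError("loss must be 'huber' or 'squared'")
    rho = (lambda r: _huber_rho(r)) if loss == "huber" else (lambda r: r**2 / 2)
    psi = (lambda r: _huber_psi(r)) if loss == "huber" else (lambda r: r)
    target = _expected_rho(loss)

    def residuals(theta, tau2):
        v = sy**2 + theta**2 * sx**2 + tau2
        return (by - theta * bx) / np.sqrt(v), v

    def theta_objective(theta, tau2):
        r, _ = residuals(theta, tau2)
        return float(np.sum(rho(r)))

    # initialize from IVW; fixed optimization bracket around the ratio range
    theta = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    ratios = by / np.where(bx == 0, np.nan, bx)
    ratios = ratios[np.isfinite(ratios)]
    spread = max(np.ptp(ratios), 1.0) if ratios.size else 1.0
    bounds = (min(theta, ratios.min()) - 5 * spread, max(theta, ratios.max()) + 5 * spread)
    tau2 = 0.0
    clamped = False
    for _ in range(max_iter):
        res = optimize.minimize_scalar(
            theta_objective, args=(tau2,), bounds=bounds,
            method="bounded", options={"xatol": 1e-12},
        )
        theta_new = float(res.x)
        if overdispersion:
            def tau_gap(t2):
                r, _ = residuals(theta_new, t2)
                return float(np.mean(rho(r)) - target)

            gap0 = tau_gap(0.0)
            if gap0 <= 0:
                tau2_new = 0.0
                # a mean loss just under its null expectation is ordinary
                # sampling noise; warn only when the deficit is beyond two
                # standard errors of the mean loss, i.e. tau^2 is being
                # pushed genuinely negative
                r0, _ = residuals(theta_new, 0.0)
                se_loss = float(np.std(rho(r0), ddof=1)) / np.sqrt(j)
                clamped = gap0 < -2 * se_loss
            else:
                hi = max(sy.max() ** 2, 1e-4)
                while tau_gap(hi) > 0 and hi < 1e6:
                    hi *= 4
                tau2_new = float(optimize.brentq(tau_gap, 0.0, hi, xtol=1e-14))
        else:
            tau2_new = 0.0
        if (abs(theta_new - theta) < 1e-7 * (1 + abs(theta))
                and abs(tau2_new - tau2) < 1e-8 * (1 + tau2)):
            theta, tau2 = theta_new, tau2_new
            break
        theta, tau2 = theta_new, tau2_new
    else:
        raise RuntimeError("RAPS estimating equations did not converge")

    # sandwich SE for the theta-score at the solution
    r, v = residuals(theta, tau2)
    sqv = np.sqrt(v)
    drdtheta = (-bx * sqv - (by - theta * bx) * theta * sx**2 / sqv) / v
    score_terms = psi(r) * drdtheta
    h = max(1e-6, 1e-6 * abs(theta))

    def total_score(th):
        rr, vv = residuals(th, tau2)
        sq = np.sqrt(vv)
        dr = (-bx * sq - (by - th * bx) * th * sx**2 / sq) / vv
        return float(np.sum(psi(rr) * dr))

    a = (total_score(theta + h) - total_score(theta - h)) / (2 * h)
    b = float(np.sum(score_terms**2))
    se = float(np.sqrt(b) / abs(a)) if a != 0 else float("inf")

    result = _result("raps", theta, se, j, overdispersion=float(tau2))
    if clamped and overdispersion:
        import warnings

        warnings.warn("RAPS overdispersion driven negative; clamped to 0", stacklevel=2)
    return result


def mvmr_ivw(
    beta_exposures: np.ndarray,
    beta_out: np.ndarray,
    se_out: np.ndarray,
    exposure_names: list[str] | None = None,
) -> list[MRResult]:
    """Multivariable IVW: weighted regression of outcome effects on k
    exposure-effect columns without intercept, with multiplicative
    random-effects SE inflation ``max(1, sqrt(Q / (J - k)))``.
    """
    X = np.asarray(beta_exposures, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != len(beta_out):
        raise ValueError("beta_exposures must be (J instruments, k exposures)")
    by = np.asarray(beta_out, dtype=float)
    sy = np.asarray(se_out, dtype=float)
    j, k = X.shape
    if j <= k:
        raise ValueError("need more instruments than exposures")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("exposure-effect matrix is rank deficient")

    w = 1 / sy**2
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(q / (j - k)))
    cov = np.linalg.inv(xtwx) * phi**2

    names = exposure_names or [f"exposure_{i}" for i in range(k)]
    return [
        _result(f"mvmr_ivw[{names[i]}]", coef[i], np.sqrt(cov[i, i]), j,
                heterogeneity_scale=float(phi))
        for i in range(k)
    ]


def all_estimators(
    hset: HarmonizedSet, seed: int = 0, n_bootstrap: int = 1000
) -> list[MRResult]:
    """Run the five standard estimators on one harmonized set."""
    return [
        ivw(hset, random_effects=True),
        maximum_likelihood(hset),
        weighted_median(hset, n_bootstrap=n_bootstrap, seed=seed),
        mr_egger(hset),
        mr_raps(hset),
    ]
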