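"""Robust negative-binomial error model, fitted per alteration across a cohort.

The model: at one candidate alteration, the alternate read count of sample
``i`` follows ``AO_i ~ NB(mu_i, sigma)`` with a linear link and zero
intercept, ``mu_i = e * DP_i``, and variance ``mu + sigma * mu**2``
(``sigma -> 0`` recovers Poisson).  ``e`` is the per-read error rate shared
by the cohort; samples carrying a real variant are outliers and must not
drag the estimate, so the fit is an iterative M-estimator:

1. Pearson residuals under the current ``(e, sigma)``;
2. Huber weights ``w_i = min(1, c / |r_i|)``;
3. ``e`` update from the weighted estimating equation, with a
   Fisher-consistency correction (exact by summation at moderate ``mu``,
   zero by Gaussian symmetry at high coverage);
4. ``sigma`` update by maximizing the log-likelihood restricted to
   observations within the Huber band.

A classical (non-robust) profile-likelihood fit is provided as an
initializer-grade baseline and as an independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import optimize, special, stats

if TYPE_CHECKING:  # pragma: no cover
    from .pileup import SitePileup

__all__ = [
    "FitConfig",
    "ErrorModelFit",
    "FitError",
    "nb_tail_prob",
    "fit_error_model",
    "classical_nb_fit",
]

_POISSON_SIGMA = 1e-8  # below this, the NB is numerically Poisson


class FitError(RuntimeError):
    """Raised when the error model cannot be fitted."""


@dataclass
class FitConfig:
    """Tuning of the robust fit."""

    huber_c: float = 2.5
    tol: float = 1e-6
    max_iter: int = 50
    sigma_bounds: tuple[float, float] = (1e-8, 1e4)
    normal_approx_mu: float = 100.0
    extra_robust: bool = False
    extra_robust_vaf: float = 0.2

    def __post_init__(self) -> None:
        if self.huber_c <= 0:
            raise ValueError("huber_c must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        lo, hi = self.sigma_bounds
        if not (0 < lo < hi):
            raise ValueError(f"invalid sigma_bounds {self.sigma_bounds}")


@dataclass
class ErrorModelFit:
    """Fitted error rate and overdispersion with robustness diagnostics.

    ``weights`` has one entry per cohort sample (fitting order): Huber
    weight for fitted samples, 1.0 for zero-depth samples (excluded from
    the fit by necessity), 0.0 for samples pre-excluded by extra-robust
    mode.
    """

    e_hat: float
    sigma_hat: float
    weights: np.ndarray
    n_iter: int
    converged: bool
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.e_hat < 0 or self.sigma_hat < 0:
            raise ValueError("estimates must be non-negative")


# ---------------------------------------------------------------------------
# NB distribution helpers


def _nb_logpmf(k: np.ndarray, mu: np.ndarray, sigma: float) -> np.ndarray:
    """log P(X = k) for X ~ NB(mean mu, var mu + sigma*mu^2), elementwise.

    mu = 0 gives a point mass at zero; sigma below the Poisson threshold
    uses the Poisson pmf.
    """
    k = np.asarray(k, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), k.shape).copy()
    out = np.full(k.shape, -np.inf)
    zero = mu == 0
    out[zero & (k == 0)] = 0.0
    pos = ~zero
    if not np.any(pos):
        return out
    kp, mp = k[pos], mu[pos]
    if sigma < _POISSON_SIGMA:
        out[pos] = kp * np.log(mp) - mp - special.gammaln(kp + 1)
    else:
        n = 1.0 / sigma
        logp = -np.log1p(sigma * mp)  # log p, p = 1/(1+sigma*mu)
        log1mp = np.log(sigma * mp) + logp
        out[pos] = (
            special.gammaln(kp + n)
            - special.gammaln(n)
            - special.gammaln(kp + 1)
            + n * logp
            + kp * log1mp
        )
    return out


def nb_tail_prob(a, mu, sigma) -> float | np.ndarray:
    """Upper tail P(X >= a) for X ~ NB(mean mu, var mu + sigma*mu^2).

    ``sigma = 0`` is the Poisson limit; ``mu = 0`` returns 1 when a == 0
    and 0 otherwise.  Accepts scalars or broadcastable arrays.
    """
    a_arr = np.asarray(a, dtype=float)
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(a_arr < 0) or np.any(mu_arr < 0) or sigma < 0:
        raise ValueError("nb_tail_prob requires a >= 0, mu >= 0, sigma >= 0")
    if not np.all(a_arr == np.floor(a_arr)):
        raise ValueError("a must be integral")
    a_b, mu_b = np.broadcast_arrays(a_arr, mu_arr)
    out = np.empty(a_b.shape, dtype=float)
    zero_mu = mu_b == 0
    out[zero_mu] = np.where(a_b[zero_mu] == 0, 1.0, 0.0)
    pos = ~zero_mu
    if np.any(pos):
        ap, mp = a_b[pos], mu_b[pos]
        if sigma < _POISSON_SIGMA:
            out[pos] = stats.poisson.sf(ap - 1, mp)
        else:
            n = 1.0 / sigma
            p = 1.0 / (1.0 + sigma * mp)
            out[pos] = stats.nbinom.sf(ap - 1, n, p)
    if out.ndim == 0 or (np.isscalar(a) and np.isscalar(mu)):
        return float(out.reshape(-1)[0]) if out.size == 1 else out
    return out


# ---------------------------------------------------------------------------
# classical (non-robust) fit


def _nll(e: float, sigma: float, ao: np.ndarray, dp: np.ndarray) -> float:
    return -float(np.sum(_nb_logpmf(ao, e * dp, sigma)))


def _profile_e(sigma: float, ao: np.ndarray, dp: np.ndarray) -> float:
    """MLE of e for fixed sigma (1-D bounded search in log10 e)."""
    res = optimize.minimize_scalar(
        lambda le: _nll(10.0**le, sigma, ao, dp),
        bounds=(-12.0, 0.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return 10.0 ** float(res.x)


def classical_nb_fit(
    site: "SitePileup",
    sigma_bounds: tuple[float, float] = (1e-8, 1e4),
) -> tuple[float, float]:
    """Zero-intercept, linear-link maximum-likelihood NB fit (no weights).

    Profile likelihood: the outer search maximizes over sigma within
    ``sigma_bounds``, the inner over e.  Returns ``(e_hat, sigma_hat)``.
    """
    ao = np.array([s.ao for s in site.samples], dtype=float)
    dp = np.array([s.dp for s in site.samples], dtype=float)
    usable = dp > 0
    if usable.sum() < 2:
        raise FitError("insufficient cohort: need >= 2 samples with DP > 0")
    ao, dp = ao[usable], dp[usable]
    if np.all(ao == 0):
        return 0.0, sigma_bounds[0]
    lo, hi = np.log10(sigma_bounds)

    def neg_profile(ls: float) -> float:
        sigma = 10.0**ls
        return _nll(_profile_e(sigma, ao, dp), sigma, ao, dp)

    res = optimize.minimize_scalar(
        neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    sigma_hat = 10.0 ** float(res.x)
    e_hat = _profile_e(sigma_hat, ao, dp)
    if not (np.isfinite(e_hat) and np.isfinite(sigma_hat)):
        raise FitError("non-finite optimizer state in classical fit")
    return e_hat, sigma_hat


# ---------------------------------------------------------------------------
# robust fit


def _fisher_correction(mu: float, sigma: float, c: float, normal_approx_mu: float) -> float:
    """E[w(r(X)) * (X - mu)] under the model, for the e estimating equation.

    Exact by summation over the NB support when mu is moderate; for large
    mu the NB is close to Gaussian and the Huber-weighted first moment
    vanishes by symmetry, so 0 is returned.
    """
    if mu <= 0 or mu > normal_approx_mu:
        return 0.0
    var = mu + sigma * mu * mu
    sd = np.sqrt(var)
    kmax = int(np.ceil(mu + 12.0 * sd + 20.0))
    k = np.arange(kmax + 1, dtype=float)
    pmf = np.exp(_nb_logpmf(k, np.full_like(k, mu), sigma))
    r = (k - mu) / sd
    w = np.minimum(1.0, c / np.maximum(np.abs(r), 1e-12))
    return float(np.sum(w * (k - mu) * pmf))


def _sigma_mle_truncated(
    ao: np.ndarray, dp: np.ndarray, e: float, keep: np.ndarray, bounds: tuple[float, float]
) -> float:
    """Maximize the log-likelihood over sigma using only in-band samples."""
    if keep.sum() < 2:
        keep = np.ones_like(keep, dtype=bool)
    a, d = ao[keep], dp[keep]
    if np.all(a == 0):
        # zeros alone cannot identify overdispersion (their likelihood is
        # monotone in sigma); default to the parsimonious Poisson end
        return bounds[0]
    lo, hi = np.log10(bounds)
    res = optimize.minimize_scalar(
        lambda ls: _nll(e, 10.0**ls, a, d),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    return 10.0 ** float(res.x)


def _irls(
    ao: np.ndarray, dp: np.ndarray, e: float, sigma: float, cfg: FitConfig
) -> tuple[float, float, np.ndarray, int, bool]:
    """One run of the robust iteration from a given starting point."""
    c = cfg.huber_c
    converged = False
    n_iter = 0
    w = np.ones_like(ao)
    for n_iter in range(1, cfg.max_iter + 1):
        mu = e * dp
        var = np.maximum(mu + sigma * mu * mu, 1e-300)
        r = (ao - mu) / np.sqrt(var)
        w = np.minimum(1.0, c / np.maximum(np.abs(r), 1e-12))

        # Fisher-consistency correction, grouped by unique mu
        corr = np.zeros_like(mu)
        if np.any(mu <= cfg.normal_approx_mu):
            uniq, inv = np.unique(mu, return_inverse=True)
            cvals = np.array(
                [_fisher_correction(m, sigma, c, cfg.normal_approx_mu) for m in uniq]
            )
            corr = cvals[inv]

        num = float(np.sum(w * ao * dp / var) - np.sum(dp / var * corr))
        den = float(np.sum(w * dp * dp / var))
        if not np.isfinite(num) or not np.isfinite(den) or den <= 0:
            raise FitError(
                f"non-finite optimizer state (e={e:.3g}, sigma={sigma:.3g}, iter={n_iter})"
            )
        e_new = max(num / den, 0.0)
        if e_new == 0.0:
            e_new = 1.0 / float(np.sum(dp))  # keep the link alive; data has AO > 0

        var_new = np.maximum(e_new * dp * (1 + sigma * e_new * dp), 1e-300)
        keep = np.abs((ao - e_new * dp) / np.sqrt(var_new)) <= c
        sigma_new = _sigma_mle_truncated(ao, dp, e_new, keep, cfg.sigma_bounds)

        de = abs(e_new - e) / max(e, 1e-300)
        ds = abs(sigma_new - sigma) / max(sigma, 1e-300)
        e, sigma = e_new, sigma_new
        if de < cfg.tol and ds < cfg.tol:
            converged = True
            break
    return e, sigma, w, n_iter, converged


def fit_error_model(site: "SitePileup", cfg: FitConfig | None = None) -> ErrorModelFit:
    """Robust per-alteration fit of ``(e, sigma)`` across the cohort.

    Samples with DP = 0 are excluded from fitting (weight reported as 1);
    in extra-robust mode, samples with VAF above ``extra_robust_vaf`` are
    pre-excluded whenever at least two such samples exist (weight 0,
    counted in ``n_excluded``).  Deterministic for fixed input and config.
    """
    if cfg is None:
        cfg = FitConfig()
    ao_all = np.array([s.ao for s in site.samples], dtype=float)
    dp_all = np.array([s.dp for s in site.samples], dtype=float)
    n = len(ao_all)
    weights = np.ones(n)

    fit_mask = dp_all > 0
    n_excluded = 0
    if cfg.extra_robust:
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(dp_all > 0, ao_all / np.maximum(dp_all, 1), 0.0)
        high = fit_mask & (vaf > cfg.extra_robust_vaf)
        if high.sum() >= 2:
            fit_mask &= ~high
            n_excluded = int(high.sum())
            weights[high] = 0.0

    if fit_mask.sum() < 2:
        raise FitError("insufficient cohort: need >= 2 samples with DP > 0")
    ao, dp = ao_all[fit_mask], dp_all[fit_mask]

    if np.all(ao == 0):
        return ErrorModelFit(
            e_hat=0.0,
            sigma_hat=cfg.sigma_bounds[0],
            weights=weights,
            n_iter=0,
            converged=True,
            n_excluded=n_excluded,
        )

    # initialization: pooled rate; method-of-moments overdispersion on the
    # Poisson-scale residuals, trimmed of outliers so spiked samples do not
    # inflate the starting sigma (untrimmed fallback when trimming removes
    # nearly everything, i.e. heavy contamination)
    e0 = float(np.sum(ao) / np.sum(dp))
    mu0 = e0 * dp
    with np.errstate(invalid="ignore", divide="ignore"):
        r0 = (ao - mu0) / np.sqrt(mu0)
        mom = ((ao - mu0) ** 2 / mu0 - 1.0) / mu0
    inlier = np.abs(r0) <= cfg.huber_c
    if inlier.sum() >= 2:
        sigma0 = float(np.clip(np.nanmean(mom[inlier]), *cfg.sigma_bounds))
    else:
        sigma0 = float(np.clip(np.nanmean(mom), *cfg.sigma_bounds))

    e, sigma, w, n_iter, converged = _irls(ao, dp, e0, sigma0, cfg)

    # Degenerate-solution escape hatch.  When the rate estimate is grossly
    # inflated relative to the cohort's typical rate (or sigma ran to its
    # bound), the iteration was likely captured by a solution that absorbs
    # extreme outliers into the error model.  Refit from a resistant
    # starting point and keep that fit only when it rejects a small
    # minority of samples — within the estimator's breakdown regime.
    # Heavier contamination (variants shared by >~20% of the cohort) is
    # deliberately left absorbed.
    e_floor = max(float(np.median(ao / dp)), 1.0 / float(np.sum(dp)))
    degenerate = sigma >= 0.99 * cfg.sigma_bounds[1] or e > 10.0 * e_floor
    if degenerate:
        e_r, sigma_r, w_r, it_r, conv_r = _irls(ao, dp, e_floor, cfg.sigma_bounds[0], cfg)
        hard = float(np.mean(w_r <= 0.2))
        if sigma_r < 0.99 * cfg.sigma_bounds[1] and hard <= 0.10:
            e, sigma, w, n_iter, converged = e_r, sigma_r, w_r, it_r, conv_r

    weights[fit_mask] = w
    return ErrorModelFit(
        e_hat=e,
        sigma_hat=sigma,
        weights=weights,
        n_iter=n_iter,
        converged=converged,
        n_excluded=n_excluded,
    )
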