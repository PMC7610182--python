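"""Two-sample Mendelian randomisation estimators and sensitivity diagnostics.

Given J harmonised instruments with SNP-exposure effects (gamma_hat,
sigma_gamma) and SNP-outcome effects (Gamma_hat, sigma_Gamma), the causal
effect of the exposure on the outcome is estimated five ways, each robust to
a different pattern of horizontal pleiotropy:

* inverse-variance weighted (IVW) — weighted regression of Gamma_hat on
  gamma_hat through the origin; consistent when all instruments are valid;
* MR-Egger — the same regression with an intercept absorbing directional
  pleiotropy under the InSIDE assumption, with a SIMEX correction for the
  regression dilution caused by noisy exposure effects (quantified by I2_GX);
* weighted median — consistent when under half the weight sits on invalid
  instruments;
* weighted mode — consistent when the largest group of instruments sharing a
  Wald ratio is valid (plurality rule);
* MR-RAPS — profile-likelihood estimation accounting for exposure-side
  measurement error, optionally with a robust (Huber) loss and an
  overdispersion parameter for systematic pleiotropy.

Diagnostics: Cochran's Q heterogeneity, the Egger intercept test, I2_GX,
the mean F statistic of instrument strength, and Steiger directionality
filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("smokemr")

Z95 = 1.959963984540054  # Phi^{-1}(0.975)
HUBER_C = 1.345


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


class ConvergenceError(RuntimeError):
    """Optimiser failed; carries the optimiser trace in ``trace``."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate (log-OR scale for binary outcomes)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    note: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


class EggerResult(NamedTuple):
    estimate: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class Diagnostics:
    """Sensitivity diagnostics accompanying an MR analysis."""

    cochran_q: float = np.nan
    q_df: int = 0
    q_pval: float = np.nan
    egger_intercept: float = np.nan
    intercept_se: float = np.nan
    intercept_pval: float = np.nan
    i2_gx: float = np.nan
    mean_f: float = np.nan
    steiger_correct_fraction: float = np.nan
    steiger_overall_correct: Optional[bool] = None
    steiger_pval: float = np.nan


def _unpack(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept a HarmonisedDataset, a DataFrame or a 4-tuple of arrays."""
    if hasattr(data, "gamma_hat") and hasattr(data, "sigma_Gamma"):
        return (
            np.asarray(data.gamma_hat, float),
            np.asarray(data.sigma_gamma, float),
            np.asarray(data.Gamma_hat, float),
            np.asarray(data.sigma_Gamma, float),
        )
    if hasattr(data, "columns"):
        return (
            data["gamma_hat"].to_numpy(float),
            data["sigma_gamma"].to_numpy(float),
            data["Gamma_hat"].to_numpy(float),
            data["sigma_Gamma"].to_numpy(float),
        )
    g, sg, G, sG = (np.asarray(a, float) for a in data)
    return g, sg, G, sG


def _estimate(method, beta, se, n_snp, df=None, note="") -> MREstimate:
    beta, se = float(beta), float(se)
    if df is not None and df > 0:
        pval = 2 * stats.t.sf(abs(beta / se), df) if se > 0 else 0.0
    else:
        pval = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 0.0
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pval=float(pval),
        n_snp=int(n_snp),
        note=note,
    )


# ---------------------------------------------------------------------------
# Single-SNP base case
# ---------------------------------------------------------------------------

def wald_ratio(
    gamma_hat: float,
    sigma_gamma: float,
    Gamma_hat: float,
    sigma_Gamma: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-SNP ratio estimate Gamma_hat / gamma_hat.

    The default SE is the first-order delta method sigma_Gamma/|gamma_hat|;
    ``second_order`` adds the exposure-uncertainty inflation term
    Gamma_hat^2 * sigma_gamma^2 / gamma_hat^4.
    """
    if gamma_hat == 0:
        raise ZeroDivisionError("Wald ratio undefined: SNP-exposure effect is zero")
    beta = Gamma_hat / gamma_hat
    var = sigma_Gamma**2 / gamma_hat**2
    if second_order:
        var += Gamma_hat**2 * sigma_gamma**2 / gamma_hat**4
    return _estimate("Wald", beta, np.sqrt(var), 1)


# ---------------------------------------------------------------------------
# IVW and MR-Egger (weighted regressions)
# ---------------------------------------------------------------------------

def ivw(data, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of Gamma_hat on gamma_hat through the origin with
    weights 1/sigma_Gamma^2. With ``random_effects`` (default) the SE is
    inflated by the multiplicative residual scale max(1, sqrt(Q/(J-1))); the
    p-value comes from a t distribution with J-1 df. A single SNP delegates
    to :func:`wald_ratio`.
    """
    g, sg, G, sG = _unpack(data)
    J = g.size
    if J == 0:
        raise InsufficientInstrumentsError("no instruments")
    if J == 1:
        return wald_ratio(g[0], sg[0], G[0], sG[0])
    w = 1.0 / sG**2
    beta = np.sum(w * g * G) / np.sum(w * g**2)
    Q = float(np.sum(w * (G - beta * g) ** 2))
    scale = max(1.0, np.sqrt(Q / (J - 1))) if random_effects else 1.0
    se = scale / np.sqrt(np.sum(w * g**2))
    return _estimate("IVW", beta, se, J, df=J - 1)


def _orient(g, G):
    """Force all SNP-exposure effects non-negative by joint sign flips."""
    s = np.where(g < 0, -1.0, 1.0)
    return s * g, s * G


def _wls_line(x, y, w):
    """Weighted least squares y ~ a + b x; returns a, b, se_a, se_b, rss_w, df."""
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    b = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    a = ybar - b * xbar
    resid = y - a - b * x
    rss_w = float(np.sum(w * resid**2))
    var_b = 1.0 / sxx
    var_a = 1.0 / W + xbar**2 / sxx
    return a, b, np.sqrt(var_a), np.sqrt(var_b), rss_w, x.size - 2


def egger(data, random_effects: bool = True) -> EggerResult:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy (valid under InSIDE).

    Instruments are canonically oriented (gamma_hat >= 0 via joint sign
    flips) before the weighted regression with intercept, weights
    1/sigma_Gamma^2; p-values use t with J-2 df and the same multiplicative
    random-effects scaling as IVW.
    """
    g, sg, G, sG = _unpack(data)
    J = g.size
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {J}")
    g, G = _orient(g, G)
    w = 1.0 / sG**2
    a, b, se_a, se_b, rss_w, dof = _wls_line(g, G, w)
    scale = max(1.0, np.sqrt(rss_w / dof)) if random_effects else 1.0
    se_b *= scale
    se_a *= scale
    est = _estimate("Egger", b, se_b, J, df=dof)
    int_p = 2 * stats.t.sf(abs(a / se_a), dof) if se_a > 0 else 0.0
    return EggerResult(est, float(a), float(se_a), float(int_p))


# ---------------------------------------------------------------------------
# Heterogeneity / instrument-strength diagnostics
# ---------------------------------------------------------------------------

def cochran_q(data, beta: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of per-SNP effects about a causal slope."""
    g, sg, G, sG = _unpack(data)
    J = g.size
    if J < 2:
        raise InsufficientInstrumentsError("Q needs >= 2 SNPs")
    Q = float(np.sum((G - beta * g) ** 2 / sG**2))
    df = J - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def i2_gx(gamma_hat, sigma_gamma) -> float:
    """I2_GX: fraction of variability in the SNP-exposure effects not due to
    their estimation error. Values near 1 mean MR-Egger suffers little
    regression dilution; low values trigger a SIMEX correction."""
    g = np.asarray(gamma_hat, float)
    sg = np.asarray(sigma_gamma, float)
    if g.size < 2:
        raise InsufficientInstrumentsError("I2_GX needs >= 2 SNPs")
    w = 1.0 / sg**2
    gbar = np.sum(w * g) / np.sum(w)
    Q = float(np.sum(w * (g - gbar) ** 2))
    if Q <= 0:
        return 0.0
    return float(np.clip((Q - (g.size - 1)) / Q, 0.0, 1.0))


def mean_f(gamma_hat, sigma_gamma) -> float:
    """Mean per-SNP F statistic, gamma_hat^2/sigma_gamma^2 — instrument
    strength; values well above 10 indicate weak-instrument bias is minor."""
    g = np.asarray(gamma_hat, float)
    sg = np.asarray(sigma_gamma, float)
    if g.size < 1:
        raise InsufficientInstrumentsError("mean F needs >= 1 SNP")
    return float(np.mean(g**2 / sg**2))


# ---------------------------------------------------------------------------
# SIMEX-corrected Egger
# ---------------------------------------------------------------------------

def simex_egger(
    data,
    lambda_grid: Sequence[float] = tuple(np.arange(0.0, 2.25, 0.25)),
    n_boot: int = 1000,
    seed: Optional[int] = None,
    weighted: bool = False,
    se_boot: int = 100,
) -> MREstimate:
    """Simulation-extrapolation correction of the Egger slope for
    exposure-side measurement error.

    For each lambda in the grid, measurement error in gamma_hat is inflated
    by adding sqrt(lambda)*sigma_gamma*eps noise; the (by default unweighted)
    Egger slope is averaged over ``n_boot`` replicates; a quadratic in lambda
    is extrapolated to lambda = -1, the error-free limit. The SE comes from a
    nonparametric bootstrap over SNPs. A degenerate extrapolation fit falls
    back to the uncorrected slope with a warning, flagged in ``note``.
    """
    g, sg, G, sG = _unpack(data)
    J = g.size
    if J < 3:
        raise InsufficientInstrumentsError(f"SIMEX-Egger needs >= 3 SNPs, got {J}")
    rng = np.random.default_rng(seed)
    g, G = _orient(g, G)
    w = 1.0 / sG**2 if weighted else np.ones(J)

    point = _simex_point(g, sg, G, w, np.asarray(lambda_grid, float), n_boot, rng)
    if point is None:
        warnings.warn(
            "SIMEX extrapolation degenerate: returning uncorrected Egger slope",
            RuntimeWarning,
            stacklevel=2,
        )
        b = _wls_line(g, G, w)[1]
        se = egger((g, sg, G, sG)).estimate.se
        return _estimate("Egger-SIMEX", b, se, J, note="degenerate extrapolation; uncorrected")

    boots = np.empty(se_boot)
    inner = max(50, n_boot // 10)
    for b_i in range(se_boot):
        idx = rng.integers(0, J, J)
        val = _simex_point(
            g[idx], sg[idx], G[idx], w[idx], np.asarray(lambda_grid, float), inner, rng
        )
        boots[b_i] = point if val is None else val
    se = float(np.std(boots, ddof=1))
    return _estimate("Egger-SIMEX", point, se, J)


def _simex_point(g, sg, G, w, lambdas, n_boot, rng) -> Optional[float]:
    """Mean noisy-Egger slope per lambda, quadratically extrapolated to -1."""
    means = np.empty(lambdas.size)
    for i, lam in enumerate(lambdas):
        if lam == 0:
            means[i] = _wls_line(g, G, w)[1]
            continue
        eps = rng.standard_normal((n_boot, g.size))
        gs = g + np.sqrt(lam) * sg * eps  # (B, J)
        means[i] = np.mean(_batch_wls_slope(gs, G, w))
    if lambdas.size == 1:
        return float(means[0])
    deg = 2 if lambdas.size >= 3 else 1
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coef = np.polyfit(lambdas, means, deg)
        except np.exceptions.RankWarning:
            return None
    if not np.all(np.isfinite(coef)):
        return None
    return float(np.polyval(coef, -1.0))


def _batch_wls_slope(X, y, w):
    """Weighted slope with intercept for each row of X against common y."""
    W = np.sum(w)
    xbar = X @ w / W  # (B,)
    ybar = np.sum(w * y) / W
    dx = X - xbar[:, None]
    sxy = dx @ (w * (y - ybar))
    sxx = np.sum(w * dx**2, axis=1)
    return sxy / sxx


# ---------------------------------------------------------------------------
# Weighted median and weighted mode
# ---------------------------------------------------------------------------

def _ratio_weights(g, sg, G, sG):
    ratios = G / g
    weights = g**2 / sG**2  # first-order inverse variance of the ratio
    return ratios, weights


def weighted_median_point(ratios, weights) -> float:
    """Weighted median with linear interpolation at the 50% weight crossing."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5))
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1]))


def weighted_median(data, n_boot: int = 1000, seed: Optional[int] = None) -> MREstimate:
    """Weighted-median estimator; SE by parametric bootstrap resampling
    (gamma_hat, Gamma_hat) from their standard errors."""
    g, sg, G, sG = _unpack(data)
    J = g.size
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {J}")
    ratios, weights = _ratio_weights(g, sg, G, sG)
    beta = weighted_median_point(ratios, weights)
    se = _parametric_boot_se(g, sg, G, sG, weighted_median_point, n_boot, seed)
    return _estimate("weighted-median", beta, se, J)


def _silverman_bandwidth(ratios, factor: float) -> float:
    r = np.asarray(ratios, float)
    s = np.std(r, ddof=1)
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    if spread <= 0:
        spread = max(abs(np.mean(r)), 1.0) * 1e-8
    return factor * 0.9 * spread * r.size ** (-0.2)


def weighted_mode_point(ratios, weights, bandwidth: float) -> float:
    """Mode of the weight-weighted normal-kernel density of the ratios."""
    r = np.asarray(ratios, float)
    w = np.asarray(weights, float)
    h = max(bandwidth, 1e-300)
    grid = np.concatenate([np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512), r])
    grid = np.unique(grid)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def weighted_mode(
    data,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> MREstimate:
    """Weighted-mode estimator: the densest cluster of Wald ratios under an
    inverse-variance-weighted normal kernel (bandwidth = factor x modified
    Silverman rule); SE by parametric bootstrap."""
    g, sg, G, sG = _unpack(data)
    J = g.size
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs >= 3 SNPs, got {J}")
    ratios, weights = _ratio_weights(g, sg, G, sG)
    h = _silverman_bandwidth(ratios, bandwidth_factor)
    beta = weighted_mode_point(ratios, weights, h)

    def _point(rr, ww):
        return weighted_mode_point(rr, ww, _silverman_bandwidth(rr, bandwidth_factor))

    se = _parametric_boot_se(g, sg, G, sG, _point, n_boot, seed)
    return _estimate("weighted-mode", beta, se, J)


def _parametric_boot_se(g, sg, G, sG, point_fn, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        gb = g + sg * rng.standard_normal(g.size)
        Gb = G + sG * rng.standard_normal(g.size)
        gb = np.where(gb == 0, np.finfo(float).tiny, gb)
        ests[b] = point_fn(Gb / gb, gb**2 / sG**2)
    return float(np.std(ests, ddof=1))


# ---------------------------------------------------------------------------
# MR-RAPS (robust adjusted profile score)
# ---------------------------------------------------------------------------

def _huber_rho(t, c=HUBER_C):
    a = np.abs(t)
    return np.where(a <= c, 0.5 * t**2, c * a - 0.5 * c**2)


def _delta(loss: str) -> float:
    """Consistency constant E[psi(Z)Z] for Z ~ N(0,1).

    For the Huber psi: E[Z^2 1{|Z|<c}] + c E[|Z| 1{|Z|>=c}]
    = (1 - 2*sf(c) - 2c*pdf(c)) + c*2*pdf(c) = P(|Z| < c).
    """
    if loss == "simple":
        return 1.0
    return 1.0 - 2.0 * stats.norm.sf(HUBER_C)


def mr_raps(
    data,
    overdispersion: bool = False,
    loss: str = "simple",
) -> MREstimate:
    """MR-RAPS: profile-likelihood causal estimate accounting for
    measurement error in the SNP-exposure effects.

    Standardised residuals t_j(beta) = (Gamma_hat_j - beta*gamma_hat_j) /
    sqrt(sigma_Gamma_j^2 + beta^2*sigma_gamma_j^2) are combined through a
    simple squared loss or a Huber loss (tuning constant 1.345). With
    ``overdispersion`` a non-negative variance-inflation parameter tau2 is
    estimated jointly, absorbing systematic (balanced) pleiotropy. The SE is
    the sandwich estimate from the profile score.
    """
    g, sg, G, sG = _unpack(data)
    J = g.size
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-RAPS needs >= 3 SNPs, got {J}")
    if loss not in ("simple", "huber"):
        raise ValueError(f"unknown loss {loss!r}")
    rho = (lambda t: 0.5 * t**2) if loss == "simple" else _huber_rho
    delta = _delta(loss)

    def tvals(beta, tau2):
        v = sG**2 + beta**2 * sg**2 + tau2
        return (G - beta * g) / np.sqrt(v), v

    def objective(params):
        beta = params[0]
        tau2 = np.exp(params[1]) if overdispersion else 0.0
        t, v = tvals(beta, tau2)
        return float(np.sum(rho(t)) + 0.5 * delta * np.sum(np.log(v)))

    beta0 = ivw((g, sg, G, sG), random_effects=False).beta
    if overdispersion:
        x0 = np.array([beta0, np.log(np.mean(sG**2) + 1e-8)])
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if not res.success:
            raise ConvergenceError(f"MR-RAPS failed to converge: {res.message}", trace=res)
        beta_hat, tau2_hat = float(res.x[0]), float(np.exp(res.x[1]))
    else:
        f1 = lambda b: objective([b])
        br = max(1.0, 10 * abs(beta0))
        res = optimize.minimize_scalar(f1, bracket=(beta0 - br, beta0, beta0 + br),
                                       method="brent", options={"xtol": 1e-12})
        if not np.isfinite(res.x):
            raise ConvergenceError("MR-RAPS failed to converge", trace=res)
        beta_hat, tau2_hat = float(res.x), 0.0

    se = _raps_sandwich_se(g, sg, G, sG, beta_hat, tau2_hat, rho, delta)
    note = f"loss={loss}, overdispersion={overdispersion}"
    return _estimate("RAPS", beta_hat, se, J, note=note)


def _raps_sandwich_se(g, sg, G, sG, beta, tau2, rho, delta) -> float:
    """Sandwich variance A^-1 B A^-1 from numerical profile-score derivatives."""
    h = 1e-5 * max(1.0, abs(beta))

    def per_snp_loss(b):
        v = sG**2 + b**2 * sg**2 + tau2
        return rho((G - b * g) / np.sqrt(v)) + 0.5 * delta * np.log(v)

    s_plus = per_snp_loss(beta + h)
    s_minus = per_snp_loss(beta - h)
    score_j = (s_plus - s_minus) / (2 * h)  # per-SNP d rho/d beta
    B = float(np.sum(score_j**2))
    total = lambda b: float(np.sum(per_snp_loss(b)))
    A = (total(beta + h) - 2 * total(beta) + total(beta - h)) / h**2
    if A <= 0 or B <= 0:
        # fall back to inverse observed information
        return float(np.sqrt(1.0 / max(A, np.finfo(float).tiny)))
    return float(np.sqrt(B) / A)


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

@dataclass
class SteigerResult:
    flags: np.ndarray  # per SNP: "correct" | "reverse" | "indeterminate" | "unknown"
    r2_exposure: np.ndarray
    r2_outcome: np.ndarray
    overall_correct: bool
    z: float
    pval: float
    retained_index: np.ndarray


def snp_r2(beta, eaf) -> np.ndarray:
    """Variance explained by one SNP on a standardised trait scale:
    2 * beta^2 * eaf * (1 - eaf). Used as a liability-scale approximation
    for binary traits."""
    beta = np.asarray(beta, float)
    eaf = np.asarray(eaf, float)
    return 2.0 * beta**2 * eaf * (1 - eaf)


def steiger_filter(
    data,
    exposure_n: float,
    outcome_n: float,
    eaf: Optional[np.ndarray] = None,
) -> SteigerResult:
    """Per-SNP directionality check: a valid instrument for exposure -> outcome
    should explain more variance in the exposure than in the outcome.

    SNPs with ``r2_exposure > r2_outcome`` are flagged correct and retained;
    reverse-direction SNPs are filtered out; exact ties are flagged
    indeterminate and retained (logged); SNPs with missing allele frequency
    cannot be assessed ("unknown") and are retained, logged. The overall
    direction combines a majority vote with a z-test comparing the summed
    variance explained between studies (Fisher-z on the implied multiple
    correlations)."""
    g, sg, G, sG = _unpack(data)
    if eaf is None:
        eaf = np.asarray(getattr(data, "eaf"), float)
    else:
        eaf = np.asarray(eaf, float)
    J = g.size
    r2x = snp_r2(g, eaf)
    r2y = snp_r2(G, eaf)
    flags = np.empty(J, dtype=object)
    for j in range(J):
        if not np.isfinite(eaf[j]):
            flags[j] = "unknown"
            logger.warning("Steiger: SNP %d missing eaf, excluded from filtering", j)
        elif r2x[j] > r2y[j]:
            flags[j] = "correct"
        elif r2x[j] < r2y[j]:
            flags[j] = "reverse"
        else:
            flags[j] = "indeterminate"
            logger.info("Steiger: SNP %d has r2_X == r2_Y, retained as indeterminate", j)
    retained = np.array([f in ("correct", "indeterminate", "unknown") for f in flags])

    known = np.isfinite(eaf)
    sum_x = float(np.clip(np.nansum(np.where(known, r2x, 0.0)), 0, 0.999999))
    sum_y = float(np.clip(np.nansum(np.where(known, r2y, 0.0)), 0, 0.999999))
    rX, rY = np.sqrt(sum_x), np.sqrt(sum_y)
    denom = np.sqrt(1.0 / max(exposure_n - 3, 1) + 1.0 / max(outcome_n - 3, 1))
    z = (np.arctanh(rX) - np.arctanh(rY)) / denom
    pval = 2 * stats.norm.sf(abs(z))
    n_correct = int(np.sum(flags == "correct"))
    n_reverse = int(np.sum(flags == "reverse"))
    overall = n_correct >= n_reverse
    return SteigerResult(
        flags=flags,
        r2_exposure=r2x,
        r2_outcome=r2y,
        overall_correct=bool(overall),
        z=float(z),
        pval=float(pval),
        retained_index=np.flatnonzero(retained),
    )


# ---------------------------------------------------------------------------
# Orchestration: all five methods + diagnostics
# ---------------------------------------------------------------------------

@dataclass
class MRConfig:
    """Settings for a full per-direction MR analysis."""

    outcome_type: str = "binary"  # "binary" reports ORs; "continuous" betas
    random_effects: bool = True
    i2_simex_trigger: float = 0.9
    simex_lambda_grid: tuple = tuple(np.arange(0.0, 2.25, 0.25))
    n_boot: int = 1000
    seed: int = 0
    bandwidth_factor: float = 1.0
    raps_overdispersion: bool = False
    raps_loss: str = "simple"
    steiger: bool = False
    exposure_n: float = np.nan
    outcome_n: float = np.nan
    exclude_snps: tuple = ()


def run_mr(data, config: Optional[MRConfig] = None):
    """Run the five estimators plus diagnostics on a harmonised dataset.

    Returns ``(results, diagnostics)`` where results is a pandas DataFrame
    with one row per method (OR columns populated for binary outcomes) and
    diagnostics a :class:`Diagnostics`. Per-method failures become row
    annotations; they never abort the remaining methods. One SNP yields the
    Wald-ratio row alone.
    """
    import pandas as pd

    cfg = config or MRConfig()
    if cfg.exclude_snps and hasattr(data, "exclude"):
        data = data.exclude(cfg.exclude_snps)
    g, sg, G, sG = _unpack(data)
    J = g.size
    diag = Diagnostics()
    rows: list[dict] = []

    def add(est: MREstimate):
        row = {
            "method": est.method,
            "n_snp": est.n_snp,
            "beta": est.beta,
            "se": est.se,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "pval": est.pval,
            "note": est.note,
        }
        if cfg.outcome_type == "binary":
            row["or"] = est.odds_ratio
            row["or_ci_low"], row["or_ci_high"] = est.or_ci
        rows.append(row)

    def add_error(method, exc):
        rows.append({"method": method, "n_snp": J, "beta": np.nan, "se": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "pval": np.nan,
                     "note": f"failed: {exc}"})

    if J == 0:
        raise InsufficientInstrumentsError("no instruments after filtering")
    if J == 1:
        add(wald_ratio(g[0], sg[0], G[0], sG[0]))
        return pd.DataFrame(rows), diag

    ivw_est = None
    try:
        ivw_est = ivw(data, random_effects=cfg.random_effects)
        add(ivw_est)
    except Exception as exc:  # noqa: BLE001 — per-method isolation
        add_error("IVW", exc)

    diag.mean_f = mean_f(g, sg)
    diag.i2_gx = i2_gx(g, sg)
    if ivw_est is not None:
        diag.cochran_q, diag.q_df, diag.q_pval = cochran_q(data, ivw_est.beta)

    try:
        eg = egger(data, random_effects=cfg.random_effects)
        add(eg.estimate)
        diag.egger_intercept = eg.intercept
        diag.intercept_se = eg.intercept_se
        diag.intercept_pval = eg.intercept_pval
    except Exception as exc:
        add_error("Egger", exc)

    if diag.i2_gx < cfg.i2_simex_trigger:
        try:
            add(simex_egger(data, lambda_grid=cfg.simex_lambda_grid,
                            n_boot=cfg.n_boot, seed=cfg.seed))
        except Exception as exc:
            add_error("Egger-SIMEX", exc)

    try:
        add(weighted_median(data, n_boot=cfg.n_boot, seed=cfg.seed))
    except Exception as exc:
        add_error("weighted-median", exc)
    try:
        add(weighted_mode(data, bandwidth_factor=cfg.bandwidth_factor,
                          n_boot=cfg.n_boot, seed=cfg.seed))
    except Exception as exc:
        add_error("weighted-mode", exc)
    try:
        add(mr_raps(data, overdispersion=cfg.raps_overdispersion, loss=cfg.raps_loss))
    except Exception as exc:
        add_error("RAPS", exc)

    if cfg.steiger and np.isfinite(cfg.exposure_n) and np.isfinite(cfg.outcome_n):
        try:
            st = steiger_filter(data, cfg.exposure_n, cfg.outcome_n)
            diag.steiger_correct_fraction = float(np.mean(st.flags == "correct"))
            diag.steiger_overall_correct = st.overall_correct
            diag.steiger_pval = st.pval
        except Exception as exc:
            logger.warning("Steiger filtering failed: %s", exc)

    return pd.DataFrame(rows), diag
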