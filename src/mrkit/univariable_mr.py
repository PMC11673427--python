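"""Univariable two-sample MR estimators.

Given harmonised per-SNP effects (beta_x, se_x) on the exposure and
(beta_y, se_y) on the outcome for J independent instruments, the causal
effect theta of a 1-SD change in the exposure on the outcome (log-odds
for a binary outcome) is estimated by:

* per-SNP Wald ratios beta_y / beta_x;
* IVW — inverse-variance-weighted meta-analysis of the ratios,
  equivalently zero-intercept weighted regression of beta_y on beta_x
  with weights 1/se_y^2, with multiplicative random effects (SE inflated
  by sqrt(max(1, Q/(J-1))));
* the weighted median of the ratios, consistent with up to 50% invalid
  instruments, with a parametric-bootstrap SE;
* MR-Egger — the same regression with a free intercept estimating the
  average directional pleiotropic effect (requires positive exposure
  orientation and the InSIDE assumption);
* MR-Egger with SIMEX, correcting the regression-dilution ("NOME
  violation") bias of Egger's slope when the SNP-exposure effects carry
  non-negligible measurement error (low I2_GX): noise of variance
  lambda * se_x^2 is added for a grid of lambda, the coefficient trend is
  modelled quadratically and extrapolated back to lambda = -1.

Estimates are reported on the log scale with normal 95% CIs and, for
reporting against a binary outcome, as odds ratios by exponentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats_io import HarmonisedSet, orient_positive_exposure

__all__ = [
    "MREstimate",
    "EggerFit",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "mr_egger",
    "egger_simex",
]

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MREstimate:
    """A method-labelled causal estimate on the log(-odds) scale."""

    method: str
    beta: float
    se: float
    n_snps: int
    pval: float | None = None

    def __post_init__(self) -> None:
        if self.pval is None:
            self.pval = 2.0 * float(stats.norm.sf(abs(self.beta) / self.se))

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def or_scale(self) -> tuple[float, float, float]:
        """(OR, CI low, CI high) by exponentiation, for binary outcomes."""
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))

    def as_row(self) -> dict:
        orr, lo, hi = self.or_scale
        return {
            "method": self.method,
            "n_snp": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "or": orr,
            "ci_low": lo,
            "ci_high": hi,
            "pval": self.pval,
        }


@dataclass
class EggerFit:
    """MR-Egger slope plus the pleiotropy intercept and I2_GX diagnostic."""

    slope: MREstimate
    intercept_beta: float
    intercept_se: float
    intercept_p: float
    i2_gx: float | None = None
    q_prime: float | None = None


def wald_ratios(h: HarmonisedSet, second_order: bool = False) -> list[MREstimate]:
    """Per-SNP causal estimates beta_y / beta_x.

    SE is the first-order delta-method |se_y / beta_x| by default; the
    second-order form adds the beta_x uncertainty term
    beta_y^2 se_x^2 / beta_x^4.  SNPs with beta_x == 0 are dropped with
    a warning; all zero is an error.
    """
    nz = h.beta_x != 0
    if not nz.any():
        raise ValueError("all exposure betas are zero; Wald ratios undefined")
    bx, by, sx, sy = h.beta_x[nz], h.beta_y[nz], h.se_x[nz], h.se_y[nz]
    ratio = by / bx
    var = sy**2 / bx**2
    if second_order:
        var = var + by**2 * sx**2 / bx**4
    se = np.sqrt(var)
    return [
        MREstimate(method="Wald_ratio", beta=float(r), se=float(s), n_snps=1)
        for r, s in zip(ratio, se)
    ]


def ivw(
    h: HarmonisedSet, re_mode: str = "multiplicative_random"
) -> tuple[MREstimate, float]:
    """IVW estimate and Cochran's Q.

    Weighted zero-intercept regression of beta_y on beta_x with weights
    1/se_y^2.  Under multiplicative random effects the fixed-effect SE is
    inflated by sqrt(phi), phi = max(1, Q/(J-1)); fixed and random
    coincide when Q <= J-1.
    """
    j = len(h)
    if j < 2:
        raise ValueError("IVW requires at least 2 SNPs")
    w = 1.0 / h.se_y**2
    sxx = float(np.sum(w * h.beta_x**2))
    theta = float(np.sum(w * h.beta_x * h.beta_y)) / sxx
    q = float(np.sum(w * (h.beta_y - theta * h.beta_x) ** 2))
    se = math.sqrt(1.0 / sxx)
    if re_mode == "multiplicative_random":
        se *= math.sqrt(max(1.0, q / (j - 1)))
    elif re_mode != "fixed":
        raise ValueError(f"unknown re_mode {re_mode!r}")
    return MREstimate(method="IVW", beta=theta, se=se, n_snps=j), q


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w  # cumulative midpoint of each ratio's mass
    k = int(np.searchsorted(s, 0.5))
    if k == 0:
        return float(r[0])
    if k == len(r):
        return float(r[-1])
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for (B, J) bootstrap matrices."""
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    s = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(ratios.shape[0])
    for i in range(ratios.shape[0]):  # searchsorted is per-row; J is small
        si, ri = s[i], r[i]
        k = int(np.searchsorted(si, 0.5))
        if k == 0:
            out[i] = ri[0]
        elif k == len(ri):
            out[i] = ri[-1]
        else:
            out[i] = ri[k - 1] + (ri[k] - ri[k - 1]) * (0.5 - si[k - 1]) / (
                si[k] - si[k - 1]
            )
    return out


def weighted_median(
    h: HarmonisedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios with parametric-bootstrap SE.

    Ratios are weighted by the inverse variance of each ratio (first-order
    delta method).  The SE is the SD of the estimate over ``n_boot``
    parametric resamples beta_x* ~ N(beta_x, se_x), beta_y* ~ N(beta_y,
    se_y) with the given seed.
    """
    j = len(h)
    if j < 3:
        raise ValueError("weighted median requires at least 3 SNPs")
    ratios = h.beta_y / h.beta_x
    weights = (h.beta_x / h.se_y) ** 2
    theta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_x, h.se_x, size=(n_boot, j))
    by = rng.normal(h.beta_y, h.se_y, size=(n_boot, j))
    bx = np.where(bx == 0, np.finfo(float).tiny, bx)
    boot = _weighted_median_rows(by / bx, (bx / h.se_y) ** 2)
    se = float(np.std(boot, ddof=1))
    return MREstimate(method="weighted_median", beta=theta, se=se, n_snps=j)


def _egger_wls(
    bx: np.ndarray, by: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form weighted regression by = a + b*bx, row-broadcastable.

    Returns (intercept, slope, var_intercept, var_slope, q_prime) where
    the variances are the unscaled normal-equation variances and q_prime
    the weighted residual sum of squares.
    """
    sw = np.sum(w + 0 * bx, axis=-1)
    swx = np.sum(w * bx, axis=-1)
    swy = np.sum(w * by, axis=-1)
    swxx = np.sum(w * bx * bx, axis=-1)
    swxy = np.sum(w * bx * by, axis=-1)
    det = sw * swxx - swx**2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept[..., None] - slope[..., None] * bx
    q_prime = np.sum(w * resid**2, axis=-1)
    return intercept, slope, swxx / det, sw / det, q_prime


def mr_egger(
    h: HarmonisedSet, orient: bool = True, t_dist: bool = False
) -> EggerFit:
    """MR-Egger regression: weighted fit of beta_y = b0 + theta*beta_x.

    Weights are 1/se_y^2.  Slope and intercept SEs are inflated by
    sqrt(max(1, Q'/(J-2))) (Rucker's Q' is the weighted residual sum of
    squares).  The exposure is positively oriented first (a no-op on
    already-oriented input).  P-values use the normal reference by
    default; ``t_dist=True`` uses t with J-2 degrees of freedom.
    """
    j = len(h)
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    if orient:
        h = orient_positive_exposure(h)
    if np.ptp(h.beta_x) == 0:
        raise ValueError("degenerate exposure betas: Egger slope unidentifiable")
    w = 1.0 / h.se_y**2
    b0, theta, v0, v1, q_prime = _egger_wls(h.beta_x, h.beta_y, w)
    phi = max(1.0, float(q_prime) / (j - 2))
    se_slope = math.sqrt(float(v1) * phi)
    se_int = math.sqrt(float(v0) * phi)

    if t_dist:
        pval = 2.0 * float(stats.t.sf(abs(theta) / se_slope, df=j - 2))
        int_p = 2.0 * float(stats.t.sf(abs(b0) / se_int, df=j - 2))
    else:
        pval = 2.0 * float(stats.norm.sf(abs(theta) / se_slope))
        int_p = 2.0 * float(stats.norm.sf(abs(b0) / se_int))

    from .pleiotropy import i2_gx  # late import; pleiotropy depends on this module

    slope = MREstimate(
        method="MR_Egger", beta=float(theta), se=se_slope, n_snps=j, pval=pval
    )
    return EggerFit(
        slope=slope,
        intercept_beta=float(b0),
        intercept_se=se_int,
        intercept_p=int_p,
        i2_gx=i2_gx(h),
        q_prime=float(q_prime),
    )


def egger_simex(
    h: HarmonisedSet,
    lambdas: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0),
    B: int = 1000,
    seed: int = 0,
    t_dist: bool = False,
) -> EggerFit:
    """Simulation-extrapolation correction of the MR-Egger fit.

    For each lambda > 0 in the grid, ``B`` pseudo-datasets are built by
    adding N(0, lambda * se_x^2) noise to each beta_x, re-orienting, and
    refitting Egger; the per-lambda mean slope and intercept (lambda = 0
    is the plain fit) are modelled as quadratics in lambda and
    extrapolated to lambda = -1, the zero-measurement-error limit.  SEs
    use the naive SIMEX variance: the quadratic extrapolation of
    (mean model variance - between-replicate variance) per lambda, with
    the plain-Egger variance as a floor guard if extrapolation turns
    non-positive.
    """
    if np.any(~np.isfinite(h.se_x)):
        raise ValueError("egger_simex requires se_x for every SNP")
    j = len(h)
    plain = mr_egger(h, t_dist=t_dist)
    ho = orient_positive_exposure(h)
    w = 1.0 / ho.se_y**2

    lambdas = tuple(sorted(set(float(l) for l in lambdas)))
    if 0.0 not in lambdas:
        lambdas = (0.0,) + lambdas
    rng = np.random.default_rng(seed)

    mean_slope, mean_int = [], []
    tau2_slope, tau2_int = [], []
    for lam in lambdas:
        if lam == 0.0:
            mean_slope.append(plain.slope.beta)
            mean_int.append(plain.intercept_beta)
            tau2_slope.append(plain.slope.se**2)
            tau2_int.append(plain.intercept_se**2)
            continue
        # orientation is applied once, before noise: re-orienting inside a
        # replicate folds the noise distribution and biases the trend
        bx = ho.beta_x + rng.normal(0.0, 1.0, size=(B, j)) * np.sqrt(lam) * ho.se_x
        b0, b1, v0, v1, qp = _egger_wls(bx, ho.beta_y, w)
        phi = np.maximum(1.0, qp / (j - 2))
        mean_slope.append(float(b1.mean()))
        mean_int.append(float(b0.mean()))
        tau2_slope.append(float((v1 * phi).mean() - b1.var(ddof=1)))
        tau2_int.append(float((v0 * phi).mean() - b0.var(ddof=1)))

    lam_arr = np.asarray(lambdas)

    def extrapolate(values: list[float]) -> float:
        if np.ptp(values) == 0:  # degenerate (e.g. se_x = 0): constant trend
            return float(values[0])
        coef = np.polyfit(lam_arr, np.asarray(values), deg=2)
        return float(np.polyval(coef, -1.0))

    slope_sx = extrapolate(mean_slope)
    int_sx = extrapolate(mean_int)
    var_slope = extrapolate(tau2_slope)
    var_int = extrapolate(tau2_int)
    if not var_slope > 0:
        var_slope = plain.slope.se**2
    if not var_int > 0:
        var_int = plain.intercept_se**2
    se_slope, se_int = math.sqrt(var_slope), math.sqrt(var_int)

    if t_dist:
        pval = 2.0 * float(stats.t.sf(abs(slope_sx) / se_slope, df=j - 2))
        int_p = 2.0 * float(stats.t.sf(abs(int_sx) / se_int, df=j - 2))
    else:
        pval = 2.0 * float(stats.norm.sf(abs(slope_sx) / se_slope))
        int_p = 2.0 * float(stats.norm.sf(abs(int_sx) / se_int))

    slope = MREstimate(
        method="MR_Egger_SIMEX", beta=slope_sx, se=se_slope, n_snps=j, pval=pval
    )
    return EggerFit(
        slope=slope,
        intercept_beta=int_sx,
        intercept_se=se_int,
        intercept_p=int_p,
        i2_gx=plain.i2_gx,
        q_prime=plain.q_prime,
    )
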