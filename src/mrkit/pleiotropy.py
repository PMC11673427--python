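"""Heterogeneity and horizontal-pleiotropy diagnostics.

Cochran's Q (against the IVW fit) and Rucker's Q' (against the Egger fit)
measure excess heterogeneity among the per-SNP estimates; I2_GX measures
how much of the spread in the SNP-exposure effects is signal rather than
measurement error (low values violate Egger's NOME assumption and call
for SIMEX); MR-PRESSO tests globally for pleiotropy via the residual sum
of squares against a parametric simulation, flags outlying SNPs, and
re-estimates IVW without them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import HarmonisedSet, orient_positive_exposure
from .univariable_mr import EggerFit, MREstimate, ivw

__all__ = [
    "DiagnosticsReport",
    "cochran_q",
    "rucker_q",
    "i2_gx",
    "mr_presso",
    "diagnostics_report",
]


@dataclass
class DiagnosticsReport:
    """Heterogeneity / pleiotropy summary for one exposure-outcome pair."""

    n_snps: int
    mean_f: float | None
    q: float
    q_df: int
    q_p: float
    q_prime: float
    q_prime_df: int
    q_prime_p: float
    i2_gx: float
    egger_intercept: tuple[float, float, float]  # (beta, se, p)
    simex_intercept: tuple[float, float, float] | None
    presso_global_p: float
    presso_outlier_ids: list[str]
    presso_corrected: MREstimate | None

    def as_row(self) -> dict:
        row = {
            "N": self.n_snps,
            "F": self.mean_f,
            "I2_GX": self.i2_gx,
            "Q": self.q,
            "Q_p": self.q_p,
            "Q_prime": self.q_prime,
            "Q_prime_p": self.q_prime_p,
            "PRESSO_global_p": self.presso_global_p,
            "Egger_intercept": self.egger_intercept[0],
            "Egger_intercept_se": self.egger_intercept[1],
            "Egger_intercept_p": self.egger_intercept[2],
        }
        if self.simex_intercept is not None:
            row.update(
                {
                    "SIMEX_intercept": self.simex_intercept[0],
                    "SIMEX_intercept_se": self.simex_intercept[1],
                    "SIMEX_intercept_p": self.simex_intercept[2],
                }
            )
        row["PRESSO_outliers"] = ",".join(map(str, self.presso_outlier_ids))
        return row


def cochran_q(h: HarmonisedSet, theta: float) -> tuple[float, int, float]:
    """Cochran's Q about the (zero-intercept) fit with slope ``theta``."""
    if len(h) < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    w = 1.0 / h.se_y**2
    q = float(np.sum(w * (h.beta_y - theta * h.beta_x) ** 2))
    df = len(h) - 1
    return q, df, float(stats.chi2.sf(q, df))


def rucker_q(h: HarmonisedSet, egger: EggerFit) -> tuple[float, int, float]:
    """Rucker's Q': weighted residual sum of squares about the Egger fit."""
    ho = orient_positive_exposure(h)
    w = 1.0 / ho.se_y**2
    resid = ho.beta_y - egger.intercept_beta - egger.slope.beta * ho.beta_x
    q_prime = float(np.sum(w * resid**2))
    df = len(h) - 2
    return q_prime, df, float(stats.chi2.sf(q_prime, df))


def i2_gx(h: HarmonisedSet) -> float:
    """I2_GX, percent: signal fraction of the SNP-exposure effect spread.

    With weights 1/se_x^2 and the weighted mean of |beta_x| after positive
    orientation, Q_GX = sum (|beta_x| - mean)^2 / se_x^2 and
    I2_GX = max(0, (Q_GX - (J-1)) / Q_GX) * 100.  Values below ~90%
    signal regression dilution in MR-Egger (NOME violation).
    """
    if len(h) < 2:
        raise ValueError("I2_GX requires at least 2 SNPs")
    bx = np.abs(h.beta_x)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        w = 1.0 / h.se_x**2
        mean = float(np.sum(w * bx) / np.sum(w))
        q_gx = float(np.sum(w * (bx - mean) ** 2))
    if q_gx == 0:
        return 0.0
    if not np.isfinite(q_gx):  # vanishing se_x: pure signal
        return 100.0
    return max(0.0, (q_gx - (len(h) - 1)) / q_gx) * 100.0


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes; broadcasts over leading axes of bx/by."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    h: HarmonisedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    distortion_test: bool = False,
) -> tuple[float, list[str], MREstimate | None, dict]:
    """MR-PRESSO: global pleiotropy test, outlier flags, corrected IVW.

    The observed statistic is RSS = sum_j w_j (beta_y_j - theta_(-j) *
    beta_x_j)^2 with theta_(-j) the leave-one-out IVW slope and w_j =
    1/se_y_j^2.  Its null distribution is built by parametric simulation:
    beta_x* ~ N(beta_x, se_x), beta_y* ~ N(theta_(-j) beta_x, se_y),
    recomputing RSS on each replicate.  Empirical p-values carry a +1
    continuity correction.  Per-SNP outlier p-values are the empirical
    tails of each SNP's own residual term, Bonferroni-adjusted by J; the
    corrected estimate is IVW on the non-outlier SNPs (omitted when no
    outlier is found).

    Returns (global_p, outlier_ids, corrected_estimate, details); the
    optional distortion test result appears in ``details`` only when
    requested.
    """
    j = len(h)
    if j < 4:
        raise ValueError("MR-PRESSO requires at least 4 SNPs")
    rng = np.random.default_rng(seed)
    w = 1.0 / h.se_y**2

    theta_loo = _loo_ivw(h.beta_x[None, :], h.beta_y[None, :], w)[0]
    obs_terms = w * (h.beta_y - theta_loo * h.beta_x) ** 2
    obs_rss = float(obs_terms.sum())

    bx_sim = rng.normal(h.beta_x, h.se_x, size=(n_sim, j))
    by_sim = rng.normal(theta_loo * h.beta_x, h.se_y, size=(n_sim, j))
    theta_loo_sim = _loo_ivw(bx_sim, by_sim, w)
    sim_terms = w * (by_sim - theta_loo_sim * bx_sim) ** 2
    sim_rss = sim_terms.sum(axis=1)

    global_p = (1.0 + float(np.sum(sim_rss >= obs_rss))) / (1.0 + n_sim)
    p_snp = (1.0 + np.sum(sim_terms >= obs_terms, axis=0)) / (1.0 + n_sim)
    p_adj = np.minimum(1.0, p_snp * j)
    outlier_mask = p_adj < outlier_alpha
    outlier_ids = [str(v) for v in h.variant_id[outlier_mask]]

    corrected: MREstimate | None = None
    details: dict = {"p_snp_adjusted": p_adj, "obs_rss": obs_rss}
    if outlier_mask.any():
        est, _ = ivw(h.subset(~outlier_mask))
        corrected = MREstimate(
            method="MR_PRESSO_corrected",
            beta=est.beta,
            se=est.se,
            n_snps=est.n_snps,
            pval=est.pval,
        )
        if distortion_test:
            full, _ = ivw(h)
            details["distortion_pct"] = 100.0 * (full.beta - corrected.beta) / abs(
                corrected.beta
            )
    return global_p, outlier_ids, corrected, details


def diagnostics_report(
    h: HarmonisedSet,
    egger: EggerFit,
    simex: EggerFit | None = None,
    mean_f: float | None = None,
    n_sim: int = 1000,
    seed: int = 0,
) -> DiagnosticsReport:
    """Assemble the full heterogeneity/pleiotropy table for one pair."""
    est, _ = ivw(h)
    q, q_df, q_p = cochran_q(h, est.beta)
    qp, qp_df, qp_p = rucker_q(h, egger)
    global_p, outlier_ids, corrected, _ = mr_presso(h, n_sim=n_sim, seed=seed)
    return DiagnosticsReport(
        n_snps=len(h),
        mean_f=mean_f,
        q=q,
        q_df=q_df,
        q_p=q_p,
        q_prime=qp,
        q_prime_df=qp_df,
        q_prime_p=qp_p,
        i2_gx=i2_gx(h),
        egger_intercept=(egger.intercept_beta, egger.intercept_se, egger.intercept_p),
        simex_intercept=None
        if simex is None
        else (simex.intercept_beta, simex.intercept_se, simex.intercept_p),
        presso_global_p=global_p,
        presso_outlier_ids=outlier_ids,
        presso_corrected=corrected,
    )


def diagnostics_to_tsv(reports: dict[tuple[str, str], DiagnosticsReport], path) -> None:
    rows = []
    for (exposure, outcome), rep in reports.items():
        row = {"exposure": exposure, "outcome": outcome}
        row.update(rep.as_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
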