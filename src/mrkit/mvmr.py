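"""Multivariable MR: direct effects of several exposures jointly.

With K exposures, the outcome effects beta_y_j of J independent SNPs are
regressed on the J x K matrix of SNP-exposure effects (no intercept for
MVMR-IVW, a free intercept for MVMR-Egger), weighted by 1/se_y^2.  Each
coefficient is the direct effect of its exposure adjusted for the
others.  Instruments are the union of each exposure's genome-wide-
significant hits, jointly re-clumped on the minimum p across exposures,
with every retained SNP's effect on every exposure taken from the full
summary tables regardless of significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDReference, ld_clump, select_instruments
from .sumstats_io import HarmonisedSet, harmonise
from .univariable_mr import MREstimate

__all__ = ["MVMRInput", "build_mvmr_input", "mvmr_ivw", "mvmr_egger"]


@dataclass
class MVMRInput:
    """Per-SNP effects on K exposures plus the outcome, one orientation."""

    exposure_labels: list[str]
    variant_id: np.ndarray
    beta_x: np.ndarray  # (J, K)
    se_x: np.ndarray  # (J, K)
    beta_y: np.ndarray
    se_y: np.ndarray

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        j, k = self.beta_x.shape
        if k != len(self.exposure_labels):
            raise ValueError("exposure count mismatch")
        if len(self.beta_y) != j:
            raise ValueError("outcome length mismatch")

    @property
    def n_snps(self) -> int:
        return self.beta_x.shape[0]

    @property
    def n_exposures(self) -> int:
        return self.beta_x.shape[1]

    def check_rank(self) -> None:
        # near-collinear exposures are as unusable as exactly collinear ones
        sv = np.linalg.svd(self.beta_x, compute_uv=False)
        if sv[-1] <= sv[0] * 1e-6:
            raise ValueError("exposure design matrix is rank deficient")
        if self.n_snps <= self.n_exposures + 1:
            raise ValueError("need J > K + 1 SNPs for multivariable MR")


def build_mvmr_input(
    exposure_tables: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    ld: LDReference | None = None,
    p_threshold: float = 5.0e-8,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
    outcome_label: str = "outcome",
) -> MVMRInput:
    """Instrument-union construction for multivariable MR.

    Selects genome-wide-significant variants per exposure, takes their
    union, clumps jointly using each variant's minimum p across
    exposures, then harmonises the outcome and every exposure's full
    table to the first exposure's effect alleles.  SNPs missing from any
    exposure's full table are dropped with a warning.
    """
    labels = list(exposure_tables)
    selected = {}
    for label, table in exposure_tables.items():
        selected[label] = select_instruments(table, p_threshold)

    union: dict[str, dict] = {}
    for label in labels:
        for _, row in selected[label].iterrows():
            vid = row["variant_id"]
            if vid not in union or row["pval"] < union[vid]["pval"]:
                union[vid] = row.to_dict()
    union_df = pd.DataFrame(union.values())
    if ld is not None:
        union_df = ld_clump(union_df, ld, r2_threshold, window_kb)

    ref = exposure_tables[labels[0]]
    keep = union_df["variant_id"]
    missing = set()
    for label in labels:
        missing |= set(keep) - set(exposure_tables[label]["variant_id"])
    missing |= set(keep) - set(outcome["variant_id"])
    if missing:
        import warnings

        warnings.warn(f"{len(missing)} union SNP(s) missing from a table; dropped")
        keep = keep[~keep.isin(missing)]

    ref = ref[ref["variant_id"].isin(keep)]
    # align outcome and every exposure to the reference exposure's alleles
    h_out, _ = harmonise(ref, outcome, labels[0], outcome_label)
    aligned: dict[str, HarmonisedSet] = {}
    for label in labels:
        aligned[label], _ = harmonise(
            ref, exposure_tables[label], labels[0], label
        )
    common = set(h_out.variant_id)
    for label in labels:
        common &= set(aligned[label].variant_id)
    order = [v for v in h_out.variant_id if v in common]
    idx_out = {v: i for i, v in enumerate(h_out.variant_id)}

    beta_x = np.empty((len(order), len(labels)))
    se_x = np.empty_like(beta_x)
    for k, label in enumerate(labels):
        idx = {v: i for i, v in enumerate(aligned[label].variant_id)}
        beta_x[:, k] = [aligned[label].beta_y[idx[v]] for v in order]
        se_x[:, k] = [aligned[label].se_y[idx[v]] for v in order]

    m = MVMRInput(
        exposure_labels=labels,
        variant_id=np.asarray(order, dtype=object),
        beta_x=beta_x,
        se_x=se_x,
        beta_y=np.asarray([h_out.beta_y[idx_out[v]] for v in order]),
        se_y=np.asarray([h_out.se_y[idx_out[v]] for v in order]),
    )
    m.check_rank()
    return m


def _wls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, dof: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via the normal equations.

    Returns (coefficients, SEs inflated by max(1, sqrt(RSS_w/dof)),
    weighted RSS).
    """
    Xw = X * w[:, None]
    xtx_inv = np.linalg.pinv(X.T @ Xw)  # pinv: tolerant of degenerate columns
    coef = xtx_inv @ (Xw.T @ y)
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / dof)
    se = np.sqrt(np.diag(xtx_inv) * phi)
    return coef, se, rss


def mvmr_ivw(m: MVMRInput) -> list[MREstimate]:
    """Multivariable IVW: weighted no-intercept regression of beta_y on
    the exposure-effect columns; SEs carry multiplicative overdispersion
    max(1, sqrt(RSS_w/(J-K)))."""
    m.check_rank()
    w = 1.0 / m.se_y**2
    coef, se, _ = _wls(m.beta_x, m.beta_y, w, m.n_snps - m.n_exposures)
    return [
        MREstimate(method="MVMR_IVW", beta=float(b), se=float(s), n_snps=m.n_snps)
        for b, s in zip(coef, se)
    ]


def mvmr_egger(m: MVMRInput, orient_on: str | int = 0) -> tuple[list[MREstimate], MREstimate]:
    """Multivariable MR-Egger: as IVW plus a free intercept, after
    negating each SNP's full effect row so the ``orient_on`` exposure's
    effect is non-negative.

    Returns (K slope estimates, intercept estimate).
    """
    m.check_rank()
    k_or = (
        m.exposure_labels.index(orient_on) if isinstance(orient_on, str) else orient_on
    )
    sign = np.where(m.beta_x[:, k_or] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(m.n_snps), m.beta_x * sign[:, None]])
    y = m.beta_y * sign
    w = 1.0 / m.se_y**2
    coef, se, _ = _wls(X, y, w, m.n_snps - m.n_exposures - 1)
    slopes = [
        MREstimate(method="MVMR_Egger", beta=float(b), se=float(s), n_snps=m.n_snps)
        for b, s in zip(coef[1:], se[1:])
    ]
    intercept = MREstimate(
        method="MVMR_Egger_intercept", beta=float(coef[0]), se=float(se[0]), n_snps=m.n_snps
    )
    return slopes, intercept
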