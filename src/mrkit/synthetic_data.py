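"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are drawn directly at the summary level (no
individual-level genotypes): for SNP j with minor-allele frequency p_j,
true per-allele effect gamma_j on a standardised exposure and direct
(pleiotropic) outcome effect alpha_j,

    se_x_j = 1 / sqrt(2 n_x p_j (1 - p_j))          (continuous trait)
    se_y_j = 1 / sqrt(2 n_y K (1 - K) p_j (1 - p_j))  (binary, case
                                                       fraction K)
    beta_x_j ~ N(gamma_j, se_x_j^2)
    beta_y_j ~ N(theta * gamma_j + alpha_j, se_y_j^2)

The gamma are drawn as magnitudes (the effect allele is taken to be the
exposure-increasing allele) and scaled so that the explained exposure
variance sum(2 p (1-p) gamma^2) hits a target R^2.  Default parameters
emulate the ApoA (UK Biobank, n = 364,987, R^2 = 0.11, 308 instruments)
against AMD (FinnGen, 8,913 cases + 348,936 controls) configuration; the
default true effect is the log of the odds ratio 1.14 per SD.

Pleiotropy regimes: ``none``; ``balanced`` (mean-zero alpha on the
invalid fraction); ``directional`` (mean mu_alpha > 0, violating the
zero-average assumption but not InSIDE); ``inside_violating`` (alpha
correlated with gamma).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDReference

__all__ = [
    "SimulationConfig",
    "simulate_two_sample",
    "simulate_mvmr",
    "simulate_ld_panel",
]

_AMD_CASES = 8913
_AMD_N = 357_849


@dataclass
class SimulationConfig:
    """Generative parameters for synthetic two-sample summary statistics."""

    theta: float = float(np.log(1.14))  # causal log-odds per SD exposure
    J: int = 308  # instrument count
    n_exposure: int = 364_987
    n_outcome: int = _AMD_N
    case_fraction: float = _AMD_CASES / _AMD_N
    target_r2: float = 0.11  # exposure variance explained by instruments
    maf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy: str = "none"  # none | balanced | directional | inside_violating
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    prop_invalid: float = 0.0
    weak_fraction: float = 0.0
    weak_scale: float = 0.1
    ld_blocks: tuple[int, int, float] = (20, 5, 0.8)  # (n_blocks, size, r2)
    seed: int = 0

    def validate(self) -> None:
        if self.J <= 0 or self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 0 <= self.prop_invalid <= 1:
            raise ValueError("prop_invalid must be in [0, 1]")
        if not 0 < self.target_r2 < 1:
            raise ValueError(
                "target_r2 outside (0, 1) is unreachable for any J and maf_range"
            )
        lo, hi = self.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise ValueError("maf_range must sit within (0.01, 0.5]")
        if self.pleiotropy not in {"none", "balanced", "directional", "inside_violating"}:
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")


def _variant_frame(
    cfg: SimulationConfig,
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> pd.DataFrame:
    j = cfg.J
    ids = [f"snp_{i + 1:05d}" for i in range(j)]
    chrom = [(i % 22) + 1 for i in range(j)]
    # successive variants on one chromosome sit > 10 Mb apart: independent
    pos = [1_000_000 + (i // 22) * 20_000_000 for i in range(j)]
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": [str(c) for c in chrom],
            "position": pos,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf,
            "beta": beta,
            "se": se,
            # floor keeps extreme associations representable in the tables
            "pval": np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300),
            "n": n,
        }
    )


def _draw_gamma(rng: np.random.Generator, cfg: SimulationConfig, maf: np.ndarray) -> np.ndarray:
    gamma = np.abs(rng.normal(0.0, 1.0, size=cfg.J))
    if cfg.weak_fraction > 0:
        n_weak = int(round(cfg.weak_fraction * cfg.J))
        weak = rng.choice(cfg.J, size=n_weak, replace=False)
        gamma[weak] *= cfg.weak_scale
    var = 2.0 * maf * (1.0 - maf)
    scale = np.sqrt(cfg.target_r2 / np.sum(var * gamma**2))
    return gamma * scale


def _draw_alpha(
    rng: np.random.Generator, cfg: SimulationConfig, gamma: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    alpha = np.zeros(cfg.J)
    invalid = np.zeros(cfg.J, dtype=bool)
    if cfg.pleiotropy == "none" or cfg.prop_invalid == 0:
        return alpha, invalid
    n_invalid = int(round(cfg.prop_invalid * cfg.J))
    idx = rng.choice(cfg.J, size=n_invalid, replace=False)
    invalid[idx] = True
    if cfg.pleiotropy == "balanced":
        alpha[idx] = rng.normal(0.0, cfg.sigma_alpha, size=n_invalid)
    elif cfg.pleiotropy == "directional":
        alpha[idx] = rng.normal(cfg.mu_alpha, cfg.sigma_alpha, size=n_invalid)
    else:  # inside_violating: alpha tracks instrument strength
        alpha[idx] = cfg.mu_alpha * gamma[idx] / gamma.mean() + rng.normal(
            0.0, cfg.sigma_alpha, size=n_invalid
        )
    return alpha, invalid


def simulate_two_sample(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (exposure table, outcome table, truth record)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    maf = rng.uniform(*cfg.maf_range, size=cfg.J)
    gamma = _draw_gamma(rng, cfg, maf)
    alpha, invalid = _draw_alpha(rng, cfg, gamma)

    var = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(cfg.n_exposure * var)
    k = cfg.case_fraction
    se_y = 1.0 / np.sqrt(cfg.n_outcome * k * (1.0 - k) * var)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.theta * gamma + alpha, se_y)

    exposure = _variant_frame(cfg, maf, beta_x, se_x, cfg.n_exposure)
    outcome = _variant_frame(cfg, maf, beta_y, se_y, cfg.n_outcome)
    truth = {
        "theta": cfg.theta,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "invalid_ids": exposure.loc[invalid, "variant_id"].tolist(),
        "config": asdict(cfg),
    }
    return exposure, outcome, truth


def simulate_mvmr(
    cfg: SimulationConfig,
    true_effects: tuple[float, ...] = (float(np.log(1.14)),),
    exposure_correlation: float = 0.0,
    target_r2: tuple[float, ...] | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame, dict]:
    """Generate K correlated exposure tables plus one outcome table.

    Per-SNP true effects on the K exposures are drawn from a multivariate
    normal with pairwise correlation ``exposure_correlation`` and each
    exposure's column scaled to its target R^2; the outcome mean is the
    inner product with ``true_effects`` plus any pleiotropy.
    """
    cfg.validate()
    k_exp = len(true_effects)
    r2s = target_r2 if target_r2 is not None else (cfg.target_r2,) * k_exp
    rho = exposure_correlation
    cov = np.full((k_exp, k_exp), rho)
    np.fill_diagonal(cov, 1.0)
    rng = np.random.default_rng(cfg.seed)
    maf = rng.uniform(*cfg.maf_range, size=cfg.J)
    var = 2.0 * maf * (1.0 - maf)

    gamma = rng.multivariate_normal(np.zeros(k_exp), cov, size=cfg.J, method="svd")
    for k in range(k_exp):
        gamma[:, k] *= np.sqrt(r2s[k] / np.sum(var * gamma[:, k] ** 2))
    alpha, invalid = _draw_alpha(rng, cfg, np.abs(gamma[:, 0]))

    se_x = 1.0 / np.sqrt(cfg.n_exposure * var)
    kf = cfg.case_fraction
    se_y = 1.0 / np.sqrt(cfg.n_outcome * kf * (1.0 - kf) * var)
    exposures = []
    for k in range(k_exp):
        beta_xk = rng.normal(gamma[:, k], se_x)
        exposures.append(_variant_frame(cfg, maf, beta_xk, se_x, cfg.n_exposure))
    mean_y = gamma @ np.asarray(true_effects) + alpha
    beta_y = rng.normal(mean_y, se_y)
    outcome = _variant_frame(cfg, maf, beta_y, se_y, cfg.n_outcome)
    truth = {
        "true_effects": list(true_effects),
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "invalid_ids": outcome.loc[invalid, "variant_id"].tolist(),
        "exposure_correlation": rho,
        "config": asdict(cfg),
    }
    return exposures, outcome, truth


def simulate_ld_panel(
    cfg: SimulationConfig,
) -> tuple[LDReference, pd.DataFrame, dict]:
    """Block-structured LD reference plus an LD-inflated association table.

    Variants come in blocks with constant within-block r^2 and zero
    between-block r^2; blocks are separated physically so the clumping
    window never spans two blocks.  Association Z scores are correlated
    within blocks (z = sqrt(r2) z_index + sqrt(1-r2) noise) so clumping
    has real work to do; the truth record lists the minimum-p variant of
    each block, which greedy clumping at any r^2 threshold below the
    within-block value must return exactly.
    """
    cfg.validate()
    n_blocks, block_size, r2_within = cfg.ld_blocks
    rng = np.random.default_rng(cfg.seed)
    j = n_blocks * block_size

    ids, chroms, positions = [], [], []
    r2 = np.eye(j)
    z = np.empty(j)
    truth_index = []
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        chrom = str((b % 22) + 1)
        base = 1_000_000 + (b // 22) * 50_000_000
        z_lead = rng.normal(8.0, 2.0)
        z_block = np.sqrt(r2_within) * z_lead + np.sqrt(1 - r2_within) * rng.normal(
            0.0, 1.0, size=block_size
        )
        z[sl] = z_block
        for i in range(block_size):
            ids.append(f"blk{b + 1:03d}_snp{i + 1:02d}")
            chroms.append(chrom)
            positions.append(base + i * 10_000)
        block = np.full((block_size, block_size), r2_within)
        np.fill_diagonal(block, 1.0)
        r2[sl, sl] = block
        pvals = 2.0 * stats.norm.sf(np.abs(z_block))
        truth_index.append(ids[b * block_size + int(np.argmin(pvals))])

    se = np.full(j, 0.01)
    beta = z * se
    assoc = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chroms,
            "position": positions,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": rng.uniform(0.1, 0.5, size=j),
            "beta": beta,
            "se": se,
            "pval": 2.0 * stats.norm.sf(np.abs(z)),
            "n": cfg.n_exposure,
        }
    )
    ld = LDReference(variant_id=ids, r2=r2)
    truth = {"index_ids": truth_index, "config": asdict(cfg)}
    return ld, assoc, truth


def write_tables(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    truth: dict,
    outdir: str | Path,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Emit the TSV dialect sumstats_io reads, with the truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / f"{prefix}_exposure.tsv",
        "outcome": outdir / f"{prefix}_outcome.tsv",
        "truth": outdir / f"{prefix}_truth.json",
    }
    exposure.to_csv(paths["exposure"], sep="\t", index=False)
    outcome.to_csv(paths["outcome"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return paths
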