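"""Instrument selection: significance filtering, LD clumping, strength.

Instruments for two-sample MR are genome-wide-significant variants
(p < 5e-8 by convention) pruned to mutual independence against an external
linkage-disequilibrium reference (pairwise r^2), using the standard greedy
"clumping" rule: the most significant remaining variant indexes a clump
and absorbs every variant within the window that is in LD with it.
Instrument strength is summarised by the per-SNP F statistic and the
variance in the exposure explained by the instrument set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LDReference",
    "InstrumentDiagnostics",
    "select_instruments",
    "ld_clump",
    "instrument_strength",
]


@dataclass
class LDReference:
    """Pairwise LD (r^2) between variants, from an external reference panel."""

    variant_id: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.variant_id = list(self.variant_id)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_id)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match variant count")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 matrix must have unit diagonal")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_id)}

    def __contains__(self, vid: str) -> bool:
        return vid in self._index

    def pair_r2(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "LDReference":
        """Square matrix file: header row and first column are variant ids."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(variant_id=list(df.columns), r2=df.to_numpy(dtype=float))

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame | str | Path) -> "LDReference":
        """Long format with columns (id_a, id_b, r2); omitted pairs are r2=0."""
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.read_csv(pairs, sep=None, engine="python")
        ids = sorted(set(pairs["id_a"]) | set(pairs["id_b"]))
        idx = {v: i for i, v in enumerate(ids)}
        r2 = np.eye(len(ids))
        for _, row in pairs.iterrows():
            i, j = idx[row["id_a"]], idx[row["id_b"]]
            r2[i, j] = r2[j, i] = float(row["r2"])
        return cls(variant_id=ids, r2=r2)


@dataclass
class InstrumentDiagnostics:
    f: np.ndarray
    mean_f: float
    r2: np.ndarray | None
    total_r2: float | None

    def to_frame(self, variant_id: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"F": self.f})
        if variant_id is not None:
            df.insert(0, "variant_id", variant_id)
        if self.r2 is not None:
            df["r2"] = self.r2
        return df


def select_instruments(assoc: pd.DataFrame, p_threshold: float = 5.0e-8) -> pd.DataFrame:
    """Keep rows with ``pval`` strictly below the threshold, sorted by pval."""
    if assoc["pval"].isna().any():
        raise ValueError("pval must be present for all rows")
    out = assoc[assoc["pval"] < p_threshold].sort_values(
        ["pval", "chromosome", "position"], kind="mergesort"
    )
    if len(out) == 0:
        raise ValueError(
            f"no variant passes p < {p_threshold:g}; relax the threshold "
            "(MR cannot proceed without instruments)"
        )
    return out.reset_index(drop=True)


def ld_clump(
    assoc: pd.DataFrame,
    ld: LDReference,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> pd.DataFrame:
    """Greedy LD clumping to a mutually independent variant set.

    Repeatedly takes the remaining variant with the smallest p-value as an
    index variant and removes every remaining variant on the same
    chromosome within ``window_kb`` kilobases whose r^2 with the index is
    at or above ``r2_threshold``.  Ties in p are broken by (chromosome,
    position).  Variants absent from the LD reference are dropped with a
    warning before clumping.
    """
    present = assoc["variant_id"].map(lambda v: v in ld)
    if not present.all():
        missing = assoc.loc[~present, "variant_id"].tolist()
        warnings.warn(
            f"{len(missing)} variant(s) absent from LD reference dropped: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    df = assoc[present].sort_values(
        ["pval", "chromosome", "position"], kind="mergesort"
    )

    window_bp = window_kb * 1000
    kept_rows = []
    remaining = df.to_dict("records")
    while remaining:
        index = remaining.pop(0)
        kept_rows.append(index)
        survivors = []
        for v in remaining:
            close = (
                v["chromosome"] == index["chromosome"]
                and abs(v["position"] - index["position"]) <= window_bp
            )
            if close and ld.pair_r2(index["variant_id"], v["variant_id"]) >= r2_threshold:
                continue
            survivors.append(v)
        remaining = survivors
    return pd.DataFrame(kept_rows).reset_index(drop=True)


def instrument_strength(
    assoc: pd.DataFrame,
    n: float | None = None,
    f_from_r2: bool = False,
) -> InstrumentDiagnostics:
    """Per-SNP F statistics and exposure variance explained.

    By default F is the squared Z statistic (beta/se)^2, which needs no
    allele frequency; per-SNP r^2 follows from the t-statistic transform
    r^2 = F / (F + n - 2) and total R^2 is their sum.  With
    ``f_from_r2=True`` the F reported is instead recomputed from r^2 as
    r^2 (n - 2) / (1 - r^2), which is the exact regression F and agrees
    with the default to first order.
    """
    beta = assoc["beta"].to_numpy(dtype=float)
    se = assoc["se"].to_numpy(dtype=float)
    if n is None and "n" in assoc and assoc["n"].notna().all():
        n = float(assoc["n"].median())
    f = (beta / se) ** 2
    if n is None:
        return InstrumentDiagnostics(f=f, mean_f=float(f.mean()), r2=None, total_r2=None)
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    r2 = f / (f + n - 2)
    if f_from_r2:
        f = r2 * (n - 2) / (1 - r2)
    return InstrumentDiagnostics(
        f=f, mean_f=float(f.mean()), r2=r2, total_r2=float(r2.sum())
    )
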