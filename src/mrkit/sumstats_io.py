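"""Reading, validation and harmonisation of GWAS summary statistics.

A summary-statistics table has one row per variant with the columns

    variant_id, chromosome, position, effect_allele, other_allele,
    eaf, beta, se, pval, n

where ``beta`` is the per-allele effect of the effect allele on the trait
(SD units for continuous traits, log-odds for binary traits), ``se`` its
standard error and ``eaf`` the effect-allele frequency.  Two-sample MR
needs the exposure and outcome effects of each shared variant expressed
for the *same* effect allele; :func:`harmonise` performs that alignment,
flipping outcome effect signs where the allele labels are swapped,
resolving strand flips via base complements, and handling palindromic
(A/T, C/G) variants by allele frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COLUMNS",
    "HarmonisedSet",
    "HarmonisationReport",
    "read_summary_stats",
    "validate_associations",
    "harmonise",
    "orient_positive_exposure",
]

#: canonical column order of a validated association table
COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# reported p may disagree with 2*Phi(-|beta/se|) by rounding; tolerate one
# order of magnitude on the log10 scale, and skip the check below p=1e-300
# where the normal tail underflows
_PVAL_LOG10_TOL = 1.0


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _complement(a1) == a2


@dataclass
class HarmonisationReport:
    """Bookkeeping of what :func:`harmonise` did to the input intersection."""

    n_input_exposure: int
    n_input_outcome: int
    n_intersection: int
    n_kept: int
    n_flipped: int
    n_dropped_palindromic: int
    n_dropped_incompatible: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class HarmonisedSet:
    """Aligned per-SNP exposure/outcome effects for one exposure-outcome pair.

    All arrays cover the retained variants only; ``actions`` records the
    fate (kept / flipped / dropped_palindromic / dropped_incompatible) of
    every variant in the exposure-outcome intersection.
    """

    exposure_label: str
    outcome_label: str
    variant_id: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_x: np.ndarray | None = None
    actions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.variant_id)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in HarmonisedSet field {name}")
        if np.any(self.se_y <= 0) or np.any(self.se_x <= 0):
            raise ValueError("all standard errors must be positive")

    def __len__(self) -> int:
        return len(self.variant_id)

    def subset(self, mask: np.ndarray) -> "HarmonisedSet":
        mask = np.asarray(mask)
        return HarmonisedSet(
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            variant_id=self.variant_id[mask],
            beta_x=self.beta_x[mask],
            se_x=self.se_x[mask],
            beta_y=self.beta_y[mask],
            se_y=self.se_y[mask],
            eaf_x=None if self.eaf_x is None else np.asarray(self.eaf_x)[mask],
            actions=self.actions,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "beta_x": self.beta_x,
                "se_x": self.se_x,
                "beta_y": self.beta_y,
                "se_y": self.se_y,
            }
        )
        if self.eaf_x is not None:
            df["eaf_x"] = self.eaf_x
        return df

    def to_tsv(self, path: str | Path) -> None:
        """Serialise retained variants plus the per-variant action column."""
        df = self.to_frame()
        action = self.actions.set_index("variant_id")["action"] if len(self.actions) else {}
        df["action_taken"] = [action.get(v, "kept") for v in self.variant_id]
        df.to_csv(path, sep="\t", index=False)


def read_summary_stats(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    trait_type: str = "continuous",
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read and validate a delimited GWAS summary-statistics file.

    Parameters
    ----------
    path
        TSV or CSV file; the delimiter is sniffed from the header line
        unless given.
    column_map
        Mapping from canonical names (see :data:`COLUMNS`) to the file's
        column names, for files with non-standard headers.
    trait_type
        ``"continuous"`` or ``"binary"``; recorded in ``df.attrs`` (betas
        of binary traits are log-odds and are never exponentiated here).

    Returns
    -------
    DataFrame with canonical columns.  Rows violating the row invariants
    (invalid alleles, non-positive se, eaf outside [0, 1], p-value grossly
    inconsistent with beta/se) are dropped; counts are in ``df.attrs``.
    A missing p-value column is imputed as 2*Phi(-|beta/se|) and flagged
    via ``df.attrs["pval_imputed"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        header = path.open().readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=delimiter, dtype={"chromosome": str})

    column_map = column_map or {}
    rename = {src: canon for canon, src in column_map.items()}
    raw = raw.rename(columns=rename)

    mandatory = ["variant_id", "effect_allele", "other_allele", "beta", "se"]
    for col in mandatory:
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column: {col!r}")

    df = pd.DataFrame(index=raw.index)
    df["variant_id"] = raw["variant_id"].astype(str)
    df["chromosome"] = raw["chromosome"].astype(str) if "chromosome" in raw else ""
    df["position"] = (
        pd.to_numeric(raw["position"], errors="coerce") if "position" in raw else np.nan
    )
    df["effect_allele"] = raw["effect_allele"].astype(str).str.upper()
    df["other_allele"] = raw["other_allele"].astype(str).str.upper()
    df["eaf"] = pd.to_numeric(raw["eaf"], errors="coerce") if "eaf" in raw else np.nan
    df["beta"] = pd.to_numeric(raw["beta"], errors="coerce")
    df["se"] = pd.to_numeric(raw["se"], errors="coerce")
    df["n"] = pd.to_numeric(raw["n"], errors="coerce") if "n" in raw else np.nan

    pval_imputed = "pval" not in raw.columns
    if pval_imputed:
        z = np.abs(df["beta"] / df["se"])
        df["pval"] = 2.0 * stats.norm.sf(z)
    else:
        df["pval"] = pd.to_numeric(raw["pval"], errors="coerce")
    df = df[COLUMNS]

    df, n_dropped = validate_associations(df, check_pval=not pval_imputed)
    if len(df) == 0:
        raise ValueError(f"no valid rows in {path}")
    df.attrs["trait_type"] = trait_type
    df.attrs["n_dropped"] = n_dropped
    df.attrs["pval_imputed"] = pval_imputed
    return df


def validate_associations(
    df: pd.DataFrame, check_pval: bool = True
) -> tuple[pd.DataFrame, int]:
    """Apply the per-row invariants, returning (valid rows, number dropped).

    Row order is preserved.
    """
    ok = (
        df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["se"] > 0)
        & df["beta"].notna()
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
        & df["pval"].notna()
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
    )
    if check_pval:
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
            testable = (expected > 1e-300) & (df["pval"] > 0)
            log_gap = np.abs(
                np.log10(np.where(testable, df["pval"], 1.0))
                - np.log10(np.where(testable, expected, 1.0))
            )
        ok &= ~testable | (log_gap <= _PVAL_LOG10_TOL)
    out = df[ok].reset_index(drop=True)
    return out, int((~ok).sum())


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
    palindrome_eaf_window: float = 0.08,
) -> tuple[HarmonisedSet, HarmonisationReport]:
    """Align outcome effects to the exposure's effect allele per shared variant.

    Rules, applied per variant in the ``variant_id`` intersection:

    * alleles identical -> keep as is;
    * alleles swapped -> negate the outcome beta, ``eaf -> 1 - eaf``;
    * alleles a strand complement (possibly swapped) of the exposure's ->
      complement, then the above;
    * palindromic variants (A/T or C/G) are unresolvable from allele
      labels: kept (same orientation assumed) only when both allele
      frequencies are present, both outside
      ``[0.5 - window, 0.5 + window]`` and on the same side of 0.5;
      otherwise dropped;
    * any other allele pair -> dropped as incompatible.
    """
    exp = exposure.set_index("variant_id", drop=False)
    out = outcome.set_index("variant_id", drop=False)
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise ValueError("exposure and outcome share no variants")

    lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
    records: list[dict] = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        ea_x, oa_x = e["effect_allele"], e["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        beta_y, eaf_y = float(o["beta"]), o["eaf"]

        if _is_palindromic(ea_x, oa_x):
            eaf_x = e["eaf"]
            ambiguous = (
                pd.isna(eaf_x)
                or pd.isna(eaf_y)
                or (lo <= eaf_x <= hi)
                or (lo <= eaf_y <= hi)
                or ((eaf_x < 0.5) != (eaf_y < 0.5))
            )
            if {ea_y, oa_y} != {ea_x, oa_x} or ambiguous:
                action = "dropped_palindromic"
            else:
                action = "kept"
        elif (ea_y, oa_y) == (ea_x, oa_x):
            action = "kept"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            action = "flipped"
        elif (_complement(ea_y), _complement(oa_y)) == (ea_x, oa_x):
            action = "kept"
        elif (_complement(ea_y), _complement(oa_y)) == (oa_x, ea_x):
            action = "flipped"
        else:
            action = "dropped_incompatible"

        if action == "flipped":
            beta_y = -beta_y
            eaf_y = np.nan if pd.isna(eaf_y) else 1.0 - eaf_y
        records.append(
            {
                "variant_id": vid,
                "action": action,
                "beta_x": float(e["beta"]),
                "se_x": float(e["se"]),
                "beta_y": beta_y,
                "se_y": float(o["se"]),
                "eaf_x": e["eaf"],
            }
        )

    actions = pd.DataFrame(records)
    kept = actions[actions["action"].isin(["kept", "flipped"])]
    report = HarmonisationReport(
        n_input_exposure=len(exposure),
        n_input_outcome=len(outcome),
        n_intersection=len(shared),
        n_kept=int((actions["action"] == "kept").sum()),
        n_flipped=int((actions["action"] == "flipped").sum()),
        n_dropped_palindromic=int((actions["action"] == "dropped_palindromic").sum()),
        n_dropped_incompatible=int((actions["action"] == "dropped_incompatible").sum()),
    )
    h = HarmonisedSet(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        variant_id=kept["variant_id"].to_numpy(),
        beta_x=kept["beta_x"].to_numpy(),
        se_x=kept["se_x"].to_numpy(),
        beta_y=kept["beta_y"].to_numpy(),
        se_y=kept["se_y"].to_numpy(),
        eaf_x=kept["eaf_x"].to_numpy(dtype=float),
        actions=actions[["variant_id", "action"]],
    )
    return h, report


def orient_positive_exposure(h: HarmonisedSet) -> HarmonisedSet:
    """Return a copy with every SNP oriented so its exposure effect is >= 0.

    SNPs with a negative exposure beta have both betas negated (equivalent
    to relabelling which allele is the effect allele), which leaves every
    Wald ratio unchanged.  MR-Egger requires this orientation for its
    intercept to estimate the average pleiotropic effect.
    """
    if len(h) == 0:
        raise ValueError("empty HarmonisedSet")
    flip = h.beta_x < 0
    eaf = None if h.eaf_x is None else np.where(flip, 1.0 - np.asarray(h.eaf_x), h.eaf_x)
    return HarmonisedSet(
        exposure_label=h.exposure_label,
        outcome_label=h.outcome_label,
        variant_id=h.variant_id.copy(),
        beta_x=np.where(flip, -h.beta_x, h.beta_x),
        se_x=h.se_x.copy(),
        beta_y=np.where(flip, -h.beta_y, h.beta_y),
        se_y=h.se_y.copy(),
        eaf_x=eaf,
        actions=h.actions,
    )
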