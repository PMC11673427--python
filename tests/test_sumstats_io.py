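"""Reading, validation, harmonisation and orientation of summary stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrkit import (
    harmonise,
    ivw,
    orient_positive_exposure,
    read_summary_stats,
    weighted_median,
)
from mrkit.sumstats_io import validate_associations

from conftest import make_set


def _write(tmp_path, rows, name="stats.tsv", columns=None, sep="\t"):
    columns = columns or [
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
    path = tmp_path / name
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=sep, index=False)
    return path


_BASE_ROWS = [
    ["rs1", "1", 1000, "A", "G", 0.3, 0.10, 0.02, 2 * stats.norm.sf(5), 1000],
    ["rs2", "1", 5000, "C", "T", 0.4, -0.05, 0.02, 2 * stats.norm.sf(2.5), 1000],
    ["rs3", "2", 9000, "G", "A", 0.2, 0.02, 0.02, 2 * stats.norm.sf(1), 1000],
]


class TestRead:
    def test_valid_rows_pass_through(self, tmp_path):
        df = read_summary_stats(_write(tmp_path, _BASE_ROWS))
        assert len(df) == 3
        assert df.attrs["n_dropped"] == 0
        assert list(df["variant_id"]) == ["rs1", "rs2", "rs3"]

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        rows = [list(r) for r in _BASE_ROWS]
        rows[1][7] = 0.0
        df = read_summary_stats(_write(tmp_path, rows))
        assert len(df) == 2
        assert df.attrs["n_dropped"] == 1

    def test_missing_pval_imputed_from_normal_tail(self, tmp_path):
        rows = [["rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.02, 1000]]
        cols = [
            "variant_id", "chromosome", "position", "effect_allele",
            "other_allele", "eaf", "beta", "se", "n",
        ]
        df = read_summary_stats(_write(tmp_path, rows, columns=cols))
        assert df.attrs["pval_imputed"]
        assert df["pval"].iloc[0] == pytest.approx(2 * stats.norm.sf(0.1 / 0.02), rel=1e-12)

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        cols = ["variant_id", "effect_allele", "other_allele", "beta"]
        rows = [["rs1", "A", "G", 0.1]]
        with pytest.raises(ValueError, match="se"):
            read_summary_stats(_write(tmp_path, rows, columns=cols))

    def test_comma_delimiter_sniffed(self, tmp_path):
        df = read_summary_stats(_write(tmp_path, _BASE_ROWS, name="s.csv", sep=","))
        assert len(df) == 3

    def test_inconsistent_pval_dropped(self):
        df = pd.DataFrame(
            {
                "variant_id": ["rs1"],
                "chromosome": ["1"],
                "position": [1],
                "effect_allele": ["A"],
                "other_allele": ["G"],
                "eaf": [0.3],
                "beta": [0.1],
                "se": [0.02],
                "pval": [0.5],  # z = 5 implies p ~ 5.7e-7: orders off
                "n": [100],
            }
        )
        kept, dropped = validate_associations(df)
        assert dropped == 1 and len(kept) == 0


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chromosome", "position", "effect_allele",
            "other_allele", "eaf", "beta", "se", "pval", "n",
        ],
    )


class TestHarmonise:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = _table([["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-9, 100]])
        out = _table([["rs1", "1", 1, "G", "A", 0.7, 0.05, 0.02, 0.01, 100]])
        h, rep = harmonise(exp, out)
        assert rep.n_flipped == 1
        assert h.beta_y[0] == pytest.approx(-0.05)

    def test_strand_complement_resolved(self):
        exp = _table([["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-9, 100]])
        out = _table([["rs1", "1", 1, "T", "C", 0.3, 0.05, 0.02, 0.01, 100]])
        h, _ = harmonise(exp, out)
        assert len(h) == 1 and h.beta_y[0] == pytest.approx(0.05)

    def test_ambiguous_palindromic_dropped(self):
        exp = _table([["rs1", "1", 1, "A", "T", 0.50, 0.1, 0.02, 1e-9, 100]])
        out = _table([["rs1", "1", 1, "A", "T", 0.2, 0.05, 0.02, 0.01, 100]])
        h, rep = harmonise(exp, out)
        assert len(h) == 0 and rep.n_dropped_palindromic == 1

    def test_confident_palindromic_kept(self):
        exp = _table([["rs1", "1", 1, "C", "G", 0.2, 0.1, 0.02, 1e-9, 100]])
        out = _table([["rs1", "1", 1, "C", "G", 0.25, 0.05, 0.02, 0.01, 100]])
        h, _ = harmonise(exp, out)
        assert len(h) == 1 and h.beta_y[0] == pytest.approx(0.05)

    def test_palindromic_missing_eaf_dropped_not_error(self):
        exp = _table([["rs1", "1", 1, "A", "T", np.nan, 0.1, 0.02, 1e-9, 100]])
        out = _table([["rs1", "1", 1, "A", "T", 0.2, 0.05, 0.02, 0.01, 100]])
        h, rep = harmonise(exp, out)
        assert rep.n_dropped_palindromic == 1

    def test_incompatible_alleles_dropped(self):
        exp = _table([["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-9, 100]])
        out = _table([["rs1", "1", 1, "A", "C", 0.3, 0.05, 0.02, 0.01, 100]])
        h, rep = harmonise(exp, out)
        assert len(h) == 0 and rep.n_dropped_incompatible == 1

    def test_empty_intersection_is_hard_error(self):
        exp = _table([["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-9, 100]])
        out = _table([["rs2", "1", 1, "A", "G", 0.3, 0.05, 0.02, 0.01, 100]])
        with pytest.raises(ValueError, match="share no variants"):
            harmonise(exp, out)

    def test_report_counts_are_additive(self):
        exp = _table(
            [
                ["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-9, 100],
                ["rs2", "1", 2, "A", "T", 0.5, 0.1, 0.02, 1e-9, 100],
                ["rs3", "1", 3, "C", "T", 0.4, 0.1, 0.02, 1e-9, 100],
            ]
        )
        out = _table(
            [
                ["rs1", "1", 1, "G", "A", 0.7, 0.05, 0.02, 0.01, 100],
                ["rs2", "1", 2, "A", "T", 0.5, 0.05, 0.02, 0.01, 100],
                ["rs3", "1", 3, "C", "T", 0.4, 0.05, 0.02, 0.01, 100],
            ]
        )
        h, rep = harmonise(exp, out)
        total = (
            rep.n_kept + rep.n_flipped + rep.n_dropped_palindromic
            + rep.n_dropped_incompatible
        )
        assert total == rep.n_intersection == 3
        assert len(h) == rep.n_kept + rep.n_flipped

    def test_involution_safe(self):
        """Harmonising already-aligned tables changes nothing."""
        exp = _table(
            [
                ["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-9, 100],
                ["rs2", "1", 2, "C", "T", 0.4, -0.2, 0.03, 1e-11, 100],
            ]
        )
        out = _table(
            [
                ["rs1", "1", 1, "A", "G", 0.3, 0.05, 0.02, 0.01, 100],
                ["rs2", "1", 2, "C", "T", 0.4, -0.01, 0.02, 0.6, 100],
            ]
        )
        h1, rep1 = harmonise(exp, out)
        assert rep1.n_flipped == 0
        np.testing.assert_array_equal(h1.beta_y, out["beta"].to_numpy())

    def test_sign_convention_invariance(self):
        """Swapping outcome allele labels (and beta sign, eaf) is a no-op."""
        exp = _table(
            [
                ["rs1", "1", 1, "A", "G", 0.3, 0.1, 0.02, 1e-9, 100],
                ["rs2", "1", 2, "C", "T", 0.4, -0.2, 0.03, 1e-11, 100],
            ]
        )
        out = _table(
            [
                ["rs1", "1", 1, "A", "G", 0.3, 0.05, 0.02, 0.01, 100],
                ["rs2", "1", 2, "C", "T", 0.4, -0.01, 0.02, 0.6, 100],
            ]
        )
        flipped = out.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            out["other_allele"],
            out["effect_allele"],
        )
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1 - out["eaf"]
        h1, _ = harmonise(exp, out)
        h2, _ = harmonise(exp, flipped)
        np.testing.assert_allclose(h1.beta_y, h2.beta_y, atol=1e-15)
        np.testing.assert_allclose(h1.beta_x, h2.beta_x)


class TestOrient:
    def test_negative_exposure_rows_negated(self):
        h = make_set([-0.1, 0.2], [-0.05, 0.1], [0.01, 0.01])
        o = orient_positive_exposure(h)
        np.testing.assert_allclose(o.beta_x, [0.1, 0.2])
        np.testing.assert_allclose(o.beta_y, [0.05, 0.1])

    def test_identity_when_all_positive(self):
        h = make_set([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        o = orient_positive_exposure(h)
        np.testing.assert_array_equal(o.beta_x, h.beta_x)
        np.testing.assert_array_equal(o.beta_y, h.beta_y)

    def test_wald_ratios_preserved(self, rng):
        bx = rng.normal(0, 0.1, 10)
        by = rng.normal(0, 0.05, 10)
        h = make_set(bx, by, np.full(10, 0.02))
        o = orient_positive_exposure(h)
        np.testing.assert_allclose(o.beta_y / o.beta_x, by / bx, rtol=1e-14)

    def test_ivw_and_weighted_median_exactly_preserved(self, rng):
        bx = rng.normal(0, 0.1, 15)
        se_y = rng.uniform(0.01, 0.05, 15)
        by = 0.3 * bx + rng.normal(0, se_y)
        h = make_set(bx, by, se_y, se_x=np.full(15, 0.01))
        o = orient_positive_exposure(h)
        assert ivw(h)[0].beta == pytest.approx(ivw(o)[0].beta, rel=1e-12)
        assert weighted_median(h, n_boot=10, seed=1).beta == pytest.approx(
            weighted_median(o, n_boot=10, seed=1).beta, rel=1e-12
        )
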