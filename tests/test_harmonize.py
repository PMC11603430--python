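"""Allele harmonization: alignment rules, palindromes, audit conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediation import HarmonizationError, harmonize
from mrmediation.harmonize import COMPLEMENT

from conftest import make_table


def pair(exposure_rows, outcome_rows, **kw):
    exp = make_table(exposure_rows, trait_name="exp")
    out = make_table(outcome_rows, trait_name="out", trait_type="binary")
    return harmonize(exp, out, **kw)


class TestAlignmentRules:
    def test_identical_alleles_kept_unchanged(self):
        h = pair([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}],
                 [{"effect_allele": "A", "other_allele": "G", "beta": 0.2}])
        assert h.df.loc[0, "status"] == "kept"
        assert h.df.loc[0, "beta_out"] == 0.2

    def test_swapped_alleles_negate_outcome(self):
        h = pair([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}],
                 [{"effect_allele": "G", "other_allele": "A", "beta": 0.2,
                   "eaf": 0.7}])
        assert h.df.loc[0, "status"] == "sign_flipped"
        assert h.df.loc[0, "beta_out"] == -0.2
        assert h.df.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_strand_flip_aligned(self):
        h = pair([{"effect_allele": "A", "other_allele": "G"}],
                 [{"effect_allele": "T", "other_allele": "C", "beta": 0.2}])
        assert h.df.loc[0, "status"] == "strand_flipped"
        assert h.df.loc[0, "beta_out"] == 0.2

    def test_strand_flip_and_swap_negates(self):
        h = pair([{"effect_allele": "A", "other_allele": "G"}],
                 [{"effect_allele": "C", "other_allele": "T", "beta": 0.2}])
        assert h.df.loc[0, "status"] == "strand_flipped"
        assert h.df.loc[0, "beta_out"] == -0.2

    def test_irreconcilable_alleles_dropped(self):
        h = pair([{"effect_allele": "A", "other_allele": "G"}],
                 [{"effect_allele": "A", "other_allele": "C"}])
        assert h.n_snp == 0
        assert h.audit["dropped_mismatch"] == 1

    def test_empty_intersection_raises_with_names(self):
        exp = make_table([{"snp": "rs1"}], trait_name="sleep")
        out = make_table([{"snp": "rs2"}], trait_name="headache")
        with pytest.raises(HarmonizationError, match="sleep.*headache"):
            harmonize(exp, out)


class TestPalindromes:
    def test_ambiguous_eaf_dropped_by_default(self):
        h = pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}],
                 [{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        assert h.n_snp == 0
        assert h.audit["dropped_palindromic"] == 1

    def test_resolvable_by_eaf_kept(self):
        h = pair([{"effect_allele": "C", "other_allele": "G", "eaf": 0.2}],
                 [{"effect_allele": "C", "other_allele": "G", "eaf": 0.25,
                   "beta": 0.4}])
        assert h.df.loc[0, "status"] == "kept"
        assert h.df.loc[0, "beta_out"] == 0.4

    def test_eaf_contradiction_flips_sign(self):
        # allele strings say aligned, frequencies say opposite strand+swap
        h = pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.2}],
                 [{"effect_allele": "A", "other_allele": "T", "eaf": 0.8,
                   "beta": 0.4}])
        assert h.df.loc[0, "status"] == "sign_flipped"
        assert h.df.loc[0, "beta_out"] == -0.4
        assert h.df.loc[0, "eaf_out"] == pytest.approx(0.2)

    def test_drop_policy_discards_all_palindromic(self):
        h = pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.1}],
                 [{"effect_allele": "A", "other_allele": "T", "eaf": 0.1}],
                 palindrome_policy="drop")
        assert h.audit["dropped_palindromic"] == 1

    def test_keep_policy_trusts_allele_strings(self):
        h = pair([{"effect_allele": "A", "other_allele": "T", "eaf": 0.5}],
                 [{"effect_allele": "T", "other_allele": "A", "beta": 0.4,
                   "eaf": 0.5}],
                 palindrome_policy="keep")
        assert h.df.loc[0, "status"] == "sign_flipped"
        assert h.df.loc[0, "beta_out"] == -0.4

    def test_missing_eaf_palindromic_dropped(self):
        h = pair([{"effect_allele": "A", "other_allele": "T", "eaf": np.nan}],
                 [{"effect_allele": "A", "other_allele": "T", "eaf": 0.2}])
        assert h.audit["dropped_palindromic"] == 1


class TestProperties:
    def _base_rows(self):
        return [
            {"effect_allele": "A", "other_allele": "G", "beta": 0.12, "eaf": 0.25},
            {"effect_allele": "C", "other_allele": "T", "beta": -0.08, "eaf": 0.4},
            {"effect_allele": "A", "other_allele": "T", "beta": 0.05, "eaf": 0.15},
        ]

    def test_self_harmonization_is_identity(self):
        t = make_table(self._base_rows())
        h = harmonize(t, t)
        assert h.n_snp == 3
        np.testing.assert_allclose(h.df["beta_exp"], h.df["beta_out"])

    def test_involution_recovers_original_betas(self):
        rows = self._base_rows()
        t = make_table(rows, trait_name="exp")
        corrupted = []
        for r in rows:
            c = dict(r)
            c["effect_allele"], c["other_allele"] = r["other_allele"], r["effect_allele"]
            c["beta"] = -r["beta"]
            c["eaf"] = 1 - r["eaf"]
            corrupted.append(c)
        out = make_table(corrupted, trait_name="out", trait_type="binary")
        h = harmonize(t, out)
        assert h.n_snp == 3
        np.testing.assert_allclose(h.df["beta_out"], [r["beta"] for r in rows])

    def test_strand_corruption_recovered(self):
        rows = self._base_rows()[:2]  # non-palindromic only
        t = make_table(rows, trait_name="exp")
        flipped = [dict(r, effect_allele=COMPLEMENT[r["effect_allele"]],
                        other_allele=COMPLEMENT[r["other_allele"]]) for r in rows]
        out = make_table(flipped, trait_name="out", trait_type="binary")
        h = harmonize(t, out)
        assert list(h.df["status"]) == ["strand_flipped"] * 2
        np.testing.assert_allclose(h.df["beta_out"], [r["beta"] for r in rows])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(
        st.tuples(
            st.sampled_from([("A", "G"), ("G", "A"), ("A", "T"), ("C", "G"),
                             ("T", "C"), ("A", "C")]),
            st.sampled_from([("A", "G"), ("G", "A"), ("A", "T"), ("T", "A"),
                             ("C", "T"), ("C", "A")]),
            st.floats(0.05, 0.95),
        ),
        min_size=1, max_size=8,
    ))
    def test_audit_counts_conserve_intersection(self, variants):
        exp_rows = [{"snp": f"rs{i}", "effect_allele": ea, "other_allele": oa,
                     "eaf": round(f, 3)}
                    for i, ((ea, oa), _, f) in enumerate(variants)]
        out_rows = [{"snp": f"rs{i}", "effect_allele": ea, "other_allele": oa,
                     "eaf": round(1 - f, 3)}
                    for i, (_, (ea, oa), f) in enumerate(variants)]
        h = pair(exp_rows, out_rows)
        assert sum(h.audit.values()) == len(variants)
        assert h.n_snp == h.audit["kept"] + h.audit["sign_flipped"] \
            + h.audit["strand_flipped"]
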