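"""Lipid-name grammar, mTIC normalization and class summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiophen.lipids import (
    Chain,
    LipidParseError,
    LipidSpecies,
    LipidTable,
    class_sum,
    cl_contains_chain,
    fold_change,
    mtic_normalize,
    parse_lipid_name,
    presence_filter,
    render_lipid_name,
    tetra_cl_fraction,
)


class TestParser:
    def test_tetra_shorthand_expands_to_four_chains(self):
        sp = parse_lipid_name("tetra[18:2]-CL")
        assert sp.lipid_class == "CL"
        assert sp.chains == (Chain(18, 2, False),) * 4

    def test_bracket_shorthand(self):
        sp = parse_lipid_name("[18:1][18:1][18:2][18:2]")
        assert sp.lipid_class == "CL"
        assert [c.carbons for c in sp.chains] == [18, 18, 18, 18]
        assert [c.double_bonds for c in sp.chains] == [1, 1, 2, 2]

    def test_hydroxylated_acylcarnitine(self):
        sp = parse_lipid_name("AC(16:0-OH)")
        assert sp.lipid_class == "AC"
        assert sp.chains == (Chain(16, 0, True),)
        assert sp.hydroxylated

    def test_two_chain_cl_rejected(self):
        with pytest.raises(LipidParseError, match="4 chains"):
            parse_lipid_name("CL(18:2/18:2)")

    def test_unparseable_name_reports_position(self):
        with pytest.raises(LipidParseError) as err:
            parse_lipid_name("TG(16:0/xx/18:1)")
        assert err.value.position == 8

    @pytest.mark.parametrize(
        "name",
        [
            "CL(18:1/18:1/18:2/18:2)",
            "tetra[18:2]-CL",
            "[14:0][16:1][18:1][18:2]",
            "MLCL(18:2/18:2/18:2)",
            "TG(16:0/18:1/18:2)",
            "AC(16:0)",
            "AC(18:1-OH)",
            "FFA(16:0-OH)",
        ],
    )
    def test_parse_render_round_trip(self, name):
        sp = parse_lipid_name(name)
        assert parse_lipid_name(render_lipid_name(sp)) == sp

    @settings(deadline=None, max_examples=60)
    @given(
        cls=st.sampled_from(["CL", "MLCL", "TG", "AC", "FFA"]),
        data=st.data(),
    )
    def test_round_trip_property(self, cls, data):
        """parse(render(s)) == s for arbitrary grammar productions."""
        n = {"CL": 4, "MLCL": 3, "TG": 3, "AC": 1, "FFA": 1}[cls]
        chains = tuple(
            Chain(
                data.draw(st.integers(2, 30)),
                data.draw(st.integers(0, 6)),
                data.draw(st.booleans()),
            )
            for _ in range(n)
        )
        sp = LipidSpecies(raw_name="synthetic", lipid_class=cls, chains=chains)
        assert parse_lipid_name(render_lipid_name(sp)) == sp


def _toy_table():
    ab = pd.DataFrame(
        {
            "WT_1": [3.0, 1.0, 4.0, 2.0, 5.0],
            "WT_2": [3.0, 1.0, 4.0, 2.0, 5.0],
            "KO_1": [1.0, 2.0, 8.0, 2.0, 5.0],
        },
        index=[
            "tetra[18:2]-CL",
            "[18:1][18:1][18:2][18:2]",
            "AC(16:0)",
            "AC(8:0)",
            "unknown_1",
        ],
    )
    groups = pd.Series({"WT_1": "WT", "WT_2": "WT", "KO_1": "KO"})
    identified = pd.Series(
        {n: n != "unknown_1" for n in ab.index}
    )
    return LipidTable(abundance=ab, groups=groups, identified=identified)


class TestMtic:
    def test_identified_sums_equal_after_normalization(self):
        table = mtic_normalize(_toy_table())
        sums = table.abundance.loc[table.identified].sum(axis=0)
        np.testing.assert_allclose(sums, sums.iloc[0])

    def test_scaling_one_sample_leaves_its_profile_unchanged(self):
        """A uniform rescale of one sample's raw values is removed by mTIC:
        the sample's normalized profile is unchanged (the cross-sample mean
        target only moves every sample by one common global factor)."""
        base = _toy_table()
        scaled_ab = base.abundance.copy()
        scaled_ab["KO_1"] *= 10.0
        scaled = LipidTable(
            abundance=scaled_ab, groups=base.groups, identified=base.identified
        )
        a = mtic_normalize(base).abundance
        b = mtic_normalize(scaled).abundance
        ratio = b / a
        np.testing.assert_allclose(ratio, ratio.iloc[0, 0])

    def test_two_sample_hand_computation(self):
        """Spreadsheet oracle on a 2-sample table."""
        ab = pd.DataFrame(
            {"s1": [6.0, 2.0], "s2": [2.0, 2.0]},
            index=["AC(16:0)", "FFA(18:1)"],
        )
        table = LipidTable(
            abundance=ab, groups=pd.Series({"s1": "a", "s2": "b"})
        )
        # sums: 8 and 4, mean 6 -> factors 0.75 and 1.5
        out = mtic_normalize(table).abundance
        np.testing.assert_allclose(out["s1"], [4.5, 1.5])
        np.testing.assert_allclose(out["s2"], [3.0, 3.0])

    def test_zero_identified_sum_rejected(self):
        ab = pd.DataFrame({"s1": [5.0], "s2": [0.0]}, index=["AC(16:0)"])
        table = LipidTable(abundance=ab, groups=pd.Series({"s1": "a", "s2": "b"}))
        with pytest.raises(ValueError, match="zero identified"):
            mtic_normalize(table)


class TestSummaries:
    def test_cl_chain_query_hand_computation(self):
        """CL species {tetra[18:2] at 3, mixed at 1}: contains-chain(18:1)
        sum = 1 and tetra[18:2] fraction = 0.75."""
        table = _toy_table()
        np.testing.assert_allclose(
            cl_contains_chain(table, 18, 1)[["WT_1", "WT_2"]], 1.0
        )
        np.testing.assert_allclose(
            tetra_cl_fraction(table)[["WT_1", "WT_2"]], 0.75
        )

    def test_long_chain_predicate_on_short_species_is_zero(self):
        ab = pd.DataFrame({"s1": [2.0]}, index=["AC(8:0)"])
        table = LipidTable(abundance=ab, groups=pd.Series({"s1": "g"}))
        assert class_sum(table, "AC", min_carbons=14)["s1"] == 0.0

    def test_class_sums_additive_over_partition(self):
        """Medium + long + out-of-range = class total."""
        table = _toy_table()
        total = class_sum(table, "AC")
        medium = class_sum(table, "AC", min_carbons=6, max_carbons=12)
        long_ = class_sum(table, "AC", min_carbons=14)
        short = class_sum(table, "AC", max_carbons=5)
        np.testing.assert_allclose(total, medium + long_ + short)

    def test_fold_change_reference_is_one(self):
        fc, flagged = fold_change(_toy_table(), "WT")
        np.testing.assert_allclose(
            fc[["WT_1", "WT_2"]].mean(axis=1), 1.0
        )
        assert flagged == []

    def test_fold_change_invariant_to_shared_mtic(self):
        base = _toy_table()
        fc_raw, _ = fold_change(base, "WT")
        fc_norm, _ = fold_change(mtic_normalize(base), "WT")
        # KO sample scaled by its own factor relative to reference:
        # invariance holds when reference and sample share normalization,
        # i.e. for the reference columns and ratios of identified sums
        ratio = fc_norm / fc_raw
        np.testing.assert_allclose(ratio["WT_1"], ratio["WT_1"].iloc[0])
        np.testing.assert_allclose(ratio["KO_1"], ratio["KO_1"].iloc[0])

    def test_fold_change_zero_reference_flagged(self):
        ab = pd.DataFrame(
            {"r1": [0.0, 2.0], "t1": [3.0, 4.0]},
            index=["AC(16:0)", "FFA(18:1)"],
        )
        table = LipidTable(
            abundance=ab, groups=pd.Series({"r1": "ref", "t1": "tx"})
        )
        fc, flagged = fold_change(table, "ref")
        assert flagged == ["AC(16:0)"]
        assert np.isnan(fc.loc["AC(16:0)", "t1"])

    def test_presence_filter_drops_group_absent_species(self):
        ab = pd.DataFrame(
            {
                "a1": [1.0, 0.0], "a2": [1.0, 0.0],
                "b1": [1.0, 2.0], "b2": [1.0, 2.0],
            },
            index=["AC(16:0)", "FFA(18:1)"],
        )
        table = LipidTable(
            abundance=ab,
            groups=pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
        )
        kept_all = presence_filter(table, mode="all").abundance.index
        kept_any = presence_filter(table, mode="any").abundance.index
        assert list(kept_all) == ["AC(16:0)"]
        assert list(kept_any) == ["AC(16:0)", "FFA(18:1)"]
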