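"""Spine/synapse classification, counts, densities, proportions."""

import numpy as np
import pandas as pd
import pytest

from spinemorph import census
from spinemorph.cohort import CohortConfig, generate_cohort
from spinemorph.errors import DataIntegrityError, InvalidInputError


def make_spines(rows):
    base = {
        "branch_group_id": None,
        "has_synapse": False,
        "head_protrusion_of": None,
        "oblique": False,
        "incomplete": False,
        "asi_um2": np.nan,
        **{o: False for o in census.ORGANELLE_COLUMNS},
        "presyn_fiber_id": None,
    }
    out = pd.DataFrame([{**base, **r} for r in rows])
    for c in census.SPINE_FLAG_COLUMNS:
        out[c] = out[c].astype(bool)
    return out


class TestNakedClassification:
    def test_taxonomy_labels(self):
        sp = make_spines(
            [
                {"spine_id": "a", "dendrite_id": "d"},
                {"spine_id": "b", "dendrite_id": "d", "branch_group_id": "g1"},
                {"spine_id": "c", "dendrite_id": "d", "branch_group_id": "g1"},
                {"spine_id": "e", "dendrite_id": "d", "branch_group_id": "g2"},
                {"spine_id": "f", "dendrite_id": "d", "branch_group_id": "g2", "has_synapse": True},
                {"spine_id": "g", "dendrite_id": "d", "has_synapse": True},
                {"spine_id": "h", "dendrite_id": "d", "head_protrusion_of": "g"},
            ]
        )
        got = census.classify_naked_types(sp)
        expect = [
            "single_naked",
            "branched_both_naked",
            "branched_both_naked",
            "branched_one_naked",
            "not_naked",
            "not_naked",
            "head_protrusion",
        ]
        assert list(got) == expect
        # scalar variant agrees row by row
        for i, row in sp.iterrows():
            gid = row["branch_group_id"]
            group = sp[sp["branch_group_id"] == gid] if pd.notna(gid) else sp.iloc[[i]]
            assert census.classify_naked_type(row, group) == expect[i]

    def test_mismatched_group_raises(self):
        sp = make_spines(
            [
                {"spine_id": "a", "dendrite_id": "d", "branch_group_id": "g1"},
                {"spine_id": "b", "dendrite_id": "d", "branch_group_id": "g2"},
            ]
        )
        with pytest.raises(DataIntegrityError):
            census.classify_naked_type(sp.iloc[0], sp)


class TestCounts:
    def test_branched_counting_rule(self):
        # one fully-synapsed pair + three lone synapses: 5 synapses, 2 branched
        sp = make_spines(
            [
                {"spine_id": "p1", "dendrite_id": "d", "branch_group_id": "g", "has_synapse": True},
                {"spine_id": "p2", "dendrite_id": "d", "branch_group_id": "g", "has_synapse": True},
                *(
                    {"spine_id": f"s{i}", "dendrite_id": "d", "has_synapse": True}
                    for i in range(3)
                ),
            ]
        )
        c = census.synapse_counts(sp)
        assert c == {
            "all_spines": 5,
            "synapses": 5,
            "branched_synapses": 2,
            "single_synapses": 3,
            "branched_spines": 2,
            "naked_spines": 0,
        }

    def test_triple_branched_group_counts_three(self):
        sp = make_spines(
            [
                {"spine_id": f"t{i}", "dendrite_id": "d", "branch_group_id": "g", "has_synapse": True}
                for i in range(3)
            ]
        )
        assert census.synapse_counts(sp)["branched_synapses"] == 3

    def test_counts_match_naive_recount_on_cohort(self, default_cohort):
        mice, dendrites, spines = default_cohort
        c = census.synapse_counts(spines)
        # brute-force per-record loop
        sizes = spines.groupby("branch_group_id").size().to_dict()
        syn = br = naked = 0
        for _, r in spines.iterrows():
            if r["has_synapse"]:
                syn += 1
                if pd.notna(r["branch_group_id"]) and sizes[r["branch_group_id"]] >= 2:
                    br += 1
            else:
                naked += 1
        assert (c["synapses"], c["branched_synapses"], c["naked_spines"]) == (syn, br, naked)
        assert c["single_synapses"] + c["branched_synapses"] == c["synapses"]
        assert c["synapses"] + c["naked_spines"] == c["all_spines"]


class TestDensities:
    def test_density_is_exact_ratio(self):
        den = pd.Series({"dendrite_id": "d", "surface_area_um2": 10.0, "length_um": 5.0})
        assert census.density(20, den) == 2.0
        assert census.density(20, den, "length") == 4.0
        assert census.density(0, den) == 0.0

    def test_zero_denominator_rejected(self):
        den = pd.Series({"dendrite_id": "d", "surface_area_um2": 0.0, "length_um": 5.0})
        with pytest.raises(InvalidInputError):
            census.density(3, den)

    def test_cumulative_asi_density(self):
        den = pd.Series({"dendrite_id": "d", "surface_area_um2": 1.5})
        sp = make_spines(
            [
                {"spine_id": "a", "dendrite_id": "d", "has_synapse": True, "asi_um2": 0.1},
                {"spine_id": "b", "dendrite_id": "d", "has_synapse": True, "asi_um2": 0.2},
                {"spine_id": "c", "dendrite_id": "d", "has_synapse": True, "oblique": True},
            ]
        )
        val, n_excluded = census.cumulative_asi_density(sp, den)
        assert val == pytest.approx(0.2)
        assert n_excluded == 1
        none = sp.assign(asi_um2=np.nan)
        val0, n0 = census.cumulative_asi_density(none, den)
        assert val0 == 0.0 and n0 == 3

    def test_per_dendrite_table_invariants_and_idempotence(self, default_cohort):
        mice, dendrites, spines = default_cohort
        t1 = census.per_dendrite_table(dendrites, spines)
        t2 = census.per_dendrite_table(dendrites, spines)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["all_spines"] == t1["synapses"] + t1["naked_spines"]).all()
        assert (t1["synapses"] == t1["single_synapses"] + t1["branched_synapses"]).all()
        # densities are exact ratios
        assert np.allclose(
            t1["synapse_density_per_um2"], t1["synapses"] / t1["surface_area_um2"]
        )


class TestProportions:
    def test_two_denominator_conventions(self):
        mice = pd.DataFrame({"mouse_id": ["m1"], "condition": ["W"]})
        dendrites = pd.DataFrame(
            {"dendrite_id": ["d"], "mouse_id": ["m1"], "surface_area_um2": [30.0],
             "length_um": [8.0], "diameter_um": [1.3]}
        )
        rows = [{"spine_id": f"s{i}", "dendrite_id": "d", "has_synapse": True} for i in range(6)]
        rows += [
            {"spine_id": "b1", "dendrite_id": "d", "branch_group_id": "g", "has_synapse": True},
            {"spine_id": "b2", "dendrite_id": "d", "branch_group_id": "g", "has_synapse": True},
            {"spine_id": "n1", "dendrite_id": "d"},
            {"spine_id": "n2", "dendrite_id": "d"},
        ]
        sp = make_spines(rows)
        all_conv = census.per_mouse_proportions(sp, dendrites, mice, "all_spines")
        syn_conv = census.per_mouse_proportions(sp, dendrites, mice, "with_synapse")
        assert all_conv.loc[0, "branched_pct"] == pytest.approx(100 * 2 / 10)
        assert syn_conv.loc[0, "branched_pct"] == pytest.approx(100 * 2 / 8)

    def test_orphan_spine_raises(self):
        mice = pd.DataFrame({"mouse_id": ["m1"], "condition": ["W"]})
        dendrites = pd.DataFrame(
            {"dendrite_id": ["d"], "mouse_id": ["m1"], "surface_area_um2": [30.0],
             "length_um": [8.0], "diameter_um": [1.3]}
        )
        sp = make_spines([{"spine_id": "s", "dendrite_id": "nowhere", "has_synapse": True}])
        with pytest.raises(DataIntegrityError):
            census.per_mouse_proportions(sp, dendrites, mice)

    def test_proportions_match_loop_oracle(self, default_cohort):
        mice, dendrites, spines = default_cohort
        got = census.per_mouse_proportions(spines, dendrites, mice, "with_synapse")
        sp = spines.merge(dendrites[["dendrite_id", "mouse_id"]], on="dendrite_id")
        sizes = spines.groupby("branch_group_id").size().to_dict()
        for _, row in got.iterrows():
            s = sp[sp["mouse_id"] == row["mouse_id"]]
            n_syn = n_br = n_spinula = 0
            for _, r in s.iterrows():
                if r["has_synapse"]:
                    n_syn += 1
                    n_spinula += bool(r["spinula"])
                    if pd.notna(r["branch_group_id"]) and sizes[r["branch_group_id"]] >= 2:
                        n_br += 1
            assert row["branched_pct"] == pytest.approx(100 * n_br / n_syn)
            assert row["spinula_pct"] == pytest.approx(100 * n_spinula / n_syn)

    def test_single_mouse_group_sd_zero_with_warning(self):
        cfg = CohortConfig(seed=3, n_mice={"W": 1, "EW": 1, "S": 1}, dendrites_per_mouse=3)
        mice, dendrites, spines = generate_cohort(cfg)
        t = census.per_dendrite_table(dendrites, spines)
        pm = census.per_mouse_proportions(spines, dendrites, mice)
        with pytest.warns(UserWarning, match="single mouse"):
            gs = census.group_summary(t, pm, mice)
        assert (gs["branched_pct_sd"] == 0.0).all()


class TestValidation:
    def test_asi_on_naked_spine_rejected(self):
        mice = pd.DataFrame({"mouse_id": ["m1"], "condition": ["W"]})
        dendrites = pd.DataFrame(
            {"dendrite_id": ["d"], "mouse_id": ["m1"], "surface_area_um2": [30.0],
             "length_um": [8.0], "diameter_um": [1.3]}
        )
        sp = make_spines([{"spine_id": "s", "dendrite_id": "d", "asi_um2": 0.2}])
        with pytest.raises(DataIntegrityError):
            census.validate_tables(dendrites, sp, mice)

    def test_inclusion_criteria_warn_not_fail(self):
        mice = pd.DataFrame({"mouse_id": ["m1"], "condition": ["W"]})
        dendrites = pd.DataFrame(
            {"dendrite_id": ["d"], "mouse_id": ["m1"], "surface_area_um2": [30.0],
             "length_um": [1.0], "diameter_um": [0.5]}
        )
        sp = make_spines([{"spine_id": "s", "dendrite_id": "d", "has_synapse": True}])
        with pytest.warns(UserWarning, match="inclusion"):
            census.validate_tables(dendrites, sp, mice)

    def test_prop_with_synapse_reports_both_conventions(self, default_cohort):
        mice, dendrites, spines = default_cohort
        got = census.prop_with_synapse(spines, dendrites)
        assert got["pooled"] == pytest.approx(spines["has_synapse"].mean())
        assert 0.8 < got["per_mouse_mean"] < 1.0
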