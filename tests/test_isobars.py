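"""Database filters, lipid name rule and isobar grouping statistics."""

import numpy as np
import pytest

from identmix import (
    CompoundRecord,
    FilterRules,
    cumulative_isobar_curve,
    filter_records,
    is_lipid_name,
    isobar_group_sizes,
    window_density,
)
from identmix.isobars import read_records_tsv


def record(i, mass, name=None, **kw):
    return CompoundRecord(id=f"r{i}", name=name or f"compound {i}", mass=mass, **kw)


#: the five database entries sharing formula C3H7NO2 (mass 89.0477):
#: beta-alanine, D-alanine, L-alanine, ethyl carbamate, sarcosine
ALANINE_ISOMERS = [
    record(i, 89.0477, name)
    for i, name in enumerate(
        ["beta-Alanine", "D-Alanine", "L-Alanine", "Ethyl carbamate", "Sarcosine"]
    )
]


class TestFilterRecords:
    def test_mass_cutoff_removes_heavy_records(self):
        recs = [record(0, 1600.0), record(1, 180.06)]
        kept, audit = filter_records(recs, FilterRules(max_mass=1500))
        assert [r.id for r in kept] == ["r1"]
        assert audit["max_mass"] == 1

    def test_status_whitelist(self):
        recs = [
            record(0, 100.0, status="detected"),
            record(1, 101.0, status="quantified"),
            record(2, 102.0, status="expected"),
        ]
        kept, audit = filter_records(
            recs, FilterRules(status_whitelist=["detected", "quantified"])
        )
        assert {r.status for r in kept} == {"detected", "quantified"}
        assert audit["status_whitelist"] == 1

    def test_unknown_whitelist_status_warns_not_errors(self):
        recs = [record(0, 100.0, status="detected")]
        with pytest.warns(UserWarning, match="predicted"):
            kept, _ = filter_records(recs, FilterRules(status_whitelist=["detected", "predicted"]))
        assert len(kept) == 1

    def test_empty_rule_set_is_identity(self):
        recs = [record(0, 100.0), record(1, 1600.0)]
        kept, audit = filter_records(recs, FilterRules())
        assert kept == recs
        assert audit == {}

    def test_organic_filter_requires_carbon(self):
        recs = [
            record(0, 100.0, formula="C6H12O6"),
            record(1, 101.0, formula="NaCl"),
            record(2, 102.0, formula="CaCO3"),  # carbonate: contains a bare C
            record(3, 103.0, formula=None),
        ]
        kept, _ = filter_records(recs, FilterRules(organic_only=True))
        assert [r.id for r in kept] == ["r0", "r2"]

    def test_audit_counts_sum_to_input_count(self):
        rng = np.random.default_rng(5)
        recs = [
            record(
                i,
                float(rng.uniform(50, 2000)),
                name="PC(16:0/18:1)" if i % 3 == 0 else f"cmpd {i}",
                formula="C6H12O6" if i % 2 == 0 else None,
            )
            for i in range(60)
        ]
        rules = FilterRules(require_formula=True, max_mass=1500, lipid_exclusion=True)
        kept, audit = filter_records(recs, rules)
        assert sum(audit.values()) + len(kept) == len(recs)


class TestLipidNameRule:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("PC(16:0/18:1)", True),
            ("TG(52:2)", True),
            ("Glucose", False),
            ("Vitamin D3 1:1 complex", True),  # documented false positive
            ("NAD+", False),
            ("Coenzyme Q10", False),
        ],
    )
    def test_two_numbers_separated_by_colon(self, name, expected):
        assert is_lipid_name(name) is expected


class TestGroupSizes:
    def test_alanine_isomer_group_of_five(self):
        sizes = isobar_group_sizes(ALANINE_ISOMERS, "exact")
        assert (sizes == 5).all()

    def test_unit_resolution_merges_close_masses(self):
        recs = [record(0, 89.0477), record(1, 89.0932)]
        exact = isobar_group_sizes(recs, "exact")
        unit = isobar_group_sizes(recs, "unit")
        assert exact.tolist() == [1, 1]
        assert unit.tolist() == [2, 2]

    def test_missing_mass_error_lists_ids(self):
        recs = [record(0, 100.0), CompoundRecord(id="r1", name="x", mass=None)]
        with pytest.raises(ValueError, match="r1"):
            isobar_group_sizes(recs, "exact")

    @pytest.mark.parametrize("resolution", ["exact", "unit"])
    def test_matches_brute_force_pairwise_oracle(self, resolution, rng):
        # draw masses with deliberate collisions
        pool = np.round(rng.uniform(50, 500, 60), 4)
        masses = rng.choice(pool, 200)
        recs = [record(i, float(m)) for i, m in enumerate(masses)]
        sizes = isobar_group_sizes(recs, resolution)

        def key(m):
            return round(m, 4) if resolution == "exact" else float(np.sign(m) * np.floor(abs(m) + 0.5))

        brute = [sum(key(a.mass) == key(b.mass) for b in recs) for a in recs]
        assert sizes.tolist() == brute

    def test_unit_sizes_at_least_exact_sizes(self, rng):
        masses = np.round(rng.uniform(50, 500, 150), 4)
        recs = [record(i, float(m)) for i, m in enumerate(masses)]
        exact = isobar_group_sizes(recs, "exact").to_numpy()
        unit = isobar_group_sizes(recs, "unit").to_numpy()
        assert (unit >= exact).all()


class TestCumulativeCurve:
    def test_all_unique_drops_to_zero_at_one(self):
        recs = [record(i, 100.0 + i) for i in range(10)]
        curve = cumulative_isobar_curve(isobar_group_sizes(recs, "exact"))
        assert curve.cumulative_percent.iloc[0] == 100.0
        assert curve[curve.threshold == 1].cumulative_percent.iloc[0] == 0.0

    def test_toy_mixture_gives_62_5_percent(self):
        # a 5-group plus three singletons: 5 of 8 compounds have >= 1 partner
        recs = ALANINE_ISOMERS + [record(10, 150.0), record(11, 151.0), record(12, 152.0)]
        curve = cumulative_isobar_curve(isobar_group_sizes(recs, "exact"))
        at1 = curve[curve.threshold == 1].cumulative_percent.iloc[0]
        assert at1 == pytest.approx(62.5)
        at4 = curve[curve.threshold == 4].cumulative_percent.iloc[0]
        assert at4 == pytest.approx(62.5)  # each of the five has exactly 4 partners
        at5 = curve[curve.threshold == 5].cumulative_percent.iloc[0]
        assert at5 == 0.0

    def test_monotone_non_increasing(self, rng):
        masses = rng.choice(np.round(rng.uniform(50, 200, 30), 4), 100)
        recs = [record(i, float(m)) for i, m in enumerate(masses)]
        curve = cumulative_isobar_curve(isobar_group_sizes(recs, "exact"))
        assert (np.diff(curve.cumulative_percent) <= 0).all()


class TestWindowDensity:
    def test_single_record_window_max_one(self):
        out = window_density([record(0, 123.4)])
        assert out.window_start.tolist() == [120.0]
        assert out.max_count.tolist() == [1]

    def test_alanine_group_dominates_its_window(self):
        recs = ALANINE_ISOMERS + [record(10, 87.5), record(11, 88.2)]
        out = window_density(recs)
        row = out[out.window_start == 85.0]
        assert row.max_count.iloc[0] == 5

    def test_boundary_mass_belongs_to_upper_window(self):
        out = window_density([record(0, 90.0), record(1, 89.999)])
        assert out.window_start.tolist() == [85.0, 90.0]
        assert out.max_count.tolist() == [1, 1]


class TestRecordsTsv:
    def test_read_with_schema_mapping(self, tmp_path):
        path = tmp_path / "export.tsv"
        path.write_text(
            "HMDB_ID\tcompound\tMW\tannotation_status\n"
            "HMDB01\tL-Alanine\t89.0477\tdetected\n"
            "HMDB02\tSarcosine\t89.0477\t\n"
        )
        recs = read_records_tsv(
            path,
            schema={"id": "HMDB_ID", "name": "compound", "mass": "MW", "status": "annotation_status"},
        )
        assert recs[0].id == "HMDB01"
        assert recs[0].mass == pytest.approx(89.0477)
        assert recs[1].status is None
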