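"""Drug scores, cost averaging, burden estimates and in vitro mutant matching."""

import numpy as np
import pytest

from gpcrvar.drugs import (
    DrugTargetEntry,
    DrugTargetMap,
    InVitroMutant,
    PrescriptionRecord,
    average_annual_cost,
    burden_table,
    economic_burden,
    match_in_vitro_mutants,
    rank_drugs_by_polymorphic_score,
    read_drug_target_tsv,
    read_prescriptions_csv,
    score_affected,
    score_polymorphic,
    write_drug_target_tsv,
    write_prescriptions_csv,
)
from gpcrvar.population import CRITERIA, GenotypeMatrix, fraction_affected
from gpcrvar.variants import MissenseVariant


def _map(*pairs):
    return DrugTargetMap([DrugTargetEntry(d, t) for d, t in pairs])


class TestScorePolymorphic:
    def test_sum_over_targets(self):
        tm = _map(("d1", "R1"), ("d1", "R2"))
        assert score_polymorphic("d1", tm, {"R1": 0.2, "R2": 0.3}) == pytest.approx(0.5)

    def test_single_target(self):
        tm = _map(("d1", "R1"))
        assert score_polymorphic("d1", tm, {"R1": 0.44}) == pytest.approx(0.44)

    def test_zero_fraction_target_is_neutral(self):
        tm1 = _map(("d1", "R1"))
        tm2 = _map(("d1", "R1"), ("d1", "R3"))
        fr = {"R1": 0.25, "R3": 0.0}
        assert score_polymorphic("d1", tm1, fr) == score_polymorphic("d1", tm2, fr)

    def test_unknown_drug_raises(self):
        with pytest.raises(KeyError):
            score_polymorphic("nope", _map(("d1", "R1")), {})

    def test_ranking_stable_with_name_tie_break(self):
        tm = _map(("b", "R1"), ("a", "R1"), ("c", "R2"))
        ranked = rank_drugs_by_polymorphic_score(tm, {"R1": 0.5, "R2": 0.1})
        assert list(ranked["drug"]) == ["a", "b", "c"]

    def test_trial_targets_excluded_by_default(self):
        tm = DrugTargetMap(
            [
                DrugTargetEntry("d1", "R1", status="approved"),
                DrugTargetEntry("d1", "R2", status="trial"),
            ]
        )
        assert tm.targets_of("d1") == ["R1"]
        assert score_polymorphic("d1", tm, {"R1": 0.2, "R2": 0.9}) == pytest.approx(0.2)


class TestScoreAffected:
    def _gm(self):
        calls = np.array([[2, 0], [0, 1], [0, 0], [0, 0]], dtype=np.int8)
        return GenotypeMatrix(
            ["i0", "i1", "i2", "i3"], ["v0", "v1"], calls,
            {"v0": "R1", "v1": "R2"},
        )

    def test_union_over_targets_matches_enumeration(self):
        gm = self._gm()
        flags = {"v0": (True, False), "v1": (True, False)}
        tm = _map(("d1", "R1"), ("d1", "R2"))
        got = score_affected("d1", tm, gm, flags, "any_known")
        assert got == pytest.approx(0.5)  # i0 via R1, i1 via R2

    def test_union_dominates_single_targets(self):
        gm = self._gm()
        flags = {"v0": (True, False), "v1": (True, False)}
        tm = _map(("d1", "R1"), ("d1", "R2"))
        union = score_affected("d1", tm, gm, flags, "any_known")
        singles = [
            fraction_affected(gm, flags, [t], "any_known") for t in ("R1", "R2")
        ]
        assert union >= max(singles)


class TestAverageAnnualCost:
    def _ledger(self, totals_by_year, drug="d1"):
        out = []
        for year, total in totals_by_year.items():
            for month in range(1, 13):
                out.append(PrescriptionRecord(drug, year, month, 10, total / 12))
        return out

    def test_four_equal_years(self):
        ledger = self._ledger({y: 400.0 for y in range(2013, 2017)})
        assert average_annual_cost(ledger, "d1") == pytest.approx(400.0)

    def test_partial_boundary_years_excluded(self):
        ledger = self._ledger({y: 400.0 for y in range(2013, 2017)})
        ledger += [
            PrescriptionRecord("d1", 2012, 12, 5, 1e6),
            PrescriptionRecord("d1", 2017, 1, 5, 1e6),
        ]
        assert average_annual_cost(ledger, "d1") == pytest.approx(400.0)

    def test_two_year_window(self):
        ledger = self._ledger({2013: 100.0, 2014: 300.0})
        assert average_annual_cost(ledger, "d1", year_window=(2013, 2014)) == pytest.approx(200.0)

    def test_no_data_in_window_raises(self):
        ledger = self._ledger({2010: 50.0})
        with pytest.raises(ValueError):
            average_annual_cost(ledger, "d1")


class TestEconomicBurden:
    def test_worked_example_millions(self):
        # 432 M GBP/yr at a 7% affected fraction -> ~30 M GBP/yr
        assert economic_burden(432.0, 0.07) == pytest.approx(30.24)

    def test_zero_fraction(self):
        assert economic_burden(1000.0, 0.0) == 0.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            economic_burden(-1.0, 0.5)
        with pytest.raises(ValueError):
            economic_burden(1.0, 1.5)

    def test_monotone_across_criteria_and_additive(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(30)],
            ["v0", "v1", "v2", "v3"],
            calls,
            {"v0": "R1", "v1": "R1", "v2": "R2", "v3": "R3"},
        )
        flags = {
            "v0": (True, False), "v1": (False, True),
            "v2": (True, True), "v3": (False, False),
        }
        tm = _map(("d1", "R1"), ("d2", "R2"), ("d2", "R3"))
        ledger = []
        for drug, total in (("d1", 1200.0), ("d2", 2400.0)):
            for year in range(2013, 2017):
                for month in range(1, 13):
                    ledger.append(PrescriptionRecord(drug, year, month, 1, total / 12))
        table = burden_table(tm, ledger, gm, flags, criteria=list(CRITERIA))
        for _, row in table.iterrows():
            assert row["burden_hom_known"] <= row["burden_any_known"] + 1e-12
            assert row["burden_any_known"] <= row["burden_any_known_or_putative"] + 1e-12
        # additivity: panel total equals the sum of per-drug burdens
        total = table["burden_any_known"].sum()
        per_drug = sum(
            economic_burden(
                average_annual_cost(ledger, d),
                score_affected(d, tm, gm, flags, "any_known"),
            )
            for d in tm.drugs
        )
        assert total == pytest.approx(per_drug)

    def test_unmapped_drug_reported_unscored(self):
        gm = GenotypeMatrix(["i0"], ["v0"], np.array([[0]], dtype=np.int8), {"v0": "R1"})
        tm = _map(("d1", "R1"))
        ledger = [PrescriptionRecord("orphan", 2014, 1, 1, 10.0)]
        table = burden_table(tm, ledger, gm, {}, criteria=["any_known"])
        row = table.set_index("drug").loc["orphan"]
        assert not row["in_target_map"]
        assert np.isnan(row["burden_any_known"])


class TestInVitroMatching:
    def _variant(self, receptor="R1", pos=100, wt="K", mut="N"):
        return MissenseVariant(receptor, pos, wt, mut, 1, 100)

    def test_max_abs_fold_change_and_flag(self):
        db = [
            InVitroMutant("R1", 100, "K", "N", "lig1", 2.0),
            InVitroMutant("R1", 100, "K", "N", "lig2", -7.0),
        ]
        out = match_in_vitro_mutants([self._variant()], db)
        assert out.iloc[0]["max_abs_fold_change"] == 7.0
        assert bool(out.iloc[0]["above_cutoff"])

    def test_below_cutoff_not_flagged(self):
        db = [InVitroMutant("R1", 100, "K", "N", "lig1", 4.9)]
        out = match_in_vitro_mutants([self._variant()], db)
        assert not bool(out.iloc[0]["above_cutoff"])

    def test_ortholog_with_nonidentical_human_residue_unmatched(self):
        db = [
            InVitroMutant(
                "R1", 100, "K", "N", "lig1", 9.0,
                species="mouse", human_identical_at_position=False,
            )
        ]
        assert match_in_vitro_mutants([self._variant()], db).empty

    def test_requires_identical_substitution(self):
        db = [InVitroMutant("R1", 100, "K", "Q", "lig1", 9.0)]
        assert match_in_vitro_mutants([self._variant()], db).empty


def test_target_map_and_ledger_round_trip(tmp_path):
    tm = DrugTargetMap(
        [
            DrugTargetEntry("d1", "R1", role="primary", status="approved"),
            DrugTargetEntry("d1", "R2", role="secondary", status="trial"),
        ]
    )
    records = [PrescriptionRecord("d1", 2014, 3, 12, 99.5)]
    tpath, ppath = tmp_path / "dt.tsv", tmp_path / "rx.csv"
    write_drug_target_tsv(tm, tpath)
    write_prescriptions_csv(records, ppath)
    tm2 = read_drug_target_tsv(tpath)
    assert {(e.drug, e.target, e.role, e.status) for e in tm2.entries} == {
        ("d1", "R1", "primary", "approved"),
        ("d1", "R2", "secondary", "trial"),
    }
    assert read_prescriptions_csv(ppath) == records
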