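"""Per-individual counts, the four affected-fraction criteria, polymorphic
site fractions and the de novo rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpcrvar.numbering import GenericPosition
from gpcrvar.population import (
    CRITERIA,
    GenotypeMatrix,
    TrioSummary,
    de_novo_rate,
    fraction_affected,
    fraction_sites_polymorphic,
    per_individual_counts,
)
from gpcrvar.sites import FunctionalSiteAnnotation
from gpcrvar.variants import MissenseVariant

from conftest import make_toy_segment_map


def _matrix(calls, receptors):
    calls = np.asarray(calls, dtype=np.int8)
    sites = [f"v{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(calls.shape[0])],
        sites=sites,
        calls=calls,
        site_receptors={s: r for s, r in zip(sites, receptors)},
    )


def brute_force_fraction_affected(gm, site_flags, targets, criterion):
    """Independent per-individual enumeration oracle."""
    include_putative = str(criterion).endswith("or_putative") or criterion in (3, 4)
    hom = str(criterion).startswith("hom") or criterion in (1, 3)
    targets = set(targets)
    n_affected = 0
    for i in range(gm.n_individuals):
        affected = False
        for j, s in enumerate(gm.sites):
            if gm.site_receptors[s] not in targets:
                continue
            known, putative = site_flags.get(s, (False, False))
            qualifying = known or (include_putative and putative)
            if not qualifying:
                continue
            g = gm.calls[i, j]
            if (hom and g == 2) or (not hom and g >= 1):
                affected = True
                break
        n_affected += affected
    return n_affected / gm.n_individuals


class TestPerIndividualCounts:
    def test_toy_enumeration(self):
        # individual 0: het at v0 (R1), hom at v1 (R1) -> n_mv 2, n_receptors 1
        gm = _matrix([[1, 2, 0], [0, 0, 0]], ["R1", "R1", "R2"])
        out = per_individual_counts(gm, clinical_sites=["v1"])
        assert out.loc["i0", "n_mv"] == 2
        assert out.loc["i0", "n_receptors"] == 1
        assert out.loc["i0", "n_clinical"] == 1
        assert tuple(out.loc["i1"]) == (0, 0, 0)

    def test_random_matrices_match_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_i, n_s = int(rng.integers(1, 15)), int(rng.integers(1, 20))
            calls = rng.integers(0, 3, size=(n_i, n_s))
            receptors = [f"R{int(r)}" for r in rng.integers(1, 4, size=n_s)]
            gm = _matrix(calls, receptors)
            out = per_individual_counts(gm)
            for i in range(n_i):
                assert out.iloc[i]["n_mv"] == (calls[i] >= 1).sum()
                expect_receptors = {
                    receptors[j] for j in range(n_s) if calls[i, j] >= 1
                }
                assert out.iloc[i]["n_receptors"] == len(expect_receptors)


class TestFractionAffected:
    def test_toy_cohort(self):
        # 4 individuals, one site known-functional in R1:
        # i0 hom, i1 het, i2/i3 reference
        gm = _matrix([[2], [1], [0], [0]], ["R1"])
        flags = {"v0": (True, False)}
        assert fraction_affected(gm, flags, ["R1"], 1) == 0.25
        assert fraction_affected(gm, flags, ["R1"], 2) == 0.50

    def test_no_qualifying_sites_is_zero(self):
        gm = _matrix([[2], [1]], ["R1"])
        for crit in CRITERIA:
            assert fraction_affected(gm, {"v0": (False, False)}, ["R1"], crit) == 0.0

    def test_empty_cohort_rejected(self):
        gm = GenotypeMatrix([], ["v0"], np.zeros((0, 1)), {"v0": "R1"})
        with pytest.raises(ValueError):
            fraction_affected(gm, {}, ["R1"], 1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_and_monotone(self, data):
        n_i = data.draw(st.integers(1, 12))
        n_s = data.draw(st.integers(1, 10))
        calls = np.array(
            data.draw(
                st.lists(
                    st.lists(st.integers(0, 2), min_size=n_s, max_size=n_s),
                    min_size=n_i, max_size=n_i,
                )
            ),
            dtype=np.int8,
        )
        receptors = [
            f"R{data.draw(st.integers(1, 3))}" for _ in range(n_s)
        ]
        flags = {
            f"v{j}": (data.draw(st.booleans()), data.draw(st.booleans()))
            for j in range(n_s)
        }
        gm = _matrix(calls, receptors)
        targets = ["R1", "R2"]
        fr = {c: fraction_affected(gm, flags, targets, c) for c in CRITERIA}
        for c in CRITERIA:
            assert fr[c] == pytest.approx(
                brute_force_fraction_affected(gm, flags, targets, c)
            )
        # criterion i <= ii <= iv and i <= iii <= iv
        assert fr["hom_known"] <= fr["any_known"] <= fr["any_known_or_putative"]
        assert fr["hom_known"] <= fr["hom_known_or_putative"] <= fr["any_known_or_putative"]


class TestFractionSitesPolymorphic:
    def _variants(self, sm, residues):
        out = []
        for r in residues:
            wt = sm.sequence[r - 1]
            mut = "A" if wt != "A" else "V"
            out.append(MissenseVariant("R1", r, wt, mut, 1, 100))
        return out

    def test_fraction(self):
        sm = make_toy_segment_map()
        known = [FunctionalSiteAnnotation("R1", "ptm", residue_index=i) for i in range(1, 11)]
        mvs = self._variants(sm, [1, 2, 3, 4])
        assert fraction_sites_polymorphic(mvs, known, sm) == pytest.approx(0.4)

    def test_all_and_none(self):
        sm = make_toy_segment_map()
        known = [FunctionalSiteAnnotation("R1", "ptm", residue_index=i) for i in (1, 2)]
        assert fraction_sites_polymorphic(self._variants(sm, [1, 2]), known, sm) == 1.0
        assert fraction_sites_polymorphic([], known, sm) == 0.0

    def test_generic_sites_match_through_segment_map(self):
        sm = make_toy_segment_map()
        pos = GenericPosition("3", 50)
        idx = sm.residue_of(pos)
        known = [pos, GenericPosition("6", 50)]
        assert fraction_sites_polymorphic(self._variants(sm, [idx]), known, sm) == 0.5

    def test_zero_known_sites_flagged_zero(self):
        sm = make_toy_segment_map()
        assert fraction_sites_polymorphic([], [], sm) == 0.0


class TestDeNovoRate:
    def test_printed_trio_counts_round_to_300(self):
        rate, label = de_novo_rate(TrioSummary(1762, 6))
        assert rate == pytest.approx(6 / 1762)
        assert label == "1 in ~300"

    def test_all_offspring_affected(self):
        _, label = de_novo_rate(TrioSummary(10, 10))
        assert label == "1 in ~1"

    def test_not_observed_sentinel(self):
        rate, label = de_novo_rate(TrioSummary(100, 0))
        assert rate == 0.0 and label == "not observed"


def test_genotype_matrix_tsv_round_trip(tmp_path):
    gm = _matrix([[0, 1], [2, 0]], ["R1", "R2"])
    path = tmp_path / "gt.tsv"
    gm.write_tsv(path)
    back = GenotypeMatrix.read_tsv(path, site_receptors=gm.site_receptors)
    assert back.individuals == gm.individuals
    assert back.sites == gm.sites
    assert (back.calls == gm.calls).all()


def test_genotype_matrix_rejects_bad_calls():
    with pytest.raises(ValueError):
        _matrix([[3]], ["R1"])
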