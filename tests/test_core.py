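"""Strain/ecology combinatorics, viability, and the growth-rate model."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolwell.core import (
    ALL_STRAINS,
    FIG_RATE_VECTOR,
    STRAINS,
    Metabolite,
    Source,
    Strain,
    ecology_from_index,
    ecology_from_presence,
    enumerate_ecologies,
    growth_rates,
    growth_rate_vector,
    mask_members,
    members_mask,
    metabolite_source,
    viable,
)

ECOLOGIES = enumerate_ecologies()


def _subsets():
    out = []
    for r in range(5):
        out.extend(frozenset(c) for c in itertools.combinations(STRAINS, r))
    return out


SUBSETS = _subsets()

ecologies_st = st.sampled_from(ECOLOGIES)
members_st = st.sets(st.sampled_from(list(STRAINS))).map(frozenset)


class TestStrains:
    def test_each_strain_produces_its_metabolite_and_requires_the_rest(self):
        produced = {s.produces for s in STRAINS}
        assert produced == set(Metabolite)
        for s in STRAINS:
            assert s.produces not in s.requires
            assert len(s.requires) == 3


class TestEcologyEnumeration:
    def test_sixteen_distinct_presence_vectors(self):
        assert len(ECOLOGIES) == 16
        assert len({e.presence for e in ECOLOGIES}) == 16

    def test_extremes_of_richness_ordering(self):
        assert ecology_from_index(1).presence == (0, 0, 0, 0)
        assert ecology_from_index(16).presence == (1, 1, 1, 1)

    def test_his_permissive_pair_sits_at_indices_14_and_16(self):
        # the two ecologies supplying ADE, TRP and LYS (a pure-HIS
        # community's requirements) must carry the labels 14 and 16
        assert ecology_from_index(14).presence == (1, 1, 0, 1)
        assert ecology_from_index(16).presence == (1, 1, 1, 1)

    def test_index_presence_roundtrip_is_identity(self):
        for e in ECOLOGIES:
            assert ecology_from_presence(e.presence).index == e.index
            assert ecology_from_index(e.index).presence == e.presence

    def test_ordering_is_richness_then_binary_value(self):
        richness = [e.richness for e in ECOLOGIES]
        assert richness == sorted(richness)

    def test_bad_lookups_raise(self):
        with pytest.raises(ValueError):
            ecology_from_index(0)
        with pytest.raises(ValueError):
            ecology_from_presence((2, 0, 0, 0))


class TestMetaboliteSource:
    def test_rich_ecology_supplies_everything(self):
        rich = ecology_from_index(16)
        assert metabolite_source(rich, frozenset(), Metabolite.HIS) is Source.ECOLOGY

    def test_full_community_crossfeeds_in_barren_ecology(self):
        barren = ecology_from_index(1)
        assert (
            metabolite_source(barren, ALL_STRAINS, Metabolite.HIS)
            is Source.CROSSFED
        )

    def test_no_producer_no_supplement_is_absent(self):
        barren = ecology_from_index(1)
        pair = frozenset({Strain.ADE, Strain.TRP})
        assert metabolite_source(barren, pair, Metabolite.HIS) is Source.ABSENT


class TestViability:
    @pytest.mark.parametrize(
        "presence, members, expected",
        [
            ((1, 1, 0, 0), {Strain.ADE, Strain.TRP}, False),  # HIS, LYS missing
            ((0, 0, 0, 0), set(STRAINS), True),  # full cross-feeding loop
            ((1, 1, 1, 1), {Strain.HIS}, True),  # fully supplemented
            ((0, 0, 0, 0), {Strain.HIS}, False),  # nothing available
        ],
    )
    def test_reference_cases(self, presence, members, expected):
        assert viable(ecology_from_presence(presence), frozenset(members)) is expected

    def test_empty_community_is_nonviable_everywhere(self):
        for e in ECOLOGIES:
            assert not viable(e, frozenset())

    @given(ecologies_st, members_st, st.sampled_from(list(Metabolite)))
    def test_adding_a_metabolite_never_kills_a_viable_pairing(self, eco, members, m):
        if not viable(eco, members):
            return
        richer = list(eco.presence)
        richer[int(m)] = 1
        assert viable(ecology_from_presence(richer), members)

    def test_rich_ecology_supports_every_nonempty_community(self):
        rich = ecology_from_index(16)
        for members in SUBSETS:
            if members:
                assert viable(rich, members)

    def test_exactly_two_ecologies_support_the_his_monoculture(self):
        supporting = [e.index for e in ECOLOGIES if viable(e, {Strain.HIS})]
        assert supporting == [14, 16]

    def test_every_monoculture_is_viable_in_exactly_two_ecologies(self):
        # symmetric requirements: each strain needs its 3 foreign
        # metabolites, supplied by exactly 2 of the 16 ecologies
        for s in STRAINS:
            n = sum(viable(e, {s}) for e in ECOLOGIES)
            assert n == 2


class TestGrowthRates:
    def test_calibration_override_reproduces_published_vector(self, params):
        rates = growth_rates(ecology_from_index(1), ALL_STRAINS, params)
        assert tuple(rates[s] for s in STRAINS) == FIG_RATE_VECTOR

    def test_nonviable_pairing_gets_the_death_rate(self, params):
        eco = ecology_from_presence((1, 1, 0, 0))
        rates = growth_rates(eco, {Strain.ADE, Strain.TRP}, params)
        assert rates == {Strain.ADE: -2.0, Strain.TRP: -2.0}

    def test_fully_supplemented_strain_pays_no_crossfeed_penalty(self, params):
        rates = growth_rates(ecology_from_index(16), {Strain.HIS}, params)
        assert rates[Strain.HIS] == pytest.approx(params.base_rates[int(Strain.HIS)])

    def test_crossfeed_penalty_counts_only_crossfed_requirements(self, params):
        # ecology (1,1,0,1) + {HIS, LYS}: HIS gets everything from the
        # ecology; LYS gets ADE and TRP supplemented, HIS cross-fed
        eco = ecology_from_presence((1, 1, 0, 1))
        rates = growth_rates(eco, {Strain.HIS, Strain.LYS}, params)
        assert rates[Strain.HIS] == pytest.approx(params.base_rates[2])
        assert rates[Strain.LYS] == pytest.approx(
            params.base_rates[3] * params.crossfeed_factor
        )

    def test_all_pairings_viable_iff_all_rates_positive(self, params):
        for eco in ECOLOGIES:
            for members in SUBSETS:
                if not members:
                    continue
                rates = growth_rates(eco, members, params)
                assert set(rates) == members
                if viable(eco, members):
                    assert all(r > 0 for r in rates.values())
                else:
                    assert all(r == params.death_rate for r in rates.values())

    def test_rate_vector_zeroes_nonmembers(self, params):
        v = growth_rate_vector(ecology_from_index(16), {Strain.HIS}, params)
        assert v[2] > 0
        assert v[0] == v[1] == v[3] == 0


class TestMasks:
    def test_mask_roundtrip(self):
        for members in SUBSETS:
            assert mask_members(members_mask(members)) == members

    def test_malformed_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_members("111")
        with pytest.raises(ValueError):
            mask_members("11x1")
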