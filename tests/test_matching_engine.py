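"""matching_engine: the seven match types, blocking, multi-year matching."""

from __future__ import annotations

import numpy as np
import pytest

from provlink.config import MatchingConfig, RunConfig, ScoringConfig
from provlink.errors import ConfigurationError
from provlink.matching_engine import (
    MatchCandidate,
    MatchType,
    block_candidates,
    classify_match,
    enumerate_match_types,
    match_all,
    rank_of,
)
from provlink.synthetic_data import ErrorConfig, generate_cohort
from provlink.temporal_scoring import ScoringWindow

from .conftest import make_licensure, make_nppes

FUZZY = MatchingConfig(fuzzy=True)
EXACT = MatchingConfig(fuzzy=False)


class TestEnumerateMatchTypes:
    def test_exactly_seven(self):
        assert len(enumerate_match_types()) == 7

    def test_strongest_is_full_name_city_street(self):
        assert enumerate_match_types()[0] is MatchType.FL_CS

    def test_strict_order_no_duplicates(self):
        types = enumerate_match_types()
        assert len(set(types)) == 7
        ranks = [rank_of(t) for t in types]
        assert ranks == sorted(ranks) == list(range(1, 8))

    def test_bare_surname_not_a_type(self):
        # 2 name-families x 4 address-cells = 8 combinations; the bare
        # surname cell is the excluded eighth
        assert MatchType.NONE not in enumerate_match_types()
        names = {t.name for t in enumerate_match_types()}
        assert "L" not in names

    def test_default_rank_order(self):
        assert [t.name for t in enumerate_match_types()] == [
            "FL_CS", "FL_C", "FL_S", "FL", "L_CS", "L_C", "L_S",
        ]


class TestClassifyMatch:
    def test_identical_everything(self):
        assert classify_match(make_licensure(), make_nppes()) is MatchType.FL_CS

    @pytest.mark.parametrize(
        "nppes_kw,expected",
        [
            ({}, MatchType.FL_CS),
            ({"street": "9 High St"}, MatchType.FL_C),
            ({"city": "Avon"}, MatchType.FL_S),
            ({"city": "Avon", "street": "9 High St"}, MatchType.FL),
            ({"first": "Maria"}, MatchType.L_CS),
            ({"first": "Maria", "street": "9 High St"}, MatchType.L_C),
            ({"first": "Maria", "city": "Avon"}, MatchType.L_S),
            ({"first": "Maria", "city": "Avon", "street": "9 High St"}, MatchType.NONE),
        ],
    )
    def test_all_agreement_cells(self, nppes_kw, expected):
        assert classify_match(make_licensure(), make_nppes(**nppes_kw)) is expected

    def test_surname_disagreement_is_none_regardless_of_address(self):
        # same first name and full address agreement cannot bridge a
        # changed surname
        lic = make_licensure(last="Black")
        rec = make_nppes(last="Gold")
        assert classify_match(lic, rec, FUZZY) is MatchType.NONE

    def test_initial_accepts_full_first_name(self):
        lic = make_licensure(first="H", city="Avon", street="9 High St")
        rec = make_nppes(first="Helen", city="Hartford", street="1 Elm St")
        assert classify_match(lic, rec) is MatchType.FL

    def test_compound_surname_subset_rule(self):
        lic = make_licensure(last="Brown Smith")
        rec = make_nppes(last="Brown Jackson Smith")
        assert classify_match(lic, rec) is MatchType.FL_CS

    def test_fuzzy_bridges_misspelling(self):
        lic = make_licensure(first="Helen")
        rec = make_nppes(first="Hellan")
        assert classify_match(lic, rec, EXACT) is MatchType.L_CS
        assert classify_match(lic, rec, FUZZY) is MatchType.FL_CS

    def test_mailing_address_consulted(self):
        from provlink.records_io import PostalAddress

        rec = make_nppes(
            city="Avon", street="9 High St",
            mailing=PostalAddress(street="1705 Park Avenue", city="Hartford", state="CT"),
        )
        assert classify_match(make_licensure(), rec) is MatchType.FL_CS

    def test_symmetric_in_field_content(self):
        # swapping which side carries which spelling yields the same type
        a = ("Helen", "Black", "Hartford", "1705 Park Ave")
        b = ("Hellan", "Black", "Hartford", "1705 Park Avenue")
        for cfg in (EXACT, FUZZY):
            t1 = classify_match(
                make_licensure(first=a[0], last=a[1], city=a[2], street=a[3]),
                make_nppes(first=b[0], last=b[1], city=b[2], street=b[3]), cfg)
            t2 = classify_match(
                make_licensure(first=b[0], last=b[1], city=b[2], street=b[3]),
                make_nppes(first=a[0], last=a[1], city=a[2], street=a[3]), cfg)
            assert t1 is t2

    def test_adding_agreement_never_weakens(self):
        # L_S -> FL_S -> FL_CS as entities start agreeing
        base = dict(first="Maria", city="Avon")
        stronger = [
            make_nppes(**base),                      # street only
            make_nppes(city="Avon"),                 # + first
            make_nppes(),                            # + city
        ]
        ranks = [rank_of(classify_match(make_licensure(), rec)) for rec in stronger]
        assert ranks == sorted(ranks, reverse=True)

    def test_street_number_must_match_exactly_in_fuzzy_mode(self):
        lic = make_licensure(street="1705 Park Ave")
        rec = make_nppes(street="1706 Park Ave", city="Avon")
        assert classify_match(lic, rec, FUZZY) is MatchType.FL


class TestBlocking:
    def test_disjoint_surnames_empty(self):
        lics = [make_licensure(last="Black"), make_licensure(last="Smith")]
        recs = [make_nppes(last="Gold"), make_nppes(last="Jones")]
        assert block_candidates(lics, recs) == []

    def test_same_surname_pair_emitted(self):
        lic = make_licensure(first="Helen", last="Black")
        rec = make_nppes(first="Hellan", last="Black")
        assert block_candidates([lic], [rec]) == [(lic, rec)]

    def test_misspelled_surname_survives_fuzzy_blocking(self):
        lic = make_licensure(last="Black")
        rec = make_nppes(last="Blacck")  # doubled letter, edit distance 1
        assert block_candidates([lic], [rec], FUZZY) == [(lic, rec)]
        assert block_candidates([lic], [rec], EXACT) == []

    def test_compound_surname_shares_token_key(self):
        lic = make_licensure(last="Brown Smith")
        rec = make_nppes(last="Brown Jackson Smith")
        assert block_candidates([lic], [rec]) == [(lic, rec)]

    @pytest.mark.parametrize("fuzzy", [False, True])
    def test_blocking_complete_on_random_instances(self, fuzzy):
        # oracle: classify over all pairs; blocking must lose nothing
        cfg = MatchingConfig(fuzzy=fuzzy)
        errors = ErrorConfig(p_misspelling=0.3, p_name_change=0.2, p_moved=0.1)
        for seed in range(6):
            cohort = generate_cohort(40, seed=seed, errors=errors)
            lics = cohort.licensure
            recs = cohort.nppes[2017]
            blocked = set()
            for lic, rec in block_candidates(lics, recs, cfg):
                blocked.add((lic.license_number, rec.npi))
            for lic in lics:
                for rec in recs:
                    if classify_match(lic, rec, cfg) is not MatchType.NONE:
                        assert (lic.license_number, rec.npi) in blocked


def _config(fuzzy=False, block=True, start=2013, end=2017):
    return RunConfig(
        matching=MatchingConfig(fuzzy=fuzzy, block=block),
        scoring=ScoringConfig(window=ScoringWindow(start, end)),
    )


class TestMatchAll:
    def test_present_in_all_snapshots(self):
        lic = make_licensure()
        snapshots = {y: [make_nppes(year=y)] for y in range(2013, 2018)}
        cands = match_all([lic], snapshots, _config())
        assert len(cands) == 1
        assert cands[0].entity_years["last"] == set(range(2013, 2018))
        assert cands[0].match_type is MatchType.FL_CS

    def test_present_only_in_oldest_snapshot(self):
        lic = make_licensure()
        snapshots = {y: ([make_nppes(year=y)] if y == 2013 else []) for y in range(2013, 2018)}
        cands = match_all([lic], snapshots, _config())
        assert len(cands) == 1
        for years in cands[0].entity_years.values():
            assert years <= {2013}

    def test_two_matching_rows_two_candidates(self):
        lic = make_licensure()
        twin = make_nppes(npi="1245319599")
        snapshots = {y: [make_nppes(year=y), twin] for y in range(2013, 2018)}
        cands = match_all([lic], snapshots, _config())
        assert len(cands) == 2
        assert {c.nppes.npi for c in cands} == {"1234567893", "1245319599"}

    def test_missing_snapshot_year_is_config_error(self):
        with pytest.raises(ConfigurationError, match="2015"):
            match_all([make_licensure()], {2013: [], 2014: [], 2016: [], 2017: []}, _config())

    def test_entity_years_require_surname_anchor(self):
        # same address but different surname: no candidate at all
        lic = make_licensure(last="Black")
        snapshots = {y: [make_nppes(last="Gold", year=y)] for y in range(2013, 2018)}
        assert match_all([lic], snapshots, _config()) == []

    def test_best_type_across_years(self):
        # address agrees only in 2013-2015; name everywhere
        lic = make_licensure()
        snapshots = {
            y: [make_nppes(year=y) if y <= 2015
                else make_nppes(year=y, city="Avon", street="9 High St")]
            for y in range(2013, 2018)
        }
        cands = match_all([lic], snapshots, _config())
        assert len(cands) == 1
        cand = cands[0]
        assert cand.match_type is MatchType.FL_CS  # strongest over the window
        assert cand.entity_years["city"] == {2013, 2014, 2015}
        assert cand.entity_years["first"] == set(range(2013, 2018))
        assert cand.nppes.year == 2017  # merge uses the most recent record

    @pytest.mark.parametrize("fuzzy", [False, True])
    def test_blocked_equals_exhaustive(self, fuzzy):
        errors = ErrorConfig(p_misspelling=0.2, p_name_change=0.2, p_moved=0.2)
        rng = np.random.default_rng(99)
        for seed in range(4):
            cohort = generate_cohort(int(rng.integers(10, 50)), seed=seed, errors=errors)
            blocked = match_all(cohort.licensure, cohort.nppes, _config(fuzzy=fuzzy, block=True))
            full = match_all(cohort.licensure, cohort.nppes, _config(fuzzy=fuzzy, block=False))
            assert _summary(blocked) == _summary(full)


def _summary(cands):
    return sorted(
        (c.licensure.license_number, c.nppes.npi, c.match_type.name,
         tuple(sorted((e, tuple(sorted(y))) for e, y in c.entity_years.items())))
        for c in cands
    )
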