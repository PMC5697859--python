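"""Tests for profile collection, majority/hybrid selection and noise filtering."""

import numpy as np
import pytest

from pbkpred.alphabet import PB_LETTERS
from pbkpred.pentadb import (
    THRESHOLDS,
    CandidateProfile,
    TierTable,
    build_db,
    noise_filter_ladder,
    tier_predicate,
)
from pbkpred.predictor import (
    collect_profiles,
    collect_profiles_noise_filtering,
    predict_hybrid,
    predict_majority,
    predict_with_noise_filtering,
    s2_scores,
)
from pbkpred.scoring import FrequencyTable

ALL = lambda chain: True


def _tiers(chain_ids):
    table = TierTable()
    for cid in chain_ids:
        table.add_chain(cid, {t: cid for t in THRESHOLDS})
    return table


def _uniform_tripb(value=1.0):
    entries = {a + b + c: value for a in PB_LETTERS for b in PB_LETTERS for c in PB_LETTERS}
    return FrequencyTable(3, "odds", entries, {}, len(entries))


@pytest.fixture()
def toy_db():
    # chain s1: ACDEF(m) CDEFG(d) DEFGH(m); s2 contributes ACDEF(d)
    return build_db(
        [
            ("s1", "ACDEFGH", "ZZmdmZZ"),
            ("s2", "ACDEFW", "ZZdZZZ"[:6]),
        ],
        _tiers(["s1", "s2"]),
    )


class TestCollectProfiles:
    def test_one_profile_per_window(self, toy_db):
        profiles = collect_profiles("ACDEFGH", toy_db, ALL)
        assert len(profiles) == 3
        assert [p.query_position for p in profiles] == [1, 2, 3]

    def test_exact_match_never_consults_wildcard(self, toy_db):
        profiles = collect_profiles("ACDEF", toy_db, ALL)
        assert profiles[0].match_kind == "exact-pentapeptide"
        assert profiles[0].counts == {"m": 1, "d": 1}

    def test_wildcard_fallback(self, toy_db):
        # ACDEW absent as 5-mer; prefix ACDE matches ACDEF records
        profiles = collect_profiles("ACDEW", toy_db, ALL)
        assert profiles[0].match_kind == "wildcard-tetrapeptide"
        assert profiles[0].counts == {"m": 1, "d": 1}

    def test_query_too_short(self, toy_db):
        with pytest.raises(ValueError):
            collect_profiles("ACDE", toy_db, ALL)


class TestMajority:
    def test_argmax(self):
        profiles = [CandidateProfile(1, {"m": 3, "d": 1}, "exact-pentapeptide")]
        result = predict_majority(profiles)
        assert result.pb_sequence == "ZZmZZ"
        assert result.per_position[0].tied == []

    def test_tie_reports_all_and_emits_alphabetical(self):
        profiles = [CandidateProfile(1, {"c": 2, "d": 2}, "exact-pentapeptide")]
        result = predict_majority(profiles)
        assert result.pb_sequence == "ZZcZZ"
        assert result.per_position[0].tied == ["c", "d"]

    def test_empty_profile_gives_z(self):
        result = predict_majority([CandidateProfile(1, {}, "none")])
        assert result.pb_sequence == "ZZZZZ"

    def test_chosen_is_always_a_candidate(self, world, world_db, tripb_table):
        query = world.chain("F1C0")
        predicate = lambda c: c != "F1C0"
        profiles = collect_profiles(query.aa_seq, world_db, predicate)
        for result in (
            predict_majority(profiles),
            predict_hybrid(profiles, tripb_table),
        ):
            for pos in result.per_position:
                if pos.chosen != "Z":
                    assert pos.chosen in pos.profile.counts


class TestS2:
    def test_single_candidates_single_term(self):
        table = FrequencyTable(3, "odds", {"mdm": 0.7}, {}, 1)
        prev = CandidateProfile(1, {"m": 1}, "exact-pentapeptide")
        self_p = CandidateProfile(2, {"d": 1}, "exact-pentapeptide")
        nxt = CandidateProfile(3, {"m": 1}, "exact-pentapeptide")
        assert s2_scores(prev, self_p, nxt, table) == {"d": pytest.approx(0.7)}

    def test_uniform_table_counts_terms(self):
        table = _uniform_tripb(0.25)
        prev = CandidateProfile(1, {"a": 1, "b": 1}, "exact-pentapeptide")
        self_p = CandidateProfile(2, {"m": 2, "d": 5}, "exact-pentapeptide")
        nxt = CandidateProfile(3, {"c": 1, "d": 1, "e": 1}, "exact-pentapeptide")
        scores = s2_scores(prev, self_p, nxt, table)
        assert scores == {"m": pytest.approx(1.5), "d": pytest.approx(1.5)}

    def test_missing_neighbour_uses_full_alphabet(self):
        table = _uniform_tripb(1.0)
        self_p = CandidateProfile(1, {"m": 1}, "exact-pentapeptide")
        nxt = CandidateProfile(2, {"d": 1}, "exact-pentapeptide")
        scores = s2_scores(None, self_p, nxt, table)
        assert scores["m"] == pytest.approx(16.0)

    def test_brute_force_toy(self):
        rng = np.random.default_rng(2)
        motifs = {
            a + b + c: float(rng.uniform(0, 2))
            for a in "md" for b in "mdk" for c in "mk"
        }
        table = FrequencyTable(3, "odds", motifs, {}, len(motifs))
        prev = CandidateProfile(1, {"m": 1, "d": 3}, "exact-pentapeptide")
        self_p = CandidateProfile(2, {"m": 2, "d": 1, "k": 4}, "exact-pentapeptide")
        nxt = CandidateProfile(3, {"m": 1, "k": 2}, "exact-pentapeptide")
        scores = s2_scores(prev, self_p, nxt, table)
        for y in "mdk":
            expected = sum(
                motifs.get(x + y + z, 0.0) for x in "md" for z in "mk"
            )
            assert scores[y] == pytest.approx(expected)


class TestHybrid:
    def test_s1_times_s2_argmax(self):
        # S1 {c:2, d:1}; craft S2 {c:0.1, d:0.5} via single-candidate context
        table = FrequencyTable(3, "odds", {"mcm": 0.1, "mdm": 0.5}, {}, 2)
        profiles = [
            CandidateProfile(1, {"m": 1}, "exact-pentapeptide"),
            CandidateProfile(2, {"c": 2, "d": 1}, "exact-pentapeptide"),
            CandidateProfile(3, {"m": 1}, "exact-pentapeptide"),
        ]
        result = predict_hybrid(profiles, table)
        # 2 * 0.1 = 0.2 < 1 * 0.5
        assert result.per_position[1].chosen == "d"

    def test_constant_table_reduces_to_majority(self, world, world_db):
        query = world.chain("F2C0")
        profiles = collect_profiles(query.aa_seq, world_db, lambda c: c != "F2C0")
        hybrid = predict_hybrid(profiles, _uniform_tripb())
        majority = predict_majority(profiles)
        assert hybrid.pb_sequence == majority.pb_sequence

    def test_all_zero_products_fall_back_to_majority(self):
        table = FrequencyTable(3, "odds", {}, {}, 0)  # nothing observed
        profiles = [
            CandidateProfile(1, {"m": 1}, "exact-pentapeptide"),
            CandidateProfile(2, {"c": 1, "d": 4}, "exact-pentapeptide"),
            CandidateProfile(3, {"m": 1}, "exact-pentapeptide"),
        ]
        result = predict_hybrid(profiles, table)
        assert result.per_position[1].chosen == "d"


class TestNoiseFiltering:
    @pytest.fixture()
    def homolog_db(self):
        # close: central PB 'a' once; far: central PB 'b' many times
        chains = [("close", "ACDEF", "ZZaZZ")]
        chains += [(f"far{i}", "ACDEF", "ZZbZZ") for i in range(10)]
        table = TierTable()
        table.add_chain("query", {t: "fam" if t <= 95 else "query" for t in THRESHOLDS})
        table.add_chain("close", {t: "fam" if t <= 95 else "close" for t in THRESHOLDS})
        for i in range(10):
            table.add_chain(f"far{i}", {t: f"far{i}" for t in THRESHOLDS})
        return chains, table

    def test_ladder_short_circuits_on_close_hit(self, homolog_db):
        chains, tiers = homolog_db
        db = build_db(chains, tiers)
        ladder = noise_filter_ladder(tiers, "query", 100)
        profiles = collect_profiles_noise_filtering("ACDEF", db, ladder)
        assert profiles[0].counts == {"a": 1}  # close homologue wins over 10x 'b'
        result = predict_with_noise_filtering("ACDEF", db, ladder, method="majority")
        assert result.pb_sequence == "ZZaZZ"

    def test_tier_used_records_deeper_rung(self, homolog_db):
        chains, tiers = homolog_db
        db = build_db([c for c in chains if c[0] != "close"], tiers)
        ladder = noise_filter_ladder(tiers, "query", 100)
        profiles = collect_profiles_noise_filtering("ACDEF", db, ladder)
        assert profiles[0].counts == {"b": 10}
        assert profiles[0].tier_used == len(ladder) - 1  # only the final rung hits

    def test_empty_ladder_rejected(self, toy_db=None):
        from pbkpred.pentadb import PentaDB

        with pytest.raises(ValueError):
            collect_profiles_noise_filtering("ACDEF", PentaDB(), [])

    def test_single_rung_below30_equals_classic(self, world, world_db, tripb_table):
        """A one-rung <30% ladder must reproduce the classic <30% scheme."""
        tiers = world.tier_table
        for chain_id in ("F0C0", "F1C1"):
            query = world.chain(chain_id)
            ladder = noise_filter_ladder(tiers, chain_id, ("below", 30))
            noise = predict_with_noise_filtering(
                query.aa_seq, world_db, ladder, "hybrid", tripb_table
            )
            classic_profiles = collect_profiles(
                query.aa_seq, world_db, tier_predicate(tiers, chain_id, 30)
            )
            classic = predict_hybrid(classic_profiles, tripb_table)
            assert noise.pb_sequence == classic.pb_sequence

    def test_single_tier_db_ladder_consistency(self):
        """All records in one tier: noise filtering equals the classic scheme."""
        chains = [("other", "ACDEFGH", "ZZmdmZZ")]
        tiers = TierTable()
        tiers.add_chain("query", {t: "query" for t in THRESHOLDS})
        tiers.add_chain("other", {t: "other" for t in THRESHOLDS})
        db = build_db(chains, tiers)
        ladder = noise_filter_ladder(tiers, "query", 100)
        noise = predict_with_noise_filtering("ACDEFGH", db, ladder, "majority")
        classic_profiles = collect_profiles(
            "ACDEFGH", db, tier_predicate(tiers, "query", 30)
        )
        classic = predict_majority(classic_profiles)
        assert noise.pb_sequence == classic.pb_sequence
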