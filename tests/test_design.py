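"""Candidate enumeration, scoring model, positional correction, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirnakit.design import (
    GUIDE_LEN,
    N_FEATURES,
    CorrectionParams,
    FilterRules,
    Grade,
    LOW_SCORE,
    NOT_CDS,
    POLYN_TRACT,
    ScoringModel,
    SiRNACandidate,
    apply_positional_correction,
    encode_features,
    enumerate_candidates,
    filter_candidates,
    grade_efficacy,
    has_polyn_tract,
    predict_efficacy,
    select_spaced,
    train_model,
)
from sirnakit.transcripts import Region, Transcript, reverse_complement

guides = st.text(alphabet="ACGT", min_size=GUIDE_LEN, max_size=GUIDE_LEN)


def _transcript(length, cds_start=None, cds_end=None, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Transcript(id="t", symbol="g", sequence=seq,
                      cds_start=cds_start or 2, cds_end=cds_end or length - 1)


class TestEnumerate:
    def test_window_counts(self):
        assert len(enumerate_candidates(_transcript(21))) == 1
        assert len(enumerate_candidates(_transcript(100))) == 80
        assert enumerate_candidates(_transcript(20)) == []

    def test_sense_guide_consistency(self):
        t = _transcript(100)
        cands = enumerate_candidates(t)
        c = cands[4]
        assert c.start == 5
        assert c.sense == t.sequence[4:25]
        assert c.guide == reverse_complement(c.sense)
        assert [c.start for c in cands] == list(range(1, 81))


class TestEncodeFeatures:
    @given(guides)
    @settings(max_examples=50, deadline=None)
    def test_indicator_and_count_sums(self, guide):
        x = encode_features(guide)
        assert x.shape == (N_FEATURES,)
        indicators = x[: GUIDE_LEN * 4]
        assert indicators.sum() == GUIDE_LEN
        counts = x[GUIDE_LEN * 4 :]
        assert counts[:4].sum() == 21      # 1-mers
        assert counts[4:20].sum() == 20    # 2-mers
        assert counts[20:].sum() == 19     # 3-mers

    def test_homopolymer_guide(self):
        x = encode_features("A" * 21)
        assert all(x[p * 4] == 1 for p in range(21))
        # AAA is the first 3-mer in lexicographic order
        assert x[GUIDE_LEN * 4 + 4 + 16] == 19

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            encode_features("ACGT")


class TestScoringModel:
    def test_noise_free_recovery(self, rng):
        """Training on data from a planted sparse linear model recovers its
        predictions as regularization vanishes."""
        planted = np.zeros(N_FEATURES)
        planted[[3, 40, 100, 150]] = [1.5, -2.0, 0.7, 0.9]
        intercept = 60.0
        guides = ["".join(rng.choice(list("ACGT"), size=21)) for _ in range(400)]
        y = [float(intercept + encode_features(g) @ planted) for g in guides]
        assert all(0 <= v <= 100 for v in y)
        model = train_model(list(zip(guides, y)), regularization=1e-10)
        for g in guides[:50]:
            expected = intercept + encode_features(g) @ planted
            assert model.linear_predictor(g) == pytest.approx(expected, abs=1e-6)

    def test_training_is_deterministic(self, rng):
        pairs = [("".join(rng.choice(list("ACGT"), 21)), float(50 + i))
                 for i in range(10)]
        m1, m2 = train_model(pairs), train_model(pairs)
        assert m1.intercept == m2.intercept
        assert np.array_equal(m1.coef, m2.coef)

    def test_invalid_training_inputs(self, rng):
        g = "".join(rng.choice(list("ACGT"), 21))
        with pytest.raises(ValueError, match="identical"):
            train_model([(g, 50.0), (g, 60.0)])
        g2 = "".join(rng.choice(list("ACGT"), 21))
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            train_model([(g, 120.0), (g2, 50.0)])

    def test_prediction_clipping_and_intercept(self):
        m = ScoringModel(intercept=85.0, coef=np.zeros(N_FEATURES), trained=True)
        assert predict_efficacy(m, "A" * 21) == 85.0
        m.intercept = 120.0
        assert predict_efficacy(m, "A" * 21) == 100.0

    def test_untrained_model_refuses(self):
        with pytest.raises(RuntimeError):
            predict_efficacy(ScoringModel(), "A" * 21)

    def test_prediction_is_affine_in_features(self, rng):
        """Manual dot product reproduces the linear predictor."""
        coef = rng.normal(size=N_FEATURES)
        m = ScoringModel(intercept=10.0, coef=coef, trained=True)
        g = "".join(rng.choice(list("ACGT"), 21))
        assert m.linear_predictor(g) == pytest.approx(
            10.0 + float(encode_features(g) @ coef)
        )
        assert m.position_weights.shape == (21, 4)
        assert len(m.motif_weights) == 84


class TestPositionalCorrection:
    def test_cds_start1_is_reference(self):
        assert apply_positional_correction(90.0, Region.CDS, 1) == 90.0

    def test_decay_per_100bp(self):
        # 1 point per 100 bp over 1000 bp
        assert apply_positional_correction(90.0, Region.CDS, 1001) == 80.0

    def test_five_utr_penalty(self):
        assert apply_positional_correction(90.0, Region.FIVE_UTR, 1) == 51.0

    def test_three_utr_penalty(self):
        assert apply_positional_correction(90.0, Region.THREE_UTR, 1) == 64.0

    def test_monotone_nonincreasing_in_start(self):
        params = CorrectionParams()
        scores = [apply_positional_correction(90.0, Region.CDS, s, params)
                  for s in range(1, 4002, 100)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_unknown_location_rejected(self):
        with pytest.raises(ValueError):
            apply_positional_correction(90.0, "INTRON", 1)


class TestPolynTract:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GAAAAC", True), ("AGAGAGAG", False), ("UUUU", True),
         ("ACCCGT", False), ("ACCCCGT", True)],
    )
    def test_examples(self, seq, expected):
        assert has_polyn_tract(seq) is expected


def _cand(start=1, location=Region.CDS, score=90.0, sense="ACG" * 7,
          target="t", n_ot=None):
    return SiRNACandidate(
        target_id=target, symbol="g", start=start, sense=sense,
        guide=reverse_complement(sense), location=location,
        base_score=score, corrected_score=score, n_offtargets=n_ot,
    )


class TestFilterCandidates:
    def test_threshold_is_strict(self):
        retained, rejected = filter_candidates(
            [_cand(score=80.0)], FilterRules(min_score=80.0)
        )
        assert retained == [] and rejected[0].flags == {LOW_SCORE}
        retained, _ = filter_candidates(
            [_cand(score=80.01)], FilterRules(min_score=80.0)
        )
        assert len(retained) == 1

    def test_flags_are_complete(self):
        c = _cand(score=50.0, location=Region.FIVE_UTR, sense="AAAA" + "CG" * 8 + "T")
        _, rejected = filter_candidates(
            [c], FilterRules(min_score=80, cds_only=True, no_polyn=True)
        )
        assert rejected[0].flags == {LOW_SCORE, NOT_CDS, POLYN_TRACT}

    def test_empty_rules_retain_all(self):
        cands = [_cand(score=None), _cand(score=10.0)]
        retained, rejected = filter_candidates(cands, FilterRules(min_score=None))
        assert retained == cands and rejected == []

    def test_missing_offtarget_counts_error(self):
        with pytest.raises(ValueError, match="off-target"):
            filter_candidates([_cand()], FilterRules(max_offtargets=0))

    def test_retained_subset_and_reproducible_flags(self, rng):
        cands = [
            _cand(start=i, score=float(rng.uniform(0, 100)),
                  location=rng.choice([Region.CDS, Region.FIVE_UTR]),
                  n_ot=int(rng.poisson(1)))
            for i in range(1, 40)
        ]
        rules = FilterRules(min_score=80, cds_only=True, max_offtargets=0)
        retained, rejected = filter_candidates(cands, rules)
        assert set(id(c) for c in retained) <= set(id(c) for c in cands)
        for c in rejected:
            recheck = set()
            if not (c.base_score > 80):
                recheck.add(LOW_SCORE)
            if c.location is not Region.CDS:
                recheck.add(NOT_CDS)
            if c.n_offtargets > 0:
                recheck.add("OFFTARGETS")
            assert c.flags == recheck


class TestSelectSpaced:
    def test_overlap_suppression(self):
        a, b = _cand(start=10, score=95.0), _cand(start=20, score=90.0)
        assert select_spaced([a, b], k=5, min_gap=21) == [a]

    def test_zero_gap_gives_top_k(self):
        cands = [_cand(start=s, score=float(s)) for s in range(1, 11)]
        picked = select_spaced(cands, k=3, min_gap=0)
        assert [c.start for c in picked] == [10, 9, 8]

    def test_tie_breaks_toward_smaller_start(self):
        a, b = _cand(start=40, score=90.0), _cand(start=10, score=90.0)
        assert select_spaced([a, b], k=1, min_gap=5)[0].start == 10


class TestGrading:
    @pytest.mark.parametrize(
        "pct,grade",
        [(70.0, Grade.HIGH), (85.0, Grade.HIGH), (55.0, Grade.MODERATE),
         (50.0, Grade.MODERATE), (49.9, Grade.INEFFICIENT),
         (-10.0, Grade.INEFFICIENT)],
    )
    def test_boundaries(self, pct, grade):
        assert grade_efficacy(pct) is grade
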