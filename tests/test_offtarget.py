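"""Bit-parallel mismatch search and 3'UTR seed-match profiling."""

import numpy as np
import pytest

from sirnakit.offtarget import (
    SeedMatchProfile,
    mismatch_positions,
    scan_offtargets,
    seed_match_profile,
    seed_site,
    shift_add_search,
)
from sirnakit.synthetic import make_study_transcriptome, plant_offtarget, sample_study_candidates
from sirnakit.transcripts import reverse_complement

BASES = list("ACGT")


def brute_force_hits(pattern, text, k):
    """Naive sliding-window Hamming oracle: (1-based start, mismatch positions)."""
    m = len(pattern)
    out = []
    for j in range(len(text) - m + 1):
        mism = [i + 1 for i in range(m) if pattern[i] != text[j + i]]
        if len(mism) <= k:
            out.append((j + 1, mism))
    return out


def random_instance(rng, max_text=500, min_pat=1, max_pat=24):
    m = int(rng.integers(min_pat, max_pat + 1))
    n = int(rng.integers(m, max_text + 1))
    pattern = "".join(rng.choice(BASES, m))
    # bias the text toward the pattern's composition so hits actually occur
    if rng.random() < 0.5:
        text = "".join(rng.choice(list(pattern), n))
    else:
        text = "".join(rng.choice(BASES, n))
    return pattern, text


class TestShiftAddSearch:
    def test_worked_example(self):
        hits = shift_add_search("ACGT", "ACGAACGT", 1)
        assert [(h.subject_start, h.mismatch_count, h.mismatch_positions)
                for h in hits] == [(1, 1, (4,)), (5, 0, ())]

    def test_pattern_equals_text(self):
        (hit,) = shift_add_search("ACGTACGT", "ACGTACGT", 3)
        assert hit.subject_start == 1 and hit.mismatch_count == 0

    def test_exact_mode_matches_substring_search(self, rng):
        for _ in range(100):
            pattern, text = random_instance(rng, max_text=200, min_pat=2, max_pat=8)
            got = {h.subject_start for h in shift_add_search(pattern, text, 0)}
            expected, start = set(), text.find(pattern)
            while start != -1:
                expected.add(start + 1)
                start = text.find(pattern, start + 1)
            assert got == expected

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(400):
            pattern, text = random_instance(rng)
            k = int(rng.integers(0, 5))
            got = [(h.subject_start, list(h.mismatch_positions))
                   for h in shift_add_search(pattern, text, k)]
            assert got == brute_force_hits(pattern, text, k)

    def test_hits_monotone_in_k(self, rng):
        for _ in range(50):
            pattern, text = random_instance(rng)
            prev = set()
            for k in range(4):
                cur = {(h.subject_start, h.mismatch_positions)
                       for h in shift_add_search(pattern, text, k)}
                assert prev <= cur
                prev = cur

    def test_results_sorted_by_subject_start(self, rng):
        pattern, text = random_instance(rng, max_text=2000, min_pat=2, max_pat=4)
        starts = [h.subject_start for h in shift_add_search(pattern, text, 2)]
        assert starts == sorted(starts)

    def test_overlong_pattern_instructs_chunking(self):
        with pytest.raises(ValueError, match="chunk"):
            shift_add_search("A" * 33, "A" * 100, 1)


class TestScanOfftargets:
    def test_intended_target_excluded(self):
        bank = make_study_transcriptome(seed=3)
        cand = sample_study_candidates(seed=3, transcriptome=bank)[0]
        # against only the intended target, nothing is reported
        n, hits = scan_offtargets(cand, [t for t in bank if t.id == cand.target_id],
                                  k=3, exclude_ids={cand.target_id})
        assert (n, hits) == (0, [])

    def test_planted_two_mismatch_copy_found(self):
        bank = make_study_transcriptome(seed=4)
        cand = sample_study_candidates(seed=4, transcriptome=bank)[10]
        hosts = [t for t in bank if t.id != cand.target_id]
        modified, manifest = plant_offtarget(hosts, cand.sense, n_sites=1,
                                             n_mismatches=2, seed=4)
        n, hits = scan_offtargets(cand, modified, k=3,
                                  exclude_ids={cand.target_id})
        assert n == 1
        planted = manifest[0]
        match = [h for h in hits if h.subject_id == planted["transcript_id"]
                 and h.subject_start == planted["start"]]
        assert match and match[0].mismatch_count == 2
        assert list(match[0].mismatch_positions) == planted["mismatch_positions"]

    def test_no_exact_copies_at_k0(self):
        bank = make_study_transcriptome(seed=5)
        cand = sample_study_candidates(seed=5, transcriptome=bank)[0]
        n, hits = scan_offtargets(cand, bank, k=0, exclude_ids={cand.target_id})
        assert (n, hits) == (0, [])

    def test_empty_databank(self):
        cand = sample_study_candidates(seed=6)[0]
        assert scan_offtargets(cand, [], k=3) == (0, [])


class TestSeedSite:
    def test_worked_example(self):
        guide = "ACGTACGTACGTACGTACGTA"
        assert guide[1:8] == "CGTACGT"
        assert seed_site(guide) == "ACGTACG"

    def test_poly_a_guide(self):
        assert seed_site("A" * 21) == "T" * 7

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            seed_site("ACGT")


class TestSeedMatchProfile:
    def test_hit_classes(self):
        guide = "A" * 21  # site TTTTTTT
        bank = [
            ("u1", "GG" + "T" * 7 + "GG"),                  # one site
            ("u2", "T" * 7 + "AA" + "T" * 7),               # two sites
            ("u3", "ACGT" * 5),                              # none
        ]
        prof = seed_match_profile(guide, bank)
        assert prof == SeedMatchProfile(n_seqs=2, hit1=1, hit2=1, hit3plus=0)

    def test_overlapping_occurrences_counted(self):
        guide = "A" * 21
        prof = seed_match_profile(guide, [("u", "T" * 9)])  # 3 overlapping sites
        assert prof == SeedMatchProfile(n_seqs=1, hit1=0, hit2=0, hit3plus=1)

    def test_empty_databank(self):
        assert seed_match_profile("A" * 21, []) == SeedMatchProfile(0, 0, 0, 0)

    def test_counts_match_naive_scan(self, rng):
        for _ in range(20):
            guide = "".join(rng.choice(BASES, 21))
            site = seed_site(guide)
            bank = [(f"u{i}", "".join(rng.choice(list(site), int(rng.integers(7, 60)))))
                    for i in range(30)]
            prof = seed_match_profile(guide, bank)
            counts = [sum(1 for j in range(len(s) - 6) if s[j:j + 7] == site)
                      for _, s in bank]
            assert prof.hit1 == sum(1 for c in counts if c == 1)
            assert prof.hit2 == sum(1 for c in counts if c == 2)
            assert prof.hit3plus == sum(1 for c in counts if c >= 3)
            assert prof.n_seqs == sum(1 for c in counts if c >= 1)

    def test_strict_identity_mode(self):
        guide = "ACGTACGTACGTACGTACGTA"
        heptamer = guide[1:8]
        prof = seed_match_profile(guide, [("u", "GG" + heptamer + "GG")],
                                  strict_identity=True)
        assert prof.n_seqs == 1


class TestMismatchPositions:
    def test_perfect_duplex(self):
        guide = "ACGTACGTACGTACGTACGTA"
        assert mismatch_positions(guide, reverse_complement(guide)) == []

    def test_pairing_map(self, rng):
        """A substitution at window position w breaks guide position 22-w."""
        guide = "".join(rng.choice(BASES, 21))
        window = reverse_complement(guide)
        for w in (1, 7, 21):
            mutated = list(window)
            mutated[w - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[w - 1]]
            assert mismatch_positions(guide, "".join(mutated)) == [22 - w]

    def test_three_planted_substitutions(self, rng):
        guide = "".join(rng.choice(BASES, 21))
        window = list(reverse_complement(guide))
        for w in (3, 10, 17):
            window[w - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[w - 1]]
        assert mismatch_positions(guide, "".join(window)) == sorted(22 - w for w in (3, 10, 17))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mismatch_positions("A" * 21, "A" * 20)
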