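"""k-mer and alignment classifiers against brute-force oracles."""

import numpy as np
import pytest

from markerbench.classify import (
    AlignScoring, ClassificationResult, align_classify, build_index,
    classify_genome, kmer_classify, sw_score,
)
from markerbench.extract import MarkerRecord


def _rec(seq, species="spA", genome="g1", genus="genus01", copy=0,
         region="operon"):
    return MarkerRecord(f"{genome}:{region}:{copy}", genome, genus, species,
                        region, copy, seq)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# k-mer index and classifier


def brute_force_kmer_scores(query, references, k):
    """Oracle: enumerate windows, count per species via set membership."""
    by_species = {}
    for r in references:
        kmers = {r.sequence[i:i + k]
                 for i in range(len(r.sequence) - k + 1)}
        by_species.setdefault(r.species, set()).update(kmers)
    scores = {}
    for i in range(len(query) - k + 1):
        w = query[i:i + k]
        for sp, kmers in by_species.items():
            if w in kmers:
                scores[sp] = scores.get(sp, 0) + 1
    return scores


class TestKmerIndex:
    def test_window_counts(self, rng):
        one = build_index([_rec(_random_dna(rng, 31))], k=31)
        assert len(one.kmer_to_species) == 1
        hundred = build_index([_rec(_random_dna(rng, 100))], k=31)
        assert len(hundred.kmer_to_species) <= 70  # duplicates collapse
        assert sum(1 for _ in hundred.kmer_to_species) > 0
        # distinct windows of a random 100-mer are almost surely 70
        assert len(hundred.kmer_to_species) == 70

    def test_identical_references_share_all_kmers(self, rng):
        seq = _random_dna(rng, 80)
        idx = build_index([_rec(seq, "spA"), _rec(seq, "spB", genome="g2")],
                          k=31)
        for species in idx.kmer_to_species.values():
            assert species == frozenset({"spA", "spB"})

    def test_short_references_skipped(self, rng):
        idx = build_index([_rec(_random_dna(rng, 10), "spA"),
                           _rec(_random_dna(rng, 40), "spB")], k=31)
        assert idx.n_skipped_short == 1

    def test_mixed_genera_rejected(self, rng):
        with pytest.raises(ValueError):
            build_index([_rec(_random_dna(rng, 40), genus="genus01"),
                         _rec(_random_dna(rng, 40), genus="genus02")])


class TestKmerClassify:
    def test_self_match_score_is_window_count(self, rng):
        seq = _random_dna(rng, 5000)
        other = _random_dna(rng, 5000)
        idx = build_index([_rec(seq, "spA"), _rec(other, "spB", "g2")])
        res = kmer_classify(seq, idx, 0, query_id="q", true_species="spA")
        assert res.predicted_species == "spA"
        assert res.score == 5000 - 31 + 1 == 4970
        assert res.correct

    def test_matches_bruteforce_oracle_on_random_toys(self, rng):
        """100 random toys: identical per-species scores and winner set."""
        k = 5
        for _ in range(100):
            refs = [_rec(_random_dna(rng, int(rng.integers(20, 60))),
                         f"sp{j}", genome=f"g{j}")
                    for j in range(int(rng.integers(2, 5)))]
            query = _random_dna(rng, int(rng.integers(10, 50)))
            idx = build_index(refs, k=k)
            oracle = brute_force_kmer_scores(query, refs, k)
            res = kmer_classify(query, idx, rng, query_id="q",
                                true_species="sp0")
            if not oracle:
                assert res.predicted_species is None
                assert res.score == 0
            else:
                best = max(oracle.values())
                winners = {sp for sp, sc in oracle.items() if sc == best}
                assert res.predicted_species in winners
                assert res.score == best
                assert res.tie_broken == (len(winners) > 1)

    def test_dominance(self):
        # query shares many windows with A, fewer with B
        a = "ACGTACGTACGTACGTAAAA"
        b = "ACGTATTTTTTTTTTTTTTT"
        idx = build_index([_rec(a, "spA"), _rec(b, "spB", "g2")], k=5)
        res = kmer_classify("ACGTACGTACGTACGT", idx, 0)
        oracle = brute_force_kmer_scores("ACGTACGTACGTACGT",
                                         [_rec(a, "spA"),
                                          _rec(b, "spB", "g2")], 5)
        assert oracle["spA"] > oracle["spB"]
        assert res.predicted_species == "spA"

    def test_score_invariant_to_reference_order(self, rng):
        refs = [_rec(_random_dna(rng, 60), f"sp{j}", genome=f"g{j}")
                for j in range(4)]
        query = refs[2].sequence[:40]
        s1 = kmer_classify(query, build_index(refs, k=7), 0).score
        s2 = kmer_classify(query, build_index(refs[::-1], k=7), 0).score
        assert s1 == s2

    def test_no_match_is_unclassified(self, rng):
        idx = build_index([_rec("A" * 40, "spA"), _rec("C" * 40, "spB", "g2")])
        res = kmer_classify("G" * 40, idx, 0, true_species="spA")
        assert res.predicted_species is None
        assert not res.correct


# ---------------------------------------------------------------------------
# Smith-Waterman


def sw_oracle(a, b, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_extend=-2.0):
    """Full-matrix affine-gap local alignment, written independently."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_perfect_self_alignment(self, rng):
        seq = _random_dna(rng, 300)
        assert sw_score(seq, seq) == 2 * 300

    def test_single_internal_mismatch(self, rng):
        seq = _random_dna(rng, 100)
        mutated = list(seq)
        mutated[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[50]]
        mutated = "".join(mutated)
        got = sw_score(seq, mutated)
        assert got == sw_oracle(seq, mutated)
        assert got == 2 * 100 - 5  # full alignment through the mismatch

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_independent_dp_oracle(self, rng, trial):
        rng = np.random.default_rng(100 + trial)
        a = _random_dna(rng, int(rng.integers(20, 120)))
        b = _random_dna(rng, int(rng.integers(20, 120)))
        assert sw_score(a, b) == sw_oracle(a, b)

    def test_matches_biopython_aligner(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner(
            mode="local", match_score=2, mismatch_score=-3,
            open_gap_score=-5, extend_gap_score=-2)
        for _ in range(10):
            a = _random_dna(rng, 200)
            b = _random_dna(rng, 200)
            assert sw_score(a, b) == aligner.score(a, b)


class TestAlignClassify:
    def test_best_species_wins(self, rng):
        seq = _random_dna(rng, 200)
        near = seq[:100] + _random_dna(rng, 100)
        far = _random_dna(rng, 200)
        res = align_classify(seq, [_rec(near, "spA"), _rec(far, "spB", "g2")],
                             0, query_id="q", true_species="spA")
        assert res.predicted_species == "spA"
        assert res.score >= 200.0

    def test_equidistant_ties_split_evenly(self, rng):
        """Two references symmetric around the query: ~50/50 over repeats."""
        base = _random_dna(rng, 50)
        qa, qb = list(base), list(base)
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        qa[10] = rot[qa[10]]
        qb[40] = rot[qb[40]]
        refs = [_rec("".join(qa), "spA"), _rec("".join(qb), "spB", "g2")]
        picks = [align_classify(base, refs, seed).predicted_species
                 for seed in range(1000)]
        n_a = picks.count("spA")
        assert abs(n_a - 500) < 3 * np.sqrt(1000 * 0.25)

    def test_single_species_rejected(self, rng):
        with pytest.raises(ValueError):
            align_classify("ACGT", [_rec(_random_dna(rng, 40), "spA")], 0)


class TestClassifyGenome:
    def test_best_copy_rule(self):
        r1 = ClassificationResult("g1:operon:0", "spA", "spA", "kmer", 4000)
        r2 = ClassificationResult("g1:operon:1", "spA", "spB", "kmer", 4500)
        assert classify_genome([r1, r2], 0).predicted_species == "spB"

    def test_single_copy_identity(self):
        r = ClassificationResult("g1:operon:0", "spA", "spA", "kmer", 10.0)
        out = classify_genome([r], 0, genome_id="g1")
        assert out.predicted_species == "spA"
        assert out.query_id == "g1"

    def test_composition_of_oracles(self, rng):
        """Genome call = best of per-copy brute-force calls, 50 random toys."""
        k = 5
        for _ in range(50):
            refs = [_rec(_random_dna(rng, 40), f"sp{j}", genome=f"g{j}")
                    for j in range(3)]
            idx = build_index(refs, k=k)
            copies = [_random_dna(rng, 30)
                      for _ in range(int(rng.integers(1, 4)))]
            copy_results = [kmer_classify(c, idx, 0, query_id=f"q:{i}",
                                          true_species="sp0")
                            for i, c in enumerate(copies)]
            genome_res = classify_genome(copy_results, 0, genome_id="g")
            oracle_scores = [max(brute_force_kmer_scores(c, refs, k).values(),
                                 default=0) for c in copies]
            assert genome_res.score == max(oracle_scores)

    def test_empty_copy_list(self):
        with pytest.raises(ValueError):
            classify_genome([], 0)
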