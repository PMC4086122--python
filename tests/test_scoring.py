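"""Block-HMM scoring checked against independent brute-force parse enumeration."""

import numpy as np
import pytest

from cisenrich.io import GenomeSequences, MotifMatrix
from cisenrich.scoring import (BackgroundModel, ScoredMotif, score_genome,
                               stubb_window_score, train_background,
                               window_likelihood_ratio)
from cisenrich.synth import revcomp
from cisenrich.windows import tile_windows

BASES = "ACGT"


def oracle_bg_probs(seq, bg):
    """Per-position background probability, independent of the DP code."""
    out = []
    for i, ch in enumerate(seq):
        if ch == "N":
            out.append(1.0)
            continue
        c = BASES.index(ch)
        ctx = seq[i - bg.order:i] if i >= bg.order else None
        if ctx is None or "N" in ctx:
            out.append(bg.marginal[c])
        else:
            ci = 0
            for x in ctx:
                ci = ci * 4 + BASES.index(x)
            out.append(bg.cond[ci, c])
    return out


def oracle_block_prob(block, theta):
    """Strand-averaged motif emission; 0 if the block overlaps an N."""
    if "N" in block:
        return 0.0
    fwd = np.prod([theta[j, BASES.index(b)] for j, b in enumerate(block)])
    rc = revcomp(block)
    rev = np.prod([theta[j, BASES.index(b)] for j, b in enumerate(rc)])
    return 0.5 * (fwd + rev)


def oracle_likelihood(seq, motif, bg, p):
    """Sum over every parse of seq into letters and W-blocks."""
    W = motif.width
    b = oracle_bg_probs(seq, bg)
    theta = motif.theta

    def parses(i):
        if i == len(seq):
            yield ()
            return
        for rest in parses(i + 1):
            yield (("L", i),) + rest
        if i + W <= len(seq):
            for rest in parses(i + W):
                yield (("B", i),) + rest

    total = 0.0
    for parse in parses(0):
        prob = 1.0
        for kind, i in parse:
            if kind == "L":
                prob *= (1 - p) * b[i]
            else:
                prob *= p * oracle_block_prob(seq[i:i + W], theta)
        total += prob
    return total


def random_motif(rng, width):
    counts = rng.integers(1, 20, size=(width, 4)).astype(float)
    return ScoredMotif.from_counts(MotifMatrix("m", counts))


def random_bg(rng, order=0):
    cond = rng.uniform(0.5, 2.0, size=(4 ** order, 4))
    cond /= cond.sum(axis=1, keepdims=True)
    marg = rng.uniform(0.5, 2.0, size=4)
    marg /= marg.sum()
    return BackgroundModel(order=order, cond=cond, marginal=marg)


class TestTrainBackground:
    def test_degenerate_composition(self):
        bg = train_background(GenomeSequences({"c": "A" * 1000}), order=0)
        assert bg.cond[0, 0] > 0.99
        assert bg.cond[0, 1:].min() > 0

    def test_uniform_genome_near_quarter(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(BASES), size=100_000))
        bg = train_background(GenomeSequences({"c": seq}), order=0)
        np.testing.assert_allclose(bg.cond[0], 0.25, atol=0.01)

    def test_smoothing_defines_all_contexts_on_tiny_input(self):
        bg = train_background(GenomeSequences({"c": "ACGTACGTACGT" * 4}),
                              order=2)
        assert bg.cond.shape == (16, 4)
        assert (bg.cond > 0).all()
        np.testing.assert_allclose(bg.cond.sum(axis=1), 1.0, atol=1e-12)

    def test_all_n_genome_rejected(self):
        with pytest.raises(ValueError):
            train_background(GenomeSequences({"c": "N" * 100}), order=0)


class TestDPAgainstEnumeration:
    def test_fixed_p_example(self, uniform_bg):
        rng = np.random.default_rng(5)
        motif = random_motif(rng, 2)
        seq = "ACGTAC"
        want = oracle_likelihood(seq, motif, uniform_bg, 0.3)
        null = np.prod(oracle_bg_probs(seq, uniform_bg))
        got = window_likelihood_ratio(seq, motif, uniform_bg, 0.3)
        assert got == pytest.approx(want / null, abs=1e-9)

    def test_many_random_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            order = int(rng.integers(0, 2))
            bg = random_bg(rng, order)
            W = int(rng.integers(1, 4))
            motif = random_motif(rng, W)
            n = int(rng.integers(1, 13))
            seq = "".join(rng.choice(list(BASES + "N"), size=n,
                                     p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            p = float(rng.uniform(0, 0.5))
            want = oracle_likelihood(seq, motif, bg, p)
            null = np.prod(oracle_bg_probs(seq, bg)) * 1.0
            got = window_likelihood_ratio(seq, motif, bg, p)
            assert got == pytest.approx(want / null, rel=1e-9, abs=1e-12)


class TestStubbWindowScore:
    def test_sequence_shorter_than_motif_scores_zero(self, uniform_bg,
                                                     strong_motif):
        assert stubb_window_score("ACG", strong_motif, uniform_bg) == 0.0

    def test_score_nonnegative_on_random_windows(self, uniform_bg):
        rng = np.random.default_rng(3)
        for _ in range(50):
            motif = random_motif(rng, int(rng.integers(1, 9)))
            seq = "".join(rng.choice(list(BASES), size=60))
            assert stubb_window_score(seq, motif, uniform_bg) >= 0.0

    def test_strand_symmetry(self, uniform_bg):
        rng = np.random.default_rng(9)
        for _ in range(50):
            motif = random_motif(rng, int(rng.integers(1, 7)))
            seq = "".join(rng.choice(list(BASES), size=40))
            s1 = stubb_window_score(seq, motif, uniform_bg)
            s2 = stubb_window_score(revcomp(seq), motif, uniform_bg)
            assert s1 == pytest.approx(s2, abs=1e-9)

    def test_consensus_site_beats_shuffled_site(self, uniform_bg,
                                                strong_motif):
        rng = np.random.default_rng(17)
        consensus = "ACGTAC"
        wins = 0
        for _ in range(100):
            flank = rng.choice(list(BASES), size=60)
            pos = int(rng.integers(0, 60 - 6))
            with_site = flank.copy()
            with_site[pos:pos + 6] = list(consensus)
            shuffled = with_site.copy()
            shuf = rng.permutation(list(consensus))
            shuffled[pos:pos + 6] = shuf
            shuffled_seq = "".join(shuffled)
            s_site = stubb_window_score("".join(with_site), strong_motif,
                                        uniform_bg)
            s_shuf = stubb_window_score(shuffled_seq, strong_motif,
                                        uniform_bg)
            # a shuffle can accidentally recreate a consensus site (e.g.
            # across the junction with the flank); only windows where it
            # did not must score strictly lower
            if consensus in shuffled_seq or revcomp(consensus) in shuffled_seq:
                wins += 1
            elif s_site > s_shuf:
                wins += 1
        assert wins == 100

    def test_score_nondecreasing_in_planted_site_count(self, uniform_bg,
                                                       strong_motif):
        rng = np.random.default_rng(23)
        consensus = "ACGTAC"
        for _ in range(100):
            flank = rng.choice(list(BASES), size=120)
            positions = rng.choice(range(0, 114, 8), size=3, replace=False)
            prev = stubb_window_score("".join(flank), strong_motif,
                                      uniform_bg)
            for k in range(3):
                flank[positions[k]:positions[k] + 6] = list(consensus)
                cur = stubb_window_score("".join(flank), strong_motif,
                                         uniform_bg)
                assert cur >= prev - 1e-9
                prev = cur

    def test_motif_wider_than_max_rejected(self, uniform_bg):
        rng = np.random.default_rng(1)
        motif = random_motif(rng, 31)
        with pytest.raises(ValueError, match="wider"):
            stubb_window_score("A" * 40, motif, uniform_bg)


class TestScoreGenome:
    def test_profile_length_and_locality(self, uniform_bg, strong_motif):
        rng = np.random.default_rng(31)
        seq = list(rng.choice(list(BASES), size=10_000))
        genome = GenomeSequences({"chr1": "".join(seq)})
        ws = tile_windows(genome.lengths)
        base = score_genome(genome, ws, strong_motif, uniform_bg)
        assert len(base) == 39
        # plant 3 consensus sites into the window [5000, 5500) interior
        for pos in (5010, 5100, 5200):
            seq[pos:pos + 6] = list("ACGTAC")
        edited = GenomeSequences({"chr1": "".join(seq)})
        prof = score_genome(edited, ws, strong_motif, uniform_bg)
        changed = np.nonzero(prof.values != base.values)[0]
        # only windows overlapping [5010, 5206) may change
        assert len(changed) > 0
        assert all(ws.starts[i] < 5206 and ws.ends[i] > 5010 for i in changed)
        target = np.nonzero((ws.starts <= 5000) & (ws.ends >= 5500))[0]
        assert (prof.values[target] > base.values[target]).all()

    def test_all_n_window_unscorable(self, uniform_bg, strong_motif):
        genome = GenomeSequences({"c1": "N" * 500 + "ACGT" * 125})
        ws = tile_windows(genome.lengths)
        prof = score_genome(genome, ws, strong_motif, uniform_bg)
        assert prof.values[0] == 0.0 and not prof.scorable[0]
        assert prof.scorable[2]

    def test_chromosome_order_invariance(self, uniform_bg, strong_motif,
                                         small_genome):
        ws = tile_windows(small_genome.lengths)
        p1 = score_genome(small_genome, ws, strong_motif, uniform_bg)
        flipped = GenomeSequences(dict(reversed(small_genome.sequences.items())))
        ws2 = tile_windows(flipped.lengths)
        p2 = score_genome(flipped, ws2, strong_motif, uniform_bg)
        # same windows, different processing order: values must match
        for i in range(len(ws)):
            j = np.nonzero((ws2.chroms == ws.chroms[i])
                           & (ws2.starts == ws.starts[i]))[0][0]
            assert p1.values[i] == p2.values[j]
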