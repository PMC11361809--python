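"""Spaced-seed indexing, HSP search, chaining, and mapping sensitivity."""

import random

import numpy as np
import pytest

from intronalign.mapping import (
    LEVELS,
    HSP,
    ReducedAlphabet,
    SeedIndex,
    SpacedSeed,
    chain_to_loci,
    find_hsps,
    map_query,
    reduce_sequence,
    ungapped_extend,
    verify_hsp,
)
from intronalign.scoring import encode_protein
from intronalign.synthetic import SimulationConfig, simulate_dataset

from conftest import as_genome, as_query, backtranslate


class TestReducedAlphabet:
    def test_same_group_residues_map_identically(self):
        alpha = ReducedAlphabet(10)
        r = reduce_sequence(as_query("LVIM"), alpha)
        assert len(set(r.tolist())) == 1

    def test_identity_alphabet_is_bijective(self):
        alpha = ReducedAlphabet(20)
        r = reduce_sequence(as_query("ARNDCQEGHILKMFPSTWYV"), alpha)
        assert len(set(r.tolist())) == 20

    def test_x_maps_to_wildcard_group(self):
        alpha = ReducedAlphabet(10)
        r = reduce_sequence(as_query("AXA"), alpha)
        assert r[1] == alpha.size and r[0] != r[1]

    def test_mapping_total_over_amino_acids(self):
        for size in (8, 10, 12):
            mp = ReducedAlphabet(size).mapping
            assert (mp[:20] >= 0).all()


class TestSpacedSeed:
    def test_weight_is_popcount(self):
        s = SpacedSeed("11011")
        assert s.weight == 4 and s.span == 5 and s.sampled == (0, 1, 3, 4)

    def test_pattern_must_flank_with_ones(self):
        with pytest.raises(ValueError):
            SpacedSeed("0110")

    def test_level3_uses_the_new_parameters(self):
        lp = LEVELS[3]
        assert lp.seed.pattern == "11011"
        assert lp.seed.weight == 4
        assert lp.alphabet.size == 10


class TestSeedIndex:
    def test_exact_backtranslation_keys_all_present(self):
        rng = random.Random(5)
        pep = "MKWLEDHVRS" * 3
        genome = backtranslate(pep, rng)
        seed, alpha = LEVELS[3].seed, LEVELS[3].alphabet
        idx = SeedIndex(as_genome(genome), seed, alpha, both_strands=False)
        red = reduce_sequence(as_query(pep), alpha)
        found = 0
        for i in range(len(pep) - seed.span + 1):
            k = idx.key_of(red, i)
            assert k is not None
            assert 3 * i in idx.strands["+"].get(k, []), i
            found += 1
        # analytic hit count on an exact, stop-free instance
        assert found == len(pep) - seed.span + 1

    def test_empty_genome_empty_index(self):
        idx = SeedIndex(as_genome("ACG"), LEVELS[3].seed, LEVELS[3].alphabet,
                        both_strands=False)
        assert sum(len(v) for v in idx.strands["+"].values()) == 0

    def test_stop_codons_break_keys(self):
        rng = random.Random(6)
        pep = "MKWLEDHVRS"
        cds = backtranslate(pep, rng)
        # splice a stop codon into the middle of the reading frame
        genome = cds[:15] + "TAA" + cds[18:]
        idx = SeedIndex(as_genome(genome), LEVELS[3].seed, LEVELS[3].alphabet,
                        both_strands=False)
        span = LEVELS[3].seed.span
        stop_codon_index = 5
        for t in range(stop_codon_index - span + 1, stop_codon_index + 1):
            if t < 0:
                continue
            red = reduce_sequence(as_query(pep), LEVELS[3].alphabet)
            k = idx.key_of(red, t)
            positions = idx.strands["+"].get(k, []) if k is not None else []
            assert 3 * t not in positions


class TestUngappedExtend:
    def _setup(self, pep, genome):
        from intronalign.scoring import default_params

        params = default_params()
        idx = SeedIndex(as_genome(genome), LEVELS[3].seed, LEVELS[3].alphabet,
                        both_strands=False)
        taa = idx.translation("+")
        q = encode_protein(pep)
        return q, taa, params.scheme.matrix.astype(np.int64)

    def test_perfect_match_spans_whole_overlap(self):
        rng = random.Random(7)
        pep = "MKWLEDHVRSMKWLEDHVRS"
        genome = backtranslate(pep, rng)
        q, taa, subm = self._setup(pep, genome)
        hsp = ungapped_extend(q, taa, subm, 8, 24, 5, 20)
        assert (hsp.q0, hsp.q1) == (0, len(pep))
        assert hsp.score == verify_hsp(hsp, q, taa, subm)
        assert hsp.score == sum(int(subm[q[i], q[i]]) for i in range(len(pep)))

    def test_extension_halts_at_stop_run(self):
        rng = random.Random(8)
        pep = "MKWLEDHVRS"
        genome = backtranslate(pep, rng) + "TAATAATAATAA" + \
            backtranslate("MKWL", rng)
        q, taa, subm = self._setup(pep, genome)
        hsp = ungapped_extend(q, taa, subm, 0, 0, 5, 20)
        assert hsp.q1 <= len(pep)  # never extends through the stop run
        assert hsp.g1 <= 3 * len(pep) + 3

    def test_zero_xdrop_is_maximal_run_without_dip(self):
        rng = random.Random(9)
        pep = "MKWLEDHVRS"
        genome = backtranslate(pep, rng)
        q, taa, subm = self._setup(pep, genome)
        hsp = ungapped_extend(q, taa, subm, 2, 6, 5, 0)
        # all identities are positive, so X=0 still spans everything
        assert (hsp.q0, hsp.q1) == (0, len(pep))


class TestFindHsps:
    def test_exact_substring_recovered_on_correct_diagonal(self, params_full):
        rng = random.Random(11)
        pep = "MKWLEDHVRSAGPTYCFNQI" * 3
        inner = backtranslate(pep, rng)
        genome = "".join(rng.choice("ACGT") for _ in range(600)) + inner + \
            "".join(rng.choice("ACGT") for _ in range(600))
        idx = SeedIndex(as_genome(genome), LEVELS[3].seed, LEVELS[3].alphabet)
        hsps = find_hsps(as_query(pep), idx, 3, params_full)
        target = [h for h in hsps if h.strand == "+" and
                  h.g0 - 3 * h.q0 == 600]
        assert target and max(h.q1 - h.q0 for h in target) >= len(pep) - 5

    def test_mismatch_at_dont_care_position_still_hits(self, params_full):
        rng = random.Random(12)
        pep = "MKWLEDHVRSAGPTYCFNQI"
        mutated = pep[:12] + "G" + pep[13:]  # position 12 = seed's 0 slot
        genome = backtranslate(pep, rng)
        idx = SeedIndex(as_genome(genome), LEVELS[3].seed, LEVELS[3].alphabet,
                        both_strands=False)
        red = reduce_sequence(as_query(mutated), LEVELS[3].alphabet)
        k = idx.key_of(red, 10)  # window 10..15 samples 10,11,13,14
        assert k is not None and 30 in idx.strands["+"][k]

    def test_random_genome_false_positive_control(self, params_full):
        hits = 0
        for seed in range(20):
            rng = random.Random(1000 + seed)
            pep = "".join(rng.choice("ARNDCQEGHILKMFPSTWYV") for _ in range(120))
            genome = "".join(rng.choice("ACGT") for _ in range(30000))
            idx = SeedIndex(as_genome(genome), LEVELS[1].seed,
                            LEVELS[1].alphabet)
            hsps = find_hsps(as_query(pep), idx, 1, params_full)
            strong = [h for h in hsps if h.score >= 60]
            hits += bool(strong)
        assert hits <= 2  # unrelated sequence rarely yields strong HSPs

    def test_every_hsp_score_reverifies(self, params_full):
        rng = random.Random(14)
        pep = "MKWLEDHVRSAGPTYCFNQI" * 2
        genome = backtranslate(pep, rng) + "".join(
            rng.choice("ACGT") for _ in range(2000))
        idx = SeedIndex(as_genome(genome), LEVELS[3].seed, LEVELS[3].alphabet)
        q = encode_protein(pep)
        subm = params_full.scheme.matrix.astype(np.int64)
        for h in find_hsps(as_query(pep), idx, 3, params_full):
            assert h.score == verify_hsp(h, q, idx.translation(h.strand), subm)


class TestChaining:
    def _hsp(self, q0, g0, length=10, strand="+", score=50):
        return HSP(q0, q0 + length, g0, g0 + 3 * length, strand, score)

    def test_colinear_pair_within_max_intron_one_locus(self):
        h1, h2 = self._hsp(0, 0), self._hsp(20, 1030)
        loci = chain_to_loci([h1, h2], max_intron=50000, margin=100)
        assert len(loci) == 1 and len(loci[0].hsps) == 2

    def test_opposite_strands_two_loci(self):
        h1, h2 = self._hsp(0, 0, strand="+"), self._hsp(0, 0, strand="-")
        loci = chain_to_loci([h1, h2], margin=10)
        assert {l.strand for l in loci} == {"+", "-"} and len(loci) == 2

    def test_anti_colinear_not_chained(self):
        h1, h2 = self._hsp(0, 2000), self._hsp(20, 100)
        loci = chain_to_loci([h1, h2], max_intron=50000, margin=50)
        assert all(len(l.hsps) == 1 for l in loci)

    def test_gap_beyond_max_intron_splits(self):
        h1, h2 = self._hsp(0, 0), self._hsp(20, 90000)
        loci = chain_to_loci([h1, h2], max_intron=50000, margin=50)
        assert all(len(l.hsps) == 1 for l in loci)

    def test_chains_are_colinear(self):
        rng = random.Random(15)
        hsps = [self._hsp(rng.randint(0, 300), rng.randint(0, 100000),
                          score=rng.randint(30, 80)) for _ in range(40)]
        for locus in chain_to_loci(hsps, margin=100):
            chain = locus.hsps
            for a, b in zip(chain, chain[1:]):
                assert a.g0 <= b.g0 and a.q0 <= b.q0


class TestEndToEndSensitivity:
    def test_simulated_genes_recovered_as_loci(self, params_full):
        cfg = SimulationConfig(gene_count=6, seed=99, target_pid=90,
                               intergenic_median=15000, min_intergenic=4000)
        ts = simulate_dataset(cfg)
        idx = SeedIndex(ts.genome, LEVELS[1].seed, LEVELS[1].alphabet)
        recovered = 0
        for g, q in zip(ts.genes, ts.queries):
            loci = map_query(q, ts.genome, params_full, index1=idx)
            s, e = g.span
            if any(l.w0 < e and s < l.w1 and l.strand == "+" for l in loci):
                recovered += 1
        assert recovered >= 5
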