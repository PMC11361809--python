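"""The spliced-alignment recurrence: worked examples, oracle equivalence,
banded variant, forward scan, and the score audit."""

import random

import pytest

from intronalign.dp import (
    ContractViolation,
    SegmentContext,
    align_banded,
    align_full,
    forward_scan,
)
from intronalign.scoring import (
    IntronPenaltyModel,
    SpeciesParams,
    default_params,
    substitution_score,
)
from intronalign.seqio import RunConfig

from conftest import (
    AA_ORDER,
    as_genome,
    as_query,
    make_gene_instance,
    oracle_score,
)


class TestTrivialPaths:
    def test_exact_back_translation_two_codons(self, params_const):
        sc, model = align_full(as_query("MK"), as_genome("ATGAAA"), params_const)
        s = substitution_score("M", "ATG", params_const.scheme) + \
            substitution_score("K", "AAA", params_const.scheme)
        assert sc == s
        assert model.exon_intervals == [(0, 6)]
        assert model.stats.matches == 2 and model.stats.gap_columns == 0

    def test_single_codon(self, params_const):
        sc, model = align_full(as_query("M"), as_genome("ATG"), params_const)
        assert sc == substitution_score("M", "ATG", params_const.scheme)
        assert model.exon_intervals == [(0, 3)]

    def test_contract_violations(self, params_const):
        with pytest.raises(ContractViolation):
            align_full(as_query("M"), as_genome("AT"), params_const)
        with pytest.raises(ContractViolation):
            align_full(as_query(""), as_genome("ATGATG"), params_const)

    def test_no_alignment_below_min_score(self, params_const):
        cfg = RunConfig(min_report_score=10_000)
        sc, model = align_full(as_query("MK"), as_genome("ATGAAA"),
                               params_const, cfg)
        assert model is None and sc < 10_000


class TestConstructedIntron:
    def test_phase0_intron_worked_example(self, zero_signal_params):
        # MKV against ATG | 40 nt GT..AG intron | AAA GTT, IP0 = 5
        interior = "GTAAGCCCCACCCCTCCCACCCCTACCCCTTCCCTT"
        seg = "ATG" + interior + "TTAG" + "AAAGTT"
        assert len(interior) + 4 == 40
        sc, model = align_full(as_query("MKV"), as_genome(seg), zero_signal_params)
        sch = zero_signal_params.scheme
        expect = (substitution_score("M", "ATG", sch)
                  + substitution_score("K", "AAA", sch)
                  + substitution_score("V", "GTT", sch) - 5)
        assert sc == expect
        assert model.exon_intervals == [(0, 3), (43, 49)]
        assert model.introns[0][:4] == (3, 43, "GT", "AG")

    @pytest.mark.parametrize("phase", [1, 2])
    def test_bridged_codon_phases(self, zero_signal_params, phase):
        # split the K codon AAA at the given phase
        before, after = "AAA"[:phase], "AAA"[phase:]
        interior = "CCCTCCCACCCCTACCCCTTCCCTTCCCACCTCC"[: 40 - 4 - 2]
        intron = "GT" + "C" * 36 + "AG"
        seg = "ATG" + before + intron + after + "GTT"
        sc, model = align_full(as_query("MKV"), as_genome(seg), zero_signal_params)
        sch = zero_signal_params.scheme
        expect = (substitution_score("M", "ATG", sch)
                  + substitution_score("K", "AAA", sch)
                  + substitution_score("V", "GTT", sch) - 5)
        assert sc == expect
        assert len(model.introns) == 1
        assert model.introns[0][5] == phase  # recorded codon phase


class TestOracleEquivalence:
    def test_random_small_instances_match_exhaustive_enumeration(self, tiny_params):
        rng = random.Random(7)
        n_checked = 0
        for _ in range(220):
            m = rng.randint(1, 8)
            n = rng.randint(3, 60)
            q = "".join(rng.choice(AA_ORDER) for _ in range(m))
            seg = "".join(rng.choice("ACGT") for _ in range(n))
            mode = rng.choice(["CONSTANT", "FULL", "COARSE"])
            params = SpeciesParams(
                tiny_params.scheme, tiny_params.splice,
                IntronPenaltyModel(mode=mode, min_length=8, ip0=3,
                                   alpha=0.0, beta=1.5, grain=16),
            )
            sc, _model = align_full(as_query(q), as_genome(seg), params)
            assert sc == oracle_score(q, seg, params), (q, seg, mode)
            n_checked += 1
        assert n_checked >= 200

    def test_gene_like_instances_match_oracle(self, params_const):
        rng = random.Random(13)
        for _ in range(25):
            prot, seg, _exons = make_gene_instance(rng, rng.randint(8, 16),
                                                   rng.randint(0, 2),
                                                   flank=10)
            sc, _m = align_full(as_query(prot), as_genome(seg), params_const)
            assert sc == oracle_score(prot, seg, params_const)


class TestScoreProperties:
    def test_increasing_ip0_never_increases_score(self):
        rng = random.Random(3)
        prot, seg, _ = make_gene_instance(rng, 40, 2)
        prev = None
        for ip0 in (0, 3, 8, 15, 30, 60):
            params = SpeciesParams(
                default_params().scheme, default_params().splice,
                IntronPenaltyModel(mode="CONSTANT", ip0=ip0),
            )
            sc, _m = align_full(as_query(prot), as_genome(seg), params)
            if prev is not None:
                assert sc <= prev
            prev = sc

    def test_constant_floor_dominates_full(self, params_full):
        # IP0 at the minimum observed FULL penalty can only help the score
        rng = random.Random(9)
        for trial in range(5):
            prot, seg, _ = make_gene_instance(rng, 30, 2)
            scf, mf = align_full(as_query(prot), as_genome(seg), params_full)
            min_pen = min((p for *_x, p, _ph in mf.introns), default=0)
            pc = SpeciesParams(
                params_full.scheme, params_full.splice,
                IntronPenaltyModel(mode="CONSTANT", ip0=min_pen),
            )
            scc, _ = align_full(as_query(prot), as_genome(seg), pc)
            assert scc >= scf

    def test_stop_codons_disfavored_not_forbidden(self, params_const):
        # a segment whose only in-frame path crosses a stop still aligns
        seg = "ATG" + "TAA" + "GTT"
        cfg = RunConfig(min_report_score=-(1 << 20))
        sc, model = align_full(as_query("MKV"), as_genome(seg), params_const, cfg)
        assert model is not None
        # the stop either costs the stop score (if matched) or forces a gap;
        # either way the result is far below the clean-gene score
        clean = (substitution_score("M", "ATG", params_const.scheme)
                 + substitution_score("K", "AAA", params_const.scheme)
                 + substitution_score("V", "GTT", params_const.scheme))
        assert sc < clean - 5

    def test_semi_global_flanks_are_free(self, params_const):
        rng = random.Random(21)
        prot, seg, _ = make_gene_instance(rng, 30, 1, flank=0)
        sc0, _ = align_full(as_query(prot), as_genome(seg), params_const)
        flank = "".join("C" for _ in range(100))  # low-similarity flank
        sc1, _ = align_full(as_query(prot), as_genome(flank + seg), params_const)
        assert sc1 == sc0

    def test_score_audit_exact_on_battery(self, params_full):
        rng = random.Random(31)
        for _ in range(10):
            prot, seg, _ = make_gene_instance(rng, rng.randint(20, 60),
                                              rng.randint(0, 3))
            sc, model = align_full(as_query(prot), as_genome(seg), params_full)
            ctx = SegmentContext.build(as_genome(seg), params_full)
            assert model.recompute_score(prot, ctx) == sc


class TestBanded:
    def test_gapless_instance_band_one_codon(self, params_const):
        rng = random.Random(17)
        prot, seg, _ = make_gene_instance(rng, 25, 0, flank=0)
        sc_full, m_full = align_full(as_query(prot), as_genome(seg), params_const)
        sc_band, m_band = align_banded(as_query(prot), as_genome(seg),
                                       params_const, band_width=1)
        assert sc_band == sc_full and m_band.exons == m_full.exons

    def test_intron_bypasses_narrow_band(self, zero_signal_params):
        # 40 nt intron, band of 4 codons (12 nt) < intron length
        intron = "GT" + "C" * 36 + "AG"
        seg = "ATGAAACCC" + intron + "GGGTTTGTT"
        sc_full, m_full = align_full(as_query("MKPGFV"), as_genome(seg),
                                     zero_signal_params)
        sc_band, m_band = align_banded(as_query("MKPGFV"), as_genome(seg),
                                       zero_signal_params, band_width=4)
        assert sc_band == sc_full
        assert m_band.exon_intervals == m_full.exon_intervals
        assert len(m_band.introns) == 1

    def test_degenerate_band_errors(self, params_const):
        with pytest.raises(ContractViolation):
            align_banded(as_query("MK"), as_genome("ATGAAA"), params_const,
                         band_width=0)


class TestForwardScan:
    def test_score_matches_full(self, params_full):
        rng = random.Random(23)
        for _ in range(5):
            prot, seg, _ = make_gene_instance(rng, rng.randint(15, 50),
                                              rng.randint(0, 2))
            sc_full, _m = align_full(as_query(prot), as_genome(seg), params_full)
            sc_scan, _end, _links = forward_scan(as_query(prot), as_genome(seg),
                                                 params_full)
            assert sc_scan == sc_full

    def test_single_intermediate_links_give_start_coordinate(self, params_const):
        rng = random.Random(29)
        prot, seg, exons = make_gene_instance(rng, 24, 0, flank=30)
        sc, model = align_full(as_query(prot), as_genome(seg), params_const)
        _sc, (m, j_end, layer), links = forward_scan(
            as_query(prot), as_genome(seg), params_const, links=1)
        # VL[1] stores the coordinate at which the alignment starts
        i_mid = links.intermediates[0]
        j_mid = model.moves[i_mid - 1][2]  # gapless: D move per row
        assert links.VL[0, 0, j_mid] == model.genome_start == exons[0][0]
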