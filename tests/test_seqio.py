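"""FASTA/GFF3 round trips, coordinate conventions, parameter files."""

import pytest
from hypothesis import given, settings, strategies as st

from intronalign.scoring import ScoringScheme
from intronalign.seqio import (
    AnnotatedGene,
    ParseError,
    RunConfig,
    SequenceRecord,
    load_species_params,
    read_fasta,
    read_gff3,
    save_species_params,
    write_fasta,
    write_gff3,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">q1\nMKV\n")
        recs = read_fasta(p)
        assert len(recs) == 1 and recs[0].id == "q1" and recs[0].length == 3

    def test_two_records_in_file_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">b\nMK\n>a\nVW\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["b", "a"]

    def test_lowercase_nucleotides_folded(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">g\nacgt\n")
        recs = read_fasta(p, alphabet="nucleotide")
        assert recs[0].residues == "ACGT"

    def test_out_of_alphabet_maps_to_wildcard(self):
        assert SequenceRecord("q", "M?K").residues == "MXK"
        assert SequenceRecord("g", "AC&T", alphabet="nucleotide").residues == "ACNT"

    def test_empty_sequence_is_an_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">q1\n\n>q2\nMK\n")
        with pytest.raises(ParseError):
            read_fasta(p)

    @given(seqs=st.lists(st.text(alphabet="ACGT", min_size=1, max_size=80),
                         min_size=1, max_size=5))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_is_bit_stable(self, seqs, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("fa")
        recs = [SequenceRecord(f"s{i}", s, alphabet="nucleotide")
                for i, s in enumerate(seqs)]
        p1, p2 = tmp / "x.fa", tmp / "y.fa"
        write_fasta(recs, p1)
        back = read_fasta(p1, alphabet="nucleotide")
        write_fasta(back, p2)
        assert p1.read_text() == p2.read_text()
        assert [(r.id, r.residues) for r in back] == \
            [(r.id, r.residues) for r in recs]


class TestGff3:
    def test_coordinate_convention_one_based_inclusive(self, tmp_path):
        g = AnnotatedGene("g1", "chr", "+", [(10, 70)])
        p = tmp_path / "a.gff3"
        write_gff3([g], p)
        cds = [l for l in p.read_text().splitlines() if "\tCDS\t" in l][0]
        fields = cds.split("\t")
        assert (fields[3], fields[4]) == ("11", "70")

    def test_phase_column_from_codon_phase(self, tmp_path):
        # second exon at codon phase 1 -> GFF3 phase (3-1)%3 = 2
        g = AnnotatedGene("g1", "chr", "+", [(0, 10), (100, 120)])
        assert g.phases == [0, 1]
        p = tmp_path / "a.gff3"
        write_gff3([g], p)
        cds = [l.split("\t") for l in p.read_text().splitlines()
               if "\tCDS\t" in l]
        assert cds[1][7] == "2"

    def test_write_read_round_trip(self, tmp_path):
        genes = [
            AnnotatedGene("g1", "chr", "+", [(5, 20), (50, 71), (100, 130)]),
            AnnotatedGene("g2", "chr", "-", [(200, 260), (300, 331)]),
        ]
        p = tmp_path / "a.gff3"
        write_gff3(genes, p)
        back = read_gff3(p)
        assert [(g.gene_id, g.strand, g.exons) for g in back] == \
            [(g.gene_id, g.strand, g.exons) for g in genes]
        # second cycle must be byte-identical
        p2 = tmp_path / "b.gff3"
        write_gff3(back, p2)
        assert p.read_text() == p2.read_text()

    def test_unrelated_feature_types_ignored(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr\tx\tmRNA\t1\t100\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr\tx\texon\t1\t50\t.\t+\t.\tParent=m1\n"
            "chr\tx\tfive_prime_UTR\t1\t9\t.\t+\t.\tParent=m1\n"
            "chr\tx\tCDS\t10\t60\t.\t+\t0\tParent=m1\n"
        )
        genes = read_gff3(p)
        assert len(genes) == 1 and genes[0].exons == [(9, 60)]

    def test_minus_strand_phases_from_rightmost_exon(self, tmp_path):
        # translation right-to-left: rightmost exon has phase 0, the 20 nt
        # exon leaves the next one at phase 20 % 3 == 2
        g = AnnotatedGene("g1", "chr", "-", [(0, 30), (100, 120)])
        assert g.phases == [0, 2]
        p = tmp_path / "a.gff3"
        write_gff3([g], p)
        back = read_gff3(p)[0]
        assert back.phases == [0, 2] and back.strand == "-"

    def test_cds_without_parent_errors(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("chr\tx\tCDS\t1\t30\t.\t+\t0\tID=orphan\n")
        with pytest.raises(ParseError):
            read_gff3(p)

    def test_overlapping_cds_errors(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "chr\tx\tCDS\t1\t30\t.\t+\t0\tParent=m1\n"
            "chr\tx\tCDS\t20\t60\t.\t+\t0\tParent=m1\n"
        )
        with pytest.raises((ParseError, ValueError)):
            read_gff3(p)

    def test_empty_exon_list_is_contract_violation(self):
        with pytest.raises(ValueError):
            AnnotatedGene("g", "chr", "+", [])

    def test_emitted_gff_validates(self, tmp_path):
        g = AnnotatedGene("g1", "chr", "+", [(3, 33), (70, 100), (140, 170)])
        p = tmp_path / "a.gff3"
        write_gff3([g], p)
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        seen_ids = set()
        for line in lines[1:]:
            f = line.split("\t")
            assert int(f[3]) <= int(f[4])
            if f[2] == "CDS":
                assert f[7] in {"0", "1", "2"}
            attrs = dict(kv.split("=") for kv in f[8].split(";"))
            if "Parent" in attrs:
                assert attrs["Parent"] in seen_ids  # parents precede children
            if "ID" in attrs:
                seen_ids.add(attrs["ID"])


class TestSpeciesParams:
    def test_empty_file_gives_documented_defaults(self, tmp_path):
        p = tmp_path / "empty.par"
        p.write_text("")
        sp = load_species_params(p)
        assert sp.scheme.gap_open == 8 and sp.scheme.gap_extend == 2
        assert sp.intron.mode == "FULL" and sp.intron.min_length == 30
        assert sp.splice.donor_scores["GT"] == 0

    def test_constant_mode_from_file(self, tmp_path):
        p = tmp_path / "c.par"
        p.write_text("[intron]\nmode = constant\nip0 = 33\n")
        sp = load_species_params(p)
        assert sp.intron.mode == "CONSTANT" and sp.intron.ip0 == 33

    def test_invalid_value_errors(self, tmp_path):
        p = tmp_path / "c.par"
        p.write_text("[gaps]\nopen = banana\n")
        with pytest.raises(ParseError):
            load_species_params(p)

    def test_unknown_key_warns_but_loads(self, tmp_path, caplog):
        p = tmp_path / "c.par"
        p.write_text("[gaps]\nfancy = 1\n")
        with caplog.at_level("WARNING", logger="intronalign"):
            sp = load_species_params(p)
        assert sp.scheme.gap_open == 8
        assert any("unknown key" in r.message for r in caplog.records)

    def test_asymmetric_matrix_rejected(self):
        m = ScoringScheme().matrix[:, :21].copy()
        m[2, 3] = 99
        with pytest.raises(ValueError):
            ScoringScheme(matrix=m)

    def test_save_load_round_trip(self, tmp_path):
        from intronalign.scoring import default_params

        sp = default_params("COARSE")
        p = tmp_path / "s.par"
        save_species_params(sp, p)
        back = load_species_params(p)
        assert back.intron.mode == "COARSE"
        assert back.scheme.gap_open == sp.scheme.gap_open
        assert back.splice.donor_scores == sp.splice.donor_scores


class TestRunConfig:
    def test_defaults_valid(self):
        RunConfig()

    def test_invalid_vmax(self):
        with pytest.raises(ValueError):
            RunConfig(v_max=0)

    def test_banded_needs_positive_band(self):
        with pytest.raises(ValueError):
            RunConfig(algorithm="banded", band_width=0)
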