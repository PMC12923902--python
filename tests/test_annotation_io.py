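"""Input layer: sequence extraction, molecular weights, kcat policy, readers."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcforge.annotation_io import (
    AA_RESIDUE_MASS,
    GeneRecord,
    InputError,
    KcatEntry,
    NMP_MASS,
    WATER_MASS,
    apply_kcat_policy,
    extract_gene_sequence,
    peptide_mw,
    read_annotation_tsv,
    read_complex_tsv,
    read_kcat_tsv,
    reverse_complement,
    rna_mw,
)


def _rec(start, end, strand, ftype="tRNA"):
    return GeneRecord(locus_tag="g", feature_type=ftype, start=start,
                      end=end, strand=strand)


class TestExtractGeneSequence:
    def test_plus_strand_is_identity_slice(self):
        assert extract_gene_sequence("ATGAAATAG", _rec(1, 9, "+")) == "ATGAAATAG"

    def test_minus_strand_is_reverse_complement(self):
        assert extract_gene_sequence("ATGAAATAG", _rec(1, 3, "-")) == "CAT"

    def test_out_of_range_is_fatal(self):
        with pytest.raises(InputError):
            extract_gene_sequence("ATG", _rec(1, 9, "+"))

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_length_matches_naive_loop_oracle(self, data):
        genome = data.draw(st.text(alphabet="ACGT", min_size=60, max_size=60))
        start = data.draw(st.integers(1, 60))
        end = data.draw(st.integers(start, 60))
        strand = data.draw(st.sampled_from("+-"))
        seq = extract_gene_sequence(genome, _rec(start, end, strand))
        # naive character-loop oracle
        naive = "".join(genome[i - 1] for i in range(start, end + 1))
        if strand == "-":
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            naive = "".join(comp[c] for c in reversed(naive))
        assert seq == naive
        assert len(seq) == end - start + 1

    @given(st.text(alphabet="ACGT", max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_double_reverse_complement_is_identity(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestMolecularWeights:
    def test_free_glycine(self):
        assert peptide_mw("G") == pytest.approx(75.07, abs=0.005)

    def test_diglycine(self):
        assert peptide_mw("GG") == pytest.approx(132.12, abs=0.005)

    def test_empty_peptide_is_fatal(self):
        with pytest.raises(InputError):
            peptide_mw("")

    def test_unknown_residue_is_fatal(self):
        with pytest.raises(InputError):
            peptide_mw("GXZ")

    def test_single_nucleotide_is_one_nmp(self):
        assert rna_mw("A") == pytest.approx(NMP_MASS["A"])

    def test_t_read_as_u(self):
        assert rna_mw("T") == pytest.approx(NMP_MASS["U"])

    @given(st.text(alphabet="ACGU", min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composition_only_and_monotone(self, seq):
        # permutation invariance
        assert rna_mw(seq) == pytest.approx(rna_mw(seq[::-1]))
        # strict monotonicity in length
        assert rna_mw(seq + "A") > rna_mw(seq)
        # closed form against the residue table
        expected = sum(NMP_MASS[c] for c in seq) - (len(seq) - 1) * WATER_MASS
        assert rna_mw(seq) == pytest.approx(expected)

    @given(st.text(alphabet="".join(AA_RESIDUE_MASS), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_peptide_mw_composition_only_and_monotone(self, seq):
        assert peptide_mw(seq) == pytest.approx(peptide_mw(seq[::-1]))
        assert peptide_mw(seq + "G") > peptide_mw(seq)


class TestKcatPolicy:
    def test_missing_enzyme_gets_median_default(self):
        out = apply_kcat_policy([], ["e1"])
        assert out["e1"] == 5.0

    def test_low_kcat_raised_to_floor(self):
        out = apply_kcat_policy([KcatEntry("r", "e1", 0.5)], ["e1"])
        assert out["e1"] == 0.75

    def test_keep_raw_exempts_curated_slow_enzymes(self):
        # the CO dehydrogenase case: genuinely slow, kept at 0.002/s
        out = apply_kcat_policy(
            [KcatEntry("r", "codh", 0.002, keep_raw=True)], ["codh"])
        assert out["codh"] == 0.002

    def test_nonpositive_rejected_with_warning(self):
        with pytest.warns(UserWarning):
            out = apply_kcat_policy([KcatEntry("r", "e1", -1.0)], ["e1"])
        assert out["e1"] == 5.0  # treated as absent

    def test_idempotent_and_floor_respected(self):
        raw = [KcatEntry("r", "e1", 0.3), KcatEntry("r", "e2", 7.0)]
        once = apply_kcat_policy(raw, ["e1", "e2", "e3"])
        twice = apply_kcat_policy(
            [KcatEntry("r", k, v) for k, v in once.items()],
            ["e1", "e2", "e3"])
        assert once == twice
        assert all(v >= 0.75 for v in once.values())


class TestReaders:
    def test_annotation_round_trip(self, bundle, bundle_dir):
        records = read_annotation_tsv(bundle_dir / "toy_annotation.tsv")
        by_tag = {r.locus_tag: r for r in records}
        for orig in bundle.records:
            rec = by_tag[orig.locus_tag]
            assert rec.feature_type == orig.feature_type
            assert rec.nucleotide_seq == orig.nucleotide_seq
            assert rec.peptide_seq == orig.peptide_seq
            assert rec.aa_class == orig.aa_class

    def test_kcat_and_complex_tables(self, bundle, bundle_dir):
        entries = read_kcat_tsv(bundle_dir / "toy_kcats.tsv")
        assert {e.enzyme_id: e.kcat for e in entries} == \
            {e.enzyme_id: e.kcat for e in bundle.kcat_entries}
        assert all(e.keep_raw for e in entries)
        cdefs = read_complex_tsv(bundle_dir / "toy_complexes.tsv")
        assert cdefs[0].complex_id == "CPLX_upt"
        assert sorted(cdefs[0].subunits) == [("uptA", 2), ("uptB", 1)]

    def test_complex_mw_is_copy_weighted_sum(self, bundle):
        cdef = bundle.complex_defs[0]
        mws = {"uptA": 100.0, "uptB": 50.0}
        assert cdef.compute_mw(mws) == pytest.approx(250.0)


class TestGffReader:
    def test_gff3_plus_fasta(self, tmp_path):
        from pcforge.annotation_io import read_annotation_gff
        (tmp_path / "g.fa").write_text(">chr1\nATGAAATAGGGGCCCCAT\n")
        (tmp_path / "g.gff").write_text(
            "##gff-version 3\n"
            "chr1\t.\tCDS\t1\t9\t.\t+\t0\tID=c1;locus_tag=geneA\n"
            "chr1\t.\ttRNA\t10\t14\t.\t-\t.\tlocus_tag=trn1\n"
            "chr1\t.\tregion\t1\t18\t.\t+\t.\tID=skipme\n")
        records = read_annotation_gff(tmp_path / "g.gff", tmp_path / "g.fa")
        by_tag = {r.locus_tag: r for r in records}
        assert set(by_tag) == {"geneA", "trn1"}
        assert by_tag["geneA"].nucleotide_seq == "ATGAAATAG"
        assert by_tag["geneA"].peptide_seq == "MK"  # stop stripped
        assert by_tag["trn1"].nucleotide_seq == "GGCCC"  # revcomp of GGGCC


class TestGeneRecordInvariants:
    def test_peptide_required_iff_cds(self):
        with pytest.raises(InputError):
            GeneRecord("g", "CDS", 1, 3, "+", "ATG", peptide_seq="")
        with pytest.raises(InputError):
            GeneRecord("g", "tRNA", 1, 3, "+", "ATG", peptide_seq="M")

    def test_coordinate_order(self):
        with pytest.raises(InputError):
            GeneRecord("g", "tRNA", 5, 3, "+")
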