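import numpy as np
import pytest

from dhewscan.alignment_io import (
    Alignment,
    AlignmentError,
    EmptyAlignmentError,
    extract_cds,
    filter_missing,
    read_fasta_alignment,
    subsample_lines,
    write_fasta_alignment,
)

from conftest import make_alignment


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestReadFasta:
    def test_round_trip_preserves_order_and_sequences(self, tmp_path):
        p = _write(tmp_path / "g.fasta", ">b\nACGTAC\n>a\nacgtan\n")
        aln = read_fasta_alignment(p)
        assert aln.sample_ids == ["b", "a"]
        assert aln.sequences == ["ACGTAC", "ACGTAN"]  # uppercased
        out = tmp_path / "out.fasta"
        write_fasta_alignment(aln, out)
        assert read_fasta_alignment(str(out)).sequences == aln.sequences

    def test_unknown_characters_become_n(self, tmp_path):
        p = _write(tmp_path / "g.fasta", ">x\nAC?RYT\n")
        assert read_fasta_alignment(p).sequences == ["ACNNNT"]

    def test_unequal_lengths_error(self, tmp_path):
        p = _write(tmp_path / "g.fasta", ">a\nACGTAC\n>b\nACGTA\n")
        with pytest.raises(AlignmentError):
            read_fasta_alignment(p)

    def test_empty_file_error(self, tmp_path):
        p = _write(tmp_path / "g.fasta", "")
        with pytest.raises(AlignmentError):
            read_fasta_alignment(p)

    def test_crlf_and_wrapped_lines(self, tmp_path):
        p = _write(tmp_path / "g.fasta", ">a\r\nACG\r\nTAC\r\n>b\r\nACGTAC\r\n")
        aln = read_fasta_alignment(p)
        assert aln.sequences == ["ACGTAC", "ACGTAC"]

    def test_outgroup_routing(self, tmp_path):
        p = _write(tmp_path / "g.fasta", ">s1\nACGTAC\n>outgroup\nACGTAT\n")
        aln = read_fasta_alignment(p, outgroup_ids=["outgroup"])
        assert aln.sample_ids == ["s1"]
        assert "outgroup" in aln.outgroups

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(AlignmentError):
            make_alignment(["ACG", "ACG"], ids=["a", "a"])


class TestFilterMissing:
    def test_drops_sequences_above_threshold(self):
        # 20 sites; second sequence has 3 N (15%) -> dropped at 10%
        good = "ACGT" * 5
        bad = "NNNT" + "ACGT" * 4
        aln = filter_missing(make_alignment([good, good, bad]))
        assert aln.n_samples == 2

    def test_no_missing_is_identity(self, toy_alignment):
        out = filter_missing(toy_alignment)
        assert out.n_samples == toy_alignment.n_samples
        assert not out.excluded_columns.any()

    def test_all_missing_error(self):
        with pytest.raises(EmptyAlignmentError):
            filter_missing(make_alignment(["N" * 12, "N" * 12]))

    def test_residual_missing_columns_flagged(self):
        # one N in a retained sequence (5% of 20 sites) flags that column
        s1 = "ACGT" * 5
        s2 = "NCGT" + "ACGT" * 4
        out = filter_missing(make_alignment([s1, s2]))
        assert out.n_samples == 2
        assert out.excluded_columns[0] and out.excluded_columns.sum() == 1

    def test_gaps_count_as_missing(self):
        s1 = "ACGT" * 5
        s2 = "-CGT" + "ACGT" * 4
        out = filter_missing(make_alignment([s1, s2]))
        assert out.excluded_columns[0]

    def test_idempotent(self, rng):
        bases = np.array(list("ACGTN"))
        seqs = ["".join(rng.choice(bases, size=30, p=[0.23, 0.23, 0.23, 0.23, 0.08])) for _ in range(12)]
        try:
            once = filter_missing(make_alignment(seqs))
        except EmptyAlignmentError:
            pytest.skip("degenerate draw")
        twice = filter_missing(once)
        assert twice.sample_ids == once.sample_ids
        assert np.array_equal(twice.excluded_columns, once.excluded_columns)


class TestSubsample:
    def test_identity_when_k_equals_n(self, toy_alignment):
        out = subsample_lines(toy_alignment, 4, seed=1)
        assert out.sample_ids == toy_alignment.sample_ids

    def test_deterministic(self):
        aln = make_alignment(["ACGTAC"] * 20)
        a = subsample_lines(aln, 14, seed=7)
        b = subsample_lines(aln, 14, seed=7)
        assert a.sample_ids == b.sample_ids

    def test_seeds_differ(self):
        aln = make_alignment(["ACGTAC"] * 60)
        picks = {tuple(subsample_lines(aln, 5, seed=s).sample_ids) for s in range(10)}
        assert len(picks) > 1

    def test_too_large_k_error(self, toy_alignment):
        with pytest.raises(ValueError):
            subsample_lines(toy_alignment, 5, seed=0)

    def test_outgroups_untouched(self):
        aln = make_alignment(["ACG"] * 6, outgroups={"out": "ACT"})
        out = subsample_lines(aln, 3, seed=0)
        assert list(out.outgroups) == ["out"]


# ---------------------------------------------------------------------------
# CDS extraction from a 3-gene toy genome/GFF3
# ---------------------------------------------------------------------------

CHR1 = "ACGT" * 30  # 120 bp


@pytest.fixture
def toy_annotation(tmp_path):
    genome = tmp_path / "genome.fasta"
    genome.write_text(">chr1\n" + CHR1 + "\n")
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        # geneA: two isoforms, 12 nt and 15 nt CDS -> longest wins
        "chr1\t.\tgene\t10\t30\t.\t+\t.\tID=geneA\n"
        "chr1\t.\tmRNA\t10\t30\t.\t+\t.\tID=mA1;Parent=geneA\n"
        "chr1\t.\tCDS\t10\t21\t.\t+\t0\tID=cA1;Parent=mA1\n"
        "chr1\t.\tmRNA\t10\t30\t.\t+\t.\tID=mA2;Parent=geneA\n"
        "chr1\t.\tCDS\t10\t24\t.\t+\t0\tID=cA2;Parent=mA2\n"
        # geneB: minus strand single exon
        "chr1\t.\tgene\t30\t38\t.\t-\t.\tID=geneB\n"
        "chr1\t.\tmRNA\t30\t38\t.\t-\t.\tID=mB1;Parent=geneB\n"
        "chr1\t.\tCDS\t30\t38\t.\t-\t0\tID=cB1;Parent=mB1\n"
        # geneC: two-exon plus strand
        "chr1\t.\tgene\t50\t65\t.\t+\t.\tID=geneC\n"
        "chr1\t.\tmRNA\t50\t65\t.\t+\t.\tID=mC1;Parent=geneC\n"
        "chr1\t.\tCDS\t50\t55\t.\t+\t0\tID=cC1;Parent=mC1\n"
        "chr1\t.\tCDS\t60\t65\t.\t+\t0\tID=cC2;Parent=mC1\n"
        # geneD: tie on CDS length, mD1 < mD2 lexicographically
        "chr1\t.\tgene\t70\t90\t.\t+\t.\tID=geneD\n"
        "chr1\t.\tmRNA\t70\t90\t.\t+\t.\tID=mD2;Parent=geneD\n"
        "chr1\t.\tCDS\t73\t84\t.\t+\t0\tID=cD2;Parent=mD2\n"
        "chr1\t.\tmRNA\t70\t90\t.\t+\t.\tID=mD1;Parent=geneD\n"
        "chr1\t.\tCDS\t70\t81\t.\t+\t0\tID=cD1;Parent=mD1\n"
        # geneE: CDS length 11, frame violation
        "chr1\t.\tgene\t95\t105\t.\t+\t.\tID=geneE\n"
        "chr1\t.\tmRNA\t95\t105\t.\t+\t.\tID=mE1;Parent=geneE\n"
        "chr1\t.\tCDS\t95\t105\t.\t+\t0\tID=cE1;Parent=mE1\n"
    )
    return str(genome), str(gff)


def _revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


class TestExtractCds:
    def test_longest_isoform_chosen(self, toy_annotation):
        genome, gff = toy_annotation
        assert extract_cds(genome, gff, "geneA") == CHR1[9:24]

    def test_minus_strand_reverse_complement(self, toy_annotation):
        genome, gff = toy_annotation
        assert extract_cds(genome, gff, "geneB") == _revcomp(CHR1[29:38])

    def test_two_exon_concatenation(self, toy_annotation):
        genome, gff = toy_annotation
        assert extract_cds(genome, gff, "geneC") == CHR1[49:55] + CHR1[59:65]

    def test_tie_breaks_to_smallest_transcript_id(self, toy_annotation):
        genome, gff = toy_annotation
        assert extract_cds(genome, gff, "geneD") == CHR1[69:81]  # mD1

    def test_missing_gene_raises(self, toy_annotation):
        genome, gff = toy_annotation
        with pytest.raises(KeyError):
            extract_cds(genome, gff, "nope")

    def test_frame_violation_warns(self, toy_annotation):
        genome, gff = toy_annotation
        with pytest.warns(UserWarning, match="not divisible by 3"):
            seq = extract_cds(genome, gff, "geneE")
        assert len(seq) == 11
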