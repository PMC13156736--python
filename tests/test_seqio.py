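import logging
import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gapmerdesign.candgen import GapmerCandidate
from gapmerdesign.seqio import (DataError, OrthologSet, SnpRecord, TargetGene,
                                read_fasta, read_snps, write_fasta,
                                write_report)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=80)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_record(self, tmp_path):
        assert read_fasta(write(tmp_path, "a.fa", ">g1\nACGT\n")) == [("g1", "ACGT")]

    def test_multiline_and_header_token(self, tmp_path):
        path = write(tmp_path, "a.fa", ">a x\nAC\nGT\n>b\nTTTT\n")
        assert read_fasta(path) == [("a", "ACGT"), ("b", "TTTT")]

    def test_lowercase_uppercased(self, tmp_path):
        assert read_fasta(write(tmp_path, "a.fa", ">g\nacgtn\n")) == [("g", "ACGTN")]

    def test_illegal_character_located(self, tmp_path):
        with pytest.raises(DataError, match=r"g1.*position 3"):
            read_fasta(write(tmp_path, "a.fa", ">g1\nACXT\n"))

    def test_empty_file(self, tmp_path):
        with pytest.raises(DataError, match="no records"):
            read_fasta(write(tmp_path, "a.fa", ""))

    @given(st.lists(st.tuples(st.from_regex(r"[A-Za-z0-9_]{1,10}", fullmatch=True), DNA),
                    min_size=1, max_size=5, unique_by=lambda t: t[0]))
    def test_round_trip(self, records):
        import tempfile, os
        fd, path = tempfile.mkstemp(suffix=".fa")
        os.close(fd)
        try:
            write_fasta(records, path)
            assert read_fasta(path) == records
        finally:
            os.unlink(path)


class TestTargetGene:
    def test_rejects_bad_alphabet(self):
        with pytest.raises(DataError):
            TargetGene("g", "ACGU")

    def test_exons_must_be_sorted_disjoint_in_range(self):
        TargetGene("g", "A" * 50, exons=[(0, 10), (20, 30)])  # valid
        with pytest.raises(DataError):
            TargetGene("g", "A" * 50, exons=[(0, 10), (5, 30)])
        with pytest.raises(DataError):
            TargetGene("g", "A" * 50, exons=[(40, 60)])


class TestReadSnps:
    def test_vcf_one_based_conversion(self, tmp_path):
        gene = TargetGene("g1", "A" * 40)
        path = write(tmp_path, "s.vcf", "g1\t21\trs1\tA\tG\n")
        (snp,) = read_snps(path, gene)
        assert snp == SnpRecord(pos=20, ref="A", alt="G", rsid="rs1")

    def test_out_of_range_dropped(self, tmp_path, caplog):
        gene = TargetGene("g1", "A" * 40)
        path = write(tmp_path, "s.tsv", "41\tA\tG\n")
        with caplog.at_level(logging.INFO):
            assert read_snps(path, gene) == []
        assert "dropped 1" in caplog.text

    def test_empty_file_means_snp_free(self, tmp_path):
        gene = TargetGene("g1", "A" * 40)
        assert read_snps(write(tmp_path, "s.vcf", ""), gene) == []

    def test_ref_mismatch_warns_not_errors(self, tmp_path, caplog):
        gene = TargetGene("g1", "A" * 40)
        path = write(tmp_path, "s.tsv", "5\tC\tG\n")
        with caplog.at_level(logging.WARNING):
            (snp,) = read_snps(path, gene)
        assert snp.pos == 4
        assert "does not match" in caplog.text

    def test_unparseable_line_names_line_number(self, tmp_path):
        gene = TargetGene("g1", "A" * 40)
        path = write(tmp_path, "s.tsv", "5\tA\tG\nabc\tX\tY\n")
        with pytest.raises(DataError, match=":2:"):
            read_snps(path, gene)

    def test_other_chromosome_dropped(self, tmp_path):
        gene = TargetGene("g1", "A" * 40)
        path = write(tmp_path, "s.vcf", "g2\t5\trs9\tA\tG\ng1\t6\trs8\tA\tC\n")
        (snp,) = read_snps(path, gene)
        assert snp.rsid == "rs8"


def _row(**overrides):
    site = "TGTGGACAATAAGGCTATCA"
    base = dict(gene_id="g1", start=9, window=20, target_site=site,
                aso_sequence="TGATAGCCTTATTGTCCACA", gc=0.4)
    cand = GapmerCandidate(**base)
    cand.mfe = -1.2345
    cand.rnaseh1_score = 0.12345
    cand.offtarget_counts = {0: 0, 1: 0, 2: 0, 3: 1, 4: 7}
    cand.homology = overrides.pop("homology", {})
    cand.tier = "neutral"
    cand.rank = 1
    for k, v in overrides.items():
        setattr(cand, k, v)
    return cand


class TestWriteReport:
    SPECIES = ("monkey", "mouse")

    def test_zero_rows_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report([], path, species=self.SPECIES)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t") == [
            "position", "target_site", "aso_sequence", "gc", "mfe",
            "rnaseh1_score", "offtargets_mm0", "offtargets_mm1",
            "offtargets_mm2", "offtargets_mm3", "offtargets_mm4",
            "homology_monkey", "homology_mouse", "tier", "rank"]

    def test_missing_orthologs_are_na(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_report([_row()], path, species=self.SPECIES)
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        assert frame.loc[0, "homology_monkey"] == "NA"
        assert frame.loc[0, "homology_mouse"] == "NA"

    def test_round_trip_to_printed_precision(self, tmp_path):
        row = _row(homology={"monkey": 0.98765, "mouse": 1.0})
        path = tmp_path / "r.tsv"
        write_report([row], path, species=self.SPECIES)
        frame = pd.read_csv(path, sep="\t")
        rec = frame.iloc[0]
        assert rec["position"] == row.start + 1
        assert rec["target_site"] == row.target_site
        for col, val in [("gc", row.gc), ("mfe", row.mfe),
                         ("rnaseh1_score", row.rnaseh1_score),
                         ("homology_monkey", 0.98765), ("homology_mouse", 1.0)]:
            assert math.isclose(rec[col], round(val, 4), abs_tol=5e-5)
        assert rec["offtargets_mm4"] == 7

    def test_rows_must_share_one_gene(self, tmp_path):
        other = _row()
        other.gene_id = "g2"
        with pytest.raises(DataError, match="multiple genes"):
            write_report([_row(), other], tmp_path / "r.tsv", species=self.SPECIES)

    def test_json_same_records(self, tmp_path):
        path = tmp_path / "r.json"
        write_report([_row()], path, fmt="json", species=self.SPECIES)
        frame = pd.read_json(path)
        assert list(frame["position"]) == [10]
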