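"""Cassette finding and barcode extraction: exact construction, strand
symmetry, fuzzy-anchor oracle, insert round-trips, and file parsing."""
import edlib
import numpy as np
import pytest

import gseseq as g
import gseseq.readparse as rp
from gseseq._util import revcomp, write_fastq
from tests.conftest import random_seq

SPEC = g.BarcodeSpec()
BC = "ACGTACGTACGTACGTACG"  # 19-mer


def make_read(barcode=BC, insert=None, spec=SPEC):
    insert = insert if insert is not None else random_seq(400, 5)
    return spec.anchor5 + barcode + spec.anchor3 + insert, insert


def sliding_anchor_oracle(anchor: str, read: str) -> int:
    """Brute-force best semi-global placement: min Levenshtein of the anchor
    against every read substring of length len(anchor) +/- 3."""
    best = len(anchor)
    for i in range(len(read)):
        for j in range(i + max(1, len(anchor) - 3), min(len(read), i + len(anchor) + 3) + 1):
            d = edlib.align(anchor, read[i:j], mode="NW")["editDistance"]
            best = min(best, d)
    return best


class TestFindCassette:
    def test_exact_construction_plus_strand(self):
        read, _ = make_read()
        call = g.find_cassette(read, SPEC)
        assert call.status == "ok"
        assert call.barcode == BC
        assert call.strand == "+"
        assert call.anchor5_edits == 0 and call.anchor3_edits == 0

    def test_reverse_complement_same_barcode(self):
        read, _ = make_read()
        call = g.find_cassette(revcomp(read), SPEC)
        assert call.status == "ok"
        assert call.barcode == BC
        assert call.strand == "-"

    def test_single_substitution_in_anchor(self):
        mut5 = "G" + SPEC.anchor5[1:] if SPEC.anchor5[0] != "G" else "A" + SPEC.anchor5[1:]
        read = mut5 + BC + SPEC.anchor3 + random_seq(300, 6)
        call = g.find_cassette(read, SPEC, max_anchor_edits=2)
        assert call.status == "ok"
        assert call.anchor5_edits == 1
        assert call.anchor5_edits == sliding_anchor_oracle(SPEC.anchor5, read)
        assert call.barcode == BC

    def test_fuzzy_edits_match_sliding_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            read, _ = make_read(insert=random_seq(200, 100 + trial))
            # corrupt one interior base of anchor5; a substitution at the
            # anchor/barcode boundary can legitimately tie two placements
            # that shift the barcode frame, which reports as ambiguous
            pos = int(rng.integers(0, len(SPEC.anchor5) - 3))
            orig = read[pos]
            sub = "ACGT"[("ACGT".index(orig) + 1) % 4]
            mutated = read[:pos] + sub + read[pos + 1 :]
            call = g.find_cassette(mutated, SPEC, max_anchor_edits=2)
            assert call.status == "ok"
            assert call.anchor5_edits == sliding_anchor_oracle(SPEC.anchor5, mutated)

    def test_too_short_read_is_no_anchor(self):
        call = g.find_cassette("ACGT", SPEC)
        assert call.status == "no_anchor"

    def test_wrong_gap_is_length_fail(self):
        read = SPEC.anchor5 + BC[:10] + SPEC.anchor3 + random_seq(200, 7)
        call = g.find_cassette(read, SPEC, indel_slack=1)
        assert call.status in ("length_fail", "no_anchor")

    def test_orientation_invariance_on_simulated_reads(self, zero_noise_run):
        for rid, seq, _ in zero_noise_run["sim"].reads[:50]:
            c1 = g.find_cassette(seq, SPEC)
            c2 = g.find_cassette(revcomp(seq), SPEC)
            assert c1.barcode == c2.barcode
            assert {c1.strand, c2.strand} == {"+", "-"}


class TestExtractInsert:
    def test_round_trip_exact(self):
        read, insert = make_read()
        call = g.find_cassette(read, SPEC)
        got, short = g.extract_insert(read, call)
        assert got == insert and not short

    def test_minus_strand_round_trip(self):
        read, insert = make_read()
        call = g.find_cassette(revcomp(read), SPEC)
        got, short = g.extract_insert(revcomp(read), call)
        assert got == insert

    def test_short_insert_flagged(self):
        read, insert = make_read(insert=random_seq(50, 9))
        call = g.find_cassette(read, SPEC)
        got, short = g.extract_insert(read, call, min_insert=100)
        assert short and got == insert

    def test_requires_ok_call(self):
        call = g.find_cassette("ACGT", SPEC)
        with pytest.raises(ValueError):
            g.extract_insert("ACGT", call)


class TestParse:
    def test_zero_noise_ok_rate_is_one(self, zero_noise_run):
        assert zero_noise_run["parse_summary"]["ok_rate"] == 1.0

    def test_zero_noise_barcodes_and_inserts_exact(self, zero_noise_run):
        sim = zero_noise_run["sim"]
        truth = sim.read_truth.set_index("read_id")
        genomes = sim.genomes
        for p in zero_noise_run["parsed"][:200]:
            t = truth.loc[p.call.read_id]
            assert p.call.barcode == t.true_barcode
            frag = genomes[t.source_genome][t.source_start : t.source_end]
            expected = frag if t.strand == "+" else revcomp(frag)
            assert p.insert == expected

    def test_noisy_ok_rate_and_barcode_accuracy(self, noisy_run):
        assert noisy_run["parse_summary"]["ok_rate"] >= 0.95
        truth = dict(
            zip(noisy_run["sim"].read_truth.read_id, noisy_run["sim"].read_truth.true_barcode)
        )
        ok = [p for p in noisy_run["parsed"] if p.call.status == "ok"]
        close = sum(
            1
            for p in ok
            if edlib.align(p.call.barcode, truth[p.call.read_id], mode="NW", k=1)["editDistance"]
            >= 0
        )
        assert close / len(ok) >= 0.99

    def test_order_independence(self):
        reads = [make_read(insert=random_seq(200, s))[0] for s in range(20)]
        recs = [(f"r{i}", s) for i, s in enumerate(reads)]
        fwd, _ = g.parse_records(recs, SPEC)
        rev, _ = g.parse_records(recs[::-1], SPEC)
        by_id_fwd = {p.call.read_id: (p.call.barcode, p.insert) for p in fwd}
        by_id_rev = {p.call.read_id: (p.call.barcode, p.insert) for p in rev}
        assert by_id_fwd == by_id_rev

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        parsed, summary = g.parse_fastq(path, SPEC)
        assert parsed == [] and summary["n_reads"] == 0

    def test_fastq_file_round_trip(self, tmp_path):
        read, _ = make_read()
        path = tmp_path / "reads.fastq"
        write_fastq(path, [("r0", read, "?" * len(read))])
        parsed, summary = g.parse_fastq(path, SPEC)
        assert summary["counts_by_status"]["ok"] == 1
        assert parsed[0].call.barcode == BC

    def test_malformed_fastq_raises_with_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\nMALFORMED\n")
        with pytest.raises(ValueError, match="record"):
            g.parse_fastq(path, SPEC)


class TestBothEndsLayout:
    def test_agreeing_cassettes_parse(self):
        insert = random_seq(400, 12)
        cassette = SPEC.anchor5 + BC + SPEC.anchor3
        read = cassette + insert + revcomp(cassette)
        parsed, summary = g.parse_records([("r0", read)], SPEC, rp.ParseParams(layout="both-ends"))
        assert summary["counts_by_status"]["ok"] == 1
        assert parsed[0].call.barcode == BC
        assert parsed[0].insert == insert

    def test_disagreeing_barcodes_ambiguous(self):
        insert = random_seq(400, 13)
        other = "T" * 19
        read = (
            SPEC.anchor5 + BC + SPEC.anchor3 + insert + revcomp(SPEC.anchor5 + other + SPEC.anchor3)
        )
        parsed, summary = g.parse_records([("r0", read)], SPEC, rp.ParseParams(layout="both-ends"))
        assert summary["counts_by_status"]["ambiguous"] == 1
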