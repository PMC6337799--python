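"""Demultiplexing, reporter detection, trimming, and reporter filtering."""

import numpy as np
import pytest

from odnmap.config import OdnSpec, SampleSpec
from odnmap.dna import hamming_distance, revcomp
from odnmap.io import ReadPair
from odnmap.reads import (AMBIGUOUS, demultiplex, detect_reporter,
                          filter_by_reporter, trim_all, trim_fragment)


def pair(read_id, seq1, seq2):
    return ReadPair(read_id, seq1, "I" * len(seq1), seq2, "I" * len(seq2))


class TestDemultiplex:
    samples = [SampleSpec("A", "ACGTACGT"), SampleSpec("B", "TTTTCCCC")]

    def test_exact_prefix_assigned_and_stripped(self):
        bins, counts = demultiplex([pair("r", "AAAA", "ACGTACGTGGGG")], self.samples)
        assert counts == {"A": 1, "B": 0, AMBIGUOUS: 0}
        assert bins["A"][0].seq2 == "GGGG"
        assert bins["A"][0].sample_id == "A"

    def test_one_mismatch_is_ambiguous_at_tolerance_zero(self):
        bins, counts = demultiplex([pair("r", "AAAA", "ACGTACGAGGGG")], self.samples)
        assert counts[AMBIGUOUS] == 1

    def test_tolerance_one_uses_unique_nearest_barcode(self, rng):
        # oracle: Hamming distance to every barcode decides the assignment
        for _ in range(50):
            bc = rng.choice(list("ACGT"), size=8)
            read_bc = "".join(bc)
            _, counts = demultiplex([pair("r", "AAAA", read_bc + "GG")],
                                    self.samples, tolerance=1)
            dists = {s.sample_id: hamming_distance(read_bc, s.barcode)
                     for s in self.samples}
            within = [sid for sid, d in dists.items() if d <= 1]
            if len(within) == 1:
                assert counts[within[0]] == 1
            else:
                assert counts[AMBIGUOUS] == 1

    def test_conservation_every_pair_binned_once(self, small_pairs):
        bins, counts = demultiplex(small_pairs, self.samples)
        assert sum(counts.values()) == len(small_pairs)
        assert sum(len(b) for b in bins.values()) == len(small_pairs)


class TestDetectReporter:
    def test_exact_reporter_prefix(self, odn):
        hit = detect_reporter(odn.reporter + "ACGTACGT", odn)
        assert (hit.found, hit.mismatches, hit.end_pos) == (True, 0, len(odn.reporter))

    def test_unrelated_sequence_not_found(self, odn):
        hit = detect_reporter(revcomp(odn.reporter) + "ACGT", odn)
        assert not hit.found

    def test_single_substitution_tolerated(self, odn, rng):
        # oracle: Hamming count against the reporter decides found/mismatches
        rep = list(odn.reporter)
        i = int(rng.integers(0, len(rep)))
        rep[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[rep[i]]
        hit = detect_reporter("".join(rep) + "ACGTACGT", odn)
        assert (hit.found, hit.mismatches, hit.end_pos) == (True, 1, len(odn.reporter))

    def test_too_short_read(self, odn):
        hit = detect_reporter(odn.reporter[:-2], odn)
        assert not hit.found and hit.reason == "too_short"


class TestTrim:
    def test_correctly_primed_read_yields_planted_flank(self, odn):
        genomic = "ACGTTGCAAGGCTTAGGCTTACATGGACTTGA"
        p = pair("r", odn.primer2 + odn.reporter + genomic, "GGGG" + "ACGT" * 5)
        frag = trim_fragment(p, odn)
        assert frag.genomic_seq == genomic
        assert frag.reporter_found and frag.primer_trimmed

    def test_short_insert_readthrough_removed(self, odn):
        # insert shorter than read capacity: R1 runs into revcomp(adapter)
        genomic = "ACGTTGCAAGGCTTAGGC"
        r1 = odn.primer2 + odn.reporter + genomic + revcomp(odn.adapter) + "TTTT"
        r2 = odn.adapter + revcomp(genomic) + revcomp(odn.reporter)
        frag = trim_fragment(pair("r", r1, r2), odn)
        assert frag.genomic_seq == genomic
        assert frag.mate_seq == revcomp(genomic)

    def test_misprimed_pair_retained_without_reporter(self, odn):
        genomic = "TTGGCCAATTGGCCAATTGGCATA"
        frag = trim_fragment(pair("r", odn.primer2 + genomic, "ACGT" * 6), odn)
        assert frag is not None and not frag.reporter_found
        assert frag.genomic_seq == genomic

    def test_fully_consumed_fragment_dropped(self, odn):
        p = pair("r", odn.primer2 + odn.reporter, "ACGT")
        frags, dropped = trim_all([p], odn)
        assert frags == [] and dropped == 1

    def test_trimming_idempotent(self, odn, small_pairs):
        for p in small_pairs[:200]:
            frag = trim_fragment(p, odn)
            if frag is None:
                continue
            again = trim_fragment(
                ReadPair(frag.read_id, frag.genomic_seq, "I" * len(frag.genomic_seq),
                         frag.mate_seq, "I" * len(frag.mate_seq)), odn)
            assert again.genomic_seq == frag.genomic_seq
            assert again.mate_seq == frag.mate_seq


class TestReporterFilter:
    def test_tally_counts(self, odn):
        frags, _ = trim_all(
            [pair(f"r{i}", odn.primer2 + odn.reporter + "ACGTTGCAAGGCTTAGGC", "ACGT" * 8)
             for i in range(7)]
            + [pair(f"m{i}", odn.primer2 + "TTGGCCAATTGGCCAATTGG", "ACGT" * 8)
               for i in range(3)], odn)
        kept, rejected, tally = filter_by_reporter(frags)
        assert tally == {"kept": 7, "rejected": 3}

    def test_empty_stream(self):
        kept, rejected, tally = filter_by_reporter([])
        assert kept == [] and rejected == [] and tally == {"kept": 0, "rejected": 0}

    def test_no_odn_control_keeps_nothing(self, odn, b2m_guide):
        """A sample without ODN produces only misprimed molecules; reporter
        filtering keeps none of them."""
        from conftest import make_pairs, make_truth
        truth = make_truth(seed=23, odn=odn, guide=b2m_guide, length=60_000)
        ctrl_pairs = make_pairs(truth, odn, n_reads=300, seed=23, misprime_frac=1.0)
        frags, _ = trim_all(ctrl_pairs, odn)
        kept, rejected, tally = filter_by_reporter(frags)
        assert tally["kept"] == 0 and tally["rejected"] == len(frags)

    def test_conservation_on_simulated_reads(self, odn, small_pairs):
        frags, dropped = trim_all(small_pairs, odn)
        kept, rejected, tally = filter_by_reporter(frags)
        assert tally["kept"] + tally["rejected"] + dropped == len(small_pairs)

    def test_zero_false_keeps_at_tolerance_zero(self, odn, b2m_guide):
        """Misprimed reads never carry the reporter, so a strict (tolerance 0)
        filter keeps none of them; truth labels close the loop."""
        from conftest import make_pairs, make_truth
        strict = OdnSpec(reporter_max_mismatch=0)
        truth = make_truth(seed=29, odn=strict, guide=b2m_guide, length=60_000)
        pairs = make_pairs(truth, strict, n_reads=2000, seed=29, misprime_frac=0.4)
        labels = truth.reads.set_index("read_id")
        frags, _ = trim_all(pairs, strict)
        kept, _, _ = filter_by_reporter(frags)
        assert kept, "expected correctly-primed reads to survive"
        assert all(not labels.loc[f.read_id, "misprimed"] for f in kept)
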