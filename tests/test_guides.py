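"""Near-match protospacer scanning (vs a brute-force Hamming oracle),
site assignment, specificity arithmetic, and the off-target table."""

import math

import numpy as np
import pytest

from odnmap.config import GuideSpec
from odnmap.dna import IUPAC, revcomp
from odnmap.guides import (assign_sites, highlight_mismatches, offtarget_table,
                           scan_guide, specificity)
from odnmap.simulate import plant_guide_sites, simulate_genome
from odnmap.sites import Site


def brute_scan(genome, guide, match_min):
    """Oracle: per-position Hamming evaluation over both strands."""
    proto, pam = guide.protospacer, guide.pam
    P, Q = len(proto), len(pam)
    hits = set()
    for chrom, seq in genome.items():
        for strand in "+-":
            view = seq if strand == "+" else revcomp(seq)
            for p in range(len(view) - P - Q + 1):
                window, pam_seq = view[p:p + P], view[p + P:p + P + Q]
                if any(b not in IUPAC[c] for b, c in zip(pam_seq, pam)):
                    continue
                matched = sum(a == b for a, b in zip(window, proto))
                if matched >= match_min:
                    w = p if strand == "+" else len(view) - p - P
                    hits.add((chrom, strand, w, matched))
    return hits


def as_set(matches):
    return {(m.chrom, m.strand, m.protospacer_start, m.matched_bases) for m in matches}


@pytest.fixture(scope="module")
def planted(b2m_guide):
    truth = simulate_genome(40_000, seed=71)
    return plant_guide_sites(truth, b2m_guide, [3, 6], seed=72)


class TestScanGuide:
    def test_planted_on_target_found_exactly(self, b2m_guide):
        genome = {"c": "T" * 500 + b2m_guide.protospacer + "AGG" + "T" * 500}
        matches = [m for m in scan_guide(genome, b2m_guide, 14) if m.mismatches == 0]
        (m,) = matches
        assert (m.strand, m.protospacer_start, m.pam_seq) == ("+", 500, "AGG")
        assert m.cut_pos == 500 + 17  # blunt cut 3 bp 5' of the PAM
        assert m.is_on_target

    def test_threshold_and_pam_edges(self, b2m_guide, rng):
        proto = list(b2m_guide.protospacer)
        sub = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for idx in rng.choice(20, size=6, replace=False):
            proto[idx] = sub[proto[idx]]
        six_mm = "".join(proto)
        genome = {"c": "T" * 100 + six_mm + "TGG" + "T" * 100}
        # 6 substitutions, valid PAM: matched 14 >= 14 -> returned
        assert any(m.mismatches == 6 for m in scan_guide(genome, b2m_guide, 14))
        # 7 substitutions drop below the 14/20 threshold
        proto7 = list(b2m_guide.protospacer)
        for idx in range(7):
            proto7[idx] = sub[proto7[idx]]
        genome7 = {"c": "T" * 100 + "".join(proto7) + "TGG" + "T" * 100}
        assert all(m.protospacer_start != 100 for m in scan_guide(genome7, b2m_guide, 14))
        # perfect protospacer, invalid PAM -> not returned
        genome_bad_pam = {"c": "T" * 100 + b2m_guide.protospacer + "ATT" + "T" * 100}
        assert all(m.protospacer_start != 100
                   for m in scan_guide(genome_bad_pam, b2m_guide, 14))

    def test_oracle_equivalence_with_planted_loci(self, planted, b2m_guide):
        for match_min in (12, 14, 16):
            got = as_set(scan_guide(planted.genome, b2m_guide, match_min))
            assert got == brute_scan(planted.genome, b2m_guide, match_min)

    def test_planted_mismatch_counts_recovered(self, planted, b2m_guide):
        matches = scan_guide(planted.genome, b2m_guide, 14)
        by_pos = {m.protospacer_start: m for m in matches}
        for locus in planted.guide_loci:
            m = by_pos[locus.protospacer_start]
            assert m.mismatches == locus.mismatches
            assert m.strand == locus.strand
            assert m.cut_pos == locus.cut_pos

    def test_nestedness_across_thresholds(self, planted, b2m_guide):
        sets = [as_set(scan_guide(planted.genome, b2m_guide, mm))
                for mm in (16, 14, 12)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_reverse_complement_symmetry(self, planted, b2m_guide):
        genome = planted.genome
        mirrored = {c: revcomp(s) for c, s in genome.items()}
        fwd = scan_guide(genome, b2m_guide, 14)
        rev = scan_guide(mirrored, b2m_guide, 14)
        assert len(fwd) == len(rev)
        n = len(next(iter(genome.values())))
        mapped = {(m.chrom, "-" if m.strand == "+" else "+",
                   n - m.protospacer_start - 20, m.matched_bases) for m in rev}
        assert mapped == as_set(fwd)

    def test_ambiguous_base_never_matches(self, b2m_guide):
        core = b2m_guide.protospacer[:-1] + "N"
        genome = {"c": "T" * 50 + core + "AGG" + "T" * 50}
        (m,) = [m for m in scan_guide(genome, b2m_guide, 14)
                if m.protospacer_start == 50]
        assert m.mismatches == 1  # the N position counts as mismatched
        genome_n_pam = {"c": "T" * 50 + b2m_guide.protospacer + "ANG" + "T" * 50}
        assert all(m.protospacer_start != 50
                   for m in scan_guide(genome_n_pam, b2m_guide, 14))


def make_site(site_id, pos, abundance, chrom="chr1"):
    return Site(site_id=site_id, chrom=chrom, span=(pos, pos + 1), position=pos,
                strands={"+": 1}, read_count=abundance, abundance=abundance,
                events=[])


class TestAssignSites:
    def _matches(self, b2m_guide, cuts):
        from odnmap.guides import GuideMatch
        return [GuideMatch("B2M", "chr1", "+", c - 17, 20 - mm, mm, "AGG", c,
                           b2m_guide.protospacer)
                for c, mm in cuts]

    def test_window_boundary(self, b2m_guide):
        sites = [make_site("s1", 1000, 5)]
        inside = assign_sites(sites, self._matches(b2m_guide, [(1050, 0)]), 100)
        assert inside["s1"].distance == 50
        outside = assign_sites(sites, self._matches(b2m_guide, [(1101, 0)]), 100)
        assert outside == {}
        edge = assign_sites(sites, self._matches(b2m_guide, [(1100, 0)]), 100)
        assert edge["s1"].distance == 100

    def test_nearest_match_wins(self, b2m_guide):
        sites = [make_site("s1", 1000, 5)]
        a = assign_sites(sites, self._matches(b2m_guide, [(1040, 3), (1060, 0)]), 100)
        assert a["s1"].distance == 40 and a["s1"].match.mismatches == 3


class TestSpecificity:
    def test_all_on_target(self, b2m_guide):
        sites = [make_site("s1", 1000, 50)]
        asg = assign_sites(sites, TestAssignSites()._matches(b2m_guide, [(1000, 0)]), 100)
        rep = specificity(sites, asg, "B2M")
        assert rep.pct_on_target_filtered == 100.0
        assert rep.pct_on_target_unfiltered == 100.0

    def test_published_arithmetic_example(self, b2m_guide):
        """98 on-target + 2 matched off-target + 100 unmatched spontaneous:
        filtered 98.0%, unfiltered 49.0%."""
        sites = [make_site("on", 1000, 98), make_site("off", 5000, 2),
                 make_site("spont", 20_000, 100)]
        matches = TestAssignSites()._matches(b2m_guide, [(1000, 0), (5000, 3)])
        asg = assign_sites(sites, matches, 100)
        rep = specificity(sites, asg, "B2M")
        assert rep.pct_on_target_filtered == pytest.approx(98.0)
        assert rep.pct_on_target_unfiltered == pytest.approx(49.0)

    def test_zero_matched_abundance_is_nan_with_reason(self, b2m_guide):
        sites = [make_site("spont", 20_000, 10)]
        rep = specificity(sites, {}, "B2M")
        assert math.isnan(rep.pct_on_target_filtered)
        assert rep.note == "no guide-matched abundance"

    def test_filtered_at_least_unfiltered(self, b2m_guide, rng):
        for _ in range(20):
            sites = [make_site(f"s{i}", int(p), int(a)) for i, (p, a) in
                     enumerate(zip(rng.integers(0, 30_000, 8), rng.integers(1, 50, 8)))]
            matches = TestAssignSites()._matches(
                b2m_guide, [(int(sites[0].position), 0), (int(sites[1].position), 4)])
            asg = assign_sites(sites, matches, 100)
            rep = specificity(sites, asg, "B2M")
            if not math.isnan(rep.pct_on_target_filtered):
                assert rep.pct_on_target_filtered >= rep.pct_on_target_unfiltered - 1e-9


class TestOfftargetTable:
    def test_rows_sorted_and_annotated(self, b2m_guide):
        sites_a = [make_site("s1", 1000, 90), make_site("s2", 5000, 4)]
        matches = TestAssignSites()._matches(b2m_guide, [(1000, 0), (5000, 3)])
        asg = assign_sites(sites_a, matches, 100)
        table = offtarget_table({"guideseq": (sites_a, asg),
                                 "reporter": (sites_a, asg)}, b2m_guide)
        assert list(table["mismatches"]) == [0, 3]  # most abundant first
        assert table.iloc[0]["abund_guideseq"] == 90
        assert len(table) <= 100

    def test_guideseq_counts_at_least_reporter(self, b2m_guide):
        sites_gs = [make_site("s1", 1000, 95)]
        sites_ig = [make_site("s1", 1000, 80)]
        matches = TestAssignSites()._matches(b2m_guide, [(1000, 0)])
        table = offtarget_table(
            {"guideseq": (sites_gs, assign_sites(sites_gs, matches, 100)),
             "reporter": (sites_ig, assign_sites(sites_ig, matches, 100))},
            b2m_guide)
        assert (table["abund_guideseq"] >= table["abund_reporter"]).all()

    def test_mismatch_highlighting_lowercases_substitutions(self, b2m_guide):
        aligned = "t" + b2m_guide.protospacer[1:]
        assert highlight_mismatches("T" + b2m_guide.protospacer[1:],
                                    b2m_guide.protospacer) == aligned
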