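"""Control-region structure scanning, checked against brute force."""

import re

import numpy as np
import pytest

from mitokit._util import reverse_complement
from mitokit.control_region import (
    ControlRegionConfig, find_motifs, find_poly_tracts, find_stem_loops,
    find_ta_runs, scan_control_region,
)

PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def brute_force_stem_loops(seq, min_stem, loop_range, max_mismatch):
    """Independent oracle: enumerate every (arm-start, stem, loop) triple
    and apply the candidate/maximality definition literally."""
    n = len(seq)
    lmin, lmax = loop_range

    def valid(i, k, l):
        j = i + k + l
        if i < 0 or k < min_stem or not (lmin <= l <= lmax) or j + k > n:
            return None
        pairs = [(seq[i + p], seq[j + k - 1 - p]) for p in range(k)]
        mism = sum(1 for p in pairs if p not in PAIRS)
        if mism > max_mismatch:
            return None
        if pairs[0] not in PAIRS or pairs[-1] not in PAIRS:
            return None
        return mism

    def extendable(i, k, l):
        if valid(i - 1, k + 1, l) is not None:
            return True
        return valid(i, k + 1, l - 2) is not None

    hits = []
    for i in range(n):
        for k in range(min_stem, n):
            for l in range(lmin, lmax + 1):
                m = valid(i, k, l)
                if m is not None and not extendable(i, k, l):
                    hits.append((i + 1, i + k, i + k + l + 1, i + 2 * k + l, m))
    hits.sort(key=lambda h: (h[0], h[1] - h[0]))
    return hits


class TestPolyTracts:
    def test_ten_base_poly_t(self):
        tracts = find_poly_tracts("AATTTTTTTTTTGG", "T", min_len=10)
        assert [(t.start, t.length) for t in tracts] == [(3, 10)]

    def test_no_qualifying_run(self):
        assert find_poly_tracts("ACGT", "T", min_len=2) == []

    def test_agrees_with_regex_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=300, p=[.4, .1, .1, .4]))
            got = [(t.start, t.length) for t in find_poly_tracts(seq, "A", 4)]
            want = [(m.start() + 1, len(m.group()))
                    for m in re.finditer("A{4,}", seq)]
            assert got == want

    def test_tracts_never_overlap(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("AT"), size=500))
        tracts = find_poly_tracts(seq, "T", 3)
        for a, b in zip(tracts, tracts[1:]):
            assert a.end < b.start


class TestStemLoops:
    def test_perfect_hairpin(self):
        hits = find_stem_loops("GGGGAAAACCCC", min_stem=4, loop_range=(3, 8),
                               max_mismatch=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.arm5_start, h.arm5_end, h.arm3_start, h.arm3_end) == (1, 4, 9, 12)
        assert h.mismatches == 0 and h.stem_length == 4 and h.loop_length == 4

    def test_mismatch_budget(self):
        # mutate one internal arm base of GGGG AAAA CCCC
        seq = "GGCGAAAACCCC"
        assert find_stem_loops(seq, 4, (3, 8), max_mismatch=0) == []
        hits = find_stem_loops(seq, 4, (3, 8), max_mismatch=1)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_dot_bracket(self):
        h = find_stem_loops("GGGGAAAACCCC", 4, (3, 8), 0)[0]
        assert h.dot_bracket("GGGGAAAACCCC") == "((((....))))"

    @pytest.mark.parametrize("trial_block", range(4))
    def test_equals_brute_force_on_short_random_sequences(self, trial_block):
        rng = np.random.default_rng(100 + trial_block)
        for _ in range(60):
            n = int(rng.integers(12, 41))
            seq = "".join(rng.choice(list("ACGT"), size=n, p=[.35, .15, .15, .35]))
            got = [(h.arm5_start, h.arm5_end, h.arm3_start, h.arm3_end, h.mismatches)
                   for h in find_stem_loops(seq, 3, (3, 8), 1)]
            assert got == brute_force_stem_loops(seq, 3, (3, 8), 1), seq

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            fwd = find_stem_loops(seq, 3, (3, 10), 1)
            rev = find_stem_loops(reverse_complement(seq), 3, (3, 10), 1)
            mirrored = sorted(
                (n + 1 - h.arm3_end, n + 1 - h.arm3_start,
                 n + 1 - h.arm5_end, n + 1 - h.arm5_start, h.mismatches)
                for h in rev)
            assert mirrored == sorted(
                (h.arm5_start, h.arm5_end, h.arm3_start, h.arm3_end, h.mismatches)
                for h in fwd)


class TestMotifs:
    def test_literal_motif(self):
        hits = find_motifs("CCGAATCC", ["GAAT"])["GAAT"]
        assert [h.start for h in hits] == [3]

    def test_ta_run_hand_count(self):
        hits = find_ta_runs("GGTATATATAGG", min_repeats=3)
        assert [(h.start, h.length) for h in hits] == [(3, 8)]
        assert hits[0].motif == "(TA)4"

    def test_overlapping_literal_hits_all_reported(self):
        hits = find_motifs("AAAA", ["AA"])["AA"]
        assert [h.start for h in hits] == [1, 2, 3]


class TestScanControlRegion:
    def test_fixture_region_length(self, kamimuria_annotation):
        from mitokit.model import MitoGenome

        cr = kamimuria_annotation.get("CR")
        assert cr.end - cr.start + 1 == 1251  # 16179 - 14929 + 1

    def test_planted_elements_recovered_at_absolute_coordinates(
            self, synthetic_genome):
        genome, truth = synthetic_genome
        report = scan_control_region(genome)
        ct = truth["control_region"]
        assert report.length == ct["end"] - ct["start"] + 1
        assert [(t.start, t.length) for t in report.poly_tracts] == [
            (ct["poly_t"]["start"], ct["poly_t"]["length"])]
        found = {(h.arm5_start, h.arm5_end, h.arm3_start, h.arm3_end, h.mismatches)
                 for h in report.stem_loops}
        for h in ct["stem_loops"]:
            assert (h["arm5_start"], h["arm5_end"], h["arm3_start"],
                    h["arm3_end"], h["mismatches"]) in found
        assert [(h.start, h.length // 2) for h in report.motifs["(TA)n"]] == [
            (t["start"], t["repeats"]) for t in ct["ta_runs"]]
        assert [h.start for h in report.motifs["GAAT"]] == [
            g["start"] for g in ct["gaat"]]

    def test_planted_hairpins_lie_downstream_of_poly_t(self, synthetic_genome):
        genome, truth = synthetic_genome
        ct = truth["control_region"]
        tract_end = ct["poly_t"]["start"] + ct["poly_t"]["length"] - 1
        for h in ct["stem_loops"]:
            assert h["arm5_start"] > tract_end

    def test_genome_without_control_region(self):
        from mitokit.model import AnnotationTable, FeatureClass, GeneFeature, MitoGenome

        ann = AnnotationTable(
            [GeneFeature("g", FeatureClass.TRNA, 1, 30)], 30, circular=False)
        genome = MitoGenome(annotation=ann, sequence="ACGT" * 7 + "AC")
        report = scan_control_region(genome)
        assert report.length == 0
        assert report.findings and report.findings[0].category == "missing_feature"
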