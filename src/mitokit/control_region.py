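"""Structural scanning of the A+T-rich (control) region.

Insect mitogenome control regions typically carry a long poly-T tract
(implicated in replication-origin signalling), one or more hairpins
(inverted repeats able to fold into stem-loops), and short flanking
motifs such as (TA)n dinucleotide runs and GAAT.  This module finds all
three element types with explicit, configurable parameters.

Hairpin semantics
-----------------
A candidate stem-loop is a triple (arm start *i*, stem length *k*, loop
length *l*): positions ``i .. i+k-1`` pair with ``i+k+l .. i+2k+l-1``
(reversed).  It is *valid* when ``k >= min_stem``, *l* is inside the
loop range, at most ``max_mismatch`` stem pairs are non-complementary,
and both the outermost and innermost stem pairs are true Watson-Crick
pairs (stems never end on a mismatch).  Only *maximal* candidates are
reported: those that cannot be extended outward (longer stem, same loop)
or inward (consuming two loop bases) while remaining valid.  G:T
wobble pairs are not counted as pairs by default (DNA-level scan).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._util import is_wc_pair
from .composition import base_composition
from .model import FeatureClass, Finding, MitoGenome


@dataclass(frozen=True)
class PolyTract:
    """A maximal homopolymer run (1-based coordinates within the scanned
    sequence)."""

    base: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class StemLoop:
    """A hairpin candidate; coordinates are 1-based within the scanned
    sequence, arms inclusive."""

    arm5_start: int
    arm5_end: int
    arm3_start: int
    arm3_end: int
    mismatches: int

    @property
    def stem_length(self) -> int:
        return self.arm5_end - self.arm5_start + 1

    @property
    def loop_length(self) -> int:
        return self.arm3_start - self.arm5_end - 1

    def dot_bracket(self, seq: str) -> str:
        """Dot-bracket string for the [arm5_start, arm3_end] slice."""
        n = self.arm3_end - self.arm5_start + 1
        k = self.stem_length
        return "(" * k + "." * self.loop_length + ")" * k


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int
    length: int


def find_poly_tracts(seq: str, base: str, min_len: int = 10) -> list[PolyTract]:
    """All maximal runs of `base` of at least `min_len`, sorted by start."""
    base = base.upper()
    return [
        PolyTract(base, m.start() + 1, m.end() - m.start())
        for m in re.finditer(f"{re.escape(base)}+", seq.upper())
        if m.end() - m.start() >= min_len
    ]


def _stem_candidate(seq: str, i: int, k: int, l: int,  # noqa: E741
                    max_mismatch: int) -> Optional[int]:
    """Mismatch count of candidate (i, k, l) on 0-based `seq`, or None if
    invalid (bounds, mismatch budget, or mismatched terminal pair)."""
    j = i + k + l  # 3' arm start
    if i < 0 or j + k > len(seq):
        return None
    mism = 0
    for p in range(k):
        if not is_wc_pair(seq[i + p], seq[j + k - 1 - p]):
            mism += 1
    if mism > max_mismatch:
        return None
    # terminal pairs must pair
    if not is_wc_pair(seq[i], seq[j + k - 1]):
        return None
    if not is_wc_pair(seq[i + k - 1], seq[j]):
        return None
    return mism


def find_stem_loops(
    seq: str,
    min_stem: int = 6,
    loop_range: tuple[int, int] = (3, 20),
    max_mismatch: int = 1,
) -> list[StemLoop]:
    """All maximal inverted repeats satisfying the constraints, sorted by
    5' arm position then stem length.  See the module docstring for the
    exact candidate and maximality definitions."""
    seq = seq.upper()
    n = len(seq)
    lmin, lmax = loop_range
    hits: list[StemLoop] = []
    # anchor on the loop [a, a+l-1] (0-based) and grow the stem outward:
    # pair q is (a-q, a+l-1+q), so the mismatch count is incremental in q
    # and the scan stops as soon as the budget is exhausted.
    for a in range(1, n):
        for l in range(lmin, lmax + 1):  # noqa: E741
            if a + l >= n:
                break
            if not is_wc_pair(seq[a - 1], seq[a + l]):
                continue  # innermost stem pair must pair
            mism = 0
            q = 1
            while a - q - 1 >= 0 and a + l + q < n and mism <= max_mismatch:
                q += 1
                if not is_wc_pair(seq[a - q], seq[a + l + q - 1]):
                    mism += 1
            kmax = q if mism <= max_mismatch else q - 1
            for k in range(min_stem, kmax + 1):
                i = a - k
                mism = _stem_candidate(seq, i, k, l, max_mismatch)
                if mism is None:
                    continue
                # maximality: no valid outward or inward extension
                if _stem_candidate(seq, i - 1, k + 1, l, max_mismatch) is not None:
                    continue
                if l - 2 >= lmin and _stem_candidate(seq, i, k + 1, l - 2, max_mismatch) is not None:
                    continue
                hits.append(StemLoop(
                    arm5_start=i + 1, arm5_end=i + k,
                    arm3_start=i + k + l + 1, arm3_end=i + 2 * k + l,
                    mismatches=mism,
                ))
    hits.sort(key=lambda h: (h.arm5_start, h.stem_length))
    return hits


def find_ta_runs(seq: str, min_repeats: int = 3) -> list[MotifHit]:
    """Maximal (TA)n dinucleotide runs with n >= min_repeats."""
    seq = seq.upper()
    hits = []
    for m in re.finditer("(?:TA)+", seq):
        n_rep = (m.end() - m.start()) // 2
        if n_rep >= min_repeats:
            hits.append(MotifHit(f"(TA){n_rep}", m.start() + 1, 2 * n_rep))
    return hits


def find_motifs(
    seq: str, motifs: Sequence[str], ta_min_repeats: int = 3
) -> dict[str, list[MotifHit]]:
    """Exact-match positions of literal motifs; the special pattern
    ``"(TA)n"`` triggers the maximal-dinucleotide-run finder."""
    seq = seq.upper()
    out: dict[str, list[MotifHit]] = {}
    for motif in motifs:
        if motif == "(TA)n":
            out[motif] = find_ta_runs(seq, ta_min_repeats)
            continue
        pat = motif.upper()
        out[motif] = [
            MotifHit(motif, m.start() + 1, len(pat))
            for m in re.finditer(f"(?={re.escape(pat)})", seq)
        ]
    return out


@dataclass
class ControlRegionConfig:
    """Scanner parameters (all recorded in the report)."""

    poly_base: str = "T"
    poly_min_len: int = 10
    min_stem: int = 6
    loop_range: tuple[int, int] = (3, 20)
    max_mismatch: int = 1
    motifs: tuple[str, ...] = ("(TA)n", "GAAT")
    ta_min_repeats: int = 3


@dataclass
class ControlRegionReport:
    """Scan results with genome-absolute 1-based coordinates."""

    region_start: int
    region_end: int
    length: int
    at_content: float
    poly_tracts: list[PolyTract]
    stem_loops: list[StemLoop]
    motifs: dict[str, list[MotifHit]]
    config: ControlRegionConfig
    findings: list[Finding]


def _shift_tract(t: PolyTract, off: int) -> PolyTract:
    return PolyTract(t.base, t.start + off, t.length)


def _shift_loop(s: StemLoop, off: int) -> StemLoop:
    return StemLoop(s.arm5_start + off, s.arm5_end + off,
                    s.arm3_start + off, s.arm3_end + off, s.mismatches)


def scan_control_region(
    genome: MitoGenome, config: ControlRegionConfig | None = None
) -> ControlRegionReport:
    """Locate the annotated control region and report its length, AT
    content, poly-T tracts, the stem-loops downstream of the first
    qualifying poly-T tract (higher coordinate on the reference strand),
    and flanking motifs — all in genome-absolute coordinates."""
    config = config or ControlRegionConfig()
    crs = genome.annotation.by_class(FeatureClass.CONTROL_REGION)
    if not crs:
        return ControlRegionReport(
            0, 0, 0, float("nan"), [], [], {}, config,
            [Finding("missing_feature", None, "no control region annotated")])
    cr = crs[0]
    seq = genome.feature_sequence(cr)
    off = cr.start - 1  # region-local 1-based -> genome-absolute
    profile = base_composition(seq, "A+T-rich region")

    tracts = [
        _shift_tract(t, off)
        for t in find_poly_tracts(seq, config.poly_base, config.poly_min_len)
    ]
    # stem-loops are searched downstream of the first qualifying poly tract
    findings: list[Finding] = []
    if tracts:
        local_from = tracts[0].end - off  # 1-based local position of tract end
        sub = seq[local_from:]
        loops = [
            _shift_loop(s, off + local_from)
            for s in find_stem_loops(sub, config.min_stem, config.loop_range,
                                     config.max_mismatch)
        ]
    else:
        findings.append(Finding(
            "no_poly_tract", cr.name,
            f"no poly-{config.poly_base} tract >= {config.poly_min_len}; "
            "stem-loop scan covered the whole region"))
        loops = [
            _shift_loop(s, off)
            for s in find_stem_loops(seq, config.min_stem, config.loop_range,
                                     config.max_mismatch)
        ]
    motifs = {
        name: [MotifHit(h.motif, h.start + off, h.length) for h in hits]
        for name, hits in find_motifs(seq, config.motifs, config.ta_min_repeats).items()
    }
    return ControlRegionReport(
        region_start=cr.start, region_end=cr.end, length=len(seq),
        at_content=profile.at_content, poly_tracts=tracts, stem_loops=loops,
        motifs=motifs, config=config, findings=findings,
    )
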