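"""Synthetic annotated insect mitogenomes and tree-evolved protein
alignments with recorded ground truth.

The genome generator emulates the structure of a real stonefly
mitogenome: the canonical 37-gene arrangement plus control region,
realistic gene overlaps (negative intergenic counts), per-class AT
composition targets, legal initiator/terminator codons with no internal
stops under the invertebrate mitochondrial code, and a control region
carrying a poly-T tract, two plantable hairpins and (TA)n / GAAT
motifs at recorded coordinates.  Every random draw flows from a single
integer seed, and each output embeds the seed and a hash of its spec, so
analysis results can be checked against planted truth exactly.

The protein evolver is deliberately simple (equal-rates replacement, no
among-site model, no indels): along a branch of length *t* each site is
replaced with probability ``1 - (1 - mu)**t``, drawing uniformly from
the 19 other residues.  That is sufficient to exercise distance and
tree-building code; it is not a biological substitution model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from ._util import complement_base, is_wc_pair, reverse_complement
from .codon import INVERTEBRATE_MITO, GeneticCode
from .control_region import (
    ControlRegionConfig, find_motifs, find_poly_tracts, find_stem_loops,
    find_ta_runs,
)
from .errors import ParameterError, SpecError
from .model import (
    AnnotationTable, FeatureClass, GeneFeature, MitoGenome, PCG_ORDER,
    intergenic_table,
)
from .phylogeny import Partition, ProteinAlignment, parse_newick

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class GeneTemplate:
    """Shape of one feature in a genome spec (no coordinates yet)."""

    name: str
    feature_class: FeatureClass
    length: int
    strand: str = "J"
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None


@dataclass(frozen=True)
class ControlRegionPlan:
    """Planted structural elements of the synthetic control region.

    ``hairpins`` is a tuple of (stem_length, loop_length) pairs placed
    downstream of the poly-T tract.  ``scan`` holds the scanner
    parameters the construction is calibrated against: a scan at these
    parameters recovers every planted element at its exact coordinates,
    and reports no poly tracts, (TA)n runs or GAAT occurrences beyond
    the planted ones.  Background *hairpins* are left in place — an
    A+T-rich region is intrinsically full of fold-capable inverted
    repeats, exactly as real control regions are.
    """

    poly_t_length: int = 10
    hairpins: tuple[tuple[int, int], ...] = ((8, 10), (7, 16))
    ta_repeats: int = 4
    gaat_count: int = 2
    scan: ControlRegionConfig = field(default_factory=ControlRegionConfig)


@dataclass(frozen=True)
class GenomeSpec:
    """Everything needed to lay out and fill one synthetic mitogenome.

    ``igns[i]`` is the intergenic count preceding feature *i* in order;
    ``igns[0]`` is the wrap boundary (last feature to first across the
    origin).  The first feature starts at position 1, so the genome
    length is the last feature's end plus ``igns[0]``.
    """

    templates: tuple[GeneTemplate, ...]
    igns: tuple[int, ...]
    at_targets: Mapping[str, float] = field(default_factory=lambda: {
        "PCG": 0.68, "tRNA": 0.724, "rRNA": 0.71,
        "control_region": 0.782, "intergenic": 0.70,
    })
    cr_plan: ControlRegionPlan = field(default_factory=ControlRegionPlan)
    codon_frequencies: Optional[Mapping[str, float]] = None
    seed: int = 0

    def spec_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def default_genome_spec(seed: int = 0, **overrides) -> GenomeSpec:
    """Spec mirroring the published K. wangi mitogenome: its 38-feature
    arrangement, coordinate-derived lengths, published start/stop
    codons, its exact intergenic/overlap profile, and measured per-class
    AT contents."""
    from .datasets import load_annotation

    ann = load_annotation()
    templates = tuple(
        GeneTemplate(
            name=f.name, feature_class=f.feature_class,
            length=f.end - f.start + 1, strand=f.strand,
            start_codon=f.start_codon, stop_codon=f.stop_codon,
        )
        for f in ann.features
    )
    igns = tuple(ign for _, ign in intergenic_table(ann))
    kwargs = dict(templates=templates, igns=igns, seed=seed)
    kwargs.update(overrides)
    return GenomeSpec(**kwargs)


# ---------------------------------------------------------------------------
# nucleotide sampling

def _sample_bases(rng: np.random.Generator, n: int, at: float) -> list[str]:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return list(rng.choice(list("ACGT"), size=n, p=p))


def _expected_at_after_stop_rejection(t: float, stops: Sequence[str]) -> float:
    """Mean AT fraction of codons drawn base-wise at AT level `t` after
    rejecting stop codons."""
    def p_base(b: str) -> float:
        return t / 2 if b in "AT" else (1 - t) / 2

    p_stop = 0.0
    at_stop = 0.0
    for s in stops:
        p = p_base(s[0]) * p_base(s[1]) * p_base(s[2])
        p_stop += p
        at_stop += p * sum(1 for b in s if b in "AT")
    return (3 * t - at_stop) / (3 * (1 - p_stop))


def _adjusted_at(target: float, stops: Sequence[str]) -> float:
    """AT level to feed the base sampler so the accepted (stop-rejected)
    codons hit `target` in expectation.  Monotone, solved by bisection."""
    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(60):
        mid = (lo + hi) / 2
        if _expected_at_after_stop_rejection(mid, stops) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _sample_internal_codons(
    rng: np.random.Generator, n: int, at: float,
    code: GeneticCode, freqs: Optional[Mapping[str, float]],
) -> list[str]:
    """`n` non-stop codons, either from an explicit codon distribution or
    base-wise at a stop-rejection-compensated AT level."""
    stops = code.stop_codons
    if freqs is not None:
        codons = [c for c in freqs if c not in stops]
        p = np.array([freqs[c] for c in codons], dtype=float)
        p /= p.sum()
        return list(rng.choice(codons, size=n, p=p))
    t = _adjusted_at(at, stops)
    out: list[str] = []
    while len(out) < n:
        chunk = _sample_bases(rng, 3 * (n - len(out)), t)
        for k in range(0, len(chunk), 3):
            codon = "".join(chunk[k:k + 3])
            if codon not in stops:
                out.append(codon)
    return out[:n]


# ---------------------------------------------------------------------------
# control region construction

def _build_control_region(
    rng: np.random.Generator, length: int, at: float, plan: ControlRegionPlan
) -> tuple[list[str], dict]:
    """Control-region sequence plus local-coordinate truth (1-based).

    Elements are placed left to right with jittered gaps; after
    planting, the region is scrubbed so that a scan at ``plan.scan``
    parameters recovers exactly the planted elements.
    """
    cfg = plan.scan
    # compensate the sampling AT rate for the fixed-content planted
    # material (poly-T and (TA)n are pure AT, GAAT is 3/4 AT, the CC
    # flanks are pure GC) so the whole region hits `at` in expectation
    n_pieces = 1 + len(plan.hairpins) + 1 + plan.gaat_count
    fixed_len = (plan.poly_t_length + 2 * plan.ta_repeats
                 + 4 * plan.gaat_count + 4 * n_pieces)
    fixed_at = plan.poly_t_length + 2 * plan.ta_repeats + 3 * plan.gaat_count
    sampled_len = length - fixed_len
    if sampled_len <= 0:
        raise SpecError("control region too short for the planted elements")
    at_bg = min(0.95, max(0.05, (at * length - fixed_at) / sampled_len))
    seq = _sample_bases(rng, length, at_bg)

    def payload_clean(payload: str, planted_loops: int) -> bool:
        """No scanner-visible structure inside a payload (with its CC
        flanks) beyond what was planted there — protected spans can
        never be scrubbed, so they must be born clean."""
        probe = "CC" + payload + "CC"
        if len(find_stem_loops(probe, cfg.min_stem, cfg.loop_range,
                               cfg.max_mismatch)) != planted_loops:
            return False
        expect_tract = 1 if payload == "T" * len(payload) else 0
        if len(find_poly_tracts(probe, cfg.poly_base, cfg.poly_min_len)) != expect_tract:
            return False
        expect_ta = 1 if set(payload) == {"T", "A"} and payload.startswith("TA") else 0
        if len(find_ta_runs(probe, cfg.ta_min_repeats)) != expect_ta:
            return False
        expect_gaat = 1 if payload == "GAAT" else 0
        if len(find_motifs(probe, ["GAAT"])["GAAT"]) != expect_gaat:
            return False
        return True

    pieces: list[tuple[str, str, tuple]] = []  # (kind, payload, meta)
    pieces.append(("poly_t", "T" * plan.poly_t_length, ()))
    lmin = cfg.loop_range[0]
    for stem, loop in plan.hairpins:
        for _ in range(200):
            arm = "".join(_sample_bases(rng, stem, at_bg))
            loop_seq = "".join(_sample_bases(rng, loop, at_bg))
            if loop - 2 >= lmin and is_wc_pair(loop_seq[0], loop_seq[-1]):
                continue  # planted hairpin must not extend inward
            payload = arm + loop_seq + reverse_complement(arm)
            if payload_clean(payload, planted_loops=1):
                break
        else:
            raise SpecError("could not draw a clean hairpin payload")
        pieces.append(("hairpin", payload, (stem, loop)))
    pieces.append(("ta_run", "TA" * plan.ta_repeats, ()))
    for _ in range(plan.gaat_count):
        pieces.append(("gaat", "GAAT", ()))

    total = sum(len(p) for _, p, _m in pieces)
    n_pieces = len(pieces)
    slack = length - total - 4 * n_pieces - 8
    if slack < n_pieces:
        raise SpecError(
            f"control region of {length} nt cannot hold the planted elements")
    # keep planted elements further apart than the loop range so they
    # cannot pair with each other
    min_gap = min(cfg.loop_range[1] + 5, slack // (2 * n_pieces))
    jitter = rng.multinomial(slack - min_gap * n_pieces,
                             np.ones(n_pieces) / n_pieces)
    gaps = [min_gap + int(j) for j in jitter]

    truth: dict = {"poly_t": None, "stem_loops": [], "ta_runs": [], "gaat": []}
    protected: set[int] = set()  # 0-based positions that must not mutate
    pos = 4  # leave a small untouched margin at the region edges
    for (kind, payload, meta), gap in zip(pieces, gaps):
        pos += gap + 2
        start0 = pos
        end0 = pos + len(payload) - 1
        seq[start0:end0 + 1] = list(payload)
        # flanks: break run/stem continuation without creating motifs
        seq[start0 - 1] = "C"
        seq[start0 - 2] = "C"
        seq[end0 + 1] = "C"
        seq[end0 + 2] = "C"
        protected.update(range(start0 - 2, end0 + 3))
        if kind == "poly_t":
            truth["poly_t"] = {"start": start0 + 1, "length": len(payload)}
        elif kind == "hairpin":
            stem, loop = meta
            truth["stem_loops"].append({
                "arm5_start": start0 + 1, "arm5_end": start0 + stem,
                "arm3_start": start0 + stem + loop + 1,
                "arm3_end": end0 + 1, "mismatches": 0,
            })
        elif kind == "ta_run":
            truth["ta_runs"].append({"start": start0 + 1,
                                     "repeats": len(payload) // 2})
        elif kind == "gaat":
            truth["gaat"].append({"start": start0 + 1})
        pos = end0 + 3

    _scrub_control_region(rng, seq, truth, protected, cfg)
    return seq, truth


def _truth_matches(truth: dict, cfg: ControlRegionConfig):
    """Expected scanner output (local coords) from a truth record."""
    tracts = {(truth["poly_t"]["start"], truth["poly_t"]["length"])}
    loops = {(h["arm5_start"], h["arm5_end"], h["arm3_start"], h["arm3_end"])
             for h in truth["stem_loops"]}
    tas = {(t["start"], 2 * t["repeats"]) for t in truth["ta_runs"]}
    gaats = {g["start"] for g in truth["gaat"]}
    return tracts, loops, tas, gaats


def _scrub_control_region(
    rng: np.random.Generator, seq: list[str], truth: dict,
    protected: set[int], cfg: ControlRegionConfig, max_rounds: int = 200,
) -> None:
    """Mutate unprotected bases (in place) until poly tracts, (TA)n runs
    and GAAT occurrences are exactly the planted set.

    Replacement bases keep AT as AT wherever possible so the region's
    composition target is preserved.  Hairpins are deliberately NOT
    scrubbed: at realistic AT contents an A+T-rich region intrinsically
    contains many inverted repeats able to form qualifying stems (as real
    control regions do), and suppressing them all would require wholesale
    rewriting of the background.  Planted hairpins are instead guaranteed
    to be reported at their exact coordinates: their payloads are born
    free of competing structure, their CC flanks block outward extension
    and their loop edges block inward extension, so each planted hairpin
    is always a maximal candidate of the scan.
    """
    want_tracts, _want_loops, want_tas, want_gaats = _truth_matches(truth, cfg)

    def mutable(span0: Sequence[int]) -> Optional[int]:
        for p in span0:
            if p not in protected:
                return p
        return None

    for _ in range(max_rounds):
        s = "".join(seq)
        dirty = False
        for t in find_poly_tracts(s, cfg.poly_base, cfg.poly_min_len):
            if (t.start, t.length) in want_tracts:
                continue
            cur = "".join(seq[t.start - 1:t.end])
            if cur != cfg.poly_base * t.length:  # already broken this round
                dirty = True
                continue
            p = mutable(range(t.start - 1 + t.length // 2, t.end))
            p = p if p is not None else mutable(range(t.start - 1, t.end))
            if p is None:
                raise SpecError("cannot scrub a spurious poly tract")
            seq[p] = "A" if cfg.poly_base == "T" else "C"
            dirty = True
        for t in find_ta_runs(s, cfg.ta_min_repeats):
            if (t.start, t.length) in want_tas:
                continue
            cur = "".join(seq[t.start - 1:t.start - 1 + t.length])
            if cur != "TA" * (t.length // 2):  # already broken this round
                dirty = True
                continue
            p = mutable(range(t.start - 1, t.start - 1 + t.length))
            if p is None:
                raise SpecError("cannot scrub a spurious (TA)n run")
            # swapping the dinucleotide base kills the run, stays AT
            seq[p] = "A" if seq[p] == "T" else "T"
            dirty = True
        for hit in find_motifs(s, ["GAAT"])["GAAT"]:
            if hit.start in want_gaats:
                continue
            if "".join(seq[hit.start - 1:hit.start + 3]) != "GAAT":
                dirty = True
                continue
            p = mutable(range(hit.start - 1, hit.start + 3))
            if p is None:
                raise SpecError("cannot scrub a spurious GAAT")
            seq[p] = {"G": "A", "A": "T", "T": "A"}[seq[p]]
            dirty = True
        if not dirty:
            return
    raise SpecError("control region scrub did not converge")


# ---------------------------------------------------------------------------
# genome assembly

def _layout(spec: GenomeSpec) -> tuple[list[GeneFeature], int]:
    feats: list[GeneFeature] = []
    if len(spec.igns) != len(spec.templates):
        raise SpecError("igns must have one entry per feature (wrap first)")
    pos = 1
    prev_end = 0
    for i, t in enumerate(spec.templates):
        if t.length < 1:
            raise SpecError(f"{t.name}: non-positive length")
        start = 1 if i == 0 else prev_end + spec.igns[i] + 1
        if start < 1:
            raise SpecError(f"{t.name}: overlap longer than preceding span")
        end = start + t.length - 1
        feats.append(GeneFeature(
            name=t.name, feature_class=t.feature_class, start=start, end=end,
            strand=t.strand, start_codon=t.start_codon, stop_codon=t.stop_codon,
        ))
        prev_end = end
    genome_length = prev_end + spec.igns[0]
    if any(f.end > genome_length for f in feats):
        raise SpecError("features extend past the genome length implied by the wrap IGN")
    return feats, genome_length


def _coding_to_ref(f: GeneFeature, k: int) -> int:
    """0-based reference position of coding-sense position `k`."""
    return (f.start - 1 + k) if f.strand == "J" else (f.end - 1 - k)


def _write_coding(buf: list[str], f: GeneFeature, k: int, base: str) -> None:
    buf[_coding_to_ref(f, k)] = base if f.strand == "J" else complement_base(base)


def _read_coding(buf: list[str], f: GeneFeature, k: int) -> str:
    b = buf[_coding_to_ref(f, k)]
    return b if f.strand == "J" else complement_base(b)


def generate_mitogenome(spec: GenomeSpec,
                        code: GeneticCode = INVERTEBRATE_MITO
                        ) -> tuple[MitoGenome, dict]:
    """Build a circular annotated genome from a spec; returns the genome
    and a truth record (coordinates, per-gene coding sequences and
    proteins, control-region element positions, seed, spec hash).

    Construction guarantees: the annotation validates cleanly, every
    intergenic count matches the spec exactly, all protein-coding genes
    carry their requested initiator/terminator with no internal stop
    codons, and a control-region scan reports every planted element at
    its exact absolute coordinates (and no unplanted poly tracts, (TA)n
    runs or GAAT hits; see :class:`ControlRegionPlan` on background
    hairpins).
    """
    rng = np.random.default_rng(spec.seed)
    feats, G = _layout(spec)
    ann = AnnotationTable(feats, G, circular=True)
    at = dict(spec.at_targets)

    buf = _sample_bases(rng, G, at.get("intergenic", 0.70))
    cr_truth_local: dict = {}
    cr_feature: Optional[GeneFeature] = None

    # background fill per feature class (later features overwrite overlaps)
    for f in feats:
        if f.feature_class is FeatureClass.CONTROL_REGION:
            cr_seq, cr_truth_local = _build_control_region(
                rng, f.end - f.start + 1,
                at.get("control_region", 0.782), spec.cr_plan)
            if f.strand == "N":
                cr_seq = list(reverse_complement("".join(cr_seq)))
            buf[f.start - 1: f.end] = cr_seq
            cr_feature = f
        elif f.feature_class is not FeatureClass.PCG:
            buf[f.start - 1: f.end] = _sample_bases(
                rng, f.end - f.start + 1, at.get(f.feature_class.value, 0.70))

    # protein-coding genes: codon-wise bodies, then protected start/stop stamps
    pcgs = [f for f in feats if f.feature_class is FeatureClass.PCG]
    for f in pcgs:
        if (f.end - f.start + 1) % 3:
            raise SpecError(f"{f.name}: PCG length not divisible by 3")
        n_codons = (f.end - f.start + 1) // 3
        body = _sample_internal_codons(
            rng, n_codons - 2, at.get("PCG", 0.68), code, spec.codon_frequencies)
        for ci, codon in enumerate(body, start=1):
            for b_idx, b in enumerate(codon):
                _write_coding(buf, f, 3 * ci + b_idx, b)

    protected: dict[int, str] = {}
    if cr_feature is not None:
        for p in range(cr_feature.start - 1, cr_feature.end):
            protected[p] = buf[p]
    for f in pcgs:
        start = f.start_codon or "ATG"
        stop = f.stop_codon or "TAA"
        if start not in code.start_codons:
            raise SpecError(f"{f.name}: {start} is not a start codon of table "
                            f"{code.table_id}")
        if stop not in code.stop_codons:
            raise SpecError(f"{f.name}: {stop} is not a stop codon of table "
                            f"{code.table_id}")
        L = f.end - f.start + 1
        for k, b in enumerate(start):
            ref = _coding_to_ref(f, k)
            refb = b if f.strand == "J" else complement_base(b)
            if protected.get(ref, refb) != refb:
                raise SpecError(
                    f"{f.name}: start codon collides with a protected base at "
                    f"position {ref + 1}")
            protected[ref] = refb
            buf[ref] = refb
        for k, b in zip(range(L - 3, L), stop):
            ref = _coding_to_ref(f, k)
            refb = b if f.strand == "J" else complement_base(b)
            if protected.get(ref, refb) != refb:
                raise SpecError(
                    f"{f.name}: stop codon collides with a protected base at "
                    f"position {ref + 1}")
            protected[ref] = refb
            buf[ref] = refb

    # destroy internal stop codons (overlap-aware: iterate to a fixpoint)
    for _ in range(100):
        dirty = False
        for f in pcgs:
            n_codons = (f.end - f.start + 1) // 3
            for ci in range(1, n_codons - 1):
                codon = "".join(_read_coding(buf, f, 3 * ci + j) for j in range(3))
                if codon not in code.stop_codons:
                    continue
                fixes = ("C", "C", "T")  # per-position replacement breaking TAA/TAG
                for j in range(3):
                    ref = _coding_to_ref(f, 3 * ci + j)
                    if ref not in protected:
                        _write_coding(buf, f, 3 * ci + j, fixes[j])
                        dirty = True
                        break
                else:
                    raise SpecError(
                        f"{f.name}: internal stop at codon {ci} is fully "
                        "protected and cannot be repaired")
        if not dirty:
            break
    else:
        raise SpecError("internal-stop repair did not converge")

    sequence = "".join(buf)
    genome = MitoGenome(annotation=ann, sequence=sequence,
                        identifier=f"synthetic-{spec.seed}")

    truth: dict = {
        "seed": spec.seed,
        "spec_hash": spec.spec_hash(),
        "genome_length": G,
        "igns": list(spec.igns),
        "coordinates": {
            f.name: {"start": f.start, "end": f.end, "strand": f.strand,
                     "feature_class": f.feature_class.value}
            for f in feats
        },
        "pcgs": {},
        "at_targets": at,
    }
    from .phylogeny import translate_cds  # local import to avoid cycle
    for f in pcgs:
        cds = genome.feature_sequence(f)
        truth["pcgs"][f.name] = {
            "cds": cds,
            "protein": translate_cds(cds, code),
            "start_codon": f.start_codon or "ATG",
            "stop_codon": f.stop_codon or "TAA",
        }
    if cr_feature is not None:
        off = cr_feature.start - 1
        def _abs(d: dict, keys: Sequence[str]) -> dict:
            return {k: (v + off if k in keys else v) for k, v in d.items()}
        truth["control_region"] = {
            "start": cr_feature.start, "end": cr_feature.end,
            "poly_t": _abs(cr_truth_local["poly_t"], ("start",)),
            "stem_loops": [
                _abs(h, ("arm5_start", "arm5_end", "arm3_start", "arm3_end"))
                for h in cr_truth_local["stem_loops"]
            ],
            "ta_runs": [_abs(t, ("start",)) for t in cr_truth_local["ta_runs"]],
            "gaat": [_abs(g, ("start",)) for g in cr_truth_local["gaat"]],
        }
    return genome, truth


# ---------------------------------------------------------------------------
# protein evolution along a guide tree

#: published amino-acid lengths of the 13 PCGs (coordinate span / 3 - 1)
DEFAULT_GENE_LENGTHS = {
    "ND2": 345, "COI": 528, "COII": 231, "ATP8": 49, "ATP6": 225,
    "COIII": 262, "ND3": 117, "ND5": 582, "ND4": 454, "ND4L": 98,
    "ND6": 171, "CYTB": 379, "ND1": 327,
}

def _build_insect_guide_tree() -> str:
    """13-taxon ladder mirroring a basal-insect taxon sampling: two
    stoneflies plus a mayfly form the focal clade, a dragonfly is the
    outgroup, nine further orders ladder between them."""
    tree = "((stonefly_A:1.5,stonefly_B:1.5):1.0,mayfly:2.5)"
    for order in ("locust", "cockroach", "mantis", "stick_insect",
                  "gladiator", "webspinner", "moth", "sawfly", "aphid"):
        tree = f"({tree}:0.8,{order}:3)"
    return f"({tree}:0.8,dragonfly:4);"


INSECT_GUIDE_TREE = _build_insect_guide_tree()


@dataclass(frozen=True)
class EvolutionSpec:
    """Guide tree plus substitution process for the protein evolver."""

    guide_tree: str = INSECT_GUIDE_TREE
    gene_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    root_proteins: Optional[Mapping[str, str]] = None
    mu: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mu < 1):
            raise ParameterError("mu must be in [0, 1)")


def evolve_alignment(spec: EvolutionSpec
                     ) -> tuple[dict[str, ProteinAlignment], dendropy.Tree]:
    """Evolve root proteins down the guide tree; returns per-gene
    gap-free alignments (taxa = tree tips) and the truth tree."""
    tree = parse_newick(spec.guide_tree)
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if not tips:
        raise ParameterError("guide tree has no tips")
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_lengths)
    roots = {}
    for g in genes:
        L = spec.gene_lengths[g]
        if spec.root_proteins is not None:
            roots[g] = spec.root_proteins[g]
            if len(roots[g]) != L:
                raise SpecError(f"root protein for {g} has wrong length")
        else:
            roots[g] = "".join(rng.choice(list(AMINO_ACIDS), size=L))

    seqs: dict[int, dict[str, str]] = {id(tree.seed_node): roots}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        p_hit = 1.0 - (1.0 - spec.mu) ** t
        parent = seqs[id(node.parent_node)]
        mine: dict[str, str] = {}
        for g in genes:
            chars = list(parent[g])
            hits = np.flatnonzero(rng.random(len(chars)) < p_hit)
            for i in hits:
                others = AMINO_ACIDS.replace(chars[i], "")
                chars[i] = others[rng.integers(len(others))]
            mine[g] = "".join(chars)
        seqs[id(node)] = mine

    tip_nodes = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    out: dict[str, ProteinAlignment] = {}
    for g in genes:
        out[g] = ProteinAlignment(
            taxa=tuple(tips),
            rows=tuple(seqs[id(tip_nodes[t])][g] for t in tips),
            partitions=(Partition(g, 1, spec.gene_lengths[g]),),
        )
    return out, tree
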