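"""Concatenated protein-coding-gene phylogenetics.

The pipeline mirrors standard mitogenome practice: translate each of the
13 protein-coding genes, assemble a concatenated amino-acid supermatrix
(with a per-gene partition map), compute uncorrected p-distances, build
an unrooted neighbor-joining tree (Saitou & Nei agglomeration on the
Q-matrix), and attach nonparametric bootstrap supports by column
resampling.

Determinism: Q-matrix ties break on the lowest (i, j) index pair in the
current working order, so the tree is a pure function of the distance
matrix; bootstrap resampling is driven by a single integer seed and is
invariant to taxon input order (taxa are canonically sorted internally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import dendropy
import numpy as np

from .codon import INVERTEBRATE_MITO, STOP, GeneticCode
from ._util import normalize_codon
from .errors import (
    DistanceMatrixError, EmptyInputError, FrameError, NewickError,
    ParameterError,
)
from .model import PCG_ORDER

GAP = "-"


@dataclass(frozen=True)
class Partition:
    """A contiguous column block of the supermatrix (1-based inclusive)."""

    gene: str
    start: int
    end: int


@dataclass
class ProteinAlignment:
    """Equal-length amino-acid rows over an ordered taxon set."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    partitions: tuple[Partition, ...] = ()

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.rows = tuple(self.rows)
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if self.partitions:
            covered = sum(p.end - p.start + 1 for p in self.partitions)
            if covered != self.length:
                raise ValueError("partition lengths do not sum to alignment length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str],
                  partitions: Sequence[Partition] = ()) -> "ProteinAlignment":
        return cls(tuple(mapping), tuple(mapping.values()), tuple(partitions))

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def reordered(self, taxa: Sequence[str]) -> "ProteinAlignment":
        return ProteinAlignment(
            tuple(taxa), tuple(self.row(t) for t in taxa), self.partitions)

    def subsample_columns(self, indices: np.ndarray) -> "ProteinAlignment":
        rows = tuple("".join(r[i] for i in indices) for r in self.rows)
        return ProteinAlignment(self.taxa, rows)

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{r}\n" for t, r in zip(self.taxa, self.rows))

    @classmethod
    def from_fasta(cls, text: str) -> "ProteinAlignment":
        taxa, rows, cur = [], [], []
        name = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    rows.append("".join(cur))
                name = line[1:].split()[0]
                taxa.append(name)
                cur = []
            else:
                cur.append(line)
        if name is not None:
            rows.append("".join(cur))
        return cls(tuple(taxa), tuple(rows))

    def to_phylip(self) -> str:
        """Relaxed PHYLIP (names padded, single block)."""
        width = max((len(t) for t in self.taxa), default=0) + 2
        lines = [f" {len(self.taxa)} {self.length}"]
        lines += [f"{t:<{width}}{r}" for t, r in zip(self.taxa, self.rows)]
        return "\n".join(lines) + "\n"

    def partitions_tsv(self) -> str:
        lines = ["gene\tstart\tend"]
        lines += [f"{p.gene}\t{p.start}\t{p.end}" for p in self.partitions]
        return "\n".join(lines) + "\n"


def translate_cds(
    seq: str, code: GeneticCode = INVERTEBRATE_MITO,
    trim_terminal_stop: bool = True,
) -> str:
    """Per-codon translation of an in-frame CDS; the terminal stop codon
    is removed by default, internal stops are kept as '*' with a
    warning identifying the codon index."""
    seq = normalize_codon(seq)
    if len(seq) % 3:
        raise FrameError(f"CDS length {len(seq)} not divisible by 3")
    aas = [code.codon_to_aa[seq[k:k + 3]] for k in range(0, len(seq), 3)]
    if trim_terminal_stop and aas and aas[-1] == STOP:
        aas.pop()
    for idx, aa in enumerate(aas):
        if aa == STOP:
            warnings.warn(f"internal stop codon at codon index {idx}")
    return "".join(aas)


def concatenate_pcgs(
    per_gene: Mapping[str, ProteinAlignment],
    taxa: Optional[Sequence[str]] = None,
) -> ProteinAlignment:
    """Column-wise concatenation of per-gene alignments in the canonical
    mitogenome gene order (genes outside the canon are appended,
    sorted).  A taxon missing from one gene contributes an all-gap block
    there (with a warning)."""
    if not per_gene:
        raise EmptyInputError("no gene alignments supplied")
    genes = [g for g in PCG_ORDER if g in per_gene]
    genes += sorted(set(per_gene) - set(PCG_ORDER))
    if taxa is None:
        seen: list[str] = []
        for g in genes:
            for t in per_gene[g].taxa:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    parts: list[Partition] = []
    blocks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for g in genes:
        aln = per_gene[g]
        L = aln.length
        for t in taxa:
            if t in aln.taxa:
                blocks[t].append(aln.row(t))
            else:
                warnings.warn(f"taxon {t!r} missing from gene {g}; gap-filled")
                blocks[t].append(GAP * L)
        parts.append(Partition(g, pos, pos + L - 1))
        pos += L
    return ProteinAlignment(
        tuple(taxa), tuple("".join(blocks[t]) for t in taxa), tuple(parts))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise DistanceMatrixError("matrix shape does not match taxa")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise DistanceMatrixError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise DistanceMatrixError("diagonal must be zero")
        if np.any(self.values < 0):
            raise DistanceMatrixError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


def p_distance_matrix(aln: ProteinAlignment) -> DistanceMatrix:
    """Uncorrected p-distance: mismatches / compared columns over the
    columns where neither sequence has a gap.  A pair with no comparable
    columns is an error (missing distance)."""
    arr = np.frombuffer("".join(aln.rows).encode(), dtype="S1").reshape(
        len(aln.rows), aln.length).copy()
    gaps = arr == GAP.encode()
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            m = int(ok.sum())
            if m == 0:
                raise DistanceMatrixError(
                    f"no comparable columns between {aln.taxa[i]!r} and "
                    f"{aln.taxa[j]!r}")
            d[i, j] = d[j, i] = float((arr[i, ok] != arr[j, ok]).sum()) / m
    return DistanceMatrix(aln.taxa, d)


def neighbor_joining(
    dm: DistanceMatrix,
    taxon_namespace: Optional[dendropy.TaxonNamespace] = None,
) -> dendropy.Tree:
    """Classic Saitou-Nei neighbor joining.

    Returns an unrooted DendroPy tree (trifurcating seed node).  Negative
    branch lengths, which NJ can produce on non-additive input, are
    clamped to zero with the deficit moved to the sister edge; the number
    of clamped edges is recorded in the tree annotation
    ``clamped_branches``.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(list(dm.taxa))
    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        node = dendropy.Node(taxon=tns.require_taxon(label=t))
        nodes.append(node)
    D = dm.values.copy()
    active = list(range(n))
    clamped = 0

    def join(i_pos: int, j_pos: int) -> None:
        nonlocal D, clamped
        m = len(active)
        i, j = active[i_pos], active[j_pos]
        r = D[np.ix_(active, active)].sum(axis=1)
        dij = D[i, j]
        li = 0.5 * dij + (r[i_pos] - r[j_pos]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
            clamped += 1
        elif lj < 0:
            li += lj
            lj = 0.0
            clamped += 1
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances from the new node u to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for k_pos, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active.remove(i)
        active.remove(j)
        active.append(D.shape[0] - 1)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin == lowest (i, j) pair on ties
        flat = int(np.argmin(Q))
        i_pos, j_pos = divmod(flat, m)
        if i_pos > j_pos:
            i_pos, j_pos = j_pos, i_pos
        join(i_pos, j_pos)

    # resolve the final three nodes around an unrooted central vertex
    x, y, z = active
    lx = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    ly = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    lz = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    lengths = [lx, ly, lz]
    for idx in range(3):
        if lengths[idx] < 0:
            clamped += 1
            lengths[idx] = 0.0
    seed = dendropy.Node()
    for k, length in zip((x, y, z), lengths):
        seed.add_child(nodes[k])
        nodes[k].edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    tree.annotations.add_new("clamped_branches", clamped)
    return tree


def _bipartitions(tree: dendropy.Tree, ref: str) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions as frozensets of tip labels on the side
    not containing the reference taxon, mapped to their subtending node."""
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if 2 <= len(side) <= len(all_taxa) - 2:
            out[side] = node
    return out


class BootstrapResult(NamedTuple):
    tree: dendropy.Tree          # full-data NJ tree, supports on internal nodes
    consensus: dendropy.Tree     # 50% majority-rule consensus of replicates
    n_reps: int
    seed: int


def bootstrap_support(
    aln: ProteinAlignment, n_reps: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Nonparametric bootstrap of the NJ tree: resample alignment columns
    with replacement (same length), rebuild NJ per replicate, and report
    each internal edge's bipartition frequency (percent) on the
    full-data tree; a 50% majority-rule consensus is also returned.

    Supports are stored as internal node labels and in the node
    annotation ``support``.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    order = sorted(aln.taxa)  # canonical order: supports invariant to input order
    aln = aln.reordered(order)
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(list(order))
    full = neighbor_joining(p_distance_matrix(aln), taxon_namespace=tns)
    ref = order[0]
    keys = _bipartitions(full, ref)
    counts = {k: 0 for k in keys}
    replicates = dendropy.TreeList(taxon_namespace=tns)
    L = aln.length
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_aln = aln.subsample_columns(idx)
        rep_tree = neighbor_joining(p_distance_matrix(rep_aln), taxon_namespace=tns)
        replicates.append(rep_tree)
        rep_keys = _bipartitions(rep_tree, ref)
        for k in rep_keys:
            if k in counts:
                counts[k] += 1
    for k, node in keys.items():
        pct = 100.0 * counts[k] / n_reps
        node.label = f"{pct:g}"
        node.annotations.add_new("support", pct)
    consensus = replicates.consensus(min_freq=0.5)
    consensus.is_rooted = False
    return BootstrapResult(full, consensus, n_reps, seed)


def clade_support(tree: dendropy.Tree, clade: Iterable[str]) -> Optional[float]:
    """Bootstrap support (percent) of the edge splitting `clade` from the
    rest of the tree, or None when the tree has no such edge."""
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    target = frozenset(clade)
    for side, node in _bipartitions(tree, tips[0]).items():
        if side == target or side == frozenset(tips) - target:
            for ann in node.annotations:
                if ann.name == "support":
                    return float(ann.value)
            return float(node.label) if node.label else None
    return None


def write_newick(tree: dendropy.Tree) -> str:
    """Canonical single-line newick with branch lengths and internal node
    labels (supports)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def parse_newick(text: str,
                 taxon_namespace: Optional[dendropy.TaxonNamespace] = None
                 ) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed newick: {exc}") from exc
    tree.is_rooted = False
    return tree
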