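"""Phylogenomic matrix utilities.

OTU merging, gene filtering, supermatrix concatenation with partition records,
a parsimony-based per-site rate proxy, stepwise fast-site removal, chi-square
compositional site trimming, and a two-residue signature extractor.

Coordinates are 1-based inclusive throughout (partition files follow the
RAxML-style ``PROT, gene = start-end`` convention). All tie-breaks are by
ascending site index so every operation is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetrees import GeneTree

__all__ = [
    "AMINO_ACIDS",
    "GeneAlignment",
    "Partition",
    "Supermatrix",
    "MatrixError",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "merge_otus",
    "filter_genes_by_focal_count",
    "concatenate",
    "fitch_site_rates",
    "remove_fastest_sites",
    "chi2_total",
    "chi2_site_scores",
    "trim_heterogeneous_sites",
    "ef2_signature",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_MISSING = {"-", "X"}


class MatrixError(ValueError):
    """Invalid alignment/matrix operation."""


@dataclass
class GeneAlignment:
    """One gene: taxon -> aligned amino-acid row (equal lengths).

    Gap is ``'-'``; ``'X'`` is unknown-but-present (non-gap for occupancy, but
    excluded from all composition counts).
    """

    gene_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise MatrixError(f"gene {self.gene_id!r}: unequal row lengths {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def missing_count(self, taxon: str) -> int:
        row = self.rows[taxon]
        return sum(1 for c in row if c in _MISSING)

    def is_empty_row(self, taxon: str) -> bool:
        return all(c == "-" for c in self.rows[taxon])


@dataclass(frozen=True)
class Partition:
    gene_id: str
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    """Concatenated alignment with per-gene partition coordinates."""

    rows: dict[str, str]
    partitions: list[Partition] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def slice_partition(self, gene_id: str, drop_empty: bool = True) -> GeneAlignment:
        """Extract one gene back out of the supermatrix.

        With ``drop_empty`` taxa whose block is all-gap (i.e. absent from the
        original gene) are omitted, so concatenate -> slice round-trips.
        """
        part = next((p for p in self.partitions if p.gene_id == gene_id), None)
        if part is None:
            raise MatrixError(f"no partition {gene_id!r}")
        rows = {}
        for taxon, row in self.rows.items():
            block = row[part.start - 1 : part.end]
            if drop_empty and all(c == "-" for c in block):
                continue
            rows[taxon] = block
        return GeneAlignment(gene_id=gene_id, rows=rows)

    def keep_sites(self, keep: Sequence[int]) -> "Supermatrix":
        """New matrix restricted to the 0-based site indices in ``keep``
        (ascending); partitions are re-spanned and empty ones dropped."""
        keep = sorted(keep)
        rows = {t: "".join(r[i] for i in keep) for t, r in self.rows.items()}
        parts: list[Partition] = []
        pos = 0
        for part in self.partitions:
            n = sum(1 for i in keep if part.start - 1 <= i <= part.end - 1)
            if n > 0:
                parts.append(Partition(part.gene_id, pos + 1, pos + n))
                pos += n
        return Supermatrix(rows=rows, partitions=parts)

    def partition_lines(self) -> str:
        return "".join(
            f"PROT, {p.gene_id} = {p.start}-{p.end}\n" for p in self.partitions
        )


# -- FASTA I/O -------------------------------------------------------------


def read_fasta_alignment(path: str | Path, gene_id: Optional[str] = None) -> GeneAlignment:
    path = Path(path)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise MatrixError(f"{path}: duplicate taxon {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise MatrixError(f"{path}: empty FASTA")
    return GeneAlignment(gene_id=gene_id or path.stem, rows=rows)


def write_fasta_alignment(aln: GeneAlignment | Supermatrix, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in aln.rows.items()
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


# -- OTU merging & gene filtering -----------------------------------------


def merge_otus(
    genes: Sequence[GeneAlignment], otus: dict[str, Sequence[str]]
) -> list[GeneAlignment]:
    """Collapse members of each OTU to a single row per gene.

    Per gene the OTU's row is the member row with the fewest gap+X characters
    (ties broken by member order in the OTU definition); the OTU is absent
    from a gene only when all members are absent. Merging therefore never
    decreases occupancy relative to the best member.
    """
    members_of: dict[str, str] = {}
    for otu_id, members in otus.items():
        for m in members:
            members_of[m] = otu_id
    out: list[GeneAlignment] = []
    for gene in genes:
        for otu_id in otus:
            if otu_id in gene.rows and otu_id not in otus.get(otu_id, ()):
                raise MatrixError(
                    f"otu id {otu_id!r} collides with existing taxon in gene "
                    f"{gene.gene_id!r}"
                )
        rows: dict[str, str] = {}
        for taxon, row in gene.rows.items():
            if taxon not in members_of:
                rows[taxon] = row
        for otu_id, members in otus.items():
            present = [m for m in members if m in gene.rows]
            if not present:
                continue
            best = min(present, key=lambda m: (gene.missing_count(m), members.index(m)))
            rows[otu_id] = gene.rows[best]
        out.append(GeneAlignment(gene_id=gene.gene_id, rows=rows))
    return out


def filter_genes_by_focal_count(
    genes: Sequence[GeneAlignment], tmap, focal: str, min_seqs: int
) -> list[GeneAlignment]:
    """Keep genes with at least ``min_seqs`` non-empty focal-taxon rows."""
    if min_seqs < 0:
        raise MatrixError("min_seqs must be >= 0")
    kept = []
    for gene in genes:
        n = 0
        for taxon in gene.rows:
            rec = tmap.resolve_leaf(taxon, strict=False)
            if rec.focal and not gene.is_empty_row(taxon):
                n += 1
        if n >= min_seqs:
            kept.append(gene)
    return kept


# -- concatenation ---------------------------------------------------------


def concatenate(
    genes: Sequence[GeneAlignment], taxa: Optional[Sequence[str]] = None
) -> Supermatrix:
    """Concatenate gene alignments into a supermatrix.

    Missing taxon-by-gene blocks are filled with gaps; partitions are recorded
    in input gene order with 1-based inclusive coordinates.
    """
    if not genes:
        raise MatrixError("no genes to concatenate")
    seen: set[str] = set()
    for gene in genes:
        if gene.gene_id in seen:
            raise MatrixError(f"duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
    if taxa is None:
        taxa = []
        for gene in genes:
            for t in gene.rows:
                if t not in taxa:
                    taxa.append(t)
    parts: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for gene in genes:
        L = gene.length
        parts.append(Partition(gene.gene_id, pos + 1, pos + L))
        pos += L
        for t in taxa:
            chunks[t].append(gene.rows.get(t, "-" * L))
    return Supermatrix(rows={t: "".join(c) for t, c in chunks.items()}, partitions=parts)


# -- per-site rates (parsimony proxy) -------------------------------------


def fitch_site_rates(
    matrix: Supermatrix, guide_tree: GeneTree, strict: bool = True
) -> np.ndarray:
    """Per-site Fitch parsimony step counts on the guide topology.

    Gap and X characters contribute no state (a leaf with missing data places
    no constraint); columns with at most one observed state score 0.
    """
    tree_taxa = set(guide_tree.leaves)
    missing = tree_taxa - set(matrix.rows)
    if missing and strict:
        raise MatrixError(f"guide tree taxa absent from matrix: {sorted(missing)}")
    # root at an arbitrary leaf so every internal node combines its children
    # sequentially (exact Fitch on binary trees); step counts are invariant to
    # the rooting
    root = next(n for n in guide_tree.nodes() if guide_tree.is_leaf(n))
    postorder: list[tuple[int, int]] = []  # (parent, node)
    stack = [(root, root)]
    while stack:
        parent, node = stack.pop()
        postorder.append((parent, node))
        for nb in guide_tree.neighbors(node):
            if nb != parent:
                stack.append((node, nb))
    postorder.reverse()

    def leaf_state(lbl: str, site: int) -> Optional[frozenset]:
        row = matrix.rows.get(lbl)
        if row is None:
            return None
        c = row[site]
        return None if c in _MISSING else frozenset((c,))

    L = matrix.length
    rates = np.zeros(L, dtype=float)
    for site in range(L):
        states: dict[int, Optional[frozenset]] = {}
        steps = 0

        def combine(sets: list[frozenset]) -> Optional[frozenset]:
            nonlocal steps
            acc: Optional[frozenset] = None
            for s in sets:
                if acc is None:
                    acc = s
                    continue
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    steps += 1
            return acc

        for parent, node in postorder:
            lbl = guide_tree.label(node)
            if lbl is not None and node != root:
                states[node] = leaf_state(lbl, site)
            else:
                kid_sets = [
                    states[nb]
                    for nb in guide_tree.neighbors(node)
                    if nb != parent and states.get(nb) is not None
                ]
                if node == root and guide_tree.label(node) is not None:
                    own = leaf_state(guide_tree.label(node), site)
                    if own is not None:
                        kid_sets.append(own)
                states[node] = combine(kid_sets) if kid_sets else None
        rates[site] = steps
    return rates


def read_site_rates(path: str | Path, length: Optional[int] = None) -> np.ndarray:
    """Read a whitespace-delimited rate table with columns ``site`` (1-based)
    and ``rate``; '#'-prefixed lines and a ``site rate`` header are skipped."""
    path = Path(path)
    pairs: list[tuple[int, float]] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0].lower() == "site":
            continue
        pairs.append((int(fields[0]), float(fields[1])))
    if not pairs:
        raise MatrixError(f"{path}: empty rate table")
    n = length if length is not None else max(s for s, _ in pairs)
    rates = np.zeros(n, dtype=float)
    for site, rate in pairs:
        if not (1 <= site <= n):
            raise MatrixError(f"{path}: site {site} out of range 1..{n}")
        rates[site - 1] = rate
    return rates


def write_site_rates(rates: np.ndarray, path: str | Path) -> None:
    lines = ["site\trate"] + [f"{i + 1}\t{r:g}" for i, r in enumerate(rates)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# -- fast-site removal -----------------------------------------------------


def rate_order(rates: np.ndarray) -> np.ndarray:
    """Site indices sorted by rate descending, ties by index ascending."""
    # stable sort on negated rates preserves index order within ties
    return np.argsort(-np.asarray(rates, dtype=float), kind="stable")


def remove_fastest_sites(
    matrix: Supermatrix,
    rates: np.ndarray,
    step: int = 5000,
    max_removed: int = 55000,
) -> list[Supermatrix]:
    """Iteratively remove the fastest-evolving sites.

    The k-th output matrix (k = 1..floor(max_removed/step)) has the top
    ``k*step`` sites by rate removed, so the removed-site sets are nested.
    """
    rates = np.asarray(rates, dtype=float)
    if len(rates) != matrix.length:
        raise MatrixError(
            f"rates length {len(rates)} != matrix length {matrix.length}"
        )
    if step < 1:
        raise MatrixError("step must be >= 1")
    if max_removed < step:
        raise MatrixError("max_removed must be >= step")
    if max_removed >= matrix.length:
        raise MatrixError(
            f"max_removed {max_removed} would empty the {matrix.length}-site matrix"
        )
    order = rate_order(rates)
    out: list[Supermatrix] = []
    for k in range(1, max_removed // step + 1):
        removed = set(order[: k * step].tolist())
        keep = [i for i in range(matrix.length) if i not in removed]
        out.append(matrix.keep_sites(keep))
    return out


# -- chi-square compositional trimming ------------------------------------


def _composition_counts(rows: Iterable[str]) -> np.ndarray:
    counts = np.zeros((0, 20))
    mat = []
    for row in rows:
        c = np.zeros(20)
        for ch in row:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                c[idx] += 1
        mat.append(c)
    return np.vstack(mat) if mat else counts


def _chi2_from_counts(counts: np.ndarray) -> float:
    """Total compositional heterogeneity from a taxa x states count matrix."""
    n_t = counts.sum(axis=1)  # per-taxon non-missing length
    total = counts.sum()
    if total == 0:
        raise MatrixError("all-gap matrix")
    f_s = counts.sum(axis=0) / total  # matrix-wide state frequencies
    expected = np.outer(n_t, f_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def chi2_total(matrix: Supermatrix) -> float:
    """Total compositional chi-square over taxa and residue states (gaps and
    X excluded from all counts)."""
    return _chi2_from_counts(_composition_counts(matrix.rows.values()))


def chi2_site_scores(matrix: Supermatrix) -> np.ndarray:
    """Per-site heterogeneity scores.

    score(i) = X2(full matrix) - X2(matrix without site i): the reduction in
    total compositional chi-square achieved by removing the site alone. Sites
    that drive heterogeneity score high (positive); homogenising sites score
    negative. Computed incrementally from the global count matrix.
    """
    taxa = matrix.taxa
    if len(taxa) < 2 or matrix.length < 2:
        raise MatrixError("need >= 2 taxa and >= 2 sites")
    counts = _composition_counts(matrix.rows.values())
    full = _chi2_from_counts(counts)
    L = matrix.length
    scores = np.zeros(L)
    # per-site one-hot contribution of every taxon
    for site in range(L):
        col = counts.copy()
        for ti, taxon in enumerate(taxa):
            idx = _AA_INDEX.get(matrix.rows[taxon][site])
            if idx is not None:
                col[ti, idx] -= 1
        scores[site] = full - _chi2_from_counts(col)
    return scores


def trim_heterogeneous_sites(matrix: Supermatrix, fraction: float) -> Supermatrix:
    """Remove the ceil(fraction * L) highest-scoring sites (ties broken by
    ascending site index)."""
    if not (0.0 < fraction < 1.0):
        raise MatrixError("fraction must be in (0, 1)")
    L = matrix.length
    n_remove = math.ceil(fraction * L)
    if n_remove >= L:
        raise MatrixError("trimming would empty the matrix")
    scores = chi2_site_scores(matrix)
    order = np.argsort(-scores, kind="stable")
    removed = set(order[:n_remove].tolist())
    return matrix.keep_sites([i for i in range(L) if i not in removed])


# -- two-residue signature --------------------------------------------------

SIGNATURE_DERIVED = ("S", "A")
SIGNATURE_ANCESTRAL = ("G", "S")


def ef2_signature(
    gene: GeneAlignment,
    positions: tuple[int, int],
    derived: tuple[str, str] = SIGNATURE_DERIVED,
    ancestral: tuple[str, str] = SIGNATURE_ANCESTRAL,
) -> dict[str, str]:
    """Classify each taxon by the residue pair at two 1-based columns.

    Returns per taxon one of ``derived`` (the SA replacement), ``ancestral``
    (GS), ``other`` (any other non-missing pair) or ``missing`` (gap/X at
    either position).
    """
    p1, p2 = positions
    L = gene.length
    if not (1 <= p1 <= L and 1 <= p2 <= L):
        raise MatrixError(f"positions {positions} out of range 1..{L}")
    out: dict[str, str] = {}
    for taxon, row in gene.rows.items():
        pair = (row[p1 - 1], row[p2 - 1])
        if pair[0] in _MISSING or pair[1] in _MISSING:
            out[taxon] = "missing"
        elif pair == tuple(derived):
            out[taxon] = "derived"
        elif pair == tuple(ancestral):
            out[taxon] = "ancestral"
        else:
            out[taxon] = "other"
    return out
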