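"""Single-cell assembly QC rules.

Three pure-rule procedures: flagging putatively contaminant contigs from
per-protein classifications, single-linkage clustering of ribotypes for
co-assembly grouping, and marker-completeness summaries including the union
(meta-assembly) completeness.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "QCError",
    "ContigReport",
    "PresenceMatrix",
    "CompletenessReport",
    "flag_contaminant_contigs",
    "cluster_ribotypes",
    "completeness_summary",
]

CATEGORIES = frozenset({"prokaryotic_viral_only", "other", "no_hit"})
CONTAMINATION_FRACTION = 0.60


class QCError(ValueError):
    """Malformed QC input."""


@dataclass(frozen=True)
class ContigReport:
    contig_id: str
    n_proteins: int
    n_prok_viral_only: int
    flagged: bool
    note: str = ""


def flag_contaminant_contigs(
    assignments: Iterable[tuple[str, str, str]],
    contigs: Optional[Iterable[str]] = None,
    min_fraction: float = CONTAMINATION_FRACTION,
) -> list[ContigReport]:
    """Flag contigs whose proteins hit only prokaryotic/viral references.

    ``assignments`` yields ``(contig_id, protein_id, category)`` rows with
    category one of ``prokaryotic_viral_only``, ``other``, ``no_hit``. A
    contig is flagged iff it has at least one protein and the fraction of
    prokaryotic/viral-only proteins among all its proteins is >= 60%
    (inclusive). Proteins with no hits stay in the denominator. Contigs listed
    in ``contigs`` but absent from the assignments (or rows with an empty
    protein id) are reported unflagged with a zero-protein note. Output order
    is by contig id, independent of row order.
    """
    totals: dict[str, int] = {}
    prok: dict[str, int] = {}
    for contig_id, protein_id, category in assignments:
        totals.setdefault(contig_id, 0)
        prok.setdefault(contig_id, 0)
        if not protein_id:
            continue
        if category not in CATEGORIES:
            raise QCError(
                f"contig {contig_id!r} protein {protein_id!r}: malformed "
                f"category {category!r}"
            )
        totals[contig_id] += 1
        if category == "prokaryotic_viral_only":
            prok[contig_id] += 1
    for c in contigs or ():
        totals.setdefault(c, 0)
        prok.setdefault(c, 0)
    reports = []
    for contig_id in sorted(totals):
        n, k = totals[contig_id], prok[contig_id]
        if n == 0:
            reports.append(
                ContigReport(contig_id, 0, 0, flagged=False, note="zero_proteins")
            )
        else:
            reports.append(
                ContigReport(contig_id, n, k, flagged=(k / n >= min_fraction))
            )
    return reports


def cluster_ribotypes(
    identities: Iterable[tuple[str, str, float]], threshold: float = 99.0
) -> list[list[str]]:
    """Single-linkage clusters over pairs with identity strictly above the
    threshold (percent scale).

    The pair table is symmetrised on load and self-pairs are ignored; every id
    seen in the table appears in the output, singletons as their own cluster.
    Clusters are ordered by their smallest member id, members sorted.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b, ident in identities:
        ident = float(ident)
        if not (0.0 <= ident <= 100.0):
            raise QCError(f"identity {ident} for pair ({a!r}, {b!r}) outside [0, 100]")
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        if a == b:
            continue
        if ident > threshold:
            union(a, b)
    groups: dict[str, list[str]] = {}
    for x in parent:
        groups.setdefault(find(x), []).append(x)
    return [sorted(members) for _, members in sorted(groups.items())]


class PresenceMatrix:
    """Boolean markers-by-assemblies presence matrix."""

    def __init__(
        self,
        markers: Sequence[str],
        assemblies: Sequence[str],
        data: np.ndarray,
        name: str = "markers",
    ):
        if len(set(markers)) != len(markers):
            raise QCError("duplicate marker ids")
        if len(set(assemblies)) != len(assemblies):
            raise QCError("duplicate assembly ids")
        data = np.asarray(data, dtype=bool)
        if data.shape != (len(markers), len(assemblies)):
            raise QCError(
                f"data shape {data.shape} != ({len(markers)}, {len(assemblies)})"
            )
        self.markers = list(markers)
        self.assemblies = list(assemblies)
        self.data = data
        self.name = name

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "markers") -> "PresenceMatrix":
        path = Path(path)
        with path.open(newline="", encoding="utf-8") as fh:
            rows = list(
                csv.reader(
                    (l for l in fh if not l.startswith("#")), delimiter="\t"
                )
            )
        if not rows:
            raise QCError(f"{path}: empty presence matrix")
        assemblies = [c.strip() for c in rows[0][1:]]
        markers, values = [], []
        for row in rows[1:]:
            if not row or not row[0].strip():
                continue
            markers.append(row[0].strip())
            values.append([cell.strip() in ("1", "true", "True") for cell in row[1:]])
        return cls(markers, assemblies, np.array(values, dtype=bool), name=name)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["marker\t" + "\t".join(self.assemblies)]
        for i, m in enumerate(self.markers):
            lines.append(m + "\t" + "\t".join("1" if v else "0" for v in self.data[i]))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class CompletenessReport:
    per_assembly: dict[str, float]
    union: float
    marker_counts: dict[str, int]
    excluded: list[str] = field(default_factory=list)
    min_markers_keep: int = 5


def completeness_summary(
    presence: PresenceMatrix, min_markers_keep: int = 5
) -> CompletenessReport:
    """Per-assembly and union marker completeness.

    Per-assembly completeness is the fraction of markers present; union
    completeness is the fraction present in at least one assembly. Assemblies
    with strictly fewer than ``min_markers_keep`` markers are listed as
    excluded.
    """
    if presence.data.size == 0:
        raise QCError("empty presence matrix")
    n_markers = len(presence.markers)
    counts = presence.data.sum(axis=0)
    per_assembly = {
        a: counts[j] / n_markers for j, a in enumerate(presence.assemblies)
    }
    union = presence.data.any(axis=1).sum() / n_markers
    excluded = [
        a for j, a in enumerate(presence.assemblies) if counts[j] < min_markers_keep
    ]
    return CompletenessReport(
        per_assembly=per_assembly,
        union=float(union),
        marker_counts={
            a: int(counts[j]) for j, a in enumerate(presence.assemblies)
        },
        excluded=excluded,
        min_markers_keep=min_markers_keep,
    )


# -- TSV plumbing for the CLI ----------------------------------------------


def read_assignments(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a contig/protein/category TSV (header required)."""
    path = Path(path)
    out: list[tuple[str, str, str]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        rows = csv.reader((l for l in fh if not l.startswith("#")), delimiter="\t")
        header = next(rows, None)
        if header is None:
            raise QCError(f"{path}: empty assignment table")
        for row in rows:
            if not row or all(not c.strip() for c in row):
                continue
            contig, protein, category = (row + ["", "", ""])[:3]
            out.append((contig.strip(), protein.strip(), category.strip()))
    return out


def read_identities(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a pairwise identity TSV with columns a, b, percent_identity."""
    path = Path(path)
    out: list[tuple[str, str, float]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        rows = csv.reader((l for l in fh if not l.startswith("#")), delimiter="\t")
        header = next(rows, None)
        if header is None:
            raise QCError(f"{path}: empty identity table")
        for row in rows:
            if not row or all(not c.strip() for c in row):
                continue
            a, b, ident = row[0].strip(), row[1].strip(), float(row[2])
            out.append((a, b, ident))
    return out
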