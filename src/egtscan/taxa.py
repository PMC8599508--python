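"""Taxon annotation tables: plastid-ancestry groups, focal flags, assemblies.

Every leaf of every gene tree is resolved through a :class:`TaxonMap`, which
assigns the taxon to one of six plastid-ancestry groups and records whether it
is a focal single-cell taxon (and if so, which assembly it came from). The map
is the semantic ground for all downstream classification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "GROUPS",
    "PLASTID_GROUPS",
    "TaxonRecord",
    "TaxonMap",
    "TaxonTableError",
    "load_taxon_map",
]

#: The six admissible plastid-ancestry group labels.
GROUPS = frozenset(
    {
        "cyanobacteria",
        "other_bacteria",
        "plastid_photosynthetic",
        "plastid_nonphotosynthetic",
        "plastid_lacking",
        "unknown",
    }
)

#: Groups counted as having plastid ancestry.
PLASTID_GROUPS = frozenset({"plastid_photosynthetic", "plastid_nonphotosynthetic"})


class TaxonTableError(ValueError):
    """Malformed taxon table or failed leaf resolution."""


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon: its group, focal status and (optional) assembly."""

    taxon_id: str
    group: str
    focal: bool = False
    assembly_id: Optional[str] = None
    higher_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TaxonTableError(
                f"unknown group label {self.group!r} for taxon {self.taxon_id!r}; "
                f"expected one of {sorted(GROUPS)}"
            )

    @property
    def has_plastid_ancestry(self) -> bool:
        return self.group in PLASTID_GROUPS


class TaxonMap:
    """Collection of :class:`TaxonRecord` keyed by taxon id.

    Parameters
    ----------
    records:
        Iterable of records; duplicate taxon ids raise.
    leaf_delimiter:
        Single character separating the taxon id from the per-tree sequence id
        in leaf labels (``"Taxon@seq1"`` with the default ``"@"``).
    """

    def __init__(self, records: Iterable[TaxonRecord], leaf_delimiter: str = "@"):
        if len(leaf_delimiter) != 1:
            raise TaxonTableError("leaf_delimiter must be a single character")
        self.leaf_delimiter = leaf_delimiter
        self._records: dict[str, TaxonRecord] = {}
        for rec in records:
            if rec.taxon_id in self._records:
                raise TaxonTableError(f"duplicate taxon_id {rec.taxon_id!r}")
            self._records[rec.taxon_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self._records.values())

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._records

    def get(self, taxon_id: str) -> Optional[TaxonRecord]:
        return self._records.get(taxon_id)

    def resolve_leaf(self, leaf_label: str, strict: bool = True) -> TaxonRecord:
        """Resolve a tree leaf label to its taxon record.

        The taxon id is the prefix of the label up to the first occurrence of
        the leaf delimiter; resolution is therefore independent of the
        sequence-id suffix. In lenient mode an unmapped taxon yields a
        synthetic record with group ``unknown``.
        """
        taxon_id = leaf_label.split(self.leaf_delimiter, 1)[0]
        rec = self._records.get(taxon_id)
        if rec is None:
            if strict:
                raise TaxonTableError(
                    f"leaf {leaf_label!r}: taxon {taxon_id!r} not in taxon map"
                )
            return TaxonRecord(taxon_id=taxon_id, group="unknown")
        return rec

    def focal_records(self) -> list[TaxonRecord]:
        return [r for r in self._records.values() if r.focal]

    def focal_assembly_ids(self) -> set[str]:
        return {r.assembly_id for r in self.focal_records() if r.assembly_id}

    @property
    def is_multi_assembly(self) -> bool:
        """True when the focal taxa span more than one distinct assembly."""
        return len(self.focal_assembly_ids()) > 1


_REQUIRED_COLUMNS = ("taxon_id", "group", "focal", "assembly_id", "higher_group")
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(value: str, row_num: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise TaxonTableError(f"row {row_num}: cannot parse focal flag {value!r}")


def load_taxon_map(path: str | Path, leaf_delimiter: str = "@") -> TaxonMap:
    """Load a taxon map from a TSV file.

    The file must have a header with columns ``taxon_id``, ``group``,
    ``focal``, ``assembly_id``, ``higher_group`` (the last two may be empty).
    Lines starting with ``#`` are skipped.
    """
    path = Path(path)
    records: list[TaxonRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        rows = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        try:
            header = next(rows)
        except StopIteration:
            raise TaxonTableError(f"{path}: empty taxon table") from None
        header = [h.strip() for h in header]
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise TaxonTableError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in _REQUIRED_COLUMNS}
        for row_num, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            group = row[idx["group"]].strip()
            if group not in GROUPS:
                raise TaxonTableError(
                    f"{path}: row {row_num}: unknown group label {group!r}"
                )
            records.append(
                TaxonRecord(
                    taxon_id=row[idx["taxon_id"]].strip(),
                    group=group,
                    focal=_parse_bool(row[idx["focal"]], row_num),
                    assembly_id=row[idx["assembly_id"]].strip() or None,
                    higher_group=row[idx["higher_group"]].strip() or None,
                )
            )
    return TaxonMap(records, leaf_delimiter=leaf_delimiter)


def write_taxon_map(tmap: TaxonMap, path: str | Path) -> None:
    """Serialise a taxon map back to the TSV dialect read by `load_taxon_map`."""
    path = Path(path)
    lines = ["\t".join(_REQUIRED_COLUMNS)]
    for rec in tmap:
        lines.append(
            "\t".join(
                [
                    rec.taxon_id,
                    rec.group,
                    "true" if rec.focal else "false",
                    rec.assembly_id or "",
                    rec.higher_group or "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
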