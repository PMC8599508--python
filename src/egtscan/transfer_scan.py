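"""Sister-clade sorting of gene trees into EGT and HGT events.

An EGT configuration is a clade of plastid-ancestry eukaryotes containing the
focal taxa that sits sister to a clade made exclusively of cyanobacteria; an
HGT configuration is a focal clade sister to a clade made exclusively of
non-cyanobacterial bacteria. A bounded fraction of sequences with no plastid
ancestry is tolerated on the eukaryote side. Each gene tree contributes at
most one event per mode, and the EGT:HGT ratio summarises the balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genetrees import GeneTree, SubtreePair
from .taxa import TaxonMap, TaxonRecord

__all__ = [
    "ScanConfig",
    "TransferEvent",
    "PairDecision",
    "TreeScan",
    "ScanResult",
    "TransferSummary",
    "cluster_eligible_egt",
    "cluster_eligible_hgt",
    "classify_egt_pair",
    "classify_hgt_pair",
    "scan_trees",
    "egt_hgt_ratio",
]

EGT = "EGT"
HGT = "HGT"


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the sorting rules.

    ``contamination_max`` bounds the fraction of no-plastid-ancestry sequences
    tolerated on the eukaryote side (inclusive by default); ``min_cyano`` /
    ``min_bacteria`` are the minimum donor-clade sizes; ``min_focal_assemblies``
    applies only when the focal taxa span multiple assemblies;
    ``higher_group`` names the larger taxonomic group whose members may join a
    focal clade in HGT mode without counting as contamination.
    """

    contamination_max: float = 0.10
    min_cyano: int = 2
    min_focal_assemblies: int = 2
    min_bacteria: int = 2
    min_other_plastid: int = 1
    higher_group: Optional[str] = None
    contamination_inclusive: bool = True
    require_donor_purity: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_max <= 1.0):
            raise ValueError("contamination_max must be in [0, 1]")
        for name in ("min_cyano", "min_focal_assemblies", "min_bacteria",
                     "min_other_plastid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def contamination_ok(self, fraction: float) -> bool:
        if self.contamination_inclusive:
            return fraction <= self.contamination_max + 1e-12
        return fraction < self.contamination_max


@dataclass(frozen=True)
class TransferEvent:
    """One accepted EGT or HGT configuration."""

    tree_id: str
    kind: str  # EGT | HGT
    focal_species: str
    focal_assemblies: frozenset
    euk_side: frozenset
    donor_side: frozenset
    contamination: float


@dataclass(frozen=True)
class PairDecision:
    """Outcome of classifying a single sister pair."""

    event: Optional[TransferEvent]
    reject_reason: Optional[str]

    @property
    def accepted(self) -> bool:
        return self.event is not None


def _profile(
    leaves: Iterable[str], tmap: TaxonMap, strict: bool = False
) -> list[tuple[str, TaxonRecord]]:
    return [(lf, tmap.resolve_leaf(lf, strict=strict)) for lf in sorted(leaves)]


def cluster_eligible_egt(leaves: Iterable[str], tmap: TaxonMap, focal: str) -> bool:
    """Eligibility for the EGT scan: the cluster must contain at least one
    focal sequence, one cyanobacterial sequence, and one photosynthetic
    plastid-bearing (archaeplastid-type) sequence."""
    has_focal = has_cyano = has_photo = False
    for _, rec in _profile(leaves, tmap):
        if rec.focal:
            has_focal = True
        elif rec.group == "cyanobacteria":
            has_cyano = True
        elif rec.group == "plastid_photosynthetic":
            has_photo = True
    return has_focal and has_cyano and has_photo


def cluster_eligible_hgt(leaves: Iterable[str], tmap: TaxonMap, focal: str) -> bool:
    """Eligibility for the HGT scan: at least one focal sequence and at least
    one non-cyanobacterial bacterium."""
    has_focal = has_bact = False
    for _, rec in _profile(leaves, tmap):
        if rec.focal:
            has_focal = True
        elif rec.group == "other_bacteria":
            has_bact = True
    return has_focal and has_bact


def _donor_check(
    profile: Sequence[tuple[str, TaxonRecord]],
    donor_group: str,
    min_size: int,
    cfg: ScanConfig,
) -> Optional[str]:
    """Return a reject reason for the donor side, or None if it passes."""
    impure = "cyano_impure" if donor_group == "cyanobacteria" else "donor_impure"
    too_small = "cyano_too_small" if donor_group == "cyanobacteria" else "donor_too_small"
    n_donor = sum(1 for _, rec in profile if rec.group == donor_group)
    if cfg.require_donor_purity and n_donor != len(profile):
        return impure
    if n_donor < min_size:
        return too_small
    return None


def _euk_side_egt(
    profile: Sequence[tuple[str, TaxonRecord]],
    tree: Optional[GeneTree],
    tmap: TaxonMap,
    cfg: ScanConfig,
) -> tuple[Optional[str], frozenset, float]:
    """Check the eukaryote side of an EGT candidate.

    Returns ``(reject_reason_or_None, focal_assemblies, contamination)``.
    Contamination is the count of non-focal sequences with no plastid ancestry
    divided by the total number of sequences on the side; focal sequences are
    exempt from the numerator.
    """
    focal_leaves = [lf for lf, rec in profile if rec.focal]
    if not focal_leaves:
        return "no_focal", frozenset(), 0.0
    n_other_plastid = sum(
        1 for _, rec in profile if not rec.focal and rec.has_plastid_ancestry
    )
    n_contam = sum(
        1 for _, rec in profile if not rec.focal and not rec.has_plastid_ancestry
    )
    contamination = n_contam / len(profile)
    if n_other_plastid < cfg.min_other_plastid:
        return "no_other_plastid", frozenset(), contamination
    if not cfg.contamination_ok(contamination):
        return "contamination", frozenset(), contamination
    assemblies = frozenset(
        rec.assembly_id
        for lf, rec in profile
        if rec.focal and rec.assembly_id is not None
    )
    if tmap.is_multi_assembly:
        if len(assemblies) < cfg.min_focal_assemblies:
            return "assemblies", assemblies, contamination
        if tree is not None and not tree.is_clade(focal_leaves):
            return "not_monophyletic", assemblies, contamination
    return None, assemblies, contamination


def _best_reason(reasons: list[str]) -> str:
    """Prefer the most informative reason over the generic 'no_focal'."""
    for r in reasons:
        if r != "no_focal":
            return r
    return reasons[0] if reasons else "no_focal"


def classify_egt_pair(
    pair: SubtreePair,
    tmap: TaxonMap,
    focal: str,
    cfg: ScanConfig,
    tree: Optional[GeneTree] = None,
    tree_id: str = "tree",
) -> PairDecision:
    """Classify one sister pair as an EGT event or reject it.

    Both orientations of the pair are tried (either side may be the eukaryote
    side). ``tree`` is needed to test focal monophyly for multi-assembly focal
    species; without it that test is skipped.
    """
    reasons: list[str] = []
    for euk, donor in ((pair.side_a, pair.side_b), (pair.side_b, pair.side_a)):
        euk_prof = _profile(euk, tmap)
        if not any(rec.focal for _, rec in euk_prof):
            reasons.append("no_focal")
            continue
        donor_prof = _profile(donor, tmap)
        reason = _donor_check(donor_prof, "cyanobacteria", cfg.min_cyano, cfg)
        if reason is not None:
            reasons.append(reason)
            continue
        reason, assemblies, contamination = _euk_side_egt(euk_prof, tree, tmap, cfg)
        if reason is not None:
            reasons.append(reason)
            continue
        return PairDecision(
            event=TransferEvent(
                tree_id=tree_id,
                kind=EGT,
                focal_species=focal,
                focal_assemblies=assemblies,
                euk_side=euk,
                donor_side=donor,
                contamination=contamination,
            ),
            reject_reason=None,
        )
    return PairDecision(event=None, reject_reason=_best_reason(reasons))


def classify_hgt_pair(
    pair: SubtreePair,
    tmap: TaxonMap,
    focal: str,
    cfg: ScanConfig,
    tree: Optional[GeneTree] = None,
    tree_id: str = "tree",
) -> PairDecision:
    """Classify one sister pair as an HGT event or reject it.

    The focal side may contain members of ``cfg.higher_group``; any other
    non-focal sequence counts toward the contamination fraction, bounded by
    the same threshold as the EGT rule. The donor side must consist
    exclusively of at least ``min_bacteria`` non-cyanobacterial bacteria.
    """
    reasons: list[str] = []
    for euk, donor in ((pair.side_a, pair.side_b), (pair.side_b, pair.side_a)):
        euk_prof = _profile(euk, tmap)
        if not any(rec.focal for _, rec in euk_prof):
            reasons.append("no_focal")
            continue
        donor_prof = _profile(donor, tmap)
        reason = _donor_check(donor_prof, "other_bacteria", cfg.min_bacteria, cfg)
        if reason is not None:
            reasons.append(reason)
            continue
        n_contam = sum(
            1
            for _, rec in euk_prof
            if not rec.focal
            and (cfg.higher_group is None or rec.higher_group != cfg.higher_group)
        )
        contamination = n_contam / len(euk_prof)
        if not cfg.contamination_ok(contamination):
            reasons.append("contamination")
            continue
        assemblies = frozenset(
            rec.assembly_id
            for _, rec in euk_prof
            if rec.focal and rec.assembly_id is not None
        )
        return PairDecision(
            event=TransferEvent(
                tree_id=tree_id,
                kind=HGT,
                focal_species=focal,
                focal_assemblies=assemblies,
                euk_side=euk,
                donor_side=donor,
                contamination=contamination,
            ),
            reject_reason=None,
        )
    return PairDecision(event=None, reject_reason=_best_reason(reasons))


@dataclass
class TreeScan:
    """Per-tree scan outcome (for the detail report)."""

    tree_id: str
    eligible: bool
    event: Optional[TransferEvent] = None
    all_events: list = field(default_factory=list)


@dataclass
class ScanResult:
    """Outcome of scanning a collection of trees in one mode."""

    mode: str
    focal: str
    trees: list = field(default_factory=list)  # list[TreeScan]

    @property
    def events(self) -> list[TransferEvent]:
        return [t.event for t in self.trees if t.event is not None]

    @property
    def n(self) -> int:
        """Number of trees with at least one qualifying configuration."""
        return len(self.events)

    @property
    def detected_tree_ids(self) -> set[str]:
        return {e.tree_id for e in self.events}


def scan_trees(
    trees: Sequence[GeneTree],
    tmap: TaxonMap,
    focal: str,
    cfg: ScanConfig,
    mode: str = EGT,
    strict: bool = True,
    collect_all: bool = False,
) -> ScanResult:
    """Scan gene trees for transfer events in one mode.

    Per tree, cluster eligibility is checked first; eligible trees are then
    searched over their sister pairs in deterministic enumeration order, and
    the first qualifying pair is recorded as the tree's event (the counting
    unit is the tree). With ``collect_all`` every qualifying configuration is
    kept in the detail report.
    """
    if mode not in (EGT, HGT):
        raise ValueError(f"mode must be {EGT!r} or {HGT!r}, got {mode!r}")
    eligible_fn = cluster_eligible_egt if mode == EGT else cluster_eligible_hgt
    classify_fn = classify_egt_pair if mode == EGT else classify_hgt_pair
    result = ScanResult(mode=mode, focal=focal)
    for tree in trees:
        if strict:
            for lf in tree.leaves:
                tmap.resolve_leaf(lf, strict=True)
        scan = TreeScan(tree_id=tree.tree_id, eligible=False)
        if eligible_fn(tree.leaves, tmap, focal):
            scan.eligible = True
            for pair in tree.sister_pairs():
                decision = classify_fn(
                    pair, tmap, focal, cfg, tree=tree, tree_id=tree.tree_id
                )
                if decision.accepted:
                    if scan.event is None:
                        scan.event = decision.event
                    if collect_all:
                        scan.all_events.append(decision.event)
                    else:
                        break
        result.trees.append(scan)
    return result


def egt_hgt_ratio(n_egt: int, n_hgt: int) -> Optional[float]:
    """EGT:HGT ratio; ``None`` (reported as NA) when there are no HGT events."""
    if n_egt < 0 or n_hgt < 0:
        raise ValueError("counts must be non-negative")
    if n_hgt == 0:
        return None
    return n_egt / n_hgt


@dataclass(frozen=True)
class TransferSummary:
    """Per-focal-species event counts and their ratio."""

    focal: str
    n_egt: int
    n_hgt: int

    @property
    def ratio(self) -> Optional[float]:
        return egt_hgt_ratio(self.n_egt, self.n_hgt)


# -- report serialisation -------------------------------------------------

_EVENT_COLUMNS = (
    "tree_id",
    "kind",
    "focal_species",
    "assemblies",
    "euk_side",
    "donor_side",
    "contamination",
    "reject_reason",
)


def events_tsv(result: ScanResult) -> str:
    """Render a scan result as the events TSV (accepted events only;
    reject_reason column left empty for accepted configurations)."""
    lines = ["\t".join(_EVENT_COLUMNS)]
    for scan in result.trees:
        events = scan.all_events or ([scan.event] if scan.event else [])
        for ev in events:
            lines.append(
                "\t".join(
                    [
                        ev.tree_id,
                        ev.kind,
                        ev.focal_species,
                        ",".join(sorted(ev.focal_assemblies)),
                        ",".join(sorted(ev.euk_side)),
                        ",".join(sorted(ev.donor_side)),
                        f"{ev.contamination:.6f}",
                        "",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def summary_tsv(summaries: Sequence[TransferSummary]) -> str:
    lines = ["species\tn_egt\tn_hgt\tratio"]
    for s in summaries:
        ratio = s.ratio
        lines.append(
            f"{s.focal}\t{s.n_egt}\t{s.n_hgt}\t"
            + ("NA" if ratio is None else f"{ratio:.6f}")
        )
    return "\n".join(lines) + "\n"
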