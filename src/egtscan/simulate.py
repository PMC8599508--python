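"""Seed-deterministic synthetic inputs: taxon sets, gene trees with planted
transfer events and a truth table, alignments with rate and compositional
structure, and sparse marker presence matrices.

The gene-tree generator is topology-only: branch lengths are drawn (and
written) but decorative, because the downstream detector is purely
topological. Background trees are built to be certifiably event-free — they
contain at most one bacterium of each kind, so no qualifying donor clade of
size >= 2 can exist — which makes recall/false-positive assertions exact
rather than statistical.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .matrixtools import AMINO_ACIDS, GeneAlignment
from .sagqc import PresenceMatrix
from .taxa import TaxonMap, TaxonRecord, write_taxon_map

__all__ = [
    "SimConfig",
    "SimulationError",
    "TruthRow",
    "SimulatedDataset",
    "simulate_dataset",
    "SimulatedAlignment",
    "simulate_alignment",
    "simulate_presence",
]


class SimulationError(ValueError):
    """Configuration cannot produce the requested dataset."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the gene-tree simulator."""

    seed: int = 0
    n_focal_assemblies: int = 4
    n_cyano: int = 8
    n_other_bact: int = 8
    n_plastid_photo: int = 10
    n_plastid_nonphoto: int = 4
    n_plastid_lacking: int = 8
    n_genes: int = 50
    p_egt: float = 0.3
    p_hgt: float = 0.3
    p_background: float = 0.4
    contamination_level: float = 0.0
    donor_clade_size: int = 2
    event_assemblies: int = 2  # focal assemblies per planted clade
    euk_plastid_size: int = 2  # non-focal plastid sequences per planted EGT clade
    leaves_min: int = 12
    leaves_max: int = 24
    focal_name: str = "Focal"
    higher_group_label: str = "FocalKin"

    def __post_init__(self) -> None:
        total = self.p_egt + self.p_hgt + self.p_background
        if any(p < 0 or p > 1 for p in (self.p_egt, self.p_hgt, self.p_background)):
            raise SimulationError("event probabilities must be in [0, 1]")
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"event probabilities sum to {total}, expected 1")
        if not (0.0 <= self.contamination_level < 1.0):
            raise SimulationError("contamination_level must be in [0, 1)")
        if self.event_assemblies > self.n_focal_assemblies:
            raise SimulationError(
                f"event_assemblies={self.event_assemblies} exceeds "
                f"n_focal_assemblies={self.n_focal_assemblies}"
            )
        if self.donor_clade_size > self.n_cyano:
            raise SimulationError(
                f"donor_clade_size={self.donor_clade_size} exceeds n_cyano={self.n_cyano}"
            )
        if self.donor_clade_size > self.n_other_bact:
            raise SimulationError(
                f"donor_clade_size={self.donor_clade_size} exceeds "
                f"n_other_bact={self.n_other_bact}"
            )
        if self.euk_plastid_size > self.n_plastid_photo:
            raise SimulationError(
                f"euk_plastid_size={self.euk_plastid_size} exceeds "
                f"n_plastid_photo={self.n_plastid_photo}"
            )
        if self.leaves_min < 6 or self.leaves_max < self.leaves_min:
            raise SimulationError("need leaves_max >= leaves_min >= 6")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one simulated gene tree."""

    tree_id: str
    planted: str  # EGT | HGT | none
    contamination: float
    focal_assemblies_in_clade: int
    donor_size: int


@dataclass
class SimulatedDataset:
    taxon_map: TaxonMap
    newicks: list[tuple[str, str]]  # (tree_id, newick text)
    truth: list[TruthRow]
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write taxa.tsv, trees/<tree_id>.nwk, truth.tsv. Byte-deterministic."""
        outdir = Path(outdir)
        trees_dir = outdir / "trees"
        trees_dir.mkdir(parents=True, exist_ok=True)
        taxa_path = outdir / "taxa.tsv"
        write_taxon_map(self.taxon_map, taxa_path)
        for tree_id, nwk in self.newicks:
            (trees_dir / f"{tree_id}.nwk").write_text(nwk + "\n", encoding="utf-8")
        truth_path = outdir / "truth.tsv"
        lines = ["tree_id\tplanted\tcontamination\tfocal_assemblies_in_clade\tdonor_size"]
        for row in self.truth:
            lines.append(
                f"{row.tree_id}\t{row.planted}\t{row.contamination:.6f}\t"
                f"{row.focal_assemblies_in_clade}\t{row.donor_size}"
            )
        truth_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return {"taxa": taxa_path, "trees": trees_dir, "truth": truth_path}


def read_truth(path: str | Path) -> list[TruthRow]:
    rows: list[TruthRow] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        tree_id, planted, contamination, k, donor = line.split("\t")
        rows.append(TruthRow(tree_id, planted, float(contamination), int(k), int(donor)))
    return rows


# -- taxon universe --------------------------------------------------------


def build_taxon_map(cfg: SimConfig) -> TaxonMap:
    records: list[TaxonRecord] = []
    for i in range(1, cfg.n_focal_assemblies + 1):
        records.append(
            TaxonRecord(
                taxon_id=f"{cfg.focal_name}_A{i:02d}",
                group="plastid_lacking",
                focal=True,
                assembly_id=f"A{i:02d}",
                higher_group=cfg.higher_group_label,
            )
        )
    for prefix, group, n in (
        ("Cyano", "cyanobacteria", cfg.n_cyano),
        ("Bact", "other_bacteria", cfg.n_other_bact),
        ("Alga", "plastid_photosynthetic", cfg.n_plastid_photo),
        ("Cryptic", "plastid_nonphotosynthetic", cfg.n_plastid_nonphoto),
        ("Het", "plastid_lacking", cfg.n_plastid_lacking),
    ):
        for i in range(1, n + 1):
            records.append(TaxonRecord(taxon_id=f"{prefix}{i:02d}", group=group))
    return TaxonMap(records)


# -- random topology helpers ----------------------------------------------

Node = Union[str, tuple]


def _join(rng: random.Random, units: list[Node]) -> Node:
    """Random sequential pairwise merge into a binary (rooted) topology."""
    units = list(units)
    while len(units) > 1:
        i, j = sorted(rng.sample(range(len(units)), 2))
        b = units.pop(j)
        a = units.pop(i)
        units.append((a, b))
    return units[0]


def _newick(node: Node, rng: random.Random) -> str:
    if isinstance(node, str):
        return f"{node}:{rng.expovariate(10.0):.6f}"
    inner = ",".join(_newick(ch, rng) for ch in node)
    return f"({inner}):{rng.expovariate(10.0):.6f}"


def _render_tree(root: Node, rng: random.Random) -> str:
    if isinstance(root, str):
        raise SimulationError("degenerate single-leaf tree")
    inner = ",".join(_newick(ch, rng) for ch in root)
    return f"({inner});"


def _sample(rng: random.Random, pool: Sequence[str], k: int, what: str) -> list[str]:
    if k > len(pool):
        raise SimulationError(f"need {k} {what} but only {len(pool)} available")
    return rng.sample(list(pool), k)


def _contaminant_count(level: float, n_core: int) -> int:
    """Smallest-error count c with c/(n_core+c) ~= level."""
    if level <= 0.0:
        return 0
    return round(level * n_core / (1.0 - level))


# -- gene tree simulation --------------------------------------------------


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate gene trees with planted EGT/HGT events and a truth table.

    EGT trees graft [focal clade from k assemblies + photosynthetic plastid
    sequences + optional contaminants] sister to a pure cyanobacterial clade;
    HGT trees plant a focal clade sister to a pure clade of other bacteria.
    Background trees scatter focal sequences among eukaryotes with exactly one
    cyanobacterium and one other bacterium, so no donor clade of size >= 2 can
    exist in them. Identical seeds give byte-identical output.
    """
    rng = random.Random(cfg.seed)
    tmap = build_taxon_map(cfg)
    focal_ids = sorted(r.taxon_id for r in tmap.focal_records())
    pools = {
        "cyano": sorted(r.taxon_id for r in tmap if r.group == "cyanobacteria"),
        "bact": sorted(r.taxon_id for r in tmap if r.group == "other_bacteria"),
        "photo": sorted(
            r.taxon_id for r in tmap if r.group == "plastid_photosynthetic"
        ),
        "nonphoto": sorted(
            r.taxon_id for r in tmap if r.group == "plastid_nonphotosynthetic"
        ),
        "lacking": sorted(
            r.taxon_id
            for r in tmap
            if r.group == "plastid_lacking" and not r.focal
        ),
    }

    newicks: list[tuple[str, str]] = []
    truth: list[TruthRow] = []
    for g in range(1, cfg.n_genes + 1):
        tree_id = f"g{g:04d}"
        r = rng.random()
        if r < cfg.p_egt:
            kind = "EGT"
        elif r < cfg.p_egt + cfg.p_hgt:
            kind = "HGT"
        else:
            kind = "none"

        def leaf(taxon: str) -> str:
            return f"{taxon}@{tree_id}"

        target = rng.randint(cfg.leaves_min, cfg.leaves_max)
        if kind in ("EGT", "HGT"):
            assemblies = _sample(rng, focal_ids, cfg.event_assemblies, "focal assemblies")
            focal_clade = _join(rng, [leaf(t) for t in assemblies])
            if kind == "EGT":
                plastid = _sample(
                    rng, pools["photo"], cfg.euk_plastid_size, "photosynthetic taxa"
                )
                donors = _sample(rng, pools["cyano"], cfg.donor_clade_size, "cyanobacteria")
            else:
                plastid = []
                donors = _sample(
                    rng, pools["bact"], cfg.donor_clade_size, "other bacteria"
                )
            n_core = len(assemblies) + len(plastid)
            n_contam = _contaminant_count(cfg.contamination_level, n_core)
            contaminants = _sample(rng, pools["lacking"], n_contam, "contaminant taxa")
            euk_units: list[Node] = [focal_clade] + [leaf(t) for t in plastid + contaminants]
            euk = _join(rng, euk_units) if len(euk_units) > 1 else euk_units[0]
            donor_clade = _join(rng, [leaf(t) for t in donors])
            planted: Node = (euk, donor_clade)
            used = set(assemblies) | set(plastid) | set(contaminants) | set(donors)
            # background: eukaryotes only, plus one bacterium of the *other*
            # kind so the tree stays eligible for both scan modes yet can
            # never host a second donor clade
            bg_pool = [
                t
                for t in pools["photo"] + pools["nonphoto"] + pools["lacking"]
                if t not in used
            ]
            extra = pools["bact"] if kind == "EGT" else pools["cyano"]
            bg = _sample(rng, extra, 1, "background bacterium")
            n_bg = max(2, target - (n_core + n_contam + len(donors)) - 1)
            bg += _sample(rng, bg_pool, min(n_bg, len(bg_pool)), "background taxa")
            root = _join(rng, [planted] + [leaf(t) for t in bg])
            achieved = n_contam / (n_core + n_contam)
            truth.append(
                TruthRow(
                    tree_id=tree_id,
                    planted=kind,
                    contamination=achieved,
                    focal_assemblies_in_clade=len(assemblies),
                    donor_size=len(donors),
                )
            )
        else:
            n_focal = rng.randint(1, cfg.n_focal_assemblies)
            chosen = _sample(rng, focal_ids, n_focal, "focal assemblies")
            photo = _sample(rng, pools["photo"], 1, "photosynthetic taxon")
            bacteria = _sample(rng, pools["cyano"], 1, "cyanobacterium") + _sample(
                rng, pools["bact"], 1, "other bacterium"
            )
            bg_pool = [
                t
                for t in pools["photo"] + pools["nonphoto"] + pools["lacking"]
                if t not in set(chosen) | set(photo)
            ]
            n_bg = max(1, target - n_focal - 3)
            others = _sample(rng, bg_pool, min(n_bg, len(bg_pool)), "background taxa")
            units = [leaf(t) for t in chosen + photo + bacteria + others]
            root = _join(rng, units)
            truth.append(
                TruthRow(
                    tree_id=tree_id,
                    planted="none",
                    contamination=0.0,
                    focal_assemblies_in_clade=0,
                    donor_size=0,
                )
            )
        newicks.append((tree_id, _render_tree(root, rng)))
    return SimulatedDataset(taxon_map=tmap, newicks=newicks, truth=truth, config=cfg)


# -- alignment simulation --------------------------------------------------

# moderately uneven base composition over the 20 residues
_BASE_FREQS = np.array(
    [
        0.083, 0.014, 0.054, 0.062, 0.039, 0.072, 0.022, 0.052, 0.057, 0.090,
        0.022, 0.044, 0.047, 0.040, 0.051, 0.069, 0.058, 0.066, 0.013, 0.045,
    ]
)
_BASE_FREQS = _BASE_FREQS / _BASE_FREQS.sum()

# shifted composition used for biased taxa at biased sites: concentrated on
# two residues that are rare under the base composition (W and C), so full
# bias is maximally distinguishable from background substitution noise
_SHIFTED_FREQS = np.full(20, 0.1 / 18.0)
_SHIFTED_FREQS[[1, 18]] = 0.45  # C, W


@dataclass
class SimulatedAlignment:
    """A simulated alignment plus the planted structure (for truth checks)."""

    alignment: GeneAlignment
    site_rates: np.ndarray
    biased_sites: np.ndarray  # sorted 0-based indices
    biased_taxa: list[str]

    def fasta(self) -> str:
        return "".join(
            f">{t}\n{row}\n" for t, row in self.alignment.rows.items()
        )


def simulate_alignment(
    n_taxa: int,
    n_sites: int,
    gamma_shape: float = 1.0,
    biased_taxa: int | Sequence[str] = 0,
    biased_sites: float = 0.0,
    bias_strength: float = 0.0,
    seed: int = 0,
    gene_id: str = "sim",
) -> SimulatedAlignment:
    """Simulate an amino-acid alignment with gamma-like site-rate variation
    and taxon-restricted compositional bias.

    Per site a rate is drawn from a gamma distribution; each taxon copies the
    site's consensus residue with probability exp(-rate), otherwise draws from
    the base frequency vector. Taxa in ``biased_taxa`` (a count, taking the
    first k taxa, or explicit names) draw from a frequency vector mixed with a
    shifted composition at ``bias_strength`` — but only at the ``biased_sites``
    fraction of sites. Seed-deterministic.
    """
    if gamma_shape <= 0:
        raise SimulationError("gamma_shape must be positive")
    if not (0.0 <= biased_sites <= 1.0):
        raise SimulationError("biased_sites fraction must be in [0, 1]")
    if not (0.0 <= bias_strength <= 1.0):
        raise SimulationError("bias_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    taxa = [f"T{i + 1:03d}" for i in range(n_taxa)]
    if isinstance(biased_taxa, int):
        biased_names = taxa[:biased_taxa]
    else:
        biased_names = [t for t in biased_taxa]
        unknown = set(biased_names) - set(taxa)
        if unknown:
            raise SimulationError(f"biased taxa not in alignment: {sorted(unknown)}")
    n_biased_sites = round(biased_sites * n_sites)
    biased_idx = np.sort(
        rng.choice(n_sites, size=n_biased_sites, replace=False)
    ) if n_biased_sites else np.array([], dtype=int)
    biased_mask = np.zeros(n_sites, dtype=bool)
    biased_mask[biased_idx] = True

    rates = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_sites)
    p_subst = 1.0 - np.exp(-rates)
    mixed = (1.0 - bias_strength) * _BASE_FREQS + bias_strength * _SHIFTED_FREQS
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")

    consensus = rng.choice(20, size=n_sites, p=_BASE_FREQS)
    cols = np.empty((n_taxa, n_sites), dtype=int)
    for ti, taxon in enumerate(taxa):
        is_biased = taxon in biased_names
        substitute = rng.random(n_sites) < p_subst
        draws_base = rng.choice(20, size=n_sites, p=_BASE_FREQS)
        row = np.where(substitute, draws_base, consensus)
        if is_biased and n_biased_sites:
            row[biased_mask] = rng.choice(20, size=n_biased_sites, p=mixed)
        cols[ti] = row
    rows = {t: "".join(aas[cols[ti]]) for ti, t in enumerate(taxa)}
    return SimulatedAlignment(
        alignment=GeneAlignment(gene_id=gene_id, rows=rows),
        site_rates=rates,
        biased_sites=biased_idx,
        biased_taxa=biased_names,
    )


# -- presence matrix simulation -------------------------------------------


def simulate_presence(
    n_markers: int,
    n_assemblies: int,
    per_assembly_completeness: Sequence[float],
    seed: int = 0,
    name: str = "sim",
) -> PresenceMatrix:
    """Draw each assembly's present marker set uniformly at the requested
    completeness (exact counts, rounded to nearest). Seed-deterministic."""
    if len(per_assembly_completeness) != n_assemblies:
        raise SimulationError(
            f"got {len(per_assembly_completeness)} completeness values for "
            f"{n_assemblies} assemblies"
        )
    for c in per_assembly_completeness:
        if not (0.0 <= c <= 1.0):
            raise SimulationError(f"completeness {c} outside [0, 1]")
    rng = np.random.default_rng(seed)
    markers = [f"M{i + 1:04d}" for i in range(n_markers)]
    assemblies = [f"ASM{j + 1:02d}" for j in range(n_assemblies)]
    data = np.zeros((n_markers, n_assemblies), dtype=bool)
    for j, c in enumerate(per_assembly_completeness):
        k = round(c * n_markers)
        present = rng.choice(n_markers, size=k, replace=False)
        data[present, j] = True
    return PresenceMatrix(markers, assemblies, data, name=name)
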