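import pytest

from egtscan.taxa import TaxonMap, TaxonRecord


def _records():
    recs = [
        TaxonRecord("Focal_A01", "plastid_lacking", focal=True, assembly_id="A01",
                    higher_group="Kin"),
        TaxonRecord("Focal_A02", "plastid_lacking", focal=True, assembly_id="A02",
                    higher_group="Kin"),
        TaxonRecord("Focal_A03", "plastid_lacking", focal=True, assembly_id="A03",
                    higher_group="Kin"),
        TaxonRecord("Kin1", "plastid_lacking", higher_group="Kin"),
    ]
    for i in range(1, 9):
        recs.append(TaxonRecord(f"Photo{i}", "plastid_photosynthetic"))
    for i in range(1, 3):
        recs.append(TaxonRecord(f"NP{i}", "plastid_nonphotosynthetic"))
    for i in range(1, 5):
        recs.append(TaxonRecord(f"Cyano{i}", "cyanobacteria"))
    for i in range(1, 5):
        recs.append(TaxonRecord(f"Bact{i}", "other_bacteria"))
    for i in range(1, 4):
        recs.append(TaxonRecord(f"Het{i}", "plastid_lacking"))
    return recs


@pytest.fixture
def tmap():
    """Multi-assembly focal species plus all six groups."""
    return TaxonMap(_records())


@pytest.fixture
def tmap_single():
    """Single-assembly focal species (multi-assembly rule must not apply)."""
    recs = [r for r in _records() if not r.taxon_id.startswith("Focal_")]
    recs.append(
        TaxonRecord("Focal_A01", "plastid_lacking", focal=True, assembly_id="A01",
                    higher_group="Kin")
    )
    return TaxonMap(recs)
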