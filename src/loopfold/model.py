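"""Ordered bead models with genomic annotation, and PDB export.

A :class:`PolymerModel` is an ordered chain of 3D bead positions (nm).  For
image-derived models of a known genomic region the beads additionally carry
a bp-per-bead annotation and 1-based anchor bead indices; purely synthetic
chains (random walks, embeddings of contact matrices) leave the genomic
fields unset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomicRegion, bead_index, n_beads_for

#: Default nm -> PDB coordinate-unit factor.  PDB columns are conventionally
#: Angstrom; writing nm * 0.1 keeps hundreds-of-nm models within the fixed
#: column width while preserving relative geometry.
PDB_SCALE = 0.1

_PDB_MAX_BEADS = 99_999


@dataclass
class PolymerModel:
    """Ordered 3D bead chain, optionally annotated with genomic coordinates.

    Attributes
    ----------
    beads : ndarray, shape (n, 3)
        Bead positions in nm, in genomic (path) order.
    bp_per_bead : float or None
        Genomic granularity; ``None`` for non-genomic chains.
    region : GenomicRegion or None
        Covered genomic region.
    origin_bp : int or None
        Genomic coordinate at which the first bead's interval starts.
    anchor_beads : tuple of int
        1-based bead indices of loop anchors.
    """

    beads: np.ndarray
    bp_per_bead: float | None = None
    region: GenomicRegion | None = None
    origin_bp: int | None = None
    anchor_beads: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3:
            raise ValueError(f"beads must be an (n, 3) array, got {self.beads.shape}")
        for b in self.anchor_beads:
            if not (1 <= b <= len(self.beads)):
                raise ValueError(f"anchor bead {b} outside 1..{len(self.beads)}")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def reversed(self) -> "PolymerModel":
        """The same chain walked in the opposite orientation."""
        n = self.n_beads
        anchors = tuple(n - b + 1 for b in self.anchor_beads)
        return replace(self, beads=self.beads[::-1].copy(), anchor_beads=anchors)


def map_genome(
    beads,
    region: GenomicRegion,
    bp_per_bead: float,
    origin_bp: int | None = None,
) -> PolymerModel:
    """Annotate an interpolated bead chain with genomic coordinates.

    Bead ``i`` (1-based) covers ``(origin + bp*(i-1), origin + bp*i]``; the
    region's anchors are mapped to their bead indices.  The bead count must
    equal ``floor(region_length / bp_per_bead)``.
    """
    beads = np.asarray(beads, dtype=float)
    origin = region.start if origin_bp is None else int(origin_bp)
    expected = int(region.length_bp // bp_per_bead)
    if len(beads) != expected:
        raise ValueError(
            f"bead count {len(beads)} inconsistent with region {region} at "
            f"{bp_per_bead} bp/bead (expected {expected})"
        )
    anchors = []
    for a in region.anchors:
        if not (region.start <= a <= region.end):
            raise ValueError(f"anchor {a} outside region {region}")
        idx = bead_index(a, origin, int(bp_per_bead))
        if not (1 <= idx <= len(beads)):
            raise ValueError(f"anchor {a} maps to bead {idx} outside 1..{len(beads)}")
        anchors.append(idx)
    return PolymerModel(
        beads=beads,
        bp_per_bead=float(bp_per_bead),
        region=region,
        origin_bp=origin,
        anchor_beads=tuple(anchors),
    )


def anchor_distance(model: PolymerModel) -> float:
    """Euclidean distance (nm) between the two anchor beads of a model."""
    if len(model.anchor_beads) != 2:
        raise ValueError(f"expected exactly 2 anchor beads, got {len(model.anchor_beads)}")
    a, b = model.anchor_beads
    return float(np.linalg.norm(model.beads[a - 1] - model.beads[b - 1]))


def write_pdb(model: PolymerModel, path, scale: float = PDB_SCALE) -> None:
    """Export a bead model as a coarse-grained PDB chain.

    One HETATM record per bead in path order with sequential serials, CONECT
    records linking consecutive beads, and a REMARK documenting the nm ->
    coordinate-unit scale factor.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = model.n_beads
    if n == 0:
        raise ValueError("cannot write an empty model")
    if n > _PDB_MAX_BEADS:
        raise ValueError(
            f"{n} beads exceeds the PDB serial limit ({_PDB_MAX_BEADS}); "
            "increase bp_per_bead to coarsen the model"
        )
    atoms = struc.AtomArray(n)
    atoms.coord = model.beads * scale
    atoms.chain_id[:] = "A"
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name[:] = "BEA"
    atoms.atom_name[:] = "CA"
    atoms.element[:] = "C"
    atoms.hetero[:] = True
    if n > 1:
        bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        atoms.bonds = struc.BondList(n, bonds)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.lines = [
        f"REMARK 250 COARSE-GRAINED CHROMATIN BEAD MODEL ({n} BEADS)",
        f"REMARK 250 COORDINATE UNITS: NM * {scale:g}",
    ] + pdb.lines
    pdb.write(str(path))


def read_pdb(path, scale: float = PDB_SCALE) -> PolymerModel:
    """Read back a bead model written by :func:`write_pdb` (positions in nm)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    return PolymerModel(beads=atoms.coord / scale)
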