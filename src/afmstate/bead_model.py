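"""Coarse-grained sphere ("bead") representation of molecular structures.

A molecule is reduced to one sphere per amino-acid residue, centred at the
Calpha position, plus one sphere per lipid phosphorus (kind ``"PO4"``);
buried acyl chains are ignored.  All coordinates are stored in nanometres.
An :class:`Ensemble` holds many conformers of the *same* molecule, with a
stable bead ordering so that bead ``i`` corresponds to the same residue in
every conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default effective radius (nm) of a Calpha bead.
DEFAULT_CA_RADIUS = 0.38
#: Default radius (nm) of a lipid-phosphate bead (half a 0.47 nm CG bead).
DEFAULT_PO4_RADIUS = 0.235

#: Residue names treated as lipids (bead placed on the P atom).  Three-letter
#: entries cover readers that truncate the PDB resName field.
LIPID_RESNAMES = frozenset(
    {"POPC", "POPE", "POPG", "POPS", "DOPC", "DOPE", "DPPC", "DMPC", "PC", "PE",
     "POP", "DOP", "DPP", "DMP", "PLC"}
)


@dataclass(frozen=True)
class Bead:
    """A single sphere: centre (nm), radius (nm) and a kind tag."""

    center: np.ndarray
    radius: float
    kind: str

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("bead center must be a finite 3-vector")
        object.__setattr__(self, "center", c)
        if not (self.radius > 0):
            raise ValueError("bead radius must be positive")


class BeadModel:
    """An ordered collection of beads representing one conformer.

    Internally array-backed: ``centers`` is an (n, 3) float array in nm,
    ``radii`` an (n,) array, ``kinds`` a list of tags.
    """

    __slots__ = ("centers", "radii", "kinds", "name")

    def __init__(self, centers, radii, kinds, name: str = ""):
        self.centers = np.atleast_2d(np.asarray(centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(radii, dtype=float))
        self.kinds = list(kinds)
        self.name = name
        n = len(self.centers)
        if n == 0:
            raise ValueError("BeadModel must contain at least one bead")
        if self.centers.shape != (n, 3):
            raise ValueError("centers must have shape (n, 3)")
        if self.radii.shape != (n,) or len(self.kinds) != n:
            raise ValueError("centers, radii and kinds must have equal length")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("bead centers must be finite")
        if not np.all(self.radii > 0):
            raise ValueError("bead radii must be positive")

    @classmethod
    def from_beads(cls, beads, name: str = "") -> "BeadModel":
        return cls(
            [b.center for b in beads],
            [b.radius for b in beads],
            [b.kind for b in beads],
            name=name,
        )

    @property
    def beads(self):
        return [Bead(c, r, k) for c, r, k in zip(self.centers, self.radii, self.kinds)]

    def __len__(self) -> int:
        return len(self.radii)

    def centroid(self) -> np.ndarray:
        """Geometric centroid of the bead centres."""
        return self.centers.mean(axis=0)

    def copy(self) -> "BeadModel":
        return BeadModel(self.centers.copy(), self.radii.copy(), list(self.kinds), self.name)

    def translated(self, shift) -> "BeadModel":
        return BeadModel(self.centers + np.asarray(shift, float), self.radii, self.kinds, self.name)


@dataclass
class Ensemble:
    """Conformers of one molecule with consistent bead ordering."""

    conformers: list
    frame_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("Ensemble must contain at least one conformer")
        if not self.frame_ids:
            self.frame_ids = list(range(len(self.conformers)))
        if len(self.frame_ids) != len(self.conformers):
            raise ValueError("frame_ids must match conformers in length")
        ref = self.conformers[0]
        for m in self.conformers[1:]:
            if len(m) != len(ref) or m.kinds != ref.kinds:
                raise ValueError("all conformers must share bead count and kinds")

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, i) -> BeadModel:
        return self.conformers[i]

    def coordinates(self) -> np.ndarray:
        """Stacked centres with shape (n_conformers, n_beads, 3)."""
        return np.stack([m.centers for m in self.conformers])


def read_pdb_ensemble(path, radius_table=None, po4_radius: float = DEFAULT_PO4_RADIUS) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble` of bead models.

    Protein residues contribute one bead at the Calpha position with the
    residue's effective radius taken from ``radius_table`` (falling back to
    ``DEFAULT_CA_RADIUS``); recognised lipids contribute one bead per
    phosphorus atom with kind ``"PO4"``.  PDB coordinates (Angstrom) are
    converted to nm (x0.1).  Residues missing a Calpha are skipped with a
    warning; other heteroatoms are ignored.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    radius_table = dict(radius_table or {})
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()  # AtomArrayStack (models, atoms)
    if stack.array_length() == 0:
        raise ValueError(f"no atoms found in {path}")

    first = stack[0]
    amino = struc.filter_amino_acids(first)
    keep_idx = []
    kinds = []
    radii = []
    for start in struc.get_residue_starts(first):
        res_name = first.res_name[start]
        res_id = first.res_id[start]
        mask = (first.res_id == res_id) & (first.chain_id == first.chain_id[start])
        (atom_idx,) = np.nonzero(mask)
        if amino[start]:
            ca = [i for i in atom_idx if first.atom_name[i] == "CA"]
            if not ca:
                logger.warning("residue %s %d has no CA atom; skipped", res_name, res_id)
                continue
            keep_idx.append(ca[0])
            kinds.append(str(res_name))
            radii.append(float(radius_table.get(str(res_name), DEFAULT_CA_RADIUS)))
        elif res_name in LIPID_RESNAMES:
            p = [i for i in atom_idx if first.atom_name[i] == "P"]
            if not p:
                logger.warning("lipid %s %d has no P atom; skipped", res_name, res_id)
                continue
            keep_idx.append(p[0])
            kinds.append("PO4")
            radii.append(float(radius_table.get("PO4", po4_radius)))
        else:
            logger.warning("unrecognised residue %s %d skipped", res_name, res_id)
    if not keep_idx:
        raise ValueError(f"no usable beads found in {path}")

    keep_idx = np.asarray(keep_idx)
    radii = np.asarray(radii)
    conformers = []
    for m in range(stack.stack_depth()):
        coords_nm = stack[m].coord[keep_idx] * 0.1
        conformers.append(BeadModel(coords_nm, radii, kinds, name=f"model{m + 1}"))
    return Ensemble(conformers, frame_ids=list(range(len(conformers))))


def read_bead_text(path) -> Ensemble:
    """Read the plain bead-list format: lines ``x y z r kind`` (nm), frames
    separated by one blank line."""
    frames = []
    current = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                if current:
                    frames.append(current)
                    current = []
                continue
            parts = stripped.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 'x y z r kind', got {stripped!r}")
            try:
                x, y, z, r = (float(v) for v in parts[:4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field in {stripped!r}") from exc
            current.append((x, y, z, r, parts[4]))
    if current:
        frames.append(current)
    if not frames:
        raise ValueError(f"no beads found in {path}")
    conformers = [
        BeadModel(
            [row[:3] for row in frame],
            [row[3] for row in frame],
            [row[4] for row in frame],
            name=f"frame{i}",
        )
        for i, frame in enumerate(frames)
    ]
    return Ensemble(conformers)


def write_bead_text(path, ens: Ensemble) -> None:
    """Write an ensemble in the bead-list text format, losslessly (full float
    precision via ``repr``)."""
    with open(path, "w") as fh:
        for i, model in enumerate(ens.conformers):
            if i:
                fh.write("\n")
            for c, r, k in zip(model.centers, model.radii, model.kinds):
                fh.write(f"{float(c[0])!r} {float(c[1])!r} {float(c[2])!r} "
                         f"{float(r)!r} {k}\n")
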