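"""Coarse-grained tropocollagen molecules and quasi-hexagonally packed fibrils.

A molecule is a straight bead chain (~300 nm x 1.6 nm at full scale).  A
fibril replicates molecules on a quasi-hexagonal lattice of axes clipped to
a circular cross-section, groups them into 5-molecule microfibrils, staggers
them axially, and adds enzymatic crosslinks: a fraction ``beta`` of all
molecule ends is bonded to the nearest helical (non-end) bead of an
adjacent molecule, so beta = 1 means two connected ends per molecule.

The default lattice pitch (1.67 nm) is calibrated so that a 21.5-nm
cross-section contains exactly 151 molecule axes; the count is insensitive
to the pitch over roughly 1.64-1.72 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

MOLECULE_DIAMETER_NM = 1.6
DEFAULT_LATTICE_PITCH_NM = 1.67


@dataclass
class Molecule:
    """Straight bead chain along +x."""

    bead_positions: np.ndarray        # (n, 3) nm
    bead_spacing: float               # nm

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    @property
    def contour_length(self) -> float:
        return (self.n_beads - 1) * self.bead_spacing

    @property
    def bonds(self) -> np.ndarray:
        i = np.arange(self.n_beads - 1)
        return np.stack([i, i + 1], axis=1)

    @property
    def angles(self) -> np.ndarray:
        if self.n_beads < 3:
            return np.empty((0, 3), dtype=int)
        i = np.arange(self.n_beads - 2)
        return np.stack([i, i + 1, i + 2], axis=1)


def build_molecule(length_nm: float = 300.0,
                   bead_spacing_nm: float = 1.4) -> Molecule:
    """Straight chain along x with contour length within one bead spacing
    of ``length_nm``."""
    if not (length_nm > bead_spacing_nm > 0):
        raise ValueError("require length_nm > bead_spacing_nm > 0")
    n = int(round(length_nm / bead_spacing_nm)) + 1
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * bead_spacing_nm
    return Molecule(pos, bead_spacing_nm)


def hex_axis_positions(diameter_nm: float,
                       pitch_nm: float = DEFAULT_LATTICE_PITCH_NM) -> np.ndarray:
    """(y, z) lattice positions of molecule axes inside the cross-section."""
    R = diameter_nm / 2.0
    dy = pitch_nm
    dz = pitch_nm * np.sqrt(3.0) / 2.0
    jmax = int(R / dz) + 2
    imax = int(R / dy) + 2
    pts = []
    for j in range(-jmax, jmax + 1):
        z = j * dz
        off = 0.5 * dy * (j % 2)
        for i in range(-imax, imax + 1):
            y = i * dy + off
            if y * y + z * z <= R * R:
                pts.append((y, z))
    pts = np.array(pts)
    # deterministic order: by radius then angle
    r = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((ang, np.round(r, 9)))
    return pts[order]


@dataclass
class Fibril:
    """Packed, staggered, crosslinked molecule assembly.

    ``molecules`` lists every molecule (axial segments included);
    ``crosslinks`` holds (end-bead, partner-bead) global indices with the
    creation distance as the crosslink rest length.
    """

    molecules: list
    positions: np.ndarray             # (N, 3) all beads, nm
    molecule_id: np.ndarray           # (N,) molecule index per bead
    bonds: np.ndarray                 # (B, 2) backbone bonds, global indices
    angles: np.ndarray                # (A, 3) global indices
    crosslinks: np.ndarray            # (X, 2) global indices
    crosslink_rest: np.ndarray        # (X,) nm
    beta: float
    diameter: float                   # nm
    n_cross_section: int              # molecule axes in the cross-section
    microfibril_id: np.ndarray        # per cross-section site, groups of 5
    end_bead_ids: np.ndarray = field(default=None)  # (n_mol, 2)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def connected_ends_per_molecule(self) -> np.ndarray:
        """Number of this molecule's end beads bonded to another molecule."""
        ends_linked = {int(i) for i in self.crosslinks[:, 0]} if len(
            self.crosslinks) else set()
        out = np.zeros(self.n_molecules)
        for m, (e0, e1) in enumerate(self.end_bead_ids):
            out[m] = (e0 in ends_linked) + (e1 in ends_linked)
        return out


def build_fibril(diameter_nm: float = 21.5,
                 beta: float = 1.0,
                 stagger_nm: float | None = None,
                 seed: int = 0,
                 molecule_length_nm: float = 300.0,
                 bead_spacing_nm: float = 1.4,
                 n_axial: int = 1,
                 axial_gap_nm: float | None = None,
                 pitch_nm: float = DEFAULT_LATTICE_PITCH_NM) -> Fibril:
    """Build a crosslinked fibril.

    Parameters
    ----------
    diameter_nm : fibril diameter; must hold at least one molecule axis.
    beta : fraction of molecule ends crosslinked to adjacent molecules.
    stagger_nm : axial offset between the 5 members of a microfibril
        (default: a quarter molecule length).
    n_axial : number of molecules placed end-to-end on each lattice site
        (desk-scale tensile fixtures use 2 so that load must cross
        molecule junctions through crosslinks).
    axial_gap_nm : gap between consecutive molecules on a site
        (default: one bead spacing).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if diameter_nm < MOLECULE_DIAMETER_NM:
        raise ValueError("diameter smaller than one molecule")
    rng = np.random.default_rng(seed)
    axes = hex_axis_positions(diameter_nm, pitch_nm)
    n_sites = len(axes)
    microfibril_id = np.arange(n_sites) // 5
    if stagger_nm is None:
        stagger_nm = molecule_length_nm / 4.0
    if axial_gap_nm is None:
        axial_gap_nm = bead_spacing_nm

    proto = build_molecule(molecule_length_nm, bead_spacing_nm)
    seg_len = proto.contour_length + axial_gap_nm

    molecules, pos_blocks, mol_id_blocks = [], [], []
    bonds, angles, end_ids = [], [], []
    offset = 0
    mol_idx = 0
    for s, (y, z) in enumerate(axes):
        phase = s % 5
        x0 = phase * stagger_nm
        for k in range(n_axial):
            p = proto.bead_positions.copy()
            p[:, 0] += x0 + k * seg_len
            p[:, 1] += y
            p[:, 2] += z
            mol = Molecule(p, bead_spacing_nm)
            molecules.append(mol)
            pos_blocks.append(p)
            mol_id_blocks.append(np.full(mol.n_beads, mol_idx))
            bonds.append(mol.bonds + offset)
            angles.append(mol.angles + offset)
            end_ids.append((offset, offset + mol.n_beads - 1))
            offset += mol.n_beads
            mol_idx += 1

    positions = np.concatenate(pos_blocks)
    molecule_id = np.concatenate(mol_id_blocks)
    bonds = np.concatenate(bonds)
    angles = (np.concatenate(angles) if any(len(a) for a in angles)
              else np.empty((0, 3), dtype=int))
    end_ids = np.asarray(end_ids, dtype=int)

    # crosslinks: sample beta of all ends, bond each to the nearest
    # helical bead of a different molecule
    all_ends = end_ids.reshape(-1)
    n_pick = int(round(beta * all_ends.size))
    picked = (rng.choice(all_ends, size=n_pick, replace=False)
              if 0 < n_pick < all_ends.size else
              (all_ends if n_pick else np.empty(0, dtype=int)))
    is_end = np.zeros(len(positions), dtype=bool)
    is_end[all_ends] = True
    helical = np.flatnonzero(~is_end)
    xl, xl_rest = [], []
    if n_pick and len(helical):
        tree = cKDTree(positions[helical])
        for e in np.sort(picked):
            d, idx = tree.query(positions[e], k=12)
            for dist, hi in zip(np.atleast_1d(d), np.atleast_1d(idx)):
                b = helical[hi]
                if molecule_id[b] != molecule_id[e]:
                    xl.append((e, b))
                    xl_rest.append(dist)
                    break
    crosslinks = np.asarray(xl, dtype=int).reshape(-1, 2)
    crosslink_rest = np.asarray(xl_rest)

    return Fibril(molecules=molecules, positions=positions,
                  molecule_id=molecule_id, bonds=bonds, angles=angles,
                  crosslinks=crosslinks, crosslink_rest=crosslink_rest,
                  beta=beta, diameter=diameter_nm,
                  n_cross_section=n_sites, microfibril_id=microfibril_id,
                  end_bead_ids=end_ids)


def write_lammps_data(fibril: Fibril, path) -> None:
    """LAMMPS molecular-style data file (atoms, bonds, angles sections).

    Bond type 1 = backbone, 2 = crosslink; single atom and angle type.
    """
    pos = fibril.positions
    nb = len(fibril.bonds)
    nx = len(fibril.crosslinks)
    na = len(fibril.angles)
    lo = pos.min(axis=0) - 5.0
    hi = pos.max(axis=0) + 5.0
    with open(path, "w") as fh:
        fh.write("# coarse-grained collagen fibril\n\n")
        fh.write(f"{len(pos)} atoms\n{nb + nx} bonds\n{na} angles\n\n")
        fh.write("1 atom types\n2 bond types\n1 angle types\n\n")
        for d, name in zip(range(3), ("x", "y", "z")):
            fh.write(f"{lo[d]:.4f} {hi[d]:.4f} {name}lo {name}hi\n")
        fh.write("\nAtoms # molecular\n\n")
        for i, p in enumerate(pos):
            fh.write(f"{i + 1} {fibril.molecule_id[i] + 1} 1 "
                     f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        fh.write("\nBonds\n\n")
        k = 1
        for a, b in fibril.bonds:
            fh.write(f"{k} 1 {a + 1} {b + 1}\n")
            k += 1
        for a, b in fibril.crosslinks:
            fh.write(f"{k} 2 {a + 1} {b + 1}\n")
            k += 1
        if na:
            fh.write("\nAngles\n\n")
            for k, (a, b, c) in enumerate(fibril.angles, start=1):
                fh.write(f"{k} 1 {a + 1} {b + 1} {c + 1}\n")
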