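"""Rigid superposition and interface-contact detection.

Two stages connect sequence-level divergence calls to structure: (1) a
least-squares rigid superposition (Kabsch) of homologous chains over
matched C-alpha pairs, used to place a binding partner from one complex
into the frame of the other (e.g. inferring where a bacterial exchange
factor would sit on the eukaryotic elongation factor); and (2) all-heavy-
atom contact detection: an alignment column is a contact iff any atom of
its mapped residue lies within the cutoff (default 5.0 Å, inclusive) of
any atom of the partner chain.  The neighbor search uses uniform spatial
binning at cell size = cutoff; a brute-force all-pairs implementation is
kept as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np

from .data_io import ColumnResidueMap, Residue, StructureModel

__all__ = [
    "Superposition",
    "ContactSet",
    "kabsch",
    "apply_superposition",
    "superpose_partner",
    "contact_columns",
    "contact_columns_bruteforce",
]


@dataclass
class Superposition:
    """Proper rotation + translation minimizing RMSD over paired points."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class ContactSet:
    """Alignment columns whose residues touch the partner chain."""

    cutoff_A: float
    contacts: set[int]
    min_distance: dict[int, float]  # column -> min heavy-atom distance (Å)
    geometry_mode: str  # "native" | "superposed"


def kabsch(fixed_points: np.ndarray, moving_points: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Reflections are excluded by the determinant sign correction.  Requires
    >= 3 non-collinear pairs.
    """
    P = np.asarray(fixed_points, dtype=float)
    Q = np.asarray(moving_points, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matched (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 point pairs, got {n}")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    # collinearity check on either set: rank of centered coordinates < 2
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2 or np.linalg.matrix_rank(Q0, tol=1e-9) < 2:
        raise ValueError("point set is collinear; superposition is degenerate")
    H = Q0.T @ P0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Pc - R @ Qc
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_pairs=n)


def _residue_coords(res: Residue) -> np.ndarray:
    return np.array([a.xyz for a in res.atoms], dtype=float)


def apply_superposition(structure_chain: list[Residue], sup: Superposition) -> list[Residue]:
    """Return a transformed copy of a chain's residues."""
    out: list[Residue] = []
    for res in structure_chain:
        coords = sup.transform(_residue_coords(res))
        new_res = Residue(number=res.number, icode=res.icode, name=res.name)
        for atom, xyz in zip(res.atoms, coords):
            new_res.atoms.append(
                type(atom)(name=atom.name, element=atom.element, xyz=tuple(xyz))
            )
        out.append(new_res)
    return out


def superpose_partner(
    ef_structure: StructureModel,
    ef_chain: str,
    complex_structure: StructureModel,
    homolog_chain: str,
    partner_chain: str,
    pair_map: list[tuple[int, int]],
) -> tuple[list[Residue], Superposition]:
    """Place a partner chain from another complex into this structure's frame.

    ``pair_map`` lists matched residue numbers (ef_chain residue,
    homolog_chain residue); the homolog is fitted onto the reference over
    their C-alpha pairs and the same transform is applied to
    ``partner_chain``, yielding the partner's coordinates in the reference
    frame.
    """
    if len(pair_map) < 20:
        import warnings

        warnings.warn(f"only {len(pair_map)} C-alpha pairs for superposition")

    def ca_of(chain: list[Residue]) -> dict[int, np.ndarray]:
        out = {}
        for res in chain:
            for atom in res.atoms:
                if atom.name == "CA":
                    out[res.number] = np.array(atom.xyz)
                    break
        return out

    ca_ref = ca_of(ef_structure.chains[ef_chain])
    ca_mov = ca_of(complex_structure.chains[homolog_chain])
    fixed, moving = [], []
    for ref_num, mov_num in pair_map:
        if ref_num in ca_ref and mov_num in ca_mov:
            fixed.append(ca_ref[ref_num])
            moving.append(ca_mov[mov_num])
    sup = kabsch(np.array(fixed), np.array(moving))
    placed = apply_superposition(complex_structure.chains[partner_chain], sup)
    return placed, sup


def _chain_atom_coords(residues: list[Residue]) -> np.ndarray:
    coords = [a.xyz for res in residues for a in res.atoms]
    return np.array(coords, dtype=float).reshape(-1, 3)


def contact_columns(
    ef_structure: StructureModel,
    partner_residues: list[Residue],
    column_map: ColumnResidueMap,
    cutoff: float = 5.0,
    geometry_mode: str = "native",
) -> ContactSet:
    """Columns whose mapped residue has any heavy atom within ``cutoff`` Å
    of any partner heavy atom (inclusive boundary).

    Grid-accelerated: partner atoms are binned into cubic cells of side
    ``cutoff``; only the 27 neighboring cells of each query atom are
    scanned.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not column_map.pairs:
        raise ValueError("empty column-residue map")
    partner_xyz = _chain_atom_coords(partner_residues)
    if partner_xyz.size == 0:
        raise ValueError("partner chain has no atoms")

    grid: dict[tuple[int, int, int], list[int]] = defaultdict(list)
    cells = np.floor(partner_xyz / cutoff).astype(int)
    for idx, cell in enumerate(map(tuple, cells)):
        grid[cell].append(idx)

    contacts: set[int] = set()
    min_distance: dict[int, float] = {}
    for col, chain_id, resnum in column_map.pairs:
        residue = next(
            (r for r in ef_structure.chains[chain_id] if r.number == resnum), None
        )
        if residue is None or not residue.atoms:
            continue
        best = np.inf
        for atom in residue.atoms:
            p = np.asarray(atom.xyz)
            c = tuple(np.floor(p / cutoff).astype(int))
            cand: list[int] = []
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        cand.extend(grid.get((c[0] + dx, c[1] + dy, c[2] + dz), ()))
            if cand:
                d = np.sqrt(np.sum((partner_xyz[cand] - p) ** 2, axis=1)).min()
                best = min(best, float(d))
        # the grid only guarantees distances <= cutoff are found; refine
        # the reported minimum by brute force only for actual contacts
        if best <= cutoff:
            contacts.add(col)
            min_distance[col] = best
    return ContactSet(
        cutoff_A=cutoff, contacts=contacts, min_distance=min_distance,
        geometry_mode=geometry_mode,
    )


def contact_columns_bruteforce(
    ef_structure: StructureModel,
    partner_residues: list[Residue],
    column_map: ColumnResidueMap,
    cutoff: float = 5.0,
    geometry_mode: str = "native",
) -> ContactSet:
    """All-pairs reference implementation of :func:`contact_columns`."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not column_map.pairs:
        raise ValueError("empty column-residue map")
    partner_xyz = _chain_atom_coords(partner_residues)
    contacts: set[int] = set()
    min_distance: dict[int, float] = {}
    for col, chain_id, resnum in column_map.pairs:
        residue = next(
            (r for r in ef_structure.chains[chain_id] if r.number == resnum), None
        )
        if residue is None or not residue.atoms:
            continue
        xyz = _residue_coords(residue)
        d = np.sqrt(
            np.sum((xyz[:, None, :] - partner_xyz[None, :, :]) ** 2, axis=2)
        ).min()
        if d <= cutoff:
            contacts.add(col)
            min_distance[col] = float(d)
    return ContactSet(
        cutoff_A=cutoff, contacts=contacts, min_distance=min_distance,
        geometry_mode=geometry_mode,
    )


def write_contact_table(path, cs: ContactSet, column_map: ColumnResidueMap) -> None:
    with open(path, "w") as fh:
        fh.write("column\tchain\tresidue\tmin_distance_A\tgeometry_mode\n")
        for col, chain_id, resnum in column_map.pairs:
            if col in cs.contacts:
                fh.write(
                    f"{col}\t{chain_id}\t{resnum}\t"
                    f"{cs.min_distance[col]:.3f}\t{cs.geometry_mode}\n"
                )


def read_contact_table(path, cutoff: float = 5.0) -> ContactSet:
    """Read back a TSV written by :func:`write_contact_table`."""
    import csv

    contacts: set[int] = set()
    min_distance: dict[int, float] = {}
    mode = "native"
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            col = int(row[0])
            contacts.add(col)
            min_distance[col] = float(row[3])
            mode = row[4]
    return ContactSet(
        cutoff_A=cutoff, contacts=contacts, min_distance=min_distance,
        geometry_mode=mode,
    )
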