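"""Readers/writers for alignments, trees and PDB structures, and the
clustered-alignment container that every divergence statistic consumes.

A :class:`ClusteredAlignment` bundles a protein multiple sequence alignment,
a rooted bifurcating tree over the same taxa, and a two-cluster partition of
the taxa (e.g. eukaryotes vs. bacteria).  Both clusters must be monophyletic
in the tree; this is validated at construction time because every downstream
statistic (per-cluster substitution counts, Type-I/Type-II scoring) assumes
each cluster corresponds to one clade.

Conventions: alignment columns are 1-based throughout, gaps ('-') and 'X'
are missing data, and cluster labels are free strings with exactly two
clusters supported.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_CHARS = set(AMINO_ACIDS) | {"-", "X"}
MISSING_CHARS = {"-", "X"}

# residues treated as water when filtering HETATM-free structures
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


class MonophylyError(ValueError):
    """A cluster's leaves do not form a clade in the tree."""


class StructureError(ValueError):
    """Malformed PDB input."""


# ---------------------------------------------------------------------------
# alignment I/O


def read_alignment(path: str | Path, format: str = "fasta") -> tuple[list[str], list[str]]:
    """Read a protein alignment; returns ``(taxa, sequences)``.

    ``format`` is ``"fasta"`` or ``"phylip"`` (relaxed PHYLIP).  Residues are
    uppercased; the 20 canonical amino acids plus ``-`` and ``X`` are
    accepted.  Raises :class:`AlignmentError` for ragged alignments (naming
    the offending taxon) and for non-amino-acid symbols (with position).
    """
    path = Path(path)
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        taxa = [r.id for r in records]
        seqs = [str(r.seq).upper() for r in records]
    elif format == "phylip":
        taxa, seqs = _read_relaxed_phylip(path)
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    if not taxa:
        raise AlignmentError(f"no sequences found in {path}")
    _validate_alignment(taxa, seqs)
    return taxa, seqs


def _read_relaxed_phylip(path: Path) -> tuple[list[str], list[str]]:
    # relaxed PHYLIP: header "ntaxa ncols", then whitespace-separated
    # name/sequence rows, possibly interleaved
    lines = [ln.rstrip() for ln in path.read_text().splitlines() if ln.strip()]
    try:
        n_taxa, n_cols = (int(tok) for tok in lines[0].split()[:2])
    except (ValueError, IndexError) as exc:
        raise AlignmentError(f"bad PHYLIP header in {path}: {lines[0]!r}") from exc
    taxa: list[str] = []
    parts: list[list[str]] = []
    for ln in lines[1 : 1 + n_taxa]:
        toks = ln.split()
        taxa.append(toks[0])
        parts.append(["".join(toks[1:])])
    i = 1 + n_taxa
    while i < len(lines):  # interleaved continuation blocks
        for j in range(n_taxa):
            if i + j >= len(lines):
                break
            parts[j].append("".join(lines[i + j].split()))
        i += n_taxa
    seqs = ["".join(p).upper() for p in parts]
    for t, s in zip(taxa, seqs):
        if len(s) != n_cols:
            raise AlignmentError(
                f"PHYLIP sequence for {t!r} has length {len(s)}, header says {n_cols}"
            )
    return taxa, seqs


def _validate_alignment(taxa: Sequence[str], seqs: Sequence[str]) -> None:
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise AlignmentError(f"duplicate taxon names: {dupes}")
    n = len(seqs[0])
    for t, s in zip(taxa, seqs):
        if len(s) != n:
            raise AlignmentError(
                f"ragged alignment: taxon {t!r} has length {len(s)}, expected {n}"
            )
        for i, ch in enumerate(s):
            if ch not in VALID_CHARS:
                raise AlignmentError(
                    f"non-amino-acid symbol {ch!r} in taxon {t!r} at column {i + 1}"
                )
    if n < 1:
        raise AlignmentError("alignment has zero columns")


def write_alignment(path: str | Path, taxa: Sequence[str], seqs: Sequence[str]) -> None:
    """Write a FASTA alignment preserving taxa order."""
    with open(path, "w") as fh:
        for t, s in zip(taxa, seqs):
            fh.write(f">{t}\n{s}\n")


# ---------------------------------------------------------------------------
# clustered alignment


@dataclass
class ClusteredAlignment:
    """Protein MSA + rooted tree + two-cluster taxon partition.

    Use :func:`build_clustered_alignment` to construct with validation.
    """

    taxa: list[str]
    sequences: list[str]
    tree: dendropy.Tree
    cluster_of: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def cluster_labels(self) -> tuple[str, str]:
        labels = sorted(set(self.cluster_of.values()))
        return labels[0], labels[1]

    def taxa_in_cluster(self, label: str) -> list[str]:
        return [t for t in self.taxa if self.cluster_of[t] == label]

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def column(self, col: int) -> dict[str, str]:
        """States of 1-based column ``col``, keyed by taxon."""
        return {t: s[col - 1] for t, s in zip(self.taxa, self.sequences)}


def read_tree(path_or_str: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree from a file path or a Newick string."""
    src = str(path_or_str)
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    tree.is_rooted = True
    return tree


def build_clustered_alignment(
    alignment: tuple[Sequence[str], Sequence[str]],
    tree: dendropy.Tree | str | Path,
    cluster_assignment: Mapping[str, str],
) -> ClusteredAlignment:
    """Assemble and validate a :class:`ClusteredAlignment`.

    ``alignment`` is ``(taxa, sequences)`` as returned by
    :func:`read_alignment`.  ``cluster_assignment`` maps every taxon to one
    of exactly two cluster labels.  Both clusters must contain >= 2 taxa and
    be monophyletic in the (rooted) tree.
    """
    taxa, seqs = list(alignment[0]), list(alignment[1])
    _validate_alignment(taxa, seqs)
    if not isinstance(tree, dendropy.Tree):
        tree = read_tree(tree)
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if sorted(leaf_labels) != sorted(taxa):
        missing = set(taxa) - set(leaf_labels)
        extra = set(leaf_labels) - set(taxa)
        raise ValueError(
            f"tree leaves do not match alignment taxa (missing from tree: "
            f"{sorted(missing)}, extra in tree: {sorted(extra)})"
        )
    unassigned = [t for t in taxa if t not in cluster_assignment]
    if unassigned:
        raise ValueError(f"taxa without cluster assignment: {unassigned}")
    cluster_of = {t: str(cluster_assignment[t]) for t in taxa}
    labels = sorted(set(cluster_of.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two clusters required, got {labels}")
    for lab in labels:
        members = [t for t in taxa if cluster_of[t] == lab]
        if len(members) < 2:
            raise ValueError(f"cluster {lab!r} has {len(members)} taxa; >= 2 required")
        _check_monophyly(tree, members, lab)
    return ClusteredAlignment(taxa=taxa, sequences=seqs, tree=tree, cluster_of=cluster_of)


def _check_monophyly(tree: dendropy.Tree, members: Sequence[str], label: str) -> None:
    member_set = set(members)
    mrca = tree.mrca(taxon_labels=members)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    intruders = clade - member_set
    if intruders:
        raise MonophylyError(
            f"cluster {label!r} is not monophyletic: its smallest containing "
            f"clade also holds {sorted(intruders)}"
        )


def read_clusters(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``taxon<TAB>cluster`` into a dict."""
    out: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        toks = ln.split("\t")
        if len(toks) < 2:
            raise ValueError(f"bad cluster line: {ln!r}")
        out[toks[0]] = toks[1]
    return out


# ---------------------------------------------------------------------------
# PDB structures

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]


@dataclass
class Residue:
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    """Chains of residues with heavy-atom coordinates (Å)."""

    chains: dict[str, list[Residue]]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain_id])


def read_structure(path: str | Path, include_hetatm: bool = False) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    ATOM records only by default (HETATM and waters excluded); for alternate
    locations the first-listed conformer is kept; only MODEL 1 is read;
    hydrogens are dropped.  Fixed-width fields per the wwPDB v3.3 layout.
    """
    chains: dict[str, list[Residue]] = {}
    # (chain, reskey, atom name) already seen -> skip later altlocs
    seen_atoms: set[tuple[str, tuple[int, str], str]] = set()
    res_index: dict[tuple[str, tuple[int, str]], Residue] = {}
    in_later_model = False
    n_atom_records = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            try:
                in_later_model = int(line.split()[1]) != 1
            except (IndexError, ValueError):
                in_later_model = False
            continue
        if rec.startswith("ENDMDL"):
            in_later_model = True  # anything after the first ENDMDL is model >1
            continue
        if in_later_model:
            continue
        is_atom = rec == "ATOM  "
        is_het = rec == "HETATM"
        if not (is_atom or (is_het and include_hetatm)):
            continue
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain_id = line[21].strip() or " "
            resseq = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            element = line[76:78].strip() or name[:1]
        except (ValueError, IndexError) as exc:
            raise StructureError(f"unparseable ATOM record at line {lineno}: {line!r}") from exc
        if not all(math.isfinite(v) for v in (x, y, z)):
            raise StructureError(f"non-finite coordinate at line {lineno}")
        if resname in _WATER_NAMES or element == "H":
            continue
        n_atom_records += 1
        reskey = (resseq, icode)
        atom_id = (chain_id, reskey, name)
        if atom_id in seen_atoms:  # later altloc conformer
            continue
        seen_atoms.add(atom_id)
        if (chain_id, reskey) not in res_index:
            residue = Residue(number=resseq, icode=icode, name=resname)
            res_index[(chain_id, reskey)] = residue
            chains.setdefault(chain_id, []).append(residue)
        res_index[(chain_id, reskey)].atoms.append(
            Atom(name=name, element=element, xyz=(x, y, z))
        )
    if n_atom_records == 0:
        warnings.warn(f"no ATOM records parsed from {path}; empty structure")
    return StructureModel(chains=chains)


def write_structure(path: str | Path, structure: StructureModel) -> None:
    """Write a minimal PDB file (ATOM records, single model)."""
    with open(path, "w") as fh:
        serial = 1
        for chain_id, residues in structure.chains.items():
            for res in residues:
                for atom in res.atoms:
                    x, y, z = atom.xyz
                    if max(abs(x), abs(y), abs(z)) >= 1000.0:
                        raise StructureError(
                            f"coordinate {max(abs(x), abs(y), abs(z)):.1f} overflows "
                            "the fixed-width PDB coordinate field"
                        )
                    fh.write(
                        f"ATOM  {serial:5d} {atom.name:^4s} {res.name:>3s} "
                        f"{chain_id}{res.number:4d}{res.icode or ' '}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}\n"
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# alignment column <-> structure residue mapping


@dataclass
class ColumnResidueMap:
    """Mapping of 1-based alignment columns to residues of one chain."""

    pairs: list[tuple[int, str, int]]  # (column, chain_id, residue_number)
    identity: float

    @property
    def columns(self) -> list[int]:
        return [p[0] for p in self.pairs]

    def residue_of(self, column: int) -> tuple[str, int] | None:
        for col, ch, num in self.pairs:
            if col == column:
                return (ch, num)
        return None


def map_columns_to_residues(
    ca: ClusteredAlignment,
    taxon: str,
    structure: StructureModel,
    chain: str,
    min_identity: float = 0.90,
) -> ColumnResidueMap:
    """Map alignment columns of ``taxon`` to residue numbers of ``chain``.

    The taxon's ungapped sequence is globally aligned (BLOSUM62, affine
    gaps) to the chain's residue sequence; identically aligned non-gap
    positions become (column, chain, residue-number) pairs.  Raises if the
    mapping identity falls below ``min_identity`` — usually the wrong chain.
    """
    if taxon not in ca.taxa:
        raise ValueError(f"taxon {taxon!r} not in alignment")
    if chain not in structure.chains:
        raise ValueError(f"chain {chain!r} not in structure")
    aligned = ca.sequence_of(taxon)
    # ungapped residue index -> alignment column (1-based)
    cols_of_residue: list[int] = [i + 1 for i, ch in enumerate(aligned) if ch != "-"]
    seq = aligned.replace("-", "")
    chain_residues = structure.chains[chain]
    chain_seq = "".join(r.one_letter for r in chain_residues)

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(seq, chain_seq)[0]

    pairs: list[tuple[int, str, int]] = []
    n_match = 0
    n_aligned = 0
    for (s_start, s_end), (c_start, c_end) in zip(*aln.aligned):
        for off in range(s_end - s_start):
            si, ci = s_start + off, c_start + off
            n_aligned += 1
            if seq[si] == chain_seq[ci]:
                n_match += 1
            pairs.append((cols_of_residue[si], chain, chain_residues[ci].number))
    identity = n_match / n_aligned if n_aligned else 0.0
    if identity < min_identity:
        raise ValueError(
            f"column-residue mapping identity {identity:.2f} below floor "
            f"{min_identity:.2f}; chain {chain!r} may not correspond to taxon {taxon!r}"
        )
    pairs.sort()
    return ColumnResidueMap(pairs=pairs, identity=identity)
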