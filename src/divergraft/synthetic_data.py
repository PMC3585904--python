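"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here with known truth:

* two-clade protein alignments + trees, with per-site classes planted as
  null (one gamma rate shared by both clades), Type-I (independent clade
  rates at a configured fast:slow ratio, with the slow clade set per
  class), or Type-II (a single forced state switch on the stem branch and
  near-zero within-clade rates — the Conserved-But-Different footprint);
* toy two-chain complex structures in which the partner chain has exactly
  one atom within the contact cutoff of each planted interface residue and
  stays well clear of all others, plus a rigidly moved copy of the same
  complex for superposition tests;
* assay tables (band-intensity pairs and CPM replicates) with planted
  bound fractions, fold effects, and optional gross outliers.

Substitutions follow a Poisson process per branch with uniform replacement
over the 19 alternative residues — deliberately simple so every planted
signal is oracle-checkable.  All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    AMINO_ACIDS,
    Atom,
    ClusteredAlignment,
    Residue,
    StructureModel,
    build_clustered_alignment,
    write_alignment,
    write_structure,
)
from .parsimony import SiteCountTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "paperlike_config",
    "simulate_alignment",
    "simulate_counts",
    "simulate_complex",
    "simulate_band_table",
    "simulate_cpm_table",
]

SITE_CLASSES = ("null", "type1_slowA", "type1_slowB", "type2")


@dataclass
class SimConfig:
    """Study conditions for the alignment simulator.

    Defaults mirror a two-domain elongation-factor-like family: 15 + 15
    taxa, ~400 alignment columns, a 30% heterotachous site fraction (on
    the order of coefficients of functional divergence reported for deep
    inter-domain protein families) plus 5% Conserved-But-Different sites,
    exponential among-site rate variation (gamma shape 1), about five
    substitutions per site per clade at the average rate (a deep split),
    and a 10-fold fast:slow rate ratio at Type-I sites.
    """

    n_taxa_A: int = 15
    n_taxa_B: int = 15
    n_sites: int = 400
    prop_type1: float = 0.30  # split evenly between slow-A and slow-B
    prop_type2: float = 0.05
    alpha_sim: float = 1.0
    depth_A: float = 5.0
    depth_B: float = 5.0
    type1_rate_ratio: float = 10.0
    type2_within_rate: float = 0.005
    stem_length: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa_A < 2 or self.n_taxa_B < 2:
            raise ValueError("each clade needs >= 2 taxa")
        if self.prop_type1 < 0 or self.prop_type2 < 0 or (
            self.prop_type1 + self.prop_type2 > 1
        ):
            raise ValueError("site-class proportions must be >= 0 and sum <= 1")
        if self.depth_A <= 0 or self.depth_B <= 0 or self.alpha_sim <= 0:
            raise ValueError("depths and alpha_sim must be positive")
        if self.type1_rate_ratio <= 1:
            raise ValueError("type1_rate_ratio must exceed 1")


@dataclass
class SimTruth:
    """Planted per-site truth for one simulated alignment."""

    site_class: list[str]  # per column, one of SITE_CLASSES
    rate_A: np.ndarray
    rate_B: np.ndarray
    seed: int

    def sites_of_class(self, cls: str) -> set[int]:
        return {i + 1 for i, c in enumerate(self.site_class) if c == cls}


def paperlike_config(seed: int = 0) -> SimConfig:
    """The default 15 + 15 taxon study-condition preset."""
    return SimConfig(seed=seed)


# ---------------------------------------------------------------------------
# random clade trees (sequential coalescent), scaled to a target total length


def _build_clade(labels: list[str], rng: np.random.Generator):
    """Random coalescent topology; returns (node structure, total length).

    Node structure: ('leaf', label) or ('node', left, right, bl_l, bl_r).
    """
    items: list[tuple[object, float]] = [(("leaf", lab), 0.0) for lab in labels]
    height = 0.0
    total = 0.0
    while len(items) > 1:
        k = len(items)
        height += float(rng.exponential(2.0 / (k * (k - 1))))
        i, j = (int(v) for v in rng.choice(k, size=2, replace=False))
        first, second = max(i, j), min(i, j)
        a = items.pop(first)
        b = items.pop(second)
        bl_a = height - a[1]
        bl_b = height - b[1]
        total += bl_a + bl_b
        items.append((("node", a[0], b[0], bl_a, bl_b), height))
    return items[0][0], total


def _emit_newick(node, branch_length: float) -> str:
    if node[0] == "leaf":
        return node[1]
    _, left, right, _, _ = node
    return (
        f"({_emit_newick(left, branch_length)}:{branch_length:.8f},"
        f"{_emit_newick(right, branch_length)}:{branch_length:.8f})"
    )


def _clade_newick(labels: list[str], depth: float, rng: np.random.Generator) -> str:
    # balanced-ish clade: coalescent topology, equal branch lengths summing
    # to the target depth (avoids the parsimony saturation that a few very
    # long coalescent branches would cause)
    node, _ = _build_clade(labels, rng)
    n_branches = 2 * len(labels) - 2
    return _emit_newick(node, depth / n_branches)


# ---------------------------------------------------------------------------
# sequence evolution


def _mutate(state: str, n_subs: int, rng: np.random.Generator) -> str:
    for _ in range(n_subs):
        alternatives = AMINO_ACIDS.replace(state, "")
        state = alternatives[int(rng.integers(19))]
    return state


def _evolve_clade(tree, root_state: str, rate: float, rng: np.random.Generator) -> dict[str, str]:
    """Leaf states after Poisson-process evolution from the clade root."""
    states: dict[int, str] = {id(tree.seed_node): root_state}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        bl = node.edge.length or 0.0
        n_subs = int(rng.poisson(rate * bl)) if rate > 0 and bl > 0 else 0
        st = _mutate(parent_state, n_subs, rng)
        states[id(node)] = st
        if node.is_leaf():
            out[node.taxon.label] = st
    return out


def simulate_alignment(config: SimConfig) -> tuple[ClusteredAlignment, SimTruth]:
    """Simulate a two-clade alignment with planted site classes.

    Null sites share one rate lambda ~ Gamma(alpha_sim, alpha_sim) across
    both clades; Type-I sites draw independent clade rates scaled by
    1/sqrt(ratio) (slow clade) and sqrt(ratio) (fast clade); Type-II sites
    switch state once on the stem and evolve at ``type2_within_rate``
    within each clade.  Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels_A = [f"euk{i + 1:02d}" for i in range(config.n_taxa_A)]
    labels_B = [f"bac{i + 1:02d}" for i in range(config.n_taxa_B)]
    nw_A = _clade_newick(labels_A, config.depth_A, rng)
    nw_B = _clade_newick(labels_B, config.depth_B, rng)
    full_newick = f"({nw_A}:{config.stem_length},{nw_B}:{config.stem_length});"

    import dendropy

    tree_A = dendropy.Tree.get(data=nw_A + ";", schema="newick")
    tree_B = dendropy.Tree.get(data=nw_B + ";", schema="newick")
    tree_A.is_rooted = tree_B.is_rooted = True

    p1 = config.prop_type1 / 2.0
    probs = [1 - config.prop_type1 - config.prop_type2, p1, p1, config.prop_type2]
    classes = [
        SITE_CLASSES[int(k)]
        for k in rng.choice(4, size=config.n_sites, p=probs)
    ]

    ratio = config.type1_rate_ratio
    slow_f, fast_f = ratio ** -0.5, ratio ** 0.5
    rate_A = np.zeros(config.n_sites)
    rate_B = np.zeros(config.n_sites)
    cols_A: dict[str, list[str]] = {t: [] for t in labels_A}
    cols_B: dict[str, list[str]] = {t: [] for t in labels_B}

    for i, cls in enumerate(classes):
        root = AMINO_ACIDS[int(rng.integers(20))]
        if cls == "null":
            lam = float(rng.gamma(config.alpha_sim, 1.0 / config.alpha_sim))
            rA = rB = lam
            root_A = _mutate(root, int(rng.poisson(rA * config.stem_length)), rng)
            root_B = _mutate(root, int(rng.poisson(rB * config.stem_length)), rng)
        elif cls in ("type1_slowA", "type1_slowB"):
            # the prototype heterotachous contrast: one clade consistently
            # slow, the other consistently fast, geometric mean = average rate
            if cls == "type1_slowA":
                rA, rB = slow_f, fast_f
            else:
                rA, rB = fast_f, slow_f
            root_A = _mutate(root, int(rng.poisson(rA * config.stem_length)), rng)
            root_B = _mutate(root, int(rng.poisson(rB * config.stem_length)), rng)
        else:  # type2: forced stem switch, near-frozen clades
            rA = rB = config.type2_within_rate
            root_A = root
            root_B = _mutate(root, 1, rng)  # exactly one stem replacement
        rate_A[i], rate_B[i] = rA, rB
        leaf_A = _evolve_clade(tree_A, root_A, rA, rng)
        leaf_B = _evolve_clade(tree_B, root_B, rB, rng)
        for t in labels_A:
            cols_A[t].append(leaf_A[t])
        for t in labels_B:
            cols_B[t].append(leaf_B[t])

    taxa = labels_A + labels_B
    seqs = ["".join(cols_A[t]) for t in labels_A] + ["".join(cols_B[t]) for t in labels_B]
    cluster_of = {t: "A" for t in labels_A} | {t: "B" for t in labels_B}
    ca = build_clustered_alignment((taxa, seqs), full_newick, cluster_of)
    truth = SimTruth(site_class=classes, rate_A=rate_A, rate_B=rate_B, seed=config.seed)
    return ca, truth


def simulate_counts(
    n_sites: int,
    theta: float,
    alpha: float,
    D_A: float,
    D_B: float,
    rng: np.random.Generator,
) -> tuple[SiteCountTable, np.ndarray]:
    """Draw paired counts directly from the Type-I mixture (for parameter-
    recovery studies).  Returns (table, is_divergent truth array)."""
    is_div = rng.random(n_sites) < theta
    lam_shared = rng.gamma(alpha, 1.0 / alpha, n_sites)
    lam_A = np.where(is_div, rng.gamma(alpha, 1.0 / alpha, n_sites), lam_shared)
    lam_B = np.where(is_div, rng.gamma(alpha, 1.0 / alpha, n_sites), lam_shared)
    x = rng.poisson(D_A * lam_A)
    y = rng.poisson(D_B * lam_B)
    table = SiteCountTable(
        x_A=x.astype(int), x_B=y.astype(int),
        flagged=np.zeros(n_sites, dtype=bool), label_A="A", label_B="B",
    )
    return table, is_div


# ---------------------------------------------------------------------------
# toy complex structures


@dataclass
class ComplexTruth:
    planted_columns: set[int]
    cutoff: float
    rotation: np.ndarray
    translation: np.ndarray
    seed: int


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def simulate_complex(
    n_residues: int,
    planted_contact_columns: set[int],
    cutoff: float = 5.0,
    seed: int = 0,
    sequence: str | None = None,
    ef_chain_id: str = "A",
    partner_chain_id: str = "B",
) -> tuple[StructureModel, StructureModel, ComplexTruth]:
    """Build a toy EF/partner complex with exactly the planted contacts.

    The EF chain runs along a gently curving backbone with 12 Å residue
    spacing; for each planted column the partner chain holds one atom at
    cutoff - 0.5 Å from that residue's C-alpha, while every other partner
    atom stays >= cutoff + 2 Å from all EF atoms.  Returns the native
    complex, the same complex under a random rigid motion, and the truth.
    """
    if cutoff <= 0.5:
        raise ValueError("cutoff too small for the placement margins")
    planted = set(planted_contact_columns)
    if not planted <= set(range(1, n_residues + 1)):
        raise ValueError("planted columns outside 1..n_residues")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    rng = np.random.default_rng(seed)

    # CA positions snake through a coarse cubic grid: a compact self-avoiding
    # curve whose coordinates stay within PDB fixed-width fields even after
    # an arbitrary rigid motion, with every residue pair >= `spacing` apart
    # neighbor residues must stay >= cutoff + 2 from a planted partner atom
    # sitting cutoff - 0.5 above a CA, hence the cutoff-dependent spacing
    spacing = max(14.0, 2.0 * cutoff + 4.5)
    side = int(np.ceil(n_residues ** (1.0 / 3.0)))
    ef_residues: list[Residue] = []
    ca_pos: dict[int, np.ndarray] = {}
    for i in range(1, n_residues + 1):
        k = i - 1
        layer, rem = divmod(k, side * side)
        row, col = divmod(rem, side)
        if layer % 2:  # reverse row order on alternating layers
            row = side - 1 - row
        if row % 2:  # snake within each layer
            col = side - 1 - col
        ca = spacing * np.array([float(col), float(row), float(layer)])
        ca_pos[i] = ca
        res = Residue(number=i, icode="", name=_ONE_TO_THREE[sequence[i - 1]])
        res.atoms = [
            Atom("N", "N", tuple(ca + np.array([-0.8, 0.5, 0.0]))),
            Atom("CA", "C", tuple(ca)),
            Atom("C", "C", tuple(ca + np.array([0.8, 0.5, 0.0]))),
        ]
        ef_residues.append(res)

    partner_residues: list[Residue] = []
    for i in range(1, n_residues + 1):
        if i in planted:
            pos = ca_pos[i] + np.array([0.0, 0.0, cutoff - 0.5])
        else:  # parked on a rail well outside the EF grid
            pos = np.array([2.0 * i, -40.0, -40.0])
        res = Residue(number=i, icode="", name="GLY")
        res.atoms = [Atom("CA", "C", tuple(pos))]
        partner_residues.append(res)

    # verify the planted geometry before handing it to any consumer:
    # per EF residue, the min distance to ANY partner atom must respect
    # the contact / clearance margins
    partner_xyz = np.array([r.atoms[0].xyz for r in partner_residues])
    for res in ef_residues:
        res_xyz = np.array([a.xyz for a in res.atoms])
        d = np.sqrt(
            ((res_xyz[:, None, :] - partner_xyz[None, :, :]) ** 2).sum(axis=2)
        ).min()
        if res.number in planted:
            if d > cutoff:
                raise RuntimeError("planted contact placement infeasible")
        elif d < cutoff + 2.0:
            raise RuntimeError("non-contact placement violates the margin")

    native = StructureModel(chains={ef_chain_id: ef_residues, partner_chain_id: partner_residues})

    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)

    def moved_chain(residues: list[Residue]) -> list[Residue]:
        out = []
        for res in residues:
            nr = Residue(number=res.number, icode=res.icode, name=res.name)
            for a in res.atoms:
                nr.atoms.append(Atom(a.name, a.element, tuple(R @ np.array(a.xyz) + t)))
            out.append(nr)
        return out

    moved = StructureModel(
        chains={
            ef_chain_id: moved_chain(ef_residues),
            partner_chain_id: moved_chain(partner_residues),
        }
    )
    truth = ComplexTruth(
        planted_columns=planted, cutoff=cutoff, rotation=R, translation=t, seed=seed
    )
    return native, moved, truth


def write_complex_files(outdir: Path, native: StructureModel, moved: StructureModel) -> tuple[Path, Path]:
    outdir = Path(outdir)
    p1 = outdir / "complex_native.pdb"
    p2 = outdir / "complex_moved.pdb"
    write_structure(p1, native)
    write_structure(p2, moved)
    return p1, p2


# ---------------------------------------------------------------------------
# assay tables


def simulate_band_table(
    bound_fractions: dict[str, float],
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    total_intensity: float = 1000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Band-intensity pairs with planted true bound fractions (percent
    recoverable as 100 * exchange / (EF + exchange)).  Multiplicative
    lognormal noise on each band; noise_sd = 0 reproduces the planted
    fractions exactly."""
    rng = np.random.default_rng(seed)
    rows = []
    for variant, frac in bound_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"bound fraction for {variant!r} outside [0, 1]")
        for rep in range(1, n_replicates + 1):
            noise_ef = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
            noise_ex = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
            rows.append(
                {
                    "variant": variant,
                    "replicate": rep,
                    "band_EF": total_intensity * (1 - frac) * noise_ef,
                    "band_exchange": total_intensity * frac * noise_ex,
                }
            )
    return pd.DataFrame(rows)


def simulate_cpm_table(
    variant_folds: dict[str, float],
    n_replicates: int = 15,
    background_label: str = "none",
    background_mean: float = 2000.0,
    noise_sd: float = 0.15,
    outlier: tuple[str, int, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """CPM replicates per variant: background * fold + relative Gaussian
    noise, with the background variant itself at fold 1.  ``outlier``
    plants one gross value at (variant, replicate index, z SDs above the
    variant mean).  Replicates alternate between the two refolding-buffer
    labels."""
    rng = np.random.default_rng(seed)
    folds = {background_label: 1.0} | dict(variant_folds)
    rows = []
    for variant, fold in folds.items():
        mean = background_mean * fold
        sd = noise_sd * mean
        for rep in range(1, n_replicates + 1):
            value = float(mean + rng.normal(0.0, sd)) if noise_sd > 0 else mean
            if outlier is not None and outlier[0] == variant and outlier[1] == rep:
                value = mean + outlier[2] * sd
            rows.append(
                {
                    "variant": variant,
                    "replicate": rep,
                    "cpm": max(value, 0.0),
                    "buffer": "500mM_urea" if rep % 2 else "125mM_urea",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk bundle for the CLI


def write_simulated_inputs(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic input bundle (alignment, tree, clusters,
    native + donor complex structures, truth table) for a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ca, truth = simulate_alignment(config)

    aln_path = outdir / "alignment.fasta"
    write_alignment(aln_path, ca.taxa, ca.sequences)
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(ca.tree.as_string(schema="newick").strip() + "\n")
    clusters_path = outdir / "clusters.tsv"
    clusters_path.write_text(
        "".join(f"{t}\t{ca.cluster_of[t]}\n" for t in ca.taxa)
    )

    # native interface: slow-in-A Type-I sites + a margin of null contacts;
    # donor interface (for the superposed geometry): slow-in-B + Type-II
    rng = np.random.default_rng(config.seed + 1)
    null_sites = sorted(truth.sites_of_class("null"))
    extra_native = [int(s) for s in rng.choice(null_sites, size=min(17, len(null_sites)), replace=False)]
    remaining = sorted(set(null_sites) - set(extra_native))
    extra_donor = [int(s) for s in rng.choice(remaining, size=min(17, len(remaining)), replace=False)]

    recipient = ca.taxa_in_cluster("A")[0]
    seq = ca.sequence_of(recipient).replace("-", "")
    native_cols = truth.sites_of_class("type1_slowA") | set(extra_native)
    donor_cols = (
        truth.sites_of_class("type1_slowB")
        | truth.sites_of_class("type2")
        | set(extra_donor)
    )
    native_cplx, _, _ = simulate_complex(
        ca.n_columns, native_cols, seed=config.seed + 2, sequence=seq
    )
    donor_native, donor_moved, _ = simulate_complex(
        ca.n_columns, donor_cols, seed=config.seed + 3, sequence=seq
    )
    native_path = outdir / "native_complex.pdb"
    write_structure(native_path, native_cplx)
    donor_path = outdir / "donor_complex.pdb"
    write_structure(donor_path, donor_moved)  # donor complex in its own frame

    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        fh.write("site\tclass\trate_A\trate_B\tnative_contact\tdonor_contact\n")
        for i in range(config.n_sites):
            fh.write(
                f"{i + 1}\t{truth.site_class[i]}\t{truth.rate_A[i]:.6f}\t"
                f"{truth.rate_B[i]:.6f}\t{int(i + 1 in native_cols)}\t"
                f"{int(i + 1 in donor_cols)}\n"
            )
    return {
        "alignment": aln_path,
        "tree": tree_path,
        "clusters": clusters_path,
        "native_complex": native_path,
        "donor_complex": donor_path,
        "truth": truth_path,
    }
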