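import warnings

import dendropy
import numpy as np
import pytest

from divergraft.data_io import (
    AlignmentError,
    MonophylyError,
    StructureError,
    build_clustered_alignment,
    map_columns_to_residues,
    read_alignment,
    read_structure,
    read_tree,
    write_alignment,
    write_structure,
)
from divergraft.synthetic_data import simulate_complex


def test_fasta_parse_and_roundtrip(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1\nAC-D\n>s2\nACED\n")
    taxa, seqs = read_alignment(p)
    assert taxa == ["s1", "s2"]
    assert seqs == ["AC-D", "ACED"]
    out = tmp_path / "b.fa"
    write_alignment(out, taxa, seqs)
    assert read_alignment(out) == (taxa, seqs)


def test_ragged_alignment_names_offender(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1\nACDE\n>s2\nACDEF\n")
    with pytest.raises(AlignmentError, match="ragged.*s2"):
        read_alignment(p)


def test_invalid_symbol_reports_position(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1\nACZE\n>s2\nACDE\n")
    with pytest.raises(AlignmentError, match="'Z'.*column 3"):
        read_alignment(p)


def test_relaxed_phylip(tmp_path):
    p = tmp_path / "a.phy"
    p.write_text("2 4\ns1  AC-D\ns2  ACED\n")
    taxa, seqs = read_alignment(p, format="phylip")
    assert taxa == ["s1", "s2"]
    assert seqs == ["AC-D", "ACED"]


def test_quartet_clustering_valid(quartet_alignment):
    ca = quartet_alignment
    assert ca.n_columns == 4
    assert ca.cluster_labels == ("A", "B")
    assert ca.taxa_in_cluster("A") == ["a", "b"]


def test_non_monophyletic_cluster_rejected():
    taxa = ["a", "b", "c", "d"]
    seqs = ["AAAA"] * 4
    tree = "((a:1,b:1):1,(c:1,d:1):1);"
    with pytest.raises(MonophylyError):
        build_clustered_alignment(
            (taxa, seqs), tree, {"a": "A", "c": "A", "b": "B", "d": "B"}
        )


def test_tree_taxon_mismatch_rejected():
    with pytest.raises(ValueError, match="do not match"):
        build_clustered_alignment(
            (["a", "b", "c"], ["AA", "AA", "AA"]),
            "((a:1,b:1):1,(x:1,c:1):1);",
            {"a": "A", "b": "A", "c": "B"},
        )


def _brute_force_monophyletic(tree, members):
    member_set = set(members)
    for node in tree.preorder_node_iter():
        if {lf.taxon.label for lf in node.leaf_iter()} == member_set:
            return True
    return False


def test_monophyly_agrees_with_bruteforce_on_small_trees(rng):
    """Validation must agree with scanning every clade of the tree."""
    for _ in range(60):
        n = int(rng.integers(4, 9))
        labels = [f"t{i}" for i in range(n)]
        items = list(labels)
        while len(items) > 1:
            i, j = sorted(rng.choice(len(items), 2, replace=False), reverse=True)
            a, b = items.pop(int(i)), items.pop(int(j))
            items.append(f"({a}:1,{b}:1)")
        tree = read_tree(items[0] + ";")
        k = int(rng.integers(2, n - 1))
        members = [labels[int(i)] for i in rng.choice(n, size=k, replace=False)]
        rest = [t for t in labels if t not in members]
        expected = _brute_force_monophyletic(tree, members) and _brute_force_monophyletic(
            tree, rest
        ) if len(rest) >= 2 else None
        if expected is None:
            continue
        seqs = ["A" * 3] * n
        assignment = {t: ("A" if t in members else "B") for t in labels}
        if expected:
            build_clustered_alignment((labels, seqs), tree, assignment)
        else:
            with pytest.raises(MonophylyError):
                build_clustered_alignment((labels, seqs), tree, assignment)


# ---------------------------------------------------------------------------
# structures


def test_toy_pdb_roundtrip(tmp_path):
    native, _, _ = simulate_complex(10, {3, 7}, seed=5)
    p = tmp_path / "toy.pdb"
    write_structure(p, native)
    model = read_structure(p)
    assert set(model.chains) == {"A", "B"}
    assert len(model.chains["A"]) == 10
    assert len(model.chains["B"]) == 10
    # coordinates survive to PDB precision
    orig = np.array([a.xyz for r in native.chains["A"] for a in r.atoms])
    back = np.array([a.xyz for r in model.chains["A"] for a in r.atoms])
    assert np.allclose(orig, back, atol=5e-4)


def test_hetatm_only_file_is_empty_with_warning(tmp_path):
    p = tmp_path / "het.pdb"
    p.write_text(
        "HETATM    1 MG    MG A 501      10.000  10.000  10.000  1.00  0.00          MG\n"
        "END\n"
    )
    with pytest.warns(UserWarning, match="no ATOM records"):
        model = read_structure(p)
    assert model.chains == {}


def test_altloc_keeps_first_conformer(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(
        "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C\n"
        "END\n"
    )
    model = read_structure(p)
    (res,) = model.chains["A"]
    assert len(res.atoms) == 1
    assert res.atoms[0].xyz[0] == pytest.approx(1.0)


def test_models_beyond_first_ignored(tmp_path):
    p = tmp_path / "m.pdb"
    p.write_text(
        "MODEL        1\n"
        "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      2  CA  ALA A   2       2.000   0.000   0.000  1.00  0.00           C\n"
        "ENDMDL\n"
    )
    model = read_structure(p)
    assert len(model.chains["A"]) == 1


def test_bad_atom_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(
        "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  ALA A   2       xxxxx   0.000   0.000  1.00  0.00           C\n"
    )
    with pytest.raises(StructureError, match="line 2"):
        read_structure(p)


# ---------------------------------------------------------------------------
# column <-> residue mapping


def _mapping_fixture(drop_nterm: int = 0):
    taxa = ["ref", "ref2", "o1", "o2"]
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    aln = seq[:5] + "-" + seq[5:]  # one gap in the reference row
    seqs = [aln, aln, aln.replace("-", "A"), aln.replace("-", "A")]
    tree = "((ref:1,ref2:1):1,(o1:1,o2:1):1);"
    ca = build_clustered_alignment(
        (taxa, seqs), tree, {"ref": "A", "ref2": "A", "o1": "B", "o2": "B"}
    )
    native, _, _ = simulate_complex(
        len(seq) - drop_nterm, set(), seed=3, sequence=seq[drop_nterm:]
    )
    if drop_nterm:  # renumber so residue numbers match the full sequence
        for i, res in enumerate(native.chains["A"]):
            res.number = i + 1 + drop_nterm
    return ca, native


def test_identical_sequence_maps_every_nongap_column():
    ca, structure = _mapping_fixture()
    cmap = map_columns_to_residues(ca, "ref", structure, "A")
    assert cmap.identity == pytest.approx(1.0)
    aln = ca.sequence_of("ref")
    expected_cols = [i + 1 for i, ch in enumerate(aln) if ch != "-"]
    assert cmap.columns == expected_cols
    # gap column absent
    assert 6 not in cmap.columns


def test_truncated_structure_drops_those_columns_only():
    ca, structure = _mapping_fixture(drop_nterm=3)
    cmap = map_columns_to_residues(ca, "ref", structure, "A")
    full_map = map_columns_to_residues(ca, "ref", _mapping_fixture()[1], "A")
    missing = set(full_map.columns) - set(cmap.columns)
    assert missing == {1, 2, 3}
    kept = {c: r for c, _, r in cmap.pairs}
    for col, _, resnum in full_map.pairs:
        if col in kept:
            assert kept[col] == resnum


def test_wrong_chain_trips_identity_floor():
    ca, structure = _mapping_fixture()
    with pytest.raises(ValueError, match="identity"):
        map_columns_to_residues(ca, "ref", structure, "B")


def test_newick_roundtrip_preserves_topology_and_labels(tmp_path):
    nw = "((a:1.5,b:2.0):0.5,(c:1.0,d:1.0):0.5);"
    p = tmp_path / "t.nwk"
    p.write_text(nw + "\n")
    tree = read_tree(p)
    out = tmp_path / "t2.nwk"
    out.write_text(tree.as_string(schema="newick").strip() + "\n")
    tree2 = read_tree(out)
    assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {
        lf.taxon.label for lf in tree2.leaf_node_iter()
    }
    # topology + branch lengths survive via normalized newick text
    assert tree.as_string(schema="newick") == tree2.as_string(schema="newick")


def test_stage_tables_roundtrip(tmp_path, paperlike_dataset):
    from divergraft.parsimony import read_count_table, write_count_table
    from divergraft.divergence_type1 import (
        fit_type1, read_type1_table, type1_posteriors, write_type1_table,
    )
    from divergraft.divergence_type2 import read_type2_table, type2_scores, write_type2_table

    ca, _, table = paperlike_dataset
    p = tmp_path / "counts.tsv"
    write_count_table(p, table)
    back = read_count_table(p)
    assert (back.x_A == table.x_A).all() and (back.x_B == table.x_B).all()
    assert (back.flagged == table.flagged).all()
    assert (back.label_A, back.label_B) == (table.label_A, table.label_B)

    model = fit_type1(table)
    t1 = type1_posteriors(table, model)
    p1 = tmp_path / "t1.tsv"
    write_type1_table(p1, t1)
    back1 = read_type1_table(p1)
    for a, b in zip(t1, back1):
        assert (a.site, a.x_A, a.x_B, a.direction) == (b.site, b.x_A, b.x_B, b.direction)
        assert b.pp == pytest.approx(a.pp, abs=1e-6)

    t2 = type2_scores(ca, table)
    p2 = tmp_path / "t2.tsv"
    write_type2_table(p2, t2)
    back2 = read_type2_table(p2)
    for a, b in zip(t2, back2):
        assert (a.site, a.consensus_A, a.consensus_B, a.rank) == (
            b.site, b.consensus_A, b.consensus_B, b.rank
        )
        assert b.dissimilarity == pytest.approx(a.dissimilarity, abs=0.05)
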