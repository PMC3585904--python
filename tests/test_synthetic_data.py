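import numpy as np
import pytest

from divergraft.data_io import write_alignment
from divergraft.divergence_type1 import fit_type1
from divergraft.parsimony import count_table, fitch_count, cluster_subtree
from divergraft.synthetic_data import (
    SimConfig,
    paperlike_config,
    simulate_alignment,
    simulate_band_table,
    simulate_complex,
    simulate_cpm_table,
    write_simulated_inputs,
)


def test_same_seed_gives_identical_fasta_bytes(tmp_path):
    for i, out in enumerate(["a.fa", "b.fa"]):
        ca, _ = simulate_alignment(paperlike_config(seed=77))
        write_alignment(tmp_path / out, ca.taxa, ca.sequences)
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


def test_different_seeds_differ(tmp_path):
    ca1, _ = simulate_alignment(paperlike_config(seed=1))
    ca2, _ = simulate_alignment(paperlike_config(seed=2))
    assert ca1.sequences != ca2.sequences


def test_truth_covers_every_site():
    cfg = paperlike_config(seed=5)
    ca, truth = simulate_alignment(cfg)
    assert len(truth.site_class) == cfg.n_sites == ca.n_columns
    total = sum(len(truth.sites_of_class(c)) for c in
                ("null", "type1_slowA", "type1_slowB", "type2"))
    assert total == cfg.n_sites


def test_class_proportions_near_config():
    cfg = SimConfig(seed=3, n_sites=4000)
    _, truth = simulate_alignment(cfg)
    cls = np.array(truth.site_class)
    assert np.mean(cls == "type2") == pytest.approx(cfg.prop_type2, abs=0.02)
    p1 = np.mean((cls == "type1_slowA") | (cls == "type1_slowB"))
    assert p1 == pytest.approx(cfg.prop_type1, abs=0.03)


def test_all_null_config_fits_boundary_theta():
    cfg = SimConfig(seed=13, prop_type1=0.0, prop_type2=0.0, n_sites=2000)
    ca, truth = simulate_alignment(cfg)
    assert set(truth.site_class) == {"null"}
    model = fit_type1(count_table(ca))
    assert model.theta <= 0.05


def test_type2_sites_are_conserved_but_different():
    """Planted CBD sites: zero within-clade counts, differing consensus."""
    ok = total = 0
    for seed in range(3):
        ca, truth = simulate_alignment(paperlike_config(seed=50 + seed))
        table = count_table(ca)
        for site in truth.sites_of_class("type2"):
            total += 1
            i = site - 1
            if table.x_A[i] == 0 and table.x_B[i] == 0:
                col = ca.column(site)
                res_A = {col[t] for t in ca.taxa_in_cluster("A")}
                res_B = {col[t] for t in ca.taxa_in_cluster("B")}
                if len(res_A) == 1 and len(res_B) == 1 and res_A != res_B:
                    ok += 1
    assert ok / total >= 0.90  # per-site probability >= 0.95 nominal


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(prop_type1=0.8, prop_type2=0.4).validate()
    with pytest.raises(ValueError):
        SimConfig(n_taxa_A=1).validate()
    with pytest.raises(ValueError):
        SimConfig(depth_A=0).validate()


# ---------------------------------------------------------------------------
# complexes


def test_complex_truth_recovered_at_generation_cutoff():
    from divergraft.data_io import ColumnResidueMap
    from divergraft.structure_contacts import contact_columns

    native, _, truth = simulate_complex(30, {4, 9, 22}, cutoff=5.0, seed=6)
    cmap = ColumnResidueMap(pairs=[(i, "A", i) for i in range(1, 31)], identity=1.0)
    cs = contact_columns(native, native.chains["B"], cmap, cutoff=5.0)
    assert cs.contacts == truth.planted_columns
    # 1 A below the generation cutoff the planted margin empties the set
    assert contact_columns(native, native.chains["B"], cmap, cutoff=4.0).contacts == set()


def test_moved_copy_superposes_exactly():
    from divergraft.structure_contacts import kabsch

    native, moved, _ = simulate_complex(25, {3}, seed=7)
    ca_n = np.array([r.atoms[1].xyz for r in native.chains["A"]])
    ca_m = np.array([r.atoms[1].xyz for r in moved.chains["A"]])
    assert kabsch(ca_n, ca_m).rmsd < 1e-6


def test_infeasible_cutoff_rejected():
    with pytest.raises(ValueError, match="cutoff"):
        simulate_complex(5, {1}, cutoff=0.3)


def test_planted_columns_validated():
    with pytest.raises(ValueError, match="planted"):
        simulate_complex(5, {9})


# ---------------------------------------------------------------------------
# assay tables


def test_band_table_zero_noise_recovers_fractions_exactly():
    from divergraft.assay_stats import bound_fraction

    df = simulate_band_table({"wt": 0.30, "ko": 0.05}, noise_sd=0.0, seed=0)
    for _, row in df.iterrows():
        expected = 30.0 if row["variant"] == "wt" else 5.0
        assert bound_fraction(row["band_EF"], row["band_exchange"]) == pytest.approx(expected)


def test_cpm_zero_noise_recovers_folds_exactly():
    from divergraft.assay_stats import normalize_cpm

    df = simulate_cpm_table({"wt": 1.0, "ki3": 2.5}, noise_sd=0.0, seed=0)
    normed = normalize_cpm(df, background_variant="none")
    ki = normed.loc[normed["variant"] == "ki3", "fold"]
    assert np.allclose(ki, 2.5)


def test_planted_gross_outlier_is_flagged_by_grubbs():
    from divergraft.assay_stats import grubbs_iterative, normalize_cpm

    df = simulate_cpm_table(
        {"wt": 1.0}, n_replicates=15, noise_sd=0.15,
        outlier=("wt", 4, 8.0), seed=42,
    )
    vals = df.loc[df["variant"] == "wt", "cpm"].to_numpy()
    kept, removed = grubbs_iterative(vals)
    assert removed == [3]  # replicate 4 (0-based index 3)


def test_no_effect_tables_rarely_significant():
    from divergraft.assay_stats import normalize_cpm, one_tailed_t

    rejections = 0
    n_seeds = 60
    for seed in range(n_seeds):
        df = simulate_cpm_table({"wt": 2.0, "v": 2.0}, n_replicates=8, seed=seed)
        normed = normalize_cpm(df)
        v = normed.loc[normed["variant"] == "v", "fold"].to_numpy()
        wt = normed.loc[normed["variant"] == "wt", "fold"].to_numpy()
        rejections += one_tailed_t(v, wt).p < 0.05
    assert rejections / n_seeds < 0.10


# ---------------------------------------------------------------------------
# the on-disk bundle


def test_bundle_is_deterministic_and_complete(tmp_path):
    cfg = SimConfig(seed=9, n_sites=60, n_taxa_A=6, n_taxa_B=6)
    p1 = write_simulated_inputs(cfg, tmp_path / "one")
    p2 = write_simulated_inputs(cfg, tmp_path / "two")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
    truth_lines = p1["truth"].read_text().splitlines()
    assert truth_lines[0] == "# seed=9"
    assert len(truth_lines) == 62  # comment + header + one row per site
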