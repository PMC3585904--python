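"""End-to-end pipeline: counts → Type-I → Type-II → contacts → designs.

Given an alignment, tree, cluster map, a native complex (the recipient
elongation factor bound to its own exchange factor) and a donor complex
(the donor homolog bound to *its* exchange factor), the pipeline computes
per-site divergence statistics, derives native and superposed interface
contact sets, assembles the nested KnockOut/KnockIn/combined/control site
groups, grafts donor residues into the recipient, and writes a
FASTA/TSV/JSON bundle.  Output depends only on (inputs, config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .data_io import (
    build_clustered_alignment,
    map_columns_to_residues,
    read_alignment,
    read_clusters,
    read_structure,
)
from .divergence_type1 import fit_type1, type1_posteriors, write_type1_table
from .divergence_type2 import type2_scores, write_type2_table
from .parsimony import count_table, write_count_table
from .structure_contacts import contact_columns, superpose_partner, write_contact_table
from .variant_design import (
    DesignRule,
    VariantDesign,
    control_sites,
    graft,
    select_sites,
    write_mutation_table,
    write_variant_fasta,
)

log = logging.getLogger("divergraft")


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run."""

    alignment: str
    tree: str
    clusters: str
    native_complex: str
    donor_complex: str
    out_dir: str = "divergraft_out"
    # taxa
    recipient_taxon: str = ""  # default: first taxon of cluster A
    donor_taxon: str = ""  # default: first taxon of cluster B
    native_structure_taxon: str = ""  # taxon matching the native EF chain
    donor_structure_taxon: str = ""  # taxon matching the donor EF chain
    # chains
    native_ef_chain: str = "A"
    native_partner_chain: str = "B"
    donor_ef_chain: str = "A"
    donor_partner_chain: str = "B"
    # thresholds
    pp_group1: float = 0.90
    pp_group2: float = 0.80
    cutoff_A: float = 5.0
    polarize_ratio: float = 2.0
    n_top_type2: int = 10
    control_ceiling: float = 0.50
    map_identity_floor: float = 0.90
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.pp_group2 <= self.pp_group1 <= 1):
            raise ValueError("need 0 < pp_group2 <= pp_group1 <= 1")
        if self.cutoff_A <= 0:
            raise ValueError("cutoff must be positive")
        if self.polarize_ratio <= 1:
            raise ValueError("polarize_ratio must exceed 1")
        if not (0 <= self.control_ceiling <= 1):
            raise ValueError("control_ceiling must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    _PATH_FIELDS = (
        "alignment", "tree", "clusters", "native_complex", "donor_complex", "out_dir",
    )

    def digest(self) -> str:
        # hash of the analytic settings; file locations are not part of a
        # run's identity (the same inputs elsewhere give the same results)
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in self._PATH_FIELDS
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    designs: dict[str, VariantDesign]
    report: dict
    out_dir: Path


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write the output bundle.

    Any stage failure is re-raised wrapped with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load inputs"
    try:
        t0 = _stage(stage)
        aln = read_alignment(config.alignment)
        clusters = read_clusters(config.clusters)
        ca = build_clustered_alignment(aln, config.tree, clusters)
        lab_A, lab_B = ca.cluster_labels
        recipient = config.recipient_taxon or ca.taxa_in_cluster(lab_A)[0]
        donor = config.donor_taxon or ca.taxa_in_cluster(lab_B)[0]
        native_taxon = config.native_structure_taxon or recipient
        donor_struct_taxon = config.donor_structure_taxon or native_taxon
        native = read_structure(config.native_complex)
        donor_cplx = read_structure(config.donor_complex)

        stage = "substitution counts"
        t0 = _stage(stage)
        table = count_table(ca)

        stage = "Type-I mixture fit"
        t0 = _stage(stage)
        model = fit_type1(table)
        t1_results = type1_posteriors(table, model, polarize_ratio=config.polarize_ratio)

        stage = "Type-II scoring"
        t0 = _stage(stage)
        t2_results = type2_scores(ca, table)

        stage = "native contacts"
        t0 = _stage(stage)
        native_map = map_columns_to_residues(
            ca, native_taxon, native, config.native_ef_chain,
            min_identity=config.map_identity_floor,
        )
        native_contacts = contact_columns(
            native,
            native.chains[config.native_partner_chain],
            native_map,
            cutoff=config.cutoff_A,
            geometry_mode="native",
        )

        stage = "superposed contacts"
        t0 = _stage(stage)
        donor_map = map_columns_to_residues(
            ca, donor_struct_taxon, donor_cplx, config.donor_ef_chain,
            min_identity=config.map_identity_floor,
        )
        donor_res_of_col = {c: n for c, _, n in donor_map.pairs}
        pair_map = [
            (nat_num, donor_res_of_col[col])
            for col, _, nat_num in native_map.pairs
            if col in donor_res_of_col
        ]
        placed_partner, sup = superpose_partner(
            native,
            config.native_ef_chain,
            donor_cplx,
            config.donor_ef_chain,
            config.donor_partner_chain,
            pair_map,
        )
        superposed_contacts = contact_columns(
            native, placed_partner, native_map,
            cutoff=config.cutoff_A, geometry_mode="superposed",
        )

        stage = "variant design"
        t0 = _stage(stage)
        designs: dict[str, VariantDesign] = {}
        ko_sites: dict[int, set[int]] = {}
        ki_sites: dict[int, set[int]] = {}
        for g in (1, 2, 3):
            rule_ko = DesignRule(
                group_id=g, direction_required="slow_A_fast_B",
                geometry="native", n_top_type2=config.n_top_type2,
            )
            ko_sites[g] = select_sites(t1_results, t2_results, native_contacts, rule_ko)
            designs[f"KO{g}"] = graft(recipient, donor, ko_sites[g], ca, name=f"KO{g}")
            rule_ki = DesignRule(
                group_id=g, direction_required="slow_B_fast_A",
                geometry="superposed", n_top_type2=config.n_top_type2,
            )
            ki_sites[g] = select_sites(t1_results, t2_results, superposed_contacts, rule_ki)
            designs[f"KI{g}"] = graft(recipient, donor, ki_sites[g], ca, name=f"KI{g}")
        for g in (2, 3):  # the group-1 combination is deliberately not generated
            koki = ko_sites[g] | ki_sites[g]
            designs[f"KOKI{g}"] = graft(recipient, donor, koki, ca, name=f"KOKI{g}")
        ctrl = control_sites(
            t1_results, t2_results, superposed_contacts, pp_ceiling=config.control_ceiling
        )
        designs["CONTROL"] = graft(recipient, donor, ctrl, ca, name="CONTROL")

        stage = "write outputs"
        t0 = _stage(stage)
        write_count_table(out / "counts.tsv", table)
        write_type1_table(out / "type1.tsv", t1_results, labels=(lab_A, lab_B))
        write_type2_table(out / "type2.tsv", t2_results, labels=(lab_A, lab_B))
        write_contact_table(out / "contacts_native.tsv", native_contacts, native_map)
        write_contact_table(out / "contacts_superposed.tsv", superposed_contacts, native_map)
        for name, design in designs.items():
            write_variant_fasta(out / f"variant_{name}.fasta", design)
        write_mutation_table(out / "mutations.tsv", list(designs.values()))
        report = {
            "tool": "divergraft",
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
            "parameters": {
                "pp_group1": config.pp_group1,
                "pp_group2": config.pp_group2,
                "cutoff_A": config.cutoff_A,
                "polarize_ratio": config.polarize_ratio,
                "n_top_type2": config.n_top_type2,
                "control_ceiling": config.control_ceiling,
            },
            "model": {
                "theta": model.theta,
                "alpha": model.alpha,
                "D_A": model.D_A,
                "D_B": model.D_B,
                "log_likelihood": model.log_likelihood,
                "n_sites": model.n_sites,
            },
            "superposition_rmsd_A": sup.rmsd,
            "n_contacts": {
                "native": len(native_contacts.contacts),
                "superposed": len(superposed_contacts.contacts),
            },
            "variants": {
                name: {"n_sites": len(d.sites), "n_mutations": len(d.mutations)}
                for name, d in designs.items()
            },
            "recipient": recipient,
            "donor": donor,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        log.info("pipeline finished in %.1fs", time.perf_counter() - t0)
        return PipelineResult(designs=designs, report=report, out_dir=out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
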