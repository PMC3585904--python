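"""Nested KnockOut / KnockIn / combined / control site sets and residue
grafting.

Sites carrying divergence signal are clustered into three nested groups —
(1) Type-I posterior probability >= 0.90, (2) PP >= 0.80, (3) PP >= 0.80
plus the top-ranked Type-II sites — then intersected with the interface
contact set under the relevant geometry.  Type-I sites must additionally
show the required rate polarity (e.g. slow in the recipient's clade, fast
in the donor's for a KnockOut of native binding); Type-II sites are not
direction-filtered.  The control set takes contact columns with *no*
divergence signal.  Grafting replaces the recipient's residues at the
selected columns with the donor homolog's residues, producing a chimeric
("KnockOut"/"KnockIn") sequence with mutations reported in ungapped
recipient numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .data_io import ClusteredAlignment
from .divergence_type1 import Type1SiteResult
from .divergence_type2 import Type2SiteResult, top_type2
from .structure_contacts import ContactSet

__all__ = ["DesignRule", "VariantDesign", "select_sites", "control_sites", "graft"]

PP_GROUP1 = 0.90
PP_GROUP2 = 0.80


@dataclass
class DesignRule:
    """One nested selection rule (group 1, 2 or 3)."""

    group_id: int  # 1, 2 or 3
    direction_required: str  # slow_A_fast_B | slow_B_fast_A
    geometry: str  # native | superposed
    n_top_type2: int = 10

    def __post_init__(self):
        if self.group_id not in (1, 2, 3):
            raise ValueError("group_id must be 1, 2 or 3")
        if self.direction_required not in ("slow_A_fast_B", "slow_B_fast_A"):
            raise ValueError(f"bad direction: {self.direction_required!r}")

    @property
    def pp_threshold(self) -> float:
        return PP_GROUP1 if self.group_id == 1 else PP_GROUP2

    @property
    def include_type2(self) -> bool:
        return self.group_id == 3


@dataclass
class VariantDesign:
    """A named variant: selected columns, mutation list, grafted sequence."""

    name: str  # KO1..KO3, KI1..KI3, KOKI2, KOKI3, CONTROL
    sites: set[int]  # alignment columns
    mutations: list[tuple[int, str, str]]  # (recipient position, wt, donor)
    mutant_sequence: str
    dropped_sites: list[tuple[int, str]] = field(default_factory=list)


def _check_universe(type1_results, type2_results) -> None:
    cols1 = {r.site for r in type1_results}
    cols2 = {r.site for r in type2_results}
    if cols1 != cols2:
        raise ValueError("Type-I and Type-II results cover different column sets")


def select_sites(
    type1_results: list[Type1SiteResult],
    type2_results: list[Type2SiteResult],
    contact_set: ContactSet,
    rule: DesignRule,
) -> set[int]:
    """Columns selected by a nested design rule.

    Type-I columns with pp >= threshold and the required direction, plus
    (group 3 only) the top-ranked Type-II columns, intersected with the
    contact set.  Flagged sites (pp NaN) never qualify.
    """
    _check_universe(type1_results, type2_results)
    chosen = {
        r.site
        for r in type1_results
        if r.pp == r.pp  # excludes NaN
        and r.pp >= rule.pp_threshold
        and r.direction == rule.direction_required
    }
    if rule.include_type2:
        chosen |= top_type2(type2_results, rule.n_top_type2)
    return chosen & contact_set.contacts


def control_sites(
    type1_results: list[Type1SiteResult],
    type2_results: list[Type2SiteResult],
    contact_set: ContactSet,
    pp_ceiling: float = 0.50,
) -> set[int]:
    """Interface columns showing *no* divergence signal.

    Contact columns with Type-I pp < ``pp_ceiling`` (NaN excluded) that do
    not qualify as Type-II sites.
    """
    _check_universe(type1_results, type2_results)
    pp_of = {r.site: r.pp for r in type1_results}
    type2_qualifying = {r.site for r in type2_results if r.rank is not None}
    return {
        col
        for col in contact_set.contacts
        if col in pp_of
        and pp_of[col] == pp_of[col]
        and pp_of[col] < pp_ceiling
        and col not in type2_qualifying
    }


def graft(
    recipient_taxon: str,
    donor_taxon: str,
    sites: set[int],
    ca: ClusteredAlignment,
    name: str = "VARIANT",
) -> VariantDesign:
    """Graft donor residues into the recipient at the selected columns.

    Sites where the donor has a gap, the recipient has a gap, or donor and
    recipient agree are dropped from the mutation list (with the reason
    recorded).  The mutant sequence is emitted ungapped in recipient
    numbering; positions are 1-based indices into the recipient's ungapped
    sequence.
    """
    rec_aln = ca.sequence_of(recipient_taxon)
    don_aln = ca.sequence_of(donor_taxon)
    # alignment column -> recipient ungapped position
    pos_of_col: dict[int, int] = {}
    pos = 0
    for i, ch in enumerate(rec_aln):
        if ch != "-":
            pos += 1
            pos_of_col[i + 1] = pos
    mutant = list(rec_aln.replace("-", ""))
    mutations: list[tuple[int, str, str]] = []
    dropped: list[tuple[int, str]] = []
    for col in sorted(sites):
        wt = rec_aln[col - 1]
        donor = don_aln[col - 1]
        if wt == "-":
            dropped.append((col, "recipient gap"))
            warnings.warn(f"column {col}: recipient gap, site dropped from design")
            continue
        if donor == "-":
            dropped.append((col, "donor gap"))
            continue
        if donor == wt:
            dropped.append((col, "donor equals recipient"))
            continue
        p = pos_of_col[col]
        mutant[p - 1] = donor
        mutations.append((p, wt, donor))
    return VariantDesign(
        name=name,
        sites=set(sites),
        mutations=mutations,
        mutant_sequence="".join(mutant),
        dropped_sites=dropped,
    )


def write_variant_fasta(path, design: VariantDesign) -> None:
    with open(path, "w") as fh:
        fh.write(f">{design.name}\n{design.mutant_sequence}\n")


def write_mutation_table(path, designs: list[VariantDesign]) -> None:
    with open(path, "w") as fh:
        fh.write("variant\tposition\twt\tmutant\n")
        for d in designs:
            for pos, wt, donor in d.mutations:
                fh.write(f"{d.name}\t{pos}\t{wt}\t{donor}\n")
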