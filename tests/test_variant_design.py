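import numpy as np
import pytest

from divergraft.data_io import build_clustered_alignment
from divergraft.divergence_type1 import Type1SiteResult
from divergraft.divergence_type2 import Type2SiteResult
from divergraft.structure_contacts import ContactSet
from divergraft.variant_design import (
    DesignRule,
    control_sites,
    graft,
    select_sites,
)


def _t1(site, pp, direction, x_A=0, x_B=5):
    return Type1SiteResult(site, x_A, x_B, pp, 0.1, 1.0, direction)


def _t2(site, rank=None):
    return Type2SiteResult(site, rank is not None, rank is not None,
                           "A" if rank else None, "S" if rank else None,
                           99.0 if rank else 0.0, rank)


def _contacts(cols, mode="native"):
    return ContactSet(5.0, set(cols), {c: 4.0 for c in cols}, mode)


def _fixture(n=12):
    """4 strong directional Type-I sites (1-4), 2 Type-II (5-6), rest null."""
    t1, t2 = [], []
    for site in range(1, n + 1):
        if site <= 4:
            t1.append(_t1(site, 0.95, "slow_A_fast_B"))
            t2.append(_t2(site))
        elif site <= 6:
            t1.append(_t1(site, 0.10, "unpolarized", 0, 0))
            t2.append(_t2(site, rank=site - 4))
        else:
            t1.append(_t1(site, 0.20, "unpolarized", 1, 1))
            t2.append(_t2(site))
    return t1, t2


def test_empty_contact_set_yields_empty_selection():
    t1, t2 = _fixture()
    rule = DesignRule(1, "slow_A_fast_B", "native")
    assert select_sites(t1, t2, _contacts([]), rule) == set()


def test_planted_directional_sites_selected_exactly():
    t1, t2 = _fixture()
    contacts = _contacts(range(1, 13))
    rule = DesignRule(1, "slow_A_fast_B", "native")
    assert select_sites(t1, t2, contacts, rule) == {1, 2, 3, 4}


def test_direction_filter_applies_to_type1_only():
    t1, t2 = _fixture()
    contacts = _contacts(range(1, 13))
    # wrong direction: the high-PP sites drop out, but group 3 still takes
    # the top Type-II sites without any direction requirement
    rule3 = DesignRule(3, "slow_B_fast_A", "native", n_top_type2=2)
    assert select_sites(t1, t2, contacts, rule3) == {5, 6}


def test_group_nesting():
    t1, t2 = _fixture()
    t1[6] = _t1(7, 0.85, "slow_A_fast_B")  # between the two thresholds
    contacts = _contacts(range(1, 13))
    sets = [
        select_sites(t1, t2, contacts, DesignRule(g, "slow_A_fast_B", "native"))
        for g in (1, 2, 3)
    ]
    assert sets[0] <= sets[1] <= sets[2]
    assert sets[0] == {1, 2, 3, 4}
    assert sets[1] == {1, 2, 3, 4, 7}
    assert sets[2] == {1, 2, 3, 4, 5, 6, 7}


def test_mismatched_column_universes_rejected():
    t1, t2 = _fixture()
    with pytest.raises(ValueError, match="different column sets"):
        select_sites(t1, t2[:-1], _contacts([1]), DesignRule(1, "slow_A_fast_B", "native"))


def test_control_sites_are_quiet_contacts():
    t1, t2 = _fixture()
    contacts = _contacts(range(1, 13))
    ctrl = control_sites(t1, t2, contacts, pp_ceiling=0.50)
    assert ctrl == set(range(7, 13))  # null sites only: no Type-I, no Type-II
    # disjoint from every selection at thresholds >= ceiling
    for g in (1, 2, 3):
        sel = select_sites(t1, t2, contacts, DesignRule(g, "slow_A_fast_B", "native"))
        assert not (ctrl & sel - {5, 6})  # Type-II sites are excluded from ctrl anyway
        assert not (ctrl & sel)


def test_control_empty_when_all_contacts_divergent():
    t1, t2 = _fixture()
    contacts = _contacts([1, 2, 3, 4])
    assert control_sites(t1, t2, contacts) == set()


def test_seventeen_planted_quiet_contacts_recovered():
    t1 = [_t1(s, 0.95, "slow_A_fast_B") for s in range(1, 4)] + [
        _t1(s, 0.05, "unpolarized", 0, 0) for s in range(4, 21)
    ]
    t2 = [_t2(s) for s in range(1, 21)]
    contacts = _contacts(range(1, 21))
    assert control_sites(t1, t2, contacts) == set(range(4, 21))


# ---------------------------------------------------------------------------
# grafting


def _graft_ca():
    taxa = ["rec", "rec2", "don", "don2"]
    #       123456789...  (alignment columns)
    seqs = [
        "--MKTAYIAK",  # recipient: two leading gaps
        "--MKTAYIAK",
        "QRMSTAY-AK",  # donor has a gap at column 8
        "QRMSTAYYAK",
    ]
    tree = "((rec:1,rec2:1):1,(don:1,don2:1):1);"
    clusters = {"rec": "A", "rec2": "A", "don": "B", "don2": "B"}
    return build_clustered_alignment((taxa, seqs), tree, clusters)


def test_graft_empty_sites_is_wild_type():
    ca = _graft_ca()
    d = graft("rec", "don", set(), ca)
    assert d.mutant_sequence == "MKTAYIAK"
    assert d.mutations == []


def test_graft_identical_donor_changes_nothing():
    ca = _graft_ca()
    d = graft("rec", "rec2", {3, 4, 5}, ca)
    assert d.mutations == []
    assert d.mutant_sequence == "MKTAYIAK"
    assert {c for c, _ in d.dropped_sites} == {3, 4, 5}


def test_graft_positions_shift_past_recipient_gaps():
    ca = _graft_ca()
    # column 4 is recipient position 2 (two upstream gaps)
    d = graft("rec", "don", {4}, ca)
    assert d.mutations == [(2, "K", "S")]
    assert d.mutant_sequence == "MSTAYIAK"


def test_graft_drops_gap_sites_with_reason():
    ca = _graft_ca()
    with pytest.warns(UserWarning, match="recipient gap"):
        d = graft("rec", "don", {1, 8}, ca)
    assert ("1", "recipient gap") == (str(d.dropped_sites[0][0]), d.dropped_sites[0][1])
    assert (8, "donor gap") in d.dropped_sites
    assert d.mutations == []


def test_mutant_length_and_hamming_distance():
    ca = _graft_ca()
    d = graft("rec", "don", {3, 4, 8}, ca)
    wt = "MKTAYIAK"
    assert len(d.mutant_sequence) == len(wt)
    hamming = sum(a != b for a, b in zip(d.mutant_sequence, wt))
    assert hamming == len(d.mutations)
    for pos, wt_res, donor_res in d.mutations:
        assert wt[pos - 1] == wt_res
        assert d.mutant_sequence[pos - 1] == donor_res


def test_koki_union_has_no_duplicate_mutations():
    ca = _graft_ca()
    ko, ki = {3, 4}, {4, 5}  # site 4 overlaps
    d_ko = graft("rec", "don", ko, ca)
    d_ki = graft("rec", "don", ki, ca)
    d_koki = graft("rec", "don", ko | ki, ca)
    assert d_koki.sites == ko | ki
    positions = [m[0] for m in d_koki.mutations]
    assert len(positions) == len(set(positions))
    assert set(d_koki.mutations) == set(d_ko.mutations) | set(d_ki.mutations)
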