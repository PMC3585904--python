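"""Per-site, per-cluster minimum substitution counts by Fitch parsimony.

For each alignment column and each cluster's induced subtree, the count is
the minimum number of amino-acid changes needed to explain the observed leaf
states over all internal labelings (the classic Fitch bottom-up pass:
children-set intersection if non-empty, else union plus one change).  Gaps
and 'X' are missing data and contribute the full 20-state set, so they never
force a change.  These paired counts (x_A, x_B) are the raw signal that the
rate-shift mixture model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .data_io import AMINO_ACIDS, MISSING_CHARS, ClusteredAlignment

_FULL_SET = frozenset(AMINO_ACIDS)


@dataclass
class SiteCountTable:
    """Paired per-site substitution counts for the two clusters.

    ``flagged[i]`` is True where a cluster had fewer than two scored
    (non-missing) leaves at site i; flagged sites carry count 0 there and
    are excluded from model fitting.
    """

    x_A: np.ndarray  # (n_sites,) int
    x_B: np.ndarray
    flagged: np.ndarray  # (n_sites,) bool
    label_A: str
    label_B: str

    @property
    def n_sites(self) -> int:
        return len(self.x_A)

    def unflagged(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(site indices 1-based, x_A, x_B) for unflagged sites."""
        keep = ~self.flagged
        sites = np.nonzero(keep)[0] + 1
        return sites, self.x_A[keep], self.x_B[keep]


def fitch_count(tree: dendropy.Tree, column_states: dict[str, str]) -> tuple[int, bool]:
    """Minimum substitution count for one column on one (sub)tree.

    ``column_states`` maps leaf label -> amino acid, '-' or 'X'.  Returns
    ``(count, insufficient_data)``; with fewer than two scored leaves the
    count is 0 and the flag is set.
    """
    scored = sum(
        1
        for lf in tree.leaf_node_iter()
        if column_states.get(lf.taxon.label, "-") not in MISSING_CHARS
    )
    if scored < 2:
        return 0, True
    changes = 0
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state = column_states.get(node.taxon.label, "-")
            sets[id(node)] = _FULL_SET if state in MISSING_CHARS else frozenset(state)
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            acc = child_sets[0]
            for cs in child_sets[1:]:
                inter = acc & cs
                if inter:
                    acc = inter
                else:
                    acc = acc | cs
                    changes += 1
            sets[id(node)] = acc
    return changes, False


def cluster_subtree(ca: ClusteredAlignment, label: str) -> dendropy.Tree:
    """The induced subtree of one cluster's leaves (unifurcations removed)."""
    members = set(ca.taxa_in_cluster(label))
    sub = ca.tree.extract_tree(
        node_filter_fn=lambda nd: (not nd.is_leaf()) or nd.taxon.label in members
    )
    # detach from the parent tree's namespace before pruning bookkeeping
    sub.migrate_taxon_namespace(dendropy.TaxonNamespace())
    sub.suppress_unifurcations()
    sub.is_rooted = True
    return sub


def count_table(ca: ClusteredAlignment) -> SiteCountTable:
    """Fitch counts for every column on each cluster's induced subtree."""
    lab_A, lab_B = ca.cluster_labels
    sub_A = cluster_subtree(ca, lab_A)
    sub_B = cluster_subtree(ca, lab_B)
    n = ca.n_columns
    x_A = np.zeros(n, dtype=int)
    x_B = np.zeros(n, dtype=int)
    flagged = np.zeros(n, dtype=bool)
    for col in range(1, n + 1):
        states = ca.column(col)
        cA, fA = fitch_count(sub_A, states)
        cB, fB = fitch_count(sub_B, states)
        x_A[col - 1] = cA
        x_B[col - 1] = cB
        flagged[col - 1] = fA or fB
    return SiteCountTable(x_A=x_A, x_B=x_B, flagged=flagged, label_A=lab_A, label_B=lab_B)


def write_count_table(path, table: SiteCountTable) -> None:
    """TSV dump: site, x_A, x_B, flags."""
    with open(path, "w") as fh:
        fh.write(f"site\tx_{table.label_A}\tx_{table.label_B}\tflag\n")
        for i in range(table.n_sites):
            flag = "insufficient_data" if table.flagged[i] else ""
            fh.write(f"{i + 1}\t{table.x_A[i]}\t{table.x_B[i]}\t{flag}\n")


def read_count_table(path) -> SiteCountTable:
    """Read back a TSV written by :func:`write_count_table`."""
    import csv

    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        label_A = header[1].removeprefix("x_")
        label_B = header[2].removeprefix("x_")
        x_A, x_B, flagged = [], [], []
        for row in reader:
            x_A.append(int(row[1]))
            x_B.append(int(row[2]))
            flagged.append(row[3] == "insufficient_data")
    return SiteCountTable(
        x_A=np.array(x_A), x_B=np.array(x_B),
        flagged=np.array(flagged, dtype=bool), label_A=label_A, label_B=label_B,
    )
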