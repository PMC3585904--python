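"""Type-II ("Conserved-But-Different", CBD) functional-divergence scoring.

A Type-II site is conserved within each of the two clades but fixed for
different residues between them — the footprint of a transient relaxation
of constraint on the stem branch separating the clades.  Scoring here is a
transparent deterministic rule: a site qualifies iff its within-cluster
Fitch counts are both <= k (default 0, i.e. strictly conserved), both
clusters have a clear majority consensus (>= 70% of non-missing leaves by
default) and the two consensus residues differ.  Qualifying sites are
scored by the chemical dissimilarity of the consensus pair — Grantham
distance by default, a BLOSUM62-derived distance as an alternative — and
rank-ordered (1 = strongest signal).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

from Bio.Align import substitution_matrices

from .data_io import MISSING_CHARS, ClusteredAlignment
from .parsimony import SiteCountTable

__all__ = ["Type2SiteResult", "type2_scores", "top_type2", "grantham_distance"]

# Grantham (1974) amino-acid chemical-difference matrix, upper triangle,
# residues in the original row order.
_GRANTHAM_ORDER = "SRLPTAVGIFYCHQNKDEMW"
_GRANTHAM_UPPER = [
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],
    [194, 83, 99, 143, 85, 160, 122, 36, 37],
    [174, 154, 139, 202, 154, 170, 196, 215],
    [24, 68, 32, 81, 40, 87, 115],
    [46, 53, 61, 29, 101, 130],
    [94, 23, 42, 142, 174],
    [101, 56, 95, 110],
    [45, 160, 181],
    [126, 152],
    [67],
]

_GRANTHAM: dict[tuple[str, str], int] = {}
for _i, _row in enumerate(_GRANTHAM_UPPER):
    for _off, _d in enumerate(_row):
        _a = _GRANTHAM_ORDER[_i]
        _b = _GRANTHAM_ORDER[_i + 1 + _off]
        _GRANTHAM[(_a, _b)] = _d
        _GRANTHAM[(_b, _a)] = _d

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def grantham_distance(a: str, b: str) -> float:
    """Grantham chemical difference between amino acids ``a`` and ``b``."""
    if a == b:
        return 0.0
    return float(_GRANTHAM[(a, b)])


def blosum_distance(a: str, b: str) -> float:
    """A BLOSUM62-derived dissimilarity: s(a,a) + s(b,b) - 2 s(a,b)."""
    return float(_BLOSUM62[a, a] + _BLOSUM62[b, b] - 2 * _BLOSUM62[a, b])


@dataclass
class Type2SiteResult:
    site: int  # 1-based column
    conserved_A: bool
    conserved_B: bool
    consensus_A: str | None
    consensus_B: str | None
    dissimilarity: float
    rank: int | None  # 1 = strongest; None if not qualifying


def _consensus(states: list[str], min_frac: float) -> str | None:
    present = [s for s in states if s not in MISSING_CHARS]
    if not present:
        return None
    best = max(sorted(set(present)), key=present.count)
    if present.count(best) / len(present) < min_frac:
        return None
    return best


def type2_scores(
    ca: ClusteredAlignment,
    table: SiteCountTable,
    max_count: int = 0,
    min_consensus_frac: float = 0.70,
    metric: str = "grantham",
) -> list[Type2SiteResult]:
    """Score and rank every column for the CBD (Type-II) signature.

    Qualification: x_A <= max_count, x_B <= max_count, clear consensus in
    both clusters, consensus residues differ, site not flagged.  Ranking:
    dissimilarity descending, ties broken by (x_A + x_B) ascending, then by
    site index ascending.  Deterministic.
    """
    dist = {"grantham": grantham_distance, "blosum62": blosum_distance}[metric]
    lab_A, lab_B = ca.cluster_labels
    taxa_A = ca.taxa_in_cluster(lab_A)
    taxa_B = ca.taxa_in_cluster(lab_B)
    results: list[Type2SiteResult] = []
    for i in range(table.n_sites):
        col = ca.column(i + 1)
        cons_A = _consensus([col[t] for t in taxa_A], min_consensus_frac)
        cons_B = _consensus([col[t] for t in taxa_B], min_consensus_frac)
        conserved_A = table.x_A[i] <= max_count and cons_A is not None
        conserved_B = table.x_B[i] <= max_count and cons_B is not None
        qualifies = (
            not table.flagged[i]
            and conserved_A
            and conserved_B
            and cons_A != cons_B
        )
        d = dist(cons_A, cons_B) if qualifies else 0.0
        results.append(
            Type2SiteResult(
                site=i + 1, conserved_A=conserved_A, conserved_B=conserved_B,
                consensus_A=cons_A, consensus_B=cons_B,
                dissimilarity=d, rank=None,
            )
        )
    qualifying = [r for r in results if r.rank is None and r.dissimilarity > 0]
    qualifying.sort(
        key=lambda r: (
            -r.dissimilarity,
            table.x_A[r.site - 1] + table.x_B[r.site - 1],
            r.site,
        )
    )
    for rank, r in enumerate(qualifying, start=1):
        r.rank = rank
    return results


def top_type2(results: list[Type2SiteResult], n_top: int = 10) -> set[int]:
    """Columns of the ``n_top`` highest-ranked qualifying Type-II sites."""
    if n_top < 0:
        raise ValueError("n_top must be >= 0")
    ranked = sorted((r for r in results if r.rank is not None), key=lambda r: r.rank)
    if n_top > len(ranked):
        warnings.warn(
            f"requested top {n_top} Type-II sites but only {len(ranked)} qualify"
        )
    return {r.site for r in ranked[:n_top]}


def write_type2_table(path, results: list[Type2SiteResult], labels=("A", "B")) -> None:
    la, lb = labels
    with open(path, "w") as fh:
        fh.write(f"site\tconsensus_{la}\tconsensus_{lb}\tdissimilarity\trank\n")
        for r in results:
            fh.write(
                f"{r.site}\t{r.consensus_A or '.'}\t{r.consensus_B or '.'}\t"
                f"{r.dissimilarity:.1f}\t{r.rank if r.rank is not None else '.'}\n"
            )


def read_type2_table(path) -> list[Type2SiteResult]:
    """Read back a TSV written by :func:`write_type2_table`."""
    import csv

    out: list[Type2SiteResult] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            cons_A = None if row[1] == "." else row[1]
            cons_B = None if row[2] == "." else row[2]
            out.append(
                Type2SiteResult(
                    site=int(row[0]), conserved_A=cons_A is not None,
                    conserved_B=cons_B is not None, consensus_A=cons_A,
                    consensus_B=cons_B, dissimilarity=float(row[3]),
                    rank=None if row[4] == "." else int(row[4]),
                )
            )
    return out
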