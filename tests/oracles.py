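"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: parsimony by
exhaustive enumeration of internal labelings, the mixture densities by
numerical quadrature over the gamma rate, contacts by all-pairs distance
scans, and the Grubbs critical value by quadrature of the t density.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate, stats

from divergraft.data_io import AMINO_ACIDS, MISSING_CHARS


# ---------------------------------------------------------------------------
# parsimony: exhaustive minimum over internal labelings
#
# For unit-cost parsimony an optimal internal labeling never needs a state
# absent from the leaves, so enumerating observed states is exhaustive.


def exhaustive_min_changes(tree, column_states: dict[str, str]) -> int:
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    observed = sorted(
        {
            s
            for s in (column_states.get(lf.taxon.label, "-") for lf in tree.leaf_node_iter())
            if s not in MISSING_CHARS
        }
    )
    if len(observed) <= 1:
        return 0
    edges = []  # (parent index or None, child node)
    index_of = {id(nd): i for i, nd in enumerate(internals)}
    for nd in internals:
        for child in nd.child_nodes():
            edges.append((index_of[id(nd)], child))
    best = np.inf
    for labels in itertools.product(observed, repeat=len(internals)):
        cost = 0
        for parent_idx, child in edges:
            p_state = labels[parent_idx]
            if child.is_leaf():
                leaf_state = column_states.get(child.taxon.label, "-")
                if leaf_state not in MISSING_CHARS and leaf_state != p_state:
                    cost += 1
            elif labels[index_of[id(child)]] != p_state:
                cost += 1
            if cost >= best:
                break
        best = min(best, cost)
    return int(best)


def random_tree_and_column(n_leaves: int, rng: np.random.Generator, n_states: int = 4,
                           p_missing: float = 0.1):
    """A random bifurcating rooted tree (newick) + random leaf states."""
    import dendropy

    labels = [f"t{i}" for i in range(n_leaves)]
    items = list(labels)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False), reverse=True)
        a, b = items.pop(int(i)), items.pop(int(j))
        items.append(f"({a}:1,{b}:1)")
    tree = dendropy.Tree.get(data=items[0] + ";", schema="newick")
    tree.is_rooted = True
    alphabet = AMINO_ACIDS[:n_states]
    states = {
        lab: "-" if rng.random() < p_missing else alphabet[int(rng.integers(n_states))]
        for lab in labels
    }
    return tree, states


# ---------------------------------------------------------------------------
# mixture densities by quadrature over the gamma rate


def _gamma_pdf(lam, alpha):
    return stats.gamma.pdf(lam, a=alpha, scale=1.0 / alpha)


def f_null_quadrature(x: int, y: int, alpha: float, D_A: float, D_B: float) -> float:
    def integrand(lam):
        return (
            stats.poisson.pmf(x, D_A * lam)
            * stats.poisson.pmf(y, D_B * lam)
            * _gamma_pdf(lam, alpha)
        )

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val


def f_div_quadrature(x: int, y: int, alpha: float, D_A: float, D_B: float) -> float:
    def marginal(k, D):
        val, _ = integrate.quad(
            lambda lam: stats.poisson.pmf(k, D * lam) * _gamma_pdf(lam, alpha),
            0, np.inf, limit=200,
        )
        return val

    return marginal(x, D_A) * marginal(y, D_B)


# ---------------------------------------------------------------------------
# Grubbs critical value via quadrature of the t CDF
#
# G_crit = (n-1)/sqrt(n) * sqrt(t*^2/(n-2+t*^2)) where t* is the upper
# alpha/(2n) t quantile on n-2 df; here t* is found by bisection on a
# numerically integrated t density rather than stats.t.ppf.


def t_cdf_quadrature(t: float, df: int) -> float:
    from scipy.special import gammaln

    c = np.exp(gammaln((df + 1) / 2) - gammaln(df / 2)) / np.sqrt(df * np.pi)
    val, _ = integrate.quad(lambda u: c * (1 + u * u / df) ** (-(df + 1) / 2), -np.inf, t)
    return val


def grubbs_critical_quadrature(n: int, alpha: float = 0.05) -> float:
    target = 1 - alpha / (2 * n)
    lo, hi = 0.0, 100.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if t_cdf_quadrature(mid, n - 2) < target:
            lo = mid
        else:
            hi = mid
    t_star = 0.5 * (lo + hi)
    return (n - 1) / np.sqrt(n) * np.sqrt(t_star**2 / (n - 2 + t_star**2))
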