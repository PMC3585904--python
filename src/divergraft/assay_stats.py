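"""Quantitative assay analytics.

Binding is read out as the percentage of total lane intensity contributed
by the exchange-factor band; translation activity as scintillation counts
per minute (CPM) normalized to a background reaction, with gross outliers
removed by an iterated Grubbs test and variants compared to wild type with
a pooled-variance ("student's") one-tailed t-test annotated with the
conventional significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "bound_fraction",
    "normalize_cpm",
    "grubbs_critical",
    "grubbs_iterative",
    "one_tailed_t",
    "TTestResult",
]


def bound_fraction(band_EF: float, band_exchange: float) -> float:
    """Percentage of total lane intensity in the exchange-factor band."""
    if band_EF < 0 or band_exchange < 0:
        raise ValueError("band intensities must be non-negative")
    total = band_EF + band_exchange
    if total == 0:
        raise ValueError("both band intensities are zero")
    return 100.0 * band_exchange / total


def normalize_cpm(
    cpm_table: pd.DataFrame,
    background_variant: str = "none",
    variant_col: str = "variant",
    value_col: str = "cpm",
) -> pd.DataFrame:
    """Fold values relative to the mean background (no-EF) reaction.

    Returns a copy of the table with a ``fold`` column; the background
    mean is attached as ``DataFrame.attrs['background_mean']``.
    """
    bg = cpm_table.loc[cpm_table[variant_col] == background_variant, value_col]
    if len(bg) < 1:
        raise ValueError(f"no background rows for variant {background_variant!r}")
    bg_mean = float(bg.mean())
    if bg_mean <= 0:
        raise ValueError("background mean must be positive")
    out = cpm_table.copy()
    out["fold"] = out[value_col] / bg_mean
    out.attrs["background_mean"] = bg_mean
    return out


def grubbs_critical(n: int, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Grubbs critical value G_crit(n, alpha) from the t-quantile closed
    form: ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n) or alpha/n, n-2}."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    a = alpha / (2 * n) if two_sided else alpha / n
    t = stats.t.ppf(1 - a, n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_iterative(
    values,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> tuple[np.ndarray, list[int]]:
    """Iterated one-at-a-time Grubbs outlier removal.

    Each round removes the single most extreme point if its studentized
    deviation G = max|v - mean| / sd exceeds G_crit(n, alpha), recomputing
    mean and sd after each removal; stops when no point is flagged or when
    fewer than 3 points would remain.  Returns (kept values, removed
    indices into the original array).  Constant data (sd = 0) removes
    nothing.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(vals) < 3:
        raise ValueError("Grubbs test requires n >= 3")
    keep = list(range(len(vals)))
    removed: list[int] = []
    while len(keep) >= 3:
        cur = vals[keep]
        sd = cur.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(cur - cur.mean())
        imax = int(np.argmax(dev))
        G = dev[imax] / sd
        if G > grubbs_critical(len(cur), alpha, two_sided):
            removed.append(keep.pop(imax))
        else:
            break
    return vals[keep], removed


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    stars: str  # "" | "*" | "**"


def one_tailed_t(
    variant_folds,
    reference_folds,
    direction: str = "greater",
) -> TTestResult:
    """Pooled-variance two-sample t-test, one-tailed.

    ``direction`` is the alternative for the variant relative to the
    reference: "greater" or "less".  Stars: "*" for p < 0.05, "**" for
    p < 0.01.  Zero pooled variance: p = 0.5 if the means are equal,
    else 0 or 1 by the sign of the difference.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(variant_folds, dtype=float)
    b = np.asarray(reference_folds, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            t_stat, p = 0.0, 0.5
        else:
            signed_extreme = diff > 0 if direction == "greater" else diff < 0
            t_stat = np.inf if diff > 0 else -np.inf
            p = 0.0 if signed_extreme else 1.0
    else:
        t_stat = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = float(stats.t.sf(t_stat, df)) if direction == "greater" else float(
            stats.t.cdf(t_stat, df)
        )
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return TTestResult(t=float(t_stat), df=df, p=float(p), stars=stars)


def analyze_cpm_table(
    cpm_table: pd.DataFrame,
    background_variant: str = "none",
    reference_variant: str = "wild_type",
    direction: str = "greater",
    grubbs_alpha: float = 0.05,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Full CPM workflow: normalize to background, remove outliers per
    variant with the iterated Grubbs test, and compare each variant to the
    reference with a one-tailed pooled t-test.  Returns one row per
    variant with mean fold, SEM, n kept/removed, t, p and stars."""
    normed = normalize_cpm(cpm_table, background_variant=background_variant)
    if stratify_by is not None and stratify_by not in normed.columns:
        raise ValueError(f"no column {stratify_by!r} to stratify by")

    def cleaned_folds(variant: str) -> tuple[np.ndarray, int]:
        rows = normed[normed["variant"] == variant]
        if stratify_by is None:
            kept, removed = grubbs_iterative(rows["fold"].to_numpy(), alpha=grubbs_alpha)
            return kept, len(removed)
        parts, n_removed = [], 0
        for _, grp in rows.groupby(stratify_by, sort=True):
            if len(grp) >= 3:
                kept, removed = grubbs_iterative(grp["fold"].to_numpy(), alpha=grubbs_alpha)
                n_removed += len(removed)
            else:
                kept = grp["fold"].to_numpy()
            parts.append(kept)
        return np.concatenate(parts), n_removed

    ref_folds, _ = cleaned_folds(reference_variant)
    records = []
    for variant in normed["variant"].unique():
        if variant == background_variant:
            continue
        folds, n_removed = cleaned_folds(variant)
        rec = {
            "variant": variant,
            "mean_fold": float(np.mean(folds)),
            "sem": float(np.std(folds, ddof=1) / np.sqrt(len(folds))) if len(folds) > 1 else float("nan"),
            "n": len(folds),
            "n_outliers_removed": n_removed,
        }
        if variant != reference_variant:
            res = one_tailed_t(folds, ref_folds, direction=direction)
            rec |= {"t": res.t, "df": res.df, "p": res.p, "stars": res.stars}
        else:
            rec |= {"t": float("nan"), "df": 0, "p": float("nan"), "stars": ""}
        records.append(rec)
    return pd.DataFrame(records)
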