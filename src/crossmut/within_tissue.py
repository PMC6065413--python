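"""Within-tissue two-group distribution comparisons.

For one tissue, genes are split into two groups -- by chromatin state
(EpiON vs EpiOFF) or by an expression threshold -- and the distributions of
a per-gene value (mutation frequency or expression) are compared with a
one-sided two-sample Kolmogorov-Smirnov test.  Because genes are not
independent draws, the KS p-value is not trusted directly: it is used as
the test statistic of a label-permutation test, whose p-value is the
pseudocounted fraction of label permutations with a KS p-value at or below
the empirical one.

Counting permuted KS p-values below the empirical one is equivalent to
counting permuted one-sided KS distances at or above the empirical distance,
because at fixed group sizes the p-value is a decreasing function of the
distance; the permutation loop therefore works on the distance scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_generator

__all__ = [
    "GroupComparison",
    "split_genes",
    "ks_onesided_distance",
    "ks_permutation_test",
    "subsample_robustness",
    "histogram_export",
]

_ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass
class GroupComparison:
    """Outcome of one two-group KS permutation comparison."""

    tissue: str
    rule: str
    n_high: int
    n_low: int
    ks_distance: float
    ks_p: float
    perm_p: float
    n_perm: int
    alternative: str
    exact: bool = False
    flag: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.perm_p <= 1.0) and not self.flag:
            raise ValueError("permutation p-value must lie in (0, 1]")


def split_genes(values_or_states: pd.Series, rule) -> pd.Series:
    """Binary gene labels (True = high/EpiON group) under a split rule.

    ``rule`` is one of ``("state",)`` for boolean chromatin calls,
    ``("fpkm", c)`` for an absolute expression threshold, or
    ``("percentile", q)`` for a within-tissue percentile threshold computed
    over the supplied universe.
    """
    kind = rule[0]
    if kind == "state":
        return values_or_states.astype(bool)
    values = values_or_states.astype(float)
    if kind == "fpkm":
        return values > float(rule[1])
    if kind == "percentile":
        cut = np.percentile(values.values, float(rule[1]))
        return values > cut
    raise ValueError(f"unknown split rule {rule!r}")


def _run_end_mask(sorted_values: np.ndarray) -> np.ndarray:
    """True at the last position of each run of tied sorted values."""
    mask = np.empty(sorted_values.size, dtype=bool)
    mask[:-1] = sorted_values[1:] != sorted_values[:-1]
    mask[-1] = True
    return mask


def ks_onesided_distance(
    sorted_high_mask: np.ndarray, run_ends: np.ndarray, n_high: int, n_low: int, alternative: str
) -> float:
    """One-sided (or two-sided) KS distance for one labeling.

    ``sorted_high_mask`` flags high-group members along the value-sorted
    gene order; evaluation points follow the right-continuous ECDF
    convention (only the last index of each tie run counts).

    * ``greater``: high group stochastically larger,
      D = max(ECDF_low - ECDF_high);
    * ``less``: the reverse; ``two-sided``: max absolute difference.
    """
    cum_high = np.cumsum(sorted_high_mask)
    pos = np.arange(1, sorted_high_mask.size + 1)
    diff = (pos - cum_high) / n_low - cum_high / n_high  # ECDF_low - ECDF_high
    diff = diff[run_ends]
    if alternative == "greater":
        return float(np.max(diff))
    if alternative == "less":
        return float(np.max(-diff))
    return float(np.max(np.abs(diff)))


def _scipy_ks_p(high: np.ndarray, low: np.ndarray, alternative: str) -> float:
    # scipy's 'less' means CDF(first) < CDF(second), i.e. first stochastically larger
    scipy_alt = {"greater": "less", "less": "greater", "two-sided": "two-sided"}[alternative]
    return float(stats.ks_2samp(high, low, alternative=scipy_alt).pvalue)


def ks_permutation_test(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    alternative: str = "greater",
    n_perm: int = 100_000,
    seed=None,
    exact: bool = False,
    tissue: str = "",
    rule: str = "",
    min_group: int = 2,
) -> GroupComparison:
    """Label-permutation test with the one-sided KS p-value as statistic.

    With ``exact=True`` all distinct label assignments are enumerated and
    the p-value is the exact fraction of assignments whose KS distance is at
    or above the empirical one (the identity assignment guarantees p > 0);
    otherwise ``n_perm`` random label permutations are drawn and the
    pseudocount form ``(1 + hits) / (1 + n_perm)`` is used.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=bool)
    if vals.shape != labs.shape:
        raise ValueError("values and labels must align")
    n_high = int(labs.sum())
    n_low = labs.size - n_high
    if n_high == 0 or n_low == 0:
        return GroupComparison(tissue, rule, n_high, n_low, np.nan, np.nan, 1.0,
                               0, alternative, exact, flag="empty-group")
    if n_high < min_group or n_low < min_group:
        flag = "small-group"
    else:
        flag = ""

    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    run_ends = _run_end_mask(sorted_vals)
    emp_mask = labs[order]
    emp_d = ks_onesided_distance(emp_mask, run_ends, n_high, n_low, alternative)
    emp_p = _scipy_ks_p(vals[labs], vals[~labs], alternative)

    if np.all(sorted_vals == sorted_vals[0]):
        return GroupComparison(tissue, rule, n_high, n_low, emp_d, emp_p, 1.0,
                               0, alternative, exact, flag="constant-values")

    n = vals.size
    if exact:
        hits = 0
        total = 0
        base = np.zeros(n, dtype=bool)
        for combo in itertools.combinations(range(n), n_high):
            mask = base.copy()
            mask[list(combo)] = True
            d = ks_onesided_distance(mask, run_ends, n_high, n_low, alternative)
            hits += d >= emp_d - 1e-12
            total += 1
        return GroupComparison(tissue, rule, n_high, n_low, emp_d, emp_p,
                               hits / total, total, alternative, True, flag)

    rng = as_generator(seed)
    hits = 0
    done = 0
    chunk = max(1, min(n_perm, 20_000_000 // n))
    pos = np.arange(1, n + 1)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        # mark the n_high smallest keys per row as high-group members
        part = np.argpartition(keys, n_high - 1, axis=1)[:, :n_high]
        masks = np.zeros((m, n), dtype=bool)
        np.put_along_axis(masks, part, True, axis=1)
        cum_high = np.cumsum(masks, axis=1)
        diff = (pos - cum_high) / n_low - cum_high / n_high
        diff = diff[:, run_ends]
        if alternative == "greater":
            d = diff.max(axis=1)
        elif alternative == "less":
            d = (-diff).max(axis=1)
        else:
            d = np.abs(diff).max(axis=1)
        hits += int((d >= emp_d - 1e-12).sum())
        done += m
    perm_p = (1.0 + hits) / (1.0 + n_perm)
    return GroupComparison(tissue, rule, n_high, n_low, emp_d, emp_p, perm_p,
                           n_perm, alternative, False, flag)


def subsample_robustness(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    folds: Sequence[int] = (5, 10, 25, 50, 100),
    n_perm: int = 10_000,
    seed=None,
    alternative: str = "greater",
    tissue: str = "",
    rule: str = "",
) -> list[GroupComparison]:
    """Re-run the KS permutation test on uniform gene subsamples.

    For each fold ``f`` a uniform random subsample of ``n / f`` genes is
    drawn (without replacement) and the test re-run.  Folds that leave a
    group with fewer than two genes are skipped with a flag.
    """
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=bool)
    rng = as_generator(seed)
    out = []
    for fold in folds:
        size = vals.size // fold
        if size < 4:
            out.append(GroupComparison(tissue, f"{rule}|fold={fold}", 0, 0, np.nan, np.nan,
                                       1.0, 0, alternative, flag="fold-too-small"))
            continue
        idx = rng.choice(vals.size, size=size, replace=False)
        sub_labs = labs[idx]
        if sub_labs.sum() < 2 or (~sub_labs).sum() < 2:
            out.append(GroupComparison(tissue, f"{rule}|fold={fold}", int(sub_labs.sum()),
                                       int((~sub_labs).sum()), np.nan, np.nan, 1.0, 0,
                                       alternative, flag="empty-group"))
            continue
        cmp_ = ks_permutation_test(vals[idx], sub_labs, alternative=alternative,
                                   n_perm=n_perm, seed=rng, tissue=tissue,
                                   rule=f"{rule}|fold={fold}")
        out.append(cmp_)
    return out


def histogram_export(
    values: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
    bins: int | Sequence[float] = 20,
) -> pd.DataFrame:
    """Per-group histogram counts on shared bin edges (figure-panel export)."""
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=bool)
    edges = np.histogram_bin_edges(vals, bins=bins)
    high, _ = np.histogram(vals[labs], bins=edges)
    low, _ = np.histogram(vals[~labs], bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count_high": high, "count_low": low}
    )
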