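"""Cross-tissue association between mutational profiles and features.

For each candidate gene the tissues are partitioned into a lowly mutated
group 1 and a highly mutated group 2 at the largest gap between successive
sorted mutation frequencies (for the binary chromatin feature the partition
is EpiON vs EpiOFF instead).  The association statistic is the difference
of median feature values, median(group 2) - median(group 1) (for chromatin:
the difference of median mutation frequencies, EpiON - EpiOFF).  Its
significance is assessed by permuting mutation frequencies over tissues;
because the gap split depends only on the sorted frequencies, this null is
realized by randomly re-assigning tissues to the two groups with the
empirical group sizes fixed.  The test is two-sided on the absolute
statistic, with the direction (sign) reported separately, so that both
positive and negative associations are discoverable.

A permutation false-discovery rate is estimated by re-running the whole
test on frequency-label-permuted copies of the data:

    FDR = (# significant calls in permuted data)
          / (# significant empirical calls * # label permutations)
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_generator, substream

__all__ = [
    "NoSplitError",
    "SplitResult",
    "AssociationResult",
    "FeatureSummary",
    "gap_split",
    "association_statistic",
    "permutation_association",
    "associate_feature",
    "chromatin_associate",
    "estimate_fdr",
    "summarize_feature",
]


class NoSplitError(ValueError):
    """Raised when all mutation frequencies are equal and no gap exists."""


@dataclass
class SplitResult:
    """Tissue partition at the largest successive mutation-frequency gap."""

    tissues: list[str]  # ascending by mutation frequency
    boundary_index: int  # last index (in `tissues`) belonging to group 1
    gap: float
    group1: list[str]  # lowly mutated
    group2: list[str]  # highly mutated

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("both split groups must be non-empty")
        if set(self.group1) | set(self.group2) != set(self.tissues):
            raise ValueError("groups must partition the tissues")


@dataclass
class AssociationResult:
    """Per-(gene, feature) association outcome."""

    gene: str
    feature: str
    statistic: float
    p: float
    direction: str  # 'positive' | 'negative' | 'none'
    n_perm: int
    group1: tuple[str, ...]
    group2: tuple[str, ...]
    gap: float = np.nan
    alpha: float = 0.03
    flag: str = ""

    def __post_init__(self) -> None:
        if not self.flag and not (0.0 < self.p <= 1.0):
            raise ValueError("permutation p-value must lie in (0, 1]")


@dataclass
class FeatureSummary:
    """Per-feature tally of significant associations (Table-1-style row)."""

    feature: str
    n_total: int
    n_significant: int
    fraction_significant: float
    positive_fraction: float  # among significant; NaN when none
    fdr: float = np.nan
    alpha: float = 0.03
    class_crosstab: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Gap split
# ---------------------------------------------------------------------------


def gap_split(freqs: pd.Series) -> SplitResult:
    """Partition tissues at the largest successive mutation-frequency gap.

    Tissues are sorted ascending by frequency (ties broken by tissue name
    for determinism); the boundary is placed at the maximal gap between
    successive sorted frequencies, ties going to the lowest index.  Tissues
    at or below the low boundary point form group 1, the rest group 2.
    """
    if len(freqs) < 2:
        raise ValueError("gap split needs at least 2 tissues")
    order = sorted(freqs.index, key=lambda t: (freqs[t], str(t)))
    values = freqs.loc[order].to_numpy(dtype=float)
    gaps = np.diff(values)
    if np.all(gaps == 0):
        raise NoSplitError("all mutation frequencies are equal")
    boundary = int(np.argmax(gaps))  # argmax returns the lowest index on ties
    return SplitResult(
        tissues=list(order),
        boundary_index=boundary,
        gap=float(gaps[boundary]),
        group1=list(order[: boundary + 1]),
        group2=list(order[boundary + 1 :]),
    )


def association_statistic(feature_values: pd.Series, group1, group2) -> float:
    """median(feature over group 2) - median(feature over group 1).

    Tissues lacking a feature value are dropped; a group emptied by missing
    values raises.
    """
    v1 = feature_values.reindex(list(group1)).dropna()
    v2 = feature_values.reindex(list(group2)).dropna()
    if v1.empty or v2.empty:
        raise ValueError("a split group has no feature values")
    return float(v2.median() - v1.median())


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _null_median_diffs(values: np.ndarray, n2: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null statistics: median over a random n2-subset minus the complement.

    Permuting mutation frequencies over tissues and re-deriving the gap
    split is equivalent in distribution to assigning tissues to the two
    groups uniformly at random with the group sizes fixed.
    """
    n = values.size
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, n))
        order = np.argsort(keys, axis=1)
        permuted = values[order]
        out[done : done + m] = np.median(permuted[:, :n2], axis=1) - np.median(
            permuted[:, n2:], axis=1
        )
        done += m
    return out


def _exact_median_diffs(values: np.ndarray, n2: int) -> np.ndarray:
    """Statistics of all C(n, n2) group-2 choices (the literal null support)."""
    n = values.size
    stats = []
    for combo in itertools.combinations(range(n), n2):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        stats.append(np.median(values[mask]) - np.median(values[~mask]))
    return np.asarray(stats)


def permutation_association(
    feature_values: pd.Series,
    freqs: pd.Series | None = None,
    n_perm: int = 100_000,
    seed=None,
    alpha: float = 0.03,
    gene: str = "",
    feature: str = "",
    groups: tuple[list[str], list[str]] | None = None,
    exact: bool = False,
    side: str = "two-sided",
    tie_break: str = "conservative",
) -> AssociationResult:
    """Association test for one gene and one feature.

    Either ``freqs`` is given (the tissue partition comes from
    :func:`gap_split`) or ``groups=(group1, group2)`` supplies a fixed
    partition (the chromatin EpiOFF/EpiON case, where ``feature_values``
    are the mutation frequencies themselves).

    The default ``side='two-sided'`` compares absolute statistics; the
    one-sided variants ``'greater'``/``'less'`` compare signed statistics.
    With ``exact=True`` the null is enumerated over all group assignments.

    ``tie_break`` controls how null statistics tied with the empirical one
    enter the p-value.  ``'conservative'`` (default) counts them as hits,
    giving the pseudocount form ``(1 + #{null >= emp}) / (1 + n_perm)``.
    With few tissues the null support is a coarse lattice (complementary
    partitions negate the statistic), so this p-value is discrete and
    conservative; ``'randomized'`` breaks ties uniformly at random, which
    makes the p-value exactly uniform under exchangeability and is the
    variant to use for calibration studies.
    """
    gap = np.nan
    if groups is None:
        if freqs is None:
            raise ValueError("either freqs or groups must be supplied")
        try:
            split = gap_split(freqs)
        except NoSplitError:
            return AssociationResult(gene, feature, np.nan, np.nan, "none", 0,
                                     (), (), alpha=alpha, flag="no-split")
        group1, group2 = split.group1, split.group2
        gap = split.gap
    else:
        group1, group2 = list(groups[0]), list(groups[1])
        if not group1 or not group2:
            return AssociationResult(gene, feature, np.nan, np.nan, "none", 0,
                                     tuple(group1), tuple(group2), alpha=alpha,
                                     flag="empty-group")

    clean = feature_values.reindex(group1 + group2).dropna()
    g1 = [t for t in group1 if t in clean.index]
    g2 = [t for t in group2 if t in clean.index]
    if not g1 or not g2:
        return AssociationResult(gene, feature, np.nan, np.nan, "none", 0,
                                 tuple(group1), tuple(group2), alpha=alpha,
                                 flag="missing-feature")
    stat = association_statistic(clean, g1, g2)
    values = clean.loc[g2 + g1].to_numpy(dtype=float)  # group2 first
    n2 = len(g2)

    if exact:
        null = _exact_median_diffs(values, n2)
        if side == "two-sided":
            hits = int((np.abs(null) >= abs(stat) - 1e-12).sum())
        elif side == "greater":
            hits = int((null >= stat - 1e-12).sum())
        else:
            hits = int((null <= stat + 1e-12).sum())
        p = hits / null.size
        n_used = null.size
    else:
        rng = as_generator(seed)
        null = _null_median_diffs(values, n2, n_perm, rng)
        if side == "two-sided":
            null_cmp, emp_cmp = np.abs(null), abs(stat)
        elif side == "greater":
            null_cmp, emp_cmp = null, stat
        else:
            null_cmp, emp_cmp = -null, -stat
        if tie_break == "randomized":
            strict = int((null_cmp > emp_cmp + 1e-12).sum())
            ties = int((np.abs(null_cmp - emp_cmp) <= 1e-12).sum())
            p = (strict + rng.random() * (1 + ties)) / (1.0 + n_perm)
        else:
            hits = int((null_cmp >= emp_cmp - 1e-12).sum())
            p = (1.0 + hits) / (1.0 + n_perm)
        n_used = n_perm

    if p < alpha and stat != 0:
        direction = "positive" if stat > 0 else "negative"
    else:
        direction = "none"
    return AssociationResult(gene, feature, stat, p, direction, n_used,
                             tuple(g1), tuple(g2), gap=gap, alpha=alpha)


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "feature": [r.feature for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "direction": [r.direction for r in results],
            "gap": [r.gap for r in results],
            "n_group1": [len(r.group1) for r in results],
            "n_group2": [len(r.group2) for r in results],
            "flag": [r.flag for r in results],
        }
    )


def associate_feature(
    feature_matrix: pd.DataFrame,
    freq: pd.DataFrame,
    feature: str,
    n_perm: int = 100_000,
    alpha: float = 0.03,
    seed: int = 0,
    exact: bool = False,
    tie_break: str = "conservative",
) -> pd.DataFrame:
    """Run the gap-split permutation test for every gene of a feature matrix.

    ``feature_matrix`` and ``freq`` are gene x tissue frames on a shared
    tissue axis (tissue <-> cancer-type mapping applied upstream).  Each
    gene gets an independent permutation stream keyed by (seed, feature,
    gene), so results do not depend on iteration order.  Returns a tidy
    frame with one row per gene, flags included.
    """
    tissues = [t for t in freq.columns if t in feature_matrix.columns]
    if len(tissues) < 2:
        raise ValueError("need >= 2 shared tissues between features and frequencies")
    results = []
    genes = [g for g in feature_matrix.index if g in freq.index]
    for g in genes:
        res = permutation_association(
            feature_matrix.loc[g, tissues],
            freqs=freq.loc[g, tissues],
            n_perm=n_perm,
            seed=substream(seed, feature, g),
            alpha=alpha,
            gene=g,
            feature=feature,
            exact=exact,
            tie_break=tie_break,
        )
        results.append(res)
    return _results_frame(results)


def chromatin_associate(
    freq: pd.DataFrame,
    binary: pd.DataFrame,
    n_perm: int = 100_000,
    alpha: float = 0.03,
    seed: int = 0,
    exact: bool = False,
    feature: str = "chromatin",
) -> pd.DataFrame:
    """Chromatin-state association for genes with differential accessibility.

    Only EpiDIFF genes (both states present across tissues) are testable;
    the statistic is median mutation frequency (EpiON tissues) minus median
    mutation frequency (EpiOFF tissues), with frequencies permuted over
    tissues for the null.
    """
    tissues = [t for t in freq.columns if t in binary.columns]
    results = []
    for g in binary.index:
        if g not in freq.index:
            continue
        states = binary.loc[g, tissues].astype(bool)
        on = [t for t in tissues if states[t]]
        off = [t for t in tissues if not states[t]]
        if not on or not off:
            results.append(AssociationResult(g, feature, np.nan, np.nan, "none", 0,
                                             (), (), alpha=alpha, flag="not-epidiff"))
            continue
        res = permutation_association(
            freq.loc[g, tissues],
            groups=(off, on),  # group2 = EpiON
            n_perm=n_perm,
            seed=substream(seed, feature, g),
            alpha=alpha,
            gene=g,
            feature=feature,
            exact=exact,
        )
        results.append(res)
    return _results_frame(results)


# ---------------------------------------------------------------------------
# FDR and summaries
# ---------------------------------------------------------------------------


def estimate_fdr(
    results: pd.DataFrame,
    feature_matrix: pd.DataFrame,
    freq: pd.DataFrame,
    feature: str,
    n_label_perm: int = 100,
    n_perm: int = 100_000,
    alpha: float = 0.03,
    seed: int = 0,
    chromatin_binary: pd.DataFrame | None = None,
    tie_break: str = "conservative",
) -> tuple[float, str]:
    """Permutation FDR for one feature.

    Every gene's mutation-frequency labels are permuted over tissues
    ``n_label_perm`` times; the full test is re-run on each permuted copy
    and significant calls are tallied.  The estimate is

        FDR = #significant permuted calls / (#significant empirical * n_label_perm)

    Returns ``(fdr, flag)``; with zero empirical significant genes the
    estimate is undefined (NaN, flagged).
    """
    tested = results[results["flag"] == ""]
    n_sig = int((tested["p"] < alpha).sum())
    if n_sig == 0:
        return float("nan"), "no-significant-genes"
    tissues = [t for t in freq.columns if t in feature_matrix.columns] \
        if chromatin_binary is None else \
        [t for t in freq.columns if t in chromatin_binary.columns]
    sig_perm = 0
    for g in tested["gene"]:
        base = freq.loc[g, tissues].to_numpy(dtype=float)
        rng = substream(seed, "fdr", feature, g)
        for rep in range(n_label_perm):
            perm = pd.Series(rng.permutation(base), index=tissues)
            if chromatin_binary is None:
                res = permutation_association(
                    feature_matrix.loc[g, tissues], freqs=perm, n_perm=n_perm,
                    seed=rng, alpha=alpha, gene=g, feature=feature,
                    tie_break=tie_break,
                )
            else:
                states = chromatin_binary.loc[g, tissues].astype(bool)
                on = [t for t in tissues if states[t]]
                off = [t for t in tissues if not states[t]]
                res = permutation_association(
                    perm, groups=(off, on), n_perm=n_perm,
                    seed=rng, alpha=alpha, gene=g, feature=feature,
                    tie_break=tie_break,
                )
            if res.flag == "" and res.p < alpha:
                sig_perm += 1
    return sig_perm / (n_sig * n_label_perm), ""


def summarize_feature(
    results: pd.DataFrame,
    alpha: float = 0.03,
    gene_class_table: pd.Series | None = None,
    feature: str | None = None,
    fdr: float = float("nan"),
) -> FeatureSummary:
    """Tally significant associations for one feature.

    ``n_total`` counts genes that entered the test (unflagged rows);
    ``positive_fraction`` is the share of positive directions among
    significant genes (NaN when none are significant).  When a per-gene
    class table (e.g. oncogene/tumor-suppressor labels) is supplied, a
    direction x class cross-tabulation of significant genes is attached.
    """
    if results.empty:
        raise ValueError("cannot summarize an empty result set")
    tested = results[results["flag"] == ""]
    name = feature or (str(results["feature"].iloc[0]) if len(results) else "")
    n_total = len(tested)
    sig = tested[tested["p"] < alpha]
    n_sig = len(sig)
    positive = float((sig["statistic"] > 0).mean()) if n_sig else float("nan")
    crosstab = None
    if gene_class_table is not None and n_sig:
        classes = sig["gene"].map(gene_class_table).fillna("unclassified")
        direction = np.where(sig["statistic"] > 0, "positive", "negative")
        crosstab = pd.crosstab(pd.Series(direction, name="direction"),
                               classes.rename("class"))
    return FeatureSummary(
        feature=name,
        n_total=n_total,
        n_significant=n_sig,
        fraction_significant=n_sig / n_total if n_total else float("nan"),
        positive_fraction=positive,
        fdr=fdr,
        alpha=alpha,
        class_crosstab=crosstab,
    )
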