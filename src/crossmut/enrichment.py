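"""Gene-set enrichment random walks over association-ranked genes.

Genes are ranked by ascending association p-value; a walk ``y(x)`` counts
gene-set members (e.g. documented cancer genes) among the top-``x`` ranks.
Under an uninformative feature the members fall uniformly over ranks and
the expected walk is the hypergeometric mean curve ``y(n) = n K / N``.

The bivariate extension compares the *joint* walk -- members in the union
of the top-``x`` genes of two feature rankings -- against a *conditional*
walk: the expected joint count when the second feature's ranking is
uninformative, obtained from two nested hypergeometric draws conditioned on
the first feature's observed walk (how many extra genes a random top-``n``
list contributes, and how many of those are members).

Significance of a positive deviation between two walks is quantified by a
Mann-Whitney statistic on the normalized curves (treated as CDFs of
rank-valued random variables) and calibrated by permutation: re-walking
with gene-set membership placed at random ranks (univariate), or with the
second feature's ranking randomly permuted (bivariate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_generator

__all__ = [
    "RankedList",
    "WalkCurve",
    "BivariateOutcome",
    "rank_genes",
    "harmonize_universes",
    "observed_walk",
    "expected_walk",
    "joint_walk",
    "extra_genes_pmf",
    "extra_cancer_pmf",
    "expected_extra_members",
    "conditional_walk",
    "walk_pvalue",
    "bivariate_addition_pvalue",
    "classify_bivariate",
    "bivariate_gsea",
]


@dataclass
class RankedList:
    """Genes ordered by ascending association p-value with set membership."""

    genes: list[str]
    pvalues: np.ndarray
    membership: np.ndarray  # bool, aligned with genes

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.membership = np.asarray(self.membership, dtype=bool)
        if not (len(self.genes) == self.pvalues.size == self.membership.size):
            raise ValueError("genes, pvalues and membership must align")
        if np.any(np.diff(self.pvalues) < -1e-12):
            raise ValueError("p-values must be non-decreasing along ranks")
        if self.K == 0:
            raise ValueError("the gene set has no member in the universe")

    @property
    def N(self) -> int:
        return len(self.genes)

    @property
    def K(self) -> int:
        return int(self.membership.sum())

    @property
    def member_ranks(self) -> np.ndarray:
        """1-based ranks of the gene-set members."""
        return np.flatnonzero(self.membership) + 1


@dataclass
class WalkCurve:
    """Rank-indexed cumulative gene-set count.

    ``y[x-1]`` is the count at rank ``x`` (x = 1..N).  ``member_ranks``
    (observed walks) or ``r1_member_ranks`` (joint walks: the members'
    ranks in the first list) carry the information needed to re-walk under
    permutation nulls.
    """

    x: np.ndarray
    y: np.ndarray
    kind: str  # 'observed' | 'expected' | 'joint' | 'conditional'
    N: int
    K: int
    member_ranks: np.ndarray | None = field(default=None, repr=False)
    r1_member_ranks: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.N or self.y.size != self.N:
            raise ValueError("curve length must equal N")
        if np.any(np.diff(self.y) < -1e-9):
            raise ValueError("walk curves must be non-decreasing")

    @property
    def terminal(self) -> float:
        return float(self.y[-1])

    def normalized(self) -> np.ndarray:
        if self.terminal == 0:
            raise ValueError("cannot normalize an identically zero curve")
        return self.y / self.terminal


@dataclass
class BivariateOutcome:
    """Four-outcome classification of a two-feature enrichment comparison."""

    feature1: str
    feature2: str
    p_f2_adds: float  # joint vs expected-conditional-on-F1 (F2 adds info)
    p_f1_adds: float  # joint vs expected-conditional-on-F2 (F1 adds info)
    alpha: float
    classification: str


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


def rank_genes(
    results: pd.DataFrame,
    gene_set,
    universe=None,
) -> RankedList:
    """Build a ranked list from tidy association results.

    ``results`` needs ``gene`` and ``p`` columns (flagged rows, if a
    ``flag`` column exists, are dropped).  Ranks are ascending in p with
    ties broken lexicographically by gene symbol; membership comes from
    ``gene_set`` intersected with the universe.
    """
    df = results
    if "flag" in df.columns:
        df = df[df["flag"] == ""]
    if universe is not None:
        df = df[df["gene"].isin(set(universe))]
    if df.empty:
        raise ValueError("empty gene universe")
    df = df.sort_values(["p", "gene"], kind="stable")
    genes = list(df["gene"])
    members = np.array([g in set(gene_set) for g in genes])
    return RankedList(genes=genes, pvalues=df["p"].to_numpy(), membership=members)


def harmonize_universes(ranked1: RankedList, ranked2: RankedList, gene_set) -> tuple[RankedList, RankedList]:
    """Restrict two ranked lists to their shared gene universe.

    Feature universes differ (not every gene has every feature); the joint
    walk is only defined on a common rank axis, so both lists are re-ranked
    within the intersection and the member count K is recomputed there.
    """
    shared = set(ranked1.genes) & set(ranked2.genes)
    if not shared:
        raise ValueError("ranked lists share no genes")

    def _restrict(r: RankedList) -> RankedList:
        keep = [i for i, g in enumerate(r.genes) if g in shared]
        return RankedList(
            genes=[r.genes[i] for i in keep],
            pvalues=r.pvalues[keep],
            membership=np.array([r.genes[i] in set(gene_set) for i in keep]),
        )

    return _restrict(ranked1), _restrict(ranked2)


# ---------------------------------------------------------------------------
# Walks
# ---------------------------------------------------------------------------


def observed_walk(ranked: RankedList) -> WalkCurve:
    """Cumulative member count along the ranked list (+1 at each member)."""
    y = np.cumsum(ranked.membership).astype(float)
    return WalkCurve(
        x=np.arange(1, ranked.N + 1), y=y, kind="observed", N=ranked.N, K=ranked.K,
        member_ranks=ranked.member_ranks,
    )


def expected_walk(N: int, K: int) -> WalkCurve:
    """Expected walk when members are uniformly distributed over ranks.

    At rank ``n`` the count of members among a random top-``n`` set follows
    a hypergeometric law; the curve is its mean, which reduces exactly to
    the straight line ``n K / N``.  The expectation is computed from the
    distribution itself (sum over k of P(k) * k) rather than the shortcut,
    so the identity is checkable.
    """
    if not (0 < K <= N):
        raise ValueError("need 0 < K <= N")
    ks = np.arange(0, K + 1)
    ns = np.arange(1, N + 1)
    pmf = stats.hypergeom.pmf(ks[None, :], N, K, ns[:, None])  # (N, K+1)
    y = pmf @ ks.astype(float)
    return WalkCurve(x=ns, y=y, kind="expected", N=N, K=K)


def joint_walk(ranked1: RankedList, ranked2: RankedList) -> WalkCurve:
    """Members in the union of the top-x genes of two rankings.

    A member enters the union at rank min(rank in list 1, rank in list 2),
    so the curve is the cumulative count of members' minimum ranks; it
    dominates both univariate walks pointwise.
    """
    if ranked1.genes == ranked2.genes:
        pass
    elif set(ranked1.genes) != set(ranked2.genes):
        raise ValueError("joint walk requires a shared gene universe (harmonize first)")
    if ranked1.K != ranked2.K:
        raise ValueError("gene-set membership differs between the two lists")
    rank2 = {g: i + 1 for i, g in enumerate(ranked2.genes)}
    r1 = ranked1.member_ranks
    members = [ranked1.genes[i - 1] for i in r1]
    r2 = np.array([rank2[g] for g in members])
    m = np.minimum(r1, r2)
    y = np.bincount(m, minlength=ranked1.N + 1)[1:].cumsum().astype(float)
    return WalkCurve(
        x=np.arange(1, ranked1.N + 1), y=y, kind="joint", N=ranked1.N, K=ranked1.K,
        member_ranks=m, r1_member_ranks=r1,
    )


# ---------------------------------------------------------------------------
# Conditional (bivariate null) machinery
# ---------------------------------------------------------------------------


def extra_genes_pmf(N: int, n: int, n_extra: int) -> float:
    """P(a random top-n list contributes n_extra genes beyond a fixed top-n).

    Hypergeometric: of the n randomly chosen genes, ``n - n_extra`` fall
    inside the fixed top-n list and ``n_extra`` outside it.
    """
    if not (0 <= n <= N):
        raise ValueError("need 0 <= n <= N")
    if n_extra < 0 or n_extra > min(n, N - n):
        return 0.0
    return math.comb(N - n, n_extra) * math.comb(n, n - n_extra) / math.comb(N, n)


def extra_cancer_pmf(N: int, K: int, n: int, k: int, n_extra: int, k_extra: int) -> float:
    """P(k_extra of the n_extra contributed genes are gene-set members).

    Conditioned on ``n_extra`` genes drawn from the ``N - n`` genes outside
    the fixed list, of which ``K - k`` are members.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError("need 0 <= k <= min(n, K)")
    if n_extra < 0 or n_extra > N - n:
        return 0.0
    if k_extra < 0 or k_extra > min(n_extra, K - k) or n_extra - k_extra > N - n - K + k:
        return 0.0
    return (
        math.comb(K - k, k_extra)
        * math.comb(N - n - K + k, n_extra - k_extra)
        / math.comb(N - n, n_extra)
    )


def expected_extra_members(N: int, K: int, n: int, k: int) -> float:
    """Expected extra members contributed by an uninformative second list.

    The double sum over the two nested hypergeometric laws
    (``extra_genes_pmf`` then ``extra_cancer_pmf``) collapses through their
    means:  E[n_extra] = n (N - n) / N and E[k_extra | n_extra] =
    n_extra (K - k) / (N - n),  giving  n (K - k) / N  exactly.
    """
    if N == n:
        return 0.0
    return n * (K - k) / N


def conditional_walk(f1_walk: WalkCurve, N: int | None = None, K: int | None = None) -> WalkCurve:
    """Expected joint walk when the second feature is uninformative.

    At each rank ``n`` with ``k(n)`` members already contributed by the
    first feature, the curve is ``k(n)`` plus the expected number of extra
    members a randomly ordered second list would add, so that it is
    directly comparable with the joint walk (which also counts the first
    feature's contribution).
    """
    N = f1_walk.N if N is None else N
    K = f1_walk.K if K is None else K
    k = f1_walk.y
    if f1_walk.N != N or abs(f1_walk.terminal - K) > 1e-9:
        raise ValueError("F1 walk trace inconsistent with (N, K)")
    incr = np.diff(np.concatenate([[0.0], k]))
    if np.any((np.abs(incr) > 1e-9) & (np.abs(incr - 1) > 1e-9)):
        raise ValueError("F1 walk must have increments in {0, 1}")
    n = np.arange(1, N + 1)
    y = k + np.array([expected_extra_members(N, K, ni, ki) for ni, ki in zip(n, k)])
    return WalkCurve(x=n, y=y, kind="conditional", N=N, K=K)


# ---------------------------------------------------------------------------
# Mann-Whitney permutation p-values
# ---------------------------------------------------------------------------


def _curve_pmf(curve: WalkCurve) -> np.ndarray:
    y = curve.normalized()
    return np.diff(np.concatenate([[0.0], y]))


def _enrichment_gain(reference: WalkCurve) -> np.ndarray:
    """Per-rank Mann-Whitney gain G(x) = P(X_ref > x) + 0.5 P(X_ref = x).

    For a curve whose normalized increments put mass 1/K at ranks ``m``,
    the Mann-Whitney statistic P(X_curve < X_ref) + 0.5 P(=) is the mean of
    G over ``m`` -- large when the curve rises earlier than the reference.
    """
    b = _curve_pmf(reference)
    cdf = np.cumsum(b)
    return (1.0 - cdf) + 0.5 * b


def _mwu_theta(curve: WalkCurve, reference: WalkCurve) -> float:
    a = _curve_pmf(curve)
    return float(np.dot(a, _enrichment_gain(reference)))


def _distinct_ranks(N: int, K: int, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """(n_draws, K) matrix of without-replacement 1-based rank samples."""
    out = np.empty((n_draws, K), dtype=np.int64)
    chunk = max(1, min(n_draws, 20_000_000 // max(N, 1)))
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        keys = rng.random((m, N))
        out[done : done + m] = np.argpartition(keys, K - 1, axis=1)[:, :K] + 1
        done += m
    return out


def walk_pvalue(
    observed: WalkCurve,
    reference: WalkCurve,
    n_perm: int = 100_000,
    seed=None,
) -> float:
    """One-sided permutation p for a positive deviation of ``observed``.

    Both curves are normalized by their terminal values and treated as
    CDFs of rank-valued variables; the statistic is the Mann-Whitney
    probability that the observed variable precedes the reference one.  The
    null re-walks the observed curve with membership placed at K uniform
    random ranks ('observed' curves) or with the second feature's ranking
    permuted while the first list's member ranks stay fixed ('joint'
    curves), and the p-value is the pseudocounted fraction of permuted
    statistics at or above the empirical one.
    """
    if reference.terminal == 0:
        raise ValueError("reference curve is identically zero")
    theta_emp = _mwu_theta(observed, reference)
    gain = _enrichment_gain(reference)
    rng = as_generator(seed)
    N, K = observed.N, observed.K
    if observed.kind == "joint":
        if observed.r1_member_ranks is None:
            raise ValueError("joint curve lacks the F1 member ranks needed for the null")
        r1 = observed.r1_member_ranks
        r2 = _distinct_ranks(N, K, n_perm, rng)
        m = np.minimum(r1[None, :], r2)
        thetas = gain[m - 1].mean(axis=1)
    else:
        if observed.member_ranks is None:
            raise ValueError("observed curve lacks member ranks needed for the null")
        ranks = _distinct_ranks(N, K, n_perm, rng)
        thetas = gain[ranks - 1].mean(axis=1)
    hits = int((thetas >= theta_emp - 1e-12).sum())
    return (1.0 + hits) / (1.0 + n_perm)


def bivariate_addition_pvalue(
    ranked1: RankedList,
    ranked2: RankedList,
    n_perm: int = 100_000,
    seed=None,
) -> tuple[float, WalkCurve, WalkCurve]:
    """p that feature 2 adds enrichment information beyond feature 1.

    Compares the joint walk of the two rankings against the conditional
    walk (expected joint when feature 2 is uninformative); returns the
    p-value with the two curves.
    """
    joint = joint_walk(ranked1, ranked2)
    cond = conditional_walk(observed_walk(ranked1))
    return walk_pvalue(joint, cond, n_perm=n_perm, seed=seed), joint, cond


def classify_bivariate(p_f2_adds: float, p_f1_adds: float, alpha: float = 0.05,
                       feature1: str = "F1", feature2: str = "F2") -> BivariateOutcome:
    """Four-outcome call from the two conditional comparisons.

    * both significant -> each feature is indispensable;
    * only the F2-adds comparison significant -> F2 superior;
    * only the F1-adds comparison significant -> F1 superior;
    * neither -> neither informative, or largely overlapping information.
    """
    f2 = p_f2_adds < alpha
    f1 = p_f1_adds < alpha
    if f1 and f2:
        label = "both indispensable"
    elif f2:
        label = "F2 superior"
    elif f1:
        label = "F1 superior"
    else:
        label = "neither/overlapped"
    return BivariateOutcome(feature1, feature2, p_f2_adds, p_f1_adds, alpha, label)


def bivariate_gsea(
    ranked1: RankedList,
    ranked2: RankedList,
    gene_set,
    alpha: float = 0.05,
    n_perm: int = 100_000,
    seed: int = 0,
    feature1: str = "F1",
    feature2: str = "F2",
) -> BivariateOutcome:
    """Full bivariate comparison of two feature rankings on a gene set."""
    r1, r2 = harmonize_universes(ranked1, ranked2, gene_set)
    rng = as_generator(seed)
    p_f2_adds, _, _ = bivariate_addition_pvalue(r1, r2, n_perm=n_perm, seed=rng)
    p_f1_adds, _, _ = bivariate_addition_pvalue(r2, r1, n_perm=n_perm, seed=rng)
    return classify_bivariate(p_f2_adds, p_f1_adds, alpha, feature1, feature2)
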