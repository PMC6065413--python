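"""Normal-tissue feature computation.

Four candidate features are computed per (gene, tissue), plus one control:

* **chromatin accessibility** -- a binary EpiON/EpiOFF call derived from
  25-state chromatin-model labels, with replicate epigenomes of a tissue
  aggregated by a strict-majority rule;
* **own expression** -- an upper-tail permutation score of the gene's own
  expression within the tissue;
* **pathway-neighbor activity** -- the same score computed on the mean
  expression of the gene's immediate upstream/downstream pathway members
  (minimum p over mapped pathways);
* **PPI-partner activity** -- the score on the mean expression of the gene's
  first-degree protein-interaction partners;
* **control** -- the mean expression of 5 genes sampled from the gene's
  third- to seventh-degree PPI neighborhood.

Activity scores are ``-log p`` where ``p`` is the pseudocounted upper-tail
fraction of random same-size gene sets whose mean expression reaches the
observed mean; the pseudocount keeps the score finite at ``log(n_null + 1)``.
"""

from __future__ import annotations

import itertools
import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import as_generator, substream
from .io import ChromatinStateTable, ExpressionMatrix, PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EPION_STATES",
    "ActivityScore",
    "AccessibilityMatrix",
    "accessibility_label",
    "aggregate_states",
    "binarize_chromatin",
    "nth_degree_neighbors",
    "activity_score",
    "expression_activity",
    "ppi_activity",
    "pathway_activity",
    "compute_activity_matrix",
    "control_feature",
    "control_feature_matrix",
]

#: 25-state chromatin-model labels mapped to the accessible (EpiON) call.
EPION_STATES = frozenset(
    {
        "active transcription",
        "transcribed - 5' preferential",
        "strong transcription",
        "transcribed - 3' preferential",
    }
)

_unknown_states_seen: set[str] = set()


def _canon(state: str) -> str:
    # normalize typographic dashes/quotes so label variants compare equal
    text = unicodedata.normalize("NFKC", state).strip().lower()
    return text.replace("–", "-").replace("—", "-").replace("’", "'")


def accessibility_label(state_name: str) -> bool:
    """Map one 25-state label to the binary accessibility call.

    Returns True (EpiON) for the four transcription-associated states and
    False (EpiOFF) for every other label.  A precomputed ``"ON"``/``"OFF"``
    string is passed through.  Unknown strings yield EpiOFF and are logged
    once.
    """
    canon = _canon(state_name)
    if canon == "on":
        return True
    if canon == "off":
        return False
    if canon in EPION_STATES:
        return True
    if canon not in _KNOWN_OFF and canon not in _unknown_states_seen:
        _unknown_states_seen.add(canon)
        logger.debug("unrecognized chromatin state %r treated as EpiOFF", state_name)
    return False


# the full 25-state vocabulary is large; only a few common OFF labels are
# listed to keep the unknown-state log useful
_KNOWN_OFF = frozenset(
    {
        "quiescent",
        "quiescent/low",
        "heterochromatin",
        "weak transcription",
        "polycomb repressed",
        "bivalent promoter",
        "active enhancer",
        "weak enhancer",
        "primary dnase",
        "znf genes & repeats",
    }
)


def aggregate_states(states: Sequence[bool]) -> bool:
    """Strict-majority aggregation of replicate EpiON/EpiOFF calls.

    The aggregate is EpiON iff strictly more than half of the replicates are
    EpiON; an even ON/OFF split therefore aggregates to EpiOFF.
    """
    if len(states) == 0:
        raise ValueError("cannot aggregate an empty list of states")
    return sum(bool(s) for s in states) * 2 > len(states)


@dataclass
class AccessibilityMatrix:
    """Binary gene x tissue accessibility with per-gene cross-tissue category."""

    binary: pd.DataFrame  # bool, genes x tissues
    category: pd.Series  # 'EpiAllON' | 'EpiAllOFF' | 'EpiDIFF' per gene

    def __post_init__(self) -> None:
        on_any = self.binary.any(axis=1)
        on_all = self.binary.all(axis=1)
        expect = pd.Series(
            np.where(on_all, "EpiAllON", np.where(on_any, "EpiDIFF", "EpiAllOFF")),
            index=self.binary.index,
        )
        if not (expect.values == self.category.reindex(self.binary.index).values).all():
            raise ValueError("category labels inconsistent with the binary matrix")


def binarize_chromatin(table: ChromatinStateTable) -> AccessibilityMatrix:
    """Binarize 25-state labels and aggregate replicate epigenomes per tissue.

    Each label column is mapped through :func:`accessibility_label`; columns
    belonging to the same tissue are then combined by the strict-majority
    rule of :func:`aggregate_states`.
    """
    calls = table.labels.map(accessibility_label)
    by_tissue: dict[str, list[str]] = {}
    for col in table.labels.columns:
        by_tissue.setdefault(table.epigenome_tissues[col], []).append(col)
    binary = pd.DataFrame(
        {
            tissue: calls[cols].sum(axis=1) * 2 > len(cols)
            for tissue, cols in by_tissue.items()
        },
        index=calls.index,
    )
    binary = binary[list(table.tissues)]
    on_any = binary.any(axis=1)
    on_all = binary.all(axis=1)
    category = pd.Series(
        np.where(on_all, "EpiAllON", np.where(on_any, "EpiDIFF", "EpiAllOFF")),
        index=binary.index,
    )
    return AccessibilityMatrix(binary=binary, category=category)


# ---------------------------------------------------------------------------
# Network neighborhoods
# ---------------------------------------------------------------------------


def nth_degree_neighbors(net: nx.Graph, gene: str, d: int) -> set[str]:
    """Genes at shortest-path distance exactly ``d`` from ``gene``.

    A gene absent from the network yields the empty set.
    """
    if d < 1:
        raise ValueError("degree must be >= 1")
    if gene not in net:
        logger.debug("gene %r absent from network", gene)
        return set()
    dist = nx.single_source_shortest_path_length(net, gene, cutoff=d)
    return {g for g, dd in dist.items() if dd == d}


def _neighbor_pool(net: nx.Graph, gene: str, d_min: int, d_max: int) -> set[str]:
    if gene not in net:
        return set()
    dist = nx.single_source_shortest_path_length(net, gene, cutoff=d_max)
    return {g for g, dd in dist.items() if d_min <= dd <= d_max}


# ---------------------------------------------------------------------------
# Activity scoring
# ---------------------------------------------------------------------------


@dataclass
class ActivityScore:
    """Upper-tail permutation score of a gene set's mean expression."""

    gene: str
    tissue: str
    neighbors: tuple[str, ...]
    observed_mean: float
    n_null: int
    p: float
    score: float
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError("activity p-value must lie in (0, 1]")
        if not np.isfinite(self.score) or self.score < -1e-12:
            raise ValueError("activity score must be finite and non-negative")


def _sample_index_sets(universe: int, size: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, size) index matrix; rows are without-replacement draws from range(universe)."""
    if size > universe:
        raise ValueError("set size exceeds the gene universe")
    idx = rng.integers(0, universe, size=(n, size))
    if size > 1:
        srt = np.sort(idx, axis=1)
        bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
        while bad.any():
            idx[bad] = rng.integers(0, universe, size=(int(bad.sum()), size))
            srt = np.sort(idx, axis=1)
            bad = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
    return idx


def activity_score(
    target_mean: float,
    neighbor_count: int,
    tissue: str,
    expr_values: np.ndarray,
    n_null: int = 100_000,
    seed=None,
    gene: str = "",
    neighbors: Iterable[str] = (),
    exhaustive: bool = False,
) -> ActivityScore:
    """Score an observed set-mean expression against random same-size sets.

    ``expr_values`` is the expression vector of the whole gene universe in
    the tissue.  The null draws ``n_null`` gene sets of ``neighbor_count``
    genes uniformly without replacement and records their means; the
    p-value is the pseudocounted fraction of null means at or above the
    observed mean, ``p = (1 + #{null >= observed}) / (1 + n_null)``, and the
    score is ``-log p``.  With ``exhaustive=True`` all possible sets are
    enumerated instead (only sensible for tiny universes) and
    ``p = #{null >= observed} / #sets``.
    """
    if neighbor_count < 1:
        raise ValueError("neighbor_count must be >= 1")
    values = np.asarray(expr_values, dtype=float)
    universe = values.size
    if neighbor_count > universe:
        raise ValueError("neighbor_count exceeds the gene universe")
    if exhaustive:
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(universe), neighbor_count)),
            dtype=np.intp,
        ).reshape(-1, neighbor_count)
        null_means = values[combos].mean(axis=1)
        n_trials = null_means.size
        p = float((null_means >= target_mean - 1e-12).sum()) / n_trials
        p = max(p, 1.0 / n_trials)
    else:
        rng = as_generator(seed)
        n_trials = int(n_null)
        hits = 0
        chunk = max(1, min(n_trials, 50_000_000 // max(neighbor_count, 1) // 8))
        done = 0
        while done < n_trials:
            m = min(chunk, n_trials - done)
            idx = _sample_index_sets(universe, neighbor_count, m, rng)
            null_means = values[idx].mean(axis=1)
            hits += int((null_means >= target_mean - 1e-12).sum())
            done += m
        p = (1.0 + hits) / (1.0 + n_trials)
    return ActivityScore(
        gene=gene,
        tissue=tissue,
        neighbors=tuple(neighbors),
        observed_mean=float(target_mean),
        n_null=n_trials,
        p=p,
        score=float(-np.log(p)),
        exhaustive=exhaustive,
    )


def _set_activity(
    gene: str,
    neighbor_genes: set[str],
    expr: ExpressionMatrix,
    tissue: str,
    n_null: int,
    seed,
    exhaustive: bool = False,
) -> ActivityScore:
    present = sorted(neighbor_genes & set(expr.genes))
    if not present:
        raise ValueError(f"gene {gene!r}: no neighbor with expression data")
    col = expr.values[tissue]
    observed = float(col.loc[present].mean())
    return activity_score(
        observed,
        len(present),
        tissue,
        col.values,
        n_null=n_null,
        seed=seed,
        gene=gene,
        neighbors=present,
        exhaustive=exhaustive,
    )


def expression_activity(
    gene: str, expr: ExpressionMatrix, tissue: str, n_null: int = 100_000, seed=None, exhaustive: bool = False
) -> ActivityScore:
    """Activity score of the gene's own expression (a size-1 'set')."""
    return _set_activity(gene, {gene}, expr, tissue, n_null, seed, exhaustive)


def ppi_activity(
    gene: str,
    net: nx.Graph,
    expr: ExpressionMatrix,
    tissue: str,
    n_null: int = 100_000,
    seed=None,
    exhaustive: bool = False,
) -> ActivityScore:
    """Activity score of the gene's first-degree PPI partners."""
    partners = nth_degree_neighbors(net, gene, 1)
    if not partners:
        raise ValueError(f"gene {gene!r} has no PPI partner")
    return _set_activity(gene, partners, expr, tissue, n_null, seed, exhaustive)


def pathway_activity(
    gene: str,
    pathways: PathwayCollection,
    expr: ExpressionMatrix,
    tissue: str,
    n_null: int = 100_000,
    seed=None,
    exhaustive: bool = False,
) -> ActivityScore:
    """Pathway activity: minimum p over the gene's mapped pathways.

    Per mapped pathway the neighbor set is the union of immediate upstream
    and downstream members; the reported score derives from the smallest
    p-value across pathways (the strongest mapped pathway).
    """
    mapped = pathways.pathways_of(gene)
    best: ActivityScore | None = None
    for i, pw in enumerate(mapped):
        neigh = pathways.neighbors(gene, pw)
        if not neigh or not (neigh & set(expr.genes)):
            continue
        sc = _set_activity(
            gene, neigh, expr, tissue, n_null,
            seed if i == 0 or not isinstance(seed, (int, np.integer)) else seed + i,
            exhaustive,
        )
        if best is None or sc.p < best.p:
            best = sc
    if best is None:
        raise ValueError(f"gene {gene!r} has no mapped pathway with usable neighbors")
    return best


def compute_activity_matrix(
    neighbor_map: Mapping[str, set[str] | list[set[str]]],
    expr: ExpressionMatrix,
    n_null: int = 10_000,
    seed: int = 0,
    feature: str = "activity",
) -> tuple[pd.DataFrame, list[str]]:
    """Activity scores for many genes over all tissues.

    ``neighbor_map`` maps each gene to one neighbor set, or to a list of
    sets (one per mapped pathway -- the minimum p across sets is used).
    Genes whose sets have no expression coverage are excluded and returned
    in the second element.  Null draws are independent per (gene, tissue),
    seeded from ``seed`` by a stable per-gene/per-tissue key.
    """
    genes, excluded = [], []
    rows = []
    tissues = list(expr.tissues)
    gene_universe = set(expr.genes)
    for gene in sorted(neighbor_map):
        sets = neighbor_map[gene]
        if isinstance(sets, set):
            sets = [sets]
        usable = [sorted(s & gene_universe) for s in sets]
        usable = [s for s in usable if s]
        if not usable:
            excluded.append(gene)
            continue
        row = np.empty(len(tissues))
        for j, tissue in enumerate(tissues):
            col = expr.values[tissue].values
            col_series = expr.values[tissue]
            best_p = None
            for si, members in enumerate(usable):
                rng = substream(seed, feature, gene, tissue, si)
                observed = float(col_series.loc[members].mean())
                sc = activity_score(
                    observed, len(members), tissue, col, n_null=n_null, seed=rng,
                    gene=gene, neighbors=members,
                )
                if best_p is None or sc.p < best_p:
                    best_p = sc.p
            row[j] = -np.log(best_p)
        genes.append(gene)
        rows.append(row)
    matrix = pd.DataFrame(rows, index=genes, columns=tissues)
    return matrix, excluded


# ---------------------------------------------------------------------------
# Control feature
# ---------------------------------------------------------------------------


def control_feature(
    gene: str,
    net: nx.Graph,
    expr: ExpressionMatrix,
    seed=None,
    n_pick: int = 5,
    d_min: int = 3,
    d_max: int = 7,
) -> tuple[pd.Series, tuple[str, ...]]:
    """Mean expression of ``n_pick`` random remote PPI neighbors, per tissue.

    The pool is the union of shortest-path distance ``d_min``..``d_max``
    neighbors restricted to genes with expression data; the same sampled
    genes are reused across all tissues of one realization.  A pool smaller
    than ``n_pick`` raises (the caller excludes the gene).
    """
    pool = sorted(_neighbor_pool(net, gene, d_min, d_max) & set(expr.genes))
    if len(pool) < n_pick:
        raise ValueError(f"gene {gene!r}: remote-neighbor pool has {len(pool)} < {n_pick} genes")
    rng = as_generator(seed)
    picked = tuple(sorted(rng.choice(pool, size=n_pick, replace=False)))
    values = expr.values.loc[list(picked)].mean(axis=0)
    return values, picked


def control_feature_matrix(
    genes: Sequence[str],
    net: nx.Graph,
    expr: ExpressionMatrix,
    seed: int = 0,
    realization: int = 0,
    n_pick: int = 5,
) -> tuple[pd.DataFrame, list[str]]:
    """Control feature values for many genes; excluded genes returned too."""
    rows, kept, excluded = [], [], []
    for gene in genes:
        try:
            values, _ = control_feature(
                gene, net, expr, seed=substream(seed, "control", gene, realization), n_pick=n_pick
            )
        except ValueError:
            excluded.append(gene)
            continue
        kept.append(gene)
        rows.append(values)
    matrix = pd.DataFrame(rows, index=kept) if rows else pd.DataFrame(columns=expr.tissues)
    return matrix, excluded
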