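"""Input parsing, validation and gene-level primary computations.

This module reads the standard input tables of the analysis -- a somatic
mutation catalog (MAF-dialect TSV), a gene x tissue FPKM expression matrix,
a gene x epigenome chromatin-state label table, pathway definitions (GMT
and/or a directed edge list), an undirected protein-protein interaction edge
list, and plain gene lists -- and provides the gene-level computations that
feed every downstream stage:

* per-gene mutation-frequency profiles across cancer types
  (fraction of patients of a cohort carrying at least one qualifying call),
* candidate selection as the union of each cancer type's top-k most
  frequently mutated genes,
* per-gene z-normalization of expression across tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "MutationCatalog",
    "MutationFrequencyMatrix",
    "ExpressionMatrix",
    "ChromatinStateTable",
    "PathwayCollection",
    "read_mutation_catalog",
    "read_expression",
    "read_chromatin_states",
    "read_gmt",
    "read_pathway_edges",
    "read_ppi",
    "read_gene_list",
    "read_inputs",
    "mutation_frequency",
    "select_candidates",
    "znormalize",
]

#: Variant classifications counted as protein-altering for coding genes.
#: Standard MAF non-silent convention; configurable in `mutation_frequency`.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

_MAF_COLUMNS = {
    "gene": "Hugo_Symbol",
    "sample": "Tumor_Sample_Barcode",
    "variant_class": "Variant_Classification",
    "cancer_type": "Cancer_Type",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MutationCatalog:
    """Somatic mutation calls plus cohort bookkeeping.

    Parameters
    ----------
    records
        One row per call with columns ``gene``, ``sample``, ``cancer_type``,
        ``variant_class``.  Duplicate rows are dropped on construction.
    cohorts
        Mapping cancer type -> full list of profiled sample barcodes.  A
        cohort's size is the denominator of every mutation frequency, so it
        must include samples without any call.  When omitted it is inferred
        from the samples present in ``records`` (a lower bound).
    coding_genes
        Symbols flagged protein-coding.  Genes not listed are treated as
        non-coding: every record counts toward their frequency.
    """

    records: pd.DataFrame
    cohorts: dict[str, list[str]] = field(default_factory=dict)
    coding_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        required = ["gene", "sample", "cancer_type", "variant_class"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation catalog missing mandatory column(s): {missing}")
        before = len(self.records)
        self.records = self.records.drop_duplicates().reset_index(drop=True)
        if len(self.records) < before:
            logger.info("dropped %d duplicate mutation records", before - len(self.records))
        if not self.cohorts:
            self.cohorts = {
                ct: sorted(sub["sample"].unique())
                for ct, sub in self.records.groupby("cancer_type")
            }
        unknown = set(self.records["cancer_type"]) - set(self.cohorts)
        if unknown:
            raise ValueError(f"records reference cancer types without a cohort: {sorted(unknown)}")

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.cohorts)


@dataclass
class MutationFrequencyMatrix:
    """Gene x cancer-type mutation frequencies (the mutational profiles).

    ``freq.loc[g, t]`` is the fraction of cohort-``t`` patients carrying at
    least one qualifying call on gene ``g``; ``freq * cohort_sizes`` is an
    integral patient count by construction.
    """

    freq: pd.DataFrame
    cohort_sizes: pd.Series

    def __post_init__(self) -> None:
        if ((self.freq.values < -1e-12) | (self.freq.values > 1 + 1e-12)).any():
            raise ValueError("mutation frequencies must lie in [0, 1]")
        counts = self.freq.values * self.cohort_sizes.reindex(self.freq.columns).values
        if not np.allclose(counts, np.round(counts), atol=1e-6):
            raise ValueError("freq * cohort_size must be an integral patient count")

    @property
    def genes(self) -> pd.Index:
        return self.freq.index

    @property
    def cancer_types(self) -> pd.Index:
        return self.freq.columns


@dataclass
class ExpressionMatrix:
    """Gene x tissue expression values.

    ``values`` holds raw FPKM (all >= 0) or, after :func:`znormalize`,
    per-gene z-scores.  ``constant_genes`` flags genes whose raw profile was
    constant; their normalized values are set to 0.
    """

    values: pd.DataFrame
    normalized: bool = False
    normalization_axis: str | None = None
    constant_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValueError("expression matrix is empty")
        if not self.normalized and (self.values.values < 0).any():
            raise ValueError("raw FPKM values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns


@dataclass
class ChromatinStateTable:
    """Gene x epigenome chromatin-state labels from the 25-state model.

    ``labels`` columns are individual epigenomes; ``epigenome_tissues`` maps
    each epigenome column to its tissue so that replicate epigenomes of one
    tissue can be aggregated by the strict-majority rule downstream.  When a
    precomputed binary ON/OFF table is supplied, ``labels`` holds the strings
    ``"ON"``/``"OFF"`` and each column is its own tissue.
    """

    labels: pd.DataFrame
    epigenome_tissues: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.empty:
            raise ValueError("chromatin state table is empty")
        if not self.epigenome_tissues:
            self.epigenome_tissues = {c: c for c in self.labels.columns}
        missing = set(self.labels.columns) - set(self.epigenome_tissues)
        if missing:
            raise ValueError(f"epigenome columns without a tissue mapping: {sorted(missing)}")

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for col in self.labels.columns:
            seen.setdefault(self.epigenome_tissues[col], None)
        return list(seen)


@dataclass
class PathwayCollection:
    """Curated pathways: memberships and, optionally, directed edges.

    ``members`` maps pathway id -> member gene set.  ``edges`` (optional)
    maps pathway id -> :class:`networkx.DiGraph` over the member genes;
    immediate upstream/downstream neighbors are read off these graphs.  When
    a pathway has no edge information, neighbor queries fall back to "all
    other members" only if ``membership_fallback`` is set.
    """

    members: dict[str, set[str]]
    edges: dict[str, nx.DiGraph] = field(default_factory=dict)
    membership_fallback: bool = False

    def __post_init__(self) -> None:
        for pw, graph in self.edges.items():
            if pw not in self.members:
                raise ValueError(f"edges reference unknown pathway {pw!r}")
            stray = set(graph.nodes) - self.members[pw]
            if stray:
                raise ValueError(f"pathway {pw!r} edges reference non-members: {sorted(stray)}")
            loops = list(nx.selfloop_edges(graph))
            if loops:
                raise ValueError(f"pathway {pw!r} contains self-loops: {loops}")

    def pathways_of(self, gene: str) -> list[str]:
        return sorted(pw for pw, mem in self.members.items() if gene in mem)

    def neighbors(self, gene: str, pathway: str) -> set[str]:
        """Immediate upstream/downstream members of ``gene`` in ``pathway``."""
        if pathway in self.edges:
            graph = self.edges[pathway]
            if gene not in graph:
                return set()
            return set(graph.predecessors(gene)) | set(graph.successors(gene))
        if self.membership_fallback:
            return self.members[pathway] - {gene}
        return set()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_mutation_catalog(
    path,
    dialect: Mapping[str, str] | None = None,
    cohorts: Mapping[str, Sequence[str]] | None = None,
    coding_genes: Iterable[str] | None = None,
) -> MutationCatalog:
    """Read a MAF-dialect mutation TSV.

    ``dialect`` remaps internal field names (``gene``, ``sample``,
    ``cancer_type``, ``variant_class``) to the file's column headers;
    defaults to MAF-compatible names (Hugo_Symbol, Tumor_Sample_Barcode,
    Variant_Classification, Cancer_Type).
    """
    columns = dict(_MAF_COLUMNS)
    if dialect:
        columns.update(dialect)
    df = _read_tsv(path)
    missing = [col for col in columns.values() if col not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    records = df[[columns[k] for k in ("gene", "sample", "cancer_type", "variant_class")]]
    records.columns = ["gene", "sample", "cancer_type", "variant_class"]
    return MutationCatalog(
        records=records,
        cohorts={ct: list(s) for ct, s in cohorts.items()} if cohorts else {},
        coding_genes=set(coding_genes) if coding_genes is not None else set(),
    )


def read_expression(path) -> ExpressionMatrix:
    """Read a genes-in-rows, tissues-in-columns FPKM TSV."""
    df = _read_tsv(path).set_index(_first_column(path))
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    return ExpressionMatrix(values=df.astype(float))


def _first_column(path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return line.rstrip("\n").split("\t")[0]
    raise ValueError(f"{path}: no header line found")


def read_chromatin_states(path, epigenome_tissues: Mapping[str, str] | None = None) -> ChromatinStateTable:
    """Read a gene x epigenome table of 25-state labels (or ON/OFF strings)."""
    df = _read_tsv(path).set_index(_first_column(path))
    return ChromatinStateTable(
        labels=df.astype(str),
        epigenome_tissues=dict(epigenome_tissues) if epigenome_tissues else {},
    )


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: pathway id, description, then member genes."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                logger.warning("%s:%d: GMT line with <3 fields rejected", path, lineno)
                continue
            members[parts[0]] = set(g for g in parts[2:] if g)
    return members


def read_pathway_edges(path) -> dict[str, list[tuple[str, str]]]:
    """Read a directed pathway edge list TSV (pathway_id, src_gene, dst_gene)."""
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pathway edge list needs 3 columns")
    out: dict[str, list[tuple[str, str]]] = {}
    for pw, src, dst in df.iloc[:, :3].itertuples(index=False):
        out.setdefault(str(pw), []).append((str(src), str(dst)))
    return out


def load_pathways(
    gmt_path=None,
    edges_path=None,
    membership_fallback: bool = False,
) -> PathwayCollection:
    """Assemble a :class:`PathwayCollection` from a GMT and/or edge list."""
    members = read_gmt(gmt_path) if gmt_path else {}
    edges: dict[str, nx.DiGraph] = {}
    if edges_path:
        for pw, pairs in read_pathway_edges(edges_path).items():
            graph = nx.DiGraph()
            graph.add_edges_from((s, d) for s, d in pairs if s != d)
            members.setdefault(pw, set()).update(graph.nodes)
            edges[pw] = graph
    if not members:
        raise ValueError("no pathway information supplied")
    return PathwayCollection(members=members, edges=edges, membership_fallback=membership_fallback)


def read_ppi(path) -> nx.Graph:
    """Read a 2-column undirected PPI edge list; dedups symmetric pairs."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: PPI edge list needs 2 columns")
    graph = nx.Graph()
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a != b:
            graph.add_edge(str(a), str(b))
    return graph


def read_gene_list(path) -> list[str]:
    """Read a one-symbol-per-line gene list."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def read_inputs(paths: Mapping[str, str | Path], dialect_config: Mapping | None = None):
    """Read every input table named in ``paths``.

    Recognized keys: ``mutations``, ``expression``, ``chromatin``,
    ``pathways_gmt``, ``pathway_edges``, ``ppi``, ``gene_set``.  Returns a
    dict with the corresponding typed objects (missing keys are omitted).
    """
    dialect_config = dict(dialect_config or {})
    out: dict[str, object] = {}
    if "mutations" in paths:
        out["mutations"] = read_mutation_catalog(
            paths["mutations"],
            dialect=dialect_config.get("maf_columns"),
            cohorts=dialect_config.get("cohorts"),
            coding_genes=dialect_config.get("coding_genes"),
        )
    if "expression" in paths:
        out["expression"] = read_expression(paths["expression"])
    if "chromatin" in paths:
        out["chromatin"] = read_chromatin_states(
            paths["chromatin"], epigenome_tissues=dialect_config.get("epigenome_tissues")
        )
    if "pathways_gmt" in paths or "pathway_edges" in paths:
        out["pathways"] = load_pathways(
            gmt_path=paths.get("pathways_gmt"),
            edges_path=paths.get("pathway_edges"),
            membership_fallback=bool(dialect_config.get("membership_fallback", False)),
        )
    if "ppi" in paths:
        out["ppi"] = read_ppi(paths["ppi"])
    if "gene_set" in paths:
        out["gene_set"] = read_gene_list(paths["gene_set"])
    return out


# ---------------------------------------------------------------------------
# Gene-level computations
# ---------------------------------------------------------------------------


def mutation_frequency(
    catalog: MutationCatalog,
    nonsynonymous: Iterable[str] = NONSYNONYMOUS_CLASSES,
    genes: Sequence[str] | None = None,
) -> MutationFrequencyMatrix:
    """Per-gene, per-cancer-type fraction of patients with >= 1 qualifying call.

    For protein-coding genes only records whose ``variant_class`` is in the
    ``nonsynonymous`` set count; for non-coding genes every record counts.
    A sample contributes at most once per (gene, cancer type).  Genes absent
    from a cohort's catalog get frequency 0.
    """
    nonsyn = set(nonsynonymous)
    sizes = {ct: len(samples) for ct, samples in catalog.cohorts.items()}
    for ct, n in sizes.items():
        if n == 0:
            raise ValueError(f"cancer type {ct!r} has an empty cohort")
    rec = catalog.records
    if catalog.coding_genes:
        coding = rec["gene"].isin(catalog.coding_genes)
        keep = ~coding | rec["variant_class"].isin(nonsyn)
    else:
        # without a coding-gene annotation every gene is treated as coding
        keep = rec["variant_class"].isin(nonsyn)
    rec = rec[keep]
    counts = (
        rec.drop_duplicates(["gene", "sample", "cancer_type"])
        .groupby(["gene", "cancer_type"])
        .size()
        .unstack(fill_value=0)
    )
    cancer_types = sorted(catalog.cohorts)
    counts = counts.reindex(columns=cancer_types, fill_value=0)
    if genes is None:
        genes = sorted(set(catalog.records["gene"]))  # pre-filter universe
    counts = counts.reindex(index=list(genes), fill_value=0)
    counts = counts.sort_index().rename_axis(index="gene", columns=None)
    size_series = pd.Series({ct: sizes[ct] for ct in cancer_types}, name="cohort_size")
    freq = counts.divide(size_series, axis=1).astype(float)
    return MutationFrequencyMatrix(freq=freq, cohort_sizes=size_series)


def select_candidates(freq: MutationFrequencyMatrix, k: int = 50) -> list[str]:
    """Union over cancer types of each type's k most frequently mutated genes.

    Ties at the k-th frequency are all included, which makes the selection
    deterministic and independent of gene order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    selected: set[str] = set()
    for ct in freq.cancer_types:
        col = freq.freq[ct]
        if len(col) <= k:
            selected.update(col.index)
            continue
        threshold = col.nlargest(k).iloc[-1]
        selected.update(col.index[col >= threshold])
    return sorted(selected)


def znormalize(expr: ExpressionMatrix, axis: str = "gene") -> ExpressionMatrix:
    """Z-score expression values (default: per gene, across tissues).

    Constant genes (zero variance) are flagged and set to 0 rather than
    producing NaNs.  ``axis='tissue'`` standardizes each tissue column
    across genes instead.
    """
    if expr.normalized:
        raise ValueError("expression matrix is already normalized")
    if axis not in ("gene", "tissue"):
        raise ValueError("axis must be 'gene' or 'tissue'")
    values = expr.values
    if axis == "gene" and values.shape[1] < 2:
        raise ValueError("z-normalization across tissues needs >= 2 tissues")
    ax = 1 if axis == "gene" else 0
    mean = values.mean(axis=ax)
    std = values.std(axis=ax, ddof=0)
    constant = std == 0
    std = std.where(~constant, 1.0)
    normalized = values.sub(mean, axis=1 - ax).div(std, axis=1 - ax)
    if axis == "gene":
        normalized.loc[constant[constant].index] = 0.0
        flagged = set(constant[constant].index)
    else:
        normalized.loc[:, constant[constant].index] = 0.0
        flagged = set(constant[constant].index)
    return ExpressionMatrix(
        values=normalized,
        normalized=True,
        normalization_axis=axis,
        constant_genes=flagged,
    )
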