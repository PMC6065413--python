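"""Synthetic input bundles with planted ground truth.

The generator emulates the statistical regime of the real study inputs so
that every pipeline stage can be exercised and validated without any
external data:

* per-gene mutation-frequency profiles over ~a dozen tissue types, where an
  "associated" gene is highly mutated in a small minority of tissues (the
  high group) with a pronounced frequency gap to the rest, and frequencies
  are realized as binomial draws over a finite patient cohort;
* a gene x tissue FPKM matrix in which associated genes (or, for the
  pathway/PPI features, their network neighbors) are shifted between high-
  and low-mutation tissues by a configurable effect size in within-tissue
  population-SD units of the set mean;
* binary chromatin accessibility, with EpiDIFF genes aligned (or
  anti-aligned) with the high-mutation group and a uniform EpiAllON /
  EpiAllOFF background, serialized as 25-state label strings;
* a preferential-attachment PPI network (heavy-tailed degrees, so remote
  distance-3..7 neighborhoods are non-trivial) and randomly drawn pathway
  memberships with directed within-pathway edges;
* a planted "cancer gene" set concentrated among pathway-associated genes.

Most genes are marked protein-coding and their catalog records carry
non-silent variant classes (plus a sprinkle of Silent records that must be
ignored); a small fraction are non-coding, for which every record counts.

Defaults place a gene's high group on two or three tissues and only rarely
on a single tissue: with ~12 tissues a lone elevated tissue admits at most
``1 / n_tissues`` as its one-sided permutation p-value and is therefore
unidentifiable at the default significance level, so single-tissue plants
are kept as a small minority rather than a third of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream
from .features import binarize_chromatin
from .io import (
    ChromatinStateTable,
    ExpressionMatrix,
    MutationCatalog,
    MutationFrequencyMatrix,
    PathwayCollection,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticBundle",
    "generate_bundle",
    "write_bundle",
    "make_ranked_scenario",
    "truth_evaluation",
]

FEATURES = ("expression", "chromatin", "pathway", "ppi")

_ON_LABEL = "Active Transcription"
_OFF_LABEL = "Quiescent"


@dataclass
class SyntheticConfig:
    """Generator knobs; defaults define the study-like regime."""

    n_genes: int = 400
    n_tissues: int = 12
    cohort_size: int = 200
    # fraction of genes planted (positive, negative) per feature
    planted_fractions: dict = field(
        default_factory=lambda: {
            "expression": (0.10, 0.05),
            "chromatin": (0.06, 0.02),
            "pathway": (0.06, 0.02),
            "ppi": (0.06, 0.02),
        }
    )
    gap: float = 0.3  # high-group minus low-group mean mutation frequency
    effect_size: float = 3.0  # feature shift, within-tissue set-mean SD units
    baseline_freq_range: tuple[float, float] = (0.005, 0.05)
    n_high_choices: tuple[int, ...] = (1, 2, 3)
    n_high_weights: tuple[float, ...] = (0.05, 0.65, 0.30)
    network_model: str = "preferential_attachment"  # or 'erdos_renyi'
    mean_degree: float = 6.0
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (8, 30)
    cancer_gene_prob_assoc: float = 0.6  # membership prob for pathway-planted genes
    cancer_gene_prob_null: float = 0.05
    frac_epi_allon: float = 0.45
    frac_epi_alloff: float = 0.25
    frac_noncoding: float = 0.02
    silent_noise_rate: float = 0.1  # extra Silent records per mutated sample
    expr_mean_range: tuple[float, float] = (20.0, 200.0)
    expr_cv: float = 0.125  # per-gene tissue-to-tissue coefficient of variation
    materialize_catalog: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p + n for p, n in self.planted_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError("planted fractions must sum to <= 1")
        if self.n_genes < 10 or self.n_tissues < 2 or self.cohort_size < 1:
            raise ValueError("counts must be positive (and n_genes >= 10)")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway sizes exceed n_genes")
        if abs(sum(self.n_high_weights) - 1.0) > 1e-9:
            raise ValueError("n_high_weights must sum to 1")


@dataclass
class SyntheticBundle:
    """A complete generated input set plus its ground truth."""

    config: SyntheticConfig
    catalog: MutationCatalog | None
    freq: MutationFrequencyMatrix
    expression: ExpressionMatrix
    chromatin: ChromatinStateTable
    pathways: PathwayCollection
    ppi: nx.Graph
    cancer_genes: list[str]
    truth: pd.DataFrame
    tissue_map: dict[str, str]  # cancer type -> tissue

    @property
    def tissues(self) -> list[str]:
        return list(self.expression.tissues)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _make_network(cfg: SyntheticConfig, genes: list[str], rng) -> nx.Graph:
    n = len(genes)
    if cfg.network_model == "preferential_attachment":
        m = max(1, int(round(cfg.mean_degree / 2)))
        graph = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    elif cfg.network_model == "erdos_renyi":
        p = min(1.0, cfg.mean_degree / max(n - 1, 1))
        graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown network model {cfg.network_model!r}")
    return nx.relabel_nodes(graph, dict(enumerate(genes)))


def _make_pathways(cfg: SyntheticConfig, genes: list[str], rng) -> PathwayCollection:
    members: dict[str, set[str]] = {}
    edges: dict[str, nx.DiGraph] = {}
    lo, hi = cfg.pathway_size_range
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        chosen = list(rng.choice(genes, size=size, replace=False))
        graph = nx.DiGraph()
        order = list(rng.permutation(chosen))
        # a directed chain plus extra shortcuts gives every member >= 1 neighbor
        for a, b in zip(order[:-1], order[1:]):
            graph.add_edge(a, b)
        for _ in range(size // 3):
            a, b = rng.choice(chosen, size=2, replace=False)
            graph.add_edge(a, b)
        pw = f"pw{i:03d}"
        members[pw] = set(chosen)
        edges[pw] = graph
    return PathwayCollection(members=members, edges=edges)


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete, self-consistent input bundle.

    All randomness derives from ``config.seed`` through named substreams,
    so the same config always yields an identical bundle.
    """
    cfg = config
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    tissues = [f"T{i:02d}" for i in range(cfg.n_tissues)]
    cancer_types = [f"C{i:02d}" for i in range(cfg.n_tissues)]
    tissue_map = dict(zip(cancer_types, tissues))

    roles_rng = substream(cfg.seed, "roles")
    order = list(roles_rng.permutation(genes))
    cursor = 0
    planted: dict[str, tuple[str, str]] = {}  # gene -> (feature, direction)
    for feat in FEATURES:
        fpos, fneg = cfg.planted_fractions.get(feat, (0.0, 0.0))
        for direction, frac in (("positive", fpos), ("negative", fneg)):
            count = int(round(frac * cfg.n_genes))
            for g in order[cursor : cursor + count]:
                planted[g] = (feat, direction)
            cursor += count

    # high-mutation tissue group per associated gene
    high_rng = substream(cfg.seed, "high-groups")
    high_groups: dict[str, list[str]] = {}
    for g in genes:
        if g in planted:
            n_high = int(high_rng.choice(cfg.n_high_choices, p=cfg.n_high_weights))
            high_groups[g] = sorted(high_rng.choice(tissues, size=n_high, replace=False))

    # --- mutation frequencies (binomial over the cohort) ------------------
    freq_rng = substream(cfg.seed, "frequencies")
    base = freq_rng.uniform(*cfg.baseline_freq_range, size=cfg.n_genes)
    target = np.tile(base[:, None], (1, cfg.n_tissues))
    t_index = {t: j for j, t in enumerate(tissues)}
    for i, g in enumerate(genes):
        for t in high_groups.get(g, ()):
            target[i, t_index[t]] += cfg.gap
    target = np.clip(target, 0.0, 1.0)
    counts = freq_rng.binomial(cfg.cohort_size, target)
    freq_df = pd.DataFrame(counts / cfg.cohort_size, index=genes, columns=cancer_types).rename_axis("gene")
    cohort_sizes = pd.Series(cfg.cohort_size, index=cancer_types, name="cohort_size")
    freq = MutationFrequencyMatrix(freq=freq_df, cohort_sizes=cohort_sizes)

    # --- networks and pathways -------------------------------------------
    ppi = _make_network(cfg, genes, substream(cfg.seed, "ppi"))
    pathways = _make_pathways(cfg, genes, substream(cfg.seed, "pathways"))

    # pathway-planted genes must map to >= 1 pathway
    pw_rng = substream(cfg.seed, "pathway-assignment")
    pathway_ids = sorted(pathways.members)
    for g in genes:
        if g in planted and planted[g][0] == "pathway" and not pathways.pathways_of(g):
            pw = pathway_ids[int(pw_rng.integers(len(pathway_ids)))]
            anchor = sorted(pathways.members[pw])[int(pw_rng.integers(len(pathways.members[pw])))]
            pathways.members[pw].add(g)
            pathways.edges[pw].add_edge(anchor, g)

    # --- expression --------------------------------------------------------
    expr_rng = substream(cfg.seed, "expression")
    mu = expr_rng.uniform(*cfg.expr_mean_range, size=cfg.n_genes)
    sigma = mu * cfg.expr_cv
    values = mu[:, None] + sigma[:, None] * expr_rng.standard_normal((cfg.n_genes, cfg.n_tissues))
    pop_sd = values.std(axis=0, ddof=0)  # within-tissue SD across genes, pre-shift

    gene_index = {g: i for i, g in enumerate(genes)}
    collateral: set[str] = set()

    def _shift(gene_list, high, sign, per_gene_sd):
        for gname in gene_list:
            gi = gene_index[gname]
            for t in high:
                values[gi, t_index[t]] += sign * per_gene_sd[t_index[t]]

    # effect sizes are measured in units of the within-tissue null SD of the
    # corresponding set-mean statistic: pop_sd / sqrt(m) for an m-gene
    # neighbor set, pop_sd itself for the gene's own expression (m = 1)
    for g, (feat, direction) in planted.items():
        sign = 1.0 if direction == "positive" else -1.0
        high = high_groups[g]
        if feat == "expression":
            _shift([g], high, sign, cfg.effect_size * pop_sd)
        elif feat == "pathway":
            neigh: set[str] = set()
            for pw in pathways.pathways_of(g):
                neigh |= pathways.neighbors(g, pw)
            neigh.discard(g)
            if neigh:
                shift = cfg.effect_size * pop_sd / np.sqrt(len(neigh))
                _shift(sorted(neigh), high, sign, shift)
                collateral |= neigh
        elif feat == "ppi":
            neigh = set(ppi.neighbors(g)) if g in ppi else set()
            if neigh:
                shift = cfg.effect_size * pop_sd / np.sqrt(len(neigh))
                _shift(sorted(neigh), high, sign, shift)
                collateral |= neigh
    values = np.clip(values, 0.01, None)
    expression = ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=tissues).rename_axis("gene"))

    # --- chromatin states --------------------------------------------------
    chrom_rng = substream(cfg.seed, "chromatin")
    binary = np.zeros((cfg.n_genes, cfg.n_tissues), dtype=bool)
    u = chrom_rng.random(cfg.n_genes)
    for i, g in enumerate(genes):
        if g in planted and planted[g][0] == "chromatin":
            on_high = planted[g][1] == "positive"
            for j in range(cfg.n_tissues):
                is_high = tissues[j] in high_groups[g]
                binary[i, j] = is_high if on_high else not is_high
        elif u[i] < cfg.frac_epi_allon:
            binary[i, :] = True
        elif u[i] < cfg.frac_epi_allon + cfg.frac_epi_alloff:
            binary[i, :] = False
        else:
            row = chrom_rng.random(cfg.n_tissues) < 0.5
            binary[i, :] = row
    labels = pd.DataFrame(
        np.where(binary, _ON_LABEL, _OFF_LABEL), index=genes, columns=tissues
    ).rename_axis("gene")
    chromatin = ChromatinStateTable(labels=labels)

    # --- cancer genes ------------------------------------------------------
    cg_rng = substream(cfg.seed, "cancer-genes")
    cancer_genes = []
    for g in genes:
        prob = (
            cfg.cancer_gene_prob_assoc
            if g in planted and planted[g][0] == "pathway"
            else cfg.cancer_gene_prob_null
        )
        if cg_rng.random() < prob:
            cancer_genes.append(g)

    # --- catalog -----------------------------------------------------------
    catalog = None
    coding = set(genes)
    noncoding_rng = substream(cfg.seed, "noncoding")
    noncoding = set(
        noncoding_rng.choice(genes, size=int(round(cfg.frac_noncoding * cfg.n_genes)), replace=False)
    )
    coding -= noncoding
    if cfg.materialize_catalog:
        catalog = _materialize_catalog(cfg, genes, cancer_types, counts, coding,
                                       substream(cfg.seed, "catalog"))

    # --- ground truth ------------------------------------------------------
    rows = []
    for g in genes:
        feat, direction = planted.get(g, ("", ""))
        rows.append(
            {
                "gene": g,
                "planted_feature": feat,
                "direction": direction,
                "high_tissues": ",".join(high_groups.get(g, [])),
                "n_high": len(high_groups.get(g, [])),
                "effect_size": cfg.effect_size if feat else 0.0,
                "gap": cfg.gap if feat else 0.0,
                "is_cancer_gene": g in cancer_genes,
                "collateral_expression": g in collateral,
                "coding": g in coding,
            }
        )
    truth = pd.DataFrame(rows).set_index("gene")

    return SyntheticBundle(
        config=cfg,
        catalog=catalog,
        freq=freq,
        expression=expression,
        chromatin=chromatin,
        pathways=pathways,
        ppi=ppi,
        cancer_genes=cancer_genes,
        truth=truth,
        tissue_map=tissue_map,
    )


_NONSILENT = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)


def _materialize_catalog(cfg, genes, cancer_types, counts, coding, rng) -> MutationCatalog:
    samples = {ct: [f"{ct}-S{i:04d}" for i in range(cfg.cohort_size)] for ct in cancer_types}
    rec_gene, rec_sample, rec_ct, rec_class = [], [], [], []
    for i, g in enumerate(genes):
        is_coding = g in coding
        for j, ct in enumerate(cancer_types):
            c = int(counts[i, j])
            if c == 0:
                continue
            picked = rng.choice(cfg.cohort_size, size=c, replace=False)
            for s in picked:
                rec_gene.append(g)
                rec_sample.append(samples[ct][s])
                rec_ct.append(ct)
                if is_coding:
                    rec_class.append(_NONSILENT[int(rng.integers(len(_NONSILENT)))])
                else:
                    rec_class.append("RNA")
            # Silent noise on coding genes must not affect frequencies
            if is_coding and cfg.silent_noise_rate > 0:
                n_silent = rng.binomial(c, cfg.silent_noise_rate)
                for s in rng.choice(cfg.cohort_size, size=n_silent, replace=False):
                    rec_gene.append(g)
                    rec_sample.append(samples[ct][s])
                    rec_ct.append(ct)
                    rec_class.append("Silent")
    records = pd.DataFrame(
        {"gene": rec_gene, "sample": rec_sample, "cancer_type": rec_ct, "variant_class": rec_class}
    )
    return MutationCatalog(records=records, cohorts=samples, coding_genes=set(coding))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the bundle in exactly the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    if bundle.catalog is not None:
        maf = bundle.catalog.records.rename(
            columns={
                "gene": "Hugo_Symbol",
                "sample": "Tumor_Sample_Barcode",
                "cancer_type": "Cancer_Type",
                "variant_class": "Variant_Classification",
            }
        )
        paths["mutations"] = str(outdir / "mutations.tsv")
        maf.to_csv(paths["mutations"], sep="\t", index=False)

    paths["expression"] = str(outdir / "expression.tsv")
    bundle.expression.values.rename_axis("gene").to_csv(paths["expression"], sep="\t")

    paths["chromatin"] = str(outdir / "chromatin_states.tsv")
    bundle.chromatin.labels.rename_axis("gene").to_csv(paths["chromatin"], sep="\t")

    paths["pathways_gmt"] = str(outdir / "pathways.gmt")
    with open(paths["pathways_gmt"], "w") as fh:
        for pw in sorted(bundle.pathways.members):
            genes = "\t".join(sorted(bundle.pathways.members[pw]))
            fh.write(f"{pw}\tsynthetic\t{genes}\n")

    paths["pathway_edges"] = str(outdir / "pathway_edges.tsv")
    with open(paths["pathway_edges"], "w") as fh:
        fh.write("pathway_id\tsrc_gene\tdst_gene\n")
        for pw in sorted(bundle.pathways.edges):
            for a, b in sorted(bundle.pathways.edges[pw].edges):
                fh.write(f"{pw}\t{a}\t{b}\n")

    paths["ppi"] = str(outdir / "ppi.tsv")
    with open(paths["ppi"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(map(lambda e: tuple(sorted(e)), bundle.ppi.edges)):
            fh.write(f"{a}\t{b}\n")

    paths["gene_set"] = str(outdir / "cancer_genes.txt")
    with open(paths["gene_set"], "w") as fh:
        fh.write("\n".join(bundle.cancer_genes) + "\n")

    paths["truth"] = str(outdir / "truth.tsv")
    bundle.truth.to_csv(paths["truth"], sep="\t")

    paths["tissue_map"] = str(outdir / "tissue_map.tsv")
    with open(paths["tissue_map"], "w") as fh:
        fh.write("cancer_type\ttissue\n")
        for ct, t in bundle.tissue_map.items():
            fh.write(f"{ct}\t{t}\n")
    return paths


# ---------------------------------------------------------------------------
# Scenario simulation and truth recovery
# ---------------------------------------------------------------------------


def make_ranked_scenario(kind: str, N: int = 200, K: int = 30, seed: int = 0,
                         member_scale: float = 0.1):
    """Two ranked lists with a designed bivariate relationship.

    ``kind``: ``'copy'`` (F2 duplicates an informative F1),
    ``'independent'`` (both informative, independent noise), or
    ``'one_informative'`` (F1 informative, F2 pure noise).  Informative
    lists draw member scores from U(0, member_scale) against a U(0, 1)
    background, concentrating members near the top ranks.
    """
    from .enrichment import RankedList

    rng = substream(seed, "scenario", kind)
    genes = [f"g{i:04d}" for i in range(N)]
    members = set(rng.choice(genes, size=K, replace=False))
    member_mask = np.array([g in members for g in genes])

    def informative():
        s = rng.uniform(0, 1, size=N)
        s[member_mask] = rng.uniform(0, member_scale, size=K)
        return s

    def noise():
        return rng.uniform(0, 1, size=N)

    s1 = informative()
    if kind == "copy":
        s2 = s1.copy()
    elif kind == "independent":
        s2 = informative()
    elif kind == "one_informative":
        s2 = noise()
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")

    def ranked(scores):
        order = np.argsort(scores, kind="stable")
        return RankedList(
            genes=[genes[i] for i in order],
            pvalues=np.sort(scores),
            membership=member_mask[order],
        )

    return ranked(s1), ranked(s2), sorted(members)


def truth_evaluation(
    results_by_feature: dict[str, pd.DataFrame],
    truth: pd.DataFrame,
    alpha: float = 0.03,
) -> pd.DataFrame:
    """Per-feature recovery report against the planted ground truth.

    For each feature: sensitivity (planted genes called significant, among
    planted genes that entered the test), specificity (1 - false positive
    rate among genes without any planted or collateral signal), and the
    sign-recovery rate among detected planted genes.
    """
    rows = []
    for feat, results in results_by_feature.items():
        tested = results[results["flag"] == ""].set_index("gene")
        planted = truth[truth["planted_feature"] == feat]
        planted_tested = planted.index.intersection(tested.index)
        detected = tested.loc[planted_tested, "p"] < alpha
        sens = float(detected.mean()) if len(planted_tested) else float("nan")
        if detected.any():
            want = planted.loc[planted_tested, "direction"][detected]
            got = np.where(
                tested.loc[planted_tested, "statistic"][detected] > 0, "positive", "negative"
            )
            sign_rate = float((want.values == got).mean())
        else:
            sign_rate = float("nan")
        clean = truth[(truth["planted_feature"] == "") & (~truth["collateral_expression"])]
        null_tested = clean.index.intersection(tested.index)
        spec = (
            float((tested.loc[null_tested, "p"] >= alpha).mean())
            if len(null_tested)
            else float("nan")
        )
        rows.append(
            {
                "feature": feat,
                "n_planted_tested": int(len(planted_tested)),
                "sensitivity": sens,
                "sign_recovery": sign_rate,
                "specificity": spec,
                "alpha": alpha,
            }
        )
    return pd.DataFrame(rows)
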