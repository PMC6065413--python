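"""End-to-end orchestration: features -> tests -> FDR -> summaries -> enrichment.

`run_pipeline` drives the full analysis from a single :class:`RunConfig`:
it loads (or generates) the inputs, computes mutation-frequency profiles,
selects candidate genes, builds the per-feature gene x tissue matrices,
runs the cross-tissue association test with permutation FDR, summarizes
each feature, optionally runs the within-tissue EpiON/EpiOFF comparisons,
and performs univariate and bivariate cancer-gene enrichment.  Every stage
logs how many genes entered and how many were excluded and why; a JSON
manifest of parameters and seeds suffices to re-run the identical analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import enrichment as enr
from . import features as feat
from . import io as cio
from . import within_tissue as wt
from ._rng import substream
from .synthetic import SyntheticBundle, SyntheticConfig, generate_bundle

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ALL_FEATURES = ("chromatin", "expression", "pathway", "ppi", "control")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_paths: dict = field(default_factory=dict)
    tissue_map: dict = field(default_factory=dict)  # cancer type -> tissue
    synthetic: SyntheticConfig | None = None
    features: tuple[str, ...] = ("chromatin", "expression", "pathway", "ppi")
    top_k: int = 50
    alpha: float = 0.03
    enrichment_alpha: float = 0.05
    n_perm_association: int = 10_000
    n_perm_within: int = 10_000
    n_perm_enrichment: int = 10_000
    n_null_activity: int = 10_000
    n_label_perm: int = 0  # 0 disables the FDR stage
    fdr_inner_perm: int = 1_000
    do_within_tissue: bool = False
    do_enrichment: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(ALL_FEATURES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        for n in (self.n_perm_association, self.n_perm_within,
                  self.n_perm_enrichment, self.n_null_activity):
            if n < 100:
                raise ValueError("permutation counts must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "features" in raw:
            raw["features"] = tuple(raw["features"])
        return cls(**raw)


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        bundle = generate_bundle(config.synthetic)
        return bundle, dict(bundle.tissue_map)
    data = cio.read_inputs(config.input_paths)
    tissue_map = dict(config.tissue_map)
    return data, tissue_map


def _expand_to_cancer_types(matrix: pd.DataFrame, tissue_map: dict) -> pd.DataFrame:
    """Feature matrix on tissues -> matrix on cancer types via the mapping."""
    cols = {ct: matrix[t] for ct, t in tissue_map.items() if t in matrix.columns}
    return pd.DataFrame(cols)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured analysis; returns a dict of result tables.

    Keys: ``freq`` (gene x cancer-type frequencies), ``candidates``,
    ``associations`` (tidy per-gene results, all features), ``summary``
    (Table-1-style rows), ``within_tissue`` (optional), ``walks`` and
    ``enrichment_p`` and ``bivariate`` (optional), ``accounting`` (gene
    counts entering/excluded per feature), ``manifest``.
    """
    source, tissue_map = _load_inputs(config)
    is_synthetic = isinstance(source, SyntheticBundle)

    # --- frequencies and candidates ---------------------------------------
    if is_synthetic:
        if source.catalog is not None:
            freq = cio.mutation_frequency(source.catalog)
        else:
            freq = source.freq
        expression = source.expression
        chromatin = source.chromatin
        pathways = source.pathways
        ppi = source.ppi
        gene_set = list(source.cancer_genes)
    else:
        freq = cio.mutation_frequency(source["mutations"])
        expression = source.get("expression")
        chromatin = source.get("chromatin")
        pathways = source.get("pathways")
        ppi = source.get("ppi")
        gene_set = source.get("gene_set", [])
    candidates = cio.select_candidates(freq, k=config.top_k)
    logger.info("selected %d candidate genes (top-%d union)", len(candidates), config.top_k)

    zexpr = cio.znormalize(expression) if expression is not None else None
    access = feat.binarize_chromatin(chromatin) if chromatin is not None else None

    freq_cand = freq.freq.loc[[g for g in candidates if g in freq.freq.index]]

    accounting: list[dict] = []
    associations: list[pd.DataFrame] = []
    summaries: list[dict] = []
    feature_matrices: dict[str, pd.DataFrame] = {}

    for feature in config.features:
        if feature == "chromatin":
            if access is None:
                continue
            cand = [g for g in candidates if g in access.binary.index]
            binary_ct = _expand_to_cancer_types(access.binary.loc[cand], tissue_map)
            epidiff = access.category.reindex(cand) == "EpiDIFF"
            results = assoc.chromatin_associate(
                freq_cand, binary_ct.loc[epidiff[epidiff].index],
                n_perm=config.n_perm_association, alpha=config.alpha, seed=config.seed,
            )
            excluded = {"not-epidiff": int((~epidiff).sum())}
            matrix_for_fdr = None
            chromatin_binary = binary_ct
        else:
            if zexpr is None:
                continue
            if feature == "expression":
                cand = [g for g in candidates if g in zexpr.genes]
                matrix = zexpr.values.loc[cand]
                excluded = {"no-expression": len(candidates) - len(cand)}
            elif feature == "pathway":
                if pathways is None:
                    continue
                neighbor_map = {}
                for g in candidates:
                    sets = [pathways.neighbors(g, pw) for pw in pathways.pathways_of(g)]
                    sets = [s for s in sets if s]
                    if sets:
                        neighbor_map[g] = sets
                matrix, no_cov = feat.compute_activity_matrix(
                    neighbor_map, zexpr, n_null=config.n_null_activity,
                    seed=config.seed, feature="pathway",
                )
                excluded = {
                    "no-mapped-pathway": len(candidates) - len(neighbor_map),
                    "no-expression-coverage": len(no_cov),
                }
            elif feature == "ppi":
                if ppi is None:
                    continue
                neighbor_map = {
                    g: set(ppi.neighbors(g)) for g in candidates if g in ppi and ppi.degree(g) > 0
                }
                matrix, no_cov = feat.compute_activity_matrix(
                    neighbor_map, zexpr, n_null=config.n_null_activity,
                    seed=config.seed, feature="ppi",
                )
                excluded = {
                    "no-ppi-partner": len(candidates) - len(neighbor_map),
                    "no-expression-coverage": len(no_cov),
                }
            elif feature == "control":
                if ppi is None:
                    continue
                matrix, no_pool = feat.control_feature_matrix(
                    candidates, ppi, zexpr, seed=config.seed,
                )
                excluded = {"remote-pool-too-small": len(no_pool)}
            matrix_ct = _expand_to_cancer_types(matrix, tissue_map)
            feature_matrices[feature] = matrix_ct
            results = assoc.associate_feature(
                matrix_ct, freq_cand, feature,
                n_perm=config.n_perm_association, alpha=config.alpha, seed=config.seed,
            )
            matrix_for_fdr = matrix_ct
            chromatin_binary = None

        fdr = float("nan")
        if config.n_label_perm > 0:
            fdr, fdr_flag = assoc.estimate_fdr(
                results,
                matrix_for_fdr if matrix_for_fdr is not None else freq_cand,
                freq_cand,
                feature,
                n_label_perm=config.n_label_perm,
                n_perm=config.fdr_inner_perm,
                alpha=config.alpha,
                seed=config.seed,
                chromatin_binary=chromatin_binary,
            )
        summary = assoc.summarize_feature(results, alpha=config.alpha,
                                          feature=feature, fdr=fdr)
        associations.append(results)
        summaries.append(
            {
                "feature": feature,
                "n_total": summary.n_total,
                "n_significant": summary.n_significant,
                "fraction_significant": summary.fraction_significant,
                "positive_fraction": summary.positive_fraction,
                "estimated_fdr": summary.fdr,
            }
        )
        flagged = results[results["flag"] != ""]["flag"].value_counts().to_dict()
        accounting.append(
            {"feature": feature, "n_input": len(candidates),
             "n_tested": summary.n_total,
             "excluded": json.dumps({**excluded, **flagged})}
        )
        logger.info("feature %s: %d tested, %d significant", feature,
                    summary.n_total, summary.n_significant)

    out: dict = {
        "freq": freq.freq,
        "candidates": candidates,
        "associations": pd.concat(associations, ignore_index=True) if associations else pd.DataFrame(),
        "summary": pd.DataFrame(summaries),
        "accounting": pd.DataFrame(accounting),
    }

    # --- within-tissue comparisons ----------------------------------------
    if config.do_within_tissue and access is not None:
        comparisons = []
        binary_ct_all = _expand_to_cancer_types(access.binary, tissue_map)
        for ct in freq.freq.columns:
            if ct not in binary_ct_all.columns:
                continue
            genes = freq.freq.index.intersection(binary_ct_all.index)
            comp = wt.ks_permutation_test(
                freq.freq.loc[genes, ct], binary_ct_all.loc[genes, ct],
                alternative="greater", n_perm=config.n_perm_within,
                seed=substream(config.seed, "within", ct), tissue=ct, rule="EpiON/EpiOFF",
            )
            comparisons.append(dataclasses.asdict(comp))
        out["within_tissue"] = pd.DataFrame(comparisons)

    # --- enrichment ---------------------------------------------------------
    if config.do_enrichment and gene_set and associations:
        walks: list[pd.DataFrame] = []
        enrich_p = []
        ranked_by_feature: dict[str, enr.RankedList] = {}
        for results in associations:
            feature = results["feature"].iloc[0]
            tested = results[results["flag"] == ""]
            if tested.empty or not (set(tested["gene"]) & set(gene_set)):
                continue
            ranked = enr.rank_genes(tested, gene_set)
            ranked_by_feature[feature] = ranked
            obs = enr.observed_walk(ranked)
            exp = enr.expected_walk(ranked.N, ranked.K)
            p = enr.walk_pvalue(obs, exp, n_perm=config.n_perm_enrichment,
                                seed=substream(config.seed, "enrich", feature))
            enrich_p.append({"feature": feature, "N": ranked.N, "K": ranked.K, "walk_p": p})
            walks.append(pd.DataFrame({"feature": feature, "rank": obs.x,
                                       "y_observed": obs.y, "y_expected": exp.y}))
        out["enrichment_p"] = pd.DataFrame(enrich_p)
        out["walks"] = pd.concat(walks, ignore_index=True) if walks else pd.DataFrame()

        bivariate = []
        names = sorted(ranked_by_feature)
        for i, f1 in enumerate(names):
            for f2 in names[i + 1 :]:
                outcome = enr.bivariate_gsea(
                    ranked_by_feature[f1], ranked_by_feature[f2], gene_set,
                    alpha=config.enrichment_alpha, n_perm=config.n_perm_enrichment,
                    seed=substream(config.seed, "bivar", f1, f2),
                    feature1=f1, feature2=f2,
                )
                bivariate.append(dataclasses.asdict(outcome))
        out["bivariate"] = pd.DataFrame(bivariate)

    # --- manifest and export ------------------------------------------------
    manifest = {
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) and not isinstance(v, type)
                else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_candidates": len(candidates),
        "features_run": [s["feature"] for s in summaries],
    }
    out["manifest"] = manifest

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("associations", "summary", "accounting", "within_tissue",
                     "walks", "enrichment_p", "bivariate"):
            if name in out and isinstance(out[name], pd.DataFrame) and not out[name].empty:
                out[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        out["freq"].rename_axis("gene").to_csv(outdir / "mutation_frequency.tsv", sep="\t")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return out
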