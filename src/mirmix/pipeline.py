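"""End-to-end orchestration of the paired miRNA/mRNA analysis.

Runs preprocessing, miRNA-target anti-correlation, the joint ICA with
stability scoring, survival linkage (component-weight cutpoints,
differential abundance, miRNA-subset search) and gene-set enrichment, and
writes every intermediate table to a report directory. The single
configuration seed fans out to per-stage seeds (derived by hashing the
stage name together with the seed) so any stage can be rerun in isolation
and still reproduce.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import jointica, preprocess, survival, targets
from .containers import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{stage}:{base_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis, with field-standard defaults."""

    seed: int
    # preprocessing
    min_max: float = 10.0
    cv_max: float = 5.0
    pseudo: float = 0.01
    # anti-correlation
    q_max: float = 0.05
    rho_max: float = -0.3
    # joint ICA
    n_components: int | None = None  # None: random-matrix-theory estimate
    runs: int = 30
    alphas: tuple[float, ...] = (1.0, 3.0, 6.0)
    balanced: bool = True
    # survival
    outcome: str = "OS"
    min_group_frac: float = 0.1
    subset_universe: tuple[str, ...] = ()
    max_universe: int = 12
    # enrichment
    enrichment_q_max: float = 0.001


@dataclass
class PipelineResult:
    report_dir: Path
    model: jointica.JointICAModel | None = None
    pairs: pd.DataFrame | None = None
    cutoffs: pd.DataFrame | None = None
    differential: pd.DataFrame | None = None
    subsets: pd.DataFrame | None = None
    enrichment: dict[int, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    out_dir,
    config: PipelineConfig,
    clinical: ClinicalTable | None = None,
    utrs: dict[str, str] | None = None,
    mir_seqs: dict[str, str] | None = None,
    genesets: enr.GeneSetCollection | None = None,
) -> PipelineResult:
    """Execute the full analysis and write all tables under ``out_dir``.

    A missing clinical table skips the survival stages with a warning; a
    missing gene-set collection skips enrichment. Identical inputs, config
    and seed produce identical output files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(report_dir=out)
    summary: dict = {"seed": config.seed, "stages": []}

    # ---- preprocess -------------------------------------------------------
    if clinical is not None:
        mrna, mirna, clinical = preprocess.align_samples(mrna, mirna, clinical=clinical)
    else:
        mrna, mirna = preprocess.align_samples(mrna, mirna)
        logger.warning("no clinical table: survival stages will be skipped")
    mrna_f = preprocess.filter_cv_outliers(
        preprocess.filter_low_abundance(mrna, config.min_max), config.cv_max
    )
    mirna_f = preprocess.filter_cv_outliers(
        preprocess.filter_low_abundance(mirna, config.min_max), config.cv_max
    )
    mrna_log = preprocess.log2_with_pseudo(mrna_f, config.pseudo)
    mirna_log = preprocess.log2_with_pseudo(mirna_f, config.pseudo)
    preprocess.write_expression(mrna_log, out / "mrna_log2.tsv")
    preprocess.write_expression(mirna_log, out / "mirna_log2.tsv")
    summary["stages"].append("preprocess")
    summary["n_genes"] = mrna_f.n_features
    summary["n_mirs"] = mirna_f.n_features
    summary["n_samples"] = mrna_f.n_samples

    # ---- miRNA-target anti-correlation ------------------------------------
    pairs = targets.adjust_per_mirna(targets.spearman_pairs(mirna_f, mrna_f))
    seed_matches = None
    if utrs is not None and mir_seqs:
        seed_matches = []
        for mir_id, seq in mir_seqs.items():
            seed_matches.extend(targets.find_seed_matches(seq, utrs, mir_id=mir_id))
        pd.DataFrame(
            [(m.mir_id, m.utr_id, m.start) for m in seed_matches],
            columns=["mir_id", "utr_id", "start"],
        ).to_csv(out / "seed_matches.tsv", sep="\t", index=False)
    anti = targets.filter_pairs(pairs, q_max=config.q_max, rho_max=config.rho_max)
    pairs.to_csv(out / "pairs_all.tsv", sep="\t", index=False)
    anti.to_csv(out / "pairs_anticorrelated.tsv", sep="\t", index=False)
    if seed_matches is not None:
        supported = targets.filter_pairs(
            pairs, q_max=config.q_max, rho_max=config.rho_max, seed_matches=seed_matches
        )
        supported.to_csv(out / "pairs_seed_supported.tsv", sep="\t", index=False)
    summary["stages"].append("target_inference")
    summary["n_anticorrelated_pairs"] = int(len(anti))

    # ---- joint ICA ---------------------------------------------------------
    n_comp = config.n_components or jointica.choose_joint_dimension(mrna_log, mirna_log)
    n_comp = max(n_comp, 1)
    model = jointica.stability_analysis(
        mrna_log,
        mirna_log,
        n_comp,
        runs=config.runs,
        base_seed=derive_seed(config.seed, "ica"),
        balanced=config.balanced,
    )
    model.save(out / "model")
    result.model = model
    summary["stages"].append("joint_ica")
    summary["n_components"] = n_comp
    summary["stability"] = [float(s) for s in model.stability]

    sig_sets: dict[float, list[jointica.SignificantFeatureSet]] = {}
    for alpha in config.alphas:
        per_comp = [
            jointica.significant_features(model.C_m.iloc[:, i], alpha=alpha, component=i)
            for i in range(n_comp)
        ]
        sig_sets[alpha] = per_comp
        rows = [
            {"component": s.component, "feature_id": fid, "sign": int(sgn)}
            for s in per_comp
            for fid, sgn in s.features.items()
        ]
        pd.DataFrame(rows, columns=["component", "feature_id", "sign"]).to_csv(
            out / f"significant_genes_alpha{alpha:g}.tsv", sep="\t", index=False
        )

    # ---- survival ----------------------------------------------------------
    if clinical is not None:
        comp_weights = model.M_m.T  # samples x components
        comp_weights.columns = [f"IC{i+1}" for i in range(n_comp)]
        cutoffs = survival.cutoff_scan_table(
            comp_weights, clinical, outcome=config.outcome,
            min_group_frac=config.min_group_frac,
        )
        cutoffs.to_csv(out / "component_cutoffs.tsv", sep="\t", index=False)
        result.cutoffs = cutoffs

        best = cutoffs.dropna(subset=["p"]).sort_values("p").iloc[0]
        times, events, ids = clinical.outcome(config.outcome)
        grp = (comp_weights.loc[ids, best["variable"]] > best["cutoff"]).astype(int)
        diff = survival.differential_by_outcome(mirna_f.subset_samples(ids), grp.to_numpy())
        diff.to_csv(out / "differential_mirnas.tsv", sep="\t", index=False)
        result.differential = diff

        universe = list(config.subset_universe)
        if not universe:
            universe = list(diff.sort_values("q")["feature_id"].head(8))
        subsets = survival.subset_survival_search(
            mirna_f.subset_features(universe),
            clinical,
            outcome=config.outcome,
            seed=derive_seed(config.seed, "subsets"),
            max_universe=config.max_universe,
        )
        subsets.to_csv(out / "subset_ranking.tsv", sep="\t", index=False)
        result.subsets = subsets
        summary["stages"].append("survival_link")
        summary["best_component"] = str(best["variable"])
        summary["best_cutoff_p"] = float(best["p"])
    else:
        logger.warning("survival stages skipped: no clinical table")

    # ---- enrichment --------------------------------------------------------
    if genesets is not None:
        population = mrna_f.feature_ids
        alpha = 3.0 if 3.0 in config.alphas else config.alphas[0]
        for i in range(n_comp):
            sig = sig_sets[alpha][i].features.index.tolist()
            if not sig:
                continue
            table = enr.pathway_enrichment(sig, genesets, population)
            table.to_csv(out / f"enrichment_IC{i+1}.tsv", sep="\t", index=False)
            result.enrichment[i] = table
        summary["stages"].append("enrichment")

    result.pairs = pairs
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return result
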