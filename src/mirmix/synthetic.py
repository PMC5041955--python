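"""Synthetic paired miRNA/mRNA cohorts with known ground truth.

The generator emulates the statistical structure of a paired bulk-sequencing
tumor cohort: two expression views (mRNA genes, miRNA mature strands) that
share sample-level mixing of a small number of non-Gaussian latent
components; a prognostic component whose per-sample weight scales an
exponential proportional-hazards event rate under independent uniform
censoring; planted miRNA->target repression that makes targeted mRNAs load
opposite in sign to their targeting miRNAs on the shared component (and
hence anti-correlate across samples); 3'UTR sequences carrying planted 7mer
seed sites for the planted targets and none elsewhere; and a gene-set
collection containing the planted target set among random decoys.

Everything is a pure function of (config, seed): the same config yields a
byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix
from .enrichment import GeneSetCollection, write_gmt
from .preprocess import write_expression
from .targets import seed_site, write_utrs

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Stated world for the generator.

    Defaults describe a cohort of 100 samples with 2000 mRNA genes and 200
    miRNA strands driven by 3 shared non-Gaussian components, moderate
    measurement noise (sd 0.5 on the log2 scale), 10 planted miRNAs per
    repression component each repressing a share of 5% of the genes with
    unit loading magnitude, a unit log-hazard coefficient on the first
    component's mixing weight, and ~30% censoring.
    """

    G_m: int = 2000
    G_mi: int = 200
    S: int = 100
    I_true: int = 3
    source_dist: tuple[str, ...] = ("laplace", "uniform", "bimodal")
    noise_sd: float = 0.5
    n_planted_mirs: int = 10
    frac_targets: float = 0.05
    repression_strength: float = 1.0
    hazard_beta: float = 1.0
    baseline_hazard: float = 0.02  # events per month; mean survival 50 months
    censor_rate: float = 0.3
    utr_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I_true > min(self.G_mi, self.S):
            raise ValueError("I_true must not exceed min(G_mi, S)")
        if not 0 <= self.frac_targets <= 1 or not 0 <= self.censor_rate < 1:
            raise ValueError("fractions must lie in [0, 1]")
        if len(self.source_dist) < self.I_true:
            raise ValueError("need a source family per planted component")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    C_m: pd.DataFrame  # planted gene weights (G_m x I)
    C_mi: pd.DataFrame  # planted miRNA weights (G_mi x I)
    M: pd.DataFrame  # shared mixing (I x S)
    target_map: dict[str, list[str]]  # planted miR -> target genes
    mir_seqs: dict[str, str]  # planted miR 5'->3' RNA sequences
    prognostic_component: int
    planted_set: str  # name of the planted gene set in the collection


@dataclass
class SyntheticBundle:
    E_m: ExpressionMatrix
    E_mi: ExpressionMatrix
    clinical: ClinicalTable
    utrs: dict[str, str]
    genesets: GeneSetCollection
    truth: SyntheticTruth

    def save(self, directory) -> None:
        """Write the TSV/CSV/FASTA/GMT files the pipeline consumes."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_expression(self.E_m, d / "mrna.tsv")
        write_expression(self.E_mi, d / "mirna.tsv")
        self.clinical.data.reset_index(names="sample_id").to_csv(d / "clinical.csv", index=False)
        write_utrs(self.utrs, d / "utrs.fasta")
        write_gmt(self.genesets, d / "genesets.gmt")
        truth = {
            "target_map": self.truth.target_map,
            "mir_seqs": self.truth.mir_seqs,
            "prognostic_component": self.truth.prognostic_component,
            "planted_set": self.truth.planted_set,
        }
        (d / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def _draw_source(rng: np.random.Generator, family: str, size: int) -> np.ndarray:
    """Unit-variance, zero-mean draw from a non-Gaussian family."""
    if family == "laplace":
        return rng.laplace(0.0, 1.0 / np.sqrt(2.0), size)
    if family == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size)
    if family == "bimodal":
        signs = rng.choice((-1.0, 1.0), size)
        return (signs * 1.0 + rng.normal(0.0, 0.35, size)) / np.sqrt(1.0 + 0.35**2)
    raise ValueError(f"unknown source family {family!r}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_utr_sequences(
    target_map: dict[str, list[str]],
    mir_seqs: dict[str, str],
    gene_ids: list[str],
    length: int = 300,
    seed: int = 0,
) -> dict[str, str]:
    """Random UTRs with planted 7mer-m8 sites for targets and none elsewhere.

    Every gene in ``gene_ids`` gets a UTR. A target's UTR carries at least
    one seed site of each miRNA that maps to it; non-target UTRs are
    rejection-sampled until they contain no site of any provided miRNA.
    """
    if length < 7:
        raise ValueError("UTR length must be at least 7")
    rng = np.random.default_rng(seed)
    sites = {mir: seed_site(seq) for mir, seq in mir_seqs.items()}
    gene_to_mirs: dict[str, list[str]] = {}
    for mir, genes in target_map.items():
        for g in genes:
            gene_to_mirs.setdefault(g, []).append(mir)

    utrs: dict[str, str] = {}
    for gene in gene_ids:
        mirs_here = gene_to_mirs.get(gene, [])
        forbidden = [s for mir, s in sites.items() if mir not in mirs_here]
        for _ in range(1000):
            seq = _random_seq(rng, length)
            if any(s in seq for s in forbidden):
                continue
            ok = True
            for mir in mirs_here:
                site = sites[mir]
                if site not in seq:
                    pos = rng.integers(0, length - 7 + 1)
                    seq = seq[:pos] + site + seq[pos + 7 :]
            # planting one site may have created a forbidden one; re-check
            if any(s in seq for s in forbidden) or not all(
                sites[mir] in seq for mir in mirs_here
            ):
                ok = False
            if ok:
                utrs[gene] = seq
                break
        else:
            raise RuntimeError(f"could not sample a UTR for {gene}")
    return utrs


def generate_genesets(
    truth_targets: list[str],
    population: list[str],
    n_decoys: int = 200,
    set_size_range: tuple[int, int] = (20, 200),
    seed: int = 0,
    planted_name: str = "PLANTED_TARGETS",
) -> GeneSetCollection:
    """One planted set (the component-1 target genes) among random decoys."""
    rng = np.random.default_rng(seed)
    sets = {planted_name: sorted(truth_targets)}
    descriptions = {planted_name: "genes repressed by the planted prognostic miRNAs"}
    pop = np.asarray(population)
    lo, hi = set_size_range
    lo = min(lo, len(pop))
    hi = min(hi, len(pop))
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        name = f"DECOY_{i:04d}"
        sets[name] = sorted(rng.choice(pop, size=size, replace=False))
        descriptions[name] = "uniformly sampled decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def generate_joint_dataset(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a paired cohort with planted components, repression, survival.

    Construction, all on the log2 scale before exponentiation:

    1. Shared mixing M (I x S): i.i.d. standard normal rows, standardized
       to mean 0 / variance 1 per row.
    2. Gene weights C_m, C_mi: per component i, i.i.d. draws from the
       configured non-Gaussian family (unit variance).
    3. Planting on component 1: ``n_planted_mirs`` miRNAs get weight
       +repression_strength (plus a small positive jitter); each planted
       miRNA is mapped to a disjoint share of frac_targets * G_m target
       genes, which get weight -repression_strength (minus jitter).
    4. log2 expression = baseline + scale * (C @ M) + Gaussian noise;
       expression = 2 ** log2-value, giving positive RPKM/RPM-like values
       that the standard preprocessing (log2 with pseudo-count) inverts.
    5. Survival: T_s ~ Exponential(rate = baseline_hazard *
       exp(hazard_beta * M[0, s])), censored by an independent
       Uniform(0, c) with c solved from the target censoring fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"GENE{i:04d}" for i in range(cfg.G_m)]
    mir_ids = [f"miR-{100 + i}-{'3p' if i % 2 else '5p'}" for i in range(cfg.G_mi)]
    sample_ids = [f"S{i:03d}" for i in range(cfg.S)]

    M = rng.standard_normal((cfg.I_true, cfg.S))
    M = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, ddof=0, keepdims=True)

    C_m = np.column_stack(
        [_draw_source(rng, cfg.source_dist[i], cfg.G_m) for i in range(cfg.I_true)]
    )
    C_mi = np.column_stack(
        [_draw_source(rng, cfg.source_dist[i], cfg.G_mi) for i in range(cfg.I_true)]
    )

    # planted repression on component 0 (the prognostic component)
    planted_mirs = [mir_ids[i] for i in range(cfg.n_planted_mirs)]
    n_targets_total = min(int(round(cfg.frac_targets * cfg.G_m)), cfg.G_m)
    target_idx = rng.choice(cfg.G_m, size=n_targets_total, replace=False)
    per_mir = np.array_split(target_idx, cfg.n_planted_mirs)
    target_map: dict[str, list[str]] = {}
    for k, mir in enumerate(planted_mirs):
        C_mi[k, 0] = cfg.repression_strength * (1.0 + rng.uniform(0.0, 0.5))
        target_map[mir] = [gene_ids[j] for j in per_mir[k]]
        C_m[per_mir[k], 0] = -cfg.repression_strength * (
            1.0 + rng.uniform(0.0, 0.5, per_mir[k].size)
        )

    baseline_m = rng.uniform(4.0, 8.0, cfg.G_m)[:, None]
    baseline_mi = rng.uniform(4.0, 8.0, cfg.G_mi)[:, None]
    L_m = baseline_m + C_m @ M + rng.normal(0.0, cfg.noise_sd, (cfg.G_m, cfg.S))
    L_mi = baseline_mi + C_mi @ M + rng.normal(0.0, cfg.noise_sd, (cfg.G_mi, cfg.S))

    E_m = ExpressionMatrix(
        pd.DataFrame(2.0**L_m, index=gene_ids, columns=sample_ids), "RPKM", "mRNA-gene"
    )
    E_mi = ExpressionMatrix(
        pd.DataFrame(2.0**L_mi, index=mir_ids, columns=sample_ids), "RPM", "miRNA-strand"
    )

    # survival: exponential proportional hazards on component 0's weights
    rate = cfg.baseline_hazard * np.exp(cfg.hazard_beta * M[0])
    event_times = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        # for T ~ Exp(l0), C ~ U(0, c): P(C < T) = (1 - exp(-l0 c)) / (l0 c)
        from scipy.optimize import brentq

        x = brentq(lambda v: (1.0 - np.exp(-v)) / v - cfg.censor_rate, 1e-9, 1e4)
        c_max = x / cfg.baseline_hazard
        censor_times = rng.uniform(0.0, c_max, cfg.S)
    else:
        censor_times = np.full(cfg.S, np.inf)
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame(
            {"os_time": os_time, "os_event": os_event,
             "pfs_time": os_time * rng.uniform(0.5, 1.0, cfg.S), "pfs_event": os_event},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    mir_seqs = {
        mir: "".join(rng.choice(list("ACGU"), size=22)) for mir in planted_mirs
    }
    utr_genes = sorted({g for genes in target_map.values() for g in genes})
    # UTRs for targets plus a slice of non-targets keeps FASTA size modest
    non_targets = [g for g in gene_ids if g not in set(utr_genes)][: len(utr_genes)]
    utrs = generate_utr_sequences(
        target_map, mir_seqs, utr_genes + non_targets, length=cfg.utr_length,
        seed=int(rng.integers(2**31)),
    )
    genesets = generate_genesets(
        sorted({g for gs in target_map.values() for g in gs}),
        gene_ids,
        seed=int(rng.integers(2**31)),
    )
    truth = SyntheticTruth(
        C_m=pd.DataFrame(C_m, index=gene_ids, columns=range(cfg.I_true)),
        C_mi=pd.DataFrame(C_mi, index=mir_ids, columns=range(cfg.I_true)),
        M=pd.DataFrame(M, index=range(cfg.I_true), columns=sample_ids),
        target_map=target_map,
        mir_seqs=mir_seqs,
        prognostic_component=0,
        planted_set="PLANTED_TARGETS",
    )
    return SyntheticBundle(
        E_m=E_m, E_mi=E_mi, clinical=clinical, utrs=utrs, genesets=genesets, truth=truth
    )


def generate_threshold_survival(
    n: int = 200,
    threshold_quantile: float = 0.5,
    hazard_ratio: float = 2.0,
    baseline_hazard: float = 0.02,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cohort whose hazard jumps by ``hazard_ratio`` above a planted threshold.

    Returns (covariate values, times, events). The planted threshold sits at
    the given quantile of the standard-normal covariate; used to check that
    the optimal-cutpoint scan recovers a known change point.
    """
    rng = np.random.default_rng(seed)
    values = rng.standard_normal(n)
    thresh = np.quantile(values, threshold_quantile)
    rate = baseline_hazard * np.where(values > thresh, hazard_ratio, 1.0)
    event_times = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        from scipy.optimize import brentq

        x = brentq(lambda v: (1.0 - np.exp(-v)) / v - censor_rate, 1e-9, 1e4)
        censor_times = rng.uniform(0.0, x / baseline_hazard, n)
    else:
        censor_times = np.full(n, np.inf)
    times = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    return values, times, events
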