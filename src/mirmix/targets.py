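"""miRNA target inference: 7mer seed matching and expression anti-correlation.

A binding site is a 7mer seed match in a 3'UTR: the UTR carries the exact
reverse complement of miRNA nucleotides 2-8 (the 7mer-m8 convention; the
7mer-A1 variant, complement of nucleotides 2-7 followed by an A, is
available as an option). Candidate regulatory pairs are miRNA-mRNA pairs
whose abundances are significantly negatively rank-correlated across
samples, with Benjamini-Hochberg correction applied per miRNA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize(seq: str) -> str:
    """Uppercase and map RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return _normalize(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedMatch:
    """One 7mer seed-site occurrence in a UTR (1-based start)."""

    mir_id: str
    utr_id: str
    start: int
    match_length: int = 7


def seed_site(mir_sequence: str, kind: str = "7mer-m8") -> str:
    """The UTR site sequence (DNA, 5'->3') matched by a miRNA seed.

    ``7mer-m8``: reverse complement of miRNA nucleotides 2-8.
    ``7mer-A1``: reverse complement of nucleotides 2-7, followed by an A.
    """
    seq = _normalize(mir_sequence)
    if len(seq) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    if kind == "7mer-m8":
        seed = seq[1:8]
        if set(seed) - set("ACGT"):
            raise ValueError(f"ambiguous base in seed region: {seed}")
        return reverse_complement(seed)
    if kind == "7mer-A1":
        seed = seq[1:7]
        if set(seed) - set("ACGT"):
            raise ValueError(f"ambiguous base in seed region: {seed}")
        return reverse_complement(seed) + "A"
    raise ValueError(f"unknown seed kind {kind!r}")


def find_seed_matches(
    mir_sequence: str,
    utrs: dict[str, str],
    mir_id: str = "miR",
    kind: str = "7mer-m8",
) -> list[SeedMatch]:
    """Scan UTRs for every occurrence of a miRNA's 7mer seed site.

    Overlapping occurrences are all reported. Positions overlapping an
    ambiguous base (N) in the UTR never match and are skipped silently.
    """
    site = seed_site(mir_sequence, kind=kind)
    matches: list[SeedMatch] = []
    for utr_id, utr_seq in utrs.items():
        hay = _normalize(utr_seq)
        start = hay.find(site)
        while start != -1:
            matches.append(SeedMatch(mir_id=mir_id, utr_id=utr_id, start=start + 1))
            start = hay.find(site, start + 1)
    return matches


def load_utrs(path) -> dict[str, str]:
    """Read 3'UTRs from FASTA, record id = gene symbol.

    When a gene has several UTR records only the longest is kept; ties go
    to the record seen first.
    """
    utrs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if rec.id not in utrs or len(seq) > len(utrs[rec.id]):
            utrs[rec.id] = seq
    return utrs


def write_utrs(utrs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in utrs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Spearman anti-correlation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted null distribution of Spearman rho over all n! permutations.

    Valid only without ties; used for exact two-sided p-values at small n.
    """
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
    ranked = base[perms]
    d2 = ((ranked - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    return np.sort(rho)


def _exact_p(rho: float, n: int) -> float:
    null = _exact_rho_null(n)
    # two-sided: fraction of permutations at least as extreme in |rho|
    extreme = np.count_nonzero(np.abs(null) >= abs(rho) - 1e-12)
    return extreme / null.size


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho * math.sqrt(n - 2) / np.sqrt(1.0 - rho**2)
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def spearman_pairs(
    mirs: ExpressionMatrix, genes: ExpressionMatrix, exact_max_n: int = 10
) -> pd.DataFrame:
    """Spearman correlation of every miRNA against every mRNA feature.

    Samples are intersected and aligned; correlations are rank-based so the
    abundance scale (raw or log) is irrelevant. Constant vectors have no
    defined rank correlation and yield no pair. Two-sided p-values use the
    exact permutation distribution for tie-free vectors with
    n <= ``exact_max_n`` and the t approximation otherwise.

    Returns a DataFrame with columns mir_id, feature_id, rho, p, n.
    """
    shared = [s for s in mirs.sample_ids if s in set(genes.sample_ids)]
    n = len(shared)
    if n < 3:
        raise ValueError(f"need at least 3 shared samples, found {n}")
    x = mirs.subset_samples(shared).values
    y = genes.subset_samples(shared).values

    rx = np.apply_along_axis(stats.rankdata, 1, x)
    ry = np.apply_along_axis(stats.rankdata, 1, y)
    mir_const = np.ptp(x, axis=1) == 0
    gene_const = np.ptp(y, axis=1) == 0

    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((rx_c**2).sum(axis=1))
    sy = np.sqrt((ry_c**2).sum(axis=1))
    sx[sx == 0] = np.nan
    sy[sy == 0] = np.nan
    rho = (rx_c @ ry_c.T) / np.outer(sx, sy)

    mir_ids = np.asarray(mirs.feature_ids)
    gene_ids = np.asarray(genes.feature_ids)

    ii, jj = np.nonzero(np.outer(~mir_const, ~gene_const))
    flat_rho = rho[ii, jj]
    flat_p = _t_approx_p(flat_rho, n)
    if n <= exact_max_n:
        mir_has_ties = np.array([len(np.unique(row)) < n for row in x])
        gene_has_ties = np.array([len(np.unique(row)) < n for row in y])
        exact = ~(mir_has_ties[ii] | gene_has_ties[jj])
        for k in np.nonzero(exact)[0]:
            flat_p[k] = _exact_p(flat_rho[k], n)
    return pd.DataFrame(
        {
            "mir_id": mir_ids[ii],
            "feature_id": gene_ids[jj],
            "rho": flat_rho,
            "p": flat_p,
            "n": n,
        }
    )


def adjust_per_mirna(pairs: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg q-values, computed separately within each miRNA."""
    out = pairs.copy()
    out["q"] = np.nan
    for _, idx in out.groupby("mir_id").groups.items():
        p = out.loc[idx, "p"].to_numpy()
        out.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
    return out


def filter_pairs(
    pairs: pd.DataFrame,
    q_max: float = 0.05,
    rho_max: float = -0.3,
    seed_matches: list[SeedMatch] | None = None,
) -> pd.DataFrame:
    """Keep significantly anti-correlated pairs (q < q_max, rho < rho_max).

    If ``seed_matches`` is given, a pair is additionally required to have at
    least one seed site of its miRNA in the gene's UTR.
    """
    if "q" not in pairs.columns or pairs["q"].isna().any():
        raise ValueError("q-values must be filled before filtering; run adjust_per_mirna")
    keep = (pairs["q"] < q_max) & (pairs["rho"] < rho_max)
    if seed_matches is not None:
        with_site = {(m.mir_id, m.utr_id) for m in seed_matches}
        keep &= np.array(
            [
                (mir, gene) in with_site
                for mir, gene in zip(pairs["mir_id"], pairs["feature_id"])
            ]
        )
    return pairs.loc[keep].reset_index(drop=True)
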