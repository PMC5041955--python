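"""Hypergeometric gene-list overlap and gene-set overrepresentation.

The central statistic is the exact upper-tail hypergeometric probability
P(X >= x) that two gene lists of sizes d and n drawn from a population of
n_pop genes share at least x members. It is evaluated in log space, so
probabilities remain exact down to ~1e-300. The same tail is used for
gene-set overrepresentation among significant component genes, with
Benjamini-Hochberg correction across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def overlap_pvalue(n_pop: int, d: int, n: int, x: int) -> float:
    """Exact P(X >= x) for the overlap of two lists of sizes d and n.

    X is hypergeometric: the overlap of a fixed list of d genes with a
    uniformly random list of n genes from a population of n_pop. Computed
    by log-space summation of the point masses

        P(X = k) = C(d, k) C(n_pop - d, n - k) / C(n_pop, n)

    over k = x .. min(d, n), so extremely small tails do not underflow.
    """
    for name, v in (("n_pop", n_pop), ("d", d), ("n", n), ("x", x)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    n_pop, d, n, x = int(n_pop), int(d), int(n), int(x)
    if d > n_pop or n > n_pop:
        raise ValueError("list sizes cannot exceed the population size")
    if x > min(d, n):
        raise ValueError(f"overlap x={x} exceeds min(d, n)={min(d, n)}")
    k = np.arange(x, min(d, n) + 1)
    # impossible terms (n - k > n_pop - d) have log-binom = -inf naturally,
    # but guard explicitly to avoid gammaln of negative arguments
    k = k[(n - k) <= (n_pop - d)]
    if k.size == 0:
        return 0.0
    log_terms = (
        _log_binom(d, k) + _log_binom(n_pop - d, n - k) - _log_binom(n_pop, n)
    )
    logp = logsumexp(log_terms)
    return float(min(1.0, np.exp(logp)))


@dataclass
class EnrichmentResult:
    set_name: str
    set_size: int  # annotated genes in the population (G_p)
    overlap: int  # significant genes annotated (K)
    p: float
    q: float | None = None


def pathway_enrichment(
    significant, collection: GeneSetCollection, population
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each set among significant genes.

    Sets are intersected with the population before testing; the reported
    ``set_size`` is that intersection. P is the exact upper tail
    P(X >= overlap); q is BH across all tested sets. Gene ids are matched
    exactly after uppercasing.
    """
    population = {str(g).upper() for g in population}
    if not population:
        raise ValueError("empty population")
    significant = {str(g).upper() for g in significant}
    if not significant <= population:
        raise ValueError("significant genes must be a subset of the population")
    n_pop = len(population)
    n_sig = len(significant)
    rows = []
    for name, members in collection:
        in_pop = {str(g).upper() for g in members} & population
        if not in_pop:
            continue
        overlap = len(in_pop & significant)
        p = overlap_pvalue(n_pop, n_sig, len(in_pop), overlap)
        rows.append((name, len(in_pop), overlap, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> member1 <TAB> ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            seen: list[str] = []
            for g in members:
                if g and g not in seen:
                    seen.append(g)
            sets[name] = seen
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")
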