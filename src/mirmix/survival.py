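"""Linking expression features to right-censored clinical outcomes.

Provides the Kaplan-Meier product-limit estimator and two-group log-rank
test (via lifelines), exhaustive optimal-cutpoint scanning of a continuous
variable (the maximally selected log-rank strategy), Kruskal-Wallis differential
abundance with FDR correction, and an exhaustive search over subsets of a
small miRNA universe for subsets whose k-means two-group split of patients
separates survival.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CutoffResult:
    """Best high-vs-low split of a continuous variable by log-rank p.

    ``p`` is the log-rank p at the selected cutoff; because the cutoff was
    chosen to minimize it, it is anti-conservative by construction.
    ``p_adj`` corrects it for the threshold search (maximally selected
    statistic approximation) and is what cross-variable FDR adjustment
    (``q``) is computed from.
    """

    cutoff: float | None
    p: float | None
    n_low: int
    n_high: int
    p_adj: float | None = None
    q: float | None = None

    @property
    def found(self) -> bool:
        return self.cutoff is not None


@dataclass
class SubsetResult:
    members: tuple[str, ...]
    p: float
    n_small: int
    q: float | None = None


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a DataFrame with columns ``time``, ``survival`` and ``at_risk``
    describing the right-continuous step function (S(0) = 1, non-increasing).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def survival_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate a KM table (from :func:`km_estimate`) at time t."""
    idx = np.searchsorted(km["time"].to_numpy(), t, side="right") - 1
    return float(km["survival"].iloc[idx]) if idx >= 0 else 1.0


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank chi-square test (df = 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {labels.size}")
    a = groups == labels[0]
    res = _ll_logrank(times[a], times[~a], event_observed_A=events[a], event_observed_B=events[~a])
    return LogRankResult(statistic=float(res.test_statistic), df=1, p=float(res.p_value))


def _logrank_p_fast(order_times, order_events, mask_sorted) -> float:
    """Log-rank p for one split, on inputs pre-sorted by time ascending.

    Plain O-E/V hypergeometric-variance form; used by the cutpoint scan
    where thousands of splits of the same cohort are evaluated. Agrees
    with :func:`logrank_test` (checked by the test suite).
    """
    t = order_times
    uniq, start = np.unique(t, return_index=True)
    n = t.size
    # at-risk counts just before each distinct time
    at_risk = n - start
    in1 = mask_sorted.astype(float)
    cum1 = np.concatenate(([0.0], np.cumsum(in1)))
    at_risk1 = in1.sum() - cum1[start]
    ev = order_events.astype(float)
    ev1 = ev * in1
    d = np.add.reduceat(ev, start) if start.size else np.array([])
    d1 = np.add.reduceat(ev1, start) if start.size else np.array([])
    # reduceat quirk: a trailing singleton segment is fine; guard empty
    valid = (d > 0) & (at_risk > 1)
    if not valid.any():
        return 1.0
    nj = at_risk[valid]
    n1j = at_risk1[valid]
    dj = d[valid]
    d1j = d1[valid]
    O = d1j.sum()
    E = (dj * n1j / nj).sum()
    V = (dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)).sum()
    if V <= 0:
        return 1.0
    stat = (O - E) ** 2 / V
    return float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# optimal cutpoint scan
# ---------------------------------------------------------------------------


def _maxsel_p(p_min: float, eps_low: float, eps_high: float) -> float:
    """Correct the minimal scanned p for the threshold search.

    Lausen-Schumacher improved approximation for the null distribution of a
    maximally selected rank statistic over the quantile range
    (eps_low, eps_high): with b the standardized statistic at the best
    split,

        P(max |Z| > b) ~ phi(b) (b - 1/b) log[eps_high(1-eps_low) /
                          ((1-eps_high) eps_low)] + 4 phi(b)/b.

    Without this, BH across many scanned variables operates on heavily
    non-uniform minimum p-values and does not control the FDR.
    """
    b = stats.norm.isf(p_min / 2.0)
    if not np.isfinite(b) or b <= 1e-8:
        return 1.0
    phi = stats.norm.pdf(b)
    k = np.log((eps_high * (1.0 - eps_low)) / ((1.0 - eps_high) * eps_low))
    return float(min(1.0, phi * (b - 1.0 / b) * k + 4.0 * phi / b))


def optimal_cutoff(
    values, times, events, min_group_frac: float = 0.1
) -> CutoffResult:
    """Scan every admissible threshold on ``values`` for the best log-rank split.

    Candidate cutoffs are midpoints between consecutive sorted unique
    values; a candidate is admissible when both resulting groups hold at
    least ``min_group_frac`` of the samples. The cutoff minimizing the
    log-rank p is returned; ties in p are broken toward the more balanced
    split. A constant variable (or no admissible candidate) yields an
    explicit no-cutoff result rather than an exception.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = values.size
    if n < 10:
        raise ValueError("optimal cutoff scan needs at least 10 samples with outcomes")
    uniq = np.unique(values)
    if uniq.size < 2:
        return CutoffResult(cutoff=None, p=None, n_low=n, n_high=0)
    min_n = max(1, int(np.ceil(min_group_frac * n)))
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    v_sorted = values[order]
    best: CutoffResult | None = None
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = 0.5 * (lo + hi)
        low = v_sorted <= cut
        n_low = int(low.sum())
        n_high = n - n_low
        if n_low < min_n or n_high < min_n:
            continue
        p = _logrank_p_fast(t_sorted, e_sorted, low)
        cand = CutoffResult(cutoff=float(cut), p=p, n_low=n_low, n_high=n_high)
        if (
            best is None
            or p < best.p
            or (p == best.p and abs(n_low - n_high) < abs(best.n_low - best.n_high))
        ):
            best = cand
    if best is None:
        return CutoffResult(cutoff=None, p=None, n_low=n, n_high=0)
    best.p_adj = _maxsel_p(best.p, min_group_frac, 1.0 - min_group_frac)
    return best


def cutoff_scan_table(
    variables: pd.DataFrame, clinical: ClinicalTable, outcome: str = "OS",
    min_group_frac: float = 0.1,
) -> pd.DataFrame:
    """Optimal cutoff per variable (columns = variables, rows = samples),
    with BH correction of the per-variable minimal p across all variables."""
    times, events, ids = clinical.outcome(outcome)
    rows = []
    for name in variables.columns:
        vals = variables.loc[ids, name].to_numpy(dtype=float)
        res = optimal_cutoff(vals, times, events, min_group_frac=min_group_frac)
        rows.append((name, res.cutoff, res.p, res.p_adj, res.n_low, res.n_high))
    out = pd.DataFrame(
        rows, columns=["variable", "cutoff", "p", "p_adj", "n_low", "n_high"]
    )
    ok = out["p_adj"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p_adj"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------


def differential_by_outcome(m: ExpressionMatrix, groups) -> pd.DataFrame:
    """Kruskal-Wallis test per feature across outcome groups, BH over features."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    masks = [groups == g for g in labels]
    small = [g for g, msk in zip(labels, masks) if msk.sum() < 2]
    if small:
        logger.warning("groups with < 2 samples: %s; affected features get p = 1", small)
    X = m.values
    pvals = np.ones(X.shape[0])
    if not small:
        for i in range(X.shape[0]):
            samples = [X[i, msk] for msk in masks]
            if all(np.ptp(s) == 0 for s in samples) and np.ptp(X[i]) == 0:
                pvals[i] = 1.0
                continue
            try:
                pvals[i] = stats.kruskal(*samples).pvalue
            except ValueError:  # all values identical
                pvals[i] = 1.0
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"feature_id": m.feature_ids, "p": pvals, "q": qvals})


# ---------------------------------------------------------------------------
# exhaustive miRNA-subset survival search
# ---------------------------------------------------------------------------


def double_normalize(data: pd.DataFrame) -> pd.DataFrame:
    """Normalize abundance between samples, then between miRNAs.

    Rows are miRNA strands, columns samples. First each sample column is
    divided by its total over the universe (between-sample normalization),
    then each miRNA row is linearly rescaled to [0, 1] across samples so
    the abundance range of any one strand cannot dominate the clustering.
    Constant rows map to 0.
    """
    totals = data.sum(axis=0)
    totals[totals == 0] = 1.0
    norm = data / totals
    lo = norm.min(axis=1)
    span = norm.max(axis=1) - lo
    span[span == 0] = 1.0
    return norm.sub(lo, axis=0).div(span, axis=0)


def _kmeans_two_groups(X: np.ndarray, seed: int) -> np.ndarray:
    """k=2 clustering of samples; label 1 = higher mean abundance cluster."""
    km = KMeans(n_clusters=2, n_init=25, random_state=seed)
    labels = km.fit_predict(X)
    means = [X[labels == k].mean() for k in (0, 1)]
    if means[0] > means[1]:
        labels = 1 - labels
    return labels


def subset_survival_search(
    mirs: ExpressionMatrix,
    clinical: ClinicalTable,
    outcome: str = "OS",
    seed: int = 0,
    max_universe: int = 12,
) -> pd.DataFrame:
    """Exhaustively test miRNA subsets for survival-discriminating structure.

    For every non-empty subset of the strand universe the double-normalized
    abundances are clustered into two patient groups with seeded k-means,
    and the groups are compared by log-rank. P-values are BH-corrected
    across all subsets, and results ranked by q then by size of the smaller
    group (descending), favoring well-populated splits.
    """
    universe = mirs.feature_ids
    if len(universe) > max_universe:
        raise ValueError(
            f"universe of {len(universe)} strands exceeds the cap of {max_universe} "
            f"({2**len(universe) - 1} subsets); raise max_universe explicitly to proceed"
        )
    times, events, ids = clinical.outcome(outcome)
    data = mirs.data.loc[:, ids]
    normed = double_normalize(data)

    results: list[SubsetResult] = []
    for r in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, r):
            X = normed.loc[list(combo)].to_numpy().T  # samples x strands
            labels = _kmeans_two_groups(X, seed)
            n_small = int(min(labels.sum(), len(labels) - labels.sum()))
            if n_small == 0:
                continue
            p = logrank_test(times, events, labels).p
            results.append(SubsetResult(members=combo, p=p, n_small=n_small))

    df = pd.DataFrame(
        {
            "members": [",".join(r.members) for r in results],
            "size": [len(r.members) for r in results],
            "p": [r.p for r in results],
            "n_small": [r.n_small for r in results],
        }
    )
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["q", "n_small"], ascending=[True, False]).reset_index(drop=True)
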