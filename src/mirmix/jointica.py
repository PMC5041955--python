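"""Joint independent component analysis of paired expression views.

The model decomposes an expression matrix E (G features x S samples) as
E = C M, where the columns of C (G x I) are independent components — gene
weight vectors scaled to mean 0 / variance 1 — and M (I x S) holds the
per-sample component weights. For two views sharing the same samples
(mRNA genes and miRNA strands), a single orthonormal un-mixing matrix W is
estimated so that

    C_m  = centered(E_m)  K_m  W
    C_mi = centered(E_mi) K_mi W

are simultaneously maximally non-Gaussian. K_m and K_mi are per-view PCA
whitening projections onto the first I principal components. Estimation
row-stacks the two whitened views (after balancing their relative weight;
see :func:`fit_joint_ica`) and runs the fixed-point log-cosh fastICA
iteration with symmetric decorrelation on the stacked matrix. The number
of components I is picked by a random-matrix-theory bound, stability of
each component is scored over random restarts, and per-component
significant genes are thresholded on the spread of absolute weights.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dimension estimation
# ---------------------------------------------------------------------------


def estimate_num_components(m: ExpressionMatrix) -> int:
    """Estimate the latent dimension via the Marchenko-Pastur bound.

    Features are standardized to mean 0 / variance 1 across samples; the
    eigenvalues of the resulting S x S correlation-like matrix Z'Z / G are
    compared against the null upper edge lambda+ = (1 + sqrt(S/G))^2 for
    i.i.d. noise. The count of eigenvalues above the edge, capped at S-1,
    is returned. Constant features carry no information and are dropped
    first; an entirely degenerate matrix gives 0.
    """
    X = m.values
    G, S = X.shape
    if S < 2:
        raise ValueError("need at least 2 samples to estimate dimension")
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.any():
        return 0
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    G = Z.shape[0]
    # eigenvalues of the smaller-side Gram matrix; MP ratio = smaller/larger
    if G >= S:
        gram = Z.T @ Z / G
        ratio = S / G
    else:
        gram = Z @ Z.T / S
        ratio = G / S
    evals = np.linalg.eigvalsh(gram)
    lambda_plus = (1.0 + np.sqrt(ratio)) ** 2
    count = int(np.count_nonzero(evals > lambda_plus))
    return min(count, S - 1)


def choose_joint_dimension(m: ExpressionMatrix, mi: ExpressionMatrix) -> int:
    """Number of joint components: max of the per-view estimates."""
    return max(estimate_num_components(m), estimate_num_components(mi))


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------


def _double_center(E: np.ndarray) -> np.ndarray:
    """Remove per-feature means (across samples) and per-sample means.

    Per-feature baselines are constant across samples; left in place they
    form a dominant rank-one direction that would consume one component
    without carrying sample-level structure.
    """
    Ec = E - E.mean(axis=1, keepdims=True)
    return Ec - Ec.mean(axis=0, keepdims=True)


def whiten_view(m: ExpressionMatrix, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Project a view onto its first I principal components and whiten.

    Returns (X, K) with X = centered(E) @ K of shape G x I, whose columns
    are zero-mean with identity covariance over features
    (X'X / (G-1) = I). Centering removes per-feature baselines and then
    per-sample offsets. The sign of each column is fixed so that its
    largest-magnitude entry is positive.
    """
    E = m.values
    G, S = E.shape
    if n_components > min(G, S):
        raise ValueError(f"cannot extract {n_components} components from a {G}x{S} matrix")
    Ec = _double_center(E)
    # SVD of the centered matrix: Ec = U diag(s) Vt, columns of V are PCs
    U, s, Vt = np.linalg.svd(Ec, full_matrices=False)
    if np.any(s[:n_components] <= 1e-12 * s[0]):
        raise ValueError("matrix rank below requested number of components")
    # K maps samples -> whitened coords: X = Ec K with X'X/(G-1) = I
    K = Vt[:n_components].T / s[:n_components] * np.sqrt(G - 1)
    X = Ec @ K
    # deterministic sign: largest-|entry| coordinate positive
    for j in range(n_components):
        idx = np.argmax(np.abs(X[:, j]))
        if X[idx, j] < 0:
            X[:, j] *= -1
            K[:, j] *= -1
    return X, K


# ---------------------------------------------------------------------------
# fastICA core
# ---------------------------------------------------------------------------


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W')^{-1/2} W (symmetric decorrelation)."""
    evals, evecs = np.linalg.eigh(W @ W.T)
    return evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T @ W


def _fastica_parallel(
    X: np.ndarray,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Fixed-point fastICA (log-cosh contrast, a=1) on whitened data X (N x I).

    ``weights`` are optional per-row weights entering every expectation of
    the contrast (the joint two-view fit uses them to give each view equal
    total weight); X must be white under the same weighting. Returns
    (W, converged, n_iter) with W orthonormal I x I so that the columns of
    X @ W are maximally non-Gaussian.
    """
    N, I = X.shape
    if weights is None:
        w = None
        total = float(N)
    else:
        w = np.asarray(weights, dtype=float)[:, None]
        total = float(w.sum())
    W = _sym_decorrelate(rng.standard_normal((I, I)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S = X @ W.T  # N x I current source estimates
        gS = np.tanh(S)
        if w is None:
            g_prime = (1.0 - gS**2).mean(axis=0)  # E[g'(w'x)] per component
            W_new = gS.T @ X / N - g_prime[:, None] * W
        else:
            g_prime = (w * (1.0 - gS**2)).sum(axis=0) / total
            W_new = (w * gS).T @ X / total - g_prime[:, None] * W
        W_new = _sym_decorrelate(W_new)
        # convergence: every direction's dot-product with its update ~ +-1
        lim = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if lim < tol:
            converged = True
            break
    return W, converged, it


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------


@dataclass
class JointICAModel:
    """Fitted joint decomposition of two expression views."""

    n_components: int
    W: np.ndarray  # I x I orthonormal un-mixing matrix
    K_m: np.ndarray  # S x I whitening projection, mRNA view
    K_mi: np.ndarray  # S x I whitening projection, miRNA view
    C_m: pd.DataFrame  # G_m x I gene weights
    C_mi: pd.DataFrame  # G_mi x I miRNA weights
    M_m: pd.DataFrame  # I x S mixing (component weights), mRNA view
    M_mi: pd.DataFrame  # I x S mixing, miRNA view
    balance: tuple[float, float]  # per-view stacking weights used in the fit
    seed: int = 0
    runs: int = 1
    converged: bool = True
    stability: np.ndarray | None = None

    @property
    def C_stacked(self) -> np.ndarray:
        return np.vstack([self.C_m.to_numpy(), self.C_mi.to_numpy()])

    def significant_features(self, component: int, alpha: float = 3.0, view: str = "m"):
        C = self.C_m if view == "m" else self.C_mi
        return significant_features(C.iloc[:, component], alpha=alpha)

    def save(self, directory) -> None:
        """Serialize as a directory of TSV matrices plus JSON metadata."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.C_m.to_csv(d / "C_m.tsv", sep="\t")
        self.C_mi.to_csv(d / "C_mi.tsv", sep="\t")
        self.M_m.to_csv(d / "M_m.tsv", sep="\t")
        self.M_mi.to_csv(d / "M_mi.tsv", sep="\t")
        pd.DataFrame(self.W).to_csv(d / "W.tsv", sep="\t")
        meta = {
            "n_components": self.n_components,
            "seed": self.seed,
            "runs": self.runs,
            "converged": self.converged,
            "balance": list(self.balance),
            "stability": None if self.stability is None else [float(v) for v in self.stability],
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2) + "\n")


@dataclass
class SignificantFeatureSet:
    """Features whose |weight| clears alpha x SD of absolute weights."""

    component: int
    alpha: float
    features: pd.Series = field(default_factory=pd.Series)  # id -> sign (+1/-1)

    @property
    def positive(self) -> list[str]:
        return list(self.features.index[self.features > 0])

    @property
    def negative(self) -> list[str]:
        return list(self.features.index[self.features < 0])


def significant_features(
    weights: pd.Series, alpha: float = 3.0, component: int = 0
) -> SignificantFeatureSet:
    """Select features with |weight| >= alpha * SD(|weights|) in one component."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    absw = weights.abs()
    sd = float(absw.to_numpy().std(ddof=1)) if len(weights) > 1 else 0.0
    if sd == 0:
        logger.warning("degenerate component: all |weights| equal; selecting every feature")
        mask = pd.Series(True, index=weights.index)
    else:
        mask = absw >= alpha * sd
    signs = np.sign(weights[mask]).astype(int)
    return SignificantFeatureSet(component=component, alpha=alpha, features=signs)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _orient_positive_skew(C: np.ndarray, W: np.ndarray) -> None:
    """Flip component signs in place so each gene-weight column skews positive.

    Zero skew falls back to making the largest-|weight| entry positive.
    """
    for j in range(C.shape[1]):
        sk = stats.skew(C[:, j])
        if sk < 0 or (sk == 0 and C[np.argmax(np.abs(C[:, j])), j] < 0):
            C[:, j] *= -1
            W[:, j] *= -1


def fit_joint_ica(
    m: ExpressionMatrix,
    mi: ExpressionMatrix,
    n_components: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    balanced: bool = True,
) -> JointICAModel:
    """Fit the shared-un-mixing-matrix decomposition of two views.

    Both views are centered, rescaled to unit per-entry variance (so the
    two views' entries live on a common scale and neither view's rows look
    like artificial heavy tails to the contrast) and row-stacked. The
    stack is whitened with a single sample-space projection K shared by
    both views: a per-view whitening would hand each view its own
    arbitrary rotation of the shared latent coordinates, and no single
    un-mixing matrix could then separate both views at once. With
    ``balanced=True`` (default) every expectation in the whitening and in
    the log-cosh contrast weights rows so that each view carries equal
    total weight regardless of its feature count; with ``balanced=False``
    every feature row counts equally, so the larger view dominates. The
    fixed-point iteration with symmetric decorrelation estimates one
    orthonormal W for the stack, so that C_v = centered(E_v) K_v W (up to
    the final per-column standardization), K_v being the shared projection
    carrying view v's scale factor.

    Columns of the stacked component matrix have mean 0 and variance 1 by
    construction. Non-convergence returns a model flagged
    ``converged=False`` with a warning rather than raising.
    """
    if m.sample_ids != mi.sample_ids:
        raise ValueError("views must share identical, aligned sample ids")
    Ec_m = _double_center(m.values)
    Ec_mi = _double_center(mi.values)
    G_m, G_mi = Ec_m.shape[0], Ec_mi.shape[0]
    N = G_m + G_mi
    if n_components > min(N, Ec_m.shape[1]):
        raise ValueError("more components requested than the stack can support")
    s_m = 1.0 / max(Ec_m.std(), 1e-300)
    s_mi = 1.0 / max(Ec_mi.std(), 1e-300)
    Y = np.vstack([s_m * Ec_m, s_mi * Ec_mi])
    if balanced:
        row_w = np.concatenate(
            [np.full(G_m, N / (2.0 * G_m)), np.full(G_mi, N / (2.0 * G_mi))]
        )
    else:
        row_w = np.ones(N)
    # whitening under the row weighting: X'diag(w)X / sum(w) = I
    sqw = np.sqrt(row_w)[:, None]
    _, sv, Vt = np.linalg.svd(sqw * Y, full_matrices=False)
    if np.any(sv[:n_components] <= 1e-12 * sv[0]):
        raise ValueError("stacked matrix rank below requested number of components")
    K = Vt[:n_components].T / sv[:n_components] * np.sqrt(row_w.sum())
    X = Y @ K
    K_m = s_m * K
    K_mi = s_mi * K

    rng = np.random.default_rng(seed)
    W, converged, n_iter = _fastica_parallel(
        X, rng, tol=tol, max_iter=max_iter, weights=row_w if balanced else None
    )
    if not converged:
        warnings.warn(
            f"fastICA did not converge within {max_iter} iterations", RuntimeWarning
        )
    W = W.T  # store as right-multiplier: C = X W

    C = X @ W
    # exact standardization of the stacked columns (mean 0 by construction)
    C /= C.std(axis=0, ddof=1, keepdims=True)
    _orient_positive_skew(C, W)

    C_m = pd.DataFrame(C[:G_m], index=m.data.index, columns=range(n_components))
    C_mi = pd.DataFrame(C[G_m:], index=mi.data.index, columns=range(n_components))
    model = JointICAModel(
        n_components=n_components,
        W=W,
        K_m=K_m,
        K_mi=K_mi,
        C_m=C_m,
        C_mi=C_mi,
        M_m=pd.DataFrame(),
        M_mi=pd.DataFrame(),
        balance=(s_m, s_mi),
        seed=seed,
        converged=converged,
    )
    model.M_m, model.M_mi = compute_mixing(model, m, mi)
    return model


def compute_mixing(
    model: JointICAModel, m: ExpressionMatrix, mi: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Solve for the mixing matrices given the fitted un-mixing matrix.

    M_v is the least-squares solution of C_v M_v ~ centered(E_v), i.e.
    the pseudo-inverse of the composite projection (including the view
    balance factor and the column standardization absorbed into C), so
    that C_v @ M_v reproduces the rank-I principal-component approximation
    of the centered view.
    """
    out = []
    for E_mat, C in ((m, model.C_m), (mi, model.C_mi)):
        Ec = _double_center(E_mat.values)
        Cv = C.to_numpy()
        # C has orthogonal columns (orthonormal W on white data), so the
        # least-squares solve is well conditioned.
        M, *_ = np.linalg.lstsq(Cv, Ec, rcond=None)
        out.append(pd.DataFrame(M, index=range(model.n_components), columns=E_mat.sample_ids))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# stability across restarts
# ---------------------------------------------------------------------------


def _rank_standardize(A: np.ndarray) -> np.ndarray:
    """Column-wise rank transform, centered and L2-normalized."""
    R = np.apply_along_axis(stats.rankdata, 0, A)
    R -= R.mean(axis=0, keepdims=True)
    R /= np.linalg.norm(R, axis=0, keepdims=True)
    return R


def abs_spearman_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Spearman rho| between every column of A and every column of B."""
    return np.abs(_rank_standardize(A).T @ _rank_standardize(B))


def stability_analysis(
    m: ExpressionMatrix,
    mi: ExpressionMatrix,
    n_components: int,
    runs: int = 30,
    base_seed: int = 0,
    **fit_kwargs,
) -> JointICAModel:
    """Score component stability over random restarts and reorder by it.

    The decomposition is refit ``runs`` times from different random
    initializations. For each component of the reference (first) run, the
    highest |Spearman| correlation against every other run's components is
    recorded, and the per-component mean of those maxima is its stability
    in [0, 1]. The reference model is returned with components sorted by
    descending stability (C columns, M rows and W columns permuted
    together).
    """
    if runs < 2:
        raise ValueError("stability requires at least 2 runs")
    seeds = [int(s) for s in np.random.SeedSequence(base_seed).generate_state(runs) % (2**31)]
    models = [
        fit_joint_ica(m, mi, n_components, seed=s, **fit_kwargs) for s in seeds
    ]
    ref = models[0]
    ref_ranked = _rank_standardize(ref.C_stacked)
    scores = np.zeros(n_components)
    for other in models[1:]:
        corr = np.abs(ref_ranked.T @ _rank_standardize(other.C_stacked))
        scores += corr.max(axis=1)
    scores /= runs - 1

    order = np.argsort(-scores)
    ref.stability = scores[order]
    ref.W = ref.W[:, order]
    ref.C_m = ref.C_m.iloc[:, order].set_axis(range(n_components), axis=1)
    ref.C_mi = ref.C_mi.iloc[:, order].set_axis(range(n_components), axis=1)
    ref.M_m = ref.M_m.iloc[order].set_axis(range(n_components), axis=0)
    ref.M_mi = ref.M_mi.iloc[order].set_axis(range(n_components), axis=0)
    ref.runs = runs
    return ref
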