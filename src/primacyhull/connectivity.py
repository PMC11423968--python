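"""Cross-animal structure in glomerulus -> Kenyon-cell connectivity.

Quantifies the low-dimensional, individually-conserved component of binary
bipartite connectivity (KC rows x glomerulus columns): glomerulus-glomerulus
Pearson similarity, correlation of similarity matrices across animals with a
Mantel-style permutation test, degree-preserving (checkerboard-swap)
randomization as the null model, PCA and Isomap embeddings with per-dimension
variance significance, and Procrustes-aligned embedding RMSD.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import scipy.sparse as sp
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, ttest_ind
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

logger = logging.getLogger(__name__)

try:  # jitted swap chain; pure-python fallback keeps behaviour identical
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ConnectivityMatrix:
    """Binary KC x glomerulus matrix, optionally backed by synapse counts."""

    binary: np.ndarray
    kc_labels: list[str]
    glom_labels: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=bool)
        if self.binary.ndim != 2:
            raise ValueError("binary must be 2D")
        nk, ng = self.binary.shape
        self.kc_labels = list(self.kc_labels)
        self.glom_labels = list(self.glom_labels)
        if len(self.kc_labels) != nk or len(self.glom_labels) != ng:
            raise ValueError("label lengths inconsistent with matrix shape")
        if len(set(self.glom_labels)) != ng:
            raise ValueError("duplicate glomerulus labels")
        if self.weights is not None:
            self.weights = np.asarray(self.weights)
            if self.weights.shape != self.binary.shape:
                raise ValueError("weights shape mismatch")

    @property
    def n_kc(self) -> int:
        return self.binary.shape[0]

    @property
    def n_glom(self) -> int:
        return self.binary.shape[1]


@dataclasses.dataclass
class GlomSimilarity:
    """Symmetric Pearson-correlation matrix between glomerulus channels."""

    values: np.ndarray
    glom_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if len(self.glom_labels) != n:
            raise ValueError("label length mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    def restrict(self, labels: list[str]) -> "GlomSimilarity":
        idx = [self.glom_labels.index(l) for l in labels]
        return GlomSimilarity(self.values[np.ix_(idx, idx)], list(labels))


@dataclasses.dataclass
class EmbeddingResult:
    """Low-dimensional coordinates of glomeruli plus variance accounting."""

    coords: np.ndarray
    variance_explained: np.ndarray
    labels: list[str]
    method: str
    meta: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class ShuffleEnsemble:
    """Summary statistics of a degree-preserving-shuffle null ensemble."""

    method: str
    n_shuffles: int
    seed: int | None
    variance_explained: np.ndarray  # n_shuffles x d_max


# ---------------------------------------------------------------------------
# preprocessing and similarity
# ---------------------------------------------------------------------------


def binarize(
    weights: np.ndarray,
    kc_labels: list[str],
    glom_labels: list[str],
    threshold: int = 1,
) -> ConnectivityMatrix:
    """Threshold synapse counts into binary connectivity.

    Empty KC rows and glomerulus columns (after thresholding) are dropped
    with a logged warning.
    """
    weights = np.asarray(weights)
    if np.any(weights < 0):
        raise ValueError("synapse counts must be nonnegative")
    if threshold < 1:
        raise ValueError("threshold must be a positive integer")
    binary = weights >= threshold
    if not binary.any():
        raise ValueError("empty matrix: threshold exceeds all weights")
    keep_kc = binary.any(axis=1)
    keep_gl = binary.any(axis=0)
    if not keep_kc.all():
        dropped = [l for l, k in zip(kc_labels, keep_kc) if not k]
        logger.warning("dropping %d unconnected KCs: %s", len(dropped), dropped[:10])
    if not keep_gl.all():
        dropped = [l for l, k in zip(glom_labels, keep_gl) if not k]
        logger.warning("dropping %d unconnected glomeruli: %s", len(dropped), dropped)
    return ConnectivityMatrix(
        binary=binary[np.ix_(keep_kc, keep_gl)],
        kc_labels=[l for l, k in zip(kc_labels, keep_kc) if k],
        glom_labels=[l for l, k in zip(glom_labels, keep_gl) if k],
        weights=weights[np.ix_(keep_kc, keep_gl)],
    )


def glom_similarity(C: ConnectivityMatrix) -> GlomSimilarity:
    """Pearson correlation between glomerulus columns over the KC axis."""
    X = C.binary.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two KCs")
    const = X.std(axis=0) == 0
    if const.any():
        dropped = [l for l, c in zip(C.glom_labels, const) if c]
        logger.warning("dropping constant glomerulus columns: %s", dropped)
        X = X[:, ~const]
    labels = [l for l, c in zip(C.glom_labels, const) if not c]
    S = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(S, 1.0)
    return GlomSimilarity(S, labels)


def _offdiag(S: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(S.shape[0], k=1)
    return S[iu]


def offdiag_correlation(
    S1: GlomSimilarity,
    S2: GlomSimilarity,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson r between upper-triangle similarities of two animals.

    Labels are intersected first.  The p-value is a two-sided Mantel-style
    permutation test: glomerulus labels of the second matrix are permuted
    jointly on rows and columns, with a +1 pseudocount.
    """
    shared = [l for l in S1.glom_labels if l in set(S2.glom_labels)]
    if len(shared) < 3:
        raise ValueError("need at least three shared glomeruli")
    A = S1.restrict(shared).values
    B = S2.restrict(shared).values
    r_obs = float(pearsonr(_offdiag(A), _offdiag(B)).statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(shared)
    a_flat = _offdiag(A)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(m)
        Bp = B[np.ix_(perm, perm)]
        r_p = pearsonr(a_flat, _offdiag(Bp)).statistic
        if abs(r_p) >= abs(r_obs):
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return r_obs, p


# ---------------------------------------------------------------------------
# degree-preserving shuffle (checkerboard swaps)
# ---------------------------------------------------------------------------


def _swap_chain_py(M, rows, cols, n_steps, seed):
    rng = np.random.default_rng(seed)
    n_edges = rows.shape[0]
    e1s = rng.integers(0, n_edges, size=n_steps)
    e2s = rng.integers(0, n_edges, size=n_steps)
    for e1, e2 in zip(e1s, e2s):
        r1, c1 = rows[e1], cols[e1]
        r2, c2 = rows[e2], cols[e2]
        if r1 != r2 and c1 != c2 and not M[r1, c2] and not M[r2, c1]:
            M[r1, c1] = 0
            M[r2, c2] = 0
            M[r1, c2] = 1
            M[r2, c1] = 1
            cols[e1] = c2
            cols[e2] = c1


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _swap_chain_nb(M, rows, cols, n_steps, seed):  # pragma: no cover
        np.random.seed(seed)
        n_edges = rows.shape[0]
        for _ in range(n_steps):
            e1 = np.random.randint(n_edges)
            e2 = np.random.randint(n_edges)
            r1, c1 = rows[e1], cols[e1]
            r2, c2 = rows[e2], cols[e2]
            if r1 != r2 and c1 != c2 and M[r1, c2] == 0 and M[r2, c1] == 0:
                M[r1, c1] = 0
                M[r2, c2] = 0
                M[r1, c2] = 1
                M[r2, c1] = 1
                cols[e1] = c2
                cols[e2] = c1


def shuffle_degree_preserving(
    C: ConnectivityMatrix,
    n_steps: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> ConnectivityMatrix:
    """Randomize a binary matrix keeping every row and column sum fixed.

    Markov chain of checkerboard swaps: a 2x2 submatrix [[1,0],[0,1]] is
    exchanged for [[0,1],[1,0]].  Default chain length is 10x the number of
    ones.  Matrices whose margins admit a unique fill come back unchanged.
    """
    M = C.binary.astype(np.int8).copy()
    rows, cols = np.nonzero(M)
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    if n_steps is None:
        n_steps = 10 * rows.shape[0]
    if isinstance(seed, np.random.Generator):
        chain_seed = int(seed.integers(0, 2**31 - 1))
    else:
        chain_seed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    if _HAVE_NUMBA:
        _swap_chain_nb(M, rows, cols, int(n_steps), chain_seed)
    else:
        _swap_chain_py(M, rows, cols, int(n_steps), chain_seed)
    out = ConnectivityMatrix(
        binary=M.astype(bool),
        kc_labels=list(C.kc_labels),
        glom_labels=list(C.glom_labels),
    )
    assert np.array_equal(out.binary.sum(axis=0), C.binary.sum(axis=0))
    assert np.array_equal(out.binary.sum(axis=1), C.binary.sum(axis=1))
    return out


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


def pca_embed(S: GlomSimilarity, d: int) -> EmbeddingResult:
    """PCA of similarity rows treated as glomerulus feature vectors."""
    n = S.values.shape[0]
    if not (1 <= d < n):
        raise ValueError("require 1 <= d < n_glom")
    pca = PCA(n_components=d)
    coords = pca.fit_transform(S.values)
    return EmbeddingResult(
        coords=coords,
        variance_explained=pca.explained_variance_ratio_.copy(),
        labels=list(S.glom_labels),
        method="pca",
        meta={"d": d},
    )


def _smallest_connected_k(D: np.ndarray) -> int:
    n = D.shape[0]
    for k in range(1, n):
        g = kneighbors_graph(D, k, metric="precomputed", mode="distance")
        g = g.maximum(g.T)
        if connected_components(g, directed=False, return_labels=False) == 1:
            return k
    return n - 1


def isomap_embed(
    S: GlomSimilarity,
    d: int,
    k: int | None = None,
) -> EmbeddingResult:
    """Classical Isomap on the similarity-profile geometry.

    Distances are Euclidean between rows of the similarity matrix (the same
    feature vectors PCA sees); geodesics are shortest paths on the symmetrized
    k-NN graph; coordinates come from classical MDS of the geodesic Gram
    matrix, whose eigenvalue fractions give per-dimension variance explained.
    If no neighbor count is given, the smallest k that connects the graph is
    used.
    """
    X = S.values
    n = X.shape[0]
    if not (1 <= d < n):
        raise ValueError("require 1 <= d < n_glom")
    D = squareform(pdist(X))
    k_min = _smallest_connected_k(D)
    if k is None:
        k = k_min
    if not (1 <= k <= n - 1):
        raise ValueError("require 1 <= k <= n_glom - 1")
    g = kneighbors_graph(D, k, metric="precomputed", mode="distance")
    g = g.maximum(g.T)
    if connected_components(g, directed=False, return_labels=False) > 1:
        raise ValueError(
            f"k={k} neighbor graph is disconnected; smallest connecting k is {k_min}"
        )
    geo = shortest_path(sp.csr_matrix(g), directed=False)
    # classical MDS of the geodesic distances
    G2 = geo**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ G2 @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0, None)
    total = pos.sum()
    coords = evecs[:, :d] * np.sqrt(pos[:d])
    ve = pos[:d] / total if total > 0 else np.zeros(d)
    return EmbeddingResult(
        coords=coords,
        variance_explained=ve,
        labels=list(S.glom_labels),
        method="isomap",
        meta={"d": d, "k": int(k), "k_min_connected": int(k_min)},
    )


def embedding_rmsd(
    E1: EmbeddingResult,
    E2: EmbeddingResult,
) -> tuple[float, np.ndarray, list[str]]:
    """RMSD between two embeddings after orthogonal Procrustes alignment.

    The second embedding is centroid-matched and rotated/reflected (no
    scaling) onto the first over the shared labels.  Returns the RMSD, the
    per-glomerulus residual distances, and the shared label order.
    """
    shared = [l for l in E1.labels if l in set(E2.labels)]
    if len(shared) < 3:
        raise ValueError("need at least three shared glomeruli")
    if E1.coords.shape[1] != E2.coords.shape[1]:
        raise ValueError("embedding dimensions differ")
    i1 = [E1.labels.index(l) for l in shared]
    i2 = [E2.labels.index(l) for l in shared]
    X = E1.coords[i1]
    Y = E2.coords[i2]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    R, _ = orthogonal_procrustes(Yc, Xc)
    resid = np.linalg.norm(Yc @ R - Xc, axis=1)
    rmsd = float(np.sqrt(np.mean(resid**2)))
    return rmsd, resid, shared


def rmsd_significance(resid_obs: np.ndarray, resid_null: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test of per-glomerulus residuals vs a shuffle ensemble."""
    res = ttest_ind(np.asarray(resid_obs), np.asarray(resid_null))
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# shuffle-based significance of embedding dimensions
# ---------------------------------------------------------------------------


def build_shuffle_ensemble(
    C: ConnectivityMatrix,
    d_max: int,
    n_shuffles: int,
    method: str = "pca",
    seed: int | None = None,
    n_steps: int | None = None,
    isomap_k: int | None = None,
) -> ShuffleEnsemble:
    """Variance-explained spectra of the full pipeline on shuffled matrices."""
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    ve = np.empty((n_shuffles, d_max))
    for i in range(n_shuffles):
        Cs = shuffle_degree_preserving(C, n_steps=n_steps, seed=rng)
        Ss = glom_similarity(Cs)
        if method == "pca":
            E = pca_embed(Ss, d_max)
        elif method == "isomap":
            E = isomap_embed(Ss, d_max, k=isomap_k)
        else:
            raise ValueError(f"unknown method {method!r}")
        ve[i] = E.variance_explained
    return ShuffleEnsemble(method=method, n_shuffles=n_shuffles, seed=seed, variance_explained=ve)


def dimension_significance(
    S: GlomSimilarity,
    d_max: int,
    ensemble: ShuffleEnsemble,
    isomap_k: int | None = None,
) -> np.ndarray:
    """Per-dimension empirical p-value of observed variance explained.

    p_d = (1 + #{shuffles with variance_explained_d >= observed_d}) /
    (n_shuffles + 1).
    """
    if ensemble.variance_explained.shape[0] == 0:
        raise ValueError("empty ensemble")
    if ensemble.method == "pca":
        E = pca_embed(S, d_max)
    else:
        E = isomap_embed(S, d_max, k=isomap_k)
    obs = E.variance_explained[:d_max]
    null = ensemble.variance_explained[:, :d_max]
    hits = (null >= obs[None, :]).sum(axis=0)
    return (hits + 1) / (ensemble.n_shuffles + 1)
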