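"""Primacy matrices from odor-response data and connectivity enrichment.

From a normalized OR x odorant response table (DoOR-style, with missing
entries) the top-p responders per odorant define a binary primacy matrix.
Two tests relate it to glomerulus->KC connectivity:

* correlation between OR-OR similarity in primacy membership and OR-OR
  similarity in KC connectivity (Mantel-style permutation p-value), and
* enrichment of KC claw / primacy-set overlaps: the overlap matrix is the
  boolean matrix product of connectivity and primacy matrices; per odorant
  the k KCs of highest overlap are histogrammed by overlap degree and
  compared against degree-preserving shuffles of the connectivity, with
  Benjamini-Hochberg FDR across the (primacy number x degree) grid.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectivity import (
    ConnectivityMatrix,
    GlomSimilarity,
    offdiag_correlation,
    shuffle_degree_preserving,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class OdorResponseMatrix:
    """OR x odorant normalized responses in [0,1] with an observed-mask."""

    values: np.ndarray
    or_labels: list[str]
    odor_labels: list[str]
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        self.or_labels = list(self.or_labels)
        self.odor_labels = list(self.odor_labels)
        if len(self.or_labels) != n or len(self.odor_labels) != m:
            raise ValueError("label lengths inconsistent with matrix shape")
        if len(set(self.or_labels)) != n or len(set(self.odor_labels)) != m:
            raise ValueError("labels must be unique")
        if self.observed is None:
            self.observed = np.ones((n, m), dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != (n, m):
                raise ValueError("observed mask shape mismatch")
        obs = self.values[self.observed]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValueError("observed responses must lie in [0, 1]")


@dataclasses.dataclass
class PrimacyMatrix:
    """Binary OR x odorant indicator of top-p responders per odorant."""

    indicator: np.ndarray
    p: int
    or_labels: list[str]
    odor_labels: list[str]
    tied_odorants: list[str] = dataclasses.field(default_factory=list)
    dropped_odorants: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        sums = self.indicator.sum(axis=0)
        if self.indicator.shape[1] and not np.all(sums == self.p):
            raise ValueError("every retained odorant column must sum to p")


@dataclasses.dataclass
class OverlapTable:
    """KC x odorant counts of claw / primacy-set intersections."""

    counts: np.ndarray
    kc_labels: list[str]
    odor_labels: list[str]
    p: int
    provenance: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class EnrichmentResult:
    """Observed-vs-null overlap-degree histograms with BH-FDR q-values.

    ``table`` is tidy long format with columns
    p, degree, observed, null_mean, diff, p_value, q_value.
    """

    table: pd.DataFrame
    k: int
    n_shuffles: int
    seed: int | None

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] < alpha]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def primacy_matrix(
    A: OdorResponseMatrix,
    p: int,
    min_observed: int | None = None,
) -> PrimacyMatrix:
    """Mark the p strongest observed responders of each odorant.

    Odorants with fewer than ``min_observed`` (default max(p, 8)) observed
    entries are dropped and logged; ties at rank p are broken by OR order and
    the odorant is flagged.
    """
    if p < 1:
        raise ValueError("p must be positive")
    if p > len(A.or_labels):
        raise ValueError("p exceeds the number of ORs")
    if min_observed is None:
        min_observed = max(p, 8)
    n, m = A.values.shape
    cols: list[int] = []
    tied: list[str] = []
    dropped: list[str] = []
    indicator_cols: list[np.ndarray] = []
    for j in range(m):
        obs = np.flatnonzero(A.observed[:, j])
        if obs.size < min_observed or obs.size < p:
            dropped.append(A.odor_labels[j])
            continue
        vals = A.values[obs, j]
        order = np.lexsort((obs, -vals))  # descending value, then OR index
        top = obs[order[:p]]
        if p < obs.size and vals[order[p - 1]] == vals[order[p]]:
            tied.append(A.odor_labels[j])
        col = np.zeros(n, dtype=bool)
        col[top] = True
        indicator_cols.append(col)
        cols.append(j)
    if dropped:
        logger.warning("dropping %d odorants with < %d observed responses", len(dropped), min_observed)
    indicator = (
        np.stack(indicator_cols, axis=1) if indicator_cols else np.zeros((n, 0), dtype=bool)
    )
    return PrimacyMatrix(
        indicator=indicator,
        p=p,
        or_labels=list(A.or_labels),
        odor_labels=[A.odor_labels[j] for j in cols],
        tied_odorants=tied,
        dropped_odorants=dropped,
    )


def primacy_similarity(P: PrimacyMatrix) -> GlomSimilarity:
    """OR-OR Pearson correlation of primacy-membership rows."""
    if len(P.odor_labels) < 2:
        raise ValueError("need at least two retained odorants")
    X = P.indicator.astype(float)
    const = X.std(axis=1) == 0
    if const.any():
        dropped = [l for l, c in zip(P.or_labels, const) if c]
        logger.warning("dropping constant ORs (never/always primary): %s", dropped)
    X = X[~const]
    labels = [l for l, c in zip(P.or_labels, const) if not c]
    S = np.corrcoef(X)
    np.fill_diagonal(S, 1.0)
    return GlomSimilarity(S, labels)


def single_or_glomeruli(glom_or_map: pd.DataFrame) -> dict[str, str]:
    """Glomerulus -> OR for glomeruli receiving exactly one OR type.

    The map is a two-column table (glomerulus, OR); glomeruli listed with
    more than one OR are excluded from affinity comparisons.
    """
    g, o = glom_or_map.columns[:2]
    counts = glom_or_map.groupby(g)[o].nunique()
    single = counts[counts == 1].index
    sub = glom_or_map[glom_or_map[g].isin(single)]
    return dict(zip(sub[g], sub[o]))


def connectivity_vs_primacy(
    S_conn: GlomSimilarity,
    S_prim: GlomSimilarity,
    glom_or_map: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Correlate connectivity similarity with primacy similarity.

    With a glomerulus<->OR map, connectivity labels are first translated to
    OR names keeping single-OR glomeruli only; then the two similarity
    matrices are compared by the off-diagonal Mantel-style test.
    """
    if glom_or_map is not None:
        mapping = single_or_glomeruli(glom_or_map)
        keep = [l for l in S_conn.glom_labels if l in mapping]
        S_conn = GlomSimilarity(
            S_conn.restrict(keep).values, [mapping[l] for l in keep]
        )
    return offdiag_correlation(S_conn, S_prim, n_perm=n_perm, seed=seed)


def overlap_table(C: ConnectivityMatrix, P: PrimacyMatrix) -> OverlapTable:
    """Boolean matrix product of connectivity and primacy matrices.

    Entry (kc, odorant) counts the intersection of the KC's claw set with the
    odorant's primacy set, over the shared OR/glomerulus labels.
    """
    shared = [l for l in C.glom_labels if l in set(P.or_labels)]
    if not shared:
        raise ValueError("no shared OR/glomerulus labels")
    ic = [C.glom_labels.index(l) for l in shared]
    ip = [P.or_labels.index(l) for l in shared]
    counts = C.binary[:, ic].astype(np.int64) @ P.indicator[ip].astype(np.int64)
    return OverlapTable(
        counts=counts,
        kc_labels=list(C.kc_labels),
        odor_labels=list(P.odor_labels),
        p=P.p,
        provenance={"n_shared_labels": len(shared)},
    )


def _topk_degree_hist(counts: np.ndarray, k: int, p: int) -> np.ndarray:
    """Histogram of the k largest per-odorant overlap degrees, bins 0..p."""
    if k > counts.shape[0]:
        raise ValueError("k exceeds the number of KCs")
    # exactly k per odorant, deterministic tie order (descending sort is stable
    # on equal values, so ties resolve toward lower KC index)
    if k == 1:
        top = counts.max(axis=0)[None, :]
    else:
        top = -np.partition(-counts, k - 1, axis=0)[:k, :]
    return np.bincount(top.ravel(), minlength=p + 1)[: p + 1]


def topk_enrichment(
    C: ConnectivityMatrix,
    P: PrimacyMatrix | Sequence[PrimacyMatrix],
    k: int,
    n_shuffles: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
    shuffle_steps: int | None = None,
) -> EnrichmentResult:
    """Overlap-degree enrichment of the k topmost KCs per odorant vs null.

    ``k = 1`` is the grandmother-KC case.  For each primacy matrix (one per
    primacy number p) the k largest overlap counts per odorant are binned by
    degree; the null repeats this on degree-preserving shuffles of the
    connectivity (the same shuffle realizations across p).  Cells get
    two-sided empirical p-values (+1 correction) and BH q-values across the
    whole (p x degree) grid.
    """
    Ps = [P] if isinstance(P, PrimacyMatrix) else list(P)
    if k < 1:
        raise ValueError("k must be positive")
    rng = np.random.default_rng(seed)
    obs = {Pm.p: _topk_degree_hist(overlap_table(C, Pm).counts, k, Pm.p) for Pm in Ps}
    null = {Pm.p: np.zeros((n_shuffles, Pm.p + 1), dtype=np.int64) for Pm in Ps}
    for s in range(n_shuffles):
        Cs = shuffle_degree_preserving(C, n_steps=shuffle_steps, seed=rng)
        for Pm in Ps:
            null[Pm.p][s] = _topk_degree_hist(overlap_table(Cs, Pm).counts, k, Pm.p)
    rows = []
    for Pm in Ps:
        p = Pm.p
        mean = null[p].mean(axis=0)
        for deg in range(p + 1):
            o = int(obs[p][deg])
            mu = float(mean[deg])
            dev = abs(null[p][:, deg] - mu)
            hits = int((dev >= abs(o - mu)).sum())
            pval = (hits + 1) / (n_shuffles + 1)
            rows.append(
                {
                    "p": p,
                    "degree": deg,
                    "observed": o,
                    "null_mean": mu,
                    "diff": o - mu,
                    "p_value": pval,
                }
            )
    table = pd.DataFrame(rows)
    q, _ = bh_fdr(table["p_value"].tolist(), alpha=alpha)
    table["q_value"] = q
    return EnrichmentResult(table=table, k=k, n_shuffles=n_shuffles, seed=seed)


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, rejected mask)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rejected
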