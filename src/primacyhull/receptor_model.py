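"""Mass-action receptor activation and primacy sets.

A receptor ``r`` exposed to a monomolecular odorant ``o`` at concentration
``c`` activates according to the mass-action law ``f/(1-f) = K_ro * c``,
where the affinity ``K_ro`` is the inverse of the concentration at which the
receptor reaches half-maximal activation.  For mixtures the drives add:
``f/(1-f) = K_r . c = (K_r . q) * |c|`` with ``q = c/|c|`` the mixture
direction.  Under a low-rank factorization ``K = R Q`` the same activation is
``f/(1-f) = R_r . q~`` with ``q~ = Q c`` the concentration of odorant
properties.

Because activation is monotone in the projection ``K_r . q``, the identity of
the first ``p`` receptors to cross any common threshold as concentration
rises along a fixed direction depends only on the projections — this is the
primacy set, and it is threshold invariant.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AffinityMatrix:
    """Receptor x odorant nonnegative affinities with an observed-mask.

    ``values[r, o]`` is the affinity ``K_ro`` (units: inverse concentration);
    the threshold concentration is ``1/K_ro`` where ``K_ro > 0``.  Entries
    with ``observed`` false are missing (DoOR-style) and may hold any value.
    """

    values: np.ndarray
    receptor_labels: list[str]
    odorant_labels: list[str]
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D matrix")
        n, m = self.values.shape
        self.receptor_labels = list(self.receptor_labels)
        self.odorant_labels = list(self.odorant_labels)
        if len(self.receptor_labels) != n or len(self.odorant_labels) != m:
            raise ValueError("label lengths inconsistent with matrix shape")
        if len(set(self.receptor_labels)) != n:
            raise ValueError("duplicate receptor labels")
        if len(set(self.odorant_labels)) != m:
            raise ValueError("duplicate odorant labels")
        if self.observed is None:
            self.observed = np.ones((n, m), dtype=bool)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != (n, m):
                raise ValueError("observed mask shape mismatch")
        if np.any(self.values[self.observed] < 0):
            raise ValueError("observed affinities must be nonnegative")

    @property
    def n_receptors(self) -> int:
        return self.values.shape[0]

    @property
    def n_odorants(self) -> int:
        return self.values.shape[1]

    @property
    def complete(self) -> bool:
        return bool(self.observed.all())

    def threshold_concentrations(self) -> np.ndarray:
        """c_th = 1/K where K > 0 and observed; NaN elsewhere."""
        out = np.full(self.values.shape, np.nan)
        ok = self.observed & (self.values > 0)
        out[ok] = 1.0 / self.values[ok]
        return out


@dataclasses.dataclass
class MixtureConcentration:
    """Per-odorant concentration vector of a mixture."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.ndim != 1:
            raise ValueError("concentration vector must be 1D")
        if np.any(self.c < 0):
            raise ValueError("concentrations must be nonnegative")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.c))

    @property
    def q(self) -> np.ndarray:
        """Unit mixture-direction vector; undefined at zero concentration."""
        n = self.norm
        if n == 0:
            raise ValueError("direction undefined for zero concentration")
        return self.c / n


@dataclasses.dataclass
class LowRankModel:
    """Affinity factorization K = R Q into D-dimensional property space."""

    receptor_factors: np.ndarray  # N x D
    property_loadings: np.ndarray  # D x M

    def __post_init__(self) -> None:
        self.receptor_factors = np.asarray(self.receptor_factors, dtype=float)
        self.property_loadings = np.asarray(self.property_loadings, dtype=float)
        if self.receptor_factors.ndim != 2 or self.property_loadings.ndim != 2:
            raise ValueError("factors must be 2D")
        if self.receptor_factors.shape[1] != self.property_loadings.shape[0]:
            raise ValueError("inner dimensions of R and Q disagree")

    @property
    def dimension(self) -> int:
        return self.receptor_factors.shape[1]

    def affinities(self) -> np.ndarray:
        return self.receptor_factors @ self.property_loadings


@dataclasses.dataclass
class ActivationProfile:
    """Receptor activation fractions with a detection threshold theta."""

    f: np.ndarray
    theta: float = 0.5

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0, 1)")
        if np.any(self.f < 0) or np.any(self.f >= 1):
            raise ValueError("activation fractions must lie in [0, 1)")


class PrimacySet(NamedTuple):
    """The p receptors of highest projection onto a mixture direction.

    ``tied`` flags an exact tie at the p-th rank (resolved toward the lowest
    receptor index).
    """

    vertices: tuple[int, ...]
    tied: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def activate_single(K: float, c: float) -> float:
    """Mass-action activation fraction f = Kc / (1 + Kc) of one receptor."""
    if K < 0 or c < 0:
        raise ValueError("affinity and concentration must be nonnegative")
    s = K * c
    return s / (1.0 + s)


def activate_mixture(
    affinity_row: Sequence[float] | np.ndarray,
    mix: MixtureConcentration | Sequence[float],
    loadings: np.ndarray | None = None,
) -> float:
    """Activation of one receptor by a mixture: f = s/(1+s), s = K_r . c.

    With ``loadings`` given, ``affinity_row`` is interpreted as the receptor's
    row ``R_r`` in property space and the drive is ``R_r . (Q c)``; the two
    call forms agree whenever ``K_r = R_r Q``.
    """
    row = np.asarray(affinity_row, dtype=float)
    if not isinstance(mix, MixtureConcentration):
        mix = MixtureConcentration(np.asarray(mix, dtype=float))
    c = mix.c
    if loadings is not None:
        c = property_concentration(loadings, c)
    if row.shape != c.shape:
        raise ValueError("affinity row and concentration vector lengths differ")
    s = float(row @ c)
    return s / (1.0 + s)


def active_set(profile: ActivationProfile) -> set[int]:
    """Indices of receptors strictly above the detection threshold."""
    return set(np.flatnonzero(profile.f > profile.theta).tolist())


def primacy_set(points: np.ndarray, q: np.ndarray, p: int) -> PrimacySet:
    """The p receptors with the largest projection onto unit direction q.

    These are the receptors activated at the lowest mixture concentration
    along ``q`` — the primacy set.  The choice of activation threshold never
    enters.  An exact tie at the p-th rank is broken toward the lowest index
    and flagged.
    """
    points = np.asarray(points, dtype=float)
    q = np.asarray(q, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be N x D")
    n = points.shape[0]
    if not (1 <= p <= n):
        raise ValueError("p must satisfy 1 <= p <= N")
    proj = points @ q
    # stable descending order; ties fall to lower index
    order = np.lexsort((np.arange(n), -proj))
    top = order[:p]
    tied = bool(p < n and proj[order[p - 1]] == proj[order[p]])
    return PrimacySet(tuple(sorted(int(i) for i in top)), tied)


def property_concentration(Q: np.ndarray, c: Sequence[float] | np.ndarray) -> np.ndarray:
    """Project a mixture concentration vector into property space: q~ = Q c."""
    Q = np.asarray(Q, dtype=float)
    c = np.asarray(c, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != c.shape[0]:
        raise ValueError("loading matrix and concentration vector shapes disagree")
    return Q @ c


def activation_profile(
    affinity: AffinityMatrix | np.ndarray,
    mix: MixtureConcentration | Sequence[float],
    theta: float = 0.5,
) -> ActivationProfile:
    """Activation of every receptor in an affinity matrix by a mixture.

    Missing entries are disallowed here: the mass-action equations presuppose
    complete affinity rows.
    """
    if isinstance(affinity, AffinityMatrix):
        if not affinity.complete:
            raise ValueError("activation requires a fully observed affinity matrix")
        K = affinity.values
    else:
        K = np.asarray(affinity, dtype=float)
    if not isinstance(mix, MixtureConcentration):
        mix = MixtureConcentration(np.asarray(mix, dtype=float))
    s = K @ mix.c
    return ActivationProfile(s / (1.0 + s), theta=theta)
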