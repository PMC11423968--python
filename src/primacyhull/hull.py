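"""Primacy hulls: simplicial complexes swept out by mixture directions.

For each unit direction ``q`` in odor space, the ``p`` receptors of highest
projection form a primacy set, drawn as a (p-1)-simplex on the receptor
points.  Sweeping ``q`` over all admissible directions and collecting the
simplices yields the primacy hull.  It always contains the convex-hull
extreme points (the top-1 receptors) and may also contain interior points.
Receptors outside the hull belong to no primacy set and are predicted to be
pseudogenized.

Faces of primacy simplices ("subprime" simplices) are the proposed unit of
representation of higher olfactory neurons; an n-vertex face count of a
p-vertex simplex is the binomial coefficient C(p, n).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from typing import Iterable

import numpy as np

from .receptor_model import primacy_set

CONES = ("nonnegative_orthant", "full_sphere")


@dataclasses.dataclass(frozen=True)
class PrimacySimplex:
    """A primacy set of p receptors, optionally weighted by sweep support."""

    vertices: tuple[int, ...]
    support_count: int = 1

    def __post_init__(self) -> None:
        v = tuple(int(i) for i in self.vertices)
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("vertices must be strictly increasing")
        object.__setattr__(self, "vertices", v)

    @property
    def p(self) -> int:
        return len(self.vertices)


@dataclasses.dataclass
class PrimacyHull:
    """Simplicial complex of primacy sets over a sweep of directions."""

    simplices: dict[tuple[int, ...], int]  # vertex tuple -> support count
    p: int
    n_receptors: int
    dimension: int
    sweep_meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.simplices:
            if len(v) != self.p:
                raise ValueError("simplex size inconsistent with p")
            if any(i < 0 or i >= self.n_receptors for i in v):
                raise ValueError("vertex index out of range")

    @property
    def vertex_set(self) -> set[int]:
        out: set[int] = set()
        for v in self.simplices:
            out.update(v)
        return out

    def simplex_list(self) -> list[PrimacySimplex]:
        return [
            PrimacySimplex(v, c) for v, c in sorted(self.simplices.items())
        ]

    def to_json(self) -> str:
        keys = sorted(self.simplices)
        obj = {
            "p": self.p,
            "n_receptors": self.n_receptors,
            "dimension": self.dimension,
            "simplices": [list(v) for v in keys],
            "support": [self.simplices[v] for v in keys],
            "sweep_meta": self.sweep_meta,
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PrimacyHull":
        obj = json.loads(text)
        simplices = {
            tuple(v): int(s)
            for v, s in zip(obj["simplices"], obj["support"])
        }
        return cls(
            simplices=simplices,
            p=int(obj["p"]),
            n_receptors=int(obj["n_receptors"]),
            dimension=int(obj["dimension"]),
            sweep_meta=obj.get("sweep_meta", {}),
        )


# ---------------------------------------------------------------------------
# face combinatorics
# ---------------------------------------------------------------------------


def face_count(n: int, p: int) -> int:
    """Number of n-vertex faces of a p-vertex (p-1)-simplex: C(p, n)."""
    if n < 1 or p < 1 or n > p:
        raise ValueError("require 1 <= n <= p")
    return math.comb(p, n)


def faces(simplex: PrimacySimplex | Iterable[int], n: int) -> set[tuple[int, ...]]:
    """All n-vertex faces (n-subsets) of a simplex, each sorted."""
    verts = simplex.vertices if isinstance(simplex, PrimacySimplex) else tuple(sorted(simplex))
    if n < 1 or n > len(verts):
        raise ValueError("face size out of range")
    return set(itertools.combinations(verts, n))


def subprime_complex(hull: PrimacyHull, n: int) -> set[tuple[int, ...]]:
    """Union of the n-vertex faces of every simplex in the hull."""
    if n < 1 or n > hull.p:
        raise ValueError("face size out of range")
    out: set[tuple[int, ...]] = set()
    for v in hull.simplices:
        out.update(itertools.combinations(v, n))
    return out


# ---------------------------------------------------------------------------
# direction sampling and hull construction
# ---------------------------------------------------------------------------


def sample_directions(
    n_directions: int,
    dimension: int,
    cone: str = "nonnegative_orthant",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform unit directions (rows), reflected into the cone if requested.

    Gaussian normalization gives the uniform sphere measure; taking absolute
    values folds it uniformly into the nonnegative orthant.
    """
    if cone not in CONES:
        raise ValueError(f"unknown cone {cone!r}")
    if rng is None:
        rng = np.random.default_rng()
    dirs = rng.standard_normal((n_directions, dimension))
    if cone == "nonnegative_orthant":
        dirs = np.abs(dirs)
    norms = np.linalg.norm(dirs, axis=1)
    # zero-norm draws have probability zero; guard regardless
    bad = norms == 0
    if bad.any():
        dirs[bad] = 1.0 / math.sqrt(dimension)
        norms[bad] = 1.0
    return dirs / norms[:, None]


def build_hull(
    points: np.ndarray,
    p: int,
    n_directions: int = 10_000,
    cone: str = "nonnegative_orthant",
    seed: int | np.random.Generator | None = None,
    extra_directions: np.ndarray | None = None,
) -> PrimacyHull:
    """Monte-Carlo sweep: sample directions, collect primacy sets.

    Deterministic given the seed; with nested direction samples the hull can
    only grow with ``n_directions``.  ``extra_directions`` (rows, already in
    the cone) are appended to the sample — used to guarantee that specific
    mixture directions contribute their simplices.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if n < p:
        raise ValueError("need at least p points")
    if n_directions < 1:
        raise ValueError("n_directions must be positive")
    if np.allclose(points, points[0]):
        raise ValueError("degenerate points: all identical, every direction ties")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dirs = sample_directions(n_directions, d, cone=cone, rng=rng)
    if extra_directions is not None:
        extra = np.asarray(extra_directions, dtype=float)
        extra = extra / np.linalg.norm(extra, axis=1, keepdims=True)
        dirs = np.vstack([dirs, extra])

    proj = points @ dirs.T  # N x n_dirs
    top = np.argpartition(-proj, p - 1, axis=0)[:p]  # p x n_dirs
    top = np.sort(top, axis=0).T  # n_dirs x p, each row a sorted simplex
    uniq, counts = np.unique(top, axis=0, return_counts=True)
    simplices = {tuple(int(i) for i in row): int(c) for row, c in zip(uniq, counts)}
    meta = {
        "scheme": "monte_carlo",
        "n_directions": int(dirs.shape[0]),
        "cone": cone,
        "seed": None if isinstance(seed, np.random.Generator) else seed,
    }
    return PrimacyHull(simplices, p=p, n_receptors=n, dimension=d, sweep_meta=meta)


def build_hull_exact_2d(
    points: np.ndarray,
    p: int,
    cone: str = "full_sphere",
) -> PrimacyHull:
    """Exact 2D primacy hull by angular event sweep.

    The projection ranking of the points changes only at directions
    orthogonal to a pairwise difference vector.  Enumerating those O(N^2)
    critical angles and evaluating one direction inside each angular interval
    visits every primacy set exactly once, independent of any sampling.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    if d != 2:
        raise ValueError("exact sweep is implemented for D = 2 only")
    if n < p:
        raise ValueError("need at least p points")
    if cone not in CONES:
        raise ValueError(f"unknown cone {cone!r}")
    diffs = points[:, None, :] - points[None, :, :]
    iu = np.triu_indices(n, k=1)
    pair_d = diffs[iu]
    if np.any(np.all(pair_d == 0, axis=1)):
        raise ValueError("duplicate points")

    # q orthogonal to a difference vector d at angle(d) +/- pi/2
    phi = np.arctan2(pair_d[:, 1], pair_d[:, 0])
    crit = np.concatenate([phi + np.pi / 2, phi - np.pi / 2])
    two_pi = 2 * np.pi
    if cone == "full_sphere":
        lo, hi = 0.0, two_pi
        crit = np.mod(crit, two_pi)
    else:
        lo, hi = 0.0, np.pi / 2
        crit = np.mod(crit, two_pi)
        crit = crit[(crit > lo) & (crit < hi)]
    angles = np.unique(np.concatenate([crit, [lo, hi]]))
    angles = angles[(angles >= lo) & (angles <= hi)]
    # midpoints of consecutive angular intervals (plus circular wrap)
    mids = (angles[:-1] + angles[1:]) / 2.0
    mids = mids[np.diff(angles) > 1e-12]
    if cone == "full_sphere":
        wrap = (angles[-1] + angles[0] + two_pi) / 2.0
        mids = np.concatenate([mids, [np.mod(wrap, two_pi)]])

    simplices: dict[tuple[int, ...], int] = {}
    for theta in mids:
        q = np.array([np.cos(theta), np.sin(theta)])
        s = primacy_set(points, q, p)
        simplices[s.vertices] = simplices.get(s.vertices, 0) + 1
    meta = {"scheme": "exact_2d_event_sweep", "cone": cone, "n_intervals": len(mids)}
    return PrimacyHull(simplices, p=p, n_receptors=n, dimension=2, sweep_meta=meta)


def hull_membership(hull: PrimacyHull) -> tuple[list[int], list[int]]:
    """Partition receptors into hull members and predicted-pseudogenized."""
    members = hull.vertex_set
    member_list = sorted(members)
    non_members = [i for i in range(hull.n_receptors) if i not in members]
    return member_list, non_members


def discovery_rate(hull_counts: Iterable[int]) -> float:
    """Fraction of sweep directions that discovered a singleton simplex.

    A convergence diagnostic for sampled sweeps in D > 2: near convergence
    almost no simplex is supported by just one direction.
    """
    counts = list(hull_counts)
    if not counts:
        return 0.0
    return sum(1 for c in counts if c == 1) / sum(counts)
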