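"""Surrogate olfactory worlds with a planted primacy hull.

The generator emulates the three datasets the analysis consumes, tied
together by a single planted geometry: receptor points in a low-dimensional
property space, the primacy hull swept over that geometry, a DoOR-like
masked response matrix whose noise-free part is the low-rank product of
receptor points and odorant property vectors, and connectivity matrices
whose Kenyon cells sample n-vertex faces (subprime simplices) of hull
simplices.  Negative controls replace the connectivity by its
degree-preserving shuffle or fully rewire the claws.

The fly-scale preset matches the systems the analysis targets: 51
glomeruli, ~1800 KCs with 6 claws each, 156 odorants with substantial
missingness.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable

import numpy as np

from .connectivity import ConnectivityMatrix, shuffle_degree_preserving
from .hull import PrimacyHull, build_hull, sample_directions
from .overlap import OdorResponseMatrix, PrimacyMatrix, primacy_matrix
from .receptor_model import primacy_set


@dataclasses.dataclass
class WorldConfig:
    """Parameters of a surrogate world.

    Defaults are the fly-scale preset; ``preset("validation")`` gives the
    scaled-down configuration used for planted-recovery checks.
    """

    n_receptors: int = 51
    dimension: int = 6
    p: int = 5
    n_odorants: int = 156
    n_kc: int = 1800
    claws_per_kc: int = 5
    claw_noise_fraction: float = 0.2
    missing_rate: float = 0.3
    affinity_noise: float = 0.05
    hull_directions: int = 20_000
    cone: str = "nonnegative_orthant"
    seed: int | None = None
    preset: str = "fly"

    def __post_init__(self) -> None:
        if self.p > self.n_receptors:
            raise ValueError("p cannot exceed the number of receptors")
        if self.claws_per_kc > self.p:
            raise ValueError("claws per KC must not exceed p (KCs sample simplex faces)")
        for rate in (self.claw_noise_fraction, self.missing_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")

    # documentation constants for the mammalian piriform-cortex scale:
    # ~2e5 pyramidal cells of which ~1e4 respond per odor, matching
    # F(n=8, p=16) ~ 1.3e4 subprime faces.
    N_PC_MOUSE = 200_000
    N_ACTIVE_MOUSE = 10_000


def preset(name: str, seed: int | None = None) -> WorldConfig:
    """Named world configurations."""
    if name == "fly":
        return WorldConfig(seed=seed, preset="fly")
    if name == "validation":
        # scaled-down planted-recovery conditions
        return WorldConfig(
            n_receptors=30,
            dimension=4,
            p=5,
            n_odorants=60,
            n_kc=300,
            claws_per_kc=5,
            claw_noise_fraction=0.2,
            missing_rate=0.3,
            affinity_noise=0.05,
            hull_directions=4000,
            seed=seed,
            preset="validation",
        )
    raise ValueError(f"unknown preset {name!r}")


@dataclasses.dataclass
class SurrogateWorld:
    """Planted-truth bundle: geometry, hull, responses, connectivity."""

    config: WorldConfig
    points: np.ndarray  # N x D receptor coordinates
    hull: PrimacyHull
    affinity: OdorResponseMatrix
    primacy_truth: PrimacyMatrix
    connectivity: ConnectivityMatrix
    connectivity_b: ConnectivityMatrix | None = None
    kc_truth: list[tuple[int, ...]] | None = None
    is_null: bool = False
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def receptor_labels(self) -> list[str]:
        return self.affinity.or_labels


def _receptor_labels(n: int) -> list[str]:
    return [f"OR{i:02d}" for i in range(n)]


def _odor_labels(m: int) -> list[str]:
    return [f"odor{j:03d}" for j in range(m)]


def sample_receptors(
    N: int,
    D: int,
    seed: int | np.random.Generator | None = None,
    distribution: Callable[[np.random.Generator], np.ndarray] | None = None,
) -> np.ndarray:
    """Receptor points in property space; default folded standard normal.

    The folded (absolute-value) normal places every receptor in the positive
    orthant, where nonnegative mixture directions live.
    """
    if N < D + 1:
        raise ValueError("need at least D + 1 receptors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if distribution is not None:
        pts = np.asarray(distribution(rng), dtype=float)
        if pts.shape != (N, D):
            raise ValueError("custom distribution returned wrong shape")
        return pts
    return np.abs(rng.standard_normal((N, D)))


def make_affinity(
    points: np.ndarray,
    n_odorants: int,
    sigma: float = 0.0,
    missing_rate: float = 0.0,
    template_mask: np.ndarray | None = None,
    cone: str = "nonnegative_orthant",
    seed: int | np.random.Generator | None = None,
    template_values: np.ndarray | None = None,
) -> tuple[OdorResponseMatrix, np.ndarray]:
    """Low-rank masked response matrix; returns (matrix, property loadings Q).

    Odorant property columns are unit vectors drawn from the sweep cone, so
    each noise-free column's top responders form a primacy set of the same
    geometry.  Values are clip(R.Q + noise, 0) rescaled to [0, 1].  Missing
    structure is either a supplied template mask or independent Bernoulli
    dropout; a template value histogram, when supplied, is imposed by rank
    mapping.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be nonnegative")
    points = np.asarray(points, dtype=float)
    N, D = points.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = sample_directions(n_odorants, D, cone=cone, rng=rng).T  # D x M
    values = points @ Q
    if sigma > 0:
        values = values + sigma * rng.standard_normal(values.shape)
    values = np.clip(values, 0.0, None)
    top = values.max()
    if top > 0:
        values = values / top
    if template_values is not None:
        flat = np.sort(np.asarray(template_values, dtype=float).ravel())
        ranks = values.ravel().argsort().argsort()
        mapped = flat[np.floor(ranks / ranks.size * flat.size).astype(int)]
        values = mapped.reshape(values.shape)
    if template_mask is not None:
        observed = np.asarray(template_mask, dtype=bool)
        if observed.shape != values.shape:
            raise ValueError("template mask shape mismatch")
    else:
        observed = rng.random(values.shape) >= missing_rate
    A = OdorResponseMatrix(
        values=values,
        or_labels=_receptor_labels(N),
        odor_labels=_odor_labels(n_odorants),
        observed=observed,
    )
    return A, Q


def make_connectivity(
    hull: PrimacyHull,
    n_kc: int,
    n_claws: int,
    claw_noise_fraction: float = 0.0,
    seed: int | np.random.Generator | None = None,
    glom_labels: list[str] | None = None,
    kc_prefix: str = "KC",
) -> tuple[ConnectivityMatrix, list[tuple[int, ...]]]:
    """KCs sampling subprime faces of hull simplices; returns (C, truth).

    Each KC picks a hull simplex with probability proportional to its sweep
    support, then a uniform n-subset of its vertices as claws.  Each claw is
    rewired to a uniform random glomerulus with the given probability
    (duplicates redrawn so claw counts stay exact).  ``truth`` records each
    KC's generating simplex.
    """
    if not hull.simplices:
        raise ValueError("hull has no simplices")
    if n_claws > hull.p:
        raise ValueError("claws per KC must not exceed p")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    simplices = sorted(hull.simplices)
    support = np.array([hull.simplices[s] for s in simplices], dtype=float)
    probs = support / support.sum()
    N = hull.n_receptors
    binary = np.zeros((n_kc, N), dtype=bool)
    truth: list[tuple[int, ...]] = []
    choices = rng.choice(len(simplices), size=n_kc, p=probs)
    for i in range(n_kc):
        simplex = simplices[choices[i]]
        truth.append(simplex)
        claws = rng.choice(hull.p, size=n_claws, replace=False)
        claw_set = {simplex[j] for j in claws}
        if claw_noise_fraction > 0:
            rewire = rng.random(n_claws) < claw_noise_fraction
            kept = [g for g, rw in zip(sorted(claw_set), rewire) if not rw]
            claw_set = set(kept)
            while len(claw_set) < n_claws:
                claw_set.add(int(rng.integers(N)))
        binary[i, list(claw_set)] = True
    labels = glom_labels if glom_labels is not None else _receptor_labels(N)
    C = ConnectivityMatrix(
        binary=binary,
        kc_labels=[f"{kc_prefix}{i:04d}" for i in range(n_kc)],
        glom_labels=list(labels),
    )
    return C, truth


def make_world(config: WorldConfig) -> SurrogateWorld:
    """Generate a full surrogate world from a configuration."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)]
    points = sample_receptors(config.n_receptors, config.dimension, seed=seeds[0])
    A, Q = make_affinity(
        points,
        config.n_odorants,
        sigma=config.affinity_noise,
        missing_rate=config.missing_rate,
        cone=config.cone,
        seed=seeds[1],
    )
    # hull from the sweep plus the odorant directions themselves, so every
    # planted primacy set is a hull simplex by construction
    qs = Q.T / np.linalg.norm(Q.T, axis=1, keepdims=True)
    hull = build_hull(
        points,
        config.p,
        n_directions=config.hull_directions,
        cone=config.cone,
        seed=seeds[2],
        extra_directions=qs,
    )
    # planted truth: primacy set of each odorant from the noise-free geometry
    ind = np.zeros((config.n_receptors, config.n_odorants), dtype=bool)
    for j in range(config.n_odorants):
        s = primacy_set(points, qs[j], config.p)
        ind[list(s.vertices), j] = True
    truth_matrix = PrimacyMatrix(
        indicator=ind,
        p=config.p,
        or_labels=A.or_labels,
        odor_labels=A.odor_labels,
    )
    C, kc_truth = make_connectivity(
        hull,
        config.n_kc,
        config.claws_per_kc,
        claw_noise_fraction=config.claw_noise_fraction,
        seed=seeds[3],
        glom_labels=A.or_labels,
    )
    return SurrogateWorld(
        config=config,
        points=points,
        hull=hull,
        affinity=A,
        primacy_truth=truth_matrix,
        connectivity=C,
        kc_truth=kc_truth,
        metadata={"seed": config.seed, "stage_seeds": seeds},
    )


def make_second_animal(
    world: SurrogateWorld,
    rewire_fraction: float = 0.2,
    seed: int | None = None,
) -> ConnectivityMatrix:
    """An independent animal sharing the world's hull (fresh KC sampling)."""
    C, _ = make_connectivity(
        world.hull,
        world.config.n_kc,
        world.config.claws_per_kc,
        claw_noise_fraction=rewire_fraction,
        seed=seed,
        glom_labels=world.affinity.or_labels,
        kc_prefix="KCb",
    )
    return C


def make_null_world(world: SurrogateWorld, seed: int | None = None) -> SurrogateWorld:
    """Negative control: connectivity replaced by its degree-preserving shuffle."""
    shuffled = shuffle_degree_preserving(world.connectivity, seed=seed)
    meta = dict(world.metadata)
    meta["null_shuffle_seed"] = seed
    return SurrogateWorld(
        config=world.config,
        points=world.points,
        hull=world.hull,
        affinity=world.affinity,
        primacy_truth=world.primacy_truth,
        connectivity=shuffled,
        connectivity_b=world.connectivity_b,
        kc_truth=None,
        is_null=True,
        metadata=meta,
    )


def world_summary(world: SurrogateWorld) -> str:
    """One-line JSON description of a world (for run metadata)."""
    return json.dumps(
        {
            "preset": world.config.preset,
            "n_receptors": world.config.n_receptors,
            "dimension": world.config.dimension,
            "p": world.config.p,
            "n_odorants": world.config.n_odorants,
            "n_kc": world.config.n_kc,
            "n_hull_simplices": len(world.hull.simplices),
            "is_null": world.is_null,
        }
    )
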