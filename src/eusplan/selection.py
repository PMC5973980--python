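"""Optimal-plane selection by the 90th percentile of simulated TREs.

A small mean TRE alone does not guarantee a robust initialisation: a plane
whose TRE distribution has a heavy tail can still fail badly on the day.
Candidate planes (and plane pairs) are therefore ranked by the 90th
percentile of their Monte-Carlo TRE samples — the upper bound of the
nonparametric 90% prediction interval, i.e. the error the clinician can
expect not to exceed with 90% probability.  Winners are re-scored on fresh,
independent simulations to remove the optimisation winner's-curse bias, and
the per-vertex minima are assembled into a TRE map over the contact-organ
surface for visual planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anatomy import AnatomyModel, Structure
from .planes import PlaneFeature, SectorPlane
from .simulation import NoiseModel, SimulationResult, simulate_pair, simulate_plane


def percentile_90(samples) -> float:
    """Nearest-rank 90th percentile: the sorted sample at rank
    ceil(0.9 n)."""
    s = np.sort(np.asarray(samples, dtype=float))
    if s.size == 0:
        raise ValueError("percentile of an empty sample set")
    rank = math.ceil(0.9 * s.size)
    return float(s[max(rank, 1) - 1])


@dataclass(frozen=True)
class PlaneScore:
    """Summary of one plane's (or pair's) simulated TRE distribution."""

    plane_id: tuple[int, ...]  # (vertex_id, plane_id) or a 4-tuple for pairs
    p90_mm: float
    mean_mm: float
    sd_mm: float
    n_sims: int
    n_tubes: int = 0
    n_organs: int = 0


def score_from_result(plane_id: tuple[int, ...], res: SimulationResult,
                      features: list[PlaneFeature]) -> PlaneScore:
    d = res.plane_tre
    return PlaneScore(plane_id=plane_id, p90_mm=d.p90, mean_mm=d.mean,
                      sd_mm=d.sd, n_sims=d.n,
                      n_tubes=sum(f.kind == "tube" for f in features),
                      n_organs=sum(f.kind == "organ" for f in features))


def select_optimal(scores: list[PlaneScore], k: int = 1) -> list[PlaneScore]:
    """Top-k planes by ascending p90; ties broken by lower mean, then by
    plane id."""
    if not scores:
        raise ValueError("no plane scores to select from")
    return sorted(scores, key=lambda s: (s.p90_mm, s.mean_mm, s.plane_id))[:k]


def sample_pairs_lhs(usable_planes: list, n_pairs: int,
                     seed: int | np.random.Generator = 0) -> list[tuple]:
    """Latin-hypercube sample of plane pairs.

    The (plane-index x plane-index) unit square is stratified into
    ``n_pairs`` equal strata per dimension, one sample per stratum per
    dimension (random stratum pairing); samples are mapped to plane
    indices, then self-pairs and unordered duplicates are dropped, so the
    returned list can be shorter than ``n_pairs``.  Deterministic given the
    seed.
    """
    if len(usable_planes) < 2:
        raise ValueError("need at least 2 usable planes to form pairs")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(usable_planes)
    for _ in range(100):
        strata_a = rng.permutation(n_pairs)
        strata_b = rng.permutation(n_pairs)
        ua = (strata_a + rng.random(n_pairs)) / n_pairs
        ub = (strata_b + rng.random(n_pairs)) / n_pairs
        ia = np.minimum((ua * n).astype(int), n - 1)
        ib = np.minimum((ub * n).astype(int), n - 1)
        seen = set()
        pairs = []
        for a, b in zip(ia, ib):
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((usable_planes[a], usable_planes[b]))
        if pairs:
            return pairs
    raise RuntimeError("could not draw a valid non-self pair")


class SeedCollisionError(ValueError):
    pass


def reestimate(selected: PlaneScore, anatomy: AnatomyModel,
               noise: NoiseModel, *, planes, features, n: int = 1000,
               fresh_seed: int = 1, opt_seed: int = 0,
               n_starts: int = 10) -> PlaneScore:
    """Unbiased re-scoring of a selected plane or pair.

    Optimising over many noisy p90 estimates selects, in part, planes whose
    estimate happened to be low; the winner is therefore re-simulated with
    ``n`` fresh draws under a seed disjoint from the optimisation seed.

    ``planes``/``features`` are the winner's plane(s) and feature list(s):
    a single plane with its features, or a 2-tuple of each for a pair.
    """
    if fresh_seed == opt_seed:
        raise SeedCollisionError(
            "re-estimation seed must differ from the optimisation seed")
    if isinstance(planes, SectorPlane):
        res = simulate_plane(planes, anatomy, noise, features=features,
                             n_sims=n, seed=fresh_seed, n_starts=n_starts)
    else:
        res = simulate_pair(tuple(planes), anatomy, noise, features=features,
                            n_sims=n, seed=fresh_seed, n_starts=n_starts)
    flat = (features if isinstance(planes, SectorPlane)
            else [f for fs in features for f in fs])
    return score_from_result(selected.plane_id, res, flat)


@dataclass
class TreMap:
    """Per-vertex best (minimum over orientations) p90 on the contact mesh.

    Vertices where no plane had three identifiable features are flagged
    unusable and carry no value (NaN).
    """

    mesh: Structure
    values: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        assert len(self.values) == len(self.mesh.points)
        assert not np.any(np.isfinite(self.values) & ~self.usable)


def build_tre_map(anatomy: AnatomyModel, scores: list[PlaneScore],
                  contact_label: int | None = None) -> TreMap:
    """Reduce per-plane scores to a per-vertex map over the contact surface.

    ``PlaneScore.plane_id`` is (vertex_id, plane_id); the map keeps each
    vertex's minimum p90 over its orientations.
    """
    lab = contact_label if contact_label is not None else anatomy.contact_labels[0]
    mesh = anatomy.structures[lab]
    nv = len(mesh.points)
    values = np.full(nv, np.nan)
    for s in scores:
        v = s.plane_id[0]
        if not (0 <= v < nv):
            raise ValueError(f"score references vertex {v} outside the mesh")
        if not np.isfinite(values[v]) or s.p90_mm < values[v]:
            values[v] = s.p90_mm
    return TreMap(mesh=mesh, values=values, usable=np.isfinite(values))
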