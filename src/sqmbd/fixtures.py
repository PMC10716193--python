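"""Seeded synthetic systems so the whole pipeline runs with no external data.

Geometries are deliberately simple (random clusters, dimer distance scans,
helix-like chains, two-blob complexes) — they exercise every operation at
realistic interatomic distances and polarizabilities but make no claim to
chemical realism.  Randomness uses the counter-based Philox generator so
fixtures are bitwise reproducible across platforms for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import AtomicSystem, FragmentPartition

__all__ = ["FixtureSpec", "generate", "dimer_system", "dimer_scan"]

MAX_TRIES = 100_000

DEFAULT_ELEMENT_WEIGHTS = {"H": 0.50, "C": 0.30, "N": 0.10, "O": 0.08, "S": 0.02}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic system.

    ``min_dist`` (Bohr) keeps generated geometries out of the
    polarization-catastrophe regime at the default damping; ``eta_range``
    spans typical atom-in-molecule ratios of organic matter.
    """

    n_atoms: int = 10
    element_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_WEIGHTS)
    )
    geometry: str = "random_cluster"  # random_cluster | helix | two_blob
    min_dist: float = 2.0
    radius: float | None = None  # cluster half-extent; auto-scaled if None
    eta_range: tuple[float, float] = (0.7, 1.1)
    gap: float = 8.0          # two_blob inter-blob gap (Bohr)
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.Philox(self.seed))


def _sample_elements(spec: FixtureSpec, rng: np.random.Generator, n: int) -> tuple[str, ...]:
    names = list(spec.element_weights)
    w = np.array([spec.element_weights[k] for k in names], dtype=float)
    w /= w.sum()
    return tuple(rng.choice(names, size=n, p=w))


def _pack_cluster(
    rng: np.random.Generator,
    n: int,
    min_dist: float,
    center: np.ndarray,
    radius: float | None = None,
) -> np.ndarray:
    """Rejection-sample n points with pairwise distance >= min_dist."""
    if radius is None:
        # auto-scale so the box comfortably holds n spheres of radius min_dist/2
        radius = 0.75 * min_dist * max(n, 2) ** (1.0 / 3.0) + 0.5 * min_dist
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > MAX_TRIES:
            raise RuntimeError(
                f"could not place {n} atoms at min_dist={min_dist} "
                f"within {MAX_TRIES} tries"
            )
        cand = center + radius * (2.0 * rng.random(3) - 1.0)
        if all(np.linalg.norm(cand - p) >= min_dist for p in placed):
            placed.append(cand)
    return np.asarray(placed)


def _helix(n: int, min_dist: float) -> np.ndarray:
    # turn spacing chosen so consecutive atoms sit min_dist apart
    pitch = 0.45 * min_dist
    radius = 1.0 * min_dist
    t = np.arange(n) * 1.0
    return np.stack(
        [radius * np.cos(t), radius * np.sin(t), pitch * t], axis=1
    )


def generate(spec: FixtureSpec) -> tuple[AtomicSystem, FragmentPartition]:
    """Deterministically generate a system and a matching partition.

    ``two_blob`` returns a 2-fragment partition (one per blob); other
    geometries return the trivial single-fragment partition.
    """
    rng = spec.rng()
    n = spec.n_atoms
    if spec.geometry == "random_cluster":
        pos = _pack_cluster(rng, n, spec.min_dist, np.zeros(3), spec.radius)
        part = FragmentPartition.single(n)
    elif spec.geometry == "helix":
        pos = _helix(n, spec.min_dist)
        part = FragmentPartition.single(n)
    elif spec.geometry == "two_blob":
        n1 = n // 2
        n2 = n - n1
        blob1 = _pack_cluster(rng, n1, spec.min_dist, np.zeros(3), spec.radius)
        extent = blob1[:, 0].max() - blob1[:, 0].min()
        offset = np.array([extent + spec.gap, 0.0, 0.0])
        blob2 = _pack_cluster(rng, n2, spec.min_dist, offset, spec.radius)
        pos = np.vstack([blob1, blob2])
        part = FragmentPartition.from_dict(
            {"blob1": list(range(n1)), "blob2": list(range(n1, n))}, n
        )
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    elements = _sample_elements(spec, rng, n)
    eta = rng.uniform(*spec.eta_range, size=n)
    system = AtomicSystem(elements, pos, eta=eta)
    return system, part


def dimer_system(
    r: float,
    element: str = "C",
    eta: float = 1.0,
    axis: np.ndarray | None = None,
) -> tuple[AtomicSystem, FragmentPartition]:
    """Homonuclear dimer at separation r (Bohr), one atom per fragment."""
    direction = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    direction = direction / np.linalg.norm(direction)
    pos = np.stack([np.zeros(3), r * direction])
    system = AtomicSystem((element, element), pos, eta=np.array([eta, eta]))
    part = FragmentPartition.from_dict({"a": [0], "b": [1]}, 2)
    return system, part


def dimer_scan(
    distances: np.ndarray, element: str = "C", eta: float = 1.0
) -> list[tuple[AtomicSystem, FragmentPartition]]:
    """Homonuclear dimers over a distance grid (Bohr)."""
    return [dimer_system(float(r), element, eta) for r in np.asarray(distances)]
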