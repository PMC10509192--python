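"""Shared fixtures and independent brute-force oracles for the test suite.

The oracles here deliberately avoid the package's canonical-form DFS and
vectorized energy paths: walks are enumerated over all four directions and
reduced by explicit symmetry-orbit bookkeeping, contacts come from an
O(L^2) distance scan, and probabilities from direct arithmetic. They exist
so the library can be checked against something it does not share code
with.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import latticedesign as ld

# The eight symmetries of the square lattice (rotations x reflection).
SYMMETRIES = [
    lambda x, y: (x, y),
    lambda x, y: (-y, x),
    lambda x, y: (-x, -y),
    lambda x, y: (y, -x),
    lambda x, y: (x, -y),
    lambda x, y: (-y, -x),
    lambda x, y: (-x, y),
    lambda x, y: (y, x),
]


def all_walks(length: int) -> list[tuple[tuple[int, int], ...]]:
    """Every SAW of `length` monomers from the origin, all four first steps."""
    out = []

    def dfs(path, occupied):
        if len(path) == length:
            out.append(tuple(path))
            return
        x, y = path[-1]
        for dx, dy in ((1, 0), (0, 1), (-1, 0), (0, -1)):
            nxt = (x + dx, y + dy)
            if nxt in occupied:
                continue
            path.append(nxt)
            occupied.add(nxt)
            dfs(path, occupied)
            occupied.remove(nxt)
            path.pop()

    dfs([(0, 0)], {(0, 0)})
    return out


def orbit_representative(coords) -> tuple[tuple[int, int], ...]:
    """Lexicographic minimum over the 8 symmetry images, origin-translated."""
    images = []
    for sym in SYMMETRIES:
        pts = [sym(x, y) for x, y in coords]
        x0, y0 = pts[0]
        images.append(tuple((x - x0, y - y0) for x, y in pts))
    return min(images)


def contact_scan(coords) -> list[tuple[int, int]]:
    """O(L^2) pairwise-distance contact oracle."""
    found = []
    for i, j in itertools.combinations(range(len(coords)), 2):
        if j > i + 1:
            (xi, yi), (xj, yj) = coords[i], coords[j]
            if abs(xi - xj) + abs(yi - yj) == 1:
                found.append((i, j))
    return sorted(found)


def random_saw(length: int, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """Rejection-sampled self-avoiding walk (arbitrary orientation)."""
    while True:
        path = [(0, 0)]
        occupied = {(0, 0)}
        ok = True
        for _ in range(length - 1):
            x, y = path[-1]
            options = [
                (x + dx, y + dy)
                for dx, dy in ((1, 0), (0, 1), (-1, 0), (0, -1))
                if (x + dx, y + dy) not in occupied
            ]
            if not options:
                ok = False
                break
            nxt = options[rng.integers(len(options))]
            path.append(nxt)
            occupied.add(nxt)
        if ok:
            return tuple(path)


HOOK_COORDS = ((0, 0), (1, 0), (1, 1), (0, 1))


@pytest.fixture(scope="session")
def hp_alphabet() -> ld.Alphabet:
    return ld.Alphabet.from_string("HP")


@pytest.fixture(scope="session")
def hp_model(hp_alphabet) -> ld.EnsembleModel:
    """L=4 HP ensemble with E(H,H) = -1 and kT = 1."""
    return ld.EnsembleModel.build(4, hp_alphabet, ld.ContactPotential.hp())


@pytest.fixture(scope="session")
def hook_task(hp_model) -> ld.DesignTask:
    """The L=4 'hook' native: the unique conformation with a contact."""
    return ld.DesignTask.from_native(hp_model, ld.canonicalize(HOOK_COORDS))


@pytest.fixture(scope="session")
def hook_joint(hook_task) -> ld.JointModel:
    return ld.JointModel(ld.SequencePrior.uniform(hook_task.model.alphabet), hook_task.model)


def fixture_batch(seed, n_tasks, length=6, prior_kind="markov1"):
    return ld.generate_fixtures(
        ld.FixtureSpec(
            seed=seed, n_tasks=n_tasks, lengths=(length, length), prior_kind=prior_kind
        )
    )
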