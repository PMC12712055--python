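"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from piezoflux.synthgen import SynthMinfluxConfig, generate_minflux_dataset


# ---------------------------------------------------------------------------
# independent geometric oracles (deliberately brute force)


def components_oracle(points: np.ndarray, eps: float) -> list[set[int]]:
    """Connected components of the <=eps proximity graph via BFS.

    Independent of DBSCAN: plain all-pairs distances plus breadth-first
    search.
    """
    n = len(points)
    adj = [
        {j for j in range(n) if j != i and np.linalg.norm(points[i] - points[j]) <= eps}
        for i in range(n)
    ]
    seen: set[int] = set()
    comps = []
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nb in adj[node]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        comps.append(comp)
    return comps


def trimer_oracle(
    pos: np.ndarray,
    pair_max: float = 40.0,
    isolation_radius: float = 60.0,
    angle_max: float = 120.0,
) -> set[frozenset[int]]:
    """Exhaustive enumeration of all accepted site triples.

    Checks every C(n, 3) triple directly against the three rules with the
    package's strictness conventions (pairs strictly < pair_max, neighbours
    reject strictly < isolation_radius, angle strictly < angle_max).
    """
    n = len(pos)
    accepted = set()
    for i, j, k in combinations(range(n), 3):
        d = [
            np.linalg.norm(pos[a] - pos[b])
            for a, b in ((i, j), (i, k), (j, k))
        ]
        if max(d) >= pair_max:
            continue
        members = {i, j, k}
        if any(
            np.linalg.norm(pos[o] - pos[m]) < isolation_radius
            for m in members
            for o in range(n)
            if o not in members
        ):
            continue
        # internal angles via dot products, not the law-of-cosines code path
        pts = [pos[i], pos[j], pos[k]]
        max_angle = 0.0
        for v in range(3):
            a, b = pts[(v + 1) % 3] - pts[v], pts[(v + 2) % 3] - pts[v]
            cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
            max_angle = max(max_angle, np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        if max_angle >= angle_max:
            continue
        accepted.add(frozenset(members))
    return accepted


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_dataset():
    """A modest noisy MINFLUX dataset with ground truth (session-cached)."""
    config = SynthMinfluxConfig(n_trimers=40, seed=11)
    table, truth = generate_minflux_dataset(config)
    return config, table, truth


def make_loc_table(rows: list[dict]) -> pd.DataFrame:
    """Build a localization table from sparse row dicts with sane defaults."""
    defaults = {"tid": 1, "x_nm": 0.0, "y_nm": 0.0, "z_nm": 0.0,
                "cfr": 0.5, "efo": 50.0}
    out = []
    for t, row in enumerate(rows):
        full = dict(defaults, t_s=float(t) * 1e-3)
        full.update(row)
        out.append(full)
    return pd.DataFrame(out, columns=["tid", "x_nm", "y_nm", "z_nm", "cfr", "efo", "t_s"])
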