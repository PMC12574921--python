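"""Shared fixtures: independent oracles and small reusable inputs."""

from __future__ import annotations

import numpy as np
import pytest

from lisnet import PaePrediction, ScreenConfig
from lisnet.scoring import score_predictions


def brute_force_lis_lia(pred: PaePrediction, cutoff: float = 12.0) -> tuple[float, int]:
    """Independent double-loop LIS/LIA oracle over raw matrix indices.

    Walks every (i, j) cell, keeps those spanning the chain boundary
    with PAE strictly below the cutoff, and averages the rescaled
    errors with plain Python arithmetic.
    """
    a = pred.len_a
    side = a + pred.len_b
    vals = []
    for i in range(side):
        for j in range(side):
            in_a_i, in_a_j = i < a, j < a
            if in_a_i != in_a_j:  # spans the chain boundary
                v = float(pred.pae[i, j])
                if v < cutoff:
                    vals.append((cutoff - v) / cutoff)
    if not vals:
        return 0.0, 0
    return sum(vals) / len(vals), len(vals)


def exhaustive_screen(bait, candidates, provider, config=None):
    """All-pairs oracle for the three-round screen.

    Scores every unordered pair among bait and candidates up front,
    then assigns groups by breadth order from the bait over the
    passing-pair graph and re-derives the per-round edges.  Returns
    (groups dict, {(u, v) sorted: round} edge map).
    """
    config = config or ScreenConfig()
    nodes = [bait] + sorted(candidates)
    passing: dict[frozenset, tuple[float, float]] = {}
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            preds = provider(u, v)
            if not preds:
                continue
            s = score_predictions(preds, config.score, pair=tuple(sorted((u, v))))
            if s.passed:
                passing[frozenset((u, v))] = (s.lis, s.lia)

    def hits(c, pool):
        return {m for m in pool if frozenset((c, m)) in passing}

    cands = set(candidates)
    g1 = {c for c in cands if frozenset((bait, c)) in passing}
    failed = cands - g1
    g2 = {c for c in failed if hits(c, g1)}
    remaining = failed - g2
    core = ({bait} if config.include_bait_in_core else set()) | g1 | g2
    g3 = {c for c in remaining if hits(c, core)}

    edges: dict[tuple[str, str], int] = {}
    for c in g1:
        edges[tuple(sorted((bait, c)))] = 1
    for c in g2:
        for m in hits(c, g1):
            edges[tuple(sorted((c, m)))] = 2
    g1l = sorted(g1)
    for i, u in enumerate(g1l):
        for v in g1l[i + 1 :]:
            if frozenset((u, v)) in passing:
                edges[tuple(sorted((u, v)))] = 2
    for c in g3:
        for m in hits(c, core):
            edges[tuple(sorted((c, m)))] = 3
    groups = {"bait": {bait}, "group1": g1, "group2": g2, "group3": g3}
    return groups, edges


def network_edge_map(network) -> dict[tuple[str, str], int]:
    return {
        tuple(sorted((u, v))): d["round"]
        for u, v, d in network.graph.edges(data=True)
    }


@pytest.fixture
def lislia_oracle():
    return brute_force_lis_lia


@pytest.fixture
def screen_oracle():
    return exhaustive_screen


@pytest.fixture
def edge_map():
    return network_edge_map


@pytest.fixture
def worked_prediction() -> PaePrediction:
    """The hand-checked 2+2-chain example: selected inter-chain values
    {3, 6, 9} at cutoff 12, hence LIS 0.5 and LIA 3."""
    pae = np.zeros((4, 4))
    pae[:2, 2:] = [[3.0, 6.0], [9.0, 12.0]]
    pae[2:, :2] = 30.0
    return PaePrediction(pae=pae, len_a=2, len_b=2)


def random_prediction(rng: np.random.Generator) -> PaePrediction:
    la = int(rng.integers(5, 51))
    lb = int(rng.integers(5, 51))
    side = la + lb
    pae = rng.uniform(0, 31.75, (side, side))
    return PaePrediction(pae=pae, len_a=la, len_b=lb)
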