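"""Three-round iterative PPI-network construction.

Starting from a bait and its enrichment-filtered candidate list, pairs
are scored structure-first via a prediction provider (any callable
mapping an unordered protein pair to a list of PAE predictions, or
None when no prediction exists):

Round 1
    the bait is scored against every candidate; passers become
    Group 1 (direct interactors), the rest form the failed set.
Round 2
    every Group 1 member is scored against every failed candidate and
    against every other Group 1 member; a failed candidate passing
    versus at least one Group 1 member becomes Group 2 (a bridging
    interactor), and passing intra-Group-1 pairs add edges without
    adding nodes.
Round 3
    the remaining candidates are scored against the consolidated core
    (bait + Group 1 + Group 2 by default); passers become Group 3
    (tertiary contacts).

Edges are undirected, weighted by LIS, annotated with LIA and the
round of discovery; every retained node is connected to the bait
through passing edges.  Pairs without predictions count as
non-passing (logged) unless ``strict`` is set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import networkx as nx
import pandas as pd

from .enrichment import CandidateSet
from .errors import FormatError, MissingPredictionError
from .scoring import InteractionScore, PaePrediction, ScoreConfig, score_predictions

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionProvider",
    "ScreenConfig",
    "PpiNetwork",
    "round1",
    "round2",
    "round3",
    "run_screen",
    "export_network",
    "read_network",
    "DirectoryPredictionProvider",
]

#: contract: provider(a, b) -> list[PaePrediction] | None, symmetric in
#: pair order and repeatable.
PredictionProvider = Callable[[str, str], "list[PaePrediction] | None"]

GROUPS = ("bait", "group1", "group2", "group3")


@dataclass(frozen=True)
class ScreenConfig:
    """Screen-level policy around a :class:`ScoreConfig`."""

    score: ScoreConfig = field(default_factory=ScoreConfig)
    include_bait_in_core: bool = True  # Round-3 core = bait + G1 + G2
    strict: bool = False  # missing predictions: error instead of non-pass


@dataclass
class PpiNetwork:
    """Grouped, LIS-weighted interaction network plus its run manifest."""

    bait: str
    graph: nx.Graph
    config: ScreenConfig
    manifest: dict = field(default_factory=dict)

    @property
    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {g: set() for g in GROUPS}
        for n, data in self.graph.nodes(data=True):
            out[data["group"]].add(n)
        return out

    def validate(self) -> None:
        """Check the structural invariants; raises FormatError on violation."""
        groups = self.groups
        if groups["bait"] != {self.bait}:
            raise FormatError("network must contain exactly one bait node")
        for n in self.graph.nodes:
            if n != self.bait and self.graph.degree(n) == 0:
                raise FormatError(f"non-bait node {n!r} has no edge")
        for u, v, data in self.graph.edges(data=True):
            if not (
                data["lis"] >= self.config.score.tau_lis
                and data["lia"] >= self.config.score.tau_lia
            ):
                raise FormatError(f"edge ({u},{v}) fails the snapshot thresholds")
        if self.graph.number_of_nodes() > 1 and not nx.is_connected(self.graph):
            raise FormatError("every node must connect to the bait")


def _score_pair_cached(
    cache: dict[frozenset[str], InteractionScore | None],
    provider: PredictionProvider,
    a: str,
    b: str,
    config: ScreenConfig,
    skipped: list[tuple[str, str]],
) -> InteractionScore | None:
    """Score one unordered pair through the provider, with caching.

    Returns None (and records the skip) when the provider has no
    predictions, unless the strict policy is on.
    """
    key = frozenset((a, b))
    if key in cache:
        return cache[key]
    preds = provider(a, b)
    if preds is None or len(preds) == 0:
        if config.strict:
            raise MissingPredictionError(f"no predictions for pair ({a}, {b})")
        logger.warning("no predictions for pair (%s, %s); treated as non-passing", a, b)
        skipped.append(tuple(sorted((a, b))))
        cache[key] = None
        return None
    score = score_predictions(preds, config.score, pair=tuple(sorted((a, b))))
    cache[key] = score
    return score


def _candidate_ids(candidates: CandidateSet | Iterable[str]) -> tuple[str, ...]:
    if isinstance(candidates, CandidateSet):
        ids = candidates.prey_ids
    else:
        ids = tuple(candidates)
    return tuple(sorted(ids))


Edge = tuple[str, str, float, float, int]  # u, v, lis, lia, round


def round1(
    bait: str,
    candidates: CandidateSet | Iterable[str],
    provider: PredictionProvider,
    config: ScreenConfig | None = None,
    _cache: dict | None = None,
    _skipped: list | None = None,
) -> tuple[set[str], list[Edge], set[str]]:
    """Score the bait against every candidate.

    Returns (group1 nodes, round-1 edges, failed candidates); the two
    candidate sets partition the input.
    """
    config = config or ScreenConfig()
    cache = _cache if _cache is not None else {}
    skipped = _skipped if _skipped is not None else []
    group1: set[str] = set()
    edges: list[Edge] = []
    failed: set[str] = set()
    for cand in _candidate_ids(candidates):
        score = _score_pair_cached(cache, provider, bait, cand, config, skipped)
        if score is not None and score.passed:
            group1.add(cand)
            edges.append((bait, cand, score.lis, score.lia, 1))
        else:
            failed.add(cand)
    return group1, edges, failed


def round2(
    group1: set[str],
    failed: set[str],
    provider: PredictionProvider,
    config: ScreenConfig | None = None,
    _cache: dict | None = None,
    _skipped: list | None = None,
) -> tuple[set[str], list[Edge]]:
    """Screen Group 1 against the failed set and against itself.

    A failed candidate passing versus >= 1 Group 1 member becomes
    Group 2 with an edge to every passing partner; passing
    intra-Group-1 pairs add edges but no nodes.  Rescued candidates
    are not re-used as screening partners within the round.
    """
    config = config or ScreenConfig()
    cache = _cache if _cache is not None else {}
    skipped = _skipped if _skipped is not None else []
    group2: set[str] = set()
    edges: list[Edge] = []
    g1 = sorted(group1)
    for cand in sorted(failed):
        for partner in g1:
            score = _score_pair_cached(cache, provider, partner, cand, config, skipped)
            if score is not None and score.passed:
                group2.add(cand)
                edges.append((partner, cand, score.lis, score.lia, 2))
    for i, u in enumerate(g1):
        for v in g1[i + 1 :]:
            score = _score_pair_cached(cache, provider, u, v, config, skipped)
            if score is not None and score.passed:
                edges.append((u, v, score.lis, score.lia, 2))
    return group2, edges


def round3(
    remaining: set[str],
    core_set: Sequence[str],
    provider: PredictionProvider,
    config: ScreenConfig | None = None,
    _cache: dict | None = None,
    _skipped: list | None = None,
) -> tuple[set[str], list[Edge]]:
    """Score the remaining candidates against the consolidated core.

    Passers become Group 3, with edges to all passing core partners.
    """
    config = config or ScreenConfig()
    cache = _cache if _cache is not None else {}
    skipped = _skipped if _skipped is not None else []
    group3: set[str] = set()
    edges: list[Edge] = []
    core = sorted(core_set)
    for cand in sorted(remaining):
        for partner in core:
            score = _score_pair_cached(cache, provider, partner, cand, config, skipped)
            if score is not None and score.passed:
                group3.add(cand)
                edges.append((partner, cand, score.lis, score.lia, 3))
    return group3, edges


def run_screen(
    bait: str,
    candidates: CandidateSet | Iterable[str],
    provider: PredictionProvider,
    config: ScreenConfig | None = None,
) -> PpiNetwork:
    """Execute the three rounds and assemble the grouped network.

    The manifest records the configuration snapshot, per-round node
    and edge counts, the number of pair evaluations, and any pairs
    skipped for missing predictions; identical inputs give identical
    manifests.
    """
    config = config or ScreenConfig()
    cand_ids = _candidate_ids(candidates)
    cache: dict[frozenset[str], InteractionScore | None] = {}
    skipped: list[tuple[str, str]] = []

    group1, e1, failed = round1(bait, cand_ids, provider, config, cache, skipped)
    group2, e2 = round2(group1, failed, provider, config, cache, skipped)
    remaining = set(cand_ids) - group1 - group2
    core = ({bait} if config.include_bait_in_core else set()) | group1 | group2
    group3, e3 = round3(remaining, core, provider, config, cache, skipped)

    graph = nx.Graph()
    graph.add_node(bait, group="bait")
    for n in sorted(group1):
        graph.add_node(n, group="group1")
    for n in sorted(group2):
        graph.add_node(n, group="group2")
    for n in sorted(group3):
        graph.add_node(n, group="group3")
    for u, v, lis, lia, rnd in e1 + e2 + e3:
        graph.add_edge(u, v, lis=float(lis), lia=float(lia), round=int(rnd), weight=float(lis))

    manifest = {
        "bait": bait,
        "n_candidates": len(cand_ids),
        "candidates": list(cand_ids),
        "config": {
            "score": asdict(config.score),
            "include_bait_in_core": config.include_bait_in_core,
            "strict": config.strict,
        },
        "rounds": {
            "1": {"nodes": sorted(group1), "n_edges": len(e1)},
            "2": {"nodes": sorted(group2), "n_edges": len(e2)},
            "3": {"nodes": sorted(group3), "n_edges": len(e3)},
        },
        "n_pair_evaluations": len(cache),
        "skipped_pairs": sorted(skipped),
    }
    net = PpiNetwork(bait=bait, graph=graph, config=config, manifest=manifest)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# import / export


def export_network(network: PpiNetwork, path: str | Path, format: str | None = None) -> Path:
    """Write the network as GraphML, SIF or a single TSV.

    GraphML and TSV round-trip losslessly (node groups, edge
    lis/lia/round and the LIS edge weight all survive); SIF is a plain
    ``u pp v`` relation list for viewer import.  The format defaults
    to the file extension.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "sif":
        lines = [f"{u}\tpp\t{v}" for u, v in sorted(network.graph.edges)]
        isolated = [n for n in sorted(network.graph.nodes) if network.graph.degree(n) == 0]
        lines.extend(isolated)
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt in ("tsv", "txt"):
        rows = [
            {"record": "node", "u": n, "v": "", "group": d["group"],
             "lis": "", "lia": "", "round": ""}
            for n, d in sorted(network.graph.nodes(data=True))
        ]
        rows += [
            {"record": "edge", "u": u, "v": v, "group": "",
             "lis": d["lis"], "lia": d["lia"], "round": d["round"]}
            for u, v, d in sorted(network.graph.edges(data=True), key=lambda e: (e[0], e[1]))
        ]
        pd.DataFrame(rows, columns=["record", "u", "v", "group", "lis", "lia", "round"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def read_network(
    path: str | Path, config: ScreenConfig | None = None, format: str | None = None
) -> PpiNetwork:
    """Re-import a GraphML or TSV export into a PpiNetwork."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    graph = nx.Graph()
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        for n, d in raw.nodes(data=True):
            graph.add_node(n, group=d["group"])
        for u, v, d in raw.edges(data=True):
            graph.add_edge(u, v, lis=float(d["lis"]), lia=float(d["lia"]),
                           round=int(d["round"]), weight=float(d["weight"]))
    elif fmt in ("tsv", "txt"):
        df = pd.read_csv(path, sep="\t", dtype={"u": str, "v": str})
        for r in df[df["record"] == "node"].itertuples():
            graph.add_node(r.u, group=r.group)
        for r in df[df["record"] == "edge"].itertuples():
            graph.add_edge(r.u, r.v, lis=float(r.lis), lia=float(r.lia),
                           round=int(r.round), weight=float(r.lis))
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    baits = [n for n, d in graph.nodes(data=True) if d["group"] == "bait"]
    if len(baits) != 1:
        raise FormatError("imported network must contain exactly one bait node")
    return PpiNetwork(bait=baits[0], graph=graph, config=config or ScreenConfig())


def write_manifest(network: PpiNetwork, path: str | Path) -> Path:
    """Serialise the run manifest as deterministic (sorted-key) JSON."""
    path = Path(path)
    path.write_text(json.dumps(network.manifest, indent=2, sort_keys=True) + "\n")
    return path


class DirectoryPredictionProvider:
    """Prediction provider over a directory of AlphaFold-style PAE files.

    Layout: one subdirectory per pair named ``<A>__<B>`` (ids in sorted
    order) holding one JSON file per model; flat files named
    ``<A>__<B>*.json`` are also accepted.  Returns None for pairs with
    no files.
    """

    def __init__(self, root: str | Path) -> None:
        self.root = Path(root)

    def __call__(self, a: str, b: str) -> list[PaePrediction] | None:
        from .paeio import read_pae_file

        u, v = sorted((a, b))
        pair_dir = self.root / f"{u}__{v}"
        files: list[Path] = []
        if pair_dir.is_dir():
            files = sorted(pair_dir.glob("*.json"))
            files = [f for f in files if not f.name.endswith(".chains.json")]
        else:
            files = sorted(
                f for f in self.root.glob(f"{u}__{v}*.json")
                if not f.name.endswith(".chains.json")
            )
        if not files:
            return None
        return [read_pae_file(f) for f in files]
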