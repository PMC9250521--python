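"""Prediction over protein non-interaction (PPNI) / interaction networks.

A network is an undirected graph whose nodes are proteins with a ``core``
or ``satellite`` role (taken from input annotation, never inferred) and
whose edges are candidate pairs carrying an optional curated ``true_label``
plus, after prediction, a ``predicted_label`` and ``score``.  Three
topologies are of interest: a one-core star (one hub non-interacting with
its satellites), a multiple-core pathway of overlapping stars, and a
general crossing network.

Supported operations: annotate every edge with a trained classifier's
prediction, score per-network accuracy, retrain after moving a fraction of
core-protein edges (with their curated labels) into the training set —
emulating the arrival of new experimental evidence — and export to Pajek
``.net`` format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import features, models, pairs
from .seqio import GeneSequence, ProteinPair, sequence_index

ROLES = ("core", "satellite")


@dataclass
class NetworkGraph:
    """An undirected protein network with role-annotated nodes."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_pairs(cls, edge_pairs: Iterable[ProteinPair],
                   core_ids: Iterable[str] = ()) -> "NetworkGraph":
        g = nx.Graph()
        core = set(core_ids)
        for p in edge_pairs:
            a, b = p.key()
            if g.has_edge(a, b):
                raise ValueError(f"duplicate unordered edge ({a}, {b})")
            g.add_edge(a, b, true_label=p.label, predicted_label=None, score=None)
        for n in g.nodes:
            g.nodes[n]["role"] = "core" if n in core else "satellite"
        return cls(graph=g)

    @classmethod
    def from_edge_tsv(cls, path: str | Path,
                      core_ids: Iterable[str] = ()) -> "NetworkGraph":
        from .seqio import read_pair_table
        return cls.from_pairs(read_pair_table(path), core_ids)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, dict]]:
        """Edges in canonical (sorted-endpoint, sorted-edge) order."""
        out = [(min(u, v), max(u, v), d) for u, v, d in self.graph.edges(data=True)]
        return sorted(out, key=lambda e: (e[0], e[1]))

    def core_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("role") == "core")


def predict_network(model: models.TrainedModel, net: NetworkGraph,
                    sequences: Sequence[GeneSequence], variant: str = "NVDT",
                    scheme: str = "Cod5") -> NetworkGraph:
    """Annotate every edge with the classifier's score and predicted label.

    Equivalent to applying :func:`nvdt.models.predict` to each edge's
    encoded pair feature; edge input order is immaterial.  Raises when any
    node lacks a sequence.
    """
    idx = sequence_index(sequences)
    missing = sorted(n for n in net.graph.nodes if n not in idx)
    if missing:
        raise KeyError(f"no sequence for network node(s): {', '.join(missing)}")
    edge_list = net.edges()
    if not edge_list:
        return net
    feats = features.feature_matrix([idx[n] for n in net.nodes], variant=variant)
    edge_pairs = [ProteinPair(a, b) for a, b, _ in edge_list]
    mat = pairs.pair_feature_matrix(edge_pairs, feats, scheme=scheme)
    X = mat[[c for c in mat.columns if c.startswith("f")]].to_numpy(dtype=np.float64)
    labels, scores = models.predict(model, X)
    for (a, b, _), lab, sc in zip(edge_list, labels, scores):
        net.graph.edges[a, b]["predicted_label"] = int(lab)
        net.graph.edges[a, b]["score"] = float(sc)
    return net


def network_accuracy(net: NetworkGraph) -> tuple[float, pd.DataFrame]:
    """Fraction of edges predicted correctly, plus a per-edge table.

    The table's ``correct`` column partitions edges into the
    correctly/falsely predicted classes.  Requires both labels on every
    edge.
    """
    rows = []
    for a, b, d in net.edges():
        if d.get("true_label") is None or d.get("predicted_label") is None:
            raise ValueError(f"edge ({a}, {b}) lacks a true or predicted label")
        rows.append({
            "id_a": a, "id_b": b,
            "true_label": d["true_label"],
            "predicted_label": d["predicted_label"],
            "score": d.get("score"),
            "correct": d["true_label"] == d["predicted_label"],
        })
    if not rows:
        raise ValueError("network has no edges to score")
    table = pd.DataFrame(rows)
    return float(table["correct"].mean()), table


def augment_and_retrain(spec: models.ModelSpec,
                        sequences: Sequence[GeneSequence],
                        base_training_pairs: list[ProteinPair],
                        net: NetworkGraph, fraction: float, seed: int = 0,
                        variant: str = "NVDT", scheme: str = "Cod5"
                        ) -> tuple[models.TrainedModel, float]:
    """Move a seeded random fraction of each core protein's edges into
    training, retrain, and score the remaining edges.

    Emulates adding newly measured (non-)interaction evidence for core
    proteins; returns the retrained model and the accuracy on the edges
    that stayed in the evaluation set.  ``fraction=0`` is the no-op
    baseline.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    moved: set[tuple[str, str]] = set()
    for core in net.core_nodes():
        incident = sorted(
            (min(core, nb), max(core, nb)) for nb in net.graph.neighbors(core)
        )
        n_move = round(fraction * len(incident))
        if n_move:
            chosen = rng.choice(len(incident), size=n_move, replace=False)
            moved.update(incident[i] for i in sorted(chosen))
    remaining = [(a, b, d) for a, b, d in net.edges() if (a, b) not in moved]
    if not remaining:
        raise ValueError("augmentation fraction removed every evaluation edge")
    extra = [ProteinPair(a, b, net.graph.edges[a, b]["true_label"])
             for a, b in sorted(moved)]
    if any(p.label is None for p in extra):
        raise ValueError("moved edges must carry true labels")

    idx = sequence_index(sequences)
    all_pairs = base_training_pairs + extra
    feats = features.feature_matrix(
        [idx[i] for i in sorted({q for p in all_pairs for q in (p.id_a, p.id_b)}
                                | set(net.graph.nodes))],
        variant=variant)
    Xtr, ytr = pairs.split_xy(pairs.pair_feature_matrix(all_pairs, feats, scheme=scheme))
    model = models.train(Xtr, ytr, spec)

    eval_net = NetworkGraph.from_pairs(
        [ProteinPair(a, b, d["true_label"]) for a, b, d in remaining],
        core_ids=net.core_nodes())
    predict_network(model, eval_net, sequences, variant=variant, scheme=scheme)
    acc, _ = network_accuracy(eval_net)
    return model, acc


def export_pajek(net: NetworkGraph, path: str | Path) -> None:
    """Write the network as a Pajek ``.net`` file.

    ``*Vertices`` lists 1-based contiguous vertex numbers with quoted
    labels; ``*Edges`` lines carry an edge value encoding prediction
    correctness (1 = correct, 2 = false, 0 = not scored).
    """
    nodes = net.nodes
    number = {n: i + 1 for i, n in enumerate(nodes)}
    with open(path, "w") as fh:
        fh.write(f"*Vertices {len(nodes)}\n")
        for n in nodes:
            fh.write(f'{number[n]} "{n}"\n')
        fh.write("*Edges\n")
        for a, b, d in net.edges():
            t, p = d.get("true_label"), d.get("predicted_label")
            value = 0 if t is None or p is None else (1 if t == p else 2)
            fh.write(f"{number[a]} {number[b]} {value}\n")


def write_edge_table(net: NetworkGraph, path: str | Path) -> None:
    """Annotated edge list as TSV (true/predicted labels and scores)."""
    rows = []
    for a, b, d in net.edges():
        rows.append({"id_a": a, "id_b": b,
                     "true_label": d.get("true_label"),
                     "predicted_label": d.get("predicted_label"),
                     "score": d.get("score")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
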