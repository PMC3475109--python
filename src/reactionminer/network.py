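"""Aggregation of extracted reactions into a pathway network.

Reactions that are identical after name normalization (same enzyme key,
same substrate key-set, same product key-set) merge into one network
reaction whose count records how many times it was extracted from the
source texts. The network renders as a directed graph in which a
reaction with an enzyme contributes a substrate→enzyme and an
enzyme→product arrow pair, and an enzyme-less reaction a direct
substrate→product arrow.

Identity is defined by surface normalization plus an optional
user-supplied synonym map — no ontology grounding is attempted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .extract import Reaction

__all__ = [
    "NetworkReaction",
    "ReactionNetwork",
    "normalize_name",
    "aggregate",
    "export_network",
    "read_network_tsv",
    "read_synonym_map",
]


def normalize_name(
    surface: str, synonym_map: Optional[Mapping[str, str]] = None
) -> str:
    """Lowercase, collapse whitespace, strip trailing punctuation, then
    apply the synonym map (to a fixed point, so the map may chain)."""

    def base(s: str) -> str:
        return " ".join(s.split()).lower().rstrip(".,;:!?")

    key = base(surface)
    if synonym_map:
        normalized_map = {base(k): base(v) for k, v in synonym_map.items()}
        seen = set()
        while key in normalized_map and key not in seen:
            seen.add(key)
            key = normalized_map[key]
    return key


@dataclass(frozen=True)
class NetworkReaction:
    enzyme: Optional[str]
    substrates: frozenset
    products: frozenset

    def as_row(self) -> tuple:
        return (self.enzyme or "",
                ";".join(sorted(self.substrates)),
                ";".join(sorted(self.products)))


@dataclass
class ReactionNetwork:
    """Aggregated reactions with occurrence counts and evidence."""

    reactions: dict = field(default_factory=dict)
    # NetworkReaction -> list[(doc_id, sent_index)]

    def count(self, reaction: NetworkReaction) -> int:
        return len(self.reactions[reaction])

    @property
    def total_count(self) -> int:
        return sum(len(v) for v in self.reactions.values())

    def to_graph(self) -> nx.DiGraph:
        """Directed graph with node attribute ``kind`` and edge
        attributes ``count`` (number of supporting evidence records) and
        ``role`` (substrate / product / reaction)."""
        g = nx.DiGraph()
        kinds: dict[str, set] = {}
        edges: dict[tuple, list] = {}
        for nr, evidence in self.reactions.items():
            participants = [(m, "metabolite") for m in nr.substrates]
            participants += [(m, "metabolite") for m in nr.products]
            if nr.enzyme:
                participants.append((nr.enzyme, "enzyme"))
            for name, kind in participants:
                kinds.setdefault(name, set()).add(kind)
            if nr.enzyme:
                for s in nr.substrates:
                    edges.setdefault((s, nr.enzyme, "substrate"), []).extend(evidence)
                for p in nr.products:
                    edges.setdefault((nr.enzyme, p, "product"), []).extend(evidence)
            else:
                for s in nr.substrates:
                    for p in nr.products:
                        edges.setdefault((s, p, "reaction"), []).extend(evidence)
        for name in sorted(kinds):
            ks = kinds[name]
            g.add_node(name, kind="both" if len(ks) > 1 else next(iter(ks)))
        for (u, v, role), evidence in sorted(edges.items()):
            g.add_edge(u, v, role=role, count=len(evidence),
                       evidence=";".join(f"{d}:{s}" for d, s in evidence))
        return g


def aggregate(
    reactions: Iterable[Reaction],
    synonym_map: Optional[Mapping[str, str]] = None,
) -> ReactionNetwork:
    """Merge identically-normalized reactions, counting occurrences."""
    network = ReactionNetwork()
    for r in reactions:
        nr = NetworkReaction(
            enzyme=(normalize_name(r.enzyme_name, synonym_map)
                    if r.enzyme_name else None),
            substrates=frozenset(normalize_name(s, synonym_map)
                                 for s in r.substrate_names),
            products=frozenset(normalize_name(p, synonym_map)
                               for p in r.product_names),
        )
        network.reactions.setdefault(nr, []).append((r.doc_id, r.sent_index))
    for evidence in network.reactions.values():
        evidence.sort()
    return network


_TSV_HEADER = ["enzyme", "substrates", "products", "count", "evidence"]


def export_network(
    network: ReactionNetwork, path: str, fmt: str = "graphml"
) -> None:
    """Write the network as GraphML (graph view) or TSV (reaction table).

    Output is byte-stable for a given network: rows and graph elements
    are emitted in sorted order.
    """
    if fmt == "graphml":
        nx.write_graphml(network.to_graph(), path)
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_HEADER)
            for nr in sorted(network.reactions, key=lambda r: r.as_row()):
                evidence = network.reactions[nr]
                writer.writerow(
                    list(nr.as_row())
                    + [str(len(evidence)),
                       ";".join(f"{d}:{s}" for d, s in evidence)]
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network_tsv(path: str) -> ReactionNetwork:
    """Read back a TSV reaction table written by :func:`export_network`."""
    network = ReactionNetwork()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _TSV_HEADER:
            raise ValueError(f"bad network TSV header: {header!r}")
        for row in reader:
            enzyme, substrates, products, count, evidence = row
            nr = NetworkReaction(
                enzyme=enzyme or None,
                substrates=frozenset(substrates.split(";")),
                products=frozenset(products.split(";")),
            )
            records = []
            for item in evidence.split(";") if evidence else []:
                doc_id, sent = item.rsplit(":", 1)
                records.append((doc_id, int(sent)))
            if len(records) != int(count):
                raise ValueError(f"count/evidence mismatch in row {row!r}")
            network.reactions[nr] = records
    return network


def read_synonym_map(path: str) -> dict[str, str]:
    """Two-column TSV: variant <tab> canonical name."""
    out = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"synonym rows need 2 columns: {row!r}")
            out[row[0]] = row[1]
    return out
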