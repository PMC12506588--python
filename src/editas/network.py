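"""RES-RBP-AS triplet network assembly.

A triplet (editing site, RBP, AS event) requires all three evidence layers:

1. the site alters the RBP's motif score (|relative delta| > 20 %),
2. an eCLIP-style peak of that RBP overlaps the event's regulatory region
   (defining coordinates extended by a flank, default 300 nt), and
3. the site-event pair shows a significant editing-PSI correlation
   (|r| > 0.5, p < 0.05).

The network is tripartite: RES->RBP and RBP->AS edges, each belonging to at
least one triplet.  Hubs are ranked by degree with lexicographic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import UserInputError
from .io import GenomicInterval
from .splicing import ASEvent

DEFAULT_FLANK = 300


@dataclass(frozen=True)
class Triplet:
    site_id: str
    rbp: str
    event_id: str


def rbp_event_links(
    peaks_by_rbp: dict[str, list[GenomicInterval]],
    events: list[ASEvent],
    flank: int = DEFAULT_FLANK,
) -> set[tuple[str, str]]:
    """(rbp, event_id) pairs whose peak overlaps the event region +/- flank."""
    links: set[tuple[str, str]] = set()
    for ev in events:
        lo = max(1, min(ev.coords) - flank)
        hi = max(ev.coords) + flank
        region = GenomicInterval(ev.chrom, lo, hi)
        for rbp, peaks in peaks_by_rbp.items():
            if any(region.overlaps(p) for p in peaks):
                links.add((rbp, ev.event_id))
    return links


def build_triplets(
    binding_deltas: pd.DataFrame,
    links: set[tuple[str, str]],
    significant_pairs: pd.DataFrame,
) -> list[Triplet]:
    """Conjunction of the three filtered evidence layers, deduplicated and
    sorted by (site, rbp, event).

    ``binding_deltas`` must already be filtered/flagged (``altered`` column);
    ``significant_pairs`` is the filtered site-event correlation table.
    """
    altered = binding_deltas[binding_deltas["altered"].astype(bool)]
    site_rbp = set(zip(altered["site_id"], altered["rbp"]))
    site_event = set(
        zip(significant_pairs["site_id"], significant_pairs["event_id"])
    )
    out = {
        Triplet(s, b, e)
        for (s, b) in site_rbp
        for (b2, e) in links
        if b2 == b and (s, e) in site_event
    }
    return sorted(out, key=lambda t: (t.site_id, t.rbp, t.event_id))


def build_network(triplets: list[Triplet]) -> nx.Graph:
    """Tripartite graph with RES->RBP and RBP->AS edges carrying the ids of
    the triplets they support."""
    g = nx.Graph()
    for t in triplets:
        g.add_node(t.site_id, kind="RES")
        g.add_node(t.rbp, kind="RBP")
        g.add_node(t.event_id, kind="AS")
        for u, v in ((t.site_id, t.rbp), (t.rbp, t.event_id)):
            if g.has_edge(u, v):
                g[u][v]["n_triplets"] += 1
            else:
                g.add_edge(u, v, n_triplets=1)
    return g


def hub_degrees(g: nx.Graph, top_k: int | None = None) -> pd.DataFrame:
    """Nodes ranked by degree (descending), ties lexicographic."""
    rows = sorted(
        ((n, g.nodes[n].get("kind", "?"), d) for n, d in g.degree()),
        key=lambda r: (-r[2], r[0]),
    )
    df = pd.DataFrame(rows, columns=["node", "kind", "degree"])
    return df.head(top_k) if top_k else df


def export_network(g: nx.Graph, path: str | Path, fmt: str = "edge-list") -> None:
    """Write the network as a TSV edge list or GraphML."""
    path = Path(path)
    if fmt == "edge-list":
        order = {"RES": 0, "RBP": 1, "AS": 2}

        def canonical(u, v):
            ku = order.get(g.nodes[u].get("kind", "?"), 9)
            kv = order.get(g.nodes[v].get("kind", "?"), 9)
            return (u, v) if (ku, u) <= (kv, v) else (v, u)

        rows = [
            {
                "source": u, "target": v,
                "source_kind": g.nodes[u].get("kind", "?"),
                "target_kind": g.nodes[v].get("kind", "?"),
                "n_triplets": data.get("n_triplets", 1),
            }
            for (u, v), data in sorted(
                (canonical(a, b), data) for a, b, data in g.edges(data=True)
            )
        ]
        pd.DataFrame(
            rows, columns=["source", "target", "source_kind", "target_kind",
                           "n_triplets"]
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise UserInputError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str = "edge-list") -> nx.Graph:
    path = Path(path)
    if fmt == "edge-list":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_node(row["source"], kind=row["source_kind"])
            g.add_node(row["target"], kind=row["target_kind"])
            g.add_edge(row["source"], row["target"],
                       n_triplets=int(row["n_triplets"]))
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise UserInputError(f"unknown network format {fmt!r}")
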