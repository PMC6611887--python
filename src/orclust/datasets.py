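"""Bundled benchmark graphs.

Only Zachary's karate club ships with the package (via networkx); the larger
real-world benchmarks (college football 2000, the 2005 political blogosphere,
the DrugBank 4.1 interaction network) must be supplied by the user as
edge-list/GML/GraphML files.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["karate_club"]


def karate_club() -> nx.Graph:
    """Zachary's karate club as an unweighted simple graph.

    34 members (vertices 0..33), 78 friendships; the classic two-faction
    ground truth is kept in the ``club`` node attribute ('Mr. Hi'/'Officer').
    """
    raw = nx.karate_club_graph()
    g = nx.Graph()
    for v, data in raw.nodes(data=True):
        g.add_node(int(v), club=data.get("club"))
    for u, v in raw.edges():
        g.add_edge(int(u), int(v), weight=1.0)
    return g
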