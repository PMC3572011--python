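"""Ion-binding state graphs: construction, annotation, grouping, export.

A state graph summarises a site-occupancy trajectory: each node is an
ion-binding state (e.g. ``"K:0:2:4"``) with its visit statistics, and each
directed edge counts the observed frame-to-frame transitions between two
states.  Node size in the customary rendering is the log existence
probability — here ``log_existence_probability = ln(lifetime_fraction)``,
stored as a node attribute.  Edges are typed by what the transition does to
the ion count and at which mouth it does it: association from the
intracellular bulk (entry at S6/S5), association from the extracellular
bulk (entry at S0/S1), dissociation to either side, or an internal
rearrangement at constant ion count.

Graphs export to GraphML (Cytoscape-loadable) and DOT.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .occupancy import EXTRACELLULAR, INTRACELLULAR, SiteTrajectory
from .states import (
    GROUP_II,
    GROUP_IIIE,
    GROUP_IIIR,
    GROUP_IV,
    GROUP_OTHER,
    classify_group,
    parse_label,
)

__all__ = [
    "StateGraph",
    "build_state_graph",
    "annotate_edges",
    "simplify_graph",
    "export_graph",
    "import_graphml",
    "stationarity_check",
    "occupancy_histogram",
    "flow_imbalance",
]

EDGE_TYPES = (
    "association_in",
    "association_out",
    "dissociation_out",
    "dissociation_in",
    "internal",
    "composite",
)


@dataclass
class StateGraph:
    """Directed graph of occupancy states with visit and transition counts."""

    graph: nx.DiGraph
    total_frames: int

    @property
    def n_states(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def lifetime_fraction(self, label: str) -> float:
        return self.graph.nodes[label]["lifetime_fraction"]

    def node_table(self) -> pd.DataFrame:
        rows = [
            (
                lab,
                d["visit_frames"],
                d["lifetime_fraction"],
                d["log_existence_probability"],
                d.get("group", ""),
            )
            for lab, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "label",
                "visit_frames",
                "lifetime_fraction",
                "log_existence_probability",
                "group",
            ],
        ).sort_values("lifetime_fraction", ascending=False, ignore_index=True)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["count"], d.get("type", ""))
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count", "type"]).sort_values(
            "count", ascending=False, ignore_index=True
        )


def _transition_detail(frame_a, frame_b, species: str = "K"):
    """(entered, left) ion records between two frames, for edge typing."""
    a_ids = {i for i, b in frame_a.items() if b.species == species}
    b_ids = {i for i, b in frame_b.items() if b.species == species}
    entered = [(i, frame_b[i].site, frame_b[i].provenance) for i in b_ids - a_ids]
    left = [(i, frame_a[i].site, frame_a[i].provenance) for i in a_ids - b_ids]
    return entered, left


def build_state_graph(
    traj: SiteTrajectory,
    species: str = "K",
    group_overrides: dict[str, str] | None = None,
) -> StateGraph:
    """Build the state graph of a trajectory.

    One node per distinct state label, with ``visit_frames``,
    ``lifetime_fraction`` (= visit_frames / total frames) and its natural
    log; one edge per ordered pair of states observed in consecutive
    frames, with the transition count.  Self-transitions accrue to node
    lifetimes, not edges.
    """
    labels = traj.state_labels(species)
    if not labels:
        raise ValueError("empty trajectory")
    g = nx.DiGraph()
    visits = Counter(labels)
    total = len(labels)
    for lab, n in visits.items():
        frac = n / total
        g.add_node(
            lab,
            visit_frames=n,
            lifetime_fraction=frac,
            log_existence_probability=math.log(frac),
            group=classify_group(lab, group_overrides),
        )
    for i in range(len(labels) - 1):
        u, v = labels[i], labels[i + 1]
        if u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["count"] += 1
        else:
            g.add_edge(u, v, count=1, _details=[])
        entered, left = _transition_detail(traj.frames[i], traj.frames[i + 1], species)
        g[u][v]["_details"].append((tuple(entered), tuple(left)))
    return StateGraph(g, total)


def _edge_type(u: str, v: str, details: list) -> str:
    """Type an edge from the labels' ion-count change plus witnessed
    entry/exit sites and provenance."""
    _, su = parse_label(u)
    _, sv = parse_label(v)
    delta = len(sv) - len(su)
    if abs(delta) >= 2:
        return "composite"
    if delta == 0:
        return "internal"
    votes: Counter = Counter()
    for entered, left in details:
        recs = entered if delta == 1 else left
        for _, site, provenance in recs:
            if delta == 1:
                if site in (5, 6) and provenance != EXTRACELLULAR:
                    votes["association_in"] += 1
                elif site in (0, 1) and provenance != INTRACELLULAR:
                    votes["association_out"] += 1
                elif site in (5, 6):
                    votes["association_in"] += 1
                elif site in (0, 1):
                    votes["association_out"] += 1
                else:
                    votes["composite"] += 1
            else:
                if site in (0, 1):
                    votes["dissociation_out"] += 1
                elif site in (5, 6):
                    votes["dissociation_in"] += 1
                else:
                    votes["composite"] += 1
    if not votes:
        # no frame-level witness (e.g. graph loaded from tables): fall back
        # to the multiset difference of the labels
        diff = Counter(sv) - Counter(su) if delta == 1 else Counter(su) - Counter(sv)
        site = next(iter(diff))
        if delta == 1:
            return "association_in" if site >= 3 else "association_out"
        return "dissociation_out" if site <= 3 else "dissociation_in"
    return votes.most_common(1)[0][0]


def annotate_edges(sg: StateGraph) -> StateGraph:
    """Assign a transition type to every edge (in place; returns the graph).

    Edges whose endpoint states differ by two or more ions are flagged
    ``composite`` and excluded from typed statistics.
    """
    n_composite = 0
    for u, v, d in sg.graph.edges(data=True):
        t = _edge_type(u, v, d.get("_details", []))
        d["type"] = t
        if t == "composite":
            n_composite += 1
    if n_composite:
        warnings.warn(
            f"{n_composite} composite edges (>=2-ion change between frames); "
            "excluded from typed statistics"
        )
    return sg


def simplify_graph(sg: StateGraph) -> StateGraph:
    """Merge nodes by mechanistic group (II / IIIr / IIIe / IV / other).

    Lifetime fractions and edge counts are summed; transitions within a
    group are dropped.
    """
    g = nx.DiGraph()
    for lab, d in sg.graph.nodes(data=True):
        grp = d.get("group") or classify_group(lab)
        if g.has_node(grp):
            g.nodes[grp]["visit_frames"] += d["visit_frames"]
            g.nodes[grp]["lifetime_fraction"] += d["lifetime_fraction"]
        else:
            g.add_node(
                grp,
                visit_frames=d["visit_frames"],
                lifetime_fraction=d["lifetime_fraction"],
                group=grp,
            )
    for grp, d in g.nodes(data=True):
        d["log_existence_probability"] = math.log(d["lifetime_fraction"])
    for u, v, d in sg.graph.edges(data=True):
        gu = sg.graph.nodes[u].get("group") or classify_group(u)
        gv = sg.graph.nodes[v].get("group") or classify_group(v)
        if gu == gv:
            continue
        if g.has_edge(gu, gv):
            g[gu][gv]["count"] += d["count"]
        else:
            g.add_edge(gu, gv, count=d["count"])
    return StateGraph(g, sg.total_frames)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_graph(sg: StateGraph, path, format: str = "graphml") -> None:
    """Write the graph as GraphML (Cytoscape-loadable) or DOT."""
    if format == "graphml":
        g = nx.DiGraph()
        for lab, d in sg.graph.nodes(data=True):
            g.add_node(
                lab,
                label=lab,
                visit_frames=int(d["visit_frames"]),
                lifetime_fraction=float(d["lifetime_fraction"]),
                log_existence_probability=float(d["log_existence_probability"]),
                group=str(d.get("group", "")),
            )
        for u, v, d in sg.graph.edges(data=True):
            g.add_edge(u, v, count=int(d["count"]), type=str(d.get("type", "")))
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["digraph states {"]
        for lab, d in sg.graph.nodes(data=True):
            lines.append(
                f'  "{lab}" [lifetime_fraction={d["lifetime_fraction"]:.6g}, '
                f'group="{d.get("group", "")}"];'
            )
        for u, v, d in sg.graph.edges(data=True):
            lines.append(
                f'  "{u}" -> "{v}" [count={d["count"]}, type="{d.get("type", "")}"];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}; use 'graphml' or 'dot'")


def import_graphml(path) -> StateGraph:
    """Read back a GraphML export (attribute-preserving round trip)."""
    g = nx.read_graphml(path)
    out = nx.DiGraph()
    total = 0
    for lab, d in g.nodes(data=True):
        out.add_node(
            lab,
            visit_frames=int(d["visit_frames"]),
            lifetime_fraction=float(d["lifetime_fraction"]),
            log_existence_probability=float(d["log_existence_probability"]),
            group=d.get("group", ""),
        )
        total += int(d["visit_frames"])
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, count=int(d["count"]), type=d.get("type", ""))
    return StateGraph(out, total)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def stationarity_check(
    traj: SiteTrajectory, species: str = "K"
) -> tuple[float, pd.DataFrame]:
    """Stationarity diagnostic: Pearson correlation of per-state log
    existence probabilities between the first and last half of the run.

    Returns (PCC, per-state table over states present in both halves).
    """
    labels = traj.state_labels(species)
    if len(labels) < 2:
        raise ValueError("need at least 2 frames")
    half = len(labels) // 2
    first, last = Counter(labels[:half]), Counter(labels[half:])
    shared = sorted(set(first) & set(last))
    if len(shared) < 2:
        raise ValueError("insufficient overlap: fewer than 2 states in both halves")
    n1, n2 = sum(first.values()), sum(last.values())
    log_p1 = np.log([first[s] / n1 for s in shared])
    log_p2 = np.log([last[s] / n2 for s in shared])
    table = pd.DataFrame(
        {"label": shared, "log_p_first_half": log_p1, "log_p_last_half": log_p2}
    )
    if np.allclose(log_p1, log_p1[0]) or np.allclose(log_p2, log_p2[0]):
        # degenerate: a constant vector correlates perfectly iff the other
        # is constant too
        pcc = 1.0 if np.allclose(log_p1 - log_p1[0], log_p2 - log_p2[0]) else 0.0
    else:
        pcc = float(stats.pearsonr(log_p1, log_p2).statistic)
    return pcc, table


def occupancy_histogram(traj: SiteTrajectory, species: str = "K") -> dict:
    """Fractions of frames with 2, 3, 4, or another number of bound ions."""
    counts = Counter(len(traj.sites_occupied(i, species)) for i in range(len(traj)))
    total = max(1, sum(counts.values()))
    out = {2: 0.0, 3: 0.0, 4: 0.0, "other": 0.0}
    for n, c in counts.items():
        key = n if n in (2, 3, 4) else "other"
        out[key] += c / total
    return out


def flow_imbalance(sg: StateGraph) -> dict[str, int]:
    """Per-node (incoming − outgoing) transition-count imbalance.

    For a graph built from a single trajectory this is −1, 0 or +1
    everywhere (only the first and last visited states can differ).
    """
    out = {}
    for node in sg.graph.nodes:
        inflow = sum(d["count"] for _, _, d in sg.graph.in_edges(node, data=True))
        outflow = sum(d["count"] for _, _, d in sg.graph.out_edges(node, data=True))
        out[node] = inflow - outflow
    return out
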