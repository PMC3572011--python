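"""Conduction cycles: decomposition, one-letter encoding, alignment,
clustering, and mechanism classification.

The trajectory of the pore, viewed as a walk on the ion-binding state
graph, is a series of round trips that leave the resting state K:0:2:4 and
eventually return to it.  Each round trip (a *cyclic path*) is written as a
character string — one letter per visited state, the resting state being
'E' — so that conduction events can be compared by global sequence
alignment and grouped by hierarchical clustering.  Two canonical paths:

* ``"EB310HFE"`` — the outermost ion leaves first and a replacement enters
  later (two-step association/dissociation conduction, via two-ion states);
* ``"EkidKIGE"`` — a fourth ion enters first and pushes the file forward
  (one-step knock-on conduction, via four-ion states).

Mechanism labels are assigned from the groups a cycle visits, not from the
clustering; the clustering is descriptive and reported alongside.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .occupancy import ASSOCIATION_OUT, SiteTrajectory
from .states import GROUP_II, GROUP_IV, RESTING_STATE, classify_group

__all__ = [
    "StateCodeMap",
    "CyclicPath",
    "CycleDecomposition",
    "Scoring",
    "decompose_cycles",
    "encode_path",
    "align_paths",
    "path_distance_matrix",
    "cluster_paths",
    "dendrogram_newick",
    "classify_mechanism",
    "mechanism_ratio",
    "conduction_cycles",
]

#: canonical one-letter codes for the states appearing in the two worked
#: conduction paths
DEFAULT_CODES = {
    "K:0:2:4": "E",
    "K:0:1:3": "B",
    "K:1:3": "3",
    "K:1:2": "1",
    "K:0:2": "0",
    "K:0:2:6": "H",
    "K:0:2:5": "F",
    "K:0:2:4:6": "k",
    "K:0:2:4:5": "i",
    "K:0:1:3:5": "d",
    "K:1:3:5": "K",
    "K:1:3:4": "I",
    "K:1:2:4": "G",
}

KNOCK_ON = "knock_on"
ASSOC_DISSOC = "assoc_dissoc"
BACK_RUNNING = "back_running"
NO_CONDUCTION = "no_conduction"
OTHER = "other"


class StateCodeMap:
    """Bijective state-label ↔ single-character map.

    Seeded with the canonical codes; states without a code receive the next
    unused character from a fixed alphabet in first-appearance order, so the
    extension is deterministic for a given label sequence.
    """

    # ASCII first, then accented Latin and Greek: comfortably more symbols
    # than the 128 possible occupancy states of a 7-site pore
    _ALPHABET = (
        string.ascii_uppercase
        + string.ascii_lowercase
        + string.digits
        + "!#$%&'*+,-./;<=>?@[]^_`{|}~"
        + "".join(chr(c) for c in range(0x00C0, 0x0180))
        + "".join(chr(c) for c in range(0x0391, 0x03CA) if chr(c).isalpha())
    )

    def __init__(self, seed_codes: dict[str, str] | None = None) -> None:
        codes = dict(DEFAULT_CODES if seed_codes is None else seed_codes)
        if len(set(codes.values())) != len(codes):
            raise ValueError("seed codes must be a bijection")
        self._to_char = codes
        self._to_label = {c: lab for lab, c in codes.items()}

    def code(self, label: str) -> str:
        if label not in self._to_char:
            for c in self._ALPHABET:
                if c not in self._to_label:
                    self._to_char[label] = c
                    self._to_label[c] = label
                    break
            else:
                raise ValueError("alphabet exhausted: too many distinct states")
        return self._to_char[label]

    def label(self, char: str) -> str:
        return self._to_label[char]

    def encode(self, labels: Iterable[str]) -> str:
        return "".join(self.code(lab) for lab in labels)

    def items(self):
        return self._to_char.items()


@dataclass
class CyclicPath:
    """A resting-state-to-resting-state excursion.

    ``runs`` holds (state label, start_ps, end_ps) for each maximal run of
    identical consecutive states, including both terminal resting runs.
    """

    runs: list[tuple[str, float, float]]
    encoded: str = ""
    conductions: int = 0
    category: str | None = None

    @property
    def state_sequence(self) -> list[str]:
        return [lab for lab, _, _ in self.runs]

    @property
    def start_ps(self) -> float:
        return self.runs[0][1]

    @property
    def end_ps(self) -> float:
        # the cycle ends where the terminal resting run begins: the next
        # cycle owns the resting dwell
        return self.runs[-1][1]

    @property
    def duration_ps(self) -> float:
        return self.end_ps - self.start_ps


@dataclass
class CycleDecomposition:
    cycles: list[CyclicPath]
    leading_ps: float   # discarded partial segment before the first resting visit
    trailing_ps: float  # from the last resting-run start to the end of data
    n_partial: int

    def __iter__(self):
        return iter(self.cycles)

    def __len__(self):
        return len(self.cycles)


def _runs_from_labels(labels: Sequence[str], times: np.ndarray):
    runs: list[tuple[str, float, float]] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        end = times[j] if j < n else times[n - 1]
        runs.append((labels[i], float(times[i]), float(end)))
        i = j
    return runs


def decompose_cycles(
    traj: SiteTrajectory | Sequence[str],
    times: np.ndarray | None = None,
    resting: str = RESTING_STATE,
) -> CycleDecomposition:
    """Split a state sequence into resting-to-resting cyclic paths.

    Consecutive identical states are collapsed first; a cycle spans from the
    start of one resting run to the start of the next, so cycles tile the
    time between the first and last resting visits.  Leading and trailing
    partial segments are discarded but their durations are reported.
    """
    if isinstance(traj, SiteTrajectory):
        labels = traj.state_labels()
        times = traj.times
    else:
        labels = list(traj)
        if times is None:
            times = np.arange(len(labels), dtype=float)
    if resting not in labels:
        raise ValueError(f"resting state {resting!r} never visited")
    runs = _runs_from_labels(labels, np.asarray(times, dtype=float))

    resting_idx = [i for i, (lab, _, _) in enumerate(runs) if lab == resting]
    cycles: list[CyclicPath] = []
    for a, b in zip(resting_idx[:-1], resting_idx[1:]):
        cycles.append(CyclicPath(runs=runs[a : b + 1]))

    t0, t_end = runs[0][1], runs[-1][2]
    leading = runs[resting_idx[0]][1] - t0
    trailing = t_end - runs[resting_idx[-1]][1]
    n_partial = int(leading > 0) + int(trailing > 0)
    return CycleDecomposition(cycles, leading, trailing, n_partial)


def encode_path(p: CyclicPath, codes: StateCodeMap | None = None) -> str:
    """One character per state run, terminal resting states included."""
    codes = codes or StateCodeMap()
    p.encoded = codes.encode(p.state_sequence)
    return p.encoded


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    """Global-alignment scoring; the default is LCS-like (match-only)."""

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = 0.0


@dataclass(frozen=True)
class Alignment:
    score: float
    aligned_a: str
    aligned_b: str


def align_paths(a: str, b: str, scoring: Scoring | None = None) -> Alignment:
    """Optimal global alignment (Needleman–Wunsch) of two encoded paths.

    Traceback ties break diagonal > up > left, making the reported
    alignment deterministic; the score is tie-free by construction.
    """
    sc = scoring or Scoring()
    n, m = len(a), len(b)
    F = np.empty((n + 1, m + 1))
    F[0, :] = sc.gap * np.arange(m + 1)
    F[:, 0] = sc.gap * np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = F[i - 1, j - 1] + (sc.match if a[i - 1] == b[j - 1] else sc.mismatch)
            up = F[i - 1, j] + sc.gap
            left = F[i, j - 1] + sc.gap
            F[i, j] = max(diag, up, left)
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            diag = F[i - 1, j - 1] + (sc.match if a[i - 1] == b[j - 1] else sc.mismatch)
            if F[i, j] == diag:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and F[i, j] == F[i - 1, j] + sc.gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return Alignment(float(F[n, m]), "".join(reversed(out_a)), "".join(reversed(out_b)))


def path_distance_matrix(
    paths: Sequence[str], scoring: Scoring | None = None
) -> np.ndarray:
    """Pairwise distances d(a,b) = 1 − S(a,b) / max(S(a,a), S(b,b))."""
    if len(paths) < 2:
        raise ValueError("need at least 2 paths")
    sc = scoring or Scoring()
    n = len(paths)
    self_scores = [align_paths(p, p, sc).score for p in paths]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = max(self_scores[i], self_scores[j])
            s = align_paths(paths[i], paths[j], sc).score
            d[i, j] = d[j, i] = 1.0 - s / denom if denom > 0 else 0.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: np.ndarray  # flat cluster ids (1-based, scipy convention)


def cluster_paths(
    d: np.ndarray,
    linkage: str = "average",
    cut: float | None = None,
    n_clusters: int | None = None,
) -> ClusterResult:
    """Agglomerative clustering of the path distance matrix.

    Flat clusters come from ``n_clusters`` if given, else from the
    dendrogram height ``cut`` (default: half the maximum merge height).
    Ties agglomerate in index order (scipy's deterministic behaviour on
    equal distances).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("need a square distance matrix for >= 2 items")
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        if cut is None:
            cut = 0.5 * Z[:, 2].max() if len(Z) else 0.0
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
    return ClusterResult(Z, labels)


def dendrogram_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return str(leaf_names[node.id])
        left, right = walk(node.left), walk(node.right)
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return walk(tree) + ";"


# ---------------------------------------------------------------------------
# mechanism classification
# ---------------------------------------------------------------------------

def classify_mechanism(
    p: CyclicPath,
    group_overrides: dict[str, str] | None = None,
    events: pd.DataFrame | None = None,
) -> str:
    """Mechanism category of a cycle from the groups it visits.

    Conducting cycles: through four-ion states only → ``knock_on``; through
    two-ion states only → ``assoc_dissoc``; both or neither → ``other``.
    Non-conducting cycles that dip to a two-ion state and recover their S0
    ion from the extracellular side → ``back_running``; the rest →
    ``no_conduction``.
    """
    groups = {lab: classify_group(lab, group_overrides) for lab in p.state_sequence}
    visited = set(groups.values())
    if p.conductions == 0:
        if GROUP_II in visited and _extracellular_rebind(p, events):
            category = BACK_RUNNING
        else:
            category = NO_CONDUCTION
    elif GROUP_IV in visited and GROUP_II not in visited:
        category = KNOCK_ON
    elif GROUP_II in visited and GROUP_IV not in visited:
        category = ASSOC_DISSOC
    else:
        category = OTHER
    p.category = category
    return category


def _extracellular_rebind(p: CyclicPath, events: pd.DataFrame | None) -> bool:
    if events is None or not len(events):
        return False
    sel = events[
        (events["event_type"] == ASSOCIATION_OUT)
        & (events["species"] == "K")
        & (events["time_ps"] > p.start_ps)
        & (events["time_ps"] <= p.end_ps + 1e-9)
    ]
    return len(sel) > 0


@dataclass(frozen=True)
class MechanismRatio:
    n_knock_on: int
    n_assoc_dissoc: int
    ratio: float          # knock_on / assoc_dissoc; inf if undefined
    finite: bool

    def __float__(self) -> float:
        return self.ratio


def mechanism_ratio(cycles: Iterable[CyclicPath | str]) -> MechanismRatio:
    """Knock-on over association/dissociation cycle-count ratio."""
    cats = [c.category if isinstance(c, CyclicPath) else c for c in cycles]
    n_ko = sum(1 for c in cats if c == KNOCK_ON)
    n_ad = sum(1 for c in cats if c == ASSOC_DISSOC)
    if n_ad == 0:
        return MechanismRatio(n_ko, n_ad, math.inf if n_ko else math.nan, False)
    return MechanismRatio(n_ko, n_ad, n_ko / n_ad, True)


# ---------------------------------------------------------------------------
# high-level pipeline
# ---------------------------------------------------------------------------

def conduction_cycles(
    traj: SiteTrajectory,
    resting: str = RESTING_STATE,
    codes: StateCodeMap | None = None,
    group_overrides: dict[str, str] | None = None,
) -> CycleDecomposition:
    """Decompose, encode, count conductions and classify in one pass.

    Conduction attribution is by net charge: a cycle's conduction count is
    the number of K+ exits above S0 minus the number of K+ entries from the
    extracellular side within its time span.  The netting is what separates
    a back-running cycle (one ion out, another straight back in from the
    same side — no change to the membrane charge balance) from a genuine
    two-step conduction, where the replacement ion arrives from the
    intracellular bulk.
    """
    from .occupancy import DISSOCIATION_OUT

    decomp = decompose_cycles(traj, resting=resting)
    codes = codes or StateCodeMap()
    ev = traj.events
    k_ev = ev[ev["species"] == "K"] if len(ev) else ev
    exits = (
        k_ev.loc[k_ev["event_type"] == DISSOCIATION_OUT, "time_ps"].to_numpy()
        if len(k_ev)
        else np.empty(0)
    )
    reentries = (
        k_ev.loc[k_ev["event_type"] == ASSOCIATION_OUT, "time_ps"].to_numpy()
        if len(k_ev)
        else np.empty(0)
    )
    for cyc in decomp.cycles:
        encode_path(cyc, codes)
        lo, hi = cyc.start_ps, cyc.end_ps + 1e-9
        net = int(np.sum((exits > lo) & (exits <= hi))) - int(
            np.sum((reentries > lo) & (reentries <= hi))
        )
        cyc.conductions = max(0, net)
        classify_mechanism(cyc, group_overrides, traj.events)
    return decomp


def cycle_table(decomp: CycleDecomposition) -> pd.DataFrame:
    rows = [
        (c.start_ps, c.end_ps, c.encoded, c.category, c.conductions)
        for c in decomp.cycles
    ]
    return pd.DataFrame(
        rows, columns=["start_ps", "end_ps", "encoded", "category", "conductions"]
    )
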