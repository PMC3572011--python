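"""Permeation counting, current arithmetic, passage times, and tests.

Charge transport bookkeeping for single-file pore trajectories: a full
outward permeation is one particle entering from the intracellular bulk and
leaving above S0 (particles already in the pore at t = 0 count from the
trajectory start).  The single-channel current follows directly,
I = N·e / T with e the elementary charge, reported in pA; membrane voltage
under a uniform applied field is V = E·L_z.

Passage times measure how long the pore dwells in a mechanistic group
before an association or dissociation carries it to the next group; their
distributions at different ionic concentrations are compared with the
Wilcoxon rank-sum (Mann–Whitney) test — exact by enumeration for small
tie-free samples, tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .occupancy import (
    ASSOCIATION_IN,
    ASSOCIATION_OUT,
    DISSOCIATION_IN,
    DISSOCIATION_OUT,
    EXTRACELLULAR,
    INTRACELLULAR,
    SiteTrajectory,
)
from .states import RESTING_STATE, classify_group

__all__ = [
    "PermeationEvent",
    "EventDuration",
    "SimulationMeta",
    "ELEMENTARY_CHARGE_C",
    "count_permeations",
    "compute_current",
    "round_sig",
    "membrane_voltage",
    "water_ion_coflow",
    "CoflowRatio",
    "passage_times",
    "compare_distributions",
    "back_running_stats",
]

#: SI exact value
ELEMENTARY_CHARGE_C = 1.602176634e-19

OUTWARD = "outward"
INWARD = "inward"


@dataclass(frozen=True)
class PermeationEvent:
    """One full pore transit by one particle."""

    ion_id: int
    species: str
    direction: str          # outward | inward
    entry_time: float       # ps
    exit_time: float        # ps

    def __post_init__(self) -> None:
        if self.exit_time <= self.entry_time:
            raise ValueError("exit_time must exceed entry_time")


@dataclass(frozen=True)
class EventDuration:
    """Dwell in a group preceding a named group-changing transition."""

    transition: str   # e.g. "IIIr->IV"
    kind: str         # association | dissociation | relaxation
    duration: float   # ps

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


TRANSITION_KINDS = {
    "IIIr->IV": "association",
    "II->IIIe": "association",
    "IIIr->II": "dissociation",
    "IV->IIIe": "dissociation",
    "IIIe->IIIr": "relaxation",
}


@dataclass(frozen=True)
class SimulationMeta:
    """Applied-field metadata of a simulated system."""

    electric_field: float | None = None  # V/m
    box_length: float | None = None      # m (along the field/pore axis)
    duration_ns: float | None = None
    temperature_K: float | None = None


# ---------------------------------------------------------------------------
# permeation and current
# ---------------------------------------------------------------------------

def count_permeations(
    traj: SiteTrajectory,
    species: str = "K",
    window_ps: tuple[float, float] | None = None,
) -> list[PermeationEvent]:
    """Full pore transits, from the trajectory's event log.

    Outward: a particle that entered from the intracellular bulk (or was in
    the pore initially) exits above S0.  Inward: an extracellular entrant
    exits below S6.  A particle that returns to the bulk it came from is
    not a permeation.  ``window_ps`` restricts exits to a half-open time
    window (start, end].
    """
    events = traj.events
    if not len(events):
        return []
    t0 = float(traj.times[0]) if len(traj.times) else 0.0
    out: list[PermeationEvent] = []
    sel = events[events["species"] == species].sort_values(
        "time_ps", kind="stable"
    )
    entry: dict[int, tuple[float, str]] = {}
    # particles bound in the first frame entered "initially"
    if len(traj.frames):
        for ion_id, bound in traj.frames[0].items():
            if bound.species == species:
                entry[ion_id] = (t0, bound.provenance or "initial")
    for row in sel.itertuples(index=False):
        ev = row.event_type
        ion = int(row.ion_id)
        t = float(row.time_ps)
        if ev == ASSOCIATION_IN:
            entry[ion] = (t, INTRACELLULAR)
        elif ev == ASSOCIATION_OUT:
            entry[ion] = (t, EXTRACELLULAR)
        elif ev in (DISSOCIATION_OUT, DISSOCIATION_IN):
            t_in, side = entry.pop(ion, (t0, "initial"))
            if ev == DISSOCIATION_OUT and side != EXTRACELLULAR:
                direction = OUTWARD
            elif ev == DISSOCIATION_IN and side == EXTRACELLULAR:
                direction = INWARD
            else:
                continue
            if window_ps is not None and not (window_ps[0] < t <= window_ps[1]):
                continue
            out.append(
                PermeationEvent(ion, species, direction, min(t_in, t - 1e-9), t)
            )
    return out


def compute_current(
    n_permeations: int, duration_us: float, charge_per_ion: float = 1.0
) -> float:
    """Single-channel current in pA from a permeation count.

    I = N·e/T, exact elementary charge; round at the reporting layer
    (:func:`round_sig`) to match printed two-significant-figure values.
    """
    if duration_us <= 0:
        raise ValueError("duration must be positive")
    coulombs = n_permeations * charge_per_ion * ELEMENTARY_CHARGE_C
    amps = coulombs / (duration_us * 1e-6)
    return amps * 1e12


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def membrane_voltage(meta: SimulationMeta) -> float:
    """Membrane voltage of a uniform applied field: V = E·L_z."""
    if meta.electric_field is None or meta.box_length is None:
        raise ValueError("membrane_voltage needs electric_field and box_length")
    if meta.electric_field <= 0 or meta.box_length <= 0:
        raise ValueError("field and box length must be positive")
    return meta.electric_field * meta.box_length


@dataclass(frozen=True)
class CoflowRatio:
    n_water: int
    n_ions: int
    ratio: float   # nan when undefined (no conducted ions)
    defined: bool


def water_ion_coflow(traj: SiteTrajectory) -> CoflowRatio:
    """Conducted waters per conducted K+ (outward full-pore crossings)."""
    n_k = sum(
        1 for e in count_permeations(traj, "K") if e.direction == OUTWARD
    )
    n_w = sum(
        1 for e in count_permeations(traj, "water") if e.direction == OUTWARD
    )
    if n_k == 0:
        return CoflowRatio(n_w, 0, math.nan, False)
    return CoflowRatio(n_w, n_k, n_w / n_k, True)


# ---------------------------------------------------------------------------
# passage times
# ---------------------------------------------------------------------------

def passage_times(
    cycles: Iterable,
    group_overrides: dict[str, str] | None = None,
) -> list[EventDuration]:
    """Durations of group-changing transitions within each cycle.

    For every realized transition named in :data:`TRANSITION_KINDS`, the
    duration runs from the first entry into the source group (within the
    cycle) to the frame of the group change — the dwell of the whole source
    group, not of its last state.
    """
    out: list[EventDuration] = []
    for cyc in cycles:
        group_runs: list[tuple[str, float, float]] = []
        for lab, start, end in cyc.runs:
            grp = classify_group(lab, group_overrides)
            if group_runs and group_runs[-1][0] == grp:
                prev = group_runs[-1]
                group_runs[-1] = (grp, prev[1], end)
            else:
                group_runs.append((grp, start, end))
        for (g1, s1, e1), (g2, _, _) in zip(group_runs[:-1], group_runs[1:]):
            name = f"{g1}->{g2}"
            kind = TRANSITION_KINDS.get(name)
            if kind is None:
                continue
            if e1 > s1:
                out.append(EventDuration(name, kind, e1 - s1))
    return out


def durations_table(durations: Sequence[EventDuration]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.transition, d.kind, d.duration) for d in durations],
        columns=["transition", "kind", "duration_ps"],
    )


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def _exact_ranksum_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided rank-sum p by dynamic programming over the null
    distribution of the rank sum of sample ``a`` (no ties)."""
    n1, n2 = len(a), len(b)
    N = n1 + n2
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = stats.rankdata(pooled)
    w_obs = int(round(ranks[:n1].sum()))
    # f[k, w] = number of k-subsets of ranks 1..r summing to w
    max_w = N * (N + 1) // 2
    f = np.zeros((n1 + 1, max_w + 1), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            f[k, r:] += f[k - 1, : max_w + 1 - r]
    dist = f[n1]
    total = dist.sum()
    p_le = dist[: w_obs + 1].sum() / total
    p_ge = dist[w_obs:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact (enumerative null) when both samples have at most 8 observations
    and the pooled sample is tie-free; tie-corrected normal approximation
    with continuity correction otherwise.  Degenerate zero-variance input
    (all pooled values equal) returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(a) <= 8 and len(b) <= 8:
        return _exact_ranksum_p(a, b)
    if np.all(pooled == pooled[0]):
        return 1.0
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# back-running occupancy
# ---------------------------------------------------------------------------

def back_running_stats(
    traj: SiteTrajectory, resting: str = RESTING_STATE
) -> float:
    """Fraction of resting-state lifetime with a back-ran S0 ion.

    A resting-state frame counts as back-ran when its S0 occupant entered
    the pore from the extracellular side.
    """
    labels = traj.state_labels()
    resting_frames = [i for i, lab in enumerate(labels) if lab == resting]
    if not resting_frames:
        raise ValueError(f"resting state {resting!r} never visited")
    n_back = 0
    for i in resting_frames:
        occ = traj.occupant_of(i, 0)
        if occ is not None and occ[1].provenance == EXTRACELLULAR:
            n_back += 1
    return n_back / len(resting_frames)
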