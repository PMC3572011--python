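"""Kinetic Monte Carlo simulator of single-file hopping through a 7-site pore.

The pore is modelled as a continuous-time Markov chain on the discrete
binding sites S0–S6 (S0 at the extracellular mouth, S6 the central cavity).
Elementary moves are: entry of a K+ ion from either bulk into the adjacent
mouth site, exit from a mouth site to its bulk, and nearest-neighbour hops —
all under hard single-occupancy exclusion.  Three physical ingredients shape
the kinetics:

* **concentration** scales both association rates linearly (diffusive
  arrival), via :meth:`KMCParams.at_concentration`;
* **membrane voltage** enters as a single multiplicative ``bias`` on every
  outward (toward-S0) move of a charged particle, and its reciprocal on
  inward moves;
* **ion–ion repulsion** penalises moves that create nearest-neighbour ion
  pairs by a factor ``repulsion`` (< 1) per pair created, and boosts moves
  that break pairs by its reciprocal.  This is what stabilises the
  alternating resting configuration K:0:2:4 — without it a non-interacting
  chain under forward bias simply piles ions up at the outer mouth.

At low association rate an ion that leaves S0 is long gone before the next
one arrives (two-step association/dissociation conduction); at high
association rate a fourth ion usually enters while S0 is still occupied and
pushes the file forward (one-step knock-on conduction).  The simulator
therefore reproduces the concentration-driven switch between the two
mechanisms as an emergent property.

Trajectories are realised exactly (Gillespie algorithm), then sampled on a
regular frame grid; the exact event log is attached to the returned
:class:`~poregraph.occupancy.SiteTrajectory` and serves as ground truth for
every downstream statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .occupancy import (
    ASSOCIATION_IN,
    ASSOCIATION_OUT,
    DISSOCIATION_IN,
    DISSOCIATION_OUT,
    EVENT_COLUMNS,
    EXTRACELLULAR,
    HOP,
    INTRACELLULAR,
    Bound,
    SiteTrajectory,
)
from .states import encode_label, parse_label

__all__ = [
    "KMCParams",
    "ScriptedTrajectory",
    "simulate_hopping",
    "scripted_trajectory",
    "render_continuous",
]


@dataclass(frozen=True)
class KMCParams:
    """Rates (1/ns) and geometry of the single-file hopping model.

    Defaults describe the reference condition (nominally 150 mM KCl under a
    depolarising field); use :meth:`at_concentration` to scale the
    association rates to another concentration.
    """

    n_sites: int = 7
    k_assoc_in: float = 0.60    # intracellular bulk -> S6
    k_assoc_out: float = 0.15   # extracellular bulk -> S0
    k_dissoc_out: float = 0.30  # S0 -> extracellular bulk
    k_dissoc_in: float = 0.05   # S6 -> intracellular bulk
    k_hop_fwd: float = 4.0      # hop toward S0
    k_hop_bwd: float = 0.8      # hop toward S6
    bias: float = 1.4           # voltage factor on outward moves of K+
    repulsion: float = 0.1      # per created nearest-neighbour ion pair
    min_ions: int = 2           # K+ dissociation disabled at or below this count
    entry_crowding: float = 0.3  # entry penalty per K+ above min_ions
    frame_interval_ps: float = 20.0
    duration_ns: float = 1000.0
    seed: int = 0
    initial_sites: tuple[int, ...] = (0, 2, 4)
    k_water_in: float = 0.0     # water entry rates; water off by default
    k_water_out: float = 0.0

    def __post_init__(self) -> None:
        rates = (
            self.k_assoc_in, self.k_assoc_out, self.k_dissoc_out, self.k_dissoc_in,
            self.k_hop_fwd, self.k_hop_bwd, self.k_water_in, self.k_water_out,
        )
        if any(r < 0 for r in rates):
            raise ValueError("all rates must be >= 0")
        if self.duration_ns <= 0 or self.frame_interval_ps <= 0:
            raise ValueError("duration and frame interval must be positive")
        if self.bias <= 0:
            raise ValueError("bias must be positive")
        if not 0 < self.repulsion <= 1:
            raise ValueError("repulsion factor must be in (0, 1]")
        if self.min_ions < 0:
            raise ValueError("min_ions must be >= 0")
        if not 0 < self.entry_crowding <= 1:
            raise ValueError("entry_crowding must be in (0, 1]")
        if self.n_sites != 7:
            raise ValueError("the pore model is defined for 7 sites S0..S6")
        if len(set(self.initial_sites)) != len(self.initial_sites):
            raise ValueError("initial sites must be distinct (exclusion)")
        if any(not 0 <= s < self.n_sites for s in self.initial_sites):
            raise ValueError("initial site outside 0..6")

    def at_concentration(self, c_mM: float, reference_mM: float = 150.0) -> "KMCParams":
        """Scale both association rates linearly with concentration."""
        f = c_mM / reference_mM
        return replace(
            self,
            k_assoc_in=self.k_assoc_in * f,
            k_assoc_out=self.k_assoc_out * f,
            k_water_in=self.k_water_in,
            k_water_out=self.k_water_out,
        )


@dataclass(frozen=True)
class ScriptedTrajectory:
    """A deterministic test trajectory given as a sequence of state labels.

    Consecutive states must be reachable by one transition event: every ion
    shifts by at most one site (single-file order preserved, concerted push
    chains allowed), optionally together with one entry or exit at a mouth
    site (S0 extracellular, S6 intracellular).
    """

    states: tuple[str, ...]
    dwell_frames: int = 1
    frame_interval_ps: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 1:
            raise ValueError("script needs at least one state")
        if self.dwell_frames < 1:
            raise ValueError("dwell_frames must be >= 1")
        # validate on construction: building the trajectory raises on an
        # illegal jump, naming the offending step
        scripted_trajectory(self)


# ---------------------------------------------------------------------------
# Gillespie simulation
# ---------------------------------------------------------------------------

_K = "K"
_WATER = "water"


def _adjacency_delta(sites: dict[int, str], ion_site: int, new_site: int | None) -> int:
    """Change in nearest-neighbour K+ pair count when the K+ ion at
    ``ion_site`` moves to ``new_site`` (None = leaves the pore)."""

    def k_neighbours(pos: int, exclude: int) -> int:
        n = 0
        for d in (-1, 1):
            q = pos + d
            if q == exclude:
                continue
            if sites.get(q) == _K:
                n += 1
        return n

    removed = k_neighbours(ion_site, exclude=ion_site)
    created = 0
    if new_site is not None:
        created = k_neighbours(new_site, exclude=ion_site)
    return created - removed


def _entry_adjacency(sites: dict[int, str], entry_site: int) -> int:
    n = 0
    for d in (-1, 1):
        if sites.get(entry_site + d) == _K:
            n += 1
    return n


def simulate_hopping(params: KMCParams) -> SiteTrajectory:
    """Exact stochastic realisation of the hopping model, frame-sampled.

    Returns a :class:`SiteTrajectory` whose frames are snapshots every
    ``frame_interval_ps`` and whose ``events`` table is the exact Gillespie
    event log (times in ps).  Reproducible for a fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_sites

    occupant: dict[int, tuple[int, str, str]] = {}  # site -> (ion_id, species, provenance)
    next_id = 0
    for s in params.initial_sites:
        occupant[s] = (next_id, _K, "initial")
        next_id += 1

    duration_ns = params.duration_ns
    dt_frame_ns = params.frame_interval_ps / 1000.0
    frame_times_ns = np.arange(0.0, duration_ns + 0.5 * dt_frame_ns, dt_frame_ns)

    events: list[tuple[float, str, int, str, object, object]] = []
    frames: list[dict[int, Bound]] = []

    def snapshot() -> dict[int, Bound]:
        return {ion: Bound(site, sp, prov) for site, (ion, sp, prov) in occupant.items()}

    def species_at() -> dict[int, str]:
        return {site: v[1] for site, v in occupant.items()}

    t = 0.0
    frame_ptr = 0
    warned_dead = False
    bias = params.bias
    rep = params.repulsion

    while frame_ptr < len(frame_times_ns):
        # enumerate enabled moves and their rates
        moves: list[tuple[float, str, int, int | None]] = []  # rate, kind, site, target
        sp_map = species_at()
        n_k = sum(1 for v in occupant.values() if v[1] == _K)
        for site, (ion, sp, prov) in occupant.items():
            charged = sp == _K
            # outward hop (toward S0)
            if site > 0 and site - 1 not in occupant:
                r = params.k_hop_fwd * (bias if charged else 1.0)
                if charged:
                    r *= rep ** _adjacency_delta(sp_map, site, site - 1)
                moves.append((r, HOP, site, site - 1))
            # inward hop (toward S6)
            if site < n - 1 and site + 1 not in occupant:
                r = params.k_hop_bwd / (bias if charged else 1.0)
                if charged:
                    r *= rep ** _adjacency_delta(sp_map, site, site + 1)
                moves.append((r, HOP, site, site + 1))
            # the doubly occupied filter is a deep well: K+ dissociation is
            # disabled at or below min_ions occupancy
            may_leave = (not charged) or n_k > params.min_ions
            if site == 0 and may_leave:
                r = params.k_dissoc_out * (bias if charged else 1.0)
                if charged:
                    r *= rep ** _adjacency_delta(sp_map, site, None)
                moves.append((r, DISSOCIATION_OUT, site, None))
            if site == n - 1 and may_leave:
                r = params.k_dissoc_in / (bias if charged else 1.0)
                if charged:
                    r *= rep ** _adjacency_delta(sp_map, site, None)
                moves.append((r, DISSOCIATION_IN, site, None))
        # entering against the charge already bound in the pore: each K+
        # above the baseline occupancy costs a factor entry_crowding, so a
        # two-ion pore refills much faster than a three-ion pore accepts a
        # fourth ion
        crowd = params.entry_crowding ** max(0, n_k - params.min_ions)
        if n - 1 not in occupant:
            if params.k_assoc_in > 0:
                r = (params.k_assoc_in * bias * crowd
                     * rep ** _entry_adjacency(sp_map, n - 1))
                moves.append((r, ASSOCIATION_IN, -1, n - 1))
            if params.k_water_in > 0:
                moves.append((params.k_water_in, "water_in", -1, n - 1))
        if 0 not in occupant:
            if params.k_assoc_out > 0:
                r = (params.k_assoc_out / bias * crowd
                     * rep ** _entry_adjacency(sp_map, 0))
                moves.append((r, ASSOCIATION_OUT, -1, 0))
            if params.k_water_out > 0:
                moves.append((params.k_water_out, "water_out", -1, 0))

        total = sum(m[0] for m in moves)
        if total <= 0.0:
            if not warned_dead:
                warnings.warn(
                    "dead system: no enabled moves; trajectory is static from here",
                    stacklevel=2,
                )
                warned_dead = True
            while frame_ptr < len(frame_times_ns):
                frames.append(snapshot())
                frame_ptr += 1
            break

        t_next = t + rng.exponential(1.0 / total)
        # emit frames that fall before the next event
        while frame_ptr < len(frame_times_ns) and frame_times_ns[frame_ptr] < t_next:
            frames.append(snapshot())
            frame_ptr += 1
        if t_next > duration_ns:
            break
        t = t_next

        rates = np.array([m[0] for m in moves])
        idx = rng.choice(len(moves), p=rates / total)
        _, kind, site, target = moves[idx]
        t_ps = t * 1000.0

        if kind == HOP:
            ion, sp, prov = occupant.pop(site)
            occupant[target] = (ion, sp, prov)
            events.append((t_ps, HOP, ion, sp, site, target))
        elif kind == DISSOCIATION_OUT:
            ion, sp, prov = occupant.pop(site)
            events.append((t_ps, DISSOCIATION_OUT, ion, sp, site, EXTRACELLULAR))
        elif kind == DISSOCIATION_IN:
            ion, sp, prov = occupant.pop(site)
            events.append((t_ps, DISSOCIATION_IN, ion, sp, site, INTRACELLULAR))
        elif kind == ASSOCIATION_IN:
            occupant[target] = (next_id, _K, INTRACELLULAR)
            events.append((t_ps, ASSOCIATION_IN, next_id, _K, INTRACELLULAR, target))
            next_id += 1
        elif kind == ASSOCIATION_OUT:
            occupant[target] = (next_id, _K, EXTRACELLULAR)
            events.append((t_ps, ASSOCIATION_OUT, next_id, _K, EXTRACELLULAR, target))
            next_id += 1
        elif kind == "water_in":
            occupant[target] = (next_id, _WATER, INTRACELLULAR)
            events.append((t_ps, ASSOCIATION_IN, next_id, _WATER, INTRACELLULAR, target))
            next_id += 1
        elif kind == "water_out":
            occupant[target] = (next_id, _WATER, EXTRACELLULAR)
            events.append((t_ps, ASSOCIATION_OUT, next_id, _WATER, EXTRACELLULAR, target))
            next_id += 1

    # pad trailing frames if the event loop exited past the horizon
    while frame_ptr < len(frame_times_ns):
        frames.append(snapshot())
        frame_ptr += 1

    event_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return SiteTrajectory(frame_times_ns * 1000.0, frames, event_df)


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

def _match_shift(a: Sequence[int], b: Sequence[int]) -> bool:
    """True if the order-preserving ion matching moves every ion <= 1 site."""
    return len(a) == len(b) and all(abs(x - y) <= 1 for x, y in zip(a, b))


def scripted_trajectory(script: ScriptedTrajectory | Sequence[str]) -> SiteTrajectory:
    """Deterministic :class:`SiteTrajectory` realising a scripted state path.

    Ion identities and provenance are inferred from the elementary moves:
    single-file order never changes, entries happen only at mouth sites
    (S6 from the intracellular bulk, S0 from the extracellular bulk), and
    exits only from mouth sites.  Raises ``ValueError`` naming the step on
    any jump that no such transition can produce.
    """
    if isinstance(script, ScriptedTrajectory):
        labels = list(script.states)
        dwell = script.dwell_frames
        dt = script.frame_interval_ps
    else:
        labels = list(script)
        dwell, dt = 1, 20.0

    site_lists: list[tuple[int, ...]] = []
    for lab in labels:
        _, sites = parse_label(lab)
        if len(set(sites)) != len(sites):
            raise ValueError(f"state {lab!r}: duplicate site (exclusion)")
        site_lists.append(sites)

    # ions ordered extracellular -> intracellular (ascending site)
    ions: list[int] = list(range(len(site_lists[0])))  # ids in file order
    prov: dict[int, str] = {i: "initial" for i in ions}
    next_id = len(ions)

    events: list[tuple[float, str, int, str, object, object]] = []
    frames: list[dict[int, Bound]] = []
    times: list[float] = []

    def emit_frames(step: int, sites: tuple[int, ...]) -> None:
        frame = {
            ion: Bound(site, _K, prov[ion]) for ion, site in zip(ions, sites)
        }
        for j in range(dwell):
            times.append((step * dwell + j) * dt)
            frames.append(frame)

    emit_frames(0, site_lists[0])

    for step in range(1, len(site_lists)):
        a, b = site_lists[step - 1], site_lists[step]
        t_ps = step * dwell * dt
        why = (
            f"step {step}: {labels[step - 1]!r} -> {labels[step]!r} is not an "
            "elementary transition (each ion may shift one site; entries/exits "
            "only at mouth sites)"
        )
        if len(b) == len(a):
            if not _match_shift(a, b):
                raise ValueError(why)
            for ion, x, y in zip(ions, a, b):
                if x != y:
                    events.append((t_ps, HOP, ion, _K, x, y))
        elif len(b) == len(a) + 1:
            if b[-1] == 6 and _match_shift(a, b[:-1]):
                for ion, x, y in zip(ions, a, b[:-1]):
                    if x != y:
                        events.append((t_ps, HOP, ion, _K, x, y))
                events.append((t_ps, ASSOCIATION_IN, next_id, _K, INTRACELLULAR, 6))
                prov[next_id] = INTRACELLULAR
                ions.append(next_id)
                next_id += 1
            elif b[0] == 0 and _match_shift(a, b[1:]):
                for ion, x, y in zip(ions, a, b[1:]):
                    if x != y:
                        events.append((t_ps, HOP, ion, _K, x, y))
                events.append((t_ps, ASSOCIATION_OUT, next_id, _K, EXTRACELLULAR, 0))
                prov[next_id] = EXTRACELLULAR
                ions.insert(0, next_id)
                next_id += 1
            else:
                raise ValueError(why)
        elif len(b) == len(a) - 1:
            if a[0] == 0 and _match_shift(a[1:], b):
                leaving = ions.pop(0)
                events.append((t_ps, DISSOCIATION_OUT, leaving, _K, 0, EXTRACELLULAR))
                for ion, x, y in zip(ions, a[1:], b):
                    if x != y:
                        events.append((t_ps, HOP, ion, _K, x, y))
            elif a[-1] == 6 and _match_shift(a[:-1], b):
                leaving = ions.pop()
                events.append((t_ps, DISSOCIATION_IN, leaving, _K, 6, INTRACELLULAR))
                for ion, x, y in zip(ions, a[:-1], b):
                    if x != y:
                        events.append((t_ps, HOP, ion, _K, x, y))
            else:
                raise ValueError(why)
        else:
            raise ValueError(why)
        emit_frames(step, b)

    event_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    return SiteTrajectory(np.asarray(times), frames, event_df)


# ---------------------------------------------------------------------------
# continuous-coordinate rendering
# ---------------------------------------------------------------------------

def render_continuous(
    traj: SiteTrajectory,
    site_map=None,
    jitter_sd: float = 0.0,
    seed: int = 0,
):
    """Render a site trajectory as continuous axial coordinates.

    Each bound particle gets a coordinate drawn from a normal distribution
    around its site center, truncated to the site's half-open interval, so
    site assignment round-trips exactly for any jitter.  Unbound particles
    are placed in the bulk on the correct side: before entry, the side of
    their provenance; after an exit, the side of the mouth they left
    through (exits from the outer half go extracellular, from the inner
    half intracellular).  This lets the full analysis chain — projection,
    site assignment, graphs, cycles, permeation counts — be exercised
    end-to-end against the simulator's exact event log.
    """
    from scipy.stats import truncnorm

    from .trajectory import IonTrajectory, SiteMap

    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if site_map is None:
        site_map = SiteMap()
    rng = np.random.default_rng(seed)

    above = site_map.pore_top + 5.0
    below = site_map.pore_bottom - 5.0

    # per-particle bound intervals
    particles: dict[int, dict] = {}
    for i, frame in enumerate(traj.frames):
        for ion_id, bound in frame.items():
            rec = particles.setdefault(
                ion_id,
                {"species": bound.species, "provenance": bound.provenance,
                 "bound": {}},
            )
            rec["bound"][i] = bound.site

    rows: list[tuple[float, int, str, float]] = []
    bound_rows: list[int] = []   # indices into rows needing jittered site coords
    bound_sites: list[int] = []
    n = len(traj.frames)
    for ion_id in sorted(particles):
        rec = particles[ion_id]
        bound = rec["bound"]
        first = min(bound)
        last_exit_side = above  # updated as we walk past bound frames
        for i in range(n):
            t = traj.times[i]
            if i in bound:
                site = bound[i]
                last_exit_side = above if site <= 3 else below
                bound_rows.append(len(rows))
                bound_sites.append(site)
                z = site_map.center(site)
            elif i < first:
                if rec["provenance"] == INTRACELLULAR:
                    z = below
                elif rec["provenance"] == EXTRACELLULAR:
                    z = above
                else:
                    continue  # "initial" particles are bound from frame 0
            else:
                # after (or between) pore visits: side of the last exit,
                # inferred from the mouth half the particle last occupied
                z = last_exit_side
            rows.append((float(t), ion_id, rec["species"], z))

    if jitter_sd > 0 and bound_rows:
        sites_arr = np.asarray(bound_sites)
        lo = np.array([site_map.interval(s)[0] for s in range(7)])[sites_arr]
        hi = np.array([site_map.interval(s)[1] for s in range(7)])[sites_arr]
        centers = 0.5 * (lo + hi)
        a = (lo - centers) / jitter_sd
        b = (hi - centers) / jitter_sd
        z = truncnorm.rvs(a, b, loc=centers, scale=jitter_sd, random_state=rng)
        z = np.minimum(z, np.nextafter(hi, lo))  # keep the interval half-open
        for idx, zi in zip(bound_rows, z):
            t, ion_id, sp, _ = rows[idx]
            rows[idx] = (t, ion_id, sp, float(zi))

    df = pd.DataFrame(rows, columns=["time_ps", "particle_id", "species", "axial_coord"])
    df = df.sort_values(["time_ps", "particle_id"], ignore_index=True)
    if not len(df):
        df = pd.DataFrame(columns=["time_ps", "particle_id", "species", "axial_coord"])
    return IonTrajectory(df)
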