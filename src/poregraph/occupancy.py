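"""Core containers for site-resolved pore occupancy.

A :class:`SiteTrajectory` is the central in-memory object of the package: a
time-ordered sequence of frames, each frame mapping a particle id to the
binding site (0–6, S0 extracellular-most) it occupies.  Keying frames by
particle makes "an ion occupies at most one site" structural, while still
representing the rare case — possible in noisy real data, impossible under
kinetic Monte Carlo exclusion — of two ions assigned to one site.

Alongside the frames a trajectory can carry an event log: the list of
elementary moves (associations, dissociations, hops) that produced the
occupancies.  The kinetic Monte Carlo simulator and the scripted-trajectory
builder attach an exact event log; :func:`poregraph.trajectory.assign_sites`
reconstructs one from frame-to-frame differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

N_SITES = 7

#: bulk reservoir labels used in event logs (``from``/``to`` columns)
INTRACELLULAR = "intracellular"
EXTRACELLULAR = "extracellular"

EVENT_COLUMNS = ["time_ps", "event_type", "ion_id", "species", "from", "to"]

ASSOCIATION_IN = "association_in"      # entry from intracellular bulk into S6
ASSOCIATION_OUT = "association_out"    # entry from extracellular bulk into S0
DISSOCIATION_IN = "dissociation_in"    # exit from S6 to intracellular bulk
DISSOCIATION_OUT = "dissociation_out"  # exit from S0 to extracellular bulk
HOP = "hop"


@dataclass(frozen=True)
class Bound:
    """A particle's binding record within one frame.

    ``provenance`` is the bulk the particle entered the pore from
    (``"intracellular"`` / ``"extracellular"``), or ``"initial"`` for
    particles already inside at the start of the trajectory.
    """

    site: int
    species: str = "K"
    provenance: str = "initial"


def empty_event_log() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


@dataclass
class SiteTrajectory:
    """Per-frame site occupancies of the pore, with an optional event log."""

    times: np.ndarray
    frames: list[dict[int, Bound]]
    events: pd.DataFrame = field(default_factory=empty_event_log)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        for i, frame in enumerate(self.frames):
            for ion_id, bound in frame.items():
                if not 0 <= bound.site < N_SITES:
                    raise ValueError(
                        f"frame {i}: particle {ion_id} at invalid site {bound.site}"
                    )

    # -- basic protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[tuple[float, dict[int, Bound]]]:
        return iter(zip(self.times, self.frames))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration_ps(self) -> float:
        if len(self.times) < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    # -- frame queries -----------------------------------------------------

    def occupant_of(self, frame_index: int, site: int) -> tuple[int, Bound] | None:
        """(ion_id, record) of the particle at ``site``, or None if vacant."""
        for ion_id, bound in self.frames[frame_index].items():
            if bound.site == site:
                return ion_id, bound
        return None

    def sites_occupied(self, frame_index: int, species: str = "K") -> list[int]:
        """Occupied site indices (with multiplicity) for one species."""
        return sorted(
            b.site for b in self.frames[frame_index].values() if b.species == species
        )

    def state_labels(self, species: str = "K") -> list[str]:
        """Canonical occupancy-state label per frame (ions of one species)."""
        from .states import encode_label

        return [
            encode_label(self.sites_occupied(i, species)) for i in range(len(self.frames))
        ]

    def species_present(self) -> set[str]:
        return {b.species for frame in self.frames for b in frame.values()}

    def exclusion_violations(self) -> int:
        """Number of (frame, site) pairs holding more than one particle."""
        n = 0
        for frame in self.frames:
            sites = [b.site for b in frame.values()]
            n += len(sites) - len(set(sites))
        return n

    # -- tabular I/O -------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        """Long-format table; empty frames are kept as site ``-1`` rows."""
        rows = []
        for i, (t, frame) in enumerate(self):
            if not frame:
                rows.append((i, t, -1, -1, "", ""))
            for ion_id in sorted(frame):
                b = frame[ion_id]
                rows.append((i, t, b.site, ion_id, b.species, b.provenance))
        return pd.DataFrame(
            rows, columns=["frame", "time_ps", "site", "ion_id", "species", "provenance"]
        )

    @classmethod
    def from_table(cls, df: pd.DataFrame, events: pd.DataFrame | None = None) -> "SiteTrajectory":
        times: list[float] = []
        frames: list[dict[int, Bound]] = []
        for (_, t), group in df.groupby(["frame", "time_ps"], sort=True):
            times.append(float(t))
            frame: dict[int, Bound] = {}
            for row in group.itertuples(index=False):
                if int(row.site) < 0:
                    continue
                frame[int(row.ion_id)] = Bound(
                    int(row.site), str(row.species), str(row.provenance)
                )
            frames.append(frame)
        return cls(np.asarray(times), frames, events if events is not None else empty_event_log())

    def write(self, path, events_path=None) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)
        if events_path is not None:
            self.events.to_csv(events_path, sep="\t", index=False)

    @classmethod
    def read(cls, path, events_path=None) -> "SiteTrajectory":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        events = None
        if events_path is not None:
            events = pd.read_csv(events_path, sep="\t", keep_default_na=False)
        return cls.from_table(df, events)

    # -- slicing -----------------------------------------------------------

    def window(self, start: int, stop: int) -> "SiteTrajectory":
        """Frame-index slice; the event log is filtered to the time window."""
        times = self.times[start:stop]
        events = self.events
        if len(events) and len(times):
            mask = (events["time_ps"] >= times[0]) & (events["time_ps"] <= times[-1])
            events = events.loc[mask].reset_index(drop=True)
        return SiteTrajectory(times, self.frames[start:stop], events)


def concatenate(parts: Iterable[SiteTrajectory]) -> SiteTrajectory:
    """Concatenate trajectories, shifting times to keep them increasing."""
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to concatenate")
    out_times = [np.asarray(parts[0].times, dtype=float)]
    frames = list(parts[0].frames)
    offset = out_times[0][-1] if len(out_times[0]) else 0.0
    step = float(np.median(np.diff(out_times[0]))) if len(out_times[0]) > 1 else 1.0
    shifted_events = [parts[0].events]
    for part in parts[1:]:
        if not len(part.times):
            continue
        shift = offset + step - part.times[0]
        out_times.append(np.asarray(part.times, dtype=float) + shift)
        frames.extend(part.frames)
        ev = part.events.copy()
        if len(ev):
            ev["time_ps"] = ev["time_ps"] + shift
        shifted_events.append(ev)
        offset = out_times[-1][-1]
    events = pd.concat(shifted_events, ignore_index=True)
    return SiteTrajectory(np.concatenate(out_times), frames, events)
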