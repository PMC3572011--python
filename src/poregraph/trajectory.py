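"""Trajectory tables, pore-axis geometry, binding-site assignment, densities.

The package consumes plain tabular trajectories: one row per particle per
frame with columns ``time_ps, particle_id, species`` and either a
precomputed axial coordinate (``axial_coord``, Å) or Cartesian ``x, y, z``
to be projected onto a pore axis.  The axis convention is fixed here once:
**the axial coordinate increases toward the extracellular side**, while the
site index increases toward the intracellular side — S0 is the outermost
site, S6 the central cavity.

The pore axis of a K+ channel is defined from two rings of four backbone
carbonyl oxygens (the Thr and Tyr rings of the selectivity filter): origin
at the lower-ring centroid, direction toward the upper-ring centroid.

Binding sites are half-open axial intervals delimited by eight strictly
decreasing boundaries b0 > … > b7, with S_i = [b_{i+1}, b_i).  The default
boundaries are an even 3 Å spacing across the filter region (about the
spacing of adjacent carbonyl cages) with wider slabs for the peripheral
sites and a 5 Å cavity slab; they are declared approximations and fully
overridable, since only the relative assignment matters downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

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

__all__ = [
    "IonTrajectory",
    "SiteMap",
    "DensityProfile",
    "PoreAxis",
    "read_ion_table",
    "write_ion_table",
    "compute_pore_axis",
    "project_onto_axis",
    "assign_sites",
    "density_profile",
]

ALLOWED_SPECIES = ("K", "water", "Cl")

#: default site boundaries (Å): S1–S4 at 3 Å, S0/S5 slightly wider, S6 a 5 Å
#: cavity slab.  b0 is the extracellular edge of S0, b7 the cavity floor.
DEFAULT_BOUNDARIES = (15.0, 11.5, 8.5, 5.5, 2.5, -0.5, -4.0, -9.0)


@dataclass(frozen=True)
class SiteMap:
    """Axial site boundaries, S0 extracellular-most."""

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        object.__setattr__(self, "boundaries", b)
        if len(b) != 8:
            raise ValueError("a 7-site map needs exactly 8 boundaries")
        if not all(b[i] > b[i + 1] for i in range(7)):
            raise ValueError("boundaries must be strictly decreasing")

    @property
    def n_sites(self) -> int:
        return 7

    @property
    def pore_top(self) -> float:
        return self.boundaries[0]

    @property
    def pore_bottom(self) -> float:
        return self.boundaries[-1]

    def interval(self, site: int) -> tuple[float, float]:
        """Half-open interval [lower, upper) of a site."""
        return self.boundaries[site + 1], self.boundaries[site]

    def center(self, site: int) -> float:
        lo, hi = self.interval(site)
        return 0.5 * (lo + hi)

    def site_of(self, z: float) -> int | None:
        """Containing site of an axial coordinate, or None if in bulk."""
        if z >= self.pore_top or z < self.pore_bottom:
            return None
        # boundaries descending: site i covers [b[i+1], b[i])
        for i in range(7):
            if self.boundaries[i + 1] <= z < self.boundaries[i]:
                return i
        return None  # pragma: no cover

    def sites_of(self, z: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`site_of`; bulk encoded as -1."""
        asc = -np.asarray(self.boundaries)
        # site i covers [b[i+1], b[i]): asc[i] < -z <= asc[i+1]
        idx = np.searchsorted(asc, -np.asarray(z, dtype=float), side="left") - 1
        out = idx.copy()
        out[(idx < 0) | (idx >= 7)] = -1
        return out


@dataclass
class IonTrajectory:
    """Tabular per-frame particle coordinates (axial or 3-D)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"time_ps", "particle_id", "species"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if not (self.has_axial or self.has_3d):
            raise ValueError("need either an 'axial_coord' column or 'x','y','z'")
        times = self.df["time_ps"].drop_duplicates().to_numpy()
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        bad = set(self.df["species"].unique()) - set(ALLOWED_SPECIES)
        if bad:
            raise ValueError(
                f"unknown species {sorted(bad)}; allowed: {list(ALLOWED_SPECIES)}"
            )
        dup = self.df.duplicated(subset=["time_ps", "particle_id"])
        if dup.any():
            row = self.df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicated particle_id {row['particle_id']} in frame at "
                f"t={row['time_ps']} ps"
            )

    @property
    def has_axial(self) -> bool:
        return "axial_coord" in self.df.columns

    @property
    def has_3d(self) -> bool:
        return {"x", "y", "z"} <= set(self.df.columns)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_ps"].drop_duplicates().to_numpy()

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PoreAxis:
    """Axis through the pore: origin point and unit direction
    (extracellular positive)."""

    origin: np.ndarray
    direction: np.ndarray


@dataclass
class DensityProfile:
    """Normalised axial probability density per species."""

    bin_edges: np.ndarray
    density: dict[str, np.ndarray]

    def integral(self, species: str) -> float:
        widths = np.diff(self.bin_edges)
        return float(np.sum(self.density[species] * widths))

    def peak_positions(self, species: str) -> np.ndarray:
        """Bin centers of local density maxima."""
        d = self.density[species]
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        peaks = [
            i
            for i in range(len(d))
            if d[i] > 0
            and (i == 0 or d[i] >= d[i - 1])
            and (i == len(d) - 1 or d[i] >= d[i + 1])
        ]
        return centers[peaks]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ion_table(path, format: str = "tsv") -> IonTrajectory:
    """Read a tabular trajectory (TSV or CSV) into an :class:`IonTrajectory`.

    Validation errors cite the offending frame/particle where possible.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'csv'")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    return IonTrajectory(df)


def write_ion_table(traj: IonTrajectory, path, format: str = "tsv") -> None:
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'csv'")
    sep = "\t" if format == "tsv" else ","
    traj.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def compute_pore_axis(lower_ring: np.ndarray, upper_ring: np.ndarray) -> PoreAxis:
    """Axis from two 4-point carbonyl-oxygen rings (lower = intracellular).

    Origin is the lower-ring centroid; the unit direction points toward the
    upper-ring centroid, i.e. toward the extracellular side.
    """
    lower = np.asarray(lower_ring, dtype=float)
    upper = np.asarray(upper_ring, dtype=float)
    if lower.shape != (4, 3) or upper.shape != (4, 3):
        raise ValueError("each ring must be 4 points in 3-D")
    origin = lower.mean(axis=0)
    delta = upper.mean(axis=0) - origin
    norm = np.linalg.norm(delta)
    if norm < 1e-12:
        raise ValueError("degenerate axis: ring centroids coincide")
    return PoreAxis(origin=origin, direction=delta / norm)


def project_onto_axis(traj: IonTrajectory, axis: PoreAxis) -> IonTrajectory:
    """Project 3-D coordinates onto the pore axis (dot with unit direction)."""
    if traj.has_axial and not traj.has_3d:
        warnings.warn("trajectory already has axial coordinates; passing through")
        return traj
    xyz = traj.df[["x", "y", "z"]].to_numpy(dtype=float)
    axial = (xyz - axis.origin) @ axis.direction
    out = traj.df.drop(columns=["x", "y", "z"]).copy()
    out["axial_coord"] = axial
    return IonTrajectory(out)


# ---------------------------------------------------------------------------
# site assignment
# ---------------------------------------------------------------------------

def _debounce(seq: list, min_dwell: int) -> list:
    """Suppress runs shorter than ``min_dwell`` by holding the previous value."""
    if min_dwell <= 1 or not seq:
        return list(seq)
    out = list(seq)
    i = 0
    current = out[0]
    while i < len(out):
        j = i
        while j < len(out) and out[j] == out[i]:
            j += 1
        if out[i] != current and (j - i) < min_dwell:
            for k in range(i, j):
                out[k] = current
        else:
            current = out[i]
        i = j
    return out


def assign_sites(
    traj: IonTrajectory,
    site_map: SiteMap | None = None,
    min_dwell_frames: int = 1,
) -> SiteTrajectory:
    """Assign every in-pore particle to its binding site, frame by frame.

    Returns a :class:`SiteTrajectory` with per-visit provenance (the bulk a
    particle approached from: below b7 → intracellular, above b0 →
    extracellular, never seen outside → "initial") and an event log
    reconstructed from frame-to-frame differences.  Chloride is ignored.
    ``min_dwell_frames`` > 1 suppresses occupancy changes shorter than that
    many frames by holding the previous assignment (off by default).
    """
    if site_map is None:
        site_map = SiteMap()
    if not traj.has_axial:
        raise ValueError("assign_sites needs axial coordinates; project first")

    df = traj.df[traj.df["species"] != "Cl"]
    times = traj.times
    frame_index = {t: i for i, t in enumerate(times)}
    n = len(times)

    # per-particle raw assignment: site index, or "in"/"out" bulk side, or
    # None where the particle is absent from the table
    per_particle: dict[int, dict] = {}
    for pid, grp in df.groupby("particle_id", sort=True):
        raw: list = [None] * n
        for t, z in zip(grp["time_ps"].to_numpy(), grp["axial_coord"].to_numpy()):
            site = site_map.site_of(z)
            if site is None:
                raw[frame_index[t]] = "out" if z >= site_map.pore_top else "in"
            else:
                raw[frame_index[t]] = site
        species = str(grp["species"].iloc[0])
        per_particle[pid] = {"assign": _debounce(raw, min_dwell_frames), "species": species}

    frames: list[dict[int, Bound]] = [dict() for _ in range(n)]
    events: list[tuple[float, str, int, str, object, object]] = []

    for pid, info in per_particle.items():
        assign = info["assign"]
        species = info["species"]
        provenance = "initial"
        prev = None
        for i, cur in enumerate(assign):
            prev_insite = isinstance(prev, int)
            cur_insite = isinstance(cur, int)
            if cur_insite and not prev_insite:
                # pore entry (or first appearance inside the pore)
                if prev == "in":
                    provenance = INTRACELLULAR
                    events.append(
                        (times[i], ASSOCIATION_IN, pid, species, INTRACELLULAR, cur)
                    )
                elif prev == "out":
                    provenance = EXTRACELLULAR
                    events.append(
                        (times[i], ASSOCIATION_OUT, pid, species, EXTRACELLULAR, cur)
                    )
                else:
                    provenance = "initial"
            elif prev_insite and not cur_insite:
                # pore exit; side from the bulk coordinate, else from the site
                if cur == "out" or (cur is None and prev <= 1):
                    events.append(
                        (times[i], DISSOCIATION_OUT, pid, species, prev, EXTRACELLULAR)
                    )
                else:
                    events.append(
                        (times[i], DISSOCIATION_IN, pid, species, prev, INTRACELLULAR)
                    )
            elif prev_insite and cur_insite and prev != cur:
                events.append((times[i], HOP, pid, species, prev, cur))
            if cur_insite:
                frames[i][pid] = Bound(cur, species, provenance)
            prev = cur

    event_df = pd.DataFrame(
        sorted(events, key=lambda e: e[0]), columns=EVENT_COLUMNS
    )
    out = SiteTrajectory(times, frames, event_df)
    n_coll = out.exclusion_violations()
    if n_coll:
        warnings.warn(
            f"{n_coll} frame-site pairs hold more than one particle; states "
            "will repeat the site index in their labels"
        )
    return out


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def density_profile(
    traj: IonTrajectory,
    bin_width: float = 0.5,
    species: str | Sequence[str] = "K",
    window: tuple[float, float] | None = None,
) -> DensityProfile:
    """Normalised axial density histogram over a stated window.

    The window defaults to the span of the data; each species' density
    integrates to 1 over the window.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not traj.has_axial:
        raise ValueError("density_profile needs axial coordinates")
    species_list = [species] if isinstance(species, str) else list(species)
    z_all = traj.df["axial_coord"].to_numpy(dtype=float)
    if window is None:
        lo, hi = float(z_all.min()), float(z_all.max())
    else:
        lo, hi = window
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    density: dict[str, np.ndarray] = {}
    for sp in species_list:
        z = traj.df.loc[traj.df["species"] == sp, "axial_coord"].to_numpy(dtype=float)
        z = z[(z >= edges[0]) & (z < edges[-1])]
        if len(z) == 0:
            raise ValueError(f"empty selection: no {sp!r} particles in the window")
        hist, _ = np.histogram(z, bins=edges, density=True)
        density[sp] = hist
    return DensityProfile(bin_edges=edges, density=density)


# ---------------------------------------------------------------------------
# optional adapter for MD coordinate formats
# ---------------------------------------------------------------------------

def from_mdanalysis(universe, selection: str, species: str = "K") -> IonTrajectory:
    """Extract a tabular trajectory from an MDAnalysis Universe.

    Thin optional adapter (MDAnalysis is imported by the caller); keeps the
    core free of MD-format dependencies.
    """
    rows = []
    group = universe.select_atoms(selection)
    for ts in universe.trajectory:
        for atom in group:
            x, y, z = atom.position
            rows.append((float(ts.time), int(atom.ix), species, x, y, z))
    df = pd.DataFrame(rows, columns=["time_ps", "particle_id", "species", "x", "y", "z"])
    return IonTrajectory(df)
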