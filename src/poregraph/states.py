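"""Occupancy-state labels and mechanistic grouping.

An ion-binding state is the multiset of pore sites occupied by K+ at an
instant, written canonically as ``"K:"`` followed by the ascending site
indices joined by colons — e.g. ``"K:0:2:4"`` for ions in S0, S2 and S4
(the resting state).  States are grouped by ion count and topology:

``II``
    two-ion states (the sub-stable plateau of the association/dissociation
    conduction route);
``IIIr``
    three-ion states adjacent to the resting state: they hold an S0 ion and
    no peripheral (S5/S6) ion;
``IIIe``
    the remaining three-ion "entrance" states, visited while a freshly
    associated ion works its way up from the cavity;
``IV``
    four-ion states (the transient of the knock-on route).

The IIIr/IIIe predicate is the simplest rule consistent with every state
assigned to either group in the canonical conduction paths; an explicit
label → group mapping can override it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

N_SITES = 7
RESTING_STATE = "K:0:2:4"

GROUP_II = "II"
GROUP_IIIR = "IIIr"
GROUP_IIIE = "IIIe"
GROUP_IV = "IV"
GROUP_OTHER = "other"


def encode_label(occupied: Iterable[int], species: str = "K") -> str:
    """Canonical label for a multiset of occupied site indices.

    >>> encode_label({0, 2, 4})
    'K:0:2:4'
    >>> encode_label([3, 1])
    'K:1:3'
    >>> encode_label([])
    'K:'
    """
    sites = sorted(int(s) for s in occupied)
    for s in sites:
        if not 0 <= s < N_SITES:
            raise ValueError(f"site index {s} outside 0..{N_SITES - 1}")
    return f"{species}:" + ":".join(str(s) for s in sites)


def parse_label(label: str) -> tuple[str, tuple[int, ...]]:
    """Inverse of :func:`encode_label`: label -> (species, sorted site tuple)."""
    head, _, rest = label.partition(":")
    if not head:
        raise ValueError(f"malformed state label {label!r}")
    sites = tuple(int(tok) for tok in rest.split(":") if tok != "")
    if any(not 0 <= s < N_SITES for s in sites):
        raise ValueError(f"site index outside 0..{N_SITES - 1} in {label!r}")
    return head, sites


def classify_group(label_or_sites, overrides: dict[str, str] | None = None) -> str:
    """Mechanistic group of a state (II / IIIr / IIIe / IV / other)."""
    if isinstance(label_or_sites, str):
        label = label_or_sites
        _, sites = parse_label(label)
    else:
        sites = tuple(sorted(label_or_sites))
        label = encode_label(sites)
    if overrides and label in overrides:
        return overrides[label]
    n = len(sites)
    if n == 2:
        return GROUP_II
    if n == 4:
        return GROUP_IV
    if n == 3:
        if 0 in sites and not any(s in (5, 6) for s in sites):
            return GROUP_IIIR
        return GROUP_IIIE
    return GROUP_OTHER


@dataclass(frozen=True)
class OccupancyState:
    """A canonical ion-binding state with its mechanistic group."""

    occupied_sites: tuple[int, ...]
    label: str
    n_ions: int
    group: str

    @classmethod
    def from_sites(
        cls, occupied: Iterable[int], overrides: dict[str, str] | None = None
    ) -> "OccupancyState":
        sites = tuple(sorted(int(s) for s in occupied))
        label = encode_label(sites)
        return cls(sites, label, len(sites), classify_group(sites, overrides))

    @classmethod
    def from_label(
        cls, label: str, overrides: dict[str, str] | None = None
    ) -> "OccupancyState":
        _, sites = parse_label(label)
        return cls(sites, encode_label(sites), len(sites), classify_group(sites, overrides))


def encode_state(occupied: Iterable[int]) -> OccupancyState:
    """Build the canonical :class:`OccupancyState` for a site multiset."""
    return OccupancyState.from_sites(occupied)


def groups_for(labels: Iterable[str], overrides: dict[str, str] | None = None) -> dict[str, str]:
    """Map each distinct label to its group."""
    return {lab: classify_group(lab, overrides) for lab in set(labels)}
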