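# Methods

This note documents the models and conventions behind `poregraph`: what is
computed, under which assumptions, which defaults matter, and where the
package's synthetic data does and does not resemble real simulation data.

## Coordinate and site conventions

The pore axis points toward the extracellular side (axial coordinate
increases outward); the site index runs the other way, S0 outermost to S6
in the central cavity.  When 3-D coordinates are supplied, the axis is the
line between the centroids of two four-point carbonyl-oxygen rings (the
lower, intracellular ring defines the origin), and positions are projected
by a dot product with the unit direction.

Binding sites are half-open axial intervals `[lower, upper)` delimited by
eight strictly decreasing boundaries b0 > … > b7, with site i covering
`[b(i+1), b(i))`.  A coordinate exactly on a boundary belongs to the site
above it in index (below it in z); a coordinate at b0 or beyond is bulk.
The default boundaries space S0–S5 at 3–3.5 Å (the scale of adjacent
carbonyl cages) with a 5 Å cavity slab for S6.  They are declared
approximations: only the *relative* assignment matters for the analysis,
and real systems should supply measured thresholds through the config.
Assignment can optionally debounce flicker (`min_dwell_frames`); the
default is no smoothing.

Particles first seen outside the pore acquire provenance from the side
they approach from (below b7 → intracellular, above b0 → extracellular);
particles bound in the first frame are "initial".  Two ions assigned to
one site (possible in noisy data) are retained — the state label repeats
the site index — and counted in a warning.

## Ion-binding states, groups and the state graph

A frame's state is the multiset of sites occupied by K⁺, labelled
canonically (`K:0:2:4`).  Groups: two-ion states are II, four-ion states
are IV; a three-ion state is IIIr when it contains S0 and no peripheral
S5/S6 ion, otherwise IIIe.  The IIIr/IIIe predicate is the simplest rule
consistent with every state named along the two canonical conduction
paths; an explicit label→group map can override it.

The state graph has one node per observed state, carrying the visit count,
the lifetime fraction, and its natural log (the "log existence
probability" used for node sizing); one directed edge per ordered state
pair observed in consecutive frames, carrying the transition count.
Self-transitions accrue to lifetimes, not edges.  Edge types are derived
from the ion-count change and the witnessed entry/exit site and
provenance: +1 ion at S6/S5 → association from inside, +1 at S0/S1 →
association from outside, −1 from S0/S1 or S5/S6 → dissociation to the
respective side, equal counts → internal.  Transitions that change the
ion count by two or more between frames (possible at coarse sampling) are
flagged composite and excluded from typed statistics rather than silently
interpolated.

Stationarity is diagnosed by the Pearson correlation of per-state log
existence probabilities between the first and second half of a run, over
states present in both halves.

## Conduction cycles

The state sequence, with identical consecutive states collapsed, is cut at
every visit to the resting state `K:0:2:4`; each maximal segment between
successive resting visits is a cyclic path.  A cycle owns the time span
from the start of its initial resting run to the start of the terminal
one, so cycles plus the leading/trailing partial segments exactly
partition the trajectory.

Cycles are encoded one character per state.  The code map is seeded with
the established letters (E = `K:0:2:4`, B = `K:0:1:3`, 3 = `K:1:3`, 1 =
`K:1:2`, 0 = `K:0:2`, H = `K:0:2:6`, F = `K:0:2:5`, k = `K:0:2:4:6`, i =
`K:0:2:4:5`, d = `K:0:1:3:5`, K = `K:1:3:5`, I = `K:1:3:4`, G =
`K:1:2:4`); new states receive unused characters in first-appearance order
from a fixed alphabet, so the extension is deterministic.

**Conduction counting.** A cycle's conduction count is the *net* outward
charge across the extracellular mouth during its span: K⁺ exits above S0
minus K⁺ entries from the extracellular side.  Netting is what
distinguishes back-running (an ion out, another straight back in from the
same side — no change in transferred charge) from genuine two-step
conduction.  Global permeation counts are a different quantity — full
per-particle transits (intracellular entry to extracellular exit, with
initial residents counted from the trajectory start) — which is why a
trajectory can show slightly more transits than summed cycle conductions.

**Classification.** A conducting cycle through IV but not II is knock-on;
through II but not IV is A/D; both or neither is "other".  A
non-conducting cycle that visits II and re-acquires its S0 ion from the
extracellular side is back-running; the rest are no-conduction shuffles.
Classification is rule-based; hierarchical clustering of the encoded
strings is descriptive and reported as concordance, because a
cluster→mechanism mapping is an interpretation, not an algorithm.

**Alignment and clustering.** Cycle strings are compared by global
alignment with match = 1, mismatch = gap = 0 by default (an LCS-like
scheme; no established scoring exists for state strings, and this choice
is configurable).  Traceback ties break diagonal > up > left.  Distances
are d(a,b) = 1 − S(a,b)/max(S(a,a), S(b,b)), which stays in [0,1] across
unequal lengths; clustering is scipy agglomerative (average linkage by
default) with deterministic tie behaviour.

## Kinetics

Current: I = N·e/T with the SI-exact elementary charge; values are kept at
full precision and rounded to two significant figures only at the
reporting layer.  Membrane voltage under a uniform applied field:
V = E·L_z.

Passage times: within a cycle, consecutive runs of the same group are
merged; for each named group change (IIIr→IV and II→IIIe associations,
IIIr→II and IV→IIIe dissociations, IIIe→IIIr relaxation) the duration is
the dwell from first entry into the source group (within the cycle) to the
transition frame.  This generalises the single canonical worked example of
measuring "from the first E to 3" and "from 3 to H".

Distribution comparison: two-sided Wilcoxon rank-sum.  With both samples
≤ 8 and a tie-free pool, the p-value is exact — the null rank-sum
distribution is built by dynamic programming and p = min(1, 2·min(P(W ≤
w), P(W ≥ w))).  Otherwise a tie-corrected normal approximation with
continuity correction is used (scipy).  Sidedness is two-sided throughout;
degenerate zero-variance input yields p = 1.

## The synthetic trajectory generator

The simulator is a continuous-time Markov chain on the seven sites,
realised exactly with the Gillespie algorithm and then sampled on a
regular frame grid (default 20 ps) — site-level resolution is sufficient
because the whole analysis consumes only occupancy sequences.  Elementary
moves and their rates (1/ns):

| move | rate | default |
|---|---|---|
| hop toward S0 | `k_hop_fwd · bias · rep^Δ` | 4.0 |
| hop toward S6 | `k_hop_bwd / bias · rep^Δ` | 0.8 |
| entry S6 (intracellular) | `k_assoc_in · bias · crowd · rep^Δ` | 0.60 |
| entry S0 (extracellular) | `k_assoc_out / bias · crowd · rep^Δ` | 0.15 |
| exit S0 (outward) | `k_dissoc_out · bias · rep^Δ` | 0.30 |
| exit S6 (inward) | `k_dissoc_in / bias · rep^Δ` | 0.05 |

with four physical ingredients:

* **Exclusion** — at most one particle per site, always.
* **Voltage** — a single multiplicative factor `bias` (default 1.4) on
  outward moves of K⁺ and its reciprocal on inward moves, standing in for
  a uniform depolarising field; no attempt is made to map it to
  millivolts.
* **Ion–ion repulsion** — `rep^Δ` with `repulsion` = 0.1 and Δ the change
  in nearest-neighbour K⁺ pair count, penalising moves that create
  adjacent ions and boosting moves that break pairs.  This is what makes
  the alternating configuration `K:0:2:4` the resting attractor and makes
  S0 dissociation effectively push-activated (fast from `K:0:1:3`, slow
  from `K:0:2:4`), as in the physical filter.
* **Occupancy-dependent entry** — `crowd = entry_crowding^(nK − min_ions)`
  (default 0.3 per extra ion): a two-ion pore refills much faster than a
  three-ion pore accepts a fourth ion, reflecting the electrostatic cost
  of entering against already-bound charge.  K⁺ dissociation is disabled
  at or below `min_ions` = 2 bound ions — the doubly occupied filter is a
  deep well and never empties on the simulated timescale, matching the
  observed ≥ 2-ion occupancy of real filters.

Concentration enters only as a linear scale on both association rates
(`at_concentration`), the simplest model of diffusive arrival.  Water can
be enabled as a second species that competes for sites but is unbiased and
feels no repulsion; it is off by default and exists to exercise the
water/ion coflow counter.  The default duration (1000 ns) yields several
hundred conduction cycles in about a second.

No reference rate constants exist for this site-level model, so the
defaults are free parameters chosen once to reproduce the *regime* the
analysis is meant to probe: the pore holds 2–4 ions with `K:0:2:4` the
modal state; at 150 mM-equivalent the A/D mechanism dominates (knock-on/A-D
≈ 0.2) while at 600 mM-equivalent knock-on takes over (≈ 1), with
nearly-all-A/D and nearly-all-knock-on behaviour in the low- and
high-concentration limits.  The magnitudes of atomistically derived ratios, lifetimes
and back-running fractions from atomistic simulation are *not* targeted
and should not be read into the synthetic numbers: the generator has no
energetics beyond exclusion, nearest-neighbour repulsion and the two
penalty factors, no water coupling to the knock-on column, and no
structural fluctuations of the filter.  Passing tests therefore validate
the *analysis* (state reduction, graphs, cycles, statistics) against exact
event-log ground truth, and the *direction* of the concentration effect —
not quantitative agreement with any particular channel.

Scripted trajectories provide deterministic fixtures: a list of state
labels is validated as a chain of elementary transitions (each ion shifts
at most one site with single-file order preserved — concerted push chains
allowed — plus at most one mouth entry or exit per step) and realised with
ion identities and provenance inferred from the moves.

`render_continuous` converts site occupancies to axial coordinates —
truncated-normal jitter around site centers, bulk placement on the correct
side before entry and after exit — so the full chain
projection → assignment → graph → cycles → statistics can be exercised
end-to-end against the simulator's event log.  Truncation to the half-open
site interval guarantees the round trip is exact at any jitter level.

## Numerical and degenerate-case choices

* Lifetime fractions use frame counts; their sum is 1 by construction and
  asserted to 1e-9.
* Log existence probability is a natural log; the base only scales
  display.
* `K:` (empty pore) is a valid state label; empty trajectories are
  rejected by graph construction.
* A simulation whose total event rate reaches zero (no ions, no
  association) is not an error: the state is simply held to the horizon,
  with a warning.
* Distance matrices define d = 0 when both self-scores are ≤ 0 (only
  possible for empty strings under non-default scoring).
* The exact rank-sum path requires a tie-free pool; identical samples fall
  through to the tie-corrected path, which returns 1 at zero variance.

## Known limitations

* The site-boundary defaults are geometric conventions, not measured
  thresholds; real analyses should override them.
* Passage-time means inherit a small upward bias (order 5–10 % at default
  rates) from intervals in which the relevant mouth site is transiently
  blocked while the group dwell clock runs; it is invisible at a few
  hundred events but would surface in very long runs.
* Edge typing trusts frame-to-frame differences; at very coarse sampling
  more transitions become composite and are excluded from typed counts.
* The back-running detector keys on extracellular-provenance S0 ions;
  particles whose pre-entry bulk positions are absent from the input table
  (so provenance is unknown) are never counted as back-ran.
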