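# poregraph

Ion-binding state-graph analysis of single-file K⁺ conduction through
potassium-channel pores, with a kinetic Monte Carlo (KMC) simulator of
single-file hopping for synthetic trajectories.

## The problem

A potassium channel conducts K⁺ ions through a narrow selectivity filter in
single file, across seven discrete binding sites — S0 at the extracellular
mouth, S1–S4 inside the filter, S5 below it, and the central cavity S6.
Two mechanisms have been proposed for each conduction event:

* **knock-on** (one step): an incoming ion's association is tightly coupled
  to the outermost ion's dissociation — the file is pushed forward through
  a transient four-ion state;
* **association/dissociation, A/D** (two steps): the outermost ion leaves
  first, the pore waits in a two-ion state, and a replacement ion enters
  later.

Which mechanism operates, and how the balance shifts with ionic
concentration, can be read off a trajectory of pore-site occupancies.
`poregraph` implements that reading for anyone with per-frame ion
coordinates (from molecular dynamics or any other source) or with its own
synthetic trajectories:

1. **States.** Each frame is reduced to its *ion-binding state* — the
   multiset of occupied sites, written `K:0:2:4` for ions in S0, S2, S4
   (the resting state).  States are grouped as II (two-ion), IIIr
   (three-ion, resting-like: S0 occupied, no peripheral ion), IIIe
   (three-ion "entrance" states) and IV (four-ion).
2. **Graph.** The trajectory becomes a directed graph: nodes are states
   weighted by log existence probability (ln of the fraction of frames
   spent there), edges count observed transitions and are typed as
   association/dissociation at either mouth or internal rearrangement.
3. **Cycles.** The walk on the graph is cut into round trips that leave the
   resting state and return to it.  Each cycle is encoded one character per
   state (`E` = `K:0:2:4`), compared by global sequence alignment
   (Needleman–Wunsch), clustered hierarchically, and classified:
   conduction through IV and not II → knock-on; through II and not IV →
   A/D; no net conduction with an extracellular re-entry at S0 →
   back-running.
4. **Kinetics.** Full pore transits are counted per particle; the
   single-channel current is I = N·e/T (reported in pA); membrane voltage
   under a uniform field is V = E·L_z; group dwell times before
   association/dissociation transitions are extracted per cycle and
   compared across conditions with the Wilcoxon rank-sum test (exact by
   enumeration for small tie-free samples).

The KMC simulator (`simulate_hopping`) is a continuous-time Markov chain on
the seven sites with hard single-occupancy exclusion, voltage-biased
hopping, nearest-neighbour ion–ion repulsion, and concentration-scaled
association at both mouths.  Its exact event log is ground truth for every
statistic, and the concentration-driven switch from A/D to knock-on
conduction emerges from the rate competition rather than being scripted.

## Worked example

```python
import poregraph as pg

# the canonical two-step conduction cycle, as an explicit state script
ad = pg.scripted_trajectory(
    ["K:0:2:4", "K:0:1:3", "K:1:3", "K:1:2", "K:0:2",
     "K:0:2:6", "K:0:2:5", "K:0:2:4"]
)
(cycle,) = pg.conduction_cycles(ad).cycles
print(cycle.encoded, cycle.category, cycle.conductions)
# EB310HFE assoc_dissoc 1

# a synthetic trajectory and its mechanism balance at two concentrations
for c in (150.0, 600.0):
    params = pg.KMCParams(duration_ns=300.0, seed=1).at_concentration(c)
    decomp = pg.conduction_cycles(pg.simulate_hopping(params))
    r = pg.mechanism_ratio(decomp.cycles)
    print(f"{c:.0f} mM: knock-on/A-D = {r.n_knock_on}/{r.n_assoc_dissoc}")
# 150 mM: knock-on/A-D = 10/64
# 600 mM: knock-on/A-D = 58/61
```

The first block reproduces the canonical A/D cycle: the pore leaves the
resting state `E`, sheds its S0 ion (`B→3`), waits as a two-ion state
(`3`, `1`, `0`), accepts a replacement from the cavity (`H`, `F`) and
returns to `E` — one ion conducted in two separate steps.  The second block
shows the mechanism switch: scaling only the association rates by
concentration moves the knock-on/A-D cycle ratio from 0.16 to 0.95,
because at high concentration a fourth ion usually arrives before the
outermost ion has left.

The `examples/` directory has one narrative script per capability
(state graphs, cycle clustering, mechanism switching, kinetics); each
prints its numbers with a line on what they mean.  A thin CLI covers the
same stages for shell use:

```sh
poregraph simulate --seed 3 --out traj.tsv --events ev.tsv
poregraph graph   --traj traj.tsv --events ev.tsv --out graph.graphml
poregraph cycles  --traj traj.tsv --events ev.tsv --out cycles.tsv
poregraph report  --seed 3 --outdir report/
```

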