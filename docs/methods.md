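# Methods

`myxosim` simulates populations of gliding *Myxococcus xanthus* cells as
flexible self-propelled rods on a two-dimensional substrate and provides the
analysis used to classify the emergent patterns — in particular circular
aggregates (CAs): rotating, roughly disc-shaped clusters in which cells
circulate unidirectionally about a common centre.

## Agent model

Each agent is a chain of N = 7 circular nodes (diameter w = 0.5 μm) spaced
L/(N−1) = 1 μm apart, total length L = 6 μm.  One end node is the head; a
reversal swaps head and tail.  Forces on nodes:

* **Propulsion.**  The gliding motor is distributed: every node except the
  tail carries F_T/(N−1) ≈ 9.17 pN.  Interior nodes push toward their
  forward neighbour; the head node pushes along its heading, which random
  turns and slime-trail steering may redirect.  The total motor force is
  F_T = 55 pN.
* **Drag.**  Stokes-like per node, with the agent drag coefficient
  c = 22 pN·min/μm split evenly over the nodes (−(c/N)·v each), so an
  isolated straight agent glides at v* = F_T/c = 2.5 μm/min — the
  measured scale of *M. xanthus* gliding.  Reading c as a per-node
  coefficient instead would slow cells ~7-fold (0.36 μm/min), too slow
  to close an aggregate-sized loop (~60 μm circumference) within the
  ~70-min reversal period at which circular aggregates start to appear;
  the per-agent reading is the one consistent with both measured speeds
  and the emergent-onset phenomenology.
* **Bending.**  Angular springs at interior joints, energy ½k_b φ² per
  joint (k_b = 10 pN·μm/rad), forces taken as the exact energy gradient
  (momentum- and torque-free).
* **Inextensibility.**  Consecutive-node spacing is a hard constraint,
  enforced after each step by symmetric pairwise projection (four sweeps;
  spacing error stays ≲ 0.1%, centre of mass preserved).
* **Substrate adhesion.**  Each body node tethers to a focal-adhesion
  anchor by a spring (k_a = 100 pN/μm) that resists only displacement
  transverse to the local body axis, so gliding is unimpeded while
  sideways slip during collisions is resisted.  An anchor displaced
  d_a,max = 0.5 μm detaches and instantly re-forms at the node's
  position.  The head node is exempt: focal adhesions are assembled at
  the leading pole and stay substrate-fixed as the body glides over
  them, so the head's complex is always freshly formed and exerts no
  restoring force.  This matters for steering — with the head tethered
  like the body, turns and trail following barely deflect the cell and
  slime following loses its role in aggregate formation.
* **Collisions.**  The body is a capsule chain.  Overlapping capsule
  segments of different agents feel a linear penalty force
  k_rep (w − d) along the closest-approach direction, split onto segment
  endpoints barycentrically; k_rep = 300 pN/μm keeps steady pair
  interpenetration below ~10% of w while respecting the explicit-Euler
  stability bound k_rep·dt·N/c < 2.  The penalty stiffness is a tunable
  (the contact law itself is not part of the biology being tested).

Dynamics are first-order overdamped: node velocity is net force over drag.
The agent mass in the configuration is documentary; at these drag levels
the inertial timescale is ~10⁻¹⁴ min, far below dt = 0.0067 min, so inertia
is irrelevant.  A per-node displacement cap of 0.05 μm per step (the
overdamped analogue of a physics engine's maximum-velocity clamp; free
gliding moves 0.017 μm per step) guards the explicit integrator in
transiently over-compressed cluster cores.

## Reversals, turns, slime trails

Each agent carries a reversal clock r_t.  Without contacts it advances by
dt per step and the agent reverses when the clock crosses the period
τ_r = 8 min, resetting to zero.  The engine fires on the crossing itself,
so the isolated-agent interval is τ_r quantised to one step; evaluating
the printed two-branch recursion literally would spend an extra full step
on the reset and stretch the interval by a second dt when τ_r/dt is not an
integer.  Nonreversing (NR) agents have the clock pinned at zero.  Initial
clocks are staggered uniformly on [0, τ_r) to avoid artificial synchrony.

Every τ_t = 5 min an agent turns: the head propulsion direction is rotated
90° (sign chosen by a counter-based hash of seed, agent and event index —
deterministic, and independent across ablations) for 1 min.  With the
head tip mechanically free, a turn deflects the travel direction by a few
tens of degrees before body elasticity and substrate tethering relax it —
enough orientational noise for trajectories to curl and close on
themselves, which is how trail loops nucleate.

Gliding cells extrude slime behind them.  The trail field is a periodic
grid (cell 0.5 μm — one body width) storing an apolar orientation
(mod π) and a deposit time; the tail node overwrites its cell each step
(latest writer wins, i.e. reinforcement).  A head crossing a trail steers
toward the nearer of the two trail branches at ≤ ω_s = 30°/min.  Trails
have a finite lifetime, 20 min by default.  Persistence matters in both
directions: reinforcement is needed for loops to capture followers and
nucleate CAs, but trails that never expire were found to destroy CAs —
stale inner windings guide agents ever inward until the vortex winds up
into a gridlocked spiral.  With turnover, only actively travelled loops
survive and rotation persists for the whole run.  The steering rate,
grid resolution and lifetime are this package's choices (the trail
mechanism is phenomenological); all are exposed in the configuration.

## Cell-cell adhesion and contact signalling

Adhesion acts between node pairs of different agents: **end-end** bonds
(head node to a partner's tail node, reach 1.5 μm) and **lateral** bonds
(any other node pair, reach 0.9 μm).  A bond of length d pulls the nodes
together with k_adh·(d−w)/w·F_T for w < d ≤ reach and zero otherwise;
bonds break purely by distance and a re-formed bond starts at age zero.
The adhesion factor k_adh is allele-aware: 0.1 between same-allele TraAB
overexpressors (OE), 0.01 for every other compatible pair (WT level), and
0 between different TraAB alleles (kin discrimination) — so incompatible
neighbours neither stick nor signal.

Bonds older than τ_thr = 5 min gate reversal suppression: the clock
advance rate becomes 1 − Σ_ee δR_e − Σ_lat δR_l (floored so r_t ≥ 0), with
δR_e = 1 and δR_l = 0.04, summed over an agent's active bonds (node-pair
counting; one flanking neighbour can contribute several small lateral
terms — agent-pair counting is available behind a configuration flag).  A
single sustained end-end contact therefore freezes the clock, while
side-by-side packing slows it in proportion to contact area.  The age gate
distinguishes the fleeting collisions of a weakly adhesive population from
the long-lived contacts strong adhesion produces: with τ_thr = 0 even
WT-strength adhesion suppresses almost every reversal.

## Simulation procedure

M = round(η·L_sim²) straight agents (η = 0.074 μm⁻², reference domain
L_sim = 200 μm) are placed by rejection sampling without capsule overlap,
orientations uniform on [0, 2π), heads by fair coin, on a periodic square.
Each step: neighbour-list maintenance → bond update → force assembly →
overdamped update with length projection → slime deposition → clock and
turn events.  Snapshots of all node positions, polarity, clocks and
suppression flags are recorded every minute for 250 min; reversal events
and bond lifetimes are logged exactly.  Runs are bit-for-bit reproducible
for a given (config, seed): a single seeded stream with per-purpose
sub-streams (placement, heads, clocks, turn signs) keeps ablations from
shifting unrelated draws.

Neighbour search uses a cell list plus a Verlet skin (0.8 μm): candidate
pair lists are supersets rebuilt before accumulated motion could hide an
interacting pair, and all distances are recomputed per step, so the force
and bond logic is identical to an exhaustive search (asserted against a
brute-force oracle in the tests).

## Analysis

* **Reversal detection** on centroid tracks: a reversal is a direction
  change exceeding 150° between consecutive displacement intervals that
  persists ≥ 2 snapshots; sub-0.05-μm displacements count as pauses.  On
  simulated data the detector recovers ≥ 99% of engine-logged events
  within one snapshot, with zero false positives on nonreversing agents.
  The population-mean reversal interval pools cell-time over events:
  (n_cells × duration)/n_events.
* **Aggregate detection**: DBSCAN over agent centroids (periodic
  minimum-image metric, neighbourhood 3 μm, clusters of ≥ 20 agents),
  centre from a circular-mean unwrap, radius as the 90th-percentile member
  distance.  The rotational order of a cluster is the speed-weighted
  tangential fraction |Σ(r̂×v)| / Σ|v| over members — 1 for coherent
  circulation, ~M^(−1/2) for disorder.  Speed weighting reflects how CAs
  are recognised visually: their crowded cores move slowly (linear speed
  rises with distance from the centre), and near-stationary members carry
  no information about rotation sense.  A cluster with order ≥ 0.5 is a
  CA; its sense is the sign of the net circulation.  These detector
  constants were calibrated on constructed fixtures (rigid rings, null
  random motion) and are exposed as parameters.
* **Phenotype verdicts**: in reduced domains a CA's order fluctuates
  around threshold (few tens of members), so a run "forms CAs" when CAs
  are detected in ≥ 25% of snapshots sampled every 5 min over the final
  100 min — sustained rotation clears this easily, momentary collision
  swirls do not.  A mixture shows *mixed* CAs when the best CA's minority
  sub-population holds ≥ 20% of its members.
* **Radial kinematics**: per-agent speed from centred differences of
  centroids; angular speed as tangential speed over distance to the CA
  centre; means in 2-μm rings (5 μm for sparse experimental-style
  tracks).
* **Suppression statistics**: fraction of agents with ≥ 1 active
  (age > τ_thr) bond at the final snapshot, and the mean lifetime of
  bonds broken in the final 10 min.

## Problem sizes

The reference domain (200 μm, M = 2960, 250 min) is available but
expensive (~an hour per run); the shipped experiment defaults use the
reduced 100-μm domain (M = 740), and the package's own test suite and
the acceptance script scale further down.  The test suite runs the
phenotype matrix mostly on a 60-μm domain (M = 266) for 150 min, with
the robustly pattern-free controls on 40 μm/120 min and the OE+NR
mixture — whose mixed aggregates need room and time to coexist — on
70 μm for the full 250 min; the test-suite reversal-period sweep runs
150 min on a 50-μm domain.  The acceptance script uses 70-μm adhesion
runs and a 50-μm, 250-min sweep.  Density, time step and all model
parameters stay at reference values throughout.  CA formation is
local (aggregate radii 5–10 μm at these scales, under the 20-μm bound
observed at full scale), so most verdicts transfer across domain sizes;
the smaller populations mainly increase verdict noise, which the
windowed presence criterion absorbs.  Two phenomena do not survive the
reduction in this implementation: the sharp reversal-period onset
(finite-period populations mill only sporadically below the full-scale
population) and the suppression of milling in the no-slime ablation
(collision-driven mills persist at reduced scale); both are discussed
under limitations.

## What the simulations do and do not show

The generator reproduces the study conditions (geometry, forces, clocks,
densities, strain mixtures); it is not a calibrated digital twin of any
particular experiment.  Simulated CAs are single-layered and an order of
magnitude smaller than experimental ones (which grow into multilayered
mounds); quantitative speed values inside aggregates are therefore not
comparable to experiment, while the qualitative contrasts — which strain
combinations form CAs, the reversal-period onset, the inward decrease of
linear speed and increase of angular speed — are the reproducible
content.  Known limitations: no third dimension or multilayering, no
S-motility/pili, no outer-membrane exchange (adhesion enters only as
k_adh and an allele-compatibility rule), a phenomenological slime model,
and penalty-spring contacts rather than a full rigid-body solver.

Two behavioural caveats of this implementation deserve emphasis.  First,
crowded *nonreversing* rods can nucleate rotating mills from collisions
alone: frictionless capsule contacts plus the transverse body anchors
channel cells strongly along each other, and at reduced domain scale the
resulting mills are structurally indistinguishable from trail-driven
aggregates, so the slime-following ablation is not as clean here as the
mechanism story implies — slime following accelerates and stabilises
CAs rather than being strictly required.  Second, populations with
finite reversal periods (40–100 min) form CAs only sporadically in
reduced domains; the sharp period threshold for aggregation appears to
require full-scale populations.  The reversal-frequency contrast that
*is* robust at reduced scale is binary: frequently reversing populations
(τ_r ≤ 20 min) never aggregate, nonreversing (or fully suppressed)
populations do.
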