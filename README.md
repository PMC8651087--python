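# myxosim

Agent-based simulation of *Myxococcus xanthus* gliding motility and the
emergence of **circular aggregates (CAs)** — macroscopic rotating clusters in
which thousands of cells circulate clockwise or counterclockwise around a
common centre.  The package is for quantitative microbiologists and
biophysical modellers who want to ask *which single-cell behaviours are
necessary for this collective pattern*: periodic reversals, slime-trail
following, kin-discriminating (TraAB allele-aware) cell-cell adhesion, and
contact-duration-gated reversal suppression are all explicit, switchable
mechanisms.

## Model

Each cell is a flexible rod: N = 7 nodes joined by inextensible 1-μm
segments (length L = 6 μm, width w = 0.5 μm) with angular springs
(k_b = 10 pN·μm/rad) resisting bending.  Motion is overdamped.  A
distributed gliding motor applies F_p = F_T/(N−1) per node (total
F_T = 55 pN) along the body toward the head, giving an isolated cell the
closed-form speed v* = F_T/c = 2.5 μm/min at agent drag c = 22 pN·min/μm.
Focal-adhesion springs (k_a = 100 pN/μm, break distance 0.5 μm) resist
lateral slip of the body while the head tip stays mechanically free.
Cells deposit apolar slime trails and steer their heads parallel to trails
they cross; every τ_r = 8 min an internal clock fires a reversal (head and
tail swap), and every τ_t = 5 min the head force turns 90° for a minute.

Cells closer than a threshold adhere — end-to-end (head to partner tail,
reach 1.5 μm) or laterally (reach 0.9 μm) — with force
k_adh·(d−w)/w·F_T, where k_adh is 0.1 between same-allele TraAB
overexpressors (OE), 0.01 for other compatible pairs (WT level) and 0
across different alleles.  An adhesion bond older than τ_thr = 5 min
suppresses the partners' reversal clocks:

    r_{t+1} = max[ r_t + dt·(1 − Σ_ee δR_e − Σ_lat δR_l), 0 ],

with δR_e = 1 (one sustained end-end contact freezes the clock) and
δR_l = 0.04.  Populations of M = η·L_sim² agents (η = 0.074 μm⁻²) evolve
on a periodic square; analysis tools detect reversals, circular
aggregates (DBSCAN + a rotational order parameter), radial speed/angular-
speed profiles, and suppression statistics.

## Worked example

Cells tracked inside circular aggregates almost never reverse.  In the
reference tracking data set, 443 cells followed for 60 minutes yielded
only 12 reversal events; the population-mean interval between reversals
is then

```python
>>> from myxosim import mean_reversal_interval
>>> mean_reversal_interval(n_cells=443, duration_min=60, n_events=12)
36.916666666666664
```

about 37 hours — versus the ~8-minute reversal period of isolated cells,
a ~275-fold suppression.

Simulating a strongly adhesive (TraAB OE) population and scoring the
emergent pattern:

```python
from myxosim import SimulationConfig, StrainFraction, run, detect_aggregates

cfg = SimulationConfig(L_sim=70.0, run_duration=250.0,
                       strain_composition=[StrainFraction("OE", 1, 1.0)])
traj = run(cfg, seed=0)                      # 363 agents, 250 min
for ca in detect_aggregates(traj):           # final snapshot
    print(f"{len(ca.members)} cells, radius {ca.radius:.1f} um, "
          f"order {ca.rotational_order:.2f}, sense {ca.rotation_sense}")
```

prints one line per detected cluster:

```
25 cells, radius 5.8 um, order 0.32, sense none
62 cells, radius 8.9 um, order 0.01, sense none
20 cells, radius 4.3 um, order 0.61, sense CW
39 cells, radius 8.5 um, order 0.13, sense none
24 cells, radius 5.8 um, order 0.09, sense none
```

— the population has condensed into clusters, and one of them is a
circular aggregate: 20 cells a few body lengths across circulating
clockwise with rotational order 0.61.  Weak-adhesion (WT) populations
under the same seed produce stream networks with no cluster above the
rotational-order threshold.

The same machinery is scriptable from a shell:

```bash
myxosim run --config cfg.yaml --seed 1 --out results/
myxosim analyze --traj results/trajectory_seed1.csv --what aggregates --out results/
myxosim experiments --name phenotype_matrix --scale reduced --out pheno/
```

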