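# sentinet

Circuit-theory connectivity analysis for protected-area networks using a
fixed set of **sentinel nodes**.

## The problem

Conservation planners need to (1) map where animals can still move between
protected areas and (2) track whether network connectivity improves or
degrades as land use changes. Circuit-theoretic models treat the landscape
as a resistor network — animals, like electrons, spread over all available
pathways — but park-to-park analyses are hard to repeat over time: as the
park network grows or shrinks, the node set changes and indicator values
stop being comparable.

`sentinet` addresses this with a *fixed, stratified-random subset* of parks
(the sentinel nodes). Because the node set never changes, the indicator
recomputed on next decade's land cover is directly comparable to today's
baseline.

## The model

The cost raster assigns each cell a movement resistance from a five-rank
scheme: 0.1 (natural cover inside protected areas), 1 (natural cover
outside), 10 (minor roads, pasture), 100 (cropland, two-lane highways),
1000 (cities, multi-lane highways, large water). Each valid cell is a graph
node; neighboring cells *a*, *b* are joined by conductance
g = (1/c_a + 1/c_b)/2 (8-neighbor, conductance averaging, by default).

For every unordered pair of sentinel nodes (s, t), a unit current is
injected at *s* with *t* grounded, solving the graph-Laplacian system
L v = e_s − e_t. This yields:

* **R_eff(s, t)** — the effective resistance (resistance distance) between
  the pair; more, or cheaper, parallel pathways ⇒ lower R_eff;
* a per-cell **current density** map — throughflow proportional to the
  probability a random walker uses that cell.

Summed over all n(n−1)/2 pairs (1,225 pairs for 50 nodes), the current maps
give the cumulative current-density map (pinch points show as concentrated
high current). The connectivity indicator is

**MPER** = mean of R_eff over all pairs (± SE = sd/√n_pairs),

and per-node **isolation** is the mean resistance from one node to all
others. By Rayleigh monotonicity, adding a high-cost development can only
raise MPER (connectivity loss, ΔMPER ≥ 0) and adding a low-cost protected
area can only lower it — even when the new park is not itself a node.

## Worked example

```python
import sentinet as sn

land  = sn.generate_landscape(sn.LandscapeSpec(shape=(80, 80), seed=7))
parks = sn.generate_parks(sn.ParkSpec(n_parks=20, min_spacing=3000.0, seed=8), land)

model = sn.SentinelNetwork.from_parks(land, parks)   # overlay + node placement
res   = model.fit()
print(res.summary())
```

```
        Sentinel Network Connectivity Results
========================================================
Label:                      (unlabelled)
Sentinel nodes:             20
Node pairs solved:          190
Unreachable pairs:          0
Grid cells (valid):         6400
Graph edges:                25122
Connectivity:               8-neighbor, conductance averaging
--------------------------------------------------------
MPER (ohms):                4.80693
SE (ohms):                  0.378486
Mean current (A):           2.10703
Isolation min/median/max:   2.75251 / 3.23698 / 19.1222
Most isolated node:         park-019
========================================================
sentinet 0.1.0; SE = sd(pairwise R)/sqrt(n_pairs)
```

The MPER of 4.81 ± 0.38 Ω is the baseline; park-019 is the most isolated
park in this synthetic network. Simulated land-use change moves the
indicator in the expected direction:

```python
dev  = sn.generate_scenario_footprints("development", 12.0, "low",  model.cost, seed=9)
park = sn.generate_scenario_footprints("park",        12.0, "high", model.cost, seed=10)
model.with_edit(dev).fit().compare(res)    #  +0.01344  (connectivity loss)
model.with_edit(park).fit().compare(res)   #  -0.00478  (connectivity gain)
```

How many sentinel nodes are enough? Sweep subset sizes and find where the
subset current map stops changing relative to the full complement:

```python
table = sn.node_count_sweep(model.grid, model.nodes, seed=1)
k_star = sn.detect_sufficiency(table, rho_threshold=0.99)
```

A CLI mirrors the library (`sentinet simulate`, `build-cost`,
`run-pairwise`, `sweep`, `run --config cfg.yaml`); the `run` pipeline
persists the sentinel set and re-loads it on re-runs so repeated analyses
are byte-identical.

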