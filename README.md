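# thermovuln

Trait-based assessment of marine-mammal vulnerability to ocean warming, with
downstream erosion analysis of functional and phylogenetic diversity.

## The problem

Marine mammals respond to warming seas through range shifts, prey
mismatches, and reduced reproductive success, but species differ widely in
how much warming they will face and in how well their biology can absorb it.
This package implements a global, species-level vulnerability framework for
that question, aimed at macroecologists and conservation analysts:

* **Sensitivity (S)** — each species is scored on a set of biological and
  ecological traits (feeding, habitat, reproduction, social behaviour,
  intrinsic biology). Every trait is ranked on a three-point scale: 0 (least
  sensitive) to 2 (most sensitive). Quantitative traits are binned by
  splitting the observed value range into three equal parts; qualitative
  traits carry explicit modality → rank maps (e.g. epipelagic habitat use,
  being tied to the fast-warming upper mixed layer, ranks 2). The rank sum
  is normalised by the pool maximum, so S ∈ [0, 1] and the most sensitive
  species scores exactly 1.
* **Exposure (P)** — per climate model, the 30-year-mean sea-surface
  temperature change ΔSST between a baseline and a future period is computed
  on a 1° × 1° grid and averaged over the ensemble. The global distribution
  of |ΔSST| is split into three categories (terciles by default), and for
  each species' range P = a·0 + b·1 + c·2, where a, b, c are the fractions
  of its range cells in the low/mid/high categories. P ∈ [0, 2] and is
  independent of range size; warming and cooling count alike.
* **Vulnerability** — V = P × S: a sensitive species is vulnerable only
  where it is actually exposed. Species are ranked by V, and assemblage-level
  maps average V over the species present in each cell.
* **Diversity erosion** — species are removed from the pool in order of
  vulnerability, at random (999 replicates), or grouped by IUCN category
  (CR → EN → VU → NT → LC → DD), and the remaining functional richness
  (FRic: convex-hull volume in a 4-axis PCoA of function-weighted Gower
  distances) and Faith phylogenetic diversity (PD, averaged over a set of
  trees) are tracked step by step. Functional originality
  (nearest-neighbour Gower distance) and evolutionary distinctiveness
  (fair-proportion apportionment of branch lengths) flag species whose loss
  would be disproportionate.

A seeded synthetic-study generator (`thermovuln.synth`) produces inputs with
the structure the analysis assumes — 123 species with 15 sensitivity / 13
functional traits, cohesive grid ranges, an 11-member SST ensemble with a
heterogeneous warming pattern, 100 resolved trees, realistic IUCN tallies —
so the full pipeline runs and is testable with no external data.

## Worked example

```python
from thermovuln import (SynthConfig, simulate, compute_sensitivity,
                        ensemble_delta, ExposureScorer, compute_vulnerability,
                        rank_species, GowerPCoA, ErosionScenario, run_erosion,
                        compare_curves)

cfg = SynthConfig(n_species=25, seed=7,
                  lat_min=-60, lat_max=60, lon_min=-60, lon_max=60,
                  n_models=5, n_trees=10, range_size_min=10, range_size_max=400,
                  iucn_counts={"CR": 1, "EN": 3, "VU": 3, "NT": 2, "LC": 14, "DD": 2})
study = simulate(cfg)

S = compute_sensitivity(study.traits, study.schema)["S"]
delta = ensemble_delta(study.baselines, study.futures[("rcp85", "2070-2099")],
                       "rcp85", "2070-2099")
P = ExposureScorer("tertile").fit(delta).transform(study.ranges)["P"]
V = rank_species(compute_vulnerability(S, P))
print(V.head(5).round(3))

model = GowerPCoA(study.schema, n_axes=4).fit(study.traits)
vuln = run_erosion(ErosionScenario("vulnerability"), "fric",
                   space=model.space_, V=V)
rand = run_erosion(ErosionScenario("random", n_replicates=199, seed=1),
                   "fric", space=model.space_)
k = 5
print(f"FRic remaining after top-{k} extinctions: {vuln.at_step(k):.3f}")
print(f"random-order mean at the same step:      {rand.at_step(k):.3f}")
print(f"excess loss vs random: {compare_curves(vuln, rand, k):+.1f} pct points")
```

Output:

```text
             S      P      V  rank
species
sp12     0.889  1.968  1.749     1
sp17     0.722  2.000  1.444     2
sp06     0.611  2.000  1.222     3
sp20     0.611  2.000  1.222     4
sp02     0.556  2.000  1.111     5
FRic remaining after top-5 extinctions: 0.767
random-order mean at the same step:      0.763
excess loss vs random: -0.4 pct points
```

`sp12` combines the highest trait-based sensitivity (S = 0.889) with a range
almost entirely in the top warming tercile (P = 1.968), making it the most
vulnerable species (V = 1.749). After removing the top five most vulnerable
species, 76.7% of the pool's functional-trait volume remains — here
indistinguishable from random loss (−0.4 percentage points), as expected
when synthetic traits are drawn independently of the warming pattern.

The same pipeline runs from the shell:

```bash
thermovuln all --config run.yaml --seed 5 --out results/
```

where `run.yaml` holds either a `simulate:` block (as in `tests/test_cli.py`)
or an `inputs:` block pointing at trait/range/SST/tree/IUCN files.

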