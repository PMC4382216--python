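# frugitrack

Radio-telemetry habitat-use analysis for central-place-foraging bats in
fragmented agricultural landscapes.

Small frugivorous bats such as *Dermanura watsoni* roost in natural forest
fragments and forage across a mosaic of forest, degraded vegetation,
farmland, pasture and settlement.  Two observers on foot take simultaneous
compass bearings on a tagged bat every two minutes through six-hour nightly
sessions; everything downstream — where the bat was, how large and how
elongated its range is, which habitats it prefers, and what drives nightly
variation in range size — has to be inferred from those bearing pairs.
`frugitrack` implements that entire chain as a tested, reusable library for
movement ecologists, plus a simulator that generates complete synthetic
studies with known ground truth so every estimator can be validated without
field data.

## What it computes

- **Biangulation** — each bearing pair (azimuths θ₁, θ₂ from observer
  positions, degrees clockwise from grid north) is intersected as rays
  (sin θ, cos θ).  Pairs are rejected when the bearing separation falls
  outside 15–165°, the intersection lies behind an observer, or either
  observer would be beyond the 400 m transmitter range.  Consecutive fixes
  within a stationary radius (default 50 m) collapse to one point.
- **Home ranges** — percent minimum convex polygons (95% MCP = total home
  range HR_tot, peeling the fixes farthest from the centroid) and fixed
  k-LoCoH isopleths with k = round(√n): one local hull per fix from its
  k−1 nearest neighbours, unioned in order of increasing area until 50% of
  fixes are covered.  Disjoint isopleth components are the bat's focal
  foraging areas.  Shape is summarised by the isoperimetric compactness
  ratio 4πA/P² (1 for a circle, → 0 for linear ranges).
- **Habitat selection** — Manly selection ratios under design III (use and
  availability per individual): wᵢ = Σⱼuᵢⱼ / Σⱼu₊ⱼπᵢⱼ over bats j, with
  availability πᵢⱼ the composition of a circle around the day roost
  reaching the far edge of the 95% MCP, simultaneous Bonferroni confidence
  intervals at the α/(2I) quantile, and a log-likelihood χ².  Near/far
  focus-area composition is compared with exact r×c Fisher tests under a
  Holm (sequential Bonferroni) correction.
- **Daily-range models** — random-intercept linear mixed models of
  ln(daily range), y = Xβ + b_bat + ε, fitted by profiled maximum
  likelihood; all 2⁴ subsets of {disturbance, day, moon, sex} ranked by
  AICc; Akaike weights, Δ2 top set, model-averaged coefficients with
  unconditional standard errors, relative importance, conditional R², and
  VIF screening.
- **Synthetic studies** — categorical mosaic landscapes, goal-biased
  correlated-random-walk bats (residents, and commuters with nightly bouts
  to a far foraging site), and noisy two-observer bearings.

## Worked example

Summary statistics of a 16-bat reference study ship with the package:

```sh
$ frugitrack geometry
HR_tot: mean 11.3 ha, SD 9.1 ha, range 1.7-30.6 ha (n = 16)
Pearson r(ln HR_tot, compactness) = -0.73 [95% CI -0.90, -0.37], p = 0.0012
```

Total home ranges average 11.3 ± 9.1 ha, and the strong negative
correlation says that larger home ranges are increasingly linear — the
signature of directed commuting bouts rather than uniformly expanded
foraging.

A complete synthetic study runs end to end in seconds:

```sh
$ frugitrack simulate --preset field-like --seed 1 --out study/
wrote synthetic study (16 bats) to study
$ frugitrack run --bearings study/bearings.csv --landcover study/landcover.asc \
    --roosts study/roosts.csv --out report/
report bundle written to report/ (content hash aaf2b5c2440e)
```

`report/` then contains the fix and rejection logs, the per-bat home-range
table (`homerange.csv`), the selection table (`selection.csv`; in the run
above natural forest ranks highest at wᵢ ≈ 1.47 and urban lowest at 0),
the model-set and averaged-coefficient tables (`modelset.csv`,
`coefficients.csv`; disturbance enters the top models with a positive
averaged slope), the focus-area composition table and Fisher tests, and a
`manifest.json` whose content hash is identical across reruns.

## Layout

| module | contents |
| --- | --- |
| `frugitrack.telemetry` | bearing records, biangulation, filters, sessions |
| `frugitrack.homerange` | percent MCP, fixed k-LoCoH, compactness, daily ranges |
| `frugitrack.habitat` | land-cover maps, availability, selection ratios, Fisher/Holm |
| `frugitrack.models` | profiled-ML mixed models, AICc, averaging, VIF, correlations |
| `frugitrack.synthetic` | landscape, movement and bearing simulators |
| `frugitrack.io` / `.pipeline` / `.cli` | file formats, end-to-end pipeline, CLI |

See `docs/methods.md` for the statistical methods, defaults and their
rationale, and known limitations.
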