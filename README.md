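# reacheval

Individually scaled evaluation of upper-limb reaching performance after
stroke, from 2-D center-out reaching kinematics.

## The problem

Robot-aided reaching training records, for every trial, the movement time
and the hand path toward a target at distance *A* and direction *θ*.
Conventional evaluation compares the affected arm against group norms or
against its own past sessions, which ignores what *this* person's normal
reaching looks like.  `reacheval` instead builds a per-person standard of
normal performance from the **less-affected arm** and scores every reach of
the affected arm against it.

## The model and index

Three candidate movement-time models are implemented and compared:

| family | model | fitted space |
|---|---|---|
| `fitts` | T_M = a + b · log₂(2A/W) | ms |
| `almanji_simplified` | T_M = e^k · A^α · AS^β · (NS+1)^d · CI^f | log |
| `proposed` | T_M = e^k · A^α · AS^β | log |

where *AS* is the average speed (path length / T_M), *CI* the curvature
index (path length / straight start-to-target distance, 1 for a straight
reach), and *NS* the number of submovements, counted by a minimal-count
minimum-jerk speed-pulse decomposition.  The `proposed` family is the
*normal reaching* model: it deliberately omits the error-related terms
(NS, CI), so it fits normal reaching well and erroneous reaching poorly —
that asymmetry is what makes it usable as a standard.  Models are fitted by
ordinary least squares after log transformation and compared by R² and AIC.

The affected arm is then scored per target *i* with the normalized error

    e_n(i) = (T_M,a(i) − T_M,e(i)) / T_M,e(i)

where T_M,a is the actual movement time and T_M,e the ideal time predicted
by the less-affected arm's `proposed` model at the trial's own (A, AS).
e_n is computed trial-wise, averaged per target, and drawn as a polar
direction × distance workspace map (display range clipped at the 95th
percentile so one extreme target does not flatten the color axis).

Because clinical recordings are not distributable, the package includes a
seeded synthetic generator that produces full trajectories plus ground-truth
features under a *normal* law (the `proposed` model) and an *erroneous* law
(the power law with submovement and curvature inflation), at the magnitudes
typical of robot-guided reaching (T_M ≈ 1.6–5 s, AS ≈ 0.02–0.08 m/s,
8 directions × 3–5 distances of 6–14 cm).

## Worked example

Simulate a patient (24 less-affected + 48 affected trials on an
8-direction × 3-distance grid), extract features, fit the three models on
the less-affected arm, and map the affected arm's normalized error:

```sh
reacheval simulate --out sim --seed 7
reacheval features --session sim/less_affected.csv --out less.csv
reacheval features --session sim/affected.csv     --out aff.csv
reacheval fit --features less.csv --family all --out models
reacheval evaluate --model models/model_proposed.json --features aff.csv --out records.csv
reacheval map --records records.csv --out map_en
```

which logs:

```
wrote 24 less-affected and 48 affected trials to sim
24 feature rows (24 kept, 0 CI outliers, 0 skipped trials)
48 feature rows (48 kept, 0 CI outliers, 0 skipped trials)
fitts: R2 = 0.601, AIC = 386.5, n = 24
almanji_simplified: R2 = 1.000, AIC = -360.1, n = 24
proposed: R2 = 0.959, AIC = -42.4, n = 24
mean e_n over 24 reachable targets: 0.261
wrote map_en.csv, map_en.png, map_en.svg
```

Reading the numbers: on the less-affected arm Fitts' law fits poorly
(R² = 0.60, positive AIC), the proposed normal model fits well (R² = 0.96,
negative AIC), and the Almanji power law fits almost perfectly — for
kinematically consistent features it contains the identity T_M = CI·A/AS,
so its near-perfect fit carries no information about normality (see
`docs/methods.md`).  The affected arm's mean e_n of 0.26 says its reaches
take on average 26% longer than this person's predicted normal times; the
map shows where in the workspace the deficit concentrates.

The same steps are available as library calls (`generate_patient`,
`extract_features`, `fit_model`, `evaluate_affected`, `build_map`).

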