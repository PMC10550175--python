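# drillscore

Automated, expert-anchored outcome scoring for virtual dental drilling.

Training simulators for root canal access opening produce far more drilled
outcomes than expert dentists can grade by hand: the rubric used in clinical
teaching rates each of the four cardinal tooth walls and the pulp floor with
an integer error category 0–3, giving a total error of 0–15 (lower is
better), and grading hundreds of virtual outcomes this way is infeasible.
`drillscore` implements an automated replacement: the drilled tooth volume is
compared voxel-by-voxel against an expert-approved *ideal* outcome and
condensed into a single score on the same 0–15 scale.

## The method

Within the initial tooth volume, with "positive" = material present
(undrilled), each voxel of an actual outcome is classified against the ideal
outcome:

* **TP** — correctly undrilled, **TN** — correctly drilled,
* **FP** — incorrectly undrilled (*under-drilling*),
* **FN** — incorrectly drilled (*over-drilling*).

From precision `P = TP/(TP+FP)` and sensitivity `S = TP/(TP+FN)`, both are
linearly rescaled onto comparable ranges anchored at their empirically
observed lower ends,

```
P~ = (P − 0.95)/(1 − 0.95)        S~ = (S − 0.2)/(1 − 0.2)
```

and combined into the **Dentist metric**

```
D = (1 − (1.5·S~ + P~)/2.5) · 15
  = 15·(32·FP·TP + 3·FN·TP + 35·FN·FP) / (4·(TP+FN)·(TP+FP))
```

so that `D = 0` for a flawless outcome and `D = 15` at the anchor pair
`(S, P) = (0.2, 0.95)`. Sensitivity penalizes over-drilling, precision
penalizes under-drilling; the 1.5 : 1 weighting and the flip put the result
on the expert rubric scale. The package also provides the F1 baseline, a
suite of 25+ standard binary-classification metrics, essential-outcome
selection (a small, range-covering subset for expert grading), agreement
statistics (Cohen's κ, ICC(2,1)/(2,k), the information-based measure of
disagreement, Pearson r), a procedural molar phantom + drilled-outcome
generator so everything runs without proprietary data, and the pre/post
training-study analytics (learning gain `e_Δ = e₁ − e₀`, IQR outlier
filtering, paired/Welch t-tests, transfer and suitability correlations,
gaze distance, hand-tool calibration math).

## Worked example

```python
import drillscore as ds

phantom = ds.build_tooth_phantom(ds.PhantomConfig.small(seed=1))
plan = ds.DrillPlan(overdrill_extent=0.05, underdrill_fraction=0.05, roughness=0.01, seed=3)
actual = ds.simulate_outcome(phantom, plan)
counts = ds.classify_outcome(phantom.occupancy, phantom.ideal, actual)
comp = ds.component_scores(counts)
print(counts.as_dict())
print(f"P={comp.P:.4f} S={comp.S:.4f} D={ds.dentist_score_from_counts(counts).value:.3f} "
      f"F1={ds.f1_score(counts):.3f}")
```

prints

```
{'TP': 23698, 'TN': 5536, 'FP': 326, 'FN': 1973}
P=0.9864 S=0.9231 D=2.493 F1=0.954
```

— a mild over-drill (1,973 voxels removed that should remain) with a small
retained pocket (326 voxels), scoring D ≈ 2.5 on the 0–15 error scale and an
F1 of 0.95 against the ideal outcome. A flawless plan
(`ds.DrillPlan()`) reproduces the ideal exactly and scores `D = 0.0`.

The same pipeline is scriptable from the shell:

```sh
drillscore generate --n 20 --seed 7 --small --outdir out/   # volumes + manifest.csv
drillscore score --initial out/initial.nrrd --ideal out/ideal.nrrd \
                 --actual out/outcome_000.nrrd --metric all --out report.json
drillscore select-essential --in scores.csv --k 20 --out essential.csv
drillscore validate --in ratings.csv --out agreement.json
drillscore analyze --cohort cohort.csv --out analysis.json
```

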