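# herdwatch

Sentinel-herd movement analytics for human-intrusion early warning.

Savanna herbivores flee from humans long before a ranger patrol would spot
the humans themselves. If a herd of collared zebra, wildebeest, eland or
impala suddenly moves faster, straighter, more aligned and *away* from
something, that something can be detected and even placed on a map — using
nothing but the animals' GPS and accelerometer collars. `herdwatch`
implements that whole analysis chain as a tested Python library for
movement ecologists and conservation-technology developers:

1. **Synthetic study system** — multi-species herds with three-zone social
   interactions and rest/graze/walk behavioral states on a generated
   landscape; staged intrusions on foot or by vehicle; planted
   flight/regroup responses with species-specific Gamma-distributed
   durations (zebra mean 47 min, wildebeest 39, eland 46, impala 43);
   collar-realistic degradation (15/10/2-min adaptive GPS schedule, 5-m
   geofence, positional noise, spike outliers, 15-s ODBA summaries).
2. **Trajectory reconstruction** — gross-error filtering, spike correction
   (legs > 500 m, small neighbor gap, near-180° turn), a
   local-linear-trend Kalman smoother with per-track ML variances,
   ODBA-informed densification (displacement only where the accelerometer
   says the animal moved), and weighted-spline resampling to a strict
   1-min grid.
3. **Feature engineering** — individual geometry (speed, turning,
   persistence, net/gross ratio, MSD fit, first-passage-time variance),
   accelerometer, collective (alignment, synchrony, neighbor distances)
   and space-use features (habitat suitability, tree cover, Tobler
   movement-cost proxy), each standardized against contextual reference
   sets (species, 30-m area, time-of-day × 5-week period, individual) so
   that *deviation from normal behavior under comparable conditions* is
   the signal, plus moving-window variants and ordinal discretization.
4. **Per-animal classification** — RBF-kernel C-SVMs (γ = 10⁻³·², C =
   10⁻²·², first 8 principal components of the importance-selected
   feature space) emitting per-minute response probabilities, smoothed by
   a centered ±15-min running maximum, validated leave-one-intrusion-out.
5. **System-level detection** — 15-min block features of the probability
   field (level, Moran's I spatial autocorrelation, nearest-neighbor
   clustering of predicted-undisturbed sentinels, behavior-cluster odds),
   aggregated by eight summary statistics, ordered by iterative
   residualized two-sample t-tests, and classified by logistic regression
   under 25× stratified twofold cross-validation.
6. **Intruder localization** — for every map cell *i* and sentinel *j* an
   odds ratio

   O<sub>ij</sub> = [ p<sub>j</sub>·f<sub>wn</sub>(θ<sub>ij</sub>; μ<sub>j</sub>, ρ₁(t<sub>s</sub>))·f<sub>ln</sub>(γ<sub>ij</sub>; μ₁(t<sub>s</sub>), σ₁(t<sub>s</sub>)) + (1−p<sub>j</sub>)·f<sub>wn</sub>(θ<sub>ij</sub>; μ<sub>j</sub>, ρ₀)·f<sub>ln</sub>(γ<sub>ij</sub>; μ₀, σ₀) ] / [ f<sub>wn</sub>(θ<sub>ij</sub>; μ<sub>j</sub>, ρ₀)·f<sub>ln</sub>(γ<sub>ij</sub>; μ₀, σ₀) ]

   where f<sub>wn</sub> is the wrapped-normal density around the animal's
   movement direction μ<sub>j</sub>, f<sub>ln</sub> the lognormal density
   of the cell-to-animal distance γ<sub>ij</sub>, p<sub>j</sub> the
   SVM-predicted response probability, and the response-state parameters
   are 3rd-order polynomials in t<sub>s</sub>, the minutes since response
   onset (truncated at 45). The probability surface P<sub>i</sub> =
   α·Σ<sub>j</sub> O<sub>ij</sub> is normalized to integrate to 1 over the
   study bounding box; its peak is the intruder estimate and the area
   holding the top 5% of its mass scores the surface's confidence.

## Worked example

```bash
python examples/01_simulate_world.py
```

```
animals simulated:        8
animals that responded:   8
flight episodes:          15 (15 completed inside the window)
mean completed flight:    51.1 min (zebra population mean is 47 min; ...)
labelled response time:   41.8% of all animal-seconds in these four hours
```

Eight zebra met a staged intruder; every animal fled at least once, and the
completed flight episodes average close to the species' configured 47-min
mean. `examples/02_reconstruct_trajectory.py` then degrades such tracks to
collar output and reconstructs them (median 1-min position error ≈ 26 m at
25 m GPS noise), and `examples/05_detect_and_localize.py` runs the whole
chain on six staged intrusions plus paired controls:

```
detection (pooled confusion matrix, truth rows x prediction cols):
prediction  control  intrusion
truth
control          54          6
intrusion         4         56
accuracy 0.917 +/- 0.079, precision 0.921, recall 0.933
```

The remaining examples cover feature engineering (03) and the behavior
classifier with its leave-one-intrusion-out audit (04). The `herdwatch`
command exposes the same pipeline from the shell
(`herdwatch run --seed 11 --out myrun`, `herdwatch simulate`,
`herdwatch report`).

## Layout

```
src/herdwatch/        synthetic.py  preprocess.py  features.py  selection.py
                      classify.py   detect.py      localize.py  pipeline.py
                      io.py         cli.py
examples/             one narrative script per capability
docs/methods.md       models, parameters, design decisions, limitations
tests/                pytest suite (unit, property, acceptance)
```
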