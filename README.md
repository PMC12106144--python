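# routinewatch

Behaviour modelling and interpretable anomaly detection for older adults
living in sensorised smart homes.

Ambient assisted-living deployments log a stream of labelled sensor
events — each event carries a timestamp, a sensor identifier, a reading,
and the activity of daily living (ADL) recognised at that moment.
`routinewatch` turns such logs into **daily activity-dedication profiles**
(the percentage of each day spent in each of a comprehensive set of
recognised activities, 41 by default), learns the population's day-to-day
routine with recurrent neural networks, and flags days whose behaviour
deviates significantly — explaining *which* activities deviated and in
which direction. The intended users are researchers and engineers building
preventive monitoring systems, where an unexplained change in routine
(sleeping far less, entertaining guests all day, many night-time bathroom
trips) is a prompt for a professional to look closer, not a diagnosis.

## The model

Each user *i* is a sequence of days, and each day *j* is a vector
*D*<sub>*ij*</sub> = (*a*<sub>*ij*1</sub>, …, *a*<sub>*ijt*</sub>) of
dedication percentages, *a*<sub>*ijk*</sub> ∈ [0, 100]. The pipeline:

1. **Ingest** — consecutive events with the same activity label are merged
   into episodes (an episode ends where the next one begins), episodes are
   framed within calendar days, and per-day durations become percentages
   of the 86,400-second day. The unpredictable `Other_Activity` catch-all
   column is dropped.
2. **Next-day prediction** — a sliding window of *w* days (default 15)
   moves one day at a time; the first *w* − 1 days are the input block and
   day *w* is the label: *f* : ℝ<sup>(w−1)×t</sup> → ℝ<sup>t</sup>.
   Models: a column-mean baseline, per-label classical regressors on a
   single previous day (kNN, SVR, Bayesian linear, AdaBoost, random
   forest, feed-forward net), and four recurrent architectures built on
   LSTM cells — plain LSTM, bidirectional LSTM, Conv+LSTM, and LSTM with
   an additive attention layer over time steps. The final layer is
   rectified, so predicted dedications are non-negative. Models are scored
   by per-day MSE and MAE under chronological 3-fold cross-validation,
   compared with a paired t-test.
3. **Two-step anomaly detection** — per-day prediction errors
   ε<sub>*ij*</sub> = MAE(*D*<sub>*ij*</sub>, *D̂*<sub>*ij*</sub>) are
   modelled as Gaussian with population mean μ and standard deviation σ.
   A day is *flagged* when its z-score (ε − μ)/σ strictly exceeds
   Z = Φ<sup>−1</sup>(p), with p = 0.925 by default. A flagged day is
   *reported* only if at least one activity lies outside its population
   boxplot whiskers [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; those activities, with
   direction and violated limit, are the anomaly's explanation.
4. **Routine discovery** — k-means over day vectors with silhouette
   scoring, for a coarse picture of the population's routine archetypes.

A seeded synthetic-population generator (`routinewatch.simulate`)
produces corpora with known structure — behavioural archetypes, per-user
random effects, weekday/weekend modulation, logit-normal daily noise —
plus injectable ground-truth anomalies and an event-stream renderer that
inverts the ingest pipeline, so the whole system is testable end to end.

## Worked example

```
routinewatch simulate --out run/sim --users 30 --days 75 --seed 1
routinewatch train    --table run/sim/dedication.csv --out run/model \
                      -w 15 --epochs 20 --learning-rate 0.01 --seed 1
routinewatch detect   --table run/sim/dedication.csv \
                      --checkpoint run/model/checkpoint --out run/anomalies
routinewatch cluster  --table run/sim/dedication.csv --out run/clusters
```

`train` reports a test MSE of **1.76** (squared percentage points per
activity-day) against **2.82** for the mean baseline on the same corpus —
the model has learned the weekly periodicity and per-user levels the
generator planted. `detect` then prints, per subset:

```
train: step1=91 anomalies=82 mean_deviated=2.0
test: step1=28 anomalies=23 mean_deviated=2.3
```

meaning (for the test subset) 28 days exceeded the error z-score
threshold, 23 of them also had at least one activity outside its whiskers
(the rest were prediction misses without any abnormal dedication — likely
false positives the second step filtered out), and a reported anomaly
deviated in 2.3 activities on average. `run/anomalies/anomalies.csv`
lists one row per deviated activity:

```
user,day,day_id,activity,dedication,description
syn000,2012-08-24,22,Exercise,3.26%,Dedication over the 2.95%
syn001,2012-08-22,20,Bed_Toilet_Transition,0.69%,Dedication over the 0.62%
```

`cluster` reports the silhouette-maximising k over a 2–10 grid
(`best k=2 silhouette=0.322` here — the weak-but-present separation
typical of daily-routine data).

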