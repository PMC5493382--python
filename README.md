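# skintemp

Proximal and distal skin temperature are routinely monitored in circadian
and sleep research with nine wireless skin sensors: five proximal sites —
abdomen (A), left/right infra-clavicular area (LIA, RIA), left/right
mid-thigh (LMT, RMT) — and four distal sites — left/right hand (LH, RH) and
left/right foot (LF, RF). The composites are fixed weighted averages,

```
T_PROX = 0.324·T_A + 0.1465·T_LIA + 0.1465·T_RIA + 0.1915·T_LMT + 0.1915·T_RMT
T_DIST = 0.25·T_LF + 0.25·T_RF + 0.25·T_LH + 0.25·T_RH
```

In practice sensors fall off or must be removed, and the fixed formulas are
then undefined. `skintemp` answers the operational question *"which sensors
can I lose, and what accuracy should I expect?"*: for **every** nonempty
subset of each group (31 proximal, 15 distal) it re-tunes the weights by
unconstrained, no-intercept linear least squares against the full-set
reference,

```
ŵ = argmin_w ‖T − X w‖²  =  (XᵀX)⁻¹ Xᵀ T ,     T̂ = X ŵ ,
```

where X (N×P) stacks the P available sensors' pooled *macro-signals* (all
subjects' group-complete samples appended in subject order) and T is the
reference composite at the same rows. Each subset's reconstruction accuracy
is quantified by the training MSE and MAE, the leave-one-subject-out
cross-validation error (CVE), the signed-error quartiles Q1/Q3, and a
day/night MAE split — the machine-readable twin of the protocol's operative
weight tables, plus a lookup tool for whatever sensors survive.

Because no public multi-site cohort accompanies the protocol, the package
includes a first-class synthetic-cohort generator (per-site cosinor rhythms,
subject offsets, correlated left/right noise, logger quantization, non-wear
gaps) so the entire analysis is testable end to end; it also reads real
iButton-style `timestamp,temperature_C` CSV exports.

Intended users: chronobiology/sleep researchers and clinical teams running
wearable skin-temperature protocols, and methodologists studying sensor
subset selection.

## Worked example

```python
import skintemp as st

cohort = st.preprocess(st.generate_cohort(st.SyntheticConfig(seed=1)))
table  = st.fit_all(cohort, st.SiteGroup.PROX)       # all 31 proximal subsets
df     = table.to_frame()
print(df[df.n_sensors == 3].sort_values("mse").head(4).to_string(index=False))
```

```
 n_sensors subset_id  n_samples    mse    mae    cve      q1     q3  mae_day  mae_night      A    LIA    RIA    LMT    RMT
         3 A+LIA+LMT       6100 0.0011 0.0267 0.0267 -0.0225 0.0226   0.0267     0.0267 0.3402 0.2849 0.0000 0.3746 0.0000
         3 A+LIA+RMT       6100 0.0011 0.0265 0.0265 -0.0226 0.0226   0.0266     0.0263 0.3402 0.2846 0.0000 0.0000 0.3749
         3 A+RIA+RMT       6100 0.0011 0.0268 0.0268 -0.0223 0.0228   0.0268     0.0267 0.3364 0.0000 0.2871 0.0000 0.3763
         3 A+RIA+LMT       6100 0.0011 0.0267 0.0267 -0.0227 0.0227   0.0271     0.0264 0.3356 0.0000 0.2880 0.3761 0.0000
```

The four best 3-sensor proximal configurations are exactly the
*non-homologous* placements (abdomen + one infra-clavicular + one
mid-thigh): left/right homologues are strongly correlated, so a second
sensor on the same region adds little. MSE is in °C², everything else in
°C; `cve ≈ mae` means the weights generalize to unseen subjects. If only
A, RIA and RMT survive:

```python
row = table.lookup(["A", "RIA", "RMT"])
# weights A=0.3364, RIA=0.2871, RMT=0.3763; expect ~0.027 °C MAE
estimate = st.apply_weights(row.weights, cohort.recordings[0])
```

Fitting all five proximal sensors returns the fixed formula weights
(0.324, 0.1465, 0.1465, 0.1915, 0.1915) with MSE = 0 — the reference is an
exact linear combination of its sensors — and the analogous distal fit
returns 0.25 per sensor.

The package also ships the published protocol tables
(`st.load_published_table(st.SiteGroup.PROX)`) so weights can be looked up
without refitting, and a CLI mirroring the library:

```bash
skintemp simulate --out cohort/                 # synthetic cohort + manifest
skintemp fit --manifest cohort/manifest.csv --group prox --out prox.csv
skintemp lookup --available A,RIA,RMT --group prox --table prox.csv
skintemp apply --manifest cohort/manifest.csv --available LF,LH,RH \
        --group dist --out applied/
```

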