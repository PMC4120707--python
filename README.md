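# gazecues

Analysis pipeline for a classic question in social-vision psychophysics:
**how does the orientation of a person's head bias where their eyes appear
to be looking?** Observers judge the gaze of a face (rotated head, deviated
eyes) as *left*, *direct* or *right*. Two opposing biases are at work:

- a **repulsive** effect — rotating the head changes the visible geometry of
  the eye region (iris eccentricity within the eye opening), pushing
  perceived gaze *away* from the head orientation;
- an **attractive** effect — the visible head acts as a direct contextual
  cue pulling perceived gaze *toward* the head orientation (the Wollaston
  effect).

The package implements the full dual-route analysis that separates the two:
factorial trial designs, a generative trinomial observer for simulation and
parameter recovery, logistic psychometric fits, the cue-weight algebra, and
maximum-likelihood fitting of the two-criterion categorization model. It is
aimed at psychophysicists who want to run, simulate, or power-analyze this
kind of gaze-categorization experiment.

## The model

Responses are recoded (left = 0, direct = 0.5, right = 1) and the
proportion-rightward score per eye deviation *E* is fitted, per head
orientation *H*, with a logistic; its 50% point is the eye deviation of
*subjectively direct gaze* (PSE). Regressing the PSE on *H* gives a slope
*m*, which fixes the cue weights (constrained to sum to one):

```
G = 1/(1−m) · E  +  m/(m−1) · H
```

A negative head weight means repulsion. Fitting *m* separately with the
head visible (whole-head condition, m_WH) and occluded (eye-region
condition, m_ER) decomposes the whole-head percept into the two routes:

```
G_WH = (1−m_ER)/(1−m_WH) · G_ER  +  (m_WH−m_ER)/(m_WH−1) · H
```

whose second coefficient is the **direct-route weight** of head
orientation. Independently, the trinomial categorization model represents a
gaze stimulus internally as Gaussian noise (SD σ_rep) around its direction,
cut by two criteria b_L < b_R; the category probabilities are the Gaussian
areas over the three intervals. Its MLE per head orientation yields the
*peak* of perceptually direct gaze ((b_L+b_R)/2), the *width* of the cone
of direct gaze (b_R−b_L), and σ_rep.

## Worked example

Simulate a 20-observer study in the default regime (eye-route head weight
−0.25 ± 0.05, direct head weight 0.15 ± 0.05, leftward bias −1°, σ_rep = 3°,
criteria ±4°) and run every fitting stage:

```
python analysis/01_trial_designs.py
python analysis/02_simulate_study.py
python analysis/03_psychometric_and_weights.py
python analysis/04_category_model.py
python analysis/05_small_sample_robustness.py
```

The third script prints (this run's simulated population happened to draw a
true mean direct weight of 0.1747):

```
group-average cue weights:
subject  condition  slope_m  intercept_deg  w_eye  w_head
  group eye_region   0.1905         0.6959 1.2354 -0.2354
  group whole_head   0.0170         0.6710 1.0173 -0.0173

dual-route decomposition (group): {'m_WH': 0.017, 'm_ER': 0.1905,
 'w_er_route': 0.8235, 'w_direct': 0.1765, 'w_direct_subject_mean': 0.1753}

per-subject t tests against zero:
  w_head (whole head): mean=-0.020, t(19)=-1.37, p=0.19, d=-0.31
  w_head (eye region): mean=-0.237, t(19)=-19.47, p=5.2e-14, d=-4.35
  w_direct: mean=+0.175, t(19)=+17.96, p=2.2e-13, d=+4.02
```

Reading: perceived gaze is repelled from the head in both conditions
(negative head weights), much more strongly when the head context is hidden
(−0.235 vs −0.017); the decomposition attributes the difference to a
positive direct route (w_direct ≈ 0.175, recovering the simulated
population's 0.1747). The fourth script shows the same signature in the
categorization model: the peak of direct gaze shifts with head orientation
at slope 0.193 in the eye-region condition but only 0.015 with the head
visible.

The same stages are available as a CLI
(`gazecues design|simulate|fit-psychometric|fit-weights|fit-category|run`)
for use on real trial-record CSVs.

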