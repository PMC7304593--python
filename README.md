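# boutondyn

Longitudinal analysis of **en-passant axonal boutons** in chronic
two-photon imaging. Presynaptic boutons are fluorescent swellings along
thin axons (e.g. long-range corticocortical or thalamocortical axons in
cortical layer 1); following the *same* boutons over days of learning
requires detecting them along a traced axon, sizing them in an
illumination-invariant way, and re-identifying them across imaging
sessions before any turnover statistic can be computed. `boutondyn`
implements that pipeline, together with a synthetic-scene generator with
known ground truth so every stage is verifiable by parameter recovery.

## The measurements

**Bouton weight.** For a traced axon with arc-length fluorescence
profile *I(s)*, the shaft baseline *B(s)* is a robust iterative Gaussian
smooth of *I* (peaks are clipped so they cannot inflate their own
baseline), and the bouton weight is

    w(s) = I(s) / B(s)

so `w = 1` is bare shaft and a weight is independent of laser power and
labeling strength. Local maxima of *w* are bouton candidates; a peak
with `w > 2` is a putative bouton, a tracked bouton enters the
longitudinal analysis only if `w > 3` in at least one session, and a
bouton is considered **eliminated** once its weight falls below 1.3.

**Identity across sessions.** Sessions of one axon are aligned by
landmark boutons (large, stable swellings); two detections are the same
bouton when their landmark-relative arc-length positions differ by less
than 0.7 um. A bouton that disappears and later returns within 0.7 um of
its expected position re-joins the same identity (reappearance).

**Dynamics.** Per inter-session interval with `n_prev` boutons at its
start: formation rate `f = n_new / n_prev`, elimination rate
`e = n_elim / n_prev`, turnover `(f + e) / 2`; period-averaged rates are
the unweighted mean over the intervals (days 0–2, 2–4, 4–7). The
survival fraction *S(day)* is the fraction of day-0 boutons still
identifiable, with reappeared boutons counting as surviving; linear
density is boutons per um of traced axon. Group comparisons use the
pooled two-sample t-test (df = n1 + n2 − 2), the two-sample
Kolmogorov–Smirnov test for size distributions, and Pearson correlation.

## Worked example

```python
import boutondyn as bd

scene = bd.generate_scene(7, length_um=200.0)   # ground-truth field
res = bd.analyze_scene(scene)                    # render → detect → track
summ = bd.summarize_tracks(res.tracks, res.session_days,
                           res.traced_length_um, unit_id="field0")
n0 = sum(o.is_putative for o in res.observations_by_day[0])
print(f"traced axon: {res.traced_length_um:.1f} um, "
      f"day-0 boutons: {n0}, density: {n0 / res.traced_length_um:.3f} /um")
print(summ.per_interval.to_string(index=False,
      float_format=lambda v: f"{v:.3f}"))
print("period-averaged:",
      {k: round(v, 3) for k, v in summ.period_averaged.items()})
print("survival:", {d: round(s, 3) for d, s in summ.survival.items()})
```

prints

```
traced axon: 200.1 um, day-0 boutons: 24, density: 0.120 /um
 day_start  day_end  formation_rate  elimination_rate  turnover_rate
         0        2           0.095             0.095          0.095
         2        4           0.048             0.048          0.048
         4        7           0.000             0.095          0.048
period-averaged: {'formation_rate': 0.048, 'elimination_rate': 0.079, 'turnover_rate': 0.063}
survival: {0: 1.0, 2: 0.905, 4: 0.857, 7: 0.81}
```

This field was generated at the default study conditions (density
0.12 boutons/um, imaging days 0/2/4/7): 24 boutons detected on 200 um of
axon recovers the programmed density exactly; 2 of the 21
analysis-included boutons were eliminated and 1 formed during days 0–2,
giving the 0.095 interval rates; 81% of the day-0 population survives to
day 7.

Scenes round-trip through standard formats — per-session TIFF stacks,
an SWC trace and a ground-truth CSV via `bd.write_scene(scene, dir)`,
re-analysed from disk with `bd.analyze_scene_dir(dir)`.

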