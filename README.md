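# grazetrack

Analysis toolkit for GPS-collar studies of cattle grazing behavior under
pasture weed encroachment, with a matched synthetic-herd generator for
validating every stage of the pipeline against known ground truth.

The motivating study design: steers graze small (~1.3 ha) bermudagrass
paddocks assigned to three treatments — weed-free, weed-infested, or planted
weed strips (about 48% of the paddock in spiny pigweed strips) — in a
randomized complete block design with four blocks, two tester animals per
paddock, and repeated 21-day collar deployments logging one fix per second.
The questions the toolkit answers from such data:

- How far do animals travel per day, and at what rate, under each treatment?
- How is the day budgeted among resting, grazing, and traveling?
- Which paddock sites (shade, water, forage strips) are preferred relative
  to their area, and where are the use hotspots?
- Are treatment contrasts statistically supported under the block design,
  and was the herd under heat stress while observed?

## The model in brief

**Movement metrics.** Fixes are cleaned (duplicate timestamps dropped,
out-of-order fixes re-sorted), geofenced to the paddock boundary (closed
convention: boundary points count as inside), and split into local calendar
days; days below a coverage threshold (default 80% of expected fixes) are
flagged and excluded from summaries. Consecutive identical positions are
collapsed so each step measures *time to change position*; daily distance is
the sum of step lengths and rate of travel is distance over moving time, in
m/min. Steps spanning recording gaps longer than `max_gap_s` are invalid and
excluded, but long *stationary* runs are kept — immobility is data.

**Activity budgets.** Step speeds classify behavior with fixed thresholds:
resting below 2.34 m/min, traveling above 25 m/min, grazing between (both
boundaries fall to grazing). Budgets are dt-weighted percentages of
classified time per day.

**Site use.** Zone occupancy is the share of fixes inside each zone of
interest. The Landscape Preference Index is

```
LPI = (proportion of time in zone) / (proportion of area in zone)
```

so LPI = 1 means use proportional to availability. Heatmaps are kernel
density surfaces (quartic kernel by default) computed by binning fixes and
convolving with the discretized kernel, with mass conserved to the fix
count; hotspots are cells above a density quantile.

**Heat stress.** The temperature–humidity index is

```
THI = 1.8·Tdb + 32 − (0.55 − 0.0055·RH)·(1.8·Tdb − 26.8)
```

with Tdb in °C and RH in percent; 74–79 indicates light heat stress in beef
cattle. At RH = 100 it reduces to the Fahrenheit temperature and at
Tdb = 26.8/1.8 ≈ 14.9 °C it is independent of humidity.

**Statistics.** Animal-days are averaged to paddock-days (tester means),
then to paddock × period cells, and analyzed with a fixed-effects
randomized-complete-block ANOVA,

```
Y_ijk = μ + τ_i + β_j + t_k + (τ×t)_ik + ε_ijk
```

(treatment, block, period, treatment × period), with the classical balanced
sums-of-squares decomposition, treatment SEM from the residual mean square,
and compact letter displays from pairwise t tests.

**Synthetic herd.** The generator produces 1 Hz tracks from a semi-Markov
bout process (exponential bout lengths; when a target budget is set, daily
state quotas are split into bouts so the true budget equals the design), a
correlated random walk with wrapped-Cauchy turning angles, goal-directed
walks to shade/water before rests, reflective paddock boundaries, and a GPS
error model (slowly drifting correlated error with zero-order hold and
coordinate quantization, 5 m SD by default). Treatment defaults encode the
three study conditions, e.g. the weed-infested budget 85.1/8.9/6.0% with
5657 m/day designed travel.

## Worked example

```python
from grazetrack.synthetic_herd import SimulationConfig, simulate_trajectory
from grazetrack.activity_budget import day_budget_from_trajectory
from grazetrack.trajectory_metrics import daily_distance, mean_rate_of_travel, step_metrics
from grazetrack.site_use import zone_occupancy, lpi

cfg = SimulationConfig(target_budget=(85.1, 8.9, 6.0))  # weed-infested design
traj, truth = simulate_trajectory(cfg, seed=42)         # one full day at 1 Hz

steps = step_metrics(traj, max_gap_s=300.0)
budget = day_budget_from_trajectory(traj)
print(f"fixes: {len(traj)}")
print(f"daily distance: {daily_distance(steps):.0f} m")
print(f"mean rate of travel: {mean_rate_of_travel(steps):.1f} m/min")
print(f"budget: {budget.resting_pct:.1f} / {budget.grazing_pct:.1f} / "
      f"{budget.traveling_pct:.1f} % (rest/graze/travel)")

occ = zone_occupancy(traj, cfg.zones).set_index("zone")
shade = next(z for z in cfg.zones if z.name == "shade")
pref = lpi(occ.loc["shade", "pct_of_day"] / 100, shade.area_m2 / (130 * 100))
print(f"shade: {occ.loc['shade', 'hours']:.1f} h/day, LPI {pref.lpi:.1f}")
```

Output:

```
fixes: 86400
daily distance: 7398 m
mean rate of travel: 5.1 m/min
budget: 80.7 / 13.2 / 6.1 % (rest/graze/travel)
shade: 4.7 h/day, LPI 4.4
```

The designed ground-truth distance for this configuration is ~5.7 km and the
designed budget 85.1/8.9/6.0 — the overshoot in the printed estimates is the
5 m collar error at work, the same grazing-ward bias and distance inflation
seen in field collar data. Rerun with `gps_noise_sd_m=0.0` and the estimates
match the truth to within a percent.

## Command line

The same stages are exposed as a CLI:

```bash
grazetrack simulate  --out results/study --seed 2022
grazetrack process   --data results/study --out results/metrics
grazetrack summarize --metrics results/metrics --design results/study/design.csv --out results/summaries
grazetrack bias      --out results/bias.csv --reps 20
```

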