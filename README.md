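# worklife

Multistate working-life tables from longitudinal labor-force panels.

`worklife` estimates the expected number of years spent **employed**,
**jobless** and **retired** between a baseline age (40) and a censoring
age (75 for annual panels, 76 for biennial ones), by gender, parity
(number of children: 0, 1, 2, 3+) and education (low/medium/high).  It
is aimed at demographers and labor economists who study how employment
trajectories from midlife onward differ across population groups, using
register or survey panels in which individuals are observed yearly or
every second year.

## The model

Individuals move among three transient labor-force states and one
absorbing state (death).  Transitions are modelled in discrete time with
gender-stratified multinomial logistic regressions: the state at *t* +
*step* depends on the state at *t*, a restricted cubic spline in age,
education, parity, marital status, one country-style categorical
covariate, and an education × parity interaction,

&nbsp;&nbsp;&nbsp;&nbsp;log P(s<sub>t+1</sub> = j | s<sub>t</sub> = i, x) / P(s<sub>t+1</sub> = employed | ·) = α<sub>j</sub> + β<sub>j</sub>ᵀ x + f<sub>j</sub>(age),

with f<sub>j</sub> a natural cubic spline.  Predicted age-specific
transition matrices P(a) — evaluated at sample proportions for
population estimates, or at group indicators for group estimates — are
assembled into the age-expanded absorbing chain ("aged 68 and
employed", ...), whose transient-to-transient matrix U gives the
fundamental matrix **N** = (I − U)⁻¹.  The radix-weighted occupancies
from N, times the step length, are the state expectancies; they sum
exactly to the residual life expectancy over the window.  Optionally,
state-specific death probabilities are proportionally rescaled
(sequentially in age, one factor per age) so that the chain reproduces
an external period life table.  Uncertainty comes from a nonparametric
percentile bootstrap that resamples *persons* with replacement (1,000
replications, 2.5th/97.5th percentiles), preserving each person's full
trajectory.

A synthetic-panel generator with a known multinomial-logit ground truth
emulates both study designs (annual, censored at 75; biennial, censored
at 76), which makes every stage testable end to end without access to
any restricted register or survey data.

## Worked example

```python
import worklife as wl

cfg = wl.default_config(n_persons=20_000, step=1, seed=1)   # annual design
panel = wl.generate_panel(cfg)
records = wl.build_transition_records(panel)
settings = wl.EstimationSettings(groupby=("parity",))
table = wl.estimate_expectancies(records, wl.freeze_knots(records, settings))
print(table.round(1).to_string(index=False))
```

```
gender parity  employment  joblessness  retirement  total
 women      0        20.3          4.6         8.7   33.7
 women      1        21.1          3.5         8.9   33.5
 women      2        21.6          3.1         9.0   33.6
 women     3+        20.1          4.9         8.9   33.9
   men      0        20.0          4.6         8.5   33.1
   men      1        20.8          3.6         8.6   33.0
   men      2        21.6          2.8         8.5   32.9
   men     3+        21.8          2.5         8.4   32.7
```

Each row reads: between exact ages 40 and 75, a woman with two children
exposed to the estimated transition regime expects 21.6 years in
employment, 3.1 jobless, 9.0 retired — 33.6 years of residual life in
the window in total.  Under the default synthetic regime parents of two
have the longest working lives and the three expectancies add up to the
residual life expectancy row by row.

Confidence intervals (person-resampling percentile bootstrap):

```python
table, dropped = wl.bootstrap_expectancies(panel, settings, B=1000, seed=7)
```

The same pipeline is scriptable from the shell:

```sh
worklife simulate --config generator.yaml --out panel.csv
worklife expectancy --panel panel.csv --groups gender,parity --out expectancies.csv
worklife run-all --config run.yaml --outdir results/
```

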