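# metasdt

Signal-detection analysis of **prospective and retrospective metacognition**
for match/nonmatch tasks with pre-decision wagering or belief ratings:
single-subject and hierarchical Bayesian meta-d′/d′ (M-ratio) estimation with
a two-way mixed design, the accompanying behavioral statistics and exclusion
rules, and a calibrated synthetic-task generator.

## The problem

In a delayed match-to-sample task, participants judge whether a probe matches
a remembered sample. Before answering they give a *prospective* rating — a
binary bet on their success (implicit metacognition) or a binary memory
belief (explicit metacognition) — and afterwards a *retrospective* 5-point
confidence rating. The scientific question is whether the way metacognition
is elicited (bet vs. confidence instruction) changes **metacognitive
efficiency** — how well ratings track accuracy — even when task performance
itself is unchanged.

Efficiency is quantified with type-2 signal detection theory. With type-1
sensitivity d′ = z(HR) − z(FAR), **meta-d′** is the sensitivity an SDT-ideal
observer would need to produce the observed rating data (response-conditional
Gaussian model of Maniscalco & Lau), and

    M-ratio = meta-d′ / d′

is efficiency: 1 means ratings use all the evidence behind the decision,
below 1 means metacognitive information loss. Group- and condition-level
effects on M-ratio are estimated with a hierarchical Bayesian model: per
participant *s* and difficulty *c*, rating counts follow the type-2
multinomial likelihood at meta-d′ = m(s,c)·d′(s,c), with

    m(s,c) = μ + β_I·x_I + β_D·x_D + β_ID·x_I·x_D + u_s + ε(s,c),

instruction between participants (x_I = +0.5 for confidence), difficulty
within (x_D = +0.5 for hard), and a participant random intercept u_s. Effects
are summarized by the posterior median, 95% highest-density interval (HDI),
probability of direction (pd), rank-normalized split-R̂ and tail-ESS, and an
effect is declared when the HDI excludes 0 *and* pd > 0.95. The behavioral
layer implements the trial/participant exclusion rules, accuracy/d′/score
summaries, two-way mixed ANOVA with generalized η², paired *t* with Cohen's d
and the JZS Bayes factor, and Levene's test with Holm correction. See
[docs/methods.md](docs/methods.md) for every modeling choice.

## Worked example

```python
from metasdt import RunConfig, SimulationConfig, run_pipeline

config = RunConfig(
    seed=123, simulate=True, simulation=SimulationConfig(seed=321),
    iterations=1500, burnin=500, out_dir="out",
)
result = run_pipeline(config)
print(result["effects"].round(3).to_string(index=False))
```

simulates the full default cohort (104 bet + 100 confidence participants,
6 × 12 trials, d′ calibrated to 70%/60% accuracy, a true instruction effect
on M-ratio but identical d′ across groups), applies the exclusion rules, and
fits both rating phases. Output from this exact run:

```
phase      effect  median  hdi_low  hdi_high    pd  rhat  ess_tail  decision
  pre instruction  -0.400   -0.614    -0.168 1.000 1.017   446.293    effect
  pre  difficulty  -0.203   -0.421     0.022 0.955 1.009   247.392 no-effect
  pre interaction  -0.136   -0.556     0.265 0.745 1.011   562.871 no-effect
 post instruction  -0.077   -0.257     0.104 0.800 1.042   513.649 no-effect
 post  difficulty  -0.321   -0.529    -0.130 0.999 1.034   514.693    effect
 post interaction  -0.047   -0.386     0.311 0.601 1.016   435.756 no-effect
```

Reading it: the pre-phase instruction effect is −0.40 M-ratio units with a
95% HDI of [−0.61, −0.17] and pd = 1.00 — the confidence group's prospective
efficiency is credibly lower, so the decision rule fires ("effect"). The
same run's ANOVA table shows the dissociation that makes this interesting:
instruction does **not** move accuracy (F(1, 202) = 3.37, p = 0.068, η²G =
0.008) or d′ (F = 3.10, p = 0.080), while difficulty moves both (accuracy
F = 127.2, p < 0.001, η²G = 0.246). At these deliberately reduced MCMC
settings a few R-hat values sit just above the 1.01 flag threshold and are
reported as non-converged in `effects.csv`; the package default is
3 × 10,000 iterations with 1,000 burn-in.
`out/` also receives the exclusion report, participant summaries, the full
test table, posterior summaries as CSV/JSON, the simulated trials, the ground
truth, and a manifest that reproduces the run bit-for-bit.

The same pipeline runs from a shell:

```bash
metasdt simulate --out sim --seed 7
metasdt analyze --trials sim/trials.csv --out results --seed 7 \
    --chains 3 --iterations 10000 --burnin 1000
metasdt fit-meta-d --counts my_counts.csv
```

`analyze` accepts any trial CSV with the canonical columns
(`participant_id, instruction, difficulty, session, trial, stimulus,
pre_rating, type1_response, post_rating, rt_pre, rt_answer, rt_post`;
empty fields are missing responses).

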