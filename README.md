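# freeop

Simulation and analysis of **free-operant action–outcome contingency
learning**: how agents adapt their responding to the causal efficacy of an
action, and how well their subjective causal judgements track that same
contingency.

The package is aimed at behavioural and cognitive-neuroscience researchers
who study instrumental contingency learning — in particular the
dissociation, seen in healthy ageing and after ventromedial prefrontal
(vmPFC) damage, between intact *behavioural* adaptation to contingency and
impaired *awareness* of it. Everything runs from synthetic cohorts: no
human data are required to exercise, test or extend the pipeline, and a
loader is provided for archived human task data where exact reproduction
is wanted.

## The task and the model

Each block of the task divides into unsignalled 1-second bins. In a bin
the agent either presses (only the first press counts) or withholds, and
an outcome is then delivered with the block's programmed conditional
probability — P(O|A) after a press, P(O|~A) otherwise. The instrumental
contingency of a block is

    ΔP = P(O|A) − P(O|~A),

positive when pressing causes reward, negative when it prevents it. A
session is 12 blocks of 60 bins: a fixed training triplet (high, degraded,
zero contingency) followed by nine experimental blocks counterbalanced
with a 9×9 cyclic Latin square. Analyses use the five blocks in which one
probability varies while the other is held at zero
(ΔP ∈ {−0.6, −0.3, 0, 0.3, 0.6}), and two per-block outcome measures: the
response rate (presses/bins) and a block-end causal rating on a −100…100
scale.

Synthetic agents track P(O|A) and P(O|~A) with delta-rule estimators,
press via a logistic policy on the estimated ΔP, and rate via a weighted
read-out of the same estimates (see `docs/methods.md`). Group presets —
younger/older controls, an age-matched control group, vmPFC and latPFC
lesion groups — share the policy but differ in the rating read-out, which
is how the performance/awareness dissociation is generated.

The statistics module implements the analyses this task family reports:
Welch t-tests, mixed-design repeated-measures ANOVA (within: contingency
level; between: group) with Mauchly's test and Greenhouse–Geisser /
Huynh–Feldt corrections, generalised η² effect sizes, simple effects, and
Fisher's-LSD within-subject error bars.

## Worked example

```python
from freeop import GROUP_PRESETS, simulate_cohort, mixed_anova, flsd_bars
from freeop.measures import measures_frame

sessions = (
    simulate_cohort(GROUP_PRESETS["younger_control"], 15, seed=7,
                    group="younger_control")
    + simulate_cohort(GROUP_PRESETS["older_control"], 15, seed=8,
                      group="older_control")
)
table = measures_frame(sessions, "negative")   # ΔP ∈ {−0.6, −0.3, 0}
for r in mixed_anova(table, dv="rating", within="delta_p",
                     between="group", subject="subject_id"):
    print(f"{r.effect}: F({r.df_num:g},{r.df_den:g}) = {r.F:.2f}, "
          f"p = {r.p_corrected:.3g}, ges = {r.ges:.2f}")
```

prints

```
group: F(1,28) = 508.13, p = 1.72e-19, ges = 0.76
delta_p: F(2,56) = 14.16, p = 1.05e-05, ges = 0.29
group × delta_p: F(2,56) = 50.78, p = 2.63e-13, ges = 0.60
```

— a strong group × contingency interaction on the negative range: the
young cohort's ratings rise with ΔP while the older cohort's do not (its
ratings are highest at ΔP = −0.6, where free rewards are most frequent),
even though both cohorts adapt their *response rates* to the same
contingencies. The FLSD bars quantify the within-group comparisons; for
the older cohort:

```
older ΔP=-0.6: mean rating  28.80 ± 5.76
older ΔP=-0.3: mean rating  14.40 ± 5.06
older ΔP=+0.0: mean rating   9.73 ± 4.35
```

Two bars that fail to overlap differ by a paired t-test at α = 0.05.

The same pipeline runs from a shell:

```sh
freeop simulate --seed 7 --out run/        # 5 groups, 62 sessions
freeop analyze run/ --sign negative       # measures + ANOVA + report
```

`simulate` writes `session_log.csv` (one row per bin), `ratings.csv` (one
row per block) and a reproducibility manifest; identical seeds give
byte-identical files.

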