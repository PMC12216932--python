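# crowdcourt

Tools for studying when majority-vote collectives succeed and when they
fail. The package is aimed at researchers in collective behaviour and
ensemble machine learning who want to reproduce, at configurable scale, the
breakdown of the "wisdom of crowds" under correlated information — in a
closed-form population model and in committees of real classifiers.

## The models

**Condorcet jury.** `N` voters, each independently correct with probability
`q`, decide by simple majority. The group is correct with probability

    P(D) = Σ_{k > N/2} C(N, k) q^k (1 − q)^(N−k),

which tends to 1 as `N → ∞` whenever `q > 1/2`.

**Correlated-cue population.** Each group member is, with probability `p`,
an *independent* unit that is correct on its own with probability `r_L`;
the rest are *dependent* units that all follow one shared cue, drawn once
per decision problem and correct with probability `r_H` — a single voting
bloc. Independents form an effective majority only above the critical
boundary

    p > 1 / (2 r_L).

Below it, collective accuracy peaks at a finite group size `N*` and then
*declines* — the breakdown regime. The package provides a Monte-Carlo
simulator, an exact oracle (conditioning on the group composition and the
cue draw), an optimal-group-size search and `(r_L, p)` phase diagrams.

**Classifier-judge committees.** The machine-learning counterpart: a roster
of `L` independent judges (each trained on its own balanced bootstrap of
`n_L` samples) and `H` dependent judges (trained on mostly shared data —
a fraction `alpha` of their `n_H` samples is one pool-wide draw). Each test
sample is a court hearing: `N` seats are filled (independent with
probability `p` per seat), every seated judge predicts the sample, and the
strict-majority verdict is scored. Training-sample counts `n_L`, `n_H` play
the role of the reliabilities `r_L`, `r_H`; sweeping `N`, `n_L` and `p`
maps the same wisdom/breakdown phase structure for real models (RBF-kernel
SVMs and decision trees via scikit-learn).

A built-in generator produces the study's two-ring ("circles") dataset:
balanced, two-dimensional, noisy, and deliberately slow to learn; any
tabular binary-classification CSV can be loaded instead.

## Worked example

```python
import crowdcourt as cc

for N in (1, 11, 101, 1001):
    print(f"q=0.6, N={N:5d}: P(majority correct) = "
          f"{cc.majority_probability(cc.JurySpec(0.6, N)):.4f}")

params = cc.SyntheticParams(p=0.6, r_L=0.7, r_H=0.5)
print("critical p for r_L=0.7:", round(cc.critical_p(0.7), 4))
for N in (1, 7, 21, 99):
    print(f"N={N:3d}: exact accuracy = {cc.exact_accuracy(params, N):.4f}")
n_star, acc = cc.optimal_group_size(params, N_max=100)
print(f"optimal group size N* = {n_star} (accuracy {acc:.4f})")
```

prints

```
q=0.6, N=    1: P(majority correct) = 0.6000
q=0.6, N=   11: P(majority correct) = 0.7535
q=0.6, N=  101: P(majority correct) = 0.9791
q=0.6, N= 1001: P(majority correct) = 1.0000
critical p for r_L=0.7: 0.7143
N=  1: exact accuracy = 0.6200
N=  7: exact accuracy = 0.6531
N= 21: exact accuracy = 0.6136
N= 99: exact accuracy = 0.5270
optimal group size N* = 5 (accuracy 0.6544)
```

The jury column shows the classical certainty limit. The population column
sits *below* the critical boundary (p = 0.6 < 0.714): accuracy is maximal
for a five-member group and degrades towards the dependent bloc's
reliability as the group grows.

The same breakdown with real classifiers, from the shell:

```
crowdcourt ensemble-curve --seed 1 --out demo \
    --set p=0.75 --set n_L=40 --set n_H=50
```

writes `demo/curve.csv`; with the desk-scale defaults (circles dataset,
SVM judges, L=200, H=50, M=500 hearings, 20 runs) the mean accuracy rises
from 0.563 at N=1 to a maximum 0.611 at N=21 and falls back to 0.590 at
N=100 — a finite optimal committee. Every experiment kind
(`synthetic-curve`, `synthetic-phase`, `ensemble-curve`, `ensemble-phase`,
`decorrelate`, `nH-sweep`, `learning-curve`) is available as a subcommand
with `--config` (YAML/JSON), `--preset {test,paper}` and `--set key=value`
overrides, and writes CSV results plus a `manifest.json` that fully
reproduces the run.

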