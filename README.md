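# nontransim

Simulation and analysis of **nontransitive fitness evolution in killer-virus
yeast**: a package for population geneticists studying multilevel selection
in serial-transfer evolution experiments.

## The problem

*Saccharomyces cerevisiae* can host a non-infectious double-stranded RNA
"killer" virus (M1) whose K1 preprotoxin both kills virus-free neighbours
and confers immunity on its carrier. During a 1000-generation serial-transfer
experiment, selection acts on two levels at once:

- **among hosts**, nuclear beneficial mutations drive periodic selective
  sweeps;
- **within hosts**, viral variants compete inside each cell's pool of ~10²
  viral copies, and toxin-null variants with a replication advantage take
  over cell lineages, which then hitchhike to fixation on nuclear sweeps.

The combined effect is a genealogical chain Early → Intermediate → Late in
which every step is adaptive, yet the Late clone — having lost both toxin
production and immunity — can *lose* to its distant ancestor. Because the
ancestor's toxin kills in proportion to killer frequency, the outcome is
frequency dependent: writing `s(f₀)` for the Late clone's per-generation
fitness at starting frequency `f₀`, there is a bistable threshold `f*` with
`s(f₀) < 0` for `f₀ < f*` and `s(f₀) > 0` above it.

## What the package computes

| module | computation |
|---|---|
| `nontransim.simcore` | multilevel Wright–Fisher simulator: pairwise competitions under 1:2¹⁰ daily dilution, replicate population evolution with within-cell viral resampling and toxin-mediated killing, heteroplasmic single-cell-bottleneck lines, amplicon FASTQ emission |
| `nontransim.fitness` | relative fitness as the OLS slope of ln(count ratio) per generation; per-interval estimates; frequency-dependence regression with equilibrium `f* = −intercept/β` |
| `nontransim.transitivity` | additive expectations (Σsᵢ or Π(1+sᵢ)−1), triple classification (transitive / nontransitive / frequency-dependent nontransitive), dominance-cycle detection |
| `nontransim.killer_assoc` | killer-phenotype retention trajectories, forbidden-transition audits, 2×2 χ² association of viral mutations with phenotype loss |
| `nontransim.variant_freq` | variant frequency from reads containing the allele flanked by five nucleotides (exact substring, both strands), Wilson intervals, Sanger peak-height ratios, trajectory classification |
| `nontransim.seqstats` | variant effect classification on the K1 ORF, transition:transversion bias vs the 1:2 null, Nei–Gojobori dN/dS, deterministic logistic sweep time `t = (1/s)·ln[f₁(1−f₀)/(f₀(1−f₁))]` |

## Worked example

```python
from nontransim.pipeline import run_scenario

matrix, verdict, freq_dep = run_scenario({"kappa": 0.2}, seed=11)
print(verdict.verdict)            # frequency_dependent_nontransitive
print(round(verdict.expected_s_ik, 3))  # 0.05
print(round(freq_dep.f_star, 2))  # 0.78
```

The Early clone (killer, nuclear fitness 0), Intermediate (non-killer but
immune, +3.8 % per generation) and Late (non-killer, non-immune, +5.0 %)
compete pairwise at starting frequencies 0.1/0.5/0.9. The stepwise gains
predict a 5.0 % long-range advantage, but the observed Early-vs-Late
fitness is negative at low Late frequency and positive at high frequency —
the chain is frequency-dependent nontransitive, with a bistable equilibrium
near 0.78. Rerunning with `{"kappa": 0.0}` (the virus-cured ancestor)
yields `transitive`: the toxin is necessary for the nontransitivity.

The same analyses are available as numbered drivers under `analysis/`
(simulate competitions → fitness and frequency dependence → transitivity →
population phenotypes → intracellular lines → mutation spectrum), each
writing its tables under `results/`, and as a CLI:

```sh
nontransim assoc --table 57,0,1,9
nontransim sweeptime --s 0.3 --n 4e9
nontransim run --out-dir run_out --seed 1
```

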