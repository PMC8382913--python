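# ampliscope

Quantifies how fast antibiotic resistance evolves as a function of dose.
Written for microbial experimental-evolution work in which *E. coli*-like
populations are serially passaged under an erythromycin-like drug gradient,
densities are read continuously in a plate reader, and metapopulations are
deep-sequenced through time. The package implements the theory, the
phenotypic statistics and the genomic selection proxies end to end, with a
ground-truthed synthetic-data generator standing in for raw experimental
data.

## The models and statistics

**Theory.** A drug-susceptible strain S mutates (rate μ) into a resistant
strain R that feels only a fraction λ of the dose A at growth cost ℓ:

    dS/dt = (g(A) − d) S − μS,     dR/dt = (ℓ g(λA) − d) R + μS

with g a decreasing dose response, g(0)=1. With θ₁ = g(A)−d−μ and
θ₂ = ℓg(λA)−d the system solves exactly, and the selection coefficient

    s(A) = θ₂ − θ₁ = ℓ g(λA) − g(A) + μ

is single-peaked in dose — an *inverted-U* whose maximiser is the hotspot
dose, in closed form A_hot = ln(1/(ℓλ)) / (p(1−λ)) for g(A)=e^(−pA). A
logistic competition variant (`theory.simulate_competition`) shows how the
same geometry appears in population-density dose responses. MSC, MIC and
MPC (the mutant selection window) are computed from their defining
equations.

**Phenotype.** Well traces are fitted with linear/exponential/logistic
growth laws, ranked by AICc; the winning fit's blank B₀ corrects the trace.
24-h densities across doses are summarised by a decreasing Hill function;
the MIC is its IC99 (dose where density is 1% of drug-free density); the
effective antibiotic dose (EAD) of a treated culture is the Hill inverse of
its density. The rate of adaptation α = (Δr/2)/t_a (half the phenotype
change over the time to reach the halfway level) is computed per dose and
replicate, backed up by the per-capita statistics r_e and r_auc; the dose
profile of α is classified (inverted-U / monotone / flat / complex) and its
hotspot located. An FFT periodogram quantifies plate-reader oscillations
(~10 h and ~0.75 h).

**Genomics.** Feature coverage is normalized to genome depth and the
ancestral sample ("relative copies"); its time course is fitted with
F(t) = p₁(1+t)/(1+p₂(1+t)) whose maximal derivative is the amplification
*selection proxy*; a quadratic regression of the proxy on dose locates each
gene's hotspot. SNP trajectories (≥5% frequency filter) are fitted with
f(t) = 1/(1+p e^(−st)), s being the SNP selection proxy; the parallelism
coefficient p(g) = P(g)/P* measures each gene's across-dose frequency
pattern against the uniform vector.

## Worked example

```
python analysis/02_simulate_treatments.py
python analysis/04_rates_of_adaptation.py
```

simulates the default treatment design (doses 0,5,…,50 µg/ml, 7 daily
seasons, 8 replicates, 1:100 transfers, seed 1) and prints

```
ground-truth fastest-adapting dose: 30.0 ug/ml
dose profile of alpha: inverted_u, hotspot 30.0 ug/ml
 dose     mean      se  p_vs_zero_dose
  0.0  0.00001 0.00007             NaN
  5.0  0.00007 0.00008         0.57728
 10.0  0.00031 0.00003         0.00080
 ...
 30.0  0.00143 0.00002         0.00000
 35.0  0.00102 0.00001         0.00000
 40.0  0.00011 0.00000         0.13162
 ...
dominant oscillation wavelengths (h): [0.75  1.263]
```

i.e. the rate of adaptation estimated from the noisy plate reads is an
inverted-U peaking at 30 µg/ml — just below the dose at which the simulated
drug abolishes ancestral growth (32 µg/ml) — matching the generator's
ground truth, with the injected 0.75-h instrument oscillation recovered
from the same traces. The remaining drivers (`analysis/01…05`) tabulate the
theory curves, the Hill/MIC/EAD analysis and the genomic selection proxies
into `results/`. The `ampliscope` CLI exposes the same stages
(`ampliscope simulate|theory|fit-growth|dose-response|ead|roa|genomic|run`).

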