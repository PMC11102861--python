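# deadkin

Single-nucleotide kinetics of mRNA deadenylation.

The poly(A) tail of an mRNA is shortened 3'→5' by the CCR4–NOT deadenylase
complex, one nucleotide at a time, and the speed of that shortening sets the
message's lifetime. Non-adenosine residues ("mixed tailing" by TENT4
enzymes) stall the deadenylase. `deadkin` implements the analytical
framework for measuring this process at single-nucleotide resolution from
in vitro deadenylation assays run on denaturing gels: densitometry
pre-processing, a Markov decay-chain model with per-position removal rates,
Levenberg–Marquardt rate estimation with uncertainties, and a stalling
statistic that expresses each non-A residue as an equivalent number of
adenosines. A synthetic-data generator reproduces the assay design
end-to-end so every stage is testable without gel images.

## The model

Let x_i(t) be the abundance of RNA with tail length i. Removal of single
nucleotides with first-order, time-independent rates gives the linear chain

    dx_i/dt = λ_{i+1} x_{i+1} − λ_i x_i ,

with the tailless body absorbing. Rates are reported against tail position
p counted from the 3' end (p = 1 is the first residue removed); gel species
s = 1..N+1 run from the intact substrate to the bare body, with p = s for
the removal event s → s+1. Rates are estimated by MINPACK
Levenberg–Marquardt on unity-normalized intensities, with standard errors
from the Gauss–Newton curvature.

The reciprocal z_p = 1/λ_p is the reaction time to remove one nucleotide.
A non-A residue at tail position r stalls the enzyme at relative positions
−2, −1 and 0 (tail positions r−2, r−1, r). Its **stalling effect size**

    ζ = z(−2)/z_∅(−2) + z(−1)/z_∅(−1) + z(0)/z_∅(0) − 2

counts the adenosines whose removal would take as long as traversing the
residue's influence zone; ζ = 1 means no stalling. The "no stalling"
baseline z_∅ is built from a matched pure-poly(A) control fit by assuming
the gradual tail-length-dependent slowdown is proportional between
experiments:

    b = (z(−3) − z(+2)) / (z_A(−3) − z_A(+2))
    ε(i) = b · (z_A(−3) − z_A(i)),   z_∅(i) = z(−3) − ε(i).

## Worked example

Generate a wild-type A20G assay (20-nt tail, guanosines at tail positions
7 and 14, 2% multiplicative noise) plus its pure-A20 control, fit both,
and quantify the stalling effect of each guanosine:

```sh
deadkin synth --substrate A20G --variant wild_type --seed 7   --sigma 0.02 --out-matrix a20g.tsv
deadkin synth --substrate A20  --variant wild_type --seed 107 --sigma 0.02 --out-matrix a20.tsv
deadkin fit --input a20g.tsv --out-rates rates_a20g.tsv
deadkin fit --input a20.tsv  --out-rates rates_a20.tsv
deadkin stall --rates rates_a20g.tsv --control rates_a20.tsv --substrate A20G --out stall.json
deadkin design --length 100 --count G=10 --zeta G=6
```

prints

```
fit converged; residual norm 1.500e-02; rates -> rates_a20g.tsv
A20G G@7: zeta = 5.46 adenosine-equivalents (b = 1.047)
A20G G@14: zeta = 5.42 adenosine-equivalents (b = 1.058)
100-nt mixed tail ~ pure poly(A) of 150 nt (1.50-fold)
```

Each guanosine of this simulated wild-type assay costs about five and a
half adenosines' worth of reaction time (the generator's ground truth is
ζ = 5.61; the fits recover it to a few percent at this noise level), and a
designed 100-nt tail containing ten guanosines at equivalence 6 behaves
like a 150-nt pure poly(A) tail. The same library calls are available in
Python:

```python
import deadkin as dk

mixed, _ = dk.simulate_noisy_assay(dk.scenario("A20G", "wild_type", seed=7))
ctrl, _ = dk.simulate_noisy_assay(dk.scenario("A20", "wild_type", seed=107))
m_mixed = dk.DeadenylationKineticsModel().fit(mixed)    # sklearn-style
m_ctrl = dk.DeadenylationKineticsModel().fit(ctrl)
assessments = dk.assess_stalling(
    m_mixed.rate_profile(), m_ctrl.rate_profile(), dk.preset("A20G")
)
```

`deadkin quantify` converts gel-lane densitometry profiles (CSV) into the
species × time matrix, and `deadkin plot` renders the column-normalized
viridis heatmap used to visualize accumulation patterns.

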