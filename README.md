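# methylspec

Free-energy analysis of **product specificity in protein lysine
methyltransferases (PKMTs)** — why an enzyme like the SET-domain
methyltransferase GLP stops after adding one, two, or three methyl groups
to its target histone lysine, and how single active-site mutations
(F1209Y at the Phe/Tyr switch, Y1124F) flip that behaviour.

The package is written for computational chemists and structural
bioinformaticians who have umbrella-sampling or MD-style data for the
SN2 methyl transfer and want a tested, reproducible pipeline for the
downstream free-energy analysis.

## What it computes

The methyl group hops from the AdoMet sulfur (Sδ) to the lysine ε-amino
nitrogen (Nζ) in an SN2 reaction monitored by

* the reaction coordinate **R = r(C<sub>M</sub>…S<sub>δ</sub>) − r(C<sub>M</sub>…N<sub>ζ</sub>)**
  (negative in the reactant, positive in the product), and
* the alignment angle **θ** between the lone-pair direction on N<sub>ζ</sub>
  and the C<sub>M</sub>→S<sub>δ</sub> vector (θ = 0° is a perfect in-line attack).

Four stages, each usable on its own:

1. **Reactive geometry** — per-frame (r, θ, R) from labeled trajectory
   frames (multi-frame XYZ or MODEL-delimited PDB); 2-D histograms and
   Boltzmann-inverted free-energy surfaces
   F = −k<sub>B</sub>T ln(p/p<sub>max</sub>); 1-D marginals; geometric
   hydrogen-bond occupancies.
2. **PMF by WHAM** — the Weighted Histogram Analysis Method solved
   self-consistently over harmonically biased umbrella windows
   (bias w(R) = k·(R − c)², the CHARMM convention; a `half_k` flag
   switches to ½k(R − c)²), with barrier extraction and an optional
   empirical correction curve applied by monotone cubic interpolation.
3. **Specificity calculus** — per-step barriers ΔF‡₁..ΔF‡₃ become a
   free-energy triplet referenced to the wild-type first transfer, and a
   mono/di/tri call: the first step whose within-enzyme barrier increase
   reaches the blocking threshold (default 3.0 kcal/mol) stops the
   methylation ladder.
4. **Synthetic data** — analytic model potentials with exactly known
   barriers, inverse-CDF umbrella samples from the biased Boltzmann
   density, and frame ensembles with prescribed (r, θ) statistics, so
   the whole pipeline is testable without an MD engine.

## Worked example

```python
from methylspec import BarrierSet, classify_specificity, compute_triplet

wt     = BarrierSet("WT",     (13.4, 15.8, 22.1))
f1209y = BarrierSet("F1209Y", (13.8, 17.4, None))   # third step not characterized
y1124f = BarrierSet("Y1124F", (13.9, 15.9, 13.3))

for enzyme in (wt, f1209y, y1124f):
    print(enzyme.enzyme, compute_triplet(wt, enzyme).formatted(),
          classify_specificity(enzyme).call)
```

prints

```
WT (0.0, 2.4, 8.7) di
F1209Y (0.4, 4.0, x) mono
Y1124F (0.5, 2.5, -0.1) tri
```

— the wild type blocks at the third transfer (its barrier is
8.7 kcal/mol above the first, so the enzyme stalls at di-methylation),
the F1209Y mutant already blocks at the second (+3.6 kcal/mol within the
enzyme, a mono-methyltransferase), and Y1124F never blocks (a
tri-methyltransferase). The umbrella-sampling side is a few lines too:

```python
from methylspec import extract_barrier, wham_solve
from methylspec.synthetic import default_window_layout, gen_umbrella_windows, make_potential

pot = make_potential("quartic_double_well", barrier=13.4, R_a=-1.4, R_b=1.2)
centers, ks = default_window_layout(pot, n_windows=20)
windows = gen_umbrella_windows(pot, centers, ks, n_per_window=5000, seed=1)
profile = wham_solve(windows, grid=(-1.5, 1.3, 0.05))
print(f"{extract_barrier(profile).barrier:.2f} kcal/mol")   # 13.38
```

The `examples/` directory has one short narrative script per capability;
a thin CLI (`methylspec simulate|geom|pmf|triplet|classify|all`) wraps
the same library for shell use.

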