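# sharkmove

Quantitative behavioural analysis of shark trajectories filmed from above
(UAV videography), built around the whale shark (*Rhincodon typus*)
ecotourism setting: does the presence of a human swimmer change how a shark
moves?

The package takes per-frame planar coordinate tracks (one shark per video,
e.g. exported from a pose tracker such as SLEAP) and provides the full
analysis chain:

1. **Preprocessing** — body-size normalisation, Savitzky–Golay smoothing
   (window 21, cubic), and reduction of each track to *step lengths*
   (displacement per frame, in body lengths) and *turning angles* (change
   of heading per step, wrapped to (−π, π]).
2. **Movement metrics** — 16 per-video summaries: min/max/mean/SD of speed,
   acceleration and turning-angle magnitude, mean directional
   autocorrelation, the straightness indices eMaxA = b/(1−b) (b the mean
   cosine of turning angles) and eMaxB = eMaxA·p̄, and the corrected
   sinuosity S = 2·[p̄((1+c)/(1−c)+b²)]^(−1/2).
3. **Ethospace ordination** — PCA of the z-scored metric matrix, with
   per-group 95% confidence ellipses and a mean-overlap verdict, plus
   per-metric OLS regressions against the binary human-presence indicator.
4. **Hidden Markov modelling** — the core of the package. Step lengths are
   zero-inflated gamma (mean μ, SD σ, zero-mass ζ), turning angles von
   Mises (mean θ, concentration κ), per hidden behavioural state. The
   hidden state evolves as a Markov chain whose transition probabilities
   depend on human presence c ∈ {0, 1} through a multinomial-logit link:

       Γ_ij(c) = exp(η_ij) / Σ_k exp(η_ik),   η_ij = β0_ij + β1_ij·c  (η_ii = 0)

   Fitting maximises the exact forward-algorithm likelihood from many
   random starts (75 by default), model order is chosen by AIC, states are
   decoded by Viterbi, long-run (stationary) state occupancy δΓ(c) = δ is
   solved per covariate level with parametric-bootstrap CIs, and the
   covariate effect on every transition is tested by Wald z-tests.
5. **Synthetic data** — a correlated-random-walk simulator that generates
   coordinate tracks from any such covariate HMM. `whale_shark_preset()`
   reproduces the study design (39 videos — 20 with a swimmer, 19 without —
   of 167–1121 frames at 30 fps) with the three fitted behavioural states:
   slow directed transiting, fast erratic avoidance, and intermediate
   cruising. Every downstream stage is therefore testable against known
   ground truth.

## Worked example

`examples/04_fit_hmm.py` simulates the preset study and runs the full HMM
stage (a few minutes):

```
 n_states  n_parameters   loglik     aic  delta_aic
        3            29 -27385.1 54828.2        0.0
        2            15 -29988.7 60007.4     5179.1
        1             5 -35926.5 71863.1    17034.8

selected: 3-state model
state means (body-lengths/frame): [0.0222 0.2745 0.3778]
angle concentrations: [1.131 0.671 0.029]

long-run occupancy of the fast erratic state:
  swimmer absent : 0.334 (95% CI 0.313-0.358)
  swimmer present: 0.704 (95% CI 0.678-0.723)
```

Reading this: the three-state model wins decisively on AIC (ΔAIC > 5100
against simpler models); states are labelled by ascending mean step length,
so state 1 is the slow directed one (0.022 body-lengths/frame, tightly
concentrated angles) and state 3 the fast erratic one (0.378
body-lengths/frame, nearly uniform angles). Under the preset's (synthetic)
transition coefficients, a swimmer roughly doubles the long-run probability
of the erratic state — the recovered effect matches the simulation's
design, and the Wald table in the script output shows which individual
transitions drive it. `examples/01`–`03` cover simulation, the metric
battery, and the ethospace/regression stage the same way.

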