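# Methods

This note records the models, parameter choices and numerical decisions
behind `ccexchange`, and what the synthetic-data tests do and do not show
about real plate-reader data.

## Reporter model

Each peptide exists as a labelled (FAM-tagged) and an unlabelled variant.
Assemblies are parallel homo-*n*-mers treated as unordered chain multisets,
giving *n* + 1 composition species. Quenching is **binary** by default: a
labelled chain fluoresces iff it is the only labelled chain in its
assembly. This is the simplest rule consistent with proximity-driven FAM
self-quenching; whether partially quenched intermediates (e.g. two labels
at distant positions of a heptamer) emit is experimentally open, so a
`residual_quench` fraction (default 0) is exposed for sensitivity analysis.
Free labelled monomers count as fully fluorescent: at micromolar bulk
concentration an unassembled fluorophore is far below the ~10 mM
self-quenching regime.

At full label-blind mixing with label fraction *p*, compositions are
Binomial(*n*, *p*) and the fluorescent fraction of labels is
(1 − *p*)^(*n*−1). The standard assay ratio, 1:10 assembled species,
gives *p* = 1/11 for homotypic mixes.

## Exchange mechanisms

All kinetics are deterministic mass-action ODEs in μM and minutes.

**Tetrameric-intermediate mechanism (dimers).** Any two dimers associate at
`k_assoc` (flux k[A][B]; k/2·[A]² for identical partners) into a four-chain
intermediate that resolves at `k_resolve` into one of the three chain
pairings, chosen uniformly. Uniform re-pairing is a deliberate completion
of the usual "LL + UU → 2 LU" cartoon: it is the label-blind choice, it
satisfies detailed balance, and it drives the network to the binomial
state. Two exact consequences used throughout: the heterodimer quotient
[LU]²/([LL][UU]) = 4 (statistical factor), and — because the quadratic flux
has a constant derivative along the conservation manifold — the observable
relaxes as an *exact* single exponential with

    k_obs = (2/3) k_assoc [total dimer].

A `resolution="mixed_only"` switch reproduces the as-drawn scheme (a
2-labelled intermediate resolves only to mixed dimers); it preserves the
quotient but is kept non-default.

**Dissociation mechanism (dimers).** D_xy ⇌ x + y with `k_off` per dimer
and `k_on` per distinct monomer pair (k_on/2 flux for identical monomers);
K_D = k_off/k_on, default 1×10⁻⁴ μM (0.1 nM, "sub-nM"). With K_D far below
the working concentrations, monomers stay below ~1% of chains and k_obs is
k_off-limited: the two dimer mechanisms are discriminated by whether k_obs
grows linearly with the unlabelled excess or stays flat.

**Chain-swap kernel (n-mers).** Assemblies collide at `k_swap`; each
partner donates one uniformly chosen chain. This is a minimal generative
stand-in for higher-oligomer exchange, whose observed kinetics are
multi-step; it is ergodic and label-blind, so its equilibrium is again
binomial. It is not claimed to be the physical mechanism.

**Numerics.** LSODA with rtol 1e-8, atol 1e-10 μM; concentrations below
1e-12 μM are clipped to zero for reporting only. Chain conservation is
checked structurally when a network is built and holds along trajectories
to better than 1e-9 relative. A hand-written exact Gillespie simulator of
the same reaction networks (propensities k·n_A n_B/Ω, k·n_A(n_A−1)/(2Ω))
validates ODE trajectories at small copy numbers in the tests; it is never
part of the analysis path.

## Fitting layer

The exponential rise F(t) = F0 + A(1 − e^(−k_obs t)) is the minimal
three-parameter "rise with baseline" model. Initialisation: F0 = first
point, A = last − first, k = ln2 / (interpolated half-rise time); if the
first attempt fails, five log-spaced k starts over [1e-5, 1e2] are tried in
deterministic order, with k bounded in [1e-6, 1e3] min⁻¹. A fitted rate
developing less than half a half-life over the observed span is reported as
a fit failure rather than a number. Standard errors come from the fit
covariance; traces whose amplitude is under 3× the residual noise are
degenerate. Trace normalization subtracts the fitted baseline and divides
by the fitted amplitude, making every downstream quantity invariant to the
plate-reader's affine gauge (gain/offset).

Replicates are fitted separately and summarised as mean ± 1 sd (n−1),
matching the error-bar semantics of triplicate kinetic measurements, rather
than pooling points into one fit.

Arrhenius analysis regresses ln k_obs on 1/T_K (Celsius converted to Kelvin
at exactly one place), Ea = −slope·R with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹.
Unweighted OLS is the default; when per-point k standard errors are
supplied, inverse-variance weights are used and the parameter covariance is
taken from the supplied variances (absolute-sigma convention) — appropriate
in simulation studies where the noise level is known, and conservative when
the supplied errors are.

## Endpoint pipeline

Min–max scaling is **per labelled peptide**: both anchors (annealed
labelled-alone control → 0; annealed 1:10 homotypic mixture → 1) belong to
the labelled peptide, so each matrix row has its own gauge. Replicate means
enter the anchors, which makes the anchor identities exact (≤1e-12) after
averaging. Values are deliberately not clipped: a heterotypic mixture can
in principle de-quench beyond the homotypic reference, and clipping would
hide it. The orthogonality threshold (default 0.5 on the normalized
annealed value) is a package decision — the experimental read-out is
qualitative ("little to no heterotypic exchange") — and is configurable;
classification is monotone in it. "Annealed" is a single label regardless
of the anneal ceiling temperature used for fragile peptides.

## Synthetic data: what it emulates, and what it does not

`PeptideModel` holds the generator ground truth: *n*, an apparent
second-order homotypic rate constant `k_ref` at 25 °C (defined so that
k_obs = k_ref × [total assemblies]; mechanisms derive their microscopic
constants from it, e.g. k_assoc = 1.5·k_ref), an activation enthalpy `Ea`,
an optional K_D, and pairwise compatibilities c ∈ [0, 1] giving the
fraction of full random mixing a heterotypic pair reaches at equilibrium.

Calibration: CC-Di's `k_ref = ln2/(4.2 × 101)` μM⁻¹ min⁻¹ reproduces a
fitted half-life of 4.2 min at the standard condition (2 μM labelled + 200
μM unlabelled chains = 101 μM total dimers, 25 °C); Ea = 37.9 kcal (mol of
dimer)⁻¹; temperature series use 28/32/37/40 °C. Other panel rate constants
are chosen so the 1 h / 24 h / annealed progression shows the observed
classes (fast dimer, partially exchanged tetramer and hexamer at 1 h, slow
trimer/pentamer/heptamer). Compatibility values encode the qualitative
screen structure only — trimer↔tetramer and barrel-block promiscuity in
the original panel (c ≈ 0.65–0.8), residual tetramer/pentamer/hexamer
promiscuity in the redesigned panel (c ≈ 0.2–0.3), dimer faithful
(c ≈ 0.02) — and are not measurements.

Heterotypic plate cells use the labelled peptide's oligomer state for the
quench statistics and a single compatibility scalar for the equilibrium
extent, because the stoichiometry of mixed assemblies is unknown; 1 h/24 h
extents follow the pair's pseudo-first-order kinetics at 25 °C (pair rate =
geometric mean of the homotypic constants × unlabelled assembly
concentration), and annealing is modelled as full equilibrium (extent 1).
Noise is multiplicative Gaussian (default CV 2%, a typical plate-reader
repeatability; there is no published figure for this assay) plus additive
baseline noise (default 5 a.u. against a 1000 a.u. gain); all draws come
from one seeded generator, so outputs are byte-reproducible.

Passing tests therefore demonstrate *self-consistency* — the analysis
recovers the generator's parameters under the generator's noise — not the
correctness of any mechanism for real peptides. Real data add features the
generator omits: photobleaching and drift, mixing dead time, evaporation,
temperature gradients across plates, incomplete annealing and peptide
precipitation at high temperature, and genuinely multi-exponential
higher-oligomer kinetics.

## Known limitations and scale choices

* Only parallel topologies are enumerated; antiparallel and mixed-topology
  species, and sequence-based prediction of oligomer state, are out of
  scope.
* The intermediate mechanism's exact k_obs ∝ [total dimer] means the rate
  is not perfectly independent of labelled concentration: across 1–20 μM
  labelled at 200 μM unlabelled the spread is ~9% peak-to-peak (CV ~3.7%).
  The package reports the coefficient of variation as its "insensitivity"
  statistic.
* Default problem sizes keep every check desk-scale: 101–121-point time
  grids, 200-run stochastic ensembles at ~10³ copies, and 200-repeat
  simulation studies; all were chosen as the smallest sizes at which the
  Monte-Carlo error is comfortably below the tolerances being checked.
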