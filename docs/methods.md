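# Methods

## Scope and model

`kitddg` covers the inference half of an alchemical mutation-scanning
pipeline for the KIT kinase. The physical picture: a point mutation changes
the folding free energy of the kinase differently in its autoinhibited
(inactive) and active conformations. Because folding and activation legs are
hard to simulate directly, they are obtained from closed thermodynamic
cycles whose tractable legs are alchemical WT→mutant transformations in
three environments — the unfolded reference (modelled as a GXG tripeptide;
leg ΔG_1), the folded inactive state (ΔG_4) and the folded active state
(ΔG_7). Cycle closure gives

    ΔΔG_state      = ΔG_unfolded − ΔG_folded_state
    ΔΔG_Activation = ΔΔG_Active − ΔΔG_Inactive = ΔG_4 − ΔG_7.

Sign conventions: ΔΔG_state < 0 means the mutant is less stable than WT in
that state; ΔΔG_Activation > 0 means the inactive→active transition is more
favorable for the mutant. The sign of ΔΔG_state is fixed by requiring both
(i) "negative = destabilized" and (ii) consistency of the published D816V
arithmetic (26.3 = 6.5 − (−19.8)); the cycle figure alone would admit
either convention.

## ΔG estimators

Work values W from driven forward (WT→mutant) and reverse (mutant→WT)
transitions obey the Crooks fluctuation theorem
P_f(W)/P_r(−W) = exp[β(W − ΔG)], β = 1/(k_B T), k_B = 0.008314463
kJ/(mol·K).

**BAR.** The Bennett acceptance ratio in Shirts' maximum-likelihood form:
ΔG is the root of

    Σ_i [1 + exp(β(M + W_i^F − ΔG))]^(−1)
  − Σ_j [1 + exp(β(−M + W_j^R + ΔG))]^(−1) = 0,   M = β^(−1) ln(n_f/n_r).

The offset M supports unequal direction counts and vanishes for the usual
equal-count protocol. The objective is monotone in ΔG; we bracket with the
pooled work range expanded by 10 kJ/mol and bisect until |f| < 1e−10 (or the
bracket reaches machine width) — deterministic and robust over speed. A
missing sign change is reported as a non-overlap failure carrying the
overlap diagnostic.

**Crooks crossing.** Moment-based Gaussian fits (sample mean, SD with
ddof=1) to the forward and negated-reverse samples; ΔG is the crossing of
the two fitted densities between their means (midpoint for equal
variances — relative difference ≤ 1e−12; otherwise the quadratic root in
the inter-mean interval). Zero variance is an error unless both sets are
the same point mass, whose common value is returned. Moment fits rather
than ML density estimation: the simplest faithful reading of "fitting the
work distributions".

**Bootstrap.** Directions are resampled independently with replacement at
their original sizes (the protocol description does not pair them), the
estimator is re-solved 100 times (default) and the SD (ddof=1) of the
replicates is the reported standard error; we treat published ± values as
1 SD. Failure of the estimator on more than half the replicates is an
error carrying the failure count.

**Overlap diagnostic.** Histogram overlap coefficient Σ_i min(p_i, q_i) of
forward vs negated-reverse work on a shared binning (Rice rule on the
pooled size, floor of 10 bins); degenerate single-value sets are point
masses. Purely diagnostic — no threshold is enforced.

## Cycle assembly and classification

Standard errors of independent legs combine in quadrature; this choice
reproduces both published combined uncertainties (0.2⊕0.3 → 0.4 and
0.5⊕1.3 → 1.4 after rounding). Classification on
(ΔΔG_Inactive, ΔΔG_Active) with threshold τ, applied in order:

1. ΔΔG_Active < −τ → deactivating;
2. ΔΔG_Inactive < −τ or ΔΔG_Active > +τ → activating;
3. otherwise neutral;

degraded to *indeterminate* when the deciding ΔΔG is smaller in magnitude
than its own SE. τ defaults to 4 kJ/mol — the typical error scale of
computational free-energy estimates, the same scale on which a −1.6 kJ/mol
effect is called marginal. Whether τ should instead scale with each
mutation's SE is not decidable from the available data; it is exposed as a
config knob. JM-domain mutants lack a folded-active leg (the JM segment is
taken as unfolded in the active state), so ΔΔG_Active ≈ 0 ± 0 is assumed
when classifying them; this is opt-out.

### Bundled KIT table

The packaged `kit_printed_ddg.tsv` carries the published per-state values
with provenance flags. Two caveats are preserved rather than resolved:
D816V's inactive-state value is reconstructed as −19.8 ± 0.5 from the
stated WT-referenced activation baseline (it is not printed standalone),
and G812V's inactive-state value is printed twice with different SEs
(±0.5 and ±0.4); both rows are stored, the first is primary, and the
loader surfaces the alternate in the cycle's notes. V559A and V560D
per-state magnitudes appear only graphically in the source; the bundled
numbers (−7.0 ± 1.0, −9.0 ± 1.0) are synthetic stand-ins with the correct
sign and plausible magnitude, flagged `synthetic_figure_standin` — they
exercise the classification path but are not published data.

## Structural metrics

Dihedrals use the standard right-handed atan2 torsion, degrees in
(−180, 180]. Ψ is measured to the residue's own carbonyl oxygen
(N–CA–C–O) by default, matching the upstream analysis protocol exactly,
even though the textbook Ψ uses the next residue's amide nitrogen; a
config switch selects the conventional definition (the two differ by
180°). Φ is C(i−1)–N–CA–C; the first residue has no Φ. Salt-bridge
distances are the per-frame minimum over all amine-N × carboxylate-O pairs
(NZ × {OE1,OE2} or {OD1,OD2}), hence invariant to the chemically arbitrary
oxygen labelling. Residues are addressed by author numbers throughout
(D810, R791, K623 …); nothing is renumbered.

PCA: each frame's selection coordinates are least-squares superposed
(Kabsch, uniform weights, no mass weighting — recorded in the model
metadata) onto the selection's mean structure, iterated to convergence;
the 3N×3N covariance (ddof=1) is eigendecomposed; modes are orthonormal
rows sorted by non-increasing variance. The superposition reference is a
convention choice (the upstream tooling does not state one); superposing
to the converged mean is the standard one. "Backbone" means atoms
N, CA, C, O of the listed residue ranges. The spine PCA restricts to
catalytic-spine residues {A621, V603, L678, L798, L799, L800} and
regulatory-spine residues {L656, L644, F811, H790}; a duplicated token in
the published residue listing ("L7999") is read as L799. Projection
superposes incoming frames onto the model mean, subtracts it, and takes
dot products with the modes. Even subsampling uses indices
round(k(F−1)/(n−1)), keeping both endpoints; n = 750 by default. No DFG
in/out or spine aligned/broken binary calls are made — the published
thresholds for those live in supplementary figures that are not available,
so raw series are emitted and thresholds are user-pluggable.

## Synthetic-data generator

The work generator draws forward work from N(ΔG + W_diss, 2W_diss/β) and
reverse work from N(−ΔG + W_diss, 2W_diss/β): the unique Gaussian pair
satisfying the Crooks relation exactly (the fluctuation–dissipation width
σ² = 2W_diss/β makes the log-density ratio exactly β(W − ΔG)). Defaults:
450 transitions per direction (mirroring the upstream protocol), 310 K.
The generator records its ΔG ground truth in metadata for test oracles;
estimators never read it. Real work distributions need not be Gaussian —
they can be skewed or multimodal in slow-relaxing systems — so estimator
performance here bounds only the well-behaved regime; the empirical spread
of real per-transition work is not publicly available, making the Gaussian
stand-in a modelling choice, not a reconstruction.

Peptide fixtures are built by internal-coordinate (NeRF) chain construction
with idealized geometry (N–CA 0.1458, CA–C 0.1525, C–N 0.1329, C=O
0.1231 nm; trans peptide bonds), backbone atoms only; side-chain sites
(NZ, OE1/OE2, OD1/OD2) are placed only by the salt-bridge fixture
generator, at exactly the prescribed minimum distances. Gaussian ensembles
sample frames along prescribed orthogonal modes; a helper supplies the
rigid-body null space at the mean so planted modes can be made to survive
superposition unchanged in recovery tests. These fixtures have controlled,
low-dimensional structure — they validate the metric arithmetic and the
estimators, not the behaviour of real solvated-protein trajectories
(anharmonicity, coupled motions, sidechain packing are all absent), so
passing tests demonstrate correctness of the computations, not realism of
the inputs.

## Problem sizes and numerical choices

Statistical tests run at n = 5000 work values per direction for recovery
(40 seeded condition/seed combinations over ΔG ∈ {−10, 0, 5, 20} kJ/mol ×
W_diss ∈ {0.5, 2, 4} kJ/mol), n = 2000 for the bootstrap-vs-replicate
calibration (50 regenerations), and 2000 frames for PCA recovery — sizes
at which the sampling error of the checks themselves is well below the
asserted tolerances. BAR is cross-checked against an independent
exponential-form objective solved by Brent's method (agreement to 1e−8);
the Crooks crossing against a dense numeric density-grid crossing; the
overlap coefficient against the closed-form equal-σ Gaussian value
2Φ(−Δμ/2σ). All randomness flows through numpy `default_rng` seeds;
identical config + seed gives byte-identical outputs (outputs embed the
tool version and a config hash, never timestamps).

## Known limitations

- The upstream legs themselves (ΔG_1/ΔG_4/ΔG_7 of the real KIT mutants)
  require μs-scale MD and are not recomputable here; the bundled table
  carries the published per-state values instead.
- The Crooks-crossing estimator is only as good as the Gaussian fits; for
  strongly non-Gaussian work it can be biased where BAR is not.
- PDB round-trips quantize coordinates to 0.001 Å (≈1e−4 nm), so
  metric-series round-trips through files are accurate to ~0.05° rather
  than the in-memory 1e−6°.
- The classification threshold τ is a global constant; mutation-specific
  thresholds would need external calibration data.
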