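# Methods

## Model formulation

The model couples mass-balance ODEs for 74 molecular species with a
rule-based description of regulation.  Signaling species obey

    (1/τ_i) dx_i/dt = Σ_j σ_ij r_j − μ x_i

where each rate is a kinetic term times a control coefficient,
`r_j = r̄_j · v_j`.  Enzyme-catalyzed steps use saturation kinetics
`r̄_j = k_j^cat ε x_s/(K_js + x_s)`; protein–protein binding uses mass
action `r̄_j = k_j^max Π x_s^(−σ_sj)`, with reversible binding split
into two irreversible steps.  Regulation enters only through bounded
Hill transfer functions `f(x) = x^n/(κ^n + x^n) ∈ [0, 1]`; when several
factors act on one target their outputs (inhibitors as `1 − f`) are
combined by a `min` or `max` integration rule into `v_j ∈ [0, 1]`, and
a process with no declared factors has coefficient exactly 1.  Factors
may be products of species abundances where regulation is co-dependent
(Smad·LEF-1 repression of E-cadherin; Snail·Slug acting on the
E-cadherin promoter), which removes the need for explicit
transcription-factor complexes.

Each of the 23 genes adds a transcript/protein pair

    dm_j/dt = u_j α_j V_T^max G_j/(K_T + G_j) − (μ + δ_j k_dm) m_j + λ_j
    dp_j/dt = β_j V_X^max m_j/(K_X + m_j) − (μ + γ_j k_dp) p_j

with `V_T^max = k_T·RNAP`, `V_X^max = k_X·RIBO`, two gene copies per
cell, and per-gene correction factors α, β, δ, γ confined to
[0.1, 10].  Gene loci are constant; τ_i = 1 for every species (the
field is kept for extensibility).

## Network reconstruction

The packaged network (`data/emt_network.txt`) encodes the canonical
TGF-β/VEGF-A EMT architecture: TGF-β1/2 → receptor → RAS/RAF/MEK/ERK →
AP-1/Sp1 → Snail/Slug; Snail/Slug repress E-cadherin and the
hypothetical repressor YREG1; YREG1 represses LEF-1 and TGF-β3 (so
Snail/Slug act as net inducers of both through double repression);
free β-catenin–TCF-4 complexes induce TGF-β3; TGF-β3 → ALK5 → a single
consolidated Smad → LEF-1; Smad and nuclear LEF-1 co-repress
E-cadherin; β-catenin–LEF-1 complexes induce Vimentin and fibronectin;
PI3K-mediated GSK3 inactivation releases APC-sequestered β-catenin;
VEGF-A → calcineurin → NFATc1 dephosphorylation/nuclear import →
E-cadherin induction; MAPK phosphorylates Sp1.  Deactivation of
phospho-forms is catalyzed by a constant lumped phosphatase pool
(PPASE); the ALK5 and VEGFR receptor pools and PPASE are boundary
species.  Exogenously dosed ligands are held at their dose for the
whole treatment (constant-concentration bath, the usual cell-culture
media-reservoir assumption); the secreted autocrine TGF-β3 pool stays
dynamic.

The reconstruction is count-faithful: 97 nodes (74 molecular species +
23 gene loci), 169 interactions (100 reactions + 23 control
declarations + 46 expression/translation edges) and 251 searched
parameters (169 kinetic + 38 control + 44 saturation) under the
convention in `docs/model-grammar.md`.  Individual intermediates
(phospho-forms, nuclear pools, receptor complexes) are the package's
own padding choices and may differ from any particular curation of the
same pathways.

## Nominal parameterization and calibration

Characteristic expression constants are fixed once from
literature-scale magnitudes: k_T = 0.003 h⁻¹ with RNAP = 150 nM
(V_T^max = 0.45 nM/h), k_X = 0.13 h⁻¹ with RIBO = 300 nM
(V_X^max = 39 nM/h), mRNA degradation k_dm = 0.099 h⁻¹ (≈7 h
half-life), protein degradation k_dp = 0.0231 h⁻¹ (≈30 h), K_T = 10
copies, K_X = 2 nM, and a specific growth rate μ = 0.0105 h⁻¹ (≈66 h
doubling; μ is configurable).  K_T and K_X were calibrated once so the
untreated steady state lands on physiological scales: all 23 proteins
in [10, 1000] nM and all transcripts in [0.01, 1] nM (the packaged
nominal gives 16–304 nM and 0.04–0.71 nM).

Rate constants fall into documented classes (binding ~10⁻³–10⁻²
nM⁻¹h⁻¹, unbinding/translocation ~0.05–0.5 h⁻¹, basal activation leak
~0.002–0.02 h⁻¹, catalysis ~0.05–20 h⁻¹ with K_sat ~100–300 nM) with
per-reaction overrides set by inspection so that (i) the untreated
fixed point is firmly epithelial (E-cadherin high, Vimentin low, MAPK
and Smad arms quiet), and (ii) each training perturbation switches its
intended arm.  A few transcription factors (Snail, Slug, YREG1) carry
correction factors >1 on their degradation constants — TF turnover is
faster than that of structural proteins, and the Snail/Slug↔YREG1
switch must toggle within the 48-h observation window.  Five
regulatory edges around that switch are flagged cooperative (Hill
order 2); all other orders are 1.  The packaged initial values are the
nominal untreated steady state (relaxed to ‖dx/dt‖/‖x‖ < 10⁻¹³), so
an untreated 48-h run is quasi-stationary by construction.

## Numerical integration

The stiff system (97 states) is integrated with LSODA at rtol 10⁻⁶ /
atol 10⁻⁹; the right-hand side is JIT-compiled (numba) with a pure
NumPy fallback.  State values are clamped at zero inside the kernel
for rate evaluation; negative excursions beyond −10⁻⁸ (relative) abort
with an error, smaller ones are clipped.  Endpoints are stable to
<0.1% under tolerance halving and time-grid refinement (tested).

## Treatment conditions

Doses are in arbitrary units with 1 a.u. ≡ 1 nM (only dose ratios
matter).  Inhibitors act as multiplicative potencies on one named
step: U0126 scales the MEK→ERK catalytic constant, VIVIT the
calcineurin-mediated NFAT dephosphorylation, LY294002 the PI3K-AKT
inactivation of GSK3.  Dominant negatives (DN-Smad4, DN-LEF-1) scale
the transfer-function output of every factor containing the targeted
transcription factor.  Expression constructs multiply the constitutive
rate λ_j (and α_j for overexpression); knockout sets both to zero.

## Training objectives

Band and transcript intensities carry no absolute units, so each
simulated series is gauge-matched to its data by the least-squares
scale s* = ⟨sim,data⟩/⟨sim,sim⟩ before the residual
Σ((s*·sim − data)/sd)² is formed; the score is therefore invariant to
the arbitrary intensity gauge of each series.  Unknown measurement
error defaults to 10% of the series maximum.  Failed integrations map
to an infinite sentinel rather than an exception.  The default design
groups 41 series into 11 objectives by experiment family (TGF-β2
MAPK/AP-1 panel, +U0126, Snail/Slug/E-cadherin overexpression, TGF-β3
± DN-Smad4/DN-LEF-1, a temporal E-cadherin/pSmad/LEF-1/Vimentin
course, a GSK3/β-catenin family with LY294002, and VEGF-A dose
responses read at 3 h and 48 h); the grouping is data, not code, and
can be overridden through the objectives CSV.

## Synthetic data

The generator simulates a ground-truth parameter set under every
protocol and applies multiplicative lognormal noise (mean 1, default
cv 0.15 — densitometry error is multiplicative) plus an optional
additive detection floor, recording sd = cv·value.  Synthetic
populations ("cells") are independent multiplicative jitters of a
truth within ±spread — extrinsic (parametric) heterogeneity only.
The generator reproduces the real corpus's bookkeeping (series and
objective counts, sampling times) but not its actual intensities,
replicate structure, intrinsic noise, or any cell-line-specific
behavior; green tests certify the pipeline's statistical machinery
under the stated noise model, not fidelity to any wet-lab dataset.

## Ensemble estimation

The annealer searches 297 parameters (100 reaction constants, 44
saturation constants, 38 control half-saturations, 92 correction
factors, 23 constitutive rates) multiplicatively within ±30% of the
nominal set, with correction factors clipped to [0.1, 10].  Moves
alternate between the signaling and gene-expression blocks and touch a
random 5% of the active block per step with independent U[0.7, 1.3]
factors.  A trial is ranked against the archive by Pareto dominance
(rank = number of dominators; rank 0 = front).  Rank improvements are
always accepted; rank worsenings with probability exp(−Δrank/T); rank
ties — common with 10–11 objectives — are broken by a Metropolis
criterion on the relative total error with an effective temperature
0.1·T.  Cooling is geometric (×0.9 every 25 steps from T₀ = 1.44,
giving ≈50% initial acceptance for a unit rank gap).  The archive
evicts by worst rank, then highest total error, then age, so the
best-seen front is never displaced by dominated members.

Leave-one-out cross-validation partitions the 11 objectives into 10
training + 1 validation; each partition trains its own ensemble (seed
offset by the partition index) and evaluates the held-out objective on
its rank-0 front (the prediction error).  Ensemble selection takes the
union of candidates with rank ≤ max_rank and training/prediction
errors below a configurable quantile, deduplicated by parameter
vector.  The negative control is a randomized family (default
N = 100) drawn log-uniformly within ×10 of nominal with no fitting;
trained and control error samples are compared by a two-sided Wilcoxon
rank-sum (Mann-Whitney U) test with the exact small-sample null.

The packaged recovery study is deliberately scaled down: 500 annealing
steps on each of 3 leave-one-out partitions with archive capacity 100,
against a truth displaced 15% from nominal with 5% measurement noise.
At that scale the rank-0 fronts improve on the nominal error, their
trajectory envelopes bracket the truth at ≥90% of training time
points, and they separate from the randomized control at p ≪ 0.05;
recovering point estimates of all 297 parameters is neither expected
nor claimed.

## Phenotype analysis

Each ensemble member is simulated to 48 h and contributes one
(E-cadherin, Vimentin) point — virtual flow cytometry.  Quadrant
thresholds come from the untreated population: E-cad-high = untreated
median, Vim-high = untreated 90th percentile (resting cells are
E-cad-high/Vim-low, so only outliers exceed the Vim cut); both
quantiles are arguments.  Calls partition every non-failed member into
epithelial / mesenchymal / hybrid / low-low.  "Responded to
treatment" is operationalized as a per-member displacement in the
(E-cad, Vim) plane exceeding the χ²(0.95, df = 2) Mahalanobis radius
of the untreated covariance — a member identical under both conditions
can never count as a responder.  Failed members are flagged and
excluded from denominators with their count reported; a run with >10%
failures aborts.

## Known limitations

* Deterministic ensembles capture extrinsic (parametric)
  heterogeneity only; there is no intrinsic-noise or spatial
  simulation.
* The reconstruction matches printed structural counts, not a curated
  species-by-species inventory; conclusions about individual padding
  intermediates carry no weight.
* The convention for mixed activator/inhibitor targets is one
  integration rule per target over all its factor outputs; nested
  rules are not expressible.
* Whether constitutive expression applies to all genes is an open
  modeling choice; the default gives every gene a small λ_j
  (0.003–0.01 nM/h) so no transcript underflows the physiological
  floor.
* The VEGF-A calibration family is a qPCR-style dose-response design;
  a separate hand-fit calibration of VEGF-responsive processes is not
  reimplemented — those processes are estimated jointly with the rest.
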