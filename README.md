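# emtensemble

Kinetic modeling of the epithelial-to-mesenchymal transition (EMT)
driven by TGF-β isoforms and VEGF-A, for systems biologists who want
to go from a curated signaling network to an ensemble of calibrated
dynamic models and population-level phenotype predictions without a
single wet-lab number in the loop.

During EMT, polarized epithelial cells lose E-cadherin-mediated
adhesion and gain mesenchymal traits (Vimentin, motility).  The
package implements:

* **A rule-augmented ODE model.**  A 97-node network (74 molecular
  species + 23 genes, 169 interactions) declared in a plain-text
  grammar.  Signaling follows mass balances
  `(1/τ_i) dx_i/dt = Σ_j σ_ij r_j − μ x_i`, with saturation kinetics
  for catalysis, mass action for binding, and every regulatory input
  entering through bounded Hill transfer functions
  `f(x) = x^n/(κ^n + x^n)` combined by min/max integration rules into
  control coefficients `v_j, u_j ∈ [0, 1]`.  Each gene adds
  transcript/protein balances with per-gene correction factors
  (α, β, δ, γ) on characteristic transcription, translation and
  degradation constants.
* **Pareto-ensemble estimation.**  Multiobjective simulated annealing
  in a ±30% neighborhood of a nominal parameter set, scoring 11
  objective functions (41 gauge-scaled intensity series) at once,
  ranking candidates by Pareto dominance, with leave-one-out
  cross-validation, ensemble selection, and a randomized-parameter
  control compared by a Wilcoxon rank-sum test.
* **Virtual flow cytometry.**  Every ensemble member is a
  deterministic "cell"; simulating the ensemble under a treatment
  yields an (E-cadherin, Vimentin) scatter at 48 h that is classified
  into epithelial / mesenchymal / hybrid / low-low quadrants —
  including the hybrid (both-markers-high) state that appears only
  under combined TGF-β2 + VEGF-A exposure.

Training data are fully synthetic: a generator emulates blot/qPCR
intensity series (lognormal multiplicative noise) from a known ground
truth, which closes the estimation loop and makes every pipeline
property testable offline.

## Worked example

```bash
python examples/02_simulate_treatments.py
```

```
condition      E-cad     Vim    pSp1   nNFAT
untreated      268.5    66.2     2.3     0.2
tgfb2          141.8   223.7     7.6     1.3
vegf           295.1    66.2     2.7    87.9
tgfb2+vegf     270.5   226.4     7.5   109.6
```

All values are 48-h abundances in nM.  The untreated cell rests in an
epithelial state (E-cadherin high, Vimentin low).  TGF-β2 (10 a.u.)
halves E-cadherin and more than triples Vimentin — the classical
mesenchymal conversion, driven by nuclear phospho-Sp1/AP-1 and the
Snail→YREG1→TGF-β3 autocrine relay.  VEGF-A (50 a.u.) activates
calcineurin/NFATc1 (nuclear NFAT rises from 0.2 to 88 nM) and
preserves the epithelial markers.  The combination keeps E-cadherin
at untreated levels *while* Vimentin rises — the hybrid signature.
`examples/05_virtual_flow_cytometry.py` shows the same effect at the
population level: a 60-member ensemble moves from 3% to 88%
mesenchymal under TGF-β2 alone, but 40% of cells become hybrid under
the dual treatment, and NFAT inhibition (VIVIT) collapses them back to
mesenchymal.

The other examples cover the structural bookkeeping of the packaged
network (`01`), the synthetic 41-series training design (`03`), a
miniature ensemble estimation run (`04`), and the `emtensemble` CLI
(`emtensemble pipeline --help`) orchestrates synth → cross-validated
estimation → population analysis end-to-end.

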