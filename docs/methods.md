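# Methods

## Model structure

The simulator represents one cell exposed to a VEGF bath. State variables
are copy numbers (molecules/cell); bimolecular rate constants are stored in
1/(molecule·s), i.e. molar rates divided by `N_A × V_cell` with a default
cell volume of 1 pL. The ligand dose is given in ng/mL and converted
through the VEGF-A164 homodimer mass (default 38.2 kDa, overridable in
`LigandSpec.molecular_weight`; the dimer mass is used because VEGF engages
its receptors as a dimer).

Receptor activation is lumped: VEGF binding directly yields the
phosphorylated receptor `pR`, with dissociation only from the unoccupied
`pR` state. Receptor dimerization, trafficking, and internalization are
not modeled. The phosphatase PTPN is a single generalized species held at
a constant reservoir concentration (it is never limiting); VEGF is likewise
held constant by default because a 50 ng/mL bath in a culture well dwarfs
cellular receptor numbers (`LigandSpec.depletion_mode` enables consumption
for closed-volume scenarios). The post-catalysis `[A:PTPN]` complex
dissociates at `koff_PTPN`, returning the dephosphorylated adapter to its
free pool; without this return path the adapter moiety would have no
closed cycle.

### Steric site competition

The receptor carboxy terminus is a one-dimensional axis. Inter-site
distance is residue separation × `aa_spacing` (0.171 Å/aa for VEGFR1,
measured from the kinase-domain crystal structure; VEGFR2's spacing is an
input, not a built-in constant). An adapter docks by its center and
occupies `size_y / 2` toward each neighboring site. A multi-adapter
configuration is feasible iff *every* occupied pair satisfies
`size_i/2 + size_j/2 < d_ij` strictly — ties are infeasible, each site
holds at most one adapter, and feasibility is checked pairwise rather than
as a global packing problem (the weakest reading of the "combined size
smaller than available space" rule that still reproduces the observed
two-adapter VEGFR1 ceiling). Feasibility is anti-monotone in occupancy, so
the enumerator can grow configurations site by site with exact pruning; an
exhaustive brute-force filter over all site→adapter assignments is kept in
the test suite as an independent oracle.

### Network generation

The **nonspecific** variant instantiates the six-step scheme directly per
(receptor, adapter) pair, with at most one adapter bound per receptor.
The **specific** variant enumerates receptor states as feasible occupancy
maps annotated per bound adapter with one of three flags — unphosphorylated
(`u`), phosphorylated (`p`), phosphorylated with phosphatase attached
(`pP`) — and generates only transitions between feasible states: binding at
`kon_A` onto any free allowed site whose occupation stays feasible,
unbinding at `koff_A` from `u` only (a phosphorylated adapter leaves only
through phosphatase catalysis, as in the scheme), phosphorylation at
`kp` (all sites of a `pR` are simultaneously competent; there are no
per-site receptor phosphorylation states), and PTPN binding/catalysis per
bound phospho-adapter. Species ids are canonical (occupancy sorted by
residue order), so rebuilding a network is bit-reproducible. Mapping all
adapters to one shared exclusive site makes the specific variant collapse
onto the nonspecific one; this reduction is asserted to < 1e-8 relative
in the tests. Adapters translocate between sites only by full
unbind-then-rebind.

Networks export as species/reaction CSV tables. SBML export is not
provided; the reaction tables carry the same information in plain text.

## Integration and numerical choices

`dx/dt = S·v(x)` is integrated with SciPy's BDF solver using an analytic
Jacobian assembled from the reaction list (rtol 1e-8, atol 1e-10).
Boundary species rows of `S` are zeroed. Negative excursions beyond
−1e-9 molecules/cell abort the run; smaller ones are clamped to zero.
After every simulation, adapter and receptor moiety totals (computed from
species composition metadata, ligand and PTPN excluded per their boundary
treatment) are checked for relative drift < 1e-6 over the whole grid.

The default horizon is 3600 s with 601 output points — the order of
magnitude of phospho-ELISA observation windows; both are configuration
fields, and the original study's horizon and solver settings are not
published, so these are repo defaults. Halving the grid spacing moves AUC
and amplitude summaries by < 0.1% on the test fixtures.

Phosphorylated-adapter readouts sum the `p` *and* `pP` states: a
phosphatase-bound adapter is still chemically phosphorylated until
catalysis fires. The post-catalysis `[A:PTPN]` complex does not count.

## Responses, inhibitors, goodness of fit

Migration and proliferation are weighted sums of phospho-adapter traces
(weights are dimensionless, nonnegative inputs calibrated upstream of this
package); degradation is bit-identical to the c-Cbl phospho trace. AUC
uses the trapezoid rule on the stored grid. Relative integrated responses
divide each AUC by the three-response total. Model-to-model comparisons
report the relative change in those fractions (migration "relative to
proliferation and degradation") and the direct relative change in
amplitudes.

Inhibitors remove the target adapter's phosphorylation path (`kp_scale=0`)
while retaining binding, matching the catalytic mechanism of Wortmannin,
U73122 and Imatinib and preserving competition for sites; a depletion mode
(concentration → 0) is available behind a flag. Predicted significance
uses a ±10% band around the untreated integrated response with inclusive
bounds: only values strictly outside the band are flagged.

The χ² goodness-of-fit statistic scales residuals by the measurement SEM
(`Σ((obs − pred)/sem)²`, matching data reported as p/t ± SEM with
background subtraction done upstream) and compares against the χ²
critical value at `dof = n − 1`, α = 0.05. Pearson expected-value scaling
is available behind a flag, and an optional scale factor maps
molecules/cell predictions onto p/t measurement units, since that
conversion is assay-specific and not published.

Receptor decomposition zeroes every other receptor's concentration while
keeping adapter pools unchanged, so the single-receptor traces do not sum
to the full model (shared-pool competition is the point of the
decomposition). The receptor fold is the ratio of single-receptor
integrated responses.

## Sensitivity analyses

Concentration sweeps vary one adapter on a log grid over 1e2–1e5
molecules/cell (endpoints exact), re-simulating at each point. Monte
Carlo draws multiply each adapter's kon and koff by `10^U(−d, d)` with
d = 1 decade by default — the original perturbation scheme is unpublished,
so the spec is explicit, overrideable (`PerturbationSpec`), and recorded
with every result. The reference draw count is 4000; the acceptance
script and CI use 200, which resolves the coefficient of variation of
integrated responses to ~5% relative standard error. Standard deviations
use the population convention computed around the first draw, so
zero-width perturbations report exactly sd = 0.

## Parameter provenance and the fixture generator

Parameter files are four CSV tables plus a YAML scalar config (documented
in `vegfrsim.params.save_parameters`); every receptor/adapter row carries a
`provenance` flag (`SI` for values taken from a calibrated supplementary
table, `fixture` for stand-ins) so borrowed values are never silently
invented.

The packaged `HUVEC`/`RAW` presets anchor to published structural facts:
the five VEGFR1 tyrosine sites (residues 794, 1169, 1213, 1242, 1333),
0.171 Å/aa spacing, PLCγ and PI3K as the only Tyr794 binders with Src at
Tyr1169/Tyr1213, kp = 0.01/s for all adapters, a 1 pL cell volume, and
50 ng/mL VEGF-A164. Everything else is fixture-valued from field-typical
ranges fixed once: adapter extents of 48–60 Å (SH2-adapter crystal
structures are ~5 nm), SH2 dissociation constants of 0.25–1 µM, qFlow-scale
receptor densities (HUVEC: 1800 VEGFR1 / 4900 VEGFR2; RAW: 10300 / 2200,
reflecting the VEGFR1-high macrophage phenotype), adapter pools of
2×10³–1.2×10⁴ copies/cell, and migration/proliferation weights led by PLCγ
then PI3K. With these sizes the documented steric ceiling *emerges* rather
than being hard-coded: the distal site cluster (gaps 5–28 Å) cannot hold
two adapters, while Tyr794 sits ≥ 64 Å away, so at most two adapters bind
VEGFR1 and every pair includes Tyr794.

The random fixture generator (`generate_fixture_parameters`) draws adapter
concentrations log-uniformly on 1e2–1e5 molecules/cell, Kd's on
1–1000 nM, and sizes of 20–80 Å, inflating the largest adapter if needed
so at least one steric constraint is active; it is bitwise reproducible
per seed.

## What the synthetic data does and does not show

Passing tests demonstrate the engine's correctness (conservation,
equilibrium limits, reduction equivalence, enumeration against brute
force, inhibitor and null-case identities) and that the structural
conclusions are insensitive to the fixture values. They do *not*
demonstrate quantitative agreement with measured phospho-ELISA or
wound-healing data: the originally calibrated adapter roster,
concentrations, kinetics and response weights are not published in
machine-readable form, and the presets make no claim to reproduce them.
Quantities that depend on that calibration (the specific-model migration
gain, inhibitor reduction percentages, receptor folds) are therefore
reported as computed under the presets, and differ from the published
values. The acceptance suite keeps those comparisons visible (and
failing) rather than calibrating the presets toward them.

## Known limitations

- No adapter–adapter interactions or adapter-specific phosphatases; one
  generalized PTPN serves all adapters.
- No receptor trafficking; degradation is a phosphorylation readout
  (c-Cbl), not receptor removal.
- Deterministic ODEs only — stochasticity enters solely through Monte
  Carlo over parameters.
- Pairwise steric checking admits chain arrangements a full 1-D packing
  model might reject; with realistic adapter sizes the two never differ on
  VEGFR1 geometry.
- The specific model's state space grows as (feasible configurations ×
  3^bound adapters); it is comfortably small for ≤ 6 adapters and ≤ 5
  sites but not designed for receptors with dozens of sites.
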