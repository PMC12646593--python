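# Methods

This note documents the models implemented in `toxtriage`, the defaults they
ship with, the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Speciation

Each ionizable group is an independent two-state site. Relative to the fully
neutral microstate, deprotonating an acid group contributes a weight
10^(pH − pKa) and protonating a base group contributes 10^(pKa − pH); the
population of each net-charge state is the normalized sum of microstate
weights with that charge (computed by convolving per-group weight vectors in
the log domain, so extreme pKa − pH gaps stay finite). With at most two acid
and two base groups the net charge spans −2…+2; profiles with more groups are
rejected rather than silently truncated. All net-neutral microstates —
including zwitterions (deprotonated acid + protonated base) — are pooled into
the neutral fraction, which is what downstream models consume.

The independent-site treatment ignores microstate coupling (tautomer
microspeciation, interacting sites); for screening-level distribution ratios
that is the standard simplification. The implementation is cross-checked in
the tests against a brute-force enumeration over all protonation microstates
(agreement to 1e−10).

Only the neutral species is treated as volatile: D_aw(pH) = K_aw · f_neutral.
Ionic species have negligible vapor pressure, so no ionic air term is added.
K_aw is accepted as a dimensionless log10 value; converting Henry coefficients
(units, temperature) is the caller's responsibility.

## Partitioning

Per-species partition constants are predicted from log K_ow of the neutral
species through pluggable linear maps (`LinearMapModel`), then combined at a
given pH as species-fraction-weighted sums D = Σ f_i·K_i. The shipped default
coefficients are screening-level choices, not re-fits of any literature
dataset, and every one of them can be replaced from a JSON config which is
echoed into audit reports:

| map | slope | intercept | notes |
| --- | --- | --- | --- |
| liposome–water (neutral) | 1.01 | 0.12 | near-unity slope of membrane–water vs octanol–water correlations |
| BSA–water (neutral) | 1.15 | −1.85 | calibrated, see below |
| BSA–water (anion) | 0.30 | 3.00 | strong, weakly K_ow-dependent anion binding |
| structural protein–water (neutral) | 0.78 | −0.84 | muscle-protein-like, weaker than BSA |

Species rules:

* **Membranes.** Charged species carry the neutral constant reduced by
  `ion_offset` (default 1 log unit, the usual magnitude for ion partitioning
  into bilayers). log D_lip/w is floored at −1, the empirical lowest membrane
  affinity; the baseline-toxicity QSAR is not valid below it.
* **BSA.** Cations are assigned the neutral-species constant. Anions use the
  separate anion map (anions bind serum albumin much more strongly than
  lipids). Hydrophilic chemicals (log K_ow < 2) use a fixed constant of 1.31.
* **Structural proteins.** Same structure as BSA with the SP neutral map, and
  the anion term attenuated by `sp_anion_attenuation` (default 1 log unit)
  because anion binding to structural proteins is weaker than to albumin.
* Doubly charged species are treated like singly charged ones; no separate
  maps exist for them at screening level.

**The 1.31 hydrophilic constant.** Whether the fixed hydrophilic BSA value is
a log10 constant (K = 20.4 L/L) or a linear ratio (K = 1.31 L/L) is ambiguous
on its face, and the package supports both (`hydrophilic_floor_is_log`). The
default is the **linear** reading, for two reasons. First, consistency with
the observed availability pattern: with K = 20.4 L/L, 0.3 vol-% medium
protein binds ≈ 6% of any hydrophilic chemical, capping f_free at 0.94 —
contradicting the observation that hydrophilic chemicals are fully dissolved
in 10% FBS medium. Second, monotonicity: a log10 floor of 1.31 would sit
*above* the neutral map's value at log K_ow = 2, so increasing hydrophobicity
would decrease predicted binding across the cutoff.

**Calibration of the neutral BSA map.** The default slope/intercept
(1.15/−1.85) were chosen analytically, from the closed-form mass balance, so
that the default configuration reproduces the qualitative availability curve
expected for 10% FBS medium: neutral chemicals ≳95% freely dissolved up to
log D_lip/w ≈ 2.5 and ≲5% free above log D_lip/w ≈ 5. A flatter literature
map for neutral-compound albumin binding would also be defensible; anyone
preferring one can supply it via config, at the cost of a more gradual
availability transition.

## In vitro mass balance

The freely dissolved fraction is

    f_free = 1 / (1 + D_medium/w · V_sorb/V_medium + D_cell/w · V_cell/V_medium)

with D_medium/w a convex combination of D_BSA/w and D_lip/w over
sorptive-phase-normalized volume fractions, and D_cell/w built from cellular
protein (structural-protein surrogate), lipid and water fractions. Two VF
conventions circulate — per sorptive-phase volume and per total medium
volume — and they only agree if applied consistently. The package uses
sorptive-phase-normalized VFs inside D_medium/w and multiplies by the
sorptive-phase volume per medium volume in f_free, which makes the medium
sorption term exactly D_BSA/w·VF_protein,medium + D_lip/w·VF_lipid,medium
with per-medium-volume fractions — the same form the nominal-IC10 expression
uses. The equivalence is enforced by a three-compartment brute-force oracle
test (1e−12).

Defaults encode 10% FBS medium (protein 0.3 vol-%, lipid 0.007 vol-%) and a
typical cell composition (protein 3%, lipid 0.5%, water 96.5%). The cell term
V_cell/V_bioassay defaults to 0 (cellular uptake is negligible in serum-
supplemented medium unless volumes are supplied); V_medium and V_bioassay are
treated as equal. Plastic binding is not modeled; for predominantly cationic
chemicals on tissue-culture-treated (anionic) plates a warning is emitted
because no binding constants exist for that interaction.

Baseline cytotoxicity uses the critical membrane concentration
IC10_membrane = 26 mmol/L_lipid (10% inhibition of cell proliferation; nearly
species- and cell-type-invariant at fixed endpoint):

    IC10_free    = IC10_membrane / D_lip/w
    IC10_nominal = IC10_free · (1 + D_BSA/w·VF_prot,med + D_lip/w·VF_lip,med
                                  + D_cell/w·V_cell/V_bioassay)

All public returns are mol/L; the constant is stored in its customary
mmol/L_lip and converted explicitly.

**Boundary band of the availability contract.** The qualitative contract
"free below log D_lip/w 3, bound above 5" cannot hold arbitrarily close to
the lower boundary under the printed medium composition: at
log D_lip/w = 3 the medium *lipid* term alone is 0.00007·10³ = 0.07, capping
f_free at 0.935 regardless of protein binding. The packaged checks therefore
evaluate the contract on a half-log grid of neutral reference chemicals
(…, 2.0, 2.5 | 5.5, 6.0, …); within ≈0.3 log units below 3 the freely
dissolved fraction necessarily dips a few percent under 0.95. Anionic
chemicals are excluded from this particular sweep by design: they bind
proteins far more strongly than lipids, so their f_free is not a function of
D_lip/w (this is visible in the pooled analysis output, where the `<3` class
of the full synthetic pool averages well below the neutral curve).

## Baseline-toxicity QSARs

Five frozen species models of the form −log10 C = a·log D_lip/w + b, with
D_lip/w (not K_ow) as descriptor so ionizable chemicals stay in-domain:

| species | a | b | r² | n | endpoint |
| --- | --- | --- | --- | --- | --- |
| C. elegans | 0.81 | 1.15 | — | — | LC50, mol/L aqueous |
| D. magna | 0.82 | 1.48 | — | — | LC50, mol/L aqueous |
| D. rerio | 0.99 | 0.78 | — | — | LC50, mol/L aqueous |
| X. laevis | 0.61 | 2.12 | 0.690 | 22 | LC50, mol/L aqueous |
| D. melanogaster | 0.83 | 0.52 | 0.724 | 11 | BMD50, mol/L feed |

The D. melanogaster model is feed-based and carries its endpoint in the type;
cross-species summaries never pool it with aqueous LC50s. Registry models are
frozen constants with provenance strings; user fits are namespaced
separately (`provenance="user-fitted"`). Predictions below the log D_lip/w
floor of −1 are computed but flagged with a warning.

De-novo fitting is ordinary least squares (scipy's `linregress`), validated
in the tests against hand-written normal equations to 1e−10; slope CIs use
the t distribution with n−2 degrees of freedom. Fits require ≥3 points and
nonzero descriptor variance.

The specificity ratio SR = predicted baseline effect concentration /
experimental effect concentration classifies a chemical as specific/reactive
when SR ≥ 10 (boundary inclusive). The factor-10 cutoff is the conventional
narcosis-literature choice; it is a configurable argument, not a constant.

## ADME classification

CL_int (µl/min/10⁶ cells) maps to {no_metabolism = 0, very_slow < 2.5,
intermediate [2.5, 10], fast (10, 100], rapid > 100}; the 2.5–10 gap has no
established name and is labeled `intermediate`. Boundary values follow the
strict/inclusive senses of the defining inequalities. F_u splits at 50%
(inclusive) into high vs lower availability. The data source (human >
rodent > predicted) is recorded for audit but never changes the category.

## Triage

Stage 1 removes nominees outside the bioassay applicability domain:
D_aw > 1e−4 (volatile), log D_lip/w(pH 7.4) > 4 (too hydrophobic to dose),
or failing aqueous/DMSO stability. Nominees flagged `moa_exception` are
retained despite a breach (a mechanism with no in-domain representative) and
stay flagged in the result. Stage 2 enforces logistics: purity ≥ 98%,
cost ≤ 1,000 €, availability, no prohibited/controlled substances, no
chemicals too hazardous for routine handling. Every failed criterion is
recorded per record; the stage of first exclusion is the canonical label.

Stage 3 enforces mechanism diversity: within each toxicity group, nominees
are ranked (exposome membership, then reference-compound status, then lower
cost, then identifier — an invented but deterministic priority) and admitted
greedily while no mechanism tag exceeds `moa_max_per_group` (default 2,
configurable to 1) and the group stays within its target maximum (30). A
chemical may qualify for several groups; it counts toward each group's size
but is retained once, deduplicated by identifier precedence
(InChIKey > DTXSID > CAS > name). Surplus duplicate rows are booked as
excluded (`duplicate`) so that retained + excluded always equals the input.

**Greedy caveats, documented rather than hidden.** With multi-tag records the
per-group cap system is not a matroid, so the greedy rule can be suboptimal
(admitting r₁{A,B} first can block {r₂{A}, r₃{B}}), and loosening a cap can
reshuffle admissions so the retained *set* is not a superset of the tighter
run (rare: ~0.1% of random small instances in our scans, requiring multi-tag,
multi-group overlap). The tests assert greedy = exhaustive optimum on
single-tag instances, and maximality plus optimum-bounded on multi-tag
instances; threshold monotonicity is asserted for the stage-1/2 scalar
filters, where it holds exactly, and for caps on single-tag instances.

## Synthetic data

The generator reproduces the marginal structure a triage pipeline must cope
with, at the scale of a real nomination campaign:

* log K_ow ~ truncated normal, mean 2.31, sd 2.0, range −4.63…8.50. The sd
  is chosen so the range spans ~12 orders of magnitude while the bulk sits
  between −2 and 6; truncation bias on the mean is negligible (<0.03).
* Speciation mixture at pH 7.4: 40% neutral-dominant (no groups, or far-off
  pKa), 30% strongly charged (|pKa − 7.4| > 0.7 on the ionized side), 30%
  intermediate (pKa within ~0.6 of 7.4), mirroring reported proportions of
  neutral-form and charged chemicals in diversity-driven panels.
* ~10% volatile subpopulation (log K_aw between −3 and 0.5, the rest −10…−5);
  costs lognormal (median 200 €, σ = 1, putting ~5% above the 1,000 € cap);
  purities mostly 98–100%; availability/safety flags at a-few-percent rates;
  one to three toxicity groups and one to two mechanism tags per chemical;
  CAS numbers synthesized with valid checksums.

Properties are drawn independently: the generator does **not** emulate the
joint distribution of K_ow, pKa and K_aw of real chemistry, structure
(SMILES), or correlated pathologies (e.g. expensive = rare = restricted).
Passing tests on synthetic pools therefore demonstrate the pipeline's
bookkeeping, thresholds and statistical behavior, not real-world attrition
rates; stage-wise attrition on the synthetic pool is reported qualitatively
only.

Effect datasets are QSAR-consistent with lognormal noise (Gaussian on the
−log10 concentration scale, the standard error model for effect
concentrations); specifically acting chemicals are shifted by a fixed
potency offset and labeled so classification accuracy can be scored. A
single seeded generator per call makes every dataset bit-reproducible.

## Problem sizes and numerics

The packaged analyses use a 1,500-nominee pool, 200 replicate fits of n = 22
for slope recovery, 1,000 chemicals for classification accuracy, 10⁴ random
draws for speciation closure, and half-log grids for sweeps — sizes at which
every result in this repository reproduces in seconds. Numeric choices:
species-weighted sums are computed in the log domain; fraction closure is
enforced to 1e−12; OLS validation to 1e−10; the log D_lip/w floor is applied
after summation; ties in stage-3 ranking are broken by identifier so results
are order-independent.

## Known limitations

* Linear partition maps only; no LSER descriptors, no sorption-isotherm
  nonlinearity, no temperature corrections.
* No kinetics: the mass balance is equilibrium-only, with no volatilization
  or degradation loss terms (volatiles are excluded upstream).
* The C. elegans registry model is a rescaled literature value; the rescaling
  procedure itself is not reproduced, only its coefficients.
* Greedy diversity selection is order-deterministic but not globally optimal
  (see above).
* ADME categories are classifications of supplied values; no database
  querying or in silico clearance prediction is included, and metals or
  inorganics are out of the clearance model's domain (flag upstream).
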