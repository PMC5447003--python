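# Methods

## The model

Nicotinic acetylcholine receptors (nAChRs) are pentameric cation channels
whose Ca²⁺ permeability — measured as the fractional Ca²⁺ current *Pf*, the
percentage of total current carried by Ca²⁺ — varies more than tenfold with
subunit composition.  This package implements a charge-ring model of that
variation: the determinants of Ca²⁺ selectivity are taken to be the summed
electrical charges of narrow rings of residues flanking the pore-lining TM2
helix, and *Pf* is a logistic function of a weighted sum of those ring
charges.

With a single free-energy barrier per ion species and fixed concentrations,
potential and temperature, each ionic current is proportional to
e^(−ΔG/RT), so

  Pf = I_Ca / (I_Ca + I_Na) = 1 / (1 + (C_Na/C_Ca) · e^((ΔG_Ca−ΔG_Na)/RT)).

The model replaces the barrier difference by a weighted sum of regional
charges and the concentration ratio by a single constant:

  Pf = 1 / (1 + const · e^(Σᵢ kᵢ·Δqᵢ)),   Δqᵢ = −qᵢ,

where qᵢ is the signed summed charge (in natural units of electrical
charge, nuec) of ring *i* over all five subunits, kᵢ is that ring's weight
(nuec⁻¹), and const > 0.  The sign convention Δqᵢ = −qᵢ is fixed by
verification against all 19 packaged reference predictions: with the
published coefficient signs, only the negated tabulated charge reproduces
them (homomeric α1 → 57.4 %, α7 → 10.4 %, α7β2 1:4 → 0.1 %, …).  Whether
the original fit used this convention internally or reported
flipped-sign coefficients is unobservable; only the composite behaviour is,
and that is what is pinned by tests.

## Regions and charge assignment

Eight regions are distinguished, indexed in Miller prime notation from the
conserved lysine (0′) immediately preceding TM2:

| region | side | role |
|---|---|---|
| extracellular domain | — | data field only, never computed |
| TM3–TM4 intracellular domain | — | data field only |
| {−5′ −4′} | intracellular | cytoplasmic ring |
| {−1′} | intracellular | intermediate ring |
| {19′} | extracellular | α5-specific glutamate position |
| {20′} | extracellular | extracellular ring, main determinant |
| {21′–24′} | extracellular | exactly redundant with {−1′} in the panel |
| {25′–29′} | extracellular | outer ring |

Charges: D, E → −1; K, R → +1; H → +0.1 in the extracellular compartment
(pH 7.4) or +0.4 in the intracellular one (pH 7.0); everything else,
including alignment gaps, 0.  The two intracellular rings use the
intracellular histidine value, rings ≥ 19′ the extracellular one (no
histidine occurs at these positions in the packaged data, so the choice is
latent but fixed).  The 0′ lysine itself is excluded from every ring sum:
the intermediate ring counts only the −1′ residue, which is what the
packaged receptor table tabulates.  All charge arithmetic uses exact
`fractions.Fraction` values, so half-integers produced by stoichiometry
averaging (−2.5) are exact and table comparisons are bit-precise.

Pentamer charges are linear: each region is the count-weighted sum of the
member subunits' ring charges.  Receptors expressed from two-subunit
transfections assemble in two stoichiometries (3:2 and 2:3); their charge
vector is the equal-weight mean of the two alternatives, which is how a
"1:1" composition string is interpreted.

## Parameters and defaults

* `PUBLISHED_MODEL` — const = 41917, k₋₅′₋₄′ = 0.3521, k₋₁′ = −1.9747,
  k₁₉′ = −0.0798, k₂₀′ = −0.5654, k₂₅′₂₉′ = 0.4910.  The five-ring
  constants used for all default predictions.  One-, two- and three-ring
  reference constants are shipped alongside.
* Non-selective baseline: a channel passing Ca²⁺ and Na⁺ with equal
  probability carries current ∝ valence × concentration per ion; at 2 mM
  Ca²⁺ / 140 mM Na⁺ this gives *Pf* = 4/144 ≈ 2.8 %.
* Fitting: unweighted least squares on the percent scale (SEMs are not used
  as weights by default; `weighted=True` is available).  `const` is fitted
  as log(const) to enforce positivity and condition the search — the
  five-ring optimum sits at const ≈ 4×10⁴ with a nearly flat likelihood in
  that direction.  Levenberg–Marquardt from a deterministic grid of 8
  starts over log(const) ∈ [−2, 12] (k = 0) plus seeded uniform random
  starts (16 total by default) over log(const) ∈ [−2, 12], kᵢ ∈ [−3, 3];
  the best converged optimum is kept and the full restart log is reported.
* Standard errors and p-values are asymptotic (Gauss–Newton covariance at
  the optimum, t distribution with n−p degrees of freedom) and labelled
  approximate; they are not calibrated against any external reference,
  whose method for nonlinear-fit p-values is unstated.

## Screening and selection

Per-region screens are ordinary simple linear regressions of measured *Pf*
on regional charge with the classical t-test on the slope; no
multiple-testing correction is applied across the eight regions.
Redundancy between two regions is declared only for an exact affine
relation q_b = α·q_a + β holding on every observation in exact arithmetic;
on the packaged panel this identifies q₂₁′₂₄′ = q₋₁′ + 5, so {21′–24′} is
excluded from the default model candidates and {−1′} retained.  The two
whole-domain charges are screened but never offered to the model.  Forward
selection grows the sigmoidal fit one ring at a time, adding the candidate
with the highest R² at each step, warm-starting each enlarged fit from the
previous optimum (making R² non-decreasing along the nested path); ties
break by candidate order.

## Synthetic panels

`synthetic_panel` draws distinct integer ring-charge vectors from the
ranges the receptor panel actually spans ({−5′−4′}, {−1′}, {19′} ∈ [−5, 0];
{20′} ∈ [−5, 3]; {25′–29′} ∈ [−5, 1]) and generates *Pf* from a given model,
optionally adding Gaussian noise on the percent scale (clipped to
(0.05, 99.95) to keep observations positive).  These panels satisfy the
model's own assumptions by construction — independent additive noise and
charge vectors exactly of the model's form.  Passing recovery tests on
them demonstrates the correctness of the optimizer and the algebra, not
that real receptors obey the model; real sequences add effects (uncharged
pore residues, pore geometry, single extracellular-domain residues) that
the charge-ring description deliberately ignores.

## Numerical choices

* Exact rational arithmetic for all charges; floats only enter at model
  evaluation and fitting.
* Table comparisons at printed precision: charges exact, predictions at one
  decimal (percent), R² at two decimals.
* Optimizer tolerances 10⁻¹⁵ (xtol/ftol/gtol), max 20 000 function
  evaluations per start; noise-free parameter recovery is validated to
  3 significant figures on 24–25-receptor panels.
* Degenerate inputs raise typed errors: zero charge variance in a screen,
  compositions not summing to five, missing regions at prediction time,
  zero observed variance in R².
* Fit identifiability requires n ≥ p + 2 observations for p regions.

## Known data discrepancy

The packaged prediction table transcribes its source exactly.  One cell is
internally inconsistent with the subunit sequences: the homomeric α5 row
lists a {25′–29′} charge of 0, while the α5 segment SSKVI carries a lysine
at 27′ (+1 per subunit, +5 for the homopentamer), as every α5-containing
heteromer row in both tables confirms.  The published α5 prediction
(66.7 %) is only consistent with the 0 entry; evaluated on the
sequence-derived +5 the same constants give ≈ 95.9 %.  The charge calculus
therefore stays faithful to the sequences, prediction-table *Pf* values are
reproduced from the table's own charge vectors, and the reproduction suite
reports this single cell in a separate `known_discrepancies` list rather
than as a failure, so that any genuine regression still trips the diff.

## Design choices where the design was open

* The {−3′..0′} segment is stored gap-padded to four characters ("_GEK"),
  so every segment character sits at a fixed prime offset; gaps are
  length-less and chargeless.  User-sequence extraction takes contiguous
  slices around the supplied 0′ anchor, with an explicit `m3_gap` flag for
  subunits (most α/β) that lack a −3′ residue relative to the alignment.
* Subunit labels are stored in Unicode Greek and accept ASCII aliases
  (`a7`, `beta2`) everywhere; outputs use ASCII hyphen-minus, inputs also
  accept U+2212.
* Whole-domain charges are consumed as data, never computed: full-length
  sequences are not part of the packaged segment table, and the package
  performs no sequence downloads.
* Problem sizes throughout (16-receptor panel, 19-row prediction table,
  20–25-receptor synthetic panels, ≤ 16 optimizer starts) keep every
  computation in the suite at desk scale, seconds per run.

## Limitations

* The model is deliberately minimal: no pKa titration beyond the two fixed
  histidine values, no pore geometry, no uncharged-residue effects, no
  energy-profile (GHK or Poisson–Nernst–Planck) computation — the barrier
  derivation serves only to motivate the logistic form.
* The five-ring likelihood is nearly flat in const (asymptotic p ≈ 0.8 at
  the optimum); reported constants are reproducible because the multi-start
  procedure is deterministic, not because the optimum is sharp.
* Measurement SEMs are not propagated into predictions; no Bayesian
  uncertainty is offered.
* Anchors for user sequences are user-supplied; the package does no
  transmembrane-topology prediction.
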