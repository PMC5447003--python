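# nachr-pf

Charge-ring modelling of nicotinic acetylcholine receptor (nAChR) Ca²⁺
permeability.

nAChRs are pentameric cation channels built from α/β/γ/δ/ε subunits, and
the fraction of their current carried by Ca²⁺ — the fractional Ca²⁺ current
*Pf*, in percent — ranges from ~1.5 % (α4β4) to ~22 % (α9α10) depending on
subunit composition.  This package is for channel physiologists and
molecular modellers who want to relate that variation to sequence: it
computes the summed electrical charges of the residue rings flanking the
pore-lining TM2 helix and predicts *Pf* from them with a logistic
charge-ring model

    Pf = 100 / (1 + const · exp( Σᵢ kᵢ · Δqᵢ )),   Δqᵢ = −qᵢ,

where qᵢ is the signed charge (nuec, elementary charges) of ring *i* ∈
{−5′−4′, −1′, 19′, 20′, 25′–29′} summed over the five subunits, and the
packaged constants are const = 41917, k₋₅′₋₄′ = 0.3521, k₋₁′ = −1.9747,
k₁₉′ = −0.0798, k₂₀′ = −0.5654, k₂₅′₂₉′ = 0.4910.  Positions use Miller
prime notation, anchored on the conserved lysine (0′) preceding TM2.

Shipped data: a 28-subunit table of TM2-flanking segment sequences (human,
mouse, rat, chick), a 16-receptor panel of regional charges with measured
*Pf* ± SEM, and a 19-row reference table of model predictions.  The library
covers: residue/segment/pentamer charge algebra in exact rational
arithmetic (stoichiometry averaging gives exact half-integers), model
evaluation and multi-start least-squares fitting, per-region linear screens
with exact redundancy detection, forward selection, synthetic receptor
panels, and extraction of the TM2 segments from user FASTA sequences given
the 0′ anchor.

## Worked example

```python
from nachr_pf import (PUBLISHED_MODEL, parse_composition, pentamer_charges,
                      predict_pf, registry_with_mutants)

registry = registry_with_mutants()
for spec in ["α7", "α7_E237A", "α7β2 4:1", "α7β2 1:4"]:
    vec = pentamer_charges(parse_composition(spec, registry, "H"))
    print(spec, float(vec.p20), round(predict_pf(PUBLISHED_MODEL, vec), 1))
```

prints

```
α7 -5.0 10.4
α7_E237A -5.0 0.0
α7β2 4:1 -3.0 3.6
α7β2 1:4 3.0 0.1
```

Homomeric α7 carries five {20′} glutamates (q₂₀′ = −5) and a predicted
*Pf* of 10.4 %.  Removing the −1′ glutamate ring (the E237A pore mutant)
collapses *Pf* to 0.0 % — the model's account of a Ca²⁺-impermeable
channel.  Adding β2 subunits replaces {20′} glutamates with lysines; at 1:4
the ring is net positive (+3) and *Pf* drops to 0.1 %, far below the 2.8 %
a completely non-selective channel would show at 2 mM Ca²⁺ / 140 mM Na⁺
(`nonselective_pf(2, 140)`).

Composition strings accept ratios (`"α3β4α5 2:2:1"`), explicit counts
(`"α4:3,β2:2"`), dimer notation (`"(β2α4)2α5"`), and two-subunit `"1:1"`
labels, which average the coexisting 3:2 and 2:3 stoichiometries.  ASCII
aliases (`a7`, `beta2`) work everywhere.

The `examples/` directory has one narrative script per capability:
prediction, refitting, screening/selection, and user-sequence scoring.  The
same functionality is exposed as a thin CLI:

```sh
nachr-pf predict --reference            # recompute all 19 reference predictions
nachr-pf fit --regions p20 --seed 1     # one-ring refit (const ≈ 29.5, k ≈ −0.316)
nachr-pf screen                         # per-region linear screens
nachr-pf reproduce                      # full table diff; nonzero exit on mismatch
```

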