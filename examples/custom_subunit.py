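"""Score a user-supplied subunit sequence.

Extracts the TM2-flanking segments from a full-length sequence given the
position of the conserved 0' lysine, derives a pore point-mutant, and
predicts Pf for pentamers containing the new subunit.  The sequence here is
a synthetic carrier embedding the packaged human α7 segments, so the numbers
match the packaged α7 receptor.
"""

from nachr_pf import (
    AnchorConfig,
    PUBLISHED_MODEL,
    PentamerComposition,
    extract_regions,
    load_packaged_subunits,
    pentamer_charges,
    predict_pf,
    substitute,
    subunit_ring_charges,
)

registry = load_packaged_subunits()
a7 = registry.get("H", "α7")

# synthetic full-length sequence: α7 segments in a neutral scaffold;
# α7 has an alignment gap at -3', hence m3_gap=True
full = "M" + "A" * 9 + "DSGEK" + a7.seg_1_18 + a7.seg_19 + a7.seg_20 \
    + a7.seg_21_24 + a7.seg_25_29 + "A" * 10
anchor = AnchorConfig("my_subunit", 14, index_base=0, m3_gap=True)
mine = extract_regions(full, anchor, name="my_subunit")
print("extracted segments:", mine.seg_m5m4, mine.seg_m3_0, mine.seg_20,
      mine.seg_25_29)
print("per-subunit ring charges:", subunit_ring_charges(mine).to_dict())

homomer = PentamerComposition.single([(mine, 5)])
print(f"\nhomopentamer Pf: "
      f"{predict_pf(PUBLISHED_MODEL, pentamer_charges(homomer)):.1f}%")

# remove the -1' glutamate (the intermediate-ring charge): Pf collapses
mutant = substitute(mine, -1, "A")
mut_homomer = PentamerComposition.single([(mutant, 5)])
print(f"{mutant.name} homopentamer Pf: "
      f"{predict_pf(PUBLISHED_MODEL, pentamer_charges(mut_homomer)):.1f}%")
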