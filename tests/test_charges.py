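"""Residue/segment/pentamer charge algebra against independent counts."""

import warnings
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from nachr_pf import (
    PentamerComposition,
    parse_composition,
    pentamer_charges,
    residue_charge,
    segment_charge,
    subunit_ring_charges,
)
from nachr_pf.charges import EXTRACELLULAR, INTRACELLULAR
from nachr_pf.errors import CompositionError, ResidueError
from nachr_pf.regions import RING_REGIONS


def brute_force_charge(sequence, compartment):
    """Independent oracle: per-residue table lookup and plain summation."""
    table = {"D": Fraction(-1), "E": Fraction(-1),
             "K": Fraction(1), "R": Fraction(1),
             "H": Fraction(1, 10) if compartment == "extracellular"
             else Fraction(2, 5)}
    return sum((table.get(c, Fraction(0)) for c in sequence), Fraction(0))


@pytest.mark.parametrize(
    "residue, compartment, expected",
    [
        ("H", EXTRACELLULAR, Fraction(1, 10)),
        ("H", INTRACELLULAR, Fraction(2, 5)),
        ("E", INTRACELLULAR, -1),
        ("D", EXTRACELLULAR, -1),
        ("K", EXTRACELLULAR, 1),
        ("R", INTRACELLULAR, 1),
        ("G", EXTRACELLULAR, 0),
        ("_", EXTRACELLULAR, 0),
    ],
)
def test_residue_charge(residue, compartment, expected):
    assert residue_charge(residue, compartment) == expected


def test_residue_charge_rejects_unknowns():
    with pytest.raises(ResidueError):
        residue_charge("X", EXTRACELLULAR)
    with pytest.raises(ValueError):
        residue_charge("E", "membrane")


@pytest.mark.parametrize(
    "sequence, compartment, expected",
    [
        ("TSDSV", EXTRACELLULAR, -1),
        ("", EXTRACELLULAR, 0),
        ("_GEK", INTRACELLULAR, 0),  # E and K cancel, gap neutral
        ("SSKVI", EXTRACELLULAR, 1),
        ("HH", INTRACELLULAR, Fraction(4, 5)),
    ],
)
def test_segment_charge(sequence, compartment, expected):
    assert segment_charge(sequence, compartment) == expected


def test_segment_charge_names_offending_position():
    with pytest.raises(ResidueError, match="position 2"):
        segment_charge("AC*DE", EXTRACELLULAR)


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY_", max_size=30),
       st.sampled_from([EXTRACELLULAR, INTRACELLULAR]))
def test_segment_charge_matches_brute_force(sequence, compartment):
    assert segment_charge(sequence, compartment) == \
        brute_force_charge(sequence, compartment)


def test_subunit_ring_charges(registry):
    a7 = subunit_ring_charges(registry.get("H", "α7"))
    assert (a7.p20, a7.p2529, a7.m1, a7.m5m4) == (-1, -1, -1, -1)
    gamma = subunit_ring_charges(registry.get("H", "γ"))
    assert gamma.p20 == 1  # lysine
    assert gamma.m1 == 0   # glutamine at -1'
    a9 = subunit_ring_charges(registry.get("R", "α9"))
    assert a9.m5m4 == 0    # "AS"
    # the conserved 0' lysine is excluded from every ring
    assert subunit_ring_charges(registry.get("H", "α1")).m1 == -1


def test_muscle_pentamer_charges(registry):
    comp = parse_composition("α1β1εδ 2:1:1:1", registry, "H")
    vec = pentamer_charges(comp)
    assert (vec.p20, vec.m1, vec.m5m4) == (-2, -4, -4)
    assert (vec.p19, vec.p2124, vec.p2529) == (0, 1, 0)


def test_alternative_stoichiometry_mean(registry):
    comp = parse_composition("α9α10 1:1", registry, "R")
    assert comp.is_averaged
    vec = pentamer_charges(comp)
    assert vec.m5m4 == Fraction(-5, 2)
    assert vec.p2529 == -5


def test_heteromer_ratio_charges(registry):
    vec = pentamer_charges(parse_composition("α7β2 4:1", registry, "H"))
    assert vec.p20 == -3
    assert vec.p2529 == -5


def test_domain_charges_absent_without_member_data(registry):
    vec = pentamer_charges(parse_composition("α7:5", registry, "H"))
    assert vec.ext_domain is None and vec.int_domain is None


def test_pentamer_linearity_against_residue_counting(registry):
    # independent oracle: concatenate each ring's residues over all five
    # subunits and count charges residue by residue
    comp = parse_composition("α3β4α5 2:2:1", registry, "H")
    (stoich,) = comp.stoichiometries
    concatenated = {r: "" for r in RING_REGIONS}
    for rec, count in stoich:
        concatenated["m5m4"] += rec.seg_m5m4 * count
        concatenated["m1"] += rec.seg_m3_0[-2] * count
        concatenated["p19"] += rec.seg_19 * count
        concatenated["p20"] += rec.seg_20 * count
        concatenated["p2124"] += rec.seg_21_24 * count
        concatenated["p2529"] += rec.seg_25_29 * count
    vec = pentamer_charges(comp)
    for region in RING_REGIONS:
        compartment = INTRACELLULAR if region in ("m5m4", "m1") else EXTRACELLULAR
        assert vec.get(region) == brute_force_charge(
            concatenated[region], compartment
        )


def test_pentamer_permutation_invariance(registry):
    a = PentamerComposition.single(
        [(registry.get("H", "α4"), 2), (registry.get("H", "β2"), 3)]
    )
    b = PentamerComposition.single(
        [(registry.get("H", "β2"), 3), (registry.get("H", "α4"), 2)]
    )
    assert pentamer_charges(a) == pentamer_charges(b)


def test_identical_alternatives_equal_single(registry):
    members = [(registry.get("H", "α7"), 5)]
    single = PentamerComposition.single(members)
    repeated = PentamerComposition.averaged([members, members])
    assert pentamer_charges(single) == pentamer_charges(repeated)


def test_mixed_species_warns(registry):
    comp = PentamerComposition.single(
        [(registry.get("H", "α4"), 3), (registry.get("C", "β2"), 2)]
    )
    with pytest.warns(UserWarning, match="species"):
        pentamer_charges(comp)


def test_table2_charges_recomputed(registry_mut, observations):
    for obs in observations:
        comp = parse_composition(obs.composition, registry_mut, obs.species)
        vec = pentamer_charges(comp)
        for region in RING_REGIONS:
            assert vec.get(region) == obs.charges.get(region), (
                obs.receptor_label, region)


def test_table3_charges_recomputed(registry_mut, predictions):
    # one documented exception: the homomeric α5 {25'-29'} cell is
    # transcribed as published (0) but the SSKVI segment carries +1/subunit
    for row in predictions:
        comp = parse_composition(row.composition, registry_mut, "H")
        vec = pentamer_charges(comp)
        for region in RING_REGIONS:
            if (row.receptor_label, region) == ("α5", "p2529"):
                assert vec.get(region) == 5
                assert row.charges.get(region) == 0
                continue
            assert vec.get(region) == row.charges.get(region), (
                row.receptor_label, region)


@pytest.mark.parametrize(
    "spec, expected_counts",
    [
        ("α7β2 4:1", {"α7": 4, "β2": 1}),
        ("(β2α4)2α4", {"β2": 2, "α4": 3}),
        ("(β2α4)2α5", {"β2": 2, "α4": 2, "α5": 1}),
        ("α1:5", {"α1": 5}),
        ("α7", {"α7": 5}),
        ("a4:3,b2:2", {"α4": 3, "β2": 2}),
    ],
)
def test_parse_composition_counts(registry, spec, expected_counts):
    comp = parse_composition(spec, registry, "H")
    (stoich,) = comp.stoichiometries
    assert {rec.name: n for rec, n in stoich} == expected_counts


def test_parse_composition_one_to_one_averages(registry):
    comp = parse_composition("α2β2 1:1", registry, "H")
    assert comp.is_averaged
    counts = [{rec.name: n for rec, n in s} for s in comp.stoichiometries]
    assert {"α2": 3, "β2": 2} in counts and {"α2": 2, "β2": 3} in counts
    vec = pentamer_charges(comp)
    assert vec.p20 == 0
    assert vec.p2529 == Fraction(-5, 2)


@pytest.mark.parametrize("bad", ["α4β2 3:3", "α4:6", "", "α4β2γ 1:1", "q5 5"])
def test_parse_composition_rejects(registry, bad):
    with pytest.raises(CompositionError):
        parse_composition(bad, registry, "H")


def test_counts_must_sum_to_five(registry):
    with pytest.raises(CompositionError):
        PentamerComposition.single([(registry.get("H", "α7"), 4)])
    with pytest.raises(CompositionError):
        PentamerComposition.single([(registry.get("H", "α7"), 0),
                                    (registry.get("H", "β2"), 5)])
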