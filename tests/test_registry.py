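"""Packaged tables, label normalization, and region extraction."""

import warnings

import pytest

from nachr_pf import (
    AnchorConfig,
    extract_regions,
    load_observations,
    load_subunits,
    normalize_label,
    read_anchor_config,
    read_fasta,
    save_observations,
    save_subunits,
    substitute,
)
from nachr_pf.errors import AnchorError, ResidueError, SegmentError


def test_packaged_subunit_table(registry):
    assert len(registry) == 28
    a7 = registry.get("H", "α7")
    assert a7.seg_25_29 == "TSDSV"
    assert a7.seg_20 == "E"
    assert a7.seg_m5m4 == "DS"
    assert a7.accession == "P36544"
    a9 = registry.get("R", "α9")
    assert a9.seg_m5m4 == "AS"
    assert a9.seg_19 == "A"
    gamma = registry.get("H", "γ")
    assert gamma.seg_m3_0 == "GGQK"  # no gap in the muscle γ subunit


def test_every_packaged_subunit_anchored_on_lysine(registry):
    # prime numbering hinges on the conserved lysine at 0'
    assert all(rec.seg_m3_0[-1] == "K" for rec in registry)


def test_alpha_subunits_negative_at_p20(registry):
    # a feature of this data set, asserted as such: every α subunit carries
    # an acidic residue in the extracellular ring
    alphas = [rec for rec in registry if rec.name.startswith("α")]
    assert len(alphas) == 15
    assert all(rec.seg_20 in "DE" for rec in alphas)


def test_packaged_observation_table(observations):
    assert len(observations) == 16
    by_label = {(o.species, o.receptor_label): o for o in observations}
    a4b4 = by_label[("H", "α4β4")]
    assert a4b4.pf_percent == 1.5
    assert a4b4.pf_sem == 0.2
    assert float(a4b4.charges.ext_domain) == -12.75
    a9a10 = by_label[("R", "α9α10")]
    assert a9a10.pf_percent == 22
    assert float(a9a10.charges.m5m4) == -2.5
    pfs = sorted(o.pf_percent for o in observations)
    assert pfs[0] == 1.5 and pfs[-1] == 22


def test_tables_round_trip_through_tsv(tmp_path, registry, observations):
    sub_path = tmp_path / "subunits.tsv"
    save_subunits(registry, sub_path)
    assert list(load_subunits(sub_path)) == list(registry)

    obs_path = tmp_path / "observations.tsv"
    save_observations(observations, obs_path)
    assert load_observations(obs_path) == observations


@pytest.mark.parametrize(
    "alias, canonical",
    [
        ("a7", "α7"),
        ("alpha7", "α7"),
        ("b2", "β2"),
        ("beta4", "β4"),
        ("g", "γ"),
        ("delta", "δ"),
        ("e", "ε"),
        ("a7_E237A", "α7_E237A"),
        ("α9", "α9"),
    ],
)
def test_normalize_label(alias, canonical):
    assert normalize_label(alias) == canonical


def test_registry_lookup_accepts_aliases(registry):
    assert registry.get("H", "a7") is registry.get("H", "α7")
    with pytest.raises(KeyError):
        registry.get("H", "α11")


def test_substitute_builds_point_mutant(registry):
    a7 = registry.get("H", "α7")
    mutant = substitute(a7, -1, "A", name="α7_E237A")
    assert mutant.seg_m3_0 == "_GAK"
    assert mutant.name == "α7_E237A"
    # all other segments untouched
    assert mutant.seg_m5m4 == a7.seg_m5m4
    assert mutant.seg_25_29 == a7.seg_25_29
    with pytest.raises(SegmentError):
        substitute(a7, 31, "A")
    with pytest.raises(ResidueError):
        substitute(a7, -1, "X")


def test_extract_regions_offsets():
    seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"  # 40 residues
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec = extract_regions(seq, AnchorConfig("syn", 10, index_base=0))
    assert rec.seg_19 == seq[29]
    assert rec.seg_m5m4 == seq[5:7]
    assert rec.seg_m3_0 == seq[7:11]
    assert rec.seg_25_29 == seq[35:40]


def test_extract_regions_boundary_and_parse_errors():
    seq = "A" * 40
    with pytest.raises(AnchorError):
        extract_regions(seq, AnchorConfig("syn", 3, index_base=0))
    with pytest.raises(AnchorError):
        extract_regions(seq, AnchorConfig("syn", 20, index_base=0))
    with pytest.raises(ResidueError):
        extract_regions("AC1" + "A" * 40, AnchorConfig("syn", 10, index_base=0))


def test_extract_regions_warns_off_anchor():
    with pytest.warns(UserWarning, match="not the\\s+conserved lysine"):
        extract_regions("A" * 40, AnchorConfig("syn", 10, index_base=0))


def _scaffold(record, gap):
    """Synthetic full-length sequence embedding a packaged record's segments."""
    inner = record.seg_m5m4 + record.seg_m3_0.replace("_", "") \
        + record.seg_1_18 + record.seg_19 + record.seg_20 \
        + record.seg_21_24 + record.seg_25_29
    prefix, suffix = "M" + "A" * 9, "A" * 10
    anchor = len(prefix) + len(record.seg_m5m4) + len(record.seg_m3_0.replace("_", "")) - 1
    return prefix + inner + suffix, anchor


@pytest.mark.parametrize("species,name,gap", [("H", "γ", False), ("H", "α7", True)])
def test_extract_regions_reproduces_packaged_record(registry, species, name, gap):
    # synthetic scaffold: the packaged segments embedded in a neutral carrier
    rec = registry.get(species, name)
    seq, anchor = _scaffold(rec, gap)
    extracted = extract_regions(
        seq,
        AnchorConfig(name, anchor, index_base=0, m3_gap=gap),
        species=species,
        name=name,
    )
    for seg in ("seg_m5m4", "seg_m3_0", "seg_1_18", "seg_19", "seg_20",
                "seg_21_24", "seg_25_29"):
        assert getattr(extracted, seg) == getattr(rec, seg)


def test_fasta_and_anchor_config_round_trip(tmp_path, registry):
    rec = registry.get("H", "α7")
    seq, anchor = _scaffold(rec, gap=True)
    fasta = tmp_path / "subunits.fasta"
    fasta.write_text(f">a7_synthetic\n{seq}\n", encoding="utf-8")
    config = tmp_path / "anchors.yaml"
    config.write_text(
        f"a7_synthetic:\n  anchor: {anchor}\n  base: 0\n  gap: true\n",
        encoding="utf-8",
    )
    sequences = read_fasta(fasta)
    anchors = read_anchor_config(config)
    rec2 = extract_regions(sequences["a7_synthetic"], anchors["a7_synthetic"])
    assert rec2.seg_m3_0 == "_GEK"
    assert rec2.seg_m5m4 == "DS"


def test_flat_anchor_config(tmp_path):
    config = tmp_path / "anchors.cfg"
    config.write_text("# one-based positions\nmy_seq=241\n", encoding="utf-8")
    anchors = read_anchor_config(config)
    assert anchors["my_seq"].zero_based == 240
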