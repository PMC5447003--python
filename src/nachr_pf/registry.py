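"""Subunit sequence registry and receptor observation tables.

Holds the packaged transcriptions of the two receptor tables — 28 nicotinic
subunits with their seven TM2-flanking segments, and 16 receptors with
regional charges and measured fractional Ca2+ currents — and parses
user-supplied subunits from FASTA given the prime-zero anchor position.

All prime positions are integer offsets from the conserved lysine at 0'
immediately preceding TM2.  The segment at {-3'..0'} is stored gap-padded to
four characters with ``_`` (as in ``_GEK``), so that character ``i`` of every
segment always sits at a fixed prime offset.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml
from Bio import SeqIO

from .errors import AnchorError, PackagedDataError, ResidueError, SegmentError
from .regions import RegionChargeVector

GAP = "_"
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_GREEK = {
    "a": "α", "alpha": "α",
    "b": "β", "beta": "β",
    "g": "γ", "gamma": "γ",
    "d": "δ", "delta": "δ",
    "e": "ε", "eps": "ε", "epsilon": "ε",
}

_LABEL_RE = re.compile(
    r"^(α|β|γ|δ|ε|alpha|beta|gamma|delta|epsilon|eps|[abgde])"
    r"(\d*)((?:_[A-Za-z0-9]+)?)$"
)


def normalize_label(label: str) -> str:
    """Canonicalize a subunit label to its Unicode Greek form.

    Accepts ASCII aliases: ``a7`` -> ``α7``, ``beta2`` -> ``β2``, ``e`` ->
    ``ε``.  Mutant suffixes (``a7_E237A``) are preserved.  Unrecognized
    labels are returned unchanged so free-text names remain usable.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        return label.strip()
    letter, number, suffix = m.groups()
    return _GREEK.get(letter, letter) + number + suffix


# segment name -> (first prime offset, expected length)
SEGMENT_LAYOUT: Mapping[str, tuple[int, int]] = {
    "seg_m5m4": (-5, 2),
    "seg_m3_0": (-3, 4),
    "seg_1_18": (1, 18),
    "seg_19": (19, 1),
    "seg_20": (20, 1),
    "seg_21_24": (21, 4),
    "seg_25_29": (25, 5),
}


@dataclass(frozen=True)
class SubunitRecord:
    """One subunit's TM2-flanking segment sequences plus identifiers.

    ``ext_domain_charge`` / ``int_domain_charge`` are optional precomputed
    whole-domain charges (nuec); they are data fields, never derived from the
    segments.
    """

    species: str
    name: str
    accession: str
    seg_m5m4: str
    seg_m3_0: str
    seg_1_18: str
    seg_19: str
    seg_20: str
    seg_21_24: str
    seg_25_29: str
    ext_domain_charge: Fraction | None = None
    int_domain_charge: Fraction | None = None

    def __post_init__(self) -> None:
        for seg_name, (_, length) in SEGMENT_LAYOUT.items():
            seq = getattr(self, seg_name)
            if seg_name == "seg_m3_0":
                if len(seq) != 4:
                    raise SegmentError(
                        f"{self.species} {self.name}: seg_m3_0 must be "
                        f"gap-padded to 4 characters, got {seq!r}"
                    )
            elif len(seq) != length:
                raise SegmentError(
                    f"{self.species} {self.name}: {seg_name} must have "
                    f"{length} residues, got {seq!r}"
                )
            bad = set(seq) - AMINO_ACIDS - {GAP}
            if bad:
                raise ResidueError(
                    f"{self.species} {self.name}: invalid character(s) "
                    f"{sorted(bad)} in {seg_name}"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.name)

    def residue_at(self, prime_position: int) -> str:
        """Residue (or gap) at a prime offset covered by the segments."""
        for seg_name, (start, length) in SEGMENT_LAYOUT.items():
            if start <= prime_position < start + length:
                return getattr(self, seg_name)[prime_position - start]
        raise SegmentError(
            f"prime position {prime_position}' outside the stored "
            f"-5'..29' window"
        )


def substitute(
    record: SubunitRecord,
    prime_position: int,
    new_residue: str,
    *,
    name: str | None = None,
) -> SubunitRecord:
    """Derive a point-mutant record by replacing one prime position.

    E.g. the alpha7 E237A pore mutant is the -1' glutamate replaced by
    alanine: ``substitute(a7, -1, "A", name="α7_E237A")``.
    """
    new_residue = new_residue.upper()
    if new_residue not in AMINO_ACIDS:
        raise ResidueError(f"invalid replacement residue {new_residue!r}")
    for seg_name, (start, length) in SEGMENT_LAYOUT.items():
        if start <= prime_position < start + length:
            seq = getattr(record, seg_name)
            i = prime_position - start
            mutated = seq[:i] + new_residue + seq[i + 1:]
            old = seq[i]
            default = f"{record.name}_{old}{prime_position}'{new_residue}"
            return replace(
                record,
                name=name if name is not None else default,
                accession="",
                **{seg_name: mutated},
            )
    raise SegmentError(
        f"prime position {prime_position}' outside the stored -5'..29' window"
    )


class SubunitRegistry:
    """Lookup table of subunit records keyed by (species, canonical name)."""

    def __init__(self, records: Iterator[SubunitRecord] | list[SubunitRecord] = ()) -> None:
        self._records: dict[tuple[str, str], SubunitRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SubunitRecord) -> None:
        self._records[record.key] = record

    def get(self, species: str, name: str) -> SubunitRecord:
        key = (species, normalize_label(name))
        try:
            return self._records[key]
        except KeyError:
            raise KeyError(
                f"no subunit ({species}, {normalize_label(name)}) in registry"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        species, name = key
        return (species, normalize_label(name)) in self._records

    def __iter__(self) -> Iterator[SubunitRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def copy(self) -> "SubunitRegistry":
        return SubunitRegistry(list(self))


@dataclass(frozen=True)
class PfObservation:
    """A receptor's regional charge vector paired with its measured Pf.

    ``composition`` is the pentamer composition string (see
    :func:`nachr_pf.charges.parse_composition`) used to recompute the ring
    charges from subunit sequences; the two-subunit receptors expressed from
    pairwise transfections use the mean over the 3:2 and 2:3 alternative
    stoichiometries.
    """

    species: str
    receptor_label: str
    composition: str
    charges: RegionChargeVector
    pf_percent: float
    pf_sem: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.pf_percent > 0:
            raise PackagedDataError(
                f"{self.receptor_label}: pf_percent must be > 0"
            )
        if self.pf_sem < 0:
            raise PackagedDataError(f"{self.receptor_label}: negative SEM")


# ---------------------------------------------------------------------------
# Packaged tables
# ---------------------------------------------------------------------------

_SUBUNIT_COLUMNS = [
    "species", "name", "accession", "seg_m5m4", "seg_m3_0", "seg_1_18",
    "seg_19", "seg_20", "seg_21_24", "seg_25_29",
]


def packaged_data_path(filename: str) -> Path:
    return Path(str(resources.files("nachr_pf").joinpath("data", filename)))


def load_subunits(path: str | Path) -> SubunitRegistry:
    """Read a subunit segment table (TSV, one header row)."""
    registry = SubunitRegistry()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                registry.add(SubunitRecord(**{c: row[c] for c in _SUBUNIT_COLUMNS}))
            except (KeyError, TypeError, ValueError) as exc:
                raise PackagedDataError(f"{path} line {i}: {exc}") from exc
    return registry


def save_subunits(registry: SubunitRegistry, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SUBUNIT_COLUMNS)
        for rec in registry:
            writer.writerow([getattr(rec, c) for c in _SUBUNIT_COLUMNS])


def load_packaged_subunits() -> SubunitRegistry:
    """The packaged 28-subunit segment table.

    Raises :class:`PackagedDataError` if the packaged file is corrupted
    (wrong row count, malformed segment, or a 0' residue that is not the
    conserved lysine).
    """
    registry = load_subunits(packaged_data_path("subunit_segments.tsv"))
    if len(registry) != 28:
        raise PackagedDataError(
            f"expected 28 packaged subunits, found {len(registry)}"
        )
    for rec in registry:
        if rec.seg_m3_0[-1] != "K":
            raise PackagedDataError(
                f"packaged subunit {rec.species} {rec.name}: 0' residue is "
                f"{rec.seg_m3_0[-1]!r}, expected the conserved lysine"
            )
    return registry


_OBS_CHARGE_COLUMNS = [
    "ext_domain", "m5m4", "m1", "p19", "p20", "p2124", "p2529", "int_domain",
]


def load_observations(path: str | Path) -> list[PfObservation]:
    """Read a receptor observation table (TSV, one header row)."""
    observations = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            try:
                charges = RegionChargeVector(
                    **{c: Fraction(row[c].replace("−", "-"))
                       for c in _OBS_CHARGE_COLUMNS}
                )
                observations.append(
                    PfObservation(
                        species=row["species"],
                        receptor_label=row["receptor"],
                        composition=row["composition"],
                        charges=charges,
                        pf_percent=float(row["pf_percent"]),
                        pf_sem=float(row["pf_sem"]),
                        source=row.get("source", ""),
                    )
                )
            except (KeyError, TypeError, ValueError, ZeroDivisionError) as exc:
                raise PackagedDataError(f"{path} line {i}: {exc}") from exc
    return observations


def save_observations(observations: list[PfObservation], path: str | Path) -> None:
    from .regions import format_charge

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["species", "receptor", "composition"] + _OBS_CHARGE_COLUMNS
            + ["pf_percent", "pf_sem", "source"]
        )
        for obs in observations:
            writer.writerow(
                [obs.species, obs.receptor_label, obs.composition]
                + [format_charge(getattr(obs.charges, c)) for c in _OBS_CHARGE_COLUMNS]
                + [f"{obs.pf_percent:g}", f"{obs.pf_sem:g}", obs.source]
            )


def load_packaged_observations() -> list[PfObservation]:
    """The packaged 16-receptor table of charges and measured Pf values."""
    observations = load_observations(packaged_data_path("receptor_observations.tsv"))
    if len(observations) != 16:
        raise PackagedDataError(
            f"expected 16 packaged observations, found {len(observations)}"
        )
    return observations


# ---------------------------------------------------------------------------
# User-supplied sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorConfig:
    """Position of the 0' lysine within a supplied full-length sequence.

    ``m3_gap`` declares that the subunit, like most α/β subunits, has only
    three residues between the cytoplasmic ring and the 0' lysine: prime
    position -3' is then an alignment gap and the two cytoplasmic-ring
    residues sit one position closer to the anchor in the raw sequence
    (``...DSGEK`` reads as {-5'-4'} = DS, {-3'..0'} = _GEK).
    """

    sequence_id: str
    anchor_index: int
    index_base: int = 1  # biologists count from 1; stored 0-based internally
    m3_gap: bool = False

    def __post_init__(self) -> None:
        if self.index_base not in (0, 1):
            raise AnchorError(f"index_base must be 0 or 1, got {self.index_base}")

    @property
    def zero_based(self) -> int:
        return self.anchor_index - self.index_base


def extract_regions(
    full_sequence: str,
    anchor: AnchorConfig,
    *,
    species: str = "user",
    name: str | None = None,
) -> SubunitRecord:
    """Slice the seven TM2-flanking segments out of a full subunit sequence.

    The window spans prime offsets -5..29 around the anchor.  A warning is
    issued if the residue at 0' is not the conserved lysine.  Unlike the
    packaged table, a freshly extracted {-3'..0'} segment never contains a
    gap; domain charges are left unset (they cannot be derived here).
    """
    seq = full_sequence.strip().upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        pos = min(i for i, c in enumerate(seq) if c in bad)
        raise ResidueError(
            f"{anchor.sequence_id}: non-amino-acid character {seq[pos]!r} "
            f"at index {pos}"
        )
    a = anchor.zero_based
    down = 4 if anchor.m3_gap else 5  # residues needed below the anchor
    if a - down < 0 or a + 29 >= len(seq):
        lo, hi = max(0, a - down), min(len(seq) - 1, a + 29)
        raise AnchorError(
            f"{anchor.sequence_id}: anchor {a} (0-based) needs offsets "
            f"-5'..29' but only [{lo - a}'..{hi - a}'] fit in a sequence of "
            f"length {len(seq)}"
        )
    if seq[a] != "K":
        warnings.warn(
            f"{anchor.sequence_id}: residue at 0' is {seq[a]!r}, not the "
            f"conserved lysine — check the anchor position",
            stacklevel=2,
        )
    if anchor.m3_gap:
        seg_m5m4 = seq[a - 4:a - 2]
        seg_m3_0 = GAP + seq[a - 2:a + 1]
    else:
        seg_m5m4 = seq[a - 5:a - 3]
        seg_m3_0 = seq[a - 3:a + 1]
    return SubunitRecord(
        species=species,
        name=name if name is not None else anchor.sequence_id,
        accession="",
        seg_m5m4=seg_m5m4,
        seg_m3_0=seg_m3_0,
        seg_1_18=seq[a + 1:a + 19],
        seg_19=seq[a + 19],
        seg_20=seq[a + 20],
        seg_21_24=seq[a + 21:a + 25],
        seg_25_29=seq[a + 25:a + 30],
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from FASTA, keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_anchor_config(path: str | Path) -> dict[str, AnchorConfig]:
    """Read anchor positions from YAML or flat ``id=position`` lines.

    YAML values may be a bare integer (1-based) or a mapping
    ``{anchor: N, base: 0|1, gap: true|false}`` where ``gap`` marks a
    subunit with an alignment gap at -3' (see :class:`AnchorConfig`).
    """
    text = Path(path).read_text(encoding="utf-8")
    configs: dict[str, AnchorConfig] = {}
    if "=" in text and ":" not in text:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            configs[key.strip()] = AnchorConfig(key.strip(), int(value))
        return configs
    data = yaml.safe_load(text) or {}
    for key, value in data.items():
        if isinstance(value, Mapping):
            configs[key] = AnchorConfig(
                key,
                int(value["anchor"]),
                int(value.get("base", 1)),
                bool(value.get("gap", False)),
            )
        else:
            configs[key] = AnchorConfig(key, int(value))
    return configs
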