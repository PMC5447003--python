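"""Residue, segment and pentamer charge algebra.

Charge assignment follows the fixed-pKa convention used throughout the
model: aspartate and glutamate carry -1, lysine and arginine +1, and
histidine a fractional mean protonation of +0.1 on the extracellular side
(pH 7.4) or +0.4 on the intracellular side (pH 7.0).  Everything else,
including the gap character, is neutral.  All values are exact
:class:`~fractions.Fraction` so that stoichiometry averaging yields exact
half-integers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from .errors import CompositionError, ResidueError
from .registry import GAP, SubunitRecord, SubunitRegistry, normalize_label
from .regions import RegionChargeVector

EXTRACELLULAR = "extracellular"
INTRACELLULAR = "intracellular"

_ZERO = Fraction(0)


@dataclass(frozen=True)
class ChargeScheme:
    """Immutable per-residue charge assignment (nuec)."""

    negative_residues: frozenset[str] = frozenset({"D", "E"})
    positive_residues: frozenset[str] = frozenset({"K", "R"})
    histidine_extracellular: Fraction = Fraction(1, 10)
    histidine_intracellular: Fraction = Fraction(2, 5)


DEFAULT_SCHEME = ChargeScheme()

_VALID = frozenset("ACDEFGHIKLMNPQRSTVWY") | {GAP}


def residue_charge(
    residue: str,
    compartment: str,
    scheme: ChargeScheme = DEFAULT_SCHEME,
) -> Fraction:
    """Charge of a single residue in the given compartment.

    ``compartment`` is ``"extracellular"`` or ``"intracellular"`` and only
    affects histidine.
    """
    if compartment not in (EXTRACELLULAR, INTRACELLULAR):
        raise ValueError(f"unknown compartment {compartment!r}")
    if residue not in _VALID:
        raise ResidueError(f"invalid residue character {residue!r}")
    if residue in scheme.negative_residues:
        return Fraction(-1)
    if residue in scheme.positive_residues:
        return Fraction(1)
    if residue == "H":
        return (
            scheme.histidine_extracellular
            if compartment == EXTRACELLULAR
            else scheme.histidine_intracellular
        )
    return _ZERO


def segment_charge(
    sequence: str,
    compartment: str,
    scheme: ChargeScheme = DEFAULT_SCHEME,
) -> Fraction:
    """Summed charge of a residue string; gaps contribute zero."""
    total = _ZERO
    for i, residue in enumerate(sequence):
        try:
            total += residue_charge(residue, compartment, scheme)
        except ResidueError:
            raise ResidueError(
                f"invalid residue character {residue!r} at position {i} of "
                f"{sequence!r}"
            ) from None
    return total


def subunit_ring_charges(
    record: SubunitRecord,
    scheme: ChargeScheme = DEFAULT_SCHEME,
) -> RegionChargeVector:
    """Per-subunit charge contribution to each of the six TM2 rings.

    The {-5'-4'} and {-1'} rings lie on the intracellular side of TM2 and the
    19' and higher rings on the extracellular side, which fixes the histidine
    protonation used for each.  Only the residue at -1' of the {-3'..0'}
    segment enters the intermediate ring: the conserved 0' lysine is a
    structural anchor and is excluded from every ring sum.  Domain charges
    are copied from the record when present.
    """
    minus_one = record.seg_m3_0[-2]  # position -1'
    return RegionChargeVector(
        m5m4=segment_charge(record.seg_m5m4, INTRACELLULAR, scheme),
        m1=residue_charge(minus_one, INTRACELLULAR, scheme)
        if minus_one != GAP else _ZERO,
        p19=segment_charge(record.seg_19, EXTRACELLULAR, scheme),
        p20=segment_charge(record.seg_20, EXTRACELLULAR, scheme),
        p2124=segment_charge(record.seg_21_24, EXTRACELLULAR, scheme),
        p2529=segment_charge(record.seg_25_29, EXTRACELLULAR, scheme),
        ext_domain=record.ext_domain_charge,
        int_domain=record.int_domain_charge,
    )


Stoichiometry = tuple[tuple[SubunitRecord, int], ...]


@dataclass(frozen=True)
class PentamerComposition:
    """A subunit multiset with counts summing to five, or several alternative
    stoichiometries to be charge-averaged with equal weight (the convention
    for receptors expressed from two-subunit transfections, where 3:2 and
    2:3 assemblies coexist)."""

    stoichiometries: tuple[Stoichiometry, ...]

    def __post_init__(self) -> None:
        if not self.stoichiometries:
            raise CompositionError("empty composition")
        for stoich in self.stoichiometries:
            if any(count <= 0 for _, count in stoich):
                raise CompositionError("subunit counts must be positive")
            total = sum(count for _, count in stoich)
            if total != 5:
                raise CompositionError(
                    f"subunit counts must sum to 5, got {total}"
                )

    @classmethod
    def single(cls, members: Iterable[tuple[SubunitRecord, int]]) -> "PentamerComposition":
        return cls((tuple(members),))

    @classmethod
    def averaged(cls, alternatives: Iterable[Iterable[tuple[SubunitRecord, int]]]) -> "PentamerComposition":
        return cls(tuple(tuple(alt) for alt in alternatives))

    @property
    def is_averaged(self) -> bool:
        return len(self.stoichiometries) > 1

    def label(self) -> str:
        parts = []
        for stoich in self.stoichiometries:
            parts.append(
                "".join(
                    f"({rec.name})_{count}" if count > 1 else f"({rec.name})"
                    for rec, count in stoich
                )
            )
        return " / ".join(parts)


def _stoichiometry_charges(
    stoich: Stoichiometry, scheme: ChargeScheme
) -> RegionChargeVector:
    fields = {r: _ZERO for r in
              ("m5m4", "m1", "p19", "p20", "p2124", "p2529")}
    ext: Fraction | None = _ZERO
    int_: Fraction | None = _ZERO
    for record, count in stoich:
        sub = subunit_ring_charges(record, scheme)
        for r in fields:
            fields[r] += count * getattr(sub, r)
        ext = ext + count * sub.ext_domain if (
            ext is not None and sub.ext_domain is not None) else None
        int_ = int_ + count * sub.int_domain if (
            int_ is not None and sub.int_domain is not None) else None
    return RegionChargeVector(ext_domain=ext, int_domain=int_, **fields)


def pentamer_charges(
    composition: PentamerComposition,
    scheme: ChargeScheme = DEFAULT_SCHEME,
) -> RegionChargeVector:
    """Regional charge vector of a pentamer.

    For a single stoichiometry each region is the count-weighted sum of the
    member subunits' ring charges; for alternative stoichiometries the
    equal-weight mean of the per-alternative vectors.  Domain charges are
    propagated only when every member carries them.
    """
    species = {rec.species for stoich in composition.stoichiometries
               for rec, _ in stoich}
    if len(species) > 1:
        warnings.warn(
            f"pentamer mixes subunits from species {sorted(species)}",
            stacklevel=2,
        )
    vectors = [_stoichiometry_charges(s, scheme)
               for s in composition.stoichiometries]
    n = Fraction(len(vectors))

    def mean(region: str) -> Fraction | None:
        values = [getattr(v, region) for v in vectors]
        if any(v is None for v in values):
            return None
        return sum(values, _ZERO) / n

    return RegionChargeVector(
        m5m4=mean("m5m4"), m1=mean("m1"), p19=mean("p19"), p20=mean("p20"),
        p2124=mean("p2124"), p2529=mean("p2529"),
        ext_domain=mean("ext_domain"), int_domain=mean("int_domain"),
    )


# ---------------------------------------------------------------------------
# Composition parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"(α|β|γ|δ|ε|alpha|beta|gamma|delta|epsilon|eps|[abgde])"
    r"(\d*)((?:_[A-Za-z0-9]+)?)"
)

_SUBSCRIPTS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def _tokenize(names: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(names):
        m = _TOKEN_RE.match(names, pos)
        if not m:
            raise CompositionError(
                f"cannot parse subunit name at {names[pos:]!r}"
            )
        tokens.append(normalize_label(m.group(0)))
        pos = m.end()
    return tokens


def _merge(pairs: Iterable[tuple[SubunitRecord, int]]) -> Stoichiometry:
    counts: dict[tuple[str, str], list] = {}
    for rec, n in pairs:
        counts.setdefault(rec.key, [rec, 0])[1] += n
    return tuple((rec, n) for rec, n in counts.values())


def parse_composition(
    spec: str,
    registry: SubunitRegistry,
    species: str = "H",
) -> PentamerComposition:
    """Parse a pentamer composition string against a subunit registry.

    Accepted forms (subunit names may be Greek or ASCII aliases):

    * ``"α7β2 4:1"`` — concatenated names plus a ratio whose entries sum to 5;
    * ``"α4β4 1:1"`` (two subunits, ratio 1:1) — the two alternative
      stoichiometries 3:2 and 2:3 are charge-averaged;
    * ``"(β2α4)2α5"`` — a doubled dimer plus remaining subunits, as receptor
      papers write fixed-stoichiometry assemblies: β2×2 + α4×2 + α5;
    * ``"α7:5"`` or ``"α1:3,β2:2"`` — explicit name:count pairs;
    * ``"α7"`` — a bare single name means the homopentamer.
    """
    spec = spec.strip().translate(_SUBSCRIPTS).replace("−", "-")
    if not spec:
        raise CompositionError("empty composition spec")

    def get(name: str) -> SubunitRecord:
        return registry.get(species, name)

    # (group)N trailer form
    m = re.match(r"^\((?P<grp>[^)]+)\)(?P<rep>\d+)(?P<rest>.*)$", spec)
    if m:
        rep = int(m.group("rep"))
        pairs = [(get(t), rep) for t in _tokenize(m.group("grp"))]
        rest = m.group("rest").strip()
        if rest:
            pairs += [(get(t), 1) for t in _tokenize(rest)]
        return PentamerComposition.single(_merge(pairs))

    # explicit name:count pairs
    if re.search(r":\s*\d", spec) and (" " not in spec or "," in spec):
        pairs = []
        for part in spec.replace(" ", "").split(","):
            name, _, count = part.partition(":")
            if not count:
                raise CompositionError(f"missing count in {part!r}")
            pairs.append((get(normalize_label(name)), int(count)))
        return PentamerComposition.single(_merge(pairs))

    # names + ratio
    if " " in spec:
        names_part, ratio_part = spec.rsplit(None, 1)
        tokens = _tokenize(names_part)
        try:
            ratio = [int(x) for x in ratio_part.split(":")]
        except ValueError:
            raise CompositionError(f"cannot parse ratio {ratio_part!r}") from None
        if len(ratio) != len(tokens):
            raise CompositionError(
                f"ratio {ratio_part!r} has {len(ratio)} entries for "
                f"{len(tokens)} subunits"
            )
        if len(tokens) == 2 and ratio == [1, 1]:
            a, b = get(tokens[0]), get(tokens[1])
            return PentamerComposition.averaged(
                [[(a, 3), (b, 2)], [(a, 2), (b, 3)]]
            )
        if sum(ratio) != 5:
            raise CompositionError(
                f"subunit ratio {ratio_part!r} sums to {sum(ratio)}, not 5 "
                f"(only a two-subunit 1:1 ratio is averaged over 3:2/2:3)"
            )
        return PentamerComposition.single(
            _merge((get(t), r) for t, r in zip(tokens, ratio))
        )

    # bare names: single token -> homopentamer
    tokens = _tokenize(spec)
    if len(tokens) == 1:
        return PentamerComposition.single([(get(tokens[0]), 5)])
    raise CompositionError(
        f"composition {spec!r} needs an explicit ratio or counts"
    )
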