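"""Channel regions and per-region charge vectors.

A pentameric nicotinic receptor is partitioned into eight regions: the whole
extracellular domain, the TM3-TM4 intracellular domain, and six narrow rings
flanking or capping the pore-lining TM2 helix, indexed in Miller prime
notation relative to the conserved lysine at 0' (the residue immediately
preceding TM2).  Negative primes sit on the intracellular side, primes >= 19'
on the extracellular side.

Ring charges are held as exact :class:`fractions.Fraction` values so that
half-integers arising from averaging alternative stoichiometries (e.g. -2.5)
are represented without rounding.  Charges are expressed in natural units of
electrical charge (nuec, i.e. elementary charges).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

from .errors import RegionMissingError

#: The six TM2-flanking rings, intracellular to extracellular.
RING_REGIONS: tuple[str, ...] = ("m5m4", "m1", "p19", "p20", "p2124", "p2529")

#: The two large domains whose charges are supplied as data, never computed.
DOMAIN_REGIONS: tuple[str, ...] = ("ext_domain", "int_domain")

ALL_REGIONS: tuple[str, ...] = DOMAIN_REGIONS + RING_REGIONS

#: The five rings used as predictors in the full sigmoidal Pf model
#: ({21'-24'} is excluded as exactly redundant with {-1'}).
DEFAULT_MODEL_REGIONS: tuple[str, ...] = ("m5m4", "m1", "p19", "p20", "p2529")

#: Human-readable prime-notation labels.
REGION_LABELS: Mapping[str, str] = {
    "ext_domain": "extracellular domain",
    "int_domain": "TM3-TM4 intracellular domain",
    "m5m4": "{-5' -4'} cytoplasmic ring",
    "m1": "{-1'} intermediate ring",
    "p19": "{19'}",
    "p20": "{20'} extracellular ring",
    "p2124": "{21'-24'}",
    "p2529": "{25'-29'}",
}

#: Rings on the cytoplasmic side of TM2 (intracellular pH applies to His).
INTRACELLULAR_RINGS: frozenset[str] = frozenset({"m5m4", "m1"})


@dataclass(frozen=True)
class RegionChargeVector:
    """Summed charge (nuec) per channel region for one pentamer.

    Ring fields are always present; the two domain charges are optional
    because they can only be supplied as data (full-length sequences are not
    part of the packaged segment table).
    """

    m5m4: Fraction
    m1: Fraction
    p19: Fraction
    p20: Fraction
    p2124: Fraction
    p2529: Fraction
    ext_domain: Fraction | None = None
    int_domain: Fraction | None = None

    def get(self, region: str) -> Fraction:
        """Return the charge of *region*, raising if absent."""
        if region not in ALL_REGIONS:
            raise RegionMissingError(f"unknown region {region!r}")
        value = getattr(self, region)
        if value is None:
            raise RegionMissingError(f"region {region!r} not populated")
        return value

    def as_floats(self, regions: Iterable[str]) -> list[float]:
        return [float(self.get(r)) for r in regions]

    def to_dict(self) -> dict[str, Fraction | None]:
        return {r: getattr(self, r) for r in ALL_REGIONS}


def format_charge(value: Fraction | None) -> str:
    """Render a charge the way the receptor tables print it (-2.5, -5, 0)."""
    if value is None:
        return ""
    if value.denominator == 1:
        return str(value.numerator)
    return str(float(value))
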