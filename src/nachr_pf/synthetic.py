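"""Synthetic receptor panels for model validation.

Generates panels of hypothetical pentamers with ring-charge vectors drawn
from the integer ranges actually spanned by nicotinic receptors (cytoplasmic
and intermediate rings 0..-5; the {20'} ring from -5 up to +3, since
lysine-bearing non-alpha subunits can make it positive; {25'-29'} from -5 to
+1) and Pf values generated from a known charge-ring model, optionally with
additive Gaussian noise on the percent scale.

These panels exercise the fitting machinery under the model's own
assumptions — independent additive noise, charge vectors exactly of the
model's form.  They say nothing about sequence-level effects (uncharged
residues, pore geometry) that real receptors add on top.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import numpy as np

from .model import PfModel, PUBLISHED_MODEL, predict_pf
from .registry import PfObservation
from .regions import DEFAULT_MODEL_REGIONS, RegionChargeVector

#: Integer charge range per ring, matching the span seen across receptors.
CHARGE_RANGES: dict[str, tuple[int, int]] = {
    "m5m4": (-5, 0),
    "m1": (-5, 0),
    "p19": (-5, 0),
    "p20": (-5, 3),
    "p2529": (-5, 1),
}


def synthetic_panel(
    n_receptors: int,
    model: PfModel = PUBLISHED_MODEL,
    *,
    noise_sd: float = 0.0,
    seed: int = 0,
    regions: Sequence[str] = DEFAULT_MODEL_REGIONS,
) -> list[PfObservation]:
    """Draw ``n_receptors`` distinct charge vectors and model-generated Pf.

    Pf values are clipped to (0.05, 99.95)% so the positivity invariant of
    observations holds even under large noise.  ``noise_sd`` is the standard
    deviation (percent points) of the additive Gaussian measurement error;
    the recorded SEM equals ``noise_sd`` (0 gives SEM 0, a noise-free panel).
    """
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    vectors: list[tuple[int, ...]] = []
    while len(vectors) < n_receptors:
        vec = tuple(
            int(rng.integers(CHARGE_RANGES[r][0], CHARGE_RANGES[r][1] + 1))
            for r in regions
        )
        if vec not in seen:
            seen.add(vec)
            vectors.append(vec)

    observations = []
    for i, vec in enumerate(vectors):
        fields = {r: Fraction(0) for r in
                  ("m5m4", "m1", "p19", "p20", "p2124", "p2529")}
        for r, q in zip(regions, vec):
            fields[r] = Fraction(q)
        charges = RegionChargeVector(**fields)
        pf = predict_pf(model, charges)
        if noise_sd > 0:
            pf += rng.normal(0.0, noise_sd)
        pf = float(np.clip(pf, 0.05, 99.95))
        observations.append(
            PfObservation(
                species="X",
                receptor_label=f"syn-{i:03d}",
                composition="",
                charges=charges,
                pf_percent=pf,
                pf_sem=float(noise_sd),
                source="synthetic",
            )
        )
    return observations
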