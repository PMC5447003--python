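"""Per-region linear screens, redundancy detection and forward selection.

The screens regress measured Pf on each region's summed charge to identify
candidate determinants of Ca2+ permeability; exactly collinear ring pairs
(the {-1'} and {21'-24'} rings differ by a constant across all measured
receptors) are detected and reduced to one representative; the sigmoidal
model is then grown ring-by-ring, each step adding the ring that maximizes
the coefficient of determination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, FitConvergenceError
from .model import FitResult, fit_pf_model
from .registry import PfObservation
from .regions import REGION_LABELS


@dataclass(frozen=True)
class RegionScreenResult:
    """Simple linear regression of Pf (%) on one region's charge."""

    region: str
    slope: float  # nuec^-1 (angular coefficient m)
    intercept: float  # %
    r_squared: float
    p_value: float  # two-sided test of slope = 0
    n: int


def linear_screen(
    observations: Sequence[PfObservation], region: str
) -> RegionScreenResult:
    """Ordinary least-squares regression of pf_percent on a region charge."""
    if len(observations) < 3:
        raise ValueError("need at least 3 observations for a linear screen")
    x = np.array([float(obs.charges.get(region)) for obs in observations])
    y = np.array([obs.pf_percent for obs in observations])
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            f"region {region!r} ({REGION_LABELS.get(region, region)}) has "
            f"zero charge variance across observations"
        )
    fit = stats.linregress(x, y)
    return RegionScreenResult(
        region=region,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(observations),
    )


def detect_redundant_regions(
    observations: Sequence[PfObservation],
    region_a: str,
    region_b: str,
) -> tuple[bool, tuple[Fraction, Fraction] | None]:
    """Test whether ``q_b = alpha * q_a + beta`` holds exactly for all rows.

    Exact Fraction arithmetic: a pair is redundant only if the affine
    relation is satisfied with zero error on every observation.  Returns
    ``(True, (alpha, beta))`` or ``(False, None)``.  A region paired with
    itself yields the identity map.
    """
    qa = [obs.charges.get(region_a) for obs in observations]
    qb = [obs.charges.get(region_b) for obs in observations]
    if region_a == region_b:
        return True, (Fraction(1), Fraction(0))
    # solve alpha, beta from two rows with distinct q_a, then verify all
    anchor = None
    for i in range(len(qa)):
        if qa[i] != qa[0]:
            anchor = i
            break
    if anchor is None:  # q_a constant: affine only if q_b constant too
        if all(b == qb[0] for b in qb):
            return True, (Fraction(0), qb[0])
        return False, None
    alpha = (qb[anchor] - qb[0]) / (qa[anchor] - qa[0])
    beta = qb[0] - alpha * qa[0]
    if all(b == alpha * a + beta for a, b in zip(qa, qb)):
        return True, (alpha, beta)
    return False, None


@dataclass(frozen=True)
class SelectionTrace:
    """Forward-selection path: one (region added, fit) pair per step."""

    steps: tuple[tuple[str, FitResult], ...]

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(region for region, _ in self.steps)

    def final(self) -> FitResult:
        return self.steps[-1][1]


def forward_select(
    observations: Sequence[PfObservation],
    candidate_regions: Sequence[str],
    *,
    seed: int = 0,
    n_starts: int = 16,
) -> SelectionTrace:
    """Grow the sigmoidal model one ring at a time.

    Step 1 fits each candidate alone and keeps the ring with the highest
    R^2; every later step adds the candidate that maximizes R^2 of the
    enlarged fit, warm-starting from the previous optimum (so R^2 is
    non-decreasing along the trace).  Ties are broken by candidate order.
    """
    candidates = list(candidate_regions)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate regions")
    selected: list[str] = []
    steps: list[tuple[str, FitResult]] = []
    prev: FitResult | None = None
    while candidates:
        best: tuple[str, FitResult] | None = None
        for cand in candidates:
            regions = tuple(selected) + (cand,)
            x0 = None
            if prev is not None:
                x0 = [np.log(prev.model.const)] + [
                    prev.model.coefficients[r] for r in selected
                ] + [0.0]
            try:
                fit = fit_pf_model(
                    observations, regions, seed=seed, n_starts=n_starts, x0=x0
                )
            except FitConvergenceError as exc:
                warnings.warn(
                    f"fit with regions {regions} failed to converge: {exc}",
                    stacklevel=2,
                )
                continue
            if best is None or fit.r_squared > best[1].r_squared:
                best = (cand, fit)
        if best is None:
            warnings.warn(
                "no candidate addition converged; stopping selection early",
                stacklevel=2,
            )
            break
        selected.append(best[0])
        candidates.remove(best[0])
        steps.append(best)
        prev = best[1]
    return SelectionTrace(steps=tuple(steps))
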