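"""The sigmoidal fractional-Ca2+-current model.

With a single energy barrier per ion species and fixed concentrations,
potential and temperature, the fraction of current carried by Ca2+ is a
logistic function of the Ca2+/Na+ barrier difference.  Substituting that
difference by a weighted sum of the regional ring charges gives

    Pf = 1 / (1 + const * exp(sum_i k_i * dq_i)),        dq_i = -q_i

where q_i is the signed summed charge (nuec) of ring i and const > 0 absorbs
the concentration prefactors.  ``dq_i = -q_i``: the exponent uses the
negated tabulated charge — this sign convention together with the published
coefficient signs is the one that reproduces every published prediction
(e.g. a homomeric α1 pentamer at 57.4%), and is fixed here once and for all.

Pf is reported on the percent scale throughout (0 < Pf < 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .errors import DegenerateDataError, FitConvergenceError
from .regions import DEFAULT_MODEL_REGIONS, RegionChargeVector
from .registry import PfObservation


@dataclass(frozen=True)
class PfModel:
    """Constants of the charge-ring Pf model.

    ``const`` is the positive dimensionless prefactor; ``coefficients`` maps
    each included region to its weight k_i (nuec^-1).
    """

    const: float
    coefficients: Mapping[str, float]
    regions: tuple[str, ...] = DEFAULT_MODEL_REGIONS

    def __post_init__(self) -> None:
        if not self.const > 0:
            raise ValueError(f"const must be positive, got {self.const}")
        missing = [r for r in self.regions if r not in self.coefficients]
        if missing:
            raise ValueError(f"no coefficient for region(s) {missing}")

    def k(self, region: str) -> float:
        return self.coefficients[region]


#: Constants of the published five-ring fit, used for all predictions.
PUBLISHED_MODEL = PfModel(
    const=41917.0,
    coefficients={
        "m5m4": 0.3521,
        "m1": -1.9747,
        "p19": -0.0798,
        "p20": -0.5654,
        "p2529": 0.4910,
    },
)

#: Published one-ring fit: the {20'} extracellular ring alone.
PUBLISHED_MODEL_P20 = PfModel(
    const=29.5, coefficients={"p20": -0.316}, regions=("p20",)
)

#: Published two-ring fit ({20'} + cytoplasmic ring).
PUBLISHED_MODEL_2RING = PfModel(
    const=10.2, coefficients={"p20": -0.321, "m5m4": 0.266},
    regions=("p20", "m5m4"),
)

#: Published three-ring fit ({20'} + cytoplasmic + {19'}).
PUBLISHED_MODEL_3RING = PfModel(
    const=11.2,
    coefficients={"p20": -0.3806, "m5m4": 0.3197, "p19": -1.260},
    regions=("p20", "m5m4", "p19"),
)


ChargesLike = RegionChargeVector | Mapping[str, float]


def _charge(charges: ChargesLike, region: str) -> float:
    if isinstance(charges, RegionChargeVector):
        return float(charges.get(region))
    from .errors import RegionMissingError

    try:
        return float(charges[region])
    except KeyError:
        raise RegionMissingError(f"region {region!r} not populated") from None


def predict_pf(model: PfModel, charges: ChargesLike) -> float:
    """Predicted fractional Ca2+ current (%) for one charge vector."""
    exponent = sum(
        model.k(r) * -_charge(charges, r) for r in model.regions
    )
    return 100.0 * float(special.expit(-(np.log(model.const) + exponent)))


def predict_pf_many(
    model: PfModel, charge_vectors: Sequence[ChargesLike]
) -> np.ndarray:
    return np.array([predict_pf(model, c) for c in charge_vectors])


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    SS_tot is taken about the observed mean; may be negative for a model
    worse than the mean.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("observed values have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def nonselective_pf(
    ca_conc: float, na_conc: float, z_ca: int = 2, z_na: int = 1
) -> float:
    """Pf (%) of a channel with no selectivity between Ca2+ and Na+.

    Each ion permeates with equal probability, contributing current in
    proportion to valence x concentration (mM); with physiological 2 mM Ca2+
    against 140 mM Na+ this baseline is 2.8%.
    """
    if ca_conc <= 0 or na_conc <= 0:
        raise ValueError("concentrations must be positive")
    ca = z_ca * ca_conc
    return 100.0 * ca / (ca + z_na * na_conc)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a least-squares fit of the sigmoidal model."""

    model: PfModel
    r_squared: float
    residuals: np.ndarray
    standard_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    convergence_info: dict = field(default_factory=dict)


_LOG_CONST_RANGE = (-2.0, 12.0)
_K_RANGE = (-3.0, 3.0)


def fit_pf_model(
    observations: Sequence[PfObservation],
    regions: Sequence[str] = DEFAULT_MODEL_REGIONS,
    *,
    weighted: bool = False,
    n_starts: int = 16,
    seed: int = 0,
    scale: str = "percent",
    x0: Sequence[float] | None = None,
) -> FitResult:
    """Fit ``const`` and the k_i by nonlinear least squares.

    Minimizes the unweighted sum of squared residuals between predicted and
    observed Pf on the percent scale (``weighted=True`` divides residuals by
    each observation's SEM instead).  ``const`` is parameterized on the log
    scale to enforce positivity; the optimizer is run from a deterministic
    grid of starts over log(const) plus ``seed``-controlled random starts
    over both log(const) and the k_i, and the best optimum is kept.

    ``x0`` optionally adds a warm start ``[log(const), k_1..k_p]``.
    ``scale="fraction"`` fits Pf/100 instead; the optimum is identical.
    """
    regions = tuple(regions)
    n, p = len(observations), len(regions)
    if n < p + 2:
        raise ValueError(
            f"need at least {p + 2} observations to fit {p} region(s), "
            f"got {n}"
        )
    if scale not in ("percent", "fraction"):
        raise ValueError(f"unknown scale {scale!r}")
    neg_q = np.array(
        [[-float(obs.charges.get(r)) for r in regions] for obs in observations]
    )
    y = np.array([obs.pf_percent for obs in observations])
    unit = 1.0 if scale == "percent" else 0.01
    wts = 1.0 / np.array([max(obs.pf_sem, 1e-12) for obs in observations]) \
        if weighted else np.ones(n)

    def residuals(theta: np.ndarray) -> np.ndarray:
        s = theta[0] + neg_q @ theta[1:]
        pred = 100.0 * special.expit(-s)
        return (pred - y) * wts * unit

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    for lc in np.linspace(*_LOG_CONST_RANGE, 8):
        starts.append(np.concatenate([[lc], np.zeros(p)]))
    while len(starts) < max(n_starts, 8):
        starts.append(np.concatenate([
            rng.uniform(*_LOG_CONST_RANGE, 1),
            rng.uniform(*_K_RANGE, p),
        ]))

    best = None
    restart_log = []
    for i, start in enumerate(starts):
        try:
            res = optimize.least_squares(
                residuals, start, method="lm", xtol=1e-15, ftol=1e-15,
                gtol=1e-15, max_nfev=20000,
            )
        except Exception as exc:  # singular Jacobian from a wild start
            restart_log.append({"start": i, "cost": None, "error": str(exc)})
            continue
        restart_log.append(
            {"start": i, "cost": float(res.cost), "success": bool(res.success)}
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitConvergenceError(
            f"no optimizer start converged ({len(starts)} tried)"
        )

    theta = best.x
    model = PfModel(
        const=float(np.exp(theta[0])),
        coefficients={r: float(k) for r, k in zip(regions, theta[1:])},
        regions=regions,
    )
    pred = 100.0 * special.expit(-(theta[0] + neg_q @ theta[1:]))
    resid = pred - y

    # Gauss-Newton asymptotic standard errors and t-based p-values
    # (approximate; computed on the unweighted percent-scale problem).
    ses: dict[str, float] = {}
    pvals: dict[str, float] = {}
    dof = n - (p + 1)
    if dof > 0:
        jac = best.jac / (wts * unit)[:, None]
        ss_res = float(np.sum(resid**2))
        try:
            cov = ss_res / dof * np.linalg.inv(jac.T @ jac)
            se_theta = np.sqrt(np.diag(cov))
            names = ["const"] + list(regions)
            # delta method: SE(const) = const * SE(log const)
            se_vals = np.concatenate([[model.const * se_theta[0]], se_theta[1:]])
            with np.errstate(divide="ignore", invalid="ignore"):
                t_stats = np.concatenate([[theta[0] / se_theta[0]],
                                          theta[1:] / se_theta[1:]])
            for name, se, t in zip(names, se_vals, t_stats):
                ses[name] = float(se)
                pvals[name] = float(2 * stats.t.sf(abs(t), dof)) \
                    if np.isfinite(t) else 0.0
        except np.linalg.LinAlgError:
            pass

    n_ok = sum(1 for r in restart_log if r.get("success"))
    return FitResult(
        model=model,
        r_squared=r_squared(y, pred),
        residuals=resid,
        standard_errors=ses,
        p_values=pvals,
        convergence_info={
            "n_starts": len(starts),
            "n_converged": n_ok,
            "best_cost": float(best.cost),
            "final_ss_res": float(np.sum(resid**2)),
            "restart_log": restart_log,
            "seed": seed,
        },
    )
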