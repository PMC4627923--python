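"""Uncertainty propagation through the compositional inversion.

Measurement SEMs on (rho_pre, rho_post, M) are treated as standard
deviations of independent Gaussian errors on the reported means (no
distributional statement accompanies the measurements, and no
covariances are available).  Two propagation routes are provided:

* :func:`propagate` — Monte-Carlo: sample the three measurements, run the
  closed-form inversion per draw, reject draws whose solved sensitive
  fraction leaves [0, 1] (rejection, not clipping, so the propagated mean
  is not biased toward the boundary; the rejected count is reported), and
  summarize each derived quantity by its mean, SD and empirical
  percentile confidence interval.

* :func:`delta_method` — first-order analytic propagation using the exact
  partial derivatives of the closed-form inversion; serves as the
  independent cross-check on the Monte-Carlo SDs in the small-noise
  regime.

The inversion is near-linear at the bench's operating point, so the two
routes agree closely there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TreatmentMeasurements, solve_composition
from .errors import DegenerateSystemError, InfeasibleMeasurementError, InvariantError

__all__ = [
    "UncertainQuantity",
    "PropagationConfig",
    "PropagationResult",
    "propagate",
    "delta_method",
]

#: Quantities summarized by both propagation routes, in report order.
QUANTITY_NAMES = (
    "v_s_pre",
    "v_r_pre",
    "rho_r",
    "v_s_post",
    "v_r_post",
    "relative_volume",
    "diameter_ratio",
    "radius_shrinkage_pct",
)


@dataclass(frozen=True)
class UncertainQuantity:
    """A value with a propagated SD and a confidence interval."""

    value: float
    sd: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.sd >= 0:
            raise InvariantError(f"sd must be >= 0, got {self.sd}")
        if not self.ci_low <= self.value <= self.ci_high:
            raise InvariantError(
                f"value {self.value} must lie inside [{self.ci_low}, {self.ci_high}]"
            )

    def as_dict(self) -> dict[str, float]:
        return {
            "value": self.value,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class PropagationConfig:
    """Monte-Carlo settings: number of draws, RNG seed, CI level."""

    n_draws: int = 100_000
    seed: int = 20151027
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 100:
            raise InvariantError(f"n_draws must be >= 100, got {self.n_draws}")
        if not 0.0 < self.ci_level < 1.0:
            raise InvariantError(f"ci_level must be in (0, 1), got {self.ci_level}")


@dataclass(frozen=True)
class PropagationResult:
    """Mapping of quantity name -> :class:`UncertainQuantity`, plus draw accounting."""

    quantities: dict[str, UncertainQuantity]
    n_draws: int
    n_infeasible: int

    def __getitem__(self, name: str) -> UncertainQuantity:
        return self.quantities[name]

    def __iter__(self):
        return iter(self.quantities)

    @property
    def infeasible_fraction(self) -> float:
        return self.n_infeasible / self.n_draws

    def as_dict(self) -> dict:
        return {
            "quantities": {k: q.as_dict() for k, q in self.quantities.items()},
            "n_draws": self.n_draws,
            "n_infeasible": self.n_infeasible,
        }


def _derived_arrays(rho_pre, rho_post, M, rho_s):
    """Vectorized closed-form inversion and derived quantities.

    Inputs are arrays of feasible draws (callers mask infeasible ones).
    Returns a dict of arrays keyed by QUANTITY_NAMES.
    """
    v_s = (rho_pre - rho_post) / ((1.0 - M) * (rho_s - rho_post))
    v_r = 1.0 - v_s
    rho_r = (rho_pre - v_s * rho_s) / v_r
    rel_vol = v_r + v_s * M
    v_s_post = v_s * M / rel_vol
    d_ratio = np.cbrt(rel_vol)
    return {
        "v_s_pre": v_s,
        "v_r_pre": v_r,
        "rho_r": rho_r,
        "v_s_post": v_s_post,
        "v_r_post": 1.0 - v_s_post,
        "relative_volume": rel_vol,
        "diameter_ratio": d_ratio,
        "radius_shrinkage_pct": (1.0 - d_ratio) * 100.0,
    }


def _feasible_mask(rho_pre, rho_post, M, rho_s):
    """Draws on which the inversion is defined and physical."""
    with np.errstate(divide="ignore", invalid="ignore"):
        v_s = (rho_pre - rho_post) / ((1.0 - M) * (rho_s - rho_post))
    mask = (
        np.isfinite(v_s)
        & (v_s >= 0.0)
        & (v_s < 1.0)  # v_s == 1 leaves rho_r indeterminate
        & (M >= 0.0)
        & (M < 1.0)
        & (rho_post != rho_s)
    )
    # positive post-treatment volume
    mask &= (1.0 - v_s) + v_s * M > 0.0
    return mask


def propagate(
    meas: TreatmentMeasurements, cfg: PropagationConfig = PropagationConfig()
) -> PropagationResult:
    """Monte-Carlo propagation of the measurement SEMs through the inversion.

    Draws ``(rho_pre, rho_post, M)`` independently from Gaussians centred
    on the measured values with the stated SEMs, inverts each feasible
    draw, and summarizes every derived quantity by mean, SD and the
    empirical ``cfg.ci_level`` percentile interval.  A fixed seed makes
    the output bit-reproducible.

    Raises
    ------
    InfeasibleMeasurementError
        If more than half the draws are infeasible — the measurements are
        then incompatible with the two-component model at the stated
        noise level.
    """
    rng = np.random.default_rng(cfg.seed)
    rho_pre = rng.normal(meas.rho_pre, meas.rho_pre_sem, cfg.n_draws)
    rho_post = rng.normal(meas.rho_post, meas.rho_post_sem, cfg.n_draws)
    M = rng.normal(meas.mass_remaining_M, meas.mass_remaining_M_sem, cfg.n_draws)
    rho_s = meas.rho_sensitive

    mask = _feasible_mask(rho_pre, rho_post, M, rho_s)
    n_infeasible = int(cfg.n_draws - mask.sum())
    if n_infeasible > cfg.n_draws / 2:
        raise InfeasibleMeasurementError(
            f"{n_infeasible}/{cfg.n_draws} Monte-Carlo draws were infeasible; "
            "the measurements are incompatible with the two-component model "
            "at the stated uncertainty level"
        )

    arrays = _derived_arrays(rho_pre[mask], rho_post[mask], M[mask], rho_s)
    alpha = (1.0 - cfg.ci_level) / 2.0
    quantities: dict[str, UncertainQuantity] = {}
    for name in QUANTITY_NAMES:
        x = arrays[name]
        if x.size > 1 and np.ptp(x) > 0.0:
            sd = float(np.std(x, ddof=1))
            lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
            mean = float(np.mean(x))
        else:
            # degenerate distribution (all SEMs zero): exactly the
            # deterministic solution, no ulp-level noise from summation
            sd, mean = 0.0, float(x[0])
            lo = hi = mean
        quantities[name] = UncertainQuantity(
            value=mean, sd=sd, ci_low=min(float(lo), mean), ci_high=max(float(hi), mean)
        )
    return PropagationResult(
        quantities=quantities, n_draws=cfg.n_draws, n_infeasible=n_infeasible
    )


def delta_method(meas: TreatmentMeasurements) -> dict[str, float]:
    """First-order analytic SDs of every derived quantity.

    Uses the exact partial derivatives of the closed-form inversion with
    respect to ``(rho_pre, rho_post, M)``, evaluated at the deterministic
    solution; ``rho_sensitive`` is treated as exact.  With
    ``a = rho_pre``, ``b = rho_post``, ``c = rho_sensitive``:

        V_s        = (a - b) / ((1 - M)(c - b))
        dV_s/da    = 1 / ((1 - M)(c - b))
        dV_s/db    = (a - c) / ((1 - M)(c - b)^2)
        dV_s/dM    = V_s / (1 - M)
        rho_r      = (a - V_s c) / (1 - V_s)
        drho_r     = (da + dV_s (rho_r - c)) / (1 - V_s)
        RV         = 1 - V_s (1 - M) = 1 - (a - b)/(c - b)   (M-free)
        v_s_post   = V_s M / RV

    Raises :class:`DegenerateSystemError` at a degenerate evaluation
    point (``M = 1`` or ``rho_sensitive = rho_post``).
    """
    a, b, c = meas.rho_pre, meas.rho_post, meas.rho_sensitive
    M = meas.mass_remaining_M
    if M >= 1.0 or b == c:
        raise DegenerateSystemError(
            "delta method evaluated at a degenerate point (M = 1 or rho_sensitive = rho_post)"
        )
    sol = solve_composition(meas)
    v_s, rho_r, rv = sol.v_s_pre, sol.rho_r, sol.relative_volume
    v_r = 1.0 - v_s

    # gradient vectors w.r.t. (a, b, M)
    g_vs = np.array(
        [
            1.0 / ((1.0 - M) * (c - b)),
            (a - c) / ((1.0 - M) * (c - b) ** 2),
            v_s / (1.0 - M),
        ]
    )
    g_rhor = (np.array([1.0, 0.0, 0.0]) + g_vs * (rho_r - c)) / v_r
    # RV = 1 - (a - b)/(c - b): independent of M
    g_rv = -(1.0 - M) * g_vs + np.array([0.0, 0.0, v_s])
    # v_s_post = V_s M / RV
    g_vspost = (
        M * g_vs + np.array([0.0, 0.0, v_s])
    ) / rv - sol.v_s_post * g_rv / rv
    g_dratio = g_rv / (3.0 * rv ** (2.0 / 3.0))

    sigma = np.array([meas.rho_pre_sem, meas.rho_post_sem, meas.mass_remaining_M_sem])

    def sd(gradient: np.ndarray) -> float:
        return float(np.sqrt(np.sum((gradient * sigma) ** 2)))

    sd_vs = sd(g_vs)
    sd_vspost = sd(g_vspost)
    sd_dratio = sd(g_dratio)
    return {
        "v_s_pre": sd_vs,
        "v_r_pre": sd_vs,
        "rho_r": sd(g_rhor),
        "v_s_post": sd_vspost,
        "v_r_post": sd_vspost,
        "relative_volume": sd(g_rv),
        "diameter_ratio": sd_dratio,
        "radius_shrinkage_pct": 100.0 * sd_dratio,
    }
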