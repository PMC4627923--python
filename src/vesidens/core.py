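"""Two-component compositional density model of membrane vesicles.

A vesicle is modeled as a mixture of a treatment-*sensitive* component
(cholesterol and other cyclodextrin-extractable lipids, intrinsic density
``rho_s``) and a *residual* component (everything the treatment leaves in
place, intrinsic density ``rho_r``).  With volume fractions normalized to
one, the equilibrium buoyant density of the whole vesicle is the
volume-weighted sum of the component densities,

    rho = sum_j rho_j * V_j .

A treatment that leaves a mass fraction ``M`` of the sensitive component
(removing it at its own intrinsic density, so volume is removed in
proportion to mass) changes the vesicle density to

    rho_post = (V_r*rho_r + V_s*rho_s*M) / (V_r + V_s*M) .

Measuring ``rho_pre``, ``rho_post`` and ``M`` therefore determines the
pre-treatment composition ``(V_s, V_r)`` and the residual density
``rho_r`` in closed form, from which the post-treatment composition, the
relative vesicle volume ``V_r + V_s*M`` and — for spherical vesicles —
the diameter ratio ``(V_r + V_s*M)**(1/3)`` follow.

All densities are in g/mL, all volume fractions dimensionless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSystemError, InfeasibleMeasurementError, InvariantError

__all__ = [
    "ComponentMixture",
    "TreatmentMeasurements",
    "CompositionSolution",
    "SizeObservation",
    "forward_density",
    "solve_pre_composition",
    "post_density",
    "solve_post_composition",
    "relative_volume",
    "diameter_ratio",
    "radius_shrinkage_pct",
    "observed_size_change",
    "attribution_fraction",
]

#: Intrinsic density of membrane cholesterol (g/mL), the default
#: treatment-sensitive component density.
CHOLESTEROL_DENSITY = 1.067

_NORMALIZATION_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentMixture:
    """A named mixture of components with intrinsic densities and volume fractions.

    Parameters
    ----------
    components
        Sequence of ``(name, density_g_ml, volume_fraction)`` triples.
        Densities must be positive, volume fractions must lie in [0, 1]
        and sum to one (no silent renormalization is performed).
    """

    components: tuple[tuple[str, float, float], ...]

    def __init__(self, components) -> None:
        object.__setattr__(
            self,
            "components",
            tuple((str(n), float(d), float(v)) for n, d, v in components),
        )
        self._validate()

    def _validate(self) -> None:
        if not self.components:
            raise InvariantError("mixture must contain at least one component")
        for name, density, vfrac in self.components:
            if not density > 0:
                raise InvariantError(f"component {name!r}: density must be > 0, got {density}")
            if not 0.0 <= vfrac <= 1.0:
                raise InvariantError(
                    f"component {name!r}: volume fraction must be in [0, 1], got {vfrac}"
                )
        total = math.fsum(v for _, _, v in self.components)
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            raise InvariantError(
                f"volume fractions must sum to 1 (got {total!r}); "
                "renormalize explicitly before constructing the mixture"
            )

    @property
    def densities(self) -> np.ndarray:
        return np.array([d for _, d, _ in self.components])

    @property
    def volume_fractions(self) -> np.ndarray:
        return np.array([v for _, _, v in self.components])


@dataclass(frozen=True)
class TreatmentMeasurements:
    """The measured scalars the model inverts.

    ``rho_pre`` / ``rho_post`` are equilibrium buoyant densities (g/mL) of
    the vesicle population before and after treatment, each with its SEM.
    ``mass_remaining_M`` is the treated-to-untreated mass ratio of the
    sensitive component (dimensionless, in [0, 1]).  ``rho_sensitive`` is
    the intrinsic density of the sensitive component, by default membrane
    cholesterol at 1.067 g/mL, treated as exact.
    """

    rho_pre: float
    rho_pre_sem: float
    rho_post: float
    rho_post_sem: float
    mass_remaining_M: float
    mass_remaining_M_sem: float
    rho_sensitive: float = CHOLESTEROL_DENSITY

    def __post_init__(self) -> None:
        for name in ("rho_pre", "rho_post", "rho_sensitive"):
            if not getattr(self, name) > 0:
                raise InvariantError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("rho_pre_sem", "rho_post_sem", "mass_remaining_M_sem"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise InvariantError(f"{name} must be a finite value >= 0, got {value}")
        if not 0.0 <= self.mass_remaining_M <= 1.0:
            raise InvariantError(
                f"mass_remaining_M must be in [0, 1], got {self.mass_remaining_M}"
            )


@dataclass(frozen=True)
class CompositionSolution:
    """Solved composition and derived size predictions.

    ``v_s_pre``/``v_r_pre`` and ``v_s_post``/``v_r_post`` are the pre- and
    post-treatment volume fractions of the sensitive and residual
    components (each pair sums to one); ``rho_r`` is the solved intrinsic
    density of the residual component (g/mL); ``relative_volume`` is the
    treated vesicle volume as a fraction of the untreated volume and
    ``diameter_ratio`` its cube root (spherical vesicles).
    """

    v_s_pre: float
    v_r_pre: float
    rho_r: float
    v_s_post: float
    v_r_post: float
    relative_volume: float
    diameter_ratio: float

    def __post_init__(self) -> None:
        if abs(self.v_s_pre + self.v_r_pre - 1.0) > _NORMALIZATION_TOL:
            raise InvariantError("pre-treatment volume fractions must sum to 1")
        if abs(self.v_s_post + self.v_r_post - 1.0) > _NORMALIZATION_TOL:
            raise InvariantError("post-treatment volume fractions must sum to 1")
        if not self.relative_volume > 0:
            raise InvariantError("relative_volume must be > 0")
        if abs(self.diameter_ratio - self.relative_volume ** (1.0 / 3.0)) > 1e-12:
            raise InvariantError("diameter_ratio must equal relative_volume ** (1/3)")

    @property
    def radius_shrinkage_pct(self) -> float:
        """Percent reduction in vesicle radius implied by the volume change."""
        return (1.0 - self.diameter_ratio) * 100.0

    def as_dict(self) -> dict[str, float]:
        return {
            "v_s_pre": self.v_s_pre,
            "v_r_pre": self.v_r_pre,
            "rho_r": self.rho_r,
            "v_s_post": self.v_s_post,
            "v_r_post": self.v_r_post,
            "relative_volume": self.relative_volume,
            "diameter_ratio": self.diameter_ratio,
            "radius_shrinkage_pct": self.radius_shrinkage_pct,
        }


@dataclass(frozen=True)
class SizeObservation:
    """A DLS hydrodynamic-diameter summary for one condition and gradient band.

    ``condition`` is typically ``"control"`` or ``"treated"``;
    ``fraction_class`` is ``"buoyant"`` or ``"dense"``; diameters in nm.
    """

    condition: str
    fraction_class: str
    diameter_mean: float
    diameter_sd: float

    def __post_init__(self) -> None:
        if not self.diameter_mean > 0:
            raise InvariantError(f"diameter_mean must be > 0, got {self.diameter_mean}")
        if not self.diameter_sd >= 0:
            raise InvariantError(f"diameter_sd must be >= 0, got {self.diameter_sd}")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def forward_density(mixture: ComponentMixture) -> float:
    """Equilibrium density of a mixture: the volume-weighted component sum.

    The result always lies between the smallest and largest component
    density (it is a convex combination).
    """
    return float(mixture.densities @ mixture.volume_fractions)


def post_density(
    v_s_pre: float,
    v_r_pre: float,
    rho_r: float,
    rho_s: float,
    M: float,
) -> float:
    """Vesicle density after the sensitive component is reduced to mass fraction ``M``.

    Mass and volume of the sensitive component scale together by ``M``
    (its intrinsic density is unchanged by extraction), so both the mass
    numerator and the volume denominator are renormalized:

        rho_post = (V_r*rho_r + V_s*rho_s*M) / (V_r + V_s*M)

    ``M`` may exceed 1, which re-inflates the vesicle (the consistency
    check that recovers ``rho_pre`` from the post-treatment composition
    with ``1/M``).
    """
    if abs(v_s_pre + v_r_pre - 1.0) > _NORMALIZATION_TOL:
        raise InvariantError("volume fractions must be normalized (sum to 1)")
    if M < 0:
        raise InvariantError(f"M must be >= 0, got {M}")
    denom = v_r_pre + v_s_pre * M
    if denom <= 0:
        raise DegenerateSystemError(
            "post-treatment volume is non-positive (vesicle fully removed)"
        )
    return (v_r_pre * rho_r + v_s_pre * rho_s * M) / denom


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------


def _solve_v_s(rho_pre, rho_post, rho_s, M):
    """Closed-form sensitive volume fraction; array-friendly, no feasibility checks.

    Derived by eliminating ``V_r*rho_r`` between the pre- and
    post-treatment density equations:

        V_s = (rho_pre - rho_post) / ((1 - M) * (rho_s - rho_post))
    """
    return (rho_pre - rho_post) / ((1.0 - M) * (rho_s - rho_post))


def solve_pre_composition(meas: TreatmentMeasurements) -> tuple[float, float, float]:
    """Invert the measured densities to the pre-treatment composition.

    Solves the three simultaneous equations

        V_r*rho_r + V_s*rho_s = rho_pre
        V_r + V_s             = 1
        (V_r*rho_r + V_s*rho_s*M) / (V_r + V_s*M) = rho_post

    in closed form, returning ``(v_s_pre, v_r_pre, rho_r)``.

    Raises
    ------
    DegenerateSystemError
        If ``M = 1`` (the treatment removes nothing, so the two density
        equations coincide and composition is unidentifiable), if
        ``rho_sensitive == rho_post`` (division by zero), or if the
        solution has no residual component (``V_s = 1``) so ``rho_r`` is
        indeterminate.
    InfeasibleMeasurementError
        If the solved ``V_s`` falls outside [0, 1]; the message states the
        ``rho_pre`` range compatible with the other measurements.
    """
    a, b, c, M = meas.rho_pre, meas.rho_post, meas.rho_sensitive, meas.mass_remaining_M
    if M >= 1.0:
        raise DegenerateSystemError(
            "M = 1: the treatment removes no mass, so pre- and post-treatment "
            "densities coincide and the composition is unidentifiable"
        )
    if b == c:
        raise DegenerateSystemError(
            "rho_sensitive equals rho_post: the closed-form inversion divides "
            "by (rho_sensitive - rho_post)"
        )
    v_s = float(_solve_v_s(a, b, c, M))
    if not 0.0 <= v_s <= 1.0:
        lo, hi = sorted((b, b + (1.0 - M) * (c - b)))
        raise InfeasibleMeasurementError(
            f"solved sensitive volume fraction {v_s:.4f} is outside [0, 1]; "
            f"with rho_post={b} g/mL, rho_sensitive={c} g/mL and M={M}, "
            f"rho_pre would need to lie in [{lo:.4f}, {hi:.4f}] g/mL "
            f"(measured {a} g/mL)"
        )
    v_r = 1.0 - v_s
    if v_r == 0.0:
        raise DegenerateSystemError(
            "solution has no residual component (V_s = 1); rho_r is indeterminate"
        )
    rho_r = (a - v_s * c) / v_r
    return v_s, v_r, rho_r


def solve_post_composition(v_s_pre: float, v_r_pre: float, M: float) -> tuple[float, float]:
    """Post-treatment volume fractions after renormalizing the shrunken vesicle.

    The residual volume is unchanged while the sensitive volume scales by
    ``M``, so

        v_s_post = v_s_pre*M / (v_r_pre + v_s_pre*M),  v_r_post = 1 - v_s_post.
    """
    if abs(v_s_pre + v_r_pre - 1.0) > _NORMALIZATION_TOL:
        raise InvariantError("volume fractions must be normalized (sum to 1)")
    if not 0.0 <= M <= 1.0:
        raise InvariantError(f"M must be in [0, 1], got {M}")
    denom = v_r_pre + v_s_pre * M
    if denom <= 0:
        raise DegenerateSystemError("vesicle fully removed (post-treatment volume is zero)")
    v_s_post = v_s_pre * M / denom
    return v_s_post, 1.0 - v_s_post


def relative_volume(v_s_pre: float, v_r_pre: float, M: float) -> float:
    """Treated vesicle volume as a fraction of the untreated volume: ``V_r + V_s*M``."""
    if abs(v_s_pre + v_r_pre - 1.0) > _NORMALIZATION_TOL:
        raise InvariantError("volume fractions must be normalized (sum to 1)")
    if M < 0:
        raise InvariantError(f"M must be >= 0, got {M}")
    return v_r_pre + v_s_pre * M


def diameter_ratio(rel_volume: float) -> float:
    """Treated/untreated diameter ratio for spherical vesicles: cube root of the volume ratio."""
    if not rel_volume > 0:
        raise InvariantError(f"relative volume must be > 0, got {rel_volume}")
    return rel_volume ** (1.0 / 3.0)


def radius_shrinkage_pct(rel_volume: float) -> float:
    """Percent reduction in radius implied by a relative volume."""
    return (1.0 - diameter_ratio(rel_volume)) * 100.0


def solve_composition(meas: TreatmentMeasurements) -> CompositionSolution:
    """Full deterministic solution: inversion plus all derived size quantities."""
    v_s, v_r, rho_r = solve_pre_composition(meas)
    v_s_post, v_r_post = solve_post_composition(v_s, v_r, meas.mass_remaining_M)
    rel_vol = relative_volume(v_s, v_r, meas.mass_remaining_M)
    return CompositionSolution(
        v_s_pre=v_s,
        v_r_pre=v_r,
        rho_r=rho_r,
        v_s_post=v_s_post,
        v_r_post=v_r_post,
        relative_volume=rel_vol,
        diameter_ratio=diameter_ratio(rel_vol),
    )


# ---------------------------------------------------------------------------
# Observed (DLS) size change and attribution
# ---------------------------------------------------------------------------


def observed_size_change(
    control: SizeObservation, treated: SizeObservation
) -> tuple[float, float]:
    """Percent decline in diameter and in volume between two DLS observations.

    Returns ``(diameter_decline_pct, volume_decline_pct)`` where the
    volume decline assumes spherical vesicles,
    ``1 - (d_treated/d_control)**3``.  Mismatched gradient-band labels
    trigger a warning but the computation proceeds.
    """
    if control.fraction_class != treated.fraction_class:
        warnings.warn(
            f"comparing observations from different gradient bands: "
            f"{control.fraction_class!r} vs {treated.fraction_class!r}",
            stacklevel=2,
        )
    ratio = treated.diameter_mean / control.diameter_mean
    return (1.0 - ratio) * 100.0, (1.0 - ratio**3) * 100.0


def attribution_fraction(
    predicted_volume_loss_pct: float, observed_volume_loss_pct: float
) -> float:
    """Share of the observed volume shrinkage explained by the modeled component.

    Both arguments are percent volume losses in (0, 100].
    """
    if observed_volume_loss_pct == 0:
        raise InvariantError("observed volume loss is zero; attribution undefined")
    for name, value in (
        ("predicted", predicted_volume_loss_pct),
        ("observed", observed_volume_loss_pct),
    ):
        if not 0.0 < value <= 100.0:
            raise InvariantError(f"{name} volume loss must be in (0, 100], got {value}")
    return predicted_volume_loss_pct / observed_volume_loss_pct
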