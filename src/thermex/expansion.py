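"""Thermal expansion coefficients for one structure family.

The volumetric coefficient alpha_V is the fractional volume change per
kelvin from an unweighted linear least-squares fit of V against T, with a
heteroscedasticity-consistent (sandwich) standard error on the slope.  The
principal coefficients alpha_L are the eigenvalues of the temperature
derivative of the linear Lagrangian strain tensor e = (F + F.T)/2 - I built
between the lowest-temperature cell of the family and each other member
(the Schlenker construction from unit-cell parameters).  Both kinds of
coefficient are referenced to 298 K: under the linear approximation the
coefficient varies inversely with the reference length/volume, so all
values are quoted against the cell extrapolated to 298 K and expressed in
p.p.m. per kelvin.

For families with only two temperature points the line is exact, no
standard uncertainties exist, and results carry a ``two_point`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .cells import (
    OrthoConvention,
    UnitCell,
    cell_volume,
    orthogonalization_matrix,
)

__all__ = [
    "VolumeFit",
    "StrainSeries",
    "ExpansionResult",
    "DuplicateTemperatureError",
    "InconsistentSettingError",
    "UndefinedAnisotropyError",
    "volumetric_fit",
    "strain_tensor_pair",
    "principal_fit",
    "anisotropy",
    "classify_nte",
    "expansion_for_family_cells",
]

PPM = 1.0e6
REFERENCE_T = 298.0
#: an axis counts as substantially negative below this value (p.p.m./K)
NTE_SUBSTANTIAL = -10.0


class DuplicateTemperatureError(ValueError):
    """Two points at the same temperature reached a fit (dedup should prevent this)."""


class InconsistentSettingError(ValueError):
    """Cells compared for strain are too dissimilar to be the same phase."""


class UndefinedAnisotropyError(ZeroDivisionError):
    """Anisotropy is undefined when the principal coefficients sum to zero."""


@dataclass(frozen=True)
class VolumeFit:
    """Linear V-vs-T fit and the derived volumetric coefficient at 298 K."""

    slope: float  # A^3 / K
    intercept: float  # A^3
    r_squared: Optional[float]  # None for 2-point families
    alpha_v_298: float  # p.p.m. / K
    su_alpha_v: Optional[float]  # p.p.m. / K, None for 2-point families
    n_points: int
    t_min: float
    t_max: float
    residuals: Optional[np.ndarray] = None  # per-point V residuals, fit order

    @property
    def v_298(self) -> float:
        return self.intercept + REFERENCE_T * self.slope

    @property
    def two_point(self) -> bool:
        return self.n_points == 2


@dataclass(frozen=True)
class StrainSeries:
    """Linear Lagrangian strain tensors vs temperature, zero at the reference."""

    reference_temperature: float
    temperatures: np.ndarray  # (n,) including the reference
    strains: np.ndarray  # (n, 3, 3) symmetric; strains[i] at temperatures[i]

    def __post_init__(self) -> None:
        if not np.allclose(self.strains, np.swapaxes(self.strains, 1, 2), atol=1e-12):
            raise ValueError("strain tensors must be symmetric")
        i_ref = int(np.argmin(np.abs(self.temperatures - self.reference_temperature)))
        if not np.all(self.strains[i_ref] == 0.0):
            raise ValueError("strain at the reference temperature must be zero")


@dataclass(frozen=True)
class ExpansionResult:
    """Full per-family expansion record."""

    alpha_v: VolumeFit
    alpha_l: tuple[float, float, float]  # p.p.m./K, ascending
    su_l: tuple[Optional[float], Optional[float], Optional[float]]
    principal_axes: np.ndarray  # (3, 3); row i is the unit axis for alpha_l[i]
    anisotropy: Optional[float]
    nte_class: str  # none / uniaxial / biaxial / triaxial
    conclusive_nte: tuple[bool, ...]  # per negative axis, ascending order
    ref_correction: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))
    #: 1 + k (298 - T_ref) per axis: the extrapolation factor applied to each
    #: raw eigenvalue to reference it to 298 K.

    @property
    def two_point(self) -> bool:
        return self.alpha_v.two_point

    @property
    def sum_alpha_l(self) -> float:
        return float(sum(self.alpha_l))


# ---------------------------------------------------------------------------
# volumetric route
# ---------------------------------------------------------------------------

def _check_distinct(temps: np.ndarray) -> None:
    if len(np.unique(temps)) != len(temps):
        raise DuplicateTemperatureError("duplicate temperatures in fit input")


def volumetric_fit(series: Sequence[tuple[float, float]], hc_variant: str = "HC1") -> VolumeFit:
    """Fit V against T and convert the slope to alpha_V at 298 K.

    ``series`` is a sequence of (temperature/K, volume/A^3) pairs, at least
    two, with distinct temperatures.  For n >= 3 the slope standard error is
    the heteroscedasticity-consistent sandwich estimator (variant selected
    by ``hc_variant``, default HC1), propagated to alpha_V(298) through the
    first-order derivative of alpha = 1e6 * slope / V(298) with respect to
    the slope.  For n = 2 the line is exact and uncertainties are absent.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (T, V) points")
    t, v = arr[:, 0], arr[:, 1]
    _check_distinct(t)
    if len(t) == 2:
        slope = (v[1] - v[0]) / (t[1] - t[0])
        intercept = v[0] - slope * t[0]
        v298 = intercept + REFERENCE_T * slope
        return VolumeFit(
            slope=slope,
            intercept=intercept,
            r_squared=None,
            alpha_v_298=PPM * slope / v298,
            su_alpha_v=None,
            n_points=2,
            t_min=float(t.min()),
            t_max=float(t.max()),
            residuals=np.zeros(2),
        )
    model = sm.OLS(v, sm.add_constant(t)).fit(cov_type=hc_variant)
    intercept, slope = model.params
    se_slope = model.bse[1]
    v298 = intercept + REFERENCE_T * slope
    # d(alpha)/d(slope) at fixed intercept: 1e6 * intercept / V298^2
    su = PPM * se_slope * abs(intercept) / (v298 * v298)
    return VolumeFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(model.rsquared),
        alpha_v_298=float(PPM * slope / v298),
        su_alpha_v=float(su),
        n_points=len(t),
        t_min=float(t.min()),
        t_max=float(t.max()),
        residuals=np.asarray(model.resid),
    )


# ---------------------------------------------------------------------------
# tensor route
# ---------------------------------------------------------------------------

def strain_tensor_pair(
    cell_ref: UnitCell,
    cell_t: UnitCell,
    conv: OrthoConvention = OrthoConvention.X_A_Y_AB,
    *,
    setting_guard: Optional[float] = 0.12,
) -> np.ndarray:
    """Linear Lagrangian strain of ``cell_t`` relative to ``cell_ref``.

    Both cells must be in consistent (reduced, consistently oriented)
    settings; with F = A(cell_t) @ inv(A(cell_ref)) the returned tensor is
    e = (F + F.T)/2 - I.  ``setting_guard`` rejects pairs whose metric
    deformation exceeds the family tolerance, which would indicate the cells
    belong to different polymorphs; pass None to disable.
    """
    a_ref = orthogonalization_matrix(cell_ref, conv)
    a_t = orthogonalization_matrix(cell_t, conv)
    f = a_t @ np.linalg.inv(a_ref)
    e = 0.5 * (f + f.T) - np.eye(3)
    if setting_guard is not None:
        eta = 0.5 * (f.T @ f - np.eye(3))
        if float(np.sqrt(np.sum(eta * eta))) > setting_guard:
            raise InconsistentSettingError(
                "deformation between cells exceeds the setting guard; "
                "are these the same phase?"
            )
    return e


def build_strain_series(
    cells: Sequence[UnitCell],
    temperatures: Sequence[float],
    conv: OrthoConvention = OrthoConvention.X_A_Y_AB,
    setting_guard: Optional[float] = 0.12,
) -> StrainSeries:
    """Strain tensors of every family member relative to the lowest-T cell."""
    temps = np.asarray(temperatures, dtype=float)
    _check_distinct(temps)
    order = np.argsort(temps)
    temps = temps[order]
    cells = [cells[i] for i in order]
    ref = cells[0]
    strains = np.zeros((len(cells), 3, 3))
    for i, cell in enumerate(cells[1:], start=1):
        strains[i] = strain_tensor_pair(ref, cell, conv, setting_guard=setting_guard)
    return StrainSeries(reference_temperature=float(temps[0]), temperatures=temps, strains=strains)


def _alpha_298(k: float, t_ref: float) -> tuple[float, float]:
    """Convert a raw eigen-rate k (per K, referenced at t_ref) to 298 K p.p.m."""
    corr = 1.0 + k * (REFERENCE_T - t_ref)
    return PPM * k / corr, corr


def principal_fit(
    strains: StrainSeries, hc_variant: str = "HC1"
) -> tuple[
    tuple[float, float, float],
    tuple[Optional[float], Optional[float], Optional[float]],
    np.ndarray,
    tuple[float, float, float],
]:
    """Principal expansion coefficients at 298 K from a strain series.

    For n >= 3 points each of the six independent strain components is fitted
    linearly against T (free intercept, reference point included); the slope
    tensor de/dT is diagonalised, its ascending eigenvalues converted to
    298 K.  Per-axis standard uncertainties come from an HC fit of the strain
    projected onto the (fixed) eigenvector against T.  For 2-point families
    the single available strain tensor divided by the temperature step plays
    the role of the slope tensor and uncertainties are absent.

    Returns (alpha_l ascending, su_l, axes (rows), ref_corrections).
    """
    temps = strains.temperatures
    n = len(temps)
    if n < 2:
        raise ValueError("need at least two points including the reference")
    if n == 2:
        dt = temps[1] - temps[0]
        slope_tensor = strains.strains[1] / dt
        have_su = False
    else:
        design = np.column_stack([np.ones(n), temps])
        flat = strains.strains.reshape(n, 9)
        coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
        slope_tensor = coef[1].reshape(3, 3)
        slope_tensor = 0.5 * (slope_tensor + slope_tensor.T)
        have_su = True

    evals, evecs = np.linalg.eigh(slope_tensor)  # ascending
    axes = np.zeros((3, 3))
    alphas: list[float] = []
    sus: list[Optional[float]] = []
    corrs: list[float] = []
    for i in range(3):
        vec = evecs[:, i]
        if vec[np.argmax(np.abs(vec))] < 0:  # sign convention for reporting
            vec = -vec
        axes[i] = vec
        alpha, corr = _alpha_298(float(evals[i]), strains.reference_temperature)
        alphas.append(alpha)
        corrs.append(corr)
        if have_su:
            proj = np.einsum("i,nij,j->n", vec, strains.strains, vec)
            model = sm.OLS(proj, sm.add_constant(temps)).fit(cov_type=hc_variant)
            # first-order propagation through k -> 1e6 k / (1 + k (298 - T_ref))
            sus.append(float(PPM * model.bse[1] / corr**2))
        else:
            sus.append(None)
    return tuple(alphas), tuple(sus), axes, tuple(corrs)


def anisotropy(alpha_l: Sequence[float], denominator: float | None = None) -> float:
    """Anisotropy of the expansion: (max - min) / sum of the principal values.

    ``denominator`` overrides the default sum(alpha_l); passing the
    volumetric coefficient reproduces the alternative normalisation.  A
    negative result can only arise from a negative denominator and is
    treated as invalid downstream.
    """
    vals = [float(x) for x in alpha_l]
    denom = float(denominator) if denominator is not None else sum(vals)
    if denom == 0.0:
        raise UndefinedAnisotropyError("principal coefficients sum to zero")
    return (max(vals) - min(vals)) / denom


def classify_nte(
    alpha_l: Sequence[float],
    su_l: Sequence[Optional[float]] | None = None,
    substantial: float = NTE_SUBSTANTIAL,
) -> tuple[str, tuple[bool, ...]]:
    """Classify negative thermal expansion by count of negative axes.

    Returns the class (none/uniaxial/biaxial/triaxial) and a per-negative-axis
    "conclusive" flag: the coefficient is below ``substantial`` (default
    -10 p.p.m./K) and remains negative within one standard uncertainty.
    Without an s.u. (two-point families) an axis is never conclusive.
    """
    if su_l is None:
        su_l = [None] * len(alpha_l)
    classes = {0: "none", 1: "uniaxial", 2: "biaxial", 3: "triaxial"}
    negatives = [(a, s) for a, s in zip(alpha_l, su_l) if a < 0]
    conclusive = tuple(
        a < substantial and s is not None and a + s < 0 for a, s in negatives
    )
    return classes[len(negatives)], conclusive


def expansion_for_family_cells(
    cells: Sequence[UnitCell],
    temperatures: Sequence[float],
    hc_variant: str = "HC1",
    setting_guard: Optional[float] = 0.12,
    anisotropy_denominator: str = "sum",
) -> ExpansionResult:
    """Full expansion analysis for one family's (cell, temperature) series."""
    temps = np.asarray(temperatures, dtype=float)
    volumes = [cell_volume(c) for c in cells]
    vfit = volumetric_fit(list(zip(temps, volumes)), hc_variant=hc_variant)
    series = build_strain_series(cells, temps, setting_guard=setting_guard)
    alpha_l, su_l, axes, corrs = principal_fit(series, hc_variant=hc_variant)
    try:
        denom = vfit.alpha_v_298 if anisotropy_denominator == "volumetric" else None
        aniso = anisotropy(alpha_l, denominator=denom)
    except UndefinedAnisotropyError:
        aniso = None
    nte_class, conclusive = classify_nte(alpha_l, su_l)
    return ExpansionResult(
        alpha_v=vfit,
        alpha_l=alpha_l,
        su_l=su_l,
        principal_axes=axes,
        anisotropy=aniso,
        nte_class=nte_class,
        conclusive_nte=conclusive,
        ref_correction=corrs,
    )
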