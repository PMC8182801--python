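"""Population statistics for a survey of expansion coefficients.

Coefficient histograms use 25 p.p.m./K bins anchored at zero.  A normal
density (with free amplitude) is fitted to the alpha_V histogram by least
squares at bin midpoints; the pooled principal-coefficient histogram is
fitted by a skew-normal density, which is then approximated by two
half-normal curves sharing the mode and peak height but with different
widths on each side.  k-sigma thresholds from these fits define when an
expansion coefficient counts as exceptional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm, skewnorm

from .expansion import ExpansionResult

__all__ = [
    "Histogram",
    "DistributionFit",
    "FitFailure",
    "LinearityDiagnostics",
    "OutlierReport",
    "linearity_screen",
    "build_histogram",
    "fit_normal_to_histogram",
    "fit_skew_normal_to_histogram",
    "half_normal_approx",
    "sigma_thresholds",
    "tabulate_outliers",
]


class FitFailure(RuntimeError):
    """Histogram fit failed to converge or the input is degenerate."""


@dataclass(frozen=True)
class Histogram:
    bin_edges: np.ndarray  # (nbins+1,), uniform width, anchored at 0
    counts: np.ndarray  # (nbins,)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0]) if len(self.bin_edges) > 1 else 0.0

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class DistributionFit:
    """Parameters of a density fitted to histogram counts.

    family 'normal': params (mean, sd, amplitude);
    family 'skew_normal': params (location xi, scale omega, shape alpha, amplitude);
    family 'two_half_normal': params (centre, sd_lower, sd_upper, peak).
    ``goodness`` is the residual sum of squares against the fitted counts.
    """

    family: str
    params: tuple[float, ...]
    goodness: float = float("nan")

    def density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "normal":
            mean, sd, amp = self.params
            return amp * norm.pdf(x, mean, sd)
        if self.family == "skew_normal":
            xi, omega, shape, amp = self.params
            return amp * skewnorm.pdf(x, shape, loc=xi, scale=omega)
        if self.family == "two_half_normal":
            centre, sd_lo, sd_hi, peak = self.params
            out = np.where(
                x < centre,
                peak * np.exp(-0.5 * ((x - centre) / sd_lo) ** 2),
                peak * np.exp(-0.5 * ((x - centre) / sd_hi) ** 2),
            )
            return out
        raise ValueError(f"unknown family {self.family}")


# ---------------------------------------------------------------------------
# linearity screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearityDiagnostics:
    """Why a family failed the R^2 screen, with per-point residuals."""

    family_id: str
    r_squared: float
    residuals: np.ndarray  # volume residuals in fit order (ascending T)
    worst_point: int  # index of the largest |residual|


def linearity_screen(
    results: Sequence[tuple[str, ExpansionResult]], r2_min: float = 0.96
) -> tuple[list[str], list[LinearityDiagnostics]]:
    """Partition families by the R^2 of their V-vs-T fit.

    Only families with >= 3 points participate (R^2 is meaningless for an
    exact two-point line).  Failures carry residual diagnostics so the worst
    point can be inspected, mirroring the diagnosis of mislabelled
    temperatures and phase transitions.
    """
    passed: list[str] = []
    failed: list[LinearityDiagnostics] = []
    for family_id, res in results:
        vfit = res.alpha_v
        if vfit.n_points < 3:
            raise ValueError(f"{family_id}: R^2 screen needs >=3 points")
        if vfit.r_squared > r2_min:
            passed.append(family_id)
        else:
            resid = vfit.residuals if vfit.residuals is not None else np.zeros(vfit.n_points)
            failed.append(
                LinearityDiagnostics(
                    family_id=family_id,
                    r_squared=vfit.r_squared,
                    residuals=np.asarray(resid),
                    worst_point=int(np.argmax(np.abs(resid))),
                )
            )
    return passed, failed


# ---------------------------------------------------------------------------
# histograms and fits
# ---------------------------------------------------------------------------

def build_histogram(values: Sequence[float], bin_width: float = 25.0) -> Histogram:
    """Histogram with half-open bins [k*w, (k+1)*w) anchored at zero."""
    vals = np.asarray(values, dtype=float)
    if vals.size and not np.all(np.isfinite(vals)):
        raise ValueError("histogram input must be finite")
    if vals.size == 0:
        return Histogram(bin_edges=np.array([]), counts=np.array([], dtype=int))
    lo = math.floor(vals.min() / bin_width)
    hi = math.floor(vals.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    return Histogram(bin_edges=edges, counts=counts.astype(int))


def _prepare_fit(hist: Histogram, min_bins: int) -> tuple[np.ndarray, np.ndarray]:
    if int(np.count_nonzero(hist.counts)) < min_bins:
        raise FitFailure(f"need at least {min_bins} non-empty bins")
    return hist.midpoints, hist.counts.astype(float)


def fit_normal_to_histogram(hist: Histogram) -> DistributionFit:
    """Least-squares fit of amplitude * N(mean, sd) to counts at bin midpoints."""
    x, y = _prepare_fit(hist, min_bins=4)
    mean0 = float(np.average(x, weights=np.maximum(y, 1e-12)))
    sd0 = float(np.sqrt(np.average((x - mean0) ** 2, weights=np.maximum(y, 1e-12))))
    sd0 = max(sd0, hist.bin_width / 2)
    amp0 = float(y.sum() * hist.bin_width)

    def model(x, mean, sd, amp):
        return amp * norm.pdf(x, mean, abs(sd))

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=[mean0, sd0, amp0], maxfev=20000)
    except RuntimeError as exc:
        raise FitFailure(f"normal histogram fit did not converge: {exc}") from exc
    mean, sd, amp = float(popt[0]), abs(float(popt[1])), float(popt[2])
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    if sd < hist.bin_width / 10:
        raise FitFailure("fitted sd collapsed below a tenth of the bin width")
    return DistributionFit(family="normal", params=(mean, sd, amp), goodness=rss)


def fit_skew_normal_to_histogram(hist: Histogram) -> DistributionFit:
    """Least-squares fit of an amplitude-scaled skew-normal density to counts."""
    x, y = _prepare_fit(hist, min_bins=4)
    mean0 = float(np.average(x, weights=np.maximum(y, 1e-12)))
    sd0 = max(
        float(np.sqrt(np.average((x - mean0) ** 2, weights=np.maximum(y, 1e-12)))),
        hist.bin_width / 2,
    )
    amp0 = float(y.sum() * hist.bin_width)

    def model(x, xi, omega, shape, amp):
        return amp * skewnorm.pdf(x, shape, loc=xi, scale=abs(omega))

    best = None
    for shape0 in (0.0, 2.0, -2.0, 5.0):
        try:
            popt, _ = optimize.curve_fit(
                model, x, y, p0=[mean0, sd0, shape0, amp0], maxfev=20000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailure("skew-normal histogram fit did not converge")
    popt, rss = best
    xi, omega, shape, amp = float(popt[0]), abs(float(popt[1])), float(popt[2]), float(popt[3])
    return DistributionFit(family="skew_normal", params=(xi, omega, shape, amp), goodness=rss)


def _skew_normal_mode(xi: float, omega: float, shape: float) -> float:
    res = optimize.minimize_scalar(
        lambda x: -skewnorm.pdf(x, shape, loc=xi, scale=omega),
        bounds=(xi - 3 * omega, xi + 3 * omega),
        method="bounded",
        options={"xatol": 1e-10 * max(omega, 1.0)},
    )
    return float(res.x)


def half_normal_approx(skew_fit: DistributionFit, n_grid: int = 400) -> DistributionFit:
    """Approximate a fitted skew-normal by two half-normal curves.

    The composite is centred on the mode of the skew-normal, shares its peak
    height (hence is continuous at the centre), and the width on each side
    is obtained by a least-squares fit of a half-normal to the skew-normal
    curve over [mode - 6 omega, mode] and [mode, mode + 6 omega].
    """
    if skew_fit.family != "skew_normal":
        raise ValueError("half_normal_approx expects a skew_normal fit")
    xi, omega, shape, amp = skew_fit.params
    centre = _skew_normal_mode(xi, omega, shape)
    peak = float(amp * skewnorm.pdf(centre, shape, loc=xi, scale=omega))

    def side_sd(sign: int) -> float:
        xs = centre + sign * np.linspace(0.0, 6.0 * omega, n_grid)
        target = amp * skewnorm.pdf(xs, shape, loc=xi, scale=omega)

        def cost(sd: float) -> float:
            model = peak * np.exp(-0.5 * ((xs - centre) / sd) ** 2)
            return float(np.sum((model - target) ** 2))

        res = optimize.minimize_scalar(
            cost, bounds=(1e-6 * omega, 10.0 * omega), method="bounded",
            options={"xatol": 1e-12 * omega},
        )
        return float(res.x)

    sd_lower, sd_upper = side_sd(-1), side_sd(+1)
    return DistributionFit(
        family="two_half_normal",
        params=(centre, sd_lower, sd_upper, peak),
        goodness=float("nan"),
    )


def sigma_thresholds(fit: DistributionFit, k: float = 3.0) -> tuple[float, float]:
    """(lower, upper) exceptionality thresholds at k standard deviations."""
    if fit.family == "normal":
        mean, sd, _ = fit.params
        return (mean - k * sd, mean + k * sd)
    if fit.family == "two_half_normal":
        centre, sd_lo, sd_hi, _ = fit.params
        return (centre - k * sd_lo, centre + k * sd_hi)
    raise ValueError(f"no threshold rule for family {fit.family}")


# ---------------------------------------------------------------------------
# outlier tabulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierReport:
    """Families at the extremes of the survey distributions.

    ``extreme_positive``: families above the upper alpha_V threshold backed
    by at least ``min_points`` temperature points.  ``suspect_negative``:
    two-point families at or below the lower threshold (apparent zero or
    negative expansion on two points is characteristically a data error,
    e.g. an unflagged high-pressure determination).  ``extreme_anisotropy``:
    families whose anisotropy exceeds the reference value on a good linear
    fit with several points.
    """

    extreme_positive: list[str] = field(default_factory=list)
    suspect_negative: list[str] = field(default_factory=list)
    extreme_anisotropy: list[str] = field(default_factory=list)


def tabulate_outliers(
    results: Sequence[tuple[str, ExpansionResult]],
    thresholds: tuple[float, float],
    min_points: int = 4,
    anisotropy_reference: float = 3.16,
    r2_min: float = 0.96,
) -> OutlierReport:
    lower, upper = thresholds
    report = OutlierReport()
    for family_id, res in results:
        av = res.alpha_v.alpha_v_298
        if av > upper and res.alpha_v.n_points >= min_points:
            report.extreme_positive.append(family_id)
        if av <= lower and res.alpha_v.n_points == 2:
            report.suspect_negative.append(family_id)
        if (
            res.anisotropy is not None
            and res.anisotropy > anisotropy_reference
            and res.alpha_v.n_points >= min_points
            and res.alpha_v.r_squared is not None
            and res.alpha_v.r_squared > r2_min
        ):
            report.extreme_anisotropy.append(family_id)
    return report
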