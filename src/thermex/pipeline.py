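"""End-to-end survey: entry table in, coefficient distributions out.

The stages run in the order screen -> partition -> deduplicate -> filter ->
fit -> population statistics, with every discarded entry or family recorded
with a machine-readable reason.  The survey itself is deterministic: all
randomness lives in the synthetic generator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import SurveyConfig
from .expansion import (
    ExpansionResult,
    InconsistentSettingError,
    expansion_for_family_cells,
)
from .families import (
    RejectionRecord,
    StructureFamily,
    assign_temperature,
    build_families,
    entries_from_dataframe,
)
from .stats import (
    DistributionFit,
    FitFailure,
    Histogram,
    LinearityDiagnostics,
    OutlierReport,
    build_histogram,
    fit_normal_to_histogram,
    fit_skew_normal_to_histogram,
    half_normal_approx,
    linearity_screen,
    sigma_thresholds,
    tabulate_outliers,
)

__all__ = ["SurveyResult", "run_survey", "fit_single_family", "results_dataframe"]

log = logging.getLogger(__name__)


@dataclass
class SurveyResult:
    """Everything the survey computes, ready for tabulation or serialisation."""

    config: SurveyConfig
    families: list[StructureFamily]
    results: list[tuple[str, ExpansionResult]]  # (family_id, result), accepted only
    rejections: list[RejectionRecord]
    n_input_entries: int
    screen_passed: list[str] = field(default_factory=list)
    screen_failed: list[LinearityDiagnostics] = field(default_factory=list)
    alpha_v_hist: Optional[Histogram] = None
    alpha_v_fit: Optional[DistributionFit] = None
    alpha_v_thresholds: Optional[tuple[float, float]] = None
    alpha_l_hist: Optional[Histogram] = None
    alpha_l_skew_fit: Optional[DistributionFit] = None
    alpha_l_half_normal: Optional[DistributionFit] = None
    alpha_l_thresholds: Optional[tuple[float, float]] = None
    anisotropy_hist: Optional[Histogram] = None
    outliers: Optional[OutlierReport] = None

    @property
    def family_size_spectrum(self) -> dict[int, int]:
        spectrum: dict[int, int] = {}
        for fam in self.families:
            spectrum[fam.n_entries] = spectrum.get(fam.n_entries, 0) + 1
        return dict(sorted(spectrum.items()))

    @property
    def nte_counts(self) -> dict[str, int]:
        counts = {"none": 0, "uniaxial": 0, "biaxial": 0, "triaxial": 0}
        for _, res in self.results:
            counts[res.nte_class] += 1
        return counts

    @property
    def two_point_fraction(self) -> float:
        if not self.results:
            return float("nan")
        return sum(res.two_point for _, res in self.results) / len(self.results)

    def summary(self) -> dict:
        """JSON-ready summary of fitted parameters, thresholds and counts."""
        out: dict = {
            "n_input_entries": self.n_input_entries,
            "n_families": len(self.families),
            "family_size_spectrum": {str(k): v for k, v in self.family_size_spectrum.items()},
            "nte_counts": self.nte_counts,
            "two_point_fraction": self.two_point_fraction,
            "n_rejections": len(self.rejections),
        }
        if self.alpha_v_fit is not None:
            mean, sd, amp = self.alpha_v_fit.params
            out["alpha_v_fit"] = {"mean": mean, "sd": sd, "amplitude": amp}
        if self.alpha_v_thresholds is not None:
            out["alpha_v_thresholds"] = list(self.alpha_v_thresholds)
        if self.alpha_l_half_normal is not None:
            centre, sd_lo, sd_hi, peak = self.alpha_l_half_normal.params
            out["alpha_l_half_normal"] = {
                "centre": centre, "sd_lower": sd_lo, "sd_upper": sd_hi,
            }
        if self.alpha_l_thresholds is not None:
            out["alpha_l_thresholds"] = list(self.alpha_l_thresholds)
        if self.outliers is not None:
            out["outliers"] = {
                "extreme_positive": self.outliers.extreme_positive,
                "suspect_negative": self.outliers.suspect_negative,
                "extreme_anisotropy": self.outliers.extreme_anisotropy,
            }
        return out


def _analyse_family(
    fam: StructureFamily, config: SurveyConfig
) -> Optional[ExpansionResult]:
    temps = [assign_temperature(e) for e in fam.entries]
    try:
        return expansion_for_family_cells(
            list(fam.reduced_cells),
            temps,
            hc_variant=config.hc_variant,
            setting_guard=config.strain_guard,
            anisotropy_denominator=config.anisotropy_denominator,
        )
    except InconsistentSettingError:
        log.warning("family %s: member cells inconsistent beyond the strain guard", fam.family_id)
        return None


def run_survey(entries: pd.DataFrame, config: SurveyConfig | None = None) -> SurveyResult:
    """Run the full survey on a schema-conforming entry table."""
    config = config or SurveyConfig()
    entry_objs = entries_from_dataframe(entries)
    families, rejections = build_families(
        entry_objs,
        tol=config.deformation_tol,
        dedup_tol=config.dedup_tol,
        t_window=config.t_window,
        min_top_t=config.min_top_t,
        min_range=config.min_range,
        niggli_eps=config.niggli_eps,
    )
    out = SurveyResult(
        config=config,
        families=families,
        results=[],
        rejections=rejections,
        n_input_entries=len(entry_objs),
    )
    if not families:
        log.warning("survey produced no accepted families")
        return out

    for fam in families:
        res = _analyse_family(fam, config)
        if res is None:
            rejections.append(RejectionRecord(fam.family_id, None, "inconsistent_setting"))
        else:
            out.results.append((fam.family_id, res))
    out.families = [f for f in families if f.family_id in {fid for fid, _ in out.results}]

    multi = [(fid, res) for fid, res in out.results if res.alpha_v.n_points >= 3]
    if multi:
        out.screen_passed, out.screen_failed = linearity_screen(multi, r2_min=config.r2_min)

    alpha_v_values = [res.alpha_v.alpha_v_298 for _, res in out.results]
    out.alpha_v_hist = build_histogram(alpha_v_values, bin_width=config.bin_width)
    try:
        out.alpha_v_fit = fit_normal_to_histogram(out.alpha_v_hist)
        out.alpha_v_thresholds = sigma_thresholds(out.alpha_v_fit, k=config.sigma_k)
    except FitFailure as exc:
        log.warning("alpha_V histogram fit failed: %s", exc)

    alpha_l_values = [a for _, res in out.results for a in res.alpha_l]
    out.alpha_l_hist = build_histogram(alpha_l_values, bin_width=config.bin_width)
    try:
        out.alpha_l_skew_fit = fit_skew_normal_to_histogram(out.alpha_l_hist)
        out.alpha_l_half_normal = half_normal_approx(out.alpha_l_skew_fit)
        out.alpha_l_thresholds = sigma_thresholds(out.alpha_l_half_normal, k=config.sigma_k)
    except FitFailure as exc:
        log.warning("alpha_L histogram fit failed: %s", exc)

    aniso_values = [res.anisotropy for _, res in out.results if res.anisotropy is not None]
    if aniso_values:
        out.anisotropy_hist = build_histogram(aniso_values, bin_width=config.anisotropy_bin_width)

    if out.alpha_v_thresholds is not None:
        out.outliers = tabulate_outliers(
            out.results,
            out.alpha_v_thresholds,
            min_points=config.min_points_outlier,
            anisotropy_reference=config.anisotropy_reference,
            r2_min=config.r2_min,
        )
    return out


def fit_single_family(
    table: pd.DataFrame, config: SurveyConfig | None = None
) -> ExpansionResult:
    """Expansion analysis for one cell-vs-temperature table.

    ``table`` needs columns a, b, c, alpha, beta, gamma, temperature_K; rows
    are determinations of the same phase.  This is the standalone
    principal-axis calculation, bypassing family curation.
    """
    config = config or SurveyConfig()
    if len(table) < 2:
        raise ValueError("need at least two rows to fit expansion")
    from .cells import UnitCell  # local import avoids a cycle in docs builds

    cells = [
        UnitCell(r.a, r.b, r.c, r.alpha, r.beta, r.gamma)
        for r in table.itertuples(index=False)
    ]
    temps = table["temperature_K"].astype(float).tolist()
    return expansion_for_family_cells(
        cells,
        temps,
        hc_variant=config.hc_variant,
        setting_guard=config.strain_guard,
        anisotropy_denominator=config.anisotropy_denominator,
    )


def results_dataframe(survey: SurveyResult) -> pd.DataFrame:
    """Per-family results as a flat table (one row per accepted family)."""
    screen_failed = {d.family_id for d in survey.screen_failed}
    suspect = set(survey.outliers.suspect_negative) if survey.outliers else set()
    rows = []
    for fid, res in survey.results:
        vf = res.alpha_v
        row = {
            "family_id": fid,
            "n_points": vf.n_points,
            "t_min": vf.t_min,
            "t_max": vf.t_max,
            "alpha_v": vf.alpha_v_298,
            "su_alpha_v": vf.su_alpha_v,
            "r2_v": vf.r_squared,
            "anisotropy": res.anisotropy,
            "nte_class": res.nte_class,
            "two_point": res.two_point,
            "passed_screen": (None if vf.n_points < 3 else fid not in screen_failed),
            "suspect": fid in suspect,
        }
        for i in range(3):
            row[f"alpha_l{i + 1}"] = res.alpha_l[i]
            row[f"su_l{i + 1}"] = res.su_l[i]
            row[f"axis{i + 1}"] = " ".join(f"{x:.6f}" for x in res.principal_axes[i])
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(survey: SurveyResult, out_dir: str | Path) -> None:
    """Write per-family CSV, JSON summary and the rejection log."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_dataframe(survey).to_csv(out / "families.csv", index=False)
    (out / "summary.json").write_text(json.dumps(survey.summary(), indent=2))
    pd.DataFrame(
        [
            {"family_id": r.family_id, "refcode": r.refcode, "reason": r.reason}
            for r in survey.rejections
        ]
    ).to_csv(out / "rejections.csv", index=False)
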