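"""Synthetic CSD-like entry tables with planted expansion ground truth.

The real input to a database-wide expansion survey is proprietary, so this
module emulates its statistical shape: refcode families redetermined at
several temperatures in 90-300 K (~85% with just two entries, a decreasing
tail up to 14), a crystal-system mix dominated by monoclinic and triclinic
lattices, a volumetric-coefficient population Normal(161, 51) p.p.m./K
split across axes with a skewed spread (which makes uniaxial NTE common and
biaxial NTE rare), polymorphs with distinct reduced cells, alternative
space-group settings of one lattice, and the documented error modes of the
archive: wrong reported temperatures, unflagged high-pressure
determinations, phase-transition anomalies and duplicate publications.

Every emitted entry is covered exactly once by a parallel truth table, so
family recovery, coefficient recovery and error-catch rates can all be
measured against the planted values.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import skewnorm

from .cells import UnitCell, cell_from_metric, metric_tensor, niggli_reduce, orthogonalization_matrix
from .expansion import PPM, REFERENCE_T

__all__ = ["GeneratorConfig", "FamilyTruth", "generate_family", "generate_survey", "write_survey"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic survey; defaults emulate the archive statistics."""

    n_families: int = 100
    #: P(family size); ~85% two-entry with a decreasing tail to 14
    family_size_probs: tuple[tuple[int, float], ...] = (
        (2, 0.845), (3, 0.093), (4, 0.025),
        (5, 0.0148), (6, 0.0089), (7, 0.0053), (8, 0.0032),
        (9, 0.0019), (10, 0.0012), (11, 0.0007), (12, 0.0004),
        (13, 0.0003), (14, 0.0003),
    )
    t_top: float = 293.0  # K, room-temperature determination
    t_min_range: tuple[float, float] = (90.0, 210.0)  # K, lowest point drawn here
    min_spacing: float = 12.0  # K, keeps legitimate points outside the dedup tolerance
    #: fractions of (triclinic, monoclinic, orthorhombic)
    crystal_system_mix: tuple[float, float, float] = (0.3, 0.5, 0.2)
    alpha_v_mean: float = 161.0  # p.p.m./K at 298 K
    alpha_v_sd: float = 51.0
    #: scale/skew of the split of alpha_V across the three axes; at the
    #: defaults about a third of families show uniaxial NTE and a few
    #: percent biaxial, echoing the surveyed rates
    axis_split_sd: float = 95.0
    axis_split_shape: float = 4.0
    cell_noise_rel: float = 2.0e-4  # relative sigma on lengths (0.02%)
    angle_noise_deg: float = 0.02  # sigma on symmetry-free angles
    # error-injection rates (per family, mutually exclusive)
    wrong_temperature_rate: float = 0.02
    high_pressure_unflagged_rate: float = 0.02
    phase_transition_rate: float = 0.02
    duplicate_publication_rate: float = 0.02
    alternative_setting_rate: float = 0.02
    screened_entry_rate: float = 0.02  # extra entry carrying a disqualifying flag
    polymorph_rate: float = 0.0  # sibling structure family under the same refcode root
    p_missing_room_t: float = 0.5  # room-T entry archived without a temperature
    p_single_publication: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        probs = [p for _, p in self.family_size_probs]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError("family_size_probs must be a probability distribution")
        for name in (
            "wrong_temperature_rate", "high_pressure_unflagged_rate",
            "phase_transition_rate", "duplicate_publication_rate",
            "alternative_setting_rate", "screened_entry_rate", "polymorph_rate",
            "p_missing_room_t", "p_single_publication",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class FamilyTruth:
    """Planted ground truth for one structure family."""

    family_id: str
    refcodes: tuple[str, ...]
    slope_tensor: np.ndarray  # de/dT in the Cartesian frame of the reference
    alpha_l_298: tuple[float, float, float]  # ascending, p.p.m./K
    alpha_v_298: float  # the drawn population value, p.p.m./K
    error_mode: str  # '' or one of the injection labels
    error_refcode: str  # refcode carrying the injection ('' if none)
    crystal_system: str
    n_points: int


_ERROR_MODES = (
    "wrong_temperature",
    "high_pressure_unflagged",
    "phase_transition",
    "duplicate_publication",
    "alternative_setting",
    "screened_entry",
)

# P2_1/c <-> P2_1/n style re-setting: c' = c - a
_MONOCLINIC_RESET = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 1]])


def _draw_refcode_root(rng: np.random.Generator, used: set[str]) -> str:
    letters = string.ascii_uppercase
    while True:
        root = "".join(rng.choice(list(letters), size=6))
        if root not in used:
            used.add(root)
            return root


def _has_niggli_margin(cell: UnitCell, margin: float = 0.75) -> bool:
    """True when the cell sits comfortably inside the Niggli conditions.

    Reduced cells near a condition boundary can flip to a different reduced
    setting under the small strains and noise applied across a family,
    which would spuriously split it (the known discontinuity of the reduced
    cell).  Requiring |2 b.c| < margin * a^2 etc. keeps the whole family on
    one side of every boundary.
    """
    g = metric_tensor(cell)
    a2, b2 = g[0, 0], g[1, 1]
    xi, eta, zeta = 2.0 * g[1, 2], 2.0 * g[0, 2], 2.0 * g[0, 1]
    if abs(xi) > margin * b2 or abs(eta) > margin * a2 or abs(zeta) > margin * a2:
        return False
    # stay clear of the body-diagonal condition as well
    return a2 + b2 + xi + eta + zeta > (1.0 - margin) * (a2 + b2)


def _draw_reference_cell(rng: np.random.Generator, system: str) -> UnitCell:
    """A comfortably Niggli-reduced reference cell of the requested system."""
    for _ in range(1000):
        lengths = np.sort(rng.uniform(5.0, 14.0, size=3))
        if lengths[1] - lengths[0] < 1.2 or lengths[2] - lengths[1] < 1.2:
            continue
        a, b, c = lengths
        if system == "orthorhombic":
            cell = UnitCell(a, b, c, 90.0, 90.0, 90.0)
        elif system == "monoclinic":
            cell = UnitCell(a, b, c, 90.0, float(rng.uniform(95.0, 112.0)), 90.0)
        else:
            ang = rng.uniform(93.0, 108.0, size=3)
            try:
                cell = UnitCell(a, b, c, *ang)
            except ValueError:
                continue
        if not _has_niggli_margin(cell):
            continue
        reduced, _ = niggli_reduce(cell)
        if cell.approx_equal(reduced, rel=1e-6):
            return cell
    raise RuntimeError("failed to draw a reduced reference cell")


def _rotation_xz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def _planted_rates(
    rng: np.random.Generator, cfg: GeneratorConfig, t_ref: float
) -> tuple[np.ndarray, float, np.ndarray]:
    """Draw alpha_V, split it across axes, convert to eigen-rates (per K)."""
    alpha_v = rng.normal(cfg.alpha_v_mean, cfg.alpha_v_sd)
    z = skewnorm.rvs(cfg.axis_split_shape, size=3, random_state=rng)
    delta = cfg.axis_split_sd * (z - z.mean())
    alpha_axes = alpha_v / 3.0 + delta  # p.p.m./K at 298 K, sum == alpha_v
    frac = alpha_axes / PPM
    rates = frac / (1.0 - frac * (REFERENCE_T - t_ref))  # invert the 298 K reference
    return np.sort(alpha_axes), float(alpha_v), rates[np.argsort(alpha_axes)]


def _slope_tensor(
    rng: np.random.Generator, system: str, rates: np.ndarray
) -> np.ndarray:
    """Symmetric de/dT respecting the crystal system's constraints."""
    if system == "orthorhombic":
        return np.diag(rng.permutation(rates))
    if system == "monoclinic":
        # rotation about y keeps the b axis as an eigenvector
        perm = rng.permutation(rates)
        rot = _rotation_xz(float(rng.uniform(0.0, np.pi)))
        return rot @ np.diag(perm) @ rot.T
    rot = _random_rotation(rng)
    return rot @ np.diag(rates) @ rot.T


def _temperature_grid(rng: np.random.Generator, cfg: GeneratorConfig, n: int) -> np.ndarray:
    t_min = float(rng.uniform(*cfg.t_min_range))
    if n == 2:
        return np.array([t_min, cfg.t_top])
    for _ in range(200):
        inner = np.sort(rng.uniform(t_min, cfg.t_top, size=n - 2))
        temps = np.concatenate([[t_min], inner, [cfg.t_top]])
        if np.all(np.diff(temps) >= cfg.min_spacing):
            return temps
    # fall back to an even grid (guaranteed spacing for n <= 14 over >= 83 K)
    return np.linspace(t_min, cfg.t_top, n)


def _evolve_cell(ref: UnitCell, slope: np.ndarray, dt: float) -> UnitCell:
    """Exact finite deformation (I + dT * de/dT) applied to the reference basis."""
    a_ref = orthogonalization_matrix(ref)
    a_t = (np.eye(3) + dt * slope) @ a_ref
    return cell_from_metric(a_t.T @ a_t)


def _add_noise(
    rng: np.random.Generator, cell: UnitCell, system: str, cfg: GeneratorConfig
) -> UnitCell:
    a, b, c = (
        x * (1.0 + rng.normal(0.0, cfg.cell_noise_rel)) for x in cell.lengths
    )
    al, be, ga = cell.angles
    # only symmetry-free angles carry experimental scatter
    if system == "monoclinic":
        be += rng.normal(0.0, cfg.angle_noise_deg)
    elif system == "triclinic":
        al += rng.normal(0.0, cfg.angle_noise_deg)
        be += rng.normal(0.0, cfg.angle_noise_deg)
        ga += rng.normal(0.0, cfg.angle_noise_deg)
    return UnitCell(a, b, c, al, be, ga)


def _scale_volume(cell: UnitCell, factor: float) -> UnitCell:
    s = factor ** (1.0 / 3.0)
    return UnitCell(cell.a * s, cell.b * s, cell.c * s, *cell.angles)


def _shifted_temperature(
    rng: np.random.Generator, true_t: float, others: np.ndarray, spacing: float
) -> Optional[float]:
    """A wrong recorded temperature: ~100 K off, inside 90-300 K, clear of others."""
    for off in rng.permutation([100.0, -100.0, 80.0, -80.0, 120.0, -120.0, 60.0, -60.0]):
        cand = true_t + off
        if 90.0 <= cand <= 300.0 and np.all(np.abs(others - cand) >= spacing):
            return float(cand)
    return None


def _reset_cell(rng: np.random.Generator, cell: UnitCell, system: str) -> UnitCell:
    """Report the same lattice in an alternative (unimodular) setting."""
    if system == "monoclinic":
        t = _MONOCLINIC_RESET
    else:
        while True:
            t = rng.integers(-1, 2, size=(3, 3))
            if round(abs(float(np.linalg.det(t)))) == 1:
                break
    g = metric_tensor(cell)
    return cell_from_metric(t.T @ g @ t)


def _draw_size(rng: np.random.Generator, cfg: GeneratorConfig, min_n: int = 2) -> int:
    sizes = np.array([s for s, _ in cfg.family_size_probs])
    probs = np.array([p for _, p in cfg.family_size_probs])
    mask = sizes >= min_n
    probs = probs[mask] / probs[mask].sum()
    return int(rng.choice(sizes[mask], p=probs))


def generate_family(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    root: str,
    family_index: int,
    suffix_start: int = 0,
) -> tuple[list[dict], FamilyTruth, int]:
    """One structure family as raw entry rows plus its truth record.

    Returns (entry rows, truth, next free suffix index) so sibling polymorph
    families can continue the refcode suffix sequence of the same root.
    """
    mode = ""
    u = rng.random()
    acc = 0.0
    for name, rate in (
        ("wrong_temperature", cfg.wrong_temperature_rate),
        ("high_pressure_unflagged", cfg.high_pressure_unflagged_rate),
        ("phase_transition", cfg.phase_transition_rate),
        ("duplicate_publication", cfg.duplicate_publication_rate),
        ("alternative_setting", cfg.alternative_setting_rate),
        ("screened_entry", cfg.screened_entry_rate),
    ):
        acc += rate
        if u < acc:
            mode = name
            break

    # temperature mislabels and transition anomalies are only diagnosable by
    # the linearity screen, which needs several points
    min_n = 4 if mode in ("wrong_temperature", "phase_transition") else 2
    n = _draw_size(rng, cfg, min_n=min_n)
    temps = _temperature_grid(rng, cfg, n)
    t_ref = float(temps[0])

    system = str(
        rng.choice(["triclinic", "monoclinic", "orthorhombic"], p=cfg.crystal_system_mix)
    )
    ref_cell = _draw_reference_cell(rng, system)
    alpha_axes, alpha_v, rates = _planted_rates(rng, cfg, t_ref)
    slope = _slope_tensor(rng, system, rates)

    cells = [
        _add_noise(rng, _evolve_cell(ref_cell, slope, t - t_ref), system, cfg)
        for t in temps
    ]

    if cfg.p_single_publication >= 1.0 or rng.random() < cfg.p_single_publication:
        pubs = [f"PUB_{root}_{family_index}"] * n
    else:
        pubs = [f"PUB_{root}_{family_index}{chr(97 + i)}" for i in range(n)]
    r_factors = rng.uniform(0.02, 0.08, size=n)

    recorded = temps.astype(float).tolist()
    missing = [False] * n
    if abs(temps[-1] - cfg.t_top) < 1e-9 and rng.random() < cfg.p_missing_room_t:
        missing[-1] = True

    suffix_order = rng.permutation(n)
    suffixes = []
    for rank in suffix_order:
        idx = suffix_start + int(rank)
        suffixes.append("" if idx == 0 else f"{idx:02d}")
    next_suffix = suffix_start + n

    rows: list[dict] = []
    error_refcode = ""
    extra_rows: list[dict] = []

    # apply the injection
    if mode == "wrong_temperature":
        i = n // 2
        cand = _shifted_temperature(rng, temps[i], np.delete(temps, i), cfg.min_spacing)
        if cand is None:
            mode = ""
        else:
            recorded[i] = cand
            missing[i] = False
            error_refcode = root + suffixes[i]
    elif mode == "high_pressure_unflagged":
        i = n - 1
        cells[i] = _scale_volume(cells[i], 1.0 - float(rng.uniform(0.05, 0.10)))
        error_refcode = root + suffixes[i]
    elif mode == "phase_transition":
        i = n // 2
        cells[i] = _scale_volume(cells[i], 1.0 + float(rng.uniform(0.03, 0.06)))
        error_refcode = root + suffixes[i]
    elif mode == "alternative_setting":
        i = int(rng.integers(0, n))
        cells[i] = _reset_cell(rng, cells[i], system)
        error_refcode = root + suffixes[i]

    for i in range(n):
        rows.append(
            dict(
                refcode=root + suffixes[i],
                a=cells[i].a, b=cells[i].b, c=cells[i].c,
                alpha=cells[i].alpha, beta=cells[i].beta, gamma=cells[i].gamma,
                temperature_K=(np.nan if missing[i] else recorded[i]),
                r_factor=float(r_factors[i]),
                pressure_flag=False, has_coords=True, organic=True, polymeric=False,
                publication_id=pubs[i],
                _family_id=f"{root}-{family_index}",
                _error_mode=(mode if root + suffixes[i] == error_refcode else ""),
            )
        )

    if mode == "duplicate_publication":
        i = int(rng.integers(0, n))
        dup = dict(rows[i])
        dup["refcode"] = root + ("" if next_suffix == 0 else f"{next_suffix:02d}")
        next_suffix += 1
        dup["r_factor"] = float(rows[i]["r_factor"]) + float(rng.uniform(0.005, 0.03))
        dup["publication_id"] = dup["publication_id"] + "_dup"
        if not np.isnan(dup["temperature_K"]):
            dup["temperature_K"] = float(dup["temperature_K"]) + float(rng.uniform(-3, 3))
        dup["_error_mode"] = "duplicate_publication"
        error_refcode = dup["refcode"]
        extra_rows.append(dup)
    elif mode == "screened_entry":
        i = int(rng.integers(0, n))
        bad = dict(rows[i])
        bad["refcode"] = root + ("" if next_suffix == 0 else f"{next_suffix:02d}")
        next_suffix += 1
        flag = rng.choice(["pressure_flag", "polymeric", "organic", "has_coords"])
        bad[flag] = flag in ("pressure_flag", "polymeric")
        bad["_error_mode"] = "screened_entry"
        error_refcode = bad["refcode"]
        extra_rows.append(bad)

    rows.extend(extra_rows)
    truth = FamilyTruth(
        family_id=f"{root}-{family_index}",
        refcodes=tuple(r["refcode"] for r in rows),
        slope_tensor=slope,
        alpha_l_298=tuple(float(x) for x in alpha_axes),
        alpha_v_298=alpha_v,
        error_mode=mode,
        error_refcode=error_refcode,
        crystal_system=system,
        n_points=n,
    )
    return rows, truth, next_suffix


def generate_survey(cfg: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[FamilyTruth]]:
    """A full synthetic survey: entry table, per-entry truth table, truth records.

    Deterministic for a fixed ``cfg.seed``: the same configuration always
    yields byte-identical CSV output.
    """
    rng = np.random.default_rng(cfg.seed)
    used_roots: set[str] = set()
    all_rows: list[dict] = []
    truths: list[FamilyTruth] = []
    for i in range(cfg.n_families):
        root = _draw_refcode_root(rng, used_roots)
        rows, truth, nxt = generate_family(cfg, rng, root, family_index=1)
        all_rows.extend(rows)
        truths.append(truth)
        if cfg.polymorph_rate > 0 and rng.random() < cfg.polymorph_rate:
            rows2, truth2, _ = generate_family(cfg, rng, root, family_index=2, suffix_start=nxt)
            all_rows.extend(rows2)
            truths.append(truth2)

    entries = pd.DataFrame(all_rows)
    truth_df = entries[["refcode", "_family_id", "_error_mode"]].rename(
        columns={"_family_id": "family_id", "_error_mode": "error_mode"}
    )
    fam_info = pd.DataFrame(
        [
            dict(
                family_id=t.family_id,
                alpha_l1=t.alpha_l_298[0], alpha_l2=t.alpha_l_298[1], alpha_l3=t.alpha_l_298[2],
                alpha_v=t.alpha_v_298, crystal_system=t.crystal_system,
                error_mode=t.error_mode, error_refcode=t.error_refcode,
                n_points=t.n_points,
            )
            for t in truths
        ]
    )
    truth_df = truth_df.merge(fam_info.drop(columns=["error_mode"]), on="family_id", how="left")
    entries = entries.drop(columns=["_family_id", "_error_mode"])
    return entries, truth_df, truths


def write_survey(cfg: GeneratorConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``entries.csv`` and ``truth.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries, truth_df, _ = generate_survey(cfg)
    entries_path = out / "entries.csv"
    truth_path = out / "truth.csv"
    entries.to_csv(entries_path, index=False)
    truth_df.to_csv(truth_path, index=False)
    return entries_path, truth_path
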