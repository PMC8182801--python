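"""Unit-cell mathematics for metric-only crystallography.

Everything downstream of this module works from the six lattice parameters
alone: no atomic coordinates, no symmetry operators.  The module provides the
cell volume, the metric tensor G, an orthogonalization matrix A (a fixed
Cartesian frame with x parallel to a, y in the a-b plane and z along c*,
satisfying ``A.T @ A == G``), Niggli reduction to the canonical primitive
cell via the Krivy-Gruber iteration, and the scalar metric deformation
measure used to decide whether two reduced cells describe the same crystal
phase.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnitCell",
    "OrthoConvention",
    "InvalidCellError",
    "ReductionError",
    "cell_volume",
    "metric_tensor",
    "cell_from_metric",
    "orthogonalization_matrix",
    "niggli_reduce",
    "is_niggli_reduced",
    "deformation_measure",
]


class InvalidCellError(ValueError):
    """Raised when lattice parameters do not define a positive-definite metric."""


class ReductionError(RuntimeError):
    """Raised when the Niggli iteration fails to converge within the step cap."""


class OrthoConvention(enum.Enum):
    """Cartesian frame used to embed the lattice basis.

    Only one convention is provided: x parallel to a, y in the a-b plane,
    z along c* (the common crystallographic choice).  Principal-axis
    eigenvalues are invariant to this choice; the enum exists so the
    convention is explicit at call sites.
    """

    X_A_Y_AB = "x//a, y in a-b plane, z//c*"


@dataclass(frozen=True)
class UnitCell:
    """Six lattice parameters: lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise InvalidCellError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {name} must lie in (0, 180)")
        # positive discriminant <=> positive-definite metric
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise InvalidCellError("angles do not define a positive-definite metric")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def approx_equal(self, other: "UnitCell", rel: float = 1e-8) -> bool:
        """Parameter-wise comparison; lengths relative, angles in degrees."""
        scale = max(self.a, self.b, self.c)
        return all(
            abs(x - y) <= rel * scale for x, y in zip(self.lengths, other.lengths)
        ) and all(
            abs(x - y) <= rel * 180.0 for x, y in zip(self.angles, other.angles)
        )


def cell_volume(cell: UnitCell) -> float:
    """Cell volume in cubic angstroms.

    V = abc * sqrt(1 - cos^2(alpha) - cos^2(beta) - cos^2(gamma)
                   + 2 cos(alpha) cos(beta) cos(gamma))
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0.0:
        raise InvalidCellError("non-positive volume discriminant")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


def metric_tensor(cell: UnitCell) -> np.ndarray:
    """Symmetric 3x3 metric tensor G with entries in square angstroms."""
    a, b, c = cell.lengths
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    return np.array(
        [
            [a * a, a * b * cg, a * c * cb],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb, b * c * ca, c * c],
        ]
    )


def cell_from_metric(g: np.ndarray) -> UnitCell:
    """Inverse of :func:`metric_tensor` (up to orientation)."""
    g = np.asarray(g, dtype=float)
    a, b, c = (math.sqrt(g[i, i]) for i in range(3))
    alpha = math.degrees(math.acos(g[1, 2] / (b * c)))
    beta = math.degrees(math.acos(g[0, 2] / (a * c)))
    gamma = math.degrees(math.acos(g[0, 1] / (a * b)))
    return UnitCell(a, b, c, alpha, beta, gamma)


def orthogonalization_matrix(
    cell: UnitCell, conv: OrthoConvention = OrthoConvention.X_A_Y_AB
) -> np.ndarray:
    """3x3 matrix whose columns are the Cartesian basis vectors a, b, c.

    Satisfies ``A.T @ A == metric_tensor(cell)`` and ``det(A) == +V``.
    """
    if conv is not OrthoConvention.X_A_Y_AB:  # pragma: no cover - single member
        raise ValueError(f"unsupported convention {conv}")
    a, b, c = cell.lengths
    ca, cb, cg = (math.cos(math.radians(x)) for x in cell.angles)
    sg = math.sin(math.radians(cell.gamma))
    v = cell_volume(cell)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (a * b * sg)],
        ]
    )


# ---------------------------------------------------------------------------
# Niggli reduction (Krivy & Gruber iteration)
# ---------------------------------------------------------------------------

# Internal state is the Gruber parameter vector (A, B, C, xi, eta, zeta) =
# (a.a, b.b, c.c, 2 b.c, 2 a.c, 2 a.b).  Each step applies a unimodular
# change of basis, accumulated as an integer matrix M so that the reduced
# basis is (a b c) @ M.


def _cell_to_gruber(cell: UnitCell) -> list[float]:
    g = metric_tensor(cell)
    return [g[0, 0], g[1, 1], g[2, 2], 2.0 * g[1, 2], 2.0 * g[0, 2], 2.0 * g[0, 1]]


def _gruber_to_cell(p: list[float]) -> UnitCell:
    a_, b_, c_, xi, eta, zeta = p
    a, b, c = math.sqrt(a_), math.sqrt(b_), math.sqrt(c_)
    alpha = math.degrees(math.acos(xi / (2.0 * b * c)))
    beta = math.degrees(math.acos(eta / (2.0 * a * c)))
    gamma = math.degrees(math.acos(zeta / (2.0 * a * b)))
    return UnitCell(a, b, c, alpha, beta, gamma)


def _sign(x: float) -> int:
    return -1 if x < 0 else 1


def niggli_reduce(
    cell: UnitCell, eps: float = 1e-5, max_iter: int = 100
) -> tuple[UnitCell, np.ndarray]:
    """Reduce ``cell`` to its Niggli cell.

    Returns the reduced cell and the integer unimodular change-of-basis
    matrix ``M`` (det = +/-1) such that the reduced basis vectors are
    ``(a b c) @ M`` in terms of the input basis.  ``eps`` is a relative
    tolerance for the stabilised comparisons, scaled internally by the
    geometric mean of the squared lengths; the iteration cap guards against
    pathological cycling on degenerate input.
    """
    p = _cell_to_gruber(cell)
    abs_eps = eps * (p[0] * p[1] * p[2]) ** (1.0 / 3.0)
    m = np.eye(3, dtype=int)

    def apply(t: np.ndarray) -> None:
        nonlocal m
        m = m @ t

    n_steps = 0
    while True:
        n_steps += 1
        if n_steps > max_iter:
            raise ReductionError(f"Niggli reduction did not converge in {max_iter} steps")
        a_, b_, c_, xi, eta, zeta = p

        # step 1: order A <= B
        if a_ > b_ + abs_eps or (abs(a_ - b_) <= abs_eps and abs(xi) > abs(eta) + abs_eps):
            p = [b_, a_, c_, eta, xi, zeta]
            apply(np.array([[0, -1, 0], [-1, 0, 0], [0, 0, -1]]))
            a_, b_, c_, xi, eta, zeta = p
        # step 2: order B <= C
        if b_ > c_ + abs_eps or (abs(b_ - c_) <= abs_eps and abs(eta) > abs(zeta) + abs_eps):
            p = [a_, c_, b_, xi, zeta, eta]
            apply(np.array([[-1, 0, 0], [0, 0, -1], [0, -1, 0]]))
            continue
        # steps 3/4: fix angle signs
        if xi * eta * zeta > 0:
            i = -1 if xi < 0 else 1
            j = -1 if eta < 0 else 1
            k = -1 if zeta < 0 else 1
            p = [a_, b_, c_, abs(xi), abs(eta), abs(zeta)]
            apply(np.diag([i, j, k]))
        else:
            f = [1, 1, 1]
            z = -1
            if xi > abs_eps:
                f[0] = -1
            elif not xi < -abs_eps:
                z = 0
            if eta > abs_eps:
                f[1] = -1
            elif not eta < -abs_eps:
                z = 1
            if zeta > abs_eps:
                f[2] = -1
            elif not zeta < -abs_eps:
                z = 2
            if f[0] * f[1] * f[2] < 0:
                if z == -1:  # pragma: no cover - cannot happen with exact parity
                    raise ReductionError("inconsistent angle signs")
                f[z] = -1
            i, j, k = f
            p = [a_, b_, c_, j * k * xi, i * k * eta, i * j * zeta]
            apply(np.diag([i, j, k]))
        a_, b_, c_, xi, eta, zeta = p

        # step 5
        if (
            abs(xi) > b_ + abs_eps
            or (abs(xi - b_) <= abs_eps and 2.0 * eta < zeta - abs_eps)
            or (abs(xi + b_) <= abs_eps and zeta < -abs_eps)
        ):
            s = _sign(xi)
            p = [a_, b_, b_ + c_ - s * xi, xi - 2.0 * s * b_, eta - s * zeta, zeta]
            apply(np.array([[1, 0, 0], [0, 1, -s], [0, 0, 1]]))
            continue
        # step 6
        if (
            abs(eta) > a_ + abs_eps
            or (abs(eta - a_) <= abs_eps and 2.0 * xi < zeta - abs_eps)
            or (abs(eta + a_) <= abs_eps and zeta < -abs_eps)
        ):
            s = _sign(eta)
            p = [a_, b_, a_ + c_ - s * eta, xi - s * zeta, eta - 2.0 * s * a_, zeta]
            apply(np.array([[1, 0, -s], [0, 1, 0], [0, 0, 1]]))
            continue
        # step 7
        if (
            abs(zeta) > a_ + abs_eps
            or (abs(zeta - a_) <= abs_eps and 2.0 * xi < eta - abs_eps)
            or (abs(zeta + a_) <= abs_eps and eta < -abs_eps)
        ):
            s = _sign(zeta)
            p = [a_, a_ + b_ - s * zeta, c_, xi - s * eta, eta, zeta - 2.0 * s * a_]
            apply(np.array([[1, -s, 0], [0, 1, 0], [0, 0, 1]]))
            continue
        # step 8
        total = xi + eta + zeta + a_ + b_
        if total < -abs_eps or (abs(total) <= abs_eps and 2.0 * (a_ + eta) + zeta > abs_eps):
            p = [
                a_,
                b_,
                a_ + b_ + c_ + xi + eta + zeta,
                2.0 * b_ + xi + zeta,
                2.0 * a_ + eta + zeta,
                zeta,
            ]
            apply(np.array([[1, 0, 1], [0, 1, 1], [0, 0, 1]]))
            continue
        break

    det = round(float(np.linalg.det(m)))
    if det not in (-1, 1):  # pragma: no cover - defensive
        raise ReductionError("accumulated transformation is not unimodular")
    return _gruber_to_cell(p), m


def is_niggli_reduced(cell: UnitCell, eps: float = 1e-5) -> bool:
    """Check the Niggli main conditions (a <= b <= c ordering and angle types).

    This is the acceptance predicate used as a precondition by
    :func:`deformation_measure`; it re-runs a single reduction pass and
    compares, which is robust to borderline special conditions.
    """
    reduced, _ = niggli_reduce(cell, eps=eps)
    return cell.approx_equal(reduced, rel=math.sqrt(eps) * 1e-2)


def deformation_measure(cell_a: UnitCell, cell_b: UnitCell, *, check_reduced: bool = True) -> float:
    """Scalar lattice-deformation distance between two (reduced) cells.

    With F the deformation gradient mapping cell A onto cell B in a common
    Cartesian frame, the measure is the Frobenius norm of the finite
    Lagrangian strain eta = (F.T F - I) / 2.  It vanishes iff the cells are
    identical and is symmetric in its arguments to first order in strain.
    Both cells must be Niggli reduced so the comparison is
    setting-independent.
    """
    if check_reduced:
        for name, cell in (("first", cell_a), ("second", cell_b)):
            if not is_niggli_reduced(cell):
                raise ValueError(f"{name} cell is not Niggli reduced")
    mat_a = orthogonalization_matrix(cell_a)
    mat_b = orthogonalization_matrix(cell_b)
    f = mat_b @ np.linalg.inv(mat_a)
    eta = 0.5 * (f.T @ f - np.eye(3))
    return float(np.sqrt(np.sum(eta * eta)))
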