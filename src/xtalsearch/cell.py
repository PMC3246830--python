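"""Niggli cell reduction and angle-aware reduced-cell matching.

The reduction is the Krivy-Gruber (1976) iteration on the metric scalars
(A, B, C, xi, eta, zeta) with epsilon-stabilized comparisons; the accumulated
change-of-basis matrix is integer with determinant +-1, so cell volume is
conserved exactly up to floating error.

Because reduced-cell angles are numerically unstable near decision
boundaries, matching goes through a "nearly Buerger" set: the Niggli cell
plus every bounded unimodular transform of it whose lengths still satisfy
the Buerger shortest-vectors condition within tolerance and whose parameters
stay inside an expanded instability window.  A query matches a stored
reduced cell iff some member of its nearly-Buerger set agrees on all three
lengths (relative tolerance) and all three angles (absolute tolerance);
a lengths-only mode is available for comparison and always returns a
superset of the angle-aware hits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "UnitCell",
    "ReducedCell",
    "CellTolerance",
    "niggli_reduce",
    "nearly_buerger_set",
    "cells_match",
    "reduced_cell_search",
]

_MAX_ITERATIONS = 1000


@dataclass(frozen=True)
class UnitCell:
    """Lattice parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            angle = getattr(self, name)
            if not 0 < angle < 180:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        if np.linalg.det(self.metric()) <= 0:
            raise ValueError("cell metric is not positive definite")

    def metric(self) -> np.ndarray:
        a, b, c = self.a, self.b, self.c
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def volume(self) -> float:
        det = np.linalg.det(self.metric())
        return math.sqrt(det)

    @classmethod
    def from_metric(cls, g: np.ndarray) -> "UnitCell":
        a, b, c = math.sqrt(g[0, 0]), math.sqrt(g[1, 1]), math.sqrt(g[2, 2])
        alpha = math.degrees(math.acos(max(-1.0, min(1.0, g[1, 2] / (b * c)))))
        beta = math.degrees(math.acos(max(-1.0, min(1.0, g[0, 2] / (a * c)))))
        gamma = math.degrees(math.acos(max(-1.0, min(1.0, g[0, 1] / (a * b)))))
        return cls(a, b, c, alpha, beta, gamma)

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def transformed(self, m: np.ndarray) -> "UnitCell":
        """Cell described by basis vectors (old basis) @ m."""
        m = np.asarray(m, dtype=float)
        return UnitCell.from_metric(m.T @ self.metric() @ m)


@dataclass(frozen=True)
class ReducedCell:
    """Niggli-reduced parameters plus type (I: all angles < 90, else II)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    niggli_type: str = "I"

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def as_cell(self) -> UnitCell:
        return UnitCell(*self.parameters())

    @property
    def volume(self) -> float:
        return self.as_cell().volume


@dataclass(frozen=True)
class CellTolerance:
    rel_length: float = 0.01
    abs_angle: float = 1.0

    def __post_init__(self) -> None:
        if self.rel_length < 0 or self.abs_angle < 0:
            raise ValueError("tolerances must be >= 0")


def _cell_from_scalars(A: float, B: float, C: float, xi: float, eta: float, zeta: float) -> ReducedCell:
    a, b, c = math.sqrt(A), math.sqrt(B), math.sqrt(C)
    alpha = math.degrees(math.acos(max(-1.0, min(1.0, xi / (2 * b * c)))))
    beta = math.degrees(math.acos(max(-1.0, min(1.0, eta / (2 * a * c)))))
    gamma = math.degrees(math.acos(max(-1.0, min(1.0, zeta / (2 * a * b)))))
    ntype = "I" if (alpha < 90 and beta < 90 and gamma < 90) else "II"
    return ReducedCell(a, b, c, alpha, beta, gamma, ntype)


def niggli_reduce(
    cell: UnitCell, eps: Optional[float] = None
) -> tuple[ReducedCell, np.ndarray]:
    """Krivy-Gruber Niggli reduction with epsilon-stabilized comparisons.

    Returns the reduced cell and the integer change-of-basis matrix M
    (det +-1) such that reduced basis = input basis @ M, i.e. the reduced
    metric is M.T @ G @ M.
    """
    g = cell.metric()
    if np.linalg.det(g) <= 0:
        raise ValueError("degenerate cell metric")
    if eps is None:
        eps = 1e-5 * cell.volume ** (2.0 / 3.0)

    A, B, C = g[0, 0], g[1, 1], g[2, 2]
    xi, eta, zeta = 2 * g[1, 2], 2 * g[0, 2], 2 * g[0, 1]
    m_total = np.eye(3, dtype=int)

    def apply(m_step: list[list[int]]) -> None:
        nonlocal m_total
        m_total = m_total @ np.array(m_step, dtype=int)

    for _ in range(_MAX_ITERATIONS):
        # step 1: sort A <= B
        if A > B + eps or (abs(A - B) <= eps and abs(xi) > abs(eta) + eps):
            A, B, xi, eta = B, A, eta, xi
            apply([[0, -1, 0], [-1, 0, 0], [0, 0, -1]])
        # step 2: sort B <= C
        if B > C + eps or (abs(B - C) <= eps and abs(eta) > abs(zeta) + eps):
            B, C, eta, zeta = C, B, zeta, eta
            apply([[-1, 0, 0], [0, 0, -1], [0, -1, 0]])
            continue
        # steps 3/4: normalize the signs of (xi, eta, zeta)
        def sign_of(v: float) -> int:
            if v > eps:
                return 1
            if v < -eps:
                return -1
            return 0
        if sign_of(xi) * sign_of(eta) * sign_of(zeta) > 0:
            # make all positive: i = sign(eta), j = sign(xi), k = 1
            i, j, k = sign_of(eta), sign_of(xi), 1
            xi, eta, zeta = j * k * xi, i * k * eta, i * j * zeta
            apply([[i, 0, 0], [0, j, 0], [0, 0, k]])
        else:
            # make all non-positive; flip a "zero" axis if parity is odd
            f = [1, 1, 1]
            z = -1
            for idx, v in enumerate((xi, eta, zeta)):
                if v > eps:
                    f[idx] = -1
                elif not v < -eps:
                    z = idx
            if f[0] * f[1] * f[2] < 0:
                if z < 0:  # pragma: no cover - excluded by sign parity
                    raise RuntimeError("Niggli sign normalization failed")
                f[z] = -1
            i, j, k = f
            xi, eta, zeta = j * k * xi, i * k * eta, i * j * zeta
            apply([[i, 0, 0], [0, j, 0], [0, 0, k]])
        # step 5
        if (
            abs(xi) > B + eps
            or (abs(xi - B) <= eps and 2 * eta < zeta - eps)
            or (abs(xi + B) <= eps and zeta < -eps)
        ):
            s = 1 if xi > 0 else -1
            C = B + C - xi * s
            eta = eta - zeta * s
            xi = xi - 2 * B * s
            apply([[1, 0, 0], [0, 1, -s], [0, 0, 1]])
            continue
        # step 6
        if (
            abs(eta) > A + eps
            or (abs(eta - A) <= eps and 2 * xi < zeta - eps)
            or (abs(eta + A) <= eps and zeta < -eps)
        ):
            s = 1 if eta > 0 else -1
            C = A + C - eta * s
            xi = xi - zeta * s
            eta = eta - 2 * A * s
            apply([[1, 0, -s], [0, 1, 0], [0, 0, 1]])
            continue
        # step 7
        if (
            abs(zeta) > A + eps
            or (abs(zeta - A) <= eps and 2 * xi < eta - eps)
            or (abs(zeta + A) <= eps and eta < -eps)
        ):
            s = 1 if zeta > 0 else -1
            B = A + B - zeta * s
            xi = xi - eta * s
            zeta = zeta - 2 * A * s
            apply([[1, -s, 0], [0, 1, 0], [0, 0, 1]])
            continue
        # step 8
        total = xi + eta + zeta + A + B
        if total < -eps or (abs(total) <= eps and 2 * (A + eta) + zeta > eps):
            C = A + B + C + xi + eta + zeta
            xi = 2 * B + xi + zeta
            eta = 2 * A + eta + zeta
            apply([[1, 0, 1], [0, 1, 1], [0, 0, 1]])
            continue
        reduced = _cell_from_scalars(A, B, C, xi, eta, zeta)
        return reduced, m_total
    raise RuntimeError("Niggli reduction did not converge within 1000 steps")


# ---------------------------------------------------------------------------
# Nearly-Buerger sets
# ---------------------------------------------------------------------------

_unimodular_cache: Optional[np.ndarray] = None


def _unimodular_pm1() -> np.ndarray:
    """All 3x3 integer matrices with entries in {-1,0,1} and det +-1."""
    global _unimodular_cache
    if _unimodular_cache is None:
        entries = np.array(list(itertools.product((-1, 0, 1), repeat=9)), dtype=int)
        mats = entries.reshape(-1, 3, 3)
        dets = np.rint(np.linalg.det(mats)).astype(int)
        _unimodular_cache = mats[np.abs(dets) == 1]
    return _unimodular_cache


def _params_from_metrics(gs: np.ndarray) -> np.ndarray:
    """Vectorized (n,3,3) metrics -> (n,6) parameter rows (a,b,c,al,be,ga)."""
    a = np.sqrt(gs[:, 0, 0])
    b = np.sqrt(gs[:, 1, 1])
    c = np.sqrt(gs[:, 2, 2])
    alpha = np.degrees(np.arccos(np.clip(gs[:, 1, 2] / (b * c), -1, 1)))
    beta = np.degrees(np.arccos(np.clip(gs[:, 0, 2] / (a * c), -1, 1)))
    gamma = np.degrees(np.arccos(np.clip(gs[:, 0, 1] / (a * b), -1, 1)))
    return np.stack([a, b, c, alpha, beta, gamma], axis=1)


def _sort_cell_params(row: np.ndarray) -> tuple[float, ...]:
    """Canonical axis order a <= b <= c, angles carried with their axes."""
    order = np.argsort(row[:3], kind="stable")
    return tuple(row[:3][order]) + tuple(row[3:][order])


def nearly_buerger_set(cell: UnitCell, tol: CellTolerance = CellTolerance()) -> list[ReducedCell]:
    """The Niggli cell plus closely related near-Buerger cells.

    Enumerate unimodular transforms with entries in {-1,0,1} of the reduced
    basis; keep those whose sorted lengths satisfy the Buerger
    shortest-vectors condition within tol.rel_length and whose angles stay
    within 2x tol.abs_angle of the Niggli angles, deduplicated at 1e-6.
    """
    reduced, _ = niggli_reduce(cell)
    g = reduced.as_cell().metric()
    mats = _unimodular_pm1()
    gs = np.einsum("nji,jk,nkl->nil", mats, g, mats)
    params = _params_from_metrics(gs)

    niggli_sorted = np.array(_sort_cell_params(np.array(reduced.parameters())))
    members: dict[tuple[float, ...], ReducedCell] = {}
    for row in params:
        srow = np.array(_sort_cell_params(row))
        if np.any(np.abs(srow[:3] - niggli_sorted[:3]) > tol.rel_length * niggli_sorted[:3]):
            continue  # violates the Buerger shortest-vectors condition
        if np.any(np.abs(srow[3:] - niggli_sorted[3:]) > 2 * tol.abs_angle):
            continue  # outside the instability window
        key = tuple(np.round(srow, 6))
        if key not in members:
            members[key] = _cell_from_scalars(
                srow[0] ** 2,
                srow[1] ** 2,
                srow[2] ** 2,
                2 * srow[1] * srow[2] * math.cos(math.radians(srow[3])),
                2 * srow[0] * srow[2] * math.cos(math.radians(srow[4])),
                2 * srow[0] * srow[1] * math.cos(math.radians(srow[5])),
            )
    return [members[k] for k in sorted(members)]


def _params_match(
    member: ReducedCell,
    candidate: ReducedCell,
    tol: CellTolerance,
    check_angles: bool = True,
) -> bool:
    """Compare parameter sets; length ties are resolved by trying every axis
    permutation whose lengths agree within tolerance."""
    mlen, mang = member.lengths, member.angles
    clen, cang = candidate.lengths, candidate.angles
    for perm in itertools.permutations(range(3)):
        ok = True
        for i in range(3):
            if abs(mlen[perm[i]] - clen[i]) > tol.rel_length * clen[i]:
                ok = False
                break
        if not ok:
            continue
        if not check_angles:
            return True
        if all(abs(mang[perm[i]] - cang[i]) <= tol.abs_angle for i in range(3)):
            return True
    return False


def cells_match(
    query: UnitCell,
    candidate: ReducedCell,
    tol: CellTolerance = CellTolerance(),
    lengths_only: bool = False,
) -> bool:
    """True iff some nearly-Buerger member of *query* matches *candidate* on
    all three lengths and (unless lengths_only) all three angles."""
    for member in nearly_buerger_set(query, tol):
        if _params_match(member, candidate, tol, check_angles=not lengths_only):
            return True
    return False


def reduced_cell_search(
    query: UnitCell,
    db,
    tol: CellTolerance = CellTolerance(),
    lengths_only: bool = False,
) -> list[str]:
    """Refcodes of all entries whose stored reduced cell matches the query.

    Entries without cells are skipped; output ordered by refcode.
    """
    members = nearly_buerger_set(query, tol)
    hits = []
    for refcode, stored in db.iter_reduced_cells():
        if any(
            _params_match(m, stored, tol, check_angles=not lengths_only)
            for m in members
        ):
            hits.append(refcode)
    return sorted(hits)
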