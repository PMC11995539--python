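"""Aitchison-geometry primitives for 4-part 24-h time-use compositions.

A day is split into MVPA, LPA, sedentary time (ST) and sleep, carried on the
1440-minute simplex.  Only relative information is meaningful, so every
operation here works on *closed* compositions (parts rescaled to a fixed
total) and log-ratios of parts.  The isometric log-ratio (ilr) map used
throughout is the *pivot* variant, whose first coordinate contrasts the
leading part against the geometric mean of the remaining parts:

    z_j = sqrt((D-j)/(D-j+1)) * ln( x_j / gm(x_{j+1}, ..., x_D) )

for j = 1..D-1.  Group contrasts are log-ratios of per-group geometric
means with bootstrap percentile confidence intervals.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Canonical storage order of the four behaviours.
PARTS: tuple[str, ...] = ("MVPA", "LPA", "ST", "sleep")

#: Closure constant: minutes in a day.
MINUTES_PER_DAY: float = 1440.0

_REL_TOL = 1e-9


class ZeroPartError(ValueError):
    """A compositional part is zero or negative, so log-ratios are undefined."""


@dataclass(frozen=True)
class Composition:
    """A closed composition: strictly positive parts summing to ``kappa``.

    Construct via :func:`close`; the constructor assumes already-closed data.
    """

    names: tuple[str, ...]
    values: np.ndarray  # shape (D,), closed
    kappa: float = MINUTES_PER_DAY

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(self.names) != v.shape[0]:
            raise ValueError("names/values length mismatch")
        if np.any(v <= 0):
            bad = self.names[int(np.argmin(v))]
            raise ZeroPartError(f"non-positive part {bad!r}")
        if abs(v.sum() - self.kappa) > _REL_TOL * self.kappa:
            raise ValueError(
                f"parts sum to {v.sum():.9g}, expected kappa={self.kappa:.9g}"
            )

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise KeyError(f"unknown behaviour {name!r}") from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def reorder(self, names: Sequence[str]) -> "Composition":
        """Return the same composition with parts permuted into ``names``."""
        if sorted(names) != sorted(self.names):
            raise ValueError(f"{names!r} is not a permutation of {self.names!r}")
        idx = [self.names.index(n) for n in names]
        return Composition(tuple(names), self.values[idx], self.kappa)


@dataclass(frozen=True)
class IlrCoordinates:
    """Pivot-ilr coordinates (length D-1) and the part order that defines them."""

    values: np.ndarray
    parts_order: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape[0] != len(self.parts_order) - 1:
            raise ValueError("ilr vector must have length D-1")


@dataclass(frozen=True)
class GroupContrast:
    """Bootstrap log-ratio-of-geometric-means contrast for one behaviour."""

    behaviour: str
    estimate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    seed: int
    level: float = 0.95


def close(
    parts: Iterable[float] | np.ndarray,
    kappa: float = MINUTES_PER_DAY,
    names: Sequence[str] = PARTS,
) -> Composition:
    """Close a positive vector to sum ``kappa``, preserving ratios."""
    v = np.asarray(list(parts) if not isinstance(parts, np.ndarray) else parts,
                   dtype=float)
    if v.size == 0:
        raise ValueError("empty composition")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if np.any(v <= 0):
        bad = names[int(np.argmin(v))] if len(names) == v.size else f"index {int(np.argmin(v))}"
        raise ZeroPartError(f"non-positive part {bad!r}")
    return Composition(tuple(names), v * (kappa / v.sum()), kappa)


def close_rows(X: np.ndarray, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
    """Row-wise closure of a strictly positive (n, D) matrix."""
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ZeroPartError("non-positive part in matrix closure")
    return X * (kappa / X.sum(axis=1, keepdims=True))


def shift_zeros(X: np.ndarray, shift: float = 0.5) -> np.ndarray:
    """Additive pre-closure shift for zero parts (logged); use sparingly.

    Log-ratios are undefined at zero, so rows containing zeros are either
    rejected (default policy) or shifted here before closure.
    """
    X = np.asarray(X, dtype=float)
    n_zero = int(np.count_nonzero(X <= 0))
    if n_zero:
        log.warning("shifting %d zero part(s) by +%g before closure", n_zero, shift)
        X = X + shift
    return X


def pivot_basis(d: int) -> np.ndarray:
    """The D x (D-1) pivot contrast matrix V with z = clr(x) @ V, clr = V @ z."""
    V = np.zeros((d, d - 1))
    for j in range(d - 1):
        r = d - j - 1  # number of trailing parts
        c = np.sqrt(r / (r + 1.0))
        V[j, j] = c
        V[j + 1:, j] = -c / r
    return V


def pivot_ilr_values(X: np.ndarray) -> np.ndarray:
    """Vectorised pivot ilr of rows of a positive (n, D) or (D,) array."""
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ZeroPartError("non-positive part in ilr input")
    L = np.log(X)
    clr = L - L.mean(axis=-1, keepdims=True)
    return clr @ pivot_basis(X.shape[-1])


def pivot_ilr(c: Composition) -> IlrCoordinates:
    """Pivot ilr coordinates of a composition (scale-invariant)."""
    return IlrCoordinates(pivot_ilr_values(c.values), c.names)


def ilr_inverse_values(Z: np.ndarray, kappa: float = MINUTES_PER_DAY) -> np.ndarray:
    """Rows of ilr vectors back to closed compositions (softmax of clr)."""
    Z = np.asarray(Z, dtype=float)
    d = Z.shape[-1] + 1
    clr = Z @ pivot_basis(d).T
    # subtract max for numerical stability before exponentiating
    e = np.exp(clr - clr.max(axis=-1, keepdims=True))
    return e * (kappa / e.sum(axis=-1, keepdims=True))


def ilr_inverse(
    z: IlrCoordinates | np.ndarray,
    kappa: float = MINUTES_PER_DAY,
    names: Sequence[str] | None = None,
) -> Composition:
    if isinstance(z, IlrCoordinates):
        names = z.parts_order
        z = z.values
    z = np.asarray(z, dtype=float)
    if names is None:
        names = PARTS
    if z.shape[-1] != len(names) - 1:
        raise ValueError(f"ilr vector length {z.shape[-1]} != D-1 = {len(names) - 1}")
    return Composition(tuple(names), ilr_inverse_values(z, kappa), kappa)


def compositional_mean(
    rows: Sequence[Composition] | np.ndarray,
    kappa: float = MINUTES_PER_DAY,
    names: Sequence[str] = PARTS,
) -> Composition:
    """Centre of a compositional sample: closed part-wise geometric means.

    Accepts a list of :class:`Composition` (all sharing one part order) or a
    positive (n, D) matrix of raw parts.  Closure-invariant per row.
    """
    X, names = _as_matrix(rows, names)
    if X.shape[0] == 0:
        raise ValueError("empty compositional sample")
    gm = np.exp(np.log(close_rows(X, kappa)).mean(axis=0))
    return close(gm, kappa, names)


def _as_matrix(
    rows: Sequence[Composition] | np.ndarray, names: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(rows, np.ndarray):
        return np.asarray(rows, dtype=float), tuple(names)
    rows = list(rows)
    if not rows:
        return np.empty((0, len(names))), tuple(names)
    names = rows[0].names
    for r in rows[1:]:
        if r.names != names:
            raise ValueError("inconsistent part order across rows")
    return np.stack([r.values for r in rows]), names


def logratio_group_difference(
    group_a: Sequence[Composition] | np.ndarray,
    group_b: Sequence[Composition] | np.ndarray,
    behaviour: str,
    kappa: float = MINUTES_PER_DAY,
    names: Sequence[str] = PARTS,
) -> float:
    """ln( gm_A(behaviour) / gm_B(behaviour) ) on compositions closed to kappa.

    Positive values mean group A spends relatively more time in the
    behaviour.  Computed on closed data, so the contrast is invariant to
    per-row rescaling of the raw parts.
    """
    Xa, names_a = _as_matrix(group_a, names)
    Xb, names_b = _as_matrix(group_b, names)
    if Xa.shape[0] == 0 or Xb.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if behaviour not in names_a or behaviour not in names_b:
        raise KeyError(f"unknown behaviour {behaviour!r}")
    la = np.log(close_rows(Xa, kappa))[:, list(names_a).index(behaviour)]
    lb = np.log(close_rows(Xb, kappa))[:, list(names_b).index(behaviour)]
    return float(la.mean() - lb.mean())


def contrast_seed(root_seed: int, behaviour: str) -> int:
    """Deterministic per-behaviour child seed from one root seed."""
    return int(np.random.SeedSequence(
        [int(root_seed) % (2**31), zlib.crc32(behaviour.encode())]
    ).generate_state(1)[0] % (2**31))


def bootstrap_contrast(
    group_a: Sequence[Composition] | np.ndarray,
    group_b: Sequence[Composition] | np.ndarray,
    behaviour: str,
    n_replicates: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    kappa: float = MINUTES_PER_DAY,
    names: Sequence[str] = PARTS,
) -> GroupContrast:
    """Bootstrap percentile CI for the log-ratio-of-geometric-means contrast.

    Each group is resampled with replacement independently; the contrast is
    recomputed per replicate and the CI taken at the (1-level)/2 and
    1-(1-level)/2 empirical quantiles.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    Xa, names_a = _as_matrix(group_a, names)
    Xb, names_b = _as_matrix(group_b, names)
    if Xa.shape[0] == 0 or Xb.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if behaviour not in names_a:
        raise KeyError(f"unknown behaviour {behaviour!r}")
    la = np.log(close_rows(Xa, kappa))[:, list(names_a).index(behaviour)]
    lb = np.log(close_rows(Xb, kappa))[:, list(names_b).index(behaviour)]
    estimate = float(la.mean() - lb.mean())

    rng = np.random.default_rng(seed)
    ia = rng.integers(0, la.size, size=(n_replicates, la.size))
    ib = rng.integers(0, lb.size, size=(n_replicates, lb.size))
    reps = la[ia].mean(axis=1) - lb[ib].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return GroupContrast(
        behaviour=behaviour, estimate=estimate,
        ci_low=float(lo), ci_high=float(hi),
        n_replicates=n_replicates, seed=int(seed), level=level,
    )


def rotated_order(behaviour: str, base_order: Sequence[str] = PARTS) -> tuple[str, ...]:
    """Part order with ``behaviour`` pivoted first, the rest in base order."""
    if behaviour not in base_order:
        raise KeyError(f"unknown behaviour {behaviour!r}")
    return (behaviour,) + tuple(b for b in base_order if b != behaviour)
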