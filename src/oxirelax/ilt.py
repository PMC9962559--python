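"""Regularized inverse Laplace transform of CPMG decays into T2 spectra.

A relaxation curve s(t_k) is modeled as a non-negative mixture of
monoexponentials over a log-spaced T2 grid, s = K f with kernel
K[k, j] = exp(-t_k / T2_j).  The inversion is the classic ill-posed
problem, stabilized by L1/L2 penalties:

    minimize_{f >= 0}  ||K f - s||_2^2 + a1 ||f||_1 + a2 ||f||_2^2

with the signal max-normalized before solving (the penalty weights are
interpreted on that scale; the normalization constant is recorded on the
spectrum).  For f >= 0 the L1 term is linear, so for a2 > 0 the whole
objective folds into one augmented non-negative least-squares system
solved exactly by an active-set method; the a2 = 0, a1 > 0 corner uses
an in-package Lawson-Hanson-style active-set iteration with the linear
term folded into the stationarity conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .curves import RelaxationCurve
from .errors import ConvergenceError, InvalidInputError


@dataclass(frozen=True)
class T2Grid:
    """Log-spaced grid of candidate relaxation times, seconds."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise InvalidInputError("grid must be a non-empty 1-D array")
        if np.any(v <= 0) or np.any(np.diff(v) <= 0):
            raise InvalidInputError("grid must be positive and strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return self.values.size

    @classmethod
    def for_times(cls, times: np.ndarray, n_points: int = 128) -> "T2Grid":
        """Default grid spanning [first echo time, 10 x last echo time]."""
        times = np.asarray(times, dtype=float)
        return cls(np.geomspace(times.min(), 10.0 * times.max(), n_points))


@dataclass(frozen=True)
class IltPenalty:
    """Penalty weights: ``a1`` for the L1 term, ``a2`` for the L2 (ridge) term.

    ``a2 = 0.5`` is the conventional operating point for max-normalized
    benchtop CPMG signals; ``a1`` defaults to 0.
    """

    a1: float = 0.0
    a2: float = 0.5

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0:
            raise InvalidInputError("penalty weights must be >= 0")


@dataclass(frozen=True)
class T2Spectrum:
    """Non-negative amplitude distribution over a T2 grid."""

    grid: T2Grid
    amplitudes: np.ndarray
    residual_norm: float
    normalization: float = 1.0  # max of raw signal removed before solving
    penalty: IltPenalty | None = None

    def __post_init__(self):
        a = np.asarray(self.amplitudes, dtype=float)
        if a.shape != self.grid.values.shape:
            raise InvalidInputError("amplitudes must match the grid")
        if np.any(a < -1e-12):
            raise InvalidInputError("spectrum amplitudes must be non-negative")
        object.__setattr__(self, "amplitudes", np.maximum(a, 0.0))

    @property
    def total_mass(self) -> float:
        return float(self.amplitudes.sum())


def build_kernel(time_grid: np.ndarray, t2_grid: T2Grid | np.ndarray) -> np.ndarray:
    """Discretized Laplace kernel K[k, j] = exp(-t_k / T2_j)."""
    t = np.asarray(time_grid, dtype=float)
    t2 = t2_grid.values if isinstance(t2_grid, T2Grid) else np.asarray(t2_grid, dtype=float)
    if t.size == 0 or t2.size == 0:
        raise InvalidInputError("grids must be non-empty")
    return np.exp(-t[:, None] / t2[None, :])


def _active_set_qp(K, s, a1, max_iter=10_000, tol=1e-10):
    """min ||Kf - s||^2 + a1 1'f over f >= 0 by a Lawson-Hanson active set.

    Identical to classic NNLS except that the stationarity target is
    K's - a1/2 instead of K's (the L1 term is linear on the positive
    orthant).  Exact at termination; raises on iteration exhaustion.
    """
    n = K.shape[1]
    Q = K.T @ K
    c = K.T @ s - a1 / 2.0
    scale = max(np.abs(c).max(), 1.0)
    f = np.zeros(n)
    passive = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        g = Q @ f - c  # half-gradient
        free = ~passive
        if not np.any(free & (g < -tol * scale)):
            return f
        passive[np.flatnonzero(free)[np.argmin(g[free])]] = True
        while True:
            idx = np.flatnonzero(passive)
            try:
                f_p = np.linalg.solve(Q[np.ix_(idx, idx)], c[idx])
            except np.linalg.LinAlgError:
                f_p = np.linalg.lstsq(Q[np.ix_(idx, idx)], c[idx], rcond=None)[0]
            if np.all(f_p > 0):
                f = np.zeros(n)
                f[idx] = f_p
                break
            bad = f_p <= 0
            ratios = f[idx][bad] / (f[idx][bad] - f_p[bad])
            alpha = float(ratios.min())
            f[idx] += alpha * (f_p - f[idx])
            passive[idx[f[idx] <= tol]] = False
            f[~passive] = 0.0
    raise ConvergenceError("active-set ILT did not terminate", iterations=max_iter)


def invert(
    curve: RelaxationCurve,
    grid: T2Grid | None = None,
    penalty: IltPenalty = IltPenalty(),
) -> T2Spectrum:
    """Reconstruct the non-negative T2 spectrum of a relaxation curve."""
    s_raw = np.asarray(curve.amplitudes, dtype=float)
    if not np.any(s_raw != 0):
        raise InvalidInputError("curve is identically zero")
    grid = grid or T2Grid.for_times(curve.times)
    K = build_kernel(curve.times, grid)
    scale = float(np.max(np.abs(s_raw)))
    s = s_raw / scale

    a1, a2 = penalty.a1, penalty.a2
    n = grid.n_points
    if a1 == 0 and a2 == 0 and np.linalg.cond(K) > 1e8:
        warnings.warn("kernel is ill-conditioned and no penalty is set; "
                      "the solution may be unstable", stacklevel=2)
    if a2 > 0:
        # fold the ridge term into the design and the (linear) L1 term into
        # the augmented rhs: argmin ||[K; sqrt(a2) I] f - [s; -a1/(2 sqrt(a2))]||^2
        A = np.vstack([K, np.sqrt(a2) * np.eye(n)])
        b = np.concatenate([s, np.full(n, -a1 / (2.0 * np.sqrt(a2)))])
        f, _ = _scipy_nnls(A, b)
    elif a1 == 0:
        f, _ = _scipy_nnls(K, s)
    else:
        f = _active_set_qp(K, s, a1)
    residual = float(np.linalg.norm(K @ f - s))
    return T2Spectrum(grid=grid, amplitudes=f, residual_norm=residual,
                      normalization=scale, penalty=penalty)


def ilt_objective(K, s, f, penalty: IltPenalty) -> float:
    """The penalized objective value; exposed for diagnostics and testing."""
    r = K @ f - s
    return float(r @ r + penalty.a1 * np.sum(np.abs(f)) + penalty.a2 * f @ f)


def find_peaks(spectrum: T2Spectrum, min_rel_height: float = 0.05):
    """Local maxima of the spectrum above ``min_rel_height`` x global max.

    Returns ``[(t2_location, amplitude), ...]`` sorted by T2 ascending.
    A flat zero spectrum yields an empty list.  Plateau maxima report
    their left edge.
    """
    if not (0 < min_rel_height <= 1):
        raise InvalidInputError("min_rel_height must be in (0, 1]")
    a = spectrum.amplitudes
    peak = float(a.max(initial=0.0))
    if peak <= 0:
        return []
    pad = np.concatenate([[-np.inf], a, [-np.inf]])
    is_max = (pad[1:-1] > pad[:-2]) & (pad[1:-1] >= pad[2:])
    keep = is_max & (a >= min_rel_height * peak)
    idx = np.flatnonzero(keep)
    return [(float(spectrum.grid.values[i]), float(a[i])) for i in idx]
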