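"""Functional representation of fold-change time courses.

Expression time series are converted to continuous curves by penalized
B-spline smoothing (order-4 basis, knots at the sampled timepoints, second
derivative roughness penalty), following the classical functional-data-
analysis (FDA) construction.  All downstream similarity computations —
derivative inner products, RMS scaling, functional PCA — operate on the
basis-coefficient representation with exact Gram-matrix integrals, so the
unequal sampling density of the time grid (2 h spacing early, up to 32 h
late) is handled by true functional integrals rather than by treating the
timepoints as an equally spaced vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "Curve",
    "CurveSet",
    "make_basis",
    "fit_curves",
    "evaluate",
    "inner_product",
    "rms_scale",
    "fpca",
    "FPCAResult",
    "cosine_similarity",
]


# ---------------------------------------------------------------------------
# Basis construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSpec:
    """B-spline basis with knots at the sampling times.

    Parameters
    ----------
    knots : tuple of float
        Strictly increasing sampling times (hours); every data point is a
        knot, so the basis can represent any feature resolvable by the
        sampling schedule.
    order : int
        Spline order (degree + 1); 4 gives cubic smoothing splines.
    lam : float
        Second-derivative roughness penalty weight used when fitting.
    """

    knots: tuple[float, ...]
    order: int = 4
    lam: float = 0.05

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 1 or len(k) < self.order:
            raise ValueError(
                f"need at least order={self.order} knots, got {len(k)}"
            )
        if not np.all(np.diff(k) > 0):
            raise ValueError("knots must be strictly increasing")
        if not np.all(np.isfinite(k)):
            raise ValueError("knots must be finite")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def n_basis(self) -> int:
        # interior knots + order
        return len(self.knots) - 2 + self.order

    @property
    def t_min(self) -> float:
        return self.knots[0]

    @property
    def t_max(self) -> float:
        return self.knots[-1]

    @property
    def knot_vector(self) -> np.ndarray:
        """Full (clamped) knot vector with order-fold boundary knots."""
        k = np.asarray(self.knots, dtype=float)
        return np.concatenate(
            [np.repeat(k[0], self.order), k[1:-1], np.repeat(k[-1], self.order)]
        )

    def basis_matrix(self, times, deriv_order: int = 0) -> np.ndarray:
        """Evaluate all basis functions (or a derivative) at `times`.

        Returns an array of shape (len(times), n_basis).
        """
        t = np.asarray(times, dtype=float)
        if np.any(t < self.t_min - 1e-12) or np.any(t > self.t_max + 1e-12):
            raise ValueError(
                f"evaluation times outside knot range "
                f"[{self.t_min}, {self.t_max}]"
            )
        t = np.clip(t, self.t_min, self.t_max)
        spl = BSpline(self.knot_vector, np.eye(self.n_basis), self.degree,
                      extrapolate=True)
        if deriv_order:
            spl = spl.derivative(deriv_order)
        return spl(t)


def make_basis(time_grid, order: int = 4, lam: float = 0.05) -> BasisSpec:
    """Build the order-`order` B-spline basis with knots at the data points."""
    return BasisSpec(knots=tuple(float(t) for t in time_grid), order=order,
                     lam=lam)


# ---------------------------------------------------------------------------
# Exact Gram / penalty integrals
# ---------------------------------------------------------------------------

def _integration_breaks(spec: BasisSpec, window=None) -> np.ndarray:
    lo = spec.t_min if window is None else float(window[0])
    hi = spec.t_max if window is None else float(window[1])
    if not (spec.t_min - 1e-12 <= lo < hi <= spec.t_max + 1e-12):
        raise ValueError(f"window [{lo}, {hi}] outside knot range")
    interior = [k for k in spec.knots if lo < k < hi]
    return np.array([lo, *interior, hi], dtype=float)


def gram_matrix(spec: BasisSpec, deriv_order: int = 0, window=None
                ) -> np.ndarray:
    """G[j,k] = integral of B_j^(d) * B_k^(d) over the window.

    B-splines are piecewise polynomials, so fixed-order Gauss–Legendre
    quadrature on each inter-knot segment is exact (products of two
    derivative curves have degree <= 2*(order-1) < 2*order-1).
    """
    breaks = _integration_breaks(spec, window)
    nodes, weights = leggauss(spec.order)
    mids = (breaks[1:] + breaks[:-1]) / 2
    half = (breaks[1:] - breaks[:-1]) / 2
    # all quadrature points across segments
    x = (mids[:, None] + half[:, None] * nodes[None, :]).ravel()
    w = (half[:, None] * weights[None, :]).ravel()
    B = spec.basis_matrix(x, deriv_order)
    return (B * w[:, None]).T @ B


@lru_cache(maxsize=64)
def _cached_gram(spec: BasisSpec, deriv_order: int, window: tuple | None
                 ) -> np.ndarray:
    G = gram_matrix(spec, deriv_order, window)
    G.setflags(write=False)
    return G


# ---------------------------------------------------------------------------
# Curves and curve sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Curve:
    coefficients: np.ndarray
    basis: BasisSpec

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (self.basis.n_basis,):
            raise ValueError(
                f"coefficient length {c.shape} != n_basis {self.basis.n_basis}"
            )
        object.__setattr__(self, "coefficients", c)

    def __call__(self, times, deriv_order: int = 0):
        return evaluate(self, times, deriv_order)


@dataclass
class CurveSet:
    """A collection of curves over one shared basis (one row per gene)."""

    gene_ids: list[str]
    coefficients: np.ndarray  # (n_genes, n_basis)
    basis: BasisSpec

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.gene_ids), self.basis.n_basis):
            raise ValueError("coefficient matrix shape mismatch")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def curve(self, gene_id: str) -> Curve:
        i = self.gene_ids.index(gene_id)
        return Curve(self.coefficients[i], self.basis)

    def evaluate(self, times, deriv_order: int = 0) -> np.ndarray:
        B = self.basis.basis_matrix(times, deriv_order)
        return self.coefficients @ B.T

    def subset(self, gene_ids) -> "CurveSet":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from CurveSet: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return CurveSet(list(gene_ids), self.coefficients[rows], self.basis)


def fit_curves(fc, basis: BasisSpec) -> CurveSet:
    """Penalized least-squares spline fit of each gene's time course.

    `fc` is a pandas DataFrame (genes x timepoints, columns = hours as
    floats or 't<h>' labels).  Coefficients minimize
    sum_t (y_t - f(t))^2 + lam * int f''(t)^2 dt.
    """
    import pandas as pd

    if not isinstance(fc, pd.DataFrame):
        raise TypeError("fc must be a DataFrame of genes x timepoints")
    times = np.array([_parse_time(c) for c in fc.columns], dtype=float)
    if not np.allclose(times, np.asarray(basis.knots)):
        raise ValueError("fold-change timepoints must equal basis knots")
    Y = fc.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing/non-finite fold changes; impute upstream")
    B = basis.basis_matrix(times)
    # knots at data points give n_basis = n + 2 > n: the roughness
    # penalty makes the normal equations positive definite for lam > 0;
    # at lam = 0 the problem is underdetermined and we take the
    # minimum-norm interpolant instead
    if basis.lam > 0:
        # augmented least squares ||y-Bc||^2 + lam||Rc||^2, P = R'R:
        # better conditioned than the normal equations when n_basis > n
        P = gram_matrix(basis, deriv_order=2)
        w, V = np.linalg.eigh(P)
        R = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
        A = np.vstack([B, np.sqrt(basis.lam) * R])
        rhs = np.vstack([Y.T, np.zeros((R.shape[0], Y.shape[0]))])
        coef = np.linalg.lstsq(A, rhs, rcond=None)[0].T
    else:
        coef = np.linalg.lstsq(B, Y.T, rcond=None)[0].T
    return CurveSet(list(map(str, fc.index)), coef, basis)


def _parse_time(col) -> float:
    if isinstance(col, str) and col.startswith("t"):
        return float(col[1:])
    return float(col)


def evaluate(curve: Curve, times, deriv_order: int = 0) -> np.ndarray:
    if deriv_order not in (0, 1, 2):
        raise ValueError("deriv_order must be 0, 1 or 2")
    B = curve.basis.basis_matrix(times, deriv_order)
    return B @ curve.coefficients


def inner_product(f: Curve, g: Curve, deriv_order: int = 1, window=None
                  ) -> float:
    """L2 inner product of derivative curves over a time window."""
    if f.basis != g.basis:
        raise ValueError("curves must share a basis")
    G = _gram(f.basis, deriv_order, window)
    return float(f.coefficients @ G @ g.coefficients)


def _gram(spec: BasisSpec, deriv_order: int, window) -> np.ndarray:
    win = None if window is None else (float(window[0]), float(window[1]))
    return _cached_gram(spec, deriv_order, win)


def rms_scale(curves: CurveSet, window=None) -> CurveSet:
    """Scale every curve to unit root-mean-square over the window.

    Curves with (numerically) zero RMS are excluded with a warning, as they
    carry no shape information.
    """
    import warnings

    spec = curves.basis
    lo = spec.t_min if window is None else float(window[0])
    hi = spec.t_max if window is None else float(window[1])
    G0 = _gram(spec, 0, None if window is None else (lo, hi))
    sq = np.einsum("ij,jk,ik->i", curves.coefficients, G0,
                   curves.coefficients)
    rms = np.sqrt(np.maximum(sq, 0.0) / (hi - lo))
    keep = rms > 1e-12
    if not np.all(keep):
        dropped = [g for g, k in zip(curves.gene_ids, keep) if not k]
        warnings.warn(f"excluding {len(dropped)} zero-RMS curves "
                      f"(e.g. {dropped[:3]})")
    ids = [g for g, k in zip(curves.gene_ids, keep) if k]
    coef = curves.coefficients[keep] / rms[keep, None]
    return CurveSet(ids, coef, spec)


# ---------------------------------------------------------------------------
# Functional PCA
# ---------------------------------------------------------------------------

@dataclass
class FPCAResult:
    """Eigen-decomposition of the sample covariance operator.

    `harmonics` holds eigenfunction basis coefficients (one row per
    harmonic), orthonormal under the L2 inner product on the full knot
    range.  `variance_fractions` are each harmonic's share of total
    functional variance, sorted descending.  `scores[i, j]` is the L2
    projection of (curve_i - mean) on harmonic_j.
    """

    mean: Curve
    harmonics: np.ndarray
    variance_fractions: np.ndarray
    scores: np.ndarray
    basis: BasisSpec = field(repr=False)

    def harmonic(self, j: int) -> Curve:
        return Curve(self.harmonics[j], self.basis)

    def excursion(self, j: int, sign: float = 1.0, scale: float | None = None
                  ) -> Curve:
        """'mean +/- harmonic' display curve; default scale = sd of scores."""
        if scale is None:
            scale = float(np.std(self.scores[:, j]))
        return Curve(self.mean.coefficients
                     + sign * scale * self.harmonics[j], self.basis)


def fpca(curves: CurveSet, n_harmonics: int = 2) -> FPCAResult:
    """Functional PCA on the basis-coefficient representation.

    With Gram matrix G = L L^T, the covariance-operator eigenproblem
    reduces to an ordinary symmetric eigenproblem on L^T S L where S is
    the coefficient covariance; eigenvectors map back through L^{-T} to
    harmonic coefficients orthonormal in L2.
    """
    import warnings

    n = len(curves)
    if n < 2:
        raise ValueError("need at least 2 curves")
    G = _gram(curves.basis, 0, None)
    L = np.linalg.cholesky(G + 1e-12 * np.eye(G.shape[0]))
    C = curves.coefficients
    mean_c = C.mean(axis=0)
    X = C - mean_c
    S = X.T @ X / (n - 1)
    M = L.T @ S @ L
    evals, evecs = np.linalg.eigh(M)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.maximum(evals, 0.0)
    total = float(evals.sum())
    rank = int(np.sum(evals > max(total, 1e-300) * 1e-10))
    if total <= 0 or rank == 0:
        warnings.warn("zero total variance: all curves identical; "
                      "returning mean only")
        return FPCAResult(Curve(mean_c, curves.basis),
                          np.empty((0, G.shape[0])), np.empty(0),
                          np.empty((n, 0)), curves.basis)
    if n_harmonics > rank:
        warnings.warn(f"n_harmonics={n_harmonics} exceeds rank {rank}; "
                      "truncating")
        n_harmonics = rank
    U = evecs[:, :n_harmonics]
    H = np.linalg.solve(L.T, U).T            # harmonic basis coefficients
    scores = X @ G @ H.T
    return FPCAResult(Curve(mean_c, curves.basis), H,
                      evals[:n_harmonics] / total, scores, curves.basis)


# ---------------------------------------------------------------------------
# Similarity primitive shared by classification and clustering
# ---------------------------------------------------------------------------

def cosine_similarity(a: CurveSet, b: CurveSet | None = None,
                      deriv_order: int = 1, window=None) -> np.ndarray:
    """Cosine-normalized derivative inner-product similarity matrix.

    S[i, j] = <a_i^(d), b_j^(d)> / sqrt(<a_i,a_i><b_j,b_j>) over the
    window, in [-1, 1].  Rows/columns with zero derivative norm raise, as
    similarity is undefined for flat curves.
    """
    if b is None:
        b = a
    if a.basis != b.basis:
        raise ValueError("curve sets must share a basis")
    G = _gram(a.basis, deriv_order, window)
    raw = a.coefficients @ G @ b.coefficients.T
    na = np.sqrt(np.maximum(np.einsum(
        "ij,jk,ik->i", a.coefficients, G, a.coefficients), 0.0))
    nb = np.sqrt(np.maximum(np.einsum(
        "ij,jk,ik->i", b.coefficients, G, b.coefficients), 0.0))
    bad_a = np.nonzero(na <= 0)[0]
    bad_b = np.nonzero(nb <= 0)[0]
    if len(bad_a) or len(bad_b):
        names = ([a.gene_ids[i] for i in bad_a[:3]]
                 + [b.gene_ids[i] for i in bad_b[:3]])
        raise ValueError(f"zero derivative norm on window for genes {names}")
    S = raw / np.outer(na, nb)
    return np.clip(S, -1.0, 1.0)
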