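"""Hyperbolic geometry primitives: Lorentz, Poincaré-ball and Klein models.

The three models describe the same space of constant negative curvature
``-1/beta``:

* the **Lorentz (hyperboloid) model** lives on the sheet
  ``<x, x>_L = -beta, x0 > 0`` of a ``d+1``-dimensional ambient space and is
  the numerically preferred model for optimization;
* the **Poincaré ball** is the open unit ball; distances blow up towards the
  boundary, which is what makes it a natural canvas for trees;
* the **Klein model** is the ball model in which hyperbolic averages (the
  Einstein midpoint) are ordinary weighted Euclidean means.

All functions are vectorized over leading axes and operate in float64.
Points are plain ``numpy`` arrays: shape ``(..., d+1)`` for Lorentz points,
``(..., d)`` for ball-model points.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEFAULT_BETA",
    "lorentz_inner",
    "check_on_manifold",
    "squared_lorentz_distance",
    "poincare_distance",
    "lorentz_to_poincare",
    "poincare_to_lorentz",
    "lorentz_origin",
    "exp_map_origin",
    "clip_norm",
    "poincare_to_klein",
    "klein_to_poincare",
    "klein_convert",
    "einstein_midpoint",
    "mobius_add",
    "mobius_translate",
]

DEFAULT_BETA = 1.0

# Boundary guards: arccosh arguments are clamped to >= 1 + _ACOSH_EPS and
# conformal-factor denominators (1 - ||p||^2) to >= _DENOM_EPS, so that points
# arising from norm clipping at alpha ~ 1 stay representable.
_ACOSH_EPS = 1e-15
_DENOM_EPS = 1e-15
_MANIFOLD_TOL = 1e-6


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coordinates")
    return a


def lorentz_inner(x, y) -> np.ndarray:
    """Lorentzian (Minkowski) inner product ``-x0*y0 + sum_i>=1 xi*yi``.

    Broadcasts over leading axes; the last axis is the ambient dimension.
    """
    x, y = _as_array(x), _as_array(y)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError(
            f"ambient dimension mismatch: {x.shape[-1]} vs {y.shape[-1]}"
        )
    if x.shape[-1] < 2:
        raise ValueError("Lorentz ambient dimension must be >= 2")
    return np.sum(x * y, axis=-1) - 2.0 * x[..., 0] * y[..., 0]


def check_on_manifold(x, beta: float = DEFAULT_BETA, tol: float = _MANIFOLD_TOL) -> None:
    """Raise if ``x`` is not on the hyperboloid ``<x,x>_L = -beta, x0 > 0``."""
    x = _as_array(x)
    if beta <= 0:
        raise ValueError("beta must be positive")
    dev = np.abs(lorentz_inner(x, x) + beta)
    if np.any(dev > tol):
        raise ValueError(
            f"point off the Lorentz manifold: |<x,x>_L + beta| up to {float(np.max(dev)):.3g}"
        )
    if np.any(x[..., 0] <= 0):
        raise ValueError("Lorentz point must have x0 > 0 (upper sheet)")


def squared_lorentz_distance(x, y, beta: float = DEFAULT_BETA, *, validate: bool = True) -> np.ndarray:
    """Squared Lorentzian distance ``-2*beta - 2*<x,y>_L``.

    Satisfies every metric axiom except the triangle inequality. With
    ``validate`` the inputs are checked to lie on the hyperboloid for the
    given curvature.
    """
    if validate:
        check_on_manifold(x, beta)
        check_on_manifold(y, beta)
    d2 = -2.0 * beta - 2.0 * lorentz_inner(x, y)
    return np.maximum(d2, 0.0)


def _ball_check(p, what: str = "point") -> np.ndarray:
    p = _as_array(p)
    if np.any(np.sum(p * p, axis=-1) >= 1.0):
        raise ValueError(f"{what} outside the open unit ball")
    return p


def poincare_distance(p, q) -> np.ndarray:
    """Poincaré distance ``arccosh(1 + 2||p-q||^2 / ((1-||p||^2)(1-||q||^2)))``."""
    p, q = _ball_check(p), _ball_check(q)
    sq = np.sum((p - q) ** 2, axis=-1)
    den = (1.0 - np.sum(p * p, axis=-1)) * (1.0 - np.sum(q * q, axis=-1))
    arg = 1.0 + 2.0 * sq / np.maximum(den, _DENOM_EPS)
    return np.arccosh(np.maximum(arg, 1.0))


def lorentz_to_poincare(x) -> np.ndarray:
    """Map hyperboloid -> ball: ``(x1..xd) / (x0 + 1)`` (beta = 1 chart)."""
    x = _as_array(x)
    x0 = x[..., :1]
    if np.any(x0 <= -1.0):
        raise ValueError("x0 <= -1: not on the upper hyperboloid sheet")
    return x[..., 1:] / (x0 + 1.0)


def poincare_to_lorentz(p, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Inverse chart ball -> hyperboloid.

    For beta = 1: ``x0 = (1+||p||^2)/(1-||p||^2)``, ``xi = 2 pi/(1-||p||^2)``;
    general beta rescales by ``sqrt(beta)``.
    """
    p = _ball_check(p)
    sq = np.sum(p * p, axis=-1, keepdims=True)
    den = np.maximum(1.0 - sq, _DENOM_EPS)
    x0 = (1.0 + sq) / den
    rest = 2.0 * p / den
    return np.sqrt(beta) * np.concatenate([x0, rest], axis=-1)


def lorentz_origin(d: int, beta: float = DEFAULT_BETA) -> np.ndarray:
    """The hyperboloid basepoint ``(sqrt(beta), 0, ..., 0)`` in ``R^{d+1}``."""
    x = np.zeros(d + 1)
    x[0] = np.sqrt(beta)
    return x


def exp_map_origin(v, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Exponential map at the hyperboloid origin.

    ``v`` is a Euclidean vector of length ``d`` (e.g. an encoder output),
    lifted canonically to the tangent vector ``(0, v)`` at the origin, for
    which the Lorentz norm equals the Euclidean norm ``r = ||v||``. The image

        ``( sqrt(beta) cosh(r / sqrt(beta)),
            sqrt(beta) sinh(r / sqrt(beta)) v / r )``

    lies on ``<x,x>_L = -beta``; ``v = 0`` maps to the origin.
    """
    v = _as_array(v)
    if beta <= 0:
        raise ValueError("beta must be positive")
    sb = np.sqrt(beta)
    r = np.linalg.norm(v, axis=-1, keepdims=True)
    # sinh(r)/r -> 1 as r -> 0; guard the division, not the limit value
    safe = np.where(r > 0, r, 1.0)
    x0 = sb * np.cosh(r[..., 0] / sb)
    rest = sb * np.sinh(r / sb) / safe * v
    return np.concatenate([x0[..., None], rest], axis=-1)


def clip_norm(v, alpha: float) -> np.ndarray:
    """Rescale ``v`` onto the sphere of radius ``alpha`` if its norm exceeds it.

    Direction is preserved; vectors already inside the threshold pass through
    unchanged. Applied to latent embeddings before the exponential map, this
    keeps training numerically stable.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    v = _as_array(v)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    scale = np.minimum(1.0, alpha / np.maximum(n, _DENOM_EPS))
    return v * scale


def poincare_to_klein(p) -> np.ndarray:
    """Ball -> Klein coordinates: ``k = 2p / (1 + ||p||^2)``."""
    p = _ball_check(p)
    return 2.0 * p / (1.0 + np.sum(p * p, axis=-1, keepdims=True))


def klein_to_poincare(k) -> np.ndarray:
    """Klein -> ball coordinates: ``p = k / (1 + sqrt(1 - ||k||^2))``."""
    k = _ball_check(k, "Klein point")
    sq = np.sum(k * k, axis=-1, keepdims=True)
    return k / (1.0 + np.sqrt(np.maximum(1.0 - sq, 0.0)))


def klein_convert(p, direction: str) -> np.ndarray:
    """Convert between the Poincaré and Klein ball models.

    ``direction`` is ``"poincare_to_klein"`` or ``"klein_to_poincare"``.
    """
    if direction == "poincare_to_klein":
        return poincare_to_klein(p)
    if direction == "klein_to_poincare":
        return klein_to_poincare(p)
    raise ValueError(f"unknown direction {direction!r}")


def einstein_midpoint(points) -> np.ndarray:
    """Hyperbolic average of Poincaré-ball points.

    Converts to Klein coordinates, takes the Lorentz-factor-weighted mean
    ``sum_i gamma_i k_i / sum_i gamma_i`` with ``gamma_i = 1/sqrt(1-||k_i||^2)``,
    and converts back. Permutation-invariant; the midpoint of a single point
    is the point itself.
    """
    pts = np.atleast_2d(_as_array(points))
    if pts.shape[0] == 0:
        raise ValueError("einstein_midpoint of an empty set")
    k = poincare_to_klein(pts)
    gamma = 1.0 / np.sqrt(np.maximum(1.0 - np.sum(k * k, axis=-1), _DENOM_EPS))
    mid_k = (gamma[:, None] * k).sum(axis=0) / gamma.sum()
    return klein_to_poincare(mid_k)


def mobius_add(a, x) -> np.ndarray:
    """Möbius (gyrovector) addition ``a (+) x`` in the Poincaré ball."""
    a, x = _ball_check(a), _ball_check(x)
    ax = np.sum(a * x, axis=-1, keepdims=True)
    na2 = np.sum(a * a, axis=-1, keepdims=True)
    nx2 = np.sum(x * x, axis=-1, keepdims=True)
    num = (1.0 + 2.0 * ax + nx2) * a + (1.0 - na2) * x
    den = 1.0 + 2.0 * ax + na2 * nx2
    return num / np.maximum(den, _DENOM_EPS)


def mobius_translate(points, new_origin) -> np.ndarray:
    """Translate the ball so that ``new_origin`` lands on the center.

    Applies ``x -> (-a) (+) x`` with ``a = new_origin`` to every point. The
    map is a hyperbolic isometry: all pairwise Poincaré distances are
    preserved, while Euclidean resolution is amplified around the new center
    ("zoom in").
    """
    pts = np.atleast_2d(_as_array(points))
    a = -_ball_check(new_origin)
    out = mobius_add(a[None, :], pts)
    return out if np.ndim(points) > 1 else out[0]
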