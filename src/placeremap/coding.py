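"""Angular latent codes for environmental variables.

Position and cognitive variables live in ``[-1, 1]`` and are represented
internally on circles: each scalar variable ``x`` maps to an angle
``alpha = pi * (x + 1)`` and then to the unit-circle point
``(cos alpha, sin alpha)``.  A multi-module ("grid") variant encodes each
position variable with ``m`` modules whose angular frequencies are scaled by
powers of 3/2, mimicking the discrete spatial-scale ratios of entorhinal grid
modules.  Decoding inverts the first (frequency-exponent 0) module only, which
is a bijection of ``[-1, 1)`` onto the circle.

Conventions
-----------
* Positions are arrays of shape ``(P,)`` (a single point) or ``(G, P)``
  (a grid of G points, one row per point).
* Latent vectors are arrays of shape ``(Z,)`` or ``(Z, G)`` — one column per
  point, matching the columns-are-points layout of rate maps.
* For multi-module codes the latent blocks are grouped by position variable,
  then module: ``z = (cos a_{1,1}, sin a_{1,1}, ..., cos a_{1,m}, sin a_{1,m},
  cos a_{2,1}, ...)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DomainError",
    "DegenerateInputError",
    "encode_angles",
    "decode_angles",
    "encode_grid",
    "decode_grid",
    "normalize_blocks",
    "default_frequency_exponents",
    "position_grid",
]


class DomainError(ValueError):
    """An environmental variable lies outside its admissible range."""


class DegenerateInputError(ValueError):
    """A latent (cos, sin) pair has zero norm and carries no angle."""


GRID_FREQUENCY_BASE = 3.0 / 2.0


def default_frequency_exponents(m: int) -> np.ndarray:
    """Default module frequency exponents: f = (0, 1, -1, 2, -2, ...).

    The first module always has exponent 0 (unit frequency) so that position
    can be decoded from it alone.
    """
    if m < 1:
        raise ValueError(f"module count must be >= 1, got {m}")
    f = [0]
    k = 1
    while len(f) < m:
        f.append(k)
        if len(f) < m:
            f.append(-k)
        k += 1
    return np.asarray(f, dtype=int)


def position_grid(resolution: int, P: int) -> np.ndarray:
    """Equally spaced half-open grid on ``[-1, 1)^P``, shape (G, P).

    The endpoint +1 is excluded: +1 and -1 encode to the same latent point,
    so the grid covers each circle exactly once.
    """
    axis = np.linspace(-1.0, 1.0, resolution, endpoint=False)
    if P == 0:
        return np.zeros((resolution, 0))
    if P == 1:
        return axis[:, None]
    mesh = np.meshgrid(*([axis] * P), indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def _as_points(p: np.ndarray) -> tuple[np.ndarray, bool]:
    """Coerce a position argument to shape (G, P); flag whether it was 1-d."""
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        return p[None, :], True
    if p.ndim == 2:
        return p, False
    raise ValueError(f"positions must be 1-d or 2-d, got shape {p.shape}")


def _check_range(p: np.ndarray) -> None:
    bad = np.argwhere((p < -1.0) | (p > 1.0))
    if bad.size:
        i = tuple(bad[0])
        raise DomainError(
            f"position component {i} = {p[i]:g} outside [-1, 1]"
        )


def encode_angles(p: np.ndarray) -> np.ndarray:
    """Single-module angular encoding of variables in ``[-1, 1]``.

    Each component ``p_i`` maps to ``alpha_i = pi (p_i + 1)`` and the latent
    pair ``(cos alpha_i, sin alpha_i)``.  Returns shape ``(2P,)`` or
    ``(2P, G)``.
    """
    pts, single = _as_points(p)
    _check_range(pts)
    alpha = np.pi * (pts + 1.0)  # (G, P)
    G, P = pts.shape
    z = np.empty((2 * P, G))
    z[0::2, :] = np.cos(alpha).T
    z[1::2, :] = np.sin(alpha).T
    return z[:, 0] if single else z


def decode_angles(z: np.ndarray) -> np.ndarray:
    """Invert :func:`encode_angles`; returns positions in ``[-1, 1)``.

    Each (cos, sin) pair is normalized and converted to an angle in
    ``[0, 2*pi)`` via atan2 (negative branch shifted up by ``2*pi``), then to
    ``p = alpha/pi - 1``.  The seam ``p = +1`` is canonicalized to ``-1``.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    zz = z[:, None] if single else z
    if zz.shape[0] % 2:
        raise ValueError("latent dimension must be even (cos, sin pairs)")
    cos = zz[0::2, :]
    sin = zz[1::2, :]
    norm = np.hypot(cos, sin)
    if np.any(norm == 0.0):
        i = tuple(np.argwhere(norm == 0.0)[0])
        raise DegenerateInputError(f"latent pair {i} has zero norm")
    alpha = np.arctan2(sin, cos)
    alpha = np.where(alpha < 0.0, alpha + 2.0 * np.pi, alpha)
    p = alpha / np.pi - 1.0
    p = np.where(p >= 1.0, p - 2.0, p)  # canonicalize the seam to -1
    p = p.T  # (G, P)
    return p[0] if single else p


def encode_grid(p: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Multi-module (grid) angular encoding.

    Module ``j`` encodes component ``p_i`` at angle
    ``alpha_{i,j} = (3/2)**f_j * pi * (p_i + 1)``; modules with ``f_j != 0``
    wrap the interval a non-integer number of times around the circle.
    Requires ``f[0] == 0`` so the first module remains a bijection and can be
    used for decoding.  Returns shape ``(2 m P,)`` or ``(2 m P, G)``.
    """
    f = np.asarray(f, dtype=int)
    if f.ndim != 1 or f.size < 1:
        raise ValueError("f must be a non-empty 1-d integer array")
    if f[0] != 0:
        raise ValueError(
            f"first module frequency exponent must be 0 (got f[0] = {f[0]}); "
            "decoding reads position from module 1 only"
        )
    pts, single = _as_points(p)
    _check_range(pts)
    G, P = pts.shape
    m = f.size
    scale = GRID_FREQUENCY_BASE ** f.astype(float)  # (m,)
    # alpha[g, i, j] = scale_j * pi * (p_{g,i} + 1)
    alpha = scale[None, None, :] * (np.pi * (pts + 1.0))[:, :, None]
    z = np.empty((2 * m * P, G))
    z[0::2, :] = np.cos(alpha).reshape(G, m * P).T
    z[1::2, :] = np.sin(alpha).reshape(G, m * P).T
    return z[:, 0] if single else z


def decode_grid(z: np.ndarray, m: int) -> np.ndarray:
    """Decode position from an m-module code using module 1 only.

    The restriction ``f_1 = 0`` makes the first module a proxy for position
    itself; the remaining modules are ignored.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    zz = z[:, None] if single else z
    if zz.shape[0] % (2 * m):
        raise ValueError(
            f"latent dimension {zz.shape[0]} incompatible with {m} modules"
        )
    P = zz.shape[0] // (2 * m)
    # pairs are grouped (variable, module); take module 0 of each variable
    idx = np.arange(P) * 2 * m
    first = np.empty((2 * P, zz.shape[1]))
    first[0::2, :] = zz[idx, :]
    first[1::2, :] = zz[idx + 1, :]
    p = decode_angles(first)
    return p[0] if single else p


def normalize_blocks(
    z: np.ndarray,
    zp_dim: int,
    rescale_dim: int | None = None,
    rescale_cutoff: int = 4,
) -> np.ndarray:
    """Normalize the positional / cognitive blocks of a latent vector.

    With both blocks present (``0 < zp_dim < Z``) each block is scaled to
    norm ``1/sqrt(2)`` so the full vector has unit norm; with a single block
    it is scaled to norm 1.  If ``rescale_dim`` (the embedding dimensionality
    Y) is given and exceeds ``rescale_cutoff``, the whole vector is then
    multiplied by ``Y``, keeping the signal strong relative to the fixed
    thresholds as Y grows so autoencoding stays accurate.

    Operates columnwise on ``(Z, G)`` input.
    """
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    zz = z[:, None].copy() if single else z.copy()
    Z = zz.shape[0]
    if not 0 <= zp_dim <= Z:
        raise ValueError(f"zp_dim = {zp_dim} outside [0, {Z}]")
    blocks = [(0, zp_dim), (zp_dim, Z)]
    blocks = [(a, b) for a, b in blocks if b > a]
    target = 1.0 if len(blocks) == 1 else 1.0 / np.sqrt(2.0)
    for a, b in blocks:
        norms = np.linalg.norm(zz[a:b, :], axis=0)
        if np.any(norms == 0.0):
            raise DegenerateInputError(
                f"latent block [{a}:{b}] has zero norm and cannot be normalized"
            )
        zz[a:b, :] *= target / norms
    if rescale_dim is not None and rescale_dim > rescale_cutoff:
        zz *= float(rescale_dim)
    return zz[:, 0] if single else zz
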