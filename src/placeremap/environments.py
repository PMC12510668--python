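"""Per-environment inputs: cognitive trajectories and embedding maps.

An *environment* is defined by (i) a cognitive-variable trajectory ``c(p)``
over the position grid and (ii) a linear embedding map ``R`` that carries the
latent vector into the embedding space read out by the network.  Three map
families are supported:

* ``multi_chart`` — a Haar-random matrix with orthonormal columns
  (environments share a common Y-dimensional embedding subspace but use
  random charts within it);
* ``grid_shift`` — block-diagonal 2x2 rotations, one per (position variable,
  grid module), modelling grid-module phase realignment;
* ``identity`` — the trivial map, used for mixed-selective scenarios where
  remapping is carried entirely by the cognitive trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky

__all__ = [
    "CognitiveProcessConfig",
    "RewardProfileConfig",
    "EmbeddingMap",
    "sample_cognitive_trajectory",
    "reward_profile",
    "sample_multichart_map",
    "sample_gridshift_map",
    "build_embedding",
    "wrap_unit",
]

_GP_JITTER = 1e-8


@dataclass(frozen=True)
class CognitiveProcessConfig:
    """Random process generating cognitive variables over the grid.

    Parameters
    ----------
    sigma : float in [0, 1]
        Single variance parameter: the per-environment constant offset is
        drawn N(0, sigma^2) (Uniform[-1, 1] at sigma = 1) and the GP
        fluctuation has marginal standard deviation sigma.
    v : float > 0
        Squared-exponential length scale, in normalized position units.
    C : int
        Number of (i.i.d.) cognitive variables.
    """

    sigma: float
    v: float = 0.3
    C: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")
        if self.v <= 0:
            raise ValueError(f"length scale v must be positive, got {self.v}")
        if self.C < 0:
            raise ValueError(f"C must be nonnegative, got {self.C}")


@dataclass(frozen=True)
class RewardProfileConfig:
    """Deterministic reward-shaped cognitive variable.

    ``c(p) = exp(-(p - mu)^2 / (2 sigma_r^2)) - 1`` peaks at 0 at the reward
    location ``mu`` and decays to -1 far from it.
    """

    mu: float
    sigma_r: float = 0.2

    def __post_init__(self) -> None:
        if not -1.0 <= self.mu <= 1.0:
            raise ValueError(f"reward location mu must lie in [-1, 1], got {self.mu}")
        if self.sigma_r <= 0:
            raise ValueError(f"sigma_r must be positive, got {self.sigma_r}")


@dataclass
class EmbeddingMap:
    """Environment-specific linear map from latent to embedding space."""

    R: np.ndarray
    kind: str  # multi_chart | grid_shift | identity
    environment_id: str = ""
    phase_shifts: np.ndarray | None = field(default=None, repr=False)

    @property
    def Y(self) -> int:
        return self.R.shape[0]

    @property
    def Z(self) -> int:
        return self.R.shape[1]

    @classmethod
    def identity(cls, Z: int, environment_id: str = "") -> "EmbeddingMap":
        return cls(R=np.eye(Z), kind="identity", environment_id=environment_id)


def wrap_unit(c: np.ndarray) -> np.ndarray:
    """Wrap values onto the half-open interval [-1, 1) (circle topology)."""
    return np.mod(np.asarray(c, dtype=float) + 1.0, 2.0) - 1.0


def sample_cognitive_trajectory(
    grid: np.ndarray,
    cfg: CognitiveProcessConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample cognitive variables ``c(p)`` over the position grid.

    Each of the ``C`` components is an independent draw of
    ``wrap(k + g(p))`` with constant offset ``k`` (N(0, sigma^2), or
    Uniform[-1,1] at sigma = 1) and ``g ~ GP(0, K)`` for a squared-exponential
    kernel ``K(x, x') = sigma^2 exp(-||x - x'||^2 / (2 v^2))``.  Values wrap
    onto [-1, 1), matching the circular latent geometry.

    Returns shape ``(C, G)``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] == 0:
        raise ValueError("grid must be a nonempty (G, P) array")
    G = grid.shape[0]
    C = cfg.C
    if C == 0:
        return np.zeros((0, G))
    if cfg.sigma == 0.0:
        return np.zeros((C, G))  # N(0,0) and a zero-amplitude GP

    if cfg.sigma == 1.0:
        k = rng.uniform(-1.0, 1.0, size=C)
    else:
        k = rng.normal(0.0, cfg.sigma, size=C)

    if grid.shape[1] == 0:
        # positions carry no coordinates: the GP is constant over the grid
        g = np.broadcast_to(rng.normal(0.0, cfg.sigma, size=(C, 1)), (C, G))
    else:
        d2 = np.sum(
            (grid[:, None, :] - grid[None, :, :]) ** 2, axis=-1
        )  # (G, G)
        K = cfg.sigma**2 * np.exp(-d2 / (2.0 * cfg.v**2))
        K[np.diag_indices(G)] += _GP_JITTER
        L = cholesky(K, lower=True)
        g = (L @ rng.standard_normal((G, C))).T  # (C, G)
    return wrap_unit(k[:, None] + g)


def reward_profile(grid: np.ndarray, cfg: RewardProfileConfig) -> np.ndarray:
    """Reward-shaped cognitive variable over a 1-d position grid, shape (1, G)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] == 0:
        raise ValueError("grid must be a nonempty (G, P) array")
    if grid.shape[1] != 1:
        raise ValueError("reward profile is defined for 1-d position")
    p = grid[:, 0]
    c = np.exp(-((p - cfg.mu) ** 2) / (2.0 * cfg.sigma_r**2)) - 1.0
    return c[None, :]


def sample_multichart_map(
    Y: int,
    Z: int,
    rng: np.random.Generator,
    environment_id: str = "",
) -> EmbeddingMap:
    """Haar-random Y x Z matrix with orthonormal columns.

    Implemented as the QR factorization of a standard-Gaussian matrix with
    columns sign-corrected by the sign of the R-factor diagonal, which makes
    the column subspace (and the matrix itself) uniformly distributed.
    """
    if Z > Y:
        raise ValueError(f"need Z <= Y for orthonormal columns, got Z={Z} > Y={Y}")
    A = rng.standard_normal((Y, Z))
    Q, Rfac = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(Rfac))[None, :]
    return EmbeddingMap(R=Q, kind="multi_chart", environment_id=environment_id)


def sample_gridshift_map(
    m: int,
    P: int,
    rng: np.random.Generator,
    environment_id: str = "",
) -> EmbeddingMap:
    """Block-diagonal phase-shift map for grid realignment; Y = Z = 2 m P.

    Each (position variable, module) pair gets an independent 2x2 rotation
    by a phase drawn Uniform[0, 2*pi); acting on a grid code this advances
    that module's angle by its phase shift.
    """
    n_blocks = m * P
    dalpha = rng.uniform(0.0, 2.0 * np.pi, size=n_blocks)
    R = np.zeros((2 * n_blocks, 2 * n_blocks))
    c, s = np.cos(dalpha), np.sin(dalpha)
    for b in range(n_blocks):
        R[2 * b : 2 * b + 2, 2 * b : 2 * b + 2] = [[c[b], -s[b]], [s[b], c[b]]]
    return EmbeddingMap(
        R=R, kind="grid_shift", environment_id=environment_id, phase_shifts=dalpha
    )


def build_embedding(z: np.ndarray, emap: EmbeddingMap) -> np.ndarray:
    """Apply the environment map: ``y = R z`` (columnwise on (Z, G) input)."""
    z = np.asarray(z, dtype=float)
    if z.shape[0] != emap.Z:
        raise ValueError(
            f"latent dimension {z.shape[0]} does not match map Z = {emap.Z}"
        )
    if emap.kind == "identity":
        return z.copy()
    return emap.R @ z
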