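"""The autoencoder network: decoder sampling, thresholds, steady-state rates.

The network is a rate-level reduction of a spike-coding network (SCN): an
efficient autoencoder with competitive recurrent interactions ``-D^T D``.
Its steady-state firing rates at each input ``y`` solve the nonnegative
quadratic program

    r* = argmin_{r >= 0}  ||y - D r||^2 + 2 T^T r,

where ``D`` (Y x N) holds each neuron's decoding (tuning) vector as a column
and ``T > 0`` are thresholds acting as an L1 activity cost.  The solver below
is a Lawson–Hanson-style active-set method adapted to the linear cost term;
the returned solution carries a KKT certificate:

    g = 2 D^T (D r* - y) + 2 T  satisfies  g_i >= -tol  and  r*_i g_i <= tol.

Null-space remapping enters through the thresholds: raising a neuron's
threshold to ``T_suppr`` (default 10, ~10x the normal value) effectively
removes it from the map while the remaining neurons re-balance to keep the
decoded estimate ``D r`` nearly unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkModel",
    "RateMapSet",
    "ThresholdModulation",
    "SolverError",
    "sample_decoder",
    "default_thresholds",
    "modulate_thresholds",
    "solve_rates",
    "batch_solve",
    "pseudo_inverse_encoder",
    "decode_latents",
    "build_network",
]

RATE_CLAMP = 1e-9  # tiny negative / positive residues zeroed after the solve
CODES = ("M", "C", "CM", "pM", "identity")


class SolverError(RuntimeError):
    """The active-set solver failed to reach a KKT point."""


@dataclass
class NetworkModel:
    """Decoder weights, encoder (right pseudo-inverse) and thresholds."""

    D: np.ndarray  # (Y, N)
    E: np.ndarray  # (N, Y)
    T: np.ndarray  # (N,)
    code: str = "M"
    pure_P: int = 0
    pure_C: int = 0

    @property
    def Y(self) -> int:
        return self.D.shape[0]

    @property
    def N(self) -> int:
        return self.D.shape[1]


@dataclass
class RateMapSet:
    """Steady-state rate maps over a grid for one environment."""

    rates: np.ndarray  # (N, G), nonnegative
    decoded: np.ndarray  # (Y, G) = D @ rates
    null_component: np.ndarray  # (N, G) = rates - E @ decoded
    environment_id: str = ""


@dataclass(frozen=True)
class ThresholdModulation:
    """Record of a participation (excitability) modulation."""

    spar: float
    suppressed: np.ndarray = field(repr=False)
    T_suppr: float = 10.0


def sample_decoder(
    Y: int,
    N: int,
    code: str,
    rng: np.random.Generator,
    zp_dim: int | None = None,
    pure_P: int = 0,
    pure_C: int = 0,
) -> np.ndarray:
    """Sample decoder weights D (Y x N) under a normalization code.

    Codes
    -----
    M (mixed)
        Columns drawn uniformly on the unit sphere: ``||D_i|| = 1``.
    C (conjunctive)
        Every consecutive 2-row pair of every column is normalized to
        ``1/sqrt(Y/2)`` — each neuron is tuned with equal magnitude to every
        circular variable, and columns remain unit norm.
    CM (conjunctive-mixed)
        Positional rows (the first ``zp_dim``) are conjunctive within their
        block, cognitive rows are mixed; the two blocks are scaled to
        ``||D_i^P|| = ||D_i^C|| = 1/sqrt(2)`` so every neuron keeps a finite
        spatial preference regardless of the cognitive dimensionality.
    pM (pure and mixed)
        A hand-designed code: the first ``pure_P`` columns have a zero
        cognitive block, the next ``pure_C`` a zero positional block, the
        rest are mixed; all columns unit norm.  When a pure block is a single
        circle (two rows), the pure cells' preferred angles are evenly spaced
        starting at 0, guaranteeing coverage of the whole variable range
        (with four pure-cognitive cells one is tuned exactly to angle pi,
        the reward angle of the reward-coding task).
    identity
        ``D = Id_N`` (requires Y == N); the fully orthonormal full-dimensional
        case.
    """
    if code not in CODES:
        raise ValueError(f"unknown code {code!r}; expected one of {CODES}")
    if code == "identity":
        if Y != N:
            raise ValueError(f"identity code needs Y == N, got Y={Y}, N={N}")
        return np.eye(N)
    if N < Y:
        raise ValueError(f"need N >= Y, got N={N} < Y={Y}")

    A = rng.standard_normal((Y, N))

    if code == "M":
        return A / np.linalg.norm(A, axis=0, keepdims=True)

    if code == "C":
        if Y % 2:
            raise ValueError("conjunctive code needs even Y (circle pairs)")
        pair_norm = 1.0 / np.sqrt(Y / 2.0)
        for j in range(Y // 2):
            blk = A[2 * j : 2 * j + 2, :]
            blk *= pair_norm / np.linalg.norm(blk, axis=0, keepdims=True)
        return A

    if code == "CM":
        if zp_dim is None or not 0 < zp_dim < Y:
            raise ValueError("CM code needs 0 < zp_dim < Y (positional rows)")
        if zp_dim % 2:
            raise ValueError("zp_dim must be even (circle pairs)")
        blk_norm = 1.0 / np.sqrt(2.0)
        P_pairs = zp_dim // 2
        pair_norm = blk_norm / np.sqrt(P_pairs)
        for j in range(P_pairs):
            blk = A[2 * j : 2 * j + 2, :]
            blk *= pair_norm / np.linalg.norm(blk, axis=0, keepdims=True)
        cog = A[zp_dim:, :]
        cog *= blk_norm / np.linalg.norm(cog, axis=0, keepdims=True)
        return A

    # pM
    if zp_dim is None or not 0 < zp_dim < Y:
        raise ValueError("pM code needs 0 < zp_dim < Y (positional rows)")
    if pure_P + pure_C > N:
        raise ValueError(
            f"pure_P + pure_C = {pure_P + pure_C} exceeds N = {N}"
        )
    A[zp_dim:, :pure_P] = 0.0
    A[:zp_dim, pure_P : pure_P + pure_C] = 0.0
    if zp_dim == 2 and pure_P > 0:
        theta = 2.0 * np.pi * np.arange(pure_P) / pure_P
        A[0, :pure_P] = np.cos(theta)
        A[1, :pure_P] = np.sin(theta)
    if Y - zp_dim == 2 and pure_C > 0:
        theta = 2.0 * np.pi * np.arange(pure_C) / pure_C
        A[zp_dim, pure_P : pure_P + pure_C] = np.cos(theta)
        A[zp_dim + 1, pure_P : pure_P + pure_C] = np.sin(theta)
    return A / np.linalg.norm(A, axis=0, keepdims=True)


def default_thresholds(D: np.ndarray) -> np.ndarray:
    """Optimal SCN thresholds ``T_i = 1/2 ||D_i||^2`` (1/2 for unit columns)."""
    return 0.5 * np.sum(np.asarray(D, float) ** 2, axis=0)


def modulate_thresholds(
    T: np.ndarray,
    spar: float,
    rng: np.random.Generator,
    T_suppr: float = 10.0,
) -> tuple[np.ndarray, ThresholdModulation]:
    """Suppress a random subset of neurons by raising their thresholds.

    ``spar`` is the fraction of neurons left at normal excitability (the
    active fraction): ``round(N (1 - spar))`` uniformly chosen neurons get
    threshold ``T_suppr``.  ``spar = 1`` leaves T unchanged; ``spar = 0``
    silences the whole population.  The "default" map of the null-space
    remapping scenario uses ``spar = 0.5``.
    """
    if not 0.0 <= spar <= 1.0:
        raise ValueError(f"spar must lie in [0, 1], got {spar}")
    T = np.asarray(T, dtype=float)
    N = T.size
    n_suppr = int(round(N * (1.0 - spar)))
    suppressed = np.sort(rng.choice(N, size=n_suppr, replace=False))
    T_mod = T.copy()
    T_mod[suppressed] = T_suppr
    return T_mod, ThresholdModulation(spar=spar, suppressed=suppressed, T_suppr=T_suppr)


def _kkt_residuals(
    r: np.ndarray, y: np.ndarray, D: np.ndarray, T: np.ndarray
) -> tuple[float, float]:
    """(dual infeasibility, complementarity) of the nonnegative QP."""
    g = -2.0 * (D.T @ (y - D @ r) - T)
    return float(max(0.0, -np.min(g))), float(max(0.0, np.max(r * g)))


def _fista_fallback(
    y: np.ndarray,
    D: np.ndarray,
    T: np.ndarray,
    kkt_tol: float,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Projected accelerated gradient descent with a final support polish.

    Used only for the rare degenerate inputs on which the active-set
    iteration stalls (near-parallel decoder columns make the restricted
    normal equations numerically singular).  FISTA needs no linear solves,
    so degeneracy costs iterations rather than correctness; the polish step
    re-solves on the identified support for machine-precision output.
    """
    L = 2.0 * np.linalg.norm(D, 2) ** 2
    x = np.zeros(D.shape[1])
    z = x.copy()
    t = 1.0
    best = x
    for it in range(1, max_iter + 1):
        grad = 2.0 * (D.T @ (D @ z - y)) + 2.0 * T
        x_new = np.maximum(z - grad / L, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        if it % 250 == 0:
            polished = _polish_support(x, y, D, T, kkt_tol)
            if polished is not None:
                return polished
            dual, comp = _kkt_residuals(x, y, D, T)
            if dual <= kkt_tol and comp <= kkt_tol:
                return x
            best = x
    dual, comp = _kkt_residuals(best, y, D, T)
    raise SolverError(
        f"fallback solver did not converge: dual={dual:.3g}, comp={comp:.3g}"
    )


def _polish_support(
    x: np.ndarray, y: np.ndarray, D: np.ndarray, T: np.ndarray, kkt_tol: float
) -> np.ndarray | None:
    """Exact re-solve on the support suggested by an approximate solution."""
    supp = np.flatnonzero(x > 1e-8 * max(1.0, float(x.max(initial=0.0))))
    if supp.size == 0:
        r = np.zeros_like(x)
    else:
        Dp = D[:, supp]
        s, *_ = np.linalg.lstsq(Dp.T @ Dp, Dp.T @ y - T[supp], rcond=None)
        if np.any(s < 0):
            return None
        r = np.zeros_like(x)
        r[supp] = s
    dual, comp = _kkt_residuals(r, y, D, T)
    if dual <= kkt_tol and comp <= kkt_tol:
        return r
    return None


def solve_rates(
    y: np.ndarray,
    D: np.ndarray,
    T: np.ndarray,
    kkt_tol: float = 1e-6,
    max_outer: int | None = None,
) -> np.ndarray:
    """Steady-state rates: ``argmin_{r>=0} ||y - D r||^2 + 2 T^T r``.

    Lawson–Hanson active-set iteration adapted to the linear cost: the
    unconstrained restricted problem on the passive set solves
    ``D_P^T D_P s = D_P^T y - T_P``; a neuron enters the passive set while its
    (half, negated) KKT gradient ``w_i = (D^T (y - D r) - T)_i`` is positive,
    and leaves via the standard feasibility line search.  ``r = 0`` is always
    feasible, so the method cannot fail for feasibility reasons.

    Raises :class:`SolverError` with diagnostics if the iteration limit is hit
    or the final KKT residual exceeds ``kkt_tol``.
    """
    y = np.asarray(y, dtype=float).ravel()
    D = np.asarray(D, dtype=float)
    T = np.asarray(T, dtype=float).ravel()
    Y, N = D.shape
    if y.size != Y or T.size != N:
        raise ValueError(
            f"shape mismatch: y has {y.size} (need {Y}), T has {T.size} (need {N})"
        )
    if np.any(T <= 0):
        raise ValueError("thresholds must be strictly positive")

    r = np.zeros(N)
    passive = np.zeros(N, dtype=bool)
    w = D.T @ y - T
    # entry tolerance scaled to problem magnitude
    scale = max(1.0, float(np.linalg.norm(y)))
    enter_tol = 1e-10 * scale
    if max_outer is None:
        max_outer = 10 * (N + 10)

    for _ in range(max_outer):
        w_masked = np.where(passive, -np.inf, w)
        j = int(np.argmax(w_masked))
        if w_masked[j] <= enter_tol:
            break
        passive[j] = True
        # inner loop: restore feasibility on the passive set
        for _inner in range(max_outer):
            idx = np.flatnonzero(passive)
            Dp = D[:, idx]
            G = Dp.T @ Dp
            b = Dp.T @ y - T[idx]
            s, *_ = np.linalg.lstsq(G, b, rcond=None)
            resid = b - G @ s
            if np.max(np.abs(resid)) > 1e-9 * scale:
                # singular passive Gram with inconsistent normal equations:
                # the restricted objective descends along the null-space
                # direction d = resid (G d = 0, b.d = ||resid||^2 > 0); since
                # T > 0 some d_i < 0, so a component blocks the ray.
                d = resid
                rp = r[idx]
                blocking = d < 0
                tau = np.min(rp[blocking] / -d[blocking])
                rp = rp + tau * d
                hit_mask = blocking & (rp <= 1e-12)
                rp[hit_mask] = 0.0
                r[:] = 0.0
                r[idx] = np.maximum(rp, 0.0)
                drop = idx[hit_mask]
                if drop.size == 0:
                    drop = np.array([idx[int(np.argmin(d))]])
                    r[drop] = 0.0
                passive[drop] = False
                if not passive.any():
                    break
                continue
            if np.all(s > 0):
                r[:] = 0.0
                r[idx] = s
                break
            # step from r toward s until the first passive component hits zero
            rp = r[idx]
            neg = s <= 0
            denom = rp[neg] - s[neg]
            with np.errstate(divide="ignore", invalid="ignore"):
                alphas = np.where(denom > 0, rp[neg] / denom, 0.0)
            alpha = float(np.min(alphas)) if alphas.size else 0.0
            rp = rp + alpha * (s - rp)
            # only components attaining the minimum step leave the passive set
            hit = np.flatnonzero(neg)[alphas <= alpha]
            rp[hit] = 0.0
            r[:] = 0.0
            r[idx] = np.maximum(rp, 0.0)
            drop = idx[hit]
            if drop.size == 0:
                # numerical stall: force out the most negative direction
                drop = np.array([idx[int(np.argmin(s))]])
                r[drop] = 0.0
            passive[drop] = False
            if not passive.any():
                break
        w = D.T @ (y - D @ r) - T
    else:
        # degenerate instance (near-parallel columns): hand off to the
        # first-order fallback, which trades speed for unconditional progress
        r = _fista_fallback(y, D, T, kkt_tol)

    r[np.abs(r) < RATE_CLAMP] = 0.0
    r = np.maximum(r, 0.0)
    dual, comp = _kkt_residuals(r, y, D, T)
    if dual > kkt_tol or comp > kkt_tol:
        r = _fista_fallback(y, D, T, kkt_tol)
        r[np.abs(r) < RATE_CLAMP] = 0.0
        dual, comp = _kkt_residuals(r, y, D, T)
        if dual > kkt_tol or comp > kkt_tol:
            raise SolverError(
                f"KKT certificate failed: dual={dual:.3g}, comp={comp:.3g}, "
                f"tol={kkt_tol} (N={N}, Y={Y})"
            )
    return r


def batch_solve(
    Ys: np.ndarray,
    D: np.ndarray,
    T: np.ndarray,
    E: np.ndarray | None = None,
    environment_id: str = "",
) -> RateMapSet:
    """Solve the steady-state problem at every grid point (column of Ys)."""
    Ys = np.asarray(Ys, dtype=float)
    D = np.asarray(D, dtype=float)
    if E is None:
        E = pseudo_inverse_encoder(D)
    G = Ys.shape[1]
    N = D.shape[1]
    rates = np.empty((N, G))
    for g in range(G):
        try:
            rates[:, g] = solve_rates(Ys[:, g], D, T)
        except SolverError as exc:
            raise SolverError(f"grid point {g}: {exc}") from exc
    decoded = D @ rates
    null_component = rates - E @ decoded
    return RateMapSet(
        rates=rates,
        decoded=decoded,
        null_component=null_component,
        environment_id=environment_id,
    )


def pseudo_inverse_encoder(D: np.ndarray) -> np.ndarray:
    """Right pseudo-inverse ``E = D^T (D D^T)^{-1}``; satisfies D E = Id_Y."""
    D = np.asarray(D, dtype=float)
    gram = D @ D.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"decoder is (numerically) row rank-deficient: cond(DD^T) = {cond:.3g}"
        )
    return np.linalg.solve(gram, D).T


def decode_latents(
    rates: np.ndarray, D: np.ndarray, R: np.ndarray | None = None
) -> np.ndarray:
    """Decode latent estimates: ``y_hat = D r``, then ``z_hat = R^T y_hat``."""
    y_hat = np.asarray(D, float) @ np.asarray(rates, float)
    if R is None:
        return y_hat
    return np.asarray(R, float).T @ y_hat


def build_network(
    Y: int,
    N: int,
    code: str,
    rng: np.random.Generator,
    zp_dim: int | None = None,
    pure_P: int = 0,
    pure_C: int = 0,
) -> NetworkModel:
    """Sample a decoder, derive its encoder and default thresholds."""
    D = sample_decoder(Y, N, code, rng, zp_dim=zp_dim, pure_P=pure_P, pure_C=pure_C)
    E = pseudo_inverse_encoder(D)
    T = default_thresholds(D)
    return NetworkModel(D=D, E=E, T=T, code=code, pure_P=pure_P, pure_C=pure_C)
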