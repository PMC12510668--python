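"""Remapping statistics: overlap, spatial correlation, shuffles, norms.

Given steady-state rate maps ``r^A(p)`` for a set of environments, remapping
is quantified with two population measures, each against a permutation null:

* **overlap** — cosine similarity of the environment-mean population rate
  vectors; the shuffle permutes neuron identities.
* **spatial correlation** — mean cosine similarity of per-neuron rate maps
  across environments, over neurons active in both; the shuffle pairs
  mismatched neurons.

Significance of the pair means against the grand shuffle mean uses a
one-sample two-sided t-test with a Bonferroni-corrected threshold
``0.05 / n_tests``.

A complementary decomposition splits the remapping vector ``r^A - r^B`` into
the component decodable as spatial latents, the component decodable as
cognitive latents, and the residual confined to the decoder's null space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedSimilarityError",
    "EmptyStatisticError",
    "InsufficientDataError",
    "RemappingStats",
    "RemapNorms",
    "PlaceFieldStats",
    "preprocess_ratemaps",
    "overlap",
    "overlap_shuffle",
    "spatial_correlation",
    "spatial_correlation_shuffle",
    "significance",
    "remap_norms",
    "place_field_stats",
    "pairwise_stats",
]

RATE_THRESHOLD = 1e-3
DEFAULT_N_SHUFFLE = 20
ALPHA = 0.05


class UndefinedSimilarityError(ValueError):
    """Cosine similarity of a zero vector is undefined."""


class EmptyStatisticError(ValueError):
    """A statistic has no contributing samples (e.g. no co-active neurons)."""


class InsufficientDataError(ValueError):
    """Too few samples to run the requested test."""


@dataclass
class RemapNorms:
    """Norms of the remapping vector between two environments."""

    total: float
    spatial: float
    cognitive: float
    null_space: float


@dataclass
class PlaceFieldStats:
    """Single-environment place-field descriptors."""

    pct_active: float
    mean_field_size_pct: float | None
    field_sizes_pct: np.ndarray = field(repr=False, default=None)


@dataclass
class RemappingStats:
    """Pairwise remapping measures with shuffle nulls and significance."""

    pairs: list[tuple[int, int]]
    omega: np.ndarray
    omega_shuffle: np.ndarray
    rho: np.ndarray
    rho_shuffle: np.ndarray
    n_tests: int = 1
    skipped_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def omega_mean(self) -> float:
        return float(np.mean(self.omega))

    @property
    def omega_shuffle_mean(self) -> float:
        return float(np.mean(self.omega_shuffle))

    @property
    def rho_mean(self) -> float:
        return float(np.mean(self.rho))

    @property
    def rho_shuffle_mean(self) -> float:
        return float(np.mean(self.rho_shuffle))

    @property
    def p_thresh(self) -> float:
        return ALPHA / self.n_tests

    def omega_significance(self) -> tuple[float, bool]:
        return significance(self.omega, self.omega_shuffle_mean, self.n_tests)

    def rho_significance(self) -> tuple[float, bool]:
        return significance(self.rho, self.rho_shuffle_mean, self.n_tests)


def preprocess_ratemaps(
    rates: np.ndarray, threshold: float = RATE_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Zero out rates below ``threshold``; return (thresholded, mean vector).

    The mean vector averages each neuron's rate over all grid positions.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    out = np.where(rates < threshold, 0.0, rates)
    return out, out.mean(axis=1)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity of a zero vector")
    return float(a @ b / (na * nb))


def overlap(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Overlap: cosine similarity of the two mean population rate vectors."""
    return _cosine(np.asarray(mean_a, float), np.asarray(mean_b, float))


def overlap_shuffle(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    rng: np.random.Generator,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
) -> float:
    """Shuffle null for the overlap: permute neuron identities of both vectors."""
    a = np.asarray(mean_a, float)
    b = np.asarray(mean_b, float)
    vals = []
    for _ in range(n_shuffle):
        vals.append(_cosine(rng.permutation(a), rng.permutation(b)))
    return float(np.mean(vals))


def _active_mask(rates: np.ndarray) -> np.ndarray:
    """Active = any post-threshold rate > 0 at >= 1 grid position."""
    return np.any(np.asarray(rates) > 0, axis=1)


def spatial_correlation(rates_a: np.ndarray, rates_b: np.ndarray) -> float:
    """Mean per-neuron rate-map cosine similarity over co-active neurons."""
    rates_a = np.asarray(rates_a, float)
    rates_b = np.asarray(rates_b, float)
    co = _active_mask(rates_a) & _active_mask(rates_b)
    if not co.any():
        raise EmptyStatisticError("no neurons active in both environments")
    idx = np.flatnonzero(co)
    return float(np.mean([_cosine(rates_a[i], rates_b[i]) for i in idx]))


def spatial_correlation_shuffle(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    rng: np.random.Generator,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
) -> float:
    """Shuffle null: cosine similarity of mismatched co-active neuron pairs.

    Each realization pairs every co-active neuron ``i`` with a random
    co-active partner ``j != i`` and averages; the result averages over
    ``n_shuffle`` realizations.
    """
    rates_a = np.asarray(rates_a, float)
    rates_b = np.asarray(rates_b, float)
    co = np.flatnonzero(_active_mask(rates_a) & _active_mask(rates_b))
    if co.size < 2:
        raise EmptyStatisticError(
            "need >= 2 co-active neurons for a mismatched-pair shuffle"
        )
    vals = []
    for _ in range(n_shuffle):
        partner = _random_mismatch(co.size, rng)
        vals.append(
            np.mean(
                [_cosine(rates_a[co[i]], rates_b[co[partner[i]]]) for i in range(co.size)]
            )
        )
    return float(np.mean(vals))


def _random_mismatch(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random partner assignment with partner[i] != i (not nec. a bijection)."""
    partner = rng.integers(0, n - 1, size=n)
    partner[partner >= np.arange(n)] += 1
    return partner


def significance(
    pair_values: np.ndarray, shuffle_mean: float, n_tests: int = 1
) -> tuple[float, bool]:
    """One-sample two-sided t-test of per-pair means against the shuffle mean.

    Significant iff ``p < 0.05 / n_tests`` (Bonferroni over the sweep).
    """
    pair_values = np.asarray(pair_values, float)
    if pair_values.size < 2:
        raise InsufficientDataError(
            f"need >= 2 environment pairs, got {pair_values.size}"
        )
    if np.ptp(pair_values) == 0.0:
        # degenerate sample: all pair means identical
        p = 1.0 if np.isclose(pair_values[0], shuffle_mean) else 0.0
    else:
        _, p = stats.ttest_1samp(pair_values, shuffle_mean)
        if np.isnan(p):
            p = 1.0
    return float(p), bool(p < ALPHA / n_tests)


def remap_norms(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    D: np.ndarray,
    E: np.ndarray,
    spatial_rows: slice | np.ndarray | None,
    cognitive_rows: slice | np.ndarray | None,
    aggregate: str = "rms",
) -> RemapNorms:
    """Decompose the remapping vector ``dr(p) = r^A(p) - r^B(p)``.

    * total      = agg_p ||dr(p)||
    * spatial    = agg_p ||D[spatial_rows] dr(p)||
    * cognitive  = agg_p ||D[cognitive_rows] dr(p)||   (0 when absent)
    * null_space = agg_p ||dr(p) - E D dr(p)||

    where the aggregation over grid positions is root-mean-square by default
    (``aggregate="sum"`` gives the plain sum of norms).  With orthonormal
    encoder columns the per-position Pythagorean identity
    ``||dr||^2 = ||E D dr||^2 + ||dr - E D dr||^2`` holds.
    """
    dr = np.asarray(rates_a, float) - np.asarray(rates_b, float)
    dz = np.asarray(D, float) @ dr

    def agg(norms: np.ndarray) -> float:
        if aggregate == "rms":
            return float(np.sqrt(np.mean(norms**2)))
        if aggregate == "sum":
            return float(np.sum(norms))
        raise ValueError(f"unknown aggregate {aggregate!r}")

    total = agg(np.linalg.norm(dr, axis=0))
    spatial = (
        agg(np.linalg.norm(dz[spatial_rows], axis=0))
        if spatial_rows is not None
        else 0.0
    )
    cognitive = (
        agg(np.linalg.norm(dz[cognitive_rows], axis=0))
        if cognitive_rows is not None
        else 0.0
    )
    nu = dr - np.asarray(E, float) @ dz
    null_space = agg(np.linalg.norm(nu, axis=0))
    return RemapNorms(
        total=total, spatial=spatial, cognitive=cognitive, null_space=null_space
    )


def place_field_stats(
    rates: np.ndarray, field_fraction: float = 0.1
) -> PlaceFieldStats:
    """Percentage of active neurons and mean place-field size.

    A neuron's field is the set of grid positions where its (thresholded)
    rate exceeds ``field_fraction`` of its peak; size is reported as % of the
    environment, averaged over active neurons.  Multiple disjoint fields are
    counted together (contiguity is not required).
    """
    rates = np.asarray(rates, float)
    N, G = rates.shape
    active = _active_mask(rates)
    pct_active = 100.0 * active.sum() / N
    if not active.any():
        return PlaceFieldStats(
            pct_active=0.0, mean_field_size_pct=None, field_sizes_pct=np.array([])
        )
    peaks = rates[active].max(axis=1, keepdims=True)
    sizes = 100.0 * np.mean(rates[active] > field_fraction * peaks, axis=1)
    return PlaceFieldStats(
        pct_active=float(pct_active),
        mean_field_size_pct=float(np.mean(sizes)),
        field_sizes_pct=sizes,
    )


def pairwise_stats(
    ratemaps: list[np.ndarray],
    rng: np.random.Generator,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    n_tests: int = 1,
    threshold: float = RATE_THRESHOLD,
    pairs: list[tuple[int, int]] | None = None,
) -> RemappingStats:
    """Overlap and spatial correlation with shuffles over environment pairs.

    ``ratemaps`` holds one (N, G) array per environment.  By default all
    unordered pairs are evaluated; pass ``pairs`` to restrict (e.g. default
    map vs each modulated map in the null-space scenario).  Pairs for which a
    statistic is undefined (an empty rate map, or no co-active neurons) are
    recorded in ``skipped_pairs`` rather than contributing NaNs.

    Each pair draws its shuffle realizations from an independent child stream
    of ``rng`` so the statistics do not depend on pair evaluation order.
    """
    K = len(ratemaps)
    if pairs is None:
        pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    processed = [preprocess_ratemaps(r, threshold) for r in ratemaps]
    om, om_sh, rh, rh_sh = [], [], [], []
    kept, skipped = [], []
    streams = rng.spawn(len(pairs))
    for (i, j), stream in zip(pairs, streams):
        ra, ma = processed[i]
        rb, mb = processed[j]
        try:
            o = overlap(ma, mb)
            o_sh = overlap_shuffle(ma, mb, stream, n_shuffle)
            r_ = spatial_correlation(ra, rb)
            r_sh = spatial_correlation_shuffle(ra, rb, stream, n_shuffle)
        except (UndefinedSimilarityError, EmptyStatisticError):
            skipped.append((i, j))
            continue
        om.append(o)
        om_sh.append(o_sh)
        rh.append(r_)
        rh_sh.append(r_sh)
        kept.append((i, j))
    if not kept:
        raise EmptyStatisticError("no environment pair yielded defined statistics")
    return RemappingStats(
        pairs=kept,
        omega=np.array(om),
        omega_shuffle=np.array(om_sh),
        rho=np.array(rh),
        rho_shuffle=np.array(rh_sh),
        n_tests=n_tests,
        skipped_pairs=skipped,
    )
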