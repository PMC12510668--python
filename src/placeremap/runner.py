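"""Scenario orchestration: configuration, simulation, analysis, persistence.

A *scenario* specifies one of the remapping families:

==================  =========================================================
``multi_chart``     encoder-decoder remapping via Haar-random charts in a
                    shared Y-dimensional embedding space (``full_d=True``
                    gives the fully random Y = N identity-decoder variant)
``grid_realign``    encoder-decoder remapping via per-module phase shifts of
                    an m-module grid code
``space_feature``   mixed-selective remapping: shared spatial latents plus
                    environment-specific GP cognitive trajectories
``implicit_space``  mixed-selective remapping without explicit position
``null_space``      participation modulation of a single environment through
                    neuron-specific threshold elevation
``reward``          space-feature coding with a reward-shaped cognitive
                    variable at environment-specific locations
==================  =========================================================

``run_scenario`` composes the coding, environments, network and analysis
modules into an end-to-end run, returning a :class:`RunRecord`;
``persist_results`` / ``load_run`` round-trip rate maps and statistics
through an output directory.  Randomness is fully determined by the master
seed through counter-based sub-seeds, so re-running an identical
configuration reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as an
from . import coding, environments, network

__version__ = "0.1.0"
logger = logging.getLogger("placeremap")

__all__ = [
    "ScenarioConfig",
    "RunRecord",
    "ConfigError",
    "parse_config",
    "run_scenario",
    "persist_results",
    "load_run",
    "analyze_run",
    "reward_zone_analysis",
]

SCENARIO_KINDS = (
    "multi_chart",
    "grid_realign",
    "space_feature",
    "implicit_space",
    "null_space",
    "reward",
)

# default code scheme per scenario kind
_DEFAULT_CODES = {
    "multi_chart": "M",
    "grid_realign": "C",
    "space_feature": "CM",
    "implicit_space": "C",
    "null_space": "M",
    "reward": "C",
}

# sub-seed tags for counter-based derivation from the master seed
_TAG_NETWORK = 1
_TAG_ANALYSIS = 2
_TAG_MODULATION = 3
_TAG_ENV = 100  # + environment index


class ConfigError(ValueError):
    """A scenario configuration violates a per-scenario constraint."""


@dataclass
class ScenarioConfig:
    """Validated scenario configuration.

    ``P`` counts *encoded* position variables; for ``implicit_space`` it is 0
    while ``space_dims`` keeps the physical dimensionality of the arena over
    which cognitive variables vary.
    """

    kind: str
    K: int = 10
    P: int = 2
    C: int = 0
    m: int = 1
    Y: int | None = None
    N: int = 256
    code: str | None = None
    full_d: bool = False
    sigma: float = 0.3
    v: float = 0.3
    grid_resolution: int | None = None
    space_dims: int | None = None
    f: tuple[int, ...] | None = None
    spar_values: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    default_spar: float = 0.5
    n_modulation_samples: int = 5
    T_suppr: float = 10.0
    reward_mu: tuple[float, ...] = (-0.5, 0.5)
    reward_sigma: float = 0.2
    pure_P: int = 0
    pure_C: int = 0
    n_shuffle: int = 20
    field_fraction: float = 0.1
    n_tests: int = 1
    rescale_cutoff: int = 4
    seed: int = 0

    # ---- derived quantities -------------------------------------------------
    @property
    def Z(self) -> int:
        return 2 * self.m * self.P + 2 * self.C

    @property
    def zp_dim(self) -> int:
        return 2 * self.m * self.P

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(
                f"kind: unknown scenario {self.kind!r}; expected one of {SCENARIO_KINDS}"
            )
        if self.code is None:
            self.code = "identity" if self.full_d else _DEFAULT_CODES[self.kind]
        if self.space_dims is None:
            self.space_dims = self.P if self.P > 0 else 2
        if self.grid_resolution is None:
            self.grid_resolution = 100 if self.space_dims == 1 else 32
        if not 0.0 <= self.sigma <= 1.0:
            raise ConfigError(f"sigma: must lie in [0, 1], got {self.sigma}")
        if self.v <= 0:
            raise ConfigError(f"v: length scale must be positive, got {self.v}")
        if self.K < 1:
            raise ConfigError(f"K: need at least one environment, got {self.K}")

        kind = self.kind
        if kind in ("multi_chart", "null_space"):
            if self.C != 0:
                raise ConfigError(f"{kind}: encoder-decoder remapping requires C = 0")
            if self.m != 1:
                raise ConfigError(f"{kind}: requires a single module (m = 1)")
            if self.full_d:
                if self.Y is None:
                    self.Y = self.N
                if self.Y != self.N or self.code != "identity":
                    raise ConfigError(
                        "full_d: requires Y = N and the identity decoder code"
                    )
            if self.Y is None:
                raise ConfigError(f"{kind}: Y (embedding dimensionality) is required")
            if not self.Z <= self.Y <= self.N:
                raise ConfigError(
                    f"{kind}: need Z <= Y <= N, got Z={self.Z}, Y={self.Y}, N={self.N}"
                )
        elif kind == "grid_realign":
            if self.C != 0:
                raise ConfigError("grid_realign: requires C = 0")
            if self.m < 2:
                raise ConfigError("grid_realign: requires m > 1 grid modules")
            if self.f is None:
                self.f = tuple(
                    int(x) for x in coding.default_frequency_exponents(self.m)
                )
            if len(self.f) != self.m or self.f[0] != 0:
                raise ConfigError("f: need m exponents with f[0] = 0")
            if self.Y is None:
                self.Y = self.Z
            if self.Y != self.Z:
                raise ConfigError(f"grid_realign: Y = Z = 2mP required, got Y={self.Y}")
        elif kind in ("space_feature", "implicit_space", "reward"):
            if kind == "space_feature" and (self.P == 0 or self.C == 0):
                raise ConfigError("space_feature: requires P != 0 and C != 0")
            if kind == "implicit_space":
                if self.P != 0:
                    raise ConfigError("implicit_space: requires P = 0")
                if self.C == 0:
                    raise ConfigError("implicit_space: requires C != 0")
            if kind == "reward":
                if self.P != 1 or self.C != 1:
                    raise ConfigError("reward: requires P = 1 and C = 1")
                if self.reward_sigma <= 0:
                    raise ConfigError("reward_sigma: must be positive")
                if self.K != len(self.reward_mu):
                    raise ConfigError(
                        f"reward: K = {self.K} must match len(reward_mu) = "
                        f"{len(self.reward_mu)}"
                    )
            if self.m != 1:
                raise ConfigError(f"{kind}: requires a single module (m = 1)")
            if self.Y is None:
                self.Y = self.Z
            if self.Y != self.Z:
                raise ConfigError(f"{kind}: mixed-selective remapping requires Y = Z")
        if self.code == "pM" and self.pure_P + self.pure_C > self.N:
            raise ConfigError("pure_P + pure_C must not exceed N")
        if self.N < self.Y:
            raise ConfigError(f"N = {self.N} must be >= Y = {self.Y}")

    # ---- seeding ------------------------------------------------------------
    def rng(self, tag: int, index: int = 0) -> np.random.Generator:
        """Counter-derived generator: stable under adding environments."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(tag), int(index)])
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class RunRecord:
    """Everything produced by one scenario run."""

    config: ScenarioConfig
    grid: np.ndarray
    environment_ids: list[str]
    ratemaps: list[network.RateMapSet]
    net: network.NetworkModel
    embeddings: list[np.ndarray]
    stats: an.RemappingStats | None
    norms: list[an.RemapNorms]
    field_stats: list[an.PlaceFieldStats]
    decode_error_median: float
    extras: dict = field(default_factory=dict)
    version: str = __version__


# --------------------------------------------------------------------------
# configuration parsing
# --------------------------------------------------------------------------

_KNOWN_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)}
_LIST_KEYS = {"f", "spar_values", "reward_mu"}


def parse_config(path: str | Path) -> ScenarioConfig:
    """Read a YAML or JSON scenario configuration file.

    ``kind`` is required; every other key has a default.  Unknown keys warn
    and are ignored; invalid values raise :class:`ConfigError` naming the key.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of configuration keys")
    clean = {}
    for k, v in data.items():
        if k not in _KNOWN_KEYS:
            warnings.warn(f"{path}: unknown configuration key {k!r} ignored")
            continue
        clean[k] = tuple(v) if k in _LIST_KEYS and v is not None else v
    if "kind" not in clean:
        raise ConfigError(f"{path}: 'kind' is required (one of {SCENARIO_KINDS})")
    return ScenarioConfig(**clean)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


def _encode_positions(cfg: ScenarioConfig, grid: np.ndarray) -> np.ndarray | None:
    """Positional latent block (2mP, G), or None when position is not encoded."""
    if cfg.P == 0:
        return None
    pos = grid[:, : cfg.P]
    if cfg.m == 1:
        return coding.encode_angles(pos)
    return coding.encode_grid(pos, np.asarray(cfg.f, dtype=int))


def _environment_latents(
    cfg: ScenarioConfig, grid: np.ndarray, env_index: int
) -> tuple[np.ndarray, np.ndarray | None]:
    """Latent vectors (Z, G) and the raw cognitive trajectory for one environment."""
    zp = _encode_positions(cfg, grid)
    c = None
    if cfg.C > 0:
        if cfg.kind == "reward":
            c = environments.reward_profile(
                grid, environments.RewardProfileConfig(
                    mu=cfg.reward_mu[env_index], sigma_r=cfg.reward_sigma
                )
            )
        else:
            c = environments.sample_cognitive_trajectory(
                grid,
                environments.CognitiveProcessConfig(sigma=cfg.sigma, v=cfg.v, C=cfg.C),
                cfg.rng(_TAG_ENV, env_index),
            )
        zc = coding.encode_angles(c.T)
        z = zc if zp is None else np.vstack([zp, zc])
    else:
        z = zp
    z = coding.normalize_blocks(
        z, cfg.zp_dim if cfg.C > 0 else z.shape[0],
        rescale_dim=cfg.Y, rescale_cutoff=cfg.rescale_cutoff,
    )
    return z, c


def _environment_map(
    cfg: ScenarioConfig, env_index: int
) -> environments.EmbeddingMap:
    rng = cfg.rng(_TAG_ENV, 1000 + env_index)
    eid = f"env{env_index}"
    if cfg.kind in ("multi_chart", "null_space"):
        return environments.sample_multichart_map(cfg.Y, cfg.Z, rng, eid)
    if cfg.kind == "grid_realign":
        return environments.sample_gridshift_map(cfg.m, cfg.P, rng, eid)
    return environments.EmbeddingMap.identity(cfg.Z, eid)


def _build_network(cfg: ScenarioConfig) -> network.NetworkModel:
    return network.build_network(
        cfg.Y,
        cfg.N,
        cfg.code,
        cfg.rng(_TAG_NETWORK),
        zp_dim=cfg.zp_dim if cfg.code in ("CM", "pM") else None,
        pure_P=cfg.pure_P,
        pure_C=cfg.pure_C,
    )


def _latent_block_rows(cfg: ScenarioConfig) -> tuple[slice | None, slice | None]:
    """Row slices of the latent decoder for the spatial / cognitive blocks.

    For encoder-decoder and null-space scenarios the whole embedding carries
    position, so the spatial block is the full decoder and there is no
    cognitive block.
    """
    if cfg.C == 0:
        return slice(0, cfg.Y), None
    if cfg.P == 0:
        return None, slice(0, 2 * cfg.C)
    return slice(0, cfg.zp_dim), slice(cfg.zp_dim, cfg.Z)


def run_scenario(config: ScenarioConfig) -> RunRecord:
    """Simulate and analyze one scenario end to end."""
    cfg = config
    logger.info("running %s scenario (seed=%d)", cfg.kind, cfg.seed)
    grid = coding.position_grid(cfg.grid_resolution, cfg.space_dims)

    if cfg.kind == "null_space":
        return _run_null_space(cfg, grid)

    net = _build_network(cfg)
    ratemaps: list[network.RateMapSet] = []
    embeddings: list[np.ndarray] = []
    cognitive: list[np.ndarray | None] = []
    maps: list[environments.EmbeddingMap] = []
    for k in range(cfg.K):
        z, c = _environment_latents(cfg, grid, k)
        emap = _environment_map(cfg, k)
        y = environments.build_embedding(z, emap)
        rm = network.batch_solve(y, net.D, net.T, E=net.E, environment_id=emap.environment_id)
        ratemaps.append(rm)
        embeddings.append(y)
        cognitive.append(c)
        maps.append(emap)
        logger.info("  %s: solved %d grid points", emap.environment_id, grid.shape[0])

    record = _analyze(cfg, grid, net, ratemaps, embeddings)
    record.extras["cognitive"] = cognitive
    record.extras["embedding_maps"] = maps
    if cfg.kind == "reward":
        record.extras["reward"] = reward_zone_analysis(cfg, grid, net, ratemaps)
    return record


def _analyze(
    cfg: ScenarioConfig,
    grid: np.ndarray,
    net: network.NetworkModel,
    ratemaps: list[network.RateMapSet],
    embeddings: list[np.ndarray],
    pairs: list[tuple[int, int]] | None = None,
) -> RunRecord:
    stats = None
    if len(ratemaps) >= 2:
        stats = an.pairwise_stats(
            [rm.rates for rm in ratemaps],
            cfg.rng(_TAG_ANALYSIS),
            n_shuffle=cfg.n_shuffle,
            n_tests=cfg.n_tests,
            pairs=pairs,
        )
    sp_rows, cog_rows = _latent_block_rows(cfg)
    norms = []
    if stats is not None:
        for i, j in stats.pairs:
            norms.append(
                an.remap_norms(
                    ratemaps[i].rates,
                    ratemaps[j].rates,
                    net.D,
                    net.E,
                    sp_rows,
                    cog_rows,
                )
            )
    field_stats = [
        an.place_field_stats(
            an.preprocess_ratemaps(rm.rates)[0], cfg.field_fraction
        )
        for rm in ratemaps
    ]
    decode_error = _decode_error(ratemaps, embeddings)
    return RunRecord(
        config=cfg,
        grid=grid,
        environment_ids=[rm.environment_id for rm in ratemaps],
        ratemaps=ratemaps,
        net=net,
        embeddings=embeddings,
        stats=stats,
        norms=norms,
        field_stats=field_stats,
        decode_error_median=decode_error,
    )


def _decode_error(
    ratemaps: list[network.RateMapSet], embeddings: list[np.ndarray]
) -> float:
    """Median over grid and environments of ||y_hat - y|| / ||y||."""
    errs = []
    for rm, y in zip(ratemaps, embeddings):
        num = np.linalg.norm(rm.decoded - y, axis=0)
        den = np.linalg.norm(y, axis=0)
        errs.append(num / np.where(den == 0, 1.0, den))
    return float(np.median(np.concatenate(errs)))


def _run_null_space(cfg: ScenarioConfig, grid: np.ndarray) -> RunRecord:
    """Participation-modulation runs of a single multi-chart environment.

    Environment 0 is the "default" map (``default_spar`` active fraction);
    each sweep value contributes ``n_modulation_samples`` independent random
    suppression sets.  Pair statistics compare the default map against each
    modulated map.
    """
    net = _build_network(cfg)
    z, _ = _environment_latents(cfg, grid, 0)
    emap = _environment_map(cfg, 0)
    y = environments.build_embedding(z, emap)

    # T_suppr is stated relative to unit-scale inputs (~10x the normal
    # threshold); scale it with the embedding rescale so that suppression
    # always silences regardless of Y
    scale = cfg.Y if cfg.Y > cfg.rescale_cutoff else 1
    t_suppr = cfg.T_suppr * scale

    mod_rng = cfg.rng(_TAG_MODULATION)
    T_def, mod_def = network.modulate_thresholds(
        net.T, cfg.default_spar, mod_rng, t_suppr
    )
    runs = [("default", cfg.default_spar, T_def, mod_def)]
    for spar in cfg.spar_values:
        for s in range(cfg.n_modulation_samples):
            T_mod, mod = network.modulate_thresholds(net.T, spar, mod_rng, t_suppr)
            runs.append((f"spar{spar:g}_s{s}", spar, T_mod, mod))

    ratemaps, modulations = [], []
    for label, spar, T_mod, mod in runs:
        rm = network.batch_solve(y, net.D, T_mod, E=net.E, environment_id=label)
        ratemaps.append(rm)
        modulations.append(mod)
        logger.info("  %s: solved %d grid points", label, grid.shape[0])

    pairs = [(0, k) for k in range(1, len(ratemaps))]
    record = _analyze(cfg, grid, net, ratemaps, [y] * len(ratemaps), pairs=pairs)
    record.extras["modulations"] = modulations
    record.extras["spar_per_run"] = [spar for _, spar, _, _ in runs]
    record.extras["dominance"] = _null_space_dominance(net, ratemaps, pairs)
    return record


def _null_space_dominance(
    net: network.NetworkModel,
    ratemaps: list[network.RateMapSet],
    pairs: list[tuple[int, int]],
) -> dict[str, float]:
    """Median over grid of ||D dr(p)|| / ||dr(p)|| for each (default, mod) pair.

    Small values mean the rate change is confined to the decoder null space.
    Pairs involving an empty (fully silenced) map are skipped: comparing a
    map against no map at all measures the map itself, not a remapping.
    """
    out = {}
    for i, j in pairs:
        if not np.any(ratemaps[j].rates > an.RATE_THRESHOLD):
            continue
        dr = ratemaps[i].rates - ratemaps[j].rates
        num = np.linalg.norm(net.D @ dr, axis=0)
        den = np.linalg.norm(dr, axis=0)
        ok = den > 0
        if not ok.any():
            continue
        out[ratemaps[j].environment_id] = float(np.median(num[ok] / den[ok]))
    return out


# --------------------------------------------------------------------------
# reward-zone analysis
# --------------------------------------------------------------------------


def reward_zone_analysis(
    cfg: ScenarioConfig,
    grid: np.ndarray,
    net: network.NetworkModel,
    ratemaps: list[network.RateMapSet],
) -> dict:
    """Winner density in/out of the reward zone; cross-location active sets.

    The reward zone of environment k is ``|p - mu_k| <= 2 * reward_sigma``,
    covering the region where the reward signal (and hence the cognitive
    latent trajectory) varies appreciably.  Winner density is the number of
    distinct winning neurons per unit of position, inside versus outside the
    zone.  Two cross-location set comparisons are reported:

    * ``shared_core_winners`` — neurons that *win* (are most active) inside
      the reward core ``|p - mu_k| <= reward_sigma`` of every environment;
      the cores are spatially distant, so a shared core winner codes the
      reward itself rather than position.  For a conjunctive code this set
      is expected empty — reward cells remap with position.
    * ``shared_in_zones`` / ``shared_pure_cognitive`` — neurons active
      somewhere within the reward zone of every environment; for a
      pure-and-mixed code this is where a reward-pure neuron shows up at
      both reward sites.
    """
    p = grid[:, 0]
    length = p[-1] - p[0] + (p[1] - p[0])
    results = {"per_environment": [], "winner_sets": []}
    active_at_peak = []
    active_in_zone = []
    core_winners = []
    for k, rm in enumerate(ratemaps):
        rates, _ = an.preprocess_ratemaps(rm.rates)
        winner = np.argmax(rates, axis=0)
        winner[rates.max(axis=0) <= 0] = -1
        zone = np.abs(p - cfg.reward_mu[k]) <= 2.0 * cfg.reward_sigma
        core = np.abs(p - cfg.reward_mu[k]) <= cfg.reward_sigma
        core_winners.append(set(np.unique(winner[core & (winner >= 0)]).tolist()))
        inside = np.unique(winner[zone & (winner >= 0)])
        outside = np.unique(winner[~zone & (winner >= 0)])
        len_in = zone.mean() * length
        len_out = (~zone).mean() * length
        results["per_environment"].append(
            {
                "mu": cfg.reward_mu[k],
                "density_inside": inside.size / len_in,
                "density_outside": outside.size / len_out,
            }
        )
        results["winner_sets"].append(set(inside.tolist()))
        peak = int(np.argmin(np.abs(p - cfg.reward_mu[k])))
        active_at_peak.append(set(np.flatnonzero(rates[:, peak] > 0).tolist()))
        active_in_zone.append(
            set(np.flatnonzero(rates[:, zone].max(axis=1) > 0).tolist())
        )
    results["active_at_peaks"] = active_at_peak
    results["active_in_zones"] = active_in_zone
    results["core_winners"] = core_winners
    results["shared_core_winners"] = set.intersection(*core_winners)
    results["shared_at_peaks"] = set.intersection(*active_at_peak)
    shared_zone = set.intersection(*active_in_zone)
    results["shared_in_zones"] = shared_zone
    if cfg.code == "pM":
        pure_c = set(range(cfg.pure_P, cfg.pure_P + cfg.pure_C))
        results["shared_pure_cognitive"] = shared_zone & pure_c
    return results


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------


def _stats_frame(record: RunRecord) -> pd.DataFrame:
    rows = []
    stats = record.stats
    if stats is None:
        return pd.DataFrame(
            columns=["env_a", "env_b", "overlap", "overlap_shuffle",
                     "spatial_corr", "spatial_corr_shuffle",
                     "norm_total", "norm_spatial", "norm_cognitive", "norm_null"]
        )
    for idx, (i, j) in enumerate(stats.pairs):
        nm = record.norms[idx]
        rows.append(
            {
                "env_a": record.environment_ids[i],
                "env_b": record.environment_ids[j],
                "overlap": stats.omega[idx],
                "overlap_shuffle": stats.omega_shuffle[idx],
                "spatial_corr": stats.rho[idx],
                "spatial_corr_shuffle": stats.rho_shuffle[idx],
                "norm_total": nm.total,
                "norm_spatial": nm.spatial,
                "norm_cognitive": nm.cognitive,
                "norm_null": nm.null_space,
            }
        )
    return pd.DataFrame(rows)


def summary_dict(record: RunRecord) -> dict:
    """JSON-ready summary: means, p-values, significance flags, config echo."""
    out = {
        "version": record.version,
        "config": record.config.to_dict(),
        "decode_error_median": record.decode_error_median,
        "pct_active": [fs.pct_active for fs in record.field_stats],
        "mean_field_size_pct": [
            fs.mean_field_size_pct for fs in record.field_stats
        ],
    }
    stats = record.stats
    if stats is not None:
        omega_p, omega_sig = (
            stats.omega_significance() if len(stats.pairs) >= 2 else (None, None)
        )
        rho_p, rho_sig = (
            stats.rho_significance() if len(stats.pairs) >= 2 else (None, None)
        )
        out.update(
            {
                "overlap_mean": stats.omega_mean,
                "overlap_shuffle_mean": stats.omega_shuffle_mean,
                "spatial_corr_mean": stats.rho_mean,
                "spatial_corr_shuffle_mean": stats.rho_shuffle_mean,
                "overlap_p": omega_p,
                "overlap_significant": omega_sig,
                "overlap_above_shuffle": stats.omega_mean > stats.omega_shuffle_mean,
                "spatial_corr_p": rho_p,
                "spatial_corr_significant": rho_sig,
                "spatial_corr_above_shuffle": stats.rho_mean > stats.rho_shuffle_mean,
                "p_thresh": stats.p_thresh,
                "n_pairs": len(stats.pairs),
                "skipped_pairs": stats.skipped_pairs,
            }
        )
    if "dominance" in record.extras:
        out["null_space_dominance"] = record.extras["dominance"]
    if "reward" in record.extras:
        rw = record.extras["reward"]
        out["reward"] = {
            "per_environment": rw["per_environment"],
            "n_shared_core_winners": len(rw["shared_core_winners"]),
            "n_shared_pure_cognitive": len(rw.get("shared_pure_cognitive", [])),
        }
    return out


def persist_results(record: RunRecord, out_dir: str | Path) -> Path:
    """Write rate maps, stats CSV, JSON summary and a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    for rm in record.ratemaps:
        fn = out / f"rates_{rm.environment_id}.npy"
        np.save(fn, rm.rates)
        files.append(fn)
    np.save(out / "grid.npy", record.grid)
    files.append(out / "grid.npy")
    np.save(out / "decoder.npy", record.net.D)
    files.append(out / "decoder.npy")

    index = pd.DataFrame(
        {
            "environment_id": record.environment_ids,
            "file": [f"rates_{e}.npy" for e in record.environment_ids],
        }
    )
    index.to_csv(out / "ratemap_index.csv", index=False)
    files.append(out / "ratemap_index.csv")

    _stats_frame(record).to_csv(out / "stats.csv", index=False, float_format="%.12g")
    files.append(out / "stats.csv")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary_dict(record), fh, indent=2, default=_json_default)
    files.append(out / "summary.json")

    manifest = {
        "version": record.version,
        "seed": record.config.seed,
        "kind": record.config.kind,
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote %d files to %s", len(files) + 1, out)
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_run(out_dir: str | Path) -> dict:
    """Load persisted rate maps and summary; verifies the manifest version."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("version") != __version__:
        warnings.warn(
            f"manifest written by version {manifest.get('version')}, "
            f"loading with {__version__}"
        )
    index = pd.read_csv(out / "ratemap_index.csv")
    rates = {
        row.environment_id: np.load(out / row.file) for row in index.itertuples()
    }
    with open(out / "summary.json") as fh:
        summary = json.load(fh)
    return {
        "manifest": manifest,
        "rates": rates,
        "summary": summary,
        "grid": np.load(out / "grid.npy"),
        "decoder": np.load(out / "decoder.npy"),
        "stats": pd.read_csv(out / "stats.csv"),
    }


def analyze_run(out_dir: str | Path) -> pd.DataFrame:
    """Recompute pair statistics from persisted rate maps.

    Uses the persisted configuration echo, including the master seed, so the
    result matches the in-process analysis of the original run.
    """
    data = load_run(out_dir)
    cfg = ScenarioConfig(**{
        k: tuple(v) if k in _LIST_KEYS and v is not None else v
        for k, v in data["summary"]["config"].items()
    })
    ids = list(data["rates"].keys())
    maps = [data["rates"][e] for e in ids]
    pairs = None
    if cfg.kind == "null_space":
        pairs = [(0, k) for k in range(1, len(maps))]
    stats = an.pairwise_stats(
        maps, cfg.rng(_TAG_ANALYSIS), n_shuffle=cfg.n_shuffle,
        n_tests=cfg.n_tests, pairs=pairs,
    )
    rows = []
    for idx, (i, j) in enumerate(stats.pairs):
        rows.append(
            {
                "env_a": ids[i],
                "env_b": ids[j],
                "overlap": stats.omega[idx],
                "overlap_shuffle": stats.omega_shuffle[idx],
                "spatial_corr": stats.rho[idx],
                "spatial_corr_shuffle": stats.rho_shuffle[idx],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# reference configurations (desk-scale versions of the main remapping figures)
# --------------------------------------------------------------------------


def reference_config(kind: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named reference configuration for each remapping scenario.

    These are the default study conditions used by the examples and the
    acceptance checks: K = 10 environments, a 32 x 32 position grid for 2-d
    arenas, and network sizes small enough to run on a laptop while keeping
    the redundancy regimes of the full-scale simulations.
    """
    presets: dict[str, dict] = {
        "multi_chart": dict(kind="multi_chart", N=256, Y=16, P=2, C=0, K=10),
        "full_d": dict(kind="multi_chart", full_d=True, N=64, Y=64, P=2, C=0, K=10),
        "grid_realign": dict(kind="grid_realign", N=96, m=3, P=2, C=0, K=10),
        "space_feature": dict(
            kind="space_feature", N=256, P=2, C=6, sigma=0.3, K=10
        ),
        "implicit_space": dict(
            kind="implicit_space", N=256, P=0, C=6, sigma=0.3, K=10, space_dims=2
        ),
        "null_space": dict(
            kind="null_space", N=256, Y=16, P=2, C=0, K=1,
            spar_values=(0.0, 0.25, 0.5, 0.75, 1.0), n_modulation_samples=5,
        ),
        "reward": dict(
            kind="reward", N=16, P=1, C=1, K=2, reward_mu=(-0.5, 0.5),
            reward_sigma=0.2, code="C", grid_resolution=200,
        ),
        "reward_pure_mixed": dict(
            kind="reward", N=16, P=1, C=1, K=2, reward_mu=(-0.5, 0.5),
            reward_sigma=0.2, code="pM", pure_P=4, pure_C=4, grid_resolution=200,
        ),
    }
    if kind not in presets:
        raise ConfigError(
            f"unknown reference configuration {kind!r}; expected one of "
            f"{sorted(presets)}"
        )
    params = dict(presets[kind])
    params.update(overrides)
    params.setdefault("seed", seed)
    params["seed"] = seed if "seed" not in overrides else params["seed"]
    return ScenarioConfig(**params)
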