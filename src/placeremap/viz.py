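"""Visual diagnostics: winner mosaics, gnomonic projection, quick figures.

The tuning mosaic colors a mesh over two environmental variables by the most
excited neuron at each point, which exposes the tiling of angle space by the
population.  For cartooning, rates may be approximated by the feedforward
input ``D^T y`` instead of the full steady-state solve; the approximation is
for mosaics only and never feeds the analysis statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TuningMosaic",
    "feedforward_excitation",
    "argmax_mosaic",
    "gnomonic_embed",
    "winner_colors",
    "plot_mosaic",
    "plot_ratemaps_1d",
]

DEFAULT_MESH = 200
NO_WINNER = -1


@dataclass
class TuningMosaic:
    """Winner-take-all map over a 2-d mesh of environmental variables."""

    mesh_x: np.ndarray
    mesh_y: np.ndarray
    winner: np.ndarray  # (M, M) int; NO_WINNER where no neuron is excited

    def distinct_winners(self, mask: np.ndarray | None = None) -> np.ndarray:
        w = self.winner if mask is None else self.winner[mask]
        w = w[w != NO_WINNER]
        return np.unique(w)


def feedforward_excitation(y: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Per-neuron feedforward input ``D^T y`` (columnwise on (Y, G) input)."""
    return np.asarray(D, float).T @ np.asarray(y, float)


def argmax_mosaic(
    encode_fn,
    D: np.ndarray,
    mesh: int = DEFAULT_MESH,
    suppressed: np.ndarray | None = None,
    excitation_fn=None,
) -> TuningMosaic:
    """Color a mesh over ``[-1, 1]^2`` by the most excited neuron.

    ``encode_fn`` maps an (M*M, 2) array of mesh points to embedding vectors
    (Y, M*M); excitation defaults to the feedforward input ``D^T y`` (pass
    ``excitation_fn(y_cols)`` returning (N, M*M) to use e.g. full steady-state
    rates).  Suppressed neurons are zeroed before the argmax; points where no
    neuron has positive excitation carry no winner.  Ties break to the lowest
    neuron index (numpy argmax convention).
    """
    axis = np.linspace(-1.0, 1.0, mesh, endpoint=False)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    ys = encode_fn(pts)
    exc = (
        feedforward_excitation(ys, D)
        if excitation_fn is None
        else np.asarray(excitation_fn(ys), float)
    )
    if suppressed is not None and len(suppressed):
        exc = exc.copy()
        exc[np.asarray(suppressed, int), :] = 0.0
    winner = np.argmax(exc, axis=0)
    winner[np.max(exc, axis=0) <= 0.0] = NO_WINNER
    return TuningMosaic(mesh_x=gx, mesh_y=gy, winner=winner.reshape(mesh, mesh))


def gnomonic_embed(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Gnomonic projection of the plane onto the unit sphere.

    ``(x, y) -> (2x, 2y, x^2 + y^2 - 1) / (x^2 + y^2 + 1)``; the output is a
    unit vector for every real input (the origin maps to the south pole).
    Returns shape ``(..., 3)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    s = x**2 + y**2
    denom = s + 1.0
    return np.stack([2.0 * x / denom, 2.0 * y / denom, (s - 1.0) / denom], axis=-1)


def winner_colors(n_neurons: int) -> np.ndarray:
    """Deterministic neuron -> RGB assignment, stable across environments.

    Colors are derived from a fixed-seed shuffle of evenly spaced hues so
    that neighbouring indices are visually distinct but every mosaic of the
    same network uses identical colors.
    """
    import matplotlib.colors as mcolors

    hues = np.linspace(0.0, 1.0, n_neurons, endpoint=False)
    order = np.random.default_rng(1234).permutation(n_neurons)
    hsv = np.stack([hues[order], np.full(n_neurons, 0.85), np.full(n_neurons, 0.9)], axis=-1)
    return mcolors.hsv_to_rgb(hsv)


def plot_mosaic(mosaic: TuningMosaic, n_neurons: int, path=None, title: str = ""):
    """Render a winner mosaic to a matplotlib figure (PNG if path given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = winner_colors(n_neurons)
    img = np.ones(mosaic.winner.shape + (3,))
    has = mosaic.winner != NO_WINNER
    img[has] = colors[mosaic.winner[has]]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.swapaxes(img, 0, 1), origin="lower", extent=(-1, 1, -1, 1))
    ax.set_xlabel("variable 1")
    ax.set_ylabel("variable 2")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_ratemaps_1d(grid: np.ndarray, rates: np.ndarray, path=None, title: str = ""):
    """Line plot of every neuron's rate map over a 1-d position grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = winner_colors(rates.shape[0])
    for i in range(rates.shape[0]):
        ax.plot(grid[:, 0], rates[i], color=colors[i], lw=1)
    ax.set_xlabel("position p")
    ax.set_ylabel("rate")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
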