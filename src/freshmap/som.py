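"""A small seeded self-organizing map for spectral clustering.

Online Kohonen training on a rectangular node grid with a Gaussian
neighbourhood and linearly decaying learning rate / radius. The map is used
purely as a clusterer: after training, each sample is assigned to its
best-matching unit and the node index is the cluster id.
"""

from __future__ import annotations

import numpy as np


class SelfOrganizingMap:
    """Rectangular SOM trained online with a Gaussian neighbourhood.

    Parameters
    ----------
    shape : (rows, cols) of the node grid.
    n_iterations : number of sample presentations.
    learning_rate : initial learning rate, decays linearly to ~1% of itself.
    sigma : initial neighbourhood radius in grid units; defaults to half the
        larger grid dimension, decaying linearly to 0.5.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        n_iterations: int = 1000,
        learning_rate: float = 0.5,
        sigma: float | None = None,
        seed: int = 0,
    ) -> None:
        self.shape = (int(shape[0]), int(shape[1]))
        if min(self.shape) < 1:
            raise ValueError("SOM grid must be at least 1x1")
        self.n_nodes = self.shape[0] * self.shape[1]
        self.n_iterations = int(n_iterations)
        self.learning_rate = float(learning_rate)
        self.sigma = float(sigma) if sigma is not None else max(self.shape) / 2.0
        self.seed = int(seed)
        self.weights_: np.ndarray | None = None
        grid_r, grid_c = np.unravel_index(np.arange(self.n_nodes), self.shape)
        self._grid = np.stack([grid_r, grid_c], axis=1).astype(float)

    def fit(self, X: np.ndarray) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty (n, d) matrix")
        if self.n_nodes > len(X):
            raise ValueError("SOM grid larger than the sample")
        rng = np.random.default_rng(self.seed)
        # initialise nodes on distinct data points: sensible spread, seedable
        init = rng.choice(len(X), size=self.n_nodes, replace=False)
        weights = X[init].copy()

        order = rng.integers(0, len(X), size=self.n_iterations)
        for it, idx in enumerate(order):
            frac = it / max(self.n_iterations - 1, 1)
            lr = self.learning_rate * (1.0 - 0.99 * frac)
            sigma = max(self.sigma * (1.0 - frac), 0.5)
            x = X[idx]
            bmu = np.argmin(((weights - x) ** 2).sum(axis=1))
            d2 = ((self._grid - self._grid[bmu]) ** 2).sum(axis=1)
            influence = lr * np.exp(-d2 / (2.0 * sigma * sigma))
            weights += influence[:, None] * (x - weights)
        self.weights_ = weights
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Best-matching-unit index for each row of X."""
        if self.weights_ is None:
            raise RuntimeError("SOM is not fitted")
        X = np.asarray(X, dtype=float)
        # chunked distance computation keeps memory flat on large samples
        out = np.empty(len(X), dtype=np.int64)
        step = 8192
        w2 = (self.weights_**2).sum(axis=1)
        for start in range(0, len(X), step):
            block = X[start : start + step]
            d2 = w2[None, :] - 2.0 * block @ self.weights_.T
            out[start : start + step] = np.argmin(d2, axis=1)
        return out

    def fit_predict(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).predict(X)


def default_som_shape(n_samples: int, cap: int = 16) -> tuple[int, int]:
    """Node-count heuristic: ~5 * sqrt(n) nodes on a square-ish grid,
    capped at ``cap`` x ``cap``."""
    n_nodes = max(4, int(round(5.0 * np.sqrt(n_samples))))
    side = int(np.ceil(np.sqrt(n_nodes)))
    side = min(side, cap, max(int(np.sqrt(n_samples)), 1))  # never exceed n
    return (side, side)
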