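"""Self-organizing-map portrayal of spot-level transcriptomes.

Genes are the training samples: each gene's expression profile across spots
(a vector of dimension ``n_spots``, centralized log scale) is clustered onto
a 2-D grid of metagene prototype profiles (default 50 x 50 = 2500 units)
using Euclidean distance. Because every gene keeps a fixed grid position,
slicing the weight tensor at one spot's index yields that spot's
"expression portrait" — a grid image of signed over/under-expression that is
directly comparable across all spots.

Training is classical online Kohonen learning: for each sample, the
best-matching unit (BMU) is found by exhaustive Euclidean scan (ties broken
row-major) and all units are pulled toward the sample with a Gaussian
neighborhood factor; learning rate and radius decay exponentially from
their initial to final values over the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .types import DataError, ExpressionMatrix


@dataclass
class Portrait:
    """Grid-shaped metagene values for one spot or one group of spots."""

    values: np.ndarray  # (grid_rows, grid_cols)
    subject: str
    kind: str = "single_spot"  # or "group_mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("portrait values must be a 2-D grid")
        if not np.isfinite(self.values).all():
            raise DataError("portrait contains non-finite values")


def _as_profiles(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    """Accept an ExpressionMatrix (stage centralized) or a plain array."""
    if isinstance(X, ExpressionMatrix):
        if X.stage != "centralized":
            raise DataError(f"SOM expects a centralized matrix, got stage {X.stage!r}")
        return np.asarray(X.values, dtype=float), list(X.gene_ids), list(X.spot_barcodes)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise DataError("expected a 2-D genes x spots array")
    return arr, None, None


class SomPortrayal(BaseEstimator):
    """Kohonen map over gene expression profiles with portrait extraction.

    Parameters
    ----------
    grid_rows, grid_cols : int, default 50
        Metagene grid dimensions (50 x 50 = 2500 units by default).
    n_epochs : int, default 20
        Passes over the gene profiles.
    initial_learning_rate, final_learning_rate : float, default 0.5 / 0.01
        Exponentially decayed online learning rate, both in (0, 1].
    initial_radius : float or None
        Gaussian neighborhood radius at the start; ``None`` means
        ``max(grid_rows, grid_cols) / 2``.
    final_radius : float, default 1.0
        Radius at the end of training.
    init : {"pca_plane", "random"}
        ``pca_plane`` spaces initial units on the plane of the top two
        principal axes of the gene profiles (reproducible); ``random`` draws
        Gaussian weights scaled to the data.
    random_state : int, default 0
        Seed for shuffling (and random init). Fixed seed => bit-identical runs.

    Attributes
    ----------
    weights_ : ndarray of shape (grid_rows, grid_cols, n_spots)
        Metagene prototype profiles.
    gene_assignment_ : dict mapping gene id -> (row, col)
        Best-matching unit of every training gene under the final weights.
    spot_barcodes_ : list of str
        Ordering of the weight-vector dimensions.
    quantization_error_, initial_quantization_error_ : float
        Mean gene-to-BMU distance after / before training.
    """

    def __init__(
        self,
        grid_rows: int = 50,
        grid_cols: int = 50,
        n_epochs: int = 20,
        initial_learning_rate: float = 0.5,
        final_learning_rate: float = 0.01,
        initial_radius: float | None = None,
        final_radius: float = 1.0,
        init: str = "pca_plane",
        random_state: int = 0,
    ):
        self.grid_rows = grid_rows
        self.grid_cols = grid_cols
        self.n_epochs = n_epochs
        self.initial_learning_rate = initial_learning_rate
        self.final_learning_rate = final_learning_rate
        self.initial_radius = initial_radius
        self.final_radius = final_radius
        self.init = init
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _validate_params(self) -> None:
        if self.grid_rows * self.grid_cols < 4:
            raise DataError("grid must have at least 4 units")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise DataError("grid dimensions must be positive")
        if not (0 < self.final_learning_rate <= self.initial_learning_rate <= 1):
            raise DataError("need 0 < final_learning_rate <= initial_learning_rate <= 1")
        r0 = self._radius0()
        if not (0 < self.final_radius <= r0):
            raise DataError("need 0 < final_radius <= initial_radius")
        if self.init not in ("pca_plane", "random"):
            raise DataError(f"unknown init {self.init!r}")
        if self.n_epochs < 1:
            raise DataError("n_epochs must be >= 1")

    def _radius0(self) -> float:
        if self.initial_radius is not None:
            return float(self.initial_radius)
        return max(self.grid_rows, self.grid_cols) / 2.0

    def _grid_coords(self) -> np.ndarray:
        rows, cols = np.meshgrid(
            np.arange(self.grid_rows), np.arange(self.grid_cols), indexing="ij"
        )
        return np.column_stack([rows.ravel(), cols.ravel()]).astype(float)

    def _init_weights(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n_units = self.grid_rows * self.grid_cols
        mean = X.mean(axis=0)
        if self.init == "random":
            scale = X.std() or 1.0
            return mean + rng.normal(0.0, scale, size=(n_units, X.shape[1]))
        # pca_plane: regular grid spanning +-2 sd along the top two principal axes
        Xc = X - mean
        if min(Xc.shape) < 2 or not Xc.any():
            return mean + rng.normal(0.0, 1e-6, size=(n_units, X.shape[1]))
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-|.| component of each axis positive
        for i in range(min(2, Vt.shape[0])):
            j = np.argmax(np.abs(Vt[i]))
            if Vt[i, j] < 0:
                Vt[i] = -Vt[i]
        sd = s / np.sqrt(max(X.shape[0] - 1, 1))
        axis_r = Vt[0] * sd[0]
        axis_c = (Vt[1] * sd[1]) if Vt.shape[0] > 1 else np.zeros_like(axis_r)
        a = np.linspace(-2, 2, self.grid_rows) if self.grid_rows > 1 else np.zeros(1)
        b = np.linspace(-2, 2, self.grid_cols) if self.grid_cols > 1 else np.zeros(1)
        weights = (
            mean[None, None, :]
            + a[:, None, None] * axis_r[None, None, :]
            + b[None, :, None] * axis_c[None, None, :]
        )
        return weights.reshape(n_units, X.shape[1])

    # ------------------------------------------------------------------- fit

    def fit(self, X, y=None):
        """Train on gene profiles (genes x spots).

        ``X`` may be a centralized :class:`~spotsom.types.ExpressionMatrix`
        or a plain 2-D array (gene/spot identifiers then default to
        ``g0..``/``s0..``).
        """
        self._validate_params()
        profiles, gene_ids, spot_barcodes = _as_profiles(X)
        n_genes, n_spots = profiles.shape
        if n_genes == 0 or n_spots == 0:
            raise DataError("cannot train on an empty matrix")
        gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
        spot_barcodes = spot_barcodes or [f"s{j}" for j in range(n_spots)]

        rng = np.random.default_rng(self.random_state)
        weights = self._init_weights(profiles, rng)  # (n_units, n_spots)
        coords = self._grid_coords()
        # squared grid distances between unit pairs, used for the Gaussian kernel
        grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)

        self.initial_quantization_error_ = self._qe(weights, profiles)

        lr0, lr1 = float(self.initial_learning_rate), float(self.final_learning_rate)
        r0, r1 = self._radius0(), float(self.final_radius)
        total = self.n_epochs * n_genes
        step = 0
        for _ in range(self.n_epochs):
            order = rng.permutation(n_genes)
            for idx in order:
                frac = step / max(total - 1, 1)
                lr = lr0 * (lr1 / lr0) ** frac
                sigma = r0 * (r1 / r0) ** frac
                x = profiles[idx]
                diff = x[None, :] - weights
                d2 = np.einsum("ij,ij->i", diff, diff)
                bmu = int(np.argmin(d2))  # first minimum = row-major tie break
                h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
                active = h > 1e-6  # skip numerically dead updates
                weights[active] += (lr * h[active])[:, None] * diff[active]
                step += 1

        self.weights_ = weights.reshape(self.grid_rows, self.grid_cols, n_spots)
        self.gene_ids_ = gene_ids
        self.spot_barcodes_ = spot_barcodes
        self.n_features_in_ = n_spots
        bmus = self._bmu_flat(profiles)
        self.gene_assignment_ = {
            g: (int(b // self.grid_cols), int(b % self.grid_cols))
            for g, b in zip(gene_ids, bmus)
        }
        self.quantization_error_ = self._qe(weights, profiles)
        return self

    def _restore(self, weights, gene_ids, spot_barcodes, assignment, quantization_error,
                 initial_quantization_error) -> None:
        """Rehydrate fitted state from a model archive (see spotsom.io)."""
        weights = np.asarray(weights, dtype=float)
        if weights.shape[:2] != (self.grid_rows, self.grid_cols):
            raise DataError("archive weights do not match configured grid")
        self.weights_ = weights
        self.gene_ids_ = list(gene_ids)
        self.spot_barcodes_ = list(spot_barcodes)
        self.n_features_in_ = weights.shape[2]
        self.gene_assignment_ = {
            g: (int(r), int(c)) for g, (r, c) in zip(self.gene_ids_, assignment)
        }
        self.quantization_error_ = float(quantization_error)
        self.initial_quantization_error_ = float(initial_quantization_error)

    # --------------------------------------------------------------- queries

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def _flat_weights(self) -> np.ndarray:
        self._check_fitted()
        return self.weights_.reshape(self.n_units, -1)

    def _check_fitted(self) -> None:
        if not hasattr(self, "weights_"):
            raise DataError("SomPortrayal is not fitted")

    def _bmu_flat(self, profiles: np.ndarray) -> np.ndarray:
        flat = (
            self.weights_.reshape(self.n_units, -1)
            if hasattr(self, "weights_")
            else None
        )
        if flat is None:
            raise DataError("SomPortrayal is not fitted")
        if profiles.shape[1] != flat.shape[1]:
            raise DataError(
                f"profile dimension {profiles.shape[1]} does not match "
                f"model spot dimension {flat.shape[1]}"
            )
        # exact distances; argmin over row-major units = row-major tie rule
        return np.argmin(cdist(profiles, flat), axis=1)

    @staticmethod
    def _qe(flat_weights: np.ndarray, profiles: np.ndarray) -> float:
        return float(cdist(profiles, flat_weights).min(axis=1).mean())

    def best_matching_unit(self, profile: np.ndarray) -> tuple[int, int]:
        """Unit (row, col) minimizing Euclidean distance; ties row-major.

        Uses an explicit per-unit distance evaluation so that exact ties
        resolve to the lowest row, then lowest column.
        """
        self._check_fitted()
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (self.n_features_in_,):
            raise DataError(
                f"profile has dimension {profile.shape}, expected ({self.n_features_in_},)"
            )
        diff = self._flat_weights() - profile[None, :]
        d2 = np.einsum("ij,ij->i", diff, diff)
        b = int(np.argmin(d2))
        return (b // self.grid_cols, b % self.grid_cols)

    def predict(self, X) -> np.ndarray:
        """Flat (row-major) BMU index for each row of a genes x spots array."""
        arr = np.asarray(X.values if isinstance(X, ExpressionMatrix) else X, dtype=float)
        return self._bmu_flat(np.atleast_2d(arr))

    def transform(self, X) -> np.ndarray:
        """Euclidean distances from each profile to every unit, shape (n, n_units)."""
        arr = np.asarray(X.values if isinstance(X, ExpressionMatrix) else X, dtype=float)
        arr = np.atleast_2d(arr)
        flat = self._flat_weights()
        if arr.shape[1] != flat.shape[1]:
            raise DataError("profile dimension does not match model")
        return cdist(arr, flat)

    def spot_portrait(self, barcode: str) -> Portrait:
        """The grid of metagene values at one spot's weight-vector index."""
        self._check_fitted()
        try:
            j = self.spot_barcodes_.index(barcode)
        except ValueError:
            raise DataError(f"unknown spot barcode {barcode!r}") from None
        return Portrait(self.weights_[:, :, j].copy(), subject=barcode, kind="single_spot")

    def group_portrait(self, barcodes: list[str], label: str | None = None) -> Portrait:
        """Element-wise mean of the member spots' portraits."""
        self._check_fitted()
        if not barcodes:
            raise DataError("group portrait of an empty barcode list")
        idx = []
        for b in barcodes:
            try:
                idx.append(self.spot_barcodes_.index(b))
            except ValueError:
                raise DataError(f"unknown spot barcode {b!r}") from None
        values = self.weights_[:, :, idx].mean(axis=2)
        return Portrait(values, subject=label or f"group({len(barcodes)})", kind="group_mean")

    def quantization_error(self, X) -> float:
        """Mean Euclidean distance from each gene profile to its BMU."""
        self._check_fitted()
        arr = np.asarray(X.values if isinstance(X, ExpressionMatrix) else X, dtype=float)
        arr = np.atleast_2d(arr)
        flat = self._flat_weights()
        if arr.shape[1] != flat.shape[1]:
            raise DataError("matrix dimensions do not match model")
        return self._qe(flat, arr)

    def unit_genes(self) -> dict[tuple[int, int], list[str]]:
        """Inverse of gene_assignment_: unit -> ordered gene list."""
        self._check_fitted()
        out: dict[tuple[int, int], list[str]] = {}
        for g in self.gene_ids_:
            out.setdefault(self.gene_assignment_[g], []).append(g)
        return out


# --------------------------------------------------------- functional facade


def train_som(matrix: ExpressionMatrix, **som_params) -> SomPortrayal:
    """Train a :class:`SomPortrayal` on a centralized expression matrix."""
    return SomPortrayal(**som_params).fit(matrix)


def best_matching_unit(model: SomPortrayal, profile: np.ndarray) -> tuple[int, int]:
    return model.best_matching_unit(profile)


def spot_portrait(model: SomPortrayal, barcode: str) -> Portrait:
    return model.spot_portrait(barcode)


def group_portrait(model: SomPortrayal, barcodes: list[str], label: str | None = None) -> Portrait:
    return model.group_portrait(barcodes, label=label)


def quantization_error(model: SomPortrayal, matrix) -> float:
    return model.quantization_error(matrix)
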