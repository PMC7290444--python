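"""Batch self-organizing map over the 13-dimensional GVS feature space.

The map is a 10x10 rectangular grid of prototype vectors ("codebook").
Training is the deterministic batch algorithm: each epoch assigns every
sample to its best matching unit (BMU), then replaces each prototype by the
neighborhood-weighted mean of all samples,

    w_u  <-  sum_s h(bmu(s), u) x_s  /  sum_s h(bmu(s), u),

with a Gaussian neighborhood h(u, b) = exp(-d_grid(u, b)^2 / (2 sigma^2))
over Euclidean grid distance.  sigma shrinks linearly from the initial to
the final radius during the rough phase and stays at the final radius
during fine-tuning.  The codebook is initialized on the plane spanned by
the first two principal components of the data, so training is fully
deterministic; a seeded RNG backs the random fallback initializer.

Features are z-scored before training; the normalization parameters are
stored on the model so downstream clustering and BMU lookups operate in the
same space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

SERIALIZATION_VERSION = "somgait-1"


@dataclass
class SOMTrainConfig:
    """Hyperparameters of batch SOM training.

    The grid defaults to the 10x10 layout (100 units).  The neighborhood
    radius shrinks from ``radius_initial`` (default: grid size / 6) to
    ``radius_final`` (default 1.0) over the rough epochs, then holds at the
    final radius for the fine-tune epochs.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    n_epochs_rough: int = 50
    n_epochs_finetune: int = 50
    radius_initial: float | None = None
    radius_final: float = 1.0
    init_method: str = "pca_linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_epochs_rough < 1 or self.n_epochs_finetune < 0:
            raise ValueError("epoch counts must be positive")
        if self.radius_initial is None:
            self.radius_initial = max(
                max(self.grid_rows, self.grid_cols) * 10.0 / 60.0, self.radius_final
            )
        if self.radius_final <= 0 or self.radius_initial < self.radius_final:
            raise ValueError("radii must be positive and non-increasing over training")
        if self.init_method not in ("pca_linear", "random"):
            raise ValueError(f"unknown init_method {self.init_method!r}")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class SOMModel:
    """A trained map: codebook, grid layout, normalization, history."""

    codebook: np.ndarray  # (n_units, n_features), normalized space
    grid_coords: np.ndarray  # (n_units, 2) (row, col), row-major unit order
    norm_mean: np.ndarray
    norm_sd: np.ndarray  # 1.0 substituted for zero-variance features
    zero_variance: np.ndarray  # bool flags per feature
    config: SOMTrainConfig
    qe_history: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.codebook.shape[0]

    @property
    def n_features(self) -> int:
        return self.codebook.shape[1]

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """Map raw feature rows into the model's z-scored space."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.norm_mean) / self.norm_sd
        z[:, self.zero_variance] = 0.0
        return z

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return z * self.norm_sd + self.norm_mean

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": SERIALIZATION_VERSION,
            "codebook": self.codebook.tolist(),
            "grid_coords": self.grid_coords.tolist(),
            "norm_mean": self.norm_mean.tolist(),
            "norm_sd": self.norm_sd.tolist(),
            "zero_variance": self.zero_variance.astype(bool).tolist(),
            "config": asdict(self.config),
            "qe_history": self.qe_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported model version {payload.get('version')!r}")
        return cls(
            codebook=np.asarray(payload["codebook"], dtype=float),
            grid_coords=np.asarray(payload["grid_coords"], dtype=float),
            norm_mean=np.asarray(payload["norm_mean"], dtype=float),
            norm_sd=np.asarray(payload["norm_sd"], dtype=float),
            zero_variance=np.asarray(payload["zero_variance"], dtype=bool),
            config=SOMTrainConfig(**payload["config"]),
            qe_history=list(payload["qe_history"]),
        )


def normalize_features(matrix: np.ndarray) -> tuple[np.ndarray, dict]:
    """Per-feature z-score; zero-variance features become all-zero columns.

    Returns the transformed matrix and a parameter dict with keys ``mean``,
    ``sd`` (1.0 for flagged features) and ``zero_variance``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 samples to normalize")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    zero_var = sd == 0.0
    safe_sd = np.where(zero_var, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, zero_var] = 0.0
    return z, {"mean": mean, "sd": safe_sd, "zero_variance": zero_var}


def _grid_coordinates(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _pca_linear_init(data: np.ndarray, coords: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Spread the codebook over the plane of the first two principal axes."""
    center = data.mean(axis=0)
    x = data - center
    # SVD with a deterministic sign convention
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    n = data.shape[0]
    sd = s / np.sqrt(max(n - 1, 1))
    # map grid coords to [-1, 1] per axis; degenerate single-row/col axes sit at 0
    span_r = (coords[:, 0] / max(rows - 1, 1)) * 2.0 - 1.0 if rows > 1 else np.zeros(len(coords))
    span_c = (coords[:, 1] / max(cols - 1, 1)) * 2.0 - 1.0 if cols > 1 else np.zeros(len(coords))
    axes = np.zeros((2, data.shape[1]))
    scale = np.zeros(2)
    n_comp = min(2, vt.shape[0])
    axes[:n_comp] = vt[:n_comp]
    scale[:n_comp] = sd[:n_comp]
    return center + np.outer(span_r * scale[0], axes[0]) + np.outer(span_c * scale[1], axes[1])


def _bmu_indices(codebook: np.ndarray, data: np.ndarray) -> np.ndarray:
    # squared Euclidean distances, argmin ties resolved to the lowest unit index
    d2 = np.sum(codebook**2, axis=1)[None, :] - 2.0 * data @ codebook.T
    return np.argmin(d2, axis=1)


def train_som(data: np.ndarray, config: SOMTrainConfig | None = None,
              norm_params: dict | None = None) -> SOMModel:
    """Train a batch SOM on (already normalized) feature rows.

    ``norm_params`` carries the z-scoring parameters from
    :func:`normalize_features` so the model can project new raw samples; if
    omitted, identity normalization is stored.
    """
    config = config or SOMTrainConfig()
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("training data must be a non-empty 2-D array")
    n, n_features = data.shape
    coords = _grid_coordinates(config.grid_rows, config.grid_cols)
    rng = np.random.default_rng(config.seed)

    if config.init_method == "pca_linear" and n >= 2:
        codebook = _pca_linear_init(data, coords, config.grid_rows, config.grid_cols)
    else:
        lo, hi = data.min(axis=0), data.max(axis=0)
        codebook = rng.uniform(lo, hi, size=(config.n_units, n_features))

    # precomputed squared grid distances between every unit pair
    grid_d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)

    n_total = config.n_epochs_rough + config.n_epochs_finetune
    qe_history: list[float] = []
    for epoch in range(n_total):
        if epoch < config.n_epochs_rough:
            frac = epoch / max(config.n_epochs_rough - 1, 1)
            sigma = config.radius_initial + frac * (config.radius_final - config.radius_initial)
        else:
            sigma = config.radius_final
        bmus = _bmu_indices(codebook, data)
        h = np.exp(-grid_d2[:, bmus] / (2.0 * sigma**2))  # (n_units, n)
        denom = h.sum(axis=1)
        num = h @ data
        updated = num / denom[:, None]
        # Gaussian weights are strictly positive, but guard tiny denominators
        keep = denom <= 1e-300
        if np.any(keep):
            updated[keep] = codebook[keep]
        codebook = updated
        qe_history.append(_quantization_error(codebook, data))

    if norm_params is None:
        norm_params = {
            "mean": np.zeros(n_features),
            "sd": np.ones(n_features),
            "zero_variance": np.zeros(n_features, dtype=bool),
        }
    return SOMModel(
        codebook=codebook,
        grid_coords=coords,
        norm_mean=np.asarray(norm_params["mean"], dtype=float),
        norm_sd=np.asarray(norm_params["sd"], dtype=float),
        zero_variance=np.asarray(norm_params["zero_variance"], dtype=bool),
        config=config,
        qe_history=qe_history,
    )


def bmu(model: SOMModel, sample: np.ndarray) -> int:
    """Index of the nearest codebook vector (ties -> lowest unit index)."""
    sample = np.asarray(sample, dtype=float)
    if not np.all(np.isfinite(sample)):
        raise ValueError("sample must be finite")
    d2 = np.sum((model.codebook - sample) ** 2, axis=1)
    return int(np.argmin(d2))


def bmu_batch(model: SOMModel, data: np.ndarray) -> np.ndarray:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return _bmu_indices(model.codebook, data)


def hit_map(model: SOMModel, data: np.ndarray) -> np.ndarray:
    """10x10 (rows x cols) counts of BMU assignments; sums to n samples."""
    counts = np.zeros(model.n_units, dtype=int)
    data = np.asarray(data, dtype=float)
    if data.size:
        np.add.at(counts, bmu_batch(model, data), 1)
    return counts.reshape(model.config.grid_rows, model.config.grid_cols)


def component_planes(model: SOMModel) -> np.ndarray:
    """(n_features, rows, cols) codebook values de-normalized to degrees."""
    denorm = model.denormalize(model.codebook)
    return np.transpose(denorm).reshape(
        model.n_features, model.config.grid_rows, model.config.grid_cols
    )


def _quantization_error(codebook: np.ndarray, data: np.ndarray) -> float:
    bmus = _bmu_indices(codebook, data)
    return float(np.mean(np.linalg.norm(data - codebook[bmus], axis=1)))


def quantization_error(model: SOMModel, data: np.ndarray) -> float:
    """Mean Euclidean distance of samples to their BMU prototypes."""
    return _quantization_error(model.codebook, np.atleast_2d(np.asarray(data, dtype=float)))


def topographic_error(model: SOMModel, data: np.ndarray) -> float:
    """Fraction of samples whose best two units are not 8-neighbors on the grid."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    d2 = (
        np.sum(model.codebook**2, axis=1)[None, :]
        - 2.0 * data @ model.codebook.T
        + np.sum(data**2, axis=1)[:, None]
    )
    order = np.argsort(d2, axis=1, kind="stable")
    best, second = order[:, 0], order[:, 1]
    cb, cs = model.grid_coords[best], model.grid_coords[second]
    chebyshev = np.max(np.abs(cb - cs), axis=1)
    return float(np.mean(chebyshev > 1.0))
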