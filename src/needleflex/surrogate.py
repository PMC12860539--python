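"""Surrogate regressors from (tissue profile, depth) to nodal deflections.

Three model families map the 126-dimensional input (125 per-millimetre
moduli + insertion depth) to the 48 nodal deflections:

* ``ols``  — ordinary least squares on z-scored inputs and outputs,
* ``mlp``  — a multilayer perceptron with two hidden layers of 48 ReLU
  units, z-scored on both sides,
* ``ffnn`` — the same network body fed with random Fourier features
  sin/cos(2*pi*x*B^T), B ~ N(0,1)*s, which bound every network input to
  [-1, 1]; only the outputs are z-scored.

Networks are fitted with scikit-learn's Adam-trained ``MLPRegressor``; the
fitted weights are extracted into plain arrays so prediction, serialization
and reload are library-independent and bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from .dataset import EncodedDataset

__all__ = [
    "FourierMap",
    "Standardizer",
    "SurrogateModel",
    "EvalReport",
    "fourier_features",
    "train_ols",
    "train_mlp",
    "train_ffnn",
    "grid_search",
    "evaluate",
    "save_model",
    "load_model",
    "TrainingDivergedError",
]

N_INPUT = 126
N_OUTPUT = 48
HIDDEN_LAYERS = (48, 48)


class TrainingDivergedError(RuntimeError):
    """Raised when network training produces non-finite loss or weights."""


@dataclass(frozen=True)
class FourierMap:
    """Frozen random Fourier embedding x -> [sin(2*pi*x*B^T), cos(2*pi*x*B^T)].

    ``B`` has shape (m, d) with entries drawn once as N(0,1) * scale and
    never updated; the mapped dimension is 2m and every mapped value lies in
    [-1, 1] regardless of the raw input magnitude.
    """

    B: np.ndarray
    scale: float
    seed: int

    @classmethod
    def create(cls, n_features: int, scale: float, seed: int, n_frequencies: int | None = None) -> "FourierMap":
        if scale <= 0:
            raise ValueError("Fourier scale must be positive")
        m = n_frequencies if n_frequencies is not None else n_features
        rng = np.random.default_rng(seed)
        B = rng.standard_normal((m, n_features)) * scale
        B.setflags(write=False)
        return cls(B=B, scale=scale, seed=seed)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] != self.B.shape[1]:
            raise ValueError(f"expected {self.B.shape[1]} input features, got {X.shape[1]}")
        proj = 2.0 * np.pi * X @ self.B.T
        return np.concatenate([np.sin(proj), np.cos(proj)], axis=1)


def fourier_features(x: np.ndarray, fmap: FourierMap) -> np.ndarray:
    """Apply a Fourier map to one sample or a batch."""
    out = fmap.transform(np.atleast_2d(x))
    return out[0] if np.asarray(x).ndim == 1 else out


@dataclass(frozen=True)
class Standardizer:
    """Per-dimension z-scoring with exact inverse.

    Zero-variance dimensions are constants known exactly from the training
    data: ``transform`` maps them to 0 and ``inverse`` restores the constant
    itself (it scales by the true, zero, standard deviation), so downstream
    regressors cannot perturb them.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        return cls(mean=X.mean(axis=0), std=X.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / np.where(self.std == 0.0, 1.0, self.std)

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.std + self.mean


@dataclass
class SurrogateModel:
    """A fitted surrogate: weights plus the exact pre/post-processing pipeline.

    ``layers`` holds (W, b) pairs; hidden activations are ReLU and the output
    is linear (for OLS there is a single linear layer). Prediction applies,
    in order: input z-scoring (OLS/MLP) or the Fourier map (FFNN), the
    layers, then the inverse of the output z-scoring.
    """

    kind: str  # "ols" | "mlp" | "ffnn"
    layers: list[tuple[np.ndarray, np.ndarray]]
    y_standardizer: Standardizer
    x_standardizer: Standardizer | None = None
    fourier_map: FourierMap | None = None
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Batched prediction, (n, 126) -> (n, 48) deflections in mm."""
        single = np.asarray(X).ndim == 1
        H = np.atleast_2d(np.asarray(X, dtype=float))
        if self.fourier_map is not None:
            H = self.fourier_map.transform(H)
        elif self.x_standardizer is not None:
            H = self.x_standardizer.transform(H)
        for i, (W, b) in enumerate(self.layers):
            H = H @ W + b
            if i < len(self.layers) - 1:
                np.maximum(H, 0.0, out=H)
        Y = self.y_standardizer.inverse(H)
        return Y[0] if single else Y


def _check_dataset(data: EncodedDataset, min_samples: int = 1) -> None:
    if data.n_samples < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {data.n_samples}")


def train_ols(train: EncodedDataset) -> SurrogateModel:
    """Least-squares linear baseline on z-scored inputs and outputs.

    Rank-deficient designs fall back to the minimum-norm (pseudo-inverse)
    solution with a warning.
    """
    _check_dataset(train, min_samples=N_INPUT + 1)
    xs = Standardizer.fit(train.X)
    ys = Standardizer.fit(train.Y)
    Xz = xs.transform(train.X)
    Yz = ys.transform(train.Y)
    A = np.hstack([Xz, np.ones((Xz.shape[0], 1))])
    coef, _, rank, _ = np.linalg.lstsq(A, Yz, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"OLS design is rank-deficient (rank {rank} < {A.shape[1]}); "
            "using the minimum-norm pseudo-inverse solution"
        )
    W, b = coef[:-1], coef[-1]
    return SurrogateModel(
        kind="ols",
        layers=[(W, b)],
        y_standardizer=ys,
        x_standardizer=xs,
        metadata={"n_train": train.n_samples, "rank": int(rank)},
    )


def _extract_layers(net: MLPRegressor) -> list[tuple[np.ndarray, np.ndarray]]:
    return [(W.copy(), b.copy()) for W, b in zip(net.coefs_, net.intercepts_)]


def _fit_network(H: np.ndarray, Yz: np.ndarray, net: MLPRegressor, context: str) -> MLPRegressor:
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        try:
            net.fit(H, Yz)
        except ValueError as exc:
            if "infinite" in str(exc) or "NaN" in str(exc):
                raise TrainingDivergedError(f"{context}: training diverged ({exc})") from exc
            raise
    if not all(np.all(np.isfinite(W)) for W in net.coefs_):
        raise TrainingDivergedError(f"{context}: non-finite weights after training")
    return net


def train_mlp(train: EncodedDataset, seed: int = 0) -> SurrogateModel:
    """Two-hidden-layer (48, 48) perceptron, z-scored inputs and outputs.

    All optimizer settings besides the hidden-layer sizes stay at the
    scikit-learn defaults; non-convergence within the default iteration
    budget is logged as a warning and the model returned as-is.
    """
    _check_dataset(train)
    xs = Standardizer.fit(train.X)
    ys = Standardizer.fit(train.Y)
    net = MLPRegressor(hidden_layer_sizes=HIDDEN_LAYERS, random_state=seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        net = _fit_network(xs.transform(train.X), ys.transform(train.Y), net, "mlp")
    for w in caught:
        if "Maximum iterations" in str(w.message):
            warnings.warn(f"mlp: optimizer hit the iteration limit ({w.message})")
    return SurrogateModel(
        kind="mlp",
        layers=_extract_layers(net),
        y_standardizer=ys,
        x_standardizer=xs,
        metadata={
            "seed": seed,
            "n_train": train.n_samples,
            "n_epochs": int(net.n_iter_),
            "activation": "relu",
            "optimizer": "adam",
        },
    )


def train_ffnn(
    train: EncodedDataset,
    learning_rate: float = 0.005,
    scale: float = 0.2,
    seed: int = 0,
    epochs: int = 500,
) -> SurrogateModel:
    """Fourier-feature network: random sinusoidal embedding + (48, 48) MLP.

    One Fourier frequency per input dimension (m = 126, mapped dim 252).
    Raw inputs are fed to the Fourier map un-z-scored — the sinusoids already
    bound them to [-1, 1] — while outputs are z-scored. Trained with Adam at
    ``learning_rate`` for exactly ``epochs`` full-batch epochs.
    """
    if learning_rate <= 0:
        raise ValueError("learning rate must be positive")
    if scale <= 0:
        raise ValueError("Fourier scale must be positive")
    _check_dataset(train)
    fmap = FourierMap.create(train.X.shape[1], scale=scale, seed=seed)
    ys = Standardizer.fit(train.Y)
    net = MLPRegressor(
        hidden_layer_sizes=HIDDEN_LAYERS,
        solver="adam",
        learning_rate_init=learning_rate,
        batch_size=train.n_samples,  # full batch
        max_iter=epochs,
        n_iter_no_change=epochs,  # run the full epoch budget
        tol=0.0,
        random_state=seed,
    )
    try:
        net = _fit_network(fmap.transform(train.X), ys.transform(train.Y), net, "ffnn")
    except TrainingDivergedError as exc:
        raise TrainingDivergedError(f"ffnn diverged at learning rate {learning_rate}") from exc
    return SurrogateModel(
        kind="ffnn",
        layers=_extract_layers(net),
        y_standardizer=ys,
        fourier_map=fmap,
        metadata={
            "seed": seed,
            "n_train": train.n_samples,
            "learning_rate": learning_rate,
            "fourier_scale": scale,
            "n_epochs": int(net.n_iter_),
            "activation": "relu",
            "optimizer": "adam",
        },
    )


def grid_search(
    learning_rates: list[float],
    scales: list[float],
    train: EncodedDataset,
    seed: int = 0,
    tune_fraction: float = 0.2,
    epochs: int = 500,
) -> tuple[tuple[float, float], "pd.DataFrame"]:
    """FFNN hyperparameter search over a (learning rate, Fourier scale) grid.

    Trajectories are split 80/20 into train/tune portions; one model is
    trained per grid point and scored by all-depth MAE on the tune portion.
    Diverged cells score infinity. Returns the argmin pair and the full
    score table.
    """
    import pandas as pd

    if not learning_rates or not scales:
        raise ValueError("both grids must be non-empty")
    ids = np.unique(train.trajectory_id)
    rng = np.random.default_rng(seed)
    tune_ids = set(rng.choice(ids, size=max(1, int(round(tune_fraction * ids.size))), replace=False))
    tune_mask = np.isin(train.trajectory_id, list(tune_ids))
    fit_part = EncodedDataset(train.X[~tune_mask], train.Y[~tune_mask], train.trajectory_id[~tune_mask])
    tune_part = EncodedDataset(train.X[tune_mask], train.Y[tune_mask], train.trajectory_id[tune_mask])

    rows = []
    for lr in learning_rates:
        for s in scales:
            try:
                model = train_ffnn(fit_part, learning_rate=lr, scale=s, seed=seed, epochs=epochs)
                score = float(np.abs(model.predict(tune_part.X) - tune_part.Y).mean())
            except TrainingDivergedError:
                score = np.inf
            rows.append({"learning_rate": lr, "scale": s, "mae": score})
    table = pd.DataFrame(rows)
    best = table.loc[table["mae"].idxmin()]
    return (float(best["learning_rate"]), float(best["scale"])), table


@dataclass(frozen=True)
class EvalReport:
    """Surrogate-vs-simulator errors over a validation subset at one depth.

    ``errors`` are signed (prediction - simulator), per sample and node, mm.
    ``sample_mae`` averages |error| over the scoped nodes of each sample;
    ``mae`` averages those over samples. ``tip_mae`` always scores the tip
    node alone, whatever the scope.
    """

    depth: float
    node_scope: str  # "all" | "tip"
    errors: np.ndarray  # (n_samples, 48), signed, mm
    sample_mae: np.ndarray  # (n_samples,)
    mae: float
    tip_mae: float

    def error_histogram(
        self, bin_width: float = 0.01, max_error: float | None = None, clip_count: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-node histogram of |error| along the needle.

        Returns (bin_edges, counts) with counts of shape (48, n_bins); node
        index doubles as distance-from-base in element lengths. ``clip_count``
        caps each bin for display, mirroring how dense near-base bins are
        usually clipped.
        """
        abs_err = np.abs(self.errors)
        top = max_error if max_error is not None else float(abs_err.max()) + bin_width
        edges = np.arange(0.0, top + bin_width, bin_width)
        counts = np.stack([np.histogram(abs_err[:, j], bins=edges)[0] for j in range(abs_err.shape[1])])
        if clip_count is not None:
            counts = np.minimum(counts, clip_count)
        return edges, counts


def evaluate(
    model: SurrogateModel,
    validation: EncodedDataset,
    depth: float = 65.0,
    node_scope: str = "all",
) -> EvalReport:
    """Score a surrogate against simulator ground truth at one depth."""
    if node_scope not in ("all", "tip"):
        raise ValueError("node_scope must be 'all' or 'tip'")
    try:
        subset = validation.at_depth(depth)
    except ValueError as exc:
        raise ValueError(f"validation set has no samples at depth {depth} mm") from exc
    errors = model.predict(subset.X) - subset.Y
    scoped = np.abs(errors[:, -1:]) if node_scope == "tip" else np.abs(errors)
    sample_mae = scoped.mean(axis=1)
    return EvalReport(
        depth=depth,
        node_scope=node_scope,
        errors=errors,
        sample_mae=sample_mae,
        mae=float(sample_mae.mean()),
        tip_mae=float(np.abs(errors[:, -1]).mean()),
    )


def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Serialize as a named-array .npz plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {
        "y_mean": model.y_standardizer.mean,
        "y_std": model.y_standardizer.std,
    }
    for i, (W, b) in enumerate(model.layers):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if model.x_standardizer is not None:
        arrays["x_mean"] = model.x_standardizer.mean
        arrays["x_std"] = model.x_standardizer.std
    if model.fourier_map is not None:
        arrays["fourier_B"] = np.asarray(model.fourier_map.B)
    np.savez(path, **arrays)
    meta = {
        "format": "needleflex-model-v1",
        "kind": model.kind,
        "n_layers": len(model.layers),
        "fourier_scale": model.fourier_map.scale if model.fourier_map else None,
        "fourier_seed": model.fourier_map.seed if model.fourier_map else None,
        "metadata": model.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path: str | Path) -> SurrogateModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        layers = [(z[f"W{i}"], z[f"b{i}"]) for i in range(meta["n_layers"])]
        ys = Standardizer(z["y_mean"], z["y_std"])
        xs = Standardizer(z["x_mean"], z["x_std"]) if "x_mean" in z else None
        fmap = None
        if "fourier_B" in z:
            B = z["fourier_B"]
            B.setflags(write=False)
            fmap = FourierMap(B=B, scale=meta["fourier_scale"], seed=meta["fourier_seed"])
    return SurrogateModel(
        kind=meta["kind"],
        layers=layers,
        y_standardizer=ys,
        x_standardizer=xs,
        fourier_map=fmap,
        metadata=meta["metadata"],
    )
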