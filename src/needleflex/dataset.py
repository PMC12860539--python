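"""Random layered anatomies and simulator-generated supervised datasets.

Each anatomy has 1-10 homogeneous tissue layers spanning depths 0-125 mm.
Running the insertion simulator over an anatomy yields one supervised sample
per integer insertion depth: the input is a 126-vector (125 per-millimetre
elastic moduli plus the insertion depth in mm) and the target is the
48-vector of nodal needle deflections at that depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .beam_fea import NeedleSpec
from .insertion_sim import MAX_DEPTH, TissueProfile, simulate_insertion

__all__ = [
    "LayeredAnatomy",
    "EncodedDataset",
    "DatasetSplit",
    "sample_anatomy",
    "anatomy_to_profile",
    "profile_to_anatomy",
    "simulate_trajectories",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "TRAIN_DEPTHS",
]

#: Depths at which supervised samples are emitted (the deepest simulated
#: state, 125 mm, is held out of training).
TRAIN_DEPTHS = tuple(range(1, MAX_DEPTH))  # 1..124

MAX_LAYERS = 10
MODULUS_RANGE = (0.0, 0.2)  # MPa, uniform sampling range for layer stiffness


@dataclass(frozen=True)
class LayeredAnatomy:
    """Piecewise-homogeneous tissue column.

    ``boundaries`` are the n_layers-1 transition depths (mm, strictly
    increasing, interior to (0, 125)); ``layer_moduli`` gives one elastic
    modulus (MPa) per layer, ordered from the tissue surface down.
    """

    boundaries: tuple[int, ...]
    layer_moduli: tuple[float, ...]

    def __post_init__(self) -> None:
        n_layers = len(self.layer_moduli)
        if not 1 <= n_layers <= MAX_LAYERS:
            raise ValueError(f"anatomy must have 1..{MAX_LAYERS} layers")
        if len(self.boundaries) != n_layers - 1:
            raise ValueError("need exactly n_layers - 1 boundaries")
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries and not (0 < self.boundaries[0] and self.boundaries[-1] < MAX_DEPTH):
            raise ValueError(f"boundaries must lie strictly inside (0, {MAX_DEPTH})")
        if any(m < 0 for m in self.layer_moduli):
            raise ValueError("layer moduli must be non-negative")

    @property
    def n_layers(self) -> int:
        return len(self.layer_moduli)


def sample_anatomy(rng: np.random.Generator) -> LayeredAnatomy:
    """Draw a random anatomy: uniform layer count, transitions and moduli.

    The layer count is uniform over 1..10, the transition depths are drawn
    uniformly without replacement from the interior integer depths and
    sorted, and each layer modulus is uniform over [0, 0.2] MPa.
    """
    n_layers = int(rng.integers(1, MAX_LAYERS + 1))
    cuts = rng.choice(np.arange(1, MAX_DEPTH), size=n_layers - 1, replace=False)
    moduli = rng.uniform(*MODULUS_RANGE, size=n_layers)
    return LayeredAnatomy(tuple(int(c) for c in np.sort(cuts)), tuple(float(m) for m in moduli))


def anatomy_to_profile(anatomy: LayeredAnatomy) -> TissueProfile:
    """Expand an anatomy into the per-millimetre 125-value modulus array.

    A boundary at depth b puts depths 1..b in the shallower layer and
    b+1..125 in the deeper one.
    """
    values = np.empty(MAX_DEPTH)
    edges = (0, *anatomy.boundaries, MAX_DEPTH)
    for modulus, lo, hi in zip(anatomy.layer_moduli, edges[:-1], edges[1:]):
        values[lo:hi] = modulus
    return TissueProfile(values)


def profile_to_anatomy(profile: TissueProfile) -> LayeredAnatomy:
    """Infer layer boundaries back from a piecewise-constant profile."""
    vals = profile.modulus_per_mm
    change = np.flatnonzero(np.diff(vals)) + 1  # index i => boundary at depth i
    moduli = tuple(float(v) for v in vals[np.r_[0, change]])
    return LayeredAnatomy(tuple(int(c) for c in change), moduli)


@dataclass(frozen=True)
class EncodedDataset:
    """Flat supervised dataset: X (N, 126), Y (N, 48), trajectory ids (N,)."""

    X: np.ndarray
    Y: np.ndarray
    trajectory_id: np.ndarray

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != MAX_DEPTH + 1:
            raise ValueError(f"X must have {MAX_DEPTH + 1} columns")
        if self.Y.shape[0] != self.X.shape[0] or self.trajectory_id.shape[0] != self.X.shape[0]:
            raise ValueError("X, Y and trajectory_id must share their first dimension")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def depths(self) -> np.ndarray:
        return self.X[:, -1]

    def at_depth(self, depth: float) -> "EncodedDataset":
        """Subset of samples at one insertion depth (mm)."""
        mask = self.depths == depth
        if not mask.any():
            raise ValueError(f"no samples at depth {depth} mm")
        return EncodedDataset(self.X[mask], self.Y[mask], self.trajectory_id[mask])


@dataclass(frozen=True)
class DatasetSplit:
    """Train/validation datasets from disjoint trajectory sets."""

    train: EncodedDataset
    validation: EncodedDataset
    seed: int

    def __post_init__(self) -> None:
        shared = set(self.train.trajectory_id) & set(self.validation.trajectory_id)
        if shared:
            raise ValueError(f"train/validation share trajectory ids: {sorted(shared)[:5]}")


def _encode_trajectory(
    profile: TissueProfile, traj_id: int, needle: NeedleSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    traj = simulate_insertion(needle, profile, MAX_DEPTH)
    W = traj.deflection_matrix()  # (125, 48)
    n = len(TRAIN_DEPTHS)
    X = np.empty((n, MAX_DEPTH + 1))
    X[:, :MAX_DEPTH] = profile.modulus_per_mm
    X[:, -1] = TRAIN_DEPTHS
    Y = W[np.array(TRAIN_DEPTHS) - 1]
    ids = np.full(n, traj_id)
    return X, Y, ids


def simulate_trajectories(
    anatomies: list[LayeredAnatomy],
    first_id: int = 0,
    needle: NeedleSpec | None = None,
) -> EncodedDataset:
    """Simulate each anatomy to full depth and encode per-depth samples.

    Simulator failures are skipped with a warning; the returned dataset
    carries one block of 124 samples per surviving trajectory.
    """
    import warnings

    needle = needle or NeedleSpec()
    blocks_x, blocks_y, blocks_id = [], [], []
    n_failed = 0
    for i, anatomy in enumerate(anatomies):
        try:
            X, Y, ids = _encode_trajectory(anatomy_to_profile(anatomy), first_id + i, needle)
        except RuntimeError as exc:
            n_failed += 1
            warnings.warn(f"trajectory {first_id + i} failed and was skipped: {exc}")
            continue
        blocks_x.append(X)
        blocks_y.append(Y)
        blocks_id.append(ids)
    if not blocks_x:
        raise RuntimeError(f"all {len(anatomies)} trajectories failed to simulate")
    if n_failed:
        warnings.warn(f"{n_failed} of {len(anatomies)} trajectories failed and were skipped")
    return EncodedDataset(np.vstack(blocks_x), np.vstack(blocks_y), np.concatenate(blocks_id))


def generate_dataset(
    n_train: int,
    n_validation: int,
    seed: int,
    needle: NeedleSpec | None = None,
) -> DatasetSplit:
    """Sample anatomies, simulate, and split by trajectory.

    The split is by trajectory, never by depth-state: all 124 per-depth
    samples of one insertion land on the same side. Deterministic in
    ``seed``.
    """
    if n_train < 1 or n_validation < 0:
        raise ValueError("need at least one training trajectory")
    rng = np.random.default_rng(seed)
    anatomies = [sample_anatomy(rng) for _ in range(n_train + n_validation)]
    train = simulate_trajectories(anatomies[:n_train], first_id=0, needle=needle)
    validation = simulate_trajectories(anatomies[n_train:], first_id=n_train, needle=needle)
    return DatasetSplit(train=train, validation=validation, seed=seed)


def save_dataset(split: DatasetSplit, path: str | Path) -> None:
    """Write a split as one .npz of named arrays plus a JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        train_X=split.train.X,
        train_Y=split.train.Y,
        train_id=split.train.trajectory_id,
        val_X=split.validation.X,
        val_Y=split.validation.Y,
        val_id=split.validation.trajectory_id,
    )
    manifest = {
        "format": "needleflex-dataset-v1",
        "seed": split.seed,
        "n_train_samples": split.train.n_samples,
        "n_validation_samples": split.validation.n_samples,
        "n_train_trajectories": int(np.unique(split.train.trajectory_id).size),
        "n_validation_trajectories": int(np.unique(split.validation.trajectory_id).size),
    }
    manifest_path = path.with_suffix(".json")
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")


def load_dataset(path: str | Path) -> DatasetSplit:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as z:
        train = EncodedDataset(z["train_X"], z["train_Y"], z["train_id"])
        val = EncodedDataset(z["val_X"], z["val_Y"], z["val_id"])
    manifest_path = path.with_suffix(".json")
    seed = -1
    if manifest_path.exists():
        seed = json.loads(manifest_path.read_text()).get("seed", -1)
    return DatasetSplit(train=train, validation=val, seed=seed)


def export_table(dataset: EncodedDataset, path: str | Path) -> None:
    """Tabular text export (CSV): one row per sample, x then y columns."""
    import pandas as pd

    cols = (
        {"trajectory_id": dataset.trajectory_id}
        | {f"modulus_mm_{i + 1}": dataset.X[:, i] for i in range(MAX_DEPTH)}
        | {"depth_mm": dataset.X[:, -1]}
        | {f"deflection_node_{j}": dataset.Y[:, j] for j in range(dataset.Y.shape[1])}
    )
    pd.DataFrame(cols).to_csv(path, index=False)
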