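"""Structured-text configuration readers and trajectory export.

Tissue, needle and prior configurations are YAML. A tissue config gives
either an explicit 125-value ``modulus_per_mm`` array or a ``layers`` list of
``{to_depth_mm, modulus_mpa}`` entries; a prior config gives a ``layers``
list of ``{to_depth_mm, mu_mpa, sigma_mpa}``. Needle constants default to
the 18-gauge nitinol needle and can be overridden field by field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .beam_fea import NeedleSpec
from .dataset import LayeredAnatomy, anatomy_to_profile
from .insertion_sim import MAX_DEPTH, TissueProfile, Trajectory
from .uq import PriorSpec

__all__ = [
    "load_needle_config",
    "load_tissue_config",
    "load_prior_config",
    "export_trajectory_csv",
    "export_trajectory_npz",
]

_NEEDLE_FIELDS = {
    "length", "outer_diameter", "inner_diameter", "elastic_modulus",
    "bevel_angle", "n_elements",
}


def _read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return doc


def load_needle_config(path: str | Path | None) -> NeedleSpec:
    """Needle constants from YAML; missing fields keep the 18-gauge defaults."""
    if path is None:
        return NeedleSpec()
    doc = _read_yaml(path)
    unknown = set(doc) - _NEEDLE_FIELDS
    if unknown:
        raise ValueError(f"unknown needle config fields: {sorted(unknown)}")
    return NeedleSpec(**doc)


def _layers_to_boundaries(layers: list[dict], value_keys: tuple[str, ...]) -> tuple[list[int], list[dict]]:
    if not layers:
        raise ValueError("config must define at least one tissue layer")
    boundaries = []
    for layer in layers[:-1]:
        boundaries.append(int(layer["to_depth_mm"]))
    last_to = layers[-1].get("to_depth_mm", MAX_DEPTH)
    if int(last_to) != MAX_DEPTH:
        raise ValueError(f"the deepest layer must extend to {MAX_DEPTH} mm")
    for layer in layers:
        missing = [k for k in value_keys if k not in layer]
        if missing:
            raise ValueError(f"layer {layer} missing keys {missing}")
    return boundaries, layers


def load_tissue_config(path: str | Path) -> TissueProfile:
    """Tissue profile from YAML: explicit per-mm array or layer list."""
    doc = _read_yaml(path)
    if "modulus_per_mm" in doc:
        return TissueProfile(np.asarray(doc["modulus_per_mm"], dtype=float))
    boundaries, layers = _layers_to_boundaries(doc["layers"], ("modulus_mpa",))
    anatomy = LayeredAnatomy(tuple(boundaries), tuple(float(l["modulus_mpa"]) for l in layers))
    return anatomy_to_profile(anatomy)


def load_prior_config(path: str | Path) -> PriorSpec:
    """Per-layer truncated-normal prior from YAML."""
    doc = _read_yaml(path)
    boundaries, layers = _layers_to_boundaries(doc["layers"], ("mu_mpa", "sigma_mpa"))
    return PriorSpec(
        boundaries=tuple(boundaries),
        mu=tuple(float(l["mu_mpa"]) for l in layers),
        sigma=tuple(float(l["sigma_mpa"]) for l in layers),
    )


def export_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """One row per node per depth: depth, node, axial position, w, theta."""
    import pandas as pd

    positions = traj.needle.node_positions
    rows = {
        "depth_mm": np.repeat([s.depth for s in traj.states], traj.needle.n_nodes),
        "node_index": np.tile(np.arange(traj.needle.n_nodes), len(traj.states)),
        "axial_position_mm": np.tile(positions, len(traj.states)),
        "deflection_mm": np.concatenate([s.deflection for s in traj.states]),
        "slope_rad": np.concatenate([s.slope for s in traj.states]),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def export_trajectory_npz(traj: Trajectory, path: str | Path) -> None:
    """Named-array container: deflection/slope matrices plus geometry."""
    np.savez(
        path,
        depths=np.array([s.depth for s in traj.states]),
        deflection=traj.deflection_matrix(),
        slope=np.stack([s.slope for s in traj.states]),
        node_positions=traj.needle.node_positions,
        modulus_per_mm=traj.tissue.modulus_per_mm,
    )
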