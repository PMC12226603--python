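"""Container formats: HDF5 archives, PNG masks, YAML configs, seed derivation.

All HDF5 artifacts carry ``schema_version``, a config hash, and the seed that
produced them; sparse matrices are stored as CSR triplets.  Every stochastic
stage derives its generator seed deterministically from the global seed plus
a stage tag, so pipelines are reproducible end to end with no hidden global
random state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import scipy.sparse as sp
import yaml
from PIL import Image

from .geometry import AcquisitionSpec, ForwardModel, ImagingGrid
from .phantoms import SimDataset, SimulationConfig
from .uncertainty import BVIPosterior, PosteriorSummary
from .varnet import ControlPointFunction, VNLayerParams, VNParams

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """Raised on missing keys or incompatible schema versions."""


# ---------------------------------------------------------------------------
# Seeds and hashes
# ---------------------------------------------------------------------------


def seed_for(global_seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def config_hash(cfg) -> str:
    """Stable short hash of any (nested) dataclass/dict configuration."""
    blob = json.dumps(_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_meta(g, cfg_hash: str, seed: int) -> None:
    g.attrs["schema_version"] = SCHEMA_VERSION
    g.attrs["config_hash"] = cfg_hash
    g.attrs["seed"] = seed


def _check_meta(g, path) -> None:
    if "schema_version" not in g.attrs:
        raise SchemaError(f"{path}: missing schema_version attribute")
    v = int(g.attrs["schema_version"])
    if v != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {v} not supported (expected {SCHEMA_VERSION}); "
            "no migration available"
        )


def _require(g, key, path):
    if key not in g:
        raise SchemaError(f"{path}: missing required dataset/group '{key}'")
    return g[key]


# ---------------------------------------------------------------------------
# Grids / specs / forward model
# ---------------------------------------------------------------------------


def _save_grid(g, grid: ImagingGrid) -> None:
    for f in dataclasses.fields(grid):
        g.attrs[f.name] = getattr(grid, f.name)


def _load_grid(g) -> ImagingGrid:
    return ImagingGrid(
        n_ax=int(g.attrs["n_ax"]),
        n_lat=int(g.attrs["n_lat"]),
        pitch_ax=float(g.attrs["pitch_ax"]),
        pitch_lat=float(g.attrs["pitch_lat"]),
        depth_offset=float(g.attrs["depth_offset"]),
    )


def _save_spec(g, spec: AcquisitionSpec) -> None:
    g.attrs["n_transmits"] = spec.n_transmits
    g.attrs["pair_offset"] = spec.pair_offset
    g.attrs["c0"] = spec.c0
    g.attrs["vs_focal_mm"] = spec.vs_focal_mm
    g.attrs["angles_deg"] = spec.angles_deg
    if spec.aperture_width is not None:
        g.attrs["aperture_width"] = spec.aperture_width


def _load_spec(g) -> AcquisitionSpec:
    return AcquisitionSpec(
        n_transmits=int(g.attrs["n_transmits"]),
        pair_offset=int(g.attrs["pair_offset"]),
        vs_angles_deg=tuple(np.asarray(g.attrs["angles_deg"], dtype=float)),
        c0=float(g.attrs["c0"]),
        aperture_width=float(g.attrs["aperture_width"]) if "aperture_width" in g.attrs else None,
        vs_focal_mm=float(g.attrs["vs_focal_mm"]),
    )


def save_forward_model(path, model: ForwardModel, seed: int = 0) -> None:
    with h5py.File(path, "w") as f:
        _write_meta(f, config_hash(model.spec), seed)
        L = model.L.tocsr()
        f.create_dataset("indptr", data=L.indptr)
        f.create_dataset("indices", data=L.indices)
        f.create_dataset("data", data=L.data)
        f.attrs["shape"] = L.shape
        f.attrs["pairs"] = np.asarray(model.pairs)
        _save_grid(f.create_group("recon_grid"), model.recon_grid)
        _save_grid(f.create_group("meas_grid"), model.meas_grid)
        _save_spec(f.create_group("spec"), model.spec)


def load_forward_model(path) -> ForwardModel:
    with h5py.File(path, "r") as f:
        _check_meta(f, path)
        for key in ("indptr", "indices", "data", "recon_grid", "meas_grid", "spec"):
            _require(f, key, path)
        L = sp.csr_matrix(
            (f["data"][()], f["indices"][()], f["indptr"][()]),
            shape=tuple(f.attrs["shape"]),
        )
        return ForwardModel(
            L=L,
            recon_grid=_load_grid(f["recon_grid"]),
            meas_grid=_load_grid(f["meas_grid"]),
            pairs=tuple(tuple(p) for p in np.asarray(f.attrs["pairs"])),
            spec=_load_spec(f["spec"]),
        )


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


def save_dataset(path, train: SimDataset, test: SimDataset, cfg: SimulationConfig) -> None:
    with h5py.File(path, "w") as f:
        _write_meta(f, config_hash(cfg), cfg.seed)
        for name, ds in (("train", train), ("test", test)):
            g = f.create_group(name)
            g.create_dataset("d", data=ds.d)
            g.create_dataset("sos_gt", data=ds.sos_gt)
            g.create_dataset("mask", data=ds.mask)
            _save_grid(g.create_group("grid"), ds.grid)
            _save_spec(g.create_group("spec"), ds.spec)
            g.attrs["seed"] = ds.seed


def load_dataset(path) -> tuple[SimDataset, SimDataset]:
    out = []
    with h5py.File(path, "r") as f:
        _check_meta(f, path)
        for name in ("train", "test"):
            g = _require(f, name, path)
            for key in ("d", "sos_gt", "mask", "grid", "spec"):
                _require(g, key, path)
            out.append(
                SimDataset(
                    d=g["d"][()],
                    sos_gt=g["sos_gt"][()],
                    mask=g["mask"][()].astype(bool),
                    grid=_load_grid(g["grid"]),
                    spec=_load_spec(g["spec"]),
                    seed=int(g.attrs["seed"]),
                )
            )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Network checkpoints and posteriors
# ---------------------------------------------------------------------------


def save_vn_params(path, params: VNParams, cfg=None, seed: int = 0) -> None:
    with h5py.File(path, "w") as f:
        _write_meta(f, config_hash(cfg) if cfg is not None else "", seed)
        f.attrs["recon_shape"] = params.recon_shape
        f.attrs["n_pairs"] = params.n_pairs
        f.attrs["x_unit"] = params.x_unit
        f.attrs["d_unit"] = params.d_unit
        f.attrs["c0"] = params.c0
        for k, layer in enumerate(params.layers):
            g = f.create_group(f"layers/{k}")
            g.create_dataset("filters", data=layer.filters)
            g.create_dataset("w", data=layer.w)
            g.create_dataset("s", data=layer.s)
            g.create_dataset("phi_scale", data=layer.phi_scale)
            g.attrs["psi_scale"] = layer.psi_scale
            g.create_dataset("psi_knots", data=layer.psi.knots)
            g.create_dataset("psi_y", data=layer.psi.y)
            g.create_dataset("phi_knots", data=np.stack([p.knots for p in layer.phi]))
            g.create_dataset("phi_y", data=np.stack([p.y for p in layer.phi]))


def load_vn_params(path) -> VNParams:
    with h5py.File(path, "r") as f:
        _check_meta(f, path)
        layers = []
        lg = _require(f, "layers", path)
        for k in sorted(lg, key=int):
            g = lg[k]
            phi = [
                ControlPointFunction(knots=kn, y=y)
                for kn, y in zip(g["phi_knots"][()], g["phi_y"][()])
            ]
            layers.append(
                VNLayerParams(
                    filters=g["filters"][()],
                    w=g["w"][()],
                    phi=phi,
                    psi=ControlPointFunction(knots=g["psi_knots"][()], y=g["psi_y"][()]),
                    s=g["s"][()],
                    phi_scale=g["phi_scale"][()],
                    psi_scale=float(g.attrs["psi_scale"]),
                )
            )
        return VNParams(
            layers=layers,
            recon_shape=tuple(f.attrs["recon_shape"]),
            n_pairs=int(f.attrs["n_pairs"]),
            x_unit=float(f.attrs["x_unit"]),
            d_unit=float(f.attrs["d_unit"]),
            c0=float(f.attrs["c0"]),
        )


def save_bvi_posterior(path, post: BVIPosterior, seed: int = 0) -> None:
    with h5py.File(path, "w") as f:
        _write_meta(f, "", seed)
        f.create_dataset("mu", data=post.mu)
        f.create_dataset("blocks", data=post.blocks)
        f.attrs["K"] = post.K
        f.attrs["n_priors"] = post.n_priors
        f.attrs["kernel_size"] = post.kernel_size
        f.attrs["alpha"] = post.alpha


def load_bvi_posterior(path) -> BVIPosterior:
    with h5py.File(path, "r") as f:
        _check_meta(f, path)
        return BVIPosterior(
            mu=_require(f, "mu", path)[()],
            blocks=_require(f, "blocks", path)[()],
            K=int(f.attrs["K"]),
            n_priors=int(f.attrs["n_priors"]),
            kernel_size=int(f.attrs["kernel_size"]),
            alpha=float(f.attrs["alpha"]),
        )


def save_posterior_summary(path, summary: PosteriorSummary, seed: int = 0, samples=None) -> None:
    with h5py.File(path, "w") as f:
        _write_meta(f, "", seed)
        f.create_dataset("mean_sos", data=summary.mean_sos.values)
        f.create_dataset("std_map", data=summary.std_map)
        f.attrs["n_samples"] = summary.n_samples
        _save_grid(f.create_group("grid"), summary.mean_sos.grid)
        if samples is not None:
            f.create_dataset("samples", data=np.stack([s.values for s in samples]))


def load_posterior_summary(path) -> PosteriorSummary:
    from .maps import SoSMap

    with h5py.File(path, "r") as f:
        _check_meta(f, path)
        grid = _load_grid(_require(f, "grid", path))
        return PosteriorSummary(
            mean_sos=SoSMap(values=_require(f, "mean_sos", path)[()], grid=grid),
            std_map=_require(f, "std_map", path)[()],
            n_samples=int(f.attrs["n_samples"]),
        )


# ---------------------------------------------------------------------------
# PNG masks and YAML configs
# ---------------------------------------------------------------------------


def save_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def load_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 0


def load_yaml_config(path) -> dict:
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: YAML config must be a mapping")
    return data
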