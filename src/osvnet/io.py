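"""Dataset containers, model checkpoints and run configuration.

One HDF5 layout is shared by features, labels and predictions:

    /meta                    attrs: basis, n_osv, cutoff, n_occ, e_hf,
                             channel_order, flatten_order, format_version
    /pairs/{i}_{j}/tensor    (4, n_osv, n_osv) float64
    /labels/{i}_{j}          scalar e_ij (Hartree), attr e_corr on /labels
    /predictions/{i}_{j}     scalar e_ij^P

Round-trips are bit-exact (float64 throughout).  Model checkpoints store the
network spec, the standardizer statistics and every parameter array; tuned
checkpoints store the base checkpoint's hash plus only the method's deltas.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from .finetune import FineTunedPairMLP
from .models import PairMLPRegressor
from .mp2 import PairEnergyTable, PairKey
from .nn import Adapters, NetworkSpec, Standardizer
from .osv import CHANNELS, FeatureSet, PairFeature

FORMAT_VERSION = 1


# ------------------------------------------------------------------ features

def save_feature_set(fs: FeatureSet, path: str | Path,
                     labels: PairEnergyTable | None = None,
                     mode: str = "w") -> None:
    with h5py.File(path, mode) as h5:
        meta = h5.require_group("meta")
        meta.attrs.update({
            "basis": fs.basis, "n_osv": fs.n_osv, "cutoff": fs.cutoff,
            "n_occ": fs.n_occ, "e_hf": fs.e_hf,
            "channel_order": ",".join(CHANNELS),
            "flatten_order": "channel-major,row-major",
            "format_version": FORMAT_VERSION,
        })
        meta.attrs["screened_out"] = np.array(
            [[k.i, k.j] for k in fs.screened_out], dtype=np.int64).reshape(
                -1, 2)
        grp = h5.require_group("pairs")
        for f in fs.features:
            g = grp.require_group(f"{f.key.i}_{f.key.j}")
            if "tensor" in g:
                del g["tensor"]
            g.create_dataset("tensor", data=f.tensor, dtype="f8")
        if labels is not None:
            save_labels_h5(labels, h5)


def load_feature_set(path: str | Path) -> FeatureSet:
    with h5py.File(path, "r") as h5:
        meta = dict(h5["meta"].attrs)
        feats = []
        for name, g in h5["pairs"].items():
            i, j = (int(x) for x in name.split("_"))
            feats.append(PairFeature(PairKey(i, j), g["tensor"][()]))
        feats.sort(key=lambda f: (f.key.i, f.key.j))
        screened = [PairKey(int(i), int(j))
                    for i, j in meta.get("screened_out",
                                         np.empty((0, 2), int))]
    return FeatureSet(features=feats, n_occ=int(meta["n_occ"]),
                      n_osv=int(meta["n_osv"]), cutoff=float(meta["cutoff"]),
                      basis=str(meta["basis"]), screened_out=screened,
                      e_hf=float(meta["e_hf"]))


def save_labels_h5(table: PairEnergyTable, h5: h5py.File | h5py.Group) -> None:
    if "labels" in h5:
        del h5["labels"]
    g = h5.create_group("labels")
    g.attrs["e_corr"] = table.e_corr
    g.attrs["level"] = table.level
    for key, val in table.entries.items():
        g.create_dataset(f"{key.i}_{key.j}", data=float(val), dtype="f8")


def load_labels_h5(path: str | Path) -> PairEnergyTable:
    with h5py.File(path, "r") as h5:
        g = h5["labels"]
        entries = {}
        for name, ds in g.items():
            i, j = (int(x) for x in name.split("_"))
            entries[PairKey(i, j)] = float(ds[()])
        return PairEnergyTable(entries=entries,
                               e_corr=float(g.attrs["e_corr"]),
                               level=str(g.attrs["level"]))


# --------------------------------------------------------------- checkpoints

def _std_to_group(std: Standardizer, g) -> None:
    g.create_dataset("feature_mean", data=std.feature_mean, dtype="f8")
    g.create_dataset("feature_scale", data=std.feature_scale, dtype="f8")
    g.attrs["label_mean"] = std.label_mean
    g.attrs["label_scale"] = std.label_scale


def _std_from_group(g) -> Standardizer:
    std = Standardizer()
    std.feature_mean = g["feature_mean"][()]
    std.feature_scale = g["feature_scale"][()]
    std.label_mean = float(g.attrs["label_mean"])
    std.label_scale = float(g.attrs["label_scale"])
    return std


def model_hash(model: PairMLPRegressor) -> str:
    h = hashlib.sha256()
    for arr in model.weights_ + model.biases_:
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def save_checkpoint(model: PairMLPRegressor, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["kind"] = "base"
        h5.attrs["format_version"] = FORMAT_VERSION
        h5.attrs["spec"] = json.dumps(vars(model.spec_) if not hasattr(
            model.spec_, "__dataclass_fields__") else {
                k: getattr(model.spec_, k)
                for k in model.spec_.__dataclass_fields__})
        h5.attrs["hash"] = model_hash(model)
        for k, (w, b) in enumerate(zip(model.weights_, model.biases_)):
            h5.create_dataset(f"layers/{k}/W", data=w, dtype="f8")
            h5.create_dataset(f"layers/{k}/b", data=b, dtype="f8")
        _std_to_group(model.standardizer_, h5.create_group("standardizer"))


def load_checkpoint(path: str | Path) -> PairMLPRegressor:
    with h5py.File(path, "r") as h5:
        if h5.attrs["kind"] != "base":
            raise ValueError("not a base-model checkpoint")
        spec = json.loads(h5.attrs["spec"])
        model = PairMLPRegressor(
            n_hidden_layers=spec["n_hidden_layers"],
            hidden_width=spec["hidden_width"],
            activation=spec["activation"], seed=spec["seed"])
        layers = sorted(h5["layers"], key=int)
        model.weights_ = [h5[f"layers/{k}/W"][()] for k in layers]
        model.biases_ = [h5[f"layers/{k}/b"][()] for k in layers]
        model.spec_ = NetworkSpec(**spec)
        model.standardizer_ = _std_from_group(h5["standardizer"])
        model.n_features_in_ = spec["input_dim"]
        model.log_ = None
        return model


def save_tuned_checkpoint(model: FineTunedPairMLP, path: str | Path) -> None:
    """Store base hash + method deltas only (the base ships separately)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["kind"] = "tuned"
        h5.attrs["method"] = model.method
        h5.attrs["rank"] = model.rank
        h5.attrs["base_hash"] = model_hash(model.base)
        ad = model.adapters_
        if model.method == "full":
            for k, (w, b) in enumerate(zip(model.weights_, model.biases_)):
                h5.create_dataset(f"layers/{k}/W", data=w, dtype="f8")
                h5.create_dataset(f"layers/{k}/b", data=b, dtype="f8")
        if ad.has_lora():
            for k, (a, bb) in enumerate(zip(ad.lora_A, ad.lora_B)):
                h5.create_dataset(f"lora/{k}/A", data=a, dtype="f8")
                h5.create_dataset(f"lora/{k}/B", data=bb, dtype="f8")
            h5.attrs["shortcut"] = ad.shortcut
        if ad.delta_b is not None:
            for k, d in enumerate(ad.delta_b):
                h5.create_dataset(f"delta_b/{k}", data=d, dtype="f8")
        if ad.has_head():
            h5.create_dataset("head/W", data=ad.head_W, dtype="f8")
            h5.create_dataset("head/b", data=ad.head_b, dtype="f8")


def load_tuned_checkpoint(path: str | Path,
                          base: PairMLPRegressor) -> FineTunedPairMLP:
    with h5py.File(path, "r") as h5:
        if h5.attrs["kind"] != "tuned":
            raise ValueError("not a tuned-model checkpoint")
        if h5.attrs["base_hash"] != model_hash(base):
            raise ValueError("base model does not match checkpoint hash")
        model = FineTunedPairMLP(base, method=str(h5.attrs["method"]),
                                 rank=int(h5.attrs["rank"]))
        model.initialize()
        if model.method == "full":
            layers = sorted(h5["layers"], key=int)
            model.weights_ = [h5[f"layers/{k}/W"][()] for k in layers]
            model.biases_ = [h5[f"layers/{k}/b"][()] for k in layers]
        ad = model.adapters_
        if "lora" in h5:
            for k in sorted(h5["lora"], key=int):
                ad.lora_A[int(k)] = h5[f"lora/{k}/A"][()]
                ad.lora_B[int(k)] = h5[f"lora/{k}/B"][()]
        if "delta_b" in h5:
            for k in sorted(h5["delta_b"], key=int):
                ad.delta_b[int(k)] = h5[f"delta_b/{k}"][()]
        if "head" in h5:
            ad.head_W = h5["head/W"][()]
            ad.head_b = h5["head/b"][()]
        return model


# ------------------------------------------------------------- run config

class StageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FeaturizeConfig(StageConfig):
    basis: str = "sto-3g"
    n_osv: int = 8
    cutoff: float = 3.2e-5
    frozen_core: bool = True


class TrainConfig(StageConfig):
    n_hidden_layers: int = 10
    hidden_width: int = 50
    schedule: list[tuple[int, float]] = [(500, 1e-3), (500, 1e-4)]
    batch_size: int = 64
    validation_fraction: float = 0.1
    n_repeats: int = 3


class FineTuneConfig(StageConfig):
    method: str = "lora_r"
    rank: int = 1
    schedule: list[tuple[int, float]] = [(200, 1e-5), (800, 1e-6)]
    batch_size: int = 64


class RunConfig(StageConfig):
    """Schema-validated top-level configuration; unknown keys rejected."""

    seed: int = 0
    featurize: FeaturizeConfig = FeaturizeConfig()
    train: TrainConfig = TrainConfig()
    finetune: FineTuneConfig = FineTuneConfig()


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)


def provenance_record(config: dict, seed: int) -> dict:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    from . import __version__
    return {"config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "seed": seed, "package_version": __version__,
            "format_version": FORMAT_VERSION}
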