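"""Reading and writing masks, metric tables and model artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from vnqi.synthetic import VesselMask

__all__ = ["save_mask", "load_mask", "save_chain", "load_chain"]


def save_mask(mask: VesselMask, path: str | Path) -> None:
    """Write a mask as a single-channel 8-bit image (0/255), TIFF or PNG."""
    arr = (np.asarray(mask.pixels, dtype=np.uint8)) * 255
    iio.imwrite(Path(path), arr)


def load_mask(path: str | Path, pixel_pitch: float) -> VesselMask:
    """Read a single-channel image as a binary mask (any nonzero = vessel)."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:  # collapse RGB(A) exports of binary images
        arr = arr[..., :3].max(axis=-1)
    return VesselMask((arr > 0).astype(np.uint8), pixel_pitch, provenance=str(path))


def save_chain(chain, outdir: str | Path) -> None:
    """Serialize a fitted chain: NN weights as .npz, manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, nn in (("nn1", chain.nn1), ("nn2", chain.nn2)):
        arrays = {}
        for i, (w, b) in enumerate(zip(nn.coefs_, nn.intercepts_)):
            arrays[f"coef_{i}"] = w
            arrays[f"intercept_{i}"] = b
        np.savez(outdir / f"{name}_weights.npz", **arrays)
    np.savez(
        outdir / "scalers.npz",
        scaler6_mean=chain.scaler6.mean_,
        scaler6_scale=chain.scaler6.scale_,
        scaler7_mean=chain.scaler7.mean_,
        scaler7_scale=chain.scaler7.scale_,
    )
    (outdir / "manifest.json").write_text(json.dumps(chain.manifest, indent=2))


def load_chain(outdir: str | Path):
    """Reload a serialized chain into a prediction-capable object."""
    from sklearn.neural_network import MLPRegressor
    from sklearn.preprocessing import StandardScaler

    from vnqi.model import TrainedChain

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())

    def rebuild(name: str, n_in: int) -> MLPRegressor:
        data = np.load(outdir / f"{name}_weights.npz")
        n_layers = len([k for k in data.files if k.startswith("coef_")])
        coefs = [data[f"coef_{i}"] for i in range(n_layers)]
        intercepts = [data[f"intercept_{i}"] for i in range(n_layers)]
        hidden = tuple(c.shape[1] for c in coefs[:-1])
        nn = MLPRegressor(hidden_layer_sizes=hidden)
        nn.coefs_ = coefs
        nn.intercepts_ = intercepts
        nn.n_layers_ = n_layers + 1
        nn.n_outputs_ = coefs[-1].shape[1]
        nn.n_features_in_ = n_in
        nn.out_activation_ = "identity"
        nn.activation = manifest.get("activation", "relu")
        return nn

    scal = np.load(outdir / "scalers.npz")

    def rebuild_scaler(prefix: str) -> StandardScaler:
        s = StandardScaler()
        s.mean_ = scal[f"{prefix}_mean"]
        s.scale_ = scal[f"{prefix}_scale"]
        s.var_ = s.scale_**2
        s.n_features_in_ = len(s.mean_)
        return s

    return TrainedChain(
        nn1=rebuild("nn1", 6),
        nn2=rebuild("nn2", 7),
        scaler6=rebuild_scaler("scaler6"),
        scaler7=rebuild_scaler("scaler7"),
        manifest=manifest,
    )
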