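"""File I/O: PNG/NPZ images, CSV manifests and model containers.

The segmenter container is a single ``.npz`` holding the RBM arrays plus a
JSON metadata string (geometry, head coefficients); GBDT models serialize
their trees to JSON.
"""

from __future__ import annotations

import json
import pathlib

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .boosting import GBDTModel, GBDTParams
from .rbm import RBMParams
from .segmenter import DBNSegmenter

__all__ = ["write_image", "read_image", "write_mask", "read_mask",
           "save_segmenter", "load_segmenter", "save_gbdt", "load_gbdt",
           "write_dataset"]


def write_image(path, img: np.ndarray) -> None:
    path = pathlib.Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, image=np.asarray(img, dtype=np.float64))
    else:
        arr = np.clip(np.asarray(img, float), 0, 1)
        iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def read_image(path) -> np.ndarray:
    path = pathlib.Path(path)
    if path.suffix == ".npz":
        return np.load(path)["image"]
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom  # optional read path

        arr = pydicom.dcmread(path).pixel_array.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.float64) / 255.0


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def write_dataset(ds, out_dir) -> pathlib.Path:
    """Write images/masks as PNG plus a CSV manifest (path, label, split)."""
    out = pathlib.Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    part_of = {}
    for part, idxs in ds.split.items():
        for i in idxs:
            part_of[i] = part
    rows = []
    for i, s in enumerate(ds.samples):
        ipath = out / "images" / f"{i:05d}.png"
        mpath = out / "masks" / f"{i:05d}.png"
        write_image(ipath, s.image)
        write_mask(mpath, s.mask)
        rows.append({"path": str(ipath), "mask": str(mpath),
                     "label": s.label, "split": part_of[i]})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def save_segmenter(model: DBNSegmenter, path) -> None:
    meta = json.dumps({k: getattr(model, k) for k in (
        "patch_size", "stride", "n_hidden_gb", "n_hidden_bb", "threshold",
        "assembly_block")})
    arrays = {
        "meta": np.array(meta),
        "gb_W": model.rbm_gb_.W, "gb_bv": model.rbm_gb_.b_vis,
        "gb_bh": model.rbm_gb_.b_hid,
        "bb_W": model.rbm_bb_.W, "bb_bv": model.rbm_bb_.b_vis,
        "bb_bh": model.rbm_bb_.b_hid,
        "mean": model.mean_, "std": model.std_,
    }
    for i, (w, b) in enumerate(zip(model.head_.coefs_,
                                   model.head_.intercepts_)):
        arrays[f"head_W{i}"] = w
        arrays[f"head_b{i}"] = b
    np.savez_compressed(path, **arrays)


def load_segmenter(path) -> DBNSegmenter:
    import warnings

    from sklearn.neural_network import MLPClassifier

    z = np.load(path, allow_pickle=False)
    meta = json.loads(str(z["meta"]))
    model = DBNSegmenter(**meta)
    model.rbm_gb_ = RBMParams(z["gb_W"], z["gb_bv"], z["gb_bh"], kind="GB")
    model.rbm_bb_ = RBMParams(z["bb_W"], z["bb_bv"], z["bb_bh"], kind="BB")
    model.mean_ = z["mean"]
    model.std_ = z["std"]
    nv = model.mean_.size
    head = MLPClassifier(hidden_layer_sizes=(meta["n_hidden_gb"],
                                             meta["n_hidden_bb"]),
                         activation="logistic", max_iter=1)
    with warnings.catch_warnings():  # structural init only
        warnings.simplefilter("ignore")
        head.partial_fit(np.zeros((2, nv)), np.array([0, 1]),
                         classes=np.array([0, 1]))
    head.coefs_ = [z[f"head_W{i}"] for i in range(3)]
    head.intercepts_ = [z[f"head_b{i}"] for i in range(3)]
    model.head_ = head
    return model


def save_gbdt(model: GBDTModel, path) -> None:
    payload = {
        "base_score": model.base_score,
        "params": {k: getattr(model.params, k) for k in (
            "min_data_in_leaf", "n_iterations", "num_leaves", "max_depth",
            "learning_rate", "goss_b", "goss_c", "seed")},
        "trees": [{k: np.asarray(v).tolist() for k, v in t.items()}
                  for t in model.trees],
    }
    pathlib.Path(path).write_text(json.dumps(payload))


def load_gbdt(path) -> GBDTModel:
    payload = json.loads(pathlib.Path(path).read_text())
    trees = [{k: np.asarray(v) for k, v in t.items()}
             for t in payload["trees"]]
    return GBDTModel(trees=trees, base_score=payload["base_score"],
                     params=GBDTParams(**payload["params"]))
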