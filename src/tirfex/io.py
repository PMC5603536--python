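"""File formats: TIFF stacks for movies, 8/16-bit TIFF for masks and
labels, CSV tables, flat YAML configs."""

from __future__ import annotations


import numpy as np
import pandas as pd
import tifffile
import yaml


def write_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def read_movie(path) -> np.ndarray:
    movie = tifffile.imread(str(path))
    if movie.ndim == 2:
        movie = movie[None]
    return np.asarray(movie, dtype=np.float32)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def read_polygon_csv(path) -> np.ndarray:
    """Polygon vertices as one `row,col` pair per line (header optional)."""
    df = pd.read_csv(path, header=None, comment="#")
    if isinstance(df.iloc[0, 0], str):  # tolerate a header line
        df = df.iloc[1:].astype(float)
    return df.to_numpy(float)[:, :2]


def read_flat_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a flat key-value mapping")
    return data


def write_flat_config(path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
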