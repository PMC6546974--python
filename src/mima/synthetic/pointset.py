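"""Synthetic cell-centroid point sets for the density estimator."""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_LAYOUT = {
    "kind": "clustered",  # or "uniform"
    "width": 2000.0,
    "height": 2000.0,
    "n_clusters": 5,
    "cluster_sd": 60.0,
    "cluster_fraction": 0.7,
    "class_probs": {"cancer": 0.55, "stromal": 0.3, "lymphocyte": 0.15},
}


def generate_pointset(
    n_cells: int, cluster_layout: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Centroids (x, y, class) on a rectangular field, optionally clustered.

    In the clustered layout a fraction of cells sits in Gaussian blobs
    (cluster centers uniform over the field) and the rest is uniform
    background, mimicking tumor nests in stroma.
    """
    if n_cells <= 50:
        raise ValueError("n_cells must be > 50 (density needs >= N+1 points)")
    layout = {**DEFAULT_LAYOUT, **(cluster_layout or {})}
    rng = np.random.default_rng(seed)
    w, h = float(layout["width"]), float(layout["height"])

    if layout["kind"] == "uniform":
        xy = rng.uniform([0, 0], [w, h], size=(n_cells, 2))
        in_cluster = np.zeros(n_cells, dtype=bool)
        centers = np.empty((0, 2))
    elif layout["kind"] == "clustered":
        k = int(layout["n_clusters"])
        centers = rng.uniform([0.15 * w, 0.15 * h], [0.85 * w, 0.85 * h], size=(k, 2))
        in_cluster = rng.random(n_cells) < float(layout["cluster_fraction"])
        assign = rng.integers(0, k, size=n_cells)
        blob = centers[assign] + rng.normal(0, float(layout["cluster_sd"]), size=(n_cells, 2))
        background = rng.uniform([0, 0], [w, h], size=(n_cells, 2))
        xy = np.where(in_cluster[:, None], blob, background)
        xy = np.clip(xy, [0, 0], [w, h])
    else:
        raise ValueError(f"unknown layout kind {layout['kind']!r}")

    probs = layout["class_probs"]
    classes = rng.choice(list(probs), size=n_cells, p=np.array(list(probs.values())))
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "class": classes})
    df.attrs["in_cluster"] = in_cluster
    df.attrs["cluster_centers"] = centers
    df.attrs["area"] = w * h
    return df
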