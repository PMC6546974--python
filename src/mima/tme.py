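"""Tumor-microenvironment scores: cytolytic activity, immunophenogram/IPS,
and nearest-neighbor cell density on digitized-slide centroids."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

CYTOLYTIC_GENES = ("GZMA", "PRF1")
CYTOLYTIC_PSEUDOCOUNT = 0.01
IPS_CATEGORIES = ("MHC", "CP", "EC", "SC")
POINT_CLASSES = ("cancer", "stromal", "lymphocyte")


def load_panel(path=None) -> pd.DataFrame:
    """Load an immunophenogram panel (gene, parameter, category, weight).

    The packaged default is a synthetic stand-in for the published 162-gene
    panel: 26 parameters (20 single factors + 6 cell types) over the four
    categories MHC, CP, EC, SC with +/-1 weights; replace it with a real
    panel CSV of the same shape if you have one.
    """
    if path is None:
        path = resources.files("mima") / "data" / "synthetic_ips_panel.csv"
    panel = pd.read_csv(path)
    required = {"gene", "parameter", "category", "weight"}
    if not required.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(required)}")
    bad = set(panel["category"]) - set(IPS_CATEGORIES)
    if bad:
        raise ValueError(f"unknown panel categories: {sorted(bad)}")
    if not set(panel["weight"]).issubset({1, -1}):
        raise ValueError("panel weights must be +1 or -1")
    per_param = panel.groupby("parameter")[["category", "weight"]].nunique()
    if (per_param > 1).any().any():
        raise ValueError("each parameter must map to one category and one weight")
    return panel


def cytolytic_score(expression) -> float | pd.Series:
    """Geometric mean of GZMA and PRF1 expression (0.01 pseudocount).

    Accepts a mapping/Series of gene -> TPM (returns a float) or a
    genes x samples frame (returns a per-sample Series).
    """
    if isinstance(expression, pd.DataFrame):
        missing = [g for g in CYTOLYTIC_GENES if g not in expression.index]
        if missing:
            raise KeyError(f"expression matrix lacks {missing}")
        vals = expression.loc[list(CYTOLYTIC_GENES)] + CYTOLYTIC_PSEUDOCOUNT
        return np.sqrt(vals.iloc[0] * vals.iloc[1])
    try:
        gzma, prf1 = (float(expression[g]) for g in CYTOLYTIC_GENES)
    except KeyError as e:
        raise KeyError(f"expression lacks {e}") from e
    if gzma < 0 or prf1 < 0:
        raise ValueError("TPM values must be non-negative")
    return float(np.sqrt((gzma + CYTOLYTIC_PSEUDOCOUNT) * (prf1 + CYTOLYTIC_PSEUDOCOUNT)))


@dataclass
class Immunophenogram:
    parameter_z: pd.DataFrame  # parameters x samples
    category_scores: pd.DataFrame  # 4 categories x samples
    aggregate_z: pd.Series  # per sample
    ips: pd.Series  # per sample, integers 0..10


def ips_from_aggregate(aggregate_z: float) -> int:
    """Map an aggregate weighted Z to the 0-10 immunophenoscore.

    Anchors: Z >= 3 -> 10 and Z <= 0 -> 0; interior values interpolate
    linearly (x 10/3) with half-up rounding.
    """
    return int(np.clip(np.floor(aggregate_z * 10.0 / 3.0 + 0.5), 0, 10))


def immunophenogram(expression: pd.DataFrame, panel: pd.DataFrame | None = None) -> Immunophenogram:
    """Sample-wise immunophenogram: gene Z scores -> parameter -> category -> IPS.

    Gene Z scores are taken across samples (population SD; constant genes get
    Z = 0).  A parameter's score is the mean Z of its member genes present in
    the matrix (absent genes are logged and skipped); category scores average
    their parameters, and the aggregate averages the +/-1-weighted parameter
    scores.
    """
    if panel is None:
        panel = load_panel()
    if expression.shape[1] < 3:
        raise ValueError("immunophenogram needs >= 3 samples for Z scoring")
    genes = [g for g in panel["gene"].unique() if g in expression.index]
    absent = sorted(set(panel["gene"]) - set(genes))
    if absent:
        log.warning("panel genes absent from expression matrix: %s", absent)
    sub = expression.loc[genes].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd.replace(0.0, np.inf), axis=0)

    param_rows, weights, categories = {}, {}, {}
    for param, grp in panel.groupby("parameter"):
        members = [g for g in grp["gene"] if g in z.index]
        if not members:
            continue
        param_rows[param] = z.loc[members].mean(axis=0)
        weights[param] = int(grp["weight"].iloc[0])
        categories[param] = grp["category"].iloc[0]
    parameter_z = pd.DataFrame(param_rows).T
    cat_scores = pd.DataFrame(
        {
            cat: parameter_z.loc[[p for p, c in categories.items() if c == cat]].mean(axis=0)
            for cat in IPS_CATEGORIES
            if any(c == cat for c in categories.values())
        }
    ).T
    w = pd.Series(weights)
    aggregate = parameter_z.mul(w, axis=0).mean(axis=0)
    ips = aggregate.map(ips_from_aggregate).astype(int)
    return Immunophenogram(parameter_z, cat_scores, aggregate, ips)


def knn_density(
    points: pd.DataFrame, n_neighbors: int = 50, target_class: str | None = None
) -> pd.Series:
    """Density at each centroid as Sigma_N = N / (pi * d_N^2) in pixel^-2.

    ``d_N`` is the Euclidean distance to the Nth nearest neighbor within the
    density-defining population (``target_class``, or all points), excluding
    the query point itself.  Requires at least N + 1 population points.
    """
    required = {"x", "y"}
    if not required.issubset(points.columns):
        raise ValueError("points need x and y columns")
    if target_class is not None:
        if target_class not in POINT_CLASSES:
            raise ValueError(f"unknown class {target_class!r}")
        population = points[points["class"] == target_class]
    else:
        population = points
    n = n_neighbors
    if len(population) < n + 1:
        raise ValueError(
            f"density at order N={n} needs at least {n + 1} population points, "
            f"got {len(population)}"
        )
    coords = population[["x", "y"]].to_numpy(float)
    nn = NearestNeighbors(n_neighbors=n + 1).fit(coords)
    query = points[["x", "y"]].to_numpy(float)
    dist, idx = nn.kneighbors(query)
    # for queries that are themselves population members the first hit is the
    # point itself (distance 0); otherwise the Nth neighbor is column N-1
    in_pop = points.index.isin(population.index)
    d_n = np.where(in_pop, dist[:, n], dist[:, n - 1])
    return pd.Series(n / (np.pi * d_n**2), index=points.index, name="density")
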