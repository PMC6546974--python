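"""Synthetic mutational-signature catalogs.

The catalog is a 96 x K column-stochastic matrix of signature profiles.
These are synthetic stand-ins (sparse Dirichlet draws with well-separated
supports), not published reference signatures; users with a real catalog CSV
(rows = channel labels, columns = signature ids) can load it instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._channels import CHANNELS

DEFAULT_LABELS = ("SIG1", "SIG2", "SIG13", "SIG17")


def synthetic_signature_catalog(
    n_signatures: int = 4,
    seed: int = 0,
    concentration: float = 0.08,
    labels: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Draw K sparse, mutually dissimilar 96-channel signatures.

    Low Dirichlet concentration puts most mass on a handful of channels per
    signature, which keeps pairwise cosine similarity low (checked) so that
    exposure refitting and planted-signature recovery are well-posed.
    """
    if labels is None:
        labels = (
            DEFAULT_LABELS[:n_signatures]
            if n_signatures <= len(DEFAULT_LABELS)
            else tuple(f"SIG{i + 1}" for i in range(n_signatures))
        )
    rng = np.random.default_rng(seed)
    for _ in range(50):
        mat = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
        cos = _pairwise_cosine(mat)
        if n_signatures == 1 or cos < 0.5:
            return pd.DataFrame(mat, index=list(CHANNELS), columns=list(labels))
    raise RuntimeError("could not draw a well-separated signature catalog")


def load_catalog(path) -> pd.DataFrame:
    cat = pd.read_csv(path, index_col=0)
    if list(cat.index) != list(CHANNELS):
        cat = cat.reindex(list(CHANNELS))
        if cat.isna().any().any():
            raise ValueError("catalog rows do not cover the 96 channel labels")
    return cat / cat.sum(axis=0)


def _pairwise_cosine(mat: np.ndarray) -> float:
    norms = np.linalg.norm(mat, axis=0)
    gram = (mat.T @ mat) / np.outer(norms, norms)
    np.fill_diagonal(gram, 0.0)
    return float(gram.max()) if gram.size else 0.0
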