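"""Mutational-signature analysis on 96-channel profiles.

Extraction is multiplicative-update NMF under generalized KL divergence with
bootstrap consensus; per-sample refitting against a catalog is non-negative
least squares with the minimum-attribution threshold (at least 3% of the
sample's mutations or 10 mutations, whichever is larger, per attributed
signature); diagnostics are the residual RMSE, Shannon entropy of the
normalized profile, and a bootstrap cosine-similarity test.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._channels import CHANNELS, channel_index
from .datatypes import MutationRecord

log = logging.getLogger(__name__)

ATTRIBUTION_FRACTION = 0.03
ATTRIBUTION_MIN_MUTATIONS = 10
CONSENSUS_COSINE = 0.8


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class Profile96:
    """Counts over the 96 pyrimidine-centred substitution channels."""

    counts: np.ndarray
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("Profile96 requires exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("channel counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty profile cannot be normalized")
        return self.counts / self.total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS))


def build_profile96(mutations: Sequence[MutationRecord]) -> Profile96:
    """Histogram substitutions into the 96 channels (purine refs strand-collapsed).

    Non-substitution records and records with inconsistent context are
    rejected with a reason rather than raising.
    """
    counts = np.zeros(96)
    rejected = []
    for m in mutations:
        if not m.is_substitution:
            rejected.append((m.mutation_id, "not a single-base substitution"))
            continue
        try:
            counts[channel_index(m.ref, m.alt, m.trinucleotide_context)] += 1
        except (ValueError, KeyError) as e:
            rejected.append((m.mutation_id, str(e)))
    if rejected:
        log.warning("rejected %d records while building profile", len(rejected))
    return Profile96(counts, rejected)


def stratified_profiles(
    mutations: Sequence[MutationRecord], lineage: Mapping[str, str]
) -> dict[str, Profile96]:
    """Profiles for all mutations and the stem/clade/private strata.

    The three strata sum channelwise to the "all" profile.
    """
    strata = {"all": list(mutations)}
    for lab in ("stem", "clade", "private"):
        strata[lab] = [m for m in mutations if lineage.get(m.mutation_id) == lab]
    return {lab: build_profile96(muts) for lab, muts in strata.items()}


# ---------------------------------------------------------------------------
# KL-divergence NMF with bootstrap consensus
# ---------------------------------------------------------------------------


def generalized_kl(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum())


def nmf_kl(
    V: np.ndarray,
    rank: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF minimizing generalized KL divergence.

    Returns (W, H, error trajectory); the KL error is non-increasing over
    iterations by construction of the updates.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = V.shape
    eps = 1e-12
    W = rng.uniform(0, 1, size=(n, rank)) + eps
    H = rng.uniform(0, 1, size=(rank, m)) + eps
    errors = [generalized_kl(V, W @ H + eps)]
    for _ in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        err = generalized_kl(V, W @ H + eps)
        errors.append(err)
        if abs(errors[-2] - err) <= tol * max(abs(errors[-2]), 1.0):
            break
    return W, H, errors


@dataclass
class NmfRankResult:
    rank: int
    signatures: pd.DataFrame  # 96 x <=rank consensus signatures, columns sum to 1
    mean_kl_error: float
    n_bootstrap: int
    cluster_sizes: list[int]


def nmf_extract(
    profiles: Sequence[Profile96] | np.ndarray,
    rank_range: tuple[int, int] = (2, 5),
    n_bootstrap: int = 100,
    seed: int = 0,
    max_iter: int = 200,
) -> dict[int, NmfRankResult]:
    """Bootstrap-consensus signature extraction over a range of ranks.

    Samples are resampled with replacement per bootstrap; extracted signature
    columns are pooled over bootstraps and greedily clustered at cosine
    >= 0.8; each rank reports the consensus signatures of its largest
    clusters and the mean KL reconstruction error.
    """
    V = (
        np.column_stack([p.counts for p in profiles])
        if not isinstance(profiles, np.ndarray)
        else np.asarray(profiles, dtype=float)
    )
    if (V.sum(axis=0) <= 0).any():
        raise ValueError("all profiles must have positive totals")
    n_samples = V.shape[1]
    lo, hi = rank_range
    if hi > n_samples:
        raise ValueError(f"rank {hi} exceeds the number of samples ({n_samples})")
    rng = np.random.default_rng(seed)
    results = {}
    for rank in range(lo, hi + 1):
        pool, errs = [], []
        for _ in range(n_bootstrap):
            cols = rng.integers(0, n_samples, size=n_samples)
            W, H, traj = nmf_kl(V[:, cols], rank, rng, max_iter=max_iter)
            errs.append(traj[-1])
            W = W / W.sum(axis=0)
            pool.extend(W.T)
        centroids, members = [], []
        for sig in pool:
            best, best_cos = None, CONSENSUS_COSINE
            for i, c in enumerate(centroids):
                cos = _cosine(sig, c)
                if cos >= best_cos:
                    best, best_cos = i, cos
            if best is None:
                centroids.append(sig.copy())
                members.append([sig])
            else:
                members[best].append(sig)
                centroids[best] = np.mean(members[best], axis=0)
        order = np.argsort([-len(m) for m in members])[:rank]
        sigs = {}
        sizes = []
        for j, i in enumerate(order):
            consensus = np.mean(members[i], axis=0)
            sigs[f"r{rank}_sig{j + 1}"] = consensus / consensus.sum()
            sizes.append(len(members[i]))
        results[rank] = NmfRankResult(
            rank=rank,
            signatures=pd.DataFrame(sigs, index=list(CHANNELS)),
            mean_kl_error=float(np.mean(errs)),
            n_bootstrap=n_bootstrap,
            cluster_sizes=sizes,
        )
    return results


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(a @ b / (na * nb))


def cosine_match(sig: np.ndarray | pd.Series, catalog: pd.DataFrame) -> tuple[str, float]:
    """Best-matching catalog signature by cosine similarity."""
    v = np.asarray(sig, dtype=float)
    sims = {label: _cosine(v, catalog[label].to_numpy()) for label in catalog.columns}
    best = max(sims, key=sims.get)
    return best, sims[best]


# ---------------------------------------------------------------------------
# exposure refitting
# ---------------------------------------------------------------------------


@dataclass
class ExposureFit:
    exposures: pd.Series  # mutation units, >= 0
    fitted: np.ndarray
    residual: np.ndarray
    rmse: float
    attributed: list[str]
    all_dropped: bool = False


def fit_exposures(
    profile: Profile96,
    signatures: pd.DataFrame,
    attribution: bool = True,
    threshold_mode: str = "max",
) -> ExposureFit:
    """Refit per-sample signature exposures by non-negative least squares.

    Solves min ||m - S e||^2, e >= 0 on the raw 96-channel counts (exposures
    come out in mutation units because catalog columns sum to 1).  With
    attribution on, signatures below the minimum-attribution threshold —
    max(3% of total, 10) mutations by default, min(...) with
    ``threshold_mode="min"`` — are dropped and the fit re-solved iteratively
    until the surviving set is stable.
    """
    m = profile.counts
    total = profile.total
    if total <= 0:
        raise ValueError("profile total must be positive")
    if threshold_mode == "max":
        threshold = max(ATTRIBUTION_FRACTION * total, ATTRIBUTION_MIN_MUTATIONS)
    elif threshold_mode == "min":
        threshold = min(ATTRIBUTION_FRACTION * total, ATTRIBUTION_MIN_MUTATIONS)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    labels = list(signatures.columns)
    active = labels
    while True:
        if not active:
            rmse = float(np.sqrt(np.mean(m**2)))
            return ExposureFit(
                exposures=pd.Series(0.0, index=labels),
                fitted=np.zeros(96),
                residual=m.copy(),
                rmse=rmse,
                attributed=[],
                all_dropped=True,
            )
        S = signatures[active].to_numpy()
        e, _ = nnls(S, m)
        if not attribution:
            break
        surviving = [lab for lab, x in zip(active, e) if x >= threshold]
        if surviving == active:
            break
        active = surviving
    exposures = pd.Series(0.0, index=labels)
    exposures[active] = e
    fitted = signatures[labels].to_numpy() @ exposures.to_numpy()
    residual = m - fitted
    return ExposureFit(
        exposures=exposures,
        fitted=fitted,
        residual=residual,
        rmse=float(np.sqrt(np.mean(residual**2))),
        attributed=[lab for lab in active if exposures[lab] > 0],
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def profile_entropy(profile: Profile96) -> float:
    """Shannon entropy (nats) of the normalized 96-channel profile."""
    p = profile.normalized()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


@dataclass
class SimilarityBootstrap:
    cosine: float
    bootstrap_cosines: np.ndarray
    null_cosines: np.ndarray
    p_value: float


def bootstrap_profile_similarity(
    profile_a: Profile96,
    profile_b: Profile96,
    n_boot: int = 10000,
    seed: int = 0,
) -> SimilarityBootstrap:
    """Cosine similarity of two profiles with a multinomial bootstrap and
    label-swap null.

    Bootstrap replicates resample each profile's mutations multinomially.
    The null pools both profiles' mutations and splits them at the observed
    totals; p is the pseudo-counted fraction of null cosines at least as
    large as the observed cosine.
    """
    if n_boot < 100:
        log.warning("n_boot=%d is small; p-value resolution will be coarse", n_boot)
    rng = np.random.default_rng(seed)
    a, b = profile_a.counts, profile_b.counts
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("profiles must have positive totals")
    observed = _cosine(a, b)
    pa, pb = a / na, b / nb
    boot_a = rng.multinomial(na, pa, size=n_boot)
    boot_b = rng.multinomial(nb, pb, size=n_boot)
    boot = _rowwise_cosine(boot_a, boot_b)
    pooled = (a + b) / (na + nb)
    null_a = rng.multinomial(na, pooled, size=n_boot)
    null_b = rng.multinomial(nb, pooled, size=n_boot)
    null = _rowwise_cosine(null_a, null_b)
    p = (np.sum(null >= observed) + 1) / (n_boot + 1)
    return SimilarityBootstrap(observed, boot, null, float(p))


def _rowwise_cosine(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    num = np.einsum("ij,ij->i", A, B)
    den = np.linalg.norm(A, axis=1) * np.linalg.norm(B, axis=1)
    return num / np.where(den == 0, np.inf, den)
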