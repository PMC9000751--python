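"""KS-variant gene-set enrichment with an analytic null.

For a profile of M ranked keys and a gene set with N members on the list,
let C_i be the number of set members among the top i keys.  The displacement
of the set's cumulative distribution from uniform is

    D_max = max_i (C_i/N − i/M)   ≥ 0
    D_min = min_i (C_i/N − i/M)   ≤ 0

Under the null (N positions drawn uniformly from {1..M}) the sum
D_max + D_min is close to normal with mean 0 and standard deviation well
approximated by the power law

    σ(N, M) = sqrt(β − α·N/M) · N^(−γ)

with default constants α = 0.3274679, β = 0.3327016, γ = 0.491337.  The
reported statistic is Z = (D_max + D_min)/σ(N, M): positive when set members
concentrate at the top of the ranking, negative at the bottom.
:func:`calibrate_null` re-derives the constants by Monte-Carlo simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .differential import DifferentialProfile
from .errors import PreconditionError
from .ranks import RankProfile

__all__ = [
    "GeneSetCollection",
    "KSNullModel",
    "EnrichmentResult",
    "NullCalibration",
    "ks_displacements",
    "ks_sigma",
    "ks_z",
    "enrich_collection",
    "calibrate_null",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (the GMT content model)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise PreconditionError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise PreconditionError(f"duplicate gene set name {name!r}")
        members = frozenset(members)
        if not members:
            raise PreconditionError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class KSNullModel:
    """Constants of the analytic null SD law σ(N,M) = sqrt(β − αN/M)·N^(−γ)."""

    alpha: float = 0.3274679
    beta: float = 0.3327016
    gamma: float = 0.491337

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise PreconditionError("null-model constants must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set enrichment outcome; holds every symbol of the statistic."""

    name: str
    m: int  # profile length M
    n: int  # set members present N
    d_max: float
    d_min: float
    sigma: float
    z: float


@dataclass
class NullCalibration:
    """Monte-Carlo re-derivation of the σ(N,M) law on an (N, M) grid."""

    m: int
    n_grid: np.ndarray
    reps: int
    empirical_sd: np.ndarray
    empirical_mean: np.ndarray
    alpha: float
    beta: float
    gamma: float
    residuals: np.ndarray

    def sigma(self, n: int) -> float:
        return ks_sigma(n, self.m, KSNullModel(self.alpha, self.beta, self.gamma))


def _displacements(positions: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """(D_max, D_min) from sorted 1-based member positions; vectorized.

    ``positions`` has shape (..., N).  Candidate extrema: the running
    statistic jumps up at each member position p_j (value j/N − p_j/M) and
    drifts down in between, so maxima sit at member positions and minima
    just before them (value (j−1)/N − (p_j−1)/M) or at i = M (value 0).
    """
    n = positions.shape[-1]
    j = np.arange(1, n + 1, dtype=float)
    pos = positions.astype(float)
    d_max = (j / n - pos / m).max(axis=-1)
    d_min = ((j - 1.0) / n - (pos - 1.0) / m).min(axis=-1)
    return np.maximum(d_max, 0.0), np.minimum(d_min, 0.0)


def ks_displacements(
    ranked_keys: Sequence[str], gene_set: Iterable[str]
) -> tuple[float, float, int, int]:
    """Extreme displacements of a gene set on a ranked key list.

    Returns (d_max, d_min, N, M) with N the number of set members present on
    the list and M the list length.  Set members absent from the list are
    ignored; an empty intersection is an error (no statistic exists).
    """
    ranked = list(ranked_keys)
    m = len(ranked)
    if len(set(ranked)) != m:
        raise PreconditionError("ranked keys must be unique")
    members = set(gene_set)
    positions = np.array(
        [i + 1 for i, key in enumerate(ranked) if key in members], dtype=np.int64
    )
    n = positions.size
    if n == 0:
        raise PreconditionError("gene set has no members on the ranked list")
    d_max, d_min = _displacements(positions, m)
    return float(d_max), float(d_min), n, m


def ks_sigma(n: int, m: int, model: KSNullModel = KSNullModel()) -> float:
    """Analytic null SD of D_max + D_min for a size-N set on an M-list."""
    if not (1 <= n <= m):
        raise PreconditionError(f"need 1 <= N <= M, got N={n}, M={m}")
    disc = model.beta - model.alpha * n / m
    if disc <= 0:
        raise PreconditionError(
            f"sigma undefined: beta <= alpha*N/M ({model.beta} <= {model.alpha * n / m})"
        )
    return float(np.sqrt(disc) * n ** (-model.gamma))


def _ordered_keys(profile) -> list[str]:
    """Profile keys sorted by descending score, ties by ascending key."""
    if isinstance(profile, DifferentialProfile):
        scores = profile.z
    elif isinstance(profile, RankProfile):
        scores = profile.values
    elif isinstance(profile, pd.Series):
        scores = profile
    else:
        raise PreconditionError(f"cannot rank a {type(profile).__name__}")
    if scores.index.has_duplicates:
        raise PreconditionError("profile keys must be unique")
    frame = pd.DataFrame({"score": scores.to_numpy(dtype=float), "key": scores.index})
    frame = frame.sort_values(
        by=["score", "key"], ascending=[False, True], kind="mergesort"
    )
    return frame["key"].tolist()


def ks_z(
    profile,
    gene_set: Iterable[str],
    model: KSNullModel = KSNullModel(),
    name: str = "",
) -> EnrichmentResult:
    """Enrichment Z of one gene set on a profile.

    The profile (differential Z profile, rank profile, or a plain Series)
    is ordered by descending score — most up-regulated or most
    above-background first — so positive Z means enrichment at the top.
    """
    ranked = _ordered_keys(profile)
    d_max, d_min, n, m = ks_displacements(ranked, gene_set)
    sigma = ks_sigma(n, m, model)
    return EnrichmentResult(
        name=name,
        m=m,
        n=n,
        d_max=d_max,
        d_min=d_min,
        sigma=sigma,
        z=(d_max + d_min) / sigma,
    )


def enrich_collection(
    profile,
    collection: GeneSetCollection,
    model: KSNullModel = KSNullModel(),
    n_min: int = 5,
) -> list[EnrichmentResult]:
    """Score every set of a collection against a profile; sort by Z descending.

    Sets with fewer than ``n_min`` members on the profile are skipped with a
    logged notice (the σ law is unvalidated below that size).
    """
    if len(collection) == 0:
        raise PreconditionError("gene-set collection is empty")
    ranked = _ordered_keys(profile)
    on_list = set(ranked)
    m = len(ranked)
    results: list[EnrichmentResult] = []
    for set_name, members in sorted(collection.items()):
        n_present = len(members & on_list)
        if n_present < n_min:
            logger.info(
                "skipping set %s: %d members on profile (< n_min=%d)",
                set_name, n_present, n_min,
            )
            continue
        d_max, d_min, n, _ = ks_displacements(ranked, members)
        sigma = ks_sigma(n, m, model)
        results.append(
            EnrichmentResult(set_name, m, n, d_max, d_min, sigma, (d_max + d_min) / sigma)
        )
    results.sort(key=lambda r: (-r.z, r.name))
    return results


def _simulate_null_sd(
    m: int, n_grid: Sequence[int], reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical SD and mean of D_max + D_min for random N-subsets of {1..M}."""
    sds, means = [], []
    for n in n_grid:
        vals = []
        done = 0
        while done < reps:
            chunk = min(512, reps - done)
            done += chunk
            u = rng.random((chunk, m))
            pos = np.sort(np.argpartition(u, n - 1, axis=1)[:, :n], axis=1) + 1
            d_max, d_min = _displacements(pos, m)
            vals.append(d_max + d_min)
        d = np.concatenate(vals)
        sds.append(d.std(ddof=1))
        means.append(d.mean())
    return np.asarray(sds), np.asarray(means)


def calibrate_null(
    m: int,
    n_grid: Sequence[int],
    reps: int = 2000,
    seed: int = 0,
    gamma: float | None = None,
) -> NullCalibration:
    """Re-derive the σ(N,M) constants by Monte-Carlo simulation.

    For each N in the grid, ``reps`` uniform N-subsets of {1..M} are drawn
    and the empirical SD of D_max + D_min recorded.  The exponent γ is the
    negated slope of log SD on log N — identifiable on its own wherever
    N/M is small so the amplitude factor is nearly constant; pass ``gamma``
    to fix it when fitting a dense-N/M grid.  With γ in hand, (α, β) come
    from a linear fit of SD²·N^(2γ) against N/M refined by nonlinear least
    squares of the σ form itself.
    """
    n_grid = np.asarray(sorted(n_grid), dtype=np.int64)
    if reps < 100:
        raise PreconditionError("need at least 100 replicates per grid point")
    if n_grid.min() < 1 or n_grid.max() > m:
        raise PreconditionError("grid sizes must satisfy 1 <= N <= M")
    rng = np.random.default_rng(seed)
    sds, means = _simulate_null_sd(m, n_grid, reps, rng)

    if gamma is None:
        gamma_hat = float(-np.polyfit(np.log(n_grid), np.log(sds), 1)[0])
    else:
        gamma_hat = float(gamma)

    # amplitude stage: SD^2 * N^(2*gamma) = beta - alpha * N/M
    x = n_grid / m
    y = sds**2 * n_grid.astype(float) ** (2 * gamma_hat)
    slope, intercept = np.polyfit(x, y, 1)
    alpha0, beta0 = max(-slope, 1e-6), max(intercept, 1e-6)

    def model(n_over_m_and_n, alpha, beta):
        n_over_m, n = n_over_m_and_n
        return np.sqrt(np.maximum(beta - alpha * n_over_m, 1e-12)) * n ** (-gamma_hat)

    try:
        (alpha_fit, beta_fit), _ = curve_fit(
            model, (x, n_grid.astype(float)), sds, p0=[alpha0, beta0], maxfev=10000
        )
    except RuntimeError:  # pragma: no cover - fall back to the linear stage
        alpha_fit, beta_fit = alpha0, beta0
    fitted = model((x, n_grid.astype(float)), alpha_fit, beta_fit)
    return NullCalibration(
        m=m,
        n_grid=n_grid,
        reps=reps,
        empirical_sd=sds,
        empirical_mean=means,
        alpha=float(alpha_fit),
        beta=float(beta_fit),
        gamma=gamma_hat,
        residuals=sds - fitted,
    )
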