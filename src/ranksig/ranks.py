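"""Gene rank profiles (GRPs): expression quantified by rank against a background.

The relative expression of a probe in a sample set is quantified
non-parametrically: probes are ranked within each sample (0 = highest
expression, 1 = lowest, after scaling), averaged over the samples of
interest (``r``) and over a large background compendium (``r0``), and the
two are combined into a *relative rank* in [−1, +1]:

    rel(r, r0) = (r0 − r)/r0        if r < r0   (expressed above background)
                 (r0 − r)/(1 − r0)  if r > r0   (below background)
                 0                  if r = r0

Collapsing probe-level relative ranks to genes (keeping the probe of largest
magnitude) yields the gene rank profile.  Profiles are compared by Spearman
correlation with the large-sample null scaling z = ρ·sqrt(n−1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreconditionError
from .matrix import ExpressionMatrix, ProbeGeneMap

__all__ = [
    "ScaledRankVector",
    "RankProfile",
    "CorrelationResult",
    "compute_scaled_ranks",
    "compendium_background_ranks",
    "relative_rank",
    "build_grp",
    "compare_rank_profiles",
    "rank_panel",
]


@dataclass
class ScaledRankVector:
    """Per-probe mean scaled rank over a sample set.

    Scaled ranks lie in [0, 1]: 0 is the highest-expressed probe of a sample,
    1 the lowest.  Within a single sample of P probes (no ties) the scaled
    ranks are a permutation of {0, 1/(P−1), ..., 1}.
    """

    ranks: pd.Series
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.ranks.to_numpy(dtype=float)
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise PreconditionError("scaled ranks must lie in [0, 1]")


@dataclass
class RankProfile:
    """Key (gene or probe) → relative rank in [−1, +1].

    Positive values mean expression above the background rank.
    """

    values: pd.Series
    name: str | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (vals.min() < -1 - 1e-9 or vals.max() > 1 + 1e-9):
            raise PreconditionError("relative ranks must lie in [-1, 1]")
        if self.values.index.has_duplicates:
            raise PreconditionError("rank profile keys must be unique")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman comparison of two rank profiles over their shared keys."""

    rho: float
    z: float
    n: int


def compute_scaled_ranks(
    matrix: ExpressionMatrix, samples: Sequence[str]
) -> ScaledRankVector:
    """Mean scaled rank of every probe over a sample subset.

    Within each sample, probes are ranked by descending intensity (ties get
    the average rank) and ranks are scaled to [0, 1] as (rank − 1)/(P − 1).
    The returned vector is the per-probe mean over the subset.
    """
    samples = list(samples)
    if not samples:
        raise PreconditionError("sample subset is empty")
    missing = [s for s in samples if s not in matrix.values.columns]
    if missing:
        raise PreconditionError(f"samples not in matrix: {missing[:5]}")
    sub = matrix.values[samples]
    p = len(sub)
    ranks = sub.rank(axis=0, method="average", ascending=False)
    scaled = (ranks - 1.0) / (p - 1.0) if p > 1 else ranks * 0.0
    return ScaledRankVector(scaled.mean(axis=1), tuple(samples))


def compendium_background_ranks(series: Iterable[ExpressionMatrix]) -> ScaledRankVector:
    """Background mean scaled ranks (r0) over a multi-series compendium.

    Each series is rank-scaled over all of its samples; the per-series mean
    vectors are then averaged with equal series weight, so a large series
    does not dominate the background.
    """
    vectors = []
    tags: list[str] = []
    for mat in series:
        v = compute_scaled_ranks(mat, list(mat.values.columns))
        vectors.append(v.ranks)
        tags.extend(v.samples)
    if not vectors:
        raise PreconditionError("background compendium is empty")
    index = vectors[0].index
    for v in vectors[1:]:
        if not v.index.equals(index):
            raise PreconditionError("background series have mismatched probe universes")
    mean = pd.concat(vectors, axis=1).mean(axis=1)
    return ScaledRankVector(mean, tuple(tags))


def relative_rank(r, r0):
    """Relative rank of scaled rank ``r`` against background rank ``r0``.

    Accepts scalars or arrays (broadcast).  The result lies in [−1, +1]:
    +1 when the probe is top-ranked and the background is not, −1 in the
    mirror case, 0 when sample and background ranks agree.  The degenerate
    backgrounds r0 = 0 and r0 = 1 fall through to the branch whose
    denominator is nonzero, the continuous limit of the transform.
    """
    r_arr = np.asarray(r, dtype=float)
    r0_arr = np.asarray(r0, dtype=float)
    for name, a in (("r", r_arr), ("r0", r0_arr)):
        if a.size and (np.nanmin(a) < 0 or np.nanmax(a) > 1 or not np.isfinite(a).all()):
            raise PreconditionError(f"{name} must lie in [0, 1]")
    r_b, r0_b = np.broadcast_arrays(r_arr, r0_arr)
    out = np.zeros(r_b.shape, dtype=float)
    above = r_b < r0_b  # expressed above background; r0 > 0 on this branch
    below = r_b > r0_b  # below background; r0 < 1 on this branch
    out[above] = (r0_b[above] - r_b[above]) / r0_b[above]
    out[below] = (r0_b[below] - r_b[below]) / (1.0 - r0_b[below])
    if np.isscalar(r) and np.isscalar(r0):
        return float(out)
    return out


def build_grp(
    sample_ranks: ScaledRankVector,
    background_ranks: ScaledRankVector,
    probe_map: ProbeGeneMap,
    name: str | None = None,
) -> RankProfile:
    """Gene rank profile from sample and background scaled ranks.

    Per-probe relative ranks are collapsed to genes by keeping, for each
    gene, the probe of largest relative-rank magnitude; magnitude ties are
    broken toward the positive value, then by lexicographic probe ID.
    Probes without a gene annotation are dropped.
    """
    r = sample_ranks.ranks
    r0 = background_ranks.ranks
    if not r.index.equals(r0.index):
        if set(r.index) != set(r0.index):
            raise PreconditionError("sample and background probe universes differ")
        r0 = r0.reindex(r.index)
    rel = pd.Series(relative_rank(r.to_numpy(), r0.to_numpy()), index=r.index)

    genes = pd.Series({p: probe_map.gene_of(p) for p in rel.index})
    keep = genes.notna()
    frame = pd.DataFrame(
        {"gene": genes[keep], "probe": rel.index[keep], "rel": rel[keep].to_numpy()}
    )
    if frame.empty:
        raise PreconditionError("no probes map to genes")
    frame["mag"] = frame["rel"].abs()
    # max |rel| first; on exact magnitude tie the positive value, then probe ID
    frame = frame.sort_values(
        by=["mag", "rel", "probe"], ascending=[False, False, True], kind="mergesort"
    )
    collapsed = frame.drop_duplicates(subset="gene", keep="first")
    values = pd.Series(
        collapsed["rel"].to_numpy(), index=pd.Index(collapsed["gene"], name="gene")
    ).sort_index()
    return RankProfile(values, name=name)


def compare_rank_profiles(a: RankProfile, b: RankProfile) -> CorrelationResult:
    """Spearman correlation of two profiles over their shared keys.

    Returns ρ and the large-sample significance score z = ρ·sqrt(n−1).
    """
    shared = a.values.index.intersection(b.values.index)
    n = len(shared)
    if n < 3:
        raise PreconditionError(f"only {n} shared keys; need at least 3")
    x = a.values.loc[shared].to_numpy(dtype=float)
    y = b.values.loc[shared].to_numpy(dtype=float)
    rho = stats.spearmanr(x, y).statistic
    if not np.isfinite(rho):
        raise PreconditionError("Spearman correlation undefined (constant profile)")
    return CorrelationResult(rho=float(rho), z=float(rho * np.sqrt(n - 1)), n=n)


def rank_panel(
    query: RankProfile, panel: Sequence[tuple[str, RankProfile]]
) -> list[tuple[str, CorrelationResult]]:
    """Rank every panel entity by Spearman correlation with the query.

    Rows are sorted by descending ρ with name as the deterministic
    tie-break — the layout of a cancer-panel comparison table.
    """
    if not panel:
        raise PreconditionError("panel is empty")
    rows = [(name, compare_rank_profiles(query, profile)) for name, profile in panel]
    rows.sort(key=lambda item: (-item[1].rho, item[0]))
    return rows
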