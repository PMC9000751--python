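"""Treated-vs-control differential profiles and signed signatures.

The differential statistic is the two-group linear-fit Z: ordinary least
squares of log2 intensity on a treatment indicator, whose coefficient
t-statistic (pooled variance, n1+n2−2 df) is reported directly as Z, with a
variance floor and a |Z| cap so degenerate inputs stay finite.  Profiles are
collapsed to genes by maximal-magnitude Z, thresholded into up/down
signatures, compared across contexts by a one-sided Fisher exact test on
sign concordance, and combined across contexts by Stouffer's method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import PreconditionError
from .matrix import ExpressionMatrix, ProbeGeneMap

__all__ = [
    "Z_CAP",
    "VARIANCE_FLOOR",
    "DifferentialProfile",
    "SignedGeneSignature",
    "OverlapTable",
    "CombinedProfile",
    "differential_profile",
    "collapse_probes",
    "fold_change_counts",
    "threshold_signature",
    "overlap_fisher",
    "stouffer_combine",
    "concordance_tails",
]

#: cap on |Z|; reached only through the variance floor on degenerate inputs
Z_CAP = 40.0
#: floor on the pooled variance, log2-intensity units squared
VARIANCE_FLOOR = 1e-8


@dataclass
class DifferentialProfile:
    """Key → (Z, log2 fold change), at probe or gene level."""

    table: pd.DataFrame  # columns: z, log2fc
    level: str = "probe"  # "probe" | "gene"

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["z", "log2fc"]:
            raise PreconditionError("differential table must have columns (z, log2fc)")
        if self.level not in ("probe", "gene"):
            raise PreconditionError(f"unknown level {self.level!r}")
        if self.table.index.has_duplicates:
            raise PreconditionError("differential profile keys must be unique")
        arr = self.table.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise PreconditionError("differential profile contains non-finite values")
        if arr.size and np.abs(arr[:, 0]).max() > Z_CAP + 1e-9:
            raise PreconditionError(f"|z| exceeds cap {Z_CAP}")

    @property
    def z(self) -> pd.Series:
        return self.table["z"]

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


@dataclass
class SignedGeneSignature:
    """Disjoint up- and down-regulated gene sets with threshold provenance."""

    up: frozenset[str]
    down: frozenset[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.down = frozenset(self.down)
        clash = self.up & self.down
        if clash:
            raise PreconditionError(
                f"up and down sets overlap: {sorted(clash)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def swapped(self) -> "SignedGeneSignature":
        """The signature with up and down exchanged (sign negation)."""
        return SignedGeneSignature(self.down, self.up, dict(self.meta))


@dataclass(frozen=True)
class OverlapTable:
    """2×2 sign-concordance table between two thresholded profiles.

    UU counts keys up in both, UD up in the first and down in the second,
    and so on.  ``p`` is a one-sided Fisher exact probability (hypergeometric
    tail of UU given the margins); ``direction`` reports which association
    the table shows.
    """

    uu: int
    ud: int
    du: int
    dd: int
    p: float
    direction: str  # "concordant" | "discordant" | "none"

    @property
    def n(self) -> int:
        return self.uu + self.ud + self.du + self.dd


@dataclass
class CombinedProfile:
    """Gene → Stouffer-combined Z."""

    z: pd.Series

    def __post_init__(self) -> None:
        if self.z.index.has_duplicates:
            raise PreconditionError("combined profile keys must be unique")
        if len(self.z) and not np.isfinite(self.z.to_numpy(dtype=float)).all():
            raise PreconditionError("combined profile contains non-finite values")


def differential_profile(
    matrix: ExpressionMatrix,
    control: Sequence[str],
    treated: Sequence[str],
) -> DifferentialProfile:
    """Probe-level differential profile of treated vs control samples.

    log2fc is the treated-minus-control mean difference; Z is the pooled
    two-sample statistic log2fc / sqrt(s2p·(1/n1 + 1/n2)) with the pooled
    variance floored at :data:`VARIANCE_FLOOR` and |Z| capped at
    :data:`Z_CAP`.
    """
    control, treated = list(control), list(treated)
    if len(control) < 2 or len(treated) < 2:
        raise PreconditionError("each arm needs at least 2 samples")
    for s in control + treated:
        if s not in matrix.values.columns:
            raise PreconditionError(f"sample {s!r} not in matrix")
    xc = matrix.values[control].to_numpy(dtype=float)
    xt = matrix.values[treated].to_numpy(dtype=float)
    n0, n1 = xc.shape[1], xt.shape[1]
    lfc = xt.mean(axis=1) - xc.mean(axis=1)
    v0 = xc.var(axis=1, ddof=1)
    v1 = xt.var(axis=1, ddof=1)
    s2p = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    se = np.sqrt(np.maximum(s2p, VARIANCE_FLOOR) * (1.0 / n0 + 1.0 / n1))
    z = np.clip(lfc / se, -Z_CAP, Z_CAP)
    table = pd.DataFrame({"z": z, "log2fc": lfc}, index=matrix.values.index)
    return DifferentialProfile(table, level="probe")


def collapse_probes(
    profile: DifferentialProfile, probe_map: ProbeGeneMap
) -> DifferentialProfile:
    """Collapse a probe-level profile to genes by maximal-magnitude Z.

    For each gene the (Z, log2fc) pair of the probe with the largest |Z| is
    kept; magnitude ties go to the positive Z, then to the lexicographically
    smallest probe ID.  Unannotated probes are dropped.
    """
    if profile.level != "probe":
        raise PreconditionError("collapse_probes expects a probe-level profile")
    genes = pd.Series({p: probe_map.gene_of(p) for p in profile.table.index})
    keep = genes.notna()
    frame = profile.table.loc[keep].copy()
    frame.index = frame.index.rename(None)  # free the name "probe" for a column
    frame["gene"] = genes[keep]
    frame["probe"] = frame.index
    frame["mag"] = frame["z"].abs()
    frame = frame.sort_values(
        by=["mag", "z", "probe"], ascending=[False, False, True], kind="mergesort"
    )
    collapsed = frame.drop_duplicates(subset="gene", keep="first")
    table = pd.DataFrame(
        {"z": collapsed["z"].to_numpy(), "log2fc": collapsed["log2fc"].to_numpy()},
        index=pd.Index(collapsed["gene"], name="gene"),
    ).sort_index()
    return DifferentialProfile(table, level="gene")


def fold_change_counts(profile: DifferentialProfile, fold: float) -> tuple[int, int]:
    """Counts of genes at or beyond a fold change: (n_up, n_down).

    ``fold`` is a linear ratio ≥ 1; genes with log2fc ≥ log2(fold) count as
    up, ≤ −log2(fold) as down.  At fold = 1 only nonzero changes count.
    """
    if fold < 1:
        raise PreconditionError("fold must be >= 1")
    cut = math.log2(fold)
    lfc = profile.log2fc.to_numpy(dtype=float)
    if cut == 0.0:
        return int((lfc > 0).sum()), int((lfc < 0).sum())
    return int((lfc >= cut).sum()), int((lfc <= -cut).sum())


def threshold_signature(
    profile: DifferentialProfile, z_cut: float
) -> SignedGeneSignature:
    """Signed signature of keys beyond ±z_cut standard deviations."""
    if z_cut <= 0:
        raise PreconditionError("z_cut must be positive")
    z = profile.z
    up = frozenset(z.index[z >= z_cut])
    down = frozenset(z.index[z <= -z_cut])
    return SignedGeneSignature(up, down, {"z_cut": z_cut, "level": profile.level})


def concordance_tails(uu: int, ud: int, du: int, dd: int) -> tuple[float, float]:
    """One-sided Fisher exact tails of a 2×2 sign table.

    Conditioning on the margins, UU determines the table, so the exact test
    is the hypergeometric tail of UU.  Returns (p toward concordance
    [UU at least as large], p toward discordance [UU at most as large]).
    """
    for c in (uu, ud, du, dd):
        if c < 0:
            raise PreconditionError("table cells must be non-negative")
    n = uu + ud + du + dd
    if n == 0:
        return 1.0, 1.0
    r1, c1 = uu + ud, uu + du
    p_conc = float(hypergeom.sf(uu - 1, n, r1, c1))
    p_disc = float(hypergeom.cdf(uu, n, r1, c1))
    return min(p_conc, 1.0), min(p_disc, 1.0)


def overlap_fisher(
    a: DifferentialProfile, b: DifferentialProfile, z_cut: float
) -> OverlapTable:
    """Sign-concordance Fisher test between two differential profiles.

    Restricts to shared keys with |Z| ≥ z_cut in *both* profiles, tabulates
    sign agreement into UU/UD/DU/DD, and reports the one-sided Fisher exact
    probability of concordance at least as large as observed.
    """
    if z_cut <= 0:
        raise PreconditionError("z_cut must be positive")
    shared = a.table.index.intersection(b.table.index)
    za = a.z.loc[shared]
    zb = b.z.loc[shared]
    sel = (za.abs() >= z_cut) & (zb.abs() >= z_cut)
    za, zb = za[sel], zb[sel]
    uu = int(((za > 0) & (zb > 0)).sum())
    ud = int(((za > 0) & (zb < 0)).sum())
    du = int(((za < 0) & (zb > 0)).sum())
    dd = int(((za < 0) & (zb < 0)).sum())
    if uu + ud + du + dd == 0:
        return OverlapTable(0, 0, 0, 0, p=1.0, direction="none")
    p_conc, _ = concordance_tails(uu, ud, du, dd)
    diag = uu + dd - ud - du
    direction = "concordant" if diag > 0 else ("discordant" if diag < 0 else "none")
    return OverlapTable(uu, ud, du, dd, p=p_conc, direction=direction)


def stouffer_combine(
    a: DifferentialProfile, b: DifferentialProfile
) -> CombinedProfile:
    """Stouffer combination of two Z profiles over their shared keys.

    Under a shared null, z = (z_a + z_b)/sqrt(2) is again standard normal.
    """
    shared = a.table.index.intersection(b.table.index)
    if len(shared) == 0:
        raise PreconditionError("profiles share no keys")
    z = (a.z.loc[shared] + b.z.loc[shared]) / math.sqrt(2.0)
    return CombinedProfile(z.sort_index())
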