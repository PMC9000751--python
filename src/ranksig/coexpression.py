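"""Transcription-factor co-expression profiles (TFCEPs) from a compendium.

Across a compendium of expression series, a gene is *called* in a sample
when it deviates from its own series average by at least ``z_dev`` standard
deviations (+1 up, −1 down, 0 otherwise).  Two genes co-express when their
calls agree across the samples where both are called; agreement is tested
by a one-sided Fisher exact test on the 2×2 call-sign table.  Each TF is
then assigned a signed signature — its top-k positively and top-k
negatively co-expressed partner genes — and a differential signature can be
queried against the TF bank exactly like a drug bank, pointing to TFs whose
activation or repression would recapitulate the observed response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .connectivity import ConnectivityResult, SignatureBank, query_signature_bank
from .differential import SignedGeneSignature, concordance_tails
from .errors import PreconditionError
from .matrix import ExpressionMatrix

__all__ = [
    "DeviationCalls",
    "TFProfile",
    "call_deviations",
    "coexpress_pair",
    "build_tf_profile",
    "build_tfcep_bank",
    "query_tfcep",
]

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-4  # matches the differential module's variance floor of 1e-8


@dataclass
class DeviationCalls:
    """Gene × sample deviation calls in {−1, 0, +1} with series boundaries."""

    calls: pd.DataFrame  # int8, genes on rows
    series: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        listed = [s for members in self.series.values() for s in members]
        if sorted(listed) != sorted(self.calls.columns):
            raise PreconditionError("series boundaries do not partition the samples")

    @property
    def genes(self) -> pd.Index:
        return self.calls.index


@dataclass
class TFProfile:
    """A TF's ordered positive/negative co-expression partners with p values."""

    tf: str
    positive: list[str]
    negative: list[str]
    pvalues: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise PreconditionError("partner lists must be disjoint")
        if self.tf in self.positive or self.tf in self.negative:
            raise PreconditionError("a TF cannot be its own partner")

    def to_signature(self) -> SignedGeneSignature:
        return SignedGeneSignature(
            frozenset(self.positive), frozenset(self.negative), {"tf": self.tf}
        )


def call_deviations(
    compendium: Sequence[ExpressionMatrix], z_dev: float = 2.0
) -> DeviationCalls:
    """Call per-sample deviations from each series' own average.

    Within each series, every gene is standardized across the series'
    samples ((value − mean)/SD, SD floored); samples at or beyond ±z_dev
    are called ±1.  Series must share the gene universe and have at least
    4 samples each (fewer make the series average meaningless).
    """
    if z_dev <= 0:
        raise PreconditionError("z_dev must be positive")
    if not compendium:
        raise PreconditionError("compendium is empty")
    index = compendium[0].values.index
    blocks = []
    series: dict[str, list[str]] = {}
    for i, mat in enumerate(compendium):
        if mat.n_samples < 4:
            raise PreconditionError(
                f"series {i} has {mat.n_samples} samples; need at least 4"
            )
        if not mat.values.index.equals(index):
            raise PreconditionError("compendium series have mismatched gene universes")
        x = mat.values.to_numpy(dtype=float)
        mean = x.mean(axis=1, keepdims=True)
        sd = np.maximum(x.std(axis=1, ddof=1, keepdims=True), _SD_FLOOR)
        z = (x - mean) / sd
        calls = np.zeros(z.shape, dtype=np.int8)
        calls[z >= z_dev] = 1
        calls[z <= -z_dev] = -1
        blocks.append(pd.DataFrame(calls, index=index, columns=mat.values.columns))
        series[f"series{i}"] = list(mat.values.columns)
    all_calls = pd.concat(blocks, axis=1)
    if all_calls.columns.has_duplicates:
        raise PreconditionError("sample IDs collide across series")
    return DeviationCalls(all_calls, series)


def coexpress_pair(
    a: str, b: str, calls: DeviationCalls, min_joint: int = 3
) -> tuple[float, str]:
    """Fisher co-expression test of two genes over jointly-called samples.

    Tabulates call-sign agreement over samples where both genes are called,
    tests both one-sided alternatives, and returns (p, direction) for the
    smaller tail, direction in {"positive", "negative", "none"}.  With fewer
    than ``min_joint`` jointly-called samples the test is vacuous: (1.0,
    "none").  Symmetric in its gene arguments.
    """
    for g in (a, b):
        if g not in calls.calls.index:
            raise PreconditionError(f"gene {g!r} absent from the call matrix")
    ca = calls.calls.loc[a].to_numpy()
    cb = calls.calls.loc[b].to_numpy()
    joint = (ca != 0) & (cb != 0)
    if int(joint.sum()) < min_joint:
        return 1.0, "none"
    ca, cb = ca[joint], cb[joint]
    uu = int(((ca == 1) & (cb == 1)).sum())
    ud = int(((ca == 1) & (cb == -1)).sum())
    du = int(((ca == -1) & (cb == 1)).sum())
    dd = int(((ca == -1) & (cb == -1)).sum())
    p_conc, p_disc = concordance_tails(uu, ud, du, dd)
    if p_conc < p_disc:
        return p_conc, "positive"
    if p_disc < p_conc:
        return p_disc, "negative"
    return p_conc, "none"


def _pair_tests_vectorized(
    calls: DeviationCalls, tf: str, min_joint: int
) -> pd.DataFrame:
    """Both one-sided Fisher tails of every gene against one TF, vectorized."""
    c = calls.calls.to_numpy()
    ct = calls.calls.loc[tf].to_numpy()
    tf_up, tf_dn = ct == 1, ct == -1
    g_up, g_dn = c == 1, c == -1
    uu = (g_up & tf_up).sum(axis=1)
    ud = (g_dn & tf_up).sum(axis=1)  # rows: TF sign; cols: gene sign
    du = (g_up & tf_dn).sum(axis=1)
    dd = (g_dn & tf_dn).sum(axis=1)
    n = uu + ud + du + dd
    r1, c1 = uu + ud, uu + du
    with np.errstate(invalid="ignore"):
        p_conc = hypergeom.sf(uu - 1, n, r1, c1)
        p_disc = hypergeom.cdf(uu, n, r1, c1)
    vacuous = n < min_joint
    p_conc = np.where(vacuous, 1.0, np.minimum(p_conc, 1.0))
    p_disc = np.where(vacuous, 1.0, np.minimum(p_disc, 1.0))
    return pd.DataFrame(
        {"p_conc": p_conc, "p_disc": p_disc, "n_joint": n}, index=calls.calls.index
    )


def build_tf_profile(
    calls: DeviationCalls,
    tf: str,
    k: int = 500,
    min_joint: int = 3,
    p_max: float = 0.05,
) -> TFProfile:
    """Top-k positively and negatively co-expressed partners of one TF.

    Partners are ranked by ascending one-sided Fisher p in their direction
    (ties by gene name), must pass ``p_max``, and exclude the TF itself.
    Lists shorter than k are returned as-is, without padding.
    """
    if tf not in calls.calls.index:
        raise PreconditionError(f"TF {tf!r} absent from the call matrix")
    tests = _pair_tests_vectorized(calls, tf, min_joint).drop(index=tf)
    pos = tests[(tests["p_conc"] < tests["p_disc"]) & (tests["p_conc"] <= p_max)]
    neg = tests[(tests["p_disc"] < tests["p_conc"]) & (tests["p_disc"] <= p_max)]
    pos_order = sorted(pos.index, key=lambda g: (pos.at[g, "p_conc"], g))[:k]
    neg_order = sorted(neg.index, key=lambda g: (neg.at[g, "p_disc"], g))[:k]
    pvalues = {g: float(pos.at[g, "p_conc"]) for g in pos_order}
    pvalues.update({g: float(neg.at[g, "p_disc"]) for g in neg_order})
    return TFProfile(tf=tf, positive=pos_order, negative=neg_order, pvalues=pvalues)


def build_tfcep_bank(
    calls: DeviationCalls,
    tf_list: Iterable[str],
    k: int = 500,
    min_joint: int = 3,
    p_max: float = 0.05,
) -> SignatureBank:
    """Signature bank of TFCEPs for a list of transcription factors.

    TFs absent from the call matrix are skipped with a logged notice.
    """
    signatures: dict[str, SignedGeneSignature] = {}
    for tf in sorted(set(tf_list)):
        if tf not in calls.calls.index:
            logger.warning("TF %s absent from compendium; skipped", tf)
            continue
        profile = build_tf_profile(calls, tf, k=k, min_joint=min_joint, p_max=p_max)
        signatures[tf] = profile.to_signature()
    return SignatureBank(signatures, universe=len(calls.genes))


def query_tfcep(query: SignedGeneSignature, bank: SignatureBank) -> ConnectivityResult:
    """Rank TFCEPs by signed Fisher concordance with a query signature."""
    return query_signature_bank(query, bank)
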