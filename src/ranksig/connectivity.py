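"""Connectivity mapping: rank a bank of signed signatures against a query.

Each bank entry (a drug-like perturbation signature, or a TF co-expression
profile) is an up/down gene pair.  Query and target are crossed into a 2×2
sign table (UU, UD, DU, DD) and scored by a signed Fisher exact statistic:

    score = sign(UU + DD − UD − DU) · (−log10 p)

where p is the one-sided hypergeometric tail on the side of the observed
association.  Concordant signatures (drugs mimicking the query) score
positive, discordant ones (reversers) negative, and negating the query
negates every score exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .differential import OverlapTable, SignedGeneSignature, concordance_tails
from .errors import PreconditionError

__all__ = ["SignatureBank", "ConnectivityResult", "score_signature_pair", "query_signature_bank"]

_MIN_P = 1e-300  # guards log10 against an exact-zero tail


@dataclass
class SignatureBank:
    """Named signed signatures over a common gene universe.

    The universe size documents the background the signatures were derived
    from; the Fisher test itself conditions on the 2×2 margins.
    """

    signatures: dict[str, SignedGeneSignature] = field(default_factory=dict)
    universe: int = 0

    def __post_init__(self) -> None:
        span = max((len(s) for s in self.signatures.values()), default=0)
        if self.universe < span:
            raise PreconditionError(
                f"universe ({self.universe}) smaller than largest signature ({span})"
            )

    def __len__(self) -> int:
        return len(self.signatures)

    def items(self):
        return self.signatures.items()


@dataclass
class ConnectivityResult:
    """Ranked rows of (name, OverlapTable, signed score), best score first."""

    rows: list[tuple[str, OverlapTable, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": name, "uu": t.uu, "ud": t.ud, "du": t.du, "dd": t.dd,
                    "p": t.p, "score": score,
                }
                for name, t, score in self.rows
            ]
        )

    def rank_of(self, name: str) -> int:
        """1-based rank of a bank entry."""
        for i, (row_name, _, _) in enumerate(self.rows, start=1):
            if row_name == name:
                return i
        raise KeyError(name)


def score_signature_pair(
    query: SignedGeneSignature,
    target: SignedGeneSignature,
    universe: int,
) -> tuple[OverlapTable, float]:
    """Signed Fisher-exact score of a query/target signature pair.

    The p value is the one-sided tail on the side of the observed
    association (concordance if UU+DD ≥ UD+DU, discordance otherwise),
    making the score antisymmetric under up/down swap of either signature.
    """
    involved = query.genes() | target.genes()
    if universe < len(involved):
        raise PreconditionError(
            f"universe ({universe}) smaller than genes involved ({len(involved)})"
        )
    uu = len(query.up & target.up)
    ud = len(query.up & target.down)
    du = len(query.down & target.up)
    dd = len(query.down & target.down)
    if uu + ud + du + dd == 0:
        return OverlapTable(0, 0, 0, 0, p=1.0, direction="none"), 0.0
    p_conc, p_disc = concordance_tails(uu, ud, du, dd)
    diag = uu + dd - ud - du
    if diag > 0:
        table = OverlapTable(uu, ud, du, dd, p=p_conc, direction="concordant")
        return table, -math.log10(max(p_conc, _MIN_P)) + 0.0
    if diag < 0:
        table = OverlapTable(uu, ud, du, dd, p=p_disc, direction="discordant")
        return table, math.log10(max(p_disc, _MIN_P)) + 0.0
    return OverlapTable(uu, ud, du, dd, p=min(p_conc, p_disc), direction="none"), 0.0


def query_signature_bank(
    query: SignedGeneSignature, bank: SignatureBank
) -> ConnectivityResult:
    """Score every bank member against the query; best (most concordant) first.

    Ties in score break lexicographically by name.
    """
    if len(bank) == 0:
        raise PreconditionError("signature bank is empty")
    rows = []
    for name, target in bank.items():
        table, score = score_signature_pair(query, target, bank.universe)
        rows.append((name, table, score))
    rows.sort(key=lambda row: (-row[2], row[0]))
    return ConnectivityResult(rows)
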