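"""Core containers: expression matrices and probe-to-gene maps.

An :class:`ExpressionMatrix` holds normalized, log-scale intensities with
probes on the rows and samples on the columns, plus an optional sample→group
labelling (e.g. ``"core:treated"``).  Downstream analyses are rank-based, so
the absolute scale of the intensities never matters — only their within-sample
ordering does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataFormatError

__all__ = ["ExpressionMatrix", "ProbeGeneMap"]


@dataclass
class ExpressionMatrix:
    """Probe × sample matrix of log-scale intensities.

    Parameters
    ----------
    values:
        DataFrame indexed by probe ID with sample IDs as columns.  All cells
        must be finite.
    groups:
        Optional mapping from sample ID to an arbitrary group label
        (cell line, treatment arm, series, ...).
    """

    values: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise DataFormatError(f"duplicate probe IDs: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()[:5]
            raise DataFormatError(f"duplicate sample IDs: {dup}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise DataFormatError("expression matrix contains non-finite values")
        if self.groups is not None:
            unknown = set(self.groups) - set(v.columns)
            if unknown:
                raise DataFormatError(
                    f"group labels refer to unknown samples: {sorted(unknown)[:5]}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        """Sample IDs carrying the given group label, in column order."""
        if self.groups is None:
            return []
        members = {s for s, g in self.groups.items() if g == group}
        return [s for s in self.values.columns if s in members]


@dataclass
class ProbeGeneMap:
    """Many-to-one probe → gene-symbol map.

    Each probe maps to at most one gene; multiple probes may map to the same
    gene (probe degeneracy, which the collapse rules resolve).  Probes absent
    from the mapping are treated as unannotated and dropped at collapse time.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not gene:
                raise DataFormatError(f"probe {probe!r} maps to an empty gene symbol")

    def gene_of(self, probe: str) -> str | None:
        return self.mapping.get(probe)

    def genes(self) -> set[str]:
        return set(self.mapping.values())

    def probes_for(self, gene: str) -> list[str]:
        return sorted(p for p, g in self.mapping.items() if g == gene)

    def __len__(self) -> int:
        return len(self.mapping)

    def to_series(self) -> pd.Series:
        s = pd.Series(self.mapping, dtype=object)
        s.index.name = "probe"
        s.name = "gene"
        return s.sort_index()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]] | Mapping[str, str]) -> "ProbeGeneMap":
        if isinstance(pairs, Mapping):
            return cls(dict(pairs))
        mapping: dict[str, str] = {}
        for probe, gene in pairs:
            if probe in mapping and mapping[probe] != gene:
                raise DataFormatError(f"probe {probe!r} maps to more than one gene")
            mapping[probe] = gene
        return cls(mapping)
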