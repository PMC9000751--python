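"""File formats: TSV matrices and profiles, signed signatures, GMT, banks.

All writers emit ``#``-prefixed provenance header lines (stage, parameters,
seed, input digests — never timestamps, so reruns are byte-identical); all
readers skip them.  Formats:

* expression matrix — TSV, first column probe ID, header row of sample IDs;
* probe→gene map — 2-column TSV (probe, gene);
* rank profile — 2-column TSV (key, relative_rank);
* differential profile — 3-column TSV (key, z, log2fc), level in a header
  comment;
* signed signature — a ``>up`` section of genes one per line, then ``>down``;
* GMT — one set per line: name, description, then member genes, tab-separated;
* signature bank — a directory of signature files plus ``index.tsv``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import DifferentialProfile, SignedGeneSignature
from .connectivity import SignatureBank
from .enrichment import GeneSetCollection
from .errors import DataFormatError
from .matrix import ExpressionMatrix, ProbeGeneMap
from .ranks import RankProfile
from .synth import TruthRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix", "write_matrix",
    "read_probe_map", "write_probe_map",
    "read_rank_profile", "write_rank_profile",
    "read_differential", "write_differential",
    "read_signature", "write_signature",
    "read_gmt", "write_gmt",
    "read_bank", "write_bank",
    "read_truth", "write_truth",
    "file_digest",
]


def _header_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {key}: {value}" for key, value in provenance.items()]


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except (pd.errors.ParserError, ValueError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc


def _as_float(frame: pd.DataFrame, column: str, path) -> "np.ndarray":
    try:
        return frame[column].astype(float).to_numpy()
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric value in column {column!r}") from exc


def write_matrix(
    matrix: ExpressionMatrix, path: str | Path, provenance: dict | None = None
) -> None:
    lines = _header_lines(provenance)
    body = matrix.values.to_csv(sep="\t", index_label="probe", float_format="%.10g")
    Path(path).write_text("\n".join(lines + [body]) if lines else body)


def read_matrix(path: str | Path, groups: dict[str, str] | None = None) -> ExpressionMatrix:
    frame = _read_tsv(path, index_col=0)
    arr = frame.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        bad = frame.columns[[not np.issubdtype(d, np.number) for d in frame.dtypes]]
        raise DataFormatError(f"{path}: non-numeric cells in columns {list(bad)[:5]}")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(frame, groups)


def write_probe_map(
    pmap: ProbeGeneMap, path: str | Path, provenance: dict | None = None
) -> None:
    lines = _header_lines(provenance)
    lines.append("probe\tgene")
    lines += [f"{p}\t{g}" for p, g in sorted(pmap.mapping.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    frame = _read_tsv(path, dtype=str)
    if list(frame.columns) != ["probe", "gene"]:
        raise DataFormatError(f"{path}: expected columns (probe, gene)")
    if frame["probe"].duplicated().any():
        dup = frame["probe"][frame["probe"].duplicated()].tolist()[:5]
        raise DataFormatError(f"{path}: duplicate probes {dup}")
    return ProbeGeneMap(dict(zip(frame["probe"], frame["gene"])))


def write_rank_profile(
    profile: RankProfile, path: str | Path, provenance: dict | None = None
) -> None:
    prov = dict(provenance or {})
    if profile.name:
        prov.setdefault("profile", profile.name)
    lines = _header_lines(prov)
    lines.append("key\trelative_rank")
    lines += [f"{k}\t{v:.10g}" for k, v in profile.values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rank_profile(path: str | Path, name: str | None = None) -> RankProfile:
    frame = _read_tsv(path)
    if list(frame.columns) != ["key", "relative_rank"]:
        raise DataFormatError(f"{path}: expected columns (key, relative_rank)")
    if frame["key"].duplicated().any():
        raise DataFormatError(f"{path}: duplicate keys")
    values = pd.Series(
        _as_float(frame, "relative_rank", path),
        index=pd.Index(frame["key"].astype(str), name="key"),
    )
    return RankProfile(values, name=name)


def write_differential(
    profile: DifferentialProfile, path: str | Path, provenance: dict | None = None
) -> None:
    prov = dict(provenance or {})
    prov.setdefault("level", profile.level)
    lines = _header_lines(prov)
    lines.append("key\tz\tlog2fc")
    for key, row in profile.table.iterrows():
        lines.append(f"{key}\t{row['z']:.10g}\t{row['log2fc']:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_differential(path: str | Path) -> DifferentialProfile:
    level = "probe"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# level:"):
                level = line.split(":", 1)[1].strip()
            elif not line.startswith("#"):
                break
    frame = _read_tsv(path)
    if list(frame.columns) != ["key", "z", "log2fc"]:
        raise DataFormatError(f"{path}: expected columns (key, z, log2fc)")
    if frame["key"].duplicated().any():
        raise DataFormatError(f"{path}: duplicate keys")
    table = pd.DataFrame(
        {"z": _as_float(frame, "z", path), "log2fc": _as_float(frame, "log2fc", path)},
        index=pd.Index(frame["key"].astype(str), name="key"),
    )
    return DifferentialProfile(table, level=level)


def write_signature(
    signature: SignedGeneSignature, path: str | Path, provenance: dict | None = None
) -> None:
    lines = _header_lines(provenance)
    lines.append(">up")
    lines += sorted(signature.up)
    lines.append(">down")
    lines += sorted(signature.down)
    Path(path).write_text("\n".join(lines) + "\n")


def read_signature(path: str | Path) -> SignedGeneSignature:
    up: list[str] = []
    down: list[str] = []
    current: list[str] | None = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == ">up":
            current = up
        elif line == ">down":
            current = down
        elif line.startswith(">"):
            raise DataFormatError(f"{path}:{lineno}: unknown section {line!r}")
        else:
            if current is None:
                raise DataFormatError(f"{path}:{lineno}: gene before any section header")
            current.append(line)
    overlap = set(up) & set(down)
    if overlap:
        raise DataFormatError(
            f"{path}: genes in both sections: {sorted(overlap)[:5]}"
        )
    return SignedGeneSignature(frozenset(up), frozenset(down))


def write_gmt(
    collection: GeneSetCollection, path: str | Path, provenance: dict | None = None
) -> None:
    lines = _header_lines(provenance)
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        members = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GSEA-dialect GMT file: name, description, member genes.

    Duplicate set names are an error; duplicate genes within a set are
    deduplicated with a logged warning; a line with fewer than 3 tab fields
    is a parse error naming the line.
    """
    collection = GeneSetCollection()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataFormatError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
            )
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        unique = list(dict.fromkeys(genes))
        if len(unique) < len(genes):
            logger.warning(
                "%s:%d: set %s had %d duplicate genes; deduplicated",
                path, lineno, name, len(genes) - len(unique),
            )
        if name in collection.sets:
            raise DataFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        collection.add(name, unique, desc)
    return collection


def write_bank(
    bank: SignatureBank, directory: str | Path, provenance: dict | None = None
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index_lines = _header_lines({**(provenance or {}), "universe": bank.universe})
    index_lines.append("name\tpath\tn_up\tn_down")
    for name in sorted(bank.signatures):
        sig = bank.signatures[name]
        fname = f"{name}.sig"
        write_signature(sig, directory / fname)
        index_lines.append(f"{name}\t{fname}\t{len(sig.up)}\t{len(sig.down)}")
    (directory / "index.tsv").write_text("\n".join(index_lines) + "\n")


def read_bank(directory: str | Path) -> SignatureBank:
    directory = Path(directory)
    index_path = directory / "index.tsv"
    if not index_path.exists():
        raise DataFormatError(f"{directory}: no index.tsv")
    universe = 0
    for line in index_path.read_text().splitlines():
        if line.startswith("# universe:"):
            universe = int(line.split(":", 1)[1].strip())
    frame = _read_tsv(index_path, dtype=str)
    if list(frame.columns)[:2] != ["name", "path"]:
        raise DataFormatError(f"{index_path}: expected columns starting (name, path)")
    signatures = {
        row["name"]: read_signature(directory / row["path"])
        for _, row in frame.iterrows()
    }
    return SignatureBank(signatures, universe=universe)


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> TruthRecord:
    return TruthRecord.from_dict(json.loads(Path(path).read_text()))
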