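"""Readers and writers for the tabular formats of paired omics panels.

Two input dialects are supported: Illumina-style sample/probe profile
tables (one probe-id column, one or more signal columns per sample,
selected by a header tag such as ``"AVG Signal"``) and GEO series-matrix
tables (a tab-delimited block fenced by ``!series_matrix_table_begin`` /
``!series_matrix_table_end`` sentinels).  Values are taken as-is from the
file: no normalization, background correction or log transform is applied
anywhere in this module.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInfo",
    "OmicsMatrix",
    "ProbeAnnotation",
    "FormatError",
    "TableParseError",
    "AlignmentError",
    "read_probe_profile",
    "read_series_matrix",
    "read_annotation",
    "write_matrix",
    "align_modalities",
    "drop_missing_features",
    "map_probes_to_genes",
]


class FormatError(ValueError):
    """The file does not have the structure the dialect requires."""


class TableParseError(ValueError):
    """A cell of the table could not be parsed."""


class AlignmentError(ValueError):
    """Paired modalities have no samples in common."""


@dataclass(frozen=True)
class SampleInfo:
    """Identity of one array sample within the study design.

    ``(category, replicate, modality)`` uniquely identifies a sample;
    ``category`` is the cell-line label (e.g. H1, H358, iPCH460) and
    ``modality`` one of ``expression`` / ``methylation`` / ``histone``.
    """

    sample_id: str
    category: str
    replicate: int
    modality: str = "expression"

    @property
    def key(self) -> tuple[str, int]:
        return (self.category, self.replicate)


@dataclass
class OmicsMatrix:
    """A features x samples value table for one modality.

    ``values[i, j]`` is the signal of probe ``feature_ids[i]`` in sample
    ``samples[j]``, in the units of the originating array (no transform).
    """

    values: np.ndarray
    feature_ids: list[str]
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[0] != len(self.feature_ids):
            raise ValueError(
                f"{self.values.shape[0]} rows but {len(self.feature_ids)} feature ids"
            )
        if self.values.shape[1] != len(self.samples):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.samples)} samples"
            )
        seen: set[str] = set()
        for fid in self.feature_ids:
            if fid in seen:
                raise FormatError(f"duplicate probe id {fid!r}")
            seen.add(fid)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def categories(self) -> list[str]:
        """Category label of each sample, in column order."""
        return [s.category for s in self.samples]

    def with_samples(self, samples: Sequence[SampleInfo]) -> "OmicsMatrix":
        if len(samples) != self.n_samples:
            raise ValueError("sample metadata length mismatch")
        return OmicsMatrix(self.values, list(self.feature_ids), list(samples))

    def subset_features(self, keep: np.ndarray) -> "OmicsMatrix":
        keep = np.asarray(keep)
        ids = [fid for fid, k in zip(self.feature_ids, keep) if k]
        return OmicsMatrix(self.values[keep], ids, list(self.samples))

    def subset_samples(self, idx: Sequence[int]) -> "OmicsMatrix":
        idx = list(idx)
        return OmicsMatrix(
            self.values[:, idx], list(self.feature_ids), [self.samples[j] for j in idx]
        )


@dataclass
class ProbeAnnotation:
    """Probe -> (RefSeq accession, gene symbol) mapping.

    Probes absent from ``mapping`` are unannotated.  Many probes may map
    to the same gene; one probe maps to at most one gene.
    """

    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def symbol(self, probe: str) -> str | None:
        pair = self.mapping.get(probe)
        return pair[1] if pair else None

    def accession(self, probe: str) -> str | None:
        pair = self.mapping.get(probe)
        return pair[0] if pair else None


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _unquote(token: str) -> str:
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "\"'":
        return token[1:-1]
    return token


def _parse_float(token: str, row: str, col: str) -> float:
    token = token.strip()
    if token == "" or token.lower() in ("na", "nan", "null"):
        return float("nan")
    try:
        return float(token)
    except ValueError:
        raise TableParseError(
            f"non-numeric value {token!r} at probe {row!r}, column {col!r}"
        ) from None


def _placeholder_samples(names: Iterable[str], modality: str) -> list[SampleInfo]:
    return [SampleInfo(n, category=n, replicate=1, modality=modality) for n in names]


def read_probe_profile(
    path: str | Path,
    signal_column_tag: str = "AVG Signal",
    modality: str = "expression",
) -> OmicsMatrix:
    """Read a sample/probe profile table, keeping only tagged signal columns.

    The first column holds probe identifiers; every column whose header
    contains ``signal_column_tag`` is kept (in file order), all other
    columns (detection P-values etc.) are dropped.  Values are parsed as
    floats without any transformation.
    """
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file")
        header = [_unquote(h.strip()) for h in header_line.rstrip("\n").split("\t")]
        if len(header) < 2:
            raise FormatError(f"{path}: expected a probe-id column and data columns")
        keep = [j for j, h in enumerate(header[1:], start=1) if signal_column_tag in h]
        if not keep:
            raise FormatError(
                f"{path}: no column header contains {signal_column_tag!r}"
            )
        # sample names are the headers with the tag stripped ("S1.AVG Signal" -> "S1")
        sample_names = [
            header[j].replace(signal_column_tag, "").strip(" ._-") or header[j]
            for j in keep
        ]
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) != len(header):
                raise TableParseError(
                    f"{path}: row {toks[0]!r} has {len(toks)} fields, header has {len(header)}"
                )
            pid = _unquote(toks[0].strip())
            ids.append(pid)
            rows.append([_parse_float(toks[j], pid, header[j]) for j in keep])
    if not ids:
        raise FormatError(f"{path}: table has no data rows")
    values = np.array(rows, dtype=float)
    return OmicsMatrix(values, ids, _placeholder_samples(sample_names, modality))


_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"


def read_series_matrix(
    path: str | Path,
    sample_map: Mapping[str, tuple[str, int]] | None = None,
    modality: str = "methylation",
) -> OmicsMatrix:
    """Read the data table of a series-matrix file.

    Only the block between the ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` sentinels is read; metadata lines
    (prefixed ``!``) outside it are ignored and quoted identifiers are
    unquoted.  Sample ``(category, replicate)`` metadata is populated from
    *sample_map* (sample id -> (category, replicate)), never guessed from
    headers.
    """
    in_table = False
    saw_end = False
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[list[float]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not in_table:
                if line.strip() == _TABLE_BEGIN:
                    in_table = True
                continue
            if line.strip() == _TABLE_END:
                saw_end = True
                break
            if not line:
                continue
            toks = [_unquote(t.strip()) for t in line.split("\t")]
            if header is None:
                header = toks
                continue
            if len(toks) != len(header):
                raise TableParseError(
                    f"{path}: row {toks[0]!r} has {len(toks)} fields, header has {len(header)}"
                )
            ids.append(toks[0])
            rows.append(
                [_parse_float(t, toks[0], header[j]) for j, t in enumerate(toks) if j > 0]
            )
    if not in_table:
        raise FormatError(f"{path}: missing {_TABLE_BEGIN} sentinel")
    if not saw_end:
        raise FormatError(f"{path}: missing {_TABLE_END} sentinel")
    if header is None or not ids:
        raise FormatError(f"{path}: series-matrix table is empty")
    sample_names = header[1:]
    values = np.array(rows, dtype=float)
    if sample_map is not None:
        samples = []
        for name in sample_names:
            if name not in sample_map:
                raise AlignmentError(f"sample {name!r} absent from sample map")
            cat, rep = sample_map[name]
            samples.append(SampleInfo(name, category=cat, replicate=int(rep), modality=modality))
    else:
        samples = _placeholder_samples(sample_names, modality)
    return OmicsMatrix(values, ids, samples)


def read_annotation(
    path: str | Path,
    probe_column: str | None = None,
    accession_column: str = "Accession",
    symbol_column: str = "Symbol",
) -> ProbeAnnotation:
    """Read a platform annotation table into a probe -> gene mapping.

    The probe-id column defaults to the first column.  Probes whose
    accession and symbol are both empty are left unannotated.  When the
    symbol column is absent or empty, the accession doubles as the symbol.
    """
    with _open_text(path) as fh:
        header = [_unquote(h.strip()) for h in fh.readline().rstrip("\n").split("\t")]
        if probe_column is None:
            pidx = 0
        else:
            if probe_column not in header:
                raise FormatError(f"{path}: no column {probe_column!r}")
            pidx = header.index(probe_column)
        aidx = header.index(accession_column) if accession_column in header else None
        sidx = header.index(symbol_column) if symbol_column in header else None
        if aidx is None and sidx is None:
            raise FormatError(
                f"{path}: neither {accession_column!r} nor {symbol_column!r} column found"
            )
        mapping: dict[str, tuple[str, str]] = {}
        for line in fh:
            toks = [_unquote(t.strip()) for t in line.rstrip("\n").split("\t")]
            if len(toks) <= pidx or not toks[pidx]:
                continue
            acc = toks[aidx] if aidx is not None and aidx < len(toks) else ""
            sym = toks[sidx] if sidx is not None and sidx < len(toks) else ""
            if not acc and not sym:
                continue
            mapping[toks[pidx]] = (acc or sym, sym or acc)
    return ProbeAnnotation(mapping)


def write_matrix(m: OmicsMatrix, path: str | Path, id_header: str = "ID_REF") -> None:
    """Write an OmicsMatrix as a TSV that round-trips bit-exactly.

    Floats are rendered with ``repr`` (shortest string that parses back to
    the same double), so ``read_probe_profile``/``read_series_matrix`` on
    the written file reproduce ``values`` exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(id_header + "\t" + "\t".join(s.sample_id for s in m.samples) + "\n")
        for i, fid in enumerate(m.feature_ids):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in m.values[i]) + "\n")


def align_modalities(
    expr: OmicsMatrix, meth: OmicsMatrix
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Reorder columns so column j of both modalities is the same sample.

    Samples are matched on ``(category, replicate)``; the shared samples
    are ordered lexicographically by that key.  Samples present in only
    one modality are dropped with a logged warning.
    """
    ekeys = {s.key: j for j, s in enumerate(expr.samples)}
    mkeys = {s.key: j for j, s in enumerate(meth.samples)}
    shared = sorted(set(ekeys) & set(mkeys))
    if not shared:
        raise AlignmentError("no (category, replicate) keys shared between modalities")
    dropped = (set(ekeys) | set(mkeys)) - set(shared)
    if dropped:
        logger.warning(
            "dropping %d sample(s) present in only one modality: %s",
            len(dropped),
            sorted(dropped),
        )
    return (
        expr.subset_samples([ekeys[k] for k in shared]),
        meth.subset_samples([mkeys[k] for k in shared]),
    )


def drop_missing_features(
    expr: OmicsMatrix, meth: OmicsMatrix
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Drop probes with any missing value in their own modality.

    The decomposition assumes complete rows; rows with missing cells are
    removed independently per modality (the probe universes differ) and
    the counts are logged.
    """
    out = []
    for m in (expr, meth):
        keep = ~np.isnan(m.values).any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("dropping %d probe(s) with missing values", n_drop)
            m = m.subset_features(keep)
        out.append(m)
    return out[0], out[1]


def map_probes_to_genes(probes: Iterable[str], ann: ProbeAnnotation) -> set[str]:
    """Collapse a probe set to the set of annotated gene symbols.

    Unannotated probes are dropped; multiple probes of one gene collapse
    to a single symbol.  Selection always happens upstream at probe level;
    this is a post-hoc mapping for reporting.
    """
    out: set[str] = set()
    for p in probes:
        sym = ann.symbol(p)
        if sym:
            out.add(sym)
    return out
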