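"""Reading and writing expression matrices, MTI catalogs and result tables.

Expression tables are plain TSV/CSV with features in rows and tissue samples
in columns.  Sample ids carry their own annotation in the form
``<T|N>_<organ>_<replicate>`` (``T`` tumor, ``N`` normal), e.g. ``N_uterus_8``
or ``T_kidney_1``; the loader parses these into :class:`SampleAnnotation`
objects.  Missing expression values may be encoded as empty cells or ``NA``
and are represented internally as NaN — never as zero, which would corrupt
correlations downstream.

MTI (miRNA--target interaction) catalogs are delimited tables with one row
per validated interaction; column names are configurable and default to the
miRTarBase export convention (``miRNA``, ``Target Gene``).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleAnnotation",
    "ExpressionMatrix",
    "MTICatalog",
    "parse_sample_id",
    "format_sample_id",
    "load_expression",
    "save_expression",
    "load_mti_catalog",
    "save_mti_catalog",
    "restrict_catalog",
    "write_search_results_tsv",
    "write_search_result_json",
    "write_ranking_tsv",
]

_SAMPLE_ID_RE = re.compile(r"^(?P<status>[TN])_(?P<organ>[a-z][a-z0-9]*)_(?P<rep>[0-9]+)$")

_MISSING_MARKERS = ("", "NA")


class DataFormatError(ValueError):
    """Raised for malformed input tables or sample ids."""


@dataclass(frozen=True, order=True)
class SampleAnnotation:
    """Decomposed tissue-sample label.

    ``status`` is ``"tumor"`` or ``"normal"``, ``organ`` a lowercase token,
    ``replicate`` a positive integer.  ``format_sample_id`` round-trips with
    :func:`parse_sample_id`.
    """

    status: str
    organ: str
    replicate: int

    def __post_init__(self) -> None:
        if self.status not in ("tumor", "normal"):
            raise DataFormatError(f"status must be 'tumor' or 'normal', got {self.status!r}")
        if self.replicate < 1:
            raise DataFormatError(f"replicate must be a positive integer, got {self.replicate!r}")

    @property
    def sample_id(self) -> str:
        return format_sample_id(self)


def parse_sample_id(sample_id: str) -> SampleAnnotation:
    """Parse ``<T|N>_<organ>_<replicate>`` into a :class:`SampleAnnotation`.

    >>> parse_sample_id("N_uterus_8")
    SampleAnnotation(status='normal', organ='uterus', replicate=8)
    """
    match = _SAMPLE_ID_RE.match(sample_id)
    if match is None:
        head = sample_id.split("_", 1)[0]
        if head not in ("T", "N"):
            raise DataFormatError(
                f"invalid status prefix {head!r} in sample id {sample_id!r} (expected 'T' or 'N')"
            )
        raise DataFormatError(f"malformed sample id {sample_id!r} (expected '<T|N>_<organ>_<int>')")
    status = "tumor" if match.group("status") == "T" else "normal"
    return SampleAnnotation(status=status, organ=match.group("organ"), replicate=int(match.group("rep")))


def format_sample_id(annotation: SampleAnnotation) -> str:
    prefix = "T" if annotation.status == "tumor" else "N"
    return f"{prefix}_{annotation.organ}_{annotation.replicate}"


class ExpressionMatrix:
    """A features × samples matrix of log2 intensities.

    ``values`` is a float array with NaN marking missing entries.  Feature
    ids are unique (duplicates on load keep the first occurrence, with a
    warning); sample ids are unique and annotated.
    """

    def __init__(self, feature_ids: Sequence[str], samples: Sequence[SampleAnnotation], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise DataFormatError("values must be a 2-D array (features x samples)")
        if values.shape != (len(feature_ids), len(samples)):
            raise DataFormatError(
                f"shape mismatch: values {values.shape}, {len(feature_ids)} features, {len(samples)} samples"
            )
        if len(feature_ids) == 0 or len(samples) == 0:
            raise DataFormatError("empty expression matrix")
        if len(set(feature_ids)) != len(feature_ids):
            raise DataFormatError("duplicate feature ids")
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise DataFormatError("duplicate sample ids")
        self.feature_ids: list[str] = list(feature_ids)
        self.samples: list[SampleAnnotation] = list(samples)
        self.values: np.ndarray = values
        self._feature_index: dict[str, int] = {f: i for i, f in enumerate(self.feature_ids)}
        self._sample_index: dict[str, int] = {s: i for i, s in enumerate(sample_ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._feature_index

    def row(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across all samples."""
        try:
            return self.values[self._feature_index[feature_id]]
        except KeyError:
            raise KeyError(f"unknown feature id {feature_id!r}") from None

    def rows(self, feature_ids: Sequence[str]) -> np.ndarray:
        idx = [self._feature_index[f] for f in feature_ids]
        return self.values[idx]

    def sample_positions(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.samples == other.samples
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} features x {self.shape[1]} samples)"


@dataclass
class MTICatalog:
    """Validated miRNA--target interactions.

    Stored as an ordered mapping from miRNA id to its target genes (first
    occurrence order, deduplicated), so per-miRNA correlation profiles have a
    stable target order.
    """

    targets_by_mirna: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MTICatalog":
        mapping: dict[str, list[str]] = {}
        seen: set[tuple[str, str]] = set()
        for mirna, gene in pairs:
            if (mirna, gene) in seen:
                continue
            seen.add((mirna, gene))
            mapping.setdefault(mirna, []).append(gene)
        return cls({m: tuple(g) for m, g in mapping.items()})

    @property
    def interactions(self) -> list[tuple[str, str]]:
        return [(m, g) for m, targets in self.targets_by_mirna.items() for g in targets]

    @property
    def mirnas(self) -> list[str]:
        return list(self.targets_by_mirna)

    def targets(self, mirna: str) -> tuple[str, ...]:
        return self.targets_by_mirna.get(mirna, ())

    def n_targets(self, mirna: str) -> int:
        """N_m — the number of distinct targets catalogued for ``mirna``."""
        return len(self.targets_by_mirna.get(mirna, ()))

    def __len__(self) -> int:
        return sum(len(t) for t in self.targets_by_mirna.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MTICatalog):
            return NotImplemented
        return self.targets_by_mirna == other.targets_by_mirna


# -- delimiter handling ----------------------------------------------------


def _resolve_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt", ".tab"):
        return "\t"
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise DataFormatError(
        f"cannot auto-detect delimiter for {path} (only tab and comma are detected); pass delimiter explicitly"
    )


# -- expression IO ---------------------------------------------------------


def load_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Load a features × samples expression table.

    First row: sample ids in ``T|N_organ_k`` form.  First column: feature
    ids.  Empty cells and ``NA`` are read as missing.  Duplicate feature ids
    keep the first occurrence (warning); duplicate sample ids are an error.
    """
    path = Path(path)
    sep = _resolve_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise DataFormatError(f"duplicate sample ids in header of {path}: {dups}")
    frame = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=list(_MISSING_MARKERS),
        keep_default_na=False,
        dtype=str,
    )
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise DataFormatError(f"empty expression matrix in {path}")
    if frame.index.duplicated().any():
        counts = frame.index.value_counts()
        dups = {str(k): int(v) for k, v in counts[counts > 1].items()}
        warnings.warn(f"duplicate feature ids in {path}; keeping first occurrence: {dups}", stacklevel=2)
        frame = frame[~frame.index.duplicated(keep="first")]
    try:
        values = frame.astype(float).to_numpy()
    except ValueError as exc:
        raise DataFormatError(f"non-numeric cell in {path}: {exc}") from exc
    samples = [parse_sample_id(str(c).strip()) for c in frame.columns]
    return ExpressionMatrix([str(f).strip() for f in frame.index], samples, values)


def save_expression(matrix: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix as delimited text; NaN becomes ``NA``."""
    frame = matrix.to_frame()
    frame.to_csv(path, sep=delimiter, na_rep="NA", index_label="feature_id")


# -- MTI catalog IO --------------------------------------------------------


def load_mti_catalog(
    path: str | Path,
    mirna_column: str = "miRNA",
    gene_column: str = "Target Gene",
    delimiter: str | None = None,
    species_column: str | None = None,
    species: str | None = None,
) -> MTICatalog:
    """Load and deduplicate an MTI table.

    ``species_column``/``species`` optionally filter rows (e.g. keep only
    ``Homo sapiens`` entries of a multi-species export); restriction to the
    profiled id spaces is the caller's job via :func:`restrict_catalog`.
    """
    path = Path(path)
    sep = _resolve_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for column in (mirna_column, gene_column):
        if column not in frame.columns:
            raise DataFormatError(f"column {column!r} not found in {path} (columns: {list(frame.columns)})")
    if species_column is not None and species is not None:
        if species_column not in frame.columns:
            raise DataFormatError(f"species column {species_column!r} not found in {path}")
        frame = frame[frame[species_column].str.strip() == species]
    pairs = [
        (m.strip(), g.strip())
        for m, g in zip(frame[mirna_column], frame[gene_column])
        if m.strip() and g.strip()
    ]
    if not pairs:
        raise DataFormatError(f"empty MTI catalog in {path}")
    return MTICatalog.from_pairs(pairs)


def save_mti_catalog(catalog: MTICatalog, path: str | Path, delimiter: str = "\t") -> None:
    frame = pd.DataFrame(catalog.interactions, columns=["miRNA", "Target Gene"])
    frame.to_csv(path, sep=delimiter, index=False)


def restrict_catalog(
    catalog: MTICatalog,
    mirnas: Iterable[str] | None = None,
    genes: Iterable[str] | None = None,
    strip_prefix: str | None = None,
) -> MTICatalog:
    """Keep interactions whose miRNA and gene are both in the given sets.

    Matching is case-insensitive after trimming; retained ids are rewritten
    to the canonical spelling supplied in ``mirnas``/``genes`` (typically the
    expression-matrix ids), so downstream joins are exact.  ``strip_prefix``
    optionally removes a fixed prefix (e.g. ``"hsa-"``) from both sides
    before comparing.  ``None`` for either set means "no restriction on that
    side".  An empty result is allowed but warned about.
    """

    def canon(s: str) -> str:
        s = s.strip().lower()
        if strip_prefix and s.startswith(strip_prefix.lower()):
            s = s[len(strip_prefix):]
        return s

    mirna_map = None if mirnas is None else {canon(m): m for m in mirnas}
    gene_map = None if genes is None else {canon(g): g for g in genes}
    pairs = []
    for mirna, gene in catalog.interactions:
        cm, cg = canon(mirna), canon(gene)
        if mirna_map is not None and cm not in mirna_map:
            continue
        if gene_map is not None and cg not in gene_map:
            continue
        pairs.append(
            (mirna_map[cm] if mirna_map is not None else mirna, gene_map[cg] if gene_map is not None else gene)
        )
    if not pairs:
        warnings.warn("catalog restriction produced an empty catalog", stacklevel=2)
        return MTICatalog()
    return MTICatalog.from_pairs(pairs)


# -- result writers --------------------------------------------------------


def _result_record(result) -> dict:
    return {
        "mirna_id": result.mirna_id,
        "k": result.k,
        "best_subset": list(result.best_subset.sample_ids),
        "best_loss": result.best_loss,
        "mean_corr": result.profile.mean_corr,
        "p_neg": result.profile.p_neg,
        "n_evaluated": result.n_evaluated,
        "mode": result.mode,
    }


def write_search_results_tsv(results: Sequence, path: str | Path) -> None:
    """One row per per-k search result (subset ids comma-joined)."""
    rows = []
    for r in results:
        rec = _result_record(r)
        rec["best_subset"] = ",".join(rec["best_subset"])
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_search_result_json(result, path: str | Path, extra: Mapping | None = None) -> None:
    record = _result_record(result)
    if extra:
        record.update(extra)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_ranking_tsv(ranking, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(e.sample_id, e.occurrence_count, e.rank) for e in ranking.entries],
        columns=["sample_id", "occurrence_count", "rank"],
    )
    frame.to_csv(path, sep="\t", index=False)
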