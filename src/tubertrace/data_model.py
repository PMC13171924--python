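"""Core data model: ASV count tables, sample metadata, and grouping.

The pipeline operates on a taxa-by-samples table of nonnegative integer
read counts (amplicon sequence variants, ASVs) together with per-sample
metadata describing the multi-generation tuber study design: an ordered
host generation (seed < daughter < granddaughter), a tuber compartment
(flesh, peel, or tare soil), a cultivar, a field site, and a replicate
number.  Seed tubers predate the field trials, so their ``field`` is the
explicit missing level ``"(none)"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENERATIONS",
    "COMPARTMENTS",
    "NO_FIELD",
    "GroupKey",
    "CountTable",
    "SampleMetadata",
    "Dataset",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "validate_dataset",
    "group_samples",
    "result_header",
    "write_result_table",
]

#: Ordered host-generation levels (total order, transitions between
#: adjacent levels only).
GENERATIONS: tuple[str, ...] = ("seed", "daughter", "granddaughter")

#: Recognised tuber compartments.
COMPARTMENTS: tuple[str, ...] = ("flesh", "peel", "tare_soil")

#: Explicit missing level used when a sample has no field (seed tubers).
NO_FIELD = "(none)"

_GENERATION_INDEX = {g: i for i, g in enumerate(GENERATIONS)}

_FACTORS = ("generation", "compartment", "cultivar", "field")


def generation_index(generation: str) -> int:
    """Ordinal of a generation level (seed=0, daughter=1, granddaughter=2)."""
    return _GENERATION_INDEX[generation]


@dataclass(frozen=True, order=True)
class GroupKey:
    """A (generation, compartment, cultivar, field) cell of the design.

    Components not used by a grouping are ``None``; ``field`` uses the
    explicit ``"(none)"`` level for samples that predate the field trials.
    """

    generation: Optional[str] = None
    compartment: Optional[str] = None
    cultivar: Optional[str] = None
    field: Optional[str] = None

    def replace(self, **kwargs) -> "GroupKey":
        d = {
            "generation": self.generation,
            "compartment": self.compartment,
            "cultivar": self.cultivar,
            "field": self.field,
        }
        d.update(kwargs)
        return GroupKey(**d)

    def __str__(self) -> str:
        parts = [
            p for p in (self.generation, self.compartment, self.cultivar, self.field)
            if p is not None
        ]
        return "/".join(parts) if parts else "(all)"


@dataclass
class CountTable:
    """Taxa-by-samples matrix of nonnegative integer read counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if len(self.taxon_ids) == 0 or len(self.sample_ids) == 0:
            raise ValueError("count table must have at least 1 taxon and 1 sample")
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            rounded = np.rint(as_int.astype(float))
            bad = ~np.isclose(as_int.astype(float), rounded)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-integer count at taxon {self.taxon_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {as_int[i, j]!r}"
                )
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {self.counts[i, j]}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])


@dataclass(frozen=True)
class SampleMetadata:
    """Design factors attached to one sample."""

    sample_id: str
    generation: str
    compartment: str
    cultivar: str
    field: str = NO_FIELD
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.generation not in _GENERATION_INDEX:
            raise ValueError(
                f"unknown generation {self.generation!r} for sample "
                f"{self.sample_id!r}; accepted levels: {list(GENERATIONS)}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for sample "
                f"{self.sample_id!r}; accepted levels: {list(COMPARTMENTS)}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")

    @property
    def generation_level(self) -> int:
        return _GENERATION_INDEX[self.generation]


@dataclass
class Dataset:
    """A count table and its aligned metadata (same samples, same order)."""

    table: CountTable
    metadata: list[SampleMetadata]

    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids

    @property
    def taxon_ids(self) -> list[str]:
        return self.table.taxon_ids

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in self.metadata],
                "generation": [m.generation for m in self.metadata],
                "compartment": [m.compartment for m in self.metadata],
                "cultivar": [m.cultivar for m in self.metadata],
                "field": [m.field for m in self.metadata],
                "replicate": [m.replicate for m in self.metadata],
            }
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# TSV input / output
# ---------------------------------------------------------------------------

def read_count_table(path, orientation: str = "taxa_rows") -> CountTable:
    """Read a TSV count table.

    Parameters
    ----------
    path
        TSV file with a header row; the first column holds identifiers.
        Comment lines starting with ``"# "`` are skipped; a BIOM-style
        ``#OTU ID`` header is tolerated.
    orientation
        ``"taxa_rows"`` if rows are taxa (the internal convention) or
        ``"samples_rows"`` for the transposed layout.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"orientation must be 'taxa_rows' or 'samples_rows', got {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # Skip comment preamble but keep a '#OTU ID' header line (BIOM TSV export).
    rows = [
        ln for ln in lines
        if ln and not (ln.startswith("#") and not ln.startswith("#OTU ID"))
    ]
    if not rows:
        raise ValueError(f"empty count table: {path}")
    header = rows[0].split("\t")
    ids = header[1:]
    if not ids:
        raise ValueError(f"count table has no data columns: {path}")
    _check_unique(ids, "column")
    row_ids: list[str] = []
    data: list[list[int]] = []
    for ln in rows[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise ValueError(
                f"row {parts[0]!r} has {len(parts) - 1} cells, expected {len(ids)}"
            )
        row_ids.append(parts[0])
        vals = []
        for col, cell in zip(ids, parts[1:]):
            try:
                v = int(cell)
            except ValueError:
                fv = float(cell)
                if fv != int(fv):
                    raise ValueError(
                        f"non-integer count {cell!r} at row {parts[0]!r}, column {col!r}"
                    ) from None
                v = int(fv)
            if v < 0:
                raise ValueError(
                    f"negative count {cell!r} at row {parts[0]!r}, column {col!r}"
                )
            vals.append(v)
        data.append(vals)
    if not data:
        raise ValueError(f"count table has no data rows: {path}")
    _check_unique(row_ids, "row")
    mat = np.asarray(data, dtype=np.int64)
    if orientation == "samples_rows":
        return CountTable(ids, row_ids, mat.T)
    return CountTable(row_ids, ids, mat)


def write_count_table(table: CountTable, path) -> None:
    """Write a count table as plain TSV (taxa rows, integer cells)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\t" + "\t".join(table.sample_ids) + "\n")
        for tid, row in zip(table.taxon_ids, table.counts):
            fh.write(tid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


_META_COLUMNS = ("sample_id", "generation", "compartment", "cultivar", "field", "replicate")


def read_metadata(path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (columns: sample_id, generation,
    compartment, cultivar, field, replicate; field may be empty)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment=None)
    df.columns = [c.lstrip("# ") for c in df.columns]
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"duplicate sample_id in metadata: {sid!r}")
        seen.add(sid)
        gen = row["generation"].strip().lower()
        comp = row["compartment"].strip().lower().replace(" ", "_")
        fld = row["field"].strip() or NO_FIELD
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise ValueError(
                f"replicate for sample {sid!r} is not an integer: {row['replicate']!r}"
            ) from None
        out.append(
            SampleMetadata(
                sample_id=sid,
                generation=gen,
                compartment=comp,
                cultivar=row["cultivar"].strip(),
                field=fld,
                replicate=rep,
            )
        )
    _warn_design_violations(out)
    return out


def write_metadata(metadata: Sequence[SampleMetadata], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for m in metadata:
            fld = "" if m.field == NO_FIELD else m.field
            fh.write(
                f"{m.sample_id}\t{m.generation}\t{m.compartment}\t"
                f"{m.cultivar}\t{fld}\t{m.replicate}\n"
            )


def _warn_design_violations(metadata: Iterable[SampleMetadata]) -> None:
    for m in metadata:
        if m.compartment == "tare_soil" and m.generation != "granddaughter":
            warnings.warn(
                f"sample {m.sample_id!r}: tare_soil normally occurs only at the "
                f"granddaughter generation (found {m.generation!r})",
                stacklevel=3,
            )


def validate_dataset(table: CountTable, metadata: Sequence[SampleMetadata]) -> Dataset:
    """Check counts/metadata consistency and align sample order.

    The table's columns are reordered to follow the metadata order; a
    sample present in exactly one input is a hard error listing the
    symmetric difference.
    """
    meta = list(metadata)
    _check_unique([m.sample_id for m in meta], "metadata sample")
    tab_set = set(table.sample_ids)
    meta_set = {m.sample_id for m in meta}
    if tab_set != meta_set:
        only_table = sorted(tab_set - meta_set)
        only_meta = sorted(meta_set - tab_set)
        raise ValueError(
            "count table and metadata sample sets differ; "
            f"only in table: {only_table}; only in metadata: {only_meta}"
        )
    aligned = table.select_samples([m.sample_id for m in meta])
    return Dataset(aligned, meta)


def group_samples(ds: Dataset, by: Sequence[str]) -> dict[GroupKey, list[str]]:
    """Partition samples into design cells.

    ``by`` is a subset of {generation, compartment, cultivar, field}; an
    empty list yields a single group holding every sample.
    """
    for f in by:
        if f not in _FACTORS:
            raise ValueError(f"unknown factor {f!r}; accepted: {list(_FACTORS)}")
    groups: dict[GroupKey, list[str]] = {}
    for m in ds.metadata:
        key = GroupKey(**{f: getattr(m, f) for f in by})
        groups.setdefault(key, []).append(m.sample_id)
    return groups


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def result_header(subcommand: str, extra: Optional[Mapping[str, object]] = None) -> str:
    from tubertrace import __version__

    line = f"# tubertrace {__version__} {subcommand}"
    if extra:
        line += " " + " ".join(f"{k}={v}" for k, v in extra.items())
    return line


def write_result_table(
    df: pd.DataFrame, path, subcommand: str, extra: Optional[Mapping[str, object]] = None
) -> None:
    """Write a result table as TSV with the standard one-line comment header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(result_header(subcommand, extra) + "\n")
        df.to_csv(fh, sep="\t", index=False)
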