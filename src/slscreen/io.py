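"""Readers and writers for every external artifact the pipeline touches.

The screen's on-disk world is plain UTF-8 TSV with a single header row
(library annotation, per-lane barcode counts, result tables), standard
GMT gene-set files, and optionally raw FASTQ reads for exact-match
barcode counting.  All readers validate and reject rather than silently
coerce; column resolution is by name so that spreadsheet exports with
vendor column names can be mapped via ``column_map``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = ("barcode", "construct_id", "gene", "module", "is_control")


class ScreenConfigError(ValueError):
    """A configuration problem: missing column, bad parameter value."""


class ScreenValidationError(ValueError):
    """Input data violate an invariant (duplicates, negative counts, ...)."""


@dataclass(frozen=True)
class LibraryDesign:
    """The barcode/construct/gene/module catalogue of a pooled screen.

    ``table`` has one row per expression construct with columns
    ``barcode`` (short nucleotide tag), ``construct_id`` (unique opaque
    identifier), ``gene`` (symbol; empty for negative controls),
    ``module`` (small-integer sub-library label) and ``is_control``
    (bool; True for the Luciferase-targeting negative controls).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in LIBRARY_COLUMNS if c not in t.columns]
        if missing:
            raise ScreenConfigError(f"library annotation missing columns: {missing}")
        for col in ("barcode", "construct_id"):
            dup = t[col][t[col].duplicated()].unique().tolist()
            if dup:
                raise ScreenValidationError(f"duplicate {col} values: {dup[:10]}")
        if t["is_control"].dtype != bool:
            raise ScreenValidationError("is_control must be boolean")
        controls_per_module = t[t["is_control"]].groupby("module").size()
        for module in t["module"].unique():
            if controls_per_module.get(module, 0) < 1:
                raise ScreenValidationError(
                    f"module {module} has no negative-control construct; "
                    "noise-threshold estimation is impossible"
                )

    @property
    def construct_ids(self) -> pd.Index:
        return pd.Index(self.table["construct_id"])

    @property
    def modules(self) -> list:
        return sorted(self.table["module"].unique().tolist())

    @property
    def genes(self) -> list[str]:
        """Distinct target gene symbols (controls excluded)."""
        t = self.table
        return sorted(t.loc[~t["is_control"], "gene"].unique().tolist())

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class CountTable:
    """Per-construct integer read counts for one lane (one condition)."""

    lane_label: str
    counts: pd.Series  # index construct_id -> int >= 0

    def __post_init__(self) -> None:
        c = self.counts
        if not pd.api.types.is_integer_dtype(c):
            raise ScreenValidationError(
                f"lane {self.lane_label!r}: counts must be integers"
            )
        if (c < 0).any():
            bad = c[c < 0].index.tolist()
            raise ScreenValidationError(
                f"lane {self.lane_label!r}: negative counts for {bad[:10]}"
            )

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def reindex_to(self, design: LibraryDesign) -> "CountTable":
        """Align counts to a library design; absent constructs become 0.

        Dropout to zero is the signal of interest, so a construct missing
        from the count file is a zero count, not an error (warned).
        """
        missing = design.construct_ids.difference(self.counts.index)
        if len(missing):
            logger.warning(
                "lane %s: %d constructs absent from count table, counted as 0",
                self.lane_label,
                len(missing),
            )
        extra = self.counts.index.difference(design.construct_ids)
        if len(extra):
            raise ScreenValidationError(
                f"lane {self.lane_label!r}: counts for constructs not in the "
                f"library: {extra.tolist()[:10]}"
            )
        aligned = self.counts.reindex(design.construct_ids, fill_value=0).astype(int)
        return CountTable(self.lane_label, aligned)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. KEGG / Reactome pathways) from a GMT file."""

    sets: tuple[GeneSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ScreenValidationError("gene-set names are not unique")
        for s in self.sets:
            if not s.members:
                raise ScreenValidationError(f"gene set {s.name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def _resolve_columns(
    df: pd.DataFrame, required: Iterable[str], column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename vendor columns to canonical names and check presence."""
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenConfigError(
            f"required column(s) {missing} not found; available: "
            f"{df.columns.tolist()} (use column_map to rename)"
        )
    return df


def read_library_annotation(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> LibraryDesign:
    """Read a library annotation TSV into a :class:`LibraryDesign`.

    Parameters
    ----------
    path
        TSV with header; canonical columns ``barcode``, ``construct_id``,
        ``gene``, ``module``, ``is_control`` (0/1).
    column_map
        Optional mapping canonical name -> file column name, absorbing
        vendor spreadsheet headers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = _resolve_columns(df, LIBRARY_COLUMNS, column_map)
    try:
        module = pd.to_numeric(df["module"]).astype(int)
        control = pd.to_numeric(df["is_control"]).astype(int)
    except ValueError as exc:
        raise ScreenValidationError(f"non-numeric module/is_control value: {exc}")
    if not control.isin([0, 1]).all():
        raise ScreenValidationError("is_control must be 0 or 1")
    out = pd.DataFrame(
        {
            "barcode": df["barcode"],
            "construct_id": df["construct_id"],
            "gene": df["gene"],
            "module": module,
            "is_control": control.astype(bool),
        }
    )
    return LibraryDesign(out)


def write_library_annotation(design: LibraryDesign, path: str | Path) -> Path:
    path = Path(path)
    t = design.table.copy()
    t["is_control"] = t["is_control"].astype(int)
    t.to_csv(path, sep="\t", index=False)
    return path


def read_count_table(path: str | Path, lane_label: str) -> CountTable:
    """Read a two-column (construct_id, count) TSV for one lane."""
    df = pd.read_csv(path, sep="\t", dtype={"construct_id": str})
    df = _resolve_columns(df, ("construct_id", "count"), None)
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts != counts.round()) | (counts < 0)]
    if len(bad):
        # +2: 1-based and header row
        rows = [int(i) + 2 for i in bad[:10]]
        raise ScreenValidationError(
            f"lane {lane_label!r}: non-integer or negative count at file "
            f"row(s) {rows}"
        )
    series = pd.Series(
        counts.astype(int).values, index=pd.Index(df["construct_id"], name="construct_id")
    )
    if series.index.duplicated().any():
        dup = series.index[series.index.duplicated()].unique().tolist()
        raise ScreenValidationError(f"duplicate construct_id in counts: {dup[:10]}")
    return CountTable(lane_label, series)


def write_count_table(table: CountTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"construct_id": table.counts.index, "count": table.counts.values}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def count_barcodes_from_reads(
    reads: str | Path | IO[str],
    design: LibraryDesign,
    barcode_start: int,
    barcode_length: int,
    lane_label: str = "reads",
) -> tuple[CountTable, int]:
    """Count reads per construct by exact barcode match.

    Each read's subsequence ``[barcode_start, barcode_start + barcode_length)``
    is looked up against the library barcodes; only exact matches are
    assigned (no mismatch tolerance — the reproducible baseline).  Reads
    matching no barcode, or too short to contain the window, are tallied
    as unassigned.

    Returns
    -------
    (CountTable, n_unassigned)
        Assigned counts per construct (0 for unseen constructs) and the
        number of unassigned reads; assigned + unassigned equals the
        number of input reads.
    """
    lengths = design.table["barcode"].str.len().unique()
    if len(lengths) != 1 or lengths[0] != barcode_length:
        raise ScreenConfigError(
            f"design barcodes have length(s) {sorted(lengths)}, "
            f"expected uniform {barcode_length}"
        )
    if barcode_start < 0:
        raise ScreenConfigError("barcode_start must be >= 0")
    lookup = dict(zip(design.table["barcode"], design.table["construct_id"]))
    counts: dict[str, int] = {cid: 0 for cid in design.table["construct_id"]}
    unassigned = 0
    end = barcode_start + barcode_length

    handle: IO[str]
    close = False
    if isinstance(reads, (str, Path)):
        handle = open(reads)
        close = True
    else:
        handle = reads
    try:
        n_short = 0
        for _title, seq, _qual in FastqGeneralIterator(handle):
            if len(seq) < end:
                n_short += 1
                unassigned += 1
                continue
            cid = lookup.get(seq[barcode_start:end])
            if cid is None:
                unassigned += 1
            else:
                counts[cid] += 1
        if n_short:
            logger.warning(
                "%d reads shorter than barcode window [%d, %d), counted as "
                "unassigned",
                n_short,
                barcode_start,
                end,
            )
    finally:
        if close:
            handle.close()
    series = pd.Series(counts, name="count").astype(int)
    series.index.name = "construct_id"
    return CountTable(lane_label, series), unassigned


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-format GMT file (name TAB description TAB member...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ScreenValidationError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            members = frozenset(m for m in fields[2:] if m)
            sets.append(GeneSet(fields[0], fields[1], members))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")
    return path


# Deterministic column orders for the two result tables.
GENE_CALL_COLUMNS = (
    "gene",
    "modules",
    "n_constructs_total",
    "n_constructs_passing",
    "n_depleted",
    "n_enriched",
    "vote_fraction_depleted",
    "vote_fraction_enriched",
    "call",
)
ENRICHMENT_COLUMNS = ("set", "k", "K", "n", "N", "p", "q", "kept", "candidate_members")


def write_results(
    gene_calls: pd.DataFrame,
    enrichment: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write ``gene_calls.tsv`` and (if given) ``enrichment.tsv``.

    Column order is fixed; rows are sorted (genes alphabetically; sets by
    q then p then name) so identical inputs produce byte-identical files.
    Floats are written with 12 significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gc = gene_calls.reindex(columns=list(GENE_CALL_COLUMNS)).sort_values("gene")
    p = out_dir / "gene_calls.tsv"
    gc.to_csv(p, sep="\t", index=False, float_format="%.12g")
    paths["gene_calls"] = p

    if enrichment is not None:
        en = enrichment.reindex(columns=list(ENRICHMENT_COLUMNS))
        en = en.sort_values(["q", "p", "set"], kind="mergesort")
        p = out_dir / "enrichment.tsv"
        en.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths["enrichment"] = p
    return paths
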