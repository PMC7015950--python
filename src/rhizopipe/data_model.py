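"""Domain tables and tab-separated I/O for the wheat microbiota pipeline.

The pipeline operates on four kinds of tables, all plain UTF-8
tab-separated text with ``#``-prefixed comment lines ignored:

* OTU count tables (OTU x sample integer counts), one per amplicon library;
* taxonomy tables mapping each OTU to a ranked lineage plus host-plant /
  organelle flags;
* sample metadata tables carrying the experimental design factors
  (fraction, genotype line, species, ancestry class, ploidy, D-genome
  class, replicate number);
* qPCR tables with per-sample 16S and 18S cycle thresholds and the
  fraction of 18S amplicons attributed to the host plant.

Every reader validates the invariants of its type and raises
:class:`FormatError` (malformed file) or :class:`ValidationError`
(well-formed file violating a domain invariant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("rhizopipe")

#: Amplicon libraries, in the order used throughout the study design.
LIBRARIES = ("prokaryote16S", "eukaryote18S", "fungalITS1", "oomyceteITS1")

#: Default per-library sequencing-depth standardization thresholds (reads).
DEPTH_THRESHOLDS = {
    "prokaryote16S": 10_000,
    "eukaryote18S": 5_000,
    "fungalITS1": 3_000,
    "oomyceteITS1": 2_000,
}

FRACTIONS = ("bulk", "rhizosphere", "root")
ANCESTRIES = ("modern", "wild", "synthetic")
D_GENOME_CLASSES = ("none", "wild", "artificial", "mixed")
#: ploidy 0 is reserved for unplanted bulk-soil controls
PLOIDIES = (0, 2, 4, 6)
BULK_GENOTYPE = "unplanted"

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

_PLANT_LINEAGE_MARKERS = {"viridiplantae", "streptophyta", "chloroplastida"}


class FormatError(ValueError):
    """A file could not be parsed as the expected table format."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer OTU x sample counts for one amplicon library.

    Parameters
    ----------
    counts:
        DataFrame indexed by OTU id with one column per sample; integer,
        non-negative.
    library:
        One of :data:`LIBRARIES`.
    empty_ok:
        Sample ids explicitly allowed to have an all-zero column (for
        example after host-read removal stripped every read).  Any other
        all-zero column is a validation error.
    """

    counts: pd.DataFrame
    library: str
    empty_ok: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.empty_ok = frozenset(self.empty_ok)
        validate_count_matrix(self)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        cols = [s for s in sample_ids]
        return CountMatrix(self.counts[cols].copy(), self.library,
                           self.empty_ok & set(cols))


def validate_count_matrix(cm: CountMatrix) -> None:
    if cm.library not in LIBRARIES:
        raise ValidationError(
            f"unknown library {cm.library!r}; allowed: {LIBRARIES}")
    _check_unique(cm.counts.index, "OTU id")
    _check_unique(cm.counts.columns, "sample id")
    vals = cm.counts.to_numpy()
    if cm.counts.shape[1] == 0:
        raise ValidationError("count matrix has no sample columns")
    if vals.size == 0:
        # all OTUs removed: columns remain, must all be flagged empty
        vals = np.zeros((1, cm.counts.shape[1]), dtype=np.int64)
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.all(np.isfinite(vals)) or np.any(vals != np.floor(vals)):
            raise ValidationError("counts must be finite integers")
        cm.counts = cm.counts.astype(np.int64)
        vals = cm.counts.to_numpy()
    if (vals < 0).any():
        raise ValidationError("counts must be non-negative")
    zero = cm.counts.columns[vals.sum(axis=0) == 0]
    bad = [s for s in zero if s not in cm.empty_ok]
    if bad:
        raise ValidationError(
            f"all-zero sample column(s) not flagged as empty: {bad}")


@dataclass
class TaxonomyTable:
    """Per-OTU ranked lineage plus host-plant / organelle flags.

    ``table`` is indexed by OTU id with the six rank columns of
    :data:`RANKS` (empty string = unassigned at that rank) and boolean
    ``is_host_plant`` / ``is_organelle`` columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "OTU id")
        missing = [c for c in (*RANKS, "is_host_plant", "is_organelle")
                   if c not in t.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing columns {missing}")
        for c in RANKS:
            t[c] = t[c].fillna("").astype(str)
        for c in ("is_host_plant", "is_organelle"):
            t[c] = _to_bool(t[c], c)
        both = t.index[t.is_host_plant & t.is_organelle]
        for otu in both:
            lineage = {str(t.loc[otu, c]).lower() for c in RANKS}
            if not (lineage & _PLANT_LINEAGE_MARKERS):
                raise ValidationError(
                    f"OTU {otu!r} flagged both host-plant and organelle "
                    "without a plant lineage")

    @property
    def otu_ids(self) -> list:
        return list(self.table.index)

    def flagged(self) -> pd.Index:
        """OTUs flagged as host plant or organelle."""
        t = self.table
        return t.index[t.is_host_plant | t.is_organelle]


@dataclass
class SampleFrame:
    """Per-sample experimental design factors.

    Index: sample id.  Columns: ``fraction`` (bulk/rhizosphere/root),
    ``genotype`` (line label, ``unplanted`` for bulk controls),
    ``species``, ``ancestry`` (modern/wild/synthetic), ``ploidy``
    (2/4/6; 0 for bulk), ``d_genome`` (none/wild/artificial/mixed) and
    ``replicate`` (positive integer).  Genotypes nest in species, which
    nest in ancestry classes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample id")
        required = ("fraction", "genotype", "species", "ancestry",
                    "ploidy", "d_genome", "replicate")
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"metadata missing columns {missing}")
        _check_levels(t["fraction"], FRACTIONS, "fraction")
        _check_levels(t["d_genome"], D_GENOME_CLASSES, "d_genome")
        t["ploidy"] = _to_int(t["ploidy"], "ploidy")
        t["replicate"] = _to_int(t["replicate"], "replicate")
        bad_ploidy = sorted(set(t["ploidy"]) - set(PLOIDIES))
        if bad_ploidy:
            raise ValidationError(
                f"unknown ploidy level(s) {bad_ploidy}; allowed: {PLOIDIES}")
        if (t["replicate"] < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        bulk = t["fraction"] == "bulk"
        if (t.loc[bulk, "genotype"] != BULK_GENOTYPE).any():
            raise ValidationError(
                f"bulk samples must have genotype {BULK_GENOTYPE!r}")
        planted = t["genotype"] != BULK_GENOTYPE
        _check_levels(t.loc[planted, "ancestry"], ANCESTRIES, "ancestry")
        # nesting: genotype -> one species -> one ancestry
        for child, parent in (("genotype", "species"),
                              ("species", "ancestry")):
            n = t.loc[planted].groupby(child)[parent].nunique()
            broken = n[n > 1]
            if len(broken):
                raise ValidationError(
                    f"{child} level(s) {list(broken.index)} map to more "
                    f"than one {parent} (nesting violated)")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    def planted(self) -> pd.DataFrame:
        return self.table[self.table["genotype"] != BULK_GENOTYPE]

    def samples_where(self, **levels) -> list:
        """Sample ids matching all given factor == level constraints."""
        mask = pd.Series(True, index=self.table.index)
        for factor, level in levels.items():
            mask &= self.table[factor] == level
        return list(self.table.index[mask])


@dataclass
class QpcrTable:
    """Per-sample qPCR cycle thresholds and host-plant 18S fraction.

    Index: sample id.  Columns: ``ct16``, ``ct18`` (cycles, finite, > 0)
    and ``plant_frac18`` (fraction of 18S amplicons of host-plant origin,
    in [0, 1]).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        _check_unique(t.index, "sample id")
        missing = [c for c in ("ct16", "ct18", "plant_frac18")
                   if c not in t.columns]
        if missing:
            raise ValidationError(f"qPCR table missing columns {missing}")
        for c in ("ct16", "ct18", "plant_frac18"):
            t[c] = pd.to_numeric(t[c], errors="raise").astype(float)
        for c in ("ct16", "ct18"):
            if not np.all(np.isfinite(t[c])) or (t[c] <= 0).any():
                raise ValidationError(f"{c} values must be finite and > 0")
        f = t["plant_frac18"]
        if not np.all(np.isfinite(f)) or (f < 0).any() or (f > 1).any():
            raise ValidationError("plant_frac18 must lie in [0, 1]")

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)


@dataclass
class RelAbundanceMatrix:
    """OTU x sample relative abundances in percent (columns sum to 100).

    Columns listed in ``empty_ok`` are allowed to sum to 0 (empty,
    flagged samples excluded from downstream distances).
    """

    values: pd.DataFrame
    library: str
    empty_ok: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.empty_ok = frozenset(self.empty_ok)
        if self.library not in LIBRARIES:
            raise ValidationError(
                f"unknown library {self.library!r}; allowed: {LIBRARIES}")
        _check_unique(self.values.index, "OTU id")
        _check_unique(self.values.columns, "sample id")
        v = self.values.to_numpy(dtype=float)
        if (v < 0).any():
            raise ValidationError("relative abundances must be >= 0")
        sums = v.sum(axis=0)
        for s, tot in zip(self.values.columns, sums):
            if s in self.empty_ok:
                if abs(tot) > 1e-9:
                    raise ValidationError(
                        f"flagged-empty sample {s!r} has non-zero total")
            elif abs(tot - 100.0) > 1e-9:
                raise ValidationError(
                    f"sample {s!r} sums to {tot!r}, expected 100")

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    # inspect the raw header: pandas silently mangles duplicate columns
    header = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
    if header is None:
        raise FormatError(f"{path}: empty file")
    dup = [h for h in set(header) if header.count(h) > 1]
    if dup:
        raise ValidationError(f"{path}: duplicated column id(s) {sorted(dup)}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         index_col=None)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[1] == 0 or df.shape[0] == 0 and index_col is not None:
        raise FormatError(f"{path}: no data rows")
    if index_col is not None:
        df = df.set_index(df.columns[index_col])
    return df


def read_count_table(path, library: str) -> CountMatrix:
    """Read an OTU x sample integer count table.

    First column holds OTU ids, header row holds sample ids.  Non-integer
    cells and duplicated ids are rejected.
    """
    df = _read_tsv(path)
    df.index.name = "otu_id"
    out = {}
    for col in df.columns:
        nums = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[nums.isna() | (nums != np.floor(nums.fillna(0)))]
        if len(bad):
            raise FormatError(
                f"{path}: non-integer cell at row {bad[0]!r}, "
                f"column {col!r}")
        out[col] = nums.astype(np.int64)
    counts = pd.DataFrame(out, index=df.index)
    if counts.index.duplicated().any():
        dups = sorted(set(counts.index[counts.index.duplicated()]))
        raise ValidationError(f"{path}: duplicated OTU id(s) {dups}")
    return CountMatrix(counts, library)


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    df.index.name = "otu_id"
    return TaxonomyTable(df)


def read_metadata(path) -> SampleFrame:
    df = _read_tsv(path)
    df.index.name = "sample_id"
    return SampleFrame(df)


def read_qpcr(path) -> QpcrTable:
    df = _read_tsv(path)
    df.index.name = "sample_id"
    try:
        return QpcrTable(df)
    except ValueError as e:
        if isinstance(e, (ValidationError, FormatError)):
            raise
        raise FormatError(f"{path}: {e}") from None


def read_rel_abundance(path, library: str) -> RelAbundanceMatrix:
    df = _read_tsv(path).astype(float)
    df.index.name = "otu_id"
    sums = df.sum(axis=0)
    empty = frozenset(df.columns[np.abs(sums) <= 1e-9])
    return RelAbundanceMatrix(df, library, empty)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.15g"  # round-trips to well below 1e-12 relative error


def _write_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label,
              float_format=_FLOAT_FMT)


def write_count_table(cm: CountMatrix, path) -> None:
    _write_tsv(cm.counts, path, "otu_id")


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    t = tax.table.copy()
    t["is_host_plant"] = t["is_host_plant"].astype(int)
    t["is_organelle"] = t["is_organelle"].astype(int)
    _write_tsv(t, path, "otu_id")


def write_metadata(meta: SampleFrame, path) -> None:
    _write_tsv(meta.table, path, "sample_id")


def write_qpcr(q: QpcrTable, path) -> None:
    _write_tsv(q.table, path, "sample_id")


def write_rel_abundance(rel: RelAbundanceMatrix, path) -> None:
    _write_tsv(rel.values, path, "otu_id")


def write_frame(df: pd.DataFrame, path, index_label=None) -> None:
    """Write a generic result table (PERMANOVA, core sets, tests...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, float_format=_FLOAT_FMT)


def write_ordination(coordinates: pd.DataFrame, eigenvalues, proportions,
                     path) -> None:
    """Write ordination coordinates with an eigenvalue comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# eigenvalues\t" +
                 "\t".join(_FLOAT_FMT % e for e in eigenvalues) + "\n")
        fh.write("# proportion_explained\t" +
                 "\t".join(_FLOAT_FMT % p for p in proportions) + "\n")
        coordinates.to_csv(fh, sep="\t", index_label="sample_id",
                           float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dups = sorted(set(index[index.duplicated()]))
        raise ValidationError(f"duplicated {what}(s): {dups}")


def _check_levels(series: pd.Series, allowed, name: str) -> None:
    bad = sorted(set(series.astype(str)) - set(allowed))
    if bad:
        raise ValidationError(
            f"unknown {name} level(s) {bad}; allowed: {tuple(allowed)}")


def _to_int(series: pd.Series, name: str) -> pd.Series:
    nums = pd.to_numeric(series, errors="coerce")
    if nums.isna().any() or (nums != np.floor(nums)).any():
        raise ValidationError(f"{name} must be an integer")
    return nums.astype(np.int64)


def _to_bool(series: pd.Series, name: str) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    out = []
    for v in series:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
            continue
        if isinstance(v, (int, np.integer, float)) and v in (0, 1):
            out.append(bool(v))
            continue
        key = str(v).strip().lower()
        if key not in mapping:
            raise ValidationError(f"{name}: cannot interpret {v!r} as bool")
        out.append(mapping[key])
    return pd.Series(out, index=series.index)
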