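"""Tabular containers and readers/writers for germplasm fingerprinting studies.

The study design this package supports fingerprints a national collection of
clonally propagated landraces with SNP markers.  Three tables drive every
downstream analysis:

* an allele-dosage matrix (samples x loci, values 0/1/2 or missing),
* a square pairwise genetic-distance matrix, and
* per-sample metadata (collector number, administrative zone, whether the
  sample is a collected landrace or a reference, and replicate structure).

Collector numbers encode the collection zone through their alphabetic prefix
and numeric range (e.g. ``KS43``-``KS64`` were collected in the Northern
zone); :func:`assign_zones_by_prefix` resolves them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ZONES = (
    "Central",
    "Coastal",
    "Lake",
    "Northern",
    "SouthernHighlands",
    "Western",
    "Zanzibar",
)

CATEGORIES = ("collected", "reference_landrace", "reference_breeding")
REPLICATE_TYPES = ("biological", "technical")

#: Missing-value spellings accepted on input; "NA" is written on output.
MISSING_CODES = ("", "NA", "-9")

#: Ordinal 0-5 trait-score columns of a key-informant survey table.
SURVEY_SCORE_COLUMNS = (
    "storability",
    "maturity",
    "drought",
    "pest_disease",
    "cooking_quality",
    "taste",
    "processing_quality",
    "market_demand",
    "yield",
)

_DIALECTS = ("samples_as_rows", "samples_as_cols")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValidationError(f"duplicate {what} ids: {sorted(set(dups))}")


@dataclass
class GenotypeMatrix:
    """Samples x loci allele dosages with missing data as NaN.

    ``dosage[i, j]`` is the count of alternate alleles (0, 1 or 2) carried by
    sample ``sample_ids[i]`` at locus ``locus_ids[j]``, or NaN when no call
    was made.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(s) for s in self.locus_ids]
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be a 2-D array")
        if self.dosage.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.locus_ids, "locus")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"dosage values must be in {{0, 1, 2}}; found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def sample_missing_fraction(self) -> pd.Series:
        return pd.Series(
            self.missing_mask.mean(axis=1), index=self.sample_ids, name="missing_fraction"
        )

    def locus_missing_fraction(self) -> pd.Series:
        return pd.Series(
            self.missing_mask.mean(axis=0), index=self.locus_ids, name="missing_fraction"
        )

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        srows = self.sample_ids if samples is None else list(samples)
        scols = self.locus_ids if loci is None else list(loci)
        ridx = [self.sample_ids.index(s) for s in srows]
        cidx = [self.locus_ids.index(l) for l in scols]
        return GenotypeMatrix(srows, scols, self.dosage[np.ix_(ridx, cidx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.locus_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64))

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal.

    Entries may be NaN when a distance is undefined (for genetic distances:
    a sample pair with no jointly called locus).  ``bounded`` marks matrices
    of allele-sharing proportions, which must lie in [0, 1]; unbounded
    matrices (e.g. Nei's standard distance between populations) skip the
    upper check.
    """

    ids: list[str]
    values: np.ndarray
    bounded: bool = True

    _ATOL = 1e-8

    def __post_init__(self) -> None:
        self.ids = [str(s) for s in self.ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        _check_unique(self.ids, "distance-matrix")
        nan = np.isnan(self.values)
        if (nan != nan.T).any():
            raise ValidationError("undefined (NaN) entries are not symmetric")
        both = ~nan & ~nan.T
        if both.any():
            asym = np.abs(self.values - self.values.T)[both].max()
            if asym > self._ATOL:
                i, j = np.unravel_index(
                    np.nanargmax(np.where(both, np.abs(self.values - self.values.T), -1)),
                    self.values.shape,
                )
                raise ValidationError(
                    f"asymmetry {asym:.3g} between {self.ids[i]} and {self.ids[j]} "
                    f"exceeds tolerance {self._ATOL}"
                )
        diag = np.diag(self.values)
        if np.isnan(diag).any() or (np.abs(diag) > self._ATOL).any():
            raise ValidationError("diagonal must be zero")
        lo = np.nanmin(self.values) if (~nan).any() else 0.0
        if lo < -self._ATOL:
            raise ValidationError(f"negative distance {lo}")
        if self.bounded:
            hi = np.nanmax(self.values) if (~nan).any() else 0.0
            if hi > 1.0 + self._ATOL:
                raise ValidationError(f"distance {hi} exceeds 1 for a bounded matrix")
        # canonicalize: exact symmetry, exact zero diagonal
        v = self.values.copy()
        v[~nan] = ((self.values + self.values.T) / 2.0)[~nan]
        np.fill_diagonal(v, 0.0)
        if self.bounded:
            np.clip(v, 0.0, 1.0, out=v)
        else:
            np.clip(v, 0.0, None, out=v)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, sample_id: str) -> int:
        try:
            return self.ids.index(sample_id)
        except ValueError:
            raise KeyError(sample_id) from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(s) for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], bounded=self.bounded)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        nan = np.isnan(self.values)
        for i, j in zip(*np.where(np.triu(nan, k=1))):
            out.append((self.ids[i], self.ids[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def equals(self, other: "DistanceMatrix", atol: float = 0.0) -> bool:
        return self.ids == other.ids and np.allclose(
            self.values, other.values, atol=atol, rtol=0.0, equal_nan=True
        )


# ---------------------------------------------------------------------------
# dosage matrix IO
# ---------------------------------------------------------------------------


def _read_labelled_grid(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a CSV with one header row and one id column, keeping raw strings."""
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise FormatError(f"{path}: need at least one id row and one id column")
    row_ids = [str(x).strip() for x in raw.iloc[1:, 0]]
    col_ids = [str(x).strip() for x in raw.iloc[0, 1:]]
    cells = raw.iloc[1:, 1:].to_numpy(dtype=str)
    cells = np.char.strip(cells)
    return row_ids, col_ids, cells


def read_dosage_matrix(
    path: str | Path,
    dialect: str = "samples_as_rows",
    missing_codes: Sequence[str] = MISSING_CODES,
) -> GenotypeMatrix:
    """Read an allele-dosage CSV into a :class:`GenotypeMatrix`.

    ``dialect`` states explicitly whether samples are rows or columns; the
    orientation is never guessed, because a silently transposed matrix is a
    classic corruption.  Cells equal to any of ``missing_codes`` become NaN.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    row_ids, col_ids, cells = _read_labelled_grid(path)
    miss = np.isin(cells, list(missing_codes))
    vals = np.full(cells.shape, np.nan)
    flat = pd.to_numeric(pd.Series(cells[~miss].ravel()), errors="coerce").to_numpy()
    bad = np.isnan(flat) | ~np.isin(flat, (0.0, 1.0, 2.0))
    if bad.any():
        pos = np.argwhere(~miss)[np.flatnonzero(bad)[0]]
        i, j = int(pos[0]), int(pos[1])
        if dialect == "samples_as_rows":
            sample, locus = row_ids[i], col_ids[j]
        else:
            sample, locus = col_ids[j], row_ids[i]
        raise FormatError(
            f"{path}: cell for sample {sample!r}, locus {locus!r} is "
            f"{cells[i, j]!r}; expected 0, 1, 2 or a missing code"
        )
    vals[~miss] = flat
    if dialect == "samples_as_cols":
        vals = vals.T
        row_ids, col_ids = col_ids, row_ids
    return GenotypeMatrix(row_ids, col_ids, vals)


def write_dosage_matrix(
    G: GenotypeMatrix,
    path: str | Path,
    dialect: str = "samples_as_rows",
    missing_code: str = "NA",
) -> None:
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    nan = np.isnan(G.dosage)
    arr = np.where(nan, 0, G.dosage).astype(int).astype(str).astype(object)
    arr[nan] = missing_code
    df = pd.DataFrame(arr, index=G.sample_ids, columns=G.locus_ids)
    if dialect == "samples_as_cols":
        df = df.T
    df.to_csv(path)


# ---------------------------------------------------------------------------
# distance matrix IO
# ---------------------------------------------------------------------------


def read_distance_matrix(path: str | Path, bounded: bool = True) -> DistanceMatrix:
    """Read a square distance CSV (identical id order on rows and columns)."""
    row_ids, col_ids, cells = _read_labelled_grid(path)
    if len(row_ids) != len(col_ids) or row_ids != col_ids:
        raise FormatError(f"{path}: matrix is not square with matching row/column ids")
    miss = np.isin(cells, list(MISSING_CODES))
    vals = pd.to_numeric(pd.Series(cells.ravel()), errors="coerce").to_numpy()
    vals = vals.reshape(cells.shape)
    bad = np.isnan(vals) & ~miss
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(f"{path}: non-numeric cell {cells[i, j]!r} at ({row_ids[i]}, {col_ids[j]})")
    return DistanceMatrix(row_ids, vals, bounded=bounded)


def write_distance_matrix(D: DistanceMatrix, path: str | Path, decimals: int = 6) -> None:
    D.to_frame().to_csv(path, float_format=f"%.{decimals}f", na_rep="NA")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample identity, zone, category and replicate structure.

    The underlying table is indexed by sample id with columns ``given_name``
    (the farmer's name for the landrace; not unique), ``zone``, ``category``,
    ``replicate_group`` and ``replicate_type``.
    """

    table: pd.DataFrame

    COLUMNS = ("given_name", "zone", "category", "replicate_group", "replicate_type")

    def __post_init__(self) -> None:
        t = self.table.copy()
        for c in self.COLUMNS:
            if c not in t.columns:
                t[c] = np.nan
        t = t[list(self.COLUMNS)].astype(object)
        t = t.where(t.notna(), np.nan)  # normalize None/NA spellings to NaN
        t.index = t.index.astype(str)
        t.index.name = "sample_id"
        _check_unique(list(t.index), "sample")
        bad_cat = ~t["category"].isin(CATEGORIES)
        if bad_cat.any():
            raise ValidationError(
                f"unknown category for samples {list(t.index[bad_cat])[:5]}; "
                f"expected one of {CATEGORIES}"
            )
        has_zone = t["zone"].notna()
        bad_zone = has_zone & ~t["zone"].isin(ZONES)
        if bad_zone.any():
            raise ValidationError(f"unknown zone values {sorted(t.loc[bad_zone, 'zone'].unique())}")
        collected = t["category"] == "collected"
        if (collected & ~has_zone).any():
            missing = list(t.index[collected & ~has_zone])[:5]
            raise ValidationError(f"collected samples without a zone: {missing}")
        has_grp = t["replicate_group"].notna()
        has_typ = t["replicate_type"].notna()
        if (has_grp != has_typ).any():
            raise ValidationError("replicate_type must be present iff replicate_group is")
        bad_typ = has_typ & ~t["replicate_type"].isin(REPLICATE_TYPES)
        if bad_typ.any():
            raise ValidationError(f"replicate_type must be one of {REPLICATE_TYPES}")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def ids_by_category(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    @property
    def collected_ids(self) -> list[str]:
        return self.ids_by_category("collected")

    def zone_of(self, sample_ids: Iterable[str] | None = None) -> pd.Series:
        z = self.table["zone"]
        return z if sample_ids is None else z.loc[list(sample_ids)]

    def replicate_groups(self) -> dict[str, dict]:
        """Map replicate_group id -> {"type": ..., "members": [ids]}."""
        out: dict[str, dict] = {}
        sub = self.table[self.table["replicate_group"].notna()]
        for grp, rows in sub.groupby("replicate_group"):
            types = rows["replicate_type"].unique()
            out[str(grp)] = {"type": str(types[0]), "members": list(rows.index)}
        return out

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)])


def read_metadata(path: str | Path) -> SampleMetadata:
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in t.columns:
        raise FormatError(f"{path}: metadata TSV needs a sample_id column")
    t = t.set_index("sample_id")
    t = t.where(t != "", np.nan)
    return SampleMetadata(t)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# collector-number prefix -> zone mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrefixRule:
    """One collector-number rule: a prefix, an optional numeric range, a zone."""

    prefix: str
    zone: str
    lo: int | None = None
    hi: int | None = None

    def matches(self, prefix: str, number: int | None) -> bool:
        if prefix.casefold() != self.prefix.casefold():
            return False
        if self.lo is None:
            return True
        return number is not None and self.lo <= number <= self.hi


#: The field scheme of the Tanzanian collection missions.
DEFAULT_PREFIX_MAP: tuple[PrefixRule, ...] = (
    PrefixRule("KS", "Coastal", 1, 42),
    PrefixRule("KS", "Northern", 43, 64),
    PrefixRule("KS", "Coastal", 65, 75),
    PrefixRule("KSF", "Lake", 1, 62),
    PrefixRule("KSF", "Western", 63, 92),
    PrefixRule("KSF", "Central", 93, 103),
    PrefixRule("EPM", "Central"),
    PrefixRule("BKP", "SouthernHighlands"),
    PrefixRule("Horti", "Northern"),
    PrefixRule("SMS", "Zanzibar"),
)

_ID_RE = re.compile(r"^(.*?)[ _\-]*(\d+)$")


def split_collector_id(sample_id: str) -> tuple[str, int | None]:
    """Split a collector number into prefix and numeric suffix.

    The numeric suffix is the longest trailing digit run, so zero-padded and
    unpadded forms compare equal (``KS05`` == ``KS5``); separators between
    prefix and number are ignored (``Horti_35``).
    """
    m = _ID_RE.match(sample_id.strip())
    if m is None:
        return sample_id.strip(), None
    return m.group(1), int(m.group(2))


def assign_zones_by_prefix(
    sample_ids: Iterable[str],
    prefix_map: Sequence[PrefixRule] = DEFAULT_PREFIX_MAP,
) -> pd.Series:
    """Assign each collector number to a zone via the prefix map.

    Returns a Series of zone names indexed by sample id.  Raises
    :class:`ValidationError` listing any id no rule matches.
    """
    ids = [str(s) for s in sample_ids]
    zones: list[str] = []
    unassigned: list[str] = []
    for s in ids:
        prefix, number = split_collector_id(s)
        for rule in prefix_map:
            if rule.matches(prefix, number):
                zones.append(rule.zone)
                break
        else:
            unassigned.append(s)
            zones.append("")
    if unassigned:
        raise ValidationError(f"no prefix rule matches sample ids: {unassigned[:10]}")
    return pd.Series(zones, index=ids, name="zone")


# ---------------------------------------------------------------------------
# survey table
# ---------------------------------------------------------------------------


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a key-informant survey TSV.

    Trait-score columns are coerced to numeric; a score of 0 encodes
    "don't know" and is preserved as 0 (policy decisions about it belong to
    the analysis functions, not the reader).
    """
    t = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).replace("", np.nan)
    for c in t.columns:
        if c in SURVEY_SCORE_COLUMNS or c in ("age", "land_acres", "years_growing"):
            t[c] = pd.to_numeric(t[c], errors="raise")
    for c in SURVEY_SCORE_COLUMNS:
        if c in t.columns:
            vals = t[c].dropna()
            if not vals.isin(range(6)).all():
                raise ValidationError(f"survey column {c} has scores outside 0-5")
    return t


def write_survey(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")
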