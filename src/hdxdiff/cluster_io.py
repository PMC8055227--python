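"""Reading, validation and writing of DynamX-dialect cluster CSV files.

A cluster file holds one row per replicate-level centroid measurement with
the hierarchy protein > state > peptide > exposure (timepoint) > charge
state > technical replicate (raw file).  The in-memory container is a
:class:`Dataset`: a pandas DataFrame with canonical lower-case column names
plus parse warnings collected during import.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# canonical internal column -> DynamX export header
CANONICAL_HEADERS = {
    "protein": "Protein",
    "start": "Start",
    "end": "End",
    "sequence": "Sequence",
    "modification": "Modification",
    "fragment": "Fragment",
    "max_uptake": "MaxUptake",
    "mhp": "MHP",
    "state": "State",
    "exposure": "Exposure",
    "raw_file": "File",
    "charge": "z",
    "retention_time": "RT",
    "intensity": "Inten",
    "center": "Center",
}

#: built-in header synonyms (all matching is case-insensitive)
DEFAULT_SYNONYMS = {
    "charge": "charge",
    "file": "raw_file",
    "raw file": "raw_file",
    "rawfile": "raw_file",
    "intensity": "intensity",
    "center": "center",
    "centroid": "center",
    "retention time": "retention_time",
    "rt (min)": "retention_time",
    "max uptake": "max_uptake",
    "maxuptake": "max_uptake",
    "exposure (min)": "exposure",
}

MANDATORY = [
    "protein", "start", "end", "sequence", "state",
    "exposure", "raw_file", "charge", "intensity", "center",
]
OPTIONAL_DEFAULTS = {
    "modification": "",
    "fragment": "",
    "max_uptake": np.nan,
    "mhp": np.nan,
    "retention_time": np.nan,
}

NUMERIC_COLS = ["start", "end", "max_uptake", "mhp", "exposure",
                "charge", "retention_time", "intensity", "center"]

#: columns identifying one replicate-level measurement
RECORD_KEY = ["protein", "state", "start", "end", "sequence", "modification",
              "exposure", "charge", "raw_file"]

#: columns identifying one peptide
PEPTIDE_KEY = ["start", "end", "sequence", "modification"]


class ClusterFileError(ValueError):
    """Fatal problem with a cluster file (missing columns, corrupt rows)."""


def exchangeable_amides(sequence: str) -> int:
    """Number of exchangeable backbone amides of a peptide.

    The N-terminal amide back-exchanges too fast to measure and proline has
    no amide hydrogen, so the count is ``len(sequence) - 1`` minus prolines
    at positions 2..end.
    """
    return len(sequence) - 1 - sequence[1:].count("P")


@dataclass
class Dataset:
    """A parsed cluster file: canonical records plus import diagnostics."""

    records: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.records["protein"].unique())

    @property
    def states(self) -> list[str]:
        return sorted(self.records["state"].unique())

    @property
    def exposures(self) -> list[float]:
        return sorted(self.records["exposure"].unique())

    def __len__(self) -> int:
        return len(self.records)

    def select(self, protein: str, states: list[str] | None = None) -> "Dataset":
        """Subset to one protein and (optionally) a list of states.

        Record order is preserved.  Unknown labels raise with the list of
        available ones.
        """
        if protein not in set(self.records["protein"]):
            raise ClusterFileError(
                f"unknown protein {protein!r}; available: {self.proteins}")
        mask = self.records["protein"] == protein
        if states is not None:
            known = set(self.records.loc[mask, "state"])
            missing = [s for s in states if s not in known]
            if missing:
                raise ClusterFileError(
                    f"unknown state(s) {missing}; available: {sorted(known)}")
            mask &= self.records["state"].isin(states)
        return Dataset(self.records.loc[mask].reset_index(drop=True),
                       list(self.warnings))

    def canonical_sort(self) -> "Dataset":
        """Deterministic row order; parsing becomes order-independent."""
        cols = ["protein", "state", "start", "end", "sequence",
                "modification", "exposure", "charge", "raw_file"]
        out = self.records.sort_values(cols, kind="mergesort").reset_index(drop=True)
        return Dataset(out, list(self.warnings))

    def equals(self, other: "Dataset", sig_digits: int = 6) -> bool:
        """Field-for-field equality after canonical sorting.

        Numeric fields are compared to ``sig_digits`` significant digits.
        """
        a = self.canonical_sort().records
        b = other.canonical_sort().records
        if len(a) != len(b):
            return False
        for col in CANONICAL_HEADERS:
            if col == "fragment":
                continue
            if col in NUMERIC_COLS:
                x = a[col].to_numpy(dtype=float)
                y = b[col].to_numpy(dtype=float)
                both_nan = np.isnan(x) & np.isnan(y)
                close = np.isclose(x, y, rtol=10.0 ** (-sig_digits + 1), atol=0.0,
                                   equal_nan=True)
                if not np.all(close | both_nan):
                    return False
            else:
                if not (a[col].fillna("").astype(str)
                        == b[col].fillna("").astype(str)).all():
                    return False
        return True


def _resolve_headers(columns: list[str], synonyms: dict[str, str] | None):
    """Map file headers to canonical names, case-insensitively."""
    lookup = {v.lower(): k for k, v in CANONICAL_HEADERS.items()}
    lookup.update({k.lower(): v for k, v in DEFAULT_SYNONYMS.items()})
    if synonyms:
        lookup.update({k.lower(): v for k, v in synonyms.items()})
    mapping = {}
    for col in columns:
        canon = lookup.get(str(col).strip().lower())
        if canon is not None and canon not in mapping.values():
            mapping[col] = canon
    return mapping


def read_cluster_csv(path, synonyms: dict[str, str] | None = None) -> Dataset:
    """Parse a DynamX cluster CSV into a :class:`Dataset`.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.  Header matching is case-insensitive
        and extensible via `synonyms` (header text -> canonical name).
    synonyms : dict, optional
        Extra header synonyms merged over the built-in map.

    Raises
    ------
    ClusterFileError
        Empty file, missing mandatory column, rows with unparseable
        numbers, or conflicting duplicate rows.

    Notes
    -----
    Exposure is in minutes (DynamX convention; no unit auto-detection).
    Peptide groups lacking an exposure-0 reference are recorded as warnings
    on the Dataset, not rejected.  Missing MaxUptake values are filled from
    the sequence (exchangeable-amide count) with a warning.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ClusterFileError(f"empty cluster file: {path}") from None
    if raw.empty:
        raise ClusterFileError(f"cluster file has a header but no rows: {path}")

    mapping = _resolve_headers(list(raw.columns), synonyms)
    df = raw.rename(columns=mapping)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        names = [CANONICAL_HEADERS[c] for c in missing]
        raise ClusterFileError(f"missing mandatory column(s): {names}")
    for col, default in OPTIONAL_DEFAULTS.items():
        if col not in df.columns:
            df[col] = default
    df = df[list(CANONICAL_HEADERS)]

    warnings: list[str] = []
    bad_rows = np.zeros(len(df), dtype=bool)
    for col in NUMERIC_COLS:
        converted = pd.to_numeric(df[col], errors="coerce")
        optional = col in OPTIONAL_DEFAULTS
        blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
        bad = converted.isna() & ~blank if optional else converted.isna()
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad]]  # 1-based incl. header
            warnings.append(
                f"rejected {bad.sum()} row(s) with unparseable {col!r} "
                f"(file rows {rows[:10]}{'...' if len(rows) > 10 else ''})")
            bad_rows |= bad.to_numpy()
        df[col] = converted
    df = df.loc[~bad_rows].reset_index(drop=True)
    if df.empty:
        raise ClusterFileError("no parseable rows in cluster file")

    for col in ("modification", "fragment"):
        df[col] = df[col].fillna("").astype(str)
    for col in ("protein", "state", "sequence", "raw_file"):
        df[col] = df[col].astype(str)
    for col in ("start", "end", "charge"):
        df[col] = df[col].astype(int)

    _validate_records(df)

    miss_mu = df["max_uptake"].isna()
    if miss_mu.any():
        df.loc[miss_mu, "max_uptake"] = [
            exchangeable_amides(s) for s in df.loc[miss_mu, "sequence"]]
        warnings.append(
            f"filled MaxUptake from sequence for {int(miss_mu.sum())} row(s)")
    df["max_uptake"] = df["max_uptake"].astype(float)

    # duplicates: identical key+values dropped, conflicting values fatal
    dup_key = df.duplicated(subset=RECORD_KEY, keep=False)
    if dup_key.any():
        full_dup = df.duplicated(keep="first")
        conflict = dup_key & ~df.duplicated(subset=None, keep=False)
        if conflict.any():
            raise ClusterFileError(
                "conflicting duplicate rows (same key, different values) at "
                f"file rows {[int(i) + 2 for i in df.index[conflict]][:10]}")
        if full_dup.any():
            warnings.append(f"dropped {int(full_dup.sum())} duplicate row(s)")
            df = df.loc[~full_dup].reset_index(drop=True)

    # exposure-0 reference check per (protein, state, peptide)
    has_ref = df.groupby(["protein", "state"] + PEPTIDE_KEY)["exposure"].transform("min") == 0
    if (~has_ref).any():
        groups = (df.loc[~has_ref, ["protein", "state", "sequence"]]
                  .drop_duplicates().itertuples(index=False))
        for g in groups:
            warnings.append(
                f"no exposure-0 reference for {g.protein}/{g.state}/{g.sequence}")

    for w in warnings:
        log.warning("%s", w)
    return Dataset(df.reset_index(drop=True), warnings)


def _validate_records(df: pd.DataFrame) -> None:
    seq_len = df["sequence"].str.len()
    checks = {
        "start must satisfy 1 <= start <= end": (df["start"] >= 1) & (df["start"] <= df["end"]),
        "sequence length must equal end - start + 1": seq_len == df["end"] - df["start"] + 1,
        "charge must be >= 1": df["charge"] >= 1,
        "intensity must be >= 0": df["intensity"] >= 0,
        "exposure must be >= 0": df["exposure"] >= 0,
        "center must be > 0": df["center"] > 0,
        "max_uptake must be <= len(sequence) - 1":
            df["max_uptake"].isna() | (df["max_uptake"] <= seq_len - 1),
    }
    for msg, ok in checks.items():
        if not ok.all():
            rows = [int(i) + 2 for i in df.index[~ok]]
            raise ClusterFileError(f"{msg} (file rows {rows[:10]})")


def write_cluster_csv(dataset: Dataset, path) -> None:
    """Write a Dataset back to DynamX-dialect CSV (canonical column order).

    Floats are written with 9 significant digits so a read/write round trip
    is the identity to well past the 6-significant-digit contract.
    """
    if len(dataset) == 0:
        raise ClusterFileError("refusing to write an empty dataset")
    out = dataset.records[list(CANONICAL_HEADERS)].copy()
    for col in ("max_uptake", "mhp", "exposure", "retention_time",
                "intensity", "center"):
        out[col] = out[col].map(
            lambda v: "" if pd.isna(v) else f"{float(v):.9g}")
    out.columns = [CANONICAL_HEADERS[c] for c in out.columns]
    out.to_csv(path, index=False)
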