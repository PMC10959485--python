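"""Trial-table data model, CSV I/O, validation, and exclusion rules.

A common-garden trial is represented by two tidy CSV files:

``seedlings.csv``
    one row per observation unit (seedling), carrying design factors
    (family, population, optional subpopulation, block, trial year), the
    greenhouse traits (budset timing in days, first-year height in mm,
    ordinal fall frost injury 0-4), and the field survival/height history.

``families.csv``
    one row per open-pollinated family: population of origin, latitude /
    longitude of the mother tree, optional mother age, and the weight of a
    200-seed sample from the seedlot (unit-agnostic; selection analyses
    standardize by SD).

Missing values are encoded as empty cells; the string ``NA`` is also
accepted.  Heights are never unit-converted by the loader: greenhouse
heights are mm, field heights are m, as declared by the schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clinesel.errors import DataError, IntegrityError, SchemaError

log = logging.getLogger(__name__)

NA_STRINGS = ["", "NA"]

#: canonical seedling columns -> (pandas dtype, required)
SEEDLING_COLUMNS: dict[str, tuple[str, bool]] = {
    "seedling_id": ("string", True),
    "family_id": ("string", True),
    "population": ("string", True),
    "subpopulation": ("string", False),
    "block": ("string", True),
    "trial_year": ("Int64", False),
    "bst_days": ("Float64", False),
    "no_budset": ("boolean", False),
    "fyh_mm": ("Float64", False),
    "ffi_score": ("Int64", False),
    "alive_2010": ("Int64", False),
    "alive_2011": ("Int64", False),
    "alive_2017": ("Int64", False),
    "height9_m": ("Float64", False),
    "greenhouse_dead": ("boolean", False),
    "unhealthy": ("boolean", False),
    "unidentified": ("boolean", False),
}

FAMILY_COLUMNS: dict[str, tuple[str, bool]] = {
    "family_id": ("string", True),
    "population": ("string", True),
    "latitude": ("Float64", False),
    "longitude": ("Float64", False),
    "mother_age_years": ("Int64", False),
    "seed_weight": ("Float64", False),
}

#: (column, predicate on non-missing values) range rules; violations mark the
#: record excluded with reason "range" rather than being silently dropped.
_RANGE_RULES = [
    ("ffi_score", lambda s: (s >= 0) & (s <= 4)),
    ("alive_2010", lambda s: s.isin([0, 1])),
    ("alive_2011", lambda s: s.isin([0, 1])),
    ("alive_2017", lambda s: s.isin([0, 1])),
    ("bst_days", lambda s: s > 0),
    ("fyh_mm", lambda s: s >= 0),
    ("height9_m", lambda s: s >= 0),
]


@dataclass
class TrialTable:
    """Validated seedling records plus family metadata.

    ``records`` carries an ``excluded`` boolean and an ``exclusion_reason``
    string column; analysis code operates on ``table.active()``.
    """

    records: pd.DataFrame
    meta: pd.DataFrame
    provenance: str = ""

    def active(self) -> pd.DataFrame:
        """Records not flagged as excluded."""
        return self.records.loc[~self.records["excluded"].fillna(False).astype(bool)]

    def copy(self) -> "TrialTable":
        return TrialTable(self.records.copy(), self.meta.copy(), self.provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.records.reset_index(drop=True),
                other.records.reset_index(drop=True),
            )
            pd.testing.assert_frame_equal(
                self.meta.reset_index(drop=True), other.meta.reset_index(drop=True)
            )
        except AssertionError:
            return False
        return True


@dataclass(frozen=True)
class ExclusionRules:
    """Which record classes to drop and how to treat missing field trees.

    The defaults mirror standard trial practice: seedlings dead or unhealthy
    before the greenhouse assessment and unidentifiable field trees are
    dropped, and a tree missing at the final census is scored as dead.
    """

    drop_greenhouse_dead: bool = True
    drop_unhealthy: bool = True
    drop_unidentified: bool = True
    missing_scored_dead: bool = True


def _coerce(df: pd.DataFrame, spec: dict[str, tuple[str, bool]], what: str) -> tuple[pd.DataFrame, int]:
    """Coerce columns to their declared dtypes; unparseable cells -> missing."""
    bad = 0
    out = pd.DataFrame(index=df.index)
    for col, (dtype, required) in spec.items():
        if col not in df.columns:
            if required:
                raise SchemaError(f"{what}: required column {col!r} is missing")
            out[col] = pd.Series(pd.NA, index=df.index, dtype=dtype)
            continue
        raw = df[col]
        if dtype == "string":
            out[col] = raw.astype("string")
        elif dtype == "boolean":
            lowered = raw.astype("string").str.lower()
            mapped = lowered.map({"true": True, "1": True, "false": False, "0": False})
            out[col] = mapped.astype("boolean")
        else:
            # Python float() is correctly rounded (pandas' fast parser is not),
            # keeping the text round-trip exact
            def _parse(v):
                try:
                    return float(v)
                except (TypeError, ValueError):
                    return np.nan
            coerced = raw.map(_parse, na_action="ignore").astype("float64")
            bad += int((coerced.isna() & raw.notna()).sum())
            if dtype == "Int64":
                # non-integral numerics are unparseable for an integer field
                frac = coerced.dropna() % 1 != 0
                if frac.any():
                    bad += int(frac.sum())
                    coerced.loc[frac.index[frac]] = np.nan
            out[col] = coerced.astype(dtype)
    return out, bad


def _apply_range_rules(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    if "excluded" not in records.columns:
        records["excluded"] = False
        records["exclusion_reason"] = pd.Series("", index=records.index, dtype="string")
    for col, ok in _RANGE_RULES:
        vals = records[col]
        present = vals.notna()
        viol = present & ~ok(vals).fillna(False)
        if viol.any():
            records.loc[viol, "excluded"] = True
            records.loc[viol, "exclusion_reason"] = "range"
    return records


def read_trial_table(path: str | Path, schema: dict | None = None) -> TrialTable:
    """Read ``seedlings.csv`` and ``families.csv`` from a directory.

    Parameters
    ----------
    path : directory containing the two CSV files.
    schema : optional mapping with keys ``seedlings`` / ``families``, each a
        ``{source column -> canonical column}`` rename map for files whose
        headers differ from the canonical names.

    Raises
    ------
    SchemaError : a required column cannot be resolved.
    IntegrityError : duplicate record keys or family rows, or a record whose
        family_id does not resolve in the family table.
    """
    path = Path(path)
    seedlings_csv = path / "seedlings.csv"
    families_csv = path / "families.csv"
    if not seedlings_csv.exists() or not families_csv.exists():
        raise DataError(f"expected seedlings.csv and families.csv under {path}")
    raw_rec = pd.read_csv(seedlings_csv, dtype=str, keep_default_na=False,
                          na_values=NA_STRINGS)
    raw_meta = pd.read_csv(families_csv, dtype=str, keep_default_na=False,
                           na_values=NA_STRINGS)
    schema = schema or {}
    if "seedlings" in schema:
        raw_rec = raw_rec.rename(columns=schema["seedlings"])
    if "families" in schema:
        raw_meta = raw_meta.rename(columns=schema["families"])

    records, bad_r = _coerce(raw_rec, SEEDLING_COLUMNS, "seedlings.csv")
    meta, bad_m = _coerce(raw_meta, FAMILY_COLUMNS, "families.csv")
    if bad_r or bad_m:
        log.warning("read_trial_table: %d unparseable cells set to missing",
                    bad_r + bad_m)

    key = ["family_id", "block", "trial_year", "seedling_id"]
    dup = records.duplicated(subset=key)
    if dup.any():
        raise IntegrityError(
            f"{int(dup.sum())} duplicate (family_id, block, trial_year, seedling_id) keys"
        )
    if meta["family_id"].duplicated().any():
        raise IntegrityError("duplicate family_id rows in families.csv")
    unresolved = ~records["family_id"].isin(meta["family_id"])
    if unresolved.any():
        raise IntegrityError(
            f"{int(unresolved.sum())} records reference unknown family_id"
        )
    records = _apply_range_rules(records)
    return TrialTable(records=records, meta=meta, provenance=str(path))


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    """Write ``seedlings.csv`` / ``families.csv`` (RFC 4180, UTF-8, header)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec = table.records.drop(columns=["excluded", "exclusion_reason"], errors="ignore")
    # plain float64 + 17 significant digits so floats survive the text round-trip
    rec = rec.copy()
    meta = table.meta.copy()
    for df in (rec, meta):
        for col in df.columns:
            if str(df[col].dtype) == "Float64":
                df[col] = df[col].astype("float64")
    rec.to_csv(path / "seedlings.csv", index=False, float_format="%.17g")
    meta.to_csv(path / "families.csv", index=False, float_format="%.17g")


@dataclass
class ExclusionResult:
    table: TrialTable
    counts: dict[str, int] = field(default_factory=dict)


def apply_exclusions(table: TrialTable, rules: ExclusionRules | None = None) -> ExclusionResult:
    """Apply record-drop rules and the missing-tree = dead convention.

    Dropping removes records entirely (they carried no usable trait data);
    the missing-tree rule rewrites ``alive_2017`` to 0 so downstream
    survival summaries and dead-inclusive height fitness see the tree as
    dead with height 0.  Idempotent: re-applying the same rules is a no-op.
    """
    rules = rules or ExclusionRules()
    rec = table.records.copy()
    counts: dict[str, int] = {}
    for flag, rule_on, reason in [
        ("greenhouse_dead", rules.drop_greenhouse_dead, "greenhouse-dead"),
        ("unhealthy", rules.drop_unhealthy, "unhealthy"),
        ("unidentified", rules.drop_unidentified, "unidentified"),
    ]:
        if not rule_on or flag not in rec.columns:
            continue
        mask = rec[flag].fillna(False).astype(bool)
        if mask.any():
            counts[reason] = int(mask.sum())
            rec = rec.loc[~mask]
    if rules.missing_scored_dead:
        missing = rec["alive_2017"].isna()
        if missing.any():
            counts["missing-scored-dead"] = int(missing.sum())
            rec.loc[missing, "alive_2017"] = 0
    if rec.empty:
        log.warning("apply_exclusions: all records removed")
    out = TrialTable(rec.reset_index(drop=True), table.meta.copy(), table.provenance)
    return ExclusionResult(table=out, counts=counts)


def dead_inclusive_height(table: TrialTable) -> pd.Series:
    """Per-record age-9 height with dead trees contributing 0.

    Records with ``alive_2017`` missing are excluded from the result (apply
    the missing-tree rule first if they should count as dead).
    """
    rec = table.active()
    scored = rec["alive_2017"].notna()
    h = rec.loc[scored, "height9_m"].astype(float)
    dead = rec.loc[scored, "alive_2017"] == 0
    h = h.where(~dead, 0.0)
    return h


def family_survival_proportions(table: TrialTable, census: str = "alive_2017") -> pd.DataFrame:
    """Per-family proportion of surviving seedlings at a census.

    Families with no scored seedlings are omitted with a warning.  The
    overall survival equals the family-size-weighted mean of the returned
    proportions.
    """
    if census not in ("alive_2010", "alive_2011", "alive_2017"):
        raise DataError(f"unknown census flag {census!r}")
    rec = table.active()
    scored = rec.loc[rec[census].notna(), ["family_id", census]]
    n_all = rec["family_id"].nunique()
    grouped = scored.groupby("family_id")[census].agg(["mean", "count"])
    grouped = grouped.rename(columns={"mean": "proportion", "count": "n_scored"})
    grouped["proportion"] = grouped["proportion"].astype(float)
    if len(grouped) < n_all:
        log.warning("family_survival_proportions: %d families had no scored "
                    "seedlings at %s", n_all - len(grouped), census)
    return grouped.reset_index()[["family_id", "n_scored", "proportion"]]
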