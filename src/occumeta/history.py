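"""Detection histories over sites, aggregation schemes, and covariates.

A detection history is the sites x surveys 0/1 matrix fed to the occupancy
likelihood: row i is a site, column k is one marker gene of the panel.  A
site is either a single metagenome or an aggregate of all metagenomes that
share geographic coordinates (optionally also ecosystem category); within
an aggregate a marker counts as detected if any member detected it.

Site-level covariates are the ecosystem category, latitude, and the date
the metagenome was added to the source database, expressed as integer days
since 2006-01-01 and entering models square-root transformed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .panels import MarkerPanel

#: Calendar origin for the numeric add-date covariate.
DATE_EPOCH = _dt.date(2006, 1, 1)

#: The three broad ecosystem categories used as a site covariate.
ECOSYSTEMS = ("engineered", "environmental", "host-associated")

METADATA_COLUMNS = ("ecosystem", "longitude", "latitude", "add_date", "sample_date")


class AggregationScheme(str, Enum):
    """How metagenomes are grouped into sites."""

    NONE = "none"
    GEOCOORDINATES = "geocoordinates"
    GEOCOORDINATES_AND_ECOSYSTEM = "geocoordinates_and_ecosystem"


@dataclass
class DetectionHistory:
    """Sites x surveys binary matrix for one marker panel."""

    site_ids: list[str]
    y: np.ndarray  # shape (n_sites, n_surveys), values in {0, 1}
    markers: tuple[str, ...]
    members: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 2 or self.y.shape != (len(self.site_ids), len(self.markers)):
            raise ValueError("detection matrix shape must be (n_sites, n_markers)")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("detection history entries must be 0 or 1")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site ids must be unique")
        if not self.members:
            self.members = [(s,) for s in self.site_ids]

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.markers))
        df.insert(0, "site_id", self.site_ids)
        return df


def numeric_add_date(date) -> int:
    """Days since 2006-01-01 (the epoch maps to 0).

    Accepts a ``datetime.date``/``datetime`` or an ISO ``YYYY-MM-DD`` string.
    Dates before the epoch are an error, not clamped.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date.strip())
    elif isinstance(date, _dt.datetime):
        date = date.date()
    elif isinstance(date, pd.Timestamp):
        date = date.date()
    if not isinstance(date, _dt.date):
        raise TypeError(f"not a calendar date: {date!r}")
    days = (date - DATE_EPOCH).days
    if days < 0:
        raise ValueError(f"date {date.isoformat()} precedes the {DATE_EPOCH.isoformat()} epoch")
    return days


def build_history(evidence: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Per-metagenome 0/1 rows from a curated-evidence table.

    ``evidence`` has columns ``metagenome_id, marker, n_sequences``.  A cell
    is 1 iff at least one curated sequence of that marker survived for that
    metagenome, regardless of the total number of detections.
    """
    required = {"metagenome_id", "marker", "n_sequences"}
    if not required.issubset(evidence.columns):
        raise ValueError(f"evidence table needs columns {sorted(required)}")
    unknown = set(evidence["marker"]) - set(panel.markers)
    if unknown:
        raise ValueError(
            f"unknown marker symbol(s) {sorted(unknown)} for panel {panel.function_name!r}"
        )
    if (evidence["n_sequences"] < 0).any():
        raise ValueError("evidence counts must be non-negative")
    wide = (
        evidence.pivot_table(
            index="metagenome_id", columns="marker", values="n_sequences", aggfunc="sum"
        )
        .reindex(columns=list(panel.markers))
        .fillna(0)
    )
    out = (wide >= 1).astype(np.int8).reset_index()
    out.columns.name = None
    return out


def _coord_token(value) -> str:
    """Textual normalization of one coordinate: trimmed, never rounded."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return str(value).strip()


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return str(value).strip() == "" or (isinstance(value, str) and value.strip().lower() == "nan")


@dataclass
class AggregationResult:
    """Detection history plus site covariates for one scheme."""

    history: DetectionHistory
    site_table: pd.DataFrame
    scheme: AggregationScheme
    n_input_rows: int
    n_mixed_sample_date: int  # aggregated sites whose members span >1 sample date


def aggregate_sites(
    table: pd.DataFrame,
    markers: tuple[str, ...] | list[str],
    scheme: AggregationScheme | str = AggregationScheme.NONE,
) -> AggregationResult:
    """Group metagenome rows into sites and OR their detections.

    ``table`` is one row per metagenome with the marker 0/1 columns plus
    ``metagenome_id`` and the metadata columns.  Grouping keys are the
    trimmed textual coordinates — metagenomes are merged only when their
    recorded coordinates are identical, so no rounding ever fuses distinct
    sites.  Under the ecosystem-splitting scheme a rumen sample and a soil
    sample at the same coordinates stay separate sites.
    """
    scheme = AggregationScheme(scheme)
    markers = tuple(markers)
    missing = [c for c in ("metagenome_id", *markers) if c not in table.columns]
    if missing:
        raise ValueError(f"input table lacks columns {missing}")

    df = table.reset_index(drop=True)
    if scheme is AggregationScheme.NONE:
        site_ids = [str(m) for m in df["metagenome_id"]]
        hist = DetectionHistory(site_ids, df[list(markers)].to_numpy(), markers)
        site_table = _site_covariates(df, with_ecosystem=True)
        site_table.index = pd.Index(site_ids, name="site_id")
        return AggregationResult(hist, site_table, scheme, len(df), 0)

    keys = [
        df["longitude"].map(_coord_token),
        df["latitude"].map(_coord_token),
    ]
    if scheme is AggregationScheme.GEOCOORDINATES_AND_ECOSYSTEM:
        keys.append(df["ecosystem"].map(_coord_token))
    key = keys[0].str.cat(keys[1:], sep="|")

    site_ids: list[str] = []
    rows: list[np.ndarray] = []
    members: list[tuple[str, ...]] = []
    cov_rows: list[dict] = []
    n_mixed = 0
    with_eco = scheme is AggregationScheme.GEOCOORDINATES_AND_ECOSYSTEM
    for idx, (k, grp) in enumerate(df.groupby(key, sort=True)):
        site_ids.append(f"site{idx:05d}|{k}")
        rows.append(grp[list(markers)].to_numpy().max(axis=0))
        members.append(tuple(str(m) for m in grp["metagenome_id"]))
        cov_rows.append(_aggregate_covariates(grp, with_ecosystem=with_eco))
        sdates = {str(d) for d in grp.get("sample_date", pd.Series(dtype=object)) if not _is_missing(d)}
        if len(grp) > 1 and len(sdates) > 1:
            n_mixed += 1
    hist = DetectionHistory(site_ids, np.vstack(rows), markers, members)
    site_table = pd.DataFrame(cov_rows, index=pd.Index(site_ids, name="site_id"))
    return AggregationResult(hist, site_table, scheme, len(df), n_mixed)


def _site_covariates(df: pd.DataFrame, with_ecosystem: bool) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    if with_ecosystem and "ecosystem" in df.columns:
        out["ecosystem"] = [None if _is_missing(e) else str(e).strip() for e in df["ecosystem"]]
    absent = pd.Series(np.nan, index=df.index)
    out["latitude"] = [None if _is_missing(v) else float(v) for v in df.get("latitude", absent)]
    out["longitude"] = [None if _is_missing(v) else float(v) for v in df.get("longitude", absent)]
    nad = []
    for d in df.get("add_date", absent):
        nad.append(None if _is_missing(d) else numeric_add_date(d))
    out["numeric_add_date"] = nad
    out["sqrt_numeric_add_date"] = [None if v is None else float(np.sqrt(v)) for v in nad]
    return out


def _aggregate_covariates(grp: pd.DataFrame, with_ecosystem: bool) -> dict:
    row: dict = {}
    if with_ecosystem:
        # uniform within a group by construction of the grouping key
        row["ecosystem"] = None if _is_missing(grp["ecosystem"].iloc[0]) else str(grp["ecosystem"].iloc[0]).strip()
    lat = grp["latitude"].iloc[0]
    lon = grp["longitude"].iloc[0]
    row["latitude"] = None if _is_missing(lat) else float(lat)
    row["longitude"] = None if _is_missing(lon) else float(lon)
    dates = [numeric_add_date(d) for d in grp.get("add_date", []) if not _is_missing(d)]
    # earliest member add date represents the aggregated site
    nad = min(dates) if dates else None
    row["numeric_add_date"] = nad
    row["sqrt_numeric_add_date"] = None if nad is None else float(np.sqrt(nad))
    row["member_count"] = len(grp)
    return row


def drop_incomplete(
    history: DetectionHistory,
    site_table: pd.DataFrame,
    required_covariates: list[str] | tuple[str, ...],
) -> tuple[DetectionHistory, pd.DataFrame, int]:
    """Listwise removal of sites with any required covariate missing.

    Returns the filtered pair plus the number of sites removed.  Idempotent:
    applying it twice with the same requirement changes nothing.
    """
    missing_cols = [c for c in required_covariates if c not in site_table.columns]
    if missing_cols:
        raise ValueError(f"site table lacks required covariate column(s) {missing_cols}")
    keep = np.ones(history.n_sites, dtype=bool)
    for c in required_covariates:
        keep &= np.array([not _is_missing(v) for v in site_table[c]])
    new_hist = DetectionHistory(
        [s for s, k in zip(history.site_ids, keep) if k],
        history.y[keep],
        history.markers,
        [m for m, k in zip(history.members, keep) if k],
    )
    return new_hist, site_table.loc[keep], int((~keep).sum())


#: Recognized covariate terms for model design matrices.
TERM_VOCABULARY = ("1", "ecosystem", "latitude", "sqrt(numeric.add.date)")

_TERM_ALIASES = {
    "1": "1",
    "ecosystem": "ecosystem",
    "latitude": "latitude",
    "sqrt(numeric.add.date)": "sqrt(numeric.add.date)",
    "sqrt(numeric_add_date)": "sqrt(numeric.add.date)",
    "sqrt_numeric_add_date": "sqrt(numeric.add.date)",
}


def parse_terms(terms: str) -> list[str]:
    """Split a formula right-hand side like ``"ecosystem + latitude"``."""
    parts = [t.strip() for t in terms.split("+")]
    out = []
    for t in parts:
        key = _TERM_ALIASES.get(t.lower())
        if key is None:
            raise ValueError(f"unknown model term {t!r}; vocabulary: {TERM_VOCABULARY}")
        if key != "1" and key not in out:
            out.append(key)
    return out


def design_matrix(
    site_table: pd.DataFrame,
    terms: str,
    ecosystem_levels: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, list[str], tuple[str, ...] | None]:
    """Numeric design matrix for a formula right-hand side.

    The intercept column is always present.  ``ecosystem`` is encoded as
    indicator columns against a reference level (lexicographically first,
    i.e. "engineered" for the standard three categories); model likelihoods
    and AIC are invariant to this labeling choice.  Numeric terms pass
    through unstandardized.

    Returns the matrix, its column names, and the ecosystem level order
    used (``None`` when ecosystem is not a term) so that predictions on new
    data can enforce the same encoding.
    """
    parsed = parse_terms(terms)
    n = len(site_table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    levels_used: tuple[str, ...] | None = None
    for term in parsed:
        if term == "ecosystem":
            values = [str(v) for v in site_table["ecosystem"]]
            if ecosystem_levels is None:
                levels_used = tuple(sorted(set(values)))
            else:
                levels_used = tuple(ecosystem_levels)
                unseen = set(values) - set(levels_used)
                if unseen:
                    raise ValueError(f"unseen ecosystem level(s) {sorted(unseen)}")
            for lev in levels_used[1:]:
                cols.append(np.array([1.0 if v == lev else 0.0 for v in values]))
                names.append(f"ecosystem[{lev}]")
        elif term == "latitude":
            cols.append(site_table["latitude"].to_numpy(dtype=float))
            names.append("latitude")
        elif term == "sqrt(numeric.add.date)":
            cols.append(site_table["sqrt_numeric_add_date"].to_numpy(dtype=float))
            names.append("sqrt(numeric.add.date)")
    x = np.column_stack(cols)
    if not np.isfinite(x).all():
        raise ValueError("design matrix contains missing or non-finite values; run drop_incomplete first")
    return x, names, levels_used


# ---------------------------------------------------------------------------
# Occupancy-table I/O (the dialect of the source database export: one row per
# metagenome, six marker columns, then metadata).
# ---------------------------------------------------------------------------

def read_occupancy_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a per-metagenome occupancy-plus-metadata table.

    ``column_map`` renames foreign headers onto the canonical ones
    (``metagenome_id``, marker symbols, ``ecosystem``, ``longitude``,
    ``latitude``, ``add_date``, ``sample_date``).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    if "metagenome_id" not in df.columns:
        raise ValueError("occupancy table needs a metagenome_id column (use column_map to adapt headers)")
    for c in df.columns:
        if c not in ("metagenome_id", *METADATA_COLUMNS, "member_count", "member_ids"):
            # marker columns hold 0/1
            vals = set(df[c].str.strip()) - {""}
            if vals <= {"0", "1"}:
                df[c] = pd.to_numeric(df[c].replace("", "0")).astype(np.int8)
    df = df.replace("", np.nan)
    return df


def write_occupancy_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def aggregation_to_table(result: AggregationResult) -> pd.DataFrame:
    """Flatten an aggregation result to the delimited output dialect."""
    out = result.history.to_frame()
    st = result.site_table.reset_index(drop=True)
    for c in st.columns:
        out[c] = st[c].to_numpy()
    if "member_count" not in out.columns:
        out["member_count"] = [len(m) for m in result.history.members]
    out["member_ids"] = [";".join(m) for m in result.history.members]
    return out
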