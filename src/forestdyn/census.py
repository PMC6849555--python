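"""Tree-census data model, readers/writers and validation.

A census series is the raw observational unit: one permanent plot, its
metadata (location, area, region) and an ordered sequence of full
remeasurements of every stem at or above the minimum diameter threshold.
Dates are decimal calendar years throughout (e.g. ``2004.37``), which keeps
census-interval arithmetic trivial.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: The four substrate-defined strata of the plot network.
REGIONS = ("GuianaShield", "EastCentral", "Western", "BrazilianShield")

#: Default minimum stem diameter (cm) for inclusion in all analyses.
DEFAULT_DBH_THRESHOLD_CM = 10.0

#: Default minimum total monitoring period (years) for dynamic analyses.
DEFAULT_MIN_MONITORING_YEARS = 2.0


class CensusFormatError(ValueError):
    """Raised for malformed census input (missing columns, bad rows)."""


class CensusValidationError(ValueError):
    """Raised when a parsed series violates a structural invariant."""


class Status(str, enum.Enum):
    """Fixed status vocabulary for a tree at a census.

    Richer field codes (broken, resprout, ...) must be mapped onto these four
    by the input dialect; keeping the vocabulary closed keeps the demographic
    logic unambiguous.
    """

    ALIVE = "alive"
    DEAD = "dead"
    RECRUIT = "recruit_first_record"
    ABSENT_PRIOR = "absent_prior"


#: Statuses that denote a living stem carrying a measurable diameter.
LIVE_STATUSES = frozenset({Status.ALIVE, Status.RECRUIT})


@dataclass(frozen=True)
class TreeObservation:
    """One stem at one census."""

    plot_id: str
    tree_id: str
    census_date: float
    dbh: float
    status: Status
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.status in LIVE_STATUSES and not self.dbh > 0:
            raise CensusValidationError(
                f"live tree {self.tree_id} in plot {self.plot_id} at "
                f"{self.census_date} has non-positive dbh {self.dbh}"
            )

    @property
    def is_live(self) -> bool:
        return self.status in LIVE_STATUSES


@dataclass(frozen=True)
class PlotMetadata:
    """Location, size and regional stratum of a plot."""

    plot_id: str
    longitude: float
    latitude: float
    area: float  # ha
    region: str

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise CensusValidationError(
                f"plot {self.plot_id}: area must be positive, got {self.area}"
            )

    @classmethod
    def stub(cls, plot_id: str) -> "PlotMetadata":
        """Placeholder metadata for census files read without a metadata table."""
        return cls(plot_id=plot_id, longitude=math.nan, latitude=math.nan,
                   area=1.0, region="unknown")


@dataclass(frozen=True)
class CensusInterval:
    """The time span between two successive censuses."""

    start_date: float
    end_date: float

    def __post_init__(self) -> None:
        if not self.end_date > self.start_date:
            raise CensusValidationError(
                f"census interval must have positive length: "
                f"{self.start_date} -> {self.end_date}"
            )

    @property
    def t(self) -> float:
        """Interval length in years."""
        return self.end_date - self.start_date


@dataclass
class PlotSeries:
    """A plot's metadata plus its ordered censuses.

    ``censuses`` maps census date -> {tree_id: TreeObservation}; the list is
    kept sorted by date.
    """

    metadata: PlotMetadata
    censuses: list[tuple[float, dict[str, TreeObservation]]] = field(default_factory=list)

    @property
    def plot_id(self) -> str:
        return self.metadata.plot_id

    @property
    def dates(self) -> list[float]:
        return [d for d, _ in self.censuses]

    @property
    def n_censuses(self) -> int:
        return len(self.censuses)

    @property
    def monitoring_span(self) -> float:
        if self.n_censuses < 2:
            return 0.0
        return self.dates[-1] - self.dates[0]

    def intervals(self) -> list[CensusInterval]:
        d = self.dates
        return [CensusInterval(d[i], d[i + 1]) for i in range(len(d) - 1)]

    def iter_observations(self) -> Iterator[TreeObservation]:
        for _, trees in self.censuses:
            yield from trees.values()

    def live_trees(self, census_index: int) -> dict[str, TreeObservation]:
        _, trees = self.censuses[census_index]
        return {tid: obs for tid, obs in trees.items() if obs.is_live}


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensusDialect:
    """Column and status-code mapping for a delimited census table."""

    plot_id: str = "plot_id"
    tree_id: str = "tree_id"
    census_date: str = "census_date"
    dbh: str = "dbh"
    status: str = "status"
    family: str | None = "family"
    genus: str | None = "genus"
    species: str | None = "species"
    status_map: Mapping[str, Status] = dataclasses.field(
        default_factory=lambda: {s.value: s for s in Status}
    )
    delimiter: str = ","

    @property
    def mandatory_columns(self) -> tuple[str, ...]:
        return (self.plot_id, self.tree_id, self.census_date, self.dbh, self.status)


def load_census_table(
    path: str | Path,
    dialect: CensusDialect | None = None,
    metadata: Mapping[str, PlotMetadata] | None = None,
) -> list[PlotSeries]:
    """Read a delimited census table (one row per tree per census).

    Rows are grouped by plot and census date into date-sorted
    :class:`PlotSeries`. Unknown status strings and structural violations
    (a dead tree reappearing alive) are rejected.
    """
    dialect = dialect or CensusDialect()
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("census file %s is empty; returning no series", path)
        return []
    if df.empty:
        logger.warning("census file %s has no data rows; returning no series", path)
        return []

    missing = [c for c in dialect.mandatory_columns if c not in df.columns]
    if missing:
        raise CensusFormatError(
            f"census file {path} is missing mandatory column(s): {', '.join(missing)}"
        )

    rows: list[TreeObservation] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            date = float(row[dialect.census_date])
            dbh = float(row[dialect.dbh])
        except (TypeError, ValueError) as exc:
            raise CensusFormatError(
                f"{path} line {line_no}: unparseable date or diameter ({exc})"
            ) from exc
        raw_status = str(row[dialect.status]).strip()
        if raw_status not in dialect.status_map:
            raise CensusFormatError(
                f"{path} line {line_no}: unknown status code {raw_status!r}"
            )

        def _opt(col: str | None) -> str | None:
            if col is None or col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) or str(v).strip() == "" else str(v).strip()

        rows.append(TreeObservation(
            plot_id=str(row[dialect.plot_id]).strip(),
            tree_id=str(row[dialect.tree_id]).strip(),
            census_date=date,
            dbh=dbh,
            status=dialect.status_map[raw_status],
            family=_opt(dialect.family),
            genus=_opt(dialect.genus),
            species=_opt(dialect.species),
        ))

    series_by_plot: dict[str, dict[float, dict[str, TreeObservation]]] = {}
    for obs in rows:
        censuses = series_by_plot.setdefault(obs.plot_id, {})
        trees = censuses.setdefault(obs.census_date, {})
        if obs.tree_id in trees:
            raise CensusValidationError(
                f"plot {obs.plot_id}: duplicate record for tree {obs.tree_id} "
                f"at census {obs.census_date}"
            )
        trees[obs.tree_id] = obs

    out: list[PlotSeries] = []
    for plot_id in sorted(series_by_plot):
        meta = (metadata or {}).get(plot_id) or PlotMetadata.stub(plot_id)
        censuses = sorted(series_by_plot[plot_id].items())
        series = PlotSeries(metadata=meta, censuses=[(d, t) for d, t in censuses])
        _check_absorbing_death(series)
        out.append(series)
    return out


def _check_absorbing_death(series: PlotSeries) -> None:
    """Death is absorbing: a tree recorded dead never reappears alive."""
    dead: set[str] = set()
    for _, trees in series.censuses:
        for tid, obs in trees.items():
            if tid in dead and obs.is_live:
                raise CensusValidationError(
                    f"plot {series.plot_id}: tree {tid} recorded alive at "
                    f"{obs.census_date} after having been recorded dead"
                )
            if obs.status is Status.DEAD:
                dead.add(tid)


def write_census_table(
    series_list: Iterable[PlotSeries],
    path: str | Path,
    dialect: CensusDialect | None = None,
) -> None:
    """Write series back to the delimited format :func:`load_census_table` reads."""
    dialect = dialect or CensusDialect()
    inverse_status = {}
    for code, status in dialect.status_map.items():
        inverse_status.setdefault(status, code)
    records = []
    for series in series_list:
        for obs in series.iter_observations():
            rec = {
                dialect.plot_id: obs.plot_id,
                dialect.tree_id: obs.tree_id,
                dialect.census_date: obs.census_date,
                dialect.dbh: obs.dbh,
                dialect.status: inverse_status[obs.status],
            }
            for col, value in ((dialect.family, obs.family),
                               (dialect.genus, obs.genus),
                               (dialect.species, obs.species)):
                if col is not None:
                    rec[col] = value
            records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep=dialect.delimiter, index=False)


def load_plot_metadata(path: str | Path) -> dict[str, PlotMetadata]:
    """Read a plot-metadata CSV (plot_id, longitude, latitude, area_ha, region)."""
    df = pd.read_csv(path)
    required = {"plot_id", "longitude", "latitude", "area_ha", "region"}
    missing = required - set(df.columns)
    if missing:
        raise CensusFormatError(
            f"metadata file {path} is missing column(s): {', '.join(sorted(missing))}"
        )
    out = {}
    for _, row in df.iterrows():
        meta = PlotMetadata(
            plot_id=str(row["plot_id"]),
            longitude=float(row["longitude"]),
            latitude=float(row["latitude"]),
            area=float(row["area_ha"]),
            region=str(row["region"]),
        )
        out[meta.plot_id] = meta
    return out


def write_plot_metadata(metadata: Mapping[str, PlotMetadata], path: str | Path) -> None:
    pd.DataFrame.from_records([
        {"plot_id": m.plot_id, "longitude": m.longitude, "latitude": m.latitude,
         "area_ha": m.area, "region": m.region}
        for m in metadata.values()
    ]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    code: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_series` for one plot."""

    plot_id: str
    violations: list[Violation]
    usable_for_dynamics: bool

    def to_json(self) -> str:
        return json.dumps({
            "plot_id": self.plot_id,
            "usable_for_dynamics": self.usable_for_dynamics,
            "violations": [dataclasses.asdict(v) for v in self.violations],
        }, indent=2)

    def to_text(self) -> str:
        lines = [f"plot {self.plot_id}: "
                 f"{'usable' if self.usable_for_dynamics else 'NOT usable'} for dynamics"]
        for v in self.violations:
            lines.append(f"  [{v.code}] {v.message}")
        return "\n".join(lines)


def validate_series(
    series: PlotSeries,
    min_monitoring: float = DEFAULT_MIN_MONITORING_YEARS,
    dbh_threshold: float = DEFAULT_DBH_THRESHOLD_CM,
) -> ValidationReport:
    """Check a series against the structural and protocol rules.

    The report lists every violation found (non-monotonic dates, resurrection,
    sub-threshold live diameters, monitoring span below ``min_monitoring``)
    and flags whether the series is usable for dynamic (multi-census) analyses.
    """
    violations: list[Violation] = []
    dates = series.dates
    if any(d1 <= d0 for d0, d1 in zip(dates, dates[1:])):
        violations.append(Violation(
            "non_monotonic_dates",
            f"census dates are not strictly increasing: {dates}"))

    try:
        _check_absorbing_death(series)
    except CensusValidationError as exc:
        violations.append(Violation("resurrection", str(exc)))

    for obs in series.iter_observations():
        if obs.is_live and obs.dbh < dbh_threshold:
            violations.append(Violation(
                "sub_threshold_dbh",
                f"tree {obs.tree_id} live at {obs.census_date} with "
                f"dbh {obs.dbh} cm below the {dbh_threshold} cm threshold"))

    enough_censuses = series.n_censuses >= 2
    span_ok = series.monitoring_span >= min_monitoring
    if not enough_censuses:
        violations.append(Violation(
            "too_few_censuses",
            f"{series.n_censuses} census(es); dynamic analyses need at least 2"))
    elif not span_ok:
        violations.append(Violation(
            "short_monitoring",
            f"monitoring span {series.monitoring_span:.2f} yr is below the "
            f"{min_monitoring} yr minimum"))

    structural = {"non_monotonic_dates", "resurrection"}
    usable = (enough_censuses and span_ok
              and not any(v.code in structural for v in violations))
    return ValidationReport(series.plot_id, violations, usable)


# ---------------------------------------------------------------------------
# Diameter threshold
# ---------------------------------------------------------------------------

def apply_diameter_threshold(
    series: PlotSeries,
    threshold: float = DEFAULT_DBH_THRESHOLD_CM,
) -> PlotSeries:
    """Drop sub-threshold observations; promote threshold-crossers to recruits.

    The inclusion rule is ``dbh >= threshold`` (field protocols measure in mm
    and include 100 mm stems). A tree first reaching the threshold after the
    series' first census becomes a ``recruit_first_record`` at that census.
    Once a tree has been recruited it stays tracked, including its death
    record, even if its recorded diameter later shrinks below the threshold.
    """
    # First census index at which each tree qualifies while alive.
    first_qualifying: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for i, (_, trees) in enumerate(series.censuses):
        for tid, obs in trees.items():
            first_seen.setdefault(tid, i)
            if obs.is_live and obs.dbh >= threshold:
                first_qualifying.setdefault(tid, i)

    new_censuses: list[tuple[float, dict[str, TreeObservation]]] = []
    for i, (date, trees) in enumerate(series.censuses):
        kept: dict[str, TreeObservation] = {}
        for tid, obs in trees.items():
            qual = first_qualifying.get(tid)
            if qual is None or i < qual:
                continue
            if i == qual and i > first_seen[tid] and obs.status is not Status.RECRUIT:
                obs = dataclasses.replace(obs, status=Status.RECRUIT)
            kept[tid] = obs
        new_censuses.append((date, kept))
    return PlotSeries(metadata=series.metadata, censuses=new_censuses)
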