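"""Reading, standardising and filtering long-format community composition data.

The canonical in-memory containers are tidy :class:`pandas.DataFrame` objects:

* a *record* table with columns ``study_area, subsite, plot, year, taxon,
  abundance, category, treatment`` (one row per abundance observation), and
* a *cover* table with columns ``study_area, subsite, plot, year, taxon,
  cover, category`` where ``cover`` is relative cover in percent and every
  (plot, year) group sums to 100.

Abundances arrive in survey-method units (point-intercept hits or direct
cover estimates); converting each plot-year to within-plot proportions puts
both methods on a common 0–100% scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "study_area",
    "subsite",
    "plot",
    "year",
    "taxon",
    "abundance",
    "category",
    "treatment",
]

COVER_COLUMNS = ["study_area", "subsite", "plot", "year", "taxon", "cover", "category"]

VALID_CATEGORIES = frozenset({"vascular", "non_vascular", "abiotic", "morphospecies"})

#: Calendar-year bounds applied during validation (configurable per call).
DEFAULT_YEAR_BOUNDS = (1981, 2023)


class SchemaError(ValueError):
    """A required input column could not be resolved."""


class ValidationError(ValueError):
    """An input row violates the composition-data contract."""


@dataclass(frozen=True)
class CompositionSchema:
    """Mapping from canonical column names to the names used in a CSV file.

    Only the columns present in the file need to be mapped; ``category`` and
    ``treatment`` may instead be supplied via ``category_lookup`` /
    ``default_treatment`` at read time.
    """

    study_area: str = "study_area"
    subsite: str = "subsite"
    plot: str = "plot"
    year: str = "year"
    taxon: str = "taxon"
    abundance: str = "abundance"
    category: str | None = "category"
    treatment: str | None = "treatment"


@dataclass(frozen=True)
class PlotSeries:
    """Ordered survey series for one plot.

    ``covers`` maps survey year to a taxon → relative-cover Series; surveys
    are sorted ascending and span at least ``duration_years`` = end − start
    calendar years.
    """

    plot: str
    subsite: str
    study_area: str
    covers: Mapping[int, pd.Series] = field(repr=False, default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.covers)

    @property
    def start_year(self) -> int:
        return self.years[0]

    @property
    def end_year(self) -> int:
        return self.years[-1]

    @property
    def duration_years(self) -> int:
        return self.end_year - self.start_year

    @property
    def start(self) -> pd.Series:
        return self.covers[self.start_year]

    @property
    def end(self) -> pd.Series:
        return self.covers[self.end_year]


def read_composition(
    path,
    schema: CompositionSchema | Mapping[str, str] | None = None,
    *,
    category_lookup: Mapping[str, str] | None = None,
    default_treatment: str = "control",
    year_bounds: tuple[int, int] = DEFAULT_YEAR_BOUNDS,
) -> pd.DataFrame:
    """Read a long-format composition CSV into the canonical record table.

    Parameters
    ----------
    path
        CSV file with one row per (plot, year, taxon) abundance observation.
    schema
        Column-name mapping; either a :class:`CompositionSchema` or a dict
        keyed by canonical names. Unmapped extra columns are ignored (logged).
    category_lookup
        taxon → category mapping used when the file has no category column.
        Taxa absent from the lookup default to ``vascular``.
    default_treatment
        Treatment assigned when the file has no treatment column.
    year_bounds
        Inclusive calendar-year validity bounds.

    Raises
    ------
    SchemaError
        If a required column is missing from the file.
    ValidationError
        Naming the offending row, for negative abundances, invalid years or
        unknown categories.
    """
    if schema is None:
        schema = CompositionSchema()
    elif isinstance(schema, Mapping):
        schema = CompositionSchema(**schema)

    raw = pd.read_csv(path)
    required = {
        "study_area": schema.study_area,
        "subsite": schema.subsite,
        "plot": schema.plot,
        "year": schema.year,
        "taxon": schema.taxon,
        "abundance": schema.abundance,
    }
    for canonical, column in required.items():
        if column not in raw.columns:
            raise SchemaError(
                f"required column {column!r} (for {canonical!r}) not found in {path}"
            )

    df = pd.DataFrame(
        {canonical: raw[column] for canonical, column in required.items()}
    )
    mapped = set(required.values())

    if schema.category is not None and schema.category in raw.columns:
        df["category"] = raw[schema.category].astype(str)
        mapped.add(schema.category)
    elif category_lookup is not None:
        df["category"] = (
            df["taxon"].map(dict(category_lookup)).fillna("vascular").astype(str)
        )
    else:
        df["category"] = "vascular"

    if schema.treatment is not None and schema.treatment in raw.columns:
        df["treatment"] = raw[schema.treatment].astype(str)
        mapped.add(schema.treatment)
    else:
        df["treatment"] = default_treatment

    extra = [c for c in raw.columns if c not in mapped]
    if extra:
        logger.info("ignoring unmapped columns: %s", ", ".join(map(str, extra)))

    for col in ("study_area", "subsite", "plot", "taxon"):
        df[col] = df[col].astype(str)
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    df["abundance"] = pd.to_numeric(df["abundance"], errors="raise").astype(float)

    validate_records(df, year_bounds=year_bounds)
    return df[RECORD_COLUMNS]


def validate_records(
    records: pd.DataFrame, *, year_bounds: tuple[int, int] = DEFAULT_YEAR_BOUNDS
) -> None:
    """Validate the canonical record-table contract, naming offending rows."""
    neg = records.index[records["abundance"] < 0]
    if len(neg):
        raise ValidationError(f"negative abundance at rows {list(neg[:10])}")
    lo, hi = year_bounds
    bad_year = records.index[(records["year"] < lo) | (records["year"] > hi)]
    if len(bad_year):
        raise ValidationError(
            f"year outside [{lo}, {hi}] at rows {list(bad_year[:10])}"
        )
    bad_cat = records.index[~records["category"].isin(VALID_CATEGORIES)]
    if len(bad_cat):
        raise ValidationError(
            f"unknown category at rows {list(bad_cat[:10])}; "
            f"valid: {sorted(VALID_CATEGORIES)}"
        )


def filter_control(records: pd.DataFrame) -> pd.DataFrame:
    """Retain only permanently marked control plots (treatment == 'control')."""
    return records[records["treatment"] == "control"].reset_index(drop=True)


def to_relative_cover(records: pd.DataFrame) -> pd.DataFrame:
    """Convert abundances to relative cover (%) per plot-year.

    Abiotic (rock, soil, litter…) and non-vascular records are dropped before
    the conversion; the denominator is the summed abundance of the remaining
    vascular records (identified species and morphospecies alike), so each
    retained plot-year sums to exactly 100%. Plot-years with zero total
    vascular abundance are rejected and logged.
    """
    plants = records[records["category"].isin(["vascular", "morphospecies"])].copy()
    plants = plants[plants["abundance"] > 0]

    keys = ["study_area", "subsite", "plot", "year"]
    totals = plants.groupby(keys)["abundance"].transform("sum")
    all_groups = records[keys].drop_duplicates()
    kept_groups = plants[keys].drop_duplicates()
    dropped = all_groups.merge(kept_groups, how="left", on=keys, indicator=True)
    dropped = dropped[dropped["_merge"] == "left_only"]
    for _, row in dropped.iterrows():
        logger.warning(
            "plot-year rejected (zero vascular abundance): %s/%s/%s %s",
            row["study_area"], row["subsite"], row["plot"], row["year"],
        )

    out = plants.copy()
    out["cover"] = 100.0 * plants["abundance"] / totals
    # merge duplicate taxon rows within a plot-year
    out = (
        out.groupby(keys + ["taxon", "category"], as_index=False)["cover"]
        .sum()
    )
    return out[COVER_COLUMNS]


def filter_morphospecies(covers: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Drop plot-years whose summed morphospecies cover exceeds ``threshold``.

    The rule is strict: a plot-year at exactly the threshold is retained.
    Surviving plot-years then have their morphospecies rows removed and the
    identified-species covers re-normalised to 100%, so downstream indices
    operate on identified species only.
    """
    keys = ["study_area", "subsite", "plot", "year"]
    morpho = (
        covers.assign(
            m=np.where(covers["category"] == "morphospecies", covers["cover"], 0.0)
        )
        .groupby(keys)["m"]
        .sum()
    )
    bad = morpho[morpho > threshold]
    for key, share in bad.items():
        logger.info("plot-year removed (>%g%% morphospecies: %.2f%%): %s", threshold, share, key)

    merged = covers.merge(
        morpho.rename("morpho_share").reset_index(), on=keys, how="left"
    )
    kept = merged[merged["morpho_share"] <= threshold]
    kept = kept[kept["category"] != "morphospecies"].copy()
    totals = kept.groupby(keys)["cover"].transform("sum")
    kept["cover"] = 100.0 * kept["cover"] / totals
    return kept[COVER_COLUMNS].reset_index(drop=True)


def aggregate_infraspecifics(
    covers: pd.DataFrame, synonym_table: Mapping[str, str]
) -> pd.DataFrame:
    """Sum covers of infraspecific taxa (subspecies, varieties) into species.

    ``synonym_table`` maps recorded names to accepted species names; unmapped
    names pass through unchanged (logged at debug level). Totals per
    plot-year are preserved exactly.
    """
    table = dict(synonym_table)
    unmapped = sorted(set(covers["taxon"]) - set(table))
    if table and unmapped:
        logger.debug("taxa left unmapped by synonym table: %s", ", ".join(unmapped))
    out = covers.copy()
    out["taxon"] = out["taxon"].map(lambda t: table.get(t, t))
    keys = ["study_area", "subsite", "plot", "year", "taxon", "category"]
    return out.groupby(keys, as_index=False)["cover"].sum()[COVER_COLUMNS]


def build_plot_series(
    covers: pd.DataFrame, min_duration: int = 5
) -> list[PlotSeries]:
    """Assemble per-plot survey series, applying the resurvey eligibility rule.

    Plots with fewer than two surveys, or whose last-minus-first survey span
    is below ``min_duration`` years, are excluded. Survey order is ascending
    by calendar year.
    """
    series: list[PlotSeries] = []
    for (area, subsite, plot), group in covers.groupby(
        ["study_area", "subsite", "plot"], sort=True
    ):
        years = sorted(group["year"].unique())
        if len(years) < 2 or years[-1] - years[0] < min_duration:
            continue
        by_year = {
            int(year): g.set_index("taxon")["cover"].sort_index()
            for year, g in group.groupby("year")
        }
        series.append(
            PlotSeries(plot=plot, subsite=subsite, study_area=area, covers=by_year)
        )
    return series


def write_cover_csv(covers: pd.DataFrame, path) -> None:
    """Write a cover table with full float precision (round-trips to 1e-9)."""
    covers.to_csv(path, index=False, float_format="%.12g")


def read_cover_csv(path) -> pd.DataFrame:
    covers = pd.read_csv(path)
    missing = set(COVER_COLUMNS) - set(covers.columns)
    if missing:
        raise SchemaError(f"cover table missing columns: {sorted(missing)}")
    for col in ("study_area", "subsite", "plot", "taxon", "category"):
        covers[col] = covers[col].astype(str)
    covers["year"] = covers["year"].astype(int)
    return covers[COVER_COLUMNS]
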