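"""Covariate assembly: derived variables and collinearity screening.

Covariates live at the subsite level (the level at which coordinates are
available) except plot size and initial boreal status, which are per plot.
Distances are in km, elevations in m, temperatures in °C, precipitation in
mm; the elevational ("ground") treeline distance for Oro-Arctic subsites is
the hypotenuse of the horizontal distance and the site–treeline elevation
difference.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from borealis.classification import SpeciesClass
from borealis.composition import PlotSeries
from borealis.indices import boreal_cover, _require_classes
from borealis.classification import is_boreal_class

REGIONS = ("EasternNorthAmerica", "WesternNorthAmerica", "GreenlandIceland", "Eurasia")
BIOMES = ("Arctic", "OroArctic")
BARRIERS = ("uninterrupted", "small_water", "mountains", "large_water")
HERBIVORY = ("low", "medium", "high")
GRAZERS = ("none", "insects", "birds", "small_mammals", "large_mammals")
MOISTURE = ("dry", "moist", "wet", "mixed")
PERMAFROST = ("none", "sporadic", "discontinuous", "continuous")

#: Default ordinal codings for categorical variables entering the Spearman
#: screen (level orderings are a config choice; override per call).
DEFAULT_ORDINAL_CODINGS: dict[str, Sequence[str]] = {
    "region": REGIONS,
    "biome": BIOMES,
    "barrier": BARRIERS,
    "herbivory": HERBIVORY,
    "grazer": GRAZERS,
    "moisture": MOISTURE,
    "permafrost": PERMAFROST,
}


def ground_distance(
    horizontal_km: float, elev_site_m: float, elev_treeline_m: float
) -> float:
    """Ground distance (km) to an elevational treeline: the hypotenuse of
    the horizontal distance and the elevation difference.

    Applies to Oro-Arctic subsites, whose treeline is elevational rather
    than latitudinal; Arctic subsites use the horizontal distance directly.
    """
    if horizontal_km < 0:
        raise ValueError("horizontal distance must be non-negative")
    dz_km = (elev_site_m - elev_treeline_m) / 1000.0
    return math.hypot(horizontal_km, dz_km)


def centre_variable(values) -> np.ndarray:
    """Centre on zero by subtracting the mean of the finite values."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("cannot centre an all-missing variable")
    return arr - finite.mean()


def initial_boreal_status(
    series: PlotSeries,
    class_table: Mapping[str, SpeciesClass],
    mode: str,
) -> float:
    """Boreal presence at the start of a plot's monitoring period.

    ``mode='count'`` — number of boreal-class species present at the first
    survey (used in BCI models); ``mode='cover'`` — their summed relative
    cover in percent (used in BAI models).
    """
    start = series.start
    if mode == "cover":
        return boreal_cover(start, class_table)
    if mode == "count":
        present = start.index[start > 0]
        _require_classes(present, class_table)
        return float(sum(is_boreal_class(class_table[t]) for t in present))
    raise ValueError("mode must be 'count' or 'cover'")


def encode_ordinal(
    table: pd.DataFrame,
    codings: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Replace declared categorical columns with ordinal integer codes."""
    codings = dict(DEFAULT_ORDINAL_CODINGS if codings is None else codings)
    out = table.copy()
    for col, levels in codings.items():
        if col in out.columns:
            mapping = {lvl: i for i, lvl in enumerate(levels)}
            unknown = set(out[col].dropna()) - set(mapping)
            if unknown:
                raise ValueError(f"unknown levels in {col!r}: {sorted(unknown)}")
            out[col] = out[col].map(mapping)
    return out


def spearman_screen(
    table: pd.DataFrame,
    variables: Sequence[str],
    keep_priority: Sequence[str],
    threshold: float = 0.7,
    codings: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Drop one variable from every strongly rank-correlated pair.

    Pairwise Spearman correlations are computed on complete pairwise
    observations, with categorical variables ordinal-coded. For each pair
    with |ρ| > ``threshold`` (processed in decreasing |ρ|) the variable
    ranked lower in ``keep_priority`` (earlier = keep) is dropped, unless
    its partner was already dropped.

    Returns ``(retained, correlation_matrix, report)`` where ``report`` has
    one row per conflicting pair (var_a, var_b, rho, dropped).
    """
    coded = encode_ordinal(table[list(variables)], codings)
    corr = coded.corr(method="spearman")  # pairwise-complete by construction

    priority = {v: i for i, v in enumerate(keep_priority)}
    pairs = []
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            rho = corr.loc[a, b]
            if np.isfinite(rho) and abs(rho) > threshold:
                pairs.append((abs(rho), a, b, rho))
    pairs.sort(reverse=True)

    dropped: set[str] = set()
    report_rows = []
    for _, a, b, rho in pairs:
        if a in dropped or b in dropped:
            continue
        for v in (a, b):
            if v not in priority:
                raise ValueError(
                    f"variable {v!r} is in a correlated pair (|rho|={abs(rho):.2f}) "
                    "but has no entry in keep_priority"
                )
        loser = a if priority[a] > priority[b] else b
        dropped.add(loser)
        report_rows.append({"var_a": a, "var_b": b, "rho": rho, "dropped": loser})

    retained = [v for v in variables if v not in dropped]
    report = pd.DataFrame(report_rows, columns=["var_a", "var_b", "rho", "dropped"])
    return retained, corr, report


def attach_initial_status(
    covariates: pd.DataFrame,
    all_series: Sequence[PlotSeries],
    class_table: Mapping[str, SpeciesClass],
) -> pd.DataFrame:
    """Join per-plot initial boreal count and cover onto a covariate table."""
    rows = [
        {
            "plot": s.plot,
            "initial_boreal_count": initial_boreal_status(s, class_table, "count"),
            "initial_boreal_cover": initial_boreal_status(s, class_table, "cover"),
        }
        for s in all_series
    ]
    return covariates.merge(pd.DataFrame(rows), on="plot", how="left")
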