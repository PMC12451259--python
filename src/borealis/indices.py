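"""Plot- and species-level borealisation indices.

Turnover is scored from the first and last survey of each plot only
(intermediate surveys are ignored): a *coloniser* has zero cover at the
start and positive cover at the end, a *loss* the reverse. Two indices
summarise borealisation per plot:

* **BCI** (colonisation index) — the proportion of a plot's colonisers that
  belong to the boreal focal classes (Boreal + Boreal-Tundra); bounded
  [0, 1]. A plot with no colonisers carries BCI = 0 under the full-range
  convention, with an explicit ``no_colonisers`` flag so positive-only and
  full-range model subsets can be reconstructed unambiguously.
* **BAI** (abundance index) — the annual rate of change of summed relative
  cover of boreal-class species, (end − start) / duration, in % cover per
  year. Because plot-year covers sum to 100%, a boreal gain is exactly a
  non-boreal loss of the same magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from borealis.classification import SpeciesClass, is_boreal_class
from borealis.composition import PlotSeries


class UnclassifiedTaxonError(ValueError):
    """A taxon required by an index has no resolved class."""


@dataclass(frozen=True)
class PlotChangeSummary:
    """Per-plot turnover and borealisation summary (endpoint convention)."""

    plot: str
    subsite: str
    study_area: str
    duration_years: int
    colonisers: frozenset[str]
    losses: frozenset[str]
    n_colonisers: int
    n_boreal_colonisers: int
    bci: float
    no_colonisers: bool
    bai: float
    boreal_cover_start: float
    boreal_cover_end: float
    net_change: int


def _endpoint_covers(series: PlotSeries) -> tuple[pd.Series, pd.Series]:
    start = series.start
    end = series.end
    taxa = start.index.union(end.index)
    return start.reindex(taxa, fill_value=0.0), end.reindex(taxa, fill_value=0.0)


def detect_turnover(series: PlotSeries) -> tuple[frozenset[str], frozenset[str]]:
    """Colonisers and losses between a plot's first and last survey.

    Presence is cover > 0; species seen only in intermediate surveys count
    as neither colonisers nor losses.
    """
    start, end = _endpoint_covers(series)
    colonisers = frozenset(start.index[(start == 0) & (end > 0)])
    losses = frozenset(start.index[(start > 0) & (end == 0)])
    return colonisers, losses


def _require_classes(
    taxa: Iterable[str], class_table: Mapping[str, SpeciesClass]
) -> None:
    missing = [t for t in taxa if t not in class_table]
    if missing:
        raise UnclassifiedTaxonError(
            f"taxa without a species class: {sorted(missing)[:10]}"
        )


def compute_bci(
    series: PlotSeries, class_table: Mapping[str, SpeciesClass]
) -> tuple[float, bool]:
    """BCI = boreal colonisers / total colonisers.

    Returns ``(bci, no_colonisers)``; a plot without colonisers gets
    ``(0.0, True)`` under the full-range zero convention.
    """
    colonisers, _ = detect_turnover(series)
    if not colonisers:
        return 0.0, True
    _require_classes(colonisers, class_table)
    n_boreal = sum(is_boreal_class(class_table[t]) for t in colonisers)
    return n_boreal / len(colonisers), False


def boreal_cover(
    covers: pd.Series, class_table: Mapping[str, SpeciesClass]
) -> float:
    """Summed relative cover (%) of boreal-class species in one survey."""
    present = covers.index[covers > 0]
    _require_classes(present, class_table)
    return float(
        sum(covers[t] for t in present if is_boreal_class(class_table[t]))
    )


def compute_bai(
    series: PlotSeries, class_table: Mapping[str, SpeciesClass]
) -> float:
    """BAI = (boreal end cover − boreal start cover) / duration, %/yr."""
    start, end = _endpoint_covers(series)
    return (
        boreal_cover(end, class_table) - boreal_cover(start, class_table)
    ) / series.duration_years


def compute_bai_slope(
    series: PlotSeries, class_table: Mapping[str, SpeciesClass]
) -> float:
    """OLS slope of total boreal cover against survey year (%/yr).

    Used only to benchmark the end−start convention: on a two-survey plot
    the slope equals the end−start rate exactly.
    """
    years = np.array(series.years, dtype=float)
    covers = np.array(
        [boreal_cover(series.covers[int(y)], class_table) for y in years]
    )
    slope = np.polyfit(years, covers, 1)[0]
    return float(slope)


def summarise_plot(
    series: PlotSeries, class_table: Mapping[str, SpeciesClass]
) -> PlotChangeSummary:
    start, end = _endpoint_covers(series)
    colonisers, losses = detect_turnover(series)
    _require_classes(set(colonisers) | set(losses), class_table)
    bci, no_col = compute_bci(series, class_table)
    n_boreal_col = sum(is_boreal_class(class_table[t]) for t in colonisers)
    n_boreal_loss = sum(is_boreal_class(class_table[t]) for t in losses)
    return PlotChangeSummary(
        plot=series.plot,
        subsite=series.subsite,
        study_area=series.study_area,
        duration_years=series.duration_years,
        colonisers=colonisers,
        losses=losses,
        n_colonisers=len(colonisers),
        n_boreal_colonisers=n_boreal_col,
        bci=bci,
        no_colonisers=no_col,
        bai=compute_bai(series, class_table),
        boreal_cover_start=boreal_cover(start, class_table),
        boreal_cover_end=boreal_cover(end, class_table),
        net_change=n_boreal_col - n_boreal_loss,
    )


def summarise_plots(
    all_series: Sequence[PlotSeries], class_table: Mapping[str, SpeciesClass]
) -> pd.DataFrame:
    """Plot-level summary table (one row per eligible plot)."""
    rows = []
    for series in all_series:
        s = summarise_plot(series, class_table)
        rows.append(
            {
                "plot": s.plot,
                "subsite": s.subsite,
                "study_area": s.study_area,
                "duration_years": s.duration_years,
                "n_colonisers": s.n_colonisers,
                "n_boreal_colonisers": s.n_boreal_colonisers,
                "n_losses": len(s.losses),
                "bci": s.bci,
                "no_colonisers": s.no_colonisers,
                "bai": s.bai,
                "boreal_cover_start": s.boreal_cover_start,
                "boreal_cover_end": s.boreal_cover_end,
                "net_change": s.net_change,
            }
        )
    return pd.DataFrame(rows)


def summarise_species(
    all_series: Sequence[PlotSeries],
    class_table: Mapping[str, SpeciesClass],
) -> pd.DataFrame:
    """Species-level turnover and abundance-change summary.

    Per species: ``times_colonised`` / ``times_lost`` count plots where the
    species is a coloniser / loss; ``mean_abundance_change`` averages the
    per-plot annual cover change over plots where the species occurs at
    either endpoint (plots where it never appears would only shrink the
    mean toward zero); ``net_change`` = times colonised − times lost.
    ``n_colonisations_subsite_present`` counts colonisation events where the
    species was already present somewhere in the same subsite at that
    plot's start year — the 'hidden diversity' signal.
    """
    colonised: dict[str, int] = {}
    lost: dict[str, int] = {}
    changes: dict[str, list[float]] = {}
    subsite_present: dict[str, int] = {}

    # species present per (subsite, start-year of each plot) for the
    # subsite-presence check
    subsite_start_pool: dict[tuple[str, int], set[str]] = {}
    for series in all_series:
        for year, covers in series.covers.items():
            key = (series.subsite, int(year))
            pool = subsite_start_pool.setdefault(key, set())
            pool.update(covers.index[covers > 0])

    for series in all_series:
        start, end = _endpoint_covers(series)
        colonisers, losses = detect_turnover(series)
        for taxon in colonisers:
            colonised[taxon] = colonised.get(taxon, 0) + 1
            pool = subsite_start_pool.get((series.subsite, series.start_year), set())
            if taxon in pool:
                subsite_present[taxon] = subsite_present.get(taxon, 0) + 1
        for taxon in losses:
            lost[taxon] = lost.get(taxon, 0) + 1
        occurring = start.index[(start > 0) | (end > 0)]
        for taxon in occurring:
            changes.setdefault(taxon, []).append(
                (end[taxon] - start[taxon]) / series.duration_years
            )

    taxa = sorted(set(colonised) | set(lost) | set(changes))
    _require_classes(taxa, class_table)
    rows = [
        {
            "taxon": t,
            "cls": class_table[t].value,
            "times_colonised": colonised.get(t, 0),
            "times_lost": lost.get(t, 0),
            "net_change": colonised.get(t, 0) - lost.get(t, 0),
            "mean_abundance_change": float(np.mean(changes[t])) if t in changes else 0.0,
            "n_plots_occurring": len(changes.get(t, [])),
            "n_colonisations_subsite_present": subsite_present.get(t, 0),
        }
        for t in taxa
    ]
    return pd.DataFrame(rows)


def coloniser_subsite_presence_fraction(species_summary: pd.DataFrame) -> float:
    """Fraction of colonisation events by species already present in the
    colonised plot's subsite at the start of that plot's monitoring."""
    total = species_summary["times_colonised"].sum()
    if total == 0:
        return float("nan")
    return float(
        species_summary["n_colonisations_subsite_present"].sum() / total
    )
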