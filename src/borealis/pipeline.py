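"""End-to-end orchestration: standardise → classify → indices → nulls → fits.

Each stage is a pure function of (inputs, config, seed) writing CSV outputs;
the CLI wraps these with a run manifest. ``headline_report`` aggregates the
summary statistics the analysis is usually quoted by: the fraction of plots
with boreal colonisations / abundance increases, mean BCI/BAI per subset,
null-model flag fractions, the coloniser subsite-presence fraction and the
end−start vs OLS-slope agreement for the abundance index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from borealis import classification, composition, indices, inference, nullmodels
from borealis.composition import PlotSeries


@dataclass
class StandardiseResult:
    covers: pd.DataFrame
    series: list[PlotSeries]


def standardise(
    records: pd.DataFrame,
    synonym_table: Mapping[str, str] | None = None,
    morphospecies_threshold: float = 10.0,
    min_duration: int = 5,
) -> StandardiseResult:
    """Record table → relative covers → filters → eligible plot series."""
    records = composition.filter_control(records)
    covers = composition.to_relative_cover(records)
    covers = composition.filter_morphospecies(covers, morphospecies_threshold)
    if synonym_table:
        covers = composition.aggregate_infraspecifics(covers, synonym_table)
    series = composition.build_plot_series(covers, min_duration=min_duration)
    return StandardiseResult(covers=covers, series=series)


def classify(
    zone_occurrence: pd.DataFrame,
    overrides: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    return classification.classify_table(zone_occurrence, overrides)


def compute_indices(
    series: Sequence[PlotSeries], class_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    lookup = classification.class_lookup(class_table)
    plots = indices.summarise_plots(series, lookup)
    species = indices.summarise_species(series, lookup)
    return plots, species


def run_null_models(
    series: Sequence[PlotSeries],
    class_table: pd.DataFrame,
    n_resamples: int = nullmodels.DEFAULT_N_RESAMPLES,
    seed: int = 0,
    mode: str = "permute",
) -> pd.DataFrame:
    lookup = classification.class_lookup(class_table)
    return nullmodels.null_table(
        series, lookup, n_resamples=n_resamples, seed=seed, mode=mode
    )


def headline_report(
    plot_summaries: pd.DataFrame,
    species_summaries: pd.DataFrame,
    null_results: pd.DataFrame | None = None,
    bai_method_correlation: float | None = None,
) -> dict[str, float]:
    """Aggregate headline statistics across all eligible plots."""
    subsets = inference.make_subsets(plot_summaries)
    pos_bci = subsets["positive_only_bci"]
    pos_bai = subsets["positive_only_bai"]
    n = len(plot_summaries)
    report = {
        "n_plots": n,
        "n_plots_boreal_colonised": len(pos_bci),
        "pct_plots_boreal_colonised": 100.0 * len(pos_bci) / n,
        "n_plots_boreal_abundance_increase": len(pos_bai),
        "pct_plots_boreal_abundance_increase": 100.0 * len(pos_bai) / n,
        "mean_bci_positive_only": float(pos_bci["bci"].mean()) if len(pos_bci) else float("nan"),
        "mean_bci_full_range": float(plot_summaries["bci"].mean()),
        "mean_bai_positive_only": float(pos_bai["bai"].mean()) if len(pos_bai) else float("nan"),
        "mean_bai_full_range": float(plot_summaries["bai"].mean()),
        "pct_colonisations_subsite_present": 100.0
        * indices.coloniser_subsite_presence_fraction(species_summaries),
    }
    if null_results is not None:
        fractions = nullmodels.flag_fraction(null_results)
        report["pct_plots_flagged_bci"] = 100.0 * float(fractions.get("BCI", float("nan")))
        report["pct_plots_flagged_bai"] = 100.0 * float(fractions.get("BAI", float("nan")))
    if bai_method_correlation is not None:
        report["pearson_bai_endstart_vs_slope"] = float(bai_method_correlation)
    return report


def bai_method_comparison(
    series: Sequence[PlotSeries], class_table: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """End−start BAI vs OLS-slope BAI per plot, with their Pearson r."""
    lookup = classification.class_lookup(class_table)
    rows = [
        {
            "plot": s.plot,
            "bai_endstart": indices.compute_bai(s, lookup),
            "bai_slope": indices.compute_bai_slope(s, lookup),
        }
        for s in series
    ]
    frame = pd.DataFrame(rows)
    r = inference.correlate_methods(frame["bai_endstart"], frame["bai_slope"])
    return frame, r


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path,
    config: Mapping,
    seeds: Mapping[str, int],
    inputs: Mapping[str, str],
    outputs: Mapping[str, str],
) -> None:
    """Run manifest: config snapshot, input digests, seeds, output inventory."""
    import borealis

    manifest = {
        "package_version": borealis.__version__,
        "config": dict(config),
        "seeds": dict(seeds),
        "inputs": {name: file_digest(p) for name, p in inputs.items()},
        "outputs": sorted(str(p) for p in outputs.values()),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
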