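import numpy as np
import pandas as pd
import pytest

from borealis.classification import SpeciesClass
from borealis.composition import PlotSeries
from borealis.simulate import SimulationConfig, generate_dataset


def make_series(start: dict, end: dict, *, start_year=2000, end_year=2010,
                middle: dict | None = None, middle_year=2005,
                plot="p1", subsite="s1", study_area="a1") -> PlotSeries:
    """Hand-built plot series; covers given as taxon → percent."""
    covers = {start_year: pd.Series(start, dtype=float),
              end_year: pd.Series(end, dtype=float)}
    if middle is not None:
        covers[middle_year] = pd.Series(middle, dtype=float)
    return PlotSeries(plot=plot, subsite=subsite, study_area=study_area,
                      covers=covers)


@pytest.fixture
def classes_simple():
    return {
        "Bor1": SpeciesClass.BOREAL,
        "Bor2": SpeciesClass.BOREAL,
        "Bt1": SpeciesClass.BOREAL_TUNDRA,
        "Bt2": SpeciesClass.BOREAL_TUNDRA,
        "Arc1": SpeciesClass.ARCTIC,
        "Ubi1": SpeciesClass.UBIQUITOUS,
        "Ubi2": SpeciesClass.UBIQUITOUS,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """Small but structurally complete synthetic dataset (shared, read-only)."""
    return generate_dataset(SimulationConfig(n_study_areas=8, seed=11))


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    from borealis import pipeline

    res = pipeline.standardise(small_dataset.records)
    classes = pipeline.classify(small_dataset.zone_occurrence)
    plots, species = pipeline.compute_indices(res.series, classes)
    return {
        "dataset": small_dataset,
        "covers": res.covers,
        "series": res.series,
        "classes": classes,
        "plots": plots,
        "species": species,
    }
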