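"""Compute borealisation indices for a small set of resurveyed plots.

Builds a toy long-format composition table (two surveys of two plots),
standardises it to relative cover, and prints each plot's colonisation
(BCI) and abundance (BAI) indices.
"""

import pandas as pd

from borealis import pipeline
from borealis.classification import SpeciesClass
from borealis.composition import RECORD_COLUMNS
from borealis.indices import summarise_plots

rows = [
    # study_area, subsite, plot, year, taxon, abundance, category, treatment
    ("Kilpis", "K1", "K1p1", 2000, "Betula nana",        12, "vascular", "control"),
    ("Kilpis", "K1", "K1p1", 2000, "Carex bigelowii",     6, "vascular", "control"),
    ("Kilpis", "K1", "K1p1", 2000, "rock",               10, "abiotic",  "control"),
    ("Kilpis", "K1", "K1p1", 2012, "Betula nana",        10, "vascular", "control"),
    ("Kilpis", "K1", "K1p1", 2012, "Carex bigelowii",     8, "vascular", "control"),
    ("Kilpis", "K1", "K1p1", 2012, "Empetrum nigrum",     6, "vascular", "control"),
    ("Kilpis", "K1", "K1p2", 2000, "Carex bigelowii",    10, "vascular", "control"),
    ("Kilpis", "K1", "K1p2", 2012, "Carex bigelowii",     7, "vascular", "control"),
    ("Kilpis", "K1", "K1p2", 2012, "Salix glauca",        3, "vascular", "control"),
]
records = pd.DataFrame(rows, columns=RECORD_COLUMNS)

classes = {
    "Betula nana": SpeciesClass.BOREAL_TUNDRA,
    "Carex bigelowii": SpeciesClass.BOREAL_TUNDRA,
    "Empetrum nigrum": SpeciesClass.UBIQUITOUS,
    "Salix glauca": SpeciesClass.BOREAL_TUNDRA,
}

result = pipeline.standardise(records)
plots = summarise_plots(result.series, classes)
print(plots[["plot", "n_colonisers", "n_boreal_colonisers", "bci", "bai"]]
      .to_string(index=False))
print()
print("BCI is the share of each plot's colonisers that are boreal-class")
print("(Boreal/Boreal-Tundra); BAI is the annual change in their summed")
print("relative cover, in % cover per year over the survey interval.")
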