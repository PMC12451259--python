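"""Assign biogeographic range classes from subzone occurrence categories.

A species is 'present' in a zone when reported frequent or scattered;
the class follows from presence in the boreal zone, the Low Arctic
(subzones D–E) and the High Arctic (A–C).
"""

import pandas as pd

from borealis.classification import classify_table

zones = pd.DataFrame([
    {"taxon": "Betula pubescens", "A": "absent", "B": "absent", "C": "absent",
     "D": "rare", "E": "rare", "Boreal": "frequent"},
    {"taxon": "Carex bigelowii", "A": "rare", "B": "uncertain", "C": "rare",
     "D": "frequent", "E": "frequent", "Boreal": "scattered"},
    {"taxon": "Papaver radicatum", "A": "frequent", "B": "frequent",
     "C": "scattered", "D": "scattered", "E": "rare", "Boreal": "absent"},
    {"taxon": "Empetrum nigrum", "A": "scattered", "B": "frequent",
     "C": "frequent", "D": "frequent", "E": "frequent", "Boreal": "frequent"},
])

table = classify_table(zones)
print(table.to_string(index=False))
print()
print("Boreal and Boreal-Tundra species form the lowercase-'boreal' set that")
print("the borealisation indices track; Arctic and Ubiquitous species do not.")
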