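# borealis

Quantifying the **borealisation** of tundra plant communities — the
encroachment and expansion of boreal-affiliated vascular plants into Arctic
and alpine tundra — from resurveys of permanently marked monitoring plots
nested as *study area > subsite > plot* (the ITEX-style design).

The package is aimed at vegetation ecologists working with long-format
community composition tables (one record per plot × survey year × taxon).
It provides, as an importable library with a thin CLI:

- **Standardisation** — conversion of point-intercept or cover abundances
  to relative cover (each plot-year sums to 100%), removal of abiotic and
  non-vascular records, a >10% morphospecies filter, infraspecific
  aggregation, and the resurvey eligibility rule (≥2 surveys ≥5 years apart).
- **Species classification** — each species is assigned a range class from
  its reported frequency in the five Arctic bioclimatic subzones (A–E) and
  the boreal zone: *Boreal* (boreal zone only), *Boreal-Tundra* (boreal +
  Low Arctic D–E, not High Arctic A–C), *Arctic* (tundra only) or
  *Ubiquitous* (all three). "boreal" in lowercase = Boreal ∪ Boreal-Tundra.
- **Borealisation indices** per plot, from the first and last survey only:

  ```
  BCI = (number of boreal colonising species) / (total colonising species)      ∈ [0, 1]
  BAI = (Σ boreal end cover − Σ boreal start cover) / duration (years)          [% / yr]
  ```

  where a *coloniser* is absent at the start and present at the end and a
  *loss* the reverse. Because covers sum to 100%, a boreal gain is exactly a
  non-boreal decline.
- **Null models** — BCI and BAI recomputed under 999 permutations of the
  class labels among all species recorded in a study area; plots outside
  the simulated mean ± 2 SD are flagged.
- **Driver models** — hierarchical regressions with a subsite random
  intercept: beta (logit) for positive-only BCI, binomial (logit) for
  full-range BCI as boreal colonisers out of total colonisers, Gaussian for
  BAI, and negative-binomial (log) species-level colonisation/loss count
  models, with trait filtering (≥5 records per species × trait, 5 SD
  outlier removal). Effects are "clear" when the 95% interval excludes zero.
- **A synthetic-data generator** emulating the full nested design with
  known ground truth, so every stage is testable without any data download.

## Worked example

`examples/01_indices_from_surveys.py` builds two plots surveyed in 2000 and
2012 and prints:

```
plot  n_colonisers  n_boreal_colonisers  bci       bai
K1p1             1                    0  0.0 -2.083333
K1p2             1                    1  1.0  0.000000
```

Plot `K1p1` gained one species (*Empetrum nigrum*, Ubiquitous), so its only
colonisation is non-boreal (BCI = 0) and its boreal relative cover fell by
2.08 % per year. Plot `K1p2` gained *Salix glauca* (Boreal-Tundra): its one
colonisation is boreal (BCI = 1) while boreal cover stayed at 100%
(BAI = 0) — BCI measures the borealness of turnover, not of the standing
community. The other examples cover classification, null envelopes,
community driver models and species/trait models; each prints the numbers
it computes and a line on how to read them.

The same stages are available as a shell pipeline:

```bash
borealis simulate --seed 1 --outdir run/
borealis standardise --outdir run/
borealis classify --outdir run/
borealis indices --outdir run/
borealis nullmodel --outdir run/ --seed 1
borealis report --outdir run/
```

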