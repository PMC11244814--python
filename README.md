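# cocount

Crossover-interference and synaptonemal-complex (SC) morphometry statistics
from cytological focus positions.

## What it is for

During meiotic prophase, crossover (CO) sites are visible as fluorescent
foci along the synaptonemal complex of each bivalent.  Two classic
statistics quantify **crossover interference** — the tendency of COs to be
more evenly spaced than a random (Poisson) placement:

* **Gamma shape `nu`**: inter-focus distances are fitted by maximum
  likelihood to a gamma distribution; `nu = 1` corresponds to no
  interference, larger `nu` to more even spacing.
* **Coefficient of coincidence (CoC)**: each bivalent is divided into equal
  intervals; for every pair of intervals, CoC = observed frequency of
  bivalents with a CO in both / expected frequency under independence
  (product of the marginals).  Plotted against inter-interval distance, the
  curve rises from ~0 to fluctuate around 1; the distance at which it first
  reaches **CoC = 0.5** ("interference distance") summarises interference
  strength.

Around these, the package computes the routine cytological summaries:
E-distribution of foci per bivalent (E0 = 0 is the "obligatory crossover"),
focus counts, SC segment numbers/lengths, CO density per micron, the linear
regression of focus count on SC length, and Student/Welch two-sample
comparisons.  A **gamma-renewal simulator** (stationary renewal process with
gamma gaps, optional obligate-CO conditioning and fragmented-SC mode)
generates cohorts with known truth, so the whole pipeline is testable
end-to-end.  It is intended for cytogeneticists analysing focus-position
tables and for methodologists who want a transparent, tested reference
implementation of the CoC procedure.

## Worked example

```python
from cocount import (SimConfig, simulate_cohort, fit_gamma_shape,
                     pooled_distances, coc_curve, summarize)

wt  = simulate_cohort(SimConfig(n_nuclei=150, shape=5.0, seed=11, genotype="wt-like"))
mut = simulate_cohort(SimConfig(n_nuclei=150, shape=2.8, seed=12, genotype="mut-like"))

for cohort in (wt, mut):
    fit = fit_gamma_shape(pooled_distances(cohort.tracks()), n_bootstrap=200, seed=1)
    counts = summarize(cohort, "focus_count")
    curve = coc_curve(cohort.tracks(ranks={1, 2}), group="ranks 1-2")
    print(f"{cohort.genotype}: nu = {fit.shape:.2f} +/- {fit.shape_uncertainty:.2f} "
          f"(n = {fit.n_spacings} spacings), "
          f"foci/nucleus = {counts.mean:.1f} +/- {counts.sd:.1f}, "
          f"interference distance (ranks 1-2) = {curve.interference_distance:.2f} um")
```

prints

```
wt-like: nu = 4.89 +/- 0.14 (n = 2296 spacings), foci/nucleus = 22.3 +/- 3.5, interference distance (ranks 1-2) = 0.94 um
mut-like: nu = 3.16 +/- 0.10 (n = 2280 spacings), foci/nucleus = 22.1 +/- 3.5, interference distance (ranks 1-2) = 0.74 um
```

The fitted shapes recover the generating interference levels (5.0 and 2.8,
up to sampling noise and a small finite-window bias, see
`docs/methods.md`); the weaker-interference cohort keeps the same CO count
but a shorter interference distance — closely spaced double COs become more
frequent while the total stays constant.

Measured data enter through a delimited table with columns
`nucleus_id, genotype, bivalent_rank, axis_length_um, segment_start_um,
segment_end_um, focus_position_um` (one row per focus; a sentinel row with
an empty focus cell represents a focus-free segment; decimal commas are
accepted).  Supplementary-workbook sheets can be ingested with
`read_supplementary_workbook(path, sheet_map)` and converted with an
explicit column mapping.

## Command line

```
cocount validate  --in focus.csv
cocount convert   --in focus.csv --out focus.tsv --delimiter '\t'
cocount fit-gamma --in focus.csv --units um --bootstrap 1000 --seed 1
cocount coc       --in focus.csv --group 1-2 --intervals auto --out curve.csv
cocount run       --config run.yaml      # full pipeline, manifest + CSV/JSON report
```

`cocount run` is fully deterministic: identical config + seed give
byte-identical numeric outputs, and the manifest (version, seed, config
hash) suffices to re-run any result.

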