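# canrec

Pedigree-based recombination mapping and crossover-interference analysis
for the domestic dog (*Canis lupus familiaris*), a species in which the
hotspot-positioning gene *PRDM9* is pseudogenized.

`canrec` re-implements, as a tested and reusable pipeline, the analysis
chain that turns crossover calls from genotyped parent–child duos into
sex-specific genetic maps and landscape statistics:

* **QC filters** for crossover-call tables — call-probability and
  blacklist filters, removal of clustered double crossovers that recur
  with shared boundary markers across meioses of one parent (a
  genotyping-error signature), and robust removal of outlier meioses
  whose genome-wide count falls outside
  median ± 4 · 1.4826 · MAD per sex.
* **Genetic-map construction** with the *effective number of meioses*:
  at each marker interval the denominator of the recombination fraction
  is the number of duos whose informative span (first to last
  heterozygous parental marker) covers the interval, correcting the
  map shortening that runs of homozygosity would otherwise cause in
  inbred pedigrees. Fractions become distances via Haldane's map
  function *d* = −½ ln(1 − 2*r*).
* **Landscape statistics** — telomeric share of recombination,
  rate-sorted (Lorenz-type) concentration curves with chromosome
  bootstrap, TSS/CpG-island-anchored rate profiles in 10-kb bins,
  CpG-island density thinning, and a marker-framework thinning
  procedure for matched-resolution comparisons between datasets.
* **Crossover interference** — full stationary-renewal likelihoods for
  the gamma model (chiasma inter-arrivals gamma(ν, 2ν), chromatid
  thinning by ½) and the two-pathway gamma-escape (Housworth–Stahl)
  model with escape proportion *p*, with bounded maximum likelihood,
  meiosis bootstrap confidence intervals, BIC model comparison, and
  age-stratified fits.
* **A synthetic meiosis simulator** that generates ground-truth
  crossovers from the same interference model (with male telomeric
  bias, informative-span censoring, ~100-kb call resolution, and
  labelled artifacts), so every downstream stage can be validated
  against known truth.

## Worked example

```python
from canrec.filters import FilterConfig, apply_all_filters
from canrec.gmap import build_map, effective_meioses, sex_average
from canrec.interference import fit, to_genetic_scale
from canrec.landscape import telomere_proportion
from canrec.simulate import SimConfig, simulate_dataset, marker_grid

chroms = {f"chr{i}": 60_000_000 for i in range(1, 9)}
cfg = SimConfig(
    n_meioses_per_sex=100,
    chrom_lengths=chroms,
    genetic_lengths={"female": {c: 65.0 for c in chroms},
                     "male": {c: 55.0 for c in chroms}},
    seed=42,
)
data = simulate_dataset(cfg)
calls, _ = apply_all_filters(data["calls"].drop(columns="artifact"),
                             FilterConfig())
edges = {c: marker_grid(cfg, c) for c in chroms}
maps = {}
for sex in ("female", "male"):
    spans = data["spans"][data["spans"]["duo_id"].str.startswith(sex[0])]
    prof = effective_meioses(spans, edges)
    maps[sex] = build_map(calls[calls["parent_sex"] == sex], prof, edges, sex)
print(f"female map: {maps['female'].total_cm():.1f} cM   "
      f"male map: {maps['male'].total_cm():.1f} cM")
print(f"male telomeric share (5 Mb): {telomere_proportion(maps['male']):.3f}")
res = fit(to_genetic_scale(calls[calls["parent_sex"] == "female"],
                           maps["female"]),
          model="gamma", bootstrap_n=100, seed=0)
print(f"female interference: nu = {res.nu:.2f} "
      f"(95% CI {res.nu_ci[0]:.2f}-{res.nu_ci[1]:.2f})")
```

prints

```
female map: 512.9 cM   male map: 444.2 cM
male telomeric share (5 Mb): 0.383
female interference: nu = 5.76 (95% CI 4.25-8.64)
```

The female map recovers the generating total of 8 × 65 = 520 cM to
within sampling error despite 10% informative-span censoring (this is
what the effective-meioses correction buys); 38% of male recombination
falls in the distal 5 Mb, reflecting the simulated male telomeric bias;
and the interference fit's confidence interval covers the generating
shape of 5.22.

The same stages are available from the shell:

```sh
canrec simulate --out sim/ --seed 42
canrec filter --calls sim/calls.tsv --out filtered.tsv
canrec build-map --calls filtered.tsv --spans sim/spans.tsv --sex female --out map.f.tsv
canrec telomere --map map.f.tsv
canrec interference --calls filtered.tsv --map map.f.tsv --sex female --model gamma
canrec run --config config.yaml --out results/
```

## Layout

```
src/canrec/
  simulate.py      synthetic meioses, censoring, artifact injection
  filters.py       crossover and marker QC
  gmap.py          Haldane, effective meioses, map construction
  landscape.py     telomere/concentration/profiles/thinning
  interference.py  gamma and gamma-escape likelihoods and fitting
  io.py, cli.py, pipeline.py
docs/methods.md    model and design notes
```
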