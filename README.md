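# ephygraze

Quantitative analysis of jellyfish-ephyra microcosm grazing experiments:
per-predator ingestion-rate inference from bottle counts,
biovolume-to-carbon conversion, bacterial-activity rate calculations,
and community-profile statistics for 16S/18S OTU tables — with a
synthetic-data generator so the whole pipeline can be exercised and
validated without field data.

The package is aimed at plankton ecologists running bottle-incubation
predation experiments (here: *Aurelia aurita* ephyrae feeding on a
natural microplankton assemblage in 2.2-L microcosms over 24 h) who
need a tested, reproducible path from raw counts, scintillation
readings, fluorescence series and OTU tables to the rates and
statistics such studies report.

## The models at the core

**Grazing inference (exponential bottle model).** Prey taxa in
predator-free control bottles grow exponentially, C(t) = C₀·e^{kt};
in predator treatments, C(t) = C₀·e^{(k−g)t}.  Per taxon:

- k = ln(C_control(t)/C₀)/t — apparent growth coefficient (d⁻¹), one
  estimate from the mean of the control replicates;
- g = k − ln(C_treatment(t)/C₀)/t — grazing coefficient (d⁻¹), one per
  treatment replicate;
- ⟨C⟩ = C₀·(e^{(k−g)t} − 1)/((k−g)·t) — time-averaged prey concentration;
- F = g·V/n — clearance (L ind⁻¹ d⁻¹) for bottle volume V and n predators;
- I = F·⟨C⟩ — ingestion (cells ind⁻¹ d⁻¹), reported as mean ± SD over
  treatment replicates; only taxa with mean I > 2·SD are reported.

A taxon present at T0 but absent from a T24 treatment bottle is set to
1 cell L⁻¹ so the logarithms stay defined.

**Carbon conversion.** Protist per-cell quotas from biovolume V (μm³):
pg C = 0.288·V^0.811 (diatoms) and pg C = 0.216·V^0.939 (other
protists); nanoplankton as spheres × 183 fg C μm⁻³; prokaryotes at
20 fg C cell⁻¹ (heterotrophs) and 200 fg C cell⁻¹ (*Synechococcus*).

**Activity assays.** Heterotrophic carbon production from ³H-leucine
DPM (1 Ci = 2.22×10¹² DPM, specific activity 52.9 Ci mmol⁻¹, 1.55 kg C
mol⁻¹ Leu × 2 isotope dilution) and leucine-aminopeptidase activity
from blank-corrected AMC fluorescence against an OLS calibration line,
including the ×10 dilution / seawater-subtraction correction for the
predator-associated consortium.

**Community statistics** (implemented from definitions, cross-checked
against scipy/scikit-bio in the test suite): Bray–Curtis similarity
100·(1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)), group-average (UPGMA) clustering with
Newick export, rank-based permutation ANOSIM
(R = (r̄_between − r̄_within)/(n(n−1)/4)), exact Mann–Whitney U, multiple
rarefaction, shared-OTU and <1 %-relative-abundance filters.

## Worked example

Simulate a noise-free microcosm experiment from the bundled 28-taxon
reference table and invert it:

```python
import pandas as pd
pd.set_option("display.float_format", lambda v: f"{v:.4f}")

from ephygraze import grazing, synthetic
from ephygraze.core_io import taxon_records_from_table1

truth = synthetic.table1_like_truth(count_subvolume=None)  # no counting noise
counts = synthetic.simulate_grazing_experiment(truth)
taxa = taxon_records_from_table1()
result = grazing.estimate_ingestion(counts, taxa, truth.design)
print(result.summary.loc["stenosemella_nivalis"])
```

prints

```
c0                    101.5000
k                       0.0000
g_mean                  1.9334
mean_conc              44.9033
clearance               0.8507
ingestion_cells        38.2000
ingestion_cells_sd      0.0000
ingestion_carbon        0.0651
ingestion_carbon_sd     0.0000
passed_filter             True
Name: stenosemella_nivalis, dtype: object
```

i.e. with a grazing coefficient of 1.93 d⁻¹ the tintinnid
*Stenosemella nivalis* is cleared at 0.85 L per ephyra per day, and each
ephyra ingests 38.2 cells (0.065 μg C) per day — the per-cell quota
follows from the non-diatom allometric equation at V = 14 137 μm³.

The same pipeline runs from the shell, including Poisson counting
noise, biomass conversion, simulated assays and the community stage:

```sh
ephygraze run --seed 7 --out-dir out/
```

which writes `counts.tsv`, `grazing.tsv`, `biomass.tsv`, `assays.tsv`,
`selectivity.tsv`, a `community/` directory (profiles, Bray–Curtis
matrix, UPGMA Newick tree, ANOSIM report) and a `manifest.json` with
input digests, seeds and stage timings.  Reruns with the same seed are
byte-identical.

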