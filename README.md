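# extruscan

Analysis toolkit for asking whether a perturbation of cohesin-mediated loop
extrusion affects a clustered gene locus in a **genomic-distance-biased**
way — and for turning that bias into an estimate of the change in cohesin
processivity.

## The scientific problem

The clustered protocadherin (cPcdh) locus comprises three tandem gene
clusters (α, β, γ; 58 variable isoform genes in mouse, spanning roughly a
megabase) whose promoters are activated by shared downstream super-enhancers
(HS5-1 for α, HS18–22 for β, HS5-1bL for γ). Because cohesin must extrude
chromatin past intervening DNA to bring an enhancer to a promoter, the
linear genomic distance `d` between them acts as a readout of cohesin
**processivity** λ — the mean genomic length extruded before release. The
extrusion-delivered contact intensity is modeled as

    C(d) = A · exp(−d / λ) + background(d)

so a perturbation that shortens processivity from λ_wt to λ_mut depresses
the contact (and hence cohesin occupancy and transcription) of a gene at
distance `d` by

    log2 FC(d) = −η · d · (1/λ_mut − 1/λ_wt) / ln 2 ,

a straight line in `d`. Fitting that line across the 58 genes in any of
three modalities — RNA-seq fold changes, cohesin (RAD21) ChIP enrichment
fold changes, or enhancer-anchored contact (virtual-4C) fold changes — and
inverting the slope recovers λ_mut. Because the β cluster sits farther from
its enhancers than the γ cluster, reduced processivity downregulates β genes
more than γ genes.

The package implements the full analysis pipeline:

* **`extruscan.simulate`** — synthetic cPcdh-like locus with background
  genome, negative-binomial replicate counts, ChIP peak tables, symmetric
  contact matrices with planted domain structure, and 4C fragment tracks,
  all driven by an explicit (λ_wt, λ_mut) ground truth.
* **`extruscan.quantify`** — FPKM/RPM normalization, fold changes with
  Welch t-tests and Benjamini–Hochberg adjustment, DEG calling
  (|log2FC| > 0.5, padj < 0.05, strict), peak enrichment and per-gene
  virtual-4C contact values.
* **`extruscan.scan`** — genome-binned Poisson enrichment scan: 1-Mb bins,
  maximum-likelihood rate λ = mean hits per bin, log-space upper-tail
  probabilities (stable far below 1e-300) and fold enrichments k/λ — the
  Manhattan statistic.
* **`extruscan.distance`** — promoter-to-enhancer distance pairing, OLS
  distance-trend fit, processivity inversion, per-cluster contrasts.
* **`extruscan.topology`** — cis-depth normalization, Knight–Ruiz
  balancing, directionality index, Gaussian-mixture HMM state decoding,
  TAD assembly with run-length (≥3 bins) and posterior-confidence (median
  ≥0.99) filters, differential contact maps.
* **`extruscan.pipeline` / `extruscan.cli`** — reproducible orchestration
  with config hashing and per-stage seeds.

## Worked example

```sh
extruscan run-all --outdir run --seed 1234
```

or equivalently in Python:

```python
from extruscan import pipeline
report = pipeline.run_pipeline(pipeline.load_config(), "run")
```

With the default configuration (58 cluster genes + 2000 background genes on
a 100-Mb chromosome, λ_wt = 400 kb, λ_mut = 150 kb, 3 replicates per
condition, 20 M reads, 10-kb contact matrices at 5 M cis contacts) the
report contains:

```
quantify : 30 downregulated DEGs, 6 upregulated
scan     : top 1-Mb bin chrS:60,000,000 with k = 26 hits,
           86.7-fold enrichment, -log10 p = 40.3   <- the planted locus bin
distance : recovered lambda_mut  RNA 153.0 kb | ChIP 149.7 kb | contact 157.7 kb
           (planted value 150 kb; fitted slopes -5.8e-06 to -6.0e-06 per bp
            against the model value -6.01e-06 per bp)
topology : 10 TADs per condition, boundaries at the planted positions
```

Reading the output: the Poisson scan flags exactly the locus bin as the
genome's only enrichment of downregulated genes; the distance-trend slope
is the model line `−Δ(1/λ)/ln 2`; inverting it recovers the planted mutant
processivity within a few percent from each data modality independently;
and the domain caller reproduces the planted boundary set. Every output is
bit-reproducible for a fixed config and seed (the report carries the config
hash and derived per-stage seeds).

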