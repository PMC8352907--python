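# hicks

Comparative 3D-genome analysis and Ks-based whole-genome-duplication dating
for desk-scale genomics, with seeded synthetic data so every stage is
verifiable against planted ground truth.

`hicks` is aimed at researchers analysing Hi-C experiments on small
(plant-sized) genomes — typically a treatment/control comparison — together
with the comparative-genomics and multi-omics analyses that accompany such
studies. It covers the full path from valid read pairs to biological calls:

- **Contact maps** — binning 4DN-style `.pairs` text into symmetric count
  matrices, low-coverage masking, iterative correction (ICE), and the map
  resolution rule (smallest bin size at which 80% of bins collect ≥ 1000
  contacts).
- **Distance decay** — per-separation contact frequency curves and the
  interaction decay exponent (IDE): the slope of an OLS fit of
  log₁₀ *f* vs log₁₀ *d*. Per-separation z-score matrices and their
  difference (the subtractive matrix) compare two conditions.
- **A/B compartments** — PC1 of the Pearson correlation matrix of the
  distance-normalised (observed/expected) cis matrix, sign-oriented per
  chromosome by gene density; bins with positive PC1 are A (active,
  gene-dense), negative are B. Differential compartments list the bins whose
  label flips between conditions (default 100-kb bins).
- **TADs** — insulation scores at 40-kb bins (log₂ of the mean contact in a
  sliding square over its chromosomal mean), boundaries as strong insulation
  minima, domains between them, and differential insulation by sliding-window
  Pearson correlation (window 11, step 1, r < 0.6 in all overlapping
  windows).
- **Significant interactions** — an equal-occupancy distance-decay prior
  (L = 20 kb, U = 2 Mb, 200 strata, 2 passes, isotonic smoothing) with
  binomial upper-tail P values and Benjamini–Hochberg q values on raw 10-kb
  counts; a call is significant iff P < 0.01, q < 0.01 and count > 2. Trans
  pairs are tested against a uniform prior. Homoeolog interaction fractions
  summarise how much of each chromosome's trans contact mass hits its
  duplication partner.
- **FIREs** — frequently interacting regions: bins whose local (15–200 kb)
  cis contact sum is significantly elevated genome-wide, with Fisher-exact
  enrichment against compartments and TAD boundaries.
- **Ks / WGD dating** — Nei–Gojobori (NG86) counting of synonymous and
  nonsynonymous sites and differences per aligned codon pair with
  Jukes–Cantor correction K = −¾ ln(1 − 4p/3); Gaussian-KDE Ks
  distributions with peak detection; duplication ages by T = Ks / (2r) with
  r = 8×10⁻⁹ synonymous substitutions per site per year.
- **Omics networks** — transcript–metabolite Pearson edges (|r| > 0.8) and
  strict candidate gates (r² > 0.96).
- **Synthetic data** — seeded generators planting decay exponents,
  checkerboard compartments, TAD blocks, per-bin biases, homoeolog boosts,
  condition differences, synonymous-only codon divergence, and correlated
  omics modules, returning the ground truth alongside.

## Worked example

Recover a planted decay exponent from half a million simulated contacts:

```python
from hicks import contact, core, decay, synth

cs = core.ChromSizes([("chr1", 20_000_000)])
spec = synth.SyntheticSpec(cs, 40_000, decay_exponent=-0.85,
                           cis_depth=500_000, seed=1)
records, _ = synth.simulate_hic(spec)
matrix = contact.bin_pairs(records, spec.bins())
balanced = contact.ice_balance(contact.mask_low_coverage(matrix),
                               max_iter=2000, tol=1e-10)
fit = decay.fit_ide(decay.decay_curve(balanced), bin_size=40_000)
print(f"fitted IDE = {fit.exponent:.4f} +/- {fit.stderr:.4f}")
```

prints

```
fitted IDE = -0.8537 +/- 0.0029
```

the planted exponent −0.85 recovered to 0.004 from Poisson-sampled pairs —
comparable to the genome-wide IDEs near −0.85…−0.91 reported for plant
chromatin. The `examples/` directory holds one short narrative script per
capability (contact maps, IDE, compartments, TADs, interactions, FIREs, Ks
dating, omics networks); each prints the numbers it computes and what they
mean. Dating example:

```
worked example: S = 100, N = 200, Sd = 5, pS = 0.050, Ks = 0.0517, Ka = 0.0000
Ks distribution over 200 pairs: peak at Ks = 0.076
dated duplication age: 4.77 million years (T = Ks / 2r, r = 8e-9)
```

A thin command-line interface exposes each stage as a subcommand
(`hicks simulate | bin | balance | resolution | decay | compartments | tads |
diff-insulation | interactions | fires | homoeolog | ks | date | correlate`),
writing standard text formats (bedGraph, BED, BEDPE, COO triples, TSV) plus a
JSON manifest of parameters per output directory.

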