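# fruitmethyl

Whole-genome bisulfite sequencing (WGBS) analysis of DNA methylation
dynamics during fleshy-fruit development — the kind of study that compares
young (YF), expanding (EF) and mature (MF) fruit methylomes, finds CG/CHG
methylation falling while CHH methylation rises, and asks whether
hyper-methylated CHH regions near genes track expression changes.
`fruitmethyl` re-implements that analysis chain as a tested, reusable
Python library with a CLI, plus a synthetic bisulfite-count simulator so
the whole pipeline can be exercised and validated at desk scale, without
hundred-gigabyte read archives.

Intended users: plant epigenomics researchers and methods developers who
want a transparent, seed-reproducible reference implementation of the
standard windowed-DMR analysis, or a planted-truth simulator to benchmark
their own callers against.

## What it computes

* **Cytosine contexts** — every C on both strands classified CG / CHG /
  CHH (H ∈ {A,T,C}) from the reference; contexts spanning N or a contig
  end are dropped.
* **Conversion rate and methylcytosines** — the bisulfite non-conversion
  rate is pooled over an unmethylated spike-in (lambda-style control):
  conversion = 1 − Σ#C/Σ(#C+#T). A site is a methylcytosine when its
  methylated count is implausible under non-conversion noise alone:
  one-sided exact binomial P(X ≥ c | n, p₀ = 1 − conversion) < α (0.05).
* **Weighted methylation level** of any site set: Σ#C / Σ(#C+#T).
* **DMRs** — 200-bp fixed windows, counts pooled per context; a window is
  a DMR when |Δlevel| exceeds the context threshold (CG > 0.4, CHG > 0.2,
  CHH > 0.1), two-sided Fisher's exact p < 0.05, and Benjamini–Hochberg
  q < 0.05 (computed per context). Plus shared-DMR direction concordance
  between stage comparisons and genomic DMR coverage.
* **Metagene profiles** — weighted level over the 2-kb upstream flank,
  proportionally scaled gene/TE body, and 2-kb downstream flank,
  strand-aware; and DMR-midpoint density around TSS/TES versus a
  length-matched random-placement permutation background.
* **Association** — DEGs thresholded from supplied statistics
  (|log₂FC| > 2, adjusted p < 0.05), DMGs as genes whose body ± 2 kb
  intersects a DMR, one-sided hypergeometric DEG∩DMG enrichment, and
  per-candidate-gene promoter DMR reports.
* **Simulator** — per-cytosine Beta(mean, κ=20) methylation levels shared
  across stages through a latent quantile, Poisson ~40× coverage, ~1%
  non-conversion, planted 200-bp differential windows applied identically
  to both later stages, an unmethylated control contig, and expression
  statistics coupled to the planted DMGs. Everything is a deterministic
  function of one seed.

## Worked example

```bash
fruitmethyl demo --outdir demo_out --seed 7
```

prints

```
EF_vs_YF  CHH recall=1.000  fdp=0.495
MF_vs_YF  CHH recall=1.000  fdp=0.184
report    demo_out/report.json
```

and `report.json` holds, among other things, the per-stage genome-wide
weighted levels:

| stage | CG | CHG | CHH |
|-------|------|------|------|
| YF | 0.603 | 0.406 | 0.075 |
| EF | 0.509 | 0.342 | 0.176 |
| MF | 0.480 | 0.323 | 0.168 |

CG and CHG fall with development while CHH roughly doubles and then eases
off — the pattern the simulator's stage means encode. Every planted CHH
window is recovered (recall 1.0) in both comparisons. The demo's
"fdp" is measured against the *planted* windows only; under this default
configuration the CHH baseline also drifts genome-wide between stages, so
additional, genuinely differential windows are called and counted against
it (see `docs/methods.md`). The calibrated recovery/null studies — flat
baselines, planted shifts only — are what the test suite and acceptance
script evaluate.

Each intermediate file the demo writes can also be produced by the
standalone subcommands (`simulate`, `callmc`, `level`, `dmr`, `metaplot`,
`dmrdensity`, `associate`); run any of them with `--help`.

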