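# haplostat

Population-genetic analysis of mitochondrial haplotype data, built for
single-locus phylogeography: the kind of study that sequences a COI barcode
fragment from hundreds of individuals across geographic regions and asks
where the populations came from, how structured they are, and when they
expanded.

The package was designed around circum-Antarctic benthic invertebrate
datasets (hundreds of ~554-bp COI sequences from regions such as East
Antarctica, the Antarctic Peninsula, the Weddell Sea and outlying islands),
but every component is generic.

## What it computes

| stage | statistics |
|---|---|
| `seq_io` | FASTA alignment + metadata ingestion, haplotype collapsing (wildcard or strict ambiguity policy), pairwise count/p-distance matrices |
| `diversity` | n, haplotype count k, private haplotypes PH and PH/k, Nei's haplotype diversity H, segregating sites S, mean pairwise difference Π, nucleotide diversity π, Watterson's θ |
| `neutrality` | Tajima's D; Fu's Fs via the Ewens sampling distribution (log-space Stirling numbers); left-tail p-values from constant-size coalescent simulation |
| `mismatch` | observed mismatch distributions; sudden-expansion and infinite-island spatial-expansion expected curves; bounded multi-start SSD fitting; Harpending's raggedness; parametric-bootstrap goodness of fit and percentile CIs |
| `structure` | distance-based AMOVA (2- and 3-level), Φ-statistics, pairwise Φ\_ST with permutation p-values, sequential-Bonferroni correction |
| `network` | statistical-parsimony haplotype network with a 95% connection limit, inferred intermediate haplotypes, ancestral-haplotype designation, GraphML export |
| `dating` | molecular-clock conversion T = τ/(2µk) with the 10-fold short-term rate correction; effective sizes from θ = 2Nu |
| `coalsim` | coalescent simulator (constant size, sudden expansion, exponential growth, island migration; infinite-sites or HKY-like finite sites) and a four-region study-like dataset generator |

The core inferential model is the sudden-expansion mismatch distribution.
With equilibrium distribution F̂ᵢ(θ) = θⁱ/(θ+1)ⁱ⁺¹, the expected frequency of
sequence pairs differing at i sites, τ mutational time units after a
population jumped from scaled size θ₀ to θ₁, is

    Fᵢ(τ,θ₀,θ₁) = F̂ᵢ(θ₁) + e^(−τ(θ₁+1)/θ₁) Σⱼ≤ᵢ [τ^(i−j)/(i−j)!] (F̂ⱼ(θ₀) − F̂ⱼ(θ₁))

The fitted τ converts to years as T = τ/(2µk) for a k-bp fragment evolving at
µ substitutions/site/year.

## Worked example

```python
from haplostat import (
    make_study_like_dataset, summarize, fit_expansion, bootstrap_gof,
    observed_mismatch, expansion_time,
)

ds = make_study_like_dataset(seed=1)           # 364 x 554 bp, four regions
print(summarize(ds.alignment, ds.metadata, grouping="region").round(3))
```

```text
          n   k    PH  PH_ratio      H    S     Pi     pi  theta_w
region
EA      227  49  43.0     0.878  0.948   63  3.938  0.007   10.500
AI       13   8   1.0     0.125  0.859   14  4.051  0.007    4.511
AP       95  29  29.0     1.000  0.937   42  3.375  0.006    8.194
WS       29   4   3.0     0.750  0.414    3  0.448  0.001    0.764
all     364  83   NaN       NaN  0.969  107  5.316  0.010   16.530
```

The old-expansion regions (EA, AP) carry high haplotype diversity; the
recently expanded WS holds a fraction of it — the regional contrast the
generator is built to emulate.  Dating a fitted expansion age:

```python
group_of = dict(zip(ds.metadata["sample_id"], ds.metadata["region"]))
ea = ds.alignment.subset([i for i in ds.alignment.ids if group_of[i] == "EA"])
fit = bootstrap_gof(fit_expansion(observed_mismatch(ea)), (ea.n, ea.L), B=500, seed=7)
et = expansion_time(fit.tau, mu=2e-8, L=554, correction_factor=10)
print(f"tau={fit.tau:.2f}  p_SSD={fit.p_SSD:.2f}  T={et.T_corrected_kyr:.1f} kyr BP")
# tau=4.74  p_SSD=0.18  T=21.4 kyr BP
```

A non-significant SSD p-value means the expansion model cannot be rejected;
the corrected time places the expansion just after the Last Glacial Maximum.
The `examples/` directory holds one short script per capability, and the
`haplostat` command exposes the same stages as subcommands
(`simulate`, `diversity`, `neutrality`, `mismatch`, `structure`, `network`,
`date`, `run-all`).

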