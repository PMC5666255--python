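"""Per-region diversity indices for the study-like dataset.

Prints a diversity summary: sample size n, haplotype count k, private
haplotypes PH and their proportion, Nei's haplotype diversity H, segregating
sites S, mean pairwise difference Pi, per-site nucleotide diversity pi, and
Watterson's theta.
"""

from haplostat import make_study_like_dataset, summarize

ds = make_study_like_dataset(seed=42)
df = summarize(ds.alignment, ds.metadata, grouping="region")
print(df.round(5))
# Expect the old-expansion regions (EA, AP) to carry high H and Pi, the
# recently expanded WS to carry roughly half that, and the island founders
# (AI) to hold a subset of continental variation.
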