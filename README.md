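# regwas

Regulatory-element-centric aggregation of GWAS summary statistics.

Most common risk variants for complex traits are noncoding: they act by
perturbing regulatory elements (REs) — promoters and enhancers marked
by H3K27ac — that can sit hundreds of kilobases from the gene they
control. Conventional gene-level GWAS aggregation collapses SNP
associations over *gene bodies* and so misses or misassigns this
signal. `regwas` instead aggregates SNP associations over
*tissue-active regulatory elements*, maps element-level statistics to
candidate target genes through RE-to-gene links, and carries the
resulting gene ranking through preranked gene-set enrichment up to the
prioritization of "nexus" transcription factors: TFs that are both
targets of risk variation (via super-enhancers) and mediators of it
(via their binding sites in other risk elements).

It is intended for statistical geneticists and regulatory genomicists
with GWAS summary statistics, a tissue H3K27ac peak set, and an
RE-to-gene catalog in hand.

## The model

For an element containing m SNPs with two-sided P-values p_j, invert
each to a 1-df chi-square z_j² and form the mean statistic

    T = (1/m) Σ_j z_j²,      m·T | H₀ ~ Σ_i λ_i χ²₁,

where λ_1 ≥ … ≥ λ_m are the eigenvalues of the SNP correlation matrix
R estimated from a reference LD panel. LD enters the null exactly: m
duplicated SNPs collapse to the single-SNP test, m independent SNPs
reduce to χ²_m/m. The weighted-chi-square tail is evaluated by
characteristic-function inversion (Imhof's formula, tolerance 1e-10)
with a moment-matched scaled-χ² fallback in extreme tails.

Each gene then receives the minimum P over its linked, tested elements
(a Šidák min-P adjustment is reported alongside), significance is
called at the Bonferroni threshold α/n_genes, and genes are ranked by
−log₁₀(P), ties broken by −log₁₀(P) × mean tissue expression. The
ranked list feeds a preranked GSEA engine (weighted running-sum ES,
set-permutation null, NES, FDR q, leading edge) used for pathway sets,
for a super-enhancer-associated TF set, and for TF target-gene
("cistrome") sets, whose intersection defines nexus TFs
(leading-edge membership ∧ nominal P < 0.05 ∧ q < 0.25).

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

Simulate a small study with one causal regulatory element (element
index 5, noncentrality 7) and run the whole pipeline:

```sh
regwas simulate --outdir demo --seed 17 --n-genes 40 --n-res 60 \
    --n-samples 2000 --causal "5:7"
regwas all --config demo/config.yaml
```

`demo/truth.json` records the implanted signal: the causal element
`RE0005` links two genes, `G0005` and `G0006`. The gene table
(`demo/results/genes.tsv`) recovers exactly those:

```
GENE    BEST_RE  NRES  RE_CLASS  P             ADJ_P
G0005   RE0005   2     promoter  1.22960e-105  2.45920e-105
G0006   RE0005   2     promoter  1.22960e-105  2.45920e-105
G0020   RE0020   2     promoter  1.46231e-02   2.90324e-02
```

Both target genes inherit the causal element's P-value (one element,
two genes — many-to-many links are preserved), are the only entries in
`significant_genes.txt`, and `compare.tsv` shows what the RE-centric
view adds over a conventional gene-body scan of the same data:

```
metric                      value
bootstrap_p_re_lower        7.17928e-02
n_significant_re_scan       2
n_significant_gene_body     0
n_novel_genes_ld_bins       2
```

The gene-body scan finds nothing (the causal SNPs sit in a regulatory
element, not in an exon), and the LD-bin analysis reports both genes
as candidates not reachable by the conventional scan. Downstream,
`se_tf_gsea.tsv` shows the super-enhancer TF set led by the two causal
genes (`LEADING_EDGE  G0006;G0005`), and `nexus.tsv` applies the nexus
predicate to every TF.

Every stage writes a JSON manifest (input SHA-256 hashes, parameters,
seed, version); re-running any stage with the same config and seed is
byte-identical.

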