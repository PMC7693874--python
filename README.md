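# plastiqtl

Mapping the genetic basis of growth plasticity in large haploid crosses.

When the same set of genetically fixed segregants (e.g. yeast haploids from a
biparental cross) is phenotyped for growth across many environments, the
*change* of each genotype's phenotype across environments — its plasticity —
is itself a heritable trait. `plastiqtl` quantifies that plasticity, maps the
loci underlying it with a kinship-aware linear mixed model, and asks whether
those loci coincide with hub loci of environment-dependent epistatic
networks: loci whose pairwise interactions switch on and off between
environments, so their marginal additive effect in an environment tracks the
number of active interaction partners there. A bundled simulator generates
haploid crosses with exactly this G×G×E architecture and known truth.

Intended users: quantitative geneticists analyzing multi-environment growth
(or other) phenotypes in experimental crosses, and method developers who need
a reproducible G×G×E testbed.

## The measures and models

For the n × E phenotype matrix **Y** (segregants × environments):

**Overall plasticity** (one score per segregant)

- *PCA1, PCA2* — scores on the first two principal components of the
  column-centered **Y**;
- *VAR* — across-environment sample variance of a segregant's row;
- *FWR* — Finlay–Wilkinson regression: y_ij = Pc_i + b_i·E_j + ε, with the
  environment index E_j the environment mean minus the grand mean; the slope
  b_i is the plasticity score (b̄ = 1 over complete data).

**Specific plasticity** (one score per segregant per environment pair; with
E environments there are C(E,2) pairs and 2·C(E,2) measures)

- *DIFF(e1,e2)* = y_i,e1 − y_i,e2;
- *DOT(e1,e2)* = X_i·Y_i after standardizing each column to mean 0 and unit
  sum of squares, so that Σ_i DOT_i equals the Pearson correlation r of the
  two environments.

**Genetics.** Heritability comes from the polygenic mixed model
y = μ + g + e, g ~ N(0, σ²_g·G), e ~ N(0, σ²_e·I), with G the
allele-frequency-weighted IBS kinship matrix (haploid dosages coded 0/2);
h² = σ²_g/(σ²_g + σ²_e) by REML. Association scans add a marker fixed effect
(y = μ + xβ + g + e) and Wald-test β = 0 with variance components fixed from
the null fit, solved in O(n) per marker through the eigenbasis of G.
Significance uses α/Me, where Me is the effective number of independent
markers from the Li–Ji composition of the per-chromosome LD eigen-spectra.
Conditional scans add peak lead markers as covariates and iterate to find
additional signals. A mapped peak *overlaps* a hub locus when its lead
marker is within 50 kb of the hub **and** in LD with it at r² > 0.5.

## Worked example

Simulate the default study conditions — 1000 segregants, 16 chromosomes ×
125 markers (300 cM / 750 kb each, yeast-like recombination density), 18
environments, polygenic background h² = 0.3, and one epistatic hub with 8
radial partners each active in half of the environments — then run the whole
workflow:

```yaml
# run.yaml
outdir: run_out
seed: 11
measures: overall
sim:
  preset: desk
  hub: true
```

```sh
plastiqtl run --config run.yaml
```

prints (abridged):

```
- effective markers Me = 497.0
- significance cutoff = 0.000101
- overall: 4 scans, 3 unique significant QTL
- trait_mean: 18 scans, 3 unique significant QTL
- hub effect-vs-interactors correlation R = 0.98 (p = 2.1e-12)

## Heritability (overall measures and trait means)
phenotype   category     h2
env01     trait_mean  0.363
...
PCA1         overall  0.871
PCA2         overall  0.432
VAR          overall  0.139
FWR          overall  0.115

## Hub detection frequency
locus            overall  trait_mean  total
hub_chr01_m0063        4          16     20
```

Reading this: LD compresses the 2000 markers to Me ≈ 497 effective tests, so
genome-wide significance is p < 0.05/497 ≈ 1.0×10⁻⁴. Each single-environment
growth trait is moderately heritable (h² ≈ 0.3–0.6, the polygenic background
plus the hub's environment-specific effect). The hub locus is detected by
all four overall-plasticity scans and by 16 of the 18 per-environment trait
scans, and its per-environment additive effect correlates R = 0.98 with the
number of epistatically interacting partners active in each environment —
the simulated G×G×E mechanism, recovered by one-dimensional association
scans of plasticity phenotypes.

Individual steps are also available as `plastiqtl simulate | plasticity |
h2 | scan | overlap | hubprofile`; every input and output is plain
tab-delimited text (PLINK .bed/.bim/.fam is accepted read-only for
genotypes). See `docs/methods.md` for the models, defaults and caveats.

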