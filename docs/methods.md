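# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what its synthetic-data experiments can and cannot
show about real data.

## The inheritance model

*Auanema rhodensis* is trioecious: XO males, XX females and XX
hermaphrodites coexist. Gametogenesis treats the X chromosome unusually,
and the simulator (`auanema.inheritance`) encodes these transmission rules
directly:

| parent, gamete | X content | recombination |
| --- | --- | --- |
| male sperm | always the single paternal X (haplo-X) | none (hemizygous) |
| hermaphrodite sperm | both maternal X haplotypes intact (diplo-X) | off |
| hermaphrodite oocyte | nullo-X with prob 1 − `p_herm_oocyte_haploX` | off |
| female oocyte | one X (nullo-X with prob `p_female_oocyte_nulloX`) | Haldane |

Autosomes always undergo standard meiosis with Haldane (Poisson,
no-interference) crossovers: on a chromosome spanning *L* cM the crossover
count is Poisson(*L*/100) with uniform positions and a random starting
strand. Haldane was chosen because no interference model is established
for this species; default chromosome length is 50 cM.

Zygote sexing: 1 X → male; 2 X → hermaphrodite with probability
`p_herm_given_xx` (default 0.5 — brood composition varies widely between
mothers and cross types, so a neutral default is used and the parameter is
exposed), else female. Nullo-X zygotes are inviable and redrawn. Triplo-X
zygotes (haplo-X oocyte × diplo-X sperm) have no described fate and are
redrawn by default; a configurable alternative keeps them as females with
one X dropped at random, for sensitivity analysis.

`p_herm_oocyte_haploX` and `p_female_oocyte_nulloX` default to 0.05. The
qualitative facts they encode — selfed broods are almost entirely XX, rare
male self-progeny exist, female oocytes are almost always haplo-X — are
established, but the rates are not quantified anywhere; 0.05 is a
placeholder for "rare" and both are exposed parameters.

A consequence of the rules worth stating: under selfing, diplo-X sperm
meeting nullo-X oocytes yield only XX progeny, so the X genotype of a
selfing lineage is copied intact every generation — X heterozygosity is
*conserved*, not decayed, under selfing. This is the mechanism behind the
chromosome-wide X heterozygosity of hermaphrodite-derived mapping panels.

### F2-derived line panels

`simulate_f2_panel` mirrors the mapping-panel design: homozygous founder
strains (APS4 × APS6), an F1 hermaphrodite selfing to produce F2 founders,
then per-line single-individual selfing for g ~ Uniform{3..10} generations.
Each expansion generation is independently replaced, with probability
`p_female_generation` (default 0.05), by a female × sibling-male cross;
only these female-mediated generations let the X recombine and lose
heterozygosity. The default 0.05 places simulated X homozygosity near the
~10% scale attributed to female recombination during population
expansions; it is a free parameter of the simulator, not a measured rate.

The sibling male needed for a female-mediated generation cannot arise
inside the default gamete rules (diplo-X sperm never yield 1-X zygotes in
selfing), yet rare self-progeny males are real. The simulator therefore
constructs him directly as the product of a rare haplo-X oocyte meeting a
nullo-X sperm: selfed autosomal meiosis products plus one maternal X
haplotype chosen at random.

Each line is genotyped as one sampled individual (lines were founded from
single hermaphrodites and sequenced from their dauer descendants); genotype
calls are masked independently at `missing_rate`.

## Linkage mapping

Two-point recombination fractions use the standard co-dominant F2
intercross likelihood: gamete haplotype frequencies ((1−r)/2, r/2, r/2,
(1−r)/2), zygote 3×3 joint probabilities by convolution of two independent
gametes (the double-heterozygote cell is the phase mixture
((1−r)² + r²)/2). `estimate_rf_f2` maximizes the log-likelihood on
[0, 0.5] by bounded scalar optimization at tolerance 1e−6;
LOD = log₁₀ L(r̂) − log₁₀ L(0.5). For all-pairs computation on ~1,000
markers, `pairwise_rf` evaluates the likelihood on an r grid (step 0.0025)
fully vectorized; grid resolution is irrelevant at the LOD thresholds used
for grouping, and the single-pair API remains available where precision
matters.

Linkage groups are connected components of the graph with edges at
lod ≥ `lod_min` and r̂ ≤ `rf_max`. The published map used LOD 20 at its
own data scale; for simulated panels of n = 95 lines the package's
reference threshold is `lod_min = 10`, scaled to the information content
of the smaller likelihood (cross-chromosome LOD is ≈ 0 and within-
chromosome adjacent-marker LOD is ≥ 20 at this n, so the grouping is
insensitive to the exact value over a wide band).

The F2 likelihood assumes a pure intercross. Panels selfed past F2 have
fewer heterozygotes than the model expects, which inflates r̂ slightly but
leaves grouping intact; linkage-group recovery experiments therefore use
g = 0 panels, and distance estimates on expanded panels should be read as
map-scale approximations — the same caveat that applied to the original
map, where post-F2 recombination levels were unknown.

Kosambi distances d = 25·ln((1+2r)/(1−2r)) cM; greedy seriation (seed at
the highest-LOD pair, extend by nearest r̂) orders markers within groups —
ordering quality is deliberately not a headline result, so no TSP-style
refinement is attempted. The segregation-distortion scan is a per-marker
chi-square goodness-of-fit against 1:2:1 (or a selfing-decayed expectation
((1−h)/2, h, (1−h)/2), h = 0.5^(g+1), when g is known).

Duplicate-marker filtering keeps the first marker of each identical
genotype-vector class; markers missing in ≥ 50% of lines are removed
(boundary inclusive).

## Orthology and Nigon elements

Reciprocal best hits: per query, the max-bitscore subject (ties: lower
e-value, then lexicographic subject id) after discarding hits with
e-value > 0.01; a pair is kept iff mutual. Families are connected
components of the union RBH graph over ≥ 3 species; a component with two
genes of one species is repaired by removing its lowest-weight edge
(weight = min of the two directional bitscores) until consistent — the
minimal deterministic policy, since no conflict-resolution procedure is
described for pooling pairwise RBH sets.

Element inference formalizes what is classically done by inspecting
painted synteny plots. For families f, g define

    agreement(f, g) = #{species where both present, same chromosome}
                      / #{species where both present},

computed only when the denominator is ≥ 3 (two species cannot separate
shared ancestry from lineage-specific fusion). Families are joined at
agreement ≥ α and elements are the connected components with
≥ `min_element_size` (20) families, which suppresses components seeded by
spurious RBH pairs.

**Choice of α = 0.7.** With five genomes the denominator is 3–5, so
attainable agreement values are coarse (thirds, quarters, fifths). Two
elements that co-occur on one chromosome in *two* species — exactly the
situation of NX and NN, which share the X in both *C. elegans* and
*H. contortus* — produce cross-element pairs with agreement 2/5, but also
2/3 for pairs observed together in only three species. A threshold of 0.6
admits those 2/3 pairs and fuses NX with NN; 0.7 excludes 2/3 while
retaining every within-element pair (agreement 1, or ≥ 3/4 for pairs
spanning a fission boundary such as the two NA chunks split between LG3
and LG4). Hence the default α = 0.7, with the threshold exposed.

Painting orders a species' element-assigned genes by position, smooths
labels by a sliding majority vote over `window_genes` (10) consecutive
assigned genes (ties keep the gene's own label when it is among the
winners), and merges runs into blocks spanning gene extents (not
intergenic midpoints — simpler and directly testable). A chromosome is
called a fusion of every element holding ≥ `min_fusion_fraction` (0.1) of
its assigned genes. Chromosomes with fewer assigned genes than the window
get a single simple-majority block flagged low-confidence.

## Synthetic genomes

`gen_species_set` plants seven ancestral elements of `genes_per_element`
(300) genes each and lays out five genomes according to the published
mosaic (the `fig9_history` fixture). An element present on k chromosomes
of a species is cut into k contiguous chunks of its ancestral order —
reproducing the observed sub-element segments (a1/a2, c1/c2/c3, n1/n2) —
allocated proportionally to per-chromosome fractions (equal by default;
the real proportions are not quantified). Each chromosome is shuffled by
Poisson(`shuffle_intensity`, default 3) segment inversions of 5–30% of its
genes (intra-chromosomal rearrangement is rapid in these nematodes, and
element inference must be position-free); genes drop out independently at
`ortholog_dropout` (0.1). Hit tables give the true ortholog a N(500, 50)
bitscore and inject N(300, 50) decoys at `spurious_hit_rate` (0.02);
e-values are 2^(−bitscore) since only ranks matter downstream. Gene
coordinates are uniform 10 kb spacings — the generator makes no attempt at
realistic gene-length or intergenic distributions, e-value physics, or
lineage-specific gene families, so recovery results speak to the
*co-linkage geometry* of the method, not to its robustness against real
annotation noise.

## Expression and sex ratios

Counts are "corrected by library size" by total-count scaling to the
median library, then log2(x + 1); no TMM/size-factor estimation is
attempted (model-based differential expression is out of scope; a plain
threshold filter on externally computed statistics, defaults |log2FC| ≥ 2
and adjusted p < 0.01, is provided for completeness). The X:autosome test
draws 600 genes per autosome and 600 X genes without replacement
(per-autosome sampling; the alternative pooled-autosome reading is
configurable), compares all chromosomes by Kruskal-Wallis and each
autosome-X pair by Mann-Whitney, using mean per-gene expression across the
selected samples as the observation unit. The synthetic counts are
negative-binomial (gamma-Poisson, dispersion 0.1) with log-normal gene
means and a multiplicative `x_factor` planted on X genes.

The Mann-Whitney U statistic counts, over all cross pairs,
#{y < x} + ½·#{y = x}. The exact two-sided p doubles the smaller tail of
the *tie-free* null distribution of U (dynamic program over partial rank
assignments), capping at 1 — ties contribute half-counts to the observed
statistic but the null is the classical one. This is the convention of R's
`wilcox.test` exact path and is what reproduces U = 67, p = 0.001563 on
the 8-vs-9 RNAi sex-ratio comparison despite its tied pair. `auto` mode
switches to the tie-corrected, continuity-corrected normal approximation
when n₁·n₂ > 400, keeping the exact DP (O(n₁·n₂·(n₁+n₂))) cheap.

Female ratio = females/(females + hermaphrodites); males are excluded by
the definition of the measurement. The per-condition aggregate is computed
from mean counts, meanF/(meanF + meanH) — this is what the published
aggregate rows contain (0.43/0.22), and it differs from the mean of
per-mother ratios (0.454 for the RNAi arm) whenever brood sizes vary; the
report carries both, labeled.

## Problem sizes and determinism

All pipeline experiments run at desk scale by choice: 95 lines × ~1,050
markers for mapping (the published panel's scale), 300 genes/element ×
7 elements × 5 genomes (~2,100 ortholog families) for element recovery,
600-gene draws for expression. Every stochastic component threads one
seeded `numpy` generator; identical seeds give byte-identical outputs.
`scripts/acceptance.py --seed N --out results/acceptance.json` re-runs the
two simulation-backed headline quantities (X-heterozygosity percentage and
linkage-group count) from scratch.

## Known limitations

* Rates of rare gamete classes (haplo-X hermaphrodite oocytes, nullo-X
  female oocytes) and the hermaphrodite-vs-female decision probability are
  free parameters, not measurements.
* Maternal-age effects on brood sex ratio and dauer developmental logic
  are not modeled.
* The F2 likelihood ignores post-F2 selfing when estimating r; distances
  on expanded panels are approximate.
* Sub-element segment identity (which chunk of a fissioned element went
  where) is tracked only implicitly through the synthetic truth table, not
  inferred.
* Element inference needs ≥ 3 shared species per family pair; clades with
  two sequenced genomes cannot be analyzed this way.
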