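# Methods

## Setting and assumptions

The package analyses diploid samples for which parental genomes are
unavailable, so neither RNA-side SNPs nor methylation reads can be phased
to a physical allele. Both callers are therefore built around statistics
that are invariant to which allele is labelled which: max/min allele
allocation on the expression side, and an unlabelled two-component mixture
on the methylation side. The study design emulated throughout is three
genetically distinct colonies × two reproductive statuses (reproductive,
sterile), with replicate RNA samples per (colony, status) group and one
pooled bisulfite sample per group.

## ASE caller

Per (SNP, sample) row the input is a reference/alternative read-count pair.
Processing order: gene annotation (1-based inclusive containment; SNPs in
overlapping genes are duplicated per gene, strand ignored) → filtering
(coverage ≥ `min_coverage` = 10; both counts > 0, since a zero count
suggests a homozygote mis-called as heterozygous; gene assignment present)
→ allocation (allele 1 = max, allele 2 = min; ties put the reference count
on allele 1 — symmetric, so orientation invariance is preserved) →
aggregation over SNPs and replicates into one representative sample per
(gene, colony, status) → eligibility (gene present in ≥ 2 colonies for at
least one status).

**Test.** For each eligible gene, a binomial-family logit GLM of
(allele1, allele2) totals on status + colony with **sum-to-zero** coding,
so the intercept is the gene's grand-mean allelic log-odds rather than a
reference-cell mean; the per-gene significance is the test of that
intercept against 0. (Which coefficient defines the per-gene call was
genuinely open; the intercept is chosen because the call is a per-gene bias
call, not a status contrast — the status effect is still adjusted for.)
Overdispersion is handled quasibinomially: φ = Pearson χ²/df_resid, floored
at 1 (no under-dispersion credit, standard quasi-likelihood practice),
standard errors scaled by √φ, and a t reference with df_resid (= 2 in the
full 6-group design). The implementation reproduces R's
`glm(..., family = quasibinomial)` intercept p-values except where the
φ ≥ 1 floor binds. Degenerate inputs: a saturated design is refit
intercept-only; a single group, or all reads on one allele, falls back to
an exact two-sided binomial test of the pooled counts, flagged in the
output.

With only 2 residual df and a dispersion estimated from those same 2 df,
the t test is *conservative*, not exact: its empirical size at nominal 0.05
is well below 0.05 on overdispersed null data. The test suite asserts level
control (type-I ≤ nominal within Monte-Carlo error), not exactness.

**Call.** BH correction runs over the tested-gene set only. A gene is ASE
for a status when q < 0.05 *and* its mean allelic proportion across that
status's colonies exceeds 0.65. The proportion filter is not cosmetic:
allocation folds the null distribution of the proportion about 0.5, so a
balanced gene's expected observed proportion is ≈ 0.5 + E|p̂ − 0.5|. At
coverage 30 this is ≈ 0.57 for binomial counts but rises to ≈ 0.64 at
beta-binomial intra-class correlation ρ = 0.1 — at that overdispersion the
0.65 threshold no longer separates null from signal, and a large fraction
of balanced genes is called. Conclusions from these thresholds are
trustworthy only when residual overdispersion is mild; this is a property
of the procedure itself, faithfully reproduced here, and quantified by the
`ase_null_call_rate` the acceptance script reports.

## AMR caller

Windows of `window_size` = 3 consecutive CpGs slide by one CpG along each
allowed chromosome; windows with any CpG under `min_cpg_coverage` = 10
reads are skipped and counted. Reads partially covering a window
contribute only their observed CpGs to both models.

Single-profile model: per-CpG ML rate p̂ⱼ = mⱼ/nⱼ, clamped to
[10⁻⁶, 1 − 10⁻⁶]; log-likelihood is the product-Bernoulli over observed
states. Two-profile model: a mixture of two per-CpG Bernoulli profiles
with mixing fixed at 0.5 (diploid alleles; a `free_mixing` option exists
but is off by default, since pooled samples still contribute each allele
at ~50%), fit by EM (E-step read responsibilities; M-step
responsibility-weighted rates; convergence when the LL gain < 10⁻⁸ or 500
iterations). Restarts (default 5) keep the best LL; the first restart
starts both profiles at the single-profile optimum — an EM fixed point —
which guarantees the nesting invariant ℓ₂ ≥ ℓ₁ by construction; the second
splits that profile ±0.3; the rest are random from the seeded generator.

The statistic 2(ℓ₂ − ℓ₁) is referred to χ² with w degrees of freedom (the
w added profile parameters). The regularity conditions of that reference
fail for mixtures, and empirically the reference is strongly conservative
(window-level type-I ≈ 0.001–0.005 at nominal 0.05 in simulation), which
costs power but protects the false-positive rate. Window p-values are
BH-corrected; significant windows (q < 0.05) overlapping or abutting in
CpG-index space merge into regions spanning the first to last member CpG
(reported 0-based half-open). A region carries its minimum member p and
minimum member q; q is deliberately not recomputed at region level, since
the FDR statement is per window. Regions are annotated exon (any exon
overlap of an assigned gene) / intron (inside a gene body, no exon
overlap) / no-annotation. This module implements the described two-model
window comparison; equivalence with any external AMR tool's internals is
not claimed.

Gene-level weighted methylation is Σmᵢ/Σ(mᵢ+uᵢ) over the gene's CpGs; a
gene is methylated when the level strictly exceeds the conversion error
rate (0.05).

## Synthetic data

`simulate_ase_counts` draws per-(SNP, sample) coverage Poisson around
`coverage_mean` (or fixed), allele-1 counts binomially at the gene's truth
π, optionally overdispersed via a Beta(π(1−ρ)/ρ, (1−ρ)π̄/ρ) mixing
distribution (ρ = intra-class correlation). The ref/alt orientation of each
SNP locus is randomized once per locus — consistent across samples, as for
a real variant — and independently of the truly biased allele, so
downstream allocation, not column labels, must recover the bias. Gene
coordinates tile 18 linkage-group-like chromosomes, with matching GFF3
output. `simulate_epireads` places each region's CpGs on its own contig;
AMR regions draw each read from profile A with probability `mixing` (0.5)
else profile B; non-AMR regions share profile A; every state flips with
probability `conversion_error` (0.05). Reads span the whole region by
default (a uniform end-trim mode provides partial reads); the cytosine
report is exactly the column sums of the epireads.

What the generators do **not** emulate: reference-mapping bias, SNP-calling
errors, allele-specific splicing, linked SNPs sharing haplotypes, read
sampling autocorrelation along the genome, or between-individual variation
within a pooled bisulfite sample. Passing recovery tests therefore shows
the estimators recover the assumed generative structure, not that real
libraries satisfy that structure.

## Benchmark and measurement choices

* ASE recovery: one synthetic study of 150 signal genes (π = 0.85, ρ = 0)
  and 300 balanced genes (π = 0.5, ρ = 0.1), coverage 30, 3 SNPs/gene,
  analysed jointly so BH sees the realistic mixed p-value pool. Sensitivity
  is the fraction of signal genes called for either status; the null call
  rate is the analogous fraction of balanced genes (see the ASE section for
  why ρ = 0.1 drives that rate far above 0.05).
* AMR recovery: 10 replicate datasets of 40 regions (8 true AMRs, profiles
  0.9 vs 0.1, 15 reads per CpG, 12 CpGs per region). Pooling 80 true and
  320 null regions keeps the Monte-Carlo error of the recall estimate
  small: the dominant failure mode is an unlucky ~11:4 allele split among a
  region's 15 reads, which weakens every window of that region at once, so
  single-dataset recall is noticeably noisy. Window-level null type-I error
  uses a per-region cluster standard error because windows within a region
  share reads.
* All benchmark randomness derives from one seed; reruns are bit-identical.

## Numerical and tie-breaking details

Probability clamp 10⁻⁶ in both window models; BH is a single shared routine
used by every module; allocation ties (ref = alt) give allele 1 the
reference count; Dunn post hoc uses the tie-corrected pooled rank variance
with two-sided normal p-values; the overlap universe is always
caller-declared (expressed genes for ASE lists, methylated genes for ASM
lists, the joint universe for combined lists) — an overlap p-value without
a declared universe is meaningless. Empty filter results are empty outputs,
not errors; a chromosome with fewer CpGs than the window yields no windows
with a warning.

## Known limitations

The quasibinomial t test with 2 residual df is coarse: p-values cannot be
very small, and BH behaviour on such pools is dominated by the proportion
filter. The χ²_w reference for the mixture LR is conservative. Region
recall degrades when the realized allele mixture in a region is far from
50:50. The ASE caller is naive to allele-specific alternative splicing;
the AMR caller does not phase epireads with SNPs (unreliable from
bisulfite data) and treats pooled samples as one diploid-like mixture.
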