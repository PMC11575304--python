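# Methods

`metacrispr` implements CRISPR spacer amplicon typing ("metaCRISPR typing"):
personal identification from skin, saliva and touched-object microbiomes by
sequencing the spacers of *Streptococcus* CRISPR3 and CRISPR1 arrays with
fusion primers that anneal inside the conserved repeat. This note documents
the models, the parameters that matter, and the design decisions taken where
the procedure was genuinely open.

## Spacer extraction

Each paired-end read is processed through:

1. **Quality trimming** (modified Mott). Each base contributes
   `error_limit − 10^(−Q/10)` and the contiguous window with the maximal
   cumulative score is kept. The default `error_limit = 0.01` is the
   Q20-equivalent: bases below Q20 score negative, so a read whose bases are
   all below Q20 trims to empty and the pair is labelled `quality_fail`.
   Tie-break: smaller window start, then longer window. The implementation
   is a single Kadane-style scan; the test suite certifies it against an
   exhaustive O(n²) search over all windows on 1,000 random reads.
2. **Repeat-primer removal.** The locus part of the fusion primer must be a
   prefix of the mate (R1: forward part, R2: reverse part) with at most
   `max_mismatch = 2` substitutions; indels are not modelled — the primer
   regions are short and high quality on this chemistry, and alignment would
   add complexity for negligible yield. Because spacer amplicons (66–88 bp)
   are shorter than the reads, each mate reads through into the opposite
   primer; the read-through is cut at the leftmost ≥ 12 nt seed match
   (≤ 1 mismatch) into the opposite primer's reverse complement.
3. **Pair reconciliation.** The two primer-trimmed inserts (R2 reverse
   complemented) must agree: equal sequences pass, a single mismatch is
   resolved toward the base with the higher Phred score (R1 wins ties), and
   anything else — including a length difference — is a `pair_conflict`.
4. **Artifact classification.** Primer dimers leave inserts that are
   fragments of the primers themselves. An insert is flagged
   `primer_dimer_rev_tail` when its reverse complement matches the 5' end of
   an Illumina overhang tail (≥ 15 nt, ≤ 1 mismatch) and
   `primer_dimer_fwd` when it is a substring of a fusion primer under the
   same tolerance. These two patterns are exactly the artifact inserts that
   dominate no-template controls at this short insert size.
5. **Length filter.** Spacers are kept iff 20 ≤ length ≤ 40 nt (inclusive —
   "shorter than 20 / longer than 40 are removed" forces inclusivity).
   Inserts containing N are discarded (`quality_fail`): ASV identity is
   exact-sequence. Spacers are reported in forward-primer orientation; no
   lexicographic canonicalization is applied since each locus is amplified
   in one orientation.

Every pair receives exactly one label, so the per-label report always sums
to the input pair count. Identical read pairs are processed once and
weighted by their multiplicity, which makes deep amplicon samples cheap
without changing any result.

## ASV denoising

Full error-rate learning in the style of dedicated denoisers is deliberately
not re-implemented. The discriminative signal of spacer typing is the
presence and abundance of exact 20–40 nt sequences, so a simpler
abundance-ratio rule suffices: within each sample, a sequence `c` is merged
into the most abundant sequence `p` with `hamming(c, p) ≤ 1` and
`count(p)/count(c) ≥ min_fold` (default 32). Children are processed in
ascending abundance and merging repeats to a fixed point; ties between
candidate parents prefer the higher count, then the lexicographically
smaller sequence, making the result independent of input order. Merging is
per-sample, matching per-sample inference defaults of standard denoisers.
Chimera removal is omitted: 20–40 nt inserts are below any meaningful
bimera-detection scale. Per-sample totals are conserved; all-zero columns
are dropped in a separate step so the conservation property is observable.

## qPCR quantification and the copy-number QC gate

The standard curve is an OLS fit of Cq on log10(copies/µL) over a plasmid
dilution series (10⁶ down to 10² copies/µL); `r²` is the squared Pearson
correlation and efficiency is `(10^(−1/slope) − 1) × 100` (slope
−log₂10 ≈ −3.3219 ⇔ 100%). Unknowns invert the curve; duplicate Cq values
are averaged on the **copies (linear) scale** — the protocol is silent on
this point, and the linear-scale mean was chosen and flagged. A reaction
with no amplification in any replicate is ND, which is representationally
distinct from a measured value below the LOQ. The LOQ defaults to the
lowest standard (100 copies/µL): every sub-100 value in the bundled copy
table carries the below-LOQ footnote, confirming the convention.

Numeric summaries treat ND as 0 **with the row kept in the denominator**.
This was reverse-engineered from the published table: the printed skin
CRISPR1 mean (4,720.9 copies/µL) equals the column sum divided by 22, not
21, and the tests verify all four printed means exactly under this rule.

The QC gate passes a sample iff it has ≥ 100 spacer copies/µL (ND fails) —
the minimal spacer load below which typing results are noise-dominated, as
reproduced by the simulator (below).

## Identity calling, ROC and group statistics

Bray–Curtis dissimilarity `1 − 2Σmin(uᵢ,vᵢ)/(Σu + Σv)` is computed on raw
ASV counts. Two all-zero profiles are **defined** as maximally dissimilar
(1.0, logged): heavily diluted samples can lose every read, and declaring
two empty profiles identical would be a false identity signal.

Identity is the strict rule `distance < 0.8 → same_source`; equality is
`different_source` (false positives are the costly error in forensics).
ROC analysis sweeps the threshold over all distinct observed distances plus
boundary points, with same-individual pairs as positives and household
pairs among the negatives; AUC is the trapezoid over the curve, which
equals the pairwise-comparison probability with half credit for ties (the
suite certifies this against brute-force pair counting on all inputs with
≤ 8 values per class, and against scikit-learn). The "best" threshold
maximizes sensitivity + specificity (Youden); ties prefer the higher
specificity, then the lower threshold, for determinism.

Skin-vs-saliva distances are partitioned into within-individual,
within-household and between-household groups, compared by Kruskal–Wallis
and pairwise Mann–Whitney with multiply-and-cap Bonferroni. The MWU p-value
is an exact permutation enumeration when both groups have ≤ 8 members
(handling ties by construction) and the tie-corrected normal approximation
above. Spearman correlations use average ranks and are reported only when
p < 0.05, mirroring the gating convention of the assay's QC analyses.
Shannon diversity defaults to log base 2 (a common amplicon convention; the
base is configurable and flagged because upstream pipelines differ).
Z-scoring uses the population (n) denominator; binarization is `count > 0`.

## STR profile comparison

Profiles are genotype tables over the 21 autosomal GlobalFiler loci.
Electropherogram peak calling, RFU thresholds and stutter filtering are
upstream; this module consumes allele sets. A locus is **correct** only
when the called set equals the reference set exactly — consistent with the
published per-sample rates (12/21 → 57%) — otherwise it is classified
dropout_only / dropin_only / dropout_and_dropin / no_call. Homozygotes are
single-allele sets; a heterozygote called over a homozygous reference
sharing the allele is dropin_only. Percentages round half-up (57.14 → 57,
85.71 → 86), which reproduces every printed rate.

## The simulator

The generator emulates the study conditions that make low-biomass typing
fragile; its defaults are the conditions of the dilution experiment.

| parameter | default | meaning |
|---|---|---|
| `read_depth` | 20,000 | sequencer budget for spacer signal |
| `template_volume_ul` | 1.0 µL | template pipetted per reaction |
| `per_base_error_rate` | 0.001 | substitution errors fixed in the molecule |
| `dimer_reads_expected` | 15,000 | Poisson mean of primer-dimer reads |
| `contaminant_rate` | 0.001 | contaminant fraction of read depth |
| `pcr_dispersion_sigma` | 0.6 | lognormal σ of per-unit amplification |
| `background_mass` | 100 | dimer/background competition (mass units) |
| `household_shared_fraction` | 0.3 | spacer support shared within household |
| `saliva_richness` | 60 | distinct spacers per saliva pool |
| `skin_subsample_fraction` | 0.6 | share of the saliva support on skin |

Mechanisms, in order:

* Template molecules entering the reaction are Poisson(copies/µL × volume):
  the physical model of pipetting a dilution.
* Amplification units are template × spacer pairs for cloned arrays (a
  plasmid carries the whole array) and one spacer draw from the pool
  frequencies per template for individuals. Each unit receives a lognormal
  amplification factor — the simplest dispersion mechanism that makes
  replicate profiles diverge when built from few templates.
* Signal reads are Binomial(`read_depth`, `M_s/(M_s + background_mass)`)
  where `M_s` is total amplified spacer mass, then multinomial over units.
  This competitive yield is the load-bearing choice: with a constant signal
  depth, a 4-spacer profile can never exceed Bray–Curtis 0.75 against a
  uniform reference, and the empirically observed reproducibility collapse
  would be unreproducible. `background_mass = 100` places the half-yield
  point at ~10² spacer copies, the same window where reproducibility is
  lost and the QC gate sits; at 10⁰ copies the signal yield collapses to a
  few percent of reads, matching the near-total read loss seen in diluted
  libraries.
* Dimer reads are Poisson(`dimer_reads_expected`) and are constructed so
  their post-trim inserts equal the two artifact sequences that the
  classifier targets; they dominate no-template controls. Contaminants are
  drawn from a global per-locus pool shared across samples of an
  experiment, as environmental contamination recurs across libraries.
* Substitution errors are applied once per template-derived pair and shared
  by both mates (PCR errors fixed in the molecule), with Q20 at error
  positions and Q35 elsewhere. Independent per-mate sequencer errors are
  not modelled: the reconciliation rule would repair them, and the
  denoiser's target error class is the molecule-level one.

Households share `round(shared_fraction × richness)` spacers of support;
frequencies are Dirichlet(1) per individual (support is shared, abundances
are not). Skin pools are random subsets of the saliva support —
spacers are conserved in saliva and shared between saliva and skin, which
is why saliva serves as the reference sample type.

**What the simulator does not emulate:** learned read-length/quality
profiles, indel errors, chimeras, index hopping, and the qPCR fluorescence
process (Cq values for quantification tests come from an ideal curve plus
optional Gaussian noise). Passing tests therefore certify the pipeline's
logic and the copy-number dependence of reproducibility, not performance on
real MiSeq noise.

## Problem sizes and determinism

Every random operation takes an explicit integer seed; child generators are
derived by hashing (seed, labels), so identical seed + configuration gives
byte-identical FASTQ output. The dilution acceptance check uses 20 seeded
replicate experiments of 4 levels × 3 replicates at the default depth; the
noiseless array-recovery checks use depths of 1,000–2,000 reads, which is
ample for a 4–12 spacer array.

## Known limitations

* The abundance-ratio denoiser is keyed to the one reported denoising
  parameter (min fold 32) and does not reproduce quality-aware error
  models; exact numerical agreement with DADA2 is out of scope.
* The proprietary trimmer used upstream in the original workflow is
  approximated by modified-Mott at limit 0.01; the exact trim mode of that
  tool is not public.
* Published AUCs and optimal thresholds for the real cohort depend on the
  deposited reads and are not reproducible from synthetic data; the ROC
  machinery is instead certified by oracle equivalence.
* Copies/µL are treated as concentrations of the DNA extract (not of the
  original sample volume); the source tables do not state the reference
  volume.
* Object (keyboard) swab summaries have no printed reference means, so no
  target is asserted for them.
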