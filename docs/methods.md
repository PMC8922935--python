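# Methods

## Motif model and scanning policy

A CCCH zinc finger is matched as C-X{a}-C-X{b}-C-X3-H with spacer1
a ∈ [4,17] and spacer2 b ∈ [4,6] by default. Published descriptions of the
family use both 4–17 and 5–17 as the lower spacer1 bound; the scanner
defaults to the broader [4,17] (which subsumes the narrower reading) and
ships [5,17] as the `NARROW_SPACER1` preset. Because motif occurrences can
overlap, a counting convention is required: the scanner is greedy and
left-to-right — at each cysteine the match with the smallest spacer1, then
smallest spacer2, wins, and scanning resumes after the matched histidine.
This makes motif counts, tandem-finger pairing and census statistics
deterministic and reproducible; it is validated against an independent
set-based formulation (exhaustive enumeration of all (start, a, b) matches
followed by the same consume-through-H policy) on 1000 random sequences.
Ambiguity codes (X/B/Z/J/U/O) are legal spacer residues but never match C
or H — the conservative reading.

Tandem zinc fingers require a (7|8, 5) finger, a linker of exactly 16 or
18 residues, and a (5, 4) finger; pairing is greedy and no finger is used
twice. "Arginine-rich" is not quantified in the family literature, so the
upstream test defaults to ≥ 6 R within the 30 residues before the first
finger (truncated at the N-terminus); both knobs are exposed and echoed in
run configs. Architecture is a strict hierarchy: ANK-RR-TZF (TZF + RR +
externally annotated ANK) > RR-TZF > TZF > CCCH. Auxiliary domains
(KH/RRM/RING/ANK) are consumed from an annotation table, never predicted.

## Physicochemical properties

GRAVY is the mean Kyte–Doolittle hydropathy; MW uses average isotopic
residue masses plus one water, reported in kDa to 3 decimals; pI is the
bisection root of the Henderson–Hasselbalch net charge with the Bjellqvist
pKa set (termini + D, E, C, Y, H, K, R); the instability index is
(10/L)·Σ DIWV dipeptide weights. These are the conventions of the standard
web tools for protein characterization, and the implementation delegates
to Biopython's ProtParam, which encodes exactly these constants; tests
check the kernels against independently embedded constants and a fine-grid
(ΔpH = 1e-4) charge scan. Because the precise pKa table behind any given
web-tool version is unverifiable, per-protein pI values are treated as
approximate; family-level summaries instead use the packaged 53-row
published property table (`zfamkit/data/barley_ccch_table1.tsv`), whose
transcription was verified against the published summary statements (mean
length 482.2 aa, mean GRAVY −0.704, pI range 5.13–10.15, MW range
14.407–160.373 kDa, 45/53 nuclear).

Positional naming orders genes by natural chromosome order then start
coordinate; coordinate ties are broken by gene id with a warning, so the
mapping is total and order-invariant.

## Duplication, selection, dating

Tandem duplication is read strictly: same chromosome and zero intervening
annotated genes (adjacent ranks over the *full* annotation, not just
family members). Because the criterion is sometimes stated as "≤ 1
intervening gene", `max_intervening` (default 0) accommodates that
convention. Selection calls use Ka/Ks with an optional epsilon band around
1 (default 0, exact reading); Ks = 0 yields an explicit "undefined" rather
than an exception. Divergence time is T = Ks/(2λ)×10⁻⁶ My with
λ = 6.5×10⁻⁹ substitutions/site/year, the grass-lineage clock rate.
Ka/Ks values are inputs; codon-alignment estimation is out of scope.

## Genotypes and diversity

Accessions of a selfing crop are treated as inbred lines: genotypes are
haploid 0/1/missing, and heterozygous diploid VCF calls are recoded as
missing on input. Site filters follow the strict printed thresholds: alt
frequency strictly inside (0.05, 0.95), missing fraction strictly below
0.1, biallelic; samples with missing rate above 0.1 are dropped. Missing
fractions are computed as exact count ratios so boundary cases (e.g. 2/20)
compare correctly against the thresholds.

Per-site diversity is the unbiased estimator π_site = n/(n−1)·(1−p²−q²),
identical to the mean pairwise difference at the site; sites with fewer
than two calls are excluded. π is reported on the per-SNP-site average
scale (mean of π_site over retained sites, per gene and overall): published
per-population values of ~0.1 are far too large to be per-bp over gene
lengths and are consistent with averaging over the SNP set. The bottleneck
statistic is 100·(π_wild − π_dom)/π_wild.

Haplotypes are complete-case per gene: a sample with any missing call at
the gene's sites is dropped (and counted), the rest are grouped into
unique 0/1 strings with per-population counts, ordered by total count then
lexicographically. A dominant haplotype must be carried by strictly more
than half of a population's retained samples; at most one can qualify.

## Median-joining networks

The network starts from the ε-relaxed minimum spanning network (edge kept
iff its Hamming distance is within ε of the minimax path distance, i.e.
the union of minimum spanning trees at ε = 0). Consensus (coordinate-wise
majority) vectors of triplets with at least two linked pairs are candidate
medians; the insertion that most reduces the minimum spanning length of
the node set is accepted, ties broken lexicographically, until no median
helps; inferred medians whose removal leaves the spanning length unchanged
are pruned. The reported `total_length` is the spanning length of the node
set — the quantity the algorithm minimizes — while the displayed graph may
carry equally-short alternative edges. ε defaults to 0 and all tie-breaks
are lexicographic, so networks are reproducible.

## PCA

Missing calls are mean-imputed per site; each site is centered by its alt
frequency p and scaled by √(p(1−p)) (the allele-frequency normalization of
standard population-structure PCA); monomorphic sites are dropped.
Components come from the SVD of the scaled matrix, explained variance is
the eigenvalue share in percent, and each component's first nonzero
loading is made positive so signs are deterministic.

## Expression

Fold changes are linear-scale ratios (stress + c)/(control + c) with
pseudocount c = 0.01 FPKM for stability at zero controls (surfaced in the
config); induction/repression thresholds are strict at 2.0 and 0.5. When
replicate columns are supplied, replicate means feed the ratio and a
two-sided Welch t-test is reported alongside. log₂(FPKM+1) is used for
display matrices; 2^(−ΔΔCt) for qRT-PCR.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the pipeline needs,
not real sequences. Proteome backgrounds are drawn over the full alphabet
and whole proteins are rejection-sampled until the greedy scan reproduces
the planted truth exactly, so recovery tests are binary; spacer and linker
residues exclude C/H so each planted finger admits exactly one parse. The
default study sizes mirror the motivating study (53 proteins; 51 wild and
95 landrace accessions; 7 chromosomes).

The bottleneck is founder-pool subsampling, not coalescent simulation:
per gene, wild samples copy one of K_w = 20 founder haplotypes
(Bernoulli(½) alleles per site) and landrace samples copy from a fixed
subset of K_l = 3. Expected per-site diversity for a pool of K equally
likely founders is E[π] ≈ ½(1 − 1/K), so the defaults target a reduction
of 1 − (1 − 1/3)/(1 − 1/20) ≈ 29.8% — the ~30% published for this family —
with realized values scattering a few points per seed. Defaults add a
0.005/site mutation rate and 2% missingness so filters have work to do.
Per-gene SNP density is not published; 10 sites/gene is a free choice
exposed on the generator's parameter object. Not emulated: linkage disequilibrium decay,
realistic site-frequency spectra, read-level noise, indels. Passing tests
therefore demonstrate correctness of the estimators and the direction and
magnitude of the bottleneck under the model, not population-genetic
realism.

## Problem sizes and determinism

The default end-to-end run uses 53 synthetic proteins, a 56-gene catalog
with 6 planted pairs, 146 samples × 300 SNPs and a 20-gene expression
matrix — a desk-scale study that completes in seconds. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; no
global state. Identical seeds give byte-identical FASTA/VCF/TSV outputs.

## Known limitations

Per-protein pI/MW reproduction against any specific web-tool version is
approximate (pKa-table provenance); the median-joining search is greedy
and not guaranteed globally optimal for large haplotype sets (exact checks
are done by brute force on ≤ 4-site instances); the EST-support filter
operates on a precomputed hit table — homology search itself is out of
scope, as are alignment, tree building, synteny detection, variant calling
and ancestry inference.
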