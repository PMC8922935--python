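# zfamkit

Gene-family characterization and domestication-diversity analysis for CCCH
zinc-finger genes, built for plant genomicists studying how a transcription
/ RNA-binding factor family evolved and responded to crop domestication —
the motivating case is the 53-member barley family (HvC3H1–HvC3H53).

## What it computes

**Motif scanning and architecture typing.** CCCH zinc fingers follow the
consensus C-X<sub>a</sub>-C-X<sub>b</sub>-C-X<sub>3</sub>-H with variable
spacers a ∈ [4,17], b ∈ [4,6]. `motif_scan` finds all motifs with a
deterministic greedy left-to-right policy, pairs long-spacer and
short-spacer fingers into tandem zinc fingers
(C-X<sub>7/8</sub>-C-X<sub>5</sub>-C-X<sub>3</sub>-H — X<sub>16/18</sub> —
C-X<sub>5</sub>-C-X<sub>4</sub>-C-X<sub>3</sub>-H), tests for an upstream
arginine-rich region, and labels each protein CCCH / TZF / RR-TZF /
ANK-RR-TZF (ankyrin and other auxiliary domains come from an external
annotation table).

**Physicochemical annotation and naming.** `protparam` computes length, MW
(average masses, kDa), theoretical pI (Bjellqvist pKa set), GRAVY
(Kyte–Doolittle mean) and the instability index, and assigns positional
family names ordered by chromosome and coordinate.

**Duplication and divergence.** `duplication` classifies gene pairs as
tandem (same chromosome, adjacent in the full annotation) or segmental,
calls selection from Ka/Ks (<1 purifying, =1 neutral, >1 positive) and
dates divergence with T = Ks/(2λ)×10⁻⁶ My, λ = 6.5×10⁻⁹.

**Population genetics.** `popgen` filters SNPs (MAF strictly within
(0.05, 0.95), missing rate < 0.1, biallelic; samples with > 0.1 missing
dropped), computes per-site nucleotide diversity
π = n/(n−1)·(1 − p² − q²) averaged per gene and per population, quantifies
the domestication bottleneck as the percent reduction of π from wild to
landrace, enumerates per-gene haplotypes with dominant-haplotype calls
(strictly more than half of a population), builds median-joining haplotype
networks, and runs allele-frequency-scaled genotype PCA.

**Expression.** `expression_utils` normalizes FPKM as log₂(FPKM+1), calls
stress induction above a 2.0-fold ratio, and computes 2^(−ΔΔCt) relative
expression.

**Synthetic studies.** `synthetic_data` generates every input with known
ground truth — proteomes with planted architectures (rejection-sampled so
the scan recovers the truth exactly), gene catalogs with planted tandem
pairs, a wild + landrace genotype panel whose founder-pool bottleneck
targets a ~30% π reduction, and FPKM matrices with planted fold changes.
`pipeline.run_all` chains everything and writes one summary table.

## Worked example

```python
from zfamkit import motif_scan, popgen
from zfamkit.synthetic_data import BottleneckSpec, make_genotypes

seq = "A"*24 + "R"*6 + "C"+"A"*7+"C"+"A"*5+"C"+"AAA"+"H" + "A"*18 \
      + "C"+"A"*5+"C"+"A"*4+"C"+"AAA"+"H"
hits, spans, call = motif_scan.scan_protein("demo", seq)
print(len(hits), call.architecture)          # 2 RR-TZF

matrix, pops = make_genotypes(BottleneckSpec(seed=3))
wild = [s for s, p in pops.items() if p == "wild"]
land = [s for s, p in pops.items() if p == "landrace"]
pi_w = popgen.nucleotide_diversity(matrix, wild).pi_overall
pi_l = popgen.nucleotide_diversity(matrix, land).pi_overall
print(round(pi_w, 4), round(pi_l, 4),
      round(popgen.diversity_reduction(pi_w, pi_l), 2))
# 0.4738 0.3427 27.68
```

The two fingers form one tandem zinc finger preceded by six arginines, so
the protein is typed RR-TZF. The synthetic panel (51 wild, 95 landrace
accessions, 30 genes × 10 SNPs) loses 27.7% of its wild diversity in the
landraces — the realized draw of the configured ~30% founder-pool
bottleneck.

A shell interface wraps the same library:

```bash
zfamkit run --seed 1 -o out/          # full synthetic study
zfamkit scan --fasta proteome.fasta -o scan_out/
zfamkit popgen --vcf snps.vcf --pops populations.tsv -o popgen_out/
```

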