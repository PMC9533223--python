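# Methods

This note documents the estimators, conventions and simulation design
behind `sweepkit`, and what the bundled validation does and does not show.

## Data model

All statistics operate on a `HaplotypeDataset`: a biallelic-SNP haplotype
matrix for one contig with two rows per diploid sample, per-site (ref, alt)
alleles, optional per-site ancestral states, and a sample→population map.
VCF and site positions are 1-based; windows and BED exports are 0-based
half-open (each format's native convention). Multiallelic records and
indels are skipped at load time. Unphased heterozygotes are loaded but
clear a dataset-level `phased` flag; haplotype-based scans refuse such data
rather than pseudo-phase it, because EHH statistics are meaningless on
arbitrarily phased heterozygotes. Frequency-based statistics (π,
F_ST, Tajima's D, the D statistic) accept either.

Site filters (defaults: ≤ 20% missing haplotype entries, minor allele
frequency ≥ 0.05; optional mean-depth bounds that are no-ops when the
source lacks depth) are computed on haplotype entries, not diploid
genotypes, so every criterion shares one denominator. Filtering is
idempotent and reports a per-criterion removal tally.

## Window statistics

* **π** — per site 2·c₀·c₁/(n(n−1)) over non-missing haplotype counts,
  summed over the window and divided by window length in bp (invariant
  sites contribute zero). This per-bp convention matches the windowed-π
  tools common in resequencing studies, where genome-wide π of a diverse
  plant cohort is of order 10⁻³–10⁻².
* **F_ST** — per-site Weir & Cockerham (1984) variance components
  a (among populations), b (among individuals) and c (within individuals),
  computed on diploid individuals rebuilt from consecutive haplotype rows
  with the observed-heterozygosity term; the window value is the
  "weighted" ratio of sums Σa/Σ(a+b+c). A haploid variant (no
  heterozygosity term, c = 0) is available behind a switch and is used in
  oracle tests. Small negative window values are reported as computed.
* **Tajima's D** — π̂ in count units with pairwise-complete missing-data
  handling, S = segregating sites, constants a₁…e₂ from the population
  haplotype count (Tajima 1989). Windows with S = 0 are missing. Under
  heavy missingness π̂ and the constants use slightly different effective
  n; the synthetic validation uses complete data.
* **LD decay** — haplotype r² over jointly non-missing rows, binned by
  pair distance; pairs are subsampled deterministically under a seed
  (default cap 10⁶ per contig), with an exhaustive mode for tests.

## CDR scan

Z-transformed F_ST uses the sample standard deviation (n−1); the diversity
contrast is log₂((π_A + ε)/(π_B + ε)) with pseudocount ε = 10⁻⁶ per bp (one
substitution per Mb) so zero-diversity windows stay finite. A window is a
candidate divergent region when z_F_ST is at or above the genome-wide
(1−0.05) empirical quantile **and** the π-ratio is at or below the 0.05
quantile (linear interpolation between order statistics; ties fall in the
tail; per-chromosome thresholds available via config). Windows with fewer
than 3 SNPs are excluded from both quantile estimation and flagging.
Because a 5-kb-step sliding grid makes adjacent flagged windows overlap,
merging book-ended/overlapping windows into maximal intervals is the
default; both merged-region and flagged-window counts are reported.
Candidate genes are GFF3 features overlapping a region by ≥ 1 bp.
Region-vs-background contrasts use the two-sided Mann–Whitney U test —
exact when both sides have ≤ 8 untied values, otherwise the tie-corrected
normal approximation without continuity correction (so the z-statistic
equals the textbook rank-sum formula exactly).

## EHH-family statistics

EHH at offset k from a core SNP is the probability that two random carrier
haplotypes are identical over the inclusive span from the core to k
(missing entries count as their own allele state, so two missing entries
match). EHH(0) = 1 by convention; for pooled (cross-population) curves the
core's own alleles partition the sample from the first extension step.

Integrals are composite trapezoids of the curve anchored at EHH(0) = 1:
over physical distance for iHS/XP-EHH, over site index (unit steps) for
nSL/XP-nSL. Scores are ln(iHH_ancestral/iHH_derived) for iHS/nSL (strongly
negative = long derived haplotypes; both signs are thresholded, so the
sign convention does not affect results) and ln(iHH_obs/iHH_ref) for the XP
statistics (positive = sweep in the observed population). The XP scan
advances both pools over one shared support and stops when *both* pooled
EHH values are below the cutoff, which makes population swap an exact sign
flip. Core sites need MAF ≥ 0.05 (pooled across both populations for XP)
and ≥ 2 carriers per class; iHS/nSL require ancestral states (from the
VCF's AA tag, the generator's truth, or outgroup-majority polarization).

Truncation follows the standard scan tool's defaults: curves are followed
until EHH < 0.05; a core is voided when the curve is still above the
cutoff at a chromosome edge or when consecutive SNPs are > 200 kb apart;
extension is capped (integral truncated, not voided) at 1 Mb from the core
in bp mode and 200 sites in site mode. **On the 1-Mb simulated genome the
analyses cap extension at 50 kb instead** (`SCALED_SCAN_EXTEND_BP`): with
N = 200 a noticeable fraction of haplotype pairs coalesce within the last
few generations and remain identical chromosome-wide, so pooled EHH never
reaches the cutoff, and a 1-Mb cap — the size of the whole synthetic
genome — both voids cores at the edges and buries the sweep contrast
(confined to the ~50-kb footprint) under a contrast-free common tail. On
real Mb-scale chromosomes with large N_e the field default is appropriate
and remains the library default.

Standardization: iHS/nSL in 100 equal-width derived-allele-frequency bins
(bins with < 2 scores become missing), XP statistics genome-wide; both use
the sample standard deviation. Significance uses the proportion of
|score| > 2 (one-sided score > 2 for XP) SNPs per non-overlapping 500-kb
window; windows with < 100 scored SNPs are dropped and the rest are ranked
genome-wide, with tiers at the 95th and 99th percentiles.

The scans are computed by a pairwise next-mismatch index (for every
haplotype pair and site, the nearest mismatch left/right), making the EHH
curve at any core the survival function of per-pair mismatch distances;
this is algebraically identical to stepwise haplotype regrouping and is
tested for exact agreement with both the stepwise implementation and an
independent pair-enumeration oracle.

## ABBA-BABA

For (((P1,P2),P3),O), per-site pattern weights from population derived
(alt) allele frequencies: abba = (1−p₁)p₂p₃(1−p₄),
baba = p₁(1−p₂)p₃(1−p₄); D = Σ(abba−baba)/Σ(abba+baba) over informative
sites (abba+baba > 0). The frequency (not single-genome) form handles
polymorphic outgroups. SE is a delete-one block jackknife over consecutive
blocks of equal informative-site count (default 2000; choose blocks that
span several LD lengths), Z = D/SE, p two-sided normal. The trio scan
reports all three rotations of every ingroup trio, each oriented so
D ≥ 0, and marks as `best` the rotation with the largest concordant BBAA
sum — the conventional way to fix the topology before reading D as
introgression (the max-D rotation would instead be dominated by
true-sister sharing whenever the assumed topology is rotated).

## Forward simulator

Discrete-generation Wright–Fisher with N diploids per population. Each
offspring haplotype is one gamete of a sampled parent: Poisson(ρL)
crossovers at uniform positions, then Poisson(μL) new mutations at uniform
continuous positions (infinite sites; rounded to distinct integer bp only
at VCF output). Splits copy the parental pool; the outgroup is itself an
early split, so its sampled frequencies can be polymorphic. A pulse
replaces a fraction f of the target's parents with source parents for one
generation (the realized fraction is recorded). A sweep injects one copy
with additive fitness 1, 1+s, 1+2s and fitness-proportional parent
sampling; on loss (or, when fixation is required, on reaching the present
unfixed) the simulator restores the injection-time state and retries with
fresh randomness, up to a restart budget. All randomness flows through one
seeded PCG64 stream; identical parameters and seed give byte-identical
VCF, popmap and truth files. Every mutation is derived, so REF is the true
ancestral allele at every site, and sites monomorphic in the sample are
dropped at output.

**Scaled rates.** Desk-scale defaults are N = 200, L = 1 Mb, burn-in 8N
generations, and μ = ρ = 2.5×10⁻⁷ per bp per generation — deliberately
~25× real plant rates so that θ = 4Nμ = 2×10⁻⁴/bp. This keeps 500-kb
windows above the 100-SNP proportion-scan floor and provides enough
recombination (4Nρ·L = 200) that window statistics average over many
genealogies; at unscaled rates a 1-Mb locus is a single genealogy and
per-replicate π would vary by ~50%, making neutral-expectation checks
uninformative. Consequences of small N worth keeping in mind: pooled EHH
has a fat tail from very recent coalescences (hence the scaled extension
cap above), and haplotype contrasts are bounded by 2N divided by the age
of the sweep — which is why the sweep scenario injects the allele late
(115 generations before sampling; mismatches among carriers accrue at 2μ
per bp per generation from injection).

Fixed study scenarios (`simulate.py`):

* `neutral_scenario` — two recently split ingroups + outgroup at the
  defaults; within-population diversity is effectively the
  single-population equilibrium 4Nμ.
* `sweep_scenario` — split 200 generations ago, s = 0.1 hard sweep
  injected into "firm" at generation 115 and required to fix, 30 diploids
  sampled per population; `sweep=False` gives the matched neutral control.
* `pulse_scenario` — three ingroups on (((p1,p2),p3),O) with splits at
  200/120/30 generations, N = 50, L = 1.6 Mb, μ = 4×10⁻⁶, ρ = 2×10⁻⁶, and
  an f-sized pulse p3→p2 one generation before sampling. The internal
  branch is long enough that P3 carries clearly distinct variation, and
  the pulse is recent so its ancestry is not lost to drift. The genome
  length is chosen so that ~500+ informative sites yield 20+ jackknife
  blocks of 25 informative sites (~75 kb each, well above the ~2.5-kb LD
  scale): the block-jackknife Z is t-like with heavy tails when only a
  dozen blocks exist, and calibrates to near-standard-normal with 20+.
* `implant_scenario` — a neutral two-ingroup substrate for
  `implant_divergence_segment`, which collapses population-A haplotypes
  toward a template inside a chosen segment (probability = strength per
  entry) and drives a seeded fraction of segment sites to fixed
  differences; strength 0 is the identity, strength 1 zeroes π_A inside.

**What the validation shows — and does not.** The oracle tests establish
that the estimators compute their defining formulas exactly; the scenario
tests establish that, under the generator's idealized conditions (complete
phased data, no genotyping error, constant population sizes, free
recombination between replicates, a single hard sweep or single pulse),
the scans recover planted signals at the stated rates. Real resequencing
data add phasing error, depth-dependent genotype error, population
structure and reference bias, none of which the generator emulates; passing
these tests therefore validates the implementation, not the field
performance of the statistics.

## Numerical choices and edge cases

Quantiles use linear interpolation between order statistics; ties at a
threshold fall in the tail. Z-transforms and standardization use the
sample standard deviation and return all-missing with a warning when the
spread is zero. Windows of zero span are rejected; a filter pass that
removes every site returns an empty dataset with a warning. The pseudocount
distortion of the π-ratio is below 0.01 once both π exceed ~300× the
pseudocount (worst case log₂(1+ε/π_A)+log₂(1+ε/π_B)). D is undefined when
Σ(abba+baba) = 0 and its SE is undefined (with a warning) below three
jackknife blocks; a trailing partial block shorter than half a block is
folded into its predecessor. Pipelines are pure functions of
(inputs, config, seed): every output table carries the tool version, a
hash of the analysis-relevant config, and the seed, and reruns are
byte-identical.

## Known limitations

Single-contig simulation; additive selection only (no dominance); no gene
conversion or background selection; diploid organisms only; iHS/nSL
polarization for real data uses outgroup-majority calls and simply drops
unpolarizable sites; the Mann–Whitney exact path is limited to small
untied samples; per-window statistics assume a position-sorted,
biallelic-SNP input (enforced at load).
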