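# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Everything stated here is computed by the
test suite or `scripts/acceptance.py`; nothing is an external claim.

## Coordinates and formats

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive conventions of RepeatMasker `.out` and GFF3 happens only
in `refugium.io`. The `.out` parser expects the standard 15-column dialect
(three header lines; strand `C` mapped to `−`; trailing `*` overlap flags
tolerated; the ID column kept as `fragment_link` joining split fragments).
Chromosome lengths include assembly gaps (N runs) by default;
`ChromosomeRecord.ungapped_length` and the `ungapped_lengths` option of
the density summary provide the N-excluded alternative, since surveys
differ in which convention they normalize by. Unplaced scaffolds are
carried but excluded from densities and indexes by default — index
statistics are only meaningful over assembled, classified chromosomes.

## Kimura 2-parameter divergence and landscapes

For an aligned copy/consensus pair, P and Q are the proportions of
transition- and transversion-type differences over ungapped, unambiguous
(ACGT-only) columns, and

K = −½ · ln((1 − 2P − Q) · √(1 − 2Q)).

When the log argument leaves the model's domain (saturated pairs) the
result is flagged undefined rather than clamped, and callers must decide;
a tiny negative K from floating rounding at identity is clamped to 0. No
CpG-adjusted variant is applied — plain K2P only. Copy-to-consensus
alignment, when the annotation carries no divergence column, uses an
affine-gap global alignment (match +1, mismatch −1, gap open −4, extend
−1).

Landscapes bin TE bp into left-closed bins of `bin_width` percent
divergence (default 1), pooling everything at or above a 50% cap into the
last bin, and report both raw bp and bp per Mb of chromosome-class length
(both normalizations are carried because published landscape figures are
not consistent about which they use). Note that RepeatMasker's `.out`
divergence column is a raw mismatch percentage while the bin axis of a
K2P landscape is the transformed distance; for the mutation doses the
simulator plants, the two differ by less than one default bin below ~15%
divergence, and the realignment path (`AlignedPair` → `k2p_distance`)
gives the transformed distance exactly.

## Full-length TE calls

**fl-LINE / fl-DNA (homology route).** ORFs are maximal stop-to-stop
stretches in all three frames of both strands; no start codon is required
(TE ORFs are routinely truncated at the annotation edge). An insertion is
full length when an ORF of at least 600 bp (LINE) or 1000 bp (DNA
transposon) locally aligns to the endonuclease *and* reverse-transcriptase
(LINE) or transposase (DNA) domain consensus covering ≥90% of the domain
length. Local protein alignment uses BLOSUM62 with gap open −11 / extend
−1; `span_fraction` counts aligned consensus residues over consensus
length. The two LINE domains may be satisfied by different ORFs of the
same insertion (the single-ORF reading is available via
`line_same_orf=True`); the relaxed default was chosen because old intact
LINEs frequently carry a frameshift between EN and RT regions while both
domains remain recognizable, and the evidence dict records which ORFs
satisfied which domain.

**fl-ERV (structural route).** One unified detector plays the role of the
two external structural annotators whose counts the survey table reports
side by side; the two bundled criteria profiles differ only in the score
threshold and exist so censuses can be labelled per profile. The
algorithm: exact 11-mer seeds of direct repeats on the same strand,
restricted to start offsets compatible with the element bounds, grouped by
diagonal; runs of ≥2 seeds with gaps ≤40 bp are chained and extended
without gaps under an X-drop rule (match +1, mismatch −2, drop 10);
candidate LTR length must lie in [100, 1000] bp and element span in
[1.5, 15] kb. Boundaries are refined against a flanking 4–6 bp target-site
duplication, searching shifts up to ±6 bp with a preference that makes a
longer TSD pay one base of TSD length per base of boundary shift —
without that trade-off, chance 4–6-mers at large shifts displace true
TSDs and degrade boundary precision. LTR-pair identity is computed from a
global (Needleman–Wunsch) edit distance of the two repeat copies and must
reach 0.80. Overlapping candidates are resolved by score, then leftmost
start.

Retained fl-ERVs additionally need internal domain evidence: ORFs ≥300 bp
in the internal region aligned against gag/pol/env consensi, at least one
domain span ≥0.5 ("complete or partly complete" gene evidence), and a
composite score

score = 250·identity + 50·[TSD present] + 200·mean(gag, pol, env spans)

of at least 300, with ≥ semantics at the boundary. The 0–500 scale was
rescaled so the default threshold plays the same gating role as the score
cutoffs of the external annotators it replaces; the weights and threshold
are config knobs, and monotonicity (raising any threshold never increases
calls) is enforced by test. Solo-LTRs and internal-only fragments are
structurally excluded: a solo-LTR has no repeat partner within the element
bounds, and two nearby solo-LTRs or cross-pairings between neighbouring
elements fail the internal-domain requirement or lose overlap resolution
to the true, TSD-supported candidates. Domain evidence can alternatively
be ingested from a precomputed RPS-BLAST-style table via
`io.read_domain_hits`.

Boundary precision: ungapped X-drop extension overshoots a true LTR edge
when flanking bases match by chance, and TSD refinement usually but not
always recovers the exact edge; observed jitter on planted elements is
0–2 bp (occasionally ~7 bp when no TSD is recoverable). Recovery metrics
therefore match calls to planted elements by ≥95% reciprocal overlap;
counts and censuses are unaffected.

**Census.** Counts are pooled per chromosome class (autosomes together, Z,
W; X/Y are pooled with Z/W for reporting) and per category, with LINE+DNA
also reported jointly; per-chromosome tables are retained, and class
totals equal sums over member chromosomes by construction.

## Indexes and the uniformity test

RI and TI are defined in the README. Integer-count inputs flow through
`fractions.Fraction`, so survey worked examples reproduce printed
9-decimal values exactly (`render9` rounds half up, matching the survey
table's formatting). Diploid totals pool all intact-TE categories —
fl-ERV plus full-length LINE+DNA — because the published male/female
diploid totals reproduce the published indexes only under that reading
(verified programmatically for all six surveyed species). The genome-wide
%TE_exp includes all assembled chromosomes, the W itself included. The χ²
test pools autosomes into one cell (A vs Z vs W, df = 2, expectations
proportional to class length); a per-chromosome variant (df = k − 1) is
available by passing per-chromosome cells. For df = 2 the p-value equals
exp(−X²/2), which the suite checks against scipy to 1e−12.

## W-linked SNV discovery

Reads are mapped to TE consensus sequences (real cohorts: any standard
mapper, SAM text in; synthetic cohorts: the bundled `naive_map`, exact
20-mer seed + ungapped extension, best unique hit, ≤10% mismatches, ties
and overhangs dropped). Pileups count primary, non-duplicate alignments
with base quality ≥13; CIGAR-aware placement via pysam for SAM input.

Per sample and site, an alternate allele is **present** iff depth ≥5,
alt count ≥3 and alt frequency ≥0.20; **absent** iff depth ≥5 and alt
frequency ≤0.05; otherwise **indeterminate**. These four gates are package
defaults (config-exposed), chosen so that at ≥15× effective depth a
hemizygous W allele diluted to ~25–50% frequency by autosomal copies of
the same family is confidently present while mapping noise stays below
the absent ceiling. A variant is W-linked iff present in *every* female
genomic sample and absent in *every* male genomic sample; any
indeterminate call excludes the site. Zero male coverage therefore
excludes a site rather than counting as absence — the conservative
reading. A cohort with a single male triggers a warning (one male is weak
evidence of absence). Multi-allelic sites are handled per alternate
allele; only SNVs are considered (no indels in consensus space).

RNA cohorts: a W-linked variant present in ≥1 female RNA sample is
flagged transcribed; present in any male RNA sample, it is removed from
the W-linked set and flagged `discarded_male_rna` (flag ordering — every
discarded variant was previously W-linked — is tested). The permutation
specificity check re-labels the genomic samples with random non-identity
permutations of the sex vector; the identity permutation is excluded
because it is the observed labelling, not a permutation of interest.

## Expression summaries

TPM_ij = (count_ij / length_i) / Σ_i(count_ij / length_i) · 10⁶ per
sample; each sample column sums to 10⁶. Rows on the W are removed from
male samples *before* normalization (males have no W; such counts are
cross-mapping noise that would distort male library-size rescaling).
Replicates are averaged after normalization. Sex comparisons per class use
a two-sided Wilcoxon rank-sum test — exact enumeration for combined n ≤ 20
without ties, tie-corrected normal approximation otherwise. The reported
log₂ ratio of mean TPM is a plain contrast, deliberately not a modelled
differential-expression fold change (no dispersion modelling, no
shrinkage); within-sample TPM renormalization also means a uniform
whole-transcriptome shift between sexes cancels unless anchored by stable
reference copies, which the example demonstrates.

## Synthetic data generator

The generator defines the package's study conditions:

* **Library.** ERV consensus = 300 bp LTR + 100 bp UTR + gag(300 aa) /
  pol(500 aa) / env(400 aa) ORFs separated by single stops + 100 bp UTR +
  LTR (~4.4 kb); LINE = 150 bp UTR + single EN(250 aa)+RT(350 aa) ORF +
  150 bp UTR; DNA = 100 bp UTRs around a 400 aa transposase ORF. All ERV
  families share one ancestral coding region, then each family's copy is
  diverged 8% so reads map uniquely to their own family while the shared
  domain peptides still align with near-complete spans — mirroring real
  subfamily structure within a superfamily.
* **Planting.** Elements are laid left to right per chromosome with
  random gaps and a 500 bp minimum margin (annotations stay disjoint — no
  nested insertions, keeping census truth unambiguous); full-length
  elements get a 4–6 bp TSD on both sides; solo-LTRs are one LTR between
  its TSD pair (the recombination product); truncated fragments span
  mid-gag to mid-pol (no complete domain). All copies are planted on the
  forward strand; strand symmetry of the detector is tested separately by
  reverse-complementing sequences.
* **Divergence.** A target K2P distance is inverted to a raw substitution
  dose d (transition share κ/(κ+2), default κ=2); exactly round(d·L)
  distinct sites are substituted, and substitutions that would create
  in-frame stops inside ORFs of elements meant to stay intact are
  replaced by the next non-stop alternative. For small elements the
  rounding of the dose is the documented approximation. Emitted `.out`
  rows carry the realized (measured) mismatch percentage.
* **Cohorts.** Genomic samples draw uniform reads from the
  sex-appropriate haplotype pool (female 2A+Z+W, male 2A+2Z) so diploid
  autosomal depth equals the coverage target (default 30×, 100 bp reads,
  error-free by default) and hemizygous chromosomes get half; RNA samples
  draw only from elements marked transcribed for that sex. W-restricted
  SNVs are planted into every W copy of a family that also has autosomal
  copies, so males retain reference-allele coverage at the site (sites
  covered only in one sex would be excluded by the conservative rule).
* **Determinism.** One integer seed feeds fixed substreams per output, so
  equal seeds give byte-identical bundles and new outputs never perturb
  existing ones.

Scenario presets are the recovery experiments' conditions: `default`
(~2 Mb; 10/2/20 fl-ERVs on A/Z/W, 20 solo-LTRs, 20 truncated fragments,
error-free, so TI truth is exactly 18/24 = 0.75), `cohort` (3F+3M genomic
at 30× plus one RNA sample per sex; 12 W-restricted SNVs of which 7 on a
transcribed family, 8 autosomal SNVs, error-free so the W-linked truth
set is exact), `density` (planted 5/10/60% TE densities on three 100 kb
chromosomes). These sizes keep the full suite and the acceptance script
within a few CPU-minutes while leaving each recovery problem non-trivial
(decoy solo-LTRs/fragments outnumber planted elements on the W scenario's
decoy classes; autosomal variants outnumber nothing but must yield zero
false calls).

What the simulator does *not* emulate — indels in copies and reads,
nested insertions, read-quality profiles, paired-end structure, mapping
biases of real repeat families, assembly gaps/collapses on the W —
bounds what passing tests show: they validate the statistics, the
detectors and the linkage rule under clean conditions, not robustness to
every artefact of real sequencing data. Published per-species absolute
counts require the real assemblies and cohorts and are out of scope; the
recovery suites on planted truth stand in for them.

## Numerical and degenerate-input conventions

Saturated K2P pairs are flagged, never silently zero; zero comparable
columns raise. Density and landscape computations reject hits out of
chromosome bounds and unknown chromosomes by name. `uniformity_test`
requires a positive observed total and positive class lengths. TI is
undefined (raises) at n_hom = 0, RI at %TE_exp = 0. Score ties in the
detector break by leftmost start; domain-alignment ties take the first
optimal alignment of a deterministic enumerator. Empty inputs (no hits,
no calls, no variants) produce empty-but-well-formed tables.
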