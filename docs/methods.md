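# Methods

This note documents the models, conventions and numerical choices behind
`genarch`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and conventions

All internal coordinates are 0-based half-open; GFF3 output and the
"scaffold: start-end" location strings are 1-based inclusive, converted
only at I/O. A gene model stores exons as scaffold-forward intervals in
transcript order (descending starts on the minus strand), so the spliced
transcript is always the concatenation of (reverse-complemented, for '-')
exon slices. A splice site's "position" is the first genomic base of the
intron; its phase is the CDS offset of that base modulo 3, i.e. phase 0
lies exactly between codons. The residue index in a site label counts on
the sequence as it appears in the reference alignment; `offset_map` in the
projection step absorbs transit-peptide trimming or other numbering
offsets.

## Synthetic gene families

`simulate_family` evolves one protein and one intron set down a user tree.

* **Substitutions.** Equal-rates Poisson model: the number of amino-acid
  exchanges on a branch is Poisson(branch length × sites); each event picks
  a uniform site (the initiator Met is held fixed) and a uniform different
  residue. This matches the Poisson-corrected distances used downstream and
  deliberately omits rate heterogeneity and exchangeability structure.
* **Introns.** Ancestral introns (default 5) and gains are placed at a
  uniform codon with phase drawn from `phase_distribution` (default
  0.5/0.3/0.2, the empirical plant bias toward phase 0). Each branch loses
  an existing intron with probability 1 − exp(−loss_rate × t) and gains
  Poisson(gain_rate × t) new ones. Every insertion event founds a homology
  class; class membership is inherited, giving the ground truth that
  conservation calls are scored against. Intron positions are kept ≥ 45 bp
  apart and clear of the CDS ends: micro-exons are rare in real genes and
  unresolvable by overlap-based EST evidence, so the generator excludes
  them by design.
* **Realisation.** Leaf proteins are back-translated with uniform
  synonymous codons, wrapped in short ATG-scrubbed UTRs, and interleaved
  with GT..AG introns (length uniform in `intron_len_range`, default
  60–300 bp) plus 800 bp flanks; each gene lands on its own scaffold on a
  random strand. Identical seeds give byte-identical FASTA/GFF3.
* **Signals.** Transit peptides are 50–80 residue N-terminal extensions
  sampled to ≥ 34% S+T, ≥ 17% R+K, ≤ 3% D+E (comfortably above the 30/15
  screening thresholds); anchors are 22-residue C-terminal stretches with
  mean Kyte–Doolittle hydropathy ≥ 2.0; a retro-copy duplicates the
  parent's mature cDNA verbatim into a single-exon gene with unrelated
  flanks — the classic intronless-paralog signature.
* **ESTs.** Reads are contiguous substrings of the spliced cDNA (or, with
  probability `retained_intron_prob`, default 0.05, of the unspliced
  pre-mRNA), with i.i.d. substitution errors (default 1%), random
  orientation, fragment lengths 350–600 bp, and strong end-anchoring
  (40% 5'-anchored, 45% 3'-anchored). The end bias emulates the targeted
  5'/3'-end retrieval rounds real EST studies perform to complete cDNA
  ends; it is what makes full-length consensus recovery a fair benchmark.
  The generator does not model indel sequencing errors, chimerism rates,
  quality values or library normalisation, so pipeline results on real
  single-pass reads will be correspondingly noisier.

## EST pipeline

Clustering is single-linkage over pairs whose best gapless overlap (shared
k-mer diagonals, k = 15, both strands) reaches `seed_identity` (default
0.90 — the initial grouping threshold is a package choice, not a measured
constant) over ≥ 40 bp. Refinement splits each cluster into components
whose overlapping members agree at `perfect_identity` (default 1.0, the
"non-perfectly matching reads are removed" rule); excluded reads re-join
the best core whose consensus they match perfectly, otherwise they become
flagged singletons. Consensus is per-column majority with IUPAC codes on
ties and N at zero coverage. Member layout uses shared-k-mer diagonal
offsets rather than banded alignment: exact, O(n·L) and deterministic
under the substitution-only error model (exonic indels are an explicit
non-goal of the generator). EST counts assign each read to its single
best-identity cDNA; ties leave it unassigned, and zero-count genes are
reported as putatively non-expressed.

## Gene models

The spliced aligner is seed-and-chain: exact 15-mer anchors are collapsed
into diagonal blocks, chained collinearly (chain score = covered query
length − (10 + 0.01·len) per intron gap), and junctions are polished
within ±8 bp to the placement maximising exon-side matches plus a bonus
for canonical dinucleotides. Four configurations are scored — either
query orientation × either gene strand (a minus-strand gene's introns
read CT..AC on the forward genomic strand) — and the winner is chosen by
(identity, number of canonical junctions); the result is canonicalised to
transcript orientation. Identity < 0.9 raises "no confident model".
Introns shorter than 20 bp are treated as alignment gaps. When the true
exon boundary is genuinely ambiguous (the flanking base repeats such that
two adjacent placements are both canonical and equal-scoring) the smaller
coordinate wins; such cases are rare (< 1% of junctions on random intron
sequence) and are the main residual error mode of the end-to-end
benchmark.

ORF calling takes the longest ATG-initiated ORF over the three forward
frames (5'-most on ties, flagged; < 50 codons flagged "fragment").
Flank scans translate 2000 bp windows in three frames: upstream, a
transit-peptide-sized window slides over every stop-free stretch and is
scored by the targeting heuristic prepended to the current protein;
downstream, stretches are scanned for hydrophobic helices. Candidates are
ranked, never auto-accepted. The allele-vs-isogene call requires cDNA
identity ≥ 0.98 **and** mean flank identity ≥ 0.90 (10 kb windows,
infix edit-distance identity); these cutoffs are package choices
calibrated to separate haplotype pairs (~0.5% divergence) from
retro-copies and paralogs, not field constants. In-silico PCR is exact
substring matching by design: a single primer mismatch yields no product.

## Localization heuristics

The targeting score is pure composition — frac(S+T) + frac(R+K) −
frac(D+E) over the N-terminal 60 residues — with cutoff 0.45 (default
profile) or 0.30 ("chlorophyte" profile, reflecting the weaker targeting
signals of algae with a single cup-shaped chloroplast). It is an explicit,
auditable surrogate for machine-learned targeting predictors, not a
reimplementation of them; scores are permutation-invariant within the
window by construction. The TM scan uses the Kyte–Doolittle scale with a
19-residue window and threshold 1.6; consecutive above-threshold windows
merge into helices (minimum merged span 18 residues), and the reported
hydropathy is the peak window mean within the span (the span's flanks may
dip below threshold). "Membrane-anchored" means a helix ends within the
last 40 residues. A descriptive bipartite-signal flag reports a second
hydrophobic stretch inside the N-terminal 80 residues; no cleavage-site
prediction is attempted.

## Structure comparison

Sites are grouped by exact (column, phase); groups of ≥ 2 are conserved.
Remaining singletons merge closest-first (ties to the lower column) into
an existing equal-phase class within ±1 column (as near members) or with
another singleton into a near-conserved class; leftovers are unique.
Conserved and near-conserved totals are reported separately, and the
pairwise gene×gene matrix counts only exact-conserved classes shared by
both genes. UTR introns are excluded from classes but listed. GC content
is 100·(G+C)/(A+C+G+T) with ambiguity codes excluded, one decimal. The
SVG diagram is deterministic text output: proportional exon boxes and
intron lines per gene, with solid connectors between conserved and dashed
connectors between near-conserved class members.

## Phylogenetics

Distances: p-distance with pairwise gap deletion; Poisson correction
−ln(1−p); and a Scoredist-style PAM250 distance −ln σ with σ = (S_obs −
S_rand)/(S_max − S_rand), where S_max is the mean self-score and S_rand
the expectation under the two rows' residue frequencies. The PAM250
weighting is provided as a separate distance option rather than combined
with the Poisson correction, since both are standard but distinct
corrections. Saturated pairs (p ≥ 1 or σ ≤ 0) are flagged and filled with
1.5× the largest finite distance so NJ stays runnable.

NJ follows Saitou–Nei with deterministic tie-breaking (lexicographically
smallest pair of subtree keys) and a closed-form final three-node join;
negative branch estimates are clamped to zero and flagged. Minimum
evolution is NNI hill-climbing on the OLS total-tree-length criterion
with a deterministic edge sweep; on additive matrices it leaves the NJ
tree untouched. Parsimony is Fitch counting with gaps treated as missing,
computed after re-rooting on the smallest leaf's edge so every internal
node is binary. Bootstrap resamples columns with replacement from one
seeded generator; supports are percentages of successful replicates
containing each bipartition of the point-estimate tree, and replicates
whose matrix is fully saturated are dropped and counted.

The built-in progressive aligner exists so synthetic runs need no
external MSA: a 3-mer-composition UPGMA guide tree, then profile–profile
global alignment with PAM250 expected-score columns and affine gaps
(open −14, extend −3). The penalties are set in raw PAM250 units; weaker
values (e.g. −10/−1) let score variance open spurious register-shifting
gaps between divergent-but-ungapped homologs, which would corrupt
splice-site column projection. Equal-length families up to ~50%
divergence align gap-free, which is exactly the regime the generator
produces (exonic indels are out of scope). For real, indel-rich families
a dedicated aligner (e.g. MAFFT/MUSCLE) should be preferred and its
aligned FASTA passed in directly.

## Benchmark problem sizes

The validation script and acceptance-style tests use: exhaustive
splice-phase enumeration over CDS ≤ 30 codons with up to three introns at
every offset (~150 k placements); 20 eight-gene families with five
ancestral introns and one expected gain and loss each for conservation
recovery; 50 random 5–12-taxon trees for NJ additivity; 10 six-gene
replicates with error-free, 10×-mean-coverage ESTs for the end-to-end
round trip; and a 4×500 two-clade alignment with 500 bootstrap
replicates. These sizes were chosen as the smallest that exercise every
code path with stable statistics.

## Known limitations

* No exonic indel evolution, rate heterogeneity or codon-usage bias in
  the generator; real families violate all three.
* The spliced aligner assumes near-exact exon matches (≥ 90% identity)
  and canonical splice sites; it flags but does not model U12-type or
  shifted junctions.
* Targeting and anchor screens are composition heuristics; they rank and
  flag, and their numeric scores are not comparable to probabilistic
  predictor outputs.
* Intron gain/loss directionality (Dollo or ML reconstruction) is out of
  scope; conservation classes state descent, not polarity.
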