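# Methods

## Model and procedure

The pipeline treats each viral genome independently. Early anti-defense
genes are assumed to share a genome-specific regulatory sequence containing
a strong archaeal core promoter; genes are called ADGs when (1) their
regulatory occurrence contains that strong promoter and (2) the motif is
shared by several genes of the same genome. The stages are:

upstream extraction → per-genome motif discovery → matrix scanning →
promoter-core verification → dual-criteria calling → cross-genome protein
families and motif prevalence.

### Upstream regions and operons

Only single genes and operon leads own promoters here, so only their
100-bp upstream windows (coding strand) enter discovery and scanning.
Operon membership uses a standard distance heuristic: a gene is
operon-internal when its transcriptionally upstream neighbour lies on the
same strand within `max_gap = 30` nt. The heuristic and the gap are
configurable and echoed into every report; windows with more than 10%
ambiguous bases are excluded from discovery. Windows truncate at linear
genome ends and wrap across the origin of circular genomes. Coordinates
are 0-based half-open internally; GenBank's 1-based inclusive intervals
are converted at the boundary, which keeps the wrap and window arithmetic
unambiguous.

### PWM scoring and exact p-values

A motif is a W×4 column-probability matrix with a MEME-style pseudocount
(`0.25` total, distributed by the background; configurable). Words are
scored as Σ log2(p/bg) in bits against an order-0 background estimated
from the analyzed upstream set with +1 smoothing.

Site significance is the exact tail probability of the score of a
background-distributed random word, obtained by convolving per-column
score distributions on a lattice of `1e-3` bits (scores floored onto the
lattice). Observed words are placed on the same lattice, so scanning
p-values are self-consistent and reproducible; the arbitrary-threshold
p-value uses a conservative bin cut (every word that could reach the
threshold before flooring is included), which guarantees p = 1 at or below
the minimum achievable score and monotonicity in the threshold. On widths
small enough to enumerate, the DP agrees with brute-force summation over
all 4^W words to floating-point precision for thresholds between
achievable score classes.

### ZOOPS discovery

Discovery is zero-or-one occurrence per sequence: each gene has at most
one early promoter. EM is deterministic — every substring of the
candidate width is evaluated as a one-site seed (a single weighted matrix
product scores all seed/window pairs), the seed with the best initial
ZOOPS likelihood (site prior 0.5) starts EM, and the width grid
{30, 40, …, 100} is searched with the best converged likelihood winning.
Likelihoods are comparable across widths because non-site positions are
explicitly background-modelled. Convergence is a relative log-likelihood
change below `1e-6` or 200 iterations. Sites are retained at exact
p < 1e-8; a motif with fewer than two passing sites terminates the search;
retained sites are masked with N before the next of up to three rounds.
The final matrix is re-estimated from the retained site sequences, so the
reported counts are honest site counts.

Overfitting on noise is controlled by the exact-p-value retention itself:
on motif-free sequence sets the converged alignments are diffuse and no
site reaches p < 1e-8 (verified on simulated motif-free genomes, which
yield zero passing motifs and zero ADG calls).

### Scanning and e-values

Scanning reports one best occurrence per region (ties to the smallest
offset), matching the per-gene presence/absence logic downstream. The
e-value is the p-value times the number of positions actually scanned in
that run — a Bonferroni correction scoped to the corresponding genome —
and the count is stored on every hit. The pass threshold is e < 1e-8.
A gene satisfies the shared-motif criterion through either route:
a retained discovery site (p < 1e-8) or a passing scan hit (e < 1e-8).
The site route dominates in practice because the Bonferroni correction
over a few thousand positions demands roughly 11 additional bits of score.

### Promoter core

The TATA-box is matched against `TTTAWATA` with at most `max_mm = 1`
mismatch (the early-promoter cores are nearly identical across genes, so
slight degeneracy suffices); the BRE is the 6 nt immediately 5' of the
TATA start, with position −1 adjacent to it. "Strong" requires the TATA
match plus BRE purine fraction ≥ 2/3. G at −6 and A at −3 — the preferred
TFB-binding configuration — are reported as flags but not required, so
either policy can be audited downstream. A motif is a strong-promoter
motif when its majority consensus calls strong and at least half of its
sites call strong at a consistent TATA offset (±2 nt).

### Calling rules

`min_shared = 3` genes per motif is the smallest count that makes
"sharing a regulatory sequence" meaningful; it is configurable. The
low-probability rules: `core_protein` matches the product against an
editable keyword list (capsid, polymerase, terminase, …) because true
core genes are identified by conservation, which needs cross-genome data;
`tss_too_close` demotes calls whose TATA 3' end lies within
`min_tss_gap = 10` nt of the start codon, since the transcription start
site sits ~25 nt downstream of the TATA box and would fall inside the
ORF; `downstream_in_operon` lists operon-internal genes co-transcribed
behind an ADG lead. Start re-annotation moves the start to the first
in-frame ATG/GTG/TTG after the promoter, refusing to consume more than
half of the ORF.

### Families and prevalence

Protein families are single-linkage components over local alignments
(Smith–Waterman, BLOSUM62, BLAST-style gap existence 11 / extension 1)
whose Karlin–Altschul e-value (gapped parameters λ = 0.267, K = 0.041)
falls below 1e-3. This single-pass construction replaces an iterative
profile search: it needs no external binary and is fully deterministic,
but absolute family counts on real data can differ from profile-based
clusterings, and chance local similarities can occasionally chain
unrelated random proteins at this threshold. Coverage is computed over
the shorter sequence. Motif prevalence counts homologs within the
analyzed genome set: each family's longest member is searched against all
single/operon-lead gene products, and the prevalence is the flagged
fraction of the extended homolog set. The host-homolog screen keeps viral
proteins under 150 aa with host hits at e ≤ 1e-10, discards host
neighbourhoods (±5 genes) where ≥ 5 genes themselves hit viral proteins
(integrated viruses), and annotates adjacent small genes, flagging
convergent pairs as putative toxin partners.

## Synthetic data

The generator emulates the target data regime: 20–80 kb genomes, 30–80
genes, AT-rich composition (default GC 0.38), operons of 2–4 same-strand
genes, and a virus-specific implant upstream of designated ADG leads. The
implant is a width-40 matrix with near-invariant promoter-core columns
(TATA consensus bases at 0.97, BRE purines at 0.95) and virus-specific
flanks whose conservation is solved by bisection to meet an average
information-content target, default 1.2 bits/column — reflecting the
near-identity of the early-promoter core within a genome. Implants are
placed 15–30 nt upstream of the start codon, leaving a plausible 5' UTR.
ADG positions can be biased to the genome termini, one end, or uniform,
mirroring the placement patterns of rod-shaped, filamentous and
bicaudate-virus genomes.

Background sequence is i.i.d. at the specified GC, matching the order-0
scanning statistics; ORF codons are drawn from the same composition with
stops rejected. Real genomes have codon bias, dinucleotide structure and
repeat content that this generator does not reproduce, so passing the
synthetic benchmark demonstrates correctness of the machinery under its
own model assumptions, not performance on real genomes; on real data the
background mismatch inflates scores of composition-atypical windows and
the operon heuristic may differ from curated transcription units.

At the default conditions (50 genomes, 40 genes, 8 implants each) the
pipeline reaches recall ≈ 0.95 and precision 1.0 against ground truth,
with zero passing motifs on motif-free controls; these numbers are
recomputed by `scripts/acceptance.py` and the test suite.

## Numerical choices and degenerate inputs

- Lattice granularity 1e-3 bits; halving it leaves p-values unchanged for
  thresholds away from bin boundaries. Column log-odds of −∞ (pseudocount
  0) are clamped to −64 bits inside the DP so the support stays bounded.
- Seeding and linkage tie-breaks are deterministic (first-best seed,
  smallest offset, canonical input sorting), so end-to-end runs are
  bit-identical with no random seed.
- Regions shorter than the motif width are skipped in scanning; a region
  set where every region is too short is an error. Discovery refuses sets
  with fewer than 5 usable regions, and the pipeline records the skip
  reason and continues with the remaining genomes.
- Empty BRE room (TATA within 6 nt of the sequence start) disqualifies a
  TATA candidate rather than erroring.

## Known limitations

- The operon predictor is a distance heuristic; the original analyses'
  transcription-unit definitions are not recoverable from annotation
  alone.
- The e-value proxy for protein homology is calibrated for average
  BLOSUM62 statistics, not per-pair composition; families at the margin
  of the 1e-3 threshold should be reviewed.
- Only the coding strand of upstream windows is scanned (promoters are
  directional); bidirectional promoters shared by divergent gene pairs
  are attributed to each gene separately.
- Structural confirmation of candidate families (fold prediction,
  structure comparison) is out of scope.
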