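# Methods

## Model and assumptions

`pamforge` treats PAM inference as a signal-detection problem on the
flanking sequences of spacer→protospacer matches. The underlying biological
assumptions are:

- spacers in arrays adjacent to a *cas* operon were acquired from mobile
  elements that the collection of phage genomes samples densely enough for
  full-length, near-perfect rediscovery;
- the acquisition machinery requires the PAM adjacent to the protospacer, so
  true protospacer context carries a conserved motif on one side while the
  other side and the non-motif positions are close to background;
- Cas9 proteins clustered at high identity share a PAM, so matches can be
  pooled per cluster;
- array orientation is unreliable, which is why both flanks are retained and
  the call demands conservation on exactly one side — conservation on both
  sides indicates an artifact, not a PAM.

Noise sources the model tolerates: matches to the wrong phage sequence
(diluted by the per-spacer consensus and the outlier threshold), escape
mutations in the PAM (a per-base noise rate in the generator), and flank
truncation at contig ends (handled by per-position coverage).

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_len` (Cas9) | 950 | aa | discard loci with fragmentary Cas9 |
| identity levels | 0.95–1.00 | fraction | protein clustering granularity |
| `max_variations` | 4 | columns | mismatches + gap columns tolerated per match |
| `flank_len` | 30 | nt | context retrieved on each side |
| `min_spacers` | 10 | spacers | evaluation gate per cluster |
| `floor_bits` | 1.0 | bits | conservation floor |
| `iqr_mult` | 1.5 | – | outlier multiplier: `T = max(floor, Q3 + 1.5·IQR)` |
| `gap_col_frac` | 0.5 | fraction | drop alignment columns with gap fraction strictly above |
| consensus cumulative frequency | 0.9 | fraction | IUPAC letter base set |
| comparison window `W` | 10 | positions | Jensen-Shannon distance window |
| group cutoff | 0.4 | normalized distance | average-linkage cut (mirrors a 0.6-identity cut) |
| `min_group_size` | 20 | clusters | reported PAM groups |
| enrichment pseudocount | 1 | count | avoids division by zero |

## Numerical and algorithmic choices

**Matcher.** The protospacer search is exact rather than heuristic: a
vectorized semi-global dynamic program computes, for every genome end
position and strand, the minimal unit-cost alignment of the whole spacer
against a window ending there (mismatches and gap columns cost 1 each; a
length-k gap costs k; any column against N is a mismatch, including N/N).
Candidate ends within the variation budget are traced back in a small
banded window with a fixed preference order (diagonal, spacer-gap,
genome-gap), which makes start coordinates and the mismatch/gap breakdown
deterministic. A placement is suppressed only when a strictly lower-cost
placement overlaps it by at least half the spacer length: without this rule
every real site would also be reported at 1–4 bp shifts (a perfect site
admits shifted placements at cost 2–4), while equal-cost overlapping
placements — e.g. in tandem repeats — are all kept. Completeness does not
rest on seeding heuristics; the DP covers every end position. The test
suite checks equivalence against an independently coded window-scan oracle
(edlib-screened) on hundreds of random spacer/genome pairs.

**Multiple alignment.** Flanked matches of one spacer are aligned with a
deterministic center-star progressive aligner (match +1, mismatch −1,
gap −2; center = longest sequence, ties lexicographic; once-a-gap-always-a-
gap merging). Consensus collapsing absorbs aligner differences, so
equivalence with any particular external MSA tool is not a contract;
determinism is. Consensus ties take the alphabetically smallest base.

**Quartiles.** `T` uses linear interpolation between order statistics
(numpy's default percentile), the most common convention; the choice is
stated so tests can be exact.

**Information content.** `I = 2 + Σ p log2 p` with `0·log2 0 = 0`; no
small-sample correction is applied, since logos are built from consensus
sequences, not raw reads. Positions covered by fewer than `min_spacers`
consensi are excluded from logos so contig-end truncation cannot fabricate
deep-position signal.

**IUPAC encoding.** A position is non-N when its information exceeds `T/2`
(the halved threshold avoids undercalling non-N bases); its letter encodes
the smallest set of bases, in decreasing frequency, reaching 90% cumulative
frequency. The string runs from position 1 to the last non-N position;
an upstream-side consensus is written adjacent-base first.

**Distance.** Per-position Jensen-Shannon distance (sqrt of the divergence,
log base 2, so one fully disagreeing one-hot position contributes exactly
1.0) summed over the first `W = 10` anchored positions of the predicted
side; absent positions are padded uniform. Summation is what produces the
multi-bit scale on which ~2 bits separates matching from non-matching
predictions; `W = 10` covers every PAM the pipeline reports. Per-position
sqrt-JSD is a metric and sums of metrics are metrics, which the suite
verifies empirically. For hierarchical grouping the distance is normalized
to `value/W ∈ [0,1]`; predictions on opposite flanks are assigned the
maximal distance 1.0 so groups are side-pure. Group consensus PAMs pool all
members' flank consensi, rebuild the logos and re-apply the pooled
threshold.

**Allelic discrimination.** A PAM placement discriminates when it (a)
matches the mutated window, (b) overlaps the mutated bases, and (c) fails
on the wild-type window at the same placement; both strands are tested by
reverse complementing the windows. A PAM matching both alleles is never
counted even when it overlaps the variant. For length-changing variants,
placements cannot be paired across alleles, so discrimination requires a
matching placement overlapping the variant on the mutated allele and no
matching wild-type placement overlapping the variant locus — the
conservative reading. `require_wt_mismatch=False` (CLI `--overlap-only`)
gives the looser, coverage-style count. Aggregation by inheritance mode
uses exact rational arithmetic before formatting.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the pipeline assumes:
uniform i.i.d. background genomes, protospacers embedded on both strands
with a position-weight-matrix PAM sampled on one flank (default: NGG-like,
0.94 G at downstream positions 2–3, ≈1.58 bits each), per-base flank noise
(default 3%, modeling escape mutations), a decoy-spacer fraction with no
genomic site (default 10%), and a fraction of sites placed against contig
ends to truncate a flank (default 5%). Loci carry plausible *cas* operon
and array bookkeeping, with ~30% of loci stored in the reversed
orientation so the orientation step is exercised. All randomness flows from
one integer seed through a single numpy Generator, so outputs are
bit-reproducible. A truth record stores every planted coordinate and is
asserted consistent with the emitted sequences after every generation.

What the generator does **not** emulate: real phage nucleotide composition
and repeat structure, sequencing error, chimeric assemblies, spacers
shared across unrelated clusters, and PAMs whose information is spread over
many weak positions. Passing tests therefore demonstrate correctness of
the inference machinery under the stated statistical assumptions, not
performance on real metagenomic data.

`simulate_invitro_library` generates randomized-PAM cleavage read pairs:
control 8-mers uniform, cleaved 8-mers satisfying an IUPAC rule with a
given selectivity, each read carrying the constant anchor used by the
extraction step.

Problem sizes used throughout the tests and the acceptance script (one
cluster of 60 spacers with 1–5 protospacer copies each in 20 × 5 kb
genomes; 200 random matcher-oracle pairs; 50-protein planted families) are
chosen so each check completes in seconds while leaving the planted signal
strongly detectable.

## Known limitations

- Greedy first-centroid-wins clustering reproduces the cited tool family's
  behavior deterministically but not bit-for-bit; refinement across levels
  is guaranteed only on well-separated inputs.
- The per-end placement enumeration can record a degenerate equal-cost gap
  placement at an end shifted by one relative to its mirror-image scan;
  site-level results are unaffected.
- "Mapped spacers" counts unique spacer sequences with a surviving
  consensus, the reading that makes the 10-spacer gate act on evidence
  units rather than raw hit counts; duplicate flanks from identical spacers
  across member loci are pooled once.
- The locus reader consumes annotation tables (CRISPR arrays, cas gene
  coordinates, Cas9 protein); locus detection itself is upstream and out of
  scope, as are assembly, tracrRNA discovery and phylogenetic association
  of PAM groups.
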