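# Methods

This note records the model conventions, parameter choices and known
limitations behind `pacfinder`. Coordinates are 0-based half-open inside
the library; GFF3 interaction and user-facing reports are 1-based
inclusive.

## The PAC scaffold and the scanner

A PAC domain is defined by its cysteine scaffold: a Gly anchor, then six
Cys residues with gaps (residues strictly between successive anchors) of
exactly 3 (Gly→Cys1), exactly 2 (Cys1→Cys2), and ranges 10–30, 20–50,
8–20 and 25–60 for the remaining spacers. The domain span runs from the
Gly through Cys6; with the default bounds its length lies in [75, 172]
residues. The "three residues between Gly and Cys1" convention (G-x-x-x-C)
is applied uniformly, matching the between-anchors convention used for
the Cys–Cys gaps; the gap is exposed as a parameter for anyone preferring
the Gly-counted-among-three reading.

**Strict mode** requires Cys-free spacers. This makes the scan
deterministic and linear: after Cys2 the next Cys in the sequence is the
only possible candidate for each ordinal, so no search-tree enumeration
is needed, and strict output is provably identical to evaluating the
regular expression
`G[^C*]{3}C[^C*]{2}C[^C*]{10,30}C[^C*]{20,50}C[^C*]{8,20}C[^C*]{25,60}C`
at every start (the test suite and acceptance script assert this against
an independent regex oracle, including on sequences engineered to
straddle the gap bounds). Surplus Cys residues *outside* the matched
span do not disqualify a protein — the count constraint concerns the
domain, not the whole sequence.

`*` (stop codons surviving in translated transcriptome frames) and `-`
are hard walls: no match may span them. `X` never matches an anchor but
is allowed inside spacers.

**Relaxed mode** admits named deviations and reports them per match:
`missing_gly` (the ancestral Chlorophyta-like candidates), up to three
`extra_cys_in_spacer` (7–9-Cys variants), one `missing_cys` restricted
to interior ordinals 2–5 (a missing terminal Cys leaves the domain
boundary undefined, so it is not searched), and per-gap slack ±s
(`gap_out_of_bounds` names the offending gap). Enumeration is
depth-first over Cys-ordinal assignments and capped at 64 chains per
anchor with a logged truncation. Strict-valid chains reappear in
relaxed output with an empty violation list.

## Bona fide gates

The three gates are pluggable: a precomputed prediction table (exported
from an external predictor such as a neural signal-peptide or
secondary-structure tool) always overrides the built-in heuristic, so
large-scale runs can use the field's standard predictors while the
package remains self-contained.

*Signal peptide.* The built-in heuristic requires, within the first 35
residues, an 8-residue window containing ≥6 hydrophobic residues
({A,I,L,F,V,M,W,C}; the h-region) preceded by an n-region of net charge
≥ 0 (K/R minus D/E). The cleavage site is placed three residues (a short
c-region) after the hydrophobic run. Frame-translated records lacking an
initial Met return `unknown` rather than `fail` — an incomplete contig
may simply be missing its N-terminus — and `unknown` never excludes a
candidate; it is recorded in the report.

*Secondary structure.* The crystal-structure reference fold is a
seven-stranded β-barrel, and candidates with no predicted strands or
dominating helices are decoys. The gate quantifies this as: ≥3 E-runs of
length ≥3 within the match span, and helix fraction ≤0.5. Both
thresholds are package choices (the qualitative rule "no β-sheets /
large α-helices" fixes no numbers) and are exposed in `SsParams`. The
bundled fallback predictor is deliberately simple and deterministic:
per-residue helix/strand/turn propensities (Chou–Fasman scale, with the
turn column serving as the coil propensity) averaged over a centred
window of 5, argmax per position. It separates strongly helix-forming
from strongly strand-forming stretches, which is all the gate needs; it
is *not* a substitute for a modern predictor on real proteins, and
externally computed H/E/C tracks should be supplied where available.

*Foreign domains.* Any external domain hit with e-value ≤ 1e-5 whose
accession is not allow-listed fails the gate. The default allow list is
{PF01190, PS00925} — the pollen Ole e 1/PAC accessions themselves;
associated-domain detections (extensin, Pro-rich, His-rich, AGP-like,
W-W) are produced by this package's own detectors and never counted as
foreign.

## Associated domains and classification

Detector thresholds quantify qualitative field definitions and are
centralised in `DetectorParams`:

| detector | rule | score |
|---|---|---|
| extensin | S-P(≥2) instances merged within 30 aa, ≥3 instances | instance count |
| Pro-rich | 20-aa windows with Pro fraction ≥0.3, merged | Pro fraction |
| His-rich | ≥4 His in a 6-aa window, trimmed to His | His count |
| AGP-like | 20-aa windows with {AP,PA,SP,TP,VP} dipeptide coverage ≥0.3 | coverage |
| W-W | first W-X8-W anchor at/after the PAC end, extends to C-terminus | 1 |

Classification works on the mature sequence (signal peptide masked;
annotations are trimmed to start after it). A PAC is terminal when the
opposite flank is at most max(30, 10% of mature length); "whole" when it
covers ≥80% of the mature protein with no other annotation. Decision
order: extensin on both sides → Type 4 (central); whole → Type 1;
N-terminal with downstream annotations or a >30-residue tail → Type 2
(`ww_2prime` flagged when a W-W annotation follows); C-terminal with
His-rich/Pro-rich/AGP-like upstream → Type 3; anything else is
unclassified. Because merged detector windows can bleed a few residues
into the domain span, flanking annotations are assigned by their
midpoint relative to the PAC span. A Type 2 candidate may carry both a
Pro-rich region and a W-W domain; both are recorded. Proteins with
several non-overlapping strict matches are classified on the most
N-terminal one and flagged `multi_pac`. The `conserved_1prime` subtype
flag is set for Type 1 domains with ≥60% global identity to any sequence
of a user-supplied highly-conserved reference set; 60% is the lower edge
of the identity range observed for that subtype.

## Genome context

The diagnostic gene structure places an intron strictly between the last
nucleotide of the Cys2 codon and the first nucleotide of the Cys3 codon
(protein position p occupies CDS nucleotides [3p, 3p+3)). A gene with no
intron across the PAC span is `none`; an intron anywhere else in the
span is `atypical`.

Tandem duplication is not quantified in the field's usage beyond
adjacency, so the default is: PDP genes on one scaffold with at most one
intervening non-PDP gene, chained by single linkage when their PAC
domains (amino-acid spans only, not whole proteins) share **strictly
more than** 85% identity. Orientation is reported but not filtered on —
observed tandem arrays contain mixed orientations. Output is invariant
under reversal of the genomic coordinate direction.

## Similarity

`global_align` is Needleman–Wunsch/Gotoh at the classic needle defaults:
BLOSUM62, gap open 10, gap extend 0.5 (a gap of length L costs
10 + 0.5·(L−1)), terminal gaps free. Identity is identical
standard-residue columns over the alignment length; similarity is
columns with a positive substitution score. `X` and `*` score 0 against
everything and are excluded from identity, which preserves
identity ≤ similarity on X-containing sequences (both self-identity and
self-similarity fall below 100 for such sequences, deliberately).
Traceback ties are broken deterministically — diagonal, then up, then
left — and the implementation is checked against an independent
pure-Python dynamic-programming oracle and, for scores, against
Biopython's `PairwiseAligner` under the same parameters. Whether
reported percentages should be computed over the alignment length or
the shorter sequence is a genuine convention choice; the alignment-length
(EMBOSS) convention is used.

Per-species dedup clusters domains by single linkage at identity ≥ the
threshold (default 85%) and keeps the longest member per cluster (ties:
lexicographically smallest id). Distance matrices are 100 − identity,
written in relaxed PHYLIP for external tree building; multiple alignment
and maximum-likelihood phylogeny remain external to this package.

## Conservation profiles

Per-column information content is log2(20) minus the Shannon entropy of
the gap-excluded residue frequencies, scaled by the non-gap fraction so
gappy columns score low (gap treatment is a package decision). The
consensus shows the plurality residue when its gap-excluded frequency is
≥0.5, else `x`. `top_motif` returns the width-w window maximising mean
IC (ties leftmost). De novo motif discovery is out of scope; profiles
are extracted from supplied alignments, and PROSITE patterns (subset:
residue, `[SET]`, `x`, `x(n)`, `x(n,m)`) are matched exhaustively,
reporting overlapping matches and multiple ends per start. Mean window
IC is this package's conservation metric and is not comparable to motif
E-values from discovery tools. `map_accessibility` joins a profile with
per-residue RSA and secondary structure of a designated representative
row; buried is RSA < 0.2 (common convention, configurable), and columns
above the IC threshold are labelled "core" (buried) or "candidate
functional site" (exposed).

## Structure QC

`check_disulfides` passes a model only when the SG–SG pairs Cys1–Cys5,
Cys3–Cys4 and Cys2–Cys6 are within the bonding threshold *and* no other
ordinal pair is. The threshold default is 2.5 Å — the ~2.05 Å covalent
S–S bond plus modelling slack; no cutoff is standard in the source
procedure (which imposed bridges as modelling constraints), so it is
configurable. The "no extra pair" condition is enforced explicitly and
extras are reported rather than silently passed.

Solvent accessibility is Shrake–Rupley: each atom's accessible sphere
(van der Waals radius + 1.4 Å probe) sampled with a deterministic golden
spiral (default 960 points), occluded points removed. Relative solvent
accessibility normalises per-residue area by the residue's own
isolated-atom surface by default (`reference="self"`), which is exact
for the coarse synthetic models used in testing; `reference="gxg"`
switches to the conventional Gly-X-Gly theoretical maxima for full-atom
models. Values are clipped to [0, 1.2]. Secondary-structure strand
counting consumes externally computed tracks (e.g. DSSP exports) or the
fallback predictor; DSSP itself is not reimplemented.

## Synthetic data: what it emulates, and what it does not

The generator builds secreted multi-domain proteins whose every planted
feature is recoverable by construction: a cleavable signal peptide
(M + 1–3 K/R + 8–11 hydrophobic + SSA), a PAC domain with spacers drawn
uniformly inside the canonical bounds, type-specific associated blocks,
gene models with the diagnostic intron and canonical GT..AG splice
sites, tandem clusters with calibrated identity, and coarse structures
realising the expected disulfide geometry. All generators are
bit-reproducible given a seed.

Two deliberate composition constraints keep planted truth unambiguous.
Spacers exclude Cys (strict domains are Cys-free between anchors) and
Gly, so the planted Gly is the only possible anchor and the strict match
is unique. Spacers and linkers also exclude His, Pro and Trp so the
associated-domain detectors fire only on planted blocks. Spacers
alternate β-strand-favouring (V/I/Y/F/T) and coil blocks (S/N/D),
guaranteeing the secondary-structure gate passes corruption-free domains
under the fallback predictor; the `helix_decoy` corruption swaps in
A/E/L/M spacers instead. Corruptions are single-fault by default so each
gate is tested in isolation: `missing_cys` (Cys3→Ser), `extra_cys` (a
surplus Cys planted close to Cys5, where it can neither terminate nor
re-anchor a strict chain), `gap_violation` (Cys3–Cys4 spacer 19 or 51),
`missing_gly`, `helix_decoy`, `foreign_domain` (a confident PF00171 hit
emitted alongside), and `no_signal_peptide` (a 41-residue polar leader).

Tandem clusters mutate disjoint spacer-site sets per gene copy,
k = round(L·(100−t)/200) sites each, so any two copies differ at exactly
2k positions and realized pairwise identity lands within ±3 points of
the target.

Consequently, passing tests demonstrate the *pipeline's* correctness —
exact span recovery, exact type calls, gate selectivity — under clean,
composition-controlled conditions. They do not demonstrate performance
on real proteomes, where signal peptides are heterogeneous, spacer
composition is unconstrained, associated domains are degenerate, and
secondary-structure prediction is the accuracy bottleneck; on real data
the pluggable gates should be fed external predictor tables. No
evolutionary divergence model is simulated (no substitution-model
simulation along trees).

## Problem sizes and numerics

The acceptance script scans 10,000 random sequences (length 50–500, Cys
frequency 1–10%) plus 1,000 planted boundary-straddling sequences under
the default rule and 200 such sequences under each of 20 perturbed
rules; recovery uses 1,000 corruption-free PDPs (250 per type) and 100
records per corruption class; the aligner check uses 200 random pairs of
length ≤60; intron round-trips use 300 gene models; the disulfide check
uses 100 random rigid-body transforms (QR-orthogonalised Gaussian
rotations). These sizes make the whole script run in well under a
minute while keeping every estimate's sampling error negligible against
its pass margin. Floating-point comparisons in tests use exact equality
only where the arithmetic is exact (span bounds, counts), 1e-9 for
information content, and stated tolerances elsewhere (RSA ±0.05,
point-doubling drift <0.02).

## Known limitations

- The built-in signal-peptide and secondary-structure heuristics are
  calibrated for gate *logic*, not for predictive accuracy on real
  sequences; external predictions override them for production use.
- Relaxed-mode enumeration caps at 64 chains per anchor; pathological
  Cys-dense sequences with generous tolerances may be truncated (logged).
- `dedupe` computes all within-species pairs (O(n²) alignments); for
  thousands of domains per species, pre-clustering is advisable.
- The PROSITE subset covers the syntax needed for the Ole e 1 consensus
  and similar patterns; `<`/`>` anchors and `{}` exclusions are not
  implemented.
- Homology modelling, model-quality scoring, stability (ΔΔG) prediction
  and phylogenetic tree building are out of scope; the package prepares
  their inputs (deduped FASTA, distance matrices) and consumes their
  outputs (H/E/C tracks, PDB coordinates).
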