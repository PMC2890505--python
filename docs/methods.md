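# Methods

## Scope and data model

The package analyzes Type II restriction–modification (R-M) systems at the
sequence level. Its core objects are IUPAC-degenerate nucleotide sequences
(`NucSeq`, linear or circular), protein sequences with `X` for residues an
Edman read could not identify, position-set motif models, and R-M loci
(a sequence plus R/M/C genes with 1-based inclusive coordinates and
strands). Degenerate positions are treated set-theoretically throughout:
two IUPAC codes "match" when their base sets intersect, and the complement
of a code is the code denoting the set of complemented bases.

## Degenerate primer design

Back-translation maps each residue to one IUPAC codon from a table whose
entries are validated exhaustively at load: every concrete expansion of an
entry must translate to exactly that amino acid. This excludes, for
example, YTN for leucine (it would also cover TTY = Phe); the shipped
defaults are YTR/CTN/TTR for Leu, CGN/AGR for Arg, TCN/AGY for Ser, and
the unique exclusive codon families for the rest. `X` back-translates to
NNN with the caveat that it multiplies degeneracy by 64. Sense primers
trim surplus bases from the 3' end of the back-translation; antisense
primers trim from the 5' end and reverse-complement, so the primer's 3'
end always faces the peptide interior — the convention that reproduces
both published primer trims (dropped initiator A, dropped wobble R).
Degeneracy is the product of per-position set sizes; binding-site search
reports every placement on either strand (wrapping the origin on circular
templates) with at most the allowed number of set-disjoint positions.

## Motif models and scanning

Motif blocks are written in a small pattern language: literal residues,
residue sets `[DNS]`, any-residue `x`, bounded spacers `x(m,n)`, and
conservation-group wildcards `@VLIM` that match at half weight. A hit's
score is the mean per-position weight over non-spacer elements, so a score
of 1.0 means every position matched a literal set and group-wildcard
matches pull the score toward 0.5. `X` matches nothing, so Edman unknowns
cannot create spurious hits. The scanner enumerates all start positions
and spacer lengths (verified against a brute-force matcher in the tests).

Default patterns distill the prose consensus of each block: I = `G-x-G`,
II = `[DE]-[IL]`, IV = `[DNS]-P-P-Y` (variant = first residue), V-family =
`D-L-Y-x-x-A-[GS]`, VI = `G-x(1,6)-[VLIM]`; motifs VII and X have no
residue consensus and are found as 5-residue windows with ≥4 hydrophobic
residues (V,L,I,M,F,Y,W,A), reduced to locally maximal windows. Motifs III
and VIII have no usable consensus and ship disabled; motifs IVa and Xa
have figure-only consensus, so they must come from user configuration (the
synthetic generator plants clearly labelled synthetic stand-in patterns
for them). Motif X is scanned over the whole protein by default: an
N-terminal-only scan would presuppose an α/γ architecture, and in β-group
proteins it both misses the true X (which follows the TRD) and invites
spurious N-terminal windows. Endonuclease catalytic sites use the same
machinery as dyad–spacer–tail models (`[PD]-D x(21,21) E-V-K` and the
Mrr-like `D-D x(20,20) Q-I-K`), reporting the observed spacer length.

## Architecture classification

One hit per motif label is selected under three constraints: chosen hits
do not overlap; within each cluster the labels appear in canonical order
(Xa-X-I-II-III; IV-IVa-V-VI-VII-VIII); and the two clusters form
contiguous blocks along the sequence. The contiguity constraint encodes
that all three architecture groups keep each cluster together — allowing
interleaving lets equal-scoring background matches scatter a cluster
across the TRD. Selection is exact: a per-cluster chain dynamic program
(best chain ending at, and starting at, every hit) plus a boundary
combination, optimizing total score with additive tie-breaks (smaller
summed cluster span, then smaller sum of starts, then of ends). The best
assignment per cluster-ordering class is then compared across classes by
total score and, on ties, by the longest motif-free span left over: when a
random TRD segment happens to contain a compact fake cluster, the reading
that preserves one clean domain-sized span wins. The test suite checks
this two-stage objective against exhaustive subset enumeration for
batteries of up to ~10 candidate hits.

The TRD is the longest hit-free span (N-terminal, inter-hit, or
C-terminal) of at least 40 aa — a TRD is a domain, not a linker; the floor
is configurable. Group assignment compares cluster positions, summarized
by the median start of each cluster's chosen hits (robust to one stray
hit), with the TRD span: AdoMet < TRD < catalytic → α; catalytic < TRD <
AdoMet → β; AdoMet < catalytic < TRD → γ. Calls require motif IV plus at
least one of V/VI/VII, and at least two of X/I/II/III; anything weaker is
`unclassified` with the failing criterion in the evidence list. The
subgroup flag requires γ order, IV variant D, and both IVa and Xa. These
presence thresholds are policy (the source material does not quantify how
many motifs may be missing); they are recorded in every output's evidence
column.

## Comparative analysis

Pairwise alignment delegates to Biopython's `PairwiseAligner` with
BLOSUM62; the default gap penalties are the common database-search values
(open 11, extend 1, in BLAST accounting — internally open_gap_score −12 /
extend −1). Local mode is the default, since published percent-identity
figures for protein pairs typically come from local database alignments;
global mode is used for controlled tests and distance matrices. Identity
and similarity percentages are computed over columns where neither row is
gapped; "similar" means identical or sharing one of the six conservation
groups; `X` counts as neither. Distances are d = 1 − identity fraction.

The minimum-linkage tree is agglomerative single-linkage clustering,
implemented in-package because the contract requires a deterministic
lexicographic tie-break on cluster representative labels that library
implementations do not guarantee; scipy's `linkage` serves as an
independent cross-check of merge heights in the tests, and a naive
re-implementation checks merge order. Branch lengths are ultrametric
(leaves at height/2 per merge) and the final bifurcation is suppressed
into a trifurcation for the unrooted convention. The force layout is a
Fruchterman–Reingold variant with attraction k·s_ij·d, uniform repulsion
k²/d, and linear cooling from 0.1·√n over the iteration budget, seeded for
reproducibility; it is deliberately simple and is validated statistically
(planted two-family similarity separates in ≥9/10 seeds).

## R-M locus logic

ORF arithmetic: a complete ORF of 3(n+1) bp (start..stop inclusive)
encodes n residues. Intergenic gaps count the bases strictly between
translated extents; orientation is read off the strand pair (divergent
when the upstream gene points away). Cleavage uses between-base cut
offsets from the recognition start (offset 3 on both strands for the
blunt TCG↓CGA cut); fragments concatenate exactly to the input.
Methylation is an explicit set of per-position marks — a helper auto-marks
Dam (GATC) adenines — and blocking rules are context patterns over the
site and flanks: Dam methylation of the overlapping TCGCGATC context
blocks NruI but not Sbo13I, and both enzymes cut the unmethylated context.
Inverse PCR digests the genome, circularizes each fragment, and reports
every plus/minus primer pairing on one circle as a product running from
the plus primer's 5' end forward around the circle to the minus primer's
5' end, flagging products that span the self-ligation junction; a
string-surgery oracle verifies the junction products in the tests. The
N6mA/N4mC call is a transparent enumerated vote (dot-blot signals, Mrr
restriction, Dam-overlap cleavage, homology hint) — majority wins, ties
are inconclusive, and every vote is echoed in the rationale. A note on the
source record: the intergenic gap of the NruI-like layout is stated in two
places as 350 bp and 326 bp; the package's fixtures use 326 bp, the value
consistent with the stated gene coordinates, without resolving the
discrepancy.

## Synthetic data

The generator is the package's test bed. `gen_mtase` plants sampled motif
instances in the canonical order of the requested group (α, β, γ, or
subgroup) on a uniform-random background (default length 320 aa), with
4–12 aa linkers between blocks and a TRD spacer of at least 60 aa at the
group's position; motif IV is planted with the group's variant (NPPY for
γ, DPPY for α/β/subgroup). Noise substitutes a given fraction of residues
outside planted motifs (inside only on request), so planted architecture
survives by construction at the noise levels used. `gen_family` duplicates
a random parent into two clades (deep branches default to 5× the leaf
substitution count) and mutates with substitutions biased to stay within a
conservation group with probability 0.7. `gen_rm_locus` emits ORFs
(ATG…stop, configurable GC fraction for high-GC hosts) in requested
orientations and gaps, plants recognition sites or Dam-overlap contexts at
stated positions, and scrubs accidental recognition sites so planted
geometry is exact. All generators are deterministic per seed and their
truth coordinates are verifiable by slicing the emitted sequences.

What the generator does not emulate: insertions/deletions, realistic
residue composition or rate heterogeneity, motif degeneration over
evolutionary distance, and overlapping or nested genes. Passing recovery
tests therefore demonstrates correctness of the scanning/classification
machinery under the stated conditions, not classifier performance on
diverged natural sequences.

## Problem sizes and determinism

The shipped acceptance computation uses 50 synthetic proteins per group
per noise level (320 aa), 20 family runs of 6 leaves for tree recovery,
and 10 layout seeds; these sizes give stable 100% rates across seeds while
keeping a full run in seconds. All randomness flows from explicit seeds;
reruns are byte-identical, which the pipeline tests assert.

## Known limitations

- Motif IVa/Xa consensus is configuration-only; without user patterns the
  subgroup flag can never be set (the γ call is unaffected).
- Percent-identity reproduction for published protein pairs depends on the
  original alignment program and parameters, which are not stated with the
  figures; the default local configuration is a reasonable stand-in, not a
  re-derivation.
- The classifier assumes a single methyltransferase domain per protein;
  fusions or tandem domains will produce one (arbitrary but deterministic)
  reading.
- Circular-permutation handling for 5mC-type methylases is out of scope.
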