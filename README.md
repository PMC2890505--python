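# mtase-architect

Sequence-analysis toolkit for characterizing restriction–modification (R-M)
systems and classifying amino-methyltransferases by their conserved-motif
architecture. It is aimed at the workflow of cloning an R-M system from a
partial protein sequence: design degenerate inverse-PCR primers from an
Edman peptide, analyze the recovered locus (gene orientation, intergenic
gaps, recognition/cleavage sites, methylation sensitivity), scan the
methyltransferase for its conserved motif blocks, and place it among the
α/β/γ architecture groups — including the NruI/Sbo13I-like γ subgroup
(γ motif order with a DPPY P-loop plus two extra blocks, IVa and Xa).

## The model

N4-cytosine and N6-adenine methyltransferases carry two conserved motif
clusters — the AdoMet-binding region (motifs X–I–II–III) and the catalytic
region (motifs IV–VIII, anchored by the [D/N/S]PPY P-loop) — separated from
a variable target-recognition domain (TRD). The linear order of the three
regions defines the group:

    α:  X–I–II–III — TRD — IV–V–VI–VII–VIII    (motif IV = DPPY)
    β:  IV–V–VI–VII–VIII — TRD — X–I–II–III    (motif IV = DPPY/SPPY)
    γ:  X–I–II–III–IV–V–VI–VII–VIII — TRD      (motif IV = NPPY)

Motifs are modeled as residue-set patterns (e.g. `[DNS]-P-P-Y`,
`G-x(1,6)-[VLIM]`) or hydrophobic windows and scanned exhaustively; one hit
per motif is then chosen by maximizing total match score subject to
non-overlap, canonical within-cluster order, and cluster contiguity, with
ties resolved toward compact clusters and the largest motif-free span
(the presumptive TRD). The group call compares cluster median positions
with the TRD span; the subgroup flag requires γ order, a DPPY motif IV,
and both IVa and Xa.

Comparative analysis uses percent identity and percent similarity over
gap-free alignment columns, where "similar" means sharing one of the
conservation groups (E,D,Q,N), (V,L,I,M), (F,Y,W), (G,P,A), (K,R), (S,T);
families are summarized by a minimum-linkage (single-linkage) unrooted
distance tree (d = 1 − identity fraction) and a Fruchterman–Reingold-style
force layout whose attraction is proportional to pairwise similarity.

## Worked example

Reconstruct the degenerate inverse-PCR primers from the two ends of the
N-terminal endonuclease peptide MGFLADXDLSYDEINELLTDN:

```
$ mtase-architect backtranslate YDEINE --len 17
TAYGAYGARATHAAYGA (degeneracy 48)

$ mtase-architect backtranslate MGFLAD --strand antisense --len 17 --codon L=TTR --phospho
Pho RTCNGCYAARAANCCCA (degeneracy 128)
```

The sense primer covers all 48 codon combinations of YDEINE (trimmed to
17 nt); the antisense primer is the reverse complement of the MGFLAD
back-translation (Leu restricted to TTA/TTG), 5'-phosphorylated for the
ligation step.

Generate a synthetic methyltransferase family and classify it:

```
$ mtase-architect simulate mtase --out syn --seed 5 --n 3
$ mtase-architect classify syn.fasta --motifs syn.motifs.cfg | cut -f1-4
id              group   subgroup  order
syn_subgroup_5  gamma   True      Xa-X-I-II-IV-IVa-V-VI-VII-TRD
syn_subgroup_6  gamma   True      Xa-X-I-II-IV-IVa-V-VI-VII-TRD
syn_subgroup_7  gamma   True      Xa-X-I-II-IV-IVa-V-VI-VII-TRD
```

Each protein is called γ-group with the subgroup flag set: the motif order
is γ-like, motif IV is DPPY, and the extra Xa/IVa blocks are present. An
R-M locus report:

```
$ mtase-architect simulate locus --out loc --seed 2
$ mtase-architect locus loc.fasta loc.genes.tsv
gene_a  gene_b  orientation  gap_bp  overlap
nruIR   nruIM   divergent    326     False
```

The R (660 bp → 219 aa) and M (804 bp → 267 aa) genes are transcribed
divergently with a 326-bp non-coding gap. `mtase-architect run` wires
scan → classify → distance matrix → tree → layout into one report bundle;
`digest`, `ipcr` and `methcall` cover cleavage maps, inverse-PCR product
prediction and the N6mA/N4mC evidence vote.

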