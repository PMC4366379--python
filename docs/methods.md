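# Methods

## The problem and the model

Plastid–nuclear incompatibility in wide pea crosses behaves as a
Bateson–Dobzhansky–Muller interaction between a plastid-encoded subunit
and nuclear-encoded partners of the same multi-subunit enzyme. The
package models the candidate system around the heteromeric plastid
acetyl-CoA carboxylase (ACCase): the plastid gene *accD* encodes the
β-subunit of carboxyltransferase, whose nuclear partners in the complex
are the biotin carboxyl carrier protein (BCCP, the *Bccp3* candidate for
the incompatibility locus *Scs1*), biotin carboxylase and α-CT.

The compatibility model abstracts two independent molecular features of
the accD product as boolean *determinants*: a **primary** determinant
(the change set exclusive to the incompatible cytoplasms) and a
**secondary** determinant (the tandem duplication of the ISDTND
hexapeptide at alignment columns 124–135; an equivalent predicate uses
the length of the adjacent poly-E stretch). Each determinant requires a
fitted nuclear **binding site**. A cross (cytoplasm donor × nuclear
donor) is scored by strict rule order:

1. cytoplasm carries the primary determinant → `compatible` iff the
   nuclear side has the primary binding site, else `incompatible`
   (the primary *masks* the secondary entirely);
2. otherwise, cytoplasm carries the secondary determinant →
   `compatible` iff the secondary binding site is present, else
   `incompatible`;
3. otherwise (no determinants) → `partial` if the nuclear side carries a
   *vacant* secondary binding site (reduced pollen fertility, no
   lethality), else `compatible`.

The vacant-site rule is applied uniformly, including to the
721 × VIR320 combination whose published classification is ambiguous; a
single consistent rule was preferred to per-cross exceptions, and that
combination is excluded from the example-cross checks. The outcome scale
is deliberately qualitative (three classes); pollen-fertility
percentages are not modelled.

State inference (`infer_states`) is a complete backtracking search over
the 16 flag combinations per accession, pruning a partial assignment as
soon as any observed cross among assigned accessions is contradicted. It
returns *all* consistent joint assignments and reports per-flag
identifiability: a flag is identifiable when it takes one value across
every solution. With the full observed cross set for the five study
accessions, 18 of 20 flags are identifiable; the secondary-determinant
flag of the two primary-carrying cytoplasms is masked and hence free
(4 consistent assignments). On unsatisfiable inputs the module reports a
minimal (greedy-deletion) conflicting outcome subset rather than raising.

## Variant screen

Query plastomes are compared to the reference by global alignment
(edlib, edit-distance optimal) rather than by re-assembly; the analysis
consumes a difference list, not reads. Post-processing makes calls
canonical and deterministic:

* runs of adjacent mismatch columns merge into one (possibly
  multi-nucleotide) substitution record, so several substituted bases in
  one codon are a single record, matching amino-acid-level counting;
* indels are left-normalized through homopolymer/repeat context;
* clusters of events separated by ≤ 10 matching bases that contain an
  indel are re-normalized (merged, prefix/suffix-trimmed, re-emitted):
  optimal alignments can split one long indel into equal-cost pieces,
  and the canonical form is the single indel. Pure substitution
  neighborhoods are never merged — adjacent same-type events separated
  by at least one matching base stay distinct;
* clusters spanning ≥ 30 bp with ≥ 40 % mismatch density whose query
  segment is the (approximate, ≥ 80 % identity) reverse complement of
  the reference segment are flagged as a single `inversion` record with
  no effect classification — inversions are reported descriptively only.

Genomes with < 50 % alignment identity are rejected as non-colinear.
Effects are classified under NCBI translation table 11
(bacterial/plastid): `synonymous` iff every affected codon translates
identically; indels are `inframe_indel` iff the length change is a
multiple of 3; any variant disrupting the annotated start codon is
`start_loss` (dominant), then stop-codon disruption is
`stop_loss_extension`. A variant overlapping a CDS boundary (e.g. a
deletion spanning the 5′ UTR and start codon) is assigned to the CDS.

The funnel (`pattern_filter` → `funnel_counts` → `nominate_loci`) keeps
variants present in *all* incompatible-cytoplasm accessions and absent
from *all* compatible ones, partitions them into
noncoding / synonymous / non-synonymous / indel bins (a conservation
invariant: the bins sum to the filtered count), and ranks loci by
non-synonymous + indel counts, ties alphabetical. Two counting
conventions coexist on purpose: the screen counts *variant records*
(accD: 8 substitution records), while the exclusive-difference protein
table counts *replaced residues* (accD: 7); they answer different
questions and are not forced to agree.

## Protein analysis

`derive_protein` translates an annotated CDS and handles two observed
disruptions: a lost start codon triggers an in-frame scan for the first
downstream ATG within 60 codons (the observed alternative-start product
begins 11 codons downstream, so 60 is a generous cap; non-ATG starts are
unattested here and not considered), and a lost stop codon extends
translation into downstream sequence to the next in-frame stop
(`readthrough`).

`align_proteins` is a deterministic center-star scheme: every sequence
is aligned to the first by global Needleman–Wunsch (BLOSUM62, gap open
−10, extend −0.5, Biopython `PairwiseAligner`) and merged on the
center's coordinates, allotting each center position the longest
insertion observed. Input order is fixed (reference first), which fixes
the alignment. For the study loci the alignments are instead
*reconstructed* exactly from the shipped variable-position tables (see
Fixtures), which is the reporting frame of record.

`variable_position_table` reports in 1-based alignment columns. Per
column, each non-reference sequence contributes an atomic event
(replacement to a given residue, deletion, insertion of a given
residue); maximal runs of adjacent columns whose event and occurrence
set are identical merge into one row (giving multi-residue rows such as
`SD>IH`, and splitting insertions at one column by inserted residue). A
deletion run starting at column 1 is reported as N-terminal `absence`, an
insertion run ending at the last column as C-terminal `addition`. Long
indel rows (> 10 residues) omit the residue string. `exclusive_differences`
keeps rows whose occurrence set equals the target set exactly.

`find_tandem_repeats` enumerates every maximal tandem array
(copies ≥ 2): maximality means the copy count at the start is maximal
and the array cannot be extended by a full unit to the left; overlapping
arrays of different unit lengths are all reported (unit length 1 is
labelled a homopolymer run). `poly_run` returns the longest
single-residue run, leftmost on ties. `scan_zinc_finger` matches the
fixed-spacing motif C-x(2)-C-x(15)-C-x(2)-C, overlaps allowed.

## Counterpart search and linkage

The complex-partner table is a curated static YAML asset (the lookup is
a literature step, not a computation): accD → ACCase partners; rpoB →
PEP-associated factors (sigma factors, CSP41, FeSOD3, PTK); ycf1 → TIC
complex (Tic100, Tic56, Tic20-I); ycf2 → none known. Interval filtering
counts genes within the interval, counts literal
`"hypothetical protein"` descriptions, and matches keywords as
case-insensitive substrings.

RIL genotypes are A/B homozygous calls (F6 selfed lines); residual
heterozygotes are coded missing and excluded pairwise. The observable
recombinant fraction R converts to per-meiosis r by the
Haldane–Waddington relation for selfing RILs, r = R/(2 − 2R), and to map
distance by Haldane's function d = −50 ln(1 − 2r) cM. Three-point
ordering minimizes apparent double recombinants (flanks agree, middle
differs); ties are flagged ambiguous, never broken silently. Ordering —
the claim that matters — is independent of the mapping function.
Multipoint likelihood mapping is out of scope.

## Fixtures and the synthetic-data generator

The study's variable-position tables are shipped as TSV assets (29 accD
rows, 10 Bccp3 rows). The published alignment figures are not
machine-readable, so the reference profiles (WL1238 accD, 590 aa over a
610-column alignment; Bccp3, 290 aa) are **synthetic**: deterministic
sequences constructed to satisfy every tabulated constraint — the named
residues of every change row, the ISDTND duplication at columns 124–135
and its extra copy at 151–156, poly-E runs of 3/3/6/4/3 residues
(WL1238/JI1794/721/L100/VIR320), one CX₂CX₁₅CX₂C motif containing column
240, a methionine at residue 12 (so start loss yields the 579-residue
alternative product), and gap columns at 141–143, 175–180, 399–401 and
603–610. Filler positions draw from an alphabet excluding E, C and the
ISDTND letters so no motif-bearing feature can arise by accident.
Reconstructing the five accession rows from (profile + table) and
re-tabulating reproduces the shipped tables row-for-row; Bccp3's
alignment length is fixed at 290 by convention. The syntenic Medicago
interval table is likewise a synthetic emulation (166 genes, 70
hypothetical) carrying the real anchor GeneIDs.

The genome-panel generator lays out a ~15 kb plastome-like reference
(nine CDS loci with spacers and introns — small enough that the full
suite runs in seconds, large enough for anchor-unique alignment) and
plants variants with guaranteed effect class, editing local context so
that left-normalized calling recovers records exactly (planted spans are
separated by ≥ 30 bp; deletion/insertion boundaries are chosen so
normalization cannot drift). Its default composition *is* the study
design: 15 noncoding variants over 14 regions, 5 synonymous in 3
further loci, accD 8 non-synonymous + 3 indels (a 21-bp start-spanning
deletion, an 18-bp in-frame insertion, a 6-bp in-frame deletion), rpoB 1,
ycf1 3, ycf2 2 — all in the incompatible-only pattern — plus decoys that
violate the pattern. The RIL generator draws the first locus at 1/2 and
flips each interval with probability R = 2r/(1+2r), independently per
line; a fixture mode reproduces the 88-line mapping population (5
crossovers between the flanking markers, split 3/2 around the middle
locus, and a phenotype-assigned column identical to the middle locus).
One integer seed drives all generators through deterministically derived
substreams; identical seed + config gives byte-identical output.

What the generator does **not** emulate: sequencing reads and their
error models (homopolymer miscalls), mitochondrial/nuclear
contamination, structural variation beyond simple inversions, selection
or segregation distortion in RILs, and quantitative fertility. Passing
tests therefore demonstrate correctness of the analysis logic on
idealized assemblies and genotype tables, not robustness to assembly or
genotyping error.

## Numerical and reporting conventions

Internal coordinates are 0-based half-open; every table and report is
1-based inclusive. Circular genomes are linearized at the reference
origin; fixtures never place features across the origin. Assembly-gap
lengths are counted at the length of the corresponding reference region,
located by exact-matching 30 bp flanking anchors that must be unique in
the reference (non-unique or missing anchors are an error, not a guess).
CAPS site matching is IUPAC-degenerate, case-insensitive, both strands,
overlaps allowed; fragment lengths cut `cut_offset` bases into each site
(default: the middle) and always sum to the amplicon length. Reported
cM values are derived quantities; no figure-only map distances are
asserted anywhere.

## Problem sizes

The default test suite and the acceptance script use: 15 kb genome
panels (5 accessions), 88-line RIL fixture plus one 10 000-line
simulated population, 100 forward-simulated cross panels of 4–6
accessions, and exhaustive tandem-repeat checks over all strings of
length ≤ 7 plus 300 sampled strings of length ≤ 30. The whole suite runs
in a few seconds on one CPU.

## Known limitations

* The center-star protein aligner is adequate for near-identical allelic
  series but is not a general progressive MSA; heavily diverged inputs
  would deserve a profile-based aligner.
* Inversion detection assumes the inverted segment is long and random
  enough to look like a dense mismatch cluster; short or
  palindrome-heavy inversions may be reported as ordinary variants.
* `infer_states` enumerates all solutions; with very few observations the
  solution set grows exponentially in the number of unconstrained flags.
* The screen assumes colinear genomes (one inversion-flagging path
  aside); rearranged plastomes need upstream synteny handling.
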