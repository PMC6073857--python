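# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data does and does not emulate, and the
numerical choices made where the design was open.

## Signal-peptide model

Secretory signal peptides are 10–40 residues: a short n-region with a
basic residue, a hydrophobic h-region, and a c-region whose −3 and −1
positions favour small residues (Ala/Gly/Ser/Cys). The predictor scores
every candidate cleavage position p ∈ [10, 40] as

    score(p) = max over 8-residue windows ending ≥ 3 before p of
                 [ mean Kyte-Doolittle hydropathy
                   − 0.25 · max(0, gap − 3) ]
               + 1.0 · [small residue at −1] + 1.0 · [small at −3]
               + 0.5 · [≥1 Lys/Arg in residues 1–5]

where `gap` is the distance from the window end to p. The gap penalty is
deliberate: without it, any small-residue pair downstream of a strong
h-region scores as well as the true site, because the best upstream
window is a running maximum. With it, the (-3,-1) site immediately after
the h-region wins exactly. A peptide is called present when the best
score reaches the cutoff (default 3.5, calibrated so that h-regions of
Leu/Val/Ile score ≈ 6 and hydrophilic N-termini score ≈ 1–3). The
heuristic is a transparent stand-in for black-box signal-peptide
predictors; only its decision (presence + cleavage position) feeds
downstream stages.

## Convertase cleavage grammar

Dibasic motifs KR, RR, KK are always cleavage sites. A monobasic R is a
site only with a basic residue at −2, −4 or −6, or when it ends the
proprotein; furin-style R-X-X-R is available but off by default. Motifs
are consumed greedily left-to-right so reported sites never overlap, and
the basic residues of a motif are the ones removed (carboxypeptidase
trimming). Fragments between sites become mature peptides: a trailing
Gly is the amide donor (removed, C-terminus rendered `…amide`), a
leading Gln marks pyroglutamate (rendered `pQ…`). Fragments shorter than
4 residues after processing are discarded — short enough to keep every
canonical crustacean peptide (RPCH's 8-residue core) while dropping
inter-motif shrapnel. Pyroglutamate applies to Gln only; all canonical
pQ peptides derive from Gln. Fragment partitioning is exactly
conservative: fragments plus removed motif residues tile the proprotein,
a property-tested invariant.

## GPCR detection and classes

Transmembrane helices are maximal runs where the 19-residue
Kyte-Doolittle window mean is ≥ 1.6; runs under 15 residues are dropped
and runs closer than 5 residues merged (the standard sliding-window
convention; all four numbers are configurable). Candidates with fewer
than five helices are rejected — deliberately, since receptor fragments
(e.g. a receptor split into 3-TM and 4-TM pieces) should not be reported
as receptors. Duplicate amino-acid sequences collapse to one
representative (longest, then lexicographically smallest id). Class
assignment uses sequence diagnostics instead of HMM domain annotation:
D[RK]Y within 10 residues after TM3 or NPxxY within TM7 → Rhodopsin (A);
otherwise a C-x(3,12)-C pair in the TM1→TM2 extracellular loop →
Secretin (B); otherwise "other". The Cys-pair rule is a pragmatic proxy
for the Secretin ectodomain disulfide pattern and is recorded as such in
the evidence strings; an `evalue` config field is kept for users who
plug in an HMM backend, and all non-A/non-B seven-TM proteins collapse
into "other" — a coarser partition than domain-based grouping provides.
An N-terminal ectodomain over 300 residues sets a flag
(`long_n_terminus`) marking glycoprotein-hormone-receptor-like (LGR)
architecture; no leucine-rich-repeat annotation is attempted.

## Alignment, distances, trees

Progressive alignment follows the ClustalW recipe: pairwise global
alignments (BLOSUM62; a gap of length k costs 10 + 0.5k) give identity
distances, an average-linkage (UPGMA) guide tree orders profile-profile
merges, and each merge aligns column-frequency profiles with the same
affine-gap DP. Pairwise guide alignments run through Biopython's
PairwiseAligner; the profile DP is implemented here and cross-checked
against PairwiseAligner scores in the tests.

Pairwise distances are maximum-likelihood branch lengths under the JTT
amino-acid model (gamma off, pairwise gap deletion): for each pair the
site-pair count matrix C maximises Σ C_ab log(π_a P_ab(t)) over t, with
P(t) from the spectral form of the JTT rate matrix, a coarse
log-spaced grid locating the optimum and bounded scalar minimisation
refining it to 1e-10. Zero p-distance maps to distance 0; pairs with no
shared ungapped columns are undefined and are flagged with a warning
(twice the largest finite distance is substituted so the matrix stays
usable). The embedded JTT constants are the published
Jones-Taylor-Thornton exchangeabilities and frequencies, the same
numbers every phylogenetics engine ships.

Neighbor joining is the canonical Saitou-Nei agglomeration. Taxa are
first put in sorted-id order so Q-matrix ties break on the smallest id
pair, making topologies — and therefore bootstrap supports — invariant
to input order. Negative branch lengths are clamped to zero with the
deficit shifted to the sibling. On additive matrices the reconstruction
is exact (branch-length error < 1e-9, tested against matrices generated
from known random trees). The tree is rooted at the final join for
serialization; supports are written as internal node labels and the
newick round trip is byte-stable.

Bootstrap resamples alignment columns with replacement; support is the
percentage of replicate NJ trees containing each internal bipartition of
the full-data tree. The published setting is 1000 replicates; desk-scale
runs here default to 100 (a runtime choice — supports at 100 replicates
have ±5-point resolution, adequate for the ≥ 70 transfer rule).
Annotation transfer: a candidate leaf inherits a reference label when
the smallest clade containing both has support ≥ 70 and no conflicting
reference label; the ≥ 70 threshold formalises the usual
"high-confidence clade" star convention.

## Expression

Reads are assigned by the best gapless placement covering ≥ 0.75 of the
read at ≥ 0.85 identity over the overlap; ties split fractionally across
transcripts (logged). This matcher honours the two mapping fractions
that define the published contract while avoiding a full spliced
aligner, which the data (assembled CDS, simulated reads) does not need.
FPKM is exact arithmetic: counts × 10⁹ / (length_nt × per-tissue library
size); per-tissue rather than global library sizes are used. Heat-map
bins are empirical percentiles over all nonzero cells (default
quartiles) with a dedicated "absent" bin for zeros and ties resolved to
the lower bin. Stage contrasts call a transcript "immature-only" in a
tissue when FPKM ≥ 1.0 in the immature stage and < 1.0 in the mature
stage (threshold configurable; 1 FPKM is the conventional
presence floor).

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the pipeline assumes,
not real sequence evolution:

* **Precursors** follow a catalog of 22 fixed architectures spanning the
  families a decapod CNS survey reports (RPCH, corazonin, ACP, CCAP,
  proctolin, SIFamide, myosuppressin, tachykinin, allatostatins,
  FMRFamide-like, RYamide, sNPF, NPF, kinin, sulfakinin, PDH, orcokinin,
  DH31, a CHH-family member, GPA2, GPB5, phoenixin). Short mature cores
  are the canonical peptides; the long cores (GPA2/GPB5/CHH/phoenixin)
  are synthetic stand-ins whose architecture numbers (70/20/14, 120,
  143/17/126) mirror the published worked examples. Signal peptides are
  built to the (-3,-1) rule with h-regions from Leu/Val/Ile/Phe — Ala is
  excluded from h-regions and linkers so no spurious small-residue pair
  precedes the true cleavage site. Linkers avoid Lys/Arg/Gln/Gly, so
  cleavage motifs, pyroGlu starts and amide donors occur only where the
  architecture places them.
* **Receptors** are mutated copies (10% of loop/terminus residues) of a
  bundled synthetic reference panel of 18 family exemplars (15 class A
  including an LGR-like long-ectodomain GPA2/GPB5 receptor, 3 class B),
  each with 23-residue hydrophobic helices and 14-residue hydrophilic
  loops. Diagnostic motifs sit in the first 8 loop residues and are
  never mutated.
* **Decoys** are per-protein residue shuffles of generated proteins,
  preserving length and composition while destroying motifs — a
  specificity control without homology leakage.
* **Counts** use the Gamma-Poisson construction of the negative binomial
  (dispersion 10) conditioned on a fixed per-tissue depth, so column
  sums equal the stated depth exactly while marginals keep
  negative-binomial-style overdispersion. Neuropeptides are CNS-high
  (multiplier 10 in brain/thoracic ganglia/eyestalk); a subset is
  immature-ovary-biased (ovary multiplier 5 immature / 0 mature) and one
  is hepatopancreas-mature-biased, mirroring the reported
  stage-switching patterns.
* **Transcripts** embed reverse-translated CDS (uniform synonymous
  codons — downstream stages are protein-level, so codon bias is
  irrelevant) between UTRs; the 5' UTR avoids adenine so no upstream
  ATG or in-frame stop shadows the true ORF.

Default sizes are desk-scale: 22 precursors, 18 receptors, 20 decoys,
200 000 fragments per tissue, 10 tissue_stage libraries. Real decapod
surveys report several dozen precursors and a couple of hundred
receptors from assemblies that are rarely deposited; passing recovery
tests here demonstrates that the pipeline's
rules recover the structure they assume, not that they would achieve
the same rates on a real assembly with assembly artefacts, allelic
variation, fragmentary ORFs and homologous families the motif table
lacks. Read-level simulation with base qualities, sequencing error and
isoforms is out of scope.

A note on ORF selection: on short CDS the reverse strand occasionally
hosts a longer spurious ORF by chance. Published workflows resolve the
coding region manually; the pipeline automates that check by annotating
the top three ORFs per transcript and keeping the one recognised as a
precursor.

## Numerical choices and degenerate inputs

* Hydropathy windows shrink at sequence edges; unknown residues score 0
  with a logged warning.
* Cleavage on proproteins shorter than the minimum peptide length
  yields no peptides rather than an error; empty transcriptomes flow
  through the pipeline to an all-zero report.
* DP tie-breaks prefer match over gap-in-first over gap-in-second;
  signal-position ties prefer the smallest position; NJ ties the
  smallest id pair — all runs are deterministic and idempotent, and all
  randomness flows from a single integer seed through named
  substreams.
* Bootstrap supports are floats in [0, 100] formatted with `%g` into
  node labels; the root carries no support and is treated as 100 by the
  transfer rule (the whole tree is a trivially supported clade).

## Parameter recovery

The ten-seed benchmark (`scripts/acceptance.py`, `tests/test_acceptance.py`)
measures: precursor recall and family precision (truth family vs
annotated family), receptor recall (retained with the expected class),
decoy false-positive rate (decoys surviving the ≥ 5-TM filter), and
immature-ovary switch recall. At the default conditions all exceed 0.9
(FPR below 0.05); these are properties of the generator's match to the
annotator's assumptions, as discussed above.

## Known limitations

* The signal and class heuristics are transparent approximations of
  trained predictors (SignalP-class models, Pfam HMMs); on real
  divergent sequences they will under-call.
* Monobasic cleavage in vivo depends on context beyond the spaced-basic
  rule; the grammar is configurable but rule-based.
* Nested mature peptides (a 14-residue form inside a 20-residue form,
  as for vertebrate phoenixin) are not modelled; the stand-in
  architecture releases the two forms from separate cassettes.
* NJ + bootstrap is the tree engine; maximum-likelihood tree search is
  intentionally out of scope since clade-assignment decisions rest on
  topology plus support.
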