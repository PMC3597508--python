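# Methods

`splicedup` models how fungi express two distinct proteins from one gene —
alternative 3′ splice sites, intron retention, cassette-exon skipping, and
internal initiation — and how a duplicated gene pair partitions those two
products after whole-genome duplication (WGD). This note records the models,
the defaults and why they hold, and the choices made where the design was
genuinely open.

## Splice-signal model

Budding-yeast-type introns are described by three position weight matrices
(PWMs): a 6-nt donor (training sites `GTATGT`, `GTAAGT`), a 7-nt branch
point (`TACTAAC`), and a 3-nt acceptor (`TAG`, `CAG`). Counts receive a
pseudocount (default 0.5) per letter and are normalised per column; scores
are log-odds (base 2) against a uniform 0.25 background. Published gene
diagrams provide sequence logos, not matrices, so these training sites are
explicit stand-ins and the whole model is a JSON config
(`data/splice_model.json`); provenance in every report says whether the
stand-in or a user matrix was used.

Geometry defaults: intron length within [40, 1000] nt, acceptor within
[10, 200] nt of the branch point, per-signal threshold = 60% of each PWM's
maximum log-odds. Candidate enumeration requires the intron to literally
begin `GT` and end `AG` on top of the PWM scores. For each passing donor,
the highest-scoring branch point that admits at least one acceptor is kept
(leftmost on ties — a determinism rule, not biology), and **all** acceptors
compatible with the geometry are collected, sorted proximal→distal; two or
more acceptors flag the intron as alternatively spliced. Windows containing
ambiguity codes score as non-matches (conservative). Overlapping donors are
all reported; isoform assembly later drops overlapping candidates greedily
(leftmost donor wins) with a logged warning.

The single-branch-point geometry means a distal acceptor more than 200 nt
from the branch is invisible under defaults. The Lachancea-like locus in the
synthetic data places its two acceptors ~700 nt apart (see below), so its
generated splice model widens the branch-to-acceptor window to cover the
planted distal site; the widening is recorded in the model's provenance.
Real loci with distant alternative acceptors need the same config override —
biologically each 3′ splice site has its own branch point, which this model
deliberately does not represent.

## Isoforms and ORF consequences

Events are enumerated one at a time against the fully spliced background
(every intron removed at its proximal acceptor): one isoform per acceptor of
an alternatively spliced intron, a retention isoform per intron whose
retention is *functional*, one skip isoform per annotated cassette exon, and
optionally an internal-start isoform. Combinatorial stacking of events is
not attempted — observed fungal isoform sets are one-event sets, and the cap
prevents exponential blowup.

The retention rule (the *PTC7* rule): a retained intron yields a functional
product iff its length is a multiple of 3 **and** no codon of the retained
reading frame overlapping the intron is a stop. `retention_consequence` also
reports where translation of the retained message terminates (in residues)
when a stop intervenes. Retention isoforms are emitted only for
CDS-overlapping introns; retention upstream of the start codon is out of
scope.

The internal-start rule (the Candida-clade mechanism): motif S1 begins with
a methionine; if the codon at S1's first residue on the unspliced locus is
`ATG`, an isoform starting there is emitted, with its message beginning 5 nt
upstream of the start (matching the mapped 5′ end of such transcripts). The
pipeline searches for this isoform automatically only when no spliced
isoform already encodes S1 — in species with a proximal 3′ splice site the
long splice form supplies S1 and no internal-start message is expected. A
CLI flag forces the search on or off.

Translation uses NCBI tables 1 and 12 (table 12: CUG = Ser, the CTG clade);
the CDS is truncated at its first in-frame stop. Protein masses are average
(not monoisotopic) masses plus one water, reported in kDa to 0.1; gel-based
size estimates are approximate, so comparisons should use ~integer
precision. `premature_stop` is defined relative to the gene's longest
product: an isoform is prematurely terminated when it has a stop and does
not share the C-terminus (last 10 residues) of the longest isoform — length
alone is not evidence, because alternative acceptors legitimately shorten
proteins without truncating them.

## Motif complement and functional classes

Ski7/Hbs1 diagnostics are short degenerate consensus patterns
(`data/motifs.json`): S1–S3 (Ski7 N-terminal motifs), H1 (Hbs1 linker),
G1–G5 (GTPase motifs), and the structured Hbs1 N-terminal domain (NTD).
They are versioned data, not code: landmarks distilled from alignments of
fungal homologs, not profile HMMs. Scoring counts matching positions;
wildcards and *special positions* are unscored, so the catalytic histidine
of G3 is recorded but never influences whether G3 is found — a Ski7-type
G3 with Ser/Asn/Asp at that position is still a G3 hit, just a
catalytically dead one. One best hit per motif (motifs are unique landmarks
here). Thresholds (0.85 of maximum for 8–10-mers, exact for the short
motifs) keep the false-positive rate on shuffled proteins below 5%.

Classes: HBS1-like requires H1, all of G1–G5, and an intact catalytic His;
SKI7-like requires S1, S2 and S3; both sets → DUAL; neither → NEITHER. The
NTD is supporting, never required (in pre-WGD genes it rides on exon 1 into
both isoforms). Motif order along the protein is a soft check: violations
lower confidence in the evidence list but never change the class, since
strict order is not established for all species.

## Localization heuristics

The transmembrane and mitochondrial-targeting predictions are transparent
heuristic stand-ins for external topology/sorting servers; agreement with
any particular server is not promised, and every output is labelled
`heuristic stand-in`.

* TM: sliding 19-residue mean Kyte–Doolittle hydropathy; maximal runs of
  windows ≥ 1.6 merge into helices; a helix starting within the first 60
  residues makes the protein N-terminally membrane-anchored.
* MTS: over the first 30 residues, `(2·#RK − 2·#DE + 0.5·#SLA) / 30`
  clipped to [0, 1] — monotone in each component; cutoff 0.5.

The call is a fixed precedence: N-terminal TM → nuclear envelope; else
MTS ≥ cutoff → mitochondrial; else other. Precedence mirrors the biology of
retained-intron phosphatase isoforms, which carry the intron-encoded TM and
go to the nuclear envelope even though everything downstream is shared with
the mitochondrial isoform.

## Subfunctionalization calls

Each functional class maps to the set of ancestral functions it provides
(DUAL → {SKI7, HBS1}; nuclear-envelope / mitochondrial are singleton sets on
the localization axis; the two axes are never mixed in one verdict). With
ancestral function set F = union over the ancestor's isoform classes:

* SUBFUNCTIONALIZED — the paralogs jointly cover F, differ, and neither
  covers F alone;
* REDUNDANT — each paralog covers F;
* INCOMPLETE_PARTITION — anything else;
* NOT_COMPARABLE — the ancestor shows fewer than two distinct classes.

The function-set formulation was chosen over literal class-set equality
because the ancestral long isoform carries the full motif complement and
classifies DUAL; literal equality would then never call the canonical
partition (SKI7-like, HBS1-like) subfunctionalized. Coverage semantics
reproduce both case studies and is symmetric under paralog swap.

Mechanism evidence is sequence-level. Precise intron loss: the paralog
contains the ancestor's exact spliced junction — k = 12 exonic nt from each
side of the chosen acceptor concatenated with nothing between, matched with
≤ m = 2 mismatches to absorb divergence (k shrinks with a warning when a
flank is shorter). Exon-1 loss with a new start: the paralog's start codon
lies within d = 3 residues of its S1 motif and no NTD motif is detectable in
any reading frame upstream of the start. NTD presence stands in for exon-1
homology so no aligner is embedded; it is the natural diagnostic because the
domain is exon-1-encoded.

## Synthetic data

The generator emits the six architectures with exact ground truth; defaults
are the study conditions, set once:

* **ALT3SS** — one intron, two acceptors. Protein sizes are *derived at run
  time* from the target masses 70 and 96 kDa and the mean residue mass of
  the background composition (~110 Da): ~637 residues for the short form,
  ~237 encoded between the acceptors (hence the ~700-nt inter-acceptor
  distance and the widened scan window). S1/S2 sit in the alternative exon,
  S3/H1/G1–G5 on the terminal exon, the NTD on exon 1.
* **MULTI_INTRON_ALT3SS** — n introns (7 by default; 4 for the
  Aspergillus-like variant), the second carrying two acceptors 60 nt apart
  (default geometry suffices).
* **ALT_TSS** — genetic code 12; a single (distal-equivalent) acceptor;
  S1/S2 encoded inside the intron in the internal-start reading frame,
  which runs stop-free through the 3′ splice site into the terminal exon.
* **EXON_SKIP** — four exons, the 48-codon cassette exon (S1/S2) is a
  multiple of 3 so skipping preserves frame.
* **RETENTION_PAIR** — a 90-nt, frame-preserving, stop-free intron encoding
  a 22-residue I/L/V/F helix; exon 1 encodes a 30-residue presequence with
  an arginine every third residue (amphipathic, so the spliced product
  never crosses the TM threshold). The non-functional variant plants a
  103-nt intron with an in-frame stop 20 codons into the ORF and exactly
  one internal in-frame ATG, eight codons upstream of the normal stop.
* **POST_WGD_PAIR** — an ALT3SS ancestor plus two paralogs: one with the
  intron excised at the distal acceptor (HBS1-like), one truncated to S1's
  ATG behind a 60-nt leader with H1 scrambled and the G3 His changed to Asn
  (SKI7-like). A localization-axis variant derives a PTC7a-like copy
  (donor disabled by two in-frame codon changes, TM now constitutively
  encoded) and a PTC7b-like copy (intron excised).

Background: i.i.d. nucleotides at 40% GC (yeast-like) for non-coding
segments; coding background drawn from a polar-biased residue composition
(hydrophobics rare, so spurious TM stretches do not arise) and
reverse-translated with uniform synonymous codons. Planted signals are
sampled from the PWMs at a *signal strength* in [0, 1] (1.0 = consensus;
the per-column distribution is a strength-weighted blend of consensus and
PWM). 5′ leaders are kept free of ATG so a first-ATG rule lands on the
intended start.

**Sanitization.** A locus is accepted only when the candidate-intron scan
returns exactly the planted architecture (at strength 1.0) and nothing
unplanted at any strength. Offending unplanted signals are removed by
minimal edits — any base in non-coding segments, synonymous codon swaps in
coding segments (which preserve every planted motif at the amino-acid
level); planted signals, junction probes and single-codon positions are
untouchable, and the whole locus is resampled from the next substream when
no edit suffices. This makes downstream false-positive measurements
meaningful rather than luck.

**Divergence** (duplicate pairs, default 5% per site) is applied after the
architecture edits and never touches splice signals, motif codons, start
codons, the 12-nt junction flanks the intron-loss detector reads, or
introduces an in-frame stop (purifying selection). The point of the
divergence dial is to test robustness of architecture recovery, so the
features the detectors are defined on are held fixed; the mismatch
tolerance of the junction detector is exercised separately with explicit
point mutations.

What the generator does *not* emulate: codon-usage bias, indels, branch
points per acceptor, transcript abundance, nucleosome or chromatin context,
and real motif degeneracy across species. Passing the recovery criteria
therefore shows the pipeline is correct and robust to point divergence on
architecture-faithful loci — not that the default PWMs or motif patterns
are calibrated for any particular genome.

## Problem sizes and determinism

The reference corpus is 10 loci per architecture (60 loci; pair
architectures count once with three sequences), signal strength 1.0,
divergence 5%, seed 20130314 — sizes chosen so the whole corpus generates
and evaluates in well under a minute while every architecture appears ten
times. All randomness flows from a single integer seed through per-locus
substreams; a fixed seed reproduces every file byte for byte. Analysis
itself uses no randomness.

## Known limitations

* One branch point per intron; distant alternative acceptors need a widened
  window in config.
* Motif patterns and PWMs are stand-ins; on real genomes both should be
  re-trained from alignments before the classifier's output is trusted.
* The localization heuristics ignore topology, cleavage sites, and the
  signal-peptide/MTS distinction.
* NMD and expression levels are not modelled; a "functional retention" call
  is about coding potential only.
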