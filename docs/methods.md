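# Methods

## Pipeline overview

`chimeraprot` models products of programmed ribosomal frameshifting (PRF) in
three stages.

1. **ORF detection.** Each transcript is scanned in its three forward frames
   (transcripts are assumed spliced and sense-strand; reverse frames are not
   scanned). An ORF is a maximal run of non-stop codons — bounded by in-frame
   stop codons or by the transcript ends — with no start-codon requirement,
   reported when it reaches the minimum length (default 30 aa, the OpenProt
   convention; 20 aa is a common working threshold and is what the synthetic
   runs here use). Coordinates are 1-based inclusive; a trailing partial
   codon never belongs to an ORF. Stop codons are the standard-code set
   {TAA, TAG, TGA}; no alternative genetic codes are supported. Codons
   containing any non-ACGT letter translate to `X`, never to a stop, so
   ambiguity cannot terminate or split an ORF.

2. **Reference/alternative separation.** A canonical proteome defines the
   reference products. Because stop-to-stop ORFs extend beyond annotated
   start codons, an annotated protein is properly contained in the
   translation of its host ORF; the default rule therefore classifies an ORF
   as a refProt when any canonical sequence of at least 7 aa occurs as a
   contiguous substring of the ORF translation. The 7-aa floor guards
   against trivial matches; matching is transcript-agnostic because
   canonical proteomes are usually keyed by gene rather than transcript. An
   `exact` mode (sequence equality) is provided as the stricter alternative.
   Both rules are interpretations — the separation criterion is a design
   choice of this package.

3. **Chimeric modeling.** For each user-listed candidate altORF the modeler
   pairs it with every refORF and every other candidate altORF on the same
   transcript (all pairwise combinations; for altORF–altORF pairs the longer
   ORF takes the refORF role, ties broken by smaller start coordinate),
   classifies the pair geometry, and sweeps a junction across a
   scenario-specific window.

## Junction sweep

An *iteration* advances the junction by one codon of the left-arm frame.
Each iteration is emitted once per admissible PRF value; a slip of Δ
nucleotides connects frames differing by Δ mod 3, so each ordered frame pair
admits exactly two values from {−2, −1, +1, +2}, and the two values of one
iteration place the physical slip at distinct nucleotide offsets — this is
how per-nucleotide PRF positions are represented by a codon-step sweep. The
left arm ends at codon-final nucleotide *p*; the right arm starts at
*p* + 1 + Δ, which is automatically codon-aligned in the right frame.

With cap *C* = 40 aa and nominal first arm *A₀* = 10 aa, the windows are:

* **Embedded altORF (scenario tags `Within_5prime_of_altORF`,
  `Within_3prime_of_altORF`).** Five-prime side: the right (altORF) arm's
  far end is pinned at min(altORF end, altORF start + 3(C−A₀) − 1); the
  sweep starts with A₀ host residues + the full window of guest residues and
  trades one codon per iteration. Both arms have a 10-aa minimum, so an
  overlap of *L* aa (L ≤ 30) yields L − 10 + 1 iterations per PRF value —
  the count equation (L − m + 1) × 2 per side. The three-prime side mirrors
  this around the altORF end. For altORFs shorter than 90 nt the window
  truncates and every model is (10 + L) aa; the last-10-aa (five-prime) /
  first-10-aa (three-prime) residues are shared by all models of a side.

* **Partial overlap (`Overlap_5prime_UTR`, `Overlap_3prime_UTR`).** The
  window anchors at the boundary of the refORF-role ORF inside the overlap
  and sweeps 30 nominal iterations per PRF value: the first model joins 10
  aa of the UTR-side ORF to 30 aa of the partner, the last 39 aa to a single
  residue (minimum second arm 1 aa, accommodating known single-residue
  frameshift products). If the overlap is shorter than the window, the
  iterations whose growing arm would read through the partner's bounding
  stop are removed by the defect filter rather than silently truncated, so
  the emitted count reflects the usable overlap.

* **Spanning altORF (`Span_5prime_of_refORF`, `Span_3prime_of_refORF`).**
  When the designated refORF lies wholly inside an altORF, both refORF
  boundaries get partial-overlap-style windows. At the refORF stop the
  nominal 30-iteration sweep necessarily collides with that stop codon: a
  ref-frame left arm longer than 30 aa ending past the refORF reads through
  the stop. Those models are defective by construction, so a certified
  spanning pair emits 30×2 models at the refORF start but only
  (30 − 10 + 1)×2 = 42 at the refORF stop. This accounting — nominal sweep
  plus defect filtering, rather than a shortened sweep — is this package's
  resolution of the tension between "30 iterations, last model 39 + 1" and
  "stop-containing models are removed".

* **Gap (`NonOverlap_5prime_UTR`, `NonOverlap_3prime_UTR`).** Disjoint ORFs
  separated by 1–10 nt are joined by a single forward slip equal to the gap
  (same-frame joins arise when the gap is a multiple of 3): exactly one
  model, last 20 aa of the upstream ORF + first 20 aa of the downstream ORF,
  iteration index 1. Abutting ORFs (gap 0) and gaps over the maximum
  generate nothing.

**Defects vs truncation.** Far window ends are clipped to ORF spans
(models shorter than 40 aa are legitimate); a side is dropped only when even
the minimum arms cannot be formed. An arm that would *cross* a bounding stop,
leave its ORF's span at the junction-facing end, or run off the transcript
makes that single model defective; defective models are removed and (on
request) individually accounted.

**Determinism.** Models are deduplicated only on demand
(`collapse_identical`, keeping the lexicographically smallest tag — exact
tag duplicates cannot arise), sorted lexicographically by model tag, and
written with fixed 60-column wrapping, so output files are byte-identical
across thread counts and platforms. Work is partitioned by candidate ORF
when multithreaded.

**Tags.** ORF tags are `{transcript}_{frame}F_{start}-{end}_{length}`
(ASCII hyphen and sign; parsed positionally from the right so transcript
identifiers may contain underscores). Model tags append the left-arm ORF
first, then the right-arm ORF, signed PRF value, 1-based iteration, and a
scenario tag; the prime symbol is spelled out (`5prime`/`3prime`) to keep
headers byte-safe. The eight-string scenario vocabulary is this package's
own controlled set.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_orf_len_aa` | 30 | aa | OpenProt-compatible ORF floor; 20 used for denser altORF sets |
| `model_len_cap_aa` | 40 | aa | an MS peptide (7–35 aa) must span the junction |
| `min_arm_scenario1_aa` | 10 | aa | minimum arm in embedded overlaps; also the nominal first-arm length everywhere |
| `min_second_arm_scenario2_aa` | 1 | aa | single-residue frameshift products exist |
| `arm_scenario3_aa` | 20 | aa | fixed arms for gap joins |
| `max_gap_nt` | 10 | nt | forward-slip (bypass-like) joins only up to 10 nt |
| `prf_values` | {−2,−1,+1,+2} | nt | backward/forward slips of 1–2 nt |

## Synthetic fixtures

The fixture generators plant each scenario geometry with *certified*
stop-free modeling windows: bounding stops are written and locked first,
stops intruding on protected spans are resampled codon-by-codon, and
incidental ORFs at or above the certification threshold (20 aa) are broken
by planting stops at positions checked not to disturb any protected span.
Certification re-runs the detector and accepts only an exact match with the
planted ORFs, so every expected count is known in closed form before the
modeler runs. All randomness flows from a single seed (per-transcript
generators are spawned from it), making runs byte-reproducible.

Defaults: embedded pairs use a 100-aa host and 30-aa guest in frames (3, 1)
— the worked frame pair for the count equation — with the guest centered;
partial-overlap fixtures size the overlap to at least the full 30-codon
window plus the 10 upstream codons, so the nominal 60 models per side are
realizable; spanning fixtures give the altORF at least 12 codons beyond each
refORF end (60 + 42 models); gap fixtures place 25-aa ORFs.

A consequence of ORF maximality worth recording: between two maximal
stop-to-stop ORFs, gaps of 1, 2, 4 or 5 nt are impossible under the standard
code — the two bounding stop codons would have to share nucleotides in ways
no assignment satisfies (every stop starts with T and ends in A or G). The
modeler accepts the full 1–10 nt range for user-supplied records, but the
certified gap generator only produces gaps in {3} ∪ {6..}; same-frame gaps
(multiples of 3) fill the whole gap region with stops, as maximality
requires.

What the fixtures do **not** emulate: realistic codon usage or GC content,
UTR/CDS composition biases, ambiguity letters, sequencing errors, splice
variants, or multi-ORF transcripts beyond the planted pair. Passing tests
therefore demonstrate the combinatorial and coordinate correctness of the
pipeline, not its behavior on the quirks of real annotation.

## Problem sizes and verification

The test suite checks the worked counts on single certified fixtures
(42 per embedded side, 21 iterations per PRF value, 60 per partial-overlap
side, one model per gap pair), the scale arithmetic on 10,000 embedded
fixtures (exactly 840,000 models), a positional brute-force oracle over 200
randomized embedded/overlap geometries, the 40-aa cap over randomized
scenarios, tag round-trips (property-based), detector equivalence with an
independent codon-walk scanner on 200 random transcripts, and byte-identity
of output across thread counts. `scripts/acceptance.py` re-derives the
headline counts through the full file-level pipeline (detect → separate →
model) on freshly generated fixtures.

## Limitations

* Only the three forward frames are scanned; stranded transcript input is
  assumed.
* The ref/alt separation criterion is a documented interpretation, not an
  annotated ground truth.
* Sweep windows anchor at overlap boundaries only; junction sweeps starting
  at other anchor points (e.g. mid-ORF) and a symmetric/centered junction
  mode are out of scope for this version.
* MS searching, decoy generation, FDR control, conservation analysis and
  Ribo-Seq integration are external to the package; the model FASTA is
  their input.
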