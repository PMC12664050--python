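# chimeraprot

Build tagged FASTA databases of **chimeric protein models** — hypothetical
products of programmed ribosomal frameshifting (PRF) — for mass-spectrometry
proteomics searches.

During PRF a translating ribosome slips backward or forward by a few
nucleotides and continues in a different reading frame. The resulting protein
is chimeric: an N-terminal arm encoded in one frame joined to a C-terminal arm
from another. Outside viruses such products are hard to find because nothing
about them is annotated. This package takes the database side of the problem:
given only a transcriptome (spliced, sense-strand nucleotide FASTA) and a
canonical proteome, it enumerates every stop-free ORF, separates alternative
from reference products, and emits every plausible two-arm junction sequence
as a search-database entry. Matching those entries against MS spectra (with
external tools such as SearchGUI/PeptideShaker) then provides direct evidence
for individual PRF events and their positions. The intended users are
proteogenomics groups hunting non-canonical translation products in any
organism with a transcriptome and MS data.

## The model

ORFs are defined as maximal stop-free spans in the three forward frames, with
no AUG requirement — between two in-frame stop codons or a stop codon and a
transcript end. For a candidate alternative ORF (altORF) and a partner on the
same transcript, the junction between the two arms is swept codon-by-codon
("iterations") across a scenario-dependent window, once per admissible PRF
value Δ ∈ {−2, −1, +1, +2} (Δ ≡ frame difference mod 3). For an altORF
embedded in its reference ORF (refORF), with overlap length *L* (in aa,
capped at 30) and minimum arm size *m* = 10 aa, the number of models per
ORF-to-ORF switch is

```
N = (L − m + 1) × 2
```

so a 90-nt (30-aa) embedded altORF yields 42 models per side, 84 per pair.
Partial overlaps (an arm reaching into a UTR) sweep 30 iterations per PRF
value, down to a single residue from the second ORF; non-overlapping ORFs
separated by ≤ 10 nt are joined by one forward slip equal to the gap (one
20 aa + 20 aa model per pair). Total model length is capped at 40 aa so a
typical MS peptide (7–35 aa) must span the junction rather than match either
arm alone. Models that would read through a stop codon, leave their source
ORF's stop-free span, or run off the transcript are removed as defective.

Every sequence carries a parseable tag, e.g.
`MtrunA17_Chr6g0457461_3F_438-596_159` for an ORF (frame 3, nucleotides
438–596, 159 nt) and
`<orfA>_<orfB>_+2_iteration_6_Within_3prime_of_altORF` for a model (left-arm
ORF first, signed PRF value, junction step, scenario).

## Worked example

The built-in fixture generator plants certified stop-free geometries, so the
expected counts are known in closed form:

```python
from collections import Counter
from chimeraprot import classify_pair, generate_models_for_pair
from chimeraprot.fixtures import make_embedded_pair

pair = make_embedded_pair(seed=1, host_len_aa=100, guest_len_aa=30, frames=(3, 1))
print("refORF :", pair.host.tag)
print("altORF :", pair.guest.tag)

geometry = classify_pair(pair.guest, pair.host, b_is_ref=True)
models = generate_models_for_pair(pair.transcript, geometry)
print("models :", len(models))
print("by side:", dict(Counter(m.scenario_tag for m in models)))
m = models[0]
print("first  :", m.model_tag)
print("        ", m.aa_seq)
```

prints

```
refORF : embedded_seed1_3F_6-305_300
altORF : embedded_seed1_1F_112-201_90
models : 84
by side: {'Within_5prime_of_altORF': 42, 'Within_3prime_of_altORF': 42}
first  : embedded_seed1_3F_6-305_300_embedded_seed1_1F_112-201_90_-2_iteration_1_Within_5prime_of_altORF
         ESWGMVVLLKNVSAMRFQVLVLRYVILKLFIQLRSERDVR
```

The 30-aa altORF sits in frame 1 inside a frame-3 refORF; each side of the
overlap yields (30 − 10 + 1) × 2 = 42 models, and the first model joins 10
refORF residues to 30 altORF residues at a −2 slip one codon into the window.

The same stages are available from the shell:

```
chimeraprot detect-orfs --transcriptome tx.fasta --min-len-aa 20 --out orfs.fasta
chimeraprot separate-orfs --orfs orfs.fasta --proteome canonical.fasta \
    --out-alt alt.fasta --out-ref ref.fasta
chimeraprot simulate-chimeric-proteins --transcriptome tx.fasta \
    --alt alt.fasta --ref ref.fasta --candidates candidates.txt --out models.fasta
```

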