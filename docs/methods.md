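# Methods

This note records the models, conventions and design choices behind
`regevol`, in the order a user meets them.

## Coordinates, alphabet, element fixtures

All positions are 1-based and inclusive, following the `T1`/`G6`/`C3` base
naming convention (letter = base, number = position). Input residues are
normalised to uppercase; the alphabet is `{A, C, G, T, N}`. `N` means
"unknown" everywhere: it never counts as identical in alignments or
invariance, translates to `X` within a codon, and is excluded from both the
numerator and denominator of GC fractions and from CpG formation.

The seven elements of the human *SMIM45* locus are packaged as a FASTA
fixture (full silencer 230 bp = exonic silencer 38 bp + silencer b 192 bp;
enhancers of 210, 628 and 512 bp; a 60-bp embedded silencer). The exonic
silencer carries `frame_start = 3`: its first complete codon begins at base
3, leaving bases 1–2 outside the ORF. Fixtures are data, not downloads; no
network access is ever needed.

## Pairwise alignment

`global_align` is a Needleman–Wunsch/Gotoh dynamic program over three
states. A gap run of length *L* costs `gap_open + (L−1)·gap_extend`; the
defaults (match +5, mismatch −4, open 10, extend 0.5) follow the EDNAFULL
convention of the widely used global-alignment tools. The original analyses
name only the tool, not its scoring scheme, so these defaults are a
documented convention and externally sourced identities are treated as
approximate expectations, never as test surfaces.

Conventions worth knowing:

- **Identity denominator** is the full alignment length including gap
  columns, matching the cited pairwise tools; `percent_identity` reports to
  0.1%.
- **Determinism.** At score ties the traceback prefers the diagonal move,
  then a gap in the second sequence, then a gap in the first. Because a
  fixed preference is not symmetric under swapping the inputs (distinct
  optimal alignments can tie on score with different column counts), the
  pair is canonicalised by lexicographic order before the DP and the rows
  swapped back, making identity order-invariant.
- **End gaps** are penalised by default (true global mode);
  `end_gaps_free=True` gives semi-global behaviour — one leading and one
  trailing gap run cost nothing — used whenever a short element is located
  inside a longer region (conservation profiling, difference counting,
  origination dating). In this mode two fully dissimilar sequences may
  legitimately align as disjoint blocks with score 0.
- The DP is validated against a brute-force enumeration of every global
  alignment (all pairs up to length 8) and against an independent
  reference aligner configured with the same scores.

## Codon overlay and mutation effects

Classes cycle `codon_pos1, codon_pos2, wobble` from `frame_start`;
`n_codons = ⌊(length − frame_start + 1)/3⌋`, with 0–2 trailing bases
`post_orf`. Translation uses the standard genetic code only; stops appear
as `*` (reports also provide the peptide without the trailing stop, since
the 38-mer ends in TGA). `mutation_effect` recomputes the peptide before
and after a single-base change; a change outside the ORF is reported as
synonymous by location. Degeneracy is computed per codon from the code
table: a base is *forced* when no alternative base at that position
preserves the amino acid — this is the only mechanisable reading of
"neighbor bases fixed by selection" used by the exclusion policy below.

## Invariance, tripartite classes, neighbor bias

A reference position is invariant iff every compared homolog carries the
same base there, gap-free and not `N`. Homologs arrive either as a
multiple alignment (rows are read columnwise against the reference row) or
as an ortholog ladder (each member is first aligned to the reference
semi-globally). Combined with the overlay, invariant positions split into
`codon_fixed_invariant` (codon positions 1/2 — explicable by protein-level
purifying selection), `wobble_invariant` (conservation the code does not
require), and `flank_invariant` (outside the ORF, covering both pre- and
post-ORF bases); everything else is `variable`. The four counts always
partition the element.

`neighbor_bias_table` lists, for each invariant position, the extant 5′ and
3′ neighbor bases (neighbors that are themselves invariant are skipped) and
summarises the G+C fraction. Policy `all` keeps every row and is the
default; policy `exclude_forced` drops neighbors sitting at a codon
position where the encoded amino acid admits no alternative base. `all` is
the default because the published table for the exonic silencer includes
first-position bases that degeneracy does permit to vary (e.g. C12 in a Leu
codon).

The published 13-row neighbor table for the exonic silencer ships as a
constant, and `evaluate_reference_neighbor_table` judges G/C membership on
the *printed* base labels while also reporting the extant base read from
the sequence. One printed row (3′ neighbor of G22, printed `T23`) disagrees
with the extant base (C at position 23); the evaluator flags the mismatch
rather than silently overriding either value, which is why the summary is
12 of 13 rather than 13 of 13.

Ancestral states are not reconstructed anywhere: "mutations producing G/C"
are read from extant neighbor identities, exactly as the source table does.

## Runs, differences, completion

`longest_invariant_runs` returns maximal invariant runs, longest first,
5′-most first at ties. `count_differences` counts substitution columns
individually and each maximal gap run (terminal runs included) as one indel
event, over a semi-global alignment. `completion_call` declares the element
"completed" in the most anciently diverged member with zero substitutions
and zero indels over the element span; flanking differences are ignored,
and if no member qualifies the element is reference-lineage specific.

## Composition and CpG cluster enrichment

CpG counting is single-strand, overlapping, on the sequence as given.
Useful identity (tested): `n_cpg(x+y) = n_cpg(x) + n_cpg(y) + [last(x)=C ∧
first(y)=G]`; for the silencer segments this is 5 + 13 + 0 = 18.

Two null models for the CpG count are provided, both fully documented
because the original enrichment probability was produced by an unstated
method and is not reproducible:

- `binomial_tail`: `P(X ≥ k)` for `X ~ Binomial(L−1, p̂)` with
  `p̂ = freq(C)·freq(G)` estimated from the sequence itself;
- `shuffle_null`: the fraction of seeded, mononucleotide-preserving
  permutations with CpG count ≥ k (the seed is mandatory so every report is
  reproducible).

**Caveat.** The two nulls are different distributions, not two estimates of
one number. The permutation null fixes the exact base counts and induces
negative dependence between overlapping dinucleotide sites, so for strongly
skewed compositions (such as the 74% G+C silencer b, where both tails are
≈1 anyway) the models differ by more than Monte-Carlo error no matter how
many shuffles are drawn. They agree closely where the independence
approximation is adequate, and the cross-model test uses such a
composition. Raw counts, not the published rounded percentages, are the
package's test surface for GC content (e.g. 27/38 ≈ 71.1% vs a printed
70%). No CpG-island calling or methylation model is attempted.

Motif patterns are fixed letters over `ACGTN` with bounded repeats
(`TAAT T{2,6} GT`); scanning reports all, possibly overlapping, hits with
the longest match at each start. Tandem-repeat detection reports maximal
arrays of ≥2 adjacent copies of a unit (≥4 bp), each copy compared to the
*first* copy within a mismatch budget — comparing to the first copy rather
than a consensus keeps detection deterministic; arrays are anchored at
their leftmost position. Transposable-element annotation is out of scope:
TE coordinates, where needed, are inputs.

## Origination dating

Verdicts come from raw percent identity against each ladder member:
`present` at ≥55%, `absent` at ≤45%, `twilight` between — thresholds
bracketing the field's practice of treating ≈80% as clear homology on
these length scales and ≈40–45% as noise. The "twilight zone" has no
canonical bounds, so both thresholds are explicit parameters echoed in
every report. A species with no locatable ortholog is `no_data`, which
neither asserts absence nor closes the age bracket. The bracket is
[age of the oldest present species, age of the youngest older non-present
species], with an open upper bound when every older species is present.
Divergence ages are inputs, taken verbatim from the species ladder; no
timetree lookup and no alignment significance statistics (E-values) are
performed — like the analysis it implements, the package reasons from raw
identity.

## Forward simulator

The generator emulates the constraint structure the analyses detect, on a
star phylogeny (each species evolves independently from the ancestor for
its divergence age — appropriate because every analysis compares each
species to the reference independently; a shared-tree option is a
non-goal). Per branch, per site, substitution events are
Poisson(`mu`·age); defaults `mu = 0.002` substitutions/site/My (a typical
mammalian neutral rate). Events apply sequentially:

- **frozen** positions never mutate;
- at a site adjacent to a frozen position, the new base is drawn from
  `{G,C}` minus the current base with probability `beta`
  (`neighbor_gc_bias`, default 0.92 — the observed 12/13 made a parameter),
  otherwise from `{A,T}` minus the current base, so `beta` is exactly the
  probability that an accepted neighbor mutation yields G or C and
  `recover_beta`'s pooled fraction is an unbiased binomial estimate of it
  (Clopper–Pearson interval);
- with `purifying` on and a reading frame given, non-synonymous proposals
  at codon positions 1/2 are rejected (evaluated against the current,
  possibly already-mutated codon);
- elsewhere proposals are uniform over the three alternatives.

Indels default off; when enabled (Poisson events of 1–3 bp, never touching
frozen positions) the true alignment is retained. `as_alignment()` exposes
the simulator's own alignment (gapless when indels are off) so recovery
tests of the conservation stages are not confounded by alignment-inference
error; re-aligning simulated orthologs pairwise is also supported and is
exercised at milder divergence.

What the simulator does *not* model: rate heterogeneity among sites, CpG
hypermutability, selection beyond accept/reject purifying, population
processes, and shared internal tree branches. Passing recovery tests
therefore show that the analyses invert this generative model — not that
real orthologs satisfy it.

## Problem sizes in the shipped tests

The test suite validates the alignment DP against full enumeration on
hundreds of random pairs up to length 8 (enumeration grows super-
exponentially beyond that); simulator statistics use ladders of 5–15
species, elements of 36–192 bp and ~200 seeded replicates for the
beta-coverage check (n ≥ 100 qualifying mutations per replicate); the
proto-silencer recovery test evolves the real 192-bp silencer b down 12
branches of 15–48 My at `mu = 0.015` — strong enough that every free site
varies somewhere, mild enough that pairwise re-alignment is reliable. All
randomness is seeded; reruns are deterministic.

## Known limitations

- Identities for species whose orthologs are not packaged (elephant shark,
  lemur, tree shrew, koala, chimpanzee/gorilla difference counts) depend on
  externally supplied sequences and alignment parameters; they are exposed
  as opt-in, explicitly approximate checks (`regevol repro
  --external-dir`), not as tests.
- The printed enrichment probability for silencer b's CpG content is not
  reproducible from a stated model; the two nulls above are the package's
  own, documented alternatives.
- Multiple-alignment *inference* is out of scope: MSAs are consumed from
  files or produced pre-aligned by the simulator; only pairwise global
  alignment is implemented, and no local (Smith–Waterman) mode exists.
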