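# regevol

Tools for decomposing the evolutionary origin of short transcriptional
regulatory elements — silencers and enhancers — that sit in and around an
open reading frame, built around the human *SMIM45* locus.

## The problem

*SMIM45* is a bicistronic gene: an ancient, deeply conserved 68-aa
microprotein ORF sits upstream of a human-specific de novo 107-aa cistron,
and the locus carries a suite of regulatory elements — an *exonic silencer*
whose 38 bp overlap the 68-aa ORF C-terminus, a 192-bp *silencer b* in the
promoter of the 107-aa cistron, and three enhancers (one containing an
embedded silencer, another born from two *Alu* insertions). Each element
originated and matured by a different mechanism, and disentangling those
mechanisms requires several distinct comparative-genomics measurements on
the same short sequences. `regevol` packages those measurements for anyone
studying how regulatory DNA overlapping coding sequence originates:

- **Codon-constraint overlay** — with a reading frame whose first codon
  starts at base *f*, each position of an element is `pre_orf`,
  `codon_pos1`, `codon_pos2`, `wobble`, or `post_orf`. Positions 1–2 of a
  codon are largely fixed by the encoded amino acid (the "cultivator"
  constraint of the pre-existing ORF); third positions are free wherever the
  code is degenerate, so *wobble-invariant* bases mark conservation that the
  protein cannot explain.
- **Cross-species invariance** (`column_invariance`, `classify_bases`) — a
  reference position is invariant when every compared ortholog carries the
  identical base, gap-free; combined with the overlay this partitions an
  element into codon-fixed-invariant / wobble-invariant / flank-invariant /
  variable classes.
- **Nearest-neighbor GC bias** (`neighbor_bias_table`) — the bases flanking
  invariant positions, with a G+C summary; mutational input next to frozen
  bases is the proposed engine of the silencer's GC/CpG accumulation.
- **Composition statistics** (`composition`, `cpg_cluster_pvalue`) — GC
  fraction, overlapping single-strand CpG counts, and CpG cluster
  enrichment under two null models: a binomial tail with per-site
  probability `freq(C)·freq(G)`, and a seeded mononucleotide-preserving
  permutation null.
- **Proto-element detection** (`longest_invariant_runs`) — maximal invariant
  runs, the candidate nucleation sequences from which elements mature.
- **Motif and tandem-repeat scans** (`motif_scan`, `tandem_repeat_scan`) —
  e.g. the NANOG core motif `TAATTTTGT` and the `TTTT/A` *Alu* target site.
- **Origination dating** (`origination_call`) — per-species percent identity
  from affine-gap global alignment (Needleman–Wunsch/Gotoh; identity
  denominator includes gap columns) with present/twilight/absent verdicts
  and an origination-age bracket in Mya.
- **Completion calls** (`completion_call`, `count_differences`) — the most
  anciently diverged species whose element copy is already identical to the
  reference; no such species means the element is reference-lineage
  (human-) specific.
- **Forward simulation** (`simulate_ladder`, `recover_beta`) — ortholog
  ladders evolved down a star phylogeny with frozen positions,
  codon-constrained (purifying) positions, and a G/C bias `beta` at
  neighbors of frozen positions, with full per-mutation ground truth for
  recovery testing.

All coordinates are 1-based and inclusive (the `T1`/`G6` naming convention);
input is normalised to uppercase and `N` never matches anything. The seven
element sequences of the locus ship as packaged fixtures
(`load_fixture("exonic_silencer")`, …).

## Worked example

```python
import regevol as rv

exonic = rv.load_fixture("exonic_silencer")   # 38 bp, frame starts at base 3
ov = rv.overlay_frame(exonic, 3)
print(ov.class_counts())
print(ov.peptide)
print(rv.mutation_effect(exonic, 3, 6, "C").new_peptide)

rep = rv.composition(exonic)
print(rep.n_gc, rep.n_cpg)

rows, n_gc, n = rv.evaluate_reference_neighbor_table(exonic)
print(n_gc, "of", n)
```

prints

```
{'pre_orf': 2, 'codon_pos1': 12, 'codon_pos2': 12, 'wobble': 12, 'post_orf': 0}
RDNLAFGGPEV*
RHNLAFGGPEV*
27 5
12 of 13
```

Reading: under the frame starting at base 3 the 38-mer holds 12 codons, so
24 bases are at codon positions 1–2 (fixed by the 68-aa protein) and 12 are
wobble positions; the in-frame translation is RDNLAFGGPEV followed by a
stop, and changing the invariant G6 to C changes the protein (D→H), showing
how the overlapping ORF pins that base. The element is 27/38 G+C with 5
CpGs, and 12 of the 13 tabulated nearest neighbors of invariant bases are G
or C — the composition signature of neighbor-biased maturation.

The same operations are available from a shell:

```
regevol overlay --fasta exonic.fa --frame-start 3
regevol compose --fasta silencer_b.fa --cluster-model shuffle_null --shuffles 10000 --seed 1
regevol repro          # recompute every built-in reference statistic
```

`regevol repro` recomputes the fixture lengths, CpG counts (5/13/18 across
the two silencer segments and their 230-bp union), overlay counts, the
neighbor-base table, the deeply conserved 11-mer `CCTCTGCAGCC` at positions
121–131 of silencer b, and the NANOG motif hit in enhancer 3, and exits
non-zero if any check fails.

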