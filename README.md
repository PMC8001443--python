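# bpp — bioactive peptide profiling of milk proteins

`bpp` is a pipeline for hybrid *in silico* / *in vitro* studies of
protein-encrypted bioactive peptides, of the kind used to ask whether a
ripened cheese releases the antihypertensive (ACE-inhibitory) and
antidiabetic (DPP-IV-inhibitory) peptides that its casein fractions
encode.  It is aimed at food-proteomics researchers who screen protein
sequences against curated peptide databases and then follow up with
RP-HPLC-MS/MS identification and enzyme-inhibition assays.

## What it computes

**Profiling.**  A *profile of potential biological activity* is the set
of all exact occurrences of database peptides of one activity class in
a protein chain (overlaps and repeats included), found with a
multi-pattern Aho–Corasick matcher.  The headline statistic is the
frequency of occurrence

    A = a / N

with `a` the occurrence count and `N` the chain length.  Profiles come
with per-length histograms, protein rankings, amino-acid compositions
and a *fragmentomic* scan that lists bioactive submotifs encrypted in a
peptide of interest.

**Ripening-release metrics.**  Mapping the peptides experimentally
identified in a sample back onto each parent protein gives, per
(sample, protein, activity),

    A_Eexp = d / N          (frequency of released fragments)
    W_exp  = A_Eexp / A     (fraction of encrypted potential released)

where `d` counts the unique identified peptides that occur in the
chain.  Binary peptide-presence matrices (by activity, by sample, by
casein fraction) provide the heatmap view of the same data.

**Identification support.**  Monoisotopic masses, precursor m/z and
a/b/c/x/y/z fragment series at charges +1..+3, matched against
low-resolution peak lists at a configurable tolerance (default 0.3 Da);
a short peptide counts as identified only when matched ions cover every
peptide bond.  Savitzky–Golay chromatogram smoothing is included.

**Assays.**  Percent inhibition from absorbance triples and IC50 by the
log(inhibitor)-vs-normalized-response model (four-parameter logistic
with asymptotes fixed at 0/100 and free Hill slope), with asymptotic
95 % confidence intervals.  Chromatogram peak tables are summarised as
percentages of total area per retention-time segment.

**Synthetic data.**  Seeded generators produce every input format with
known ground truth (planted motifs, true IC50s, source ions, expected
segment percentages), so the whole pipeline is testable offline.

## Worked example

The built-in demo encodes the released-fragment arithmetic of a 60-day
ripened cheese sample against a 214-residue chain containing 107
encrypted ACE-inhibitory fragments, of which 13 were "identified":

```
$ bpp verify
[PASS] A_Eexp (d=13, N=214): expected 0.061, observed 0.061
[PASS] W_exp rounded-intermediate (0.061/0.5): expected 0.122, observed 0.122
[PASS] W_exp unrounded (13/107): expected 0.121, observed 0.121
[PASS] (M+H)+ of WIQP: expected 543.3, observed 543.3
```

`A_Eexp = 13/214 → 0.061` says that 0.061 bioactive peptides were
released per residue of the chain; dividing by its in-silico potential
`A = 0.5` gives the released fraction `W_exp` (the two display
conventions differ in whether the numerator is rounded first — both
are reported).  The last line is the singly protonated precursor of
the DPP-IV-inhibitory peptide WIQP.

The same numbers from files, via the profiling CLI:

```
$ bpp verify --outdir demo          # also writes the demo input files
$ bpp profile --fasta demo/demo_proteins.fasta --db demo/demo_peptide_db.tsv \
      --activity ACE_inhibitor --out demo/profile.tsv
$ cut -f1-6 demo/profile.tsv
protein_id	protein_label	activity	N	total	A
demo_as1D	alphaS1/D	ACE_inhibitor	214	107	0.5
```

Fragment ions for identification of WIQP:

```
$ bpp ions --peptide WIQP --types by --charges 1 --out demo/ions.tsv
$ cat demo/ions.tsv
ion	charge	mz
b1	1	187.0866
y1	1	116.0706
b2	1	300.1707
y2	1	244.1292
b3	1	428.2292
y3	1	357.2132
```

A spectrum containing peaks within 0.3 Da of all six ions yields
`IDENTIFIED` from `bpp identify` (every one of the three peptide bonds
is covered by a b or y ion).

Other subcommands: `bpp rank`, `bpp compose`, `bpp ripening`,
`bpp heatmap`, `bpp ic50`, `bpp segments`, `bpp simulate`, and
`bpp run --config FILE` for the full pipeline over a directory of
inputs.

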