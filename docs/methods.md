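# Methods

## Profiling model

A protein is screened for encrypted bioactive peptides by exact
multi-pattern substring matching over the 20-letter canonical alphabet.
The counting unit is the *occurrence*: every match position of every
database peptide of the selected activity, so overlapping matches and
repeats of the same peptide each count once.  This choice matters — a
dipeptide-rich database matched against a proline-rich casein easily
yields totals exceeding half the chain length — and the alternative
(unique peptides with at least one match) is exposed as
`ActivityProfile.unique_total` for comparison but is never the default.

The frequency of occurrence is `A = a/N` with `N` the full length of
the sequence record as supplied.  Some curated database entries are
precursors including the signal peptide and some are mature chains;
`bpp` deliberately does not second-guess this — `N` is whatever the
FASTA record contains, and fixtures record their intended `N`
explicitly.

Matching uses an Aho–Corasick automaton built per (database, activity)
pair; a chain of length `n` is scanned in `O(n + matches)` regardless
of database size.  The test suite holds the automaton to exact
agreement with a position-by-position naive scan over hundreds of
random instances.

Coordinates are 1-based inclusive throughout ("fragment 208–211" is a
tetrapeptide starting at residue 208).  Rankings sort by total
occurrence count descending; ties share the min-rank ordinal and are
listed alphabetically by protein label — real casein panels produce no
ties, so the tie rule is a determinism guarantee, not a scientific
claim.

Sequence validation rejects (rather than skips) the ambiguity codes
B, J, O, U, X, Z and any non-letter: exact matching over a 20-letter
alphabet is meaningless on ambiguous residues, and an error that names
the offending position is more useful than a silently shortened chain.

## Ripening-release metrics

Per (sample, protein, activity):

- `d` — unique identified peptide sequences of the activity occurring
  at least once in the chain; multiplicity within the chain does not
  increase `d`.  A peptide annotated with both activities contributes
  to each independently.  Peptides are counted per protein variant —
  a peptide matching two genetic variants of one fraction counts for
  both — because release tables report per-variant columns.
- `A_Eexp = d/N` and `W_exp = A_Eexp/A`.

Since `N` cancels, unrounded `W_exp` equals `d/a` exactly; the package
verifies this identity as a property test.  Published tables of these
metrics are sometimes computed from already-rounded intermediates, so
two display conventions exist:

- `unrounded` (default): divide exact values, round the quotient for
  display;
- `rounded_intermediate`: round `A_Eexp` half-up to three decimals
  first, then divide.

For `d = 13, N = 214, A = 0.5` the conventions give 0.121 and 0.122
respectively; neither is declared "correct", reports state which was
used, and both appear in `bpp verify`.  All display rounding is
half-up (not banker's) at three decimals, implemented with
`decimal.Decimal`; stored values are never rounded.

`w_exp` raises when `A = 0` while released peptides exist: an
identified peptide that the in-silico profile cannot see means the
identification list and the database are inconsistent, which should
stop a run rather than produce a silent infinity.

Presence matrices are binary and unclustered: rows are identified
peptides, columns are activities, samples, or casein fractions, and a
cell is 1 iff the peptide carries/was seen in/maps to the column
category.  On the activity axis the database annotation takes
precedence over the identification list's annotation when a database
is supplied.  Dendrogram clustering of heatmaps is out of scope.

## Fragment ions and identification

All masses are monoisotopic; the residue mass table is the standard
one (cross-checked against pyteomics in the tests).  Neutral fragment
masses follow prefix/suffix sums: `b = prefix`, `a = b − CO`,
`c = b + NH3`, `y = suffix + H2O`, `x = y + CO − H2`, and
`z = y − NH2` (−16.018724 Da) by default with the even-electron
Biemann convention (`y − NH3`) selectable, because fragment-ion
calculators disagree on the z offset.  m/z at charge `n` is
`(neutral + n·1.00727646688)/n`; charges above +3 are not generated.
Neutral-loss and immonium ions are not generated — the identification
rule below never uses them.

Matching assigns each theoretical ion to its nearest observed peak
within ± tolerance (default 0.3 Da, appropriate for a low-resolution
ion trap; configurable).  One observed peak may serve several
near-isobaric theoretical ions; each ion takes at most one peak.

The identification rule is *complete bond coverage*: bond `k` of an
`L`-residue peptide is covered iff a matched N-terminal ion of index
`k` or C-terminal ion of index `L−k` exists at any charge, and the
peptide is identified iff all `L−1` bonds are covered.  This is the
appropriate rule for very short peptides (2–5 residues) where search
engines are unreliable; it is deliberately binary, with no scoring.

Savitzky–Golay smoothing delegates to `scipy.signal.savgol_filter`
with polynomial-interpolated edges, after checking uniform time
spacing; the tests pin it to an explicit per-window least-squares
oracle and to exact reproduction of polynomials up to the filter
order.

## Chromatogram segments

Peak tables are summarised as percentages of total area per
retention-time segment.  Defaults: `0.00–14.00`, `14.01–40.00`,
`40.01–60.00` min, with `60.01–80.00` (column washing) excluded from
the total.  Segments are closed intervals checked in order, so a peak
exactly on a printed boundary goes to the earlier segment; a peak in
the 14.00–14.01 gap between printed boundaries is dropped with a
warning.  An alternative boundary convention (13.99/14.00) is
reachable via `--bounds`.  Peaks are points `(t_R, area)`; peak
detection and integration from raw traces are out of scope.

## IC50 estimation

The model is `Y = 100/(1 + 10^((logIC50 − X)·h))` with
`X = log10(concentration)` — the "log(inhibitor) vs. normalized
response, variable slope" parameterisation with asymptotes fixed at
0/100.  A free-asymptote 4PL is available behind `free_asymptotes`.
Fitting is `scipy.optimize.curve_fit` (Levenberg–Marquardt) from
`logIC50 = median(X)`, `h = 1`; replicates enter as independent
points; optional min-max normalization of responses is off by default
because percent inhibition is already on the 0–100 scale.  95 %
confidence intervals use the asymptotic covariance with Student-t
critical values at `n − p` degrees of freedom.  At least five distinct
concentrations are required; a flat response returns
`converged=False` rather than raising.  Monte-Carlo tests (200
simulated assays, 5 concentrations spanning 2.5–25 mg/mL × 3
replicates, Gaussian noise sd 3 %) hold the estimator to ≤ 15 % mean
bias and CI coverage in [90 %, 99 %].

## Synthetic data

Generators emulate the *structure* of the real inputs, not their
chemistry:

- `gen_protein` draws residues i.i.d. from a composition profile; the
  default mimics bovine β-casein (Pro 16.25 %, Leu 10.75 %, Gln
  10.05 %, Val 9.1 %, Glu 8.6 %, remainder uniform), giving realistic
  short-motif match statistics.  Real proteins have local sequence
  structure (phosphorylation clusters, hydrophobic C-termini) that
  i.i.d. draws do not reproduce, so passing tests demonstrate counting
  and arithmetic correctness, not biological realism.
- `plant_motifs` overwrites motifs at stated positions (non-overlap
  enforced) and records ground truth.
- `gen_identification_sets` includes each matchable database peptide
  in each sample independently with a per-sample probability; real
  ripening produces correlated early/late peptide cohorts, which the
  independence assumption ignores.
- `gen_dose_response` draws responses from the logistic model plus
  Gaussian noise and back-solves them into absorbance triples, so the
  reader plus the inhibition formula reproduce the generated responses
  to 1e-9.
- `gen_spectrum` emits one jittered peak per theoretical ion plus
  uniform decoys kept ≥ 0.6 Da (twice the default tolerance) from
  every true ion, so identification verdicts on synthetic spectra are
  unambiguous by construction.
- `gen_peak_table` Dirichlet-splits segment areas so the segment
  percentages are exact by construction.

All generators are bit-reproducible given (parameters, seed).

## Problem sizes in the test suite

Property suites run at sizes chosen to exercise the algorithms well
past the regimes used in practice while keeping the suite quick:
matcher equivalence on 500 random instances (chains ≤ 200 residues,
≤ 100 patterns), ion identities on 100 random peptides of length
2–12, 200 Monte-Carlo IC50 assays, and a 3-protein × 40-peptide ×
6-sample end-to-end ripening scenario.

## Known limitations

- Exact matching only; no fuzzy matching and no simulated enzymatic
  digestion (release metrics take identification lists as given).
- The accession-dependent checks on two real casein precursors need a
  one-time `scripts/fetch_accessions.py` run with network access;
  until then that single test reports failure by design.
- Presence matrices are qualitative; no peptide quantification, no
  per-peptide potency, and no statistical testing across samples.
- The IC50 layer fits raw replicate points; fitting replicate means is
  not offered.
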