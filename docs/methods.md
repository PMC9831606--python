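# Methods

`knotopt` packages the quantitative analytics of a structure-guided
optimization campaign for inhibitor-cystine-knot (ICK) peptide blockers of
the voltage-gated sodium channel NaV1.7. The campaign iterates four
activities around an external design engine and external instruments:
membrane simulation of the peptide-channel complex, sequence design under
per-position constraints, patch-clamp pharmacology of synthesized variants,
and efficacy recordings in sensory neurons. The engine and the instruments
are out of scope; everything computed *from* their outputs is implemented
here, together with synthetic generators that emulate those outputs with
planted ground truth.

## Variant bookkeeping (`knotopt.peptides`)

The scaffold is a 30-residue ICK toxin with six cysteines at positions
2, 9, 15, 16, 21, 25. Variants are ordered residue lists over an extended
alphabet: the 20 canonical residues plus a registry of non-canonical codes
(norArg, norLeu, 2,4-dimethyl-phenylalanine `dmF`, tert-butyl-cysteine
`tbC`). Numbering is 1-based everywhere, matching the standard "Y1H"
substitution notation.

Design choices:

* Compact alignment tables display one character per cell; extended codes
  use letters that are not amino-acid codes (norArg is "X" by the
  campaign's own convention; norLeu "J", dmF "Z", tbC "U" are this
  package's assignments, chosen from the unused letters so no collision
  with canonical codes is possible). FASTA export spells extended codes in
  square brackets (`...R[norArg]LW...`) because no standard one-letter
  codes exist.
* `apply_mutations` verifies the `from` residue of every substitution
  against the parent; a narrative mutation list that drifted from the
  actual parent sequence fails loudly with the offending position.
* Scaffold validation checks length and cysteine *positions* only.
  Disulfide connectivity is deliberately not validated: the pairing is not
  part of any sequence record this package consumes.
* C-terminal amidation is carried as metadata only; no mass computation.

## Fractional contacts (`knotopt.interface`)

Frames of the peptide-channel-membrane complex arrive as multi-model PDB
text (parsed with biotite; a pre-scan reports malformed ATOM/HETATM records
with their line numbers). Every atom is assigned exactly one environment
group - lipid head, lipid tail, water, channel, peptide, ion, other - by
residue-name rules first (water, ions, lipids), then chain membership
(peptide chains E-H, channel chains A-D by default). The rule table is
serializable to YAML.

The POPC head/tail partition is an explicit assumption shipped with the
package: head = choline, phosphate, glycerol and both ester linkages; tail
= acyl-chain carbons C22..C218 and C32..C316. Atom-name sets are listed
exhaustively in the source so the assumption is auditable.

**Fractional contact** of peptide residue *i* with group *g* is the
fraction of (frame, chain-pair) observations in which any heavy atom of
*i* lies within the cutoff (default 3.5 Å) of any heavy atom of *g*. The
channel binds four peptide copies, so pairs (A,E), (B,F), (C,G), (D,H)
each contribute one observation per frame; the channel group is restricted
to the paired chain while membrane and water atoms are shared, and all
groups divide by the same denominator n_frames x n_pairs. Values are exact
count ratios, so recomputation is bit-identical.

Numerical/design choices:

* The contact indicator is **binary per observation**, not an atom-pair
  count: contact is a per-observation event whose frequency is being
  estimated. An atom-pair-count weighting is available
  (`ContactParams.weighted`) as a documented alternative reading.
* Heavy atom = element not H/D, judged from the element column.
* Distance search uses a k-d tree; its results are required to equal the
  all-pairs brute force exactly, and both paths ship (`brute_force` flag)
  with tests enforcing the contract.
* Polar-interaction criteria (no universal convention exists, so these are
  package defaults, configurable): hydrogen bond = donor-acceptor heavy
  atoms <= 3.5 Å, plus a donor-H...acceptor angle >= 120 degrees whenever
  explicit hydrogens are present; salt bridge = side-chain charged N/O
  pair <= 4.0 Å (Arg/Lys/His vs Asp/Glu).

## Design post-processing (`knotopt.design`)

Scorefiles are whitespace tables whose data lines start with `SCORE:`; the
header must name `total_score`, a ddG-like column and a trailing
`description` tag. **Lower is better for both energies** (standard energy
convention; the engine's "top designs" are the lowest-scoring ones).

The selection cascade keeps the `n_score` = 100 lowest total-score records,
then among them the `n_ddg` = 20 lowest-ddG records. Ties break by tag in
lexicographic order so the selection is reproducible; the cascade is
idempotent and is tested against an independent double stable sort.

Position-weight matrices are exact column count ratios; information
content is log2(20) minus the column Shannon entropy, in bits, with the
small-sample correction used by some logo tools available but off by
default. Consensus is the per-position argmax with alphabetical
tie-breaking. The campaign's own consensus calls occasionally overrode the
logo with expert choices (e.g. picking a third-ranked residue); such
overrides are manual inputs by nature and are not automated. The logo
renderer is a small matplotlib stacked-letter plot.

Resfiles follow the PIKAA/NATAA/NOTAA dialect: optional default command
lines, a `start` marker, then `<resnum> <chain> <COMMAND> [args]` body
lines; parse-write round trips are lossless up to whitespace.
`derive_constraints` turns a contact profile into a resfile: NATAA for
positions pinned to their native identity, single-residue PIKAA for
empirically fixed identities, and NOTAA of the acidic residues (default
"ED") wherever lipid_head + lipid_tail fractional contact reaches the
threshold. The threshold is not a published number; the default 0.25 of
observations is this package's choice, exposed as `--lipid-threshold`.
Cysteine pinning applies only when a scaffold sequence is passed - the
campaign's own printed resfile leaves the cysteines at the default
command, with the disulfides preserved elsewhere in its protocol.

## Pharmacology (`knotopt.pharm`)

Concentration-response data are fitted with the Hill equation with floor 0
and ceiling 1 (complete block at saturation, which the campaign's
concentration-response curves reach):

    f([L]) = [L]^h / (IC50^h + [L]^h)

Optimization runs in (ln IC50, h); there the model is a logistic in log
concentration, well conditioned across the five-decade concentration
ranges these assays use. The reference fit is bounded least squares
(scipy); noiseless data are recovered to better than 1e-6 relative.

**Confidence intervals.** The default is a case-resampling bootstrap over
data points (B = 2000, seeded), **studentized on ln IC50** (bootstrap-t):
the interval is `exp(lnIC50 - t*_{97.5} s)` .. `exp(lnIC50 - t*_{2.5} s)`
with `s` the linearized standard error and `t*` quantiles of the
resampled studentized statistic. The plain percentile interval was
implemented first and measured: at the campaign's typical design (5
concentrations x 3 cells, response noise sigma ~ 0.05) it covers a true
IC50 in only ~91-92% of Monte-Carlo replicates, a known small-sample
deficiency (the bootstrap spread underestimates the sampling spread by
~5% here; BCa and stratified resampling were also measured and do no
better). The studentized interval is second-order accurate and attains
~94-95% coverage under the same conditions, so it is the default;
`ci_method="percentile"` and `"wald"` remain available for
cross-checking. Bootstrap refits use a vectorized damped Gauss-Newton
warm-started at the full-data optimum; tests verify it reaches the same
optima as the reference optimizer on independent resamples.

**Selectivity folds** are `floor(IC50_subtype / IC50_reference)` -
truncation toward zero, the convention that reproduces the campaign's
printed integers (382/3.8 prints 100, not 101). Censored entries (">X")
propagate to censored folds `> floor(X / IC50_ref)` flagged as mechanical
lower bounds; a censored reference is an error. Potency rankings order by
IC50 with ranges represented by their midpoints and stable ties.

## Excitability summaries (`knotopt.ephys`)

Voltage-clamp traces are zero-subtracted against the mean of the 0.14 s of
holding current before the step. Window statistics use a half-open
[t0, t1) convention aligned to sample times at or after t0 - unambiguous
at the 50 kHz sampling these recordings use: the early mean over
0.4-1 ms and the windowed peak over 0.4-8 ms after the step, both per
capacitance (pA/pF). Inward currents are negative; "peak" is the extremum
of the signed trace with a polarity flag (default inward). The
drug-sensitive component is the exact samplewise difference of
zero-subtracted pre- and post-drug traces.

Per-cell tables carry rheobase and AP counts per stimulus train
(10 steps at 0.1 Hz, 120 at 1, 3, 10 Hz). Derived metrics: rheobase
change % and remaining APs % (drug count / baseline count at the same
frequency). Percentages are rounded **half away from zero to one
decimal**, and group means/SEMs (sample SD over sqrt n) are computed from
those one-decimal per-cell values and themselves reported to one decimal -
the convention under which the published per-cell table's own
average/SEM rows reproduce exactly. Cells with zero baseline APs at a
frequency are undefined there and drop out of that frequency's average;
exclusion of e.g. TTX-insensitive neurons is an explicit per-cell boolean
supplied by the user, never inferred.

## Synthetic data (`knotopt.synth`)

One top-level seed fans out to per-generator substreams through
`SeedSequence([seed, crc32(label)])`, so adding a generator never perturbs
another and identical specifications yield byte-identical files.

* **Frames**: per (frame, chain-pair, residue, group) one pseudo-atom of
  the group is placed 2.5 Å from the residue with the planted probability,
  else 8 Å away; residue names are chosen so the default grouping rules
  classify them (POPC, HOH, channel chains A-D, peptide chains E-H), and
  blocks are spaced ~50 Å (residues) and ~1800 Å (pairs) apart so planted
  states cannot interfere. Geometry is deliberately minimal - one atom per
  placement; classifiability and the planted Bernoulli state are the goal,
  realism is not. Consequently these fixtures exercise the estimator, not
  molecular geometry: a real bilayer's correlated contacts, rotamer
  variability and solvent shells are absent, so passing tests certify the
  counting and normalization, nothing about force fields.
* **Scorefiles**: total score and ddG are jointly normal (defaults: means
  -300 and -40, SDs 10 and 5, correlation 0.5); an optional motif is
  planted into the cascade-winning records at a chosen enrichment so
  consensus recovery can be asserted.
* **Dose-response**: Hill curve plus Gaussian noise truncated to [0, 1];
  the default design is 5 concentrations x 3 cells, mirroring the
  "at least three concentrations per cell" acquisition rule.
* **AP tables**: baseline 10 Hz counts are drawn uniformly from 30..120
  (cells follow the fast train only partially even at baseline); drugged
  counts are binomial draws with the planted survival probability; drugged
  rheobase is baseline x multiplier with 5% lognormal jitter.
* **Traces**: each component is a(1 - e^(-t/tau_act)) e^(-t/tau_inact);
  the pair (total, slow-only) shares the same noise draw so subtraction
  recovers the fast component exactly in the noiseless case. A closed-form
  window average of the generating function serves as the oracle for the
  window statistics; its agreement is discretization-limited and tightens
  as the sampling rate grows.

## Problem sizes used by the shipped analyses

The test suite and the acceptance script run the pipeline at sizes chosen
to make the statistical assertions sharp but cheap: 500 frames x 4 chain
pairs (2000 observations, binomial SE ~ 0.01 at p = 0.3), 1000-design
scorefiles for the cascade, 500 Monte-Carlo replicates x 2000 bootstrap
resamples for CI coverage. The published IC50 panel, per-cell table,
variant table and resfile ship as plain-text package data and are
recomputed from, never hard-coded into, the analysis functions.

## Known limitations

* Automated consensus cannot reproduce expert overrides made from visual
  logo inspection; those remain inputs.
* The fractional-contact reading of "frequency of forming contact" as a
  binary per-observation event is one of two defensible readings; the
  atom-count-weighted alternative ships behind a flag.
* Selectivity folds computed from rounded published IC50s can differ from
  folds computed from unrounded source data; two published hERG folds are
  of this kind and cannot be reproduced from the printed values.
* Spike detection is out of scope: AP counts are inputs. So are
  voltage-protocol modeling, gating kinetics, and Boltzmann
  activation/inactivation fits.
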