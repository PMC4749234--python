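# Methods

## Nearest-neighbor model with a labelled nucleotide

Duplex formation is modelled as a two-state transition whose ΔH° and ΔS°
are sums over adjacent base-pair stacks plus initiation terms. The engine
ships the unified Watson–Crick parameter set, the published single
internal-mismatch tables, and terminal-mismatch parameters as plain TSV
files (`src/eprobedesign/data/params`); `scripts/make_param_tables.py`
regenerates them from the corresponding biopython dictionaries. At most one
mismatch per dinucleotide stack is parameterised, so duplexes with adjacent
mismatches (and indel-containing hybrids) are rejected rather than guessed
— the designer avoids them instead.

The labelled thymidine `Z` pairs as T for all stack lookups and then adds
incremental (ΔΔH°, ΔΔS°) terms per flanking dinucleotide context. Two
situations are distinguished:

* both neighbors matched → the full-match context increments
  (`z_match.tsv`). The shipped values are placeholders flagged
  `provenance=placeholder` (ΔΔH° = −4.0 kcal/mol, ΔΔS° = −6.5 cal/mol/K,
  ΔΔG°₃₇ ≈ −2.0, i.e. stabilising and of the same magnitude as the
  mismatch-adjacent increments); a calibration run replaces them.
* a single-base mismatch immediately 5′ or 3′ of the label → the pooled
  parameters in `z_mismatch.tsv` (NTᴱ/AN: −3.6/−4.4; TᴱN/NA: −2.9/−3.2).

A label with mismatches on *both* flanks has no published parameters and
raises an error directing the user to calibration. A mismatch at the
labelled position itself (reachable in the genotyping *near* label mode at
distance 0) is scored by the mismatch stacks with Z treated as T and no
label increment; no data exist to do better.

Salt: the entropy correction ΔS°′ = ΔS° + 0.368 (N−1) ln[Na⁺] with divalent
cations folded in as [Na⁺]eq = [mon] + 120 √([Mg²⁺] − [dNTP]) (mM). The
scheme identifier is stored with the table so it is reportable and
swappable. Default buffer: 50 mM monovalent, no divalent. Default total
strand concentration C_T = 2 µM, matching the melting experiments the
parameters derive from.

Units throughout: ΔH° kcal/mol, ΔS° cal/mol/K, °C at the API surface,
R = 1.9872 cal/mol/K.

### Self-folding Tm convention

The printed self-folding formula includes an R ln C_T term;
`tm_unimolecular` implements it as printed with an `include_ct` switch for
the conventional concentration-independent form Tm = ΔH°/ΔS° − 273.15.
The structure module uses the concentration-free form for hairpin Tm: a
design ceiling of 24 °C is only meaningful on that scale (at C_T = 2 µM the
printed form shifts hairpin Tm by tens of degrees), and a unimolecular
transition has no physical concentration dependence.

## Structure prediction

`hairpin_best` enumerates every contiguous stem (≥ 2 bp) enclosing a loop
of ≥ 3 nt and scores stem stacks plus a tabulated entropic loop penalty
(`loops.tsv`, ΔS = −1000·ΔG°₃₇(loop)/310.15, linearly interpolated between
tabulated lengths and linearly extrapolated beyond). Bulges, internal
loops and multiloops are out of scope at probe scale; the exhaustive
enumeration is exact for the model class, which is what the oracle tests
assert. A label inside the stem contributes its full-match context
increments; outside the stem it contributes nothing — the conservative
neutral choice, because dye behaviour outside a stem is experimentally
visible but unmodelled — and a label within 2 nt of a stem end attaches a
warning to the result.

`dimer_best` finds the most stable *ungapped* complementary register
between two oligos (all antiparallel offsets, maximal runs of ≥ 3 paired
bases scored as bimolecular duplexes, labels on either strand counted).
This is a deliberate simplification of a full gapped thermodynamic
alignment; at primer/probe scale gapped self-structures are rare and the
designer's hairpin ceiling already rejects strong intramolecular folds.

## The design search

Candidate enumeration is exhaustive over substring windows subject to
length/Tm/GC windows, included/excluded regions, fixed 3′-end requests
(allele-specific primers; the output contains the fully matching sequence
and the user chooses the mismatch base), and the hairpin ceilings (47 °C
for primers, 24 °C for probes). In genotyping mode primers may not overlap
the variant, probes must cover it with the variant at least
`probe_terminal_clear` (default 2) positions from each probe end, and both
allele Tm floors apply. Eprobe chemistry expands each probe window into
one candidate per admissible label position, ranked far-from-variant first
(or nearest-first in *near* mode), then central.

Scoring is a weighted sum: primer/probe Tm and length deviations from
their optima, primer-pair Tm difference, product-size deviation,
mis-hybridization margin (worst off-target Tm of the probe anywhere on
either template strand, ungapped, ≤ 3 non-adjacent mismatches; candidates
whose margin falls below 10 °C are rejected outright), the worst of the
three pairwise dimer Tm values, a small label-rank term, and in genotyping
mode −1.0 × ΔTm (a reward). The weights are package defaults in
`DesignSettings`, all exposed in task files; no published weight set exists
for this combination, so the values were chosen once to make a ~1 °C Tm
deviation, one nt of length deviation and one °C of allele gap comparable
in magnitude.

The combination search is branch-and-bound over pairs sorted by pair
penalty and probes sorted by probe penalty: since the cross-dimer and
specificity terms are non-negative, `pair_pen + probe_pen` bounds the total
from below and pruning is exact — results are identical to full
enumeration, which the oracle tests verify. Ties break
deterministically on (penalty, product-size deviation, left start, probe
strand `+` first, right start, probe start, label position); identical
inputs give byte-identical reports. Coordinates are 0-based half-open
internally; reports print 1-based inclusive and say so.

Indel genotyping: a probe spanning an indel is scored on the gap-free
template and, on the variant side, on the same-length window at the
minimum-mismatch shift, flagged `indel_mode`; when no shift is
parameterisable the probe is evaluated on the wild type only and flagged.

## Melting-curve analysis and calibration

The observable is log-fluorescence at 530 nm:

    logF(T) = θ(T) (a_b + b_b T) + (1 − θ(T)) (a_u + b_u T)

with the bound (duplex) baseline the fluorescent one and θ the two-state
bound fraction: for two complementary strands at total concentration C_T,
K = θ / ((1−θ)² C_T/2), giving K(Tm) = 4/C_T; for a self-fold
θ = K/(1+K). The same closed form is used by the synthetic generator, so
parameter-recovery tests are exact inverse problems; the explicit signal
equation is this package's declared model choice.

Fitting is nonlinear least squares (lmfit/leastsq) with six free
parameters (ΔH°, ΔS°, two baselines), multi-started: the first start takes
Tm from the five-point averaged negative derivative peak and ΔH° from the
derivative-peak width (ΔH ≈ −3.3 R Tm²/FWHM), the remaining starts spread
over a fixed enthalpy ladder (−60, −100, −150, −220 kcal/mol) plus seeded
jitter; best residual sum of squares wins. The spread ladder matters: with
realistic noise a single poorly placed start can strand the optimiser in a
steep-transition local minimum. Curves whose fitted bound fraction spans
less than 0.2 in the scanned range, or whose signal is flat, raise a
structured "no transition" error.

Calibration pipeline: fit each replicate, average (ΔH°, ΔS°) per oligo
pair (three replicates by default); per target sequence, adjust the
predicted unlabelled-duplex parameters by the mean observed-minus-predicted
offset over far-label pairs (label more than 3 nt from the mismatch) — the
positional-stability correction the mismatch tables lack; convert
mismatch-adjacent (d = 1) pairs into increment observations by subtracting
the adjusted prediction and the known match-side context increment; and
solve the pooled two-class regression by SVD least squares, run separately
on ΔΔH°, ΔΔS°, ΔΔG°₃₇ and ΔΔG°₆₀, reporting estimate ± standard error.
Rank-deficient designs fail loudly, naming the unidentifiable classes.

## Synthetic data

`gen_melt_curve` inverts the fitted signal model exactly (4–95 °C scan,
0.5 °C steps → 183 points, Gaussian noise σ = 0.01 log-units, three
replicates, C_T = 2 µM — the conditions of the underlying melting
experiments). `gen_calibration_set` builds labelled-probe/target duplexes
on a 20-mer reference with a thymidine at every second position, covering
single-base mismatches immediately 5′ and 3′ of the label (24 by default)
plus one far-label control per distinct target for the baseline
adjustment, with planted ground-truth increments. `gen_design_target`
produces random templates with an optional SNP planted in the central
third. Everything is deterministic under an explicit seed.

What the generators do **not** emulate: dye photophysics (fluorescence
amplitude vs label position, signal loss for terminal labels), non-two-state
melting (intermediates, aggregation), instrument drift, and real positional
mismatch-stability effects beyond what the mismatch tables carry. Passing
recovery tests therefore demonstrates the correctness of the fitting and
regression machinery under the declared model, not the accuracy of the
model for any particular dye chemistry — that accuracy comes from the
published parameter values the engine ships.

## Problem sizes and numerical choices

The always-on test suite uses scaled simulation sizes chosen as reasonable
defaults for routine runs: 1,000-sequence oracle comparisons for the Tm
engine and hairpin finder, 20 templates (≤ 120 nt) for the
designer-vs-enumeration check, three full 24-duplex calibration sets plus
four reduced 12-duplex sets for recovery, and 200 random genotyping tasks
for the constraint audit. Tolerances: exact (1e-9) agreement where two
implementations compute the same model; 0.5 °C against the independent
unlabelled-Tm implementation (residual differences come from its R = 1.987
rounding); 0.2 kcal/mol median error for calibration recovery, the scale
at which an increment error would visibly move a probe Tm prediction.

## Known limitations

* Hairpin scoring has no initiation/terminal corrections and no
  mismatch-containing stems; dimers are ungapped.
* Off-target search is within-template only; genome-scale specificity is
  out of scope.
* Multi-label probes (two Z) and RNA/mixed backbones are unsupported.
* The full-match label increments ship as flagged placeholders until a
  calibration dataset is supplied.
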