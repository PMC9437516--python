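# Methods

## Problem setting

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System (FAERS) collect voluntarily submitted drug adverse-event reports.
They have no exposure denominators, so absolute risks cannot be estimated;
instead, *disproportionality analysis* asks whether a drug–event
combination is reported more often than expected if drug and event were
independent across the whole database. This package implements that
analysis for respiratory toxicity of the eight immune checkpoint
inhibitors (ICIs: nivolumab, pembrolizumab, cemiplimab; atezolizumab,
avelumab, durvalumab; ipilimumab, tremelimumab), together with the
surrounding pipeline: quarterly-file ingestion, case deduplication,
vocabulary mapping, time-to-onset, and outcome descriptives.

## Data model and ingestion (`faers_io`)

FAERS quarters ship as five '$'-delimited ASCII tables (DEMO, DRUG, REAC,
OUTC, THER) keyed by PRIMARYID (a report *version*) and CASEID (a case).
Parsing is header-driven, not positional, so column reordering across
years is tolerated; text fields are uppercased and whitespace-collapsed
because verbatim drug names are inconsistent. Dates are `yyyymmdd` with
possible truncation to month or year; they are retained as partial dates
at ingestion and only filtered where a stage actually needs day precision
(the onset stage), never discarded up front. Ages are normalized to years
from the FAERS unit codes (DEC×10, MON/12, WK/52.143, DY/365.25, HR/8766;
a missing unit is read as years), and values outside [0, 130] years are
treated as missing. Rows referencing a PRIMARYID absent from DEMO are
counted as orphans and excluded, never silently dropped.

## Deduplication (`dedup`)

FAERS distributes every revision of a case; the FDA-recommended rule keeps
one report per CASEID: the version with the latest FDA receipt date
(FDA_DT), ties broken by the numerically higher PRIMARYID. An undated
version sorts below any dated one and survives only if all versions are
undated. Deduplication runs on the pooled multi-quarter corpus because
case versions span quarters. The operation is idempotent and independent
of input order (output sorted by CASEID); both properties are tested.

## Vocabularies and the pair unit (`vocab`)

Drug normalization maps verbatim names to the eight canonical ICIs with
the priority: exact active-ingredient match, exact verbatim match,
word-boundary substring match of a synonym. A record matching two
canonical drugs (e.g. "IPILIMUMAB AND NIVOLUMAB") is a fixed combination:
it maps to "other" and a counter is incremented, since combination
regimens are out of scope. Dictionary validation rejects any synonym
claimed by two canonical drugs.

MedDRA is licensed and cannot be redistributed, so the shipped event
dictionary is a **synthetic fixture**: representative preferred terms for
each of the ten respiratory event classes (bronchial, lower respiratory
tract, pleural, pulmonary vascular, respiratory NEC, respiratory tract
infections, respiratory tract neoplasms, respiratory signs and symptoms,
thoracic, upper respiratory tract disorders, with their MedDRA-style
class codes). A PT may belong to several classes. Real analyses load a
CSV dictionary derived from a licensed MedDRA copy; absolute class counts
therefore depend on the user's dictionary and are not reproduction
targets here.

The unit of analysis is the **drug–event pair**: one distinct (report,
drug, PT) occurrence. A report with two suspect drugs and three PTs
contributes six pairs. Non-ICI drugs stay in the universe (labelled
"other", keyed by their normalized verbatim name) because the
disproportionality denominator must cover all drugs. The role filter
defaults to suspect drugs only ({PS, SS}): concomitant medication would
dilute signals, and suspect-only counting is the pharmacovigilance norm.
A `monotherapy` switch drops reports matching more than one canonical ICI
(the selection rule for "monotherapy" in the source analysis is unstated;
exactly-one-matched-ICI is the natural operationalization).

## Disproportionality statistics (`disprop`)

For a drug set × event set combination, with pair-level counts
N_observed (both), N_drug (drug margin), N_event (event margin), N_total
(universe):

    N_expected = N_drug · N_event / N_total
    ROR  = (N_observed + 0.5) / (N_expected + 0.5)
    IC   = log2(ROR)                                    [bits]

The +0.5 additive shrinkage is the WHO Uppsala Monitoring Centre (UMC)
convention: it pulls small-count estimates toward the null and keeps both
statistics defined at zero counts (0 observed, 0 expected ⇒ ROR = 1,
IC = 0). Note this "ROR" is a shrunk observed/expected ratio, not the
classic 2×2 reporting odds ratio. IC = log2(ROR) holds *by construction*
to machine precision — both derive from the same shrunk ratio — and is
property-tested as such.

95% credibility bounds for the IC use the UMC closed-form approximation
with shrunk count n = N_observed + 0.5:

    IC025 = IC − 3.3 n^(−1/2) − 2   n^(−3/2)
    IC975 = IC + 2.4 n^(−1/2) − 0.5 n^(−3/2)

These formulas reproduce the published interval bounds of the reference
tables from the printed (N, ROR) pairs at 2-decimal rounding (verified in
tests and recomputed by `analysis/04_printed_table_checks.py`; a few
printed cells differ by 0.01–0.03, consistent with the publication
rounding its ROR inputs before typesetting, and those cells are not used
as checks). ROR bounds default to the IC-consistent transform
(2^IC025, 2^IC975), the natural interval for a shrunk ratio; a Wald
interval on the reconstructed 2×2 table is available for comparability
and agrees with the transform within 5% when counts are large and margins
rare. A combination is a signal when the lower bound strictly excludes
the null (ROR025 > 1 or, equivalently on the default method, IC025 > 0).
No multiple-testing adjustment is applied; shrinkage is the only guard,
matching standard practice for these statistics.

Subgroup contrasts (men vs women, ≥70 vs <70 years, fatal vs non-fatal)
use the *classic* 2×2 reporting odds ratio — (a/b)/(c/d) comparing the
stratum split between ICI pairs and other-drug pairs within the event
set — with a Wald CI and Haldane +0.5 correction on zero cells. This is
deliberately a separate result type from the shrunk-ratio signals: the
two constructions answer different questions and the published subgroup
values cannot be reconstructed from the published characteristics table
under any standard 2×2, so the formula is documented in the output
metadata rather than matched to specific published numbers.

Report tables round at 2 decimals, half away from zero, matching the
convention of printed signal tables.

## Time to onset (`onset`)

Per pair, time to onset = event date − therapy start date, in whole days,
computed only when both dates have day precision and the event does not
precede the start. Exclusions are tallied by reason (missing event,
missing start, partial precision, negative) and always reconcile with the
input count. When a report has several therapy episodes for a drug, the
earliest day-precision start is used (onset from first exposure).
Summaries report median and quartiles by linear interpolation (type-7 —
a stated convention is required for reproducibility) and cumulative
proportions at fixed landmarks of 30/60/90/180/360 days; "one month" and
"three months" are defined as 30 and 90 days because the underlying
arithmetic is in days.

## Descriptives (`descriptives`)

The characteristics table (sex, age group at the ≥70-year cut, receipt
year, outcome, reporting country) compares the ICI respiratory pairs with
the other-drug respiratory control group. Percentages are computed over
the full group including an explicit Missing level, so every dimension
sums to 100%. The outcome dimension assigns one level per record by
severity precedence DE > LT > DS > HO > CA > RI > OT (making the column
sum to the total), whereas the per-class death proportions use marginal
presence of the death code DE — the two conventions serve different
tables and coexist deliberately. Countries are grouped to the ten named
reporting countries plus Others and Missing.

## Synthetic corpus generator (`synthetic`)

The generator emulates the multi-table quarterly structure so the whole
pipeline is testable without downloads. Per case: one suspect drug
(categorical over a catalog in which the eight ICIs hold realistic small
shares, ~8% combined, anti-PD-1 dominating, against decoy drugs), and a
reaction set drawn per-PT as independent Bernoullis over ~30 PTs
(respiratory marginals 0.002–0.06, decoy PTs up to 0.12; ~1.7 expected
events per case, event-free cases dropped and tallied). Demographics,
country weights, per-class fatal-outcome probabilities (~0.30–0.37 for
the severe lower-respiratory classes, mirroring the reported severity
ordering), per-class Weibull onset models (shape <1, scale ~55–85 days,
so onsets front-load into the first three months with medians of a few
weeks), and missing-date/partial-precision rates (~30% missing event
dates) are all configurable with those defaults.

**Signal injection** raises the conditional probability P(pt | drug) so
that the *expected* shrunk ROR equals the requested target, solving the
closed-form expected-count equations by root finding (fixed-point
iteration across multiple signals; at most one signal per drug). Boosting
a conditional probability keeps all margins mutually coherent, unlike
post-hoc count editing; a target requiring P > 1 is a configuration
error. Because drug–event pair counts are sums over events, dropping
event-free cases changes no count in the disproportionality universe, so
the Bernoulli model's injected targets are exact in expectation.

Duplicate case versions perturb only FDA_DT and PRIMARYID (never clinical
content), isolating the dedup contract. Ground truth — the true pair
table, solved boosts, fully-dated duration sets, death tallies — is
returned with the corpus and written beside the ASCII files. Identical
seed and config give byte-identical output files. `build_tables=False`
skips serializing the row tables (identical draws and ground truth),
which is how the replicate studies below stay cheap.

What the generator does **not** emulate: free-text drug-name noise beyond
brand synonyms, reporting-delay waves and stimulated reporting,
indication channeling, within-report PT correlation beyond the shared
case, and real MedDRA granularity. Passing recovery tests therefore shows
the *estimators and bookkeeping* are correct under known structure, not
that real FAERS signals are unconfounded.

## Verification strategy and problem sizes

Unit tests pin hand-computable examples (a 22-pair fixture corpus whose
every count is documented in its docstring; a 10-pair toy universe with
contingency (2, 4, 5, 10)), and property tests cover dedup idempotence
and order invariance, the IC/ROR identity, monotonicity in the observed
count, and vectorized-vs-brute-force count equality on universes up to
10^4 pairs. Stochastic checks run at: 100 replicates × 20,000 cases for
injected-target recovery (targets 1, 2, 4 on a 3%-share drug and a 6%
PT, mean IC within 0.1 bits); 1,000 null universes of 500 pairs for the
false-flag rate of IC025 > 0 (≤5%; shrinkage makes it conservative); 200
replicates for interval coverage at a null target; and 10,000 durations
for Weibull median recovery within 5%. These sizes give stable acceptance
margins while keeping the full suite fast enough to run routinely.

## Known limitations

* The default event dictionary is a fixture; real analyses must supply a
  MedDRA-derived dictionary, and class-level counts depend on it.
* The shrunk-ratio "ROR" is not comparable to classic-odds-ratio RORs
  from other tools except at rare margins; use the Wald mode for that.
* Onset analysis ignores censoring and exposure duration; it describes
  reported onsets, not hazard.
* The generator's independence baseline cannot produce confounding by
  indication, so calibration results do not certify behaviour under
  confounded reporting.
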