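# Methods

## The scoring model

`herbmars` implements an additive multi-criteria rubric over six components
(A–F, total 0–8; see README for the table). The components are deliberately
independent observations about a compound, so the rubric is monotone: adding
an activity, a standard listing, a method listing, or raising the reported
concentration can never lower a component or the total. The package treats
the rubric itself as the object of interest — scores are always recomputed
from evidence, and scores *recorded* in a source table are kept as data for
auditing, never merged into the computation.

Assumptions worth making explicit:

* **A is a recorded fact, not a derivation.** "Documented constituent of the
  material" is stored as its own flag rather than inferred from the
  activities list, because a compound can be a documented constituent with no
  individually studied bioactivity (several *W. ugandensis* sesquiterpenes
  are exactly this: A=1, B=0).
* **B counts distinct symptoms, capped at 3.** Symptom strings are compared
  after NFKC normalization, trimming and casefolding; there is no stemming or
  synonym expansion, so curation controls granularity. Only activities marked
  relevant to the plant's labelled indications count, and their symptoms must
  come from the plant's indication profiles (validated). The "well-elucidated
  mechanism" nuance of the top evidence level is stored as free text and not
  operationalized — there is no defensible computable criterion for it.
* **Concentration gates are inclusive** (≥ 5 ppm, ≥ 50 ppm), and a report
  that was never determined ("ND") scores C=D=0 rather than being treated as
  zero concentration.

## Unit handling

All concentration dialects normalize to ppm w/w (1% = 10⁴ ppm, 1 mg/g =
10³ ppm; ppm is the identity). Three choices:

* **Ranges collapse to the arithmetic midpoint** — the only parameter-free
  reduction of a (low, high) pair, and the one that reproduces the
  arithmetically consistent rows of the study tables.
* **The basis/matrix never rescales values.** "10–30% of essential oil" is
  scored as 10–30%, not converted to a per-leaf-mass figure; oil-yield
  extrapolation would require data the evidence tables do not contain. The
  basis is carried as metadata so downstream users can see what the number
  refers to.
* **Everything is mass fraction**; no density corrections are applied (the
  single mL-denominated listing is handled on the costing side, not the
  concentration side).

Parsing is strict: a string that matches no known dialect raises a named
error instead of silently becoming "not determined", because a silent ND
would *lower* a score.

## Suitability, roles, compliance

The suitability rule is `total ≥ 5 AND E = 1 AND F = 1`. The two explicit
gates are not redundant with the threshold: a compound can reach 5 on
constituent + symptom + concentration points alone yet be unusable in a QC
laboratory without a reference standard or method (epicatechin in
*M. indica* is the canonical case: total 5, no standard, not suitable).

The 50 ppm boundary belongs to the quantitative arm (ties → quantitative),
for consistency with component D's inclusive threshold. Toxic compounds keep
their computed total and carry `must_screen=True`; forcing a fixed score
would conflate evidence quality with regulatory obligation, and both facts
are reported side by side. Negative-marker limits are inclusive maxima; a
0 ppm limit bans any positive measurement. Compliance is evaluated against
the record's own reported concentration (i.e., the raw material), which is
the only measurement the dataset contains.

## Costing

Unit cost = pack price / pack value, in the listing's own denomination
(€/mg, €/mL, €/g — never cross-converted). Costs are printed and summarized
at 1 decimal, rounded half-up, and the summary statistics are computed over
the rounded values by default so they agree with a printed cost column (an
unrounded variant is exposed via `cost_summary(..., rounded=False)`).
Summaries pool all denominations into one set of 37 values — reproducing the
convention of single-column vendor cost tables — and a per-denomination
breakdown is attached as the corrective view. The dispersion estimator is
the sample (n−1) standard deviation.

## Auditing

The auditor is report-only. For every record carrying recorded scores it
checks: (i) the printed components sum to the printed total
(`sum_mismatch`), (ii) each evidence component A–D recomputed from the
record's own evidence equals the printed one (`derivation_mismatch`), and
(iii) the printed availability flags E/F agree with the record's actual
standards/methods listings (`availability_mismatch`). The kinds are kept
disjoint (E/F discrepancies are always classified as availability). On the
packaged dataset the auditor reproducibly surfaces six findings: the
polygodial sum error, D granted to two 10–20 ppm ginger rows, C/D granted to
a not-determined row, and a method flag with no corresponding listing.

Two source inconsistencies are recorded but not resolvable from the data:
the prose describes nimbolide as scoring 5 and lacking a standard, while the
printed tables list a standard, a method and a total of 7 — the dataset
follows the tables; and one compound's printed pack size ("/100 mg") is
inconsistent with its own printed unit cost (34.5) and the prose, which
twice corroborate a 10 mg pack — the dataset follows the corroborated value.

## Synthetic data

The generator emulates the *structure* of a scored evidence table with known
ground truth: constituent flag ~ Bernoulli(0.95), symptom level ~
{0:0.10, 1:0.25, 2:0.25, 3:0.40}, concentration determined with probability
0.70 and then drawn log-uniformly over 10⁰–10⁶ ppm, standards/methods ~
Bernoulli(0.75/0.80), toxicity ~ Bernoulli(0.10). These defaults mirror the
empirical frequencies of the packaged 35-row table (nearly all rows are
documented constituents; about 70% of concentrations are determined; about
three quarters have standards). A drawn ppm is re-expressed in a random unit
as either a point value or a symmetric range, so the midpoint rule recovers
the drawn value and the ground-truth components are exact by construction
(the rubric is integer-valued; recovery is tested at zero tolerance).

Planted corruption perturbs one recorded field per victim record; component
corruptions co-adjust the recorded total so each plant yields exactly one
finding of a predictable kind, making the audit round-trip (ledger ↔
findings) exact. A single `random.Random(seed)` stream drives everything;
identical seeds give byte-identical datasets.

What the generator does *not* emulate: real literature text (activities and
mechanisms are placeholder strings), correlation structure between evidence
dimensions (e.g. well-studied compounds having both standards and methods),
price distributions of real vendor catalogs, and multi-clause concentration
reports. Passing synthetic tests therefore demonstrates the pipeline's
arithmetic and bookkeeping, not the fidelity of any curation.

## Numerical and design choices

* Rounding: half-up via `Decimal` (banker's rounding would disagree with
  printed cost columns at exact .x5 quotients).
* Ranking: descending total; ties broken by name ascending after NFKC
  normalization + casefold. Deterministic for any input; digits sort before
  letters, Greek letters after Latin (so "1,8-cineol" precedes
  "α-terpineol" at equal totals).
* Problem sizes: properties over synthetic data use n = 2,000–10,000
  records (the 10,000-record checks are the binding ones for the ±0.02
  frequency bands); the exhaustive rubric oracle enumerates all 96
  admissible component vectors.
* Degenerate inputs: an empty dataset is valid (and summarizing its costs is
  an error); a single-listing cost summary reports sd = 0 with n = 1; an
  empty assessment list ranks to an empty table.
* CSV round-trips preserve floats via `repr` and reject list items
  containing the `;` join separator rather than corrupting them.

## Limitations

The rubric inherits the biases of its inputs: symptom counting rewards
well-studied compounds, concentration reports from different matrices are
not commensurable (and are deliberately not made so), and availability
components reflect a vendor snapshot. The auditor can only detect
*internal* inconsistency of a scored table, not curation errors that are
self-consistent.
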