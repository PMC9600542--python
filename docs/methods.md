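# Methods

## Counting model

The unit of counting is the report (case). For a target drug and an
event PT, every report in the background universe falls in exactly one
cell of the 2×2 table; a report listing the target drug along with other
drugs still counts toward the drug's margin (co-medication is retained,
as in spontaneous-reporting practice). Listing a drug or PT twice within
one report has no effect: drugs and events are sets. Two backgrounds are
supported: `all_reports` (the whole dataset, the default) and
`listed_drugs_only` (only reports listing a drug from a comparator set,
for class-restricted analyses). Which universe a published analysis used
is often unstated; both are exposed and the choice materially changes
PRR/IC when the target drug covers a large share of the universe.

## Disproportionality statistics

PRR and ROR are computed verbatim from the table with no continuity
correction. Zero denominators make the statistic *undefined* (`None`),
never 0 or infinity: an undefined statistic fails the signal criterion,
which avoids flagging pairs through empty cells.

The information component uses the shrinkage observed-to-expected form

    IC = log2((a + 0.5) / (E + 0.5)),   E = (a+b)(a+c) / n.

The +0.5 offsets pull small counts toward IC = 0 and make the empty
margin (a = E = 0) exactly 0. The 95% credibility lower bound is, by
default, the closed-form expansion

    IC025 = IC − 3.3 (a+0.5)^(−1/2) − 2.4 (a+0.5)^(−3/2),

with a Monte-Carlo alternative: the 2.5th percentile of
`log2(G / (E + 0.5))` over draws `G ~ Gamma(shape = a + 0.5, rate = 1)`,
i.e. the gamma posterior of the observed count under the shrinkage
prior, with the expected count treated as fixed.

These two bounds are *not* the same interval, and the package does not
pretend they are. Numerically, the closed form sits below the gamma
2.5th percentile by a roughly constant relative margin (≈17% of the
penalty; an absolute gap of 0.080 at a = 3, 0.059 at a = 10, under 0.05
only for a ≳ 30). The closed form corresponds to a deeper (~1%) tail of
the fixed-E posterior — consistent with an interval that also carries
uncertainty in the margins, which the fixed-E Monte-Carlo ignores. The
practical consequence: the default IC025 is the more conservative of
the two, so using it in the signal criterion can only reduce the
false-flag rate relative to the Monte-Carlo bound. The test suite
asserts exactly this one-sided relationship.

## Signal criterion

A pair is a signal when all of: a ≥ 3 co-reports, PRR ≥ 2, ROR ≥ 2, and
IC025 > 0. The count and PRR/ROR thresholds are inclusive; the IC025
threshold is strict by default with a flag to relax to ≥, since
published criteria state it both ways. No multiple-testing adjustment
is applied — threshold-based screening of thousands of pairs is
understood to trade specificity for transparency, which is why the
package reports a measured false-flag rate on null simulations instead.
At a = 2 the IC025 penalty (≈2.69) exceeds the largest attainable IC
(log₂5 ≈ 2.32), so the IC criterion alone already implies a ≥ 3; the
explicit minimum-report rule is kept because it is the stated criterion
and remains binding under relaxed IC thresholds.

## Hierarchy and summaries

PTs map to exactly one *primary* SOC; multiaxial secondary links are
not represented, so rollups count each signal once. PTs missing from
the dictionary are surfaced in a diagnostic set and excluded from
summaries, never silently dropped. Eosinophil-related signals are PTs
containing the case-insensitive substring "eosinophil" — the singular
form, because established PT names ("Eosinophilia", "Eosinophil count
increase") do not contain the plural. All percentages are computed from
counts and rounded half-up to two decimals; the shipped dictionary is a
synthetic toy fixture (real MedDRA content is licensed).

## Synthetic database generator

The generator emulates a spontaneous-reporting extract restricted to a
drug class:

- each catalog drug is listed independently with its marginal
  probability (defaults: five biologics with marginals proportional to
  their real report shares, so multi-drug reports arise naturally);
- each PT is included independently at its baseline probability; if a
  listed drug has a planted relative reporting ratio ρ for that PT, the
  baseline is multiplied by the *maximum* ρ across the report's drugs
  (capped at 1). ρ is therefore the in-drug versus background
  reporting-rate ratio the screen should recover, and a pair with
  ρ ≥ 2 is labelled a planted (true) association;
- drug and event sets are re-drawn until non-empty. This conditioning
  inflates marginal event rates by ≈1/(1 − P(no event)); with the
  default catalogs P(no event) ≈ 0.6, so absolute rates sit above their
  nominal baselines while ratios between drugs — what the statistics
  measure — are essentially unaffected. Tests that pin absolute rates
  include a certain event so the redraw never triggers;
- demographics are drawn independently of drugs and events from
  per-field categorical marginals. The defaults reproduce the
  demographic mix of a large real omalizumab extract (78.2% Americas,
  64.6% female, 50.9% serious, 47.1% age unknown), renormalized to sum
  to one per field. The printed sex-unknown percentage (8.16%) is used
  as printed even though it is inconsistent with its own count (460 of
  32,618 = 1.41%) — the percentages are self-consistent as a set, the
  count is not. Age bands keep the reporting convention's labels
  verbatim, including the adjoining "45–65" / "65–74" bands; the
  boundary age 65 belongs to "45–65 years".

What the generator does **not** emulate: temporal reporting dynamics,
duplicate reports, stimulated-reporting (notoriety) bias, co-prescription
structure, and drug–demographic dependence. Passing recovery tests on
this generator therefore shows the *statistical machinery* is correct
under independent-reporting assumptions, not that real-data biases are
handled.

## Problem sizes and numerical choices

- Planted-recovery experiments use 100 replicate seeds of 3,000-report
  databases with one ρ = 5 pair at expected co-report count 30 — small
  enough to replicate heavily, large enough that the expected signal
  clears every criterion with margin (expected IC025 ≈ 0.7).
- Null false-flag rates use one 200,000-report database with no planted
  pairs, screening all five default drugs (~260 evaluated pairs).
- The Monte-Carlo IC025 uses 10⁶ gamma draws per table in validation
  runs (percentile standard error ≈ 0.003 bits) and 2×10⁵ in unit
  tests.
- Treemap layout is the greedy squarified algorithm on the unit square:
  items sorted by descending signal count (ties by SOC name), rows laid
  along the shorter remaining side, a row is extended only while its
  worst aspect ratio does not increase. Areas are exact ratios of
  signal counts (verified to 1e-9); colors map log10 report counts
  through a sequential colormap between the data min and max (midpoint
  when all equal).
- CSV writers emit rows sorted by (report id, drug, PT) so equal
  datasets serialize byte-identically; determinism end-to-end follows
  from a single integer seed.

## Known limitations

- The IC025 closed form and the fixed-E gamma bound differ at small
  counts (see above); neither is "the" published interval for any given
  historical analysis, since databases' custodians have used several IC
  variants over time.
- The generator's independence assumptions make null simulations
  slightly conservative: with no planted pairs the observed false-flag
  rate is near 0, well under the nominal 5%, because the composite
  criterion is stricter than any single test at level 0.025.
- Real extracts' absolute signal counts are not reproducible here: they
  depend on a restricted database and unprinted cell values. The
  package instead verifies every quantity that is recomputable from
  printed summaries and every property that is testable by simulation.
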