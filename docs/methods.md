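# Methods

## Scope and data model

`medimatch` operates on four plain-text inputs: a questionnaire table (one
row per participant; demographics, treated-with-tablets flags for
hypertension / dyslipidemia / diabetes, up to 30 free-text medication
entries), a samples x metabolites area matrix with run-day labels and
process-blank areas, a drug vocabulary (molecule name, synonyms, DrugBank
ID, pipe-separated ATC codes, optional combination components), and a
metabolite annotation table (display name with confidence suffix, drug
category, platform mode, retention index, mass). No canonical export
schema exists for such questionnaires, so column mappings are
config-driven and the default dialect is this package's own. Missing
abundances are preserved as missing everywhere; coercing them to zero
would silently turn "no approved peak" into "measured zero" and corrupt
both detection calling and level comparisons.

## Curation

Free-text entries are normalized (case-folded; punctuation, numbers, dose
units and frequency words removed — dose and frequency carry no molecule
information) and resolved in a fixed order: exact match against names and
synonyms; bounded edit-distance match (edlib), with the cap of 2 shrinking
to 1 for normalized strings of ≤5 characters so short drug names cannot be
merged by aggressive fuzzing; combination-product split into one item per
component; indication-phrase fallback to `unspecified [indication]`;
otherwise `not_annotated`. Fuzzy ties are broken deterministically by
(distance, shorter canonical name, lexicographic name). ATC codes come
only through DrugBank, so molecules without a DrugBank entry keep empty
code lists; a molecule may carry several codes and is counted once per
class when tabulating participants.

## Detection calling

Run-day normalization divides each present value by the per-metabolite
median of its run-day block (all-missing blocks are left untouched with a
warning). The same medians divide the blank areas — scalar blanks become a
run-day x metabolite table — which makes detection calls exactly invariant
under normalization. A peak is detected when present and its area is at
least `blank_multiplier` (default 3) times the blank; the boundary is kept
(only areas strictly below threshold are rejected), and a metabolite
without a blank is treated as blank 0 with a warning. Per-run-day blanks
are supported because blank levels drift across consumable lots; whether a
given dataset used global or per-day blanks is a config choice. For
exports that carry presence/absence only, a `presence_only` flag degrades
the call to "present = detected". Unknown features (names starting `X-`)
with a missing fraction strictly above 0.5 are the candidate drug
metabolites for re-screening: drugs, unlike endogenous compounds, are
absent from most samples.

## Association screen

The cohort is the set of participants with both questionnaire and linked
sample. For every (medication item, metabolite) pair the 2x2 table (both /
self-only / blood-only / neither) is tested with a two-sided Fisher exact
test: the sum of hypergeometric probabilities over tables with the
observed margins whose probability does not exceed the observed one, with
the conventional relative slack of 1e-7 on the "as extreme" comparison
(the rule mainstream stats packages use; it also absorbs floating-point
noise on exact pmf ties). Sidedness matters little here — for the extreme
screen hits one- and two-sided p agree to two significant digits. The
computation runs on cached cumulative log-factorials and a log-sum-exp, so
p-values far below 1e-92 are returned without underflow; agreement with an
exact big-integer enumeration oracle is verified exhaustively for all
tables with N ≤ 60 (observed max relative deviation ~1e-13, tolerance
1e-9). Degenerate tables (an empty margin) return p = 1 with a flag and
are retained in the output.

Multiple testing uses Bonferroni: alpha / n_items / n_metabolites, with
the counts taken from the data after filtering (items with ≥1 user in the
cohort; the metabolite set actually screened) and a config override to pin
the denominators for reproduction runs against published counts.

The mutual-best-hit rule flags a pair only when the metabolite is the
item's smallest-p partner *and* vice versa. Ties are broken by larger
`both`, then lexicographic metabolite ID, then lexicographic item — a
total order, so the flagged set is deterministic and always a partial
matching (each item and each metabolite in at most one pair). Aggregate
overlap metrics are unweighted per-pair means of both/N_self,
both/N_blood, self-only/union and blood-only/union, with zero-margin pairs
excluded from the affected mean.

## Concordance, co-detection and the false-positive contrast

Per indication, three participant sets are intersected: the tablet-flag
set, the self-report set (any item whose ATC code starts with a mapped
prefix — hypertension {C02,C03,C07,C08,C09}, dyslipidemia {C10}, diabetes
{A10} — or a matching unspecified item), and the detection set (any mapped
metabolite detected). The prefix sets ship as an editable data file: they
are a defensible approximation of "drugs prescribed for the disorder", not
a published standard. Venn region counts are exact set arithmetic;
reported percentages are relative to the union, with empty unions reported
missing.

For a multi-metabolite drug, joint detection counts samples with all / any
panel members detected; per-pathway Venns use only the members *specific*
to a route (a mixed SULT/CYP conjugate is excluded from both routes'
Venns but remains eligible as a route representative). The shipped
acetaminophen panel lists the parent compound and eight conjugates with
their detox routes, modes, retention indices and masses.

The false-positive contrast assigns two disjoint groups: self-reported
users of the target molecule, and "unlikely users" (BMI < 25 kg/m²,
HbA1c < 5.7% — strict inequalities — no diabetes diagnosis, no A10-coded
or unspecified-diabetes medication). Detection rates are reported per
group; abundance levels are compared among detected samples only (levels
do not exist otherwise) with Welch's t on log2 normalized areas — a mean
comparison on the log scale matches how such levels are summarized, and a
rank-sum alternative is available by flag since normality of log-areas is
an assumption, not a fact. p-values below 1e-16 are reported at that
floor; a group with fewer than two detected samples yields a missing p.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume.
Ages are drawn from a normal (mean 39.7, sd 12.8, truncated to 18–80) and
sex is 57% female, matching the demographic profile of a young
population cohort. Medication use follows P(≥1 medication | age) =
clamp(0.25 + 0.75·(age − 20)/50, 0, 1). Conditional on being a medication
user, each panel drug is taken independently with its configured rate;
users who draw no panel drug take an always-reported supplement
(cholecalciferol), which keeps the age model exact without inflating
panel-drug rates — supplements dominate real questionnaires and have no
metabolite on the drug panel, so the item also exercises the screen's
null behavior. BMI and HbA1c are drawn with diabetes-linked shifts so the
unlikely-user contrast group is populated; tablet flags follow drug use
with 15% questionnaire-internal discordance.

Each used-and-reported drug is rendered as free text: an indication
phrase, a brand synonym, a typo of bounded edit distance ≤2, or the
canonical name, at configured rates (defaults 0.1 / 0.2 / 0.05).
Under-reported drugs are simply absent.

Abundances: a drug user receives each metabolite with probability
`sensitivity` at lognormal(mu_user = 8.0, sigma = 0.6) over a blank of
100; non-users receive spurious peaks with probability
`false_positive_rate` at a lower lognormal (default mu_fp = 6.5),
truncated at the 3x-blank threshold so the configured rate is exactly
P(detect | non-use) — an undetected spurious peak is unobservable, so the
truncation changes nothing observable while making the rate
interpretable. User areas are untruncated and can fall below threshold
naturally. Areas carry multiplicative per-run-day effects
(lognormal, sigma 0.1 on the log scale) that median normalization removes.
All randomness flows from one master seed through named per-stage streams,
so changing one stage's parameters does not perturb another's draws, and a
fixed seed reproduces every output bit for bit.

The default panel (20 drugs, 28 drug metabolites, 12 unknown features)
mirrors the field's archetypes: a metformin-like drug with a high
false-positive rate (0.245, the rate observed among very-unlikely users
in published data) and a spurious-peak median ~8-fold below the user
median; an acetaminophen-like drug with nine pathway metabolites and
heavy under-reporting (report probability 0.05); an atorvastatin-like
drug whose detected metabolite differs from the parent; a
rosuvastatin-like drug whose metabolite is not captured by the platform
(sensitivity 0, never detected); and sixteen generics spanning usage
2–6% and sensitivity 0.45–0.95.

What the generator does *not* emulate: pharmacokinetics (dose, clearance,
sampling-time effects), correlated detection of a drug's metabolites
within a sample (members are drawn independently, so joint-detection
counts of large panels are much lower than in real data, where shared
dose and clearance correlate them), comorbidity-driven co-prescription,
and LC-MS signal structure. Passing tests therefore demonstrate that the
pipeline recovers the planted statistical structure, not that real-data
idiosyncrasies are handled.

## Verification design

Unit tests check each operation against hand-computed examples and
published 2x2 tables; property tests (hypothesis, derandomized) cover the
invariants: Fisher vs exact enumeration, transpose invariance,
mutual-best-hit vs brute-force double argmin and the matching property,
Venn counts vs membership enumeration, detection monotonicity in the
blank multiplier, and normalization invariance. The acceptance layer
re-runs the full pipeline on synthetic bundles:

* planted-pair recovery uses pairs with ≥50 *reporting* users in the
  linked cohort — the screen only observes self-reports, so a drug with
  many users but few reporters (the acetaminophen archetype) is
  legitimately underpowered, and a report-blind criterion would demand
  significance from data the method never sees. Every qualifying pair
  must be Bonferroni-significant, and each qualifying drug's
  mutual-best-hit partner must be one of its planted metabolites (a drug
  with several planted metabolites can have only one partner).
* the null screen sets every metabolite's sensitivity equal to its
  false-positive rate (detection independent of use) at the full panel
  scale, where the small Bonferroni threshold and the discreteness of
  sparse tables make the realized family-wise error well below the
  nominal 0.05; at most 1 of 20 seeds may show any hit.
* the permutation check screens label-permuted dense grids (25 items x 25
  metabolites at 25% prevalence, n = 2000, where the discrete test is
  nearly continuous); because pairs within a grid share margins, the
  type-I rate is averaged over four independent replicate grids before
  comparison with the nominal 5%.

Problem sizes (3000-participant bundles, 20 null seeds at n = 1500, the
exhaustive oracle sweep at N ≤ 60) were chosen so the full suite and the
acceptance script each complete in a few minutes while keeping every
check statistically meaningful.

## Known limitations

* Manual curation decisions of any real study (which brand maps where)
  are not reproducible; the shipped vocabulary is a small synthetic
  subset in the open DrugBank dialect, so absolute molecule counts are
  not comparable across vocabularies.
* The indication maps and the metabolite-to-indication assignment via
  platform drug categories are approximations; published concordance
  percentages from restricted cohort data are not reproduction targets.
* The mean both/union aggregate is sensitive to rounding of the printed
  per-pair counts and is not reported as a headline metric.
* Fisher p-values below ~1e-300 are not representable in double
  precision; the screen's contract covers the magnitudes the analysis
  produces (down to ~1e-92 and well beyond, but not arbitrarily small).
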