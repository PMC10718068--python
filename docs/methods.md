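# Methods

This note records the model behind each pipeline stage, the defaults that
matter, and the design choices made where the design was genuinely open.

## Input model

An entry is one database line: a reaction text (`"2 A + B = C"` — names and
integer coefficients, one `=` separator, terms joined by `" + "`), a
four-field EC number, a reversibility tag (`reversible` / `irreversible` /
`unknown`; synonyms like `r`, `ir`, `?` are normalized), a natural-substrate
flag, and provenance (organism, protein references). EC numbers classify
reaction chemistry, not enzymes or sequences; all class-level statistics
(rule frequency, reverse-template queries, product suggestion) operate on
this grouping.

## Name resolution

Resolution is a chain of strategies behind one interface; the default chain
is a single local dictionary so the package runs offline and
deterministically. Remote strategies (compound-database queries,
name-to-structure parsing) plug into the same interface and are off by
default; their failures are logged and treated as no-answer. All answers are
standardized (RDKit cleanup + canonicalization) and pooled — no precedence is
imposed among strategies, so one name can legitimately map to several
structures, and candidate reactions are assembled as the Cartesian product of
per-name choices (capped at 64 per entry, truncated deterministically).
Tautomer canonicalization is deliberately not applied: resolved structures
often are the tautomer the entry meant, and collapsing tautomers corrupts
more reactions than it repairs. Names match case-sensitively after
whitespace normalization because d-/l- prefixes are case-meaningful.

## Balance corrections

The balance report is the per-element count difference (products minus
reactants, implicit hydrogens included) plus total formal charge. Corrections
are tried least-intrusive first, and the first change that zeroes the report
exactly wins:

1. integer re-scaling of coefficients of species already present
   (multipliers 1–4, preferring the fewest changed species);
2. hydrogen addition — protons (the only correction allowed to change
   charge) or H2;
3. adding 1–4 copies of one configured corrective species (defaults: H+,
   H2, H2O, O2, H2O2).

Failure leaves the entry flagged unbalanced but still eligible for product
suggestion. Corrections never remove a species the entry listed; every
change is written to a correction log. Cofactor *swaps* (replacing one
cofactor by another) are declined as ambiguous. Enantiomeric pairs on one
side are merged into a single stereo-free molecule of the combined count;
meso compounds (their own mirror image) and diastereomers are left alone.

## Rule-based atom mapping

Rules are reaction SMARTS with mapped templates. Application enumerates
every embedding (all assignments of input molecules to reactant templates,
all substructure matches); each heavy atom is tracked through the rewrite:
spectator atoms keep pre-assigned map numbers, matched atoms inherit the
template correspondence, template-introduced atoms get fresh numbers.
Outcomes that are equivalent up to symmetry collapse under canonical map
standardization. Explicit-hydrogen counts copied from matched reactant atoms
(e.g. a chiral CH) can violate valence after the rewrite; hydrogens on
changed atoms are then recomputed from valence.

A rule succeeds on an entry when some outcome's product multiset equals the
recorded products on stereo-stripped canonical SMILES — stereochemistry is
reconciled afterwards, not during matching. Among succeeding rules the one
changing the fewest atoms plus bonds wins (the two counts are summed; a
lexicographic alternative was considered and rejected as arbitrary), ties go
to the more frequently applicable rule, then to rule id. Edit counts are
derived from the rule's own pattern (bonds between mapped template atoms
whose presence/order differ; atoms incident to those bonds or with charge
changes). Applicability is counted corpus-wide over all input entries, and
map numbers live on heavy atoms only (reaction-SMILES convention).

The final mapped product side is rebuilt from the *recorded* product
structures with the outcome's map numbers copied over, so recorded
stereocenters survive mapping; reactions whose achiral sides are identical
(racemizations, cis/trans isomerizations) are mapped directly by canonical
atom correspondence under the reserved rule id `stereo_only`, since rule
sets generally lack stereochemistry-only transformations.

## Multi-step mapping

Entries unreachable in one application are searched breadth-first over
sequences of up to `max_steps` rule applications (default 2, configurable),
exhaustively and seed-free, memoizing on the canonical intermediate state.
The rule set is restricted to rules already used successfully in the same EC
class during single-step mapping (full set if the class has none) — a pure
speed measure. Because step order is unknown, *all* successful orderings are
kept; the overall record (flagged `multi`) keeps the full stoichiometry,
while each step becomes a standalone record (flagged `single from multi`)
with that step's spectators removed, deduplicated across orderings by
standardized mapped SMILES.

## Stereo correction and bond edits

The reaction center is the set of mapped atoms with any changed bond
(presence or order) or changed formal charge. For every tetrahedral center
*outside* it whose parity differs between the sides, the product parity is
overwritten with the reactant parity — the reactant entry is statistically
the more reliable one; this is a heuristic, not a guarantee of correct
stereochemistry. Parities are compared via a map-number-normalized
convention (explicit-hydrogen form, permutation sign from bond order to map
order), so they are meaningful across differently written molecules.
Reacting-center stereo is never touched, double-bond configuration adjacent
to the center is treated as center stereo, and `stereo_only` records are
exempt (their stereo difference *is* the reaction).

A bond edit is one heavy-atom bond whose presence or order differs under the
mapping; an order change counts once, hydrogen-count changes never count.
Among the candidate reactions of one entry (alternative name resolutions),
only those attaining the minimal edit count survive — this is what prunes
mixed open/closed ring-form assemblies, which spend extra edits on the ring
opening. The atoms-involved count is recorded but unused for tie-breaking
(the natural reading keeps all minimal-edit records).

## Templates and round-trip validation

A template is cut out of the standardized mapped reaction: center atoms plus
a configurable environment radius (default 1 bond), atoms written as
element+charge queries (`[#6;+1:3]`), bond orders explicit, multi-component
fragments of one molecule kept grouped. Standardizing first makes equivalent
mappings yield byte-identical templates; map values are additionally
renumbered for comparisons (`canonical_template`). Templates are achiral —
product comparison is stereo-stripped, with stereo consistency enforced by
the correction pass; this is simpler than chirality-aware template
machinery and is a known limitation.

Round-trip validation re-applies the record's own template (in a strict
variant whose center atoms also carry hydrogen counts) to its reactants and
requires the recorded product multiset among the outcomes; extraction or
application failure fails the record. The check certifies that the mapping
is locally realizable and conserving — it cannot distinguish between
automorphically equivalent mappings of the same reaction, which are
chemically interchangeable at this level. Records with an empty center
(identity template) validate iff their sides agree up to stereochemistry.

## Product suggestion

For entries that stay unbalanced or unmapped: the most reactant-similar
mapped classmate (Tanimoto over 2048-bit radius-2 circular fingerprints,
union over the molecules of a side) serves as reference; all rules used in
the class are applied to the query reactants; outcomes are ranked by the
geometric mean of product similarity (to the reference products) and
reactant similarity — chosen because it is monotone in each component and
zero when either is — with rule frequency and rule id as tie-breaks. The
top-k (default 1) outcomes that pass the same gates as direct records
(balance, conservation, round trip) are exported as `source=suggested`.
Suggestion flags rather than filters: users decide whether to trust it.

## Post-processing

Map standardization renumbers maps 1..N along the canonical atom order of
the map-free reactant molecules, enumerating permutations of identical
molecules and graph automorphisms (capped at 2000 candidates) and keeping
the lexicographically smallest rendering — equivalent mappings become
byte-identical strings. Reversibility handling: `reversible` entries get
their backward reaction appended (`… reversed`), `unknown` entries only when
the reversed template already occurs in the EC class
(`… reversed_suggested`, matched by exact canonical template string —
deterministic and auditable), `irreversible` entries never. Quality is the
within-class relative frequency of the record's rule, computed over the
direct/split/reversed family (suggested records excluded by default,
config-switchable) and then written onto every record of the class.
Deduplication modes: `within-ec` (standardized mapped SMILES + EC — the
primary notion of a unique reaction), `global`, and `full-provenance`
(keeping organism/protein variants for users who filter first).

## Fixture bundle

The generator emits nine archetype entries — reversible hydration, two-site
double oxidation with a coefficient error, wrong-product oxidation plus two
correct classmates, wrong non-reacting stereocenter, open/closed ring-form
ambiguity, an uncorrectable carbon imbalance, and an unknown-reversibility
racemization — with a toy rule set (alkyne hydration, alcohol oxidation by
O2 and by a quinone pair, glycoside hydrolysis in ring-retaining and
ring-opening variants) and a manifest pinning each entry's terminal state
and record count. The seed only permutes entry order; content is fixed.
Molecules stay under 20 heavy atoms so brute-force oracles (embedding
enumeration, graph diffs, 100-fold random relabelings) run in milliseconds.
The bundle emulates the *failure modes* of real database entries, not their
scale or chemical diversity: passing on it demonstrates the correctness of
the machinery, not coverage of a real rule set over a real database, and the
wrong-product archetype is constructed so the class rules admit exactly one
plausible correction.

## Numerical and degenerate-input choices

Everything is deterministic: no stage samples, the multi-step search is
exhaustive, sorts are stable with explicit tie-breaks, and the only seeded
operation is the optional train/validation/test split (80/10/10 by
default). Degenerate inputs: empty entry tables yield empty outputs and
zero-count reports; per-entry failures are logged events, never aborts;
unparseable SMILES fail only the name they belong to. Thresholds: the
frequent-product filter defaults to 100 occurrences, flat-accuracy
thresholding uses >= 0.5, and top-1 groups with score ties count as
failures (strict reading of "higher").

## Known limitations

- Coverage is bounded by the supplied rule set; reactions no rule reproduces
  end as `unmapped` (or `suggested`, if the class has precedent).
- Stereo correction handles tetrahedral parities; double-bond E/Z outside
  the immediate center neighborhood is not corrected.
- Templates are achiral and validation is stereo-stripped.
- The quality score is a class-frequency heuristic: a correct but rare
  transformation in a large class scores low.
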