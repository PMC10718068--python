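# biocatmap

Curation, correction, atom mapping and validation of enzymatic reaction
records.

Enzyme reaction databases store reactions as free-text lines — trivial
compound names, an EC number, and a reversibility tag — and the entries are
riddled with systematic errors: missing stoichiometric coefficients, wrong
stereoisomers retrieved during name resolution, open- versus closed-ring
forms of sugars mixed within one reaction, and products entered under the
wrong compound name (a ketone recorded as an aldehyde is a classic).
Machine-learning models for biocatalysis — retrosynthesis planners,
regioselectivity classifiers — need the opposite: balanced, atom-mapped,
stereochemically consistent reaction SMILES.

`biocatmap` turns raw entries into exactly that. Instead of generic
atom-mapping tools it maps reactions by applying a user-supplied set of
reaction rules (reaction SMARTS) while tracking every atom through the
rewrite. Recording *which* rule mapped each reaction is what powers the
rest of the pipeline: stereo errors outside the reaction center can be
overwritten with the reactant configuration, implausible name resolutions
are pruned by minimal bond-edit counts, wrong products are replaced by
applying the rules of the same EC class and ranking outcomes by Tanimoto
similarity of Morgan fingerprints, and every record receives a quality
score — the relative frequency of its rule within its EC class — that flags
likely database errors.

## Pipeline

For each entry:

1. **Parse** the reaction text into names and stoichiometry.
2. **Resolve** names to canonical SMILES via a resolver chain (a local
   dictionary by default; remote resolvers are pluggable), taking all
   combinations when a name has several structures.
3. **Balance**: element/charge check, then automated corrections
   (coefficient re-scaling, hydrogen addition, small corrective species such
   as H2O/O2/H2O2), and merging of racemic pairs.
4. **Map** via a single rule application (reactions whose achiral sides are
   identical are mapped directly, without a rule), choosing among competing
   rules by fewest atoms+bonds changed, then rule frequency. Reactions
   needing several rule applications are mapped by exhaustive multi-step
   search (default depth 2) and split into flagged single-step records.
5. **Suggest** products for unbalanced/unmappable entries from the rules and
   records of the same EC class.
6. **Post-process**: canonical atom-map renumbering, retro-template
   round-trip validation, reverse-reaction generation from reversibility
   tags (or from reverse templates already present in the class), quality
   scoring, deduplication, CSV export.

Every exported record satisfies atom conservation (identical element ×
map-number multisets on both sides) and round-trip validation (the template
extracted around its reaction center regenerates its products).

## Worked example

The bundled fixture generator builds a nine-entry archetype set covering the
curation failure modes (`biocatmap make-fixtures --out-dir fx` writes it to
disk):

```python
from biocatmap import make_fixture_bundle, run_pipeline, records_to_frame

bundle = make_fixture_bundle(seed=0)
records, report = run_pipeline(bundle.entries, bundle.ligands, bundle.rules)
print(report.counts)
print(len(records), "exported records")
```

prints

```
{'mapped-direct': 6, 'mapped-multi': 1, 'mapped-suggested': 1, 'unbalanced': 1, 'unmapped': 0, 'unresolved': 0}
14 exported records
```

Six entries map directly — among them the reversible acetylene hydration,
which exports a forward and a reversed record:

```
C#C.O>>CC=O        (source=direct)
CC=O>>C#C.O        (source=direct reversed)
```

The 1,2-butanediol double oxidation (whose entry text lacks one O2) is
corrected, mapped in two steps, and split into four distinct single-step
records; the wrong-product isopropanol oxidation is unbalanceable and gets
`CC(C)O.O=O>>CC(C)=O.OO` suggested from its EC classmates; a wrong epimer at
a non-reacting center is reset to the reactant configuration; an entry whose
sugar-like name resolves to open and closed ring forms keeps only the
minimal-bond-edit variant; one deliberately uncorrectable entry stays
unbalanced.

The same objects feed the dataset builders
(`biocatmap build-datasets`): `build_retro_dataset` produces single-product
reactions plus a template vocabulary (frequent-product filter, unmatched
reactant removal, deduplication, single-product filter), and
`build_regio_dataset` re-applies each record's own template to its reactants
to enumerate alternative reaction sites, labeling the recorded outcome 1 and
the alternatives 0. `regio_metrics` scores classifiers on such data by flat
accuracy and strict top-1 accuracy per (reactants, template) group.

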