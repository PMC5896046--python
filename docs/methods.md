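# Methods

## Object model and identity semantics

The in-memory model mirrors the MIF element set: an `Entry` owns pools of
experiments and interactors, an ordered interaction list (evidence and/or
abstract interactions) and free-text attributes.  All cross-references —
participant → interactor, cooperative effect → affected interaction,
condition set → variable value — are direct Python object references; the
integer ids carried by identified objects exist only for serialization.
Consequently `semantic_equal` ignores id *values* entirely and compares the
reference graph structurally, and a document and its copy with all ids
renumbered are equal by construction.  A single integer id namespace per
entry is shared by experiments, interactors, interactions, participants,
features, candidates, availabilities and variable values; nothing in the
format's description suggests separate namespaces, and one namespace keeps
reference resolution a single dictionary lookup.

Lists the schema treats as unordered — attribute lists, secondary xrefs,
interactor candidates — compare as multisets; every other list, including
condition-set members (which carry `order` attributes), is
order-sensitive.  Shared objects and potential reference cycles are handled
with an in-progress memo (bisimulation-style), so hierarchical complexes
that reference sub-complexes terminate.

`normalize` produces the canonical form: candidates sorted by interactor
label, attributes by (name, ac, value), secondary xrefs by (db, id); pools
reordered to first-use order with declared-but-unreferenced objects kept at
the tail (normalization never drops content); ids renumbered densely from 1
in document walk order.  Canonical ordering runs *before* pool completion,
because candidate reordering feeds the first-use order — this is what makes
`normalize` idempotent to the byte.

## Coordinates, decimals, defaults

Feature positions are 1-based inclusive on the interactor sequence.
Negative values are upstream (promoter-region) coordinates; they are valid
model content at level 3.0.  Position 0 is accepted by the model but
flagged as a warning (`POSITION_ZERO`): 1-based biological coordinate
conventions skip zero.  A negative position on a participant whose
interactor is a protein (MI:0326) draws a `NEG_POS_ON_PROTEIN` warning —
signed coordinates exist for gene-region use cases, not protein sequences.

Stoichiometries and parameter factors are stored as `decimal.Decimal`
constructed from the lexical form in the file, so `2.50` round-trips as
`2.50` while comparing numerically equal to `2.5`.  `negative`,
`intra_molecular` and `is_link` default to false and are serialized only
when true.

How individual interactions reference the variable-parameter values they
were observed under is modelled as `condition_sets`: a list of sets of
variable-value references, serialized as an `experimentalVariableValueList`
of `variableValueRef` groups.  An interaction with an empty list is
unconditioned.  This element grammar is this package's own convention for
the document form of that link.  Duplicate `order` values within a
variable-value list are permitted by the model and flagged as a warning.

## Reading and writing

Both document forms parse to the same graph.  The compact reader resolves
`experimentRef`/`interactorRef` ids; the extended reader unifies repeated
inline definitions by id, so two interactions inlining the same experiment
share one object.  The writer normalizes first, which makes output bytes a
pure function of document content (attribute order included); it emits
compact form by default, the form designed for larger datasets.  In
extended form, used objects are inlined and entry-level lists retain only
declared-but-unreferenced ones, so no content is lost in either form.
Streams may be gzip-compressed; compression is sniffed from magic bytes.

In strict mode a dangling id reference is fatal (no document is returned);
otherwise it is reported as a warning and dropped.  Unknown elements are
reported as info findings and skipped rather than preserved verbatim:
opaque pass-through extras would have to flow through equality,
normalization and both schemas, a cost with no consumer in this codebase.

Schema conformance is checked against two **authored structural schemas**
(`src/psimif/schemas/*.xsd`, loaded with lxml): synthetic stand-ins for the
official MIF schemas, written for this package to encode the exact element
nesting, ordering and attribute types the writer produces — signed
(`xs:long`) positions at 3.0 versus unsigned at 2.5, the 3.0 `bibref`
sequence versus the 2.5 choice, featureDetectionMethod repeatability, and
the presence/absence of every 3.0-only element.  They are deliberately
subset schemas: they validate what this package emits, not every document
the official schemas accept.

## Validation profiles and severity policy

Profiles are cumulative: `structural` (ids, required non-empty lists,
well-formed CV terms and xrefs), `semantic` (content rules), `cv`
(accession checks).  Severity follows the rule's provenance: violations of
stated format rules — a `resultingSequence` with neither sequences nor
xref, an inverted stoichiometry range, an abstract interaction carrying
experiment references — are errors; coordinate-convention and
mixed-content issues (zero positions, evidence and abstract interactions
in one list, duplicate order values) are warnings.  `validate` is pure:
findings come out in document walk order and are byte-stable, and any code
can be suppressed individually.

The embedded CV table holds ~40 MI terms: every accession the 3.0 use
cases rely on (MI:0442, MI:0367, MI:0363, MI:0364, MI:0638, MI:0925,
MI:0326, MI:0904) plus the terms the fixture generator emits, each with a
label and parent links.  `load_cv` merges an OBO file over this table
(file wins on label conflicts) via `obonet`; an unparseable stream degrades
to the embedded table with a warning, and lookups are total.

## Downgrade rules and the annotation grammar

`downgrade` first normalizes (dense, unique ids — these become the
reference keys), then rewrites per entry:

1. negative/zero positions → range statuses set to undetermined (MI:0339),
   coordinates preserved in a `psimi3:range` feature attribute;
2. resulting sequences → `psimi3:resulting-sequence` feature attribute,
   xref additionally copied into the feature xref for 2.5 visibility;
3. detection methods beyond the **first** → `psimi3:feature-detection-method`
   attributes.  Document order is curation priority, so the first method is
   kept (the often-cited "last one parsed" behaviour describes legacy
   parsers, not a serialization rule);
4. feature roles → `psimi3:feature-role` attribute;
5. feature parameters → moved to the interaction parameter list plus a
   `psimi3:feature-parameter` linking attribute;
6. variable parameters → `psimi3:variable-parameter` experiment attributes;
   per-interaction condition sets → one `psimi3:variable-values` attribute;
7. abstract interactions → ordinary interactions backed by a synthesized
   experiment whose detection method is inferred-by-curator (MI:0364) and
   whose bibref reuses the abstract interaction's xref when available;
   interactor type, organism, evidence type and binding features ride in a
   `psimi3:abstract-interaction` attribute;
8. cooperative effects → `psimi3:cooperative-effect` interaction
   attributes (evidence, outcome, response, affected ids, allostery
   details);
9. candidate sets → one synthesized molecule-set (MI:1304) interactor with
   the members as xrefs and `member` attributes; the full set rides in a
   `psimi3:candidate-set` attribute and member interactors stay in the
   interactor pool;
10. stoichiometry elements → `psimi3:stoichiometry` participant attribute
    (lexical form preserved);
11. a bibref holding both xref and attributes → xref stays, attributes move
    to the owner's attribute list with a `psimi3:bibref-split` marker.

Attribute payloads are compact JSON over a small typed codec of the model
(Decimals keep lexical form).  Cross-construct references use the
pre-downgrade ids, pinned onto their objects as `psimi3:orig-id` marker
attributes, which makes the payloads robust against any later renumbering
of the 2.5 document.  Abstract↔evidence conversion swaps the instance's
class in place, so participants' interaction references and affected-
interaction lists stay valid without pointer fix-ups.  Each rewritten
construct is recorded exactly once in the loss report (one item per range,
per feature with extra methods, per moved parameter, per variable
parameter, per conditioned interaction, per effect, per candidate set, per
stoichiometry, per split bibref, per abstract interaction).

`upgrade` lifts the level; with `promote=True` it rebuilds the marker map,
restores every construct from its payload, removes the synthesized
carriers and strips all `psimi3:` annotations.  The round trip
`upgrade(downgrade(d), promote=True)` is the identity up to `normalize` on
every golden fixture and on random all-flag documents;
`downgrade(upgrade(d25))` is the identity with an empty report.

## MITAB export

Evidence interactions export as MITAB 2.7 (42 columns; multi-valued cells
pipe-separated, empty cells `-`, tabs/newlines/pipes scrubbed from free
text).  N-ary interactions spoke-expand to n−1 pairs hubbed on the bait
(MI:0496) participant, else the first participant, in document order;
two-participant interactions are unexpanded and a single intra-molecular
participant yields a self-pair.  Abstract interactions have no evidence to
tabulate and are skipped with a logged notice; negative interactions are
exported with the negative column true.  Feature ranges serialize as
`type:start-end` with `?` for undetermined positions.  Candidate-set
participants — which no MITAB column can represent — export under the
set's own identifier with members in the alias column.

## Fixture generators

`build_use_case` returns one minimal, finding-free document per use case
(a..k), each with a manifest stating the exact loss-category counts its
downgrade must report; fixture content (coordinates like −2000..−1, the
three CALM candidates, the 0/4/8-hour time course) matches the scenarios
the format additions were designed for, with invented identifiers
throughout.  `generate_random` composes the same construct builders with
seeded `random.Random` choices; documents are validator-error-free by
construction, every enabled flag is instantiated at least once, and the
same spec+seed serializes byte-identically.  Generated documents exercise
structure, not statistics: no realistic network topology, degree
distribution, sequence content or curation depth — passing tests show
format fidelity, not biological plausibility, and real curated files may
exercise dialect corners (unknown elements, exotic CV usage) the generator
does not produce.

Problem sizes used by the test suite and the acceptance script — 200
random documents for the round-trip sweep, 20 for schema conformance,
documents of 1–4 interactions each — keep a full run in the tens of
seconds while covering every construct combination the flags can produce.

## Known limitations

* The structural schemas validate this package's output grammar, not the
  full official element set (e.g. participant `experimentRefList`s and
  attribute name controlled lists are out of scope).
* CV checking is accession-format and known-accession only; is-a reasoning
  is limited to the parent links present in the embedded table.
* No constant-memory streaming parse: documents are desk-scale.
* The `psimi3:` annotation names are this package's convention; other
  producers' 2.5 encodings of cooperativity or stoichiometry are readable
  only as plain attributes, not promotable.
* MI-JSON and PSICQUIC access are out of scope.
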