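# psimif

A Python toolkit for **PSI-MI XML level 3.0**, the HUPO Proteomics Standards
Initiative interchange format for molecular-interaction data, with full
support for level 2.5 and tab-delimited MITAB 2.7 export.

## Why

Interaction databases (IntAct, MINT, DIP, the Complex Portal, and the other
IMEx members) exchange curated molecular-interaction records as MIF XML.
Level 2.5 describes single-publication experimental evidence well, but a
number of data types outgrew it:

* **signed feature coordinates** — a transcription-factor binding site in a
  gene promoter sits *upstream* of the sequence start (e.g. −2000..−1);
* **resulting sequences** — the actual sequence change of a site-directed
  mutation (R→A at position 128), not just its location;
* **repeatable feature detection methods** and **feature roles** — a PTM
  seen both by a specific antibody and by mass spectrometry, and whether it
  is a *prerequisite* for or an *effect* of the interaction
  (prerequisite-PTM MI:0638, observed-PTM MI:0925);
* **feature-level kinetic parameters** — the K_d of a mutant attached to
  the mutation itself, while the wild-type K_d stays on the interaction;
* **dynamic interactions** — partner profiles changing along a variable
  condition (hours post-viral infection, agonist concentration), modelled
  as experiment-level variable parameters referenced per interaction;
* **abstract (modelled) interactions** — curated reference complexes and
  other content inferred from *many* publications, hence evidence-free;
* **cooperative effects** — allostery (an event at one site changing
  binding at a distal site of the same molecule) and pre-assembly
  (creation/abrogation of a binding site), each pointing at the affected
  interactions with their own evidence;
* **molecule sets** — participants that are one of several
  indistinguishable molecules, e.g. calmodulin, an identical protein
  produced by the CALM1, CALM2 and CALM3 genes;
* **stoichiometries** as first-class mean values or decimal ranges, and
  **publication references** that carry both an identifier and descriptive
  attributes.

`psimif` implements an object model covering all of the above, readers and
writers for both the *compact* (list + id references; suited to large
datasets) and *extended* (everything inlined) document forms, a semantic
validator with a published finding-code list, a **documented lossy
downgrade to 2.5** that records every dropped construct in a machine-
readable loss report (and can promote its annotations back to 3.0), and a
MITAB 2.7 exporter with spoke expansion of n-ary interactions.

## Worked example

Build the calmodulin molecule-set document (use case *i*), downgrade it to
2.5 with a loss report, and export MITAB:

```bash
$ psimif fixture --case i -o calm.xml
$ psimif validate calm.xml --profile cv
0 finding(s), 0 error(s)

$ psimif convert calm.xml --to 2.5 -o calm25.xml --loss-report loss.json
downgraded with 1 lost construct(s)
$ cat loss.json
{
  "counts": {
    "CANDIDATE_SET": 1
  },
  "items": [
    {
      "category": "CANDIDATE_SET",
      "path": "entry[1]/interaction[1]/participant[2]",
      "detail": "3 candidate(s) collapsed to one molecule-set interactor"
    }
  ]
}

$ psimif export calm.xml | tail -1 | cut -f1,2,7,12
demo:prot-0018	psimif:calmodulin	psi-mi:"MI:0096"(pull down)	psi-mi:"MI:0915"(physical association)
```

The loss report says exactly what 2.5 cannot express: the three-candidate
calmodulin set was collapsed to a single molecule-set interactor (its
members survive as xrefs/attributes and are restored by
`psimif convert calm25.xml --to 3.0 --promote`).  The MITAB row keeps the
set as interactor B with the members in the alias column.

The same functionality is available as a library:

```python
from psimif import build_use_case, downgrade, upgrade, semantic_equal, normalize

doc = build_use_case("i")
doc25, report = downgrade(doc)          # report.counts() == {"CANDIDATE_SET": 1}
restored = upgrade(doc25, promote=True)
assert semantic_equal(normalize(restored), normalize(doc)).equal
```

## Command reference

| command | purpose |
|---|---|
| `psimif validate IN [--profile structural\|semantic\|cv] [--cv file.obo] [--json]` | semantic validation; exit 1 on errors |
| `psimif convert IN --to 2.5\|3.0 [-o OUT] [--loss-report J] [--promote]` | lossy downgrade / promotable upgrade |
| `psimif export IN [--format mitab27] [-o TSV]` | MITAB 2.7 export (42 columns, spoke expansion) |
| `psimif roundtrip IN [--form compact\|extended]` | parse → re-serialize → self-compare |
| `psimif fixture --case a..k\|all \| --random --seed N` | deterministic document generation |

Inputs may be gzip-compressed (sniffed from magic bytes).  All logging goes
to stderr; stdout carries only the data artifact.

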