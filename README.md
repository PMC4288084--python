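# phenolink

Terminology-agnostic phenotyping over a unified clinical concept graph.

Electronic health records encode the same clinical fact in many coding
systems at once — problems in SNOMED CT or ICD-9/10-CM, laboratory tests in
LOINC, medications in RxNorm or NDC, procedures in HCPCS/CPT — and local,
non-standard codes on top. `phenolink` integrates such coded observation
streams through a Metathesaurus-style concept layer: every source code is
mapped to a concept unique identifier (CUI) that unifies synonymous atoms
across vocabularies, and all downstream querying, browsing and counting
happens at the concept level. The intended users are clinical-informatics
and translational researchers who need cohort-level queries ("all patients
with any cardiovascular disease") over heterogeneously coded data.

## What it does

- **Terminology store** — parses pipe-delimited RRF-subset files
  (MRCONSO/MRREL/MRSTY/MRSAT-compatible, with a minimal fixture-friendly
  dialect) into a concept graph, and derives a source-restricted hierarchy:
  only hierarchical relations asserted by trusted vocabularies are
  traversed, plus configured augmentation relations (e.g. LOINC
  `measured_by`, RxNorm `has_ingredient`) that give the flat lab and drug
  terminologies useful parents.
- **Search** — a TF-IDF inverted index over atom strings
  (idf(t) = ln N/df(t)) with five-tier query relaxation: exact phrase →
  proximity → all tokens → accumulate (majority of tokens, the rest
  ignored) → fuzzy/stemming/wildcard, so typos like "cron disease" still
  find Crohn disease, ranked below any exact hits.
- **Crosswalk** — bidirectional code translation through the CUI pivot,
  including projection into vocabularies never used for annotation and
  visibility of retired codes reactivated by an active sibling atom.
- **ELT pipeline** — observations are loaded verbatim (target, feature,
  protocol, value), then annotated with concepts in a separate, repeatable
  transform; local codes map through a curated local-code map; explicit
  value sets (smoking status, DVT/AMI history) create negated complements
  for patients lacking a condition.
- **Expansion & propagation** — patient annotations expand to ancestor
  concepts sharing the origin's semantic type (traversal passes *through*
  excluded ancestors); cycles are condensed by strongly connected
  components; *sets* of unique patient identifiers are propagated up the
  resulting DAG, so multiple inheritance and duplicate annotations can
  never inflate cohort counts; complements are taken relative to the
  propagated universe.
- **Compaction & navigation** — hub concepts ranked by source count and
  branching factor supply browser entry points; a shortest-path minimum
  Steiner tree approximation compacts the hierarchy to the concepts a
  dataset actually uses, with orphaned concepts attached under a synthetic
  root; a three-pane parents/siblings/children view carries propagated
  patient counts.
- **Fixtures** — because the real Metathesaurus is licensed, the package
  generates its own inputs: a hand-built reference mini-terminology,
  seeded random terminologies (multi-parent, cyclic, multi-source), and a
  simulated warfarin-dosing cohort (demographics, CYP2C9/VKORC1 genotypes,
  daily doses, scheduled INR measurements).

## Worked example

```sh
phenolink fixture --out fix
phenolink --seed 7 simulate --n 5 --out cohort.tsv
phenolink transform --terminology fix --observations cohort.tsv \
    --local-map fix/local_code_map.json --value-sets fix/value_sets.json \
    --out run
phenolink expand    --terminology fix --profiles run/profiles.json --out run/expanded.json
phenolink propagate --terminology fix --profiles run/expanded.json --out run/counts.tsv
phenolink tree      --terminology fix --terminals-from run/counts.tsv --out run/tree.json
```

The simulate step prints `wrote 5 patients x 130 records to cohort.tsv`:
each virtual patient contributes 10 baseline variables, 90 daily warfarin
doses, and 30 scheduled INR measurements. The transform step prints
`{"records": 650, "unmapped": 0}` — every simulator code resolves through
the local-code map, so concept coverage is complete. `run/counts.tsv` then
holds one row per concept with its distinct-patient count and complement
count; e.g. a patient annotated with deep venous thrombosis is counted once
at `C0149871` and once at every same-typed ancestor up to `C0012634`
(Disease), never twice through parallel parent paths.

Crosswalk and search on the same fixture:

```sh
$ phenolink xwalk SNOMEDCT 128053003 --to ICD10CM --terminology fix
ICD10CM  I82.40  C0149871  active  Acute embolism and thrombosis of unspecified deep veins of lower extremity

$ phenolink search "cron disease" --terminology fix --max 3
[ {"tier": 5, "score": 5.601196, "cui": "C0010346", "label": "Crohn Disease"}, ... ]
```

The SNOMED CT code for deep venous thrombosis translates into ICD-10-CM
through the shared concept `C0149871`; the misspelled query is recovered at
the fuzzy tier (tier 5) with its score equal to the summed idf of the
matched tokens.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The script rebuilds everything from scratch at the given seed: it writes
the reference terminology, simulates a 1000-patient cohort, runs load →
annotate → value sets → expansion → condensation → propagation with
complements → Steiner compaction, executes the documented crosswalk and the
three worked search queries, prints a summary of what it computed, and
writes the JSON report to `--out`.
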