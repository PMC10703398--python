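# Methods

This note documents the data model, algorithms, defaults and known
limitations of `provreplay`, in the order the pipeline runs.

## Archive format

A result archive is a standard ZIP with exactly one top-level directory
named by the result's version-4 UUID:

```
<uuid>/VERSION                     three lines: FORMAT / archive / framework
<uuid>/metadata.yaml               uuid, semantic type, data format
<uuid>/checksums.md5               manifest (format version >= 2)
<uuid>/data/...                    payload — opaque to this tool
<uuid>/provenance/                 the result's own action record
    VERSION  metadata.yaml  citations.bib  action/action.yaml
<uuid>/provenance/artifacts/<ancestor>/    one subtree per ancestor
    VERSION  metadata.yaml  citations.bib  action/action.yaml
```

Provenance capture is *decentralized*: every result carries the records
of its entire ancestry, so any single archive is self-describing and
archives can be combined later without a central database. Payload under
`data/` is deliberately never interpreted — replay needs provenance, not
data semantics — and identity is the UUID, not a content hash: whole-file
hashing is used only for the (small) archive members, since checksums of
large payload files are impractical as identifiers.

Two archive-format versions are modeled: version 1 (no checksum
manifest; validation reports `predates-checksums` as a warning) and
version ≥ 2 (manifest required; its absence is reported as an
alteration). The `VERSION` file records the version for forward
dispatch.

## Integrity validation

`checksums.md5` uses md5sum-compatible lines — 32 lowercase hex digits,
two spaces, path relative to the root-UUID directory — sorted by path,
excluding the manifest itself, so any stock `md5sum -c` can verify an
unzipped archive. Validation rehashes every member and *reports* (never
raises): per-path mismatches, listed-but-missing members, and unlisted
extras. It operates directly on the ZIP container and does not require
the identity files to parse, because corrupted identity files are
precisely a case it must detect. Two caveats follow from the design:

* the manifest cannot attest to itself — a byte flipped inside
  `checksums.md5` is detected (status `invalid` or `unparseable`) but is
  attributed to the entry whose line was damaged, not to the manifest;
* MD5 is an integrity alert against accidental post-creation
  modification, not a security boundary.

Validation failure does not block replay by default (`--validate warn`);
`--validate strict` aborts with exit status 2 before writing anything.

## Action records

`action/action.yaml` captures one execution: execution UUID, action type
(`import`, `method`, `visualizer`, `pipeline`), plugin and action names,
inputs (name → UUID or null), parameters, output name, ISO-8601 start and
end timestamps with timezone offsets, environment (platform, language,
framework and plugin versions), and citation keys. Inputs and parameters
are stored as lists of single-key maps so their order survives YAML
round-trips, and parameters are restricted to flat scalars (or flat
lists of scalars) — nested structures are rejected, which keeps code
generation faithful. Every parameter of the action is recorded,
*including defaults and nulls*; the parser preserves all keys verbatim.
Unknown top-level keys are carried through in a pass-through bag for
forward compatibility. A metadata-typed parameter is recorded with the
local YAML tag `!metadata <filename>`, which keeps it a flat scalar
while letting the planner treat it specially. Pipeline records are
parsed identically to methods; output-alias indirection is not modeled.

Import records carry no inputs and no plugin; instead they fingerprint
the imported files (filename + MD5) so reference data can be identified
unambiguously at replay time.

## DAG construction

Results are the nodes, keyed by UUID; one edge runs from each non-null
input to each output of the recording action. Actions are not a second
node class: an execution that emitted several results is recovered by
grouping nodes on the shared execution UUID (this also drives the DOT
export, which draws one box per execution). Acyclicity is checked on
construction. Inputs naming UUIDs with no parsed record become stub
nodes (`has_provenance=False`) rather than errors, and results whose
subtree lacks an action record likewise degrade to no-provenance nodes
with a warning — replay surfaces both as explicit user-action-needed
comments instead of silently dropping them.

`union` merges DAGs by UUID: a full-provenance node always replaces a
stub, the first-parsed record wins among equals, and two conflicting
full records for one UUID are an error, since results are immutable once
created. Topological order breaks ties by ascending (start time, UUID);
the tie-break exists purely to make output byte-stable across runs and
input orderings — any valid order would replay correctly.

## Replay generation

Planning emits one statement per execution group in that deterministic
order, guaranteeing def-before-use. Variable names derive from recorded
output names (lowercased, non-alphanumerics collapsed to `_`, `r_`
prefix for leading digits, `_0`/`_1`… on collision) and are shared
between both dialects, so a result is called the same thing in the shell
and Python documents.

Dialect rules:

* shell: `qiime <plugin> <action> --i-<input> <var>.qza --p-<param>
  <value> --o-<output> <var>.qza`, kebab-case flags, `.qzv` for
  visualizer outputs; booleans as `--p-name` / `--p-no-name`; nulls are
  omitted (shell has no null literal) with a trailing comment noting the
  recorded default; metadata parameters render as
  `--m-<name>-file <var>_metadata.tsv` — the `--m-` spelling is the
  natural extension of the flag dialect for the file-valued parameter
  class;
* Python: one call per action with keyword arguments, outputs unpacked
  by attribute; nulls render as explicit `None`; metadata parameters as
  `Metadata.load('<var>_metadata.tsv')`.

Metadata is never silently reused: the recorded filename appears in a
TODO comment, and the user must supply the placeholder file, because
replayed analyses typically target new sample metadata. Headers list the
tool version, generation timestamp, every source result UUID exactly
once, numbered usage instructions, and a caveat that parameters are
replayed verbatim. `--pin-timestamp` substitutes a fixed token for the
timestamp so documents are byte-identical across runs (used by the
golden/determinism tests and recommended for published supplements).

## Citations

Each provenance subtree's `citations.bib` uses keys namespaced per
attribution target (`framework|<version>`, `plugin|<name>|<version>`,
`action|<plugin>|<action>|<n>`). Collation resolves each node's keys
against its own bib file in topological order of first appearance, then
deduplicates — entries sharing a normalized DOI (case-folded, resolver
prefixes stripped) merge keeping the first; DOI-less entries dedup on
exact key; surviving key collisions get `_a`, `_b`… suffixes. DOI-first
precedence is deliberate: keys are namespaced per result and collide
meaninglessly across archives, while a DOI is a stable cross-result
identity. The bibliography is flat, in provenance order. BibTeX parsing
and rendering are implemented in-package (brace/quote values, field
order preserved, deterministic output) and are round-trip stable.

## Synthetic analyses

The generator emulates amplicon-workflow provenance: imports of sequence
data followed by actions drawn from a small realistic vocabulary
(demux/emp-single, dada2/denoise-single, feature-classifier/
classify-sklearn, phylogeny/align-to-tree-mafft-fasttree,
diversity/core-metrics, taxa/barplot, feature-table/summarize), with
multi-output pipelines, optional unused inputs, null-valued defaults and
metadata-typed parameters, monotone timestamps (2-minute spacing from a
fixed base instant), a fixed synthetic environment record, and citation
entries whose DOIs use the reserved test prefix `10.5555/` and are a
deterministic function of the citation key — which is how tests know the
expected DOI set without trusting the collation path. One archive is
written per terminal result. Generation is fully deterministic per spec
(seeded RNG, fixed ZIP member dates), so identical specs produce
byte-identical archives.

Defaults (`AnalysisSpec`): 2 imports, 6 actions, ≤ 2 inputs per action,
30 % multi-output executions, 25 % metadata-parameter rate, archive
format version 2. These shapes mirror small real analyses; the
end-to-end checks sample 3–40 executions per analysis, and the scale
check uses 450 executions (80 imports, 370 actions), the "very large
analysis" regime, chosen as a bushy forest so ancestry depth stays
realistic. `make_overlapping_pair` builds a second analysis on top of a
regenerated copy of the first and returns the exact node overlap
(computed by intersecting the two ground-truth graphs), for union tests.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: meaningful payload contents, the full
historical zoo of real archive-format versions, pipeline output
aliasing, non-ASCII or adversarial YAML, and clock skew between
machines (timestamps are strictly monotone). The generator writes
syntactically valid records by construction, so parser robustness to
malformed records is exercised by dedicated schema tests, not by the
round-trip suite.

## Numerical and procedural choices

* Timestamps are compared as absolute instants (timezone-aware).
* Stub nodes sort before timestamped nodes in the topological tie-break.
* Duplicate archives of the same result are harmless: union collapses
  them by UUID.
* Manifest parsing is strict (exact md5sum dialect, duplicates
  rejected); bibliography parsing is tolerant (bad entries skipped with
  a warning, error only when nothing parses).
* The end-to-end measurement sizes (25 round-trip seeds, 5 archives for
  exhaustive tamper, 100 replay DAGs, 3 overlapping pairs, one
  450-execution scale run) are the package's own verification budget;
  all complete in well under a minute on one CPU.

## Known limitations

* Replay scripts are faithful transcriptions, not guaranteed-runnable
  programs: they target whatever plugin versions the provenance records,
  and `provreplay` does not verify that those plugins exist or that the
  generated commands execute (out of scope, as is any workflow-system
  dialect beyond shell and Python).
* No-provenance ancestry cannot be reconstructed, only flagged.
* MD5 collisions are not a considered threat model.
* Recorded metadata tables are not reconstructed; placeholders are
  emitted instead. An option to reuse recorded metadata verbatim is
  deliberately not implemented, as the recorded tables are not stored in
  the archives this tool defines.
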