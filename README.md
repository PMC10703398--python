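# provreplay

Turn the provenance *recorded inside* zipped analysis results back into
executable documentation.

Bioinformatics platforms that practice decentralized retrospective
provenance capture store, inside every result archive they write, a
complete record of how that result came to be: the action that produced
it (with **every** parameter, defaults included), the inputs it consumed
(by version-4 UUID), the software environment (OS, language, framework
and plugin versions), an execution identifier and timestamps, citation
records for every tool involved, and the same information for every
ancestor result. `provreplay` is for researchers, reviewers and data
stewards who hold such archives — for example from a microbiome amplicon
analysis — and need to answer "exactly how was this made, and how do I
run it again?" without the original scripts or lab notes.

Given one or more archives (`.zip` / `.qza` / `.qzv`), the package

1. **validates integrity** against the archive's MD5 checksum manifest,
   alerting when a result was altered after creation;
2. **parses the provenance tree** of each result — terminal action record
   plus all ancestor records — into typed nodes;
3. **reconstructs the provenance DAG**: results are nodes, an edge runs
   from each input to the result it produced, multiple archives are
   unioned over shared UUIDs so common ancestry appears exactly once;
4. **generates replay scripts** in two dialects (shell command lines and
   a Python API script) in dependency order, self-documenting and
   byte-deterministic;
5. **collates a BibTeX bibliography** for every action, plugin and
   framework version in the analysis, deduplicated by DOI; and
6. bundles all of it into a single-command **reproducibility supplement**.

The model behind step 3: each recorded action `a` with inputs
`I(a) ⊂ U` (UUIDs) and outputs `O(a) ⊂ U` contributes edges
`{(u, v) : u ∈ I(a), v ∈ O(a)}` to a DAG over results. Replay emits one
statement per *execution group* (the set of outputs sharing one execution
UUID) in a topological order made deterministic by the tie-break
(start time, result UUID), so every variable is defined before use and
the rendered documents are byte-stable across runs and input orderings.

## Worked example

The package ships a synthetic-analysis generator, so you can try the
whole pipeline without any real data. Generate a seeded analysis of one
import and three downstream actions:

```
$ cat spec.yaml
seed: 7
n_imports: 1
n_actions: 3
$ provreplay fixture --spec spec.yaml --out-dir archives
archives/4cbd87ad-5c90-4958-b403-e430ec66a787.qza
archives/930d6eaf-14f4-433f-be7d-1bfbc7a2ea20.qza
...
5 archives, 7 results
```

Five archives because every terminal result gets its own archive; seven
results because one action emitted four outputs. Validate and replay:

```
$ provreplay validate archives
archives/4cbd87ad-5c90-4958-b403-e430ec66a787.qza  valid
...
$ provreplay provenance archives --out-dir replay --dialect cli --pin-timestamp
wrote replay/replay.sh
```

`replay.sh` begins with self-documentation (the source result UUIDs and
numbered usage instructions) and then replays the analysis in dependency
order — note the boolean flag spelling, and that a parameter recorded as
null is surfaced rather than dropped:

```
# import (execution a6a3a450-6513-470e-a69e-0d37f2a74de4)
# import manifest: demux_sequences_0.fastq.gz (md5 f0ac1a19e6f814992409dc72740abf4d)
qiime tools import --type 'SampleData[SequencesWithQuality]' --input-path TODO-import-path --output-path demux_sequences.qza

# demux emp-single (execution 1fb17c23-90c1-42cf-93ac-94af0f21ddb6)
qiime demux emp-single --i-seqs demux_sequences.qza --p-rev-comp-barcodes --p-rev-comp-mapping-barcodes --p-no-golay-error-correction --o-per-sample-sequences per_sample_sequences.qza

# diversity core-metrics (execution 6d76b07e-881e-4162-ae2e-b1547f150524)
qiime diversity core-metrics --i-table per_sample_sequences.qza --p-sampling-depth 514 --p-no-with-replacement --o-observed-features-vector observed_features_vector.qza --o-evenness-vector evenness_vector.qza --o-rarefied-table rarefied_table.qza --o-shannon-vector shannon_vector.qza  # --p-metadata left at its recorded default (null)
```

A one-command supplement (replay scripts in both dialects, bibliography,
source list, instructions, all in one zip):

```
$ provreplay supplement archives/*.qza --out supplement.zip --pin-timestamp
wrote supplement.zip
```

If someone flips a single byte anywhere in an archive,
`provreplay validate` reports `invalid` and names exactly the altered
member; archives written before checksum manifests existed (format
version 1) report `predates-checksums` as a warning, not a failure.

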