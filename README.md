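# plexqueue

Queue expansion and ipTM-guided pruning for multiprotein complex
prediction campaigns.

## The problem

Deep-learning structure predictors score a candidate protein complex
with ipTM, the interface-weighted predicted TM-score, which correlates
well with whether the modelled assembly is real. That makes it tempting
to screen an interactome for higher-order complexes by predicting every
combination of proteins — but the combinatorics are hopeless. For an
interactome of *n* proteins, the number of candidate complexes of size
2 through *r*<sub>max</sub> is

&nbsp;&nbsp;&nbsp;&nbsp;N(n, r<sub>max</sub>) = Σ<sub>r=2..r_max</sub> C(n, r)

Even a small 40-protein neighbourhood gives
N(40, 40) = 1,099,511,627,735 candidates — over a trillion — while a
single prediction costs minutes to hours of GPU time. Any practical
screen must (a) enumerate only combinations with some experimental
support and (b) prune aggressively as scores arrive.

`plexqueue` is the bookkeeping half of such a screen. It ingests binary
protein–protein interactions (CSV or BioGRID TAB3), expands them into a
queue of candidate complexes, dispatches predictions strictly level by
level (all dimers, then all trimers, …), and prunes the queue by two
rules driven by the scores coming back:

* **Priority propagation.** When a complex *S* finishes with ipTM ≥ τ
  (the priority threshold), every still-pending supercomplex *T* ⊋ *S*
  inherits that score as a priority:

  &nbsp;&nbsp;&nbsp;&nbsp;priority(T) = max { ipTM(S) : S ⊊ T, S scored, ipTM(S) ≥ τ }

  Higher-priority complexes are dispatched first, so promising corners
  of the lattice are explored early.

* **Dead-end elimination.** At each level boundary, any pending complex
  of the next size whose priority is still undefined — no scored
  subcomplex reached τ — is marked *poisoned* and never dispatched.
  Poisoning a complex implicitly removes its entire supercomplex cone
  from consideration.

The max rule (rather than requiring *all* subcomplexes to score well)
is deliberate: linear or bridged assemblies contain subcomplexes with
no physical interface, which legitimately score low.

The prediction engine itself is pluggable: a hash-based mock and a
planted-truth backend ship for testing, and a file-based adapter
prepares inputs for and collects scores from an external
AlphaFold-Multimer-style engine.

## Worked example

Build a small bait-centred interactome (one bait, five partners),
expand it to complexes of size ≤ 3 containing the bait, run a campaign
with the deterministic mock backend at threshold 0.7, and report the
top trimers:

```sh
$ plexqueue make-fixture --out star.csv --n-partners 5 --seed 3
wrote 5 interactions to star.csv
$ plexqueue init --db q.db
initialized store at q.db
$ plexqueue import --db q.db --interactions star.csv
6 proteins, 5 edges
$ plexqueue enumerate --db q.db --max-complex-size 3 \
    --trim-all-complexes-to-include BAIT
queued 15 candidate complexes
$ plexqueue work --db q.db --backend mock --seed 1 \
    --priority-threshold 0.7 --max-level 3
{"scored": 12, "failures": 0, "queue": {"pending": 0, "running": 0, "done": 12, "failed": 0, "poisoned": 3}}
$ plexqueue report --db q.db --level 3 --top-fraction 0.3
canonical_name,size,iptm,ptm,mean_plddt,status
BAIT_P001_P005,3,0.8104057511852291,0.4462259501663779,0.1363286705672386,done
BAIT_P003_P005,3,0.6343933075233787,0.4575966657979274,0.037860479067875985,done
BAIT_P003_P004,3,0.569037558865581,0.5117163979352678,0.7406958931182611,done
```

The 15 queued candidates are the 5 bait–partner dimers plus the
C(5,2) = 10 bait-containing trimers. Three trimers were poisoned: none
of their scored dimers reached 0.7, so they were never sent to the
backend.

The same pipeline is available as a library. The propagation rule on a
three-complex lattice:

```python
>>> from plexqueue import (ComplexSpec, MemoryStore, PredictionResult,
...                        SchedulerConfig, Status, record_result)
>>> store = MemoryStore()
>>> for s in (ComplexSpec.of("A", "B"), ComplexSpec.of("B", "C"),
...           ComplexSpec.of("A", "B", "C")):
...     store.add(s)
>>> cfg = SchedulerConfig(priority_threshold=0.5)
>>> for members, iptm in ((("A", "B"), 0.55), (("B", "C"), 0.60)):
...     spec = ComplexSpec.of(*members)
...     store.transition(spec.canonical_name, Status.RUNNING,
...                      expect=(Status.PENDING,))
...     record_result(store, spec,
...                   PredictionResult(complex=spec, iptm=iptm, ptm=iptm), cfg)
>>> store.get("A_B_C").priority
0.6
```

Both dimers cleared the 0.5 threshold, and the trimer holds the larger
of the two scores.

## Layout

* `plexqueue.interactome` — interaction CSV / BioGRID TAB3 parsing,
  FASTA sequences, monomer model caching.
* `plexqueue.enumeration` — `ComplexSpec`, connected-subgraph and
  all-vs-all expansion, target mode, stoichiometry, exact counting.
* `plexqueue.scheduler` — statuses, priority propagation, dead-end
  elimination, level-by-level campaign loop (in-memory store).
* `plexqueue.store` — SQLite-backed job store with atomic claiming,
  wall-time leases, an append-only event log, ranking and network
  export.
* `plexqueue.trimming` — pLDDT-based trimming of disordered regions
  from monomer models.
* `plexqueue.backends` — mock, planted-truth and file-based engine
  adapters.
* `plexqueue.fixtures` — synthetic interactomes, truth tables and
  CA-trace model files for tests and demos.
* `plexqueue.cli` — the `plexqueue` command
  (`init`/`import`/`enumerate`/`trim`/`work`/`report`/`export-network`/`make-fixture`).

See `docs/methods.md` for the model, its assumptions and parameter
defaults.
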