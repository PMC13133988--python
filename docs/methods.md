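# Methods

## Model

`plexqueue` treats a complex-prediction screen as a scheduling problem
over the multiset-containment lattice of candidate complexes. A
candidate complex is a multiset of protein accessions of size ≥ 2,
canonically named by joining its sorted members with underscores
(`A_B_C`). The screen proceeds in three stages:

1. **Expansion.** Binary interactions form an undirected graph. Under
   the default `connected-subgraph` rule, the candidate set is every
   connected induced subgraph of size 2..`max_size`; enumeration grows
   each connected set by one neighbour at a time, which reaches every
   connected set exactly once up to deduplication (any connected set
   can be shrunk to a connected pair by repeatedly deleting spanning-tree
   leaves). The `all-vs-all` rule instead takes every combination of
   nodes, for baits whose partner lists carry no pairwise evidence.
   Target mode (`required_member`) keeps only candidates containing a
   designated bait. Explicit stoichiometry (`ID=COPIES`) sets the copy
   number of an accession in every candidate that contains it.

2. **Level-by-level scoring.** All complexes of size *n* are resolved
   before any complex of size *n*+1 is dispatched. Within a level, jobs
   are claimed in order of descending priority (unscored-priority last),
   ties broken by canonical name. When a result with ipTM ≥ τ arrives,
   every pending strict supercomplex's priority is raised to
   max(current, ipTM). When a result falls below τ it propagates
   nothing.

3. **Dead-end elimination.** At the boundary after level *n* completes,
   every pending complex of size > *n* whose priority is still below τ
   (or unset) is marked *poisoned*: none of its scored subcomplexes
   showed a credible interface, so it is removed from the campaign
   without spending a prediction. Poisoning is final — a poisoned
   record never holds a result and is never dispatched.

The **max rule** — a complex survives if *any* scored subcomplex
reaches τ, not *all* — is a deliberate design decision. Linear and
bridged assemblies (A–B–C where A and C never touch) contain
subcomplexes with no physical interface whose low ipTM is correct, not
evidence against the larger complex. Requiring all subcomplexes to pass
would systematically discard such architectures. The cost is a more
permissive queue; the threshold τ controls that trade-off.

## Assumptions

* ipTM from the backend is comparable across complexes and levels, and
  a score above τ on a subcomplex is evidence that the supercomplex is
  worth evaluating. Both are heuristics, not guarantees.
* The interaction graph is trusted as-is after filtering; false-positive
  edges inflate the queue and false negatives remove candidates that
  connected-subgraph expansion can never recover (all-vs-all mode is
  the escape hatch).
* Failed jobs (backend exceptions, exhausted attempts) neither
  propagate priority nor poison anything: a crash is not evidence about
  the complex. A level with failed jobs still completes; only pending
  or running jobs block the boundary.

## Parameters and defaults

| Parameter | Default | Rationale |
|---|---|---|
| `priority_threshold` τ | 0.5 | Below ~0.5 ipTM, predicted interfaces are rarely credible; the test suite exercises 0.5–0.9 and asserts the poisoned set grows monotonically in τ. |
| `max_size` / `max_level` | 4 | Queue growth is combinatorial in size; dimers–tetramers cover most screening campaigns while keeping queues tractable. |
| `connectivity_rule` | `connected-subgraph` | Requires every candidate to be supported edge-by-edge by binary evidence; `all-vs-all` is opt-in. |
| pLDDT `cutoff` | 0.7 | Conventional boundary between confident and low-confidence residues on the 0–1 scale; residues below it are treated as disordered. |
| `min_segment` | 5 | Kept segments shorter than 5 residues are discarded: fragments that short cannot form an independent structured unit and only add noise to assemblies. |
| `max_attempts` | 1 | Prediction failures are usually deterministic (OOM, malformed input); retries are opt-in. |
| wall-time lease `wall_limit` | per-call | A claimed job whose lease expires returns to pending with the attempt counted, so crashed workers cannot strand jobs. |

## Synthetic data

The fixtures are built for testing the *bookkeeping*, not the biology:

* **Interactomes** are Erdős–Rényi graphs at a configurable edge
  density, with the edges of any *planted* complexes forced present.
  Sequences are uniform random strings over the 20 amino acids —
  they exercise parsing and length accounting only and encode no
  structural signal.
* **Scores.** The mock backend hashes (canonical name, seed) to a
  deterministic uniform value in [0, 1): reproducible and
  order-independent, but score-structure-free. The planted backend
  returns 0.85 for every sub-multiset of a planted complex and 0.2
  baseline otherwise, plus per-complex seeded Gaussian noise — a
  caricature of "real complexes score high" with a large margin, so
  recovery tests measure the scheduler, not the score model.
* **Model files** are CA-trace PDB files whose B-factor column carries
  pLDDT × 100. Per-residue pLDDT is drawn from a two-component
  truncated-normal mixture — low component N(0.45, 0.1) on [0, 0.7),
  high component N(0.88, 0.05) on [0.7, 1] — so the fraction of
  residues below the 0.7 cutoff is exactly binomial at the profile rate
  (0.22 well-folded, 0.59 disordered, 0.40 mixed). That makes the
  3-standard-error calibration tests statistically exact. The mixture
  has no spatial autocorrelation, so real proteins' long disordered
  runs are only partially emulated.

None of the fixtures emulate GPU inference, real ipTM distributions,
conformational heterogeneity, or interactome-scale noise.

## Numerical and representational choices

* Complex counts use exact big-integer arithmetic (`math.comb`); the
  40-protein bound 1,099,511,627,735 is computed, never hard-coded
  outside tests.
* Priorities only increase, and all tie-breaks are by canonical name
  ascending, so campaigns are bit-for-bit deterministic given a seed
  and a backend.
* pLDDT is held internally on [0, 1]; values parsed above 1 are assumed
  to be on the 0–100 scale and divided by 100.
* Trimmed segments are reported 1-based inclusive (the structural-biology
  convention); internal indexing is 0-based.
* Concurrent claiming uses SQLite `BEGIN IMMEDIATE` plus a
  compare-and-set update with a rowcount check, so two workers can
  never hold the same job. Leases use an injectable clock for
  deterministic expiry tests.
* Every state change is appended to an event log; replaying the log
  reproduces the live queue state exactly (asserted in the tests).

## Evaluation choices

* Planted-complex recovery asserts that each planted complex ranks in
  the top decile *of its own level* (e.g. among completed tetramers),
  since ipTM is compared within a size class, not across the whole
  queue.
* Problem sizes in the test suite (≤ 10-node graphs for the enumeration
  oracle, ≤ 6 proteins for the lattice oracle, 15 proteins with two
  planted tetramers for recovery, 1000-residue chains for trimming
  calibration) are this package's own desk-scale choices: large enough
  for the brute-force oracles to be meaningful, small enough to run in
  seconds without a GPU.

## Limitations

* Priority propagation is a heuristic ordering, not a statistical
  model; no calibration of ipTM against complex truth is attempted.
* Dead-end elimination is irreversible within a campaign; a complex
  poisoned by a borderline subcomplex score cannot be rescued without
  re-running at a lower threshold.
* The connected-subgraph rule inherits every bias of the input
  interactome.
* The file-based engine adapter covers prepare/collect round-trips
  only; no live prediction engine is driven or validated here.
* Stoichiometry handling sets copy numbers globally per accession; it
  cannot express different copy numbers of the same protein in
  different candidate complexes.
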