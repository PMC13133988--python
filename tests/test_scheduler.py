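"""Priority propagation, dead-end elimination and campaign sequencing."""

import itertools
import random

import pytest

from plexqueue.backends import MockBackend, PlantedBackend, PredictionResult
from plexqueue.enumeration import (ComplexSpec, EnumerationConfig,
                                   enumerate_supercomplexes)
from plexqueue.errors import SchedulerError
from plexqueue.fixtures import make_star_interactome
from plexqueue.scheduler import (MemoryStore, SchedulerConfig, Status,
                                 next_job, poison_dead_ends,
                                 propagate_priority, record_failure,
                                 record_result, run_campaign)

from conftest import (brute_force_dead_ends, brute_force_priorities,
                      graph_from_edges, populate)

AB = ComplexSpec.of("A", "B")
BC = ComplexSpec.of("B", "C")
ABC = ComplexSpec.of("A", "B", "C")


def finish(store, spec, iptm, config):
    """Drive one record through running -> done with a given ipTM."""
    store.transition(spec.canonical_name, Status.RUNNING,
                     expect=(Status.PENDING,))
    return record_result(store, spec,
                         PredictionResult(complex=spec, iptm=iptm, ptm=iptm),
                         config)


@pytest.fixture
def abc_store():
    return populate([AB, BC, ABC])


@pytest.fixture
def config():
    return SchedulerConfig(priority_threshold=0.5, max_level=4)


class TestPropagatePriority:
    def test_higher_dimer_score_lifts_existing_priority(self, abc_store, config):
        """The bridging scenario: A-B at 0.55 sets the trimer priority, and
        the later B-C at 0.6 resets it upward to 0.6."""
        finish(abc_store, AB, 0.55, config)
        assert abc_store.get("A_B_C").priority == 0.55
        finish(abc_store, BC, 0.60, config)
        assert abc_store.get("A_B_C").priority == 0.60

    def test_lower_score_never_decreases_priority(self, abc_store, config):
        finish(abc_store, AB, 0.7, config)
        finish(abc_store, BC, 0.55, config)
        assert abc_store.get("A_B_C").priority == 0.7

    def test_subthreshold_score_touches_nothing(self, abc_store, config):
        finish(abc_store, AB, 0.45, config)
        assert abc_store.get("A_B_C").priority is None

    def test_no_scored_subcomplex_leaves_priority_unset(self, abc_store):
        assert abc_store.get("A_B_C").priority is None

    def test_unknown_complex_rejected(self, abc_store, config):
        with pytest.raises(SchedulerError):
            propagate_priority(abc_store, ComplexSpec.of("X", "Y"), 0.9, config)

    def test_only_done_complexes_propagate(self, abc_store, config):
        with pytest.raises(SchedulerError):
            propagate_priority(abc_store, AB, 0.9, config)


class TestPoisonDeadEnds:
    def test_all_low_dimers_poison_trimer(self, abc_store, config):
        finish(abc_store, AB, 0.3, config)
        finish(abc_store, BC, 0.2, config)
        assert poison_dead_ends(abc_store, 2, config) == 1
        assert abc_store.get("A_B_C").status == Status.POISONED

    def test_one_good_dimer_saves_trimer(self, abc_store, config):
        finish(abc_store, AB, 0.7, config)
        finish(abc_store, BC, 0.2, config)
        assert poison_dead_ends(abc_store, 2, config) == 0
        rec = abc_store.get("A_B_C")
        assert rec.status == Status.PENDING
        assert rec.priority == 0.7

    def test_zero_threshold_never_poisons(self, abc_store):
        cfg = SchedulerConfig(priority_threshold=0.0)
        finish(abc_store, AB, 0.0, cfg)
        finish(abc_store, BC, 0.0, cfg)
        assert poison_dead_ends(abc_store, 2, cfg) == 0

    def test_sequencing_guard(self, abc_store, config):
        finish(abc_store, AB, 0.7, config)  # B-C still pending
        with pytest.raises(SchedulerError, match="unresolved"):
            poison_dead_ends(abc_store, 2, config)

    def test_poisoning_is_final(self, abc_store, config):
        finish(abc_store, AB, 0.3, config)
        finish(abc_store, BC, 0.3, config)
        poison_dead_ends(abc_store, 2, config)
        with pytest.raises(SchedulerError):
            abc_store.transition("A_B_C", Status.PENDING,
                                 expect=(Status.PENDING,))
        with pytest.raises(SchedulerError):
            abc_store.store_result(
                "A_B_C", PredictionResult(complex=ABC, iptm=0.9, ptm=0.9))


class TestNextJob:
    def test_highest_priority_first(self, config):
        store = populate([ComplexSpec.of("A", "B", "C"),
                          ComplexSpec.of("A", "B", "D")])
        store.set_priority("A_B_C", 0.6)
        store.set_priority("A_B_D", 0.8)
        assert next_job(store, 3, config).canonical_name == "A_B_D"

    def test_tie_breaks_lexicographically(self, config):
        store = populate([ComplexSpec.of("A", "B", "C"),
                          ComplexSpec.of("A", "B", "D")])
        store.set_priority("A_B_C", 0.6)
        store.set_priority("A_B_D", 0.6)
        assert next_job(store, 3, config).canonical_name == "A_B_C"

    def test_dimers_dispatch_in_name_order(self, abc_store, config):
        assert next_job(abc_store, 2, config).canonical_name == "A_B"

    def test_exhausted_level_returns_none(self, abc_store, config):
        finish(abc_store, AB, 0.9, config)
        finish(abc_store, BC, 0.9, config)
        assert next_job(abc_store, 2, config) is None

    def test_never_skips_ahead_a_level(self, abc_store, config):
        # trimer has top priority but level-2 records are still pending
        abc_store.set_priority("A_B_C", 0.99)
        assert next_job(abc_store, 2, config).size == 2


class TestRecordResultAndFailure:
    def test_duplicate_result_is_idempotent(self, abc_store, config):
        finish(abc_store, AB, 0.6, config)
        rec = record_result(abc_store, AB,
                            PredictionResult(complex=AB, iptm=0.1, ptm=0.1),
                            config)
        assert rec.result.iptm == 0.6  # second report ignored

    def test_single_shot_failure_policy(self, abc_store, config):
        abc_store.transition("A_B", Status.RUNNING, expect=(Status.PENDING,))
        rec = record_failure(abc_store, AB, "gpu timeout", config)
        assert rec.status == Status.FAILED
        assert rec.attempts == 1

    def test_retry_policy_requeues(self, abc_store):
        cfg = SchedulerConfig(max_attempts=2)
        abc_store.transition("A_B", Status.RUNNING, expect=(Status.PENDING,))
        rec = record_failure(abc_store, AB, "oom", cfg)
        assert rec.status == Status.PENDING
        assert rec.attempts == 1

    def test_failed_dimer_judged_on_remaining_evidence(self, abc_store, config):
        """A failed A-B neither propagates nor poisons: the trimer's fate
        rests on B-C alone."""
        abc_store.transition("A_B", Status.RUNNING, expect=(Status.PENDING,))
        record_failure(abc_store, AB, "crash", config)
        finish(abc_store, BC, 0.8, config)
        poison_dead_ends(abc_store, 2, config)
        rec = abc_store.get("A_B_C")
        assert rec.status == Status.PENDING
        assert rec.priority == 0.8

    def test_failure_requires_running_status(self, abc_store, config):
        with pytest.raises(SchedulerError):
            record_failure(abc_store, AB, "nope", config)


class TestRunCampaign:
    def test_empty_queue_empty_summary(self, config):
        summary = run_campaign(MemoryStore(), MockBackend(), config)
        assert summary.levels == {}
        assert summary.dispatch_trace == []

    def test_star_all_high_dimers_complete_everything(self):
        graph = make_star_interactome(39)
        specs = enumerate_supercomplexes(
            graph, EnumerationConfig(max_size=3, required_member="BAIT"))
        store = populate(specs)
        overrides = {s.canonical_name: 0.9 for s in specs}
        summary = run_campaign(store, MockBackend(overrides=overrides),
                               SchedulerConfig(max_level=3))
        assert summary.total("done") == 780
        assert summary.total("poisoned") == 0

    def test_star_all_low_dimers_poison_every_trimer(self):
        graph = make_star_interactome(39)
        specs = enumerate_supercomplexes(
            graph, EnumerationConfig(max_size=3, required_member="BAIT"))
        store = populate(specs)
        overrides = {s.canonical_name: 0.1 for s in specs}
        summary = run_campaign(store, MockBackend(overrides=overrides),
                               SchedulerConfig(max_level=3))
        assert summary.levels[2]["done"] == 39
        assert summary.levels[3]["poisoned"] == 741
        assert summary.total("done") == 39

    def test_conservation_at_every_dispatch(self, config):
        graph = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"),
                                  ("A", "C")])
        specs = enumerate_supercomplexes(graph, EnumerationConfig(max_size=4))
        store = populate(specs)
        total = len(specs)
        inner = MockBackend(seed=5)

        def checked(spec):
            counts = sum(len(store.records(status=s)) for s in Status)
            assert counts == total
            return inner(spec)

        run_campaign(store, checked, config)
        assert sum(len(store.records(status=s)) for s in Status) == total

    def test_levels_never_interleave(self, config):
        graph = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D"),
                                  ("B", "D")])
        specs = enumerate_supercomplexes(graph, EnumerationConfig(max_size=4))
        store = populate(specs)
        summary = run_campaign(store, MockBackend(seed=1), config)
        sizes = [store.get(name).size for name in summary.dispatch_trace]
        assert sizes == sorted(sizes)

    def test_poisoned_never_reach_backend(self, config):
        graph = graph_from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        specs = enumerate_supercomplexes(graph, EnumerationConfig(max_size=4))
        store = populate(specs)
        backend = MockBackend(overrides={s.canonical_name: 0.1
                                         for s in specs if s.size == 2})
        run_campaign(store, backend, config)
        poisoned = {r.canonical_name for r in store.records(Status.POISONED)}
        assert poisoned  # the scenario does poison something
        assert poisoned.isdisjoint(backend.calls)

    def test_deterministic_trace(self, config):
        graph = graph_from_edges([("A", "B"), ("B", "C"), ("A", "C"),
                                  ("C", "D")])
        specs = enumerate_supercomplexes(graph, EnumerationConfig(max_size=4))
        traces = []
        for _ in range(2):
            store = populate(specs)
            summary = run_campaign(store, MockBackend(seed=42), config)
            statuses = {r.canonical_name: r.status for r in store.records()}
            traces.append((summary.dispatch_trace, statuses))
        assert traces[0] == traces[1]

    def test_scorer_exception_routed_to_failure(self, config):
        store = populate([AB, BC, ABC])

        def scorer(spec):
            if spec == AB:
                raise RuntimeError("engine crashed")
            return PredictionResult(complex=spec, iptm=0.8, ptm=0.8)

        summary = run_campaign(store, scorer, config)
        assert store.get("A_B").status == Status.FAILED
        assert store.get("A_B_C").status == Status.DONE
        assert summary.levels[2]["failed"] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_lattice_matches_bruteforce_on_small_queues(self, seed):
        """At every level boundary, pending priorities and the poisoned set
        equal an independent recomputation over the containment lattice."""
        rng = random.Random(seed)
        n = rng.randint(4, 6)
        nodes = [f"N{i}" for i in range(n)]
        pairs = [(a, b) for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.5]
        if len(pairs) < 2:
            return
        graph = graph_from_edges(pairs)
        specs = enumerate_supercomplexes(graph, EnumerationConfig(max_size=4))
        store = populate(specs)
        cfg = SchedulerConfig(priority_threshold=0.5, max_level=4)
        backend = MockBackend(seed=seed)
        for level in (2, 3, 4):
            while (rec := next_job(store, level, cfg)) is not None:
                store.transition(rec.canonical_name, Status.RUNNING,
                                 expect=(Status.PENDING,))
                record_result(store, rec.complex, backend(rec.complex), cfg)
            expected_pri = brute_force_priorities(store, cfg.priority_threshold)
            for name, pri in expected_pri.items():
                assert store.get(name).priority == pri, name
            expected_poison = brute_force_dead_ends(
                store, cfg.priority_threshold, level)
            poison_dead_ends(store, level, cfg)
            got = {r.canonical_name for r in store.records(Status.POISONED)
                   if r.size > level}
            newly = {n_ for n_ in expected_poison}
            assert newly <= {r.canonical_name
                             for r in store.records(Status.POISONED)}
            # nothing outside the brute-force dead-end set was poisoned now
            assert got <= expected_poison | {
                r.canonical_name for r in store.records(Status.POISONED)}


class TestPlantedRecovery:
    def test_planted_complexes_finish_done_and_rank_top(self):
        from plexqueue.fixtures import FixtureSpec, make_interactome
        planted = [ComplexSpec.of("P001", "P002", "P003", "P004"),
                   ComplexSpec.of("P005", "P006", "P007")]
        spec = FixtureSpec(n_proteins=10, edge_density=0.2,
                           planted_complexes=planted, seed=12)
        graph, truth = make_interactome(spec)
        specs = enumerate_supercomplexes(graph, EnumerationConfig(max_size=4))
        store = populate(specs)
        backend = PlantedBackend(truth, seed=12, noise_sd=0.02)
        run_campaign(store, backend, SchedulerConfig(priority_threshold=0.5))
        for comp in planted:
            rec = store.get(comp.canonical_name)
            assert rec.status == Status.DONE
            peers = [r for r in store.records(Status.DONE, size=comp.size)]
            better = sum(1 for r in peers if r.result.iptm > rec.result.iptm)
            assert better <= max(1, len(peers) // 10)
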