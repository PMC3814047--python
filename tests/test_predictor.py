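"""Subset enumeration, candidate ranking, the query workflow, and reports."""

import itertools

import pytest

from erp.measurements import NonDeducibleError, measurement_vector
from erp.predictor import (
    EXACT_MATCH,
    FAILURE,
    SUBSET_MATCH,
    ArchitectureTooLargeError,
    enumerate_subarchitectures,
    format_report,
    parse_query_file,
    parse_query_line,
    parse_report,
    predict,
    predict_batch,
    rank_candidates,
)
from erp.universe import DomainArchitecture


def powerset_oracle(domains):
    out = set()
    for size in range(1, len(domains)):
        out |= {frozenset(c) for c in itertools.combinations(domains, size)}
    return out


class TestEnumeration:
    def test_three_domain_worked_example(self):
        arch = DomainArchitecture(["SSF50729", "SSF56112", "SSF57889"])
        subsets = enumerate_subarchitectures(arch)
        assert [sorted(s) for s in subsets] == [
            ["SSF50729", "SSF56112"],
            ["SSF50729", "SSF57889"],
            ["SSF56112", "SSF57889"],
            ["SSF50729"],
            ["SSF56112"],
            ["SSF57889"],
        ]

    def test_singleton_has_no_proper_subsets(self):
        assert enumerate_subarchitectures(DomainArchitecture(["SSF54814"])) == []

    @pytest.mark.parametrize("d", range(2, 11))
    def test_count_and_membership_match_powerset_oracle(self, d):
        arch = DomainArchitecture([f"SSF{i}" for i in range(d)])
        subsets = enumerate_subarchitectures(arch)
        assert len(subsets) == 2**d - 2
        assert {frozenset(s) for s in subsets} == powerset_oracle(sorted(arch))

    def test_ordering_is_size_then_canonical(self):
        arch = DomainArchitecture(["B", "A", "C"])
        subsets = enumerate_subarchitectures(arch)
        sizes = [len(s) for s in subsets]
        assert sizes == sorted(sizes, reverse=True)
        for size in set(sizes):
            block = [s.canonical for s in subsets if len(s) == size]
            assert block == sorted(block)

    def test_cap_is_enforced(self):
        arch = DomainArchitecture([f"SSF{i}" for i in range(21)])
        with pytest.raises(ArchitectureTooLargeError):
            enumerate_subarchitectures(arch)


class TestRankCandidates:
    def test_worked_example_top_candidate(self, fig2_universe):
        query = DomainArchitecture(["SSF50729", "SSF56112", "SSF57889"])
        ranking = rank_candidates(fig2_universe, enumerate_subarchitectures(query))
        assert len(ranking) == 6
        assert all(v.existence == 1 for v in ranking)
        top = ranking[0]
        assert sorted(top.architecture) == ["SSF56112", "SSF57889"]
        assert top.succinctness.value == pytest.approx(0.6)

    def test_single_candidate_is_top(self, section3_universe):
        (top,) = rank_candidates(section3_universe, [DomainArchitecture(["SSF54814"])])
        assert sorted(top.architecture) == ["SSF54814"]

    def test_ordering_matches_field_wise_oracle(self, random_universe):
        candidates = [e.architecture for e in random_universe.entries[:30]]
        candidates += [
            DomainArchitecture([d]) for d in sorted(random_universe.domains)[:10]
        ]
        ranking = rank_candidates(random_universe, candidates)
        # independent per-field recomputation and sort
        oracle = []
        seen = set()
        for arch in candidates:
            if frozenset(arch) in seen:
                continue
            seen.add(frozenset(arch))
            try:
                vec = measurement_vector(random_universe, arch)
            except NonDeducibleError:
                continue
            oracle.append(
                (
                    -vec.existence,
                    -vec.succinctness.value,
                    vec.consistency,
                    vec.simplicity,
                    vec.architecture.canonical,
                )
            )
        oracle.sort()
        assert [v.sort_key for v in ranking] == oracle


class TestPredict:
    def test_exact_match_scenario(self, section3_universe):
        result = predict(section3_universe, DomainArchitecture(["SSF51110", "SSF55486"]))
        assert result.status == EXACT_MATCH
        assert result.chosen.architecture == frozenset(["SSF51110", "SSF55486"])
        assert result.chosen.succinctness.value == 1.0
        assert result.chosen.consistency == 0.0
        ((ec, count, value),) = result.ranked_ecs
        assert (ec, count, value) == ("3.4.24.21", 1, 1.0)
        assert result.proteins == [("F4KTN6", "F4KTN6_9SPHI")]

    def test_subset_match_scenario(self, section3_universe):
        result = predict(section3_universe, DomainArchitecture(["SSF54211", "SSF54814"]))
        assert result.status == SUBSET_MATCH
        assert sorted(result.chosen.architecture) == ["SSF54814"]
        assert result.chosen.succinctness.value == 1.0
        assert result.chosen.consistency == 0.0
        assert result.ranked_ecs[0].ec == "2.7.7.8"
        assert result.ranked_ecs[0].intensity == 1.0
        assert result.proteins == [("D9PMT6", "D9PMT6_9ZZZZ")]

    def test_failure_scenario(self, section3_universe):
        result = predict(section3_universe, DomainArchitecture(["SSF54211", "SSF54236"]))
        assert result.status == FAILURE
        assert result.chosen is None
        assert result.ranked_ecs == []

    def test_exact_match_never_enumerates(self, fig2_universe, monkeypatch):
        import erp.predictor as mod

        def boom(*args, **kwargs):  # pragma: no cover
            raise AssertionError("enumeration must not run for exact matches")

        monkeypatch.setattr(mod, "enumerate_subarchitectures", boom)
        entry = fig2_universe.entries[0]
        result = mod.predict(fig2_universe, entry.architecture)
        assert result.status == EXACT_MATCH

    def test_chosen_equals_exhaustive_argmax(self, random_universe):
        # For unseen queries of <= 6 domains the chosen candidate must be the
        # argmax over all deducible candidates under the documented key.
        domains = sorted(random_universe.domains)
        queries = [
            DomainArchitecture(domains[i : i + 4] + ["SSFNOVEL"]) for i in range(0, 12, 4)
        ]
        for query in queries:
            result = predict(random_universe, query)
            keys = []
            for size in range(1, len(query) + 1):
                for combo in itertools.combinations(sorted(query), size):
                    if frozenset(combo) == frozenset(query) or size < len(query):
                        try:
                            keys.append(
                                measurement_vector(
                                    random_universe, DomainArchitecture(combo)
                                ).sort_key
                            )
                        except NonDeducibleError:
                            pass
            if not keys:
                assert result.status == FAILURE
            else:
                assert result.chosen.sort_key == min(keys)

    def test_failure_is_monotone_in_disjoint_vocabulary(self, section3_universe):
        query = DomainArchitecture(["SSF54211", "SSF54236"])
        assert predict(section3_universe, query).status == FAILURE
        assert query.isdisjoint(section3_universe.domains)


class TestPredictBatch:
    def test_three_scenarios_in_order(self, section3_universe):
        queries = [
            DomainArchitecture(["SSF54211", "SSF54236"]),
            DomainArchitecture(["SSF51110", "SSF55486"]),
            DomainArchitecture(["SSF54211", "SSF54814"]),
        ]
        statuses = [r.status for r in predict_batch(section3_universe, queries)]
        assert statuses == [FAILURE, EXACT_MATCH, SUBSET_MATCH]

    def test_empty_batch(self, section3_universe):
        assert predict_batch(section3_universe, []) == []

    def test_matches_sequential_predict(self, random_universe):
        queries = [e.architecture for e in random_universe.entries[:40]]
        batch = predict_batch(random_universe, queries)
        sequential = [predict(random_universe, q) for q in queries]
        assert [r.to_dict() for r in batch] == [r.to_dict() for r in sequential]

    def test_per_query_error_recorded(self, section3_universe):
        big = DomainArchitecture([f"SSF{i}" for i in range(25)])
        results = predict_batch(section3_universe, [big])
        assert results[0].status == FAILURE
        assert "enumeration cap" in results[0].error or "exceeds" in results[0].error


class TestReports:
    def test_exact_match_report_contents(self, section3_universe):
        result = predict(section3_universe, DomainArchitecture(["SSF51110", "SSF55486"]))
        text = format_report(result)
        assert "3.4.24.21" in text
        assert "succinctness: 1" in text
        assert "consistency: 0" in text
        assert "F4KTN6" in text

    def test_failure_report_names_query(self, section3_universe):
        result = predict(section3_universe, DomainArchitecture(["SSF54211", "SSF54236"]))
        text = format_report(result)
        assert "SSF54211,SSF54236" in text
        assert "could not be deduced" in text

    def test_round_trip_extraction(self, random_universe):
        domains = sorted(random_universe.domains)
        queries = [e.architecture for e in random_universe.entries[:30]]
        queries += [DomainArchitecture([d, "SSFNOVEL"]) for d in domains[:20]]
        for result in predict_batch(random_universe, queries):
            status, chosen, top_ec = parse_report(format_report(result))
            assert status == result.status
            if result.status == FAILURE:
                assert chosen is None and top_ec is None
            else:
                assert chosen == result.chosen.architecture
                assert top_ec == result.ranked_ecs[0].ec


class TestQueryParsing:
    @pytest.mark.parametrize(
        "line",
        ["SSF1,SSF2", "SSF1 SSF2", "SSF1, SSF2", "  SSF2\tSSF1  "],
    )
    def test_comma_or_space_delimited(self, line):
        assert parse_query_line(line) == frozenset(["SSF1", "SSF2"])

    def test_query_file_skips_comments_and_blanks(self):
        lines = ["# q\n", "\n", "SSF1,SSF2\n", "SSF3\n"]
        assert parse_query_file(lines) == [
            frozenset(["SSF1", "SSF2"]),
            frozenset(["SSF3"]),
        ]
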