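"""Entity-state propagation, beam path search, serialization and the CC1 gate."""

import itertools

import numpy as np
import pytest

from qamt.audit import AuditTrail
from qamt.data_model import ClinicalEvent, StaticEventData
from qamt.hkg_cot import (QuestionContext, TokenOverlapScorer, generate_paths,
                          init_entity_state, reason_steps, serialize_paths,
                          transition_matrix, validate_event_sequence)
from qamt.knowledge_graph import HealthKnowledgeGraph, KGEdge, KGNode


class UnitScorer:
    def score(self, q_t, relation):
        return 1.0


def event_graph(edges, n=None):
    """Small instance graph over event nodes (relation 'after' allows any wiring)."""
    g = HealthKnowledgeGraph()
    nodes = sorted({x for e in edges for x in (e[0], e[1])})
    if n is not None:
        nodes = sorted(set(nodes) | {f"n{i}" for i in range(n)})
    for nid in nodes:
        g.add_node(KGNode(nid, "event", "Event", nid))
    for s, t in edges:
        g.add_edge(KGEdge(s, "after", t))
    return g


# -- entity state -----------------------------------------------------------

def test_init_state_is_indicator_vector(toy_kg):
    st = init_entity_state(["DIS:COPD"], toy_kg)
    assert st.values.sum() == 1.0
    assert st.values[st.node_order.index("DIS:COPD")] == 1.0
    assert init_entity_state([], toy_kg).values.sum() == 0.0


def test_init_state_idempotent(toy_kg):
    a = init_entity_state(["DIS:COPD", "SYM:fever"], toy_kg)
    b = init_entity_state(["DIS:COPD", "SYM:fever"], toy_kg)
    assert np.array_equal(a.values, b.values)


def test_chain_propagation_concentrates_mass_on_terminal():
    g = event_graph([("a", "b"), ("b", "c")])
    ctx = QuestionContext("walk", T=2)
    st = init_entity_state(["a"], g)
    out = reason_steps(st, ctx, g, UnitScorer())
    assert out.values[out.node_order.index("c")] == pytest.approx(1.0)
    assert out.values.sum() == pytest.approx(1.0)
    # input untouched
    assert st.values[st.node_order.index("a")] == 1.0


def test_reason_steps_matches_dense_matrix_power_oracle():
    rng = np.random.default_rng(42)
    for trial in range(5):
        n = 6
        edges = [(f"n{i}", f"n{j}") for i in range(n) for j in range(n)
                 if i != j and rng.random() < 0.4]
        if not edges:
            continue
        g = event_graph(edges, n=n)
        ctx = QuestionContext("oracle check", T=3)
        scorer = TokenOverlapScorer("oracle check")
        start = ["n0"]
        out = reason_steps(init_entity_state(start, g), ctx, g, scorer)
        # independent dense propagation
        w = transition_matrix(g, ctx.q, scorer)
        e = init_entity_state(start, g).values
        for _ in range(3):
            e = e @ w
        assert np.allclose(out.values, np.clip(e, 0, 1), atol=1e-9)


def test_row_normalization_keeps_state_in_unit_interval():
    g = event_graph([("a", "b"), ("a", "c"), ("a", "d")])
    w = transition_matrix(g, np.zeros(4), UnitScorer())
    assert w.sum(axis=1).max() <= 1.0 + 1e-12


# -- beam search ------------------------------------------------------------

def exhaustive_simple_paths(g, start, ctx, scorer, max_len):
    """Brute-force enumeration of simple paths of length 1..max_len."""
    out_edges = {}
    for e in g.edges:
        out_edges.setdefault(e.source, []).append((e.relation, e.target))
    results = {}

    def extend(node, hops, score, visited, depth):
        if depth == max_len:
            return
        q_t = ctx.f_t(ctx.q, depth + 1)
        for rel, tgt in out_edges.get(node, []):
            if tgt in visited:
                continue
            s = score * scorer.score(q_t, rel)
            path = hops + ((node, rel, tgt),)
            results[path] = s
            extend(tgt, path, s, visited | {tgt}, depth + 1)

    for nid in sorted(set(start)):
        extend(nid, (), 1.0, {nid}, 0)
    return results


@pytest.mark.parametrize("k", [1, 3, 200])
def test_beam_equals_exhaustive_enumeration_when_wide_enough(toy_kg, k):
    ctx = QuestionContext("which condition progresses to next", T=2)
    scorer = TokenOverlapScorer(ctx.question)
    start = ["DIS:Prediabetes", "DIS:COPD"]
    oracle = exhaustive_simple_paths(toy_kg, start, ctx, scorer, 2)
    ranked = sorted(oracle.items(),
                    key=lambda kv: (-kv[1], (kv[0][0][0],) + tuple(h[2] for h in kv[0])))
    got = generate_paths(toy_kg, start, ctx, scorer, k=k)
    if k >= len(oracle):  # beam provably exhaustive at this width
        assert [(p.hops, p.score) for p in got] == ranked[:k]
    else:
        assert [p.hops for p in got] == [hops for hops, _ in ranked[:k]]


def test_single_path_graph_returns_that_path_regardless_of_k():
    g = event_graph([("a", "b")])
    ctx = QuestionContext("q", T=2)
    for k in (1, 5, 50):
        paths = generate_paths(g, ["a"], ctx, UnitScorer(), k=k)
        assert [p.hops for p in paths] == [(("a", "after", "b"),)]


def test_paths_are_simple_no_repeated_nodes(toy_kg):
    ctx = QuestionContext("q", T=3)
    for p in generate_paths(toy_kg, ["DIS:COPD"], ctx, UnitScorer(), k=50):
        nodes = p.node_ids()
        assert len(nodes) == len(set(nodes))


# -- serialization ----------------------------------------------------------

def test_serialize_one_hop_path_as_natural_line(toy_kg):
    from qamt.hkg_cot import ReasoningPath
    p = ReasoningPath((("DIS:Prediabetes", "progresses_to",
                        "DIS:Type_2_Diabetes_Mellitus"),), 1.0)
    text = serialize_paths([p], toy_kg)
    assert "Prediabetes progresses_to Type 2 Diabetes Mellitus" in text


def test_serialize_empty_paths_is_instruction_only(toy_kg):
    text = serialize_paths([], toy_kg)
    assert "reasoning paths" in text
    assert "\n" not in text.strip()


def test_serialization_injective_on_distinct_path_lists(toy_kg):
    ctx = QuestionContext("q", T=2)
    paths = generate_paths(toy_kg, ["DIS:COPD"], ctx, UnitScorer(), k=6)
    texts = {serialize_paths(list(combo), toy_kg)
             for combo in itertools.permutations(paths, 2)}
    assert len(texts) == len(list(itertools.permutations(paths, 2)))


# -- CC1 gate ---------------------------------------------------------------

def seq(*codes):
    return StaticEventData(events=[ClinicalEvent(c, 24 * i) for i, c in enumerate(codes)])


def test_single_event_passes_with_zero_backend_calls(toy_kg, backend):
    audit = AuditTrail()
    cc1, verdicts = validate_event_sequence(seq("Prediabetes"), toy_kg, backend,
                                            audit=audit)
    assert (cc1, verdicts) == (1, [])
    assert len(audit) == 0


def test_supported_progression_passes(toy_kg, backend):
    cc1, verdicts = validate_event_sequence(
        seq("Prediabetes", "Type 2 Diabetes Mellitus"), toy_kg, backend)
    assert cc1 == 1
    assert all(ok for _, ok, _ in verdicts)


def test_unsupported_succession_fails_with_single_feedback(toy_kg, backend):
    calls = []
    cc1, verdicts = validate_event_sequence(
        seq("Prediabetes", "COPD"), toy_kg, backend,
        feedback=calls.append, first_pass=True)
    assert cc1 == 0
    assert len(calls) == 1
    cc1_again, _ = validate_event_sequence(
        seq("Prediabetes", "COPD"), toy_kg, backend,
        feedback=calls.append, first_pass=False)
    assert cc1_again == 0 and len(calls) == 1  # no feedback on the second pass


def test_unlinked_event_fails_with_reason(toy_kg, backend):
    cc1, verdicts = validate_event_sequence(
        seq("Prediabetes", "xyzzy-unknown-condition"), toy_kg, backend)
    assert cc1 == 0
    assert "unlinked" in verdicts[0][2]


def test_appending_supported_successor_preserves_passing_prefix(toy_kg, backend):
    base = seq("COPD", "Pneumonia")
    extended = seq("COPD", "Pneumonia", "Sepsis")
    cc1_base, v_base = validate_event_sequence(base, toy_kg, backend)
    cc1_ext, v_ext = validate_event_sequence(extended, toy_kg, backend)
    assert cc1_base == 1 and cc1_ext == 1
    assert [ok for _, ok, _ in v_ext[:len(v_base)]] == [ok for _, ok, _ in v_base]
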