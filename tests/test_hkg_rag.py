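"""Demographic sampling and judging, entity linking, top-K retrieval,
few-shot generation and the retrieval-width feedback loop."""

import numpy as np
from hypothesis import given, strategies as st

from qamt.audit import AuditTrail
from qamt.data_model import Dataset, QA_CONSTRAINED
from qamt.hkg_cot import validate_event_sequence
from qamt.hkg_rag import (RAGConfig, build_prompt, generate_static_events,
                          generate_with_feedback, judge_demographics,
                          recognize_and_link, retrieve_context, sample_demographics,
                          sample_index_condition)
from qamt.knowledge_graph import token_similarity, triples
from qamt.llm_interface import mock_backend
from qamt.synthetic_fixtures import make_feedback_fixture


# -- demographic sampling ---------------------------------------------------

def test_single_patient_source_reproduces_their_fields(cohort200):
    one = Dataset(patients=cohort200.patients[:1], schema=cohort200.schema)
    c = sample_demographics(one, seed=0)
    assert c == one.patients[0].visits[0].static.covariates


def test_sampling_is_seed_deterministic(cohort200):
    assert sample_demographics(cohort200, seed=5) == sample_demographics(cohort200, seed=5)


def test_sampled_marginals_match_source_within_binomial_bounds(cohort200):
    draws = [sample_demographics(cohort200, seed=s)["gender"] for s in range(10_000)]
    p_emp = sum(1 for p in cohort200.patients
                if p.visits[0].static.covariates["gender"] == "F") / len(cohort200.patients)
    n = len(draws)
    freq = draws.count("F") / n
    sigma = np.sqrt(p_emp * (1 - p_emp) / n)
    assert abs(freq - p_emp) < 3 * sigma


# -- judging ----------------------------------------------------------------

def test_judge_passes_and_is_idempotent(backend):
    c = {"age": 65, "marital_status": "MARRIED"}
    once = judge_demographics(c, backend)
    assert once == c
    assert judge_demographics(once, backend) == c


def test_judge_rejects_implausible_combination(backend):
    assert judge_demographics({"age": 6, "marital_status": "MARRIED"}, backend) is None


# -- entity linking ---------------------------------------------------------

def test_prompt_with_single_label_links_single_node(toy_kg, backend):
    n_q = recognize_and_link("presenting with Pneumonia", toy_kg, 0.5, backend)
    assert n_q == ["DIS:Pneumonia"]


def test_threshold_above_one_links_nothing(toy_kg, backend):
    assert recognize_and_link("Pneumonia and COPD", toy_kg, 1.01, backend) == []


def test_linking_agrees_with_exhaustive_similarity_scan(toy_kg, backend):
    prompt = "Heart Failure after Type 2 Diabetes Mellitus"
    n_q = recognize_and_link(prompt, toy_kg, 0.5, backend)
    mentions = backend.complete(
        __import__("qamt.llm_interface", fromlist=["PromptRequest"])
        .PromptRequest("extractor", prompt)).parsed
    oracle = set()
    for mention in mentions:
        scored = [(token_similarity(mention, n.label), nid)
                  for nid, n in toy_kg.nodes.items()]
        best = max(scored, key=lambda t: (t[0], [c for c in t[1]]))
        best_score = max(s for s, _ in scored)
        winners = sorted(nid for s, nid in scored if s == best_score)
        if best_score > 0.5:
            oracle.add(winners[0])
    assert set(n_q) == oracle


# -- retrieval --------------------------------------------------------------

def test_empty_subject_set_gives_empty_context(toy_kg):
    ctx = retrieve_context([], toy_kg, 5)
    assert ctx.tuples == [] and ctx.sentences == []


def test_shared_object_grouped_into_nary_tuple(toy_kg):
    ctx = retrieve_context(["DIS:COPD", "DIS:Pneumonia"], toy_kg, 20)
    fever = [t for t in ctx.tuples if t[2] == "SYM:fever"]
    assert len(fever) == 1
    subjects, pred, obj, count = fever[0]
    assert subjects == ("DIS:COPD", "DIS:Pneumonia")
    assert (pred, count) == ("has_symptom", 2)
    assert any(s.startswith("COPD, Pneumonia has_symptom fever") for s in ctx.sentences)


def test_top_k_object_selection_matches_exhaustive_count(toy_kg):
    n_q = ["DIS:COPD", "DIS:Pneumonia", "DIS:Prediabetes", "DIS:Hypertension"]
    k = 3
    ctx = retrieve_context(n_q, toy_kg, k)
    counts = {}
    for _, _, obj in triples(toy_kg, n_q):
        counts[obj] = counts.get(obj, 0) + 1
    oracle = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    assert [(o, c) for o, _, c in ctx.objects] == oracle
    assert len({obj for _, _, obj, _ in ctx.tuples}) <= k


def test_retrieval_invariant_to_subject_order(toy_kg):
    a = retrieve_context(["DIS:COPD", "DIS:Pneumonia"], toy_kg, 5)
    b = retrieve_context(["DIS:Pneumonia", "DIS:COPD"], toy_kg, 5)
    assert a.tuples == b.tuples and a.sentences == b.sentences


@given(st.integers(min_value=1, max_value=12))
def test_distinct_objects_never_exceed_retrieval_width(k):
    from qamt.synthetic_fixtures import make_toy_kg
    g = make_toy_kg()
    ctx = retrieve_context(sorted(n for n in g.nodes if n.startswith("DIS:")), g, k)
    assert len({obj for _, _, obj, _ in ctx.tuples}) <= k


# -- generation -------------------------------------------------------------

def test_generated_events_stay_within_retrieved_objects(toy_kg, backend):
    ctx = retrieve_context(["DIS:COPD"], toy_kg, 5)
    m = generate_static_events({"age": 50}, ctx, backend, seed=1)
    labels = {lab for _, lab, _ in ctx.objects}
    assert set(e.code for e in m.events) <= labels
    assert m.qa_status == "raw"
    assert [e.timestamp for e in m.events] == [24 * i for i in range(len(m.events))]


def test_generation_is_deterministic_under_fixed_seed(toy_kg, backend):
    ctx = retrieve_context(["DIS:Prediabetes"], toy_kg, 5)
    a = generate_static_events({"age": 50}, ctx, backend, seed=9,
                               index_condition="Prediabetes")
    b = generate_static_events({"age": 50}, ctx, backend, seed=9,
                               index_condition="Prediabetes")
    assert [e.code for e in a.events] == [e.code for e in b.events]
    assert a.outcomes == b.outcomes


# -- feedback loop ----------------------------------------------------------

def make_cc1(g, be, audit=None):
    def cc1_check(m, first_pass):
        return validate_event_sequence(m, g, be, first_pass=first_pass, audit=audit)
    return cc1_check


def test_passing_first_attempt_needs_single_generation(toy_kg, backend):
    audit = AuditTrail()
    cfg = RAGConfig(seed=2)
    m = generate_with_feedback({"age": 50}, toy_kg, cfg, backend,
                               make_cc1(toy_kg, backend, audit),
                               index_condition="Prediabetes", audit=audit)
    assert m is not None and m.qa_status == QA_CONSTRAINED
    gen_calls = [e for e in audit.entries
                 if e.detail and e.detail.get("role") == "generator"]
    assert len(gen_calls) == 1


def test_expanded_retrieval_rescues_failing_sequence():
    g, demo, index = make_feedback_fixture()
    be = mock_backend(g, seed=0)
    audit = AuditTrail()
    observed = []

    def cc1_check(m, first_pass):
        cc1, v = validate_event_sequence(m, g, be, first_pass=first_pass, audit=audit)
        observed.append(cc1)
        return cc1, v

    m = generate_with_feedback(demo, g, RAGConfig(seed=1), be, cc1_check,
                               index_condition=index, audit=audit, record_id="r1")
    assert observed == [0, 1]
    assert [e.code for e in m.events] == ["Renal Stage One", "Renal Stage Two"]
    widths = [e.detail["K_rag"] for e in audit.entries
              if e.detail and "K_rag" in e.detail]
    assert widths == [5, 10]


def test_both_attempts_failing_discards_record(toy_kg, backend):
    def always_fail(m, first_pass):
        return 0, []
    m = generate_with_feedback({"age": 50}, toy_kg, RAGConfig(seed=3), backend,
                               always_fail, index_condition="Prediabetes")
    assert m is None


def test_prompt_template_fills_named_slots():
    text = build_prompt({"age": 50, "gender": "F"}, index_condition="COPD")
    assert "age 50" in text and "COPD" in text


def test_index_condition_sampling_follows_first_event_marginal(cohort200):
    draws = {sample_index_condition(cohort200, seed=s) for s in range(40)}
    firsts = {p.visits[0].static.events[0].code for p in cohort200.patients}
    assert draws <= firsts and len(draws) > 1
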