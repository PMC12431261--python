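"""Fidelity metrics against brute-force oracles; privacy audit calibration."""

import copy

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qamt.data_model import (ClinicalEvent, Dataset, PatientRecord, StaticEventData,
                             TemporalPoint, TemporalSeries, Visit)
from qamt.evaluation import (EmbeddingMatrix, NGRAM_KINDS, TSTRTask,
                             hamming_event_distance, inject_noise, mia_privacy,
                             msecorr, ngram_correlation, ngram_probs, noise_harness,
                             prdc, temporal_embeddings, utility_tstr)
from qamt.synthetic_fixtures import FixtureSpec, make_cohort


def patient(pid, visit_events, temporal=None):
    visits = []
    for i, events in enumerate(visit_events):
        visits.append(Visit(
            f"2023-0{i+1}-01T00:00:00",
            StaticEventData(events=[ClinicalEvent(c, 24 * j)
                                    for j, c in enumerate(events)]),
            temporal or TemporalSeries(),
        ))
    return PatientRecord(pid, visits)


# -- n-grams ----------------------------------------------------------------

def test_unigram_probability_is_patient_frequency():
    d = Dataset(patients=[patient("a", [["A", "B"]]), patient("b", [["A"]])])
    table = ngram_probs(d, "unigram")
    assert table.probs[("A",)] == 1.0
    assert table.probs[("B",)] == 0.5


def test_sequential_bigram_spans_consecutive_visits():
    d = Dataset(patients=[patient("a", [["A"], ["B"]])])
    table = ngram_probs(d, "sequential_bigram")
    assert table.probs == {("A", "B"): 1.0}


def test_ngram_tables_match_bruteforce_enumeration():
    rng = np.random.default_rng(0)
    codes = list("ABCDE")
    patients = []
    for i in range(10):
        visits = [[str(rng.choice(codes)) for _ in range(int(rng.integers(1, 5)))]
                  for _ in range(int(rng.integers(1, 3)))]
        patients.append(patient(f"p{i}", visits))
    d = Dataset(patients=patients)
    for kind, n in [("unigram", 1), ("bigram", 2), ("trigram", 3)]:
        table = ngram_probs(d, kind)
        oracle = {}
        for p in patients:
            grams = set()
            for v in p.visits:
                seq = [e.code for e in v.static.events]
                for j in range(len(seq) - n + 1):
                    grams.add(tuple(seq[j:j + n]))
            for g_ in grams:
                oracle[g_] = oracle.get(g_, 0) + 1
        oracle = {g_: c / 10 for g_, c in oracle.items()}
        assert table.probs == oracle


def test_self_correlation_is_unity(cohort200):
    for kind in NGRAM_KINDS:
        t = ngram_probs(cohort200, kind)
        assert ngram_correlation(t, t).r == pytest.approx(1.0)


def test_disjoint_vocabulary_reports_undefined():
    real = ngram_probs(Dataset(patients=[patient("a", [["A", "B"]]),
                                         patient("b", [["A"]])]), "unigram")
    gen = ngram_probs(Dataset(patients=[patient("c", [["X"]])]), "unigram")
    out = ngram_correlation(real, gen)
    assert out.r is None and "distinct" in out.reason


def test_correlation_agrees_with_textbook_formula():
    rng = np.random.default_rng(3)
    grams = [tuple(g) for g in ("AB", "BC", "CD", "DE", "EA")]
    real_t = ngram_probs(Dataset(), "bigram")
    gen_t = ngram_probs(Dataset(), "bigram")
    real_t.probs = {g: float(rng.uniform(0.1, 1)) for g in grams}
    gen_t.probs = {g: float(rng.uniform(0.1, 1)) for g in grams}
    got = ngram_correlation(real_t, gen_t).r
    x = np.array([real_t.probs[g] for g in sorted(grams, key=lambda g: (-real_t.probs[g], g))])
    y = np.array([gen_t.probs[g] for g in sorted(grams, key=lambda g: (-real_t.probs[g], g))])
    manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert got == pytest.approx(manual, abs=1e-12)


# -- embeddings -------------------------------------------------------------

def embed_patient(values, times=None):
    times = times or list(range(0, 6 * len(values), 6))
    pts = [TemporalPoint(t, [("v", float(x))]) for t, x in zip(times, values)]
    return Dataset(patients=[PatientRecord("p", [Visit(
        "2023-01-01T00:00:00", StaticEventData(), TemporalSeries(points=pts))])],
        schema={"variables": ["v"], "labels": []})


def test_constant_series_embeds_as_min_max_mean_zero_std():
    emb = temporal_embeddings(embed_patient([5, 5, 5]))
    assert emb.values[0].tolist() == [5, 5, 5, 0]


def test_two_value_window_uses_population_std():
    emb = temporal_embeddings(embed_patient([1, 3]))
    assert emb.values[0].tolist() == [1, 3, 2, 1]


def test_measurements_outside_48h_window_excluded():
    emb = temporal_embeddings(embed_patient([1, 3, 99], times=[0, 24, 48]))
    assert emb.values[0].tolist() == [1, 3, 2, 1]


# -- PRDC -------------------------------------------------------------------

def test_prdc_identity_fixed_point(cohort200):
    emb = temporal_embeddings(cohort200)
    out = prdc(emb, emb)
    assert (out.precision, out.recall, out.coverage) == (1.0, 1.0, 1.0)


def test_prdc_density_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(15, 4))
    y = rng.normal(size=(12, 4))
    ex = EmbeddingMatrix(x, [f"c{i}" for i in range(4)], [f"r{i}" for i in range(15)])
    ey = EmbeddingMatrix(y, [f"c{i}" for i in range(4)], [f"g{i}" for i in range(12)])
    k = 5
    out = prdc(ex, ey, k=k, standardize=False)
    radii = []
    for i in range(len(x)):
        dists = sorted(np.linalg.norm(x[i] - x[j]) for j in range(len(x)) if j != i)
        radii.append(dists[k - 1])
    count = sum(1 for j in range(len(y)) for i in range(len(x))
                if np.linalg.norm(y[j] - x[i]) <= radii[i])
    assert out.density == pytest.approx(count / (k * len(y)), abs=1e-9)


def test_prdc_collapses_under_large_shift():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(20, 3))
    y = rng.normal(size=(20, 3)) + 100.0
    ex = EmbeddingMatrix(x, list("abc"), [str(i) for i in range(20)])
    ey = EmbeddingMatrix(y, list("abc"), [str(i) for i in range(20)])
    out = prdc(ex, ey, standardize=False)
    assert out.precision == 0.0 and out.coverage == 0.0 and out.density == 0.0


# -- correlation MSE --------------------------------------------------------

def test_msecorr_self_is_zero(cohort200):
    assert msecorr(cohort200, cohort200) == 0.0


def test_msecorr_two_variable_case_is_squared_difference():
    rng = np.random.default_rng(5)
    a = rng.normal(size=(200, 2))
    b = np.column_stack([a[:, 0], a[:, 0] * 0.5 + rng.normal(size=200)])
    r1 = pd.DataFrame(a).corr().iloc[0, 1]
    r2 = pd.DataFrame(b).corr().iloc[0, 1]
    assert msecorr(a, b) == pytest.approx((r1 - r2) ** 2, abs=1e-12)


def test_msecorr_matches_per_pair_oracle():
    rng = np.random.default_rng(6)
    a = rng.normal(size=(100, 5))
    b = rng.normal(size=(100, 5))
    got = msecorr(a, b)
    diffs = []
    for i in range(5):
        for j in range(i + 1, 5):
            ra = np.corrcoef(a[:, i], a[:, j])[0, 1]
            rb = np.corrcoef(b[:, i], b[:, j])[0, 1]
            diffs.append((ra - rb) ** 2)
    assert got == pytest.approx(float(np.mean(diffs)), abs=1e-9)


# -- privacy ----------------------------------------------------------------

def test_hamming_pads_unequal_sequences():
    assert hamming_event_distance(["A", "B"], ["A"]) == 0.5
    assert hamming_event_distance([], []) == 0.0
    assert hamming_event_distance(["A"], ["B", "C"]) == 1.0


def test_identical_member_and_holdout_distances_are_null():
    spec = FixtureSpec(n_patients=8)
    d = make_cohort(spec, seed=1)
    # duplicate the member half as the holdout half: identical distance samples
    twin = copy.deepcopy(d)
    twin.patients = copy.deepcopy(d.patients[:4]) + copy.deepcopy(d.patients[:4])
    gen = make_cohort(spec, seed=2)
    report = mia_privacy(twin, gen, side="temporal")
    assert report.wd == pytest.approx(0.0, abs=1e-12)
    assert report.jsd == pytest.approx(0.0, abs=1e-12)
    assert report.auroc == pytest.approx(0.5)


def test_exact_copy_of_member_half_is_detected():
    d = make_cohort(FixtureSpec(n_patients=60), seed=1)
    leak = copy.deepcopy(d)
    leak.patients = copy.deepcopy(d.patients[:30])
    report = mia_privacy(d, leak, side="temporal")
    assert report.auroc > 0.9


# -- utility ----------------------------------------------------------------

def label_task(spec):
    def label(p):
        return 1 if "COPD" in p.visits[0].static.outcomes else 0

    def features(p):
        vals = {}
        for pt in p.visits[0].temporal.points:
            for n, v in pt.measurements:
                vals.setdefault(n, []).append(v)
        return np.array([np.mean(vals[v]) for v in sorted(spec.variables)])

    return TSTRTask(label=label, features=features, name="copd")


def test_tstr_self_consistency_and_shuffled_chance(spec):
    real = make_cohort(FixtureSpec(n_patients=150), seed=1)
    gen = make_cohort(FixtureSpec(n_patients=150), seed=2)
    task = label_task(spec)
    same = utility_tstr(real, real, task)
    assert abs(same["difference"]) < 0.05
    cross = utility_tstr(real, gen, task, seed=0)
    assert cross["train_gen_test_real"] > 0.9  # planted signal is learnable
    # destroying the labels destroys transfer
    shuffled = copy.deepcopy(gen)
    rng = np.random.default_rng(0)
    feats = [task.features(p) for p in shuffled.patients]
    rng.shuffle(feats)
    shuffled_task = TSTRTask(
        label=task.label,
        features=lambda p, _m={id(q): f for q, f in zip(shuffled.patients, feats)}:
            _m.get(id(p), task.features(p)),
        name="shuffled")
    chance = utility_tstr(real, shuffled, shuffled_task, seed=0)
    majority = max(np.mean([task.label(p) for p in real.patients]),
                   1 - np.mean([task.label(p) for p in real.patients]))
    assert chance["train_gen_test_real"] <= majority + 0.05


# -- permutation invariance -------------------------------------------------

def test_fidelity_metrics_invariant_to_patient_order(cohort200):
    shuffled = copy.deepcopy(cohort200)
    rng = np.random.default_rng(4)
    rng.shuffle(shuffled.patients)
    for kind in NGRAM_KINDS:
        assert ngram_probs(shuffled, kind).probs == ngram_probs(cohort200, kind).probs
    a = prdc(temporal_embeddings(cohort200), temporal_embeddings(shuffled))
    assert (a.precision, a.recall, a.coverage) == (1.0, 1.0, 1.0)
    assert msecorr(cohort200, shuffled) == pytest.approx(0.0, abs=1e-12)


# -- noise harness ----------------------------------------------------------

def test_noise_level_zero_is_identical_to_baseline():
    d = make_cohort(FixtureSpec(n_patients=40), seed=3)
    table, achieved = noise_harness(d, [0.0, 0.1], seed=1)
    assert len(table) == 2
    row0 = table.iloc[0]
    assert (row0["precision"], row0["recall"], row0["coverage"]) == (1.0, 1.0, 1.0)
    assert row0["msecorr"] == 0.0
    assert all(v == 0.0 for v in achieved[0.0].values())


def test_injected_noise_std_matches_requested_level():
    d = make_cohort(FixtureSpec(n_patients=150), seed=3)  # 1200 points/variable
    from qamt.evaluation import _dataset_variable_stds
    base = _dataset_variable_stds(d)
    _, achieved = inject_noise(d, 0.2, seed=9)
    for var, sd in achieved.items():
        assert sd == pytest.approx(0.2 * base[var], rel=0.05)


@given(st.sampled_from([-0.1, 1.5]))
def test_noise_levels_outside_unit_interval_rejected(level):
    d = make_cohort(FixtureSpec(n_patients=5), seed=0)
    with pytest.raises(ValueError):
        noise_harness(d, [level])
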