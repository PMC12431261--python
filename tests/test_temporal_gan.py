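"""Condition encoding, autodiff correctness, training contract and
conditional faithfulness of the adversarial temporal model."""

import numpy as np
import pytest

from qamt._autodiff import Tensor
from qamt.data_model import StaticEventData, TemporalPoint, TemporalSeries, \
    ClinicalEvent, QA_CONSTRAINED
from qamt.synthetic_fixtures import FixtureSpec, make_cohort, training_pairs
from qamt.temporal_gan import (GANConfig, GANModel,
                               discriminator_accuracy, generate_temporal,
                               series_to_grid, summarize_condition, train_gan)


def constrained(outcomes=(), events=(), covariates=None):
    return StaticEventData(
        covariates=covariates or {"age": 60, "gender": "F"},
        outcomes=set(outcomes),
        events=[ClinicalEvent(c, 24 * i) for i, c in enumerate(events)],
        qa_status=QA_CONSTRAINED,
    )


# -- condition encoding -----------------------------------------------------

def test_condition_vector_deterministic_and_schema_sized(condition_schema):
    m = constrained(outcomes=["COPD"], events=["COPD", "Pneumonia"])
    a = summarize_condition(m, condition_schema)
    b = summarize_condition(m, condition_schema)
    assert np.array_equal(a, b)
    assert len(a) == condition_schema.width


def test_empty_outcomes_give_zero_multihot_block(condition_schema):
    m = constrained()
    vec = summarize_condition(m, condition_schema)
    n_labels = len(condition_schema.labels)
    label_block = vec[-(n_labels + 1):-1]
    assert np.all(label_block == 0)


def test_raw_static_data_cannot_condition(condition_schema):
    m = constrained()
    m.qa_status = "raw"
    with pytest.raises(ValueError, match="constrained"):
        summarize_condition(m, condition_schema)


# -- autodiff core ----------------------------------------------------------

def test_gradients_match_finite_differences():
    rng = np.random.default_rng(0)

    def loss(params):
        a, b, c = params
        x = (a @ b).softmax(axis=-1)
        return ((x @ c).tanh().sigmoid().log()).mean()

    params = [Tensor(rng.normal(size=s)) for s in [(3, 4, 5), (5, 6), (6, 4)]]
    out = loss(params)
    out.backward()
    eps = 1e-6
    for p in params:
        flat = p.data.ravel()
        for idx in range(0, flat.size, max(1, flat.size // 5)):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = loss(params).data
            flat[idx] = orig - eps
            lm = loss(params).data
            flat[idx] = orig
            assert (lp - lm) / (2 * eps) == pytest.approx(p.grad.ravel()[idx], abs=1e-6)


# -- grid regularization ----------------------------------------------------

def test_irregular_series_locf_onto_grid():
    series = TemporalSeries(points=[
        TemporalPoint(0, [("hr", 60.0)]),
        TemporalPoint(13, [("hr", 80.0), ("bp", 120.0)]),
    ])
    cfg = GANConfig(n_variables=2, sequence_length=4, grid_hours=6)
    values, mask = series_to_grid(series, ["bp", "hr"], cfg)
    assert values[:, 1].tolist() == [60.0, 60.0, 80.0, 80.0]  # hr carried forward
    assert mask[0].tolist() == [0.0, 1.0]
    assert mask[2].tolist() == [1.0, 1.0]
    assert mask[3].tolist() == [0.0, 0.0]


# -- training contract ------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_pairs():
    spec = FixtureSpec(n_patients=40)
    cohort = make_cohort(spec, seed=3)
    return training_pairs(cohort, spec.condition_schema())


def test_zero_epochs_returns_seeded_initialization_that_generates(tiny_pairs, tmp_path):
    cfg = GANConfig(n_variables=8, epochs=0, seed=4)
    model = train_gan(tiny_pairs, cfg)
    assert model.history == []
    out = generate_temporal(model, tiny_pairs[0][1], 2, seed=1)
    assert len(out) == 2
    model.save(tmp_path / "m.npz")
    assert GANModel.load(tmp_path / "m.npz").cfg == cfg


def test_same_seed_gives_bit_identical_loss_trace(tiny_pairs):
    cfg = GANConfig(n_variables=8, epochs=3, seed=6)
    a = train_gan(tiny_pairs, cfg)
    b = train_gan(tiny_pairs, cfg)
    assert a.history == b.history


def test_too_few_training_pairs_rejected(tiny_pairs):
    with pytest.raises(ValueError):
        train_gan(tiny_pairs[:1], GANConfig(n_variables=8))


# -- generation contract ----------------------------------------------------

def test_generate_zero_samples_is_empty(tiny_pairs):
    model = train_gan(tiny_pairs, GANConfig(n_variables=8, epochs=0, seed=4))
    assert generate_temporal(model, tiny_pairs[0][1], 0, seed=0) == []


def test_generation_deterministic_and_on_declared_grid(tiny_pairs):
    cfg = GANConfig(n_variables=8, epochs=2, seed=4)
    model = train_gan(tiny_pairs, cfg)
    a = generate_temporal(model, tiny_pairs[0][1], 3, seed=8)
    b = generate_temporal(model, tiny_pairs[0][1], 3, seed=8)
    assert all(pa.measurements == pb.measurements
               for sa, sb in zip(a, b) for pa, pb in zip(sa.points, sb.points))
    for s in a:
        assert [p.time for p in s.points] == [i * cfg.grid_hours
                                              for i in range(cfg.sequence_length)]
        assert s.qa_status == "raw"


def test_condition_dimension_mismatch_rejected(tiny_pairs):
    model = train_gan(tiny_pairs, GANConfig(n_variables=8, epochs=0, seed=4))
    with pytest.raises(ValueError, match="dimension"):
        generate_temporal(model, np.zeros(model.cond_dim + 1), 1, seed=0)


def test_save_load_round_trip_generates_identically(tiny_pairs, tmp_path):
    model = train_gan(tiny_pairs, GANConfig(n_variables=8, epochs=3, seed=4))
    model.save(tmp_path / "m.npz")
    twin = GANModel.load(tmp_path / "m.npz")
    a = generate_temporal(model, tiny_pairs[0][1], 2, seed=5)
    b = generate_temporal(twin, tiny_pairs[0][1], 2, seed=5)
    assert all(pa.measurements == pb.measurements
               for sa, sb in zip(a, b) for pa, pb in zip(sa.points, sb.points))


# -- learning behaviour -----------------------------------------------------

def test_discriminator_accuracy_drifts_toward_chance():
    spec = FixtureSpec(n_patients=200)
    cohort = make_cohort(spec, seed=9)
    pairs = training_pairs(cohort, spec.condition_schema())
    train, held = pairs[:160], pairs[160:]
    checkpoints = (60, 360, 600)
    gaps = []
    for epochs in checkpoints:
        model = train_gan(train, GANConfig(n_variables=8, epochs=epochs, seed=5))
        gaps.append(abs(discriminator_accuracy(model, held, seed=1) - 0.5))
    # monotone drift toward chance (slack 0.05 per step for adversarial
    # fluctuation) with a clear overall drop
    assert all(b <= a + 0.05 for a, b in zip(gaps, gaps[1:]))
    assert gaps[-1] <= gaps[0] - 0.05
    assert gaps[-1] <= 0.25


def test_conditional_sign_pattern_follows_planted_shifts(trained_gan, spec,
                                                         condition_schema):
    """Hypertension-conditioned output has higher systolic pressure than
    COPD-conditioned output (and symmetrically for respiratory rate)."""
    m_hyp = constrained(outcomes=["Hypertension", "Heart Failure"],
                        events=["Hypertension", "Heart Failure"])
    m_copd = constrained(outcomes=["COPD", "Pneumonia"], events=["COPD", "Pneumonia"])

    def mean_of(model, m, var):
        cond = summarize_condition(m, condition_schema)
        vals = [v for s in generate_temporal(model, cond, 60, seed=3)
                for pt in s.points for n, v in pt.measurements if n == var]
        return float(np.mean(vals))

    assert mean_of(trained_gan, m_hyp, "systolic_bp") > \
        mean_of(trained_gan, m_copd, "systolic_bp") + 1.0
    assert mean_of(trained_gan, m_copd, "respiratory_rate") > \
        mean_of(trained_gan, m_hyp, "respiratory_rate") + 1.0
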