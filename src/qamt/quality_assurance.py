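"""Quality gates and the audited end-to-end generation pipeline.

A generated record is emitted only when all three binary gates pass:

* **CC1** — logical consistency of the event sequence, enforced during
  static-event generation via KG chain-of-thought reasoning;
* **CC2** — every temporal value inside the value range its clinical
  indicator carries in the concept knowledge graph (variables with no
  matched constraint are skipped with a logged notice);
* **VD** — variable dependencies: diagnoses predicted from the temporal data
  must be judged consistent with the constrained static event data.

The pipeline loops sample -> judge -> retrieval-augmented generation (with
one CC1 feedback round) -> condition summary -> adversarial temporal
generation -> CC2 -> event prediction -> consistency judgment -> assembly,
auditing every model interaction, until the target count is emitted or the
attempt budget (10x the target by default) is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .audit import AuditTrail
from .data_model import (Dataset, PatientRecord, StaticEventData, TemporalSeries,
                         Visit, QA_CONSTRAINED)
from .hkg_cot import validate_event_sequence
from .hkg_rag import (RAGConfig, generate_with_feedback, judge_demographics,
                      sample_demographics, sample_index_condition)
from .knowledge_graph import HealthKnowledgeGraph, constraint_for_variable
from .llm_interface import Backend, BackendError, PromptRequest, complete
from .temporal_gan import ConditionSchema, GANModel, generate_temporal, summarize_condition

logger = logging.getLogger(__name__)


@dataclass
class QAVerdict:
    cc1: int = 0
    cc2: int = 0
    vd: int = 0
    reasons: list[str] = field(default_factory=list)

    @property
    def emit(self) -> bool:
        return self.cc1 * self.cc2 * self.vd == 1


@dataclass(frozen=True)
class PredictedEvents:
    tuples: tuple[str, ...]


# ---------------------------------------------------------------------------
# CC2

def check_cc2(t: TemporalSeries, g: HealthKnowledgeGraph,
              tau: float = 0.5) -> tuple[int, list[str]]:
    """Value-range gate: 0 iff any observed value falls outside the range its
    matched clinical indicator carries; order-invariant over time points."""
    violations: list[str] = []
    constraints = {}
    for name in t.variables():
        vc = constraint_for_variable(name, g, tau)
        if vc is None:
            logger.info("CC2: no value constraint matched for variable %r; skipped", name)
        constraints[name] = vc
    for point in t.points:
        for name, value in point.measurements:
            vc = constraints.get(name)
            if vc is None:
                continue
            if not (vc.lower <= value <= vc.upper):
                violations.append(
                    f"{name}@t={point.time}: value {value:g} outside "
                    f"[{vc.lower:g}, {vc.upper:g}] {vc.units}".rstrip()
                )
    return (0 if violations else 1), violations


# ---------------------------------------------------------------------------
# VD: event prediction from temporal data + consistency judgment

EVPREDICT_INSTRUCTION_START = (
    "Given the following temporal measurements of one patient, predict the "
    "clinical events of the corresponding static event data.\nContext: "
)
EVPREDICT_INSTRUCTION_END = "\nAnswer with a tuple of predicted events."


def predict_events(t: TemporalSeries, backend: Backend,
                   audit: Optional[AuditTrail] = None, seed: int = 0,
                   record_id: Optional[str] = None) -> PredictedEvents:
    """Format (variable: values) tuples into the three-part prompt and parse
    the predicted event tuple.  Requires a non-empty, constrained series."""
    if not t.points:
        raise ValueError("predict_events requires a non-empty temporal series")
    if t.qa_status != QA_CONSTRAINED:
        raise ValueError("predict_events requires a constrained series (cc2=1)")
    by_var: dict[str, list[float]] = {}
    for point in t.points:
        for name, value in point.measurements:
            by_var.setdefault(name, []).append(value)
    context_text = ", ".join(
        f"({name}: {', '.join(f'{v:g}' for v in values)})"
        for name, values in sorted(by_var.items())
    )
    prompt = EVPREDICT_INSTRUCTION_START + context_text + EVPREDICT_INSTRUCTION_END
    req = PromptRequest("ev_predict", prompt,
                        context={"tuples": sorted(by_var.items())}, seed=seed)
    out = complete(req, backend, audit=audit, stage="g", record_id=record_id)
    if not isinstance(out.parsed, (list, tuple)):
        raise BackendError("ev_predict output unparseable as an event tuple")
    return PredictedEvents(tuples=tuple(str(x) for x in out.parsed))


def check_vd(m: StaticEventData, predicted: PredictedEvents, backend: Backend,
             audit: Optional[AuditTrail] = None, seed: int = 0,
             record_id: Optional[str] = None) -> int:
    """Same-patient consistency verdict between predicted and constrained
    static events (both in tuple form)."""
    reference = tuple(e.code for e in m.events)
    prompt = (f"Do the predicted events {predicted.tuples} and the recorded "
              f"events {reference} plausibly come from the same patient?")
    req = PromptRequest("ts_assure", prompt,
                        context={"predicted": list(predicted.tuples),
                                 "reference": list(reference)},
                        seed=seed)
    out = complete(req, backend, audit=audit, stage="h", record_id=record_id)
    return 1 if out.parsed else 0


# ---------------------------------------------------------------------------
# assembly

def assemble_record(m: StaticEventData, t: TemporalSeries, verdict: QAVerdict,
                    patient_id: str = "synthetic-0",
                    visit_time: str = "2000-01-01T00:00:00") -> Optional[PatientRecord]:
    """Final assembly: one visit joining the two modalities, iff all gates pass."""
    if not verdict.emit:
        return None
    return PatientRecord(patient_id=patient_id,
                         visits=[Visit(visit_time=visit_time, static=m, temporal=t)])


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class PipelineConfig:
    rag: RAGConfig = field(default_factory=RAGConfig)
    schema: ConditionSchema = field(default_factory=ConditionSchema)
    tau: float = 0.5
    cot_T: int = 2
    cot_k: int = 5
    attempt_budget_factor: int = 10
    visit_time: str = "2000-01-01T00:00:00"


def _backend_for(backends: Union[Backend, dict], role: str) -> Backend:
    if isinstance(backends, dict):
        return backends[role]
    return backends


def run_pipeline(n_target: int, source: Dataset, g: HealthKnowledgeGraph,
                 model: GANModel, backends: Union[Backend, dict],
                 cfg: Optional[PipelineConfig] = None, seed: int = 0,
                 ) -> tuple[Dataset, AuditTrail, dict]:
    """Generate ``n_target`` fully constrained records; returns the dataset,
    the audit trail, and exact discard accounting
    (attempts = emitted + judge_rejected + cc1 + cc2 + vd discards)."""
    cfg = cfg or PipelineConfig()
    audit = AuditTrail(config={"seed": seed, "n_target": n_target,
                               "rag": vars(cfg.rag), "tau": cfg.tau})
    stats = {"attempts": 0, "emitted": 0, "judge_rejected": 0,
             "cc1_discarded": 0, "cc2_discarded": 0, "vd_discarded": 0,
             "budget_exhausted": False, "emitted_records": []}
    out = Dataset(schema={"variables": list(model.variables),
                          "labels": list(cfg.schema.labels)})
    budget = cfg.attempt_budget_factor * max(n_target, 1)
    attempt = 0
    while stats["emitted"] < n_target and attempt < budget:
        attempt += 1
        stats["attempts"] += 1
        rid = f"rec-{attempt:05d}"
        step_seed = (seed * 7_919 + attempt) % (2**31)

        c = sample_demographics(source, seed=step_seed)
        c_ok = judge_demographics(c, _backend_for(backends, "judge"),
                                  audit=audit, seed=step_seed, record_id=rid)
        if c_ok is None:
            stats["judge_rejected"] += 1
            continue

        index_condition = sample_index_condition(source, seed=step_seed)

        def cc1_check(m: StaticEventData, first_pass: bool):
            return validate_event_sequence(
                m, g, _backend_for(backends, "cot_reasoner"),
                first_pass=first_pass, tau=cfg.tau, T=cfg.cot_T, k=cfg.cot_k,
                audit=audit, seed=step_seed, record_id=rid)

        rag_cfg = replace(cfg.rag, seed=step_seed)
        m2 = generate_with_feedback(c_ok, g, rag_cfg,
                                    _backend_for(backends, "generator"),
                                    cc1_check, index_condition=index_condition,
                                    audit=audit, record_id=rid)
        if m2 is None:
            stats["cc1_discarded"] += 1
            continue

        cond = summarize_condition(m2, cfg.schema)
        t_prime = generate_temporal(model, cond, 1, seed=step_seed)[0]
        cc2, violations = check_cc2(t_prime, g, cfg.tau)
        audit.append("f", f"CC2 range check for {rid}",
                     "; ".join(violations) or "all values in range",
                     verdict=cc2, record_id=rid)
        if cc2 == 0:
            stats["cc2_discarded"] += 1
            continue
        t_prime.qa_status = QA_CONSTRAINED

        try:
            predicted = predict_events(t_prime, _backend_for(backends, "ev_predict"),
                                       audit=audit, seed=step_seed, record_id=rid)
            vd = check_vd(m2, predicted, _backend_for(backends, "ts_assure"),
                          audit=audit, seed=step_seed, record_id=rid)
        except BackendError:
            vd = 0
        if vd == 0:
            stats["vd_discarded"] += 1
            continue

        verdict = QAVerdict(cc1=1, cc2=1, vd=1)
        record = assemble_record(m2, t_prime, verdict,
                                 patient_id=f"synthetic-{stats['emitted']:05d}",
                                 visit_time=cfg.visit_time)
        assert record is not None
        out.patients.append(record)
        stats["emitted_records"].append({"patient_id": record.patient_id, "record_id": rid})
        stats["emitted"] += 1
    stats["budget_exhausted"] = stats["emitted"] < n_target
    return out, audit, stats


def recheck_record(record: PatientRecord, g: HealthKnowledgeGraph,
                   backends: Union[Backend, dict], tau: float = 0.5,
                   cot_T: int = 2, cot_k: int = 5, seed: int = 0) -> QAVerdict:
    """Independently re-run the three gates on an emitted record."""
    verdict = QAVerdict()
    visit = record.visits[0]
    cc1, verdicts = validate_event_sequence(
        visit.static, g, _backend_for(backends, "cot_reasoner"),
        first_pass=False, tau=tau, T=cot_T, k=cot_k, seed=seed)
    verdict.cc1 = cc1
    verdict.reasons += [r for _, ok, r in verdicts if not ok]
    cc2, violations = check_cc2(visit.temporal, g, tau)
    verdict.cc2 = cc2
    verdict.reasons += violations
    try:
        predicted = predict_events(visit.temporal, _backend_for(backends, "ev_predict"),
                                   seed=seed)
        verdict.vd = check_vd(visit.static, predicted,
                              _backend_for(backends, "ts_assure"), seed=seed)
    except (BackendError, ValueError) as exc:
        verdict.vd = 0
        verdict.reasons.append(str(exc))
    return verdict
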