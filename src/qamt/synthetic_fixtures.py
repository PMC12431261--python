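"""Seeded toy fixtures: a small health knowledge graph and patient cohorts
with planted structure, so every pipeline stage and metric is testable
without any restricted clinical dataset.

The planted structure mirrors what the quality gates look for:

* event sequences are random walks along the graph's disease-progression
  chains, so they are logically consistent (CC1-true) by construction;
* temporal values are Normal(range midpoint + per-diagnosis shift, noise std)
  clipped inside the declared value ranges (CC2-true by construction);
* each diagnosis shifts the mean of one designated variable, planting the
  variable->diagnosis dependency the VD gate relies on.

``plant_violations`` corrupts a known subset of records per violation kind
(range, logic, dependency) and returns the ground-truth labels, turning the
cohort into an exact confusion-matrix oracle for the QA suite.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .data_model import (ClinicalEvent, Dataset, PatientRecord, StaticEventData,
                         TemporalPoint, TemporalSeries, Visit, QA_CONSTRAINED)
from .knowledge_graph import HealthKnowledgeGraph, KGEdge, KGNode, save_kg
from .temporal_gan import ConditionSchema

DEFAULT_VARIABLES: dict[str, tuple[float, float, str]] = {
    "heart_rate": (40.0, 180.0, "bpm"),
    "systolic_bp": (70.0, 200.0, "mmHg"),
    "diastolic_bp": (40.0, 120.0, "mmHg"),
    "respiratory_rate": (5.0, 45.0, "breaths/min"),
    "spo2": (60.0, 100.0, "%"),
    "glucose": (50.0, 400.0, "mg/dL"),
    "creatinine": (0.1, 15.0, "mg/dL"),
    "lactate": (0.0, 20.0, "mmol/L"),
}

DEFAULT_LABELS = [
    "Prediabetes", "Type 2 Diabetes Mellitus", "Heart Failure",
    "Hypertension", "COPD", "Pneumonia", "Sepsis",
]

DEFAULT_CHAINS = [
    ["Prediabetes", "Type 2 Diabetes Mellitus", "Heart Failure"],
    ["Hypertension", "Heart Failure"],
    ["COPD", "Pneumonia", "Sepsis"],
]

# non-uniform chain prevalence so n-gram probabilities are non-degenerate
DEFAULT_CHAIN_WEIGHTS = [0.4, 0.3, 0.3]

# which variable each diagnosis shifts (the planted VD signal)
DEFAULT_SHIFT_VARIABLES = {
    "Prediabetes": "glucose",
    "Type 2 Diabetes Mellitus": "creatinine",
    "Heart Failure": "lactate",
    "Hypertension": "systolic_bp",
    "COPD": "respiratory_rate",
    "Pneumonia": "heart_rate",
    "Sepsis": "diastolic_bp",
}

DEMOGRAPHIC_CATEGORIES = {
    "gender": ["F", "M"],
    "ethnicity": ["Asian", "Black", "White"],
    "marital_status": ["DIVORCED", "MARRIED", "SINGLE", "WIDOWED"],
}

_AGES = [5, 12, 30, 45, 60, 75, 85]
_AGE_PROBS = [0.05, 0.05, 0.2, 0.2, 0.2, 0.2, 0.1]


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", text).strip("_")


@dataclass
class FixtureSpec:
    """Declarative toy-scale study conditions."""

    n_patients: int = 200
    variables: dict[str, tuple[float, float, str]] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLES))
    labels: list[str] = field(default_factory=lambda: list(DEFAULT_LABELS))
    chains: list[list[str]] = field(default_factory=lambda: [list(c) for c in DEFAULT_CHAINS])
    shift_variables: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SHIFT_VARIABLES))
    chain_weights: list[float] = field(
        default_factory=lambda: list(DEFAULT_CHAIN_WEIGHTS))
    shift: float = 3.0
    noise_std: float = 1.0
    multi_visit_fraction: float = 0.25
    n_time_points: int = 8
    grid_hours: int = 6

    def __post_init__(self) -> None:
        # chains must be acyclic and over declared labels
        for chain in self.chains:
            if len(set(chain)) != len(chain):
                raise ValueError(f"chain has a repeated label: {chain}")
            for label in chain:
                if label not in self.labels:
                    raise ValueError(f"chain label {label!r} not in label vocabulary")
        for label, var in self.shift_variables.items():
            lo, hi, _ = self.variables[var]
            mid = 0.5 * (lo + hi)
            if not (lo < mid + self.shift < hi):
                raise ValueError(f"shift for {label!r} pushes {var!r} outside its range")

    def midpoint(self, var: str) -> float:
        lo, hi, _ = self.variables[var]
        return 0.5 * (lo + hi)

    def shifted_mean(self, var: str, outcome_labels: set[str]) -> float:
        mean = self.midpoint(var)
        for label in outcome_labels:
            if self.shift_variables.get(label) == var:
                mean += self.shift
        return mean

    def condition_schema(self) -> ConditionSchema:
        return ConditionSchema(
            categorical_fields={k: list(v) for k, v in DEMOGRAPHIC_CATEGORIES.items()},
            labels=list(self.labels),
        )

    def mock_rules(self) -> dict:
        """Rules for the mock backend inverting the planted variable map."""
        profiles = {
            label: {var: self.midpoint(var) + self.shift}
            for label, var in self.shift_variables.items()
        }
        return {
            "diagnosis_profiles": profiles,
            "variable_baselines": {v: self.midpoint(v) for v in self.variables},
        }


# ---------------------------------------------------------------------------
# toy knowledge graph

def make_toy_kg(spec: Optional[FixtureSpec] = None,
                out_dir: Optional[str | Path] = None) -> HealthKnowledgeGraph:
    """Disease concepts with progression chains, clinical indicators with
    value-range constraints, and a few symptom/medication concepts."""
    spec = spec or FixtureSpec()
    g = HealthKnowledgeGraph()
    for label in spec.labels:
        g.add_node(KGNode(f"DIS:{_slug(label)}", "concept", "Dis", label))
    for var, (lo, hi, units) in spec.variables.items():
        g.add_node(KGNode(f"CI:{var}", "concept", "CI", var.replace("_", " ")))
        g.add_node(KGNode(f"CC:{var}", "concept", "CC", f"{lo:g}-{hi:g} {units}",
                          payload={"lower": lo, "upper": hi, "units": units}))
        g.add_edge(KGEdge(f"CI:{var}", "constraints", f"CC:{var}"))
    # canonical blood-gas indicator with its textbook range
    g.add_node(KGNode("CI:pao2", "concept", "CI", "PaO2"))
    g.add_node(KGNode("CC:pao2", "concept", "CC", "20-50 mmHg",
                      payload={"lower": 20.0, "upper": 50.0, "units": "mmHg"}))
    g.add_edge(KGEdge("CI:pao2", "constraints", "CC:pao2"))
    for chain in spec.chains:
        for a, b in zip(chain, chain[1:]):
            g.add_edge(KGEdge(f"DIS:{_slug(a)}", "progresses_to", f"DIS:{_slug(b)}"))
    for label, var in spec.shift_variables.items():
        g.add_edge(KGEdge(f"DIS:{_slug(label)}", "indicated_by", f"CI:{var}"))
    g.add_node(KGNode("SYM:fever", "concept", "Sym", "fever"))
    g.add_node(KGNode("MED:beta_agonist", "concept", "Med", "beta agonist"))
    for dis in ("COPD", "Pneumonia"):
        if dis in spec.labels:
            g.add_edge(KGEdge(f"DIS:{_slug(dis)}", "has_symptom", "SYM:fever"))
    if "COPD" in spec.labels:
        g.add_edge(KGEdge("SYM:fever", "cause", "DIS:COPD"))
        g.add_edge(KGEdge("DIS:COPD", "is_treated_by", "MED:beta_agonist"))
        g.add_edge(KGEdge("MED:beta_agonist", "treated", "DIS:COPD"))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_kg(g, out_dir / "nodes.csv", out_dir / "edges.csv")
    return g


# ---------------------------------------------------------------------------
# cohort generation

def _sample_demographics(rng: np.random.Generator) -> dict:
    age = int(rng.choice(_AGES, p=_AGE_PROBS))
    cov = {
        "age": age,
        "gender": str(rng.choice(DEMOGRAPHIC_CATEGORIES["gender"])),
        "ethnicity": str(rng.choice(DEMOGRAPHIC_CATEGORIES["ethnicity"])),
    }
    if age < 16:
        cov["marital_status"] = "SINGLE"  # keep demographics internally consistent
    else:
        cov["marital_status"] = str(rng.choice(DEMOGRAPHIC_CATEGORIES["marital_status"]))
    return cov


def _walk(spec: FixtureSpec, rng: np.random.Generator,
          start: Optional[tuple[int, int]] = None) -> tuple[list[str], tuple[int, int]]:
    """Random walk along a progression chain, never starting at a terminal."""
    if start is None:
        w = np.asarray(spec.chain_weights, dtype=float)
        ci = int(rng.choice(len(spec.chains), p=w / w.sum()))
        chain = spec.chains[ci]
        si = int(rng.integers(len(chain) - 1))
    else:
        ci, si = start
        chain = spec.chains[ci]
    length = int(rng.integers(2, 4))  # 2 or 3 events
    events = chain[si:si + length]
    return events, (ci, si + len(events) - 1)


def _temporal_series(spec: FixtureSpec, outcomes: set[str],
                     rng: np.random.Generator) -> TemporalSeries:
    points = []
    for step in range(spec.n_time_points):
        meas = []
        for var in spec.variables:
            lo, hi, _ = spec.variables[var]
            mean = spec.shifted_mean(var, outcomes)
            value = float(np.clip(rng.normal(mean, spec.noise_std), lo, hi))
            meas.append((var, value))
        points.append(TemporalPoint(step * spec.grid_hours, meas))
    return TemporalSeries(points=points, qa_status=QA_CONSTRAINED)


def make_cohort(spec: Optional[FixtureSpec] = None,
                seed: int = 0) -> Dataset:
    """Toy cohort with planted chains, ranges and dependencies (see module
    docstring); pure function of (spec, seed)."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(spec.n_patients):
        cov = _sample_demographics(rng)
        events, last_pos = _walk(spec, rng)
        visits = [_make_visit("2023-01-01T00:00:00", cov, events, spec, rng)]
        if rng.random() < spec.multi_visit_fraction:
            ci, si = last_pos
            chain = spec.chains[ci]
            if si + 1 < len(chain):
                events2 = chain[si + 1:si + 3]
            else:
                events2, _ = _walk(spec, rng)
            visits.append(_make_visit("2023-02-01T00:00:00", cov, events2, spec, rng))
        patients.append(PatientRecord(patient_id=f"P{i:04d}", visits=visits))
    return Dataset(patients=patients,
                   schema={"variables": sorted(spec.variables),
                           "labels": list(spec.labels)})


def _make_visit(visit_time: str, cov: dict, events: list[str],
                spec: FixtureSpec, rng: np.random.Generator) -> Visit:
    outcomes = set(events)
    static = StaticEventData(
        covariates=dict(cov),
        outcomes=outcomes,
        events=[ClinicalEvent(code, 24 * j) for j, code in enumerate(events)],
        qa_status=QA_CONSTRAINED,
    )
    return Visit(visit_time=visit_time, static=static,
                 temporal=_temporal_series(spec, outcomes, rng))


def training_pairs(cohort: Dataset, schema: ConditionSchema,
                   ) -> list[tuple[TemporalSeries, np.ndarray]]:
    """(series, condition-vector) pairs from first visits, for model training."""
    pairs = []
    for p in cohort.patients:
        if p.visits:
            v = p.visits[0]
            pairs.append((v.temporal, schema.encode(v.static)))
    return pairs


# ---------------------------------------------------------------------------
# violation planting

VIOLATION_KINDS = ("range", "logic", "dependency")


def _reachable_labels(first: str, spec: FixtureSpec,
                      g: Optional[HealthKnowledgeGraph], depth: int = 2) -> set[str]:
    """Labels reachable from ``first`` within ``depth`` hops — these would be
    legitimately accepted by depth-``depth`` reasoning, so logic corruption
    must avoid them."""
    if g is not None:
        by_label = {n.label: n.node_id for n in g.nodes.values()}
        frontier = {by_label.get(first)}
        reached: set[str] = set()
        for _ in range(depth):
            nxt = {e.target for e in g.edges if e.source in frontier}
            reached |= nxt
            frontier = nxt
        return {g.nodes[nid].label for nid in reached if nid in g.nodes}
    succ: dict[str, set[str]] = {}
    for chain in spec.chains:
        for a, b in zip(chain, chain[1:]):
            succ.setdefault(a, set()).add(b)
    frontier, reached = {first}, set()
    for _ in range(depth):
        nxt = {b for a in frontier for b in succ.get(a, ())}
        reached |= nxt
        frontier = nxt
    return reached


def plant_violations(d: Dataset, kind: str, fraction: float, seed: int = 0,
                     spec: Optional[FixtureSpec] = None,
                     g: Optional[HealthKnowledgeGraph] = None,
                     ) -> tuple[Dataset, list[str]]:
    """Corrupt a seeded subset of records; returns (corrupted dataset,
    ground-truth corrupted patient ids).

    * ``range`` — push one measurement below its declared lower bound;
    * ``logic`` — replace the second event with a label the graph does not
      support as a successor (directly or transitively within the reasoning
      depth) of the first;
    * ``dependency`` — relabel the record with a diagnosis whose planted
      variable signature the (unchanged) temporal data contradicts.
    """
    if kind not in VIOLATION_KINDS:
        raise ValueError(f"unknown violation kind {kind!r}")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    spec = spec or FixtureSpec()
    out = copy.deepcopy(d)
    rng = np.random.default_rng(seed)
    n_corrupt = max(1, round(fraction * len(out.patients)))
    chosen = sorted(rng.choice(len(out.patients), size=n_corrupt, replace=False).tolist())
    corrupted_ids = []
    for idx in chosen:
        p = out.patients[idx]
        visit = p.visits[0]
        if kind == "range":
            var, value = visit.temporal.points[0].measurements[0]
            lo = spec.variables[var][0]
            visit.temporal.points[0].measurements[0] = (var, lo - 10.0)
        elif kind == "logic":
            first = visit.static.events[0].code
            reachable = _reachable_labels(first, spec, g)
            bad_choices = [l for l in spec.labels
                           if l != first and l not in reachable]
            bad = str(rng.choice(bad_choices))
            if len(visit.static.events) >= 2:
                old = visit.static.events[1]
                visit.static.events[1] = ClinicalEvent(bad, old.timestamp, old.event_type)
                del visit.static.events[2:]
            else:
                visit.static.events.append(ClinicalEvent(bad, 24))
            visit.static.outcomes = {e.code for e in visit.static.events}
        else:  # dependency
            present = {e.code for e in visit.static.events}
            other = [l for l in spec.labels if l not in present]
            bad = str(rng.choice(other))
            visit.static.events = [ClinicalEvent(bad, 0)]
            visit.static.outcomes = {bad}
        corrupted_ids.append(p.patient_id)
    return out, corrupted_ids


# ---------------------------------------------------------------------------
# retrieval-feedback fixture

def make_feedback_fixture() -> tuple[HealthKnowledgeGraph, dict, str]:
    """Graph, demographics and index condition engineered so that only the
    expanded retrieval width (top-10) surfaces the valid successor event.

    With the default width (top-5), object ranking by frequency then id keeps
    a decoy diagnosis and four symptoms, so the first generation fails CC1;
    the widened retrieval includes the true successor and the retry passes.
    """
    g = HealthKnowledgeGraph()
    g.add_node(KGNode("n00_start", "concept", "Dis", "Renal Stage One"))
    g.add_node(KGNode("n99_follow", "concept", "Dis", "Renal Stage Two"))
    g.add_node(KGNode("n01_decoy", "concept", "Dis", "Gallstone Disease"))
    g.add_node(KGNode("n0_link", "concept", "Sym", "Flank Pain"))
    g.add_edge(KGEdge("n00_start", "progresses_to", "n99_follow"))
    g.add_edge(KGEdge("n0_link", "cause", "n01_decoy"))
    for i in range(2, 7):
        g.add_node(KGNode(f"n{i:02d}_sym", "concept", "Sym", f"Renal Sign {i - 1}"))
        g.add_edge(KGEdge("n00_start", "has_symptom", f"n{i:02d}_sym"))
    demographics = {"age": 50, "gender": "F", "marital_status": "MARRIED",
                    "complaint": "Flank Pain"}
    return g, demographics, "Renal Stage One"
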