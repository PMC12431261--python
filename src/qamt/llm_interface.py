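"""Pluggable text-model backend contract and a deterministic KG-grounded mock.

Six model roles appear in the generation workflow:

* ``judge`` — plausibility check on sampled demographics;
* ``extractor`` — zero-shot entity recognition in a prompt;
* ``generator`` — few-shot static-event generation from retrieved context;
* ``cot_reasoner`` — answering from serialized knowledge-graph reasoning paths;
* ``ev_predict`` — predicting diagnoses from temporal measurements;
* ``ts_assure`` — judging whether two event-tuple sets plausibly describe the
  same patient.

A backend is anything with ``complete(PromptRequest) -> Completion``.  The
shipped :class:`MockBackend` implements all six roles as pure functions of
(prompt text, structured context, seed) grounded in a supplied knowledge
graph, so the whole pipeline is exercisable offline and reproducibly.  Real
hosted models can be wired in through the same contract via a per-role
backend mapping in the run configuration; they are never required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol

import numpy as np

from .audit import AuditTrail
from .knowledge_graph import HealthKnowledgeGraph, token_similarity

ROLES = {"judge", "extractor", "generator", "cot_reasoner", "ev_predict", "ts_assure"}


class BackendError(RuntimeError):
    """Typed failure (timeout, refusal, unparseable output) from a backend."""


@dataclass(frozen=True)
class PromptRequest:
    role: str
    text: str
    context: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.text:
            raise ValueError("PromptRequest.text must be non-empty")


@dataclass(frozen=True)
class Completion:
    text: str
    parsed: Optional[object] = None
    backend_id: str = ""


class Backend(Protocol):
    def complete(self, req: PromptRequest) -> Completion: ...


def complete(req: PromptRequest, backend: Backend,
             audit: Optional[AuditTrail] = None, stage: str = "c",
             record_id: Optional[str] = None, retries: int = 1) -> Completion:
    """Run one backend call, retrying once on typed failure, and audit it."""
    last_exc: Optional[BackendError] = None
    for _ in range(retries + 1):
        try:
            out = backend.complete(req)
            if audit is not None:
                audit.append(stage, req.text, out.text, verdict=out.parsed,
                             record_id=record_id, detail={"role": req.role})
            return out
        except BackendError as exc:
            last_exc = exc
    if audit is not None:
        audit.append(stage, req.text, f"<error: {last_exc}>", record_id=record_id,
                     detail={"role": req.role})
    raise last_exc  # type: ignore[misc]


# ---------------------------------------------------------------------------
# mock backend

DEFAULT_MOCK_RULES: dict = {
    # demographic plausibility
    "min_partner_age": 16,
    "max_age": 120,
    "partnered_statuses": {"MARRIED", "DIVORCED", "WIDOWED", "SEPARATED"},
    # generator
    "n_events": 2,
    # ts_assure
    "jaccard_cutoff": 0.5,
    # ev_predict: filled from the fixture spec (diagnosis -> {variable: shifted mean})
    "diagnosis_profiles": {},
    "variable_baselines": {},
}


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass
class MockBackend:
    """Hermetic rule-table backend grounded in a knowledge graph.

    Pure given (request text, context, seed): no network, no filesystem
    writes, no hidden state.  Behaviour per role is documented on the
    corresponding ``_do_*`` method.
    """

    g: HealthKnowledgeGraph
    rules: dict = field(default_factory=dict)
    seed: int = 0
    backend_id: str = "mock"

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_MOCK_RULES)
        merged.update(self.rules)
        self.rules = merged

    # -- dispatch -----------------------------------------------------------

    def complete(self, req: PromptRequest) -> Completion:
        handler = getattr(self, f"_do_{req.role}")
        text, parsed = handler(req)
        return Completion(text=text, parsed=parsed, backend_id=self.backend_id)

    def _rng(self, req: PromptRequest) -> np.random.Generator:
        # derive from both the backend seed and the request seed so distinct
        # requests with the same backend differ but remain reproducible
        return np.random.default_rng((self.seed * 1_000_003 + req.seed) % (2**31))

    # -- roles --------------------------------------------------------------

    def _do_judge(self, req: PromptRequest) -> tuple[str, bool]:
        """Declarative plausibility rules on demographics (age range,
        age/marital-status consistency)."""
        cov = (req.context or {}).get("covariates", {})
        ok = True
        reasons = []
        age = cov.get("age")
        if age is not None:
            try:
                age = float(age)
            except (TypeError, ValueError):
                ok, age = False, None
                reasons.append("age not numeric")
        if age is not None:
            if not (0 <= age <= self.rules["max_age"]):
                ok = False
                reasons.append(f"age {age} outside [0, {self.rules['max_age']}]")
            status = str(cov.get("marital_status", "")).upper()
            if age < self.rules["min_partner_age"] and status in self.rules["partnered_statuses"]:
                ok = False
                reasons.append(f"age {age} inconsistent with marital status {status}")
        text = "PASS" if ok else "FAIL: " + "; ".join(reasons)
        return text, ok

    def _do_extractor(self, req: PromptRequest) -> tuple[str, list[str]]:
        """Longest-match dictionary scan of KG node labels over the prompt."""
        text_lower = req.text.lower()
        labels = sorted({n.label for n in self.g.nodes.values() if n.label},
                        key=lambda s: (-len(s), s))
        found: list[tuple[int, str]] = []
        claimed = [False] * len(text_lower)
        for label in labels:
            start = 0
            needle = label.lower()
            while True:
                pos = text_lower.find(needle, start)
                if pos < 0:
                    break
                if not any(claimed[pos:pos + len(needle)]):
                    for j in range(pos, pos + len(needle)):
                        claimed[j] = True
                    found.append((pos, label))
                start = pos + 1
        found.sort()
        mentions = [label for _, label in found]
        return ", ".join(mentions), mentions

    def _do_cot_reasoner(self, req: PromptRequest) -> tuple[str, list[str]]:
        """Answer with the terminal labels of the reasoning paths shown."""
        paths = (req.context or {}).get("paths", [])
        terminals: list[str] = []
        for hops in paths:
            if hops:
                terminals.append(hops[-1][2])
        terminals = sorted(set(terminals))
        return ", ".join(terminals), terminals

    def _do_generator(self, req: PromptRequest) -> tuple[str, dict]:
        """Sample outcomes and an event chain from the retrieved few-shot
        objects, anchored at the prompt's index condition when it names a
        disease concept and preferring knowledge-graph-supported successors."""
        ctx = req.context or {}
        objects = list(ctx.get("objects", []))  # (object_id, label, count)
        n_events = int(ctx.get("n_events", self.rules["n_events"]))
        dis = [(oid, label) for oid, label, _ in objects
               if oid in self.g.nodes and self.g.nodes[oid].subtype == "Dis"]
        rng = self._rng(req)
        index_condition = ctx.get("index_condition")
        anchor = None
        if index_condition:
            by_label = {n.label: n for n in self.g.nodes.values() if n.subtype == "Dis"}
            if index_condition in by_label:
                node = by_label[index_condition]
                anchor = (node.node_id, node.label)
        if anchor is None:
            if not dis:
                raise BackendError("no disease object in retrieved context")
            order = rng.permutation(len(dis))
            anchor = dis[order[0]]
        current_id, current_label = anchor
        events = [current_label]
        used = {current_id}
        for _ in range(n_events - 1):
            successors = sorted(
                t for s, r, t in ((e.source, e.relation, e.target) for e in self.g.edges)
                if s == current_id and r == "progresses_to" and t not in used
            )
            in_ctx = [t for t in successors if any(oid == t for oid, _, _ in objects)]
            if in_ctx:
                nxt = in_ctx[int(rng.integers(len(in_ctx)))]
            else:
                remaining = [d for d in dis if d[0] not in used]
                if not remaining:
                    break
                nxt = remaining[int(rng.integers(len(remaining)))][0]
            used.add(nxt)
            current_id = nxt
            events.append(self.g.nodes[nxt].label if nxt in self.g.nodes else nxt)
        parsed = {"outcomes": sorted(set(events)), "events": events}
        return "; ".join(events), parsed

    def _do_ev_predict(self, req: PromptRequest) -> tuple[str, list[str]]:
        """Invert a planted variable->diagnosis map: a diagnosis is predicted
        when every variable it shifts has an observed mean closer to the
        shifted profile than to the baseline."""
        tuples = (req.context or {}).get("tuples", [])
        means = {var: float(np.mean(values)) for var, values in tuples if len(values)}
        baselines = self.rules["variable_baselines"]
        predicted = []
        for diag, profile in sorted(self.rules["diagnosis_profiles"].items()):
            hits = 0
            total = 0
            for var, shifted_mean in profile.items():
                if var not in means or var not in baselines:
                    continue
                total += 1
                if abs(means[var] - shifted_mean) < abs(means[var] - baselines[var]):
                    hits += 1
            if total > 0 and hits == total:
                predicted.append(diag)
        return ", ".join(predicted), predicted

    def _do_ts_assure(self, req: PromptRequest) -> tuple[str, bool]:
        """Set-overlap verdict: same patient iff Jaccard of the two event-tuple
        sets reaches the configured cutoff."""
        ctx = req.context or {}
        a = {str(x).lower() for x in ctx.get("predicted", [])}
        b = {str(x).lower() for x in ctx.get("reference", [])}
        score = _jaccard(a, b)
        ok = score >= self.rules["jaccard_cutoff"]
        return f"{'CONSISTENT' if ok else 'INCONSISTENT'} (overlap={score:.3f})", ok


def mock_backend(g: HealthKnowledgeGraph, rules: Optional[dict] = None,
                 seed: int = 0) -> MockBackend:
    """Factory matching the documented backend contract."""
    return MockBackend(g=g, rules=rules or {}, seed=seed)


def similarity_of_labels(a: str, b: str) -> float:
    """Convenience re-export of the default deterministic similarity."""
    return token_similarity(a, b)
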