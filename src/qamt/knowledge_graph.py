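"""Typed health knowledge graph (HKG) with concept/instance views.

The HKG mixes three node kinds:

* **concept** nodes from curated vocabularies — diseases (``Dis``), symptoms
  (``Sym``), medications (``Med``), treatments (``Tre``), clinical indicators
  (``CI``) and clinical constraints (``CC``, carrying a numeric value range);
* **entity** nodes describing patients and context (age ``A``, ethnicity
  ``Eth``, location ``L``, time ``T``, event type ``ET``, ...);
* **event** nodes extracted from patient records.

The concept-only subgraph is the CKG (slowly updated, knowledge-base derived);
the entity+event subgraph is the IKG (record derived, frequently updated).
Edges follow a closed relation schema; loading rejects edges whose endpoint
kinds/subtypes the schema does not allow.

Node matching is similarity-based.  The default encoder is a deterministic
lowercase token-set representation scored with Jaccard similarity, so matching
is hermetic and reproducible; any callable mapping text to a token set (or a
vector-space encoder wrapped with its own similarity) can be plugged in
through the same contract.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

import networkx as nx

from .data_model import Dataset

logger = logging.getLogger(__name__)

CONCEPT_SUBTYPES = {"Dis", "Sym", "Med", "Tre", "CI", "CC"}
ENTITY_SUBTYPES = {"A", "Eth", "L", "T", "ET", "Patient", "Other"}
EVENT_SUBTYPES = {"Event"}

_KIND_SUBTYPES = {
    "concept": CONCEPT_SUBTYPES,
    "entity": ENTITY_SUBTYPES,
    "event": EVENT_SUBTYPES,
}

# Closed relation schema: relation -> (allowed source specs, allowed target specs).
# A spec is either a kind ("entity", "event") or a concept subtype ("Dis", ...),
# or a kind-qualified entity subtype ("entity:A").
EDGE_SCHEMA: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "has_symptom": (frozenset({"Dis"}), frozenset({"Sym"})),
    "is_treated_by": (frozenset({"Dis", "Sym"}), frozenset({"Med", "Tre"})),
    "indicated_by": (frozenset({"Dis"}), frozenset({"CI"})),
    "progresses_to": (frozenset({"Dis"}), frozenset({"Dis"})),
    "treated": (frozenset({"Med", "Tre"}), frozenset({"Dis", "Sym"})),
    "cause": (frozenset({"Sym"}), frozenset({"Dis"})),
    "measured": (frozenset({"CI"}), frozenset({"Dis"})),
    "constraints": (frozenset({"CI"}), frozenset({"CC"})),
    "conforms_to": (frozenset({"entity", "event"}), frozenset({"CC"})),
    "diagnoses": (frozenset({"event"}), frozenset({"Dis"})),
    "prescribes": (frozenset({"event"}), frozenset({"Med", "Tre"})),
    "associated_with": (frozenset({"event"}), frozenset({"CI"})),
    "participate_in": (frozenset({"entity"}), frozenset({"event"})),
    "associate_with": (frozenset({"entity:A", "entity:Eth", "entity:Other"}), frozenset({"event"})),
    "occurs_at": (frozenset({"event"}), frozenset({"entity:L"})),
    "time_is": (frozenset({"event"}), frozenset({"entity:T"})),
    "event_type_is": (frozenset({"event"}), frozenset({"entity:ET"})),
    "after": (frozenset({"event"}), frozenset({"event"})),
    "before": (frozenset({"event"}), frozenset({"event"})),
}


class KGSchemaError(ValueError):
    """Raised when nodes or edges violate the declared graph schema."""


@dataclass(frozen=True)
class KGNode:
    node_id: str
    kind: str  # concept | entity | event
    subtype: str
    label: str
    payload: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_SUBTYPES:
            raise KGSchemaError(f"node {self.node_id}: unknown kind {self.kind!r}")
        if self.subtype not in _KIND_SUBTYPES[self.kind]:
            raise KGSchemaError(
                f"node {self.node_id}: subtype {self.subtype!r} invalid for kind {self.kind!r}"
            )
        if self.subtype == "CC" and self.payload is not None:
            lo, hi = self.payload.get("lower"), self.payload.get("upper")
            if lo is None or hi is None or lo > hi:
                raise KGSchemaError(
                    f"CC node {self.node_id}: payload must carry lower <= upper, got {self.payload}"
                )


@dataclass(frozen=True)
class KGEdge:
    source: str
    relation: str
    target: str


@dataclass(frozen=True)
class ValueConstraint:
    """Permissible value range for a clinical indicator, e.g. PaO2 in 20-50 mmHg."""

    indicator: str  # CI node id
    lower: float
    upper: float
    units: str
    source_cc: str  # CC node id


# ---------------------------------------------------------------------------
# default deterministic encoder

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> frozenset[str]:
    return frozenset(_TOKEN_RE.findall(text.lower()))


def token_similarity(a: str, b: str) -> float:
    """Jaccard similarity of lowercase token sets; 1.0 for identical token sets."""
    ta, tb = tokenize(a), tokenize(b)
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


Similarity = Callable[[str, str], float]


@dataclass
class HealthKnowledgeGraph:
    nodes: dict[str, KGNode] = field(default_factory=dict)
    edges: list[KGEdge] = field(default_factory=list)
    similarity: Similarity = token_similarity

    def __post_init__(self) -> None:
        self._graph: Optional[nx.MultiDiGraph] = None

    # -- construction -------------------------------------------------------

    def add_node(self, node: KGNode) -> None:
        self.nodes[node.node_id] = node
        self._graph = None

    def add_edge(self, edge: KGEdge) -> None:
        self._check_edge(edge)
        self.edges.append(edge)
        self._graph = None

    def _node_specs(self, node: KGNode) -> set[str]:
        specs = {node.kind, f"{node.kind}:{node.subtype}"}
        if node.kind == "concept":
            specs.add(node.subtype)
        return specs

    def _check_edge(self, edge: KGEdge) -> None:
        if edge.relation not in EDGE_SCHEMA:
            raise KGSchemaError(f"unknown relation {edge.relation!r}")
        for endpoint in (edge.source, edge.target):
            if endpoint not in self.nodes:
                raise KGSchemaError(f"edge references missing node {endpoint!r}")
        src_allowed, tgt_allowed = EDGE_SCHEMA[edge.relation]
        if not (self._node_specs(self.nodes[edge.source]) & src_allowed):
            raise KGSchemaError(
                f"relation {edge.relation!r} forbids source "
                f"{self.nodes[edge.source].kind}/{self.nodes[edge.source].subtype}"
            )
        if not (self._node_specs(self.nodes[edge.target]) & tgt_allowed):
            raise KGSchemaError(
                f"relation {edge.relation!r} forbids target "
                f"{self.nodes[edge.target].kind}/{self.nodes[edge.target].subtype}"
            )

    # -- graph access -------------------------------------------------------

    def graph(self) -> nx.MultiDiGraph:
        """networkx view (cached); edge data carries the relation name."""
        if self._graph is None:
            g = nx.MultiDiGraph()
            for nid, node in self.nodes.items():
                g.add_node(nid, node=node)
            for e in self.edges:
                g.add_edge(e.source, e.target, relation=e.relation)
            self._graph = g
        return self._graph

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def copy(self) -> "HealthKnowledgeGraph":
        return HealthKnowledgeGraph(dict(self.nodes), list(self.edges), self.similarity)


# ---------------------------------------------------------------------------
# load / save

_RANGE_RE = re.compile(
    r"^\s*(-?\d+(?:\.\d+)?)\s*[-–—~]\s*(-?\d+(?:\.\d+)?)\s*(\S.*)?$"
)


def parse_cc_payload(text: str) -> dict:
    """Parse a textual constraint like ``"20-50 mmHg"`` (en-dash accepted)."""
    m = _RANGE_RE.match(text)
    if not m:
        raise KGSchemaError(f"malformed clinical-constraint payload: {text!r}")
    lo, hi = float(m.group(1)), float(m.group(2))
    if lo > hi:
        raise KGSchemaError(f"constraint lower > upper in {text!r}")
    return {"lower": lo, "upper": hi, "units": (m.group(3) or "").strip()}


def load_kg(nodes_path: str | Path, edges_path: str | Path,
            similarity: Similarity = token_similarity) -> HealthKnowledgeGraph:
    """Load a graph from the two-file CSV form (see docs of save_kg).

    CC node payloads may be given either as a JSON object with lower/upper/units
    or as the textual range form ``"20-50 mmHg"``; both parse to the same payload.
    """
    g = HealthKnowledgeGraph(similarity=similarity)
    with Path(nodes_path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            payload = None
            raw = (row.get("payload") or "").strip()
            if raw:
                if raw.startswith("{"):
                    payload = json.loads(raw)
                else:
                    payload = parse_cc_payload(raw)
            try:
                g.add_node(KGNode(row["node_id"], row["kind"], row["subtype"],
                                  row["label"], payload))
            except KGSchemaError as exc:
                raise KGSchemaError(f"{nodes_path} line {i}: {exc}") from exc
    with Path(edges_path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                g.add_edge(KGEdge(row["source"], row["relation"], row["target"]))
            except KGSchemaError as exc:
                raise KGSchemaError(f"{edges_path} line {i}: {exc}") from exc
    return g


def save_kg(g: HealthKnowledgeGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Write the two-file CSV form: nodes(node_id,kind,subtype,label,payload), edges(source,relation,target)."""
    with Path(nodes_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "kind", "subtype", "label", "payload"])
        for nid in sorted(g.nodes):
            n = g.nodes[nid]
            payload = json.dumps(n.payload, sort_keys=True) if n.payload is not None else ""
            w.writerow([n.node_id, n.kind, n.subtype, n.label, payload])
    with Path(edges_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "relation", "target"])
        for e in sorted(g.edges, key=lambda e: (e.source, e.relation, e.target)):
            w.writerow([e.source, e.relation, e.target])


# ---------------------------------------------------------------------------
# views

def ckg_view(g: HealthKnowledgeGraph) -> HealthKnowledgeGraph:
    """Concept knowledge graph: induced subgraph on concept nodes (no mutation)."""
    return _induced(g, {"concept"})


def ikg_view(g: HealthKnowledgeGraph) -> HealthKnowledgeGraph:
    """Instance knowledge graph: induced subgraph on entity and event nodes."""
    return _induced(g, {"entity", "event"})


def _induced(g: HealthKnowledgeGraph, kinds: set[str]) -> HealthKnowledgeGraph:
    nodes = {nid: n for nid, n in g.nodes.items() if n.kind in kinds}
    edges = [e for e in g.edges if e.source in nodes and e.target in nodes]
    return HealthKnowledgeGraph(nodes, edges, g.similarity)


# ---------------------------------------------------------------------------
# matching and retrieval

def match_node(text: str, g: HealthKnowledgeGraph, tau: float = 0.5,
               kinds: Optional[set[str]] = None,
               subtypes: Optional[set[str]] = None) -> Optional[tuple[KGNode, float]]:
    """Best similarity match of ``text`` against node labels, or None below ``tau``.

    Ties break on highest score then lexicographically smallest node id,
    making the result deterministic across runs and platforms.
    """
    if not text:
        raise ValueError("match_node: empty text")
    best: Optional[tuple[float, str]] = None
    for nid in sorted(g.nodes):
        node = g.nodes[nid]
        if kinds is not None and node.kind not in kinds:
            continue
        if subtypes is not None and node.subtype not in subtypes:
            continue
        score = g.similarity(text, node.label)
        if score > tau and (best is None or score > best[0]):
            best = (score, nid)
    if best is None:
        return None
    return g.nodes[best[1]], best[0]


def triples(g: HealthKnowledgeGraph, subjects: Iterable[str],
            relation_filter: Optional[str] = None) -> list[tuple[str, str, str]]:
    """Outgoing (subject, relation, object) triples of ``subjects``, stably ordered."""
    subject_set = set(subjects)
    unknown = subject_set - set(g.nodes)
    if unknown:
        raise KeyError(f"triples: unknown subject node(s) {sorted(unknown)}")
    out = [
        (e.source, e.relation, e.target)
        for e in g.edges
        if e.source in subject_set and (relation_filter is None or e.relation == relation_filter)
    ]
    out.sort()
    return out


def constraint_for_variable(name: str, g: HealthKnowledgeGraph,
                            tau: float = 0.5) -> Optional[ValueConstraint]:
    """Value range for a temporal variable, found by similarity match to a
    clinical-indicator concept and traversal of its ``constraints`` edge."""
    hit = match_node(name, g, tau, kinds={"concept"}, subtypes={"CI"})
    if hit is None:
        return None
    ci, _ = hit
    for _, _, cc_id in triples(g, [ci.node_id], relation_filter="constraints"):
        cc = g.nodes[cc_id]
        if cc.payload is None:
            continue
        return ValueConstraint(
            indicator=ci.node_id,
            lower=float(cc.payload["lower"]),
            upper=float(cc.payload["upper"]),
            units=str(cc.payload.get("units", "")),
            source_cc=cc.node_id,
        )
    logger.info("indicator %s matched for %r but has no constraints edge", ci.node_id, name)
    return None


# ---------------------------------------------------------------------------
# lightweight IKG construction from records

def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", text).strip("_")


def build_ikg_from_dataset(d: Dataset, g: HealthKnowledgeGraph,
                           tau: float = 0.5) -> HealthKnowledgeGraph:
    """Extend ``g`` with instance nodes/edges extracted from patient records.

    Adds one event node per clinical-event occurrence (deterministic ids
    ``EV:<patient>:<visit>:<index>:<code-slug>``), entity nodes for demographic
    values, ``associate_with`` edges from demographics to events, ``after``
    edges between consecutive events, and ``diagnoses`` edges to disease
    concepts whose label matches the event code above ``tau``.  Returns a new
    graph; ``g`` is not mutated.
    """
    out = g.copy()
    ent_subtype = {"age": "A", "ethnicity": "Eth", "location": "L"}
    for p in d.patients:
        for vi, visit in enumerate(p.visits):
            ent_ids = []
            for name, value in sorted(visit.static.covariates.items()):
                sub = ent_subtype.get(name, "Other")
                eid = f"ENT:{_slug(name)}:{_slug(str(value))}"
                if eid not in out.nodes:
                    out.add_node(KGNode(eid, "entity", sub, f"{name} {value}"))
                ent_ids.append(eid)
            prev_event_id = None
            for ei, event in enumerate(visit.static.events):
                evid = f"EV:{p.patient_id}:{vi}:{ei}:{_slug(event.code)}"
                out.add_node(KGNode(evid, "event", "Event", event.code))
                for eid in ent_ids:
                    out.add_edge(KGEdge(eid, "associate_with", evid))
                if prev_event_id is not None:
                    out.add_edge(KGEdge(evid, "after", prev_event_id))
                prev_event_id = evid
                hit = match_node(event.code, g, tau, kinds={"concept"}, subtypes={"Dis"})
                if hit is not None:
                    out.add_edge(KGEdge(evid, "diagnoses", hit[0].node_id))
    return out
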