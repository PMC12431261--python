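"""Step-by-step reasoning over the health knowledge graph and the CC1 gate.

The reasoner propagates an entity-state vector through per-step transition
matrices built from relation scores, accumulates top-k reasoning paths by
beam search, serializes them into a prompt, and asks a backend to answer from
those paths.  The CC1 quality gate applies this machinery to a generated
event sequence: each event is turned into a question, and the sequence passes
only if, for every consecutive pair, the answer reachable from the earlier
event contains the later event's linked entity.

Reasoning state
---------------
* entity state ``e_0`` is an indicator vector over the graph's nodes (sorted
  node-id order), ``e_t = e_{t-1} W_t``;
* ``W_t[u, v]`` accumulates the relation score of every edge (u, r, v); rows
  whose mass exceeds 1 are L1-normalized so the state stays inside [0, 1];
* a path's score is the product of its per-hop relation scores; ties break on
  the lexicographic node-id sequence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .audit import AuditTrail
from .data_model import StaticEventData
from .knowledge_graph import HealthKnowledgeGraph, match_node, tokenize
from .llm_interface import Backend, Completion, PromptRequest, complete

QUESTION_EMBED_DIM = 32


def embed_question(text: str, dim: int = QUESTION_EMBED_DIM) -> np.ndarray:
    """Deterministic hashed bag-of-tokens embedding (L2-normalized)."""
    v = np.zeros(dim)
    for tok in tokenize(text):
        h = int(hashlib.md5(tok.encode()).hexdigest(), 16)
        v[h % dim] += 1.0
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


@dataclass
class QuestionContext:
    """A question, its embedding q, the step count T and the per-step
    transform f_t producing q_t (identity by default)."""

    question: str
    q: np.ndarray = field(default=None)  # type: ignore[assignment]
    T: int = 2
    f_t: Callable[[np.ndarray, int], np.ndarray] = staticmethod(lambda q, t: q)

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.q is None:
            self.q = embed_question(self.question)


class RelationScorer(Protocol):
    def score(self, q_t: np.ndarray, relation: str) -> float: ...


@dataclass
class TokenOverlapScorer:
    """Default untrained relation scorer: Jaccard overlap between the question
    tokens and the relation-name tokens, plus-one smoothed so every edge keeps
    strictly positive mass.  A trainable scorer can replace it through the
    same contract."""

    question: str

    def __post_init__(self) -> None:
        self._q_tokens = tokenize(self.question)

    def score(self, q_t: np.ndarray, relation: str) -> float:
        r_tokens = tokenize(relation.replace("_", " "))
        if not self._q_tokens or not r_tokens:
            overlap = 0.0
        else:
            overlap = len(self._q_tokens & r_tokens) / len(self._q_tokens | r_tokens)
        return 1.0 + overlap


@dataclass
class EntityState:
    """Confidence in [0,1] per graph node, aligned with ``node_order``."""

    values: np.ndarray
    node_order: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.node_order):
            raise ValueError("state length must equal number of nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("entity state contains non-finite entries")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("entity state entries must lie in [0, 1]")


@dataclass(frozen=True)
class ReasoningPath:
    hops: tuple[tuple[str, str, str], ...]  # (node_id, relation, node_id)
    score: float

    def __post_init__(self) -> None:
        for a, b in zip(self.hops, self.hops[1:]):
            if a[2] != b[0]:
                raise ValueError("reasoning-path hops must chain")

    def node_ids(self) -> tuple[str, ...]:
        if not self.hops:
            return ()
        return (self.hops[0][0],) + tuple(h[2] for h in self.hops)


def init_entity_state(question_entities: Sequence[str], g: HealthKnowledgeGraph) -> EntityState:
    order = g.node_ids()
    unknown = set(question_entities) - set(order)
    if unknown:
        raise KeyError(f"entities not in graph: {sorted(unknown)}")
    idx = {nid: i for i, nid in enumerate(order)}
    v = np.zeros(len(order))
    for nid in question_entities:
        v[idx[nid]] = 1.0
    return EntityState(v, order)


def transition_matrix(g: HealthKnowledgeGraph, q_t: np.ndarray,
                      scorer: RelationScorer) -> np.ndarray:
    """W_t[u, v] = sum of relation scores over edges (u, r, v); rows whose
    outgoing mass exceeds 1 are L1-normalized (argmax ordering preserved)."""
    order = g.node_ids()
    idx = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    w = np.zeros((n, n))
    for e in g.edges:
        s = scorer.score(q_t, e.relation)
        if s < 0:
            raise ValueError(f"relation scorer returned negative score for {e.relation!r}")
        w[idx[e.source], idx[e.target]] += s
    row_sums = w.sum(axis=1)
    over = row_sums > 1.0
    w[over] = w[over] / row_sums[over, None]
    return w


def reason_steps(state: EntityState, ctx: QuestionContext, g: HealthKnowledgeGraph,
                 scorer: RelationScorer) -> EntityState:
    """Propagate e_t = e_{t-1} W_t for T steps; the input state is not mutated."""
    e = state.values.copy()
    for t in range(1, ctx.T + 1):
        q_t = ctx.f_t(ctx.q, t)
        w = transition_matrix(g, q_t, scorer)
        e = e @ w
        if not np.all(np.isfinite(e)):
            raise FloatingPointError(f"non-finite entity state at step {t}")
    return EntityState(np.clip(e, 0.0, 1.0), list(state.node_order))


def generate_paths(g: HealthKnowledgeGraph, start: Sequence[str], ctx: QuestionContext,
                   scorer: RelationScorer, k: int = 5) -> list[ReasoningPath]:
    """Top-k simple reasoning paths of length 1..T from the start entities.

    Beam search keeps the k best partial paths at each step and adds every
    step's beam to the candidate pool, so shorter completed paths compete with
    longer ones.  Scores multiply per hop; ties break on the lexicographic
    node-id sequence.  With beam width at least the number of partial paths at
    every step, the result equals exhaustive enumeration of simple paths.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    unknown = set(start) - set(g.nodes)
    if unknown:
        raise KeyError(f"start entities not in graph: {sorted(unknown)}")
    out_edges: dict[str, list[tuple[str, str]]] = {}
    for e in g.edges:
        out_edges.setdefault(e.source, []).append((e.relation, e.target))
    for lst in out_edges.values():
        lst.sort(key=lambda rt: (rt[1], rt[0]))

    def order_key(item: tuple[tuple[tuple[str, str, str], ...], float]):
        hops, score = item
        nodes = (hops[0][0],) + tuple(h[2] for h in hops) if hops else ()
        return (-score, nodes)

    # seed one empty partial per start node by tracking the frontier node
    frontier: list[tuple[str, tuple[tuple[str, str, str], ...], float]] = [
        (nid, (), 1.0) for nid in sorted(set(start))
    ]
    candidates: dict[tuple[tuple[str, str, str], ...], float] = {}
    for t in range(1, ctx.T + 1):
        q_t = ctx.f_t(ctx.q, t)
        extended: list[tuple[str, tuple[tuple[str, str, str], ...], float]] = []
        for node, hops, score in frontier:
            visited = {node} | {h[0] for h in hops} | {h[2] for h in hops}
            for rel, tgt in out_edges.get(node, []):
                if tgt in visited:
                    continue  # simple paths only
                s = scorer.score(q_t, rel)
                extended.append((tgt, hops + ((node, rel, tgt),), score * s))
        extended.sort(key=lambda it: order_key((it[1], it[2])))
        frontier = extended[:k]
        for _, hops, score in frontier:
            candidates[hops] = score
    ranked = sorted(candidates.items(), key=order_key)[:k]
    return [ReasoningPath(hops, score) for hops, score in ranked]


PATH_INSTRUCTION = (
    "Answer the question using only the reasoning paths below. "
    "List every entity the paths support as the answer.\n"
)


def serialize_paths(paths: Sequence[ReasoningPath], g: HealthKnowledgeGraph) -> str:
    """One deterministic line per path: ``A relation B relation C`` (labels)."""
    lines = [PATH_INSTRUCTION.rstrip()]
    for p in paths:
        parts: list[str] = []
        for i, (s, r, o) in enumerate(p.hops):
            if i == 0:
                parts.append(g.nodes[s].label if s in g.nodes else s)
            parts.append(r)
            parts.append(g.nodes[o].label if o in g.nodes else o)
        lines.append(" ".join(parts))
    return "\n".join(lines)


def _paths_as_label_triples(paths: Sequence[ReasoningPath],
                            g: HealthKnowledgeGraph) -> list[list[tuple[str, str, str]]]:
    def lab(nid: str) -> str:
        return g.nodes[nid].label if nid in g.nodes else nid
    return [[(lab(s), r, lab(o)) for s, r, o in p.hops] for p in paths]


def answer_question(question: str, g: HealthKnowledgeGraph, backend: Backend,
                    T: int = 2, k: int = 5, tau: float = 0.5,
                    scorer: Optional[RelationScorer] = None,
                    start_entities: Optional[Sequence[str]] = None,
                    audit: Optional[AuditTrail] = None, seed: int = 0,
                    record_id: Optional[str] = None) -> Completion:
    """Full reasoning round: link question entities, propagate, collect paths,
    serialize, and ask the backend to answer from the paths."""
    ctx = QuestionContext(question=question, T=T)
    scorer = scorer or TokenOverlapScorer(question)
    if start_entities is None:
        extraction = complete(
            PromptRequest("extractor", question, seed=seed), backend,
            audit=audit, stage="d", record_id=record_id)
        start_entities = []
        for mention in extraction.parsed or []:
            hit = match_node(mention, g, tau)
            if hit is not None:
                start_entities.append(hit[0].node_id)
        start_entities = sorted(set(start_entities))
    if start_entities:
        state = init_entity_state(start_entities, g)
        reason_steps(state, ctx, g, scorer)  # confidence propagation (audited implicitly via paths)
        paths = generate_paths(g, start_entities, ctx, scorer, k=k)
    else:
        paths = []
    prompt = serialize_paths(paths, g) + f"\nQuestion: {question}"
    req = PromptRequest("cot_reasoner", prompt,
                        context={"paths": _paths_as_label_triples(paths, g),
                                 "question": question},
                        seed=seed)
    return complete(req, backend, audit=audit, stage="d", record_id=record_id)


EVENT_QUESTION_TEMPLATE = (
    "A patient is diagnosed with {event}. "
    "The condition progresses to which related conditions?"
)


def validate_event_sequence(m: StaticEventData, g: HealthKnowledgeGraph,
                            backend: Backend, feedback=None, first_pass: bool = True,
                            tau: float = 0.5, T: int = 2, k: int = 5,
                            audit: Optional[AuditTrail] = None, seed: int = 0,
                            record_id: Optional[str] = None,
                            ) -> tuple[int, list[tuple[str, bool, str]]]:
    """CC1 gate: logical consistency of a generated event sequence.

    Events are checked pairwise in timestamp order: event i passes when the
    path-grounded answer about event i contains the linked entity of event
    i+1.  The last event passes vacuously, so sequences of length <= 1 incur
    zero backend calls.  On the first failing pair, ``feedback`` (if given and
    ``first_pass``) is invoked exactly once with the verdict list, signalling
    the upstream generator to retry with an expanded retrieval context.
    """
    events = m.events
    verdicts: list[tuple[str, bool, str]] = []
    if len(events) <= 1:
        return 1, verdicts
    ts = [e.timestamp for e in events]
    if ts != sorted(ts):
        raise ValueError("validate_event_sequence requires timestamp-sorted events")
    cc1 = 1
    for i in range(len(events) - 1):
        cur, nxt = events[i], events[i + 1]
        cur_hit = match_node(cur.code, g, tau)
        nxt_hit = match_node(nxt.code, g, tau)
        if cur_hit is None or nxt_hit is None:
            missing = cur.code if cur_hit is None else nxt.code
            verdicts.append((cur.code, False, f"unlinked: {missing!r} has no KG match above tau"))
            cc1 = 0
            break
        question = EVENT_QUESTION_TEMPLATE.format(event=cur_hit[0].label)
        ans = answer_question(question, g, backend, T=T, k=k, tau=tau,
                              start_entities=[cur_hit[0].node_id],
                              audit=audit, seed=seed + i, record_id=record_id)
        answered = {str(x) for x in (ans.parsed or [])}
        ok = nxt_hit[0].label in answered
        reason = "" if ok else f"answer does not contain {nxt_hit[0].label!r}"
        verdicts.append((cur.code, ok, reason))
        if not ok:
            cc1 = 0
            break
    if cc1 == 0 and first_pass and feedback is not None:
        feedback(verdicts)
    return cc1, verdicts
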