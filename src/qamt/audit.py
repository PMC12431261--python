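"""Append-only audit trail for every model interaction in a generation run.

Each prompt/response exchange is recorded with the workflow stage it belongs
to — ``c`` static-event generation, ``d`` static-event quality assurance,
``g`` event prediction from temporal data, ``h`` variable-dependency
assurance — so the logical flow of a generated record can be replayed and
inspected after the fact.  The trail is the interpretability contract of the
pipeline: a completion that is not reachable from the trail did not happen.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


@dataclass(frozen=True)
class AuditEntry:
    stage: str  # one of the workflow step tags: c, d, g, h (or a free tag)
    prompt: str
    response: str
    verdict: Optional[object] = None
    record_id: Optional[str] = None
    detail: Optional[dict] = None
    index: int = 0
    config_hash: str = ""


@dataclass
class AuditTrail:
    """Ordered, append-only log; every backend call produces exactly one entry."""

    config: dict = field(default_factory=dict)
    entries: list[AuditEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        blob = json.dumps(self.config, sort_keys=True, default=str)
        self._config_hash = hashlib.sha256(blob.encode()).hexdigest()[:12]

    def append(self, stage: str, prompt: str, response: str,
               verdict: Optional[object] = None, record_id: Optional[str] = None,
               detail: Optional[dict] = None) -> AuditEntry:
        entry = AuditEntry(stage=stage, prompt=prompt, response=response,
                           verdict=verdict, record_id=record_id, detail=detail,
                           index=len(self.entries), config_hash=self._config_hash)
        self.entries.append(entry)
        return entry

    def for_record(self, record_id: str) -> list[AuditEntry]:
        return [e for e in self.entries if e.record_id == record_id]

    def stages_for_record(self, record_id: str) -> set[str]:
        return {e.stage for e in self.for_record(record_id)}

    def write_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(json.dumps({
                    "index": e.index, "stage": e.stage, "record_id": e.record_id,
                    "prompt": e.prompt, "response": e.response,
                    "verdict": e.verdict, "detail": e.detail,
                    "config_hash": e.config_hash,
                }, sort_keys=True, default=str) + "\n")

    def __len__(self) -> int:
        return len(self.entries)
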