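"""Run bookkeeping: oracle-call counters, label provenance and diagnostics.

Every successful reference-oracle evaluation increments exactly one stage
counter (idg / al / probe / recompute); failed calls are counted separately.
The ledger is the single source of truth for the conservation invariant

    successful calls = dataset size + probe count + recompute count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field


@dataclass
class ProbeRecord:
    """Unbiased ground-truth probe: uncertainty and true max-atom force error."""

    delta: float
    true_error: float
    trajectory_id: int
    step: int

    def __post_init__(self) -> None:
        if self.delta < 0 or self.true_error < 0:
            raise ValueError("probe quantities must be non-negative")


@dataclass
class RunLedger:
    """Counters and traces for one workflow run (IDG + AL + recompute)."""

    oracle_calls: dict = field(
        default_factory=lambda: {
            "idg": 0, "al": 0, "probe": 0, "recompute": 0, "failed": 0
        }
    )
    labels_by_system: dict = field(default_factory=dict)
    md_steps: dict = field(default_factory=dict)
    probe_records: list = field(default_factory=list)
    threshold_trace: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def record_label(self, stage: str, tag: str) -> None:
        self.oracle_calls[stage] += 1
        per = self.labels_by_system.setdefault(tag, {"idg": 0, "al": 0})
        per[stage] = per.get(stage, 0) + 1

    def record_failure(self) -> None:
        self.oracle_calls["failed"] += 1

    def record_probe(self, record: ProbeRecord) -> None:
        self.oracle_calls["probe"] += 1
        self.probe_records.append(record)

    def record_recompute(self) -> None:
        self.oracle_calls["recompute"] += 1

    def record_md_steps(self, key: str, steps: int) -> None:
        self.md_steps[key] = self.md_steps.get(key, 0) + steps

    def record_threshold(
        self, step: int, trajectory_id: int, delta: float,
        threshold: float | None, labeled: bool,
    ) -> None:
        self.threshold_trace.append(
            {
                "step": step,
                "trajectory_id": trajectory_id,
                "delta": delta,
                "threshold": threshold,
                "labeled": labeled,
            }
        )

    def log(self, event: str) -> None:
        self.events.append(event)

    @property
    def total_successful_calls(self) -> int:
        return sum(v for k, v in self.oracle_calls.items() if k != "failed")

    @property
    def total_md_steps(self) -> int:
        return sum(self.md_steps.values())

    def to_dict(self) -> dict:
        return {
            "oracle_calls": dict(self.oracle_calls),
            "labels_by_system": {k: dict(v) for k, v in self.labels_by_system.items()},
            "md_steps": dict(self.md_steps),
            "probe_records": [asdict(p) for p in self.probe_records],
            "threshold_trace": list(self.threshold_trace),
            "events": list(self.events),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
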