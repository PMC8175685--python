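"""Event log shared by the virtual rig and the injection sequencer."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SequenceEvent", "EventLog", "CountingRNG"]


@dataclass
class SequenceEvent:
    step_index: int
    state: str
    zygote_id: str
    detail: dict
    rng_draws: int = 0


class EventLog:
    """Append-only log with a strictly increasing step index."""

    def __init__(self):
        self.events: list[SequenceEvent] = []

    def record(self, state: str, zygote_id: str, detail: dict,
               rng_draws: int = 0) -> SequenceEvent:
        ev = SequenceEvent(step_index=len(self.events), state=state,
                           zygote_id=zygote_id, detail=dict(detail),
                           rng_draws=rng_draws)
        self.events.append(ev)
        return ev

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


class CountingRNG:
    """Thin wrapper around numpy's Generator that counts draw calls, so
    event records can report how much randomness each step consumed."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self.count = 0

    def normal(self, *args, **kwargs):
        self.count += 1
        return self._rng.normal(*args, **kwargs)

    def uniform(self, *args, **kwargs):
        self.count += 1
        return self._rng.uniform(*args, **kwargs)

    def random(self, *args, **kwargs):
        self.count += 1
        return self._rng.random(*args, **kwargs)

    def generator(self) -> np.random.Generator:
        """Access the raw generator (counts one draw per access site)."""
        self.count += 1
        return self._rng
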