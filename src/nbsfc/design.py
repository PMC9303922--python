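"""Task designs: event tables and randomized event-related sequences.

A trial consists of a 200 ms central fixation cross, a 100 ms stimulus
display, and a 1000 ms blank interval; trials are separated by an
interstimulus interval jittered uniformly (default 2-6 s).  The recorded
event is the stimulus display (onset, 0.1 s duration); the fixation and
blank are structural and carry no event of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError

FIXATION_S = 0.2
STIMULUS_S = 0.1
BLANK_S = 1.0

# dead time appended after the last trial of a run so the haemodynamic
# response of late trials is observed
RUN_TAIL_S = 24.0
RUN_LEAD_IN_S = 4.0


@dataclass(frozen=True)
class TrialEvent:
    """One stimulus event: condition label, onset (s from run start), duration (s)."""

    condition: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise InvalidArgumentError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise InvalidArgumentError(
                f"event duration must be > 0, got {self.duration}"
            )


@dataclass
class TaskDesign:
    """Event table plus scan timing.

    ``events`` hold global onsets: run ``r`` occupies the time interval
    ``[r * n_frames * tr, (r + 1) * n_frames * tr)``.  ``n_frames`` is the
    frame count per run; the total series length is ``n_frames * n_runs``.
    """

    events: list[TrialEvent] = field(default_factory=list)
    tr: float = 2.0
    n_frames: int = 0
    n_runs: int = 1

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise InvalidArgumentError(f"tr must be > 0, got {self.tr}")
        if self.n_frames < 1:
            raise InvalidArgumentError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.n_runs < 1:
            raise InvalidArgumentError(f"n_runs must be >= 1, got {self.n_runs}")
        self.events = sorted(self.events, key=lambda e: e.onset)
        total = self.total_duration
        for prev, nxt in zip(self.events, self.events[1:]):
            if prev.onset + prev.duration > nxt.onset + 1e-12:
                raise InvalidArgumentError(
                    f"events overlap: ({prev.condition}@{prev.onset:.3f}s, "
                    f"{nxt.condition}@{nxt.onset:.3f}s)"
                )
        if self.events:
            last = self.events[-1]
            if last.onset + last.duration > total + 1e-9:
                raise InvalidArgumentError(
                    f"last event ends at {last.onset + last.duration:.3f}s, "
                    f"after the scan end at {total:.3f}s"
                )

    @property
    def total_frames(self) -> int:
        return self.n_frames * self.n_runs

    @property
    def total_duration(self) -> float:
        return self.total_frames * self.tr

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.condition, None)
        return list(seen)

    def run_of_frame(self, frame: int) -> int:
        return frame // self.n_frames

    def events_in_run(self, run: int) -> list[TrialEvent]:
        start = run * self.n_frames * self.tr
        end = (run + 1) * self.n_frames * self.tr
        return [e for e in self.events if start <= e.onset < end]


def generate_design(
    n_trials_per_condition: int,
    conditions: list[str],
    tr: float = 2.0,
    isi_range: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
    n_runs: int = 1,
) -> TaskDesign:
    """Randomized event-related design with jittered interstimulus intervals.

    Trials of all conditions are shuffled together, split evenly over runs
    and laid out sequentially: fixation (0.2 s) + stimulus (0.1 s) + blank
    (1.0 s) + ISI ~ U(isi_range).  Exactly ``n_trials_per_condition`` events
    per condition; the order is randomized by ``seed``.
    """
    if not conditions:
        raise InvalidArgumentError("conditions must be a non-empty list")
    if len(set(conditions)) != len(conditions):
        raise InvalidArgumentError(f"duplicate condition labels: {conditions}")
    if n_trials_per_condition < 1:
        raise InvalidArgumentError(
            f"n_trials_per_condition must be >= 1, got {n_trials_per_condition}"
        )
    lo, hi = isi_range
    if lo > hi:
        raise InvalidArgumentError(f"isi_range low {lo} > high {hi}")
    if lo < 0:
        raise InvalidArgumentError(f"isi_range must be nonnegative, got {isi_range}")
    if tr <= 0:
        raise InvalidArgumentError(f"tr must be > 0, got {tr}")
    if n_runs < 1:
        raise InvalidArgumentError(f"n_runs must be >= 1, got {n_runs}")

    rng = np.random.default_rng(seed)
    trials = [c for c in conditions for _ in range(n_trials_per_condition)]
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]

    # split the shuffled trial list into contiguous, near-equal run chunks
    chunks = np.array_split(np.arange(len(trials)), n_runs)

    run_events: list[list[tuple[str, float]]] = []
    max_end = 0.0
    for chunk in chunks:
        t = RUN_LEAD_IN_S
        evs: list[tuple[str, float]] = []
        for i in chunk:
            onset = t + FIXATION_S
            evs.append((trials[i], onset))
            t = onset + STIMULUS_S + BLANK_S + rng.uniform(lo, hi)
        run_events.append(evs)
        if evs:
            max_end = max(max_end, evs[-1][1] + STIMULUS_S)
    n_frames = int(np.ceil((max_end + RUN_TAIL_S) / tr))

    events = [
        TrialEvent(cond, onset + r * n_frames * tr, STIMULUS_S)
        for r, evs in enumerate(run_events)
        for cond, onset in evs
    ]
    return TaskDesign(events=events, tr=tr, n_frames=n_frames, n_runs=n_runs)
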