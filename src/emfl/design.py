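"""Counterbalanced crossed visual x auditory block design.

The localizer presents five visual conditions (movie clips) simultaneously
with five unrelated auditory conditions.  Each run contains ten 22 s stimulus
blocks and three 18 s fixation blocks (274 s per run).  Within a run every
visual condition occurs twice in palindromic order and every auditory
condition twice in semi-palindromic order; across the five canonical runs
each of the 25 (visual, auditory) pairings occurs exactly twice, so the two
stimulus streams are mutually unconfounded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# -- timing constants (seconds) ----------------------------------------------
BLOCK_DURATION = 22.0
FIXATION_DURATION = 18.0
CLIP_DURATION = 3.0
N_CLIPS = 7
AUDIO_DURATION = 20.5
RESPONSE_WINDOW = (20.5, 22.0)
N_SLOTS = 10          # stimulus blocks per run
N_FIXATIONS = 3       # fixation blocks per run
RUN_DURATION = N_SLOTS * BLOCK_DURATION + N_FIXATIONS * FIXATION_DURATION  # 274
TR = 2.0
N_RUNS_CANONICAL = 5

VISUAL_CONDITIONS = ("faces", "scenes", "objects", "bodies", "words_scrambled")
AUDITORY_CONDITIONS = (
    "false_belief",
    "false_photo",
    "nonwords",
    "quilted_audio",
    "arithmetic",
)
ALL_CONDITIONS = VISUAL_CONDITIONS + AUDITORY_CONDITIONS


class InvalidDesignError(ValueError):
    """Raised when a requested or supplied schedule violates the design rules."""


@dataclass(frozen=True)
class Condition:
    """A single stimulus condition within one modality."""

    name: str
    modality: str  # "visual" | "auditory"
    index: int     # 0-4 within modality

    def __post_init__(self):
        if self.modality not in ("visual", "auditory"):
            raise ValueError(f"unknown modality {self.modality!r}")
        registry = VISUAL_CONDITIONS if self.modality == "visual" else AUDITORY_CONDITIONS
        if not (0 <= self.index < 5) or registry[self.index] != self.name:
            raise ValueError(f"condition {self.name!r} inconsistent with index {self.index}")


def condition(name: str) -> Condition:
    """Look up a :class:`Condition` by label."""
    if name in VISUAL_CONDITIONS:
        return Condition(name, "visual", VISUAL_CONDITIONS.index(name))
    if name in AUDITORY_CONDITIONS:
        return Condition(name, "auditory", AUDITORY_CONDITIONS.index(name))
    raise KeyError(f"unknown condition {name!r}")


def modality_of(name: str) -> str:
    return condition(name).modality


@dataclass(frozen=True)
class Block:
    run_index: int      # 1-based
    slot_index: int     # 0-9 within run
    visual: Condition
    auditory: Condition
    onset: float        # seconds from run start
    duration: float = BLOCK_DURATION


@dataclass(frozen=True)
class FixationBlock:
    run_index: int
    onset: float
    duration: float = FIXATION_DURATION


@dataclass(frozen=True)
class BlockTimeline:
    """Within-block micro-timing of one 22 s stimulus block."""

    clip_onsets: tuple
    clip_duration: float = CLIP_DURATION
    audio_onset: float = 0.0
    audio_duration: float = AUDIO_DURATION
    response_window: tuple = RESPONSE_WINDOW


@dataclass(frozen=True)
class Run:
    index: int                 # 1-based
    blocks: tuple              # 10 Blocks, ordered by onset
    fixations: tuple           # 3 FixationBlocks

    @property
    def total_duration(self) -> float:
        return sum(b.duration for b in self.blocks) + sum(f.duration for f in self.fixations)


@dataclass(frozen=True)
class ExperimentSchedule:
    runs: tuple
    seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def blocks(self):
        return [b for run in self.runs for b in run.blocks]

    def subset(self, run_indices) -> "ExperimentSchedule":
        """Schedule restricted to the given 1-based run indices."""
        keep = tuple(r for r in self.runs if r.index in set(run_indices))
        if not keep:
            raise InvalidDesignError(f"no runs match {run_indices}")
        return ExperimentSchedule(runs=keep, seed=self.seed)


def _slot_onset(slot: int) -> float:
    # Fixation blocks sit at run start, after slot 4, and at run end.
    onset = FIXATION_DURATION + slot * BLOCK_DURATION
    if slot >= 5:
        onset += FIXATION_DURATION
    return onset


def generate_schedule(n_runs: int = 5, seed: int = 0, allow_noncanonical: bool = False) -> ExperimentSchedule:
    """Generate a counterbalanced schedule.

    Visual order per run is a random permutation of the five conditions
    followed by its reversal (a positional palindrome).  Auditory labels are
    assigned by Latin-square offsets: in the first half a block with visual
    index v of run r (0-based) receives auditory index (v + r) mod 5, in the
    reversed half (v + r + 1) mod 5.  Over five runs this yields every
    (visual, auditory) pairing exactly twice, with the two occurrences of
    each visual condition in a run paired with different auditory conditions.
    """
    if n_runs != N_RUNS_CANONICAL and not allow_noncanonical:
        raise InvalidDesignError(
            f"canonical design has {N_RUNS_CANONICAL} runs; got {n_runs} "
            "(pass allow_noncanonical=True to override)"
        )
    if n_runs < 1:
        raise InvalidDesignError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    runs = []
    for r in range(n_runs):
        perm = rng.permutation(5)
        visual_seq = np.concatenate([perm, perm[::-1]])
        blocks = []
        for slot, v in enumerate(visual_seq):
            offset = r if slot < 5 else r + 1
            a = (int(v) + offset) % 5
            blocks.append(
                Block(
                    run_index=r + 1,
                    slot_index=slot,
                    visual=condition(VISUAL_CONDITIONS[int(v)]),
                    auditory=condition(AUDITORY_CONDITIONS[a]),
                    onset=_slot_onset(slot),
                )
            )
        fixations = (
            FixationBlock(run_index=r + 1, onset=0.0),
            FixationBlock(run_index=r + 1, onset=FIXATION_DURATION + 5 * BLOCK_DURATION),
            FixationBlock(run_index=r + 1, onset=RUN_DURATION - FIXATION_DURATION),
        )
        runs.append(Run(index=r + 1, blocks=tuple(blocks), fixations=fixations))
    return ExperimentSchedule(runs=tuple(runs), seed=seed)


def block_timeline(block: Block) -> BlockTimeline:
    """Micro-timing of one stimulus block: seven 3 s clips, 20.5 s audio,
    1.5 s silent response window."""
    if block.duration != BLOCK_DURATION:
        raise InvalidDesignError(
            f"nonstandard block duration {block.duration}; expected {BLOCK_DURATION}"
        )
    return BlockTimeline(clip_onsets=tuple(float(i * CLIP_DURATION) for i in range(N_CLIPS)))


@dataclass
class CounterbalanceReport:
    passed: bool
    pair_counts: pd.DataFrame          # 5x5, visual rows x auditory columns
    per_run_condition_counts: pd.DataFrame
    palindrome_ok: dict
    violations: list = field(default_factory=list)


def validate_counterbalance(schedule: ExperimentSchedule) -> CounterbalanceReport:
    """Exhaustively recount every counterbalancing constraint.

    Checks: 274 s per run, each condition twice per run, palindromic visual
    order, distinct auditory partners for a visual condition's two
    occurrences, non-overlapping increasing onsets, and the 25-cell pair
    count matrix equal to 2 everywhere (for the canonical 5-run schedule).
    """
    if schedule is None or schedule.n_runs == 0:
        raise InvalidDesignError("empty schedule")
    violations = []
    pair_counts = pd.DataFrame(
        0, index=list(VISUAL_CONDITIONS), columns=list(AUDITORY_CONDITIONS), dtype=int
    )
    run_rows = []
    palindrome_ok = {}
    for run in schedule.runs:
        dur = run.total_duration
        if dur != RUN_DURATION:
            violations.append(f"run {run.index}: total duration {dur} != {RUN_DURATION}")
        events = sorted(
            [(b.onset, b.duration) for b in run.blocks]
            + [(f.onset, f.duration) for f in run.fixations]
        )
        for (o1, d1), (o2, _) in zip(events, events[1:]):
            if o1 + d1 > o2 + 1e-9:
                violations.append(f"run {run.index}: overlapping events at {o1:.1f}s/{o2:.1f}s")
        counts = {c: 0 for c in ALL_CONDITIONS}
        vis_seq = [b.visual.name for b in sorted(run.blocks, key=lambda b: b.onset)]
        partners = {}
        for b in run.blocks:
            counts[b.visual.name] += 1
            counts[b.auditory.name] += 1
            partners.setdefault(b.visual.name, []).append(b.auditory.name)
            pair_counts.loc[b.visual.name, b.auditory.name] += 1
        for c, n in counts.items():
            if n != 2:
                violations.append(f"run {run.index}: condition {c} occurs {n} times, expected 2")
        pal = vis_seq == vis_seq[::-1]
        palindrome_ok[run.index] = pal
        if not pal:
            violations.append(f"run {run.index}: visual order is not palindromic")
        for v, auds in partners.items():
            if len(auds) == 2 and auds[0] == auds[1]:
                violations.append(
                    f"run {run.index}: both occurrences of {v} paired with {auds[0]}"
                )
        run_rows.append(pd.Series(counts, name=run.index))
    per_run_counts = pd.DataFrame(run_rows)
    if schedule.n_runs == N_RUNS_CANONICAL:
        bad = pair_counts.stack()[pair_counts.stack() != 2]
        for (v, a), n in bad.items():
            violations.append(f"pair ({v}, {a}) occurs {n} times across runs, expected 2")
    else:
        violations.append(
            f"pair-count check requires {N_RUNS_CANONICAL} runs, schedule has {schedule.n_runs}"
        )
    return CounterbalanceReport(
        passed=not violations,
        pair_counts=pair_counts,
        per_run_condition_counts=per_run_counts,
        palindrome_ok=palindrome_ok,
        violations=violations,
    )


# -- events I/O ---------------------------------------------------------------

def schedule_to_events(schedule: ExperimentSchedule) -> pd.DataFrame:
    """Long-format events table: onset, duration, trial_type, run.

    trial_type is "<visual>_<auditory>" for stimulus blocks and "fixation"
    for fixation blocks.
    """
    rows = []
    for run in schedule.runs:
        for b in sorted(run.blocks, key=lambda b: b.onset):
            rows.append((b.onset, b.duration, f"{b.visual.name}_{b.auditory.name}", run.index))
        for f in run.fixations:
            rows.append((f.onset, f.duration, "fixation", run.index))
    df = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "run"])
    return df.sort_values(["run", "onset"], kind="stable").reset_index(drop=True)


def parse_trial_type(trial_type: str):
    """Split a combined trial_type back into (visual, auditory) labels.

    Returns (None, None) for fixation and (label, None) / (None, label) for
    single-modality trial types as used by the standard-localizer sessions.
    """
    if trial_type == "fixation":
        return None, None
    if trial_type in VISUAL_CONDITIONS or trial_type == "english":
        return (trial_type, None) if trial_type in VISUAL_CONDITIONS else (None, trial_type)
    if trial_type in AUDITORY_CONDITIONS:
        return None, trial_type
    for v in VISUAL_CONDITIONS:
        if trial_type.startswith(v + "_"):
            a = trial_type[len(v) + 1:]
            if a in AUDITORY_CONDITIONS:
                return v, a
    raise ValueError(f"unparseable trial_type {trial_type!r}")


def write_events(schedule: ExperimentSchedule, directory) -> list:
    """Write one BIDS-style events TSV per run plus a design.json sidecar.

    Onsets are run-relative with 3-decimal precision; the sidecar records the
    generating seed so a round-trip read reproduces the schedule exactly.
    """
    if not str(directory):
        raise IOError("empty output directory")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    events = schedule_to_events(schedule)
    paths = []
    for run_idx, sub in events.groupby("run"):
        path = directory / f"run-{run_idx:02d}_events.tsv"
        out = sub.copy()
        out["onset"] = out["onset"].map(lambda x: f"{x:.3f}")
        out.to_csv(path, sep="\t", index=False)
        paths.append(path)
    sidecar = directory / "design.json"
    sidecar.write_text(json.dumps({"seed": schedule.seed, "n_runs": schedule.n_runs}, indent=1))
    return paths


def read_events(directory) -> ExperimentSchedule:
    """Rebuild an :class:`ExperimentSchedule` from a directory written by
    :func:`write_events`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "design.json").read_text())
    runs = []
    for path in sorted(directory.glob("run-*_events.tsv")):
        df = pd.read_csv(path, sep="\t")
        run_idx = int(df["run"].iloc[0])
        blocks, fixations, slot = [], [], 0
        for _, row in df.sort_values("onset").iterrows():
            v, a = parse_trial_type(row["trial_type"])
            if v is None and a is None:
                fixations.append(
                    FixationBlock(run_index=run_idx, onset=float(row["onset"]),
                                  duration=float(row["duration"]))
                )
            else:
                blocks.append(
                    Block(run_index=run_idx, slot_index=slot, visual=condition(v),
                          auditory=condition(a), onset=float(row["onset"]),
                          duration=float(row["duration"]))
                )
                slot += 1
        runs.append(Run(index=run_idx, blocks=tuple(blocks), fixations=tuple(fixations)))
    return ExperimentSchedule(runs=tuple(runs), seed=sidecar["seed"])
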