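"""Factorial stimulus space and counterbalanced run schedules.

The experiment shows 5.4-s video clips in which an actor performs four
manipulative acts (push or flick) on four sequentially ejected balls (white
or orange).  Within a clip one act appears once and the other three times,
and likewise one ball colour appears once and the other three times.  Six
factors are crossed: majority action, actor gender, majority ball colour,
actor position, and a 3-level order variant for each of actions and balls,
giving 2 x 2 x 2 x 2 x 3 x 3 = 144 clips, of which a balanced half (72) is
used in a session of nine runs.

One run is four cycles; a cycle is one fixation trial (announced by a
"random" instruction) followed by the four discrimination blocks
("1-action", "3-actions", "1-ball", "3-balls"), each block being one 2.7-s
instruction plus two 8.1-s discrimination trials.  Every event boundary
falls on the 2.7-s TR grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TR = 2.7
VIDEO_DURATION = 5.4
RESPONSE_DURATION = 2.7
INSTRUCTION_DURATION = 2.7
FIXATION_DURATION = 5.4
#: onsets of the four ball ejections within a video, seconds from video onset
BALL_ONSETS = (0.0, 1.2, 2.4, 3.6)

#: the four discrimination block labels, canonical order
BLOCK_LABELS = ("1-action", "3-actions", "1-ball", "3-balls")
ACTION_BLOCKS = ("1-action", "3-actions")
BALL_BLOCKS = ("1-ball", "3-balls")

GENDERS = ("male", "female")
ACTIONS = ("push", "flick")
BALL_COLORS = ("white", "orange")
POSITIONS = ("right", "left")
ORDER_VARIANTS = (1, 2, 3)

N_CYCLES = 4
TRIALS_PER_BLOCK = 2
VIDEOS_PER_RUN = 8
N_RUNS_DEFAULT = 9

# balanced 4x4 Latin square: each symbol occupies each position exactly once
_LATIN_ROWS = ((0, 1, 2, 3), (1, 3, 0, 2), (3, 2, 1, 0), (2, 0, 3, 1))


@dataclass(frozen=True)
class StimulusVideo:
    """One video clip of the factorial stimulus space."""

    video_id: int
    actor_gender: str
    action_labels: tuple
    ball_labels: tuple
    actor_position: str
    action_order_variant: int
    ball_order_variant: int

    @property
    def action_majority(self) -> str:
        """The action performed three times in the clip."""
        return max(set(self.action_labels), key=self.action_labels.count)

    @property
    def ball_majority(self) -> str:
        return max(set(self.ball_labels), key=self.ball_labels.count)


@dataclass(frozen=True)
class TrialEvent:
    onset: float
    duration: float
    kind: str  # instruction | video | response | fixation
    block_label: str  # one of BLOCK_LABELS, "fixation", or "none"
    video_id: Optional[int] = None
    ball_onsets: tuple = BALL_ONSETS


@dataclass(frozen=True)
class RunSchedule:
    """Timed event list for one run plus its cycle structure."""

    run_index: int
    events: tuple  # of TrialEvent, contiguous, TR-aligned
    block_orders: tuple  # 4 cycles x 4 block labels
    video_ids: tuple  # the 8 videos of this run

    @property
    def duration(self) -> float:
        last = self.events[-1]
        return last.onset + last.duration

    @property
    def n_tr(self) -> int:
        return int(round(self.duration / TR))

    def video_events(self, block_label: Optional[str] = None) -> list:
        out = [e for e in self.events if e.kind == "video"]
        if block_label is not None:
            out = [e for e in out if e.block_label == block_label]
        return out

    def fixation_events(self) -> list:
        return [e for e in self.events if e.kind == "fixation"]


def _ordered_labels(majority: str, minority: str, variant: int) -> tuple:
    # minority event at serial position variant+1 (an arbitrary but fixed
    # realisation of the three order variants)
    labels = [majority] * 4
    labels[variant] = minority
    return tuple(labels)


def enumerate_videos() -> list:
    """Full factorial crossing of the six stimulus factors (144 videos).

    Deterministic ordering by factor index: gender, majority action,
    majority ball colour, actor position, action order variant, ball order
    variant (slowest to fastest).
    """
    videos = []
    for vid, (g, act, ball, pos, av, bv) in enumerate(
        itertools.product(GENDERS, ACTIONS, BALL_COLORS, POSITIONS,
                          ORDER_VARIANTS, ORDER_VARIANTS)
    ):
        other_act = ACTIONS[1 - ACTIONS.index(act)]
        other_ball = BALL_COLORS[1 - BALL_COLORS.index(ball)]
        videos.append(
            StimulusVideo(
                video_id=vid,
                actor_gender=g,
                action_labels=_ordered_labels(act, other_act, av),
                ball_labels=_ordered_labels(ball, other_ball, bv),
                actor_position=pos,
                action_order_variant=av,
                ball_order_variant=bv,
            )
        )
    return videos


def _binary_key(v: StimulusVideo) -> tuple:
    return (
        GENDERS.index(v.actor_gender),
        ACTIONS.index(v.action_majority),
        BALL_COLORS.index(v.ball_majority),
        POSITIONS.index(v.actor_position),
    )


def select_balanced_subset(videos: Sequence[StimulusVideo], seed: int,
                           size: int = 72) -> list:
    """Select ``size`` videos with equal marginal counts on the four binary
    factors (gender, majority action, majority ball colour, position).

    The 144 videos form 16 strata of 9 (one per combination of the binary
    factors).  Cells with an even number of factor-1 levels contribute one
    extra video, which balances every binary margin exactly for any seed.
    """
    videos = list(videos)
    if len(videos) != 144:
        raise ValueError("expected the full 144-video factorial set, got "
                         f"{len(videos)}")
    if size % 8 != 0 or not (0 < size <= 144):
        raise ValueError(f"no balanced subset of size {size} exists with "
                         "this stratified construction (need a multiple of 8)")
    base, extra = divmod(size, 16)
    # extra is 0 or 8; give the extra video to the even-parity strata
    strata: dict = {}
    for v in videos:
        strata.setdefault(_binary_key(v), []).append(v)
    rng = np.random.default_rng(seed)
    subset = []
    for key in sorted(strata):
        take = base + (1 if extra and sum(key) % 2 == 0 else 0)
        if take > len(strata[key]):
            raise ValueError(f"subset size {size} unsatisfiable: stratum "
                             f"{key} holds only {len(strata[key])} videos")
        idx = rng.choice(len(strata[key]), size=take, replace=False)
        subset.extend(strata[key][i] for i in sorted(idx))
    return subset


def _cycle_events(tr_index: int, block_order: Sequence[str],
                  pair_for_block: dict) -> tuple:
    """Events of one cycle starting at TR ``tr_index``.

    Onsets are computed as integer TR counts times TR so they survive a
    text round trip bit-exactly.  Returns (events, next_tr_index).
    """
    events = []
    i = tr_index

    def _add(n_tr: int, kind: str, label: str, vid=None):
        nonlocal i
        events.append(TrialEvent(i * TR, n_tr * TR, kind, label, vid))
        i += n_tr

    # fixation trial, announced by the "random" instruction
    _add(1, "instruction", "fixation")
    _add(2, "fixation", "fixation")
    _add(1, "response", "fixation")
    for label in block_order:
        _add(1, "instruction", label)
        for vid in pair_for_block[label]:
            _add(2, "video", label, int(vid))
            _add(1, "response", label)
    return tuple(events), i


def build_run(run_index: int, video_ids: Sequence[int],
              label_perm: Sequence[str]) -> RunSchedule:
    """Assemble one run from its 8 videos.

    The 8 videos form 4 fixed pairs; in cycle ``c`` the block labelled
    ``label_perm[j]`` presents pair ``(j - c) mod 4``, a Latin-square
    rotation under which every video appears exactly once per block label
    across the four cycles.  Block order within a cycle follows the balanced
    Latin square, rotated by run so that over nine runs each label occupies
    each within-cycle position exactly nine times.
    """
    if len(video_ids) != VIDEOS_PER_RUN:
        raise ValueError("a run needs exactly 8 videos")
    pairs = [tuple(int(v) for v in video_ids[2 * j:2 * j + 2])
             for j in range(4)]
    events: list = []
    block_orders = []
    t = 0
    for c in range(N_CYCLES):
        row = _LATIN_ROWS[(run_index - 1 + c) % 4]
        order = tuple(label_perm[j] for j in row)
        pair_for_block = {label_perm[j]: pairs[(j - c) % 4] for j in range(4)}
        cyc, t = _cycle_events(t, order, pair_for_block)
        events.extend(cyc)
        block_orders.append(order)
    # record videos in first-appearance order (recoverable from the events
    # table, so written and re-read schedules compare equal)
    seen: list = []
    for e in events:
        if e.kind == "video" and e.video_id not in seen:
            seen.append(e.video_id)
    return RunSchedule(run_index=run_index, events=tuple(events),
                       block_orders=tuple(block_orders),
                       video_ids=tuple(seen))


def build_session(videos72: Sequence[StimulusVideo], seed: int) -> list:
    """Partition 72 balanced videos into 9 counterbalanced run schedules."""
    if len(videos72) != 72:
        raise ValueError(f"expected 72 videos, got {len(videos72)}")
    rng = np.random.default_rng(seed)
    ids = np.array([v.video_id for v in videos72])
    rng.shuffle(ids)
    label_perm = list(BLOCK_LABELS)
    rng.shuffle(label_perm)
    runs = []
    for r in range(N_RUNS_DEFAULT):
        run_ids = ids[r * VIDEOS_PER_RUN:(r + 1) * VIDEOS_PER_RUN]
        runs.append(build_run(r + 1, list(run_ids), label_perm))
    return runs


# ---------------------------------------------------------------------------
# events table I/O (BIDS-style TSV)

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "video_id",
                  "block_label"]


def export_events(schedule: RunSchedule) -> pd.DataFrame:
    rows = [
        {"onset": e.onset, "duration": e.duration, "trial_type": e.kind,
         "video_id": e.video_id if e.video_id is not None else "n/a",
         "block_label": e.block_label}
        for e in schedule.events
    ]
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def write_events(schedule: RunSchedule, path) -> None:
    export_events(schedule).to_csv(path, sep="\t", index=False)


def read_events(path, run_index: int) -> RunSchedule:
    """Rebuild a RunSchedule from an events TSV written by write_events."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"],
                     float_precision="round_trip")
    events = []
    for _, row in df.iterrows():
        vid = None if pd.isna(row["video_id"]) else int(row["video_id"])
        events.append(TrialEvent(float(row["onset"]), float(row["duration"]),
                                 str(row["trial_type"]),
                                 str(row["block_label"]), vid))
    # recover cycle structure: block instructions in order, 4 per cycle
    block_orders = []
    order: list = []
    video_ids: list = []
    seen = set()
    for e in events:
        if e.kind == "instruction" and e.block_label in BLOCK_LABELS:
            order.append(e.block_label)
            if len(order) == 4:
                block_orders.append(tuple(order))
                order = []
        if e.kind == "video" and e.video_id not in seen:
            seen.add(e.video_id)
            video_ids.append(e.video_id)
    return RunSchedule(run_index=run_index, events=tuple(events),
                       block_orders=tuple(block_orders),
                       video_ids=tuple(video_ids))


def write_session_events(runs: Sequence[RunSchedule], out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run in runs:
        p = out_dir / f"run-{run.run_index:02d}_events.tsv"
        write_events(run, p)
        paths.append(p)
    return paths
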