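"""Deterministic state machines for the three therapy game modes.

A session is a time-ordered stream of classified frames at a fixed rate
(30 fps by default, matching the wearable's logging rate). Feedback events
are *debounced* — the same label must be detected on ``debounce_frames``
consecutive frames — and rate-limited by a refractory interval, so raw
per-frame classifier output does not spam the child with cues. One feedback
event is emitted per debounced run at most.

Modes
-----
free_play
    A cue fires whenever any of the eight emotions is (debounced-)detected.
capture_the_smile
    The child is prompted to evoke a specific emotion; a debounced detection
    of the prompted emotion scores a success and advances the prompt. The
    game ends at 180 s or 20 successes, whichever comes first.
guess_the_emotion
    App-only rounds of (parent emotion, child guess); the classifier is
    never invoked. A cue fires on each correct guess. Untimed.

Session logs serialize as JSON Lines (header record + one record per event)
and replay deterministically: identical inputs give byte-identical logs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .labels import NONE_LABEL, canonical

__all__ = [
    "SessionConfig",
    "FrameRecord",
    "FeedbackEvent",
    "GameEvent",
    "SessionLog",
    "run_free_play",
    "run_capture_the_smile",
    "run_guess_the_emotion",
    "build_timeline",
    "UsagePolicy",
    "validate_usage",
    "summarize_usage",
    "capture_prompts",
    "CAPTURE_MAX_SUCCESSES",
    "CAPTURE_MAX_SECONDS",
]

#: protocol constants of the prompted-evocation game
CAPTURE_MAX_SUCCESSES = 20
CAPTURE_MAX_SECONDS = 180.0

MODES = ("free_play", "capture_the_smile", "guess_the_emotion")
FEEDBACK_CHANNELS = ("audio", "visual", "both")


@dataclass(frozen=True)
class SessionConfig:
    mode: str = "free_play"
    feedback: str = "both"
    fps: float = 30.0
    debounce_frames: int = 5
    refractory_s: float = 2.0
    rng_seed: int | None = None
    suppress_neutral: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.feedback not in FEEDBACK_CHANNELS:
            raise ValueError(f"unknown feedback channel {self.feedback!r}")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.debounce_frames < 1:
            raise ValueError("debounce_frames must be >= 1")


@dataclass(frozen=True)
class FrameRecord:
    """One logged frame: time, detected label (or 'none'), confidence."""

    t: float
    label: str
    confidence: float = 1.0


@dataclass(frozen=True)
class FeedbackEvent:
    t: float
    label: str
    channel: str


@dataclass(frozen=True)
class GameEvent:
    t: float
    kind: str  # prompt | success | round | cue
    label: str = ""
    detail: str = ""


@dataclass
class SessionLog:
    session_id: str
    config: SessionConfig
    frames: list[FrameRecord] = field(default_factory=list)
    feedback_events: list[FeedbackEvent] = field(default_factory=list)
    game_events: list[GameEvent] = field(default_factory=list)
    score: int | None = None
    start_t: float = 0.0
    end_t: float = 0.0
    session_date: str | None = None  # ISO wall-clock date, for usage accounting

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def to_jsonl(self) -> str:
        header = {
            "record": "header",
            "schema_version": "1.0",
            "session_id": self.session_id,
            "config": asdict(self.config),
            "score": self.score,
            "start_t": self.start_t,
            "end_t": self.end_t,
            "session_date": self.session_date,
        }
        lines = [json.dumps(header, sort_keys=True)]
        for f in self.frames:
            lines.append(json.dumps({"record": "frame", **asdict(f)}, sort_keys=True))
        for e in self.feedback_events:
            lines.append(json.dumps({"record": "feedback", **asdict(e)}, sort_keys=True))
        for g in self.game_events:
            lines.append(json.dumps({"record": "game", **asdict(g)}, sort_keys=True))
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_jsonl())

    @classmethod
    def from_jsonl(cls, text_or_path) -> "SessionLog":
        if isinstance(text_or_path, (str,)) and "\n" not in text_or_path and Path(text_or_path).exists():
            text = Path(text_or_path).read_text()
        elif isinstance(text_or_path, Path):
            text = text_or_path.read_text()
        else:
            text = text_or_path
        lines = [json.loads(l) for l in text.strip().splitlines()]
        header = next(l for l in lines if l["record"] == "header")
        log = cls(
            session_id=header["session_id"],
            config=SessionConfig(**header["config"]),
            score=header.get("score"),
            start_t=header["start_t"],
            end_t=header["end_t"],
            session_date=header.get("session_date"),
        )
        for l in lines:
            if l["record"] == "frame":
                log.frames.append(FrameRecord(l["t"], l["label"], l["confidence"]))
            elif l["record"] == "feedback":
                log.feedback_events.append(FeedbackEvent(l["t"], l["label"], l["channel"]))
            elif l["record"] == "game":
                log.game_events.append(GameEvent(l["t"], l["kind"], l["label"], l["detail"]))
        return log


def _check_ordered(frames: Sequence[FrameRecord]) -> None:
    for i in range(1, len(frames)):
        if frames[i].t < frames[i - 1].t:
            raise ValueError(f"frame timestamps out of order at index {i}")


def _coerce_frames(frames: Iterable) -> list[FrameRecord]:
    out = []
    for f in frames:
        if isinstance(f, FrameRecord):
            rec = f
        else:
            t, label = f[0], f[1]
            conf = f[2] if len(f) > 2 else 1.0
            rec = FrameRecord(float(t), str(label), float(conf))
        label = rec.label
        if label != NONE_LABEL:
            label = canonical(label)
            rec = FrameRecord(rec.t, label, rec.confidence)
        out.append(rec)
    _check_ordered(out)
    return out


class _Debouncer:
    """Tracks consecutive identical detections; fires once per run, subject
    to the refractory interval."""

    def __init__(self, debounce_frames: int, refractory_s: float):
        self.k = debounce_frames
        self.refractory = refractory_s
        self.run_label: str | None = None
        self.run_len = 0
        self.run_fired = False
        self.last_event_t: float | None = None

    def step(self, t: float, label: str) -> str | None:
        """Feed one frame; returns the label when an event should fire."""
        if label == NONE_LABEL:
            self.run_label, self.run_len, self.run_fired = None, 0, False
            return None
        if label == self.run_label:
            self.run_len += 1
        else:
            self.run_label, self.run_len, self.run_fired = label, 1, False
        if self.run_len >= self.k and not self.run_fired:
            if self.last_event_t is None or t - self.last_event_t >= self.refractory:
                self.run_fired = True
                self.last_event_t = t
                return label
        return None


def run_free_play(
    frames: Iterable,
    config: SessionConfig | None = None,
    session_id: str = "session",
    session_date: str | None = None,
) -> SessionLog:
    """Unstructured mode: a feedback event per debounced emotion detection."""
    config = config or SessionConfig(mode="free_play")
    recs = _coerce_frames(frames)
    log = SessionLog(session_id=session_id, config=config, session_date=session_date)
    deb = _Debouncer(config.debounce_frames, config.refractory_s)
    for r in recs:
        log.frames.append(r)
        label = r.label
        if config.suppress_neutral and label == "neutral":
            label = NONE_LABEL
        fired = deb.step(r.t, label)
        if fired is not None:
            log.feedback_events.append(FeedbackEvent(r.t, fired, config.feedback))
    if recs:
        log.start_t = recs[0].t
        log.end_t = recs[-1].t + 1.0 / config.fps
    return log


def capture_prompts(rng_seed: int | None, n: int = 64) -> list[str]:
    """Seeded uniform prompt sequence without immediate repetition."""
    from .labels import EMOTIONS

    rng = np.random.default_rng(rng_seed)
    prompts: list[str] = []
    while len(prompts) < n:
        e = EMOTIONS[rng.integers(len(EMOTIONS))]
        if prompts and prompts[-1] == e:
            continue
        prompts.append(e)
    return prompts


def run_capture_the_smile(
    frames: Iterable,
    prompts: Sequence[str] | None = None,
    config: SessionConfig | None = None,
    session_id: str = "session",
    session_date: str | None = None,
) -> SessionLog:
    """Prompted-evocation game: ends at 180 s or 20 successes.

    A success is a debounced detection of the *currently prompted* emotion;
    each success advances to the next prompt. ``log.score`` holds the number
    of successes (0..20).
    """
    config = config or SessionConfig(mode="capture_the_smile")
    recs = _coerce_frames(frames)
    if prompts is None:
        prompts = capture_prompts(config.rng_seed, n=max(CAPTURE_MAX_SUCCESSES + 4, 24))
    prompts = [canonical(p) for p in prompts]
    log = SessionLog(session_id=session_id, config=config, session_date=session_date)
    score = 0
    prompt_i = 0
    t0 = recs[0].t if recs else 0.0
    log.start_t = t0
    log.game_events.append(GameEvent(t0, "prompt", prompts[0]))
    run_len = 0
    end_t = t0 + CAPTURE_MAX_SECONDS
    for r in recs:
        if r.t - t0 >= CAPTURE_MAX_SECONDS:
            break
        log.frames.append(r)
        if r.label == prompts[prompt_i % len(prompts)]:
            run_len += 1
        else:
            run_len = 0
        if run_len >= config.debounce_frames:
            score += 1
            log.game_events.append(GameEvent(r.t, "success", prompts[prompt_i % len(prompts)]))
            log.feedback_events.append(FeedbackEvent(r.t, prompts[prompt_i % len(prompts)], config.feedback))
            if score >= CAPTURE_MAX_SUCCESSES:
                end_t = r.t
                break
            prompt_i += 1
            run_len = 0
            log.game_events.append(
                GameEvent(r.t, "prompt", prompts[prompt_i % len(prompts)])
            )
    log.score = score
    log.end_t = min(end_t, t0 + CAPTURE_MAX_SECONDS)
    return log


def run_guess_the_emotion(
    rounds: Sequence[tuple[str, str]],
    config: SessionConfig | None = None,
    session_id: str = "session",
    session_date: str | None = None,
    round_spacing_s: float = 10.0,
) -> SessionLog:
    """App-controlled guessing rounds; never calls the emotion classifier.

    One cue event per correct round; score = number of correct guesses.
    The game is untimed (no duration cap); round times are bookkeeping only.
    """
    config = config or SessionConfig(mode="guess_the_emotion")
    # validate every label before any round runs
    canon = [(canonical(p), canonical(g)) for p, g in rounds]
    log = SessionLog(session_id=session_id, config=config, session_date=session_date)
    score = 0
    t = 0.0
    for parent, guess in canon:
        correct = parent == guess
        log.game_events.append(
            GameEvent(t, "round", parent, detail=f"guess={guess};correct={correct}")
        )
        if correct:
            score += 1
            log.feedback_events.append(FeedbackEvent(t, parent, config.feedback))
        t += round_spacing_s
    log.score = score
    log.start_t = 0.0
    log.end_t = max(0.0, t - round_spacing_s)
    return log


def build_timeline(log: SessionLog) -> list[tuple[float, float, str]]:
    """Run-length encode detected labels into (t_start, t_end, label) segments.

    'none' frames produce gaps; each segment's end is the last frame time of
    the run plus one frame period, so segment durations sum to
    (detected-frame count)/fps.
    """
    period = 1.0 / log.config.fps
    segments: list[tuple[float, float, str]] = []
    cur_label: str | None = None
    cur_start = 0.0
    cur_end = 0.0
    for f in log.frames:
        if f.label == NONE_LABEL:
            if cur_label is not None:
                segments.append((cur_start, cur_end, cur_label))
                cur_label = None
            continue
        if f.label == cur_label:
            cur_end = f.t + period
        else:
            if cur_label is not None:
                segments.append((cur_start, cur_end, cur_label))
            cur_label = f.label
            cur_start = f.t
            cur_end = f.t + period
    if cur_label is not None:
        segments.append((cur_start, cur_end, cur_label))
    return segments


# ---------------------------------------------------------------------------
# study-protocol usage accounting


@dataclass(frozen=True)
class UsagePolicy:
    """At-home protocol: >= 3 sessions of >= 20 min per week, <= 2 sessions/day."""

    min_sessions_per_week: int = 3
    min_session_min: float = 20.0
    max_sessions_per_day: int = 2

    def __post_init__(self) -> None:
        if min(self.min_sessions_per_week, self.min_session_min, self.max_sessions_per_day) <= 0:
            raise ValueError("policy fields must be positive")


def _as_date(d) -> date:
    if isinstance(d, date) and not isinstance(d, datetime):
        return d
    if isinstance(d, datetime):
        return d.date()
    return date.fromisoformat(str(d))


def validate_usage(sessions: Sequence[dict], policy: UsagePolicy | None = None) -> dict:
    """Check a participant's session summaries against the usage policy.

    ``sessions``: dicts with keys ``date`` (ISO string or date) and
    ``duration_min``. Weeks are consecutive 7-day blocks anchored at the
    first session's date; a partial final week is excluded from the weekly
    minimum. Returns a report dict with per-week qualifying counts, the
    per-day cap violations, and the overall ``compliant`` flag.
    """
    policy = policy or UsagePolicy()
    if not sessions:
        return {"compliant": False, "weeks": [], "day_violations": [], "n_sessions": 0}
    parsed = []
    for s in sessions:
        dur = float(s["duration_min"])
        if dur < 0:
            raise ValueError(f"negative session duration: {dur}")
        parsed.append((_as_date(s["date"]), dur))
    parsed.sort(key=lambda x: x[0])
    first = parsed[0][0]
    last = parsed[-1][0]
    n_full_weeks = ((last - first).days + 1) // 7

    weeks = []
    for w in range(max(n_full_weeks, 1)):
        lo = first + timedelta(days=7 * w)
        hi = lo + timedelta(days=7)
        in_week = [dur for d, dur in parsed if lo <= d < hi]
        qualifying = sum(1 for dur in in_week if dur >= policy.min_session_min)
        weeks.append(
            {
                "week_start": lo.isoformat(),
                "n_sessions": len(in_week),
                "n_qualifying": qualifying,
                "meets_minimum": qualifying >= policy.min_sessions_per_week,
                "full_week": w < n_full_weeks,
            }
        )
    per_day: dict[date, int] = {}
    for d, _ in parsed:
        per_day[d] = per_day.get(d, 0) + 1
    day_violations = [
        {"date": d.isoformat(), "n_sessions": c}
        for d, c in sorted(per_day.items())
        if c > policy.max_sessions_per_day
    ]
    full_weeks = [w for w in weeks if w["full_week"]]
    compliant = bool(full_weeks) and all(w["meets_minimum"] for w in full_weeks)
    return {
        "compliant": compliant,
        "weeks": weeks,
        "day_violations": day_violations,
        "n_sessions": len(parsed),
        "total_min": sum(dur for _, dur in parsed),
    }


def summarize_usage(sessions: Sequence[dict]) -> dict:
    """Cohort usage summary from session records carrying ``participant_id``,
    ``date`` and ``duration_min``.

    Returns per-participant totals plus cohort total/mean/SD/min/max minutes;
    the mean equals total / n_participants exactly.
    """
    if not sessions:
        raise ValueError("no sessions to summarize")
    df = pd.DataFrame(sessions)
    df["date"] = df["date"].map(_as_date)
    per = []
    for pid, grp in df.groupby("participant_id", sort=True):
        total = float(grp["duration_min"].sum())
        span_days = (grp["date"].max() - grp["date"].min()).days + 1
        weeks = max(span_days / 7.0, 1 / 7.0)
        per.append(
            {
                "participant_id": pid,
                "total_min": total,
                "n_sessions": int(len(grp)),
                "weeks_at_home": span_days / 7.0,
                "sessions_per_week": len(grp) / weeks,
            }
        )
    totals = np.array([p["total_min"] for p in per])
    return {
        "participants": per,
        "n_participants": len(per),
        "total_min": float(totals.sum()),
        "mean_min": float(totals.sum() / len(per)),
        "sd_min": float(totals.std(ddof=1)) if len(per) > 1 else 0.0,
        "min_min": float(totals.min()),
        "max_min": float(totals.max()),
    }
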