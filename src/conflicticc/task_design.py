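"""Emotional-conflict trial sequences: generation, coding and events I/O.

The task presents happy or fearful faces with the word "HAPPY" or "FEAR"
superimposed; the participant names the facial emotion.  A trial is
*congruent* when the face emotion matches the word and *incongruent*
otherwise.  Each run is counterbalanced for exactly equal numbers of
congruent and incongruent trials and for equal numbers of happy and fearful
faces.  Conflict-adaptation labels code each trial by the congruency of the
preceding trial: cC, cI, iC, iI (previous, current), with the first trial of
each run labeled ``first``; labels never cross run boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

EMOTIONS = ("happy", "fear")
ADAPTATION_LABELS = ("first", "cC", "cI", "iC", "iI")

#: stimulus duration in seconds (faces are shown for 1 s)
STIMULUS_DURATION = 1.0


class BalanceError(ValueError):
    """Raised when the requested trial counts cannot be counterbalanced."""


class SequencingError(ValueError):
    """Raised when trial ordering within a run is inconsistent."""


class EventsParseError(ValueError):
    """Raised when an events file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class TrialEvent:
    """One task trial: design attributes, independent of any response."""

    run_index: int            # 1-based run number
    trial_index: int          # 1-based position within the run
    onset: float              # seconds from run start
    duration: float           # seconds, fixed at 1.0
    face_emotion: str         # 'happy' | 'fear'
    word: str                 # 'HAPPY' | 'FEAR'
    congruent: bool
    adaptation_label: str     # 'first' | 'cC' | 'cI' | 'iC' | 'iI'
    isi_after: float          # seconds of fixation following the stimulus

    def __post_init__(self):
        if self.face_emotion not in EMOTIONS:
            raise ValueError(f"unknown face emotion {self.face_emotion!r}")
        if self.word not in ("HAPPY", "FEAR"):
            raise ValueError(f"unknown word {self.word!r}")
        if self.congruent != (self.face_emotion == self.word.lower()):
            raise ValueError("congruent flag inconsistent with face/word pair")
        if self.adaptation_label not in ADAPTATION_LABELS:
            raise ValueError(f"unknown adaptation label {self.adaptation_label!r}")


@dataclass
class TaskSequence:
    """An ordered multi-run trial sequence for one scan session."""

    trials: list[TrialEvent]
    n_runs: int
    seed: int | None = None
    trials_per_run: int = field(default=0)

    def __post_init__(self):
        if self.trials and not self.trials_per_run:
            self.trials_per_run = max(
                t.trial_index for t in self.trials if t.run_index == 1
            )

    def run(self, run_index: int) -> list[TrialEvent]:
        return [t for t in self.trials if t.run_index == run_index]

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view of the sequence, one row per trial."""
        return pd.DataFrame(
            {
                "run": [t.run_index for t in self.trials],
                "trial": [t.trial_index for t in self.trials],
                "onset": [t.onset for t in self.trials],
                "duration": [t.duration for t in self.trials],
                "face_emotion": [t.face_emotion for t in self.trials],
                "word": [t.word for t in self.trials],
                "congruent": [t.congruent for t in self.trials],
                "adaptation_label": [t.adaptation_label for t in self.trials],
                "isi_after": [t.isi_after for t in self.trials],
            }
        )


def _cell_counts(trials_per_run: int, rng: np.random.Generator) -> dict[tuple[bool, str], int]:
    """Split a run into the congruency x face-emotion cells.

    Both marginals (congruent/incongruent, happy/fear) are exactly balanced.
    With 37 trials per congruency cell an exactly even happy/fear split
    within each cell is impossible; the odd trial is assigned at random
    (seeded) in a complementary way that keeps the emotion marginal exact.
    """
    half = trials_per_run // 2
    base, rem = divmod(half, 2)
    if rem == 0:
        return {
            (True, "happy"): base,
            (True, "fear"): base,
            (False, "happy"): base,
            (False, "fear"): base,
        }
    # odd congruency cell: give the extra happy face to one congruency cell
    # and the extra fear face to the other, so emotions stay 50/50 overall
    extra_happy_congruent = bool(rng.integers(2))
    return {
        (True, "happy"): base + (1 if extra_happy_congruent else 0),
        (True, "fear"): base + (0 if extra_happy_congruent else 1),
        (False, "happy"): base + (0 if extra_happy_congruent else 1),
        (False, "fear"): base + (1 if extra_happy_congruent else 0),
    }


def _min_transition_count(trials_per_run: int, requested: int) -> int:
    # requiring >= `requested` instances of each adaptation cell is only
    # feasible for reasonably long runs; scale the requirement down for
    # short (toy) runs instead of looping forever
    feasible = max(0, (trials_per_run - 1) // 6)
    return min(requested, feasible)


def generate_sequence(
    n_runs: int,
    trials_per_run: int = 74,
    isi_range: tuple[float, float] = (3.0, 5.0),
    seed: int = 0,
    lead_in: float = 10.0,
    min_adaptation_count: int = 10,
    max_reshuffles: int = 1000,
) -> TaskSequence:
    """Generate a counterbalanced emotional-conflict trial sequence.

    Parameters
    ----------
    n_runs : int
        Number of runs (the study protocol uses 2 consecutive runs).
    trials_per_run : int
        Trials per run; must be even so congruent/incongruent counts can be
        exactly equal (default 74, i.e. 148 trials over two runs).
    isi_range : (float, float)
        Bounds of the jittered inter-stimulus fixation interval in seconds
        (default 3-5 s); ISIs are drawn uniformly and rounded to 0.1 s.
    seed : int
        Seed for the jitter and trial-order shuffling; sequences are
        deterministic given the seed.
    lead_in : float
        Fixation lead-in before the first stimulus of each run, seconds.
    min_adaptation_count : int
        Orders are reshuffled until each of cC/cI/iC/iI occurs at least this
        many times per run (scaled down automatically for short runs), which
        keeps the conflict-adaptation contrast estimable.

    Returns
    -------
    TaskSequence
    """
    if n_runs <= 0 or trials_per_run <= 0:
        raise ValueError("n_runs and trials_per_run must be positive")
    if trials_per_run % 2:
        raise BalanceError(
            f"trials_per_run={trials_per_run} is odd; congruent/incongruent "
            "counts cannot be balanced"
        )
    lo, hi = isi_range
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid isi_range {isi_range}")

    rng = np.random.default_rng(seed)
    required = _min_transition_count(trials_per_run, min_adaptation_count)
    trials: list[TrialEvent] = []

    for run in range(1, n_runs + 1):
        cells = _cell_counts(trials_per_run, rng)
        pool = [
            (congruent, emotion)
            for (congruent, emotion), count in cells.items()
            for _ in range(count)
        ]
        order = None
        for _ in range(max_reshuffles):
            perm = [pool[i] for i in rng.permutation(len(pool))]
            counts = {"cC": 0, "cI": 0, "iC": 0, "iI": 0}
            for prev, cur in zip(perm, perm[1:]):
                lab = ("c" if prev[0] else "i") + ("C" if cur[0] else "I")
                counts[lab] += 1
            if all(v >= required for v in counts.values()):
                order = perm
                break
        if order is None:  # pragma: no cover - requirement scaled to be feasible
            raise BalanceError(
                "could not satisfy adaptation-cell counts after "
                f"{max_reshuffles} reshuffles"
            )

        isis = np.round(rng.uniform(lo, hi, size=len(order)), 1)
        onset = float(lead_in)
        for idx, ((congruent, emotion), isi) in enumerate(zip(order, isis), start=1):
            word = emotion.upper() if congruent else (
                "FEAR" if emotion == "happy" else "HAPPY"
            )
            trials.append(
                TrialEvent(
                    run_index=run,
                    trial_index=idx,
                    onset=round(onset, 3),
                    duration=STIMULUS_DURATION,
                    face_emotion=emotion,
                    word=word,
                    congruent=congruent,
                    adaptation_label="first",
                    isi_after=float(isi),
                )
            )
            onset += STIMULUS_DURATION + float(isi)

    seq = TaskSequence(trials=trials, n_runs=n_runs, seed=seed,
                       trials_per_run=trials_per_run)
    return code_adaptation(seq)


def code_adaptation(seq: TaskSequence) -> TaskSequence:
    """Label every trial by (previous congruency, current congruency).

    Labels are cC, cI, iC, iI; the first trial of each run is ``first``.
    Labels never cross run boundaries.  Raises ``SequencingError`` if onsets
    are not strictly increasing within a run.
    """
    coded: list[TrialEvent] = []
    prev: TrialEvent | None = None
    for t in sorted(seq.trials, key=lambda t: (t.run_index, t.trial_index)):
        if prev is not None and prev.run_index == t.run_index:
            if t.onset <= prev.onset:
                raise SequencingError(
                    f"onsets not strictly increasing in run {t.run_index} "
                    f"at trial {t.trial_index}"
                )
            label = ("c" if prev.congruent else "i") + ("C" if t.congruent else "I")
        else:
            label = "first"
        coded.append(replace(t, adaptation_label=label))
        prev = t
    return TaskSequence(trials=coded, n_runs=seq.n_runs, seed=seq.seed,
                        trials_per_run=seq.trials_per_run)


def run_duration(seq: TaskSequence, run_index: int, trailing: float = 0.0) -> float:
    """Total duration of one run in seconds, including trailing fixation."""
    trials = seq.run(run_index)
    if not trials:
        return 0.0
    last = trials[-1]
    return last.onset + last.duration + last.isi_after + trailing


# ---------------------------------------------------------------------------
# events I/O (BIDS-events-like TSV)
# ---------------------------------------------------------------------------

_COLUMNS = ["onset", "duration", "trial_type", "isi_after"]


def _trial_type(t: TrialEvent) -> str:
    cong = "congruent" if t.congruent else "incongruent"
    return f"run-{t.run_index:02d}_{cong}_{t.face_emotion}-face_{t.adaptation_label}"


def _parse_trial_type(s: str, line: int) -> tuple[int, bool, str, str]:
    parts = s.split("_")
    if len(parts) != 4 or not parts[0].startswith("run-"):
        raise EventsParseError(f"malformed trial_type {s!r}", line)
    try:
        run = int(parts[0][4:])
    except ValueError:
        raise EventsParseError(f"malformed run index in {s!r}", line) from None
    if parts[1] not in ("congruent", "incongruent"):
        raise EventsParseError(f"unknown congruency in {s!r}", line)
    emotion = parts[2].removesuffix("-face")
    if emotion not in EMOTIONS:
        raise EventsParseError(f"unknown face emotion in {s!r}", line)
    if parts[3] not in ADAPTATION_LABELS:
        raise EventsParseError(f"unknown adaptation label in {s!r}", line)
    return run, parts[1] == "congruent", emotion, parts[3]


def write_events(seq: TaskSequence, path) -> None:
    """Write a sequence as a tab-separated BIDS-events-like table."""
    rows = []
    for t in seq.trials:
        rows.append(
            {
                "onset": f"{t.onset:.3f}",
                "duration": f"{t.duration:.3f}",
                "trial_type": _trial_type(t),
                "isi_after": f"{t.isi_after:.1f}",
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path) -> TaskSequence:
    """Read an events table written by :func:`write_events`.

    Raises ``EventsParseError`` naming the 1-based file line of the first
    malformed row.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise EventsParseError(f"unexpected header {header}", 1)
        trials: list[TrialEvent] = []
        run_counters: dict[int, int] = {}
        for line_no, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(_COLUMNS):
                raise EventsParseError(
                    f"expected {len(_COLUMNS)} fields, got {len(fields)}", line_no
                )
            try:
                onset = float(fields[0])
                duration = float(fields[1])
                isi = float(fields[3])
            except ValueError as exc:
                raise EventsParseError(str(exc), line_no) from None
            if not (math.isfinite(onset) and math.isfinite(duration)):
                raise EventsParseError("non-finite onset/duration", line_no)
            run, congruent, emotion, label = _parse_trial_type(fields[2], line_no)
            run_counters[run] = run_counters.get(run, 0) + 1
            word = emotion.upper() if congruent else (
                "FEAR" if emotion == "happy" else "HAPPY"
            )
            trials.append(
                TrialEvent(
                    run_index=run,
                    trial_index=run_counters[run],
                    onset=onset,
                    duration=duration,
                    face_emotion=emotion,
                    word=word,
                    congruent=congruent,
                    adaptation_label=label,
                    isi_after=isi,
                )
            )
    n_runs = max(run_counters, default=0)
    return TaskSequence(trials=trials, n_runs=n_runs)


def events_filename(subject: int, session: int, run: int) -> str:
    """BIDS-style events filename for one run."""
    return f"sub-{subject:02d}_ses-{session:02d}_run-{run:02d}_events.tsv"
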