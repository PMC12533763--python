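"""Duration-normalized sentence frame and the 20 ms analysis-bin grid.

Every sentence in the design shares one word-timing frame: the five words
(``the1 agent verb the2 object``) were normalized to fixed durations, so a
single set of word onsets applies to all items.  Time zero is audio onset;
the 2000 ms image preview lives at negative times and is excluded from the
default analysis window, which runs from audio onset through the selection
cue (2000 ms after audio offset).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError

#: Canonical word order of the sentence frame.
WORD_LABELS = ("the1", "agent", "verb", "the2", "object")

#: Normalized word durations (ms) of the experimental sentence frame.
NORMALIZED_WORD_DURATIONS_MS: Mapping[str, float] = {
    "the1": 93.58,
    "agent": 612.72,
    "verb": 602.05,
    "the2": 130.27,
    "object": 464.45,
}

#: Delay (ms) between audio offset and the selection cue (green border).
DEFAULT_POST_STIMULUS_DELAY_MS = 2000.0

#: Duration (ms) of the image preview before audio onset.
DEFAULT_PREVIEW_MS = 2000.0

DEFAULT_BIN_MS = 20


@dataclass(frozen=True)
class StimulusTimeline:
    """Word onsets/durations of the normalized sentence frame.

    Onsets are cumulative sums of the durations, with the first word at
    t = 0 (audio onset).  ``selection_cue_ms`` is when the response cue
    appears, i.e. audio end plus the post-stimulus delay.
    """

    word_labels: tuple[str, ...]
    word_durations_ms: tuple[float, ...]
    word_onsets_ms: tuple[float, ...]
    audio_end_ms: float
    selection_cue_ms: float

    def onset(self, label: str) -> float:
        return self.word_onsets_ms[self.word_labels.index(label)]

    def duration(self, label: str) -> float:
        return self.word_durations_ms[self.word_labels.index(label)]

    def __post_init__(self) -> None:
        if len(self.word_labels) != len(self.word_durations_ms):
            raise ValidationError("word_labels and word_durations_ms lengths differ")
        for lab, dur in zip(self.word_labels, self.word_durations_ms):
            if not dur > 0:
                raise ValidationError(f"word {lab!r} has nonpositive duration {dur}")


def build_timeline(
    durations: Mapping[str, float] | None = None,
    post_delay_ms: float = DEFAULT_POST_STIMULUS_DELAY_MS,
) -> StimulusTimeline:
    """Build a :class:`StimulusTimeline` from an ordered label→duration map.

    Parameters
    ----------
    durations
        Ordered mapping of word label to duration in ms.  Defaults to the
        normalized durations of the experimental sentence frame.
    post_delay_ms
        Delay between audio offset and the selection cue.

    Raises
    ------
    ValidationError
        If any duration is missing, non-numeric or not strictly positive.
    """
    if durations is None:
        durations = NORMALIZED_WORD_DURATIONS_MS
    labels = tuple(durations)
    if not labels:
        raise ValidationError("timeline needs at least one word")
    durs = []
    for lab in labels:
        d = durations[lab]
        if d is None or not isinstance(d, (int, float)) or math.isnan(d):
            raise ValidationError(f"word {lab!r} has missing duration")
        if not d > 0:
            raise ValidationError(f"word {lab!r} has nonpositive duration {d}")
        durs.append(float(d))
    onsets = [0.0]
    for d in durs[:-1]:
        onsets.append(onsets[-1] + d)
    audio_end = onsets[-1] + durs[-1]
    return StimulusTimeline(
        word_labels=labels,
        word_durations_ms=tuple(durs),
        word_onsets_ms=tuple(onsets),
        audio_end_ms=audio_end,
        selection_cue_ms=audio_end + float(post_delay_ms),
    )


def default_timeline() -> StimulusTimeline:
    """The normalized sentence frame with the standard 2000 ms cue delay."""
    return build_timeline()


@dataclass(frozen=True)
class BinGrid:
    """Half-open 20 ms analysis bins over a time window.

    Bin ``i`` covers ``[window_start_ms + i*bin_ms, window_start_ms +
    (i+1)*bin_ms)``.  ``n_bins`` is the number of complete bins inside the
    window; a trailing partial bin is dropped.
    """

    bin_ms: int = DEFAULT_BIN_MS
    window_start_ms: float = 0.0
    window_end_ms: float = 3900.0

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ValidationError("bin_ms must be a positive integer")
        if self.window_end_ms <= self.window_start_ms:
            raise ValidationError("window_end_ms must exceed window_start_ms")
        if self.n_bins < 1:
            raise ValidationError("window shorter than one bin")

    @property
    def n_bins(self) -> int:
        return int(math.floor((self.window_end_ms - self.window_start_ms) / self.bin_ms))

    @property
    def bin_starts_ms(self):
        import numpy as np

        return self.window_start_ms + self.bin_ms * np.arange(self.n_bins)

    def bin_index(self, t_ms):
        """Index of the bin containing t (vectorized); −1 outside the window."""
        import numpy as np

        t = np.asarray(t_ms, dtype=float)
        idx = np.floor((t - self.window_start_ms) / self.bin_ms).astype(int)
        idx = np.where((idx < 0) | (idx >= self.n_bins), -1, idx)
        return idx if t.ndim else int(idx)

    @classmethod
    def for_timeline(
        cls,
        timeline: StimulusTimeline,
        bin_ms: int = DEFAULT_BIN_MS,
        window_start_ms: float = 0.0,
        window_end_ms: float | None = None,
    ) -> "BinGrid":
        """Default analysis grid: audio onset through the selection cue."""
        if window_end_ms is None:
            window_end_ms = timeline.selection_cue_ms
        return cls(bin_ms=bin_ms, window_start_ms=window_start_ms, window_end_ms=window_end_ms)


def round_to_bin(t_ms: float, grid: BinGrid) -> float:
    """Nearest multiple of the bin width; exact half-bin ties round up.

    Used for reporting word onsets of the fractional-ms sentence frame on
    the bin grid (e.g. a verb onset of 706.30 ms reports as 700 ms with
    20 ms bins).
    """
    b = grid.bin_ms
    return float(math.floor(t_ms / b + 0.5) * b)
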