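"""Raw signal -> 256-sample normalized movement vectors.

Locomotion: stance phases are segmented per foot with a 50 N threshold
(heel strike to toe-off), each contact is normalized by body weight and
time-normalized to 128 samples, and a left contact is concatenated with
the right contact that follows it, giving one 256-sample stride vector
that always begins with the left foot.

Handwriting: the pressure series is smoothed with a first-order
Savitzky-Golay filter (window 13), the first letter is extracted from
the pen-down signal (cutting at the pressure minimum between the W and
a connected 'e'), time-normalized to 256 samples, z-standardized and
scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .synthetic import GRAVITY, RawForceRecording, RawPenRecording

__all__ = [
    "MovementVector",
    "ContactInterval",
    "DegenerateSegmentError",
    "DegenerateTrialError",
    "EmptyTrialError",
    "TrialDiscardedError",
    "VECTOR_LENGTH",
    "detect_ground_contacts",
    "pair_contacts",
    "time_normalize",
    "build_stride_pair",
    "scale_unit_interval",
    "savitzky_golay",
    "extract_first_letter",
    "preprocess_writing",
    "locomotion_stride_vectors",
    "preprocess_locomotion",
]

VECTOR_LENGTH = 256
HALF_LENGTH = 128
DEFAULT_THRESHOLD_N = 50.0
SG_WINDOW = 13
SG_ORDER = 1


class DegenerateSegmentError(ValueError):
    """Segment too short to interpolate (< 2 samples)."""


class DegenerateTrialError(ValueError):
    """Constant trial cannot be scaled to [0, 1]."""


class EmptyTrialError(ValueError):
    """Pen recording contains no pen-down sample."""


class TrialDiscardedError(ValueError):
    """First letter not written in one piece; trial is dropped."""


@dataclass(frozen=True)
class ContactInterval:
    """Half-open [start, end) sample interval of one foot's stance."""

    start: int
    end: int
    foot: str = "left"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("contact interval must satisfy end > start")


@dataclass
class MovementVector:
    """One preprocessed trial: 256 values in [0, 1] plus labels.

    For locomotion, samples 0-127 are the left contact and 128-255 the
    right one.  ``origin`` distinguishes measured trials from trials
    produced by the translation model (which then carry the domain the
    signal was translated from in ``source_domain``).
    """

    values: np.ndarray
    domain: str
    subject_id: int | None = None
    condition: str | None = None
    source_trial_id: str | None = None
    origin: str = "original"
    source_domain: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (VECTOR_LENGTH,):
            raise ValueError(
                f"movement vector must have {VECTOR_LENGTH} values, "
                f"got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("movement vector contains non-finite values")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("movement vector values must lie in [0, 1]")


def detect_ground_contacts(force: np.ndarray,
                           threshold: float = DEFAULT_THRESHOLD_N,
                           foot: str = "left") -> list[ContactInterval]:
    """Maximal runs with force >= threshold, in temporal order.

    Runs touching the first or last sample are discarded as incomplete
    stances.  An empty series yields an empty list.
    """
    force = np.asarray(force, dtype=np.float64)
    if force.size == 0:
        return []
    if not np.all(np.isfinite(force)):
        raise ValueError("force series must be finite")
    if force.min() < 0:
        raise ValueError("force series must be non-negative")
    above = force >= threshold
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(force.size)
    intervals = []
    for s, e in zip(starts, ends):
        if s == 0 or e == force.size:
            continue  # clipped at the recording boundary
        intervals.append(ContactInterval(int(s), int(e), foot))
    return intervals


def pair_contacts(left: list[ContactInterval],
                  right: list[ContactInterval]
                  ) -> list[tuple[ContactInterval, ContactInterval]]:
    """Pair each left contact with the earliest right contact after it.

    Each right contact is used at most once; contacts without a partner
    are dropped (the behaviour when one foot's contact was deleted).
    """
    pairs = []
    j = 0
    for lc in left:
        while j < len(right) and right[j].start <= lc.start:
            j += 1
        if j == len(right):
            break
        pairs.append((lc, right[j]))
        j += 1
    return pairs


def time_normalize(segment: np.ndarray, target_len: int) -> np.ndarray:
    """Linearly interpolate a segment onto ``target_len`` equally spaced
    points spanning its first and last sample (endpoints preserved)."""
    segment = np.asarray(segment, dtype=np.float64)
    n = segment.size
    if n < 2:
        raise DegenerateSegmentError(
            f"cannot time-normalize a segment of {n} sample(s)")
    return np.interp(np.linspace(0.0, n - 1.0, target_len),
                     np.arange(n), segment)


def build_stride_pair(left_segment: np.ndarray, right_segment: np.ndarray,
                      body_mass: float) -> np.ndarray:
    """Body-weight-normalize and concatenate one left+right contact.

    Returns the 256-sample stride vector *before* unit-interval scaling.
    """
    if body_mass <= 0:
        raise ValueError("body mass must be positive")
    weight = body_mass * GRAVITY
    left = time_normalize(np.asarray(left_segment) / weight, HALF_LENGTH)
    right = time_normalize(np.asarray(right_segment) / weight, HALF_LENGTH)
    return np.concatenate([left, right])


def scale_unit_interval(vector: np.ndarray, mode: str = "per_trial",
                        global_min: float | None = None,
                        global_max: float | None = None) -> np.ndarray:
    """Affine map onto [0, 1].

    ``per_trial`` uses the vector's own min/max; ``global`` uses
    statistics computed on the translation-model training partition and
    clips the output to [0, 1].
    """
    vector = np.asarray(vector, dtype=np.float64)
    if mode == "per_trial":
        lo, hi = vector.min(), vector.max()
        if hi <= lo:
            raise DegenerateTrialError("constant trial cannot be scaled")
        return (vector - lo) / (hi - lo)
    if mode == "global":
        if global_min is None or global_max is None or global_max <= global_min:
            raise ValueError("global mode requires global_min < global_max")
        return np.clip((vector - global_min) / (global_max - global_min),
                       0.0, 1.0)
    raise ValueError(f"unknown scaling mode {mode!r}")


def savitzky_golay(series: np.ndarray, window: int = SG_WINDOW,
                   polyorder: int = SG_ORDER) -> np.ndarray:
    """Least-squares polynomial smoothing over a sliding window.

    Interior samples take the window-centre value of the local fit
    (for order 1 this equals the window mean); edges are filled by
    evaluating the polynomial fitted to the terminal window.
    """
    series = np.asarray(series, dtype=np.float64)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if series.size < window:
        raise ValueError(
            f"series of {series.size} samples shorter than window {window}")
    return savgol_filter(series, window, polyorder, mode="interp")


def _first_letter(series: np.ndarray) -> np.ndarray:
    """Extract the first letter from a pen-down pressure series.

    The first pen-down run must contain the four W strokes; if a fifth
    prominent stroke (a connected 'e') follows, the letter is cut at
    the pressure minimum between the fourth and fifth stroke.
    """
    series = np.asarray(series, dtype=np.float64)
    idx = np.flatnonzero(series > 0)
    if idx.size == 0:
        raise EmptyTrialError("recording contains no pen-down sample")
    gaps = np.flatnonzero(np.diff(idx) > 1)
    s = int(idx[0])
    e = int(idx[gaps[0]] + 1) if gaps.size else int(idx[-1] + 1)
    segment = series[s:e]
    peaks, _ = find_peaks(segment, prominence=0.05 * segment.max())
    if len(peaks) >= 5:
        rel_cut = peaks[3] + int(np.argmin(segment[peaks[3]:peaks[4]]))
        return segment[:rel_cut]
    if len(peaks) == 4:
        return segment
    raise TrialDiscardedError(
        f"first pen-down run holds {len(peaks)} prominent strokes; "
        "the letter was not written in one piece")


def extract_first_letter(raw: RawPenRecording) -> np.ndarray:
    """First-letter pressure samples of a raw pen recording."""
    return _first_letter(raw.pressure)


def preprocess_writing(raw: RawPenRecording, subject_id: int | None = None,
                       trial_id: str | None = None) -> MovementVector:
    """Full handwriting chain: filter -> first letter -> 256 samples ->
    z-standardize -> per-trial [0, 1] scaling."""
    filtered = savitzky_golay(raw.pressure)
    filtered = np.where(np.asarray(raw.pressure) > 0,
                        np.clip(filtered, 0.0, None), 0.0)
    letter = _first_letter(filtered)
    values = time_normalize(letter, VECTOR_LENGTH)
    sd = values.std()
    if sd == 0:
        raise DegenerateTrialError("constant letter signal")
    values = (values - values.mean()) / sd
    values = scale_unit_interval(values, mode="per_trial")
    return MovementVector(values=values, domain="writing",
                          subject_id=subject_id, condition=raw.condition,
                          source_trial_id=trial_id)


def locomotion_stride_vectors(raw: RawForceRecording,
                              threshold: float = DEFAULT_THRESHOLD_N
                              ) -> list[np.ndarray]:
    """All unscaled 256-sample stride vectors of a locomotion recording."""
    left = detect_ground_contacts(raw.left, threshold, foot="left")
    right = detect_ground_contacts(raw.right, threshold, foot="right")
    vectors = []
    for lc, rc in pair_contacts(left, right):
        vectors.append(build_stride_pair(raw.left[lc.start:lc.end],
                                         raw.right[rc.start:rc.end],
                                         raw.body_mass))
    return vectors


def preprocess_locomotion(raw: RawForceRecording, domain: str,
                          subject_id: int | None = None,
                          trial_id: str | None = None,
                          threshold: float = DEFAULT_THRESHOLD_N,
                          scaling: str = "per_trial",
                          global_min: float | None = None,
                          global_max: float | None = None
                          ) -> list[MovementVector]:
    """Segment, pair, normalize and scale one locomotion recording.

    With ``scaling='global'`` the caller supplies min/max statistics
    from the translation-model training partition.
    """
    vectors = []
    for i, vec in enumerate(locomotion_stride_vectors(raw, threshold)):
        scaled = scale_unit_interval(vec, mode=scaling,
                                     global_min=global_min,
                                     global_max=global_max)
        suffix = f"_p{i:03d}" if trial_id is not None else None
        vectors.append(MovementVector(
            values=scaled, domain=domain, subject_id=subject_id,
            condition=raw.condition,
            source_trial_id=(trial_id + suffix) if trial_id else None))
    return vectors
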