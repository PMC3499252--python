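"""Behavioral scoring: E_SI, ICL%, vulva-contact metrics, centroid kinematics.

The spicule-insertion efficiency score E_SI summarises, for one male paired
with a paralyzed hermaphrodite and observed for at most 120 s of contact,

    E_SI = (t_prod / t_total) * (1 / max(t_nonprod, 1 s)) * (1 + bonus)

where ``t_prod`` is time spent prodding the vulva (insertion attempts),
``t_nonprod`` is time in contact but not attempting insertion (e.g.
scanning), ``t_total = t_prod + t_nonprod``, and the bonus is the fraction
of the observation window remaining after a successful spicule penetration
(0 if no penetration).  A male that prods immediately and penetrates ~1 s
after contact scores ~1.99; a male that spends the whole window in contact
without a single vulval insertion attempt scores 0.

The penalty denominator is clamped at 1 s: a perfectly diligent male has
zero non-productive contact, and the unclamped formula would be undefined
exactly where the score should be maximal.  The clamp is the minimal rule
that reproduces the canonical 1.99 = 1 x 1 x (1 + 119/120) score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

#: Fixed vocabulary of timeline labels. ``off`` means not in contact with the
#: mate; ``scanning`` covers all non-productive contact (backward scanning and
#: ectopic, off-vulva prodding); ``vulva_prodding`` is spicule insertion
#: attempts at the vulval slit; ``insertion`` marks successful penetration and
#: is terminal.
TIMELINE_LABELS = ("off", "scanning", "vulva_prodding", "insertion")

#: Labels that count as contact with the hermaphrodite.
CONTACT_LABELS = ("scanning", "vulva_prodding", "insertion")

DEFAULT_OBSERVATION_CAP = 120.0


@dataclass
class BehaviorTimeline:
    """Labeled, non-overlapping behavioral intervals for one male.

    ``intervals`` is an ordered list of ``(start_s, end_s, label)`` tuples
    with labels drawn from :data:`TIMELINE_LABELS`.  At most one
    ``insertion`` interval is allowed and it must be the last one; its start
    is the penetration time.
    """

    intervals: list
    observation_cap: float = DEFAULT_OBSERVATION_CAP

    def __post_init__(self) -> None:
        if self.observation_cap <= 0:
            raise ValueError("observation_cap must be positive")
        prev_end = -math.inf
        for i, (start, end, label) in enumerate(self.intervals):
            if label not in TIMELINE_LABELS:
                raise ValueError(f"unknown timeline label {label!r}")
            if not start < end:
                raise ValueError(
                    f"interval {i} has non-positive duration ({start}, {end})"
                )
            if start < prev_end:
                raise ValueError(f"interval {i} overlaps its predecessor")
            prev_end = end
        ins = [i for i, iv in enumerate(self.intervals) if iv[2] == "insertion"]
        if len(ins) > 1:
            raise ValueError("at most one insertion interval is allowed")
        if ins and ins[0] != len(self.intervals) - 1:
            raise ValueError("the insertion interval must be terminal")

    @property
    def penetration_time(self) -> Optional[float]:
        """Start of the ``insertion`` interval, or None if no penetration."""
        if self.intervals and self.intervals[-1][2] == "insertion":
            return self.intervals[-1][0]
        return None

    @property
    def penetrated(self) -> bool:
        return self.penetration_time is not None

    def total(self, label: str, t_max: Optional[float] = None) -> float:
        """Total duration carrying ``label`` within ``[0, t_max)``."""
        if t_max is None:
            t_max = self.observation_cap
        tot = 0.0
        for start, end, lab in self.intervals:
            if lab == label:
                tot += max(0.0, min(end, t_max) - min(start, t_max))
        return tot


@dataclass
class EsiResult:
    """Spicule-insertion efficiency score and its components (seconds)."""

    t_prod: float
    t_nonprod: float
    t_total: float
    penetrated: bool
    bonus: float
    score: float


@dataclass
class ContactMetrics:
    n_vulva_contacts: int
    total_vulva_contact: float
    mean_interval_between_attempts: Optional[float]
    cumulative_contact: float
    average_contact: float


@dataclass
class CentroidTrack:
    """Centroid trajectory of a crawling male.

    ``times`` in seconds (strictly increasing), ``xy`` of shape ``(n, 2)``
    in pixels, ``px_per_mm`` the spatial calibration.
    """

    times: np.ndarray
    xy: np.ndarray
    px_per_mm: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n_frames, 2)")
        if len(self.times) != len(self.xy):
            raise ValueError("times and xy lengths differ")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")


@dataclass
class KinematicsResult:
    """Distance traveled (mm) and per-step velocity series (mm/s)."""

    distance_mm: float
    velocity_mm_s: np.ndarray
    step_times: np.ndarray


def compute_esi(timeline: BehaviorTimeline) -> EsiResult:
    """Score one male's timeline with the spicule-insertion efficiency index.

    Durations are truncated at the observation cap and, when the male
    penetrates, at the penetration time (observation stops there).  Raises
    ``ValueError`` when the timeline contains no contact at all.
    """
    cap = timeline.observation_cap
    pen = timeline.penetration_time
    window_end = cap if pen is None else min(pen, cap)

    t_prod = timeline.total("vulva_prodding", window_end)
    t_nonprod = timeline.total("scanning", window_end)
    t_total = t_prod + t_nonprod
    if t_total <= 0:
        raise ValueError("timeline contains no contact time; E_SI undefined")

    penetrated = pen is not None and pen < cap
    bonus = (cap - pen) / cap if penetrated else 0.0
    score = (t_prod / t_total) * (1.0 / max(t_nonprod, 1.0)) * (1.0 + bonus)
    return EsiResult(
        t_prod=t_prod,
        t_nonprod=t_nonprod,
        t_total=t_total,
        penetrated=penetrated,
        bonus=bonus,
        score=score,
    )


def compute_icl(contact_length: float, body_length: float) -> float:
    """In-contact length as a percentage of total body length.

    ``contact_length`` is the length of the male body outline touching the
    mate's cuticle; both lengths in the same units (e.g. pixels).  Low ICL%
    indicates an arched posture.
    """
    if body_length <= 0:
        raise ValueError("body_length must be positive")
    if contact_length < 0:
        raise ValueError("contact_length must be non-negative")
    if contact_length > body_length:
        raise ValueError("contact_length cannot exceed body_length")
    return 100.0 * contact_length / body_length


def contact_metrics(timeline: BehaviorTimeline) -> ContactMetrics:
    """Vulva-contact counts and durations for one timeline.

    A *contact episode* is a maximal run of time-adjacent non-``off``
    intervals.  The mean interval between insertion attempts is the mean
    in-contact time separating successive ``vulva_prodding`` bouts, and is
    ``None`` when fewer than two such bouts exist.
    """
    iv = timeline.intervals
    prod = [(s, e) for s, e, lab in iv if lab == "vulva_prodding"]
    n_vulva = len(prod)
    total_vulva = sum(e - s for s, e in prod)

    # in-contact time separating successive prodding bouts
    intervals_between = []
    for (s0, e0), (s1, e1) in zip(prod, prod[1:]):
        between = 0.0
        for s, e, lab in iv:
            if lab in CONTACT_LABELS and lab != "vulva_prodding":
                between += max(0.0, min(e, s1) - max(s, e0))
        intervals_between.append(between)
    mean_between = float(np.mean(intervals_between)) if intervals_between else None

    # contact episodes: merge adjacent contact intervals
    cumulative = 0.0
    n_episodes = 0
    prev_end = None
    for s, e, lab in iv:
        if lab not in CONTACT_LABELS:
            prev_end = None
            continue
        cumulative += e - s
        if prev_end is None or s > prev_end + 1e-9:
            n_episodes += 1
        prev_end = e
    average = cumulative / n_episodes if n_episodes else 0.0

    return ContactMetrics(
        n_vulva_contacts=n_vulva,
        total_vulva_contact=total_vulva,
        mean_interval_between_attempts=mean_between,
        cumulative_contact=cumulative,
        average_contact=average,
    )


def centroid_kinematics(track: CentroidTrack) -> KinematicsResult:
    """Distance traveled and per-step velocity from a centroid trajectory."""
    if len(track.times) < 2:
        raise ValueError("at least two frames are required for kinematics")
    steps_px = np.linalg.norm(np.diff(track.xy, axis=0), axis=1)
    dts = np.diff(track.times)
    steps_mm = steps_px / track.px_per_mm
    velocity = steps_mm / dts
    return KinematicsResult(
        distance_mm=float(steps_mm.sum()),
        velocity_mm_s=velocity,
        step_times=track.times[1:],
    )


def potency_fraction(outcomes: Sequence) -> tuple:
    """Proportion of potent males (sired cross-progeny) and the sample size.

    ``outcomes`` may contain booleans or the strings ``"potent"`` /
    ``"not_potent"``.  Returns ``(proportion, n)``.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes supplied")
    flags = []
    for o in outcomes:
        if isinstance(o, str):
            if o not in ("potent", "not_potent"):
                raise ValueError(f"unknown outcome {o!r}")
            flags.append(o == "potent")
        else:
            flags.append(bool(o))
    return sum(flags) / len(flags), len(flags)
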