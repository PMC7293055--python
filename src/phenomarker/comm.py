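"""Call and text-message biomarkers from event logs.

Texts: distribution features of inter-message gaps (all / incoming /
outgoing), the across-contact SD of each per-contact gap feature
(contact variability), and the total message count.
Calls: total count, fraction missed, fraction arriving while the phone was
idle, distinct contacts, and distribution features of inter-call gaps.

Gap vectors with fewer than three gaps yield MISSING (NaN) distribution
features rather than silent zeros; tree learners downstream route NaN
natively.  All functions sort events internally, so input order never
affects a biomarker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .accel import DIST_FEATURE_NAMES, distribution_features
from .cohort import CommEvent

__all__ = [
    "TextBiomarkers",
    "CallBiomarkers",
    "interevent_gaps",
    "text_biomarkers",
    "call_biomarkers",
    "TEXT_FEATURE_COUNT",
    "CALL_FEATURE_COUNT",
]

TEXT_FEATURE_COUNT = 3 * 109 + 109 + 1   # 437
CALL_FEATURE_COUNT = 4 + 109             # 113

_NAN109 = np.full(109, math.nan)


@dataclass
class TextBiomarkers:
    gaps_all: np.ndarray          # 109 distribution features (or NaN)
    gaps_incoming: np.ndarray
    gaps_outgoing: np.ndarray
    contact_variability: np.ndarray
    total_texts: int

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.gaps_all, self.gaps_incoming, self.gaps_outgoing,
            self.contact_variability, [float(self.total_texts)],
        ])


@dataclass
class CallBiomarkers:
    total_calls: int
    pct_missed: float
    pct_idle: float
    n_contacts: int
    gaps: np.ndarray

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            [float(self.total_calls), self.pct_missed, self.pct_idle,
             float(self.n_contacts)], self.gaps,
        ])


def _sorted_times(events: Iterable[CommEvent]) -> np.ndarray:
    return np.sort(np.array([e.timestamp for e in events], dtype=float))


def interevent_gaps(events: Sequence[CommEvent], selector: str = "all"):
    """Gaps (seconds) between consecutive selected events.

    selector: 'all', 'incoming', 'outgoing', or 'per-contact' (the latter
    returns a dict contact_id -> gap vector).  Empty selections yield empty
    vectors.
    """
    if selector == "per-contact":
        out: dict[str, np.ndarray] = {}
        contacts = sorted({e.contact_id for e in events})
        for c in contacts:
            t = _sorted_times(e for e in events if e.contact_id == c)
            out[c] = np.diff(t)
        return out
    if selector in ("incoming", "outgoing"):
        events = [e for e in events if e.direction == selector]
    elif selector != "all":
        raise ValueError(f"unknown selector {selector!r}")
    return np.diff(_sorted_times(events))


def _dist_or_missing(gaps: np.ndarray) -> np.ndarray:
    if len(gaps) < 3:
        return _NAN109.copy()
    return distribution_features(gaps)


def text_biomarkers(events: Sequence[CommEvent]) -> TextBiomarkers:
    """Text-message biomarkers; *events* must contain only texts."""
    if any(e.channel != "text" for e in events):
        raise ValueError("text_biomarkers received non-text events")
    gaps_all = interevent_gaps(events, "all")
    feats = TextBiomarkers(
        gaps_all=_dist_or_missing(gaps_all),
        gaps_incoming=_dist_or_missing(interevent_gaps(events, "incoming")),
        gaps_outgoing=_dist_or_missing(interevent_gaps(events, "outgoing")),
        contact_variability=_contact_variability(events),
        total_texts=len(events),
    )
    return feats


def _contact_variability(events: Sequence[CommEvent]) -> np.ndarray:
    """SD across contacts of each per-contact gap distribution feature.

    Per-contact features use relaxed rules (>= 1 gap, i.e. >= 2 events per
    contact); contacts with fewer events contribute nothing.  The SD is the
    population (divide-by-n) convention over contacts with a defined value,
    so a single contact yields an all-zero vector.  No eligible contact at
    all yields MISSING.
    """
    per_contact = interevent_gaps(events, "per-contact")
    rows = []
    for gaps in per_contact.values():
        if len(gaps) >= 1:
            rows.append(distribution_features(gaps, relaxed=True))
    if not rows:
        return _NAN109.copy()
    mat = np.vstack(rows)
    out = np.empty(109)
    for j in range(109):
        col = mat[:, j]
        col = col[np.isfinite(col)]
        out[j] = float(np.std(col)) if len(col) else math.nan
    return out


def call_biomarkers(events: Sequence[CommEvent]) -> CallBiomarkers:
    """Call biomarkers; *events* must contain only calls.

    pct_missed = missed incoming calls / total calls; pct_idle is the share
    of all calls flagged as arriving while the phone was idle.  With zero
    calls, counts are 0 and the proportions and gap features are MISSING.
    """
    if any(e.channel != "call" for e in events):
        raise ValueError("call_biomarkers received non-call events")
    n = len(events)
    if n == 0:
        return CallBiomarkers(0, math.nan, math.nan, 0, _NAN109.copy())
    missed = sum(1 for e in events if e.status == "missed")
    idle = sum(1 for e in events if e.phone_idle)
    return CallBiomarkers(
        total_calls=n,
        pct_missed=missed / n,
        pct_idle=idle / n,
        n_contacts=len({e.contact_id for e in events}),
        gaps=_dist_or_missing(interevent_gaps(events, "all")),
    )
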