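"""Position-specific active-site profiles for PRX subfamily classification.

The modern PRX classification keys on the sequence surrounding the
peroxidatic cysteine (C_P).  A query window of +/-w residues around C_P is
scored against each subfamily profile; the score is the mean per-position
log-odds of the observed residue against a uniform 1/20 background.  The
best label wins only if its margin over the runner-up clears a threshold,
otherwise the sequence stays unclassified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

BACKGROUND = 1.0 / 20.0
_STANDARD = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SubfamilyProfile:
    """Consensus-with-concentration residue profile over a C_P window."""

    label: str
    consensus: str
    concentration: float = 0.7

    def prob(self, position: int, residue: str) -> float:
        """Probability of ``residue`` at 0-based window ``position``.

        ``X`` (unknown) and any non-standard residue score at background,
        i.e. neutrally.  ``U`` is treated as ``C`` here: profile scoring is
        not where the Sec/Cys call is made.
        """
        if residue == "U":
            residue = "C"
        if residue not in _STANDARD:
            return BACKGROUND
        if residue == self.consensus[position]:
            return self.concentration
        return (1.0 - self.concentration) / 19.0

    def score(self, window: str, offset: int = 0) -> float:
        """Mean log-odds of ``window`` against this profile.

        ``offset`` aligns a truncated window: it is the 0-based profile
        position of the window's first residue (windows clipped at a
        sequence end score over the available positions only).
        """
        n = len(self.consensus)
        scores = []
        for i, res in enumerate(window):
            pos = offset + i
            if 0 <= pos < n:
                scores.append(math.log(self.prob(pos, res) / BACKGROUND))
        if not scores:
            raise ValueError("window does not overlap the profile")
        return sum(scores) / len(scores)


def load_profiles(path=None) -> tuple[dict[str, SubfamilyProfile], int]:
    """Load bundled (or user-supplied) subfamily profiles.

    Returns (label -> profile, window half-width).
    """
    if path is None:
        raw = json.loads(
            resources.files("peroxfam.data").joinpath("prx_profiles.json").read_text()
        )
    else:
        with open(path) as fh:
            raw = json.load(fh)
    w = int(raw["window_halfwidth"])
    profiles = {
        label: SubfamilyProfile(
            label=label,
            consensus=d["consensus"],
            concentration=float(d.get("concentration", 0.7)),
        )
        for label, d in raw["profiles"].items()
    }
    for p in profiles.values():
        if len(p.consensus) != 2 * w + 1:
            raise ValueError(
                f"profile {p.label}: consensus length {len(p.consensus)} != {2*w+1}"
            )
    return profiles, w


def extract_window(sequence: str, cp_position: int, halfwidth: int) -> tuple[str, int, bool]:
    """Window of +/-``halfwidth`` residues around a 1-based C_P position.

    Returns (window, profile offset of first residue, truncated flag).
    """
    n = len(sequence)
    lo = cp_position - 1 - halfwidth  # 0-based, may be negative
    hi = cp_position - 1 + halfwidth  # inclusive
    start = max(0, lo)
    end = min(n - 1, hi)
    window = sequence[start : end + 1]
    offset = start - lo
    truncated = (start != lo) or (end != hi)
    return window, offset, truncated


@dataclass(frozen=True)
class ProfileScore:
    label: str | None
    scores: Mapping[str, float]
    margin: float
    truncated: bool


def classify_window(
    sequence: str,
    cp_position: int,
    profiles: Mapping[str, SubfamilyProfile],
    halfwidth: int,
    margin_threshold: float = 0.5,
) -> ProfileScore:
    """Score the C_P window against every profile; label iff the margin clears.

    The margin is best score minus runner-up score (in mean-nats).  A margin
    below ``margin_threshold`` leaves the sequence unlabelled, so raising
    the threshold can only convert classified -> unclassified.
    """
    window, offset, truncated = extract_window(sequence, cp_position, halfwidth)
    scores = {label: p.score(window, offset) for label, p in profiles.items()}
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        margin = math.inf
    else:
        margin = ranked[0][1] - ranked[1][1]
    label = ranked[0][0] if margin >= margin_threshold else None
    return ProfileScore(label=label, scores=scores, margin=margin, truncated=truncated)
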