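"""Points-based ACMG/AMP evidence scoring and five-band classification.

Each asserted criterion (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7, ...)
carries a strength, worth 8 points for very strong, 4 for strong, 2 for
moderate and 1 for supporting evidence.  Pathogenic-direction criteria add
points, benign-direction criteria subtract the same magnitude.  The summed
evidence score ``x`` maps onto five bands::

    x < 0        benign / likely benign (B/LB)
    0 <= x < 5   variant of uncertain significance (VUS)
    x == 5       VUS favouring pathogenic (VUS-FP)
    6 <= x < 10  likely pathogenic (LP)
    x >= 10      pathogenic (P)

With integer weights the open interval (5, 6) is unreachable; the
classifier folds it into VUS-FP so that the bands partition the reals even
under a user-supplied non-integer weight table.

Strength modulation (e.g. applying PM2 at supporting strength) is the
caller's responsibility: codes are validated only for uniqueness, never for
code/strength compatibility, since criterion assessment happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .errors import InvalidInputError

__all__ = [
    "Direction",
    "Strength",
    "Band",
    "EvidenceAssertion",
    "DEFAULT_WEIGHTS",
    "weight_of",
    "score_variant",
    "classify_score",
    "classify_assertions",
    "parse_assertions",
    "format_assertions",
    "band_index",
]


class Direction(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Band(str, Enum):
    """Five-band classification, ordered from benign to pathogenic."""

    BENIGN_LIKELY_BENIGN = "B/LB"
    VUS = "VUS"
    VUS_FP = "VUS-FP"
    LIKELY_PATHOGENIC = "LP"
    PATHOGENIC = "P"


_BAND_ORDER = [
    Band.BENIGN_LIKELY_BENIGN,
    Band.VUS,
    Band.VUS_FP,
    Band.LIKELY_PATHOGENIC,
    Band.PATHOGENIC,
]


def band_index(band: Band) -> int:
    """Position of *band* on the benign-to-pathogenic ordering (0..4)."""
    return _BAND_ORDER.index(Band(band))


#: Points per strength level.  A JSON config may override this table.
DEFAULT_WEIGHTS: Mapping[Strength, int] = {
    Strength.VERY_STRONG: 8,
    Strength.STRONG: 4,
    Strength.MODERATE: 2,
    Strength.SUPPORTING: 1,
}


@dataclass(frozen=True)
class EvidenceAssertion:
    """One asserted ACMG criterion with its direction and strength."""

    code: str
    direction: Direction
    strength: Strength

    def __post_init__(self):
        if not self.code:
            raise InvalidInputError("assertion code must be non-empty")
        object.__setattr__(self, "direction", Direction(self.direction))
        object.__setattr__(self, "strength", Strength(self.strength))


def weight_of(
    assertion: EvidenceAssertion,
    weights: Mapping[Strength, int] | None = None,
) -> int:
    """Signed point value of one assertion.

    Pathogenic-direction assertions contribute +8/+4/+2/+1 for very strong /
    strong / moderate / supporting; benign-direction assertions contribute
    the negated magnitude (required for the x < 0 benign band to be
    reachable).
    """
    table = DEFAULT_WEIGHTS if weights is None else weights
    try:
        magnitude = table[Strength(assertion.strength)]
    except (KeyError, ValueError) as exc:
        raise InvalidInputError(
            f"unknown strength {assertion.strength!r}"
        ) from exc
    return magnitude if assertion.direction == Direction.PATHOGENIC else -magnitude


def score_variant(
    assertions: Iterable[EvidenceAssertion],
    weights: Mapping[Strength, int] | None = None,
) -> int:
    """Tabulate the evidence score: the sum of signed assertion weights.

    The empty set scores 0.  Duplicate criterion codes are rejected — each
    criterion may be asserted at most once per variant.
    """
    assertions = list(assertions)
    codes = [a.code for a in assertions]
    if len(codes) != len(set(codes)):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise InvalidInputError(f"duplicate criterion codes: {', '.join(dupes)}")
    return sum(weight_of(a, weights) for a in assertions)


def classify_score(score: float) -> Band:
    """Map an evidence score onto its classification band."""
    if score < 0:
        return Band.BENIGN_LIKELY_BENIGN
    if score < 5:
        return Band.VUS
    if score < 6:
        return Band.VUS_FP
    if score < 10:
        return Band.LIKELY_PATHOGENIC
    return Band.PATHOGENIC


def classify_assertions(
    assertions: Iterable[EvidenceAssertion],
    weights: Mapping[Strength, int] | None = None,
) -> Band:
    """Score an assertion set and classify it in one step."""
    return classify_score(score_variant(assertions, weights))


# ---------------------------------------------------------------------------
# TSV token dialect: semicolon-joined "CODE:STRENGTH[:B]", B marking a
# benign-direction assertion, e.g. "PVS1:very_strong;PM2:moderate" or
# "BA1:very_strong:B".

def parse_assertions(text: str) -> list[EvidenceAssertion]:
    """Parse a semicolon-joined criteria token string.

    Empty string or the missing-value marker "." yields an empty list.
    """
    text = (text or "").strip()
    if text in ("", "."):
        return []
    out = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        parts = token.split(":")
        if len(parts) not in (2, 3):
            raise InvalidInputError(f"malformed criteria token {token!r}")
        code, strength = parts[0], parts[1].lower()
        direction = Direction.PATHOGENIC
        if len(parts) == 3:
            if parts[2].upper() != "B":
                raise InvalidInputError(f"malformed criteria token {token!r}")
            direction = Direction.BENIGN
        try:
            strength_enum = Strength(strength)
        except ValueError as exc:
            raise InvalidInputError(
                f"unknown strength {strength!r} in token {token!r}"
            ) from exc
        out.append(EvidenceAssertion(code, direction, strength_enum))
    return out


def format_assertions(assertions: Iterable[EvidenceAssertion]) -> str:
    """Emit assertions back in the TSV token dialect ("." if empty)."""
    tokens = []
    for a in assertions:
        token = f"{a.code}:{a.strength.value}"
        if a.direction == Direction.BENIGN:
            token += ":B"
        tokens.append(token)
    return ";".join(tokens) if tokens else "."
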