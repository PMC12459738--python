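"""Questionnaire scoring, clinical cut-offs, count transforms and the model time basis.

The outcome instruments are the 16-item QIDS (Quick Inventory of Depressive
Symptomatology, scored onto the 0-27 severity metric by the standard 9-domain
rule) and the Brief LSAS (14 social situations, each rated 0-3 for fear and
for avoidance), administered once per virtual-community and once per
physical-community context.  Brief LSAS raw totals are rescaled by 24/14 onto
the full 24-item LSAS metric so the established clinical cut-off of 30 applies;
the QIDS cut-off is 6.

Game behaviour counts (bell rings, avatar customizations) are heavy tailed and
are analysed as ``log2(count + 1)``.

The latent growth curve's time basis uses the same transform on elapsed months:
``F[t] = log2(months + 1)``, which for waves at 0, 1, 2, 3 months gives the
loadings 0.000, 1.000, 1.585, 2.000 and encodes fast-then-slow symptom change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "QidsResponse",
    "BriefLsasResponse",
    "TimeBasis",
    "score_qids",
    "score_brief_lsas",
    "adjust_lsas",
    "classify_depression",
    "classify_social_anxiety",
    "log2p1",
    "time_basis",
    "LSAS_RESCALE",
    "QIDS_CUTOFF",
    "LSAS_CUTOFF",
]

#: rescaling factor mapping the 14-item Brief LSAS raw total onto the 24-item metric
LSAS_RESCALE = 24.0 / 14.0
#: clinical cut-off on the QIDS total (inclusive)
QIDS_CUTOFF = 6
#: clinical cut-off on the adjusted (24-item metric) LSAS score (inclusive)
LSAS_CUTOFF = 30.0

# QIDS 9-domain scoring: index groups over the 16 items (0-based).
# Domains scored as the max of their group; singleton domains pass through.
_QIDS_DOMAINS: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 3),      # sleep (initial/middle/late insomnia, hypersomnia)
    (4,),              # sad mood
    (5, 6, 7, 8),      # appetite / weight change
    (9,),              # concentration / decision making
    (10,),             # self-view
    (11,),             # suicidal ideation
    (12,),             # general interest
    (13,),             # energy level
    (14, 15),          # psychomotor slowing / agitation
)


def _check_items(items: Sequence[int], n: int, label: str) -> list[int]:
    vals = list(items)
    if len(vals) != n:
        raise ValueError(f"{label}: expected {n} items, got {len(vals)}")
    for k, v in enumerate(vals):
        if not float(v).is_integer() or not (0 <= int(v) <= 3):
            raise ValueError(f"{label}: item {k + 1} = {v!r} outside 0..3")
    return [int(v) for v in vals]


@dataclass(frozen=True)
class QidsResponse:
    """One participant's 16 QIDS item responses, each on the 0-3 scale."""

    items: Sequence[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(_check_items(self.items, 16, "QIDS")))


@dataclass(frozen=True)
class BriefLsasResponse:
    """Brief LSAS response: fear and avoidance ratings for 14 situations.

    ``context`` records whether the situations were framed in the virtual
    (in-game) or physical community.
    """

    fear: Sequence[int]
    avoidance: Sequence[int]
    context: Literal["virtual", "physical"]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fear", tuple(_check_items(self.fear, 14, "LSAS fear")))
        object.__setattr__(
            self, "avoidance", tuple(_check_items(self.avoidance, 14, "LSAS avoidance"))
        )
        if self.context not in ("virtual", "physical"):
            raise ValueError(f"context must be 'virtual' or 'physical', got {self.context!r}")


def score_qids(resp: QidsResponse, *, plain_sum: bool = False) -> int:
    """Total QIDS severity on the 0-27 metric.

    The standard rule forms 9 domain scores — max over the sleep group, max
    over the appetite/weight group, max over the psychomotor pair, the six
    remaining items as-is — and sums them.  ``plain_sum=True`` instead sums
    all 16 items (a sensitivity-check variant, 0-48 metric).
    """
    if plain_sum:
        return int(sum(resp.items))
    return int(sum(max(resp.items[i] for i in grp) for grp in _QIDS_DOMAINS))


def score_brief_lsas(resp: BriefLsasResponse) -> int:
    """Raw Brief LSAS total: sum of fear and avoidance ratings (0-84)."""
    return int(sum(resp.fear) + sum(resp.avoidance))


def adjust_lsas(raw: float) -> float:
    """Rescale a Brief LSAS raw total onto the 24-item LSAS metric (x 24/14)."""
    if raw < 0:
        raise ValueError(f"raw LSAS total must be non-negative, got {raw}")
    return raw * 24.0 / 14.0  # multiply first: exact at the cut-off (17.5 -> 30.0)


def classify_depression(qids_total: float) -> bool:
    """True when the QIDS total meets the clinical cut-off (>= 6)."""
    if not (0 <= qids_total <= 27):
        raise ValueError(f"QIDS total must lie in 0..27, got {qids_total}")
    return qids_total >= QIDS_CUTOFF


def classify_social_anxiety(adjusted: float) -> bool:
    """True when the adjusted LSAS score meets the clinical cut-off (>= 30)."""
    if adjusted < 0:
        raise ValueError(f"adjusted LSAS score must be non-negative, got {adjusted}")
    return adjusted >= LSAS_CUTOFF


def log2p1(count):
    """``log2(count + 1)`` — the transform applied to behaviour counts.

    Accepts scalars or arrays of non-negative counts; 0 maps to 0 and the
    transform is strictly increasing.
    """
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(count) or arr.ndim == 0 else out


@dataclass(frozen=True)
class TimeBasis:
    """Measurement waves, their times in months, and the slope loadings F[t]."""

    months: tuple[float, ...]
    loadings: tuple[float, ...] = field(init=False)
    waves: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        m = tuple(float(x) for x in self.months)
        if len(m) == 0:
            raise ValueError("time basis needs at least one wave")
        if any(x < 0 for x in m):
            raise ValueError("wave times must be non-negative")
        if any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError("wave times must be strictly increasing")
        object.__setattr__(self, "months", m)
        object.__setattr__(self, "loadings", tuple(float(np.log2(x + 1.0)) for x in m))
        object.__setattr__(self, "waves", tuple(range(1, len(m) + 1)))

    @property
    def n_waves(self) -> int:
        return len(self.months)

    def loading_array(self) -> np.ndarray:
        return np.asarray(self.loadings, dtype=float)


def time_basis(months: Sequence[float]) -> TimeBasis:
    """Build the log-time basis ``F[t] = log2(months + 1)`` for the given waves.

    The first wave must be at 0 months so the intercept is the baseline level.
    """
    m = list(months)
    if not m or m[0] != 0:
        raise ValueError("the first wave must be at 0 months (baseline)")
    return TimeBasis(months=tuple(m))
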