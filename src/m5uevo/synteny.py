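"""Gene-neighborhood conservation scores used as orthology evidence.

Scores use set semantics over ortholog families within a +/- k gene window:
gene order and strand are deliberately ignored, since the underlying
comparison is of regional gene content, not exact order conservation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .datamodel import GeneNeighborhood

DEFAULT_WINDOW = 5
#: Jaccard score at or above which a neighborhood counts as conserved
#: context for a subfamily (shared with the subfamily classifier).
CONTEXT_THRESHOLD = 0.3


@dataclass
class ContextProfile:
    """Reference neighbor sets of one subfamily, one set per genome."""

    family_id: str
    reference_neighbor_sets: list[frozenset[str]] = field(default_factory=list)
    window: int = DEFAULT_WINDOW

    def __post_init__(self):
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        self.reference_neighbor_sets = [
            frozenset(s) - {self.family_id} for s in self.reference_neighbor_sets
        ]


def _jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def neighborhood_jaccard(a: GeneNeighborhood, b: GeneNeighborhood, k: int = DEFAULT_WINDOW) -> float:
    """Jaccard similarity of the two ortholog-family sets within +/- k genes."""
    if k < 1:
        raise ValueError(f"window k must be >= 1, got {k}")
    return _jaccard(a.family_set(k), b.family_set(k))


def context_score(query: GeneNeighborhood, profile: ContextProfile) -> float:
    """Best-match conservation of ``query`` against the profile (max Jaccard)."""
    if not profile.reference_neighbor_sets:
        raise ValueError(f"empty context profile for {profile.family_id}")
    qset = query.family_set(profile.window)
    return max(_jaccard(qset, ref) for ref in profile.reference_neighbor_sets)


def build_profile(
    neighborhoods: list[GeneNeighborhood], family_id: str, window: int = DEFAULT_WINDOW
) -> ContextProfile:
    return ContextProfile(
        family_id=family_id,
        reference_neighbor_sets=[n.family_set(window) for n in neighborhoods],
        window=window,
    )


def profile_to_json(profile: ContextProfile) -> str:
    return json.dumps(
        {
            "family_id": profile.family_id,
            "window": profile.window,
            "reference_neighbor_sets": [sorted(s) for s in profile.reference_neighbor_sets],
        },
        indent=2,
        sort_keys=True,
    )


def profile_from_json(text: str) -> ContextProfile:
    payload = json.loads(text)
    return ContextProfile(
        family_id=payload["family_id"],
        reference_neighbor_sets=[frozenset(s) for s in payload["reference_neighbor_sets"]],
        window=payload["window"],
    )
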