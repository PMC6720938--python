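"""Interaction-score confirmation of fished compound-target pairs.

Docking-style scores use the energy convention: more negative means
stronger binding.  A candidate pair is confirmed when its score is at or
below the cutoff (study default −8.0).  Scoring itself is pluggable — any
(compound_id, target_id, score) table can be supplied — and a deterministic
stub scorer is provided for testing.
"""

from __future__ import annotations

import hashlib
import io
import logging
import math
from dataclasses import dataclass

import pandas as pd

from .target_fishing import CandidatePair

__all__ = [
    "InteractionScore",
    "FilterResult",
    "apply_score_filter",
    "stub_score",
    "read_score_table",
    "write_score_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionScore:
    compound_id: str
    target_id: str
    score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for ({self.compound_id}, {self.target_id})")


@dataclass
class FilterResult:
    retained: list[CandidatePair]
    n_distinct_compounds: int
    n_distinct_targets: int


def apply_score_filter(
    candidates: list[CandidatePair],
    scores: list[InteractionScore],
    cutoff: float = -8.0,
    missing: str = "error",
    stronger_is_lower: bool = True,
) -> FilterResult:
    """Retain candidates whose interaction score is at least as strong as the cutoff.

    With the default energy convention a pair survives iff score <= cutoff;
    ``stronger_is_lower=False`` flips the direction for positive-is-better
    scoring functions.  ``missing`` is "error" (default) or "drop" for
    candidates without a score row.
    """
    if missing not in ("error", "drop"):
        raise ValueError(f"missing policy must be 'error' or 'drop', got {missing!r}")
    lookup: dict[tuple[str, str], float] = {}
    for s in scores:
        key = (s.compound_id, s.target_id)
        if key in lookup:
            raise ValueError(f"duplicate score row for {key}")
        lookup[key] = s.score
    retained = []
    for cand in candidates:
        key = (cand.compound_id, cand.target_id)
        if key not in lookup:
            if missing == "error":
                raise ValueError(f"candidate {key} has no interaction score")
            logger.warning("candidate %s has no score; dropped", key)
            continue
        score = lookup[key]
        keep = score <= cutoff if stronger_is_lower else score >= cutoff
        if keep:
            retained.append(cand)
    return FilterResult(
        retained=retained,
        n_distinct_compounds=len({p.compound_id for p in retained}),
        n_distinct_targets=len({p.target_id for p in retained}),
    )


def stub_score(compound_id: str, target_id: str, seed: int) -> InteractionScore:
    """Deterministic pseudo-random score in [−12, −4] from the pair ids and seed."""
    digest = hashlib.sha256(f"{compound_id}|{target_id}|{seed}".encode()).digest()
    frac = int.from_bytes(digest[:8], "big") / 2**64
    return InteractionScore(compound_id, target_id, score=-12.0 + 8.0 * frac)


def read_score_table(path) -> list[InteractionScore]:
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "target_id": str})
    missing = {"compound_id", "target_id", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    return [
        InteractionScore(row.compound_id, row.target_id, float(row.score))
        for row in df.itertuples(index=False)
    ]


def write_score_table(scores: list[InteractionScore], path=None) -> str | None:
    df = pd.DataFrame(
        [{"compound_id": s.compound_id, "target_id": s.target_id, "score": round(s.score, 4)}
         for s in scores],
        columns=["compound_id", "target_id", "score"],
    )
    if path is None:
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    df.to_csv(path, sep="\t", index=False)
    return None
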