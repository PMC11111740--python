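"""Deployment path: score a phage panel against a new bacterium and emit
top-k recommendation reports for laboratory validation.

All top-k phages are reported even when every score is low — in practice
the k best-scored candidates are spotted regardless — unless an explicit
score floor is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import EntityRepresentation, build_pair_feature
from .model import PhageHostClassifier

DEFAULT_TOP_K = 5


@dataclass(frozen=True)
class RankingResult:
    """Full descending-score ranking of a phage panel for one bacterium."""

    bacterium_id: str
    ranking: tuple[tuple[int, str, float], ...]  # (rank, phage_id, score)
    k_top: int

    def top(self, k: int) -> tuple[tuple[int, str, float], ...]:
        return self.ranking[:k]


def rank_phages(
    model: PhageHostClassifier,
    bacterium_rep: EntityRepresentation,
    phage_reps: Sequence[EntityRepresentation],
) -> RankingResult:
    """Score every panel phage against the bacterium and rank descending.

    Ties in score are broken lexicographically by phage_id; ranks are
    contiguous from 1.
    """
    if not phage_reps:
        raise ValueError("phage panel is empty")
    X = np.vstack([
        build_pair_feature(p, bacterium_rep).vector for p in phage_reps
    ])
    scores = model.predict_scores(X)
    order = sorted(
        range(len(phage_reps)),
        key=lambda i: (-scores[i], phage_reps[i].entity_id),
    )
    ranking = tuple(
        (rank, phage_reps[i].entity_id, float(scores[i]))
        for rank, i in enumerate(order, start=1)
    )
    return RankingResult(bacterium_rep.entity_id, ranking, len(ranking))


def write_topk_report(
    rankings: Sequence[RankingResult],
    k: int = DEFAULT_TOP_K,
    path: str | Path | None = None,
    score_floor: float | None = None,
) -> pd.DataFrame:
    """Emit the top-k report: k rows per bacterium, deterministic order.

    Columns are (bacterium_id, rank, phage_id, score); rows are sorted by
    bacterium_id then rank.  ``score_floor`` optionally drops rows scoring
    below it (off by default).  When ``path`` is given the frame is also
    written as CSV with fixed 6-decimal scores, so reruns are
    byte-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    panel_sizes = {r.k_top for r in rankings}
    if any(k > size for size in panel_sizes):
        raise ValueError(f"k={k} exceeds panel size {min(panel_sizes)}")
    rows = []
    for result in sorted(rankings, key=lambda r: r.bacterium_id):
        for rank, phage_id, score in result.top(k):
            if score_floor is not None and score < score_floor:
                continue
            rows.append((result.bacterium_id, rank, phage_id, score))
    frame = pd.DataFrame(rows, columns=["bacterium_id", "rank", "phage_id", "score"])
    if path is not None:
        frame.to_csv(path, index=False, float_format="%.6f")
    return frame
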