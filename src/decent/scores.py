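"""Per-read score container.

Scores follow the convention ``s_i = P(read i is maternal)``: high scores
are maternal (cumulus) reads, low scores are embryonic reads.  Optional
labels use 0 for embryonic and 1 for maternal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EMBRYONIC = 0
MATERNAL = 1


@dataclass
class ScoreSet:
    """Per-read maternal-origin probabilities with optional true labels."""

    scores: np.ndarray
    labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.scores.shape:
                raise ValueError("labels must align with scores")

    def __len__(self) -> int:
        return self.scores.size

    def subset(self, index) -> "ScoreSet":
        labels = None if self.labels is None else self.labels[index]
        return ScoreSet(self.scores[index], labels, dict(self.provenance))

    def concat(self, other: "ScoreSet") -> "ScoreSet":
        scores = np.concatenate([self.scores, other.scores])
        labels = None
        if self.labels is not None and other.labels is not None:
            labels = np.concatenate([self.labels, other.labels])
        return ScoreSet(scores, labels)
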