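"""Slice-to-image aggregation of per-slice lesion probabilities.

An image (one lesion case) contributes n slice-level probabilities.  Two
aggregation rules produce the image-level label:

* majority voting: threshold each probability at 0.5 and take the modal
  binary label;
* average voting: threshold the mean probability at 0.5.

Mode ties in majority voting (possible for even n) resolve toward malignant —
the sensitivity-favoring choice consistent with screening practice; the policy
is explicit and configurable.  Both thresholds are inclusive (">= 0.5").
For threshold-free metrics the image-level probability is the slice mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PredictionSet:
    """Per-slice probabilities for one image, with the true label."""

    image_id: str
    probs: np.ndarray
    label: int

    def __post_init__(self):
        self.probs = np.atleast_1d(np.asarray(self.probs, dtype=np.float64))
        if self.probs.size == 0:
            raise ValueError("a prediction set needs at least one slice")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def majority_vote(ps: PredictionSet, threshold: float = 0.5,
                  tie_break: int = 1) -> int:
    """Modal thresholded slice label; ties resolve to ``tie_break``
    (default 1 = malignant)."""
    votes = (ps.probs >= threshold).astype(int)
    pos, neg = int(votes.sum()), int(votes.size - votes.sum())
    if pos > neg:
        return 1
    if neg > pos:
        return 0
    return int(tie_break)


def average_vote(ps: PredictionSet, threshold: float = 0.5) -> int:
    """1 iff the mean slice probability reaches the (inclusive) threshold."""
    return int(ps.probs.mean() >= threshold)


def image_probability(ps: PredictionSet) -> float:
    """Mean slice probability; the image-level score used for AUC."""
    return float(ps.probs.mean())


def group_predictions(image_ids, probs, labels) -> list[PredictionSet]:
    """Group aligned per-slice arrays into one PredictionSet per image,
    preserving first-appearance order."""
    image_ids = np.asarray(image_ids)
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    sets = []
    seen = {}
    for iid in image_ids:
        if iid not in seen:
            mask = image_ids == iid
            lab = np.unique(labels[mask])
            if lab.size != 1:
                raise ValueError(f"conflicting labels within image {iid!r}")
            seen[iid] = True
            sets.append(PredictionSet(str(iid), probs[mask], int(lab[0])))
    return sets
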