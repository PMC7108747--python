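"""Partition labels and the per-family assignment rule.

Component 1 of the mixture is the persistent genome, component K the
cloud, and everything in between shell.  A family is assigned to its
maximum-posterior component only when that posterior exceeds 0.5;
otherwise it falls back to the shell (the intermediate-frequency
partition), keeping the best shell component as a sub-label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PERSISTENT",
    "SHELL",
    "CLOUD",
    "PARTITION_COLORS",
    "Partitioning",
    "assign_partitions",
]

PERSISTENT = "persistent"
SHELL = "shell"
CLOUD = "cloud"

# node viz convention: persistent orange, shell green, cloud blue
PARTITION_COLORS = {
    PERSISTENT: (237, 118, 0),
    SHELL: (0, 170, 75),
    CLOUD: (79, 129, 189),
}


@dataclass
class Partitioning:
    """Per-family partition assignment with the posteriors behind it.

    ``components`` are 1-based mixture component indices (1 = persistent,
    K = cloud); ``labels`` collapse them to the three biological classes.
    ``decided`` is False where no posterior exceeded 0.5 and the family
    was sent to the shell by convention.
    """

    family_ids: list[str]
    K: int
    labels: np.ndarray  # dtype str, length F
    components: np.ndarray  # 1-based ints, length F
    posteriors: np.ndarray  # F×K
    decided: np.ndarray = field(default=None)  # bool, length F

    def __post_init__(self) -> None:
        if self.decided is None:
            self.decided = np.ones(len(self.labels), dtype=bool)

    def label_of(self, family_id: str) -> str:
        return str(self.labels[self.family_ids.index(family_id)])

    def counts(self) -> dict[str, int]:
        """Number of families per partition label."""
        out = {PERSISTENT: 0, SHELL: 0, CLOUD: 0}
        for lab in self.labels:
            out[str(lab)] += 1
        return out

    def as_dict(self) -> dict[str, str]:
        return {f: str(l) for f, l in zip(self.family_ids, self.labels)}


def component_label(k: int, K: int) -> str:
    """Biological class of 1-based component k in a K-component model."""
    if k == 1:
        return PERSISTENT
    if k == K:
        return CLOUD
    return SHELL


def assign_partitions(
    T: np.ndarray, K: int | None = None, family_ids: list[str] | None = None
) -> Partitioning:
    """Harden posteriors into partition labels.

    A family takes its argmax component when the posterior is strictly
    above 0.5; ties or flat posteriors go to the shell, recording the
    highest-posterior shell component (when one exists) as sub-label.
    """
    T = np.asarray(T, dtype=float)
    if K is None:
        K = T.shape[1]
    F = T.shape[0]
    if family_ids is None:
        family_ids = [f"family_{i}" for i in range(F)]
    best = T.argmax(axis=1)  # 0-based
    confident = T[np.arange(F), best] > 0.5

    components = best + 1
    labels = np.array([component_label(k, K) for k in components], dtype=object)
    if K > 2 and not confident.all():
        shell_cols = np.arange(1, K - 1)
        shell_best = shell_cols[T[:, shell_cols].argmax(axis=1)] + 1
        components = np.where(confident, components, shell_best)
        labels = np.where(confident, labels, SHELL)
    return Partitioning(
        family_ids=list(family_ids),
        K=K,
        labels=labels.astype(object),
        components=components.astype(int),
        posteriors=T,
        decided=confident,
    )
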