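"""Agglomerative hierarchical clustering of MD profiles.

Complete linkage on raw Euclidean distances in the six-dimensional MD
space -- the features share units (dB) and magnitude, so no scaling is
applied by default.  Includes tree cutting (by cluster count or height),
majority-diagnosis accuracy with an exact binomial CI, and bootstrap
cluster stability via the Jaccard index (stable above 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MD_FEATURES
from .intervals import clopper_pearson

#: Jaccard threshold above which a cluster counts as stable.
STABILITY_THRESHOLD = 0.6


@dataclass
class Dendrogram:
    """Merge list of the agglomeration: (cluster_a, cluster_b, height).

    Clusters are identified by their smallest leaf index, which also makes
    the tie-break deterministic: among equally distant pairs the one with
    the lexicographically smallest (id_a, id_b) merges first.
    """

    merges: list[tuple[int, int, float]]
    n_leaves: int
    patient_ids: list[str] = field(default_factory=list)

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def cut(self, k: int | None = None, height: float | None = None) -> "ClusterAssignment":
        """Cut by cluster count (undo the last k-1 merges) or by height."""
        if (k is None) == (height is None):
            raise ValueError("specify exactly one of k or height")
        if k is not None:
            if not 1 <= k <= self.n_leaves:
                raise ValueError("k must be in [1, n]")
            n_merges = self.n_leaves - k
        else:
            n_merges = int(np.sum(self.heights() <= height))
        parent = np.arange(self.n_leaves)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b, _ in self.merges[:n_merges]:
            ra, rb = find(a), find(b)
            lo, hi = min(ra, rb), max(ra, rb)
            parent[hi] = lo
        roots = np.array([find(i) for i in range(self.n_leaves)])
        # Relabel clusters 1..k in order of first appearance.
        labels = np.zeros(self.n_leaves, dtype=int)
        mapping: dict[int, int] = {}
        for i, r in enumerate(roots):
            if r not in mapping:
                mapping[r] = len(mapping) + 1
            labels[i] = mapping[r]
        return ClusterAssignment(labels=labels, k=len(mapping),
                                 cut_height=height, patient_ids=self.patient_ids)


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    cut_height: float | None = None
    patient_ids: list[str] = field(default_factory=list)


def hclust_complete(profiles: pd.DataFrame | np.ndarray,
                    features: tuple[str, ...] = MD_FEATURES,
                    scale: bool = False) -> Dendrogram:
    """Complete-linkage agglomeration of the profile table.

    Each step merges the pair of clusters whose *maximum* pairwise point
    distance is minimal.  ``scale=True`` standardizes each feature first
    (off by default: the MDs share units and magnitude).
    """
    if isinstance(profiles, pd.DataFrame):
        if "patient_id" in profiles.columns:
            ids = profiles["patient_id"].astype(str).tolist()
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate patient ids")
        else:
            ids = [str(i) for i in range(len(profiles))]
        x = profiles[list(features)].to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
        ids = [str(i) for i in range(len(x))]
    n = len(x)
    if n < 2:
        raise ValueError("need at least two profiles")
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles must be complete (no NaN features)")
    if scale:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)

    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    np.fill_diagonal(d, np.inf)

    # Row i always represents the live cluster whose smallest leaf is i
    # (merges fold the larger representative into the smaller), so the
    # row-major argmin below breaks distance ties towards the
    # lexicographically smallest representative pair.
    merges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        flat = int(np.argmin(d))
        i, j = divmod(flat, n)
        keep, drop = (i, j) if i < j else (j, i)
        height = float(d[keep, drop])
        merges.append((keep, drop, height))
        # Complete linkage: distance to the merged cluster is the max of the
        # distances to its parts.
        new_row = np.maximum(d[keep, :], d[drop, :])
        d[keep, :] = new_row
        d[:, keep] = new_row
        d[keep, keep] = np.inf
        d[drop, :] = np.inf
        d[:, drop] = np.inf
    return Dendrogram(merges=merges, n_leaves=n, patient_ids=ids)


def cut_dendrogram(d: Dendrogram, k: int | None = None,
                   height: float | None = None) -> ClusterAssignment:
    return d.cut(k=k, height=height)


@dataclass
class MajorityReport:
    accuracy: float
    ci95: tuple[float, float]
    cluster_majorities: dict[int, str]
    n: int

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "ci95": list(self.ci95),
                "cluster_majorities": {int(k): v for k, v in self.cluster_majorities.items()},
                "n": self.n}


def majority_accuracy(assignment: ClusterAssignment, diagnoses: np.ndarray) -> MajorityReport:
    """Accuracy when each cluster predicts its modal diagnosis.

    Ties on the mode break alphabetically (documented, deterministic).
    """
    diagnoses = np.asarray(diagnoses).astype(str)
    if len(diagnoses) != len(assignment.labels):
        raise ValueError("labels and diagnoses must align")
    majors: dict[int, str] = {}
    correct = 0
    for c in np.unique(assignment.labels):
        sel = assignment.labels == c
        names, counts = np.unique(np.sort(diagnoses[sel]), return_counts=True)
        major = names[np.argmax(counts)]  # argmax takes the first (alphabetical) max
        majors[int(c)] = str(major)
        correct += int(np.sum(diagnoses[sel] == major))
    n = len(diagnoses)
    return MajorityReport(accuracy=correct / n, ci95=clopper_pearson(correct, n),
                          cluster_majorities=majors, n=n)


@dataclass
class StabilityReport:
    mean_jaccard: dict[int, float]
    stable: dict[int, bool]
    n_bootstrap: int
    seed: int | None
    threshold: float = STABILITY_THRESHOLD

    def to_dict(self) -> dict:
        return {"mean_jaccard": {int(k): v for k, v in self.mean_jaccard.items()},
                "stable": {int(k): bool(v) for k, v in self.stable.items()},
                "n_bootstrap": self.n_bootstrap, "seed": self.seed,
                "threshold": self.threshold}


def bootstrap_jaccard(profiles: pd.DataFrame | np.ndarray, k: int,
                      n_bootstrap: int = 100,
                      seed: int | np.random.SeedSequence = 0,
                      features: tuple[str, ...] = MD_FEATURES,
                      scale: bool = False) -> StabilityReport:
    """Bootstrap stability of the k-cluster solution.

    For each resample (with replacement): re-cluster, cut at ``k``, and for
    every original cluster record the maximum Jaccard overlap with any
    bootstrap cluster, computed on the original points present in the
    resample.  Reported per original cluster as the mean over resamples;
    clusters with mean Jaccard above 0.6 are flagged stable.
    """
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap resample")
    if isinstance(profiles, pd.DataFrame):
        x = profiles[list(features)].to_numpy(dtype=float)
    else:
        x = np.asarray(profiles, dtype=float)
    n = len(x)
    base = hclust_complete(x, scale=scale).cut(k=k)
    rng = np.random.default_rng(seed)
    sums = {int(c): 0.0 for c in np.unique(base.labels)}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boot = hclust_complete(x[idx], scale=scale).cut(k=k)
        present = np.unique(idx)
        boot_sets = []
        for c in np.unique(boot.labels):
            boot_sets.append(set(idx[boot.labels == c].tolist()))
        for c in sums:
            orig = set(np.nonzero(base.labels == c)[0].tolist()) & set(present.tolist())
            if not orig:
                continue  # cluster absent from the resample: contributes 0
            best = max((len(orig & b) / len(orig | b)) for b in boot_sets)
            sums[c] += best
    means = {c: s / n_bootstrap for c, s in sums.items()}
    seed_val = seed if isinstance(seed, int) else None
    return StabilityReport(mean_jaccard=means,
                           stable={c: m > STABILITY_THRESHOLD for c, m in means.items()},
                           n_bootstrap=n_bootstrap, seed=seed_val)
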