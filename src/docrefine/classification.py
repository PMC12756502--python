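"""Repeated random-split linear-SVM validation in [DCI, ICI] space.

Two patient groups are compared by splitting each group into near-equal
training and test halves (train size = ceil(n/2)), fitting a linear-kernel
SVM (C = 1, no class weighting; features standardized on the training half
only, since the raw [DCI, ICI] scale depends on the contrast) on the
training [DCI, ICI] points and scoring accuracy on the held-out points.
The split is repeated (500 times by default) and the full accuracy
distribution is reported together with its mean.

Two feature policies are supported:

``train_only_mask`` (default)
    The edgewise contrast — and hence the significant-edge sets defining
    DCI/ICI — is recomputed from the *training* subjects of each
    repetition; test subjects are projected into that space. No test
    information leaks into feature construction.

``whole_sample_mask``
    One contrast over all subjects of both groups defines a fixed feature
    space reused across repetitions. This mirrors protocols that select
    the edge mask on the full sample; accuracies are optimistically biased
    for overlapping groups because the mask has seen the test subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .connectivity import EdgeVector
from .contrast_features import (
    FeatureVector,
    compute_indices_matrix,
    edgewise_contrast,
)
from .errors import EmptyEdgeSetError, SplitError


@dataclass(frozen=True)
class SplitScheme:
    """Deterministic repeated-split design for two groups."""

    n_group1: int
    n_group2: int
    n_repetitions: int = 500
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        for name, n in (("group1", self.n_group1), ("group2", self.n_group2)):
            if n < 4:
                raise SplitError(
                    f"{name} has {n} subjects; need >=4 "
                    "(>=2 per train/test half)"
                )


@dataclass
class AccuracyDistribution:
    """Per-repetition test accuracies and their mean.

    Repetitions that failed (an empty edge set under ``train_only_mask``)
    are recorded as NaN and counted in ``n_failed``; the mean is taken
    over the successful repetitions.
    """

    accuracies: np.ndarray
    mean_accuracy: float
    comparison_id: str = ""
    n_failed: int = 0

    @property
    def n_repetitions(self) -> int:
        return self.accuracies.shape[0]

    def summary(self) -> str:
        """Mean accuracy as a 1-d.p. percentage, e.g. '90.2%'."""
        return f"{100 * self.mean_accuracy:.1f}%"


def make_split(
    scheme: SplitScheme, repetition_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Train/test index sets for one repetition: a seeded uniformly random
    permutation of each group, split at ceil(n/2). Returns
    (train1, test1, train2, test2) as index arrays into each group.

    The same (rng_seed, repetition_index) pair always yields the same
    split.
    """
    rng = np.random.default_rng([scheme.rng_seed, repetition_index])
    out = []
    for n in (scheme.n_group1, scheme.n_group2):
        perm = rng.permutation(n)
        k = ceil(n / 2)
        out.extend([perm[:k], perm[k:]])
    return tuple(out)  # type: ignore[return-value]


def _fit_score(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    y_test: np.ndarray,
) -> float:
    if len(set(y_train.tolist())) < 2:
        raise SplitError("degenerate training set: one class absent")
    # Standardize on the training half only: the raw [DCI, ICI] scale
    # varies with the contrast, and an un-standardized C=1 margin
    # underfits when the feature scale is small.
    mu = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd[sd == 0.0] = 1.0
    clf = SVC(kernel="linear", C=1.0)
    clf.fit((x_train - mu) / sd, y_train)
    return float(clf.score((x_test - mu) / sd, y_test))


def classify_repeated(
    group1_ids: Sequence[str],
    group2_ids: Sequence[str],
    scheme: SplitScheme,
    feature_policy: str = "train_only_mask",
    edge_vectors: Optional[dict[str, EdgeVector]] = None,
    features: Optional[dict[str, FeatureVector]] = None,
    alpha: float = 0.05,
    mean_on: str = "z",
    comparison_id: str = "",
) -> AccuracyDistribution:
    """Repeated-split linear-SVM accuracy between two groups.

    Parameters
    ----------
    group1_ids, group2_ids : subject ids of the two groups.
    scheme : the split design (must match the group sizes).
    feature_policy : "train_only_mask" recomputes the contrast per
        repetition from training subjects only (requires ``edge_vectors``);
        "whole_sample_mask" uses one contrast over all subjects — either
        computed here from ``edge_vectors`` or taken as given via a
        precomputed ``features`` map.
    alpha : edgewise significance level for contrasts computed here.
    """
    if scheme.n_group1 != len(group1_ids) or scheme.n_group2 != len(group2_ids):
        raise SplitError(
            f"scheme sizes ({scheme.n_group1}, {scheme.n_group2}) do not "
            f"match groups ({len(group1_ids)}, {len(group2_ids)})"
        )
    if feature_policy not in ("train_only_mask", "whole_sample_mask"):
        raise ValueError(f"unknown feature_policy {feature_policy!r}")

    ids1, ids2 = list(group1_ids), list(group2_ids)
    y1 = np.zeros(len(ids1))
    y2 = np.ones(len(ids2))

    if feature_policy == "whole_sample_mask":
        if features is not None:
            pts1 = np.array([features[i].as_array() for i in ids1])
            pts2 = np.array([features[i].as_array() for i in ids2])
        else:
            if edge_vectors is None:
                raise ValueError(
                    "whole_sample_mask needs edge_vectors or features"
                )
            contrast = edgewise_contrast(
                [edge_vectors[i] for i in ids1],
                [edge_vectors[i] for i in ids2],
                alpha=alpha,
                contrast_id=comparison_id or "whole_sample",
            )
            z1 = np.vstack([edge_vectors[i].z_values for i in ids1])
            z2 = np.vstack([edge_vectors[i].z_values for i in ids2])
            pts1 = compute_indices_matrix(z1, contrast, mean_on=mean_on)
            pts2 = compute_indices_matrix(z2, contrast, mean_on=mean_on)
        accs = np.empty(scheme.n_repetitions)
        for rep in range(scheme.n_repetitions):
            tr1, te1, tr2, te2 = make_split(scheme, rep)
            accs[rep] = _fit_score(
                np.vstack([pts1[tr1], pts2[tr2]]),
                np.concatenate([y1[tr1], y2[tr2]]),
                np.vstack([pts1[te1], pts2[te2]]),
                np.concatenate([y1[te1], y2[te2]]),
            )
        n_failed = 0
    else:
        if edge_vectors is None:
            raise ValueError("train_only_mask requires edge_vectors")
        ev1 = [edge_vectors[i] for i in ids1]
        ev2 = [edge_vectors[i] for i in ids2]
        z1 = np.vstack([ev.z_values for ev in ev1])
        z2 = np.vstack([ev.z_values for ev in ev2])
        accs = np.empty(scheme.n_repetitions)
        n_failed = 0
        for rep in range(scheme.n_repetitions):
            tr1, te1, tr2, te2 = make_split(scheme, rep)
            try:
                contrast = edgewise_contrast(
                    [ev1[k] for k in tr1],
                    [ev2[k] for k in tr2],
                    alpha=alpha,
                    contrast_id=f"{comparison_id or 'train_only'}_rep{rep}",
                )
                pts1 = compute_indices_matrix(z1, contrast, mean_on=mean_on)
                pts2 = compute_indices_matrix(z2, contrast, mean_on=mean_on)
            except EmptyEdgeSetError:
                accs[rep] = np.nan
                n_failed += 1
                continue
            accs[rep] = _fit_score(
                np.vstack([pts1[tr1], pts2[tr2]]),
                np.concatenate([y1[tr1], y2[tr2]]),
                np.vstack([pts1[te1], pts2[te2]]),
                np.concatenate([y1[te1], y2[te2]]),
            )
    mean = float(np.nanmean(accs)) if np.any(np.isfinite(accs)) else float("nan")
    return AccuracyDistribution(
        accuracies=accs,
        mean_accuracy=mean,
        comparison_id=comparison_id,
        n_failed=n_failed,
    )


def accuracy_histogram(
    dist: AccuracyDistribution, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the accuracy distribution on [0, 1] (counts, edges)."""
    finite = dist.accuracies[np.isfinite(dist.accuracies)]
    counts, edges = np.histogram(finite, bins=n_bins, range=(0.0, 1.0))
    return counts, edges
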