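"""Edgewise group contrasts and the [DCI, ICI] feature space.

Given two groups of Fisher-z edge vectors, every edge is compared with a
two-sided two-sample t-test (pooled variance by default). Edges significant
at the chosen level split into two sets by the sign of the group difference:

* *decreased* edges — connectivity lower in group 2 than in group 1;
* *increased* edges — connectivity higher in group 2 than in group 1.

A subject's *decreased connectivity index* (DCI) is the mean of their edge
values over the decreased set, and the *increased connectivity index* (ICI)
the mean over the increased set. The pair [DCI, ICI] is the 2-D feature
vector in which all downstream refinement and classification happens. Any
subject — inside or outside the contrast-defining groups — can be projected
into the space defined by a contrast.

Means are taken on the Fisher-z scale by default (``mean_on="z"``), the same
scale the tests use; ``mean_on="r"`` averages back-transformed correlations
instead. No multiple-comparison correction is applied by default (the edge
mask is a feature-selection device, not an inference), but Bonferroni and
Benjamini-Hochberg hooks are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import EdgeVector
from .errors import EmptyEdgeSetError, InsufficientGroupError, ShapeError


@dataclass
class EdgeContrast:
    """Per-edge statistics of a two-group comparison plus the significant
    edge sets that define the current feature space.

    The t statistic follows the (group1 - group2) convention: decreased
    edges (group2 below group1) have t > 0, increased edges t < 0.
    """

    t_stats: np.ndarray
    p_values: np.ndarray
    decreased_edges: np.ndarray  # sorted edge indices
    increased_edges: np.ndarray
    alpha: float
    group1_ids: list[str]
    group2_ids: list[str]
    n_regions: int
    contrast_id: str = ""

    @property
    def n_edges(self) -> int:
        return self.t_stats.shape[0]

    def to_json(self, path=None) -> str:
        """Serialize the replayable part (edge sets, level, groups)."""
        payload = {
            "contrast_id": self.contrast_id,
            "alpha": self.alpha,
            "n_regions": self.n_regions,
            "group1_ids": list(self.group1_ids),
            "group2_ids": list(self.group2_ids),
            "decreased_edges": self.decreased_edges.tolist(),
            "increased_edges": self.increased_edges.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


@dataclass(frozen=True)
class FeatureVector:
    """A subject's [DCI, ICI] point, tied to the contrast that defined it."""

    dci: float
    ici: float
    subject_id: str = ""
    contrast_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.dci, self.ici], dtype=float)


def _stack(group: Sequence[EdgeVector], name: str) -> np.ndarray:
    if len(group) < 2:
        raise InsufficientGroupError(
            f"{name} needs >=2 subjects for a two-sample t-test, "
            f"got {len(group)}"
        )
    n_regions = group[0].n_regions
    for ev in group:
        if ev.n_regions != n_regions or ev.z_values.shape != group[0].z_values.shape:
            raise ShapeError(
                f"mismatched edge vectors in {name}: subject "
                f"{ev.subject_id!r} has {ev.n_regions} regions, expected "
                f"{n_regions}"
            )
    return np.vstack([ev.z_values for ev in group])


def edgewise_contrast(
    group1: Sequence[EdgeVector],
    group2: Sequence[EdgeVector],
    alpha: float = 0.05,
    equal_var: bool = True,
    correction: str = "none",
    contrast_id: str = "",
) -> EdgeContrast:
    """Two-sided two-sample t-test at every edge, group1 vs group2.

    Parameters
    ----------
    alpha : significance level; strict inequality (p < alpha) per the
        usual reporting convention, so ties at alpha are not significant.
    equal_var : pooled-variance Student's t (True, default) or Welch.
    correction : {"none", "bonferroni", "fdr_bh"} multiplicity adjustment
        applied to the p-values before thresholding.
    """
    a = _stack(group1, "group1")
    b = _stack(group2, "group2")
    if a.shape[1] != b.shape[1]:
        raise ShapeError(
            f"edge-length mismatch between groups: {a.shape[1]} vs {b.shape[1]}"
        )
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if correction != "none":
        method = {"bonferroni": "bonferroni", "fdr_bh": "fdr_bh"}[correction]
        p = multipletests(p, alpha=alpha, method=method)[1]
    diff = a.mean(axis=0) - b.mean(axis=0)
    sig = p < alpha
    decreased = np.flatnonzero(sig & (diff > 0))
    increased = np.flatnonzero(sig & (diff < 0))
    return EdgeContrast(
        t_stats=t,
        p_values=p,
        decreased_edges=decreased,
        increased_edges=increased,
        alpha=alpha,
        group1_ids=[ev.subject_id for ev in group1],
        group2_ids=[ev.subject_id for ev in group2],
        n_regions=group1[0].n_regions,
        contrast_id=contrast_id,
    )


def compute_indices(
    subject: EdgeVector, contrast: EdgeContrast, mean_on: str = "z"
) -> FeatureVector:
    """Project one subject into the [DCI, ICI] space of a contrast.

    Works identically for subjects inside or outside the contrast-defining
    groups. Raises :class:`EmptyEdgeSetError` naming the empty set when the
    contrast found no decreased or no increased edges.
    """
    if subject.z_values.shape[0] != contrast.n_edges:
        raise ShapeError(
            f"subject {subject.subject_id!r} has {subject.z_values.shape[0]} "
            f"edges, contrast has {contrast.n_edges}"
        )
    for name, idx in (
        ("decreased", contrast.decreased_edges),
        ("increased", contrast.increased_edges),
    ):
        if idx.size == 0:
            raise EmptyEdgeSetError(
                f"contrast {contrast.contrast_id!r}: empty {name} edge set; "
                "DCI/ICI undefined"
            )
    vals = subject.z_values if mean_on == "z" else np.tanh(subject.z_values)
    return FeatureVector(
        dci=float(vals[contrast.decreased_edges].mean()),
        ici=float(vals[contrast.increased_edges].mean()),
        subject_id=subject.subject_id,
        contrast_id=contrast.contrast_id,
    )


def compute_indices_matrix(
    z_matrix: np.ndarray, contrast: EdgeContrast, mean_on: str = "z"
) -> np.ndarray:
    """Vectorized projection of many subjects: (n_subjects, n_edges) z-value
    rows -> (n_subjects, 2) array of [DCI, ICI]. Same contract as
    :func:`compute_indices`."""
    if z_matrix.shape[1] != contrast.n_edges:
        raise ShapeError(
            f"z matrix has {z_matrix.shape[1]} edges, contrast has "
            f"{contrast.n_edges}"
        )
    for name, idx in (
        ("decreased", contrast.decreased_edges),
        ("increased", contrast.increased_edges),
    ):
        if idx.size == 0:
            raise EmptyEdgeSetError(
                f"contrast {contrast.contrast_id!r}: empty {name} edge set; "
                "DCI/ICI undefined"
            )
    vals = z_matrix if mean_on == "z" else np.tanh(z_matrix)
    return np.column_stack(
        [
            vals[:, contrast.decreased_edges].mean(axis=1),
            vals[:, contrast.increased_edges].mean(axis=1),
        ]
    )


def export_feature_table(
    features: dict[str, FeatureVector],
    labels: dict[str, str],
    path,
) -> None:
    """Write a delimited feature table: subject_id, label, dci, ici."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("subject_id,label,dci,ici\n")
        for sid, fv in features.items():
            fh.write(
                f"{sid},{labels.get(sid, '')},{fv.dci:.10g},{fv.ici:.10g}\n"
            )
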