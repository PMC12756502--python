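"""EM-like iterative refinement of UWS membership in [DCI, ICI] space.

The procedure identifies *representative* patients — those whose
connectivity features are consistent with their clinical label — starting
from a high-confidence seed of UWS patients with CRS-R totals <= 5:

1. Contrast the seed (later: the currently selected UWS set) against the
   healthy controls edgewise; compute [DCI, ICI] for every subject under
   the resulting significant-edge sets.
2. Fit a bivariate-Gaussian model (centroid mu, covariance Sigma) to the
   selected-UWS and HC feature clouds. The 90% confidence ellipse of a
   group is the region (x - mu)^T Sigma^-1 (x - mu) <= chi2_{0.9, df=2}
   = 4.605 (boundary inclusive).
3. E-step: the new selected-UWS set is exactly the UWS patients inside the
   UWS ellipse — boundary patients previously selected are dropped,
   excluded ones falling inside are re-included.
4. M-step: recompute the contrast, every feature vector, both group models
   and the monitoring objective
   L = sum_{i in selected UWS} d_M(x_i, mu_UWS)^2
     + sum_{i in HC} d_M(x_i, mu_HC)^2
     - lambda * d_M(mu_UWS, mu_HC)^2,
   with the between-centroid term measured in the pooled within-group
   covariance.
5. Stop on label stability, a centroid shift below 1e-4, or after at most
   3 iterations (the process empirically stabilizes in 2-3).
6. Optionally fine-tune: greedily toggle UWS patients whose d^2 lies within
   a relative band of the ellipse boundary, keeping a toggle only if it
   strictly decreases L.

At convergence, UWS patients inside the final UWS ellipse are
representative; MCS patients are representative when they fall *outside*
that ellipse (those inside resemble the UWS cluster and are excluded).
Only UWS membership is ever updated; the HC group is fixed and its model
is merely refit when features change.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .cohort_io import Cohort, select_seed_uws
from .connectivity import EdgeVector
from .contrast_features import (
    EdgeContrast,
    FeatureVector,
    compute_indices_matrix,
    edgewise_contrast,
)
from .errors import CollapseError, DegenerateGroupError

logger = logging.getLogger(__name__)

#: Condition number above which the covariance is ridge-regularized.
COND_MAX = 1e8

#: Minimum members needed for a nondegenerate 2-D covariance.
MIN_GROUP = 3


@dataclass
class GroupModel:
    """Bivariate Gaussian summary of a feature cluster and its confidence
    ellipse (d^2 <= chi2 quantile at ``level``, df=2; 4.605 at 0.9)."""

    centroid: np.ndarray
    covariance: np.ndarray
    level: float = 0.9
    chi2_threshold: float = field(default=0.0)
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.chi2_threshold:
            self.chi2_threshold = float(sps.chi2.ppf(self.level, df=2))


@dataclass
class RefinementConfig:
    """Tunable parameters of the refinement.

    seed_max_crsr : CRS-R ceiling for the initial UWS seed (default 5).
    level : confidence level of the containment ellipses (default 0.9).
    lambda_ : weight of the between-centroid separation term in L.
    centroid_tol : centroid-shift convergence threshold (default 1e-4).
    max_iter : iteration safeguard (default 3).
    fine_tune / fine_tune_band : enable boundary fine-tuning and set the
        relative band (1 +- band) * chi2 threshold defining "near" the
        ellipse (defaults: off, 0.1).
    alpha : edgewise significance level (default 0.05).
    mean_on : scale on which DCI/ICI average ("z" or "r").
    rng_seed : seed for any stochastic component (the core loop is
        deterministic; kept for provenance of downstream steps).
    """

    seed_max_crsr: int = 5
    level: float = 0.9
    lambda_: float = 1.0
    centroid_tol: float = 1e-4
    max_iter: int = 3
    fine_tune: bool = False
    fine_tune_band: float = 0.1
    alpha: float = 0.05
    mean_on: str = "z"
    rng_seed: int = 0

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")


@dataclass
class IterationRecord:
    iteration: int
    selected_uws: list[str]
    uws_centroid: np.ndarray
    hc_centroid: np.ndarray
    n_decreased: int
    n_increased: int
    objective_value: float


@dataclass
class RefinementState:
    """Everything the algorithm knows after one M-step."""

    iteration: int
    selected_uws: set[str]
    excluded_uws: set[str]
    hc_ids: list[str]
    contrast: EdgeContrast
    features: dict[str, FeatureVector]
    uws_model: GroupModel
    hc_model: GroupModel
    objective_value: float
    trace: list[IterationRecord] = field(default_factory=list)


@dataclass
class RefinementResult:
    representative_uws: set[str]
    excluded_uws: set[str]
    representative_mcs: set[str]
    excluded_mcs: set[str]
    final_state: RefinementState
    converged_by: str  # label_stability | centroid_stability | max_iter

    def to_json(self, path=None) -> str:
        st = self.final_state
        payload = {
            "representative_uws": sorted(self.representative_uws),
            "excluded_uws": sorted(self.excluded_uws),
            "representative_mcs": sorted(self.representative_mcs),
            "excluded_mcs": sorted(self.excluded_mcs),
            "converged_by": self.converged_by,
            "iterations": st.iteration,
            "objective_value": st.objective_value,
            "uws_model": {
                "centroid": st.uws_model.centroid.tolist(),
                "covariance": st.uws_model.covariance.tolist(),
                "chi2_threshold": st.uws_model.chi2_threshold,
            },
            "hc_model": {
                "centroid": st.hc_model.centroid.tolist(),
                "covariance": st.hc_model.covariance.tolist(),
                "chi2_threshold": st.hc_model.chi2_threshold,
            },
            "trace": [
                {
                    "iteration": r.iteration,
                    "selected_uws": r.selected_uws,
                    "uws_centroid": r.uws_centroid.tolist(),
                    "hc_centroid": r.hc_centroid.tolist(),
                    "n_decreased": r.n_decreased,
                    "n_increased": r.n_increased,
                    "objective_value": r.objective_value,
                }
                for r in st.trace
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


# ---------------------------------------------------------------------------
# Group models and Mahalanobis geometry
# ---------------------------------------------------------------------------

def _as_point(x) -> np.ndarray:
    if isinstance(x, FeatureVector):
        return x.as_array()
    return np.asarray(x, dtype=float)


def fit_group_model(
    features: Sequence[FeatureVector] | np.ndarray,
    level: float = 0.9,
    member_ids: Optional[list[str]] = None,
) -> GroupModel:
    """Centroid and sample covariance (divisor n-1) of a feature cloud.

    A ridge eps*I with eps = 1e-8 * trace(Sigma)/2 is added only when the
    covariance's condition number exceeds 1e8 — small seed groups can be
    nearly collinear in feature space. Fewer than 3 members, or a
    covariance that remains singular, raise :class:`DegenerateGroupError`.
    """
    if isinstance(features, np.ndarray):
        pts = np.asarray(features, dtype=float)
        ids = list(member_ids) if member_ids else []
    else:
        pts = np.array([f.as_array() for f in features], dtype=float)
        ids = member_ids or [f.subject_id for f in features]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("features must be n x 2 points")
    n = pts.shape[0]
    if n < MIN_GROUP:
        raise DegenerateGroupError(
            f"group model needs >={MIN_GROUP} members, got {n}"
        )
    centroid = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > COND_MAX:
        eps = 1e-8 * np.trace(cov) / 2.0
        cov = cov + eps * np.eye(2)
        eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 0:
        raise DegenerateGroupError(
            "zero-variance direction in feature cloud even after ridge"
        )
    return GroupModel(
        centroid=centroid, covariance=cov, level=level, member_ids=ids
    )


def mahalanobis_sq(x, model: GroupModel) -> float:
    """Squared Mahalanobis distance (x - mu)^T Sigma^-1 (x - mu)."""
    d = _as_point(x) - model.centroid
    try:
        sol = np.linalg.solve(model.covariance, d)
    except np.linalg.LinAlgError:
        raise DegenerateGroupError("singular covariance in Mahalanobis") from None
    return float(d @ sol)


def _mahalanobis_sq_many(pts: np.ndarray, model: GroupModel) -> np.ndarray:
    d = pts - model.centroid
    sol = np.linalg.solve(model.covariance, d.T).T
    return np.einsum("ij,ij->i", d, sol)


def inside_ellipse(x, model: GroupModel) -> bool:
    """Boundary-inclusive containment test d^2 <= chi2 threshold."""
    return mahalanobis_sq(x, model) <= model.chi2_threshold


def pooled_covariance(m1: GroupModel, m2: GroupModel) -> np.ndarray:
    """Pooled within-group covariance weighted by members (n_k - 1)."""
    n1 = max(len(m1.member_ids), 2)
    n2 = max(len(m2.member_ids), 2)
    return ((n1 - 1) * m1.covariance + (n2 - 1) * m2.covariance) / (
        n1 + n2 - 2
    )


def objective(state: RefinementState, lambda_: float = 1.0) -> float:
    """The monitoring objective L: within-group Mahalanobis scatter of the
    selected-UWS and HC clouds minus lambda times the squared between-
    centroid distance (measured in the pooled within-group covariance)."""
    uws_pts = np.array(
        [state.features[i].as_array() for i in sorted(state.selected_uws)]
    )
    hc_pts = np.array([state.features[i].as_array() for i in state.hc_ids])
    within = float(
        _mahalanobis_sq_many(uws_pts, state.uws_model).sum()
        + _mahalanobis_sq_many(hc_pts, state.hc_model).sum()
    )
    pooled = pooled_covariance(state.uws_model, state.hc_model)
    diff = state.uws_model.centroid - state.hc_model.centroid
    between = float(diff @ np.linalg.solve(pooled, diff))
    return within - lambda_ * between


def e_step(state: RefinementState) -> set[str]:
    """Membership update: the new selected-UWS set is exactly the UWS
    patients (currently selected or excluded) whose feature vector lies
    inside the current UWS ellipse. Previously selected patients falling
    outside are deselected; excluded ones falling inside are re-included.

    Raises :class:`CollapseError` (carrying the trace) if fewer than 3
    patients remain, since no group model could then be fit.
    """
    uws_ids = sorted(state.selected_uws | state.excluded_uws)
    pts = np.array([state.features[i].as_array() for i in uws_ids])
    d2 = _mahalanobis_sq_many(pts, state.uws_model)
    new = {
        sid
        for sid, dd in zip(uws_ids, d2)
        if dd <= state.uws_model.chi2_threshold
    }
    if len(new) < MIN_GROUP:
        raise CollapseError(
            f"selected-UWS set collapsed to {len(new)} member(s) at "
            f"iteration {state.iteration}",
            trace=state.trace,
        )
    return new


# ---------------------------------------------------------------------------
# The refinement loop
# ---------------------------------------------------------------------------

class Refiner:
    """Runs the E/M alternation on one cohort.

    Parameters
    ----------
    cohort : the clinical cohort (must contain HC, UWS and MCS subjects).
    edge_vectors : subject_id -> :class:`EdgeVector`, one per subject,
        all sharing the canonical edge order.
    config : :class:`RefinementConfig`.
    """

    def __init__(
        self,
        cohort: Cohort,
        edge_vectors: dict[str, EdgeVector],
        config: Optional[RefinementConfig] = None,
    ):
        self.cohort = cohort
        self.config = config or RefinementConfig()
        self.hc_ids = cohort.ids("HC")
        self.uws_ids = cohort.ids("UWS")
        self.mcs_ids = cohort.ids("MCS")
        for grp, name in ((self.hc_ids, "HC"), (self.uws_ids, "UWS")):
            if not grp:
                raise DegenerateGroupError(f"cohort has no {name} subjects")
        self.all_ids = self.hc_ids + self.uws_ids + self.mcs_ids
        missing = [i for i in self.all_ids if i not in edge_vectors]
        if missing:
            raise KeyError(f"edge vectors missing for subjects: {missing[:5]}")
        self.edge_vectors = edge_vectors
        self._row = {sid: k for k, sid in enumerate(self.all_ids)}
        self._z = np.vstack(
            [edge_vectors[sid].z_values for sid in self.all_ids]
        )

    # -- M-step -------------------------------------------------------------

    def m_step(self, selected_uws: set[str], iteration: int) -> RefinementState:
        """Recompute contrast, all feature vectors, both group models and L
        for a given selected-UWS membership."""
        cfg = self.config
        sel = sorted(selected_uws)
        contrast = edgewise_contrast(
            [self.edge_vectors[i] for i in self.hc_ids],
            [self.edge_vectors[i] for i in sel],
            alpha=cfg.alpha,
            contrast_id=f"HC_vs_selectedUWS_iter{iteration}",
        )
        feats = compute_indices_matrix(self._z, contrast, mean_on=cfg.mean_on)
        features = {
            sid: FeatureVector(
                dci=float(feats[k, 0]),
                ici=float(feats[k, 1]),
                subject_id=sid,
                contrast_id=contrast.contrast_id,
            )
            for sid, k in self._row.items()
        }
        uws_model = fit_group_model(
            feats[[self._row[i] for i in sel]],
            level=cfg.level,
            member_ids=sel,
        )
        hc_model = fit_group_model(
            feats[[self._row[i] for i in self.hc_ids]],
            level=cfg.level,
            member_ids=list(self.hc_ids),
        )
        state = RefinementState(
            iteration=iteration,
            selected_uws=set(sel),
            excluded_uws=set(self.uws_ids) - set(sel),
            hc_ids=list(self.hc_ids),
            contrast=contrast,
            features=features,
            uws_model=uws_model,
            hc_model=hc_model,
            objective_value=0.0,
        )
        state.objective_value = objective(state, cfg.lambda_)
        return state

    # -- E-step -------------------------------------------------------------

    def e_step(self, state: RefinementState) -> set[str]:
        return e_step(state)

    # -- main loop ----------------------------------------------------------

    def run(self) -> "RefinementResult":
        cfg = self.config
        selected = select_seed_uws(self.cohort, cfg.seed_max_crsr)
        trace: list[IterationRecord] = []
        prev_centroids: Optional[np.ndarray] = None
        converged_by = "max_iter"
        state = None
        for it in range(1, cfg.max_iter + 1):
            state = self.m_step(selected, iteration=it)
            state.trace = trace
            trace.append(
                IterationRecord(
                    iteration=it,
                    selected_uws=sorted(selected),
                    uws_centroid=state.uws_model.centroid.copy(),
                    hc_centroid=state.hc_model.centroid.copy(),
                    n_decreased=state.contrast.decreased_edges.size,
                    n_increased=state.contrast.increased_edges.size,
                    objective_value=state.objective_value,
                )
            )
            centroids = np.concatenate(
                [state.uws_model.centroid, state.hc_model.centroid]
            )
            logger.info(
                "iteration %d: |selected|=%d, dec=%d, inc=%d, L=%.6g",
                it,
                len(selected),
                state.contrast.decreased_edges.size,
                state.contrast.increased_edges.size,
                state.objective_value,
            )
            if (
                prev_centroids is not None
                and float(np.linalg.norm(centroids - prev_centroids))
                < cfg.centroid_tol
            ):
                converged_by = "centroid_stability"
                break
            new_selected = self.e_step(state)
            if new_selected == selected:
                converged_by = "label_stability"
                break
            if it == cfg.max_iter:
                converged_by = "max_iter"
                break
            prev_centroids = centroids
            selected = new_selected
        assert state is not None
        if cfg.fine_tune:
            state = self.fine_tune(state)
            state.trace = trace
        return self._finalize(state, converged_by)

    # -- fine-tuning --------------------------------------------------------

    def fine_tune(self, state: RefinementState) -> RefinementState:
        """Greedy boundary fine-tuning.

        Candidates are UWS patients whose d^2 to the UWS centroid lies in
        (1 +- band) * chi2 threshold. Each candidate's membership is
        toggled in turn; a toggle is kept only when it strictly decreases
        L (with contrast, features and models recomputed), so L never
        increases. Sweeps repeat until no toggle improves.
        """
        cfg = self.config
        thr = state.uws_model.chi2_threshold
        lo, hi = (1 - cfg.fine_tune_band) * thr, (1 + cfg.fine_tune_band) * thr
        pts = np.array([state.features[i].as_array() for i in self.uws_ids])
        d2 = _mahalanobis_sq_many(pts, state.uws_model)
        candidates = [
            sid for sid, dd in zip(self.uws_ids, d2) if lo <= dd <= hi
        ]
        if not candidates:
            return state
        selected = set(state.selected_uws)
        improved = True
        while improved:
            improved = False
            for cand in candidates:
                trial_sel = selected ^ {cand}
                if len(trial_sel) < MIN_GROUP:
                    continue
                trial = self.m_step(trial_sel, iteration=state.iteration)
                if trial.objective_value < state.objective_value:
                    logger.info(
                        "fine-tune: toggling %s lowers L %.6g -> %.6g",
                        cand,
                        state.objective_value,
                        trial.objective_value,
                    )
                    state = trial
                    selected = trial_sel
                    improved = True
        return state

    # -- final assignment ---------------------------------------------------

    def _finalize(
        self, state: RefinementState, converged_by: str
    ) -> RefinementResult:
        # The final assignment reads containment off the final ellipse for
        # both patient groups: UWS inside are representative, MCS inside
        # are UWS-like and therefore excluded.
        rep_uws = {
            sid
            for sid in self.uws_ids
            if inside_ellipse(state.features[sid], state.uws_model)
        }
        rep_mcs, exc_mcs = set(), set()
        for sid in self.mcs_ids:
            if inside_ellipse(state.features[sid], state.uws_model):
                exc_mcs.add(sid)
            else:
                rep_mcs.add(sid)
        result = RefinementResult(
            representative_uws=rep_uws,
            excluded_uws=set(self.uws_ids) - rep_uws,
            representative_mcs=rep_mcs,
            excluded_mcs=exc_mcs,
            final_state=state,
            converged_by=converged_by,
        )
        # partition soundness, asserted on every run
        assert result.representative_uws | result.excluded_uws == set(
            self.uws_ids
        )
        assert not result.representative_uws & result.excluded_uws
        assert result.representative_mcs | result.excluded_mcs == set(
            self.mcs_ids
        )
        assert not result.representative_mcs & result.excluded_mcs
        return result


def refine(
    cohort: Cohort,
    edge_vectors: dict[str, EdgeVector],
    config: Optional[RefinementConfig] = None,
) -> RefinementResult:
    """Run the full refinement on a cohort (see module docstring)."""
    return Refiner(cohort, edge_vectors, config).run()
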