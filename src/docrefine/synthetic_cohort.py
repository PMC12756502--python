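"""Synthetic multi-group ROI time series with planted cluster structure.

The generator emulates the statistical situation the refinement assumes: a
healthy-control (HC) connectivity profile, a strongly altered profile for
*representative* UWS patients, an intermediate profile shared by the
mislabeled groups (UWS patients who look MCS-like and representative MCS
patients), and the UWS-like profile again for mislabeled MCS patients.

Construction, per cohort:

1. A base HC correlation matrix from a low-rank factor model (moderate
   positive and negative couplings, strictly positive definite).
   Optionally each subject perturbs the factor loadings individually
   (``subject_loading_sd``, default 0), adding edgewise trait variance
   correlated across edges that share a region.
2. Disjoint random *decreased* and *increased* edge sets. The
   representative-UWS profile shifts the base correlations by
   ``decrease_delta`` / ``increase_delta`` on those edges; the
   intermediate profile applies half the shifts; every shifted matrix is
   projected back to the nearest positive-definite correlation matrix by
   eigenvalue clipping with diagonal renormalization.
3. Each subject carries two individual traits, both uniform (trait
   variation within a diagnostic class is bounded, so uniform rather
   than Gaussian tails):

   * a *severity* per alteration type — multipliers on the planted
     decrease and increase deltas, drawn jointly and uniformly from a
     disk of radius ``severity_halfwidth`` around the class center (1
     for the fully altered profiles, 1/2 for the intermediate ones, 0
     for HC). Focal decreases and increases progress semi-independently,
     so the patient clusters are genuinely two-dimensional and visibly
     more widespread than the HC cloud, the way clinical cohorts are;
     severity within a diagnostic class is bounded, hence the compact
     disk rather than Gaussian tails; and
   * a *global coupling* factor that scales every off-diagonal
     correlation: 1 minus ``coupling_severity_slope`` times the
     subject's mean severity (global hypoconnectivity deepens with the
     severity of the disorder), plus optional individual jitter within
     ``coupling_halfwidth`` (default 0). Group contrasts therefore
     combine focal planted alterations with a diffuse graded global
     reduction, the way patient connectomes differ from controls.
4. The subject's time series is drawn i.i.d. over time from a zero-mean
   Gaussian with the severity-scaled covariance, plus isotropic
   observation noise ``noise_sd`` (which also guarantees |r| < 1
   empirically).
5. CRS-R totals follow the clinical convention: representative UWS score
   3-7 with a fixed number (13 by default) at <= 5 so seeding mirrors a
   realistic low-score subset; mislabeled UWS score 6-7; all MCS score
   6-18; HC have no score. Mislabeled subjects carry their *clinical*
   label (exc_UWS is labeled UWS, exc_MCS labeled MCS) — the label noise
   is the point.

Temporal structure is i.i.d. (no BOLD autocorrelation, no motion or
physiological artifacts): the pipeline consumes only Pearson correlations,
for which i.i.d. sampling is sufficient. This is a deliberate
simplification of real fMRI dynamics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort_io import Cohort, ROITimeSeries, Subject, save_manifest
from .connectivity import n_edges
from .errors import BlueprintError

#: Planted classes, in generation order.
CLASSES = ("HC", "rep_UWS", "exc_UWS", "rep_MCS", "exc_MCS")

#: Clinical label emitted in the manifest for each planted class.
CLINICAL_LABEL = {
    "HC": "HC",
    "rep_UWS": "UWS",
    "exc_UWS": "UWS",
    "rep_MCS": "MCS",
    "exc_MCS": "MCS",
}


def _default_group_sizes() -> dict[str, int]:
    return {"HC": 20, "rep_UWS": 31, "exc_UWS": 27, "rep_MCS": 23, "exc_MCS": 7}


@dataclass
class CohortBlueprint:
    """Parameters of one synthetic cohort.

    Defaults reproduce the study-scale design: 116 regions, 206 retained
    volumes, 20 HC / 58 UWS (31 representative + 27 mislabeled) / 30 MCS
    (23 representative + 7 mislabeled); 5% of edges decreased by 0.3 and
    2% increased by 0.2 on the correlation scale in the fully altered
    profile; 13 representative-UWS patients with CRS-R <= 5.
    """

    n_regions: int = 116
    n_timepoints: int = 206
    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    decreased_edge_fraction: float = 0.05
    increased_edge_fraction: float = 0.02
    decrease_delta: float = -0.3
    increase_delta: float = 0.2
    noise_sd: float = 0.3
    base_loading_sd: float = 0.45
    subject_loading_sd: float = 0.0
    severity_halfwidth: float = 0.3
    coupling_halfwidth: float = 0.0
    coupling_severity_slope: float = 0.25
    rep_uws_low_crsr_count: int = 13
    rng_seed: int = 0

    def __post_init__(self):
        for frac in (self.decreased_edge_fraction, self.increased_edge_fraction):
            if not 0.0 < frac < 1.0:
                raise BlueprintError("edge fractions must lie in (0, 1)")
        if self.decreased_edge_fraction + self.increased_edge_fraction >= 1.0:
            raise BlueprintError("edge fractions must sum to < 1")
        for cls in CLASSES:
            if cls not in self.group_sizes:
                raise BlueprintError(f"group_sizes missing class {cls!r}")
            if self.group_sizes[cls] < 0:
                raise BlueprintError(f"negative size for class {cls!r}")
        if self.n_regions < 3:
            raise BlueprintError("need >= 3 regions")
        if self.rep_uws_low_crsr_count > self.group_sizes["rep_UWS"]:
            raise BlueprintError(
                "rep_uws_low_crsr_count exceeds the rep_UWS group size"
            )

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path) -> "CohortBlueprint":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def null_blueprint(rng_seed: int = 0, **overrides) -> CohortBlueprint:
    """A blueprint with every class effect zeroed (deltas and the
    coupling-severity slope): all groups share one covariance, so any
    significant edges or classification signal downstream is pure noise."""
    kwargs = dict(
        decrease_delta=0.0,
        increase_delta=0.0,
        coupling_severity_slope=0.0,
        rng_seed=rng_seed,
    )
    kwargs.update(overrides)
    return CohortBlueprint(**kwargs)


def small_blueprint(rng_seed: int = 0) -> CohortBlueprint:
    """A fast 20-region preset with the same group structure, for tests."""
    return CohortBlueprint(
        n_regions=20,
        n_timepoints=120,
        group_sizes={"HC": 12, "rep_UWS": 14, "exc_UWS": 10,
                     "rep_MCS": 10, "exc_MCS": 4},
        decreased_edge_fraction=0.15,
        increased_edge_fraction=0.08,
        rep_uws_low_crsr_count=7,
        rng_seed=rng_seed,
    )


@dataclass
class GroundTruth:
    """Planted class per subject, the altered edge index sets, and each
    subject's drawn severity and global-coupling traits."""

    classes: dict[str, str]
    decreased_edges: np.ndarray
    increased_edges: np.ndarray
    severities: dict[str, float] = field(default_factory=dict)
    couplings: dict[str, float] = field(default_factory=dict)

    def ids(self, cls: str) -> list[str]:
        return [s for s, c in self.classes.items() if c == cls]

    def to_json(self, path=None) -> str:
        payload = {
            "classes": self.classes,
            "decreased_edges": self.decreased_edges.tolist(),
            "increased_edges": self.increased_edges.tolist(),
            "severities": self.severities,
            "couplings": self.couplings,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

def _nearest_correlation(a: np.ndarray, eps: float = 1e-4,
                         max_iter: int = 20) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix
    by alternating eigenvalue clipping and diagonal renormalization."""
    c = (a + a.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(c)
        if w[0] >= eps and np.allclose(np.diag(c), 1.0, atol=1e-12):
            return c
        w = np.clip(w, eps, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
    w = np.linalg.eigvalsh(c)
    if w[0] <= 0:
        raise BlueprintError(
            "positive-definite projection failed; try smaller deltas"
        )
    return c


N_FACTORS = 6


def _loadings_to_correlation(w: np.ndarray) -> np.ndarray:
    cov = w @ w.T + np.eye(w.shape[0])
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def _base_loadings(
    n: int, rng: np.random.Generator, loading_sd: float = 0.45
) -> np.ndarray:
    return rng.normal(0.0, loading_sd, size=(n, N_FACTORS))


def _base_correlation(
    n: int, rng: np.random.Generator, loading_sd: float = 0.45
) -> np.ndarray:
    """Low-rank factor-model correlation matrix with moderate couplings.
    With ``loading_sd = 0`` the base is the identity (independent regions),
    useful for null calibration checks."""
    return _loadings_to_correlation(_base_loadings(n, rng, loading_sd))


def _shift_and_project(
    base: np.ndarray,
    dec_idx: np.ndarray,
    inc_idx: np.ndarray,
    dec_delta: float,
    inc_delta: float,
) -> np.ndarray:
    n = base.shape[0]
    iu = np.triu_indices(n, k=1)
    r = base[iu].copy()
    r[dec_idx] = np.clip(r[dec_idx] + dec_delta, -0.95, 0.95)
    r[inc_idx] = np.clip(r[inc_idx] + inc_delta, -0.95, 0.95)
    out = np.eye(n)
    out[iu] = r
    out[(iu[1], iu[0])] = r
    return _nearest_correlation(out)


def _apply_deltas(
    base: np.ndarray,
    dec_idx: np.ndarray,
    inc_idx: np.ndarray,
    dec_delta: float,
    inc_delta: float,
    n_compensate: int = 2,
) -> np.ndarray:
    """Shift the planted edges and project back to a PD correlation matrix.

    Shifting hundreds of edges by +-0.3 makes the matrix strongly
    indefinite, and the positive-definite projection systematically
    shrinks the realized shifts; a couple of compensation rounds rescale
    the requested deltas so the realized mean shift on each planted set
    lands near its target.
    """
    req_d, req_i = dec_delta, inc_delta
    iu = np.triu_indices(base.shape[0], k=1)
    out = _shift_and_project(base, dec_idx, inc_idx, req_d, req_i)
    for _ in range(n_compensate):
        got = (out - base)[iu]
        gd, gi = got[dec_idx].mean(), got[inc_idx].mean()
        if dec_delta != 0.0 and gd != 0.0:
            req_d *= float(np.clip(dec_delta / gd, 0.5, 2.0))
        if inc_delta != 0.0 and gi != 0.0:
            req_i *= float(np.clip(inc_delta / gi, 0.5, 2.0))
        out = _shift_and_project(base, dec_idx, inc_idx, req_d, req_i)
    return out


def _plan(
    bp: CohortBlueprint, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the cohort-level design: base loadings and planted edge sets."""
    m = n_edges(bp.n_regions)
    n_dec = max(1, round(bp.decreased_edge_fraction * m))
    n_inc = max(1, round(bp.increased_edge_fraction * m))
    chosen = rng.choice(m, size=n_dec + n_inc, replace=False)
    dec_idx = np.sort(chosen[:n_dec])
    inc_idx = np.sort(chosen[n_dec:])
    loadings = _base_loadings(bp.n_regions, rng, bp.base_loading_sd)
    return loadings, dec_idx, inc_idx


def build_covariances(
    bp: CohortBlueprint, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Per-class region correlation matrices plus the planted edge sets.

    Returns ``(covariances, decreased_edges, increased_edges)``. The HC
    matrix is the factor-model base; rep_UWS (and exc_MCS, which shares
    the profile) applies the full deltas; exc_UWS and rep_MCS apply half
    deltas. All matrices are symmetric, unit-diagonal and strictly
    positive definite.
    """
    rng = rng if rng is not None else np.random.default_rng(bp.rng_seed)
    loadings, dec_idx, inc_idx = _plan(bp, rng)
    hc = _loadings_to_correlation(loadings)
    full = _apply_deltas(
        hc, dec_idx, inc_idx, bp.decrease_delta, bp.increase_delta
    )
    half = _apply_deltas(
        hc, dec_idx, inc_idx, bp.decrease_delta / 2, bp.increase_delta / 2
    )
    covs = {
        "HC": hc,
        "rep_UWS": full,
        "exc_UWS": half,
        "rep_MCS": half,
        "exc_MCS": full,
    }
    for cls, c in covs.items():
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise BlueprintError(
                f"class {cls}: covariance not positive definite; "
                "try smaller deltas"
            )
    return covs, dec_idx, inc_idx


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _draw_crsr(cls: str, k: int, n_in_class: int, bp: CohortBlueprint,
               rng: np.random.Generator) -> Optional[int]:
    """CRS-R total for the k-th member of a class (see module docstring)."""
    if cls == "HC":
        return None
    if cls == "rep_UWS":
        if k < bp.rep_uws_low_crsr_count:
            return int(rng.integers(3, 6))  # 3-5: the seeding subset
        return int(rng.integers(6, 8))  # 6-7
    if cls == "exc_UWS":
        return int(rng.integers(6, 8))
    return int(rng.integers(6, 19))  # MCS: 6-18


#: Class center of the per-subject severity multiplier on the deltas.
SEVERITY_CENTER = {
    "HC": 0.0,
    "rep_UWS": 1.0,
    "exc_UWS": 0.5,
    "rep_MCS": 0.5,
    "exc_MCS": 1.0,
}


def simulate_cohort(
    bp: CohortBlueprint,
) -> tuple[Cohort, dict[str, ROITimeSeries], GroundTruth]:
    """Draw a full synthetic cohort in memory.

    Returns the cohort manifest object (clinical labels only — mislabeled
    groups keep their clinical label), the per-subject time series, and
    the ground truth. Deterministic given ``bp.rng_seed``.
    """
    rng = np.random.default_rng(bp.rng_seed)
    loadings, dec_idx, inc_idx = _plan(bp, rng)
    subjects: list[Subject] = []
    timeseries: dict[str, ROITimeSeries] = {}
    classes: dict[str, str] = {}
    severities: dict[str, float] = {}
    couplings: dict[str, float] = {}
    counter = 0
    for cls in CLASSES:
        for k in range(bp.group_sizes[cls]):
            counter += 1
            sid = f"sub{counter:03d}"
            w_s = loadings + bp.subject_loading_sd * rng.standard_normal(
                loadings.shape
            )
            base_s = _loadings_to_correlation(w_s)
            if cls == "HC":
                sev_dec = sev_inc = 0.0
                corr = base_s
            else:
                center = SEVERITY_CENTER[cls]
                while True:  # rejection-sample the unit disk
                    u1, u2 = 2.0 * rng.random(2) - 1.0
                    if u1 * u1 + u2 * u2 <= 1.0:
                        break
                sev_dec = float(
                    np.clip(center + bp.severity_halfwidth * u1, 0.0, 1.3)
                )
                sev_inc = float(
                    np.clip(center + bp.severity_halfwidth * u2, 0.0, 1.3)
                )
                corr = _apply_deltas(
                    base_s, dec_idx, inc_idx,
                    sev_dec * bp.decrease_delta, sev_inc * bp.increase_delta,
                )
            sev = (sev_dec + sev_inc) / 2.0
            coupling = (
                1.0
                - bp.coupling_severity_slope * sev
                + bp.coupling_halfwidth * (2.0 * rng.random() - 1.0)
            )
            scaled = coupling * (corr - np.eye(bp.n_regions)) + np.eye(
                bp.n_regions
            )
            chol = np.linalg.cholesky(_nearest_correlation(scaled))
            latent = rng.standard_normal((bp.n_timepoints, bp.n_regions))
            x = latent @ chol.T
            x = x + bp.noise_sd * rng.standard_normal(x.shape)
            timeseries[sid] = ROITimeSeries(data=x, subject_id=sid)
            classes[sid] = cls
            severities[sid] = sev
            couplings[sid] = coupling
            subjects.append(
                Subject(
                    subject_id=sid,
                    clinical_label=CLINICAL_LABEL[cls],
                    crsr_total=_draw_crsr(cls, k, bp.group_sizes[cls], bp, rng),
                )
            )
    cohort = Cohort(
        subjects=subjects,
        provenance=f"synthetic cohort (seed {bp.rng_seed})",
    )
    truth = GroundTruth(
        classes=classes,
        decreased_edges=dec_idx,
        increased_edges=inc_idx,
        severities=severities,
        couplings=couplings,
    )
    return cohort, timeseries, truth


def generate_cohort(bp: CohortBlueprint, out_dir) -> dict[str, Path]:
    """Write a synthetic cohort to disk: ``manifest.csv``, one delimited
    time-series file per subject under ``timeseries/``, the ground truth
    and a blueprint echo as JSON. Bytewise reproducible under the same
    seed. Returns the paths written."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    cohort, timeseries, truth = simulate_cohort(bp)
    for s in cohort:
        np.savetxt(
            ts_dir / f"{s.subject_id}.tsv",
            timeseries[s.subject_id].data,
            fmt="%.6f",
            delimiter="\t",
        )
    cohort = Cohort(
        subjects=[
            replace(s, timeseries_path=f"timeseries/{s.subject_id}.tsv")
            for s in cohort
        ],
        provenance=cohort.provenance,
    )
    manifest = out / "manifest.csv"
    save_manifest(cohort, manifest)
    truth_path = out / "ground_truth.json"
    truth.to_json(truth_path)
    bp_path = out / "blueprint.json"
    bp.to_json(bp_path)
    return {
        "manifest": manifest,
        "timeseries_dir": ts_dir,
        "ground_truth": truth_path,
        "blueprint": bp_path,
    }
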