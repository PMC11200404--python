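"""Cycle-wise multivariate monitoring: PCA, Hotelling T², DModX, control charts.

Each completed cycle is landmark-resampled onto a fixed-length feature
vector (L points per sensor trace, concatenated sensor-major), autoscaled
with the reference window's column means and standard deviations, and
compared against a frozen steady-state PCA model.  Two statistics are
tracked per cycle: Hotelling T² (distance within the model plane) and DModX
(normalised distance to the model plane), each with an F-based control
limit at confidence 1 - α following the SIMCA convention.  Univariate
mean ± k·SD charts are provided for discrete at-line series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .historian import CycleRecord

__all__ = [
    "CycleMatrix",
    "PCAModel",
    "CycleAssessment",
    "merge_cycle_records",
    "build_cycle_matrix",
    "scale_vector",
    "fit_pca",
    "assess_cycle",
    "univariate_limits",
    "Monitor",
    "monitor_campaign",
    "export_charts",
]

CHROM_SENSORS = (
    "proa:uv", "proa:ph", "proa:cond", "proa:press",
    "cex:uv", "cex:ph_load", "cex:ph", "cex:cond", "cex:press",
)
UFDF_SENSORS = ("ufdf:press_feed", "ufdf:press_retentate", "ufdf:press_permeate")

#: default landmarks per trace: keeps p = n_sensors * L small enough that the
#: SIMCA F-limit stays calibrated for prediction with a 36-cycle reference
DEFAULT_LANDMARKS = 15


class MonitorError(ValueError):
    pass


@dataclass
class CycleMatrix:
    """Landmark-resampled cycle vectors with reference-based autoscaling."""

    X: np.ndarray  # (n, p), scaled
    cycle_ids: list[int]
    sensors: list[str]
    L: int
    mean: np.ndarray  # (p,) reference column means
    sd: np.ndarray  # (p,) reference column sds (1.0 where zero variance)
    zero_variance: np.ndarray  # (p,) bool flags
    ref_ids: list[int] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def feature_names(self) -> list[str]:
        return [f"{s}@{j}" for s in self.sensors for j in range(self.L)]

    def row(self, cycle_id: int) -> np.ndarray:
        return self.X[self.cycle_ids.index(cycle_id)]


@dataclass
class PCAModel:
    """Frozen steady-state reference model (SIMCA-style conventions)."""

    k: int
    loadings: np.ndarray  # (p, k), orthonormal columns
    score_sd: np.ndarray  # (k,) standard deviation of reference scores
    s0: float  # pooled residual scale of the reference set
    n_ref: int
    p: int
    alpha: float
    t2_limit: float
    dmodx_limit: float
    explained: np.ndarray  # (k,) fraction of reference variance per component
    mean: np.ndarray | None = None  # scaling carried over from the CycleMatrix
    sd: np.ndarray | None = None


@dataclass
class CycleAssessment:
    cycle_id: int
    scores: np.ndarray
    t2: float
    dmodx: float
    status: str  # in_control | warning | out_of_control
    contributions: np.ndarray  # squared residual per feature

    @property
    def out_of_control(self) -> bool:
        return self.status == "out_of_control"


def merge_cycle_records(per_unit: Sequence[Sequence[CycleRecord]]) -> list[CycleRecord]:
    """Join per-unit cycle lists on cycle id, namespacing traces as unit:sensor.

    Only cycle ids present in every unit are kept; the merged window spans
    the earliest start to the latest end.
    """
    by_id: dict[int, list[CycleRecord]] = {}
    for recs in per_unit:
        for r in recs:
            by_id.setdefault(r.cycle_id, []).append(r)
    n_units = len(per_unit)
    merged = []
    for cid in sorted(by_id):
        group = by_id[cid]
        if len(group) != n_units:
            continue
        rec = CycleRecord(
            cycle_id=cid,
            unit_id="+".join(sorted({g.unit_id for g in group})),
            start=min(g.start for g in group),
            end=max(g.end for g in group),
        )
        for g in group:
            for sid, tv in g.traces.items():
                rec.traces[f"{g.unit_id}:{sid}"] = tv
        merged.append(rec)
    return merged


def _landmarks(rec: CycleRecord, sensor: str, L: int) -> np.ndarray:
    if sensor not in rec.traces:
        raise MonitorError(f"cycle {rec.cycle_id}: missing sensor {sensor!r}")
    t, v = rec.traces[sensor]
    if len(t) == 0:
        raise MonitorError(f"cycle {rec.cycle_id}: sensor {sensor!r} has no samples")
    grid = rec.start + np.arange(L) * (rec.end - rec.start) / L
    return np.interp(grid, t, v)


def build_cycle_matrix(
    cycles: Sequence[CycleRecord],
    sensors: Sequence[str],
    L: int = DEFAULT_LANDMARKS,
    ref_ids: Sequence[int] | None = None,
) -> CycleMatrix:
    """Resample each cycle's traces onto L landmarks and autoscale.

    Each trace is linearly interpolated onto L equispaced points over the
    cycle's own [start, end) window; features are concatenated sensor-major.
    Column means/sds are computed from the reference cycles only (default:
    all cycles); zero-variance columns are scaled by 1 and flagged.
    """
    if L < 2:
        raise MonitorError("need at least 2 landmarks")
    if not cycles:
        raise MonitorError("no cycles to assemble")
    ids = [c.cycle_id for c in cycles]
    raw = np.stack(
        [np.concatenate([_landmarks(c, s, L) for s in sensors]) for c in cycles]
    )
    if ref_ids is None:
        ref_ids = ids
    ref_mask = np.array([i in set(ref_ids) for i in ids])
    if not ref_mask.any():
        raise MonitorError("reference window contains no assembled cycles")
    ref = raw[ref_mask]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1) if ref.shape[0] > 1 else np.zeros(raw.shape[1])
    zero = sd <= 0
    sd_safe = np.where(zero, 1.0, sd)
    X = (raw - mean) / sd_safe
    return CycleMatrix(
        X=X, cycle_ids=ids, sensors=list(sensors), L=L,
        mean=mean, sd=sd_safe, zero_variance=zero, ref_ids=list(ref_ids),
    )


def scale_vector(m: CycleMatrix, raw: np.ndarray) -> np.ndarray:
    """Apply the matrix's reference autoscaling to a raw feature vector."""
    return (np.asarray(raw, dtype=float) - m.mean) / m.sd


def fit_pca(m: CycleMatrix, k: int | float = 3, alpha: float = 0.05) -> PCAModel:
    """Fit the steady-state PCA model on the matrix's reference rows.

    ``k`` is either a component count or a variance fraction in (0, 1).
    Loadings and score variances come from the SVD of the scaled reference
    matrix; the residual scale is s0² = RSS / ((n-k-1)(p-k)).  Control
    limits: T² ~ k(n²-1)/(n(n-k)) · F(1-α; k, n-k) and DModX ~
    sqrt(F(1-α; p-k, (n-k-1)(p-k))).
    """
    ref_mask = np.array([i in set(m.ref_ids) for i in m.cycle_ids])
    X = m.X[ref_mask]
    n, p = X.shape
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    lam = S**2 / max(n - 1, 1)  # component variances
    total = lam.sum()
    if isinstance(k, float) and 0 < k < 1:
        frac = np.cumsum(lam) / total if total > 0 else np.ones_like(lam)
        k = int(np.searchsorted(frac, k - 1e-12) + 1)
    k = int(k)
    if k > n - 2:
        raise MonitorError(f"k={k} needs at least {k + 2} reference cycles, have {n}")
    if k < 1 or k > min(n - 1, p):
        raise MonitorError(f"invalid component count k={k}")
    P = Vt[:k].T.copy()
    # sign convention: the largest-magnitude element of each loading is positive
    for a in range(k):
        j = np.argmax(np.abs(P[:, a]))
        if P[j, a] < 0:
            P[:, a] = -P[:, a]
    score_sd = np.sqrt(lam[:k])
    rss = float((S[k:] ** 2).sum())
    dof = (n - k - 1) * (p - k)
    s0 = np.sqrt(rss / dof) if dof > 0 else 0.0
    t2_limit = k * (n**2 - 1) / (n * (n - k)) * stats.f.ppf(1 - alpha, k, n - k)
    dmodx_limit = float(np.sqrt(stats.f.ppf(1 - alpha, p - k, dof))) if dof > 0 else np.inf
    return PCAModel(
        k=k, loadings=P, score_sd=score_sd, s0=float(s0), n_ref=n, p=p,
        alpha=alpha, t2_limit=float(t2_limit), dmodx_limit=dmodx_limit,
        explained=lam[:k] / total if total > 0 else np.zeros(k),
        mean=m.mean.copy(), sd=m.sd.copy(),
    )


def assess_cycle(model: PCAModel, x: np.ndarray, cycle_id: int = 0) -> CycleAssessment:
    """Score one scaled cycle vector against the frozen model.

    T² = Σ (t_a / s_a)²; DModX = sqrt(RSS / (p-k)) / s0; status is
    out_of_control beyond either limit, warning when any score exceeds
    2 s_a, else in_control.  Contributions are squared residuals per feature.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.p,):
        raise MonitorError(f"cycle vector has length {x.size}, model expects {model.p}")
    scores = model.loadings.T @ x
    with np.errstate(divide="ignore", invalid="ignore"):
        std_scores = np.where(model.score_sd > 0, scores / model.score_sd, 0.0)
    t2 = float((std_scores**2).sum())
    resid = x - model.loadings @ scores
    contrib = resid**2
    rss = float(contrib.sum())
    dmodx = np.sqrt(rss / (model.p - model.k)) / model.s0 if model.s0 > 0 else 0.0
    if t2 > model.t2_limit or dmodx > model.dmodx_limit:
        status = "out_of_control"
    elif np.any(np.abs(scores) > 2 * model.score_sd):
        status = "warning"
    else:
        status = "in_control"
    return CycleAssessment(
        cycle_id=cycle_id, scores=scores, t2=t2, dmodx=float(dmodx),
        status=status, contributions=contrib,
    )


def univariate_limits(series, k_sd: float = 1.0):
    """Mean ± k·SD control lines plus per-point exceedance flags.

    The display default k=1 matches ±1 SD chart lines; alarms typically use
    k=3.  A constant series collapses the limits onto the mean, so every
    off-mean point flags.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("series must have at least 2 points")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    lower, upper = mu - k_sd * sd, mu + k_sd * sd
    flags = (x < lower) | (x > upper)
    return (mu, lower, upper), flags


class Monitor:
    """Streaming monitor: frozen reference model + incremental assessments.

    The model is fitted once on the reference window and never refit; each
    refresh assesses the newest cycle against the frozen limits and can
    export the score/DModX charts.
    """

    def __init__(self, sensors: Sequence[str], L: int = DEFAULT_LANDMARKS, k: int | float = 3,
                 alpha: float = 0.05):
        self.sensors = list(sensors)
        self.L = L
        self.k = k
        self.alpha = alpha
        self.matrix: CycleMatrix | None = None
        self.model: PCAModel | None = None
        self.assessments: list[CycleAssessment] = []

    def fit(self, reference_cycles: Sequence[CycleRecord]) -> PCAModel:
        ids = [c.cycle_id for c in reference_cycles]
        self.matrix = build_cycle_matrix(reference_cycles, self.sensors, self.L, ref_ids=ids)
        self.model = fit_pca(self.matrix, self.k, self.alpha)
        self.assessments = [
            assess_cycle(self.model, self.matrix.X[i], cid)
            for i, cid in enumerate(self.matrix.cycle_ids)
        ]
        return self.model

    def refresh(self, cycle: CycleRecord, chart_dir=None) -> CycleAssessment:
        """Assess one new cycle against the frozen model; optionally export charts."""
        if self.model is None or self.matrix is None:
            raise MonitorError("refresh before fit: fit the reference model first")
        raw = np.concatenate([_landmarks(cycle, s, self.L) for s in self.sensors])
        a = assess_cycle(self.model, scale_vector(self.matrix, raw), cycle.cycle_id)
        self.assessments.append(a)
        if chart_dir is not None:
            export_charts(self.assessments, self.model, chart_dir,
                          ref_ids=self.matrix.ref_ids)
        return a

    def dominant_sensor(self, a: CycleAssessment) -> str:
        """Sensor with the largest summed residual contribution (ties: id order)."""
        per_sensor = a.contributions.reshape(len(self.sensors), self.L).sum(axis=1)
        order = np.argsort(per_sensor)[::-1]
        best = per_sensor[order[0]]
        candidates = sorted(self.sensors[i] for i in range(len(self.sensors))
                            if per_sensor[i] >= best * (1 - 1e-12))
        return candidates[0]


def monitor_campaign(
    proa_cycles: Sequence[CycleRecord],
    cex_cycles: Sequence[CycleRecord],
    ufdf_cycles: Sequence[CycleRecord] = (),
    L: int = DEFAULT_LANDMARKS,
    k: int | float = 3,
    alpha: float = 0.05,
    chrom_ref: tuple[int, int] = (7, 42),
    ufdf_ref: tuple[int, int] = (1, 4),
) -> dict:
    """Assess a full campaign: one joint chromatography monitor (Protein A +
    CEX sensors per cycle) and one UF-DF monitor over the filtration cycles.

    Returns {"chrom": {...}, "ufdf": {...}} with the Monitor objects, the
    per-cycle assessments and the first out-of-control cycle index of each.
    """
    merged = merge_cycle_records([proa_cycles, cex_cycles])
    ref = [c for c in merged if chrom_ref[0] <= c.cycle_id <= chrom_ref[1]]
    if len(ref) < 4:
        raise MonitorError(f"chromatography reference window has only {len(ref)} cycles")
    chrom = Monitor(CHROM_SENSORS, L=L, k=k, alpha=alpha)
    chrom.fit(ref)
    for c in merged:
        if c.cycle_id > chrom_ref[1]:
            chrom.refresh(c)
    out = {"chrom": _summarise(chrom)}

    if ufdf_cycles:
        ufdf_cycles = merge_cycle_records([ufdf_cycles])  # namespace as ufdf:sensor
        ref_u = [c for c in ufdf_cycles if ufdf_ref[0] <= c.cycle_id <= ufdf_ref[1]]
        if len(ref_u) < 3:  # cannot fit even a one-component reference
            return out
        k_u = min(int(k) if not isinstance(k, float) else 3, max(len(ref_u) - 2, 1))
        ufdf = Monitor(UFDF_SENSORS, L=L, k=k_u, alpha=alpha)
        ufdf.fit(ref_u)
        for c in ufdf_cycles:
            if c.cycle_id > ufdf_ref[1]:
                ufdf.refresh(c)
        out["ufdf"] = _summarise(ufdf)
    return out


def _summarise(mon: Monitor) -> dict:
    """Campaign summary.  Reference cycles are re-assessed for the charts and
    the calibration check, but monitoring proper starts once the reference
    model is frozen: ``first_out_of_control`` is the first flagged cycle
    outside the reference window (the training set is not under
    surveillance against limits it defined)."""
    ref = set(mon.matrix.ref_ids) if mon.matrix is not None else set()
    flagged = sorted(a.cycle_id for a in mon.assessments if a.out_of_control)
    monitored_flagged = [c for c in flagged if c not in ref]
    return {
        "monitor": mon,
        "assessments": sorted(mon.assessments, key=lambda a: a.cycle_id),
        "flagged_cycles": monitored_flagged,
        "flagged_reference_cycles": [c for c in flagged if c in ref],
        "first_out_of_control": monitored_flagged[0] if monitored_flagged else None,
    }


def export_charts(assessments: Sequence[CycleAssessment], model: PCAModel, out_dir,
                  ref_ids: Sequence[int] = (), prefix: str = "chrom") -> list[str]:
    """Write PC1-PC2 / PC1-PC3 score plots and the DModX-per-cycle chart."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = set(ref_ids)
    files = []
    pairs = [(0, 1)] + ([(0, 2)] if model.k >= 3 else [])
    for i, j in pairs:
        fig, ax = plt.subplots(figsize=(5, 4))
        for a in assessments:
            is_ref = a.cycle_id in ref
            sj = a.scores[j] if model.k > j else 0.0
            ax.scatter(a.scores[i], sj,
                       c="tab:blue" if is_ref else ("tab:red" if a.out_of_control else "tab:orange"),
                       s=18)
            if not is_ref:
                ax.annotate(str(a.cycle_id), (a.scores[i], sj), fontsize=7)
        ax.set_xlabel(f"PC{i + 1} score")
        ax.set_ylabel(f"PC{j + 1} score")
        ax.set_title(f"{prefix}: PC{i + 1} vs PC{j + 1}")
        f = out_dir / f"{prefix}_scores_pc{i + 1}_pc{j + 1}.png"
        fig.savefig(f, dpi=100)
        plt.close(fig)
        files.append(str(f))
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ids = [a.cycle_id for a in assessments]
    ax.bar(ids, [a.dmodx for a in assessments],
           color=["tab:red" if a.out_of_control else "tab:blue" for a in assessments])
    ax.axhline(model.dmodx_limit, ls="--", c="k", lw=1, label=f"limit (α={model.alpha})")
    ax.set_xlabel("cycle")
    ax.set_ylabel("DModX")
    ax.legend()
    f = out_dir / f"{prefix}_dmodx.png"
    fig.savefig(f, dpi=100)
    plt.close(fig)
    files.append(str(f))
    return files
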