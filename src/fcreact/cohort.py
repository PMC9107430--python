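"""Synthetic cohorts for a levodopa-challenge connectivity study.

Generates complete, self-contained study data — clinical records and per-session
ROI time series — with the statistical structure the downstream pipeline assumes:

* two patient groups (dopamine-resistant / dopamine-responsive tremor) whose
  tremor change rates cluster around distinct targets,
* OFF and ON medication sessions per subject, with one *planted* cholinergic
  edge whose population correlation is identical across groups in OFF but drops
  only in the responsive group in ON,
* an optional normal-control arm with no session effect,
* demographically matched covariates (age, gender, education).

Time series are multivariate Gaussian.  The background correlation structure is
a one-factor (global-signal-like) model: every ROI loads on a single latent
factor, which yields a uniform pairwise correlation at any level in (0, 1)
while keeping the covariance matrix positive definite by construction.
Dopaminergic and cholinergic subcortical ROIs can be given their own
subcortico-cortical background levels, and patients' levels can be scaled per
session to emulate disease-related attenuation that levodopa partially
restores.  The planted edge is then overridden on top of this background.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DA_LABELS",
    "ACH_LABELS",
    "SimParams",
    "ClinicalRecord",
    "SessionTimeSeries",
    "cortical_labels",
    "roi_covariance",
    "sample_correlated_series",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "EXCLUSION_FLAGS",
]

#: Dopaminergic seed ROIs: bilateral thalamus, caudate, putamen, pallidum.
DA_LABELS = [
    "L.Thalamus", "R.Thalamus",
    "L.Caudate", "R.Caudate",
    "L.Putamen", "R.Putamen",
    "L.Pallidum", "R.Pallidum",
]

#: Cholinergic basal-forebrain seed ROIs (Ch1-2-3 and Ch4 cell groups).
ACH_LABELS = ["L.BF123", "R.BF123", "L.BF4", "R.BF4"]

#: Exclusion flags, in the order the subject-flow filter applies them.
EXCLUSION_FLAGS = [
    "lacunar_infarction",
    "baseline_on_status",
    "no_tremor",
    "no_mri",
    "high_motion",
]


def cortical_labels(n: int) -> list[str]:
    """Labels for ``n`` cortical parcels, left hemisphere first."""
    half = (n + 1) // 2
    left = [f"L.Ctx{i:02d}" for i in range(1, half + 1)]
    right = [f"R.Ctx{i:02d}" for i in range(1, n - half + 1)]
    return left + right


@dataclass
class SimParams:
    """Parameters of the synthetic cohort.

    Correlation parameters are Pearson correlations of the underlying
    stationary Gaussian process (so their Fisher-z images are what the
    connectivity stage estimates).  ``planted_edge`` is
    ``(system, subcortical_index, cortical_index)`` with system in
    ``{"da", "ach"}``.
    """

    n_resistant: int = 24
    n_responsive: int = 28
    n_controls: int = 93
    n_timepoints: int = 200
    n_cortical: int = 96
    n_da_rois: int = 8
    n_ach_rois: int = 4

    # Background connectivity (control level); patient sessions are scaled.
    rho_background: float = 0.20
    rho_background_da: float | None = 0.31
    rho_background_ach: float | None = 0.20
    da_scale_off: float = 0.78
    da_scale_on: float = 0.91
    ach_scale_off: float = 0.85
    ach_scale_on: float = 0.85

    # Planted cholinergic edge (defaults: right BF123 -> a right parietal parcel).
    planted_edge: tuple[str, int, int] = ("ach", 1, 91)
    rho_off: float = 0.16
    rho_on_resistant: float = 0.17
    rho_on_responsive: float = 0.01

    # Clinical targets: tremor change-rate distributions per group.
    tremor_mu_resistant: float = 0.27
    tremor_sd_resistant: float = 0.24
    tremor_mu_responsive: float = 0.92
    tremor_sd_responsive: float = 0.13
    tremor_off_mean: float = 4.0
    tremor_off_sd: float = 3.0

    # Demographics, matched across groups by construction.
    age_mean: float = 60.0
    age_sd: float = 9.0
    education_mean: float = 9.0
    education_sd: float = 4.4
    male_prop: float = 0.6
    duration_mean: float = 4.7
    duration_sd: float = 3.5
    led_mean: float = 475.0
    led_sd: float = 385.0

    temporal_ar1: float = 0.0
    seed: int = 0

    #: Counts of extra recruits planted with each exclusion flag.
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_resistant < 2 or self.n_responsive < 2:
            raise ValueError("group sizes must be >= 2")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if not 0.0 <= self.temporal_ar1 < 1.0:
            raise ValueError("temporal_ar1 must lie in [0, 1)")
        for name in ("rho_background", "rho_off", "rho_on_resistant",
                     "rho_on_responsive"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly inside (-1, 1)")
        sys, s, c = self.planted_edge
        if sys not in ("da", "ach"):
            raise ValueError("planted_edge system must be 'da' or 'ach'")
        n_sub = self.n_da_rois if sys == "da" else self.n_ach_rois
        if not (0 <= s < n_sub and 0 <= c < self.n_cortical):
            raise ValueError("planted_edge indices out of range")
        unknown = set(self.exclusions) - set(EXCLUSION_FLAGS)
        if unknown:
            raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
        # Covariance must be constructible for every group/session cell.
        for group in ("resistant", "responsive", "control"):
            for session in ("OFF", "ON"):
                roi_covariance(self, group, session)

    # -- derived labels -----------------------------------------------------
    @property
    def roi_labels(self) -> list[str]:
        return (cortical_labels(self.n_cortical)
                + DA_LABELS[: self.n_da_rois]
                + ACH_LABELS[: self.n_ach_rois])

    @property
    def roi_partition(self) -> dict[str, str]:
        part = {}
        for lab in cortical_labels(self.n_cortical):
            part[lab] = "cortical"
        for lab in DA_LABELS[: self.n_da_rois]:
            part[lab] = "dopaminergic"
        for lab in ACH_LABELS[: self.n_ach_rois]:
            part[lab] = "cholinergic"
        return part

    def planted_edge_labels(self) -> tuple[str, str, str]:
        """(system, subcortical label, cortical label) of the planted edge."""
        sys, s, c = self.planted_edge
        sub = (DA_LABELS if sys == "da" else ACH_LABELS)[s]
        return sys, sub, cortical_labels(self.n_cortical)[c]


@dataclass
class ClinicalRecord:
    subject_id: str
    cohort: str                      # "patient" | "control"
    age: float
    gender: str                      # "M" | "F"
    education: float
    disease_duration: float | None = None
    led: float | None = None
    updrs3_off: int | None = None
    updrs3_on: int | None = None
    tremor_off: int | None = None
    tremor_on: int | None = None
    rigidity_off: int | None = None
    rigidity_on: int | None = None
    bradykinesia_off: int | None = None
    bradykinesia_on: int | None = None
    tremor_responsiveness: float | None = None
    group: str = "unassigned"        # resistant | responsive | control | unassigned
    lacunar_infarction: bool = False
    baseline_on_status: bool = False
    no_tremor: bool = False
    no_mri: bool = False
    high_motion: bool = False

    def validate(self) -> None:
        if self.cohort == "patient" and self.updrs3_off is not None:
            for state in ("off", "on"):
                total = getattr(self, f"updrs3_{state}")
                parts = sum(getattr(self, f"{k}_{state}") or 0
                            for k in ("tremor", "rigidity", "bradykinesia"))
                if parts > total:
                    raise ValueError(
                        f"{self.subject_id}: sub-scores exceed UPDRS III {state.upper()}")
        if (self.tremor_responsiveness is not None
                and self.tremor_on is not None and self.tremor_on >= 0
                and self.tremor_responsiveness > 1 + 1e-12):
            raise ValueError(f"{self.subject_id}: responsiveness > 1")


@dataclass
class SessionTimeSeries:
    subject_id: str
    session: str                     # "OFF" | "ON"
    values: np.ndarray               # timepoints x ROIs
    roi_labels: list[str]
    roi_partition: dict[str, str]

    def validate(self) -> None:
        if self.session not in ("OFF", "ON"):
            raise ValueError("session must be OFF or ON")
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.subject_id}/{self.session}: non-finite values")
        if len(self.roi_labels) != v.shape[1]:
            raise ValueError("roi_labels length does not match column count")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        zero = v.std(axis=0) == 0
        if zero.any():
            bad = [l for l, z in zip(self.roi_labels, zero) if z]
            raise ValueError(f"zero-variance ROI(s): {bad}")

    def columns(self, klass: str) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.roi_labels)
               if self.roi_partition[lab] == klass]
        return self.values[:, idx]


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------

def roi_covariance(params: SimParams, group: str, session: str) -> np.ndarray:
    """Population ROI correlation matrix for one group/session cell.

    One-factor background: cortical ROIs load ``a = sqrt(rho_background)`` on a
    shared factor, subcortical ROIs load ``rho_sys / a`` so that every
    subcortico-cortical pair has correlation ``rho_sys``.  Patients' levels are
    scaled per session (disease attenuation / levodopa restoration); controls
    use the unscaled level in both sessions.  The planted edge is overridden
    last.  Positive definiteness is checked numerically; invalid background
    loadings are rescaled with a warning, a planting that breaks positive
    definiteness is rejected naming the pair.
    """
    p = params
    a = math.sqrt(p.rho_background)
    rho_da = p.rho_background_da if p.rho_background_da is not None else p.rho_background
    rho_ach = p.rho_background_ach if p.rho_background_ach is not None else p.rho_background
    if group in ("resistant", "responsive"):
        rho_da *= p.da_scale_off if session == "OFF" else p.da_scale_on
        rho_ach *= p.ach_scale_off if session == "OFF" else p.ach_scale_on

    loadings = np.concatenate([
        np.full(p.n_cortical, a),
        np.full(p.n_da_rois, rho_da / a),
        np.full(p.n_ach_rois, rho_ach / a),
    ])
    if np.any(np.abs(loadings) >= 1.0):
        scale = 0.99 / np.max(np.abs(loadings))
        warnings.warn(
            "background correlations imply factor loadings >= 1; "
            f"rescaling subcortical loadings by {scale:.3f}", stacklevel=2)
        loadings = np.clip(loadings, -0.99, 0.99)

    cov = np.outer(loadings, loadings)
    np.fill_diagonal(cov, 1.0)

    # Planted edge override (patients: session/group specific; controls: OFF level).
    sys_tag, s_idx, c_idx = p.planted_edge
    if group == "control" or session == "OFF":
        rho_edge = p.rho_off
    else:
        rho_edge = p.rho_on_resistant if group == "resistant" else p.rho_on_responsive
    s_global = p.n_cortical + (s_idx if sys_tag == "da" else p.n_da_rois + s_idx)
    cov[s_global, c_idx] = cov[c_idx, s_global] = rho_edge

    w = np.linalg.eigvalsh(cov)
    if w[0] <= 1e-10:
        _, sub, cort = p.planted_edge_labels()
        raise ValueError(
            f"ROI covariance not positive definite after rescaling "
            f"(min eigenvalue {w[0]:.3e}); offending pair: {sub}-{cort}")
    return cov


def sample_correlated_series(cov: np.ndarray, T: int, ar1: float = 0.0,
                             seed=None) -> np.ndarray:
    """Draw a ``T x p`` zero-mean Gaussian series with cross-ROI covariance ``cov``.

    With ``ar1 > 0`` each ROI additionally carries AR(1) temporal
    autocorrelation; the stationary cross-sectional covariance is preserved
    (innovations scaled by ``sqrt(1 - ar1**2)``).
    """
    cov = np.asarray(cov, dtype=float)
    if not 0.0 <= ar1 < 1.0:
        raise ValueError("ar1 must lie in [0, 1)")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(cov)
        raise ValueError(
            f"covariance is not positive definite (smallest eigenvalue {w[0]:.3e})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    innov = rng.standard_normal((T, cov.shape[0])) @ L.T
    if ar1 == 0.0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    c = math.sqrt(1.0 - ar1 * ar1)
    for t in range(1, T):
        out[t] = ar1 * out[t - 1] + c * innov[t]
    return out


# ---------------------------------------------------------------------------
# Clinical record sampling
# ---------------------------------------------------------------------------

def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(alpha, beta) for a mean/sd on (0, 1)."""
    var = sd * sd
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:  # variance too large for a Beta; fall back to a near-flat prior
        nu = 0.1
    return mean * nu, (1.0 - mean) * nu


def _sample_patient_clinical(rng: np.random.Generator, params: SimParams,
                             subject_id: str, group: str) -> ClinicalRecord:
    p = params
    age = round(float(rng.normal(p.age_mean, p.age_sd)), 1)
    gender = "M" if rng.random() < p.male_prop else "F"
    education = max(0, int(round(rng.normal(p.education_mean, p.education_sd))))
    duration = round(max(0.25, float(rng.normal(p.duration_mean, p.duration_sd))), 2)
    led = round(max(0.0, float(rng.normal(p.led_mean, p.led_sd))), 1)

    tremor_off = max(1, int(round(rng.normal(p.tremor_off_mean, p.tremor_off_sd))))
    if group == "resistant":
        a, b = _beta_params(p.tremor_mu_resistant, p.tremor_sd_resistant)
    else:
        a, b = _beta_params(p.tremor_mu_responsive, p.tremor_sd_responsive)
    c = float(np.clip(rng.beta(a, b), 0.0, 1.0))
    tremor_on = max(0, int(round(tremor_off * (1.0 - c))))

    def _improved(off: int, mu: float = 0.35, sd: float = 0.25) -> int:
        frac = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
        return max(0, int(round(off * (1.0 - frac))))

    rigidity_off = max(0, int(round(rng.normal(5.4, 4.3))))
    rigidity_on = _improved(rigidity_off)
    brady_off = max(0, int(round(rng.normal(9.0, 7.0))))
    brady_on = _improved(brady_off)
    axial_off = max(0, int(round(rng.normal(4.0, 3.0))))
    axial_on = _improved(axial_off, 0.30, 0.25)

    rec = ClinicalRecord(
        subject_id=subject_id, cohort="patient", age=age, gender=gender,
        education=education, disease_duration=duration, led=led,
        updrs3_off=tremor_off + rigidity_off + brady_off + axial_off,
        updrs3_on=tremor_on + rigidity_on + brady_on + axial_on,
        tremor_off=tremor_off, tremor_on=tremor_on,
        rigidity_off=rigidity_off, rigidity_on=rigidity_on,
        bradykinesia_off=brady_off, bradykinesia_on=brady_on,
        tremor_responsiveness=(tremor_off - tremor_on) / tremor_off,
        group=group,
    )
    rec.validate()
    return rec


def generate_cohort(params: SimParams
                    ) -> tuple[list[ClinicalRecord], list[SessionTimeSeries]]:
    """Generate clinical records and OFF/ON time series for a full cohort.

    Deterministic: identical ``params`` (including seed) give bitwise-identical
    output.  Extra recruits carrying exclusion flags (``params.exclusions``)
    receive clinical records only — the subject-flow filter removes them before
    any imaging stage runs.
    """
    p = params
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    records: list[ClinicalRecord] = []
    series: list[SessionTimeSeries] = []

    covs = {(g, s): roi_covariance(p, g, s)
            for g in ("resistant", "responsive", "control") for s in ("OFF", "ON")}
    labels, part = p.roi_labels, p.roi_partition

    def _emit_sessions(subject_id: str, group: str) -> None:
        for session in ("OFF", "ON"):
            vals = sample_correlated_series(
                covs[(group, session)], p.n_timepoints, p.temporal_ar1, rng)
            ts = SessionTimeSeries(subject_id, session, vals, list(labels), dict(part))
            ts.validate()
            series.append(ts)

    sid = 0
    for group, n in (("resistant", p.n_resistant), ("responsive", p.n_responsive)):
        for _ in range(n):
            sid += 1
            rec = _sample_patient_clinical(rng, p, f"sub-{sid:04d}", group)
            records.append(rec)
            _emit_sessions(rec.subject_id, group)

    for i in range(p.n_controls):
        rec = ClinicalRecord(
            subject_id=f"con-{i + 1:04d}", cohort="control",
            age=round(float(rng.normal(p.age_mean, p.age_sd)), 1),
            gender="M" if rng.random() < p.male_prop else "F",
            education=max(0, int(round(rng.normal(p.education_mean, p.education_sd)))),
            group="control",
        )
        records.append(rec)
        _emit_sessions(rec.subject_id, "control")

    for flag in EXCLUSION_FLAGS:
        for _ in range(p.exclusions.get(flag, 0)):
            sid += 1
            rec = _sample_patient_clinical(rng, p, f"sub-{sid:04d}", "unassigned")
            rec.group = "unassigned"
            setattr(rec, flag, True)
            if flag == "no_tremor":
                rec.tremor_off = 0
                rec.tremor_on = 0
                rec.tremor_responsiveness = None
            records.append(rec)

    return records, series


# ---------------------------------------------------------------------------
# Disk round-trip (TSV/CSV/JSON dialect)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"


def write_cohort(out_dir, records: list[ClinicalRecord],
                 series: list[SessionTimeSeries], params: SimParams) -> None:
    """Write one TSV per subject-session plus participants/partition/params files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        out / "participants.csv", index=False, float_format=_FLOAT_FMT)
    if series:
        part = series[0].roi_partition
        pd.DataFrame({"roi": list(part), "class": [part[k] for k in part]}).to_csv(
            out / "roi_partition.tsv", sep="\t", index=False)
    for ts in series:
        pd.DataFrame(ts.values, columns=ts.roi_labels).to_csv(
            out / f"{ts.subject_id}_{ts.session}_ts.tsv",
            sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(out / "sim_params.json", "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_cohort(in_dir) -> tuple[list[ClinicalRecord], list[SessionTimeSeries]]:
    """Read a cohort written by :func:`write_cohort` (or any same-dialect data)."""
    root = Path(in_dir)
    df = pd.read_csv(root / "participants.csv")
    records = []
    for _, row in df.iterrows():
        kw = {}
        for f in dataclasses.fields(ClinicalRecord):
            v = row[f.name]
            if pd.isna(v):
                v = None
            elif f.type.startswith("bool"):
                v = bool(v)
            elif f.type.startswith("int | None"):
                v = int(v)
            kw[f.name] = v
        records.append(ClinicalRecord(**kw))
    part_df = pd.read_csv(root / "roi_partition.tsv", sep="\t")
    part = dict(zip(part_df["roi"], part_df["class"]))
    series = []
    for path in sorted(root.glob("*_ts.tsv")):
        stem = path.name[: -len("_ts.tsv")]
        subject_id, session = stem.rsplit("_", 1)
        tab = pd.read_csv(path, sep="\t", float_precision="round_trip")
        ts = SessionTimeSeries(subject_id, session, tab.to_numpy(float),
                               list(tab.columns), part)
        ts.validate()
        series.append(ts)
    return records, series
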