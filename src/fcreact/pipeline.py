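"""End-to-end orchestration: simulate -> connectivity -> reactivity -> split
-> stability selection -> group statistics.

Stages are plain functions over in-memory objects; :func:`run_pipeline` wires
them together, enforces the subject-flow filters, and writes a reproducible
result bundle (CSV/JSON/markdown plus a manifest with per-file checksums).
A single master seed drives every stochastic component: the simulator and the
selection loop receive seeds derived deterministically from it via
``numpy.random.SeedSequence(master).generate_state``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (EXCLUSION_FLAGS, ClinicalRecord, SessionTimeSeries,
                     SimParams, generate_cohort, read_cohort)
from .connectivity import (ConnectivitySet, build_networks, connectivity_long,
                           mean_network_strength)
from .reactivity import (GroupAssignment, ReactivityTable,
                         build_reactivity_table, median_split,
                         tremor_responsiveness)
from .selection import SelectionConfig, SelectionResult, run_standard_selections
from . import stats as gstats

log = logging.getLogger("fcreact")

__all__ = [
    "ConfigError",
    "DataError",
    "NumericalError",
    "PipelineConfig",
    "ExclusionLog",
    "apply_subject_filters",
    "run_pipeline",
    "PipelineResult",
]

_FLOAT_FMT = "%.17g"


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 1)."""


class DataError(Exception):
    """Invalid or insufficient data (CLI exit code 2)."""


class NumericalError(Exception):
    """Numerical failure in a model fit (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    systems: tuple = ("da", "ach", "combined")
    include_controls: bool = True
    write_time_series: bool = False
    input_dir: str | None = None
    out_dir: str = "results"
    seed: int | None = None

    def __post_init__(self) -> None:
        bad = set(self.systems) - {"da", "ach", "combined"}
        if bad:
            raise ConfigError(f"unknown selection system(s): {sorted(bad)}")
        if self.seed is not None:
            state = np.random.SeedSequence(self.seed).generate_state(2)
            self.sim = dataclasses.replace(self.sim, seed=int(state[0] % 2**31))
            self.selection = dataclasses.replace(
                self.selection, seed=int(state[1] % 2**31))

    @classmethod
    def from_file(cls, path, seed: int | None = None,
                  out_dir: str | None = None) -> "PipelineConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except (OSError, yaml.YAMLError) as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        raw = raw or {}
        try:
            sim = SimParams(**raw.pop("sim", {}))
            sel = SelectionConfig(**raw.pop("selection", {}))
            if "systems" in raw:
                raw["systems"] = tuple(raw["systems"])
            cfg = cls(sim=sim, selection=sel, **raw)
        except (TypeError, ValueError) as err:
            raise ConfigError(f"invalid config: {err}") from err
        if seed is not None:
            cfg = dataclasses.replace(cfg, seed=seed)
        if out_dir is not None:
            cfg.out_dir = out_dir
        return cfg


@dataclass
class ExclusionLog:
    """Ordered record of the subject-flow filters and their arithmetic."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, n_before: int, removed: list[str]) -> None:
        self.steps.append({
            "filter": name,
            "n_before": n_before,
            "n_removed": len(removed),
            "n_after": n_before - len(removed),
            "removed": removed,
        })

    def validate(self) -> None:
        for prev, step in zip(self.steps, self.steps[1:]):
            if step["n_before"] != prev["n_after"]:
                raise ValueError("exclusion chain is inconsistent")
        for step in self.steps:
            if step["n_after"] != step["n_before"] - step["n_removed"]:
                raise ValueError("exclusion arithmetic is inconsistent")


def apply_subject_filters(records: list[ClinicalRecord]
                          ) -> tuple[list[ClinicalRecord], ExclusionLog]:
    """Apply the recruitment filters in order; controls pass through untouched.

    Order: lacunar infarction -> baseline ON status -> no baseline tremor
    (flag or tremor_off == 0) -> no MRI -> high head motion.
    """
    patients = [r for r in records if r.cohort == "patient"]
    controls = [r for r in records if r.cohort != "patient"]
    logbook = ExclusionLog()
    current = patients
    for flag in EXCLUSION_FLAGS:
        def hit(r, flag=flag):
            if flag == "no_tremor":
                return r.no_tremor or (r.tremor_off is not None and r.tremor_off == 0)
            return bool(getattr(r, flag))
        removed = [r.subject_id for r in current if hit(r)]
        kept = [r for r in current if not hit(r)]
        logbook.add(flag, len(current), removed)
        current = kept
    logbook.validate()
    if len(current) < 4:
        raise DataError(
            f"only {len(current)} analyzable subjects remain after exclusions")
    return current + controls, logbook


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def compute_connectivity(series: list[SessionTimeSeries],
                         subject_ids: set[str]) -> list[ConnectivitySet]:
    sets = []
    for ts in series:
        if ts.subject_id in subject_ids:
            sets.append(build_networks(ts))
    if not sets:
        raise DataError("no time series for the retained subjects")
    return sets


def responsiveness_and_split(patients: list[ClinicalRecord]
                             ) -> tuple[dict[str, float], GroupAssignment]:
    resp = {}
    for r in patients:
        if r.tremor_off is None or r.tremor_off <= 0:
            raise DataError(f"{r.subject_id}: no baseline tremor score")
        resp[r.subject_id] = tremor_responsiveness(r.tremor_off, r.tremor_on)
    return resp, median_split(resp)


def _covariate_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "age": [r.age for r in records],
        "gender": [1.0 if r.gender == "M" else 0.0 for r in records],
        "education": [float(r.education) for r in records],
    })


def _edge_values(sets: list[ConnectivitySet], edge, session: str,
                 subject_ids: list[str]) -> np.ndarray:
    by_subj = {cs.subject_id: cs for cs in sets if cs.session == session}
    pos = None
    vals = []
    for sid in subject_ids:
        cs = by_subj[sid]
        if pos is None:
            pos = cs.edge_index.index(edge)
        vals.append(cs.flatten()[pos])
    return np.asarray(vals)


def compute_statistics(patients: list[ClinicalRecord],
                       controls: list[ClinicalRecord],
                       conn: list[ConnectivitySet],
                       reactivity: ReactivityTable,
                       groups: GroupAssignment,
                       selections: dict[str, SelectionResult],
                       responsiveness: dict[str, float]) -> dict:
    """All downstream group statistics for a result bundle."""
    pat_ids = [r.subject_id for r in patients]
    grp = np.array([groups.assignments[s] for s in pat_ids])
    cov_pat = _covariate_frame(patients)
    report: dict[str, dict] = {"demographics": {}, "selected_edges": {},
                               "network_summary": {}}

    # Table-1-style demographics between patient groups
    demo_vars = {
        "age": ([r.age for r in patients], "continuous"),
        "gender": ([r.gender for r in patients], "categorical"),
        "education": ([r.education for r in patients], "continuous"),
        "disease_duration": ([r.disease_duration for r in patients], "continuous"),
        "led": ([r.led for r in patients], "continuous"),
        "updrs3_off": ([r.updrs3_off for r in patients], "continuous"),
        "updrs3_on": ([r.updrs3_on for r in patients], "continuous"),
        "tremor_change_rate": ([responsiveness[s] for s in pat_ids], "continuous"),
    }
    for name, (vals, kind) in demo_vars.items():
        try:
            res = gstats.demographic_comparison(vals, grp, kind, name=name)
            report["demographics"][name] = res.to_dict()
        except ValueError as err:
            report["demographics"][name] = {"error": str(err)}

    # Selected edges: union over the canonical runs
    selected_edges = []
    for res in selections.values():
        for j in np.flatnonzero(res.selected):
            e = res.edge_index[j]
            if e not in selected_edges:
                selected_edges.append(e)
    m = max(len(selected_edges), 1)
    thr = gstats.bonferroni_threshold(gstats.ALPHA, m)
    report["bonferroni"] = {"alpha": gstats.ALPHA, "m": m, "threshold": thr}

    resp_vec = np.array([responsiveness[s] for s in pat_ids])
    for edge in selected_edges:
        key = f"{edge.system}:{edge.subcortical}-{edge.cortical}"
        rx = reactivity.edge_column(edge)
        z_off = _edge_values(conn, edge, "OFF", pat_ids)
        z_on = _edge_values(conn, edge, "ON", pat_ids)
        entry = {
            "reactivity_group_glm": gstats.adjusted_group_comparison(
                rx, grp, cov_pat, threshold=thr,
                name=f"reactivity_glm[{key}]").to_dict(),
            "fc_off_group_glm": gstats.adjusted_group_comparison(
                z_off, grp, cov_pat, name=f"fc_off_glm[{key}]").to_dict(),
            "fc_on_group_glm": gstats.adjusted_group_comparison(
                z_on, grp, cov_pat, name=f"fc_on_glm[{key}]").to_dict(),
            "interaction": gstats.mixed_interaction(
                z_off, z_on, grp, cov_pat,
                name=f"interaction[{key}]").to_dict(),
        }
        for gname in ("resistant", "responsive"):
            mask = grp == gname
            entry[f"paired_off_on_{gname}"] = gstats.paired_comparison(
                z_off[mask], z_on[mask],
                name=f"paired[{key}|{gname}]").to_dict()
        r, p = gstats.partial_correlation(rx, resp_vec, cov_pat)
        entry["partial_correlation_with_responsiveness"] = {
            "r": r, "p": p, "covariates": ["age", "gender", "education"]}
        if controls:
            con_ids = [r_.subject_id for r_ in controls]
            cov_con = _covariate_frame(controls)
            z_nc = _edge_values(conn, edge, "OFF", con_ids)
            for gname in ("resistant", "responsive"):
                mask = grp == gname
                for session, zvals in (("OFF", z_off), ("ON", z_on)):
                    res = gstats.selected_edge_vs_controls(
                        zvals[mask], z_nc, cov_pat[mask.tolist()].reset_index(drop=True),
                        cov_con, m=2, name=f"nc[{key}|{gname}|{session}]")
                    entry[f"vs_nc_{gname}_{session}"] = res.to_dict()
        report["selected_edges"][key] = entry

    # Network-level summaries versus controls
    def _means_frame(ids: list[str]) -> pd.DataFrame:
        rows = []
        for cs in conn:
            if cs.subject_id in ids:
                rows.append((cs.subject_id, cs.session,
                             mean_network_strength(cs, "da"),
                             mean_network_strength(cs, "ach")))
        return pd.DataFrame(rows, columns=["subject_id", "session", "da", "ach"])

    if controls:
        con_ids = [r.subject_id for r in controls]
        net = gstats.network_summary_report(
            _means_frame(pat_ids), _means_frame(con_ids),
            cov_pat, _covariate_frame(controls))
        report["network_summary"] = {k: v.to_dict() for k, v in net.items()}
    return report


# ---------------------------------------------------------------------------
# The driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    records: list[ClinicalRecord]
    exclusion_log: ExclusionLog
    groups: GroupAssignment
    reactivity: ReactivityTable
    selections: dict[str, SelectionResult]
    stats_report: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the result bundle under ``config.out_dir``.

    Reruns with an identical configuration reproduce all outputs bitwise
    (no timestamps enter the bundle).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.input_dir is not None:
            records, series = read_cohort(config.input_dir)
        else:
            records, series = generate_cohort(config.sim)
        log.info("cohort: %d records, %d sessions", len(records), len(series))

        stage = "subject_filters"
        records, excl = apply_subject_filters(records)
        patients = [r for r in records if r.cohort == "patient"]
        controls = [r for r in records if r.cohort == "control"] \
            if config.include_controls else []

        stage = "connectivity"
        keep = {r.subject_id for r in patients} | {r.subject_id for r in controls}
        conn = compute_connectivity(series, keep)

        stage = "reactivity"
        pat_ids = {r.subject_id for r in patients}
        off = [c for c in conn if c.session == "OFF" and c.subject_id in pat_ids]
        on = [c for c in conn if c.session == "ON" and c.subject_id in pat_ids]
        reactivity = build_reactivity_table(off, on)
        responsiveness, groups = responsiveness_and_split(patients)

        stage = "selection"
        selections = run_standard_selections(reactivity, groups,
                                             config.selection, config.systems)
        for sys_tag, res in selections.items():
            log.info("selection[%s]: %d/%d edges >= %.0f%%", sys_tag,
                     int(res.selected.sum()), len(res.edge_index),
                     100 * config.selection.frequency_threshold)

        stage = "statistics"
        stats_report = compute_statistics(patients, controls, conn, reactivity,
                                          groups, selections, responsiveness)
    except (ConfigError, DataError, NumericalError):
        raise
    except np.linalg.LinAlgError as err:
        (out / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise NumericalError(f"stage {stage}: {err}") from err
    except ValueError as err:
        (out / "FAILED").write_text(f"stage {stage}: {err}\n")
        raise DataError(f"stage {stage}: {err}") from err

    # ---- outputs ----------------------------------------------------------
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        out / "participants.csv", index=False, float_format=_FLOAT_FMT)
    _write_json(out / "exclusion_log.json", excl.steps)
    connectivity_long(conn).to_csv(out / "connectivity.csv", index=False,
                                   float_format=_FLOAT_FMT)
    reactivity.to_long().to_csv(out / "reactivity.csv", index=False,
                                float_format=_FLOAT_FMT)
    pd.DataFrame({
        "subject_id": list(groups.assignments),
        "responsiveness": [responsiveness[s] for s in groups.assignments],
        "group": [groups.assignments[s] for s in groups.assignments],
        "cohort_median": groups.cohort_median,
    }).to_csv(out / "groups.csv", index=False, float_format=_FLOAT_FMT)
    for sys_tag, res in selections.items():
        res.to_frame().to_csv(out / f"selection_frequencies_{sys_tag}.csv",
                              index=False, float_format=_FLOAT_FMT)
        with open(out / f"selection_log_{sys_tag}.jsonl", "w") as fh:
            for rec in res.iterations:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    _write_json(out / "selection_config.json",
                dataclasses.asdict(config.selection))
    _write_json(out / "stats_report.json", stats_report)
    (out / "report.md").write_text(render_report(stats_report))
    if config.write_time_series and config.input_dir is None:
        from .cohort import write_cohort
        write_cohort(out / "cohort", records, series, config.sim)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "sim": dataclasses.asdict(config.sim),
            "selection": dataclasses.asdict(config.selection),
            "systems": list(config.systems),
            "include_controls": config.include_controls,
            "input_dir": config.input_dir,
        },
        "checksums": {p.name: _sha256(p) for p in sorted(out.iterdir())
                      if p.is_file() and p.name != "manifest.json"},
    }
    _write_json(out / "manifest.json", manifest)
    return PipelineResult(config, records, excl, groups, reactivity,
                          selections, stats_report, out)


def render_report(stats_report: dict) -> str:
    """Human-readable markdown mirror of the statistics report."""
    lines = ["# Analysis report", "", "## Demographic and clinical variables", "",
             "| variable | test | statistic | p | significant |",
             "|---|---|---|---|---|"]
    for name, res in stats_report.get("demographics", {}).items():
        if "error" in res:
            lines.append(f"| {name} | - | - | - | {res['error']} |")
            continue
        lines.append(f"| {name} | {res['branch']} | {res['statistic']:.3f} "
                     f"| {res['p']:.3g} | {'*' if res['significant'] else ''} |")
    bf = stats_report.get("bonferroni", {})
    lines += ["", f"Selected-edge threshold: alpha {bf.get('alpha')} / "
                  f"m {bf.get('m')} = {bf.get('threshold')}", ""]
    for key, entry in stats_report.get("selected_edges", {}).items():
        lines += [f"## Edge {key}", "",
                  "| comparison | branch | statistic | p | significant |",
                  "|---|---|---|---|---|"]
        for cname, res in entry.items():
            if cname == "partial_correlation_with_responsiveness":
                lines.append(f"| partial correlation with responsiveness | pearson-on-residuals "
                             f"| r={res['r']:.3f} | {res['p']:.3g} | |")
                continue
            lines.append(f"| {cname} | {res.get('branch')} | {res['statistic']:.3f} "
                         f"| {res['p']:.3g} | {'*' if res['significant'] else ''} |")
        lines.append("")
    if stats_report.get("network_summary"):
        lines += ["## Network summaries versus controls", "",
                  "| comparison | statistic | p | significant |", "|---|---|---|---|"]
        for key, res in stats_report["network_summary"].items():
            lines.append(f"| {key} | {res['statistic']:.3f} | {res['p']:.3g} "
                         f"| {'*' if res['significant'] else ''} |")
        lines.append("")
    return "\n".join(lines)
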