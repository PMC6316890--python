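"""Ligament-deficiency study: scenarios, statistics, comparison tables.

Runs the four ligament conditions (intact, isolated MCL anterior-bundle
deficiency, isolated MCL posterior-bundle deficiency, complete MCL
deficiency) through the identical passive-flexion drive, samples the
clinical degrees of freedom every 2 degrees of flexion over the 50-130
degree window (40 samples per condition), and compares each deficient
condition against the intact elbow: per-DOF mean difference +- SD,
one-way ANOVA over ligament state, and Tukey-Kramer pairwise tests at
alpha = 0.01.

A statistical caveat carried over faithfully from the source protocol:
the 40 flexion-grid points of one simulation are serially correlated, not
independent replicates, so the p-values describe the sampled curves, not
a population of specimens.
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
from scipy import stats as sps

from .contact import ContactParameters
from .geometry import ElbowGeometry, GeometryConfig, generate_elbow
from .kinematics import (
    DOF_NAMES,
    JCSSample,
    decompose_jcs,
    difference_vs_intact,
    frame_from_landmarks,
    resample_by_flexion,
)
from .ligament import (
    SCENARIOS,
    LigamentBundle,
    build_bundles,
    section_bundles,
    wrap_route,
)
from .simulate import (
    ExternalLoad,
    MotionDrive,
    SimulationConfig,
    SimulationTrace,
    assemble_system,
    reference_poses,
    run_flexion_sim,
)

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioResult",
    "StatResult",
    "run_study",
    "one_way_anova",
    "tukey_kramer",
    "build_report",
    "reference_bundle_lengths",
    "FLEXION_WINDOW",
]

#: flexion sampling window (start, stop, step) in degrees; half-open grid
FLEXION_WINDOW = (50.0, 130.0, 2.0)

COMPLEXES = ("LUCL", "RCL", "MCL_AB", "MCL_PB", "annular")


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """One ligament condition: kinematic samples, contact and load summaries."""

    scenario: str
    grid: np.ndarray                                  # flexion grid, deg
    jcs: dict[str, list[JCSSample]]                   # body -> 40 samples
    peak_pressure: dict[str, float]                   # region -> MPa
    contact_area: dict[str, np.ndarray]               # region -> mm^2 on grid
    contact_fraction: dict[str, np.ndarray]           # region -> loaded fraction on grid
    peak_load: dict[str, float]                       # complex -> N (NaN if sectioned)
    max_strain: dict[str, float]                      # complex -> strain (NaN if sectioned)
    dislocation_candidate: bool
    medial_contact_fraction: np.ndarray = field(default_factory=lambda: np.zeros(0))
    #: extreme ulna excursions over the closed flexion window, finely
    #: sampled (the 2-degree statistics grid is half-open and can clip a
    #: peak that falls between 128 and 130 degrees)
    peak_internal_rotation: float = float("nan")     # deg
    peak_lateral_translation: float = float("nan")   # mm
    #: per-element pressure snapshots for map rendering:
    #: flexion angle -> DataFrame (region, u, v, area, delta, pressure)
    pressure_maps: dict = field(default_factory=dict)

    def jcs_matrix(self, body: str) -> np.ndarray:
        return np.stack([s.as_array() for s in self.jcs[body]])


@dataclass
class StatResult:
    """Per-DOF omnibus and pairwise statistics for one body."""

    body: str
    dof: str
    F: float
    p: float
    pairwise_p: dict[str, float]          # deficient scenario -> p vs intact


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def one_way_anova(groups) -> tuple[float, float]:
    """Classic one-way ANOVA from the between/within decomposition.

    Returns ``(F, p)``.  With zero variance everywhere and equal means the
    convention ``F = 0, p = 1`` applies; zero within-group variance with
    unequal means gives ``p = 0``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two groups with at least two samples each")
    n = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = float(np.concatenate(groups).mean())
    ssb = float(np.sum(n * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    dfb = len(groups) - 1
    dfw = int(n.sum()) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return F, p


def tukey_kramer(groups) -> np.ndarray:
    """All-pairs Tukey-Kramer p-value matrix.

    The studentized-range statistic for pair (i, j) uses the Kramer
    unequal-sample-size correction,

        q_ij = |m_i - m_j| / sqrt(MSW / 2 * (1/n_i + 1/n_j)),

    with p from the studentized range distribution on (k, dfw).  Equal
    sample sizes reduce it to the standard Tukey HSD.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    n = np.array([len(g) for g in groups])
    if np.any(n < 2):
        raise ValueError("each group needs at least two samples")
    means = np.array([g.mean() for g in groups])
    dfw = int(n.sum()) - k
    msw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means))) / dfw

    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            if msw == 0.0:
                pij = 1.0 if diff == 0.0 else 0.0
            else:
                q = diff / np.sqrt(msw / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
                pij = float(sps.studentized_range.sf(q, k, dfw))
            p[i, j] = p[j, i] = min(max(pij, 0.0), 1.0)
    return p


# --------------------------------------------------------------------------
# scenario execution
# --------------------------------------------------------------------------

def reference_bundle_lengths(geometry: ElbowGeometry) -> dict[str, float]:
    """Bundle path lengths (wrapping included) at the nested reference pose."""
    refs = reference_poses(geometry)
    lengths = {}
    for name, att in geometry.attachments.items():
        pa, Ra = refs[att.origin_body]
        pb, Rb = refs[att.insertion_body]
        a_w = pa + Ra @ att.origin
        b_w = pb + Rb @ att.insertion
        if att.wraps:
            prim = att.wraps[0]
            pw, Rw = refs[prim.body]
            a_l = Rw.T @ (a_w - pw)
            b_l = Rw.T @ (b_w - pw)
            lengths[name], _, _, _ = wrap_route(a_l, b_l, att.wraps)
        else:
            lengths[name] = float(np.linalg.norm(b_w - a_w))
    return lengths


def _trace_jcs(trace: SimulationTrace, geometry: ElbowGeometry) -> dict[str, list[JCSSample]]:
    """Per-step clinical DOF samples for ulna and radius vs the humerus.

    Both series are indexed by the elbow (ulna) flexion angle, which is
    the grid coordinate of the study.
    """
    out: dict[str, list[JCSSample]] = {"ulna": [], "radius": []}
    n = trace.n_samples()
    for i in range(n):
        frames = {}
        for body in ("humerus", "ulna", "radius"):
            p = trace.positions[body][i]
            R = trace.rotations[body][i]
            world = {k: p + R @ v for k, v in geometry.landmarks[body].items()}
            frames[body] = frame_from_landmarks(body, world)
        su = decompose_jcs(frames["humerus"], frames["ulna"])
        sr = decompose_jcs(frames["humerus"], frames["radius"])
        sr.flexion = su.flexion   # grid coordinate = elbow flexion
        out["ulna"].append(su)
        out["radius"].append(sr)
    return out


def summarize_trace(trace: SimulationTrace, geometry: ElbowGeometry,
                    scenario: str,
                    window=FLEXION_WINDOW) -> ScenarioResult:
    """Reduce a raw trace to the study quantities on the flexion grid."""
    start, stop, step = window
    jcs_raw = _trace_jcs(trace, geometry)
    jcs = {body: resample_by_flexion(samples, start, stop, step)
           for body, samples in jcs_raw.items()}
    grid = np.array([s.flexion for s in jcs["ulna"]])

    # window extremes on a fine closed grid
    fine = resample_by_flexion(jcs_raw["ulna"], start, stop + 0.25, 0.25)
    fine_mat = np.stack([s.as_array() for s in fine])
    peak_ir = float(np.max(fine_mat[:, DOF_NAMES.index("I-E")]))
    peak_lat = float(np.max(-fine_mat[:, DOF_NAMES.index("M-L")]))

    in_window = (trace.flexion >= start) & (trace.flexion <= stop)
    if not np.any(in_window):
        raise ValueError("trace never enters the flexion window")

    peak_pressure = {}
    contact_area = {}
    contact_fraction = {}
    for region, delta in trace.contact_delta.items():
        areas = trace.element_area[region]
        force = trace.contact_force[region]
        pressure = force / areas[None, :]
        peak_pressure[region] = float(pressure[in_window].max()) if in_window.any() else 0.0
        loaded = delta > 0.0
        area_series = (loaded * areas[None, :]).sum(axis=1)
        frac_series = loaded.mean(axis=1)
        contact_area[region] = np.interp(grid, trace.flexion[in_window],
                                         area_series[in_window])
        contact_fraction[region] = np.interp(grid, trace.flexion[in_window],
                                             frac_series[in_window])

    # medial-compartment engagement: trochlear elements with centre x < 0
    medial_ids = np.array([e.center[0] < 0.0 for e in geometry.elements_in("trochlea")])
    delta_t = trace.contact_delta["trochlea"]
    med_frac = (delta_t[:, medial_ids] > 0.0).mean(axis=1)
    medial_contact_fraction = np.interp(grid, trace.flexion[in_window],
                                        med_frac[in_window])

    # pressure-map snapshots at representative flexion angles
    pressure_maps = {}
    for angle in (60.0, 90.0, 120.0):
        if not (trace.flexion.min() <= angle <= trace.flexion.max()):
            continue
        i = int(np.argmin(np.abs(trace.flexion - angle)))
        rows = []
        for region in trace.contact_delta:
            uv = trace.element_uv[region]
            areas = trace.element_area[region]
            for j in range(uv.shape[0]):
                rows.append({
                    "region": region,
                    "u": float(uv[j, 0]), "v": float(uv[j, 1]),
                    "area": float(areas[j]),
                    "delta": float(trace.contact_delta[region][i, j]),
                    "pressure": float(trace.contact_force[region][i, j] / areas[j]),
                })
        pressure_maps[angle] = pd.DataFrame(rows)

    sectioned = SCENARIOS[scenario]
    peak_load: dict[str, float] = {}
    max_strain: dict[str, float] = {}
    bundle_complex = {name: att.complex for name, att in geometry.attachments.items()}
    for cx in COMPLEXES:
        if cx in sectioned:
            peak_load[cx] = float("nan")
            max_strain[cx] = float("nan")
            continue
        names = [n for n, c in bundle_complex.items() if c == cx]
        total = np.sum([trace.ligament[n]["force"] for n in names], axis=0)
        strain = np.max([trace.ligament[n]["eps"] for n in names], axis=0)
        peak_load[cx] = float(total[in_window].max())
        max_strain[cx] = float(strain[in_window].max())

    return ScenarioResult(
        scenario=scenario,
        grid=grid,
        jcs=jcs,
        peak_pressure=peak_pressure,
        contact_area=contact_area,
        contact_fraction=contact_fraction,
        peak_load=peak_load,
        max_strain=max_strain,
        dislocation_candidate=trace.dislocation_candidate,
        medial_contact_fraction=medial_contact_fraction,
        peak_internal_rotation=peak_ir,
        peak_lateral_translation=peak_lat,
        pressure_maps=pressure_maps,
    )


def _study_key(geometry_cfg: GeometryConfig, drive: MotionDrive,
               sim: SimulationConfig, loads: ExternalLoad,
               stiffness, pretension) -> str:
    blob = json.dumps(
        {
            "geometry": dataclasses.asdict(geometry_cfg),
            "drive": dataclasses.asdict(drive),
            "sim": dataclasses.asdict(sim),
            "loads": dataclasses.asdict(loads),
            "stiffness": stiffness,
            "pretension": pretension,
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _save_result(result: ScenarioResult, path: Path):
    arrays = {
        "grid": result.grid,
        "medial_contact_fraction": result.medial_contact_fraction,
    }
    for body in result.jcs:
        arrays[f"jcs_{body}"] = result.jcs_matrix(body)
    for region in result.contact_area:
        arrays[f"area_{region}"] = result.contact_area[region]
        arrays[f"frac_{region}"] = result.contact_fraction[region]
    for angle, df in result.pressure_maps.items():
        arrays[f"pmap_{angle:g}"] = df[["u", "v", "area", "delta", "pressure"]].to_numpy()
        arrays[f"pmapregion_{angle:g}"] = np.array(
            [r == "trochlea" for r in df["region"]], dtype=bool)
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {
        "scenario": result.scenario,
        "peak_pressure": result.peak_pressure,
        "peak_load": result.peak_load,
        "max_strain": result.max_strain,
        "dislocation_candidate": result.dislocation_candidate,
        "peak_internal_rotation": result.peak_internal_rotation,
        "peak_lateral_translation": result.peak_lateral_translation,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def _load_result(path: Path) -> ScenarioResult:
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        grid = data["grid"]
        jcs = {}
        for body in ("ulna", "radius"):
            mat = data[f"jcs_{body}"]
            jcs[body] = [JCSSample(body, *row) for row in mat]
        regions = sorted({k[5:] for k in data.files if k.startswith("area_")})
        contact_area = {r: data[f"area_{r}"] for r in regions}
        contact_fraction = {r: data[f"frac_{r}"] for r in regions}
        med = data["medial_contact_fraction"]
        pressure_maps = {}
        for key in data.files:
            if key.startswith("pmap_"):
                angle = float(key[5:])
                mat = data[key]
                is_troch = data[f"pmapregion_{angle:g}"]
                df = pd.DataFrame(mat, columns=["u", "v", "area", "delta", "pressure"])
                df.insert(0, "region",
                          np.where(is_troch, "trochlea", "capitellum"))
                pressure_maps[angle] = df
    return ScenarioResult(
        scenario=meta["scenario"],
        grid=grid,
        jcs=jcs,
        peak_pressure=meta["peak_pressure"],
        contact_area=contact_area,
        contact_fraction=contact_fraction,
        peak_load={k: (float("nan") if v is None else v) for k, v in meta["peak_load"].items()},
        max_strain={k: (float("nan") if v is None else v) for k, v in meta["max_strain"].items()},
        dislocation_candidate=meta["dislocation_candidate"],
        medial_contact_fraction=med,
        peak_internal_rotation=meta.get("peak_internal_rotation", float("nan")),
        peak_lateral_translation=meta.get("peak_lateral_translation", float("nan")),
        pressure_maps=pressure_maps,
    )


def run_study(
    geometry: ElbowGeometry | GeometryConfig,
    scenarios=("intact", "MCL_AB_deficient", "MCL_PB_deficient", "both_MCL_deficient"),
    drive: MotionDrive | None = None,
    sim: SimulationConfig | None = None,
    loads: ExternalLoad | None = None,
    stiffness: dict[str, float] | None = None,
    pretension: dict[str, float] | None = None,
    contact_uh: ContactParameters | None = None,
    contact_rh: ContactParameters | None = None,
    out_dir: str | Path | None = None,
    reuse_cache: bool = True,
) -> dict[str, ScenarioResult]:
    """Run the ligament conditions under one identical drive.

    The intact condition always runs first; every deficiency uses the same
    geometry, drive, loads and solver settings.  With ``out_dir`` set,
    results are cached per scenario keyed by the full configuration, and
    re-running the same study reuses the cache.  If a scenario fails, the
    completed ones stay persisted and the error names the failures.
    """
    if isinstance(geometry, GeometryConfig):
        geometry = generate_elbow(geometry)
    drive = MotionDrive() if drive is None else drive
    sim = SimulationConfig() if sim is None else sim
    loads = ExternalLoad() if loads is None else loads

    for s in scenarios:
        if s not in SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}; valid: {sorted(SCENARIOS)}")
    ordered = ["intact"] + [s for s in scenarios if s != "intact"] \
        if "intact" in scenarios else list(scenarios)

    ref_lengths = reference_bundle_lengths(geometry)
    base_bundles = build_bundles(geometry.attachments, ref_lengths,
                                 stiffness=stiffness, pretension=pretension)

    cache_dir = None
    if out_dir is not None:
        key = _study_key(geometry.config, drive, sim, loads,
                         stiffness or {}, pretension or {})
        cache_dir = Path(out_dir) / f"study_{key}"
        cache_dir.mkdir(parents=True, exist_ok=True)

    results: dict[str, ScenarioResult] = {}
    failures: dict[str, str] = {}
    for scenario in ordered:
        if cache_dir is not None and reuse_cache:
            stem = cache_dir / scenario
            if stem.with_suffix(".npz").exists() and stem.with_suffix(".json").exists():
                results[scenario] = _load_result(stem)
                log.info("reused cached result for %s", scenario)
                continue
        try:
            bundles = section_bundles(base_bundles, scenario)
            model = assemble_system(geometry, bundles, loads=loads,
                                    contact_uh=contact_uh, contact_rh=contact_rh)
            trace = run_flexion_sim(model, geometry, drive=drive, config=sim)
            results[scenario] = summarize_trace(trace, geometry, scenario)
            if cache_dir is not None:
                _save_result(results[scenario], cache_dir / scenario)
        except Exception as exc:  # noqa: BLE001 - partial results must survive
            failures[scenario] = str(exc)
            log.exception("scenario %s failed", scenario)
    if failures:
        done = ", ".join(results) or "none"
        raise RuntimeError(
            f"scenarios failed: {failures}; completed and persisted: {done}"
        )
    return results


# --------------------------------------------------------------------------
# statistics over a study & report building
# --------------------------------------------------------------------------

STAT_DOFS = ("I-E", "VR-VL", "S-I", "A-P", "M-L")


def study_statistics(results: dict[str, ScenarioResult]) -> list[StatResult]:
    """Per-body, per-DOF ANOVA over ligament state plus pairwise vs intact."""
    if "intact" not in results:
        raise ValueError("statistics require the intact baseline")
    order = list(results)
    intact_idx = order.index("intact")
    out: list[StatResult] = []
    for body in ("ulna", "radius"):
        for dof in STAT_DOFS:
            j = DOF_NAMES.index(dof)
            groups = [results[s].jcs_matrix(body)[:, j] for s in order]
            F, p = one_way_anova(groups)
            pmat = tukey_kramer(groups)
            pairwise = {
                s: float(pmat[intact_idx, i])
                for i, s in enumerate(order) if s != "intact"
            }
            out.append(StatResult(body=body, dof=dof, F=F, p=p, pairwise_p=pairwise))
    return out


def kinematic_difference_table(results: dict[str, ScenarioResult],
                               stats: list[StatResult] | None = None) -> pd.DataFrame:
    """Mean difference +- SD (and pairwise p) vs intact, Tables-1/2 layout."""
    if "intact" not in results:
        raise ValueError("difference table requires the intact baseline")
    stats = study_statistics(results) if stats is None else stats
    pmap = {(s.body, s.dof): s.pairwise_p for s in stats}
    rows = []
    for body in ("ulna", "radius"):
        for scenario, res in results.items():
            if scenario == "intact":
                continue
            _, summary = difference_vs_intact(res.jcs[body], results["intact"].jcs[body])
            row = {"body": body, "condition": scenario}
            for dof in STAT_DOFS:
                mean, sd = summary[dof]
                row[f"{dof} mean"] = mean
                row[f"{dof} sd"] = sd
                row[f"{dof} p"] = pmap[(body, dof)][scenario]
            rows.append(row)
    return pd.DataFrame(rows)


def ligament_peak_table(results: dict[str, ScenarioResult]) -> pd.DataFrame:
    """Peak intact-ligament loads and strains, Tables-3/4 layout.

    Sectioned complexes appear as missing values: they provide no
    constraint in that condition.
    """
    rows = []
    for cx in ("LUCL", "RCL", "MCL_AB", "MCL_PB"):
        row = {"ligament": cx}
        for scenario, res in results.items():
            row[f"{scenario} peak load (N)"] = res.peak_load.get(cx, float("nan"))
            row[f"{scenario} max strain"] = res.max_strain.get(cx, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def build_report(results: dict[str, ScenarioResult], out_dir: str | Path,
                 stats: list[StatResult] | None = None,
                 plots: bool = False) -> dict[str, str]:
    """Write the comparison tables, per-scenario curves and summaries.

    Deterministic: regenerating from the same results is byte-identical.
    CSV uses '.' decimals, ',' separators and a header row.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "intact" not in results:
        raise ValueError("report requires the intact baseline (differences are undefined)")
    stats = study_statistics(results) if stats is None else stats
    written: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        written[name] = str(path)

    save(kinematic_difference_table(results, stats), "kinematic_differences.csv")
    save(ligament_peak_table(results), "ligament_peaks.csv")

    curves = []
    for scenario, res in results.items():
        for body in ("ulna", "radius"):
            mat = res.jcs_matrix(body)
            for i, g in enumerate(res.grid):
                row = {"scenario": scenario, "body": body, "flexion": g}
                row.update({dof: mat[i, j] for j, dof in enumerate(DOF_NAMES)})
                curves.append(row)
    save(pd.DataFrame(curves), "kinematic_curves.csv")

    contact_rows = []
    for scenario, res in results.items():
        for i, g in enumerate(res.grid):
            contact_rows.append({
                "scenario": scenario, "flexion": g,
                "ulnohumeral_area": res.contact_area["trochlea"][i],
                "radiohumeral_area": res.contact_area["capitellum"][i],
                "medial_contact_fraction": res.medial_contact_fraction[i],
            })
    save(pd.DataFrame(contact_rows), "contact_series.csv")

    for scenario, res in results.items():
        for angle, df in res.pressure_maps.items():
            save(df, f"pressure_map_{scenario}_{angle:g}deg.csv")

    stat_rows = [
        {"body": s.body, "dof": s.dof, "F": s.F, "p": s.p,
         **{f"p vs intact ({k})": v for k, v in s.pairwise_p.items()}}
        for s in stats
    ]
    save(pd.DataFrame(stat_rows), "statistics.csv")

    summary = {
        scenario: {
            "peak_pressure_MPa": res.peak_pressure,
            "peak_load_N": {k: (None if np.isnan(v) else v)
                            for k, v in res.peak_load.items()},
            "max_strain": {k: (None if np.isnan(v) else v)
                           for k, v in res.max_strain.items()},
            "dislocation_candidate": res.dislocation_candidate,
        }
        for scenario, res in results.items()
    }
    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written["summary.json"] = str(path)

    if plots:
        written.update(_plot_curves(results, out))
    return written


def _plot_curves(results: dict[str, ScenarioResult], out: Path) -> dict[str, str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    for body in ("ulna", "radius"):
        fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
        for j, dof in enumerate(DOF_NAMES):
            ax = axes.flat[j]
            for scenario, res in results.items():
                ax.plot(res.grid, res.jcs_matrix(body)[:, j], label=scenario)
            ax.set_title(f"{body} {dof}")
            ax.set_xlabel("flexion (deg)")
        axes.flat[0].legend(fontsize=7)
        fig.tight_layout()
        name = f"kinematics_{body}.png"
        fig.savefig(out / name, dpi=110)
        plt.close(fig)
        written[name] = str(out / name)
    return written
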