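"""End-to-end runs: generate → register → isolate → measure → stats.

A run takes a cohort directory (as written by
:func:`rootmorph.synthetic_data.generate_cohort`, or any directory with
the same layout of per-tooth T0/T1 STL + landmark JSON files), processes
every tooth pair through registration, CEJ root isolation, volume /
length / deviation measurement, adds per-patient arch-expansion metrics,
and emits a measurement table, report tables, a ground-truth recovery
report when truth manifests are present, and a hash manifest. Identical
config + seed reproduces byte-identical outputs (timestamps live only in
the run log, never in hashed artifacts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expansion_metrics as em
from . import root_analysis as ra
from . import stats as st
from . import synthetic_data as syn
from .mesh_core import TriangleMesh, ValidationError, read_mesh
from .registration import IcpParams, apply_transform, icp_register, landmark_align

__all__ = ["RunConfig", "analyze_tooth_pair", "run_all", "make_report", "assemble_cohort_table"]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    input_dir: str = ""  # existing cohort; empty = generate synthetically
    output_dir: str = "run"
    seed: int = 0
    tolerance_mm: float = 0.3
    icp: IcpParams = field(default_factory=IcpParams)
    cohort: syn.CohortSpec | None = None
    length_mode: str = "vertex"  # apex re-detected on the mesh ("landmark" trusts it)
    export_colormaps: bool = False

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if d["cohort"] is not None:
            d["cohort"]["effects"] = _effects_to_plain(d["cohort"]["effects"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "icp" in d and isinstance(d["icp"], dict):
            d["icp"] = IcpParams(**d["icp"])
        if d.get("cohort") is not None:
            c = d["cohort"]
            for key in ("tooth_classes", "sides"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = syn.CohortSpec(**c)
        return cls(**d)


def _effects_to_plain(effects: dict):
    if isinstance(effects, dict):
        return {k: _effects_to_plain(v) for k, v in effects.items()}
    if isinstance(effects, tuple):
        return list(effects)
    return effects


def analyze_tooth_pair(
    t0: TriangleMesh,
    t1: TriangleMesh,
    lm0: ra.LandmarkSet,
    lm1: ra.LandmarkSet,
    tolerance: float = 0.3,
    icp_params: IcpParams | None = None,
    length_mode: str = "vertex",
    tooth_id: str = "",
) -> dict:
    """Full single-tooth measurement chain; T1 is moved into the T0 frame.

    Returns a flat dict: registration quality, per-root lengths at both
    timepoints, root volumes, deviation matching percentage, and the
    registered roots (for optional colour-map export).
    """
    init = landmark_align(lm1.registration_points(), lm0.registration_points())
    transform, report = icp_register(t1, t0, init=init, params=icp_params)
    t1_reg = apply_transform(t1, transform)

    template, plane = ra.build_radicular_template(t0, lm0)
    t0_root, t1_root = ra.cut_roots_synchronized(t0, t1_reg, plane)
    vol = ra.volume_change(t0_root, t1_root, tooth_id)
    field_ = ra.deviation_analysis(t0_root, t1_root, tolerance=tolerance)

    lengths = {}
    for root in lm0.roots:
        l0 = ra.root_length(lm0, t0, root, mode=length_mode)
        l1 = ra.root_length(lm0, t1_reg, root, mode=length_mode)
        lengths[root] = (l0, l1)

    return {
        "tooth_id": tooth_id,
        "icp_initial_rms": report.initial_rms,
        "icp_final_rms": report.final_rms,
        "icp_iterations": report.iterations,
        "icp_converged": report.converged,
        "transform": transform,
        "cej_plane": plane,
        "v_t0": vol.v_t0,
        "v_t1": vol.v_t1,
        "delta_v": vol.delta_v,
        "delta_v_pct": vol.delta_v_pct,
        "matching_pct": field_.matching_pct,
        "lengths": lengths,
        "deviation": field_,
        "t0_root": t0_root,
        "t1_root": t1_root,
    }


def _pair_files(cohort_dir: Path):
    """Yield (patient, stem, t0_stl, t1_stl, lm0, lm1) for every tooth pair."""
    for pdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        for t0_path in sorted(pdir.glob("*_T0.stl")):
            stem = t0_path.name[: -len("_T0.stl")]
            t1_path = pdir / f"{stem}_T1.stl"
            lm0_path = pdir / f"{stem}_T0.landmarks.json"
            lm1_path = pdir / f"{stem}_T1.landmarks.json"
            if not (t1_path.exists() and lm0_path.exists() and lm1_path.exists()):
                raise ValidationError(f"incomplete tooth pair for {pdir.name}/{stem}")
            yield pdir.name, stem, t0_path, t1_path, lm0_path, lm1_path


def assemble_cohort_table(cohort_dir, config: RunConfig, log=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process every tooth pair in a cohort directory.

    Returns (tooth_table, root_table): one row per tooth with volume /
    matching metrics and one row per root with length changes. Group and
    arch factors are parsed from the file layout; arch-width changes are
    joined per patient and level.
    """
    cohort_dir = Path(cohort_dir)
    tooth_rows, root_rows = [], []
    expansion: dict[str, dict] = {}
    for pdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        a0 = pdir / "arch_landmarks_T0.json"
        a1 = pdir / "arch_landmarks_T1.json"
        if a0.exists() and a1.exists():
            arch0 = em.ArchLandmarks.from_json(a0.read_text())
            arch1 = em.ArchLandmarks.from_json(a1.read_text())
            levels = [
                lev for lev in em.LEVELS
                if lev in arch0.points.get("PW", {}) and lev in arch1.points.get("PW", {})
            ]
            recs = em.expansion_change(arch0, arch1, levels=levels)
            expansion[pdir.name] = {r.level: r for r in recs}

    for patient, stem, t0p, t1p, lm0p, lm1p in _pair_files(cohort_dir):
        cls, side, arch = stem.split("_")
        t0 = read_mesh(t0p)
        t1 = read_mesh(t1p)
        lm0 = ra.LandmarkSet.from_json(Path(lm0p).read_text())
        lm1 = ra.LandmarkSet.from_json(Path(lm1p).read_text())
        tooth_id = f"{patient}/{stem}"
        try:
            res = analyze_tooth_pair(
                t0, t1, lm0, lm1,
                tolerance=config.tolerance_mm,
                icp_params=config.icp,
                length_mode=config.length_mode,
                tooth_id=tooth_id,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'analyze' failed for tooth {tooth_id}") from exc
        group = patient.rstrip("0123456789")
        exp = expansion.get(patient, {}).get(cls)
        tooth_rows.append(
            {
                "patient": patient,
                "group": group,
                "arch": arch,
                "tooth_class": cls,
                "side": side,
                "v_t0": res["v_t0"],
                "v_t1": res["v_t1"],
                "delta_v": res["delta_v"],
                "delta_v_pct": res["delta_v_pct"],
                "matching_pct": res["matching_pct"],
                "pwe": exp.pwe if exp else np.nan,
                "dae": exp.dae if exp else np.nan,
                "icp_final_rms": res["icp_final_rms"],
            }
        )
        for root, (l0, l1) in res["lengths"].items():
            root_rows.append(
                {
                    "patient": patient,
                    "group": group,
                    "arch": arch,
                    "tooth_class": cls,
                    "side": side,
                    "root": root,
                    "length_t0": l0,
                    "length_t1": l1,
                    "delta_length": l0 - l1,
                }
            )
        if log is not None:
            plane = res["cej_plane"]
            log.append(
                f"{tooth_id}: icp_rms={res['icp_final_rms']:.5f} "
                f"iters={res['icp_iterations']} "
                f"cej_plane point={np.round(plane.point, 3).tolist()} "
                f"normal={np.round(plane.normal, 4).tolist()}"
            )
        if config.export_colormaps:
            from .mesh_core import write_mesh

            out = Path(config.output_dir) / "colormaps"
            out.mkdir(parents=True, exist_ok=True)
            write_mesh(
                res["t0_root"],
                out / f"{patient}_{stem}_deviation.ply",
                fmt="ply",
                scalars=res["deviation"].distances,
                tolerance=config.tolerance_mm,
            )
    return pd.DataFrame(tooth_rows), pd.DataFrame(root_rows)


# ---------------------------------------------------------------------------
# reports

def _fmt_mean_sd(series: pd.Series) -> str:
    return f"{series.mean():.2f} ({series.std(ddof=1):.2f})"


def make_report(
    tooth_table: pd.DataFrame,
    root_table: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables of the cohort analysis.

    Produces descriptive+inferential tables per quantity: demographics,
    volumetric change (mm^3 and %), length change per root, matching
    percentage, expansion (PWE/DAE), and the per-class regression of
    volume loss on expander type and expansion. Values are recomputed
    from the measurement table with the stats layer, never transcribed.
    """
    tables: dict[str, pd.DataFrame] = {}
    groups = sorted(tooth_table["group"].unique())

    if demographics is not None and len(demographics):
        rows = []
        counts = demographics.groupby(["group", "gender"]).size().unstack(fill_value=0)
        gender_p = np.nan
        if set(counts.index) == set(groups) and counts.shape == (2, 2):
            gender_p = st.chi_square_counts(counts.to_numpy())["p"]
        age_p = st.two_sample_t(demographics, "age", "group")["p"] if len(groups) == 2 else np.nan
        for g in groups:
            sub = demographics[demographics["group"] == g]
            rows.append(
                {
                    "group": g,
                    "n": len(sub),
                    "male/female": f"{(sub['gender']=='M').sum()}/{(sub['gender']=='F').sum()}",
                    "age_mean_sd": _fmt_mean_sd(sub["age"]),
                    "gender_chi2_p": gender_p,
                    "age_t_p": age_p,
                }
            )
        tables["demographics"] = pd.DataFrame(rows)

    def change_table(df: pd.DataFrame, var: str, by: str) -> pd.DataFrame:
        rows = []
        for arch in sorted(df["arch"].unique()):
            for level in sorted(df[df["arch"] == arch][by].unique()):
                sub = df[(df["arch"] == arch) & (df[by] == level)]
                row = {"arch": arch, by: level}
                for g in groups:
                    s = sub[sub["group"] == g][var]
                    row[f"{g}_n"] = len(s)
                    row[f"{g}_mean"] = s.mean()
                    row[f"{g}_sd"] = s.std(ddof=1)
                if len(groups) == 2 and all((sub["group"] == g).sum() >= 2 for g in groups):
                    row["between_groups_p"] = st.two_sample_t(sub, var, "group")["p"]
                rows.append(row)
            # intra-group ANOVA across levels, per arch
            for g in groups:
                sub = df[(df["arch"] == arch) & (df["group"] == g)]
                if sub[by].nunique() >= 2 and sub.groupby(by).size().min() >= 2:
                    res = st.anova_bonferroni(sub, var, by)
                    for row in rows:
                        if row["arch"] == arch:
                            row[f"{g}_anova_p"] = res["p"]
        return pd.DataFrame(rows)

    tables["volume_change_mm3"] = change_table(tooth_table, "delta_v", "tooth_class")
    tables["volume_change_pct"] = change_table(tooth_table, "delta_v_pct", "tooth_class")
    tables["length_change_mm"] = change_table(root_table, "delta_length", "root")
    upper = tooth_table[tooth_table["arch"] == "upper"]
    if len(upper):
        tables["matching_pct"] = change_table(upper, "matching_pct", "tooth_class")

    if upper["pwe"].notna().any():
        rows = []
        per_patient = (
            upper.dropna(subset=["pwe", "dae"])
            .groupby(["patient", "group", "tooth_class"], as_index=False)[["pwe", "dae"]]
            .first()
        )
        for level in sorted(per_patient["tooth_class"].unique()):
            sub = per_patient[per_patient["tooth_class"] == level]
            for kind in ("pwe", "dae"):
                row = {"level": level, "kind": kind.upper()}
                for g in groups:
                    s = sub[sub["group"] == g][kind]
                    row[f"{g}_n"] = len(s)
                    row[f"{g}_mean"] = s.mean()
                    row[f"{g}_sd"] = s.std(ddof=1)
                if len(groups) == 2 and all((sub["group"] == g).sum() >= 2 for g in groups):
                    row["between_groups_p"] = st.two_sample_t(sub, kind, "group")["p"]
                rows.append(row)
        tables["expansion"] = pd.DataFrame(rows)

    # regression per tooth class: volume loss ~ expander + PWE + DAE
    reg_rows = []
    if len(groups) == 2 and upper["pwe"].notna().any():
        coded = upper.dropna(subset=["pwe", "dae"]).copy()
        coded["expander"] = (coded["group"] == groups[1]).astype(float)
        for cls in sorted(coded["tooth_class"].unique()):
            sub = coded[coded["tooth_class"] == cls]
            if len(sub) < 6:
                continue
            try:
                rr = st.err_regression(sub, "delta_v", ["expander", "pwe", "dae"])
            except ValidationError:
                continue
            for _, c in rr.coef.iterrows():
                reg_rows.append({"tooth_class": cls, "r_squared": rr.r_squared, **c})
    if reg_rows:
        tables["regression"] = pd.DataFrame(reg_rows)
    return tables


# ---------------------------------------------------------------------------
# run orchestration

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write reports + hash manifest.

    With no ``input_dir``, a synthetic cohort is generated first (into
    ``output_dir/cohort``) and ground truth joined into a recovery
    report. Returns the manifest dict (also written as
    ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    stages: dict[str, str] = {}

    if config.input_dir:
        cohort_dir = Path(config.input_dir)
        stages["generate"] = "skipped (existing input)"
    else:
        cohort = config.cohort or syn.CohortSpec(seed=config.seed)
        cohort_dir = out / "cohort"
        syn.generate_cohort(cohort, cohort_dir)
        stages["generate"] = "ok"
        log.append(f"generated cohort at {cohort_dir}")

    tooth_table, root_table = assemble_cohort_table(cohort_dir, config, log=log)
    stages["analyze"] = "ok"
    report_dir = out / "reports"
    report_dir.mkdir(exist_ok=True)
    tooth_table.to_csv(out / "tooth_measurements.csv", index=False, float_format="%.6f")
    root_table.to_csv(out / "root_measurements.csv", index=False, float_format="%.6f")

    demo_path = cohort_dir / "demographics.csv"
    demographics = pd.read_csv(demo_path) if demo_path.exists() else None
    tables = make_report(tooth_table, root_table, demographics)
    for name, df in tables.items():
        df.to_csv(report_dir / f"{name}.csv", index=False, float_format="%.6f")
    stages["report"] = "ok"

    # ground-truth recovery when the cohort carries a manifest
    truth_path = cohort_dir / "manifest.csv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        joined = tooth_table.merge(
            truth,
            on=["patient", "group", "arch", "tooth_class", "side"],
            how="inner",
        )
        joined["abs_err_delta_v"] = (joined["delta_v"] - joined["true_delta_v_mm3"]).abs()
        joined["abs_err_delta_v_pct"] = (
            joined["delta_v_pct"] - joined["true_delta_v_pct"]
        ).abs()
        recovery = joined[
            [
                "patient", "group", "arch", "tooth_class", "side",
                "delta_v", "true_delta_v_mm3", "abs_err_delta_v",
                "delta_v_pct", "true_delta_v_pct", "abs_err_delta_v_pct",
            ]
        ]
        recovery.to_csv(out / "recovery_volume.csv", index=False, float_format="%.6f")
        lt_path = cohort_dir / "length_truth.csv"
        if lt_path.exists():
            lt = pd.read_csv(lt_path)
            jl = root_table.merge(
                lt, on=["patient", "group", "arch", "tooth_class", "side", "root"], how="inner"
            )
            jl["abs_err_delta_length"] = (
                jl["delta_length"] - jl["true_delta_length_mm"]
            ).abs()
            jl.to_csv(out / "recovery_length.csv", index=False, float_format="%.6f")
        stages["recovery"] = "ok"

    (out / "run.log").write_text("\n".join(log) + "\n")
    (out / "config.yaml").write_text(config.to_yaml())

    hashed = {}
    for path in sorted(out.rglob("*")):
        # run.log and config.yaml are provenance (carry machine paths),
        # not results; hashing them would break rerun comparability
        if path.is_file() and path.name not in ("run.log", "manifest.json", "config.yaml"):
            hashed[str(path.relative_to(out))] = _sha256(path)
    manifest = {
        "stages": stages,
        "seed": config.seed,
        "software": "rootmorph 0.1.0",
        "files": hashed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
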