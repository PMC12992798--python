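"""End-to-end analysis pipeline on a synthetic MER cohort.

Stages: cohort generation (or loading from a cohort directory) → unit
feature extraction with quality filters → NRMS normalisation, depth
alignment and cluster-based group comparison → EEG sedation indexing →
spatial mapping of MER sites and electrodes → the group-statistics layer.
The report mirrors the six headline analyses of the emulated study:

* ``fig2b``  NRMS cluster tests (LA vs high-dose GA, LA vs low-dose GA)
* ``fig2d``  one-way ANOVA of aligned single-unit depths across conditions
* ``fig2e``  MANOVA of unit xyz coordinates across conditions
* ``fig3``   two-way ANOVAs (structure × anesthesia) of FR, BI, CV
* ``fig4b``  SEF95 vs normalized first-unit distance from the dorsal border
* ``fig4c``  SEF95 vs FR / BI / CV
* ``fig5``   BI vs sweetspot distance, separately under LA and GA
* ``fig6cd`` electrode-center sweetspot distance and z-deviation ANOVAs
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nrms as nrms_mod
from . import spatial, stats, synthetic
from .eeg import EEGRecord, sedation_for_mer
from .exceptions import InsufficientDataError, StageError
from .spike_features import extract_features, quality_filter, read_segments
from .synthetic import Cohort, CohortConfig, generate_cohort, write_cohort

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "run",
    "analyze_cohort",
    "load_cohort",
    "compute_features",
    "compute_nrms",
    "compute_sedation",
    "compute_map",
]

BLOCK_KEYS = (
    "fig2b",
    "fig2d",
    "fig2e",
    "fig3",
    "fig4b",
    "fig4c",
    "fig5",
    "fig6cd",
)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 1
    out_dir: str | Path | None = None
    n_perm: int = 2000
    cluster_alpha: float = 0.05
    grid: np.ndarray = field(default_factory=lambda: nrms_mod.DEFAULT_GRID.copy())
    enable_eeg: bool = True

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | Path | None = None) -> "RunConfig":
        """Load a YAML or JSON config file (unknown keys are an error)."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known_run = {"seed", "n_perm", "cluster_alpha", "enable_eeg", "cohort"}
        unknown = set(raw) - known_run
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort_raw = raw.pop("cohort", {})
        cfg_fields = {f.name for f in CohortConfig.__dataclass_fields__.values()}
        unknown = set(cohort_raw) - cfg_fields
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        if "feature_params" in cohort_raw:
            cohort_raw["feature_params"] = {
                k: synthetic.FeatureParams(**v)
                for k, v in cohort_raw["feature_params"].items()
            }
        for tup_key in ("propofol_range", "depth_range", "segment_duration_range",
                        "rms_depth_range"):
            if tup_key in cohort_raw:
                cohort_raw[tup_key] = tuple(cohort_raw[tup_key])
        cohort = CohortConfig(**cohort_raw)
        rc = cls(cohort=cohort, **{k: raw[k] for k in raw})
        if seed is not None:
            rc.seed = seed
        if out_dir is not None:
            rc.out_dir = out_dir
        return rc


@dataclass
class AnalysisReport:
    """Per-analysis result blocks plus provenance."""

    blocks: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"blocks": self.blocks, "provenance": self.provenance}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# --- stage computations ------------------------------------------------------

def compute_features(cohort: Cohort, seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Quality-filter segments and extract FR/BI/CV per retained unit.

    Returns the per-unit table (with segment metadata, dose condition and
    sweetspot distance) and the exclusion tally.
    """
    kept, tally = quality_filter(cohort.segments)
    dose_by_patient = dict(
        zip(cohort.patients["patient_id"], cohort.patients["propofol_rate"])
    )
    cond_by_patient = dict(
        zip(cohort.patients["patient_id"], cohort.patients["condition"])
    )
    geom_by_traj = {t.trajectory_id: t.geometry for t in cohort.trajectories}
    rows = []
    for seg in kept:
        f = extract_features(seg, seed=seed)
        cond = cond_by_patient[seg.patient_id]
        dose = dose_by_patient[seg.patient_id]
        dose = None if pd.isna(dose) else float(dose)
        if cond == "LA":
            dcond = "LA"
        else:
            dcond = "GA_low" if dose <= cohort.config.dose_threshold else "GA_high"
        xyz = spatial.locate_mer_site(geom_by_traj[seg.trajectory_id], seg.depth_to_target)
        rows.append(
            {
                "segment_id": seg.segment_id,
                "patient_id": seg.patient_id,
                "trajectory_id": seg.trajectory_id,
                "depth_to_target": seg.depth_to_target,
                "structure": seg.structure_imaging,
                "condition": cond,
                "dose_condition": dcond,
                "propofol_rate": dose,
                "fr": f.fr,
                "bi": f.bi,
                "bi_degenerate": f.bi_degenerate,
                "cv": f.cv,
                "n_spikes": f.n_spikes,
                "x": xyz[0],
                "y": xyz[1],
                "z": xyz[2],
                "distance_to_sweetspot": spatial.sweetspot_distance(
                    xyz, cohort.atlas.sweetspot
                ),
            }
        )
    return pd.DataFrame(rows), tally


def compute_nrms(cohort: Cohort) -> tuple[list, dict]:
    """Normalise trajectory RMS profiles; tally non-normalizable passes."""
    profiles = []
    tally = {"non_normalizable": 0}
    for t in cohort.trajectories:
        try:
            profiles.append((t, nrms_mod.normalize_trajectory(t.profile)))
        except InsufficientDataError:
            tally["non_normalizable"] += 1
    return profiles, tally


def compute_sedation(cohort: Cohort) -> pd.DataFrame:
    """SEF95 per patient over the MER window of its EEG record."""
    dose_by_patient = dict(
        zip(cohort.patients["patient_id"], cohort.patients["propofol_rate"])
    )
    rows = []
    for pid, rec in cohort.eeg.items():
        dose = dose_by_patient.get(pid)
        dose = None if pd.isna(dose) else float(dose)
        idx = sedation_for_mer(rec, propofol_rate=dose)
        rows.append(
            {
                "patient_id": pid,
                "sef95": idx.sef95,
                "n_epochs_used": idx.n_epochs_used,
                "n_epochs_rejected": idx.n_epochs_rejected,
                "propofol_rate": dose,
            }
        )
    return pd.DataFrame(rows)


def compute_map(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MER site positions and electrode-center summaries."""
    geom_by_traj = {t.trajectory_id: t.geometry for t in cohort.trajectories}
    site_rows = []
    for seg in cohort.segments:
        g = geom_by_traj[seg.trajectory_id]
        xyz = spatial.locate_mer_site(g, seg.depth_to_target)
        site_rows.append(
            {
                "segment_id": seg.segment_id,
                "trajectory_id": seg.trajectory_id,
                "depth_to_target": seg.depth_to_target,
                "x": xyz[0],
                "y": xyz[1],
                "z": xyz[2],
                "structure_imaging": seg.structure_imaging,
                "distance_to_sweetspot": spatial.sweetspot_distance(
                    xyz, cohort.atlas.sweetspot
                ),
            }
        )
    elec_rows = []
    for e in cohort.electrodes:
        m = spatial.electrode_center(e.model, cohort.atlas.sweetspot)
        elec_rows.append(
            {
                "electrode_id": e.electrode_id,
                "patient_id": e.patient_id,
                "hemisphere": e.hemisphere,
                "dose_condition": e.dose_condition,
                "center_x": m.center[0],
                "center_y": m.center[1],
                "center_z": m.center[2],
                "distance_to_sweetspot": m.distance_to_sweetspot,
                "z_deviation": m.z_deviation,
            }
        )
    return pd.DataFrame(site_rows), pd.DataFrame(elec_rows)


# --- full analysis -----------------------------------------------------------

def analyze_cohort(
    cohort: Cohort,
    n_perm: int = 2000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    grid: np.ndarray | None = None,
    enable_eeg: bool = True,
) -> AnalysisReport:
    """Run the full statistics layer on a cohort and assemble the report."""
    if grid is None:
        grid = nrms_mod.DEFAULT_GRID
    blocks: dict = {}

    # -- features ------------------------------------------------------------
    try:
        units, tally = compute_features(cohort, seed=seed)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("features", exc)
    counts = {
        "n_segments": len(cohort.segments),
        "n_units_retained": len(units),
        "exclusions": tally,
    }

    # -- NRMS: normalise, exclude, align, cluster tests ------------------------
    try:
        norm_profiles, nrms_tally = compute_nrms(cohort)
        spans = [t.span for t, _ in norm_profiles]
        kept_idx, excl_tally = spatial.exclude_trajectories(spans)
        kept = [norm_profiles[i] for i in kept_idx]
        shifts, reference_mid = spatial.align_depths([t.span for t, _ in kept])
        shift_by_traj = {
            t.trajectory_id: s for (t, _), s in zip(kept, shifts)
        }
        groups: dict[str, list[np.ndarray]] = {"LA": [], "GA_high": [], "GA_low": []}
        grouped = nrms_mod.group_by_dose(
            [p for _, p in kept], threshold=cohort.config.dose_threshold
        )
        for gname, plist in grouped.items():
            for p in plist:
                shifted = nrms_mod.TrajectoryProfile(
                    trajectory_id=p.trajectory_id,
                    condition=p.condition,
                    propofol_rate=p.propofol_rate,
                    depths=p.depths + shift_by_traj[p.trajectory_id],
                    durations=p.durations,
                    rms=p.rms,
                    nrms=p.nrms,
                    aligned=True,
                )
                groups[gname].append(nrms_mod.resample_to_grid(shifted, grid))
        fig2b = {}
        rng = np.random.default_rng(seed)
        for label, other in (("LA_vs_GA_high", "GA_high"), ("LA_vs_GA_low", "GA_low")):
            if len(groups["LA"]) >= 2 and len(groups[other]) >= 2:
                res = stats.cluster_permutation_test(
                    np.array(groups["LA"]),
                    np.array(groups[other]),
                    grid,
                    n_perm=n_perm,
                    cluster_alpha=cluster_alpha,
                    seed=int(rng.integers(2**31 - 1)),
                )
                fig2b[label] = {
                    "clusters": [vars(c) for c in res.clusters],
                    "significant": [vars(c) for c in res.significant()],
                    "n_permutations": res.n_permutations,
                    "group_sizes": [len(groups["LA"]), len(groups[other])],
                }
            else:
                fig2b[label] = {"skip": "fewer than 2 trajectories in a group"}
        blocks["fig2b"] = fig2b
        counts["trajectory_exclusions"] = {**nrms_tally, **excl_tally}
        counts["reference_midpoint_mm"] = reference_mid
    except Exception as exc:
        raise StageError("nrms", exc)

    # -- aligned SUA depths (fig2d) and spatial MANOVA (fig2e) -----------------
    try:
        units_kept = units[units["trajectory_id"].isin(shift_by_traj)].copy()
        units_kept["aligned_depth"] = units_kept["depth_to_target"] + units_kept[
            "trajectory_id"
        ].map(shift_by_traj)
        by_cond = {
            c: g["aligned_depth"].to_numpy()
            for c, g in units_kept.groupby("dose_condition")
        }
        order = [c for c in ("LA", "GA_high", "GA_low") if c in by_cond]
        if len(order) >= 2:
            summ = stats.anova_oneway(
                *[by_cond[c] for c in order], name="sua_depth_by_condition"
            )
            posthoc = {}
            from scipy.stats import ttest_ind

            pairs = [(a, b) for i, a in enumerate(order) for b in order[i + 1:]]
            raw_p = [
                float(ttest_ind(by_cond[a], by_cond[b]).pvalue) for a, b in pairs
            ]
            corr = stats.bonferroni(raw_p, m=len(pairs))
            for (a, b), pc in zip(pairs, corr):
                posthoc[f"{a}_vs_{b}"] = {
                    "p": float(pc),
                    "mean_diff": float(np.mean(by_cond[a]) - np.mean(by_cond[b])),
                    "cohen_d": stats.cohen_d_two_sample(by_cond[a], by_cond[b]),
                }
            blocks["fig2d"] = {
                "anova": summ.to_dict(),
                "posthoc_bonferroni": posthoc,
                "group_means": {c: float(np.mean(by_cond[c])) for c in order},
                "group_sizes": {c: int(by_cond[c].size) for c in order},
            }
        else:
            blocks["fig2d"] = {"skip": "need at least 2 dose conditions with units"}

        xyz_groups = [
            units_kept[units_kept["dose_condition"] == c][["x", "y", "z"]].to_numpy()
            for c in order
        ]
        if len(xyz_groups) >= 2 and all(g.shape[0] >= 4 for g in xyz_groups):
            blocks["fig2e"] = stats.manova(xyz_groups, name="mni_xyz_by_condition").to_dict()
        else:
            blocks["fig2e"] = {"skip": "too few units per condition for MANOVA"}
    except Exception as exc:
        raise StageError("sua_depths", exc)

    # -- two-way feature ANOVAs (fig3) -----------------------------------------
    try:
        fig3 = {}
        in_nuclei = units[units["structure"].isin(["STN", "SNr"])]
        for feat in ("fr", "bi", "cv"):
            res = stats.anova_twoway(
                in_nuclei[feat],
                in_nuclei["structure"],
                in_nuclei["condition"],
                names=("structure", "anesthesia"),
            )
            fig3[feat] = {k: v.to_dict() for k, v in res.items()}
        fig3["group_means"] = {
            feat: {
                cond: float(g[feat].mean())
                for cond, g in in_nuclei.groupby("condition")
            }
            for feat in ("fr", "bi", "cv")
        }
        fig3["structure_means"] = {
            feat: {s: float(g[feat].mean()) for s, g in in_nuclei.groupby("structure")}
            for feat in ("fr", "bi", "cv")
        }
        blocks["fig3"] = fig3
    except Exception as exc:
        raise StageError("features_anova", exc)

    # -- sedation-linked analyses (fig4) ---------------------------------------
    if enable_eeg and cohort.eeg:
        try:
            sed = compute_sedation(cohort)
            sef_by_patient = dict(zip(sed["patient_id"], sed["sef95"]))
            # first-SUA normalized distance per kept trajectory
            rows = []
            for t, _p in kept:
                entry, exit_ = t.span
                sua = units[units["trajectory_id"] == t.trajectory_id][
                    "depth_to_target"
                ].to_numpy()
                nd = spatial.first_sua_normalized_distance(entry, exit_, sua)
                if nd is not None:
                    rows.append(
                        {
                            "trajectory_id": t.trajectory_id,
                            "normalized_first_sua": nd,
                            "sef95": sef_by_patient[t.patient_id],
                        }
                    )
            fig4b_df = pd.DataFrame(rows)
            if len(fig4b_df) >= 4:
                blocks["fig4b"] = {
                    **stats.spearman(
                        fig4b_df["sef95"],
                        fig4b_df["normalized_first_sua"],
                        n_comparisons=4,
                        name="sef95_vs_first_sua_distance",
                    ).to_dict(),
                    "n_trajectories": len(fig4b_df),
                }
            else:
                blocks["fig4b"] = {"skip": "fewer than 4 trajectories with a qualifying first unit"}
            u = units.copy()
            u["sef95"] = u["patient_id"].map(sef_by_patient)
            fig4c = {}
            for feat in ("fr", "bi", "cv"):
                fig4c[feat] = stats.spearman(
                    u["sef95"], u[feat], n_comparisons=4, name=f"sef95_vs_{feat}"
                ).to_dict()
            blocks["fig4c"] = fig4c
        except Exception as exc:
            raise StageError("sedation", exc)
    else:
        reason = "EEG disabled in config" if not enable_eeg else "no EEG records"
        blocks["fig4b"] = {"skip": reason}
        blocks["fig4c"] = {"skip": reason}

    # -- BI vs sweetspot distance (fig5) ---------------------------------------
    try:
        fig5 = {}
        for cond, g in units.groupby("condition"):
            if len(g) >= 4:
                fig5[cond] = stats.spearman(
                    g["bi"],
                    g["distance_to_sweetspot"],
                    n_comparisons=2,
                    name=f"bi_vs_sweetspot_{cond}",
                ).to_dict()
        blocks["fig5"] = fig5
    except Exception as exc:
        raise StageError("sweetspot_correlation", exc)

    # -- electrode placement (fig6) --------------------------------------------
    try:
        _, elec = compute_map(cohort)
        by_cond = {c: g for c, g in elec.groupby("dose_condition")}
        order = [c for c in ("LA", "GA_high", "GA_low") if c in by_cond]
        fig6 = {}
        if len(order) >= 2 and all(len(by_cond[c]) >= 2 for c in order):
            for metric in ("distance_to_sweetspot", "z_deviation"):
                fig6[metric] = stats.anova_oneway(
                    *[by_cond[c][metric].to_numpy() for c in order],
                    name=f"electrode_{metric}",
                ).to_dict()
                fig6[metric]["group_means"] = {
                    c: float(by_cond[c][metric].mean()) for c in order
                }
        else:
            fig6 = {"skip": "too few electrodes per condition"}
        blocks["fig6cd"] = fig6
    except Exception as exc:
        raise StageError("electrodes", exc)

    blocks["counts"] = counts
    cfg_hash = hashlib.sha256(
        json.dumps(synthetic._config_to_jsonable(cohort.config), sort_keys=True,
                   default=str).encode()
    ).hexdigest()[:16]
    provenance = {
        "seed": cohort.seed,
        "analysis_seed": seed,
        "config_hash": cfg_hash,
        "n_permutations": n_perm,
    }
    # every enabled analysis must produce a block or an explicit skip
    for key in BLOCK_KEYS:
        blocks.setdefault(key, {"skip": "not computed"})
    return AnalysisReport(blocks=blocks, provenance=provenance)


def run(config: RunConfig) -> AnalysisReport:
    """Generate a cohort, analyse it and (optionally) write all outputs."""
    cohort = generate_cohort(config.cohort, seed=config.seed)
    report = analyze_cohort(
        cohort,
        n_perm=config.n_perm,
        cluster_alpha=config.cluster_alpha,
        seed=config.seed,
        grid=config.grid,
        enable_eeg=config.enable_eeg,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "cohort")
        units, _ = compute_features(cohort, seed=config.seed)
        units.to_csv(out / "unit_features.tsv", sep="\t", index=False)
        sites, elec = compute_map(cohort)
        sites.to_csv(out / "mer_sites.tsv", sep="\t", index=False)
        elec.to_csv(out / "electrode_summary.tsv", sep="\t", index=False)
        if config.enable_eeg:
            compute_sedation(cohort).to_csv(out / "sedation.tsv", sep="\t", index=False)
        report.to_json(out / "report.json")
    return report


# --- cohort loading from a written directory ---------------------------------

def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Reconstruct a :class:`Cohort` from the tables written by
    :func:`mertopo.synthetic.write_cohort`."""
    d = Path(cohort_dir)
    for required in ("patients.tsv", "trajectories.tsv", "segments.tsv",
                     "rms_profiles.tsv", "manifest.json"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing upstream table: {d / required}")
    manifest = json.loads((d / "manifest.json").read_text())
    atlas = synthetic.default_atlas()
    atlas.sweetspot = np.asarray(manifest["sweetspot"], dtype=float)
    patients = pd.read_csv(d / "patients.tsv", sep="\t")
    traj_df = pd.read_csv(d / "trajectories.tsv", sep="\t")
    rms_df = pd.read_csv(d / "rms_profiles.tsv", sep="\t")
    segments = read_segments(d / "segments.tsv", d / "spikes")

    trajectories = []
    for row in traj_df.itertuples(index=False):
        geom = spatial.TrajectoryGeometry(
            target_point=(row.target_x, row.target_y, row.target_z),
            direction=(row.dir_x, row.dir_y, row.dir_z),
            implantation_offset=float(row.implantation_offset),
        )
        span = (
            None
            if pd.isna(row.stn_entry)
            else (float(row.stn_entry), float(row.stn_exit))
        )
        prof_rows = rms_df[rms_df["trajectory_id"] == row.trajectory_id]
        dose = None if pd.isna(row.propofol_rate) else float(row.propofol_rate)
        profile = nrms_mod.TrajectoryProfile(
            trajectory_id=str(row.trajectory_id),
            condition=str(row.condition),
            propofol_rate=dose,
            depths=prof_rows["depth"].to_numpy(),
            durations=prof_rows["duration"].to_numpy(),
            rms=prof_rows["rms"].to_numpy(),
            stn_entry=None if span is None else span[0],
            stn_exit=None if span is None else span[1],
        )
        trajectories.append(
            synthetic.TrajectoryRecord(
                trajectory_id=str(row.trajectory_id),
                patient_id=str(row.patient_id),
                hemisphere=str(row.hemisphere),
                condition=str(row.condition),
                propofol_rate=dose,
                geometry=geom,
                span=span,
                profile=profile,
            )
        )

    eeg: dict[str, EEGRecord] = {}
    eeg_dir = d / "eeg"
    if eeg_dir.exists():
        for f in sorted(eeg_dir.glob("*.csv")):
            with open(f) as fh:
                header = fh.readline().strip().lstrip("#").strip()
            meta = dict(kv.split("=") for kv in header.split(","))
            data = np.loadtxt(f, delimiter=",", skiprows=2)
            eeg[f.stem] = EEGRecord(
                channels=data.T,
                fs=float(meta["fs"]),
                mer_window=(float(meta["mer_start"]), float(meta["mer_end"])),
            )

    electrodes = []
    elec_path = d / "electrodes.tsv"
    if elec_path.exists():
        elec_df = pd.read_csv(elec_path, sep="\t")
        for eid, g in elec_df.groupby("electrode_id", sort=True):
            model = spatial.electrode_center(
                spatial.ElectrodeModel(
                    contact_positions=g[["x", "y", "z"]].to_numpy()
                ),
                atlas.sweetspot,
            )
            electrodes.append(
                synthetic.ElectrodeRecord(
                    electrode_id=str(eid),
                    patient_id=str(g["patient_id"].iloc[0]),
                    hemisphere=str(g["hemisphere"].iloc[0]),
                    dose_condition=str(g["dose_condition"].iloc[0]),
                    model=model,
                )
            )

    cfg_raw = manifest.get("config", {})
    cfg = CohortConfig()
    for key in ("n_patients", "frac_la", "dose_threshold"):
        if key in cfg_raw:
            setattr(cfg, key, cfg_raw[key])
    return Cohort(
        config=cfg,
        seed=int(manifest.get("seed", 0)),
        atlas=atlas,
        patients=patients,
        trajectories=trajectories,
        segments=segments,
        eeg=eeg,
        electrodes=electrodes,
    )
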