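"""End-to-end run orchestration: simulate -> score -> lesionload ->
disconnectome -> voxelstats -> stats, with a content-hashed run manifest.

Each stage reads only files a previous stage wrote into the run directory,
so the CLI subcommands can be re-run individually, and a completed run is
reproducible from its manifest (seeds and configuration are recorded; the
deterministic stages are bit-identical across reruns, the stochastic ones
identical for a fixed seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats as cs
from . import lesion_load as ll
from . import scoring, synthetic
from .disconnectome import DisconnectomeBuilder, group_difference_tfce
from .volumes import read_streamlines, read_volume, write_streamlines, write_volume

log = logging.getLogger("proprio_disconnect")

__all__ = ["RunConfig", "run_all", "STAGES"]


@dataclass
class RunConfig:
    """Every analysis constant with its default, plus cohort sizes.

    The thresholds carry the published defaults: impairment cut 1.96,
    FDR q = 0.05, tract-inclusion minimum 25, 4000 permutations, TFCE
    E = 0.5 / H = 2.
    """

    seed: int = 0
    # toy brain
    shape: tuple[int, int, int] = synthetic.DEFAULT_SHAPE
    voxel_mm: float = synthetic.DEFAULT_VOXEL_MM
    n_tracts: int = 4
    n_streamline_controls: int = 10
    # cohorts
    n_stroke: int = 203
    right_fraction: float = 118.0 / 203.0
    n_normative_controls: int = 799
    n_normative_assessments: int = 2227
    # ground truth
    truth: synthetic.GroundTruth = field(default_factory=synthetic.GroundTruth.null)
    # thresholds
    impairment_threshold: float = 1.96
    fdr_q: float = 0.05
    inclusion_min_n: int = 25
    n_perm: int = 4000
    tfce_E: float = 0.5
    tfce_H: float = 2.0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for name in ("impairment_threshold", "fdr_q", "inclusion_min_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.shape = tuple(self.shape)  # type: ignore[assignment]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML or JSON document (keys mirror the fields)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        truth = raw.pop("truth", None)
        cfg = cls(**raw)
        if truth is not None:
            cfg.truth = synthetic.GroundTruth(**truth)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data: dict = {"config": config.to_dict(), "stages": {}, "files": {}}

    def record(self, stage: str, paths: list[Path], seconds: float, seed) -> None:
        self.data["stages"][stage] = {
            "seconds": round(seconds, 3),
            "seed": seed,
            "outputs": [str(p.relative_to(self.outdir)) for p in paths],
        }
        for p in paths:
            self.data["files"][str(p.relative_to(self.outdir))] = _sha256(p)
        self.write()

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(json.dumps(self.data, indent=1))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name, manifest, seed):
    """Context manager logging wall-clock and recording outputs."""

    class _Ctx:
        def __init__(self):
            self.outputs: list[Path] = []

        def __enter__(self):
            log.info("stage %s starting (seed=%s)", name, seed)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, exc) from exc
            dt = time.perf_counter() - self.t0
            manifest.record(name, self.outputs, dt, seed)
            log.info("stage %s done in %.2fs", name, dt)

    return _Ctx()


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(rng.integers(2**31 - 1)) for k in ("brain", "normative", "stroke")}
    with _stage("simulate", manifest, cfg.seed) as st:
        brain = synthetic.make_brain(
            seeds["brain"],
            cfg.shape,
            n_tracts=cfg.n_tracts,
            n_controls=cfg.n_streamline_controls,
            voxel_mm=cfg.voxel_mm,
        )
        atlas = outdir / "atlas"
        st.outputs.append(write_volume(brain.grid, atlas / "brain_mask.nii.gz"))
        st.outputs.append(write_volume(brain.gm_mask, atlas / "gm_mask.nii.gz"))
        for label, vol in brain.tract_maps.items():
            st.outputs.append(write_volume(vol, atlas / f"{label}.nii.gz"))
        for control in brain.controls:
            st.outputs.append(
                write_streamlines(
                    control, outdir / "controls" / f"{control.control_id}.txt"
                )
            )

        norm = synthetic.make_normative_cohort(
            seeds["normative"], cfg.n_normative_controls, cfg.n_normative_assessments
        )
        sessions = {f"a{i:04d}": s for i, s in enumerate(norm["session"])}
        cov = norm[["control_id", "age", "sex", "handedness"]].copy()
        cov.insert(0, "assessment_id", list(sessions))
        p = outdir / "normative_covariates.csv"
        cov.to_csv(p, index=False)
        st.outputs.append(p)
        p = outdir / "normative_trials.csv"
        scoring.sessions_to_trials(sessions).to_csv(p, index=False)
        st.outputs.append(p)

        cohort = synthetic.make_stroke_cohort(
            seeds["stroke"],
            brain,
            cfg.truth,
            n=cfg.n_stroke,
            right_fraction=cfg.right_fraction,
        )
        for pid, lesion in cohort.lesions.items():
            st.outputs.append(
                write_volume(lesion, outdir / "lesions" / f"{pid}.nii.gz")
            )
        p = outdir / "cohort.csv"
        cohort.table.to_csv(p, index=False)
        st.outputs.append(p)
        p = outdir / "stroke_trials.csv"
        scoring.sessions_to_trials(cohort.sessions or {}).to_csv(p, index=False)
        st.outputs.append(p)


def stage_score(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    with _stage("score", manifest, None) as st:
        ncov = pd.read_csv(outdir / "normative_covariates.csv").set_index(
            "assessment_id"
        )
        ntrials = pd.read_csv(outdir / "normative_trials.csv")
        nsessions = scoring.sessions_from_trials(ntrials, ncov)
        model = scoring.normative_fit(list(nsessions.values()))
        p = outdir / "normative_model.json"
        model.to_json(p)
        st.outputs.append(p)

        cohort = pd.read_csv(outdir / "cohort.csv").set_index(
            "participant_id", drop=False
        )
        strials = pd.read_csv(outdir / "stroke_trials.csv")
        ssessions = scoring.sessions_from_trials(strials, cohort)
        rows = []
        for pid, session in ssessions.items():
            res = scoring.task_score(session, model)
            rows.append(
                {
                    "participant_id": pid,
                    "task_score": res.task_score,
                    "rss": res.rss,
                    "impaired": int(res.task_score > cfg.impairment_threshold),
                }
            )
        p = outdir / "task_scores.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        st.outputs.append(p)


def _load_atlas(outdir: Path):
    atlas = outdir / "atlas"
    gm = read_volume(atlas / "gm_mask.nii.gz")
    tracts = {
        f.name.removesuffix(".nii.gz"): read_volume(f)
        for f in sorted(atlas.glob("tract*.nii.gz"))
    }
    return gm, tracts


def _load_lesions(outdir: Path):
    return {
        f.name.removesuffix(".nii.gz"): read_volume(f, require_mask=True)
        for f in sorted((outdir / "lesions").glob("*.nii.gz"))
    }


def stage_lesionload(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    with _stage("lesionload", manifest, None) as st:
        gm, tracts = _load_atlas(outdir)
        lesions = _load_lesions(outdir)
        loads = ll.tract_load_table(lesions, tracts, gm)
        for fam in sorted({ll.split_homologue(t)[0] for t in tracts}):
            loads[fam] = loads[f"{fam}_left"] + loads[f"{fam}_right"]
        p = outdir / "tract_loads.csv"
        loads.rename_axis("participant_id").to_csv(p)
        st.outputs.append(p)


def stage_disconnectome(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    with _stage("disconnectome", manifest, None) as st:
        lesions = _load_lesions(outdir)
        grid = next(iter(lesions.values()))
        controls = [
            read_streamlines(f) for f in sorted((outdir / "controls").glob("*.txt"))
        ]
        builder = DisconnectomeBuilder(controls, grid)
        for pid, lesion in lesions.items():
            st.outputs.append(
                write_volume(
                    builder.map(lesion), outdir / "disconnectome" / f"{pid}.nii.gz"
                )
            )


def stage_voxelstats(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    seed = int(np.random.default_rng(cfg.seed + 1).integers(2**31 - 1))
    with _stage("voxelstats", manifest, seed) as st:
        scores = pd.read_csv(outdir / "task_scores.csv").set_index("participant_id")
        loads = pd.read_csv(outdir / "tract_loads.csv").set_index("participant_id")
        pids = list(scores.index)
        maps = [read_volume(outdir / "disconnectome" / f"{p}.nii.gz") for p in pids]
        res = group_difference_tfce(
            maps,
            scores["impaired"].astype(bool).to_numpy(),
            covariate=loads.loc[pids, "gm_volume_cc"].to_numpy(),
            n_perm=cfg.n_perm,
            seed=seed,
            E=cfg.tfce_E,
            H=cfg.tfce_H,
        )
        vs = outdir / "voxelstats"
        for name, vol in (
            ("t_map", res.t_map),
            ("tfce_map", res.tfce_map),
            ("p_fwe", res.p_fwe),
            ("sig_mask_p05", res.sig_mask_05),
            ("sig_mask_p001", res.sig_mask_001),
        ):
            st.outputs.append(write_volume(vol, vs / f"{name}.nii.gz"))


def stage_stats(cfg: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    with _stage("stats", manifest, None) as st:
        cohort = pd.read_csv(outdir / "cohort.csv").set_index(
            "participant_id", drop=False
        )
        scores = pd.read_csv(outdir / "task_scores.csv").set_index("participant_id")
        loads = pd.read_csv(outdir / "tract_loads.csv").set_index("participant_id")
        pids = list(cohort.index)
        y = scores.loc[pids, "task_score"].to_numpy()
        side = cohort["side"].to_numpy()

        anc = cs.ancova_side(y, side, loads.loc[pids, "total_volume_cc"].to_numpy())
        left = cohort["side"] == "left"
        ipsi = cohort["ipsi_motor_impaired"].astype(bool)
        table = [
            [int((left & ipsi).sum()), int((left & ~ipsi).sum())],
            [int((~left & ipsi).sum()), int((~left & ~ipsi).sum())],
        ]
        chi2, chi2_p = cs.chi_square_2x2(table)

        tract_cols = [c for c in loads.columns if c.endswith(("_left", "_right"))]
        included = ll.tract_inclusion_filter(
            loads[tract_cols], min_n=cfg.inclusion_min_n
        )
        gm = loads.loc[pids, "gm_volume_cc"].to_numpy()
        battery = None
        pcr_table = None
        if included:
            battery = cs.tract_regression_battery(
                y, loads.loc[pids], included, side, gm, q=cfg.fdr_q
            )
            p = outdir / "tract_regressions.csv"
            battery.to_csv(p, index=False)
            st.outputs.append(p)

            predictors = loads.loc[pids, included].copy()
            predictors["gm_volume_cc"] = gm
            pca = cs.pca_predictors(predictors)
            pcr = cs.pc_regression(pca, y, q=cfg.fdr_q)
            pcr_table = pcr.table
            p = outdir / "pca_loadings.csv"
            pca.loadings.rename_axis("predictor").to_csv(p)
            st.outputs.append(p)
            p = outdir / "pc_regression.csv"
            pcr.table.rename_axis("component").to_csv(p)
            st.outputs.append(p)

        summary = {
            "n": len(pids),
            "ancova_side": {"F": anc.F, "p": anc.p},
            "chi_square_ipsi": {"chi2": chi2, "p": chi2_p, "table": table},
            "included_tracts": included,
            "n_fdr_comparisons": (None if battery is None else int(len(battery))),
            "impaired_n": int(scores["impaired"].sum()),
            "pc_selected": (None if pcr_table is None else int(len(pcr_table))),
        }
        p = outdir / "stats_summary.json"
        p.write_text(json.dumps(summary, indent=1))
        st.outputs.append(p)


STAGES = {
    "simulate": stage_simulate,
    "score": stage_score,
    "lesionload": stage_lesionload,
    "disconnectome": stage_disconnectome,
    "voxelstats": stage_voxelstats,
    "stats": stage_stats,
}
#: voxelstats needs score + disconnectome outputs, so it runs after both
_ORDER = ["simulate", "score", "lesionload", "disconnectome", "voxelstats", "stats"]


def run_all(cfg: RunConfig, outdir: str | Path, stages: list[str] | None = None) -> Path:
    """Run the pipeline (or a subset of stages) into a run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, cfg)
    # reuse an existing manifest so single-stage reruns keep earlier records
    existing = outdir / "manifest.json"
    if existing.exists():
        manifest.data = json.loads(existing.read_text())
        manifest.data["config"] = cfg.to_dict()
    for name in stages or _ORDER:
        STAGES[name](cfg, outdir, manifest)
    return outdir
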