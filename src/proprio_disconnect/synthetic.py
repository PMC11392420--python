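"""Synthetic miniature study with known ground truth.

Generates every ingredient of the analysis at desk scale: a toy brain on a
small voxel grid (default 32x38x32 at 3 mm), left/right homologous tubular
tract probability maps, a grey-matter shell, per-control streamline bundles
jittered around each tract's centreline, hemisphere-confined ellipsoidal
lesions, a normative control cohort of APM sessions, and a stroke cohort
whose latent impairment follows a known linear model

    latent = b0 + b_side * side + sum_t b_t * z(load_t) + b_gm * z(gm) + eps

with tract loads standardised within the cohort.  The latent severity drives
the trial-level phenotypes: systematic lateral shift (10*s mm), workspace
contraction (factor max(0.2, 1 - 0.1*s)) and trial noise (5 + 3*s mm SD).

Everything is deterministic for a fixed seed, so calibration (null) and
recovery (known-effect) experiments are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from . import lesion_load as ll
from .scoring import MatchingSession, N_BLOCKS, N_TARGETS
from .volumes import StreamlineSet, VolumeGrid

__all__ = [
    "GroundTruth",
    "SyntheticBrain",
    "NormativeConfig",
    "make_brain",
    "make_lesion",
    "make_normative_cohort",
    "make_stroke_cohort",
    "generate_session",
    "target_layout",
    "StrokeCohort",
]

DEFAULT_SHAPE = (32, 38, 32)
DEFAULT_VOXEL_MM = 3.0


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Generative parameters of the stroke cohort.

    ``causal_tracts`` maps tract-family labels to effects in latent-score
    units per SD of lesion load; ``side_effect`` is the right-vs-left shift
    (side coded left=0, right=1); ``gm_effect`` is per SD of grey-matter
    lesion volume; ``noise_sd`` is the latent residual SD.
    """

    causal_tracts: dict[str, float] = field(default_factory=dict)
    side_effect: float = 0.0
    gm_effect: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 1.0
    # latent severity s -> trial-level phenotype (means of the trait model)
    shift_mm_per_s: float = 10.0
    contraction_per_s: float = 0.1
    contraction_floor: float = 0.2
    trial_noise_base_mm: float = 5.0
    trial_noise_per_s_mm: float = 3.0
    trial_noise_floor_mm: float = 0.5  # human matching is never noise-free
    # between-subject trait dispersion around those means: real control
    # cohorts differ in their true matching ability, not just in sampling
    # noise of the parameter estimates
    shift_between_sd_mm: float = 5.0
    contraction_between_sd: float = 0.05
    noise_between_log_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.contraction_floor <= 0:
            raise ConfigurationError("contraction floor must be > 0")

    def trial_model(self, severity: float) -> tuple[float, float, float]:
        """Mean (lateral shift mm, contraction factor, trial noise SD mm)."""
        s = float(severity)
        shift = self.shift_mm_per_s * s
        contraction = max(self.contraction_floor, 1.0 - self.contraction_per_s * s)
        noise = max(
            self.trial_noise_floor_mm,
            self.trial_noise_base_mm + self.trial_noise_per_s_mm * s,
        )
        return shift, contraction, noise

    def draw_traits(
        self, rng: np.random.Generator, severity: float
    ) -> tuple[np.ndarray, float, float]:
        """One subject's true (shift vector mm, contraction, noise SD mm):
        the trial-model means plus between-subject trait dispersion."""
        shift_mean, contraction_mean, noise_mean = self.trial_model(severity)
        shift = np.array([shift_mean, 0.0]) + rng.normal(
            0.0, self.shift_between_sd_mm, 2
        )
        contraction = max(
            self.contraction_floor,
            contraction_mean + rng.normal(0.0, self.contraction_between_sd),
        )
        noise = noise_mean * np.exp(rng.normal(0.0, self.noise_between_log_sd))
        return shift, contraction, noise

    @classmethod
    def null(cls, **kwargs) -> "GroundTruth":
        """All effects zero: the calibration (type-I error) condition."""
        return cls(causal_tracts={}, side_effect=0.0, gm_effect=0.0, **kwargs)


# ---------------------------------------------------------------------------
# Toy brain


@dataclass
class SyntheticBrain:
    grid: VolumeGrid  # brain mask on the reference grid
    tract_maps: dict[str, VolumeGrid]  # label -> probability map in [0, 1]
    gm_mask: VolumeGrid
    controls: list[StreamlineSet]
    #: per control, the tract label each streamline belongs to (same order)
    streamline_labels: dict[str, list[str]]
    centrelines: dict[str, np.ndarray]  # label -> (n, 3) world-mm polyline

    @property
    def tract_families(self) -> list[str]:
        fams = sorted({ll.split_homologue(lbl)[0] for lbl in self.tract_maps})
        return fams

    def hemisphere_mask(self, side: str) -> np.ndarray:
        nx = self.grid.shape[0]
        mask = np.zeros(self.grid.shape, dtype=bool)
        if side == "left":
            mask[: nx // 2] = True
        elif side == "right":
            mask[nx - nx // 2 :] = True
        else:
            raise ConfigurationError(f"unknown side {side!r}")
        return mask & self.grid.values.astype(bool)


def _tract_centreline_voxels(
    f: int, n_tracts: int, shape, rng: np.random.Generator
) -> np.ndarray:
    """Smooth left-hemisphere curve in voxel coordinates, (n, 3)."""
    nx, ny, nz = shape
    half = nx // 2
    # lateral position and depth: evenly spaced lanes with a little jitter
    x0 = 2.5 + (half - 6.0) * (f + 0.5) / n_tracts + rng.uniform(-0.3, 0.3)
    z0 = 4.0 + (nz - 9.0) * ((f * 2 + 1) % n_tracts + 0.5) / n_tracts
    z0 += rng.uniform(-0.3, 0.3)
    amp_x = rng.uniform(0.8, 2.0)
    amp_z = rng.uniform(0.8, 2.0)
    phase = rng.uniform(0, 2 * np.pi)
    y = np.linspace(2.5, ny - 3.5, 2 * ny)
    t = (y - y[0]) / (y[-1] - y[0])
    x = x0 + amp_x * np.sin(np.pi * t + phase)
    z = z0 + amp_z * np.cos(np.pi * t)
    x = np.clip(x, 1.5, half - 2.0)
    z = np.clip(z, 1.5, nz - 2.5)
    return np.column_stack([x, y, z])


def make_brain(
    seed: int,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    n_tracts: int = 4,
    n_controls: int = 10,
    voxel_mm: float = DEFAULT_VOXEL_MM,
    tract_radius_mm: float = 5.0,
    streamlines_per_tract: int = 8,
) -> SyntheticBrain:
    """Build the toy brain: tract atlas, grey-matter shell, control bundles.

    ``n_tracts`` counts tract *families*; each yields a left and a mirrored
    right homologue, so the atlas holds ``2 * n_tracts`` maps.  Per control
    and per tract, ``streamlines_per_tract`` polylines are drawn: the first
    is the exact bundle core (the centreline), the rest are jittered copies.
    """
    if n_tracts < 2 or n_controls < 2:
        raise ConfigurationError("need at least 2 tract families and 2 controls")
    nx, ny, nz = shape
    if min(shape) < 12 or nx < 16:
        raise ConfigurationError(f"grid {shape} too small to host tubular tracts")
    rng = np.random.default_rng(seed)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])

    # brain mask: centred ellipsoid
    centre = (np.array(shape) - 1) / 2.0
    semi = np.array(shape) * 0.48
    idx = np.indices(shape)
    r2 = sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3))
    brain = (r2 <= 1.0).astype(np.uint8)
    grid = VolumeGrid(brain, affine)

    # grey matter: outer shell of the brain ellipsoid
    gm = ((r2 <= 1.0) & (r2 >= 0.55)).astype(np.uint8)
    gm_mask = VolumeGrid(gm, affine)

    tract_maps: dict[str, VolumeGrid] = {}
    centrelines: dict[str, np.ndarray] = {}
    for f in range(n_tracts):
        cl_vox = _tract_centreline_voxels(f, n_tracts, shape, rng)
        mask = np.zeros(shape, dtype=bool)
        ivox = np.round(cl_vox).astype(int)
        mask[ivox[:, 0], ivox[:, 1], ivox[:, 2]] = True
        dist_mm = ndi.distance_transform_edt(~mask, sampling=(voxel_mm,) * 3)
        prob = np.exp(-((dist_mm / tract_radius_mm) ** 2))
        prob[dist_mm > 2.0 * tract_radius_mm] = 0.0
        label = f"tract{f}"
        tract_maps[f"{label}_left"] = VolumeGrid(prob, affine)
        tract_maps[f"{label}_right"] = VolumeGrid(prob[::-1].copy(), affine)
        centrelines[f"{label}_left"] = cl_vox * voxel_mm
        right = cl_vox.copy()
        right[:, 0] = (nx - 1) - right[:, 0]
        centrelines[f"{label}_right"] = right * voxel_mm

    controls: list[StreamlineSet] = []
    streamline_labels: dict[str, list[str]] = {}
    max_jitter = 2.0 * tract_radius_mm  # keeps bundles inside the map support
    for c in range(n_controls):
        cid = f"control{c:02d}"
        lines: list[np.ndarray] = []
        labels: list[str] = []
        for label in sorted(centrelines):
            core = centrelines[label]
            for k in range(streamlines_per_tract):
                if k == 0:
                    line = core.copy()
                else:
                    offset = rng.normal(0.0, tract_radius_mm / 2.0, size=3)
                    offset = np.clip(offset, -max_jitter / 2, max_jitter / 2)
                    wobble = rng.normal(0.0, 0.8, size=(len(core), 3))
                    wobble = ndi.uniform_filter1d(wobble, size=7, axis=0)
                    line = core + offset + wobble
                lines.append(line)
                labels.append(label)
        controls.append(StreamlineSet(cid, lines))
        streamline_labels[cid] = labels

    return SyntheticBrain(
        grid=grid,
        tract_maps=tract_maps,
        gm_mask=gm_mask,
        controls=controls,
        streamline_labels=streamline_labels,
        centrelines=centrelines,
    )


def make_lesion(
    seed: int, brain: SyntheticBrain, side: str, volume_cc: float
) -> VolumeGrid:
    """A connected ellipsoidal lesion confined to one hemisphere.

    The lesion is the set of the K voxels closest to a random centre under
    an anisotropic ellipsoidal norm, restricted to the hemisphere (K chosen
    from the target volume, achieved exactly up to voxel rounding).
    """
    rng = np.random.default_rng(seed)
    hemi = brain.hemisphere_mask(side)
    voxel_cc = brain.grid.voxel_volume_mm3 / 1000.0
    k = int(round(volume_cc / voxel_cc))
    if k < 1:
        raise ConfigurationError(f"target volume {volume_cc} cc below one voxel")
    if k > int(hemi.sum()):
        raise ConfigurationError(
            f"target volume {volume_cc} cc exceeds the {side} hemisphere"
        )
    coords = np.argwhere(hemi)
    # bias the centre away from the hemisphere edge so the blob stays compact
    interior = ndi.binary_erosion(hemi, iterations=2)
    pool = np.argwhere(interior) if interior.any() else coords
    centre = pool[rng.integers(len(pool))]
    scales = np.exp(rng.normal(0.0, 0.35, size=3))
    scales /= scales.prod() ** (1.0 / 3.0)
    norm2 = (((coords - centre) / scales) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(len(coords)), norm2))  # deterministic ties
    chosen = coords[order[:k]]
    values = np.zeros(brain.grid.shape, dtype=np.uint8)
    values[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = 1
    # the truncated-ellipsoid sublevel set is 6-connected in practice; keep
    # the centre's component if discretisation ever splits it
    lab, n = ndi.label(values)
    if n > 1:
        keep = lab[tuple(centre)]
        values = (lab == keep).astype(np.uint8)
    return brain.grid.like(values)


# ---------------------------------------------------------------------------
# APM trial generation


def target_layout(
    spacing_mm: float = 60.0, centre_xy: tuple[float, float] = (-150.0, 250.0)
) -> np.ndarray:
    """The nine robot target positions (3x3 square) in the affected-arm
    frame, mm; the participant midline is x = 0."""
    cx, cy = centre_xy
    offs = np.array([-1.0, 0.0, 1.0]) * spacing_mm
    return np.array([[cx + dx, cy + dy] for dy in offs for dx in offs])


@dataclass
class NormativeConfig:
    """Covariate structure of the control cohort generator.

    Small, stated effects so that z-scoring matters without dominating:
    trial noise scales linearly with age (``age_slope`` per year relative
    to the cohort mid-age).
    """

    age_range: tuple[float, float] = (18.0, 85.0)
    female_fraction: float = 0.5
    right_handed_fraction: float = 0.9
    age_slope: float = 0.004  # relative trial-noise increase per year
    spacing_mm: float = 60.0


def generate_session(
    rng: np.random.Generator,
    age: float,
    sex: int,
    handedness: int,
    severity: float,
    truth: GroundTruth,
    noise_scale: float = 1.0,
    spacing_mm: float = 60.0,
) -> MatchingSession:
    """Simulate one 54-trial session at a given latent severity.

    The subject's true shift, contraction and trial-noise level are drawn
    from the trait model at this severity; the mirrored match position is
    the target contracted about the workspace centroid, shifted, plus
    isotropic trial noise; it is reflected back across the midline into the
    matching-arm frame.
    """
    targets = target_layout(spacing_mm)
    centroid = targets.mean(axis=0)
    shift, contraction, noise_sd = truth.draw_traits(rng, severity)
    noise_sd = max(0.0, noise_sd * noise_scale)

    order = np.concatenate([rng.permutation(N_TARGETS) for _ in range(N_BLOCKS)])
    block = np.repeat(np.arange(1, N_BLOCKS + 1), N_TARGETS)
    robot = targets[order]
    ideal = centroid + contraction * (robot - centroid)
    mirrored = ideal + shift + rng.normal(0, noise_sd, robot.shape)
    match = mirrored.copy()
    match[:, 0] = -match[:, 0]  # back into the matching-arm frame (midline 0)
    return MatchingSession(
        age=age,
        sex=sex,
        handedness=handedness,
        target_index=order + 1,
        block=block,
        robot_xy=robot,
        match_xy=match,
    )


def make_normative_cohort(
    seed: int,
    n_controls: int = 799,
    n_assessments: int = 2227,
    config: NormativeConfig | None = None,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Control cohort at severity 0: one row per assessment.

    Columns: ``control_id, age, sex, handedness, session`` (the
    :class:`MatchingSession` object).  Assessments beyond one per control
    are assigned to random controls, emulating repeat visits.
    """
    if n_assessments < n_controls:
        raise ConfigurationError("need at least one assessment per control")
    config = config or NormativeConfig()
    truth = truth or GroundTruth.null()
    rng = np.random.default_rng(seed)

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n_controls)
    sex = (rng.random(n_controls) < config.female_fraction).astype(int)
    hand = np.where(rng.random(n_controls) < config.right_handed_fraction, 1, -1)

    who = np.concatenate(
        [np.arange(n_controls), rng.integers(0, n_controls, n_assessments - n_controls)]
    )
    mid_age = (lo + hi) / 2.0
    rows = []
    for i in who:
        scale = 1.0 + config.age_slope * (age[i] - mid_age)
        session = generate_session(
            rng,
            float(age[i]),
            int(sex[i]),
            int(hand[i]),
            severity=0.0,
            truth=truth,
            noise_scale=max(0.05, scale),
            spacing_mm=config.spacing_mm,
        )
        rows.append(
            {
                "control_id": f"c{i:04d}",
                "age": float(age[i]),
                "sex": int(sex[i]),
                "handedness": int(hand[i]),
                "session": session,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stroke cohort


@dataclass
class StrokeCohort:
    table: pd.DataFrame  # covariates, loads, volumes, latent score, side
    lesions: dict[str, VolumeGrid]
    sessions: dict[str, MatchingSession] | None
    truth: GroundTruth


def _standardize_or_zero(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def make_stroke_cohort(
    seed: int,
    brain: SyntheticBrain,
    truth: GroundTruth,
    n: int = 203,
    right_fraction: float = 118.0 / 203.0,
    volume_mean_cc: float = 30.5,
    volume_sd_cc: float = 39.3,
    max_volume_cc: float = 120.0,
    ipsi_motor_rate: tuple[float, float] = (0.153, 0.203),
    with_sessions: bool = True,
) -> StrokeCohort:
    """Draw a stroke cohort with lesions, loads and latent impairments.

    Lesion volumes are log-normal with the cohort mean/SD of the emulated
    population (30.5 +/- 39.3 cc), truncated to what the toy hemispheres can
    host.  Family lesion load is the sum of the left and right homologue
    loads (only the ipsilesional one is ever nonzero for these unilateral
    lesions).  The latent score uses loads standardised within the cohort.
    """
    if n < 2:
        raise ConfigurationError("cohort needs n >= 2")
    unknown = set(truth.causal_tracts) - set(brain.tract_families)
    if unknown:
        raise ConfigurationError(f"causal tracts not in atlas: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    sigma2 = np.log(1.0 + (volume_sd_cc / volume_mean_cc) ** 2)
    mu = np.log(volume_mean_cc) - sigma2 / 2.0
    volumes = np.exp(rng.normal(mu, np.sqrt(sigma2), n))
    voxel_cc = brain.grid.voxel_volume_mm3 / 1000.0
    hemi_cap = 0.8 * voxel_cc * min(
        int(brain.hemisphere_mask("left").sum()),
        int(brain.hemisphere_mask("right").sum()),
    )
    volumes = np.clip(volumes, 0.5, min(max_volume_cc, hemi_cap))
    sides = np.where(rng.random(n) < right_fraction, "right", "left")
    # binary ipsilesional motor-impairment flag, side-specific base rates
    ipsi_p = np.where(sides == "right", ipsi_motor_rate[1], ipsi_motor_rate[0])
    ipsi = (rng.random(n) < ipsi_p).astype(int)
    age = np.clip(rng.normal(62.2, 14.4, n), 18.0, 95.0)
    sex = (rng.random(n) < 75.0 / 203.0).astype(int)
    hand = np.where(rng.random(n) < 0.9, 1, -1)

    lesions: dict[str, VolumeGrid] = {}
    pids = [f"p{i:03d}" for i in range(n)]
    for i, pid in enumerate(pids):
        lesions[pid] = make_lesion(
            int(rng.integers(2**31 - 1)), brain, str(sides[i]), float(volumes[i])
        )

    loads = ll.tract_load_table(lesions, brain.tract_maps, brain.gm_mask)
    families = brain.tract_families
    for fam in families:
        loads[fam] = loads[f"{fam}_left"] + loads[f"{fam}_right"]

    side01 = (sides == "right").astype(float)
    z_gm = _standardize_or_zero(loads["gm_volume_cc"].to_numpy())
    latent = truth.intercept + truth.side_effect * side01 + truth.gm_effect * z_gm
    for fam, beta in truth.causal_tracts.items():
        latent = latent + beta * _standardize_or_zero(loads[fam].to_numpy())
    latent = latent + rng.normal(0.0, truth.noise_sd, n)

    sessions: dict[str, MatchingSession] | None = None
    if with_sessions:
        sessions = {}
        for i, pid in enumerate(pids):
            sessions[pid] = generate_session(
                rng,
                float(age[i]),
                int(sex[i]),
                int(hand[i]),
                severity=float(latent[i]),
                truth=truth,
            )

    table = loads.loc[pids].copy()
    table.insert(0, "participant_id", pids)
    table["side"] = sides
    table["age"] = age
    table["sex"] = sex
    table["handedness"] = hand
    table["ipsi_motor_impaired"] = ipsi
    table["latent_score"] = latent
    table = table.set_index("participant_id", drop=False)
    return StrokeCohort(table=table, lesions=lesions, sessions=sessions, truth=truth)
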