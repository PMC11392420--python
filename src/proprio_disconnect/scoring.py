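"""Arm position matching (APM) task scoring.

The robot passively places one arm at each of nine targets (a 3x3 square,
six blocks, 54 trials); the participant mirror-matches with the other arm,
without vision.  Performance is summarised by six matching parameters:

* ``abs_error_xy`` — mean absolute mirrored position error, x and y pooled (mm)
* ``variability_xy`` — mean over the nine targets of the per-target SDs of the
  matched positions, x and y pooled (mm)
* ``shift_x``, ``shift_y`` — mean signed mirrored error (systematic shift, mm)
* ``ratio_x``, ``ratio_y`` — contraction/expansion: the span of the
  participant's mean positions between the three left-most and three
  right-most targets (proximal/distal for y), divided by the robot's span

Each parameter is standardised against a normative control cohort with a
linear age/sex/handedness model (log pre-transform for strictly positive
parameters), giving Z-scores.  One-sided parameters are folded so 0 is best:
absolute error and variability via the zeta transform
``zeta(z) = Phi^-1((Phi(z)+1)/2)``, systematic shift via ``|z|`` (the same
fold expressed on a symmetric null); the two-sided ratios stay as Z-scores.
The root-sum-square (RSS) of the six components is mapped through the
empirical normative RSS distribution (rank-based inverse normal) and
zeta-transformed into the one-sided Task Score: 0 is the best possible
performance and scores above 1.96 classify impairment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "TrialRecord",
    "MatchingSession",
    "MatchingParameters",
    "NormativeModel",
    "TaskScoreResult",
    "mirror_match",
    "compute_matching_parameters",
    "normative_fit",
    "zeta_transform",
    "task_score",
    "IMPAIRMENT_THRESHOLD",
    "PARAMETER_NAMES",
]

N_TARGETS = 9
N_BLOCKS = 6
N_TRIALS = N_TARGETS * N_BLOCKS

#: Task Scores above this are classified impaired (95th-percentile rule).
IMPAIRMENT_THRESHOLD = 1.96

PARAMETER_NAMES = (
    "abs_error_xy",
    "variability_xy",
    "shift_x",
    "shift_y",
    "ratio_x",
    "ratio_y",
)

#: per-parameter (pre-transform, component fold) conventions
DEFAULT_TRANSFORMS: dict[str, str] = {
    "abs_error_xy": "log",
    "variability_xy": "log",
    "shift_x": "identity",
    "shift_y": "identity",
    "ratio_x": "log",
    "ratio_y": "log",
}
COMPONENT_KIND: dict[str, str] = {
    "abs_error_xy": "zeta",  # one-sided: larger is worse
    "variability_xy": "zeta",
    "shift_x": "abs",  # one-sided on |z|: badness in either direction
    "shift_y": "abs",
    "ratio_x": "z",  # two-sided, left as a Z-score
    "ratio_y": "z",
}


class IncompleteSessionError(ValueError):
    """Session does not contain the full 9 targets x 6 blocks design."""


@dataclass
class TrialRecord:
    target_index: int  # 1..9
    block: int  # 1..6
    robot_xy: tuple[float, float]  # affected-arm frame, mm
    match_xy: tuple[float, float]  # matching-arm frame, mm


@dataclass
class MatchingSession:
    """One 54-trial APM assessment plus the participant covariates."""

    age: float
    sex: int  # {0, 1}
    handedness: int  # {-1, +1}
    target_index: np.ndarray  # (54,) ints 1..9
    block: np.ndarray  # (54,) ints 1..6
    robot_xy: np.ndarray  # (54, 2) mm
    match_xy: np.ndarray  # (54, 2) mm
    midline_x: float = 0.0

    def __post_init__(self) -> None:
        self.target_index = np.asarray(self.target_index, dtype=int)
        self.block = np.asarray(self.block, dtype=int)
        self.robot_xy = np.asarray(self.robot_xy, dtype=float)
        self.match_xy = np.asarray(self.match_xy, dtype=float)
        n = len(self.target_index)
        if not (
            n == N_TRIALS
            and self.block.shape == (N_TRIALS,)
            and self.robot_xy.shape == (N_TRIALS, 2)
            and self.match_xy.shape == (N_TRIALS, 2)
        ):
            raise IncompleteSessionError(
                f"expected {N_TRIALS} trials (9 targets x 6 blocks), got {n}"
            )
        counts = np.zeros((N_TARGETS, N_BLOCKS), dtype=int)
        if (
            self.target_index.min() < 1
            or self.target_index.max() > N_TARGETS
            or self.block.min() < 1
            or self.block.max() > N_BLOCKS
        ):
            raise IncompleteSessionError("target/block indices out of range")
        np.add.at(counts, (self.target_index - 1, self.block - 1), 1)
        if not np.all(counts == 1):
            raise IncompleteSessionError(
                "each target must appear exactly once in each block"
            )
        if not (
            np.all(np.isfinite(self.robot_xy)) and np.all(np.isfinite(self.match_xy))
        ):
            raise IncompleteSessionError("non-finite trial coordinates")

    @property
    def trials(self) -> list[TrialRecord]:
        return [
            TrialRecord(
                int(t), int(b), (rx, ry), (mx, my)
            )
            for t, b, (rx, ry), (mx, my) in zip(
                self.target_index, self.block, self.robot_xy, self.match_xy
            )
        ]


@dataclass
class MatchingParameters:
    abs_error_xy: float
    variability_xy: float
    shift_x: float
    shift_y: float
    ratio_x: float
    ratio_y: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


def mirror_match(match_xy, midline_x: float = 0.0):
    """Reflect matched positions across the participant midline (x only)."""
    pts = np.asarray(match_xy, dtype=float)
    out = pts.copy()
    out[..., 0] = 2.0 * midline_x - out[..., 0]
    return out


def compute_matching_parameters(session: MatchingSession) -> MatchingParameters:
    """The six matching parameters of one session.

    Sample (n-1) standard deviations are used for the per-target variability.
    """
    mirrored = mirror_match(session.match_xy, session.midline_x)
    delta = mirrored - session.robot_xy

    abs_error = float(np.mean(np.abs(delta)))  # x and y errors pooled
    shift_x, shift_y = (float(v) for v in delta.mean(axis=0))

    tgt = session.target_index - 1
    robot_means = np.zeros((N_TARGETS, 2))
    match_means = np.zeros((N_TARGETS, 2))
    sds = np.zeros((N_TARGETS, 2))
    for t in range(N_TARGETS):
        sel = tgt == t
        robot_means[t] = session.robot_xy[sel].mean(axis=0)
        match_means[t] = mirrored[sel].mean(axis=0)
        sds[t] = mirrored[sel].std(axis=0, ddof=1)
    variability = float(sds.mean())

    def span_ratio(axis: int) -> float:
        order = np.argsort(robot_means[:, axis], kind="stable")
        low, high = order[:3], order[-3:]
        robot_span = abs(
            robot_means[high, axis].mean() - robot_means[low, axis].mean()
        )
        if robot_span <= 0:
            raise ValueError("degenerate target layout: zero robot span")
        match_span = abs(
            match_means[high, axis].mean() - match_means[low, axis].mean()
        )
        return float(match_span / robot_span)

    return MatchingParameters(
        abs_error_xy=abs_error,
        variability_xy=variability,
        shift_x=shift_x,
        shift_y=shift_y,
        ratio_x=span_ratio(0),
        ratio_y=span_ratio(1),
    )


# ---------------------------------------------------------------------------
# Normative model


def zeta_transform(z):
    """Fold a Z-score so the best possible performance maps to zero.

    ``zeta(z) = Phi^-1((Phi(z) + 1) / 2)``: strictly increasing, >= 0 for
    any finite z, and half-normal distributed when z is standard normal.
    """
    z = np.asarray(z, dtype=float)
    out = ndtri((ndtr(z) + 1.0) / 2.0)
    # deep left tail: Phi(z) underflows; the fold is ~0 there
    out = np.where(np.isfinite(out), out, np.where(z < 0, 0.0, np.inf))
    return out if out.ndim else float(out)


def zeta_inverse(zeta):
    z = np.asarray(zeta, dtype=float)
    out = ndtri(2.0 * ndtr(z) - 1.0)
    return out if out.ndim else float(out)


def _design(age, sex, handedness) -> np.ndarray:
    age = np.atleast_1d(np.asarray(age, dtype=float))
    sex = np.atleast_1d(np.asarray(sex, dtype=float))
    hand = np.atleast_1d(np.asarray(handedness, dtype=float))
    return np.column_stack([np.ones_like(age), age, sex, hand])


def _pretransform(name: str, values, transforms: Mapping[str, str]):
    values = np.asarray(values, dtype=float)
    kind = transforms.get(name, "identity")
    if kind == "log":
        if np.any(values <= 0):
            raise ValueError(
                f"{name}: non-positive value under log pre-transform"
            )
        return np.log(values)
    return values


def _mid_rank_percentile(values, sample) -> np.ndarray:
    """ECDF percentile of each value in a reference sample (mid-rank, open)."""
    sample = np.sort(np.asarray(sample, dtype=float))
    values = np.atleast_1d(np.asarray(values, dtype=float))
    less = np.searchsorted(sample, values, side="left")
    leq = np.searchsorted(sample, values, side="right")
    m = len(sample)
    return (less + 0.5 * (leq - less) + 0.5) / (m + 1.0)


@dataclass
class _ParameterFit:
    transform: str
    beta: np.ndarray  # (4,) intercept, age, sex, handedness
    resid_sd: float


@dataclass
class NormativeModel:
    """Per-parameter covariate regressions plus the normative RSS sample.

    Fit on a control cohort; yields covariate-adjusted Z-scores for new
    assessments and the empirical RSS distribution the Task Score is
    standardised against.
    """

    fits: dict[str, _ParameterFit]
    rss_sample: np.ndarray
    transforms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFORMS)
    )

    def zscore(self, name: str, value, age, sex, handedness):
        """Covariate-adjusted Z-score of one parameter value."""
        fit = self.fits[name]
        y = _pretransform(name, value, {name: fit.transform})
        pred = _design(age, sex, handedness) @ fit.beta
        z = (np.atleast_1d(y) - pred) / fit.resid_sd
        return z if np.ndim(value) else float(z[0])

    def components(self, params: MatchingParameters, age, sex, handedness):
        comp = {}
        for name in PARAMETER_NAMES:
            z = self.zscore(name, getattr(params, name), age, sex, handedness)
            kind = COMPONENT_KIND[name]
            if kind == "zeta":
                comp[name] = zeta_transform(z)
            elif kind == "abs":
                comp[name] = abs(z)
            else:
                comp[name] = z
        return comp

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fits": {
                name: {
                    "transform": f.transform,
                    "beta": f.beta.tolist(),
                    "resid_sd": f.resid_sd,
                }
                for name, f in self.fits.items()
            },
            "rss_sample": self.rss_sample.tolist(),
            "transforms": self.transforms,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NormativeModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        fits = {
            name: _ParameterFit(
                d["transform"], np.asarray(d["beta"]), float(d["resid_sd"])
            )
            for name, d in payload["fits"].items()
        }
        return cls(
            fits=fits,
            rss_sample=np.asarray(payload["rss_sample"], dtype=float),
            transforms=dict(payload["transforms"]),
        )


def _rss_from_components(comp: Mapping[str, float]) -> float:
    vals = np.array([comp[name] for name in PARAMETER_NAMES], dtype=float)
    return float(np.sqrt(np.sum(vals**2)))


def normative_fit(
    sessions: Sequence[MatchingSession],
    transforms: Mapping[str, str] | None = None,
) -> NormativeModel:
    """Fit the normative model on a cohort of control assessments.

    Each of the six parameters is regressed on (1, age, sex, handedness);
    the residual SD uses the regression degrees of freedom.  Every fitting
    assessment is then pushed through the full scoring chain to build the
    empirical normative RSS sample.
    """
    if len(sessions) < 30:
        raise ValueError("normative fit requires at least 30 assessments")
    transforms = dict(DEFAULT_TRANSFORMS if transforms is None else transforms)

    params = [compute_matching_parameters(s) for s in sessions]
    age = np.array([s.age for s in sessions], dtype=float)
    sex = np.array([s.sex for s in sessions], dtype=float)
    hand = np.array([s.handedness for s in sessions], dtype=float)
    for cov, label in ((age, "age"), (sex, "sex"), (hand, "handedness")):
        if np.ptp(cov) == 0:
            raise ValueError(f"degenerate normative design: constant {label}")

    X = _design(age, sex, hand)
    n, k = X.shape
    fits: dict[str, _ParameterFit] = {}
    for name in PARAMETER_NAMES:
        y = _pretransform(
            name, [getattr(p, name) for p in params], transforms
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = float(np.sqrt(np.sum(resid**2) / (n - k)))
        if sd <= 0:
            raise ValueError(f"degenerate normative fit: zero residual SD for {name}")
        fits[name] = _ParameterFit(transforms.get(name, "identity"), beta, sd)

    model = NormativeModel(fits=fits, rss_sample=np.empty(0), transforms=transforms)
    rss = np.array(
        [
            _rss_from_components(model.components(p, s.age, s.sex, s.handedness))
            for p, s in zip(params, sessions)
        ]
    )
    model.rss_sample = rss
    return model


@dataclass
class TaskScoreResult:
    components: dict[str, float]
    rss: float
    task_score: float
    impaired: bool


def task_score(session: MatchingSession, model: NormativeModel) -> TaskScoreResult:
    """The one-sided APM Task Score of a session under a fitted model.

    The parameter components' RSS is located in the empirical normative RSS
    distribution (mid-rank ECDF), mapped through the inverse normal CDF and
    zeta-transformed, so held-out control scores share the percentiles of a
    normal distribution and ~5% exceed the 1.96 impairment cut.
    """
    params = compute_matching_parameters(session)
    comp = model.components(params, session.age, session.sex, session.handedness)
    rss = _rss_from_components(comp)
    p = _mid_rank_percentile(rss, model.rss_sample)[0]
    score = float(zeta_transform(ndtri(p)))
    return TaskScoreResult(
        components=comp,
        rss=rss,
        task_score=score,
        impaired=bool(score > IMPAIRMENT_THRESHOLD),
    )


def score_sessions(
    sessions: Iterable[MatchingSession], model: NormativeModel
) -> list[TaskScoreResult]:
    return [task_score(s, model) for s in sessions]


# ---------------------------------------------------------------------------
# Tabular IO: one row per trial, covariates in a separate table


def sessions_to_trials(sessions: Mapping[str, MatchingSession]):
    """Long trial table: participant_id, target, block, robot/match x/y."""
    import pandas as pd

    rows = []
    for pid, s in sessions.items():
        for t, b, (rx, ry), (mx, my) in zip(
            s.target_index, s.block, s.robot_xy, s.match_xy
        ):
            rows.append(
                {
                    "participant_id": pid,
                    "target": int(t),
                    "block": int(b),
                    "robot_x": rx,
                    "robot_y": ry,
                    "match_x": mx,
                    "match_y": my,
                }
            )
    return pd.DataFrame(rows)


def sessions_from_trials(trials, covariates) -> dict[str, MatchingSession]:
    """Rebuild sessions from a trial table plus a covariate table.

    ``covariates`` must be indexed by participant_id with columns
    age, sex, handedness.
    """
    out: dict[str, MatchingSession] = {}
    for pid, grp in trials.groupby("participant_id", sort=False):
        cov = covariates.loc[pid]
        out[str(pid)] = MatchingSession(
            age=float(cov["age"]),
            sex=int(cov["sex"]),
            handedness=int(cov["handedness"]),
            target_index=grp["target"].to_numpy(),
            block=grp["block"].to_numpy(),
            robot_xy=grp[["robot_x", "robot_y"]].to_numpy(),
            match_xy=grp[["match_x", "match_y"]].to_numpy(),
        )
    return out
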