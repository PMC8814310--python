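"""Trial isolation: motion-probability classification + constrained change points.

Each movement recording holds three trials separated by rests.  Segmentation
proceeds in two stages, mirroring a semi-supervised bootstrap:

1. A random-forest classifier (40 trees), trained on the labelled fraction
   of the cohort (ground-truth labels for synthetic data, standing in for
   manual annotation), maps the per-timestep feature vector
   (‖a_left‖, ‖a_right‖, θ_E_left, θ_E_right) to a motion probability
   p_motion(t) ∈ [0, 1].
2. An exact dynamic program cuts p_motion(t) into exactly 7 segments
   (rest/motion alternating, starting and ending at rest), minimising the
   within-segment squared deviation from the segment mean subject to every
   segment lasting more than 1 s and less than 20 s.

Each motion segment is then split into ascending and lowering phases at the
mid-elevation timestep: the candidate minimising a local mirror-symmetry
loss of the elevation angles,

    L_sym^s(t) = (1/w) Σ_{i=1..w} (θ_E^s(t−i) − θ_E^s(t+i))²,

with the left/right sides fused by root-sum-of-squares (window w = 100
timesteps by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import (
    DegenerateTrainingError,
    InfeasibleSegmentationError,
    InvalidArgumentError,
)

DEFAULT_WINDOW = 100  # symmetry-loss half-window, timesteps
N_ESTIMATORS = 40


@dataclass
class MotionProbability:
    """Per-timestep probability of being a motion sample."""

    p: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise InvalidArgumentError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class SegmentationResult:
    """7 alternating rest/motion segments plus per-trial mid-elevation."""

    fs: float
    n_samples: int
    boundaries: list  # 6 interior change-points, sample indices
    labels: list = field(
        default_factory=lambda: ["rest", "motion"] * 3 + ["rest"]
    )
    midpoints: list | None = None  # one per motion segment (None: not computed)
    sym_loss: dict = field(default_factory=dict)  # trial -> (candidates, losses)

    def __post_init__(self) -> None:
        b = list(self.boundaries)
        if len(b) != len(self.labels) - 1:
            raise InvalidArgumentError("boundaries/labels length mismatch")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise InvalidArgumentError("boundaries must be strictly increasing")
        if self.labels[0] != "rest" or self.labels[-1] != "rest":
            raise InvalidArgumentError("first and last segments must be rest")
        if any(
            self.labels[i] == self.labels[i + 1] for i in range(len(self.labels) - 1)
        ):
            raise InvalidArgumentError("labels must strictly alternate")

    def segments(self) -> list:
        edges = [0, *self.boundaries, self.n_samples]
        return [(edges[i], edges[i + 1]) for i in range(len(self.labels))]

    def motion_segments(self) -> list:
        return [s for s, l in zip(self.segments(), self.labels) if l == "motion"]


def extract_features(kin_left, kin_right) -> np.ndarray:
    """Stack the classifier features: (‖a_left‖, ‖a_right‖, θ_E_left, θ_E_right)."""
    if len(kin_left) != len(kin_right):
        raise InvalidArgumentError("left/right kinematic series differ in length")
    return np.column_stack(
        [kin_left.accel_norm, kin_right.accel_norm, kin_left.theta_E, kin_right.theta_E]
    )


def train_motion_classifier(
    features, labels, n_estimators: int = N_ESTIMATORS, rng_seed: int = 0
):
    """Fit the motion/rest random forest; returns (classifier, train accuracy)."""
    X = np.vstack(features)
    y = np.concatenate([np.asarray(l, dtype=int) for l in labels])
    if len(X) != len(y):
        raise InvalidArgumentError("features and labels are not aligned")
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=rng_seed, n_jobs=1
    )
    clf.fit(X, y)
    return clf, float(clf.score(X, y))


def predict_motion_probability(clf, features, fs: float) -> MotionProbability:
    """Per-timestep motion probability from a fitted classifier."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != clf.n_features_in_:
        raise InvalidArgumentError(
            f"classifier expects {clf.n_features_in_} features, got {features.shape}"
        )
    idx = int(np.flatnonzero(clf.classes_ == 1)[0])
    return MotionProbability(p=clf.predict_proba(features)[:, idx], fs=fs)


def smooth_probability(p: np.ndarray, fs: float, window_s: float = 0.2) -> np.ndarray:
    """Moving-average smoothing to suppress single-step classifier flicker."""
    win = max(1, int(round(window_s * fs)))
    if win % 2 == 0:
        win += 1
    kernel = np.ones(win) / win
    padded = np.pad(np.asarray(p, dtype=float), win // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def segment_alternating(
    p,
    fs: float | None = None,
    n_segments: int = 7,
    min_dur_s: float = 1.0,
    max_dur_s: float = 20.0,
    smooth_s: float = 0.2,
) -> SegmentationResult:
    """Globally optimal alternating segmentation of a motion-probability series.

    Minimises the total within-segment squared deviation from the segment
    mean over all placements of ``n_segments − 1`` interior change points
    such that every segment duration d satisfies min_dur_s < d < max_dur_s.
    Labels alternate rest/motion starting and ending with rest.

    Raises
    ------
    InfeasibleSegmentationError
        If no boundary placement satisfies the duration constraints.
    """
    if isinstance(p, MotionProbability):
        fs = p.fs
        p = p.p
    if fs is None:
        raise InvalidArgumentError("fs is required when p is a bare array")
    p = np.asarray(p, dtype=float)
    if smooth_s > 0:
        p = smooth_probability(p, fs, smooth_s)
    T = len(p)
    K = n_segments
    min_len = int(math.floor(min_dur_s * fs)) + 1  # strictly more than min_dur_s
    max_len = int(math.ceil(max_dur_s * fs)) - 1  # strictly less than max_dur_s
    if K * min_len > T or K * max_len < T:
        raise InfeasibleSegmentationError(
            f"{T} samples cannot be split into {K} segments of "
            f"({min_dur_s}, {max_dur_s}) s at fs={fs}"
        )

    c1 = np.concatenate([[0.0], np.cumsum(p)])
    c2 = np.concatenate([[0.0], np.cumsum(p * p)])

    def seg_cost(s: np.ndarray, t: int) -> np.ndarray:
        n = t - s
        mean_term = (c1[t] - c1[s]) ** 2 / n
        return (c2[t] - c2[s]) - mean_term

    inf = np.inf
    D = np.full((K + 1, T + 1), inf)
    arg = np.zeros((K + 1, T + 1), dtype=int)
    D[0, 0] = 0.0
    for k in range(1, K + 1):
        lo = max(k * min_len, T - (K - k) * max_len)
        hi = min(k * max_len, T - (K - k) * min_len)
        for t in range(lo, hi + 1):
            s_lo = max(t - max_len, (k - 1) * min_len if k > 1 else 0)
            s_hi = t - min_len
            if s_hi < s_lo:
                continue
            s = np.arange(s_lo, s_hi + 1)
            prev = D[k - 1, s]
            feasible = np.isfinite(prev)
            if not feasible.any():
                continue
            vals = prev + seg_cost(s, t)
            i = int(np.argmin(vals))
            D[k, t] = vals[i]
            arg[k, t] = s[i]
    if not np.isfinite(D[K, T]):
        raise InfeasibleSegmentationError("no feasible segmentation found")

    cuts = []
    t = T
    for k in range(K, 0, -1):
        t = int(arg[k, t])
        cuts.append(t)
    boundaries = sorted(cuts)[1:]  # drop the leading 0
    labels = [("rest" if i % 2 == 0 else "motion") for i in range(K)]
    return SegmentationResult(
        fs=fs, n_samples=T, boundaries=boundaries, labels=labels
    )


def symmetry_loss(
    theta_E_left: np.ndarray,
    theta_E_right: np.ndarray,
    t: int,
    w: int = DEFAULT_WINDOW,
    combine: str = "rss",
) -> float:
    """Combined local mirror-symmetry loss of the elevation angles at t."""
    tl = np.asarray(theta_E_left, dtype=float)
    tr = np.asarray(theta_E_right, dtype=float)
    if t - w < 0 or t + w >= len(tl):
        raise InvalidArgumentError("symmetry window exceeds the series")
    losses = []
    for th in (tl, tr):
        before = th[t - w : t][::-1]  # θ(t−1) … θ(t−w) reversed to θ(t−i)
        after = th[t + 1 : t + w + 1]
        losses.append(float(np.mean((before - after) ** 2)))
    l_left, l_right = losses
    if combine == "rss":
        return math.hypot(l_left, l_right)
    if combine == "sum":
        return l_left + l_right
    raise InvalidArgumentError(f"unknown combine rule {combine!r}")


def _symmetry_loss_curve(
    theta_left: np.ndarray,
    theta_right: np.ndarray,
    candidates: np.ndarray,
    w: int,
    combine: str,
) -> np.ndarray:
    per_side = []
    for th in (theta_left, theta_right):
        acc = np.zeros(len(candidates))
        for i in range(1, w + 1):
            d = th[candidates - i] - th[candidates + i]
            acc += d * d
        per_side.append(acc / w)
    if combine == "rss":
        return np.hypot(per_side[0], per_side[1])
    return per_side[0] + per_side[1]


def find_mid_elevation(
    theta_E_left: np.ndarray,
    theta_E_right: np.ndarray,
    segment: tuple[int, int],
    w: int = DEFAULT_WINDOW,
    combine: str = "rss",
    return_curve: bool = False,
):
    """Mid-elevation timestep of a motion segment [start, end).

    Minimises the combined symmetry loss over candidates
    [start + w, end − 1 − w]; exact-loss ties break toward the segment's
    temporal centre, then toward the earlier candidate.
    """
    start, end = segment
    tl = np.asarray(theta_E_left, dtype=float)
    tr = np.asarray(theta_E_right, dtype=float)
    candidates = np.arange(start + w, end - w)
    if len(candidates) == 0:
        raise InvalidArgumentError(
            f"segment of {end - start} samples too short for window w={w}"
        )
    losses = _symmetry_loss_curve(tl, tr, candidates, w, combine)
    m = losses.min()
    ties = candidates[losses == m]
    centre = (start + end - 1) / 2.0
    dist = np.abs(ties - centre)
    best = ties[dist == dist.min()].min()
    if return_curve:
        return int(best), (candidates, losses)
    return int(best)


def bootstrap_manual_labels(recordings, fraction: float = 0.2, rng_seed: int = 0):
    """Deterministically select the subset of recordings to be hand-labelled.

    Emulates the manual-annotation bootstrap: ceil(fraction × N) recordings
    are drawn without replacement; for synthetic data their ground-truth
    labels stand in for manual labels.  Returns sorted indices.
    """
    n = len(recordings)
    if n < 5:
        raise InvalidArgumentError("need at least 5 recordings for a 20% subset")
    n_sel = int(math.ceil(fraction * n))
    rng = np.random.default_rng(rng_seed)
    return sorted(rng.choice(n, size=n_sel, replace=False).tolist())


def segment_movement(
    p: MotionProbability,
    kin_left,
    kin_right,
    functional: bool = False,
    w: int = DEFAULT_WINDOW,
    combine: str = "rss",
    **segment_kwargs,
) -> SegmentationResult:
    """Segment one movement and locate mid-elevation timesteps per trial."""
    result = segment_alternating(p, **segment_kwargs)
    if functional:
        result.midpoints = [None] * len(result.motion_segments())
        return result
    midpoints, curves = [], {}
    for trial, seg in enumerate(result.motion_segments(), 1):
        mid, curve = find_mid_elevation(
            kin_left.theta_E, kin_right.theta_E, seg, w=w, combine=combine,
            return_curve=True,
        )
        midpoints.append(mid)
        curves[trial] = curve
    result.midpoints = midpoints
    result.sym_loss = curves
    return result
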