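"""Design-based validation machinery.

Implements the stratified estimators of good-practice map accuracy and area
assessment: cell proportions estimated from an error matrix with map-class
stratum weights, user's / producer's / overall accuracies with standard
errors, and bias-corrected (reference-based) class area estimates with 95%
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ErrorMatrix:
    """Stratified reference-vs-map counts.

    ``counts[i, j]`` is the number of sample units mapped as stratum ``i``
    and reference-labeled as class ``j``; ``weights[i]`` is the stratum's
    share of the mapped region area (sums to 1).
    """

    counts: np.ndarray
    weights: np.ndarray
    class_names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.weights.shape != (self.counts.shape[0],):
            raise ValueError("one weight per map stratum required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("stratum weights must sum to 1")
        if self.class_names is None:
            self.class_names = [f"class_{i}" for i in range(self.counts.shape[0])]

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.counts, index=self.class_names, columns=self.class_names
        )
        frame.insert(0, "weight", self.weights)
        return frame

    @classmethod
    def from_csv(cls, path) -> "ErrorMatrix":
        frame = pd.read_csv(path, index_col=0)
        weights = frame.pop("weight").to_numpy()
        return cls(frame.to_numpy(), weights, class_names=list(frame.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def estimated_proportions(m: ErrorMatrix) -> np.ndarray:
    """Unbiased cell proportions p_ij = W_i * n_ij / n_i (sum to 1)."""
    n_i = m.row_totals
    if np.any(n_i == 0):
        raise ValueError("every stratum needs at least one sample")
    return m.weights[:, None] * m.counts / n_i[:, None]


@dataclass
class AccuracyResult:
    overall: float
    overall_se: float
    users: np.ndarray
    users_se: np.ndarray
    producers: np.ndarray
    producers_se: np.ndarray
    z: float = 1.96

    def ci(self, value, se):
        return value - self.z * se, value + self.z * se


def accuracies(m: ErrorMatrix, z: float = 1.96) -> AccuracyResult:
    """Overall, user's and producer's accuracies with standard errors.

    Variances follow the stratified good-practice estimators; the producer's
    accuracy variance uses the mapped-area weights in place of pixel totals
    (the expression is scale invariant).
    """
    p = estimated_proportions(m)
    n_i = m.row_totals
    W = m.weights
    k = m.n_classes

    overall = float(np.trace(p))
    users = np.diag(p) / p.sum(axis=1)
    col = p.sum(axis=0)
    if np.any(col == 0):
        raise ValueError("a reference class received no samples")
    producers = np.diag(p) / col

    var_oa = np.sum(W**2 * users * (1 - users) / np.maximum(n_i - 1, 1))
    var_ua = users * (1 - users) / np.maximum(n_i - 1, 1)

    var_pa = np.zeros(k)
    # N_j_hat expressed in area-weight units
    nj_hat = np.array([np.sum(W * m.counts[:, j] / n_i) for j in range(k)])
    for j in range(k):
        term1 = (
            W[j] ** 2
            * (1 - producers[j]) ** 2
            * users[j]
            * (1 - users[j])
            / max(n_i[j] - 1, 1)
        )
        term2 = 0.0
        for i in range(k):
            if i == j:
                continue
            pij = m.counts[i, j] / n_i[i]
            term2 += W[i] ** 2 * pij * (1 - pij) / max(n_i[i] - 1, 1)
        var_pa[j] = (term1 + producers[j] ** 2 * term2) / nj_hat[j] ** 2

    return AccuracyResult(
        overall=overall,
        overall_se=float(np.sqrt(var_oa)),
        users=users,
        users_se=np.sqrt(var_ua),
        producers=producers,
        producers_se=np.sqrt(var_pa),
        z=z,
    )


@dataclass
class AreaEstimate:
    areas: np.ndarray        # bias-corrected area per reference class
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    mapped: np.ndarray       # mapped (pixel-count) areas per class
    bias_pct: np.ndarray     # (corrected - mapped) / corrected * 100


def corrected_area(m: ErrorMatrix, region_area: float, z: float = 1.96) -> AreaEstimate:
    """Bias-corrected class areas with 95% confidence intervals.

    A_j = A * sum_i W_i n_ij / n_i;
    SE(A_j) = A * sqrt(sum_i W_i^2 (n_ij/n_i)(1 - n_ij/n_i) / (n_i - 1)).
    """
    n_i = m.row_totals
    if np.any(n_i < 2):
        raise ValueError("every stratum needs n_i >= 2 for variance estimation")
    props = m.counts / n_i[:, None]
    areas = region_area * np.sum(m.weights[:, None] * props, axis=0)
    var = np.sum(
        (m.weights[:, None] ** 2) * props * (1 - props) / (n_i[:, None] - 1), axis=0
    )
    se = region_area * np.sqrt(var)
    mapped = region_area * m.weights
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = np.where(areas > 0, (areas - mapped) / areas * 100.0, 0.0)
    return AreaEstimate(
        areas=areas,
        se=se,
        ci_low=areas - z * se,
        ci_high=areas + z * se,
        mapped=mapped,
        bias_pct=bias,
    )


@dataclass
class StratifiedSample:
    """Sample plots drawn by stratified systematic sampling."""

    plots: pd.DataFrame        # stratum, row, col (plot centers), order index
    allocations: dict[int, int]
    seed: int


def design_sample(
    strata: np.ndarray,
    n_total: int,
    seed: int,
    min_per_stratum: int = 2,
) -> StratifiedSample:
    """Allocate and place sample plots over a stratum raster.

    Allocation is proportional to stratum pixel counts with a floor of
    ``min_per_stratum``; within each stratum, plots follow a systematic
    sequence along the stratum's pixels (row-major) with a seeded random
    start.  Plot centers are pixel coordinates of 3x3-pixel blocks.
    """
    strata = np.asarray(strata)
    ids, counts = np.unique(strata, return_counts=True)
    keep = ids > 0
    ids, counts = ids[keep], counts[keep]
    if n_total < min_per_stratum * len(ids):
        raise ValueError("n_total too small for the per-stratum floor")
    weights = counts / counts.sum()
    alloc = np.maximum(np.floor(weights * n_total).astype(int), min_per_stratum)
    # distribute the remainder by largest fractional part
    while alloc.sum() < n_total:
        frac = weights * n_total - alloc
        alloc[np.argmax(frac)] += 1
    while alloc.sum() > n_total:
        over = alloc > min_per_stratum
        frac = np.where(over, weights * n_total - alloc, -np.inf)
        alloc[np.argmax(frac)] -= 1
    alloc = np.minimum(alloc, counts)

    rng = np.random.default_rng(seed)
    rows_out = []
    for sid, n_s, count in zip(ids.tolist(), alloc.tolist(), counts.tolist()):
        rr, cc = np.nonzero(strata == sid)
        step = count / n_s
        offset = rng.random() * step
        picks = (offset + step * np.arange(n_s)).astype(int)
        picks = np.clip(picks, 0, count - 1)
        for k, p in enumerate(picks):
            rows_out.append(
                {
                    "stratum": int(sid),
                    "row": int(rr[p]),
                    "col": int(cc[p]),
                    "grid_index": k,
                }
            )
    plots = pd.DataFrame(rows_out)
    return StratifiedSample(
        plots=plots,
        allocations=dict(zip(ids.tolist(), alloc.tolist())),
        seed=seed,
    )


def plot_reference_label(block: np.ndarray, disturbed_codes: Sequence[int]) -> int:
    """Reduce a 3x3 block of reference pixel labels to one plot label.

    Majority vote over the 9 pixels; ties resolve to the disturbed class.
    """
    vals, counts = np.unique(np.asarray(block).ravel(), return_counts=True)
    best = counts.max()
    winners = vals[counts == best]
    if len(winners) > 1:
        for w in winners:
            if int(w) in set(int(d) for d in disturbed_codes):
                return int(w)
    return int(winners[0])
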