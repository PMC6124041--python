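"""Descriptive summaries and circular statistics for mobility profiles.

Per-joint maximal angles form one sample per trial x profile group (e.g.
PCVM-lateral).  Descriptive rows (n, mean, s.d., min, max, sum) use ordinary
arithmetic on degrees -- intervertebral angles are small, and the summed
column then equals total neck mobility, ``sum = n * mean``.  Hypothesis
testing treats each angle as a direction: the Watson-Williams F-type test
for equality of mean directions is applied to the radian view, with the
standard concentration-based correction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SampleError, StatTestError

__all__ = [
    "AngleSample",
    "SummaryRow",
    "WWResult",
    "summarize",
    "watson_williams",
    "compare_all",
    "samples_from_table",
]


@dataclass
class AngleSample:
    """A labelled group of per-joint angles in degrees."""

    label: str
    angles_deg: np.ndarray
    joints: list[str] | None = None

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.angles_deg = self.angles_deg[~np.isnan(self.angles_deg)]

    @property
    def radians(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)

    @property
    def n(self) -> int:
        return len(self.angles_deg)


@dataclass
class SummaryRow:
    """Descriptive row: n, mean, s.d. (sample), min, max, sum (degrees)."""

    label: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    sum: float


@dataclass
class WWResult:
    """Watson-Williams test output for k groups of directions."""

    F: float
    df: tuple[int, int]
    p_value: float
    K: float
    kappa: float
    group_means_deg: dict[str, float]
    group_R: dict[str, float]
    pooled_R: float
    low_concentration: bool
    unequal_concentration: bool
    labels: tuple[str, ...] = field(default_factory=tuple)


def summarize(sample: AngleSample) -> SummaryRow:
    """Descriptive statistics of one group (arithmetic, on degrees)."""
    if sample.n == 0:
        raise SampleError(f"{sample.label}: empty angle sample")
    a = sample.angles_deg
    sd = float(np.std(a, ddof=1)) if sample.n > 1 else 0.0
    return SummaryRow(
        label=sample.label,
        n=sample.n,
        mean=float(np.mean(a)),
        sd=sd,
        min=float(np.min(a)),
        max=float(np.max(a)),
        sum=float(np.sum(a)),
    )


def summary_table(samples: list[AngleSample]) -> pd.DataFrame:
    """Trial-summary table: one column per group, rows n/mean/s.d./min/max/sum."""
    rows = [summarize(s) for s in samples]
    data = {
        r.label: [r.n, r.mean, r.sd, r.min, r.max, r.sum] for r in rows
    }
    return pd.DataFrame(data, index=["n", "mean", "s.d.", "min.", "max.", "sum"])


def _kappa_from_rbar(rbar: float) -> float:
    """Maximum-likelihood-style inversion of the mean resultant length."""
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    denom = rbar**3 - 4 * rbar**2 + 3 * rbar
    if denom <= 0.0:  # zero dispersion (rbar -> 1)
        return np.inf
    return 1.0 / denom


def _resultant(theta: np.ndarray) -> tuple[float, float]:
    """Resultant length R and mean direction (radians) of a direction sample."""
    c, s = np.cos(theta).sum(), np.sin(theta).sum()
    return float(np.hypot(c, s)), float(np.arctan2(s, c))


def watson_williams(groups: list[AngleSample]) -> WWResult:
    """Watson-Williams test that k groups share a mean direction.

    Uses the classical construction: per-group resultant lengths ``R_i``,
    pooled resultant ``R``, statistic

        ``F = K * (N - k) * (sum R_i - R) / ((k - 1) * (N - sum R_i))``

    with correction factor ``K = 1 + 3 / (8 kappa)``, ``kappa`` estimated
    from the weighted mean resultant length, and a p-value from the
    F(k-1, N-k) distribution.  The test assumes von Mises samples with a
    common, reasonably large concentration; flags are set when the pooled
    mean resultant length is low (< 0.45) or the per-group resultant lengths
    are widely unequal.
    """
    if len(groups) < 2:
        raise StatTestError("Watson-Williams needs at least two groups")
    for g in groups:
        if g.n < 2:
            raise StatTestError(f"group {g.label!r} needs n >= 2")
    k = len(groups)
    n_i = np.array([g.n for g in groups])
    N = int(n_i.sum())

    R_i = []
    means = {}
    rbars = []
    for g in groups:
        R, mu = _resultant(g.radians)
        R_i.append(R)
        means[g.label] = float(np.degrees(mu))
        rbars.append(R / g.n)
    R_i = np.array(R_i)
    all_theta = np.concatenate([g.radians for g in groups])
    R_pooled, _ = _resultant(all_theta)

    rbar_w = float(R_i.sum() / N)
    kappa = _kappa_from_rbar(rbar_w)
    if np.isinf(kappa):
        K = 1.0
    elif kappa > 0:
        K = 1 + 3 / (8 * kappa)
    else:
        K = np.inf

    num = (N - k) * (R_i.sum() - R_pooled)
    den = (k - 1) * (N - R_i.sum())
    F = float(K * num / den) if den > 0 else np.inf
    F = max(F, 0.0)
    p = float(sps.f.sf(F, k - 1, N - k))

    return WWResult(
        F=F,
        df=(k - 1, N - k),
        p_value=p,
        K=float(K),
        kappa=float(kappa),
        group_means_deg=means,
        group_R={g.label: float(r) for g, r in zip(groups, R_i)},
        pooled_R=float(R_pooled),
        low_concentration=rbar_w < 0.45,
        unequal_concentration=bool(max(rbars) > 2 * min(rbars)),
        labels=tuple(g.label for g in groups),
    )


def samples_from_table(df: pd.DataFrame) -> list[AngleSample]:
    """Group an angle table (``joint,profile,trial,angle_deg``) into samples.

    Group labels follow the trial-profile naming convention used in the
    summary tables, e.g. ``PCVMLat``, ``MISMDors``.
    """
    short = {"lateral": "Lat", "dorsal": "Dors", "ventral": "Vent"}
    samples = []
    for (trial, profile), sub in df.groupby(["trial", "profile"], sort=False):
        label = f"{trial}{short.get(str(profile), str(profile).capitalize())}"
        samples.append(
            AngleSample(
                label=label,
                angles_deg=sub["angle_deg"].to_numpy(),
                joints=list(sub["joint"]),
            )
        )
    return samples


def compare_all(
    samples: list[AngleSample], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[tuple[str, str], WWResult]]:
    """Pairwise Watson-Williams tests between all groups.

    Returns an upper-triangular matrix of p-values (rows/columns in group
    order; significant cells, p <= alpha, are marked with ``*`` in the
    companion string formatting) plus the full per-pair results.
    """
    if len(samples) < 2:
        raise StatTestError("need at least two groups to compare")
    labels = [s.label for s in samples]
    mat = pd.DataFrame(np.nan, index=labels[:-1], columns=labels[1:], dtype=float)
    results: dict[tuple[str, str], WWResult] = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            res = watson_williams([a, b])
            results[(a.label, b.label)] = res
            mat.loc[a.label, b.label] = res.p_value
    return mat, results


def significance_marks(mat: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """String view of a p-value matrix with ``*`` marking p <= alpha."""

    def fmt(p: float) -> str:
        if np.isnan(p):
            return ""
        mark = "*" if p <= alpha else ""
        return f"{p:.4g}{mark}"

    return mat.map(fmt)
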