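"""Nonparametric condition comparisons (Brunner-Munzel throughout).

The Brunner-Munzel test compares two samples through the stochastic
superiority p_hat = P(X < Y) + 0.5 P(X = Y), estimated from pooled
midranks; its statistic is asymptotically t-distributed with Satterthwaite
degrees of freedom and is robust to unequal variances and ties.  It is
applied to island sizes and focus appearance frequencies across treatment
conditions, and to per-island observed-vs-simulated regional focus shares
for the spatial-bias analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    p_hat: float  # estimated P(X < Y) + 0.5 P(X = Y)
    n_x: int
    n_y: int
    significance_label: str


def significance_label(p: float) -> str:
    """Ladder used in the figure legends: ***/**/* at 0.001/0.01/0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "N.S."


def brunner_munzel(x, y) -> TestResult:
    """Two-sided Brunner-Munzel test of P(X < Y) + 0.5 P(X = Y) = 1/2.

    Uses pooled and within-sample midranks; the statistic is referred to a
    t distribution with Satterthwaite degrees of freedom.  Raises on n < 2
    or when both samples are a single shared constant (zero variance).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least 2 observations")
    n = nx + ny
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx, ry = ranks[:nx], ranks[nx:]
    rx_in = sps.rankdata(x)
    ry_in = sps.rankdata(y)
    mx, my = rx.mean(), ry.mean()
    p_hat = (my - (ny + 1) / 2.0) / nx

    sx2 = np.sum((rx - rx_in - mx + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - ry_in - my + (ny + 1) / 2.0) ** 2) / (ny - 1)
    pooled = nx * sx2 + ny * sy2
    if pooled == 0:
        if mx == my:
            # fully tied samples carry no ordering information
            raise ValueError("DEGENERATE_SAMPLES: zero pooled rank variance")
        # complete separation: the t approximation breaks down; report the
        # exact two-sided permutation floor for the rank ordering instead
        logger.warning("completely separated samples; using permutation floor p")
        p = min(1.0, 2.0 / math.comb(nx + ny, nx))
        stat = math.inf if my > mx else -math.inf
        return TestResult(stat, float("nan"), p, float(p_hat), nx, ny,
                          significance_label(p))
    stat = nx * ny * (my - mx) / (n * math.sqrt(pooled))
    df = pooled**2 / (((nx * sx2) ** 2) / (nx - 1) + ((ny * sy2) ** 2) / (ny - 1))
    p = 2.0 * sps.t.sf(abs(stat), df)
    p = min(p, 1.0)
    return TestResult(float(stat), float(df), float(p), float(p_hat), nx, ny,
                      significance_label(p))


def compare_conditions(
    records: pd.DataFrame,
    measure: str,
    group_cols: tuple[str, ...] = ("antibody", "treatment_hours"),
    compare_col: str = "inhibitor",
) -> pd.DataFrame:
    """Pairwise Brunner-Munzel tests of a per-island measure across
    conditions.

    Within each combination of ``group_cols`` (e.g. antibody x treatment
    time), every pair of ``compare_col`` levels (e.g. aphidicolin vs
    roscovitine) is tested, each island contributing one value.  Groups
    with fewer than 2 islands are skipped with a log message.  Returns one
    row per comparison with medians, quartiles (25/75%), whiskers (5/95%)
    and the test result.
    """
    if measure not in records.columns:
        raise ValueError(f"measure column '{measure}' missing")
    rows = []
    for key, grp in records.groupby(list(group_cols), sort=True):
        levels = sorted(grp[compare_col].unique())
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                gx = grp.loc[grp[compare_col] == levels[i], measure].to_numpy()
                gy = grp.loc[grp[compare_col] == levels[j], measure].to_numpy()
                if len(gx) < 2 or len(gy) < 2:
                    logger.warning(
                        "skipping %s %s vs %s: fewer than 2 islands", key,
                        levels[i], levels[j]
                    )
                    continue
                res = brunner_munzel(gx, gy)
                row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
                row.update(
                    measure=measure,
                    group_x=levels[i],
                    group_y=levels[j],
                    n_x=res.n_x,
                    n_y=res.n_y,
                    median_x=float(np.median(gx)),
                    median_y=float(np.median(gy)),
                    q25_x=float(np.percentile(gx, 25)),
                    q75_x=float(np.percentile(gx, 75)),
                    q25_y=float(np.percentile(gy, 25)),
                    q75_y=float(np.percentile(gy, 75)),
                    w05_x=float(np.percentile(gx, 5)),
                    w95_x=float(np.percentile(gx, 95)),
                    w05_y=float(np.percentile(gy, 5)),
                    w95_y=float(np.percentile(gy, 95)),
                    statistic=res.statistic,
                    df=res.df,
                    p_value=res.p_value,
                    p_hat=res.p_hat,
                    label=res.significance_label,
                )
                rows.append(row)
    return pd.DataFrame(rows)


def regional_shares(
    counts_per_island: list[np.ndarray], n_proximal_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-island (proximal share, total) from per-bin focus counts.

    ``counts_per_island`` may hold observed integer counts or simulated
    mean counts; the share is count-in-proximal-bins / total count.
    Islands with zero total are returned with share = nan.
    """
    shares = np.empty(len(counts_per_island))
    totals = np.empty(len(counts_per_island))
    for i, c in enumerate(counts_per_island):
        tot = float(np.sum(c))
        totals[i] = tot
        shares[i] = float(np.sum(c[:n_proximal_bins])) / tot if tot > 0 else np.nan
    return shares, totals


def compare_profiles(
    observed_counts: list[np.ndarray],
    simulated_counts: list[np.ndarray],
    n_proximal_bins: int,
) -> dict[str, TestResult]:
    """Observed-vs-simulated regional comparison, islands as units.

    For each region, every island contributes its share of foci falling in
    that region (observed: detected counts; simulated: CSR mean counts);
    the two per-island samples are compared with the Brunner-Munzel test.
    Islands with zero total foci are excluded (logged).  Note the two
    regional shares are complementary per island, so the proximal and
    distal tests mirror each other (same p, opposite sign).
    """
    if len(observed_counts) != len(simulated_counts):
        raise ValueError("need paired observed/simulated islands")
    obs_share, obs_tot = regional_shares(observed_counts, n_proximal_bins)
    sim_share, sim_tot = regional_shares(simulated_counts, n_proximal_bins)
    keep = (obs_tot > 0) & (sim_tot > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("excluding %d islands with zero total foci", n_drop)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 islands with foci; cannot test")
    out = {}
    for region in ("proximal", "distal"):
        if region == "proximal":
            o, s = obs_share[keep], sim_share[keep]
        else:
            o, s = 1.0 - obs_share[keep], 1.0 - sim_share[keep]
        out[region] = brunner_munzel(s, o)  # p_hat = P(sim < obs) + ties/2
    return out
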