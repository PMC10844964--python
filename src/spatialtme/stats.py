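"""Group comparisons, correlation screening, and distance-band survival tests.

Small-sample paths use exact enumeration (rank-sum permutation null,
Spearman permutation p); larger samples use the standard normal/t
approximations with tie corrections.  Survival splits are compared by
product-limit Kaplan-Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_tables import SurvivalRecord
from .spatial import DistanceProfile

__all__ = [
    "GroupComparison",
    "SurvivalSplit",
    "wilcoxon_rank_sum",
    "spearman",
    "spearman_screen",
    "median_split",
    "threshold_split",
    "km_curve",
    "logrank",
    "km_logrank",
    "band_covariate",
]

EXACT_RANKSUM_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, str]
    statistic: float  # Mann-Whitney U of the first group
    p_raw: float
    p_adjusted: float
    family_size: int
    method: str = "exact"


def _rank_with_ties(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    family_size: int = 1,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with Bonferroni correction.

    Exact permutation null when n_a + n_b <= 12 (enumerating all group
    assignments of the observed ranks, valid also under ties); otherwise a
    normal approximation with tie correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    n_a, n_b = a.size, b.size
    ranks = _rank_with_ties(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= EXACT_RANKSUM_MAX_N:
        # exact conditional null: every split of the observed ranks
        u_values = []
        idx = range(n_a + n_b)
        for comb in itertools.combinations(idx, n_a):
            u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2.0
            u_values.append(u)
        u_values = np.asarray(u_values)
        mean_u = n_a * n_b / 2.0
        dev = abs(u_a - mean_u)
        p = float(np.mean(np.abs(u_values - mean_u) >= dev - 1e-12))
        method = "exact"
    else:
        mean_u = n_a * n_b / 2.0
        n = n_a + n_b
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var_u = n_a * n_b / 12.0 * (n + 1 - tie_term)
        if var_u <= 0:
            p = 1.0
        else:
            z = (u_a - mean_u) / np.sqrt(var_u)
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    p = min(1.0, p)
    return GroupComparison(
        group_labels=labels,
        statistic=float(u_a),
        p_raw=p,
        p_adjusted=min(1.0, p * family_size),
        family_size=family_size,
        method=method,
    )


# ---------------------------------------------------------------------------
# Spearman correlation screen
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with average-rank ties; exact permutation p for n <= 9.

    Returns (rho, p).  Constant inputs yield (nan, nan) rather than an
    exception.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rx = _rank_with_ties(x)
    ry = _rank_with_ties(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        # exact permutation null, vectorized: rho is a dot product of
        # centered rank vectors and the norms are permutation-invariant
        perms = np.fromiter(
            itertools.chain.from_iterable(itertools.permutations(ry)),
            dtype=float,
        ).reshape(-1, n)
        rx0 = rx - rx.mean()
        ry0 = ry - ry.mean()
        denom = np.sqrt((rx0 @ rx0) * (ry0 @ ry0))
        rhos = (perms - ry.mean()) @ rx0 / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def spearman_screen(
    density_matrix: pd.DataFrame,
    outcomes: pd.DataFrame,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of every spatial feature against every outcome.

    Rows of both frames are patients (index-aligned); missing values are
    handled pairwise-complete.  Returns a tidy frame with one row per
    (feature, outcome): rho, p, Bonferroni-adjusted p over the screen
    family, and a significance flag at ``alpha``; entries with fewer than
    ``min_pairs`` complete pairs or a constant column carry NaN rho.
    """
    common = density_matrix.index.intersection(outcomes.index)
    dm = density_matrix.loc[common]
    oc = outcomes.loc[common]
    rows = []
    for feat in dm.columns:
        for out in oc.columns:
            pair = pd.concat([dm[feat], oc[out]], axis=1).dropna()
            if len(pair) < min_pairs:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append(
                {"feature": feat, "outcome": out, "n": len(pair), "rho": rho, "p": p}
            )
    df = pd.DataFrame(rows)
    family = int(df["p"].notna().sum())
    df["p_adjusted"] = np.minimum(1.0, df["p"] * max(family, 1))
    df["significant"] = df["p"] < alpha
    df["family_size"] = family
    return df


# ---------------------------------------------------------------------------
# patient splits
# ---------------------------------------------------------------------------

def median_split(
    values_by_patient: Mapping[str, float]
) -> tuple[list[str], list[str]]:
    """Split patients into hi (> median) and lo (<= median) groups.

    Uses the mid-rank sample median over nonmissing values.  If every
    value is identical the hi group is empty (degenerate, warned).
    """
    items = {
        pid: v for pid, v in values_by_patient.items() if v is not None and np.isfinite(v)
    }
    if len(items) < 2:
        raise ValueError("need >= 2 patients with nonmissing values")
    med = float(np.median(list(items.values())))
    hi = [pid for pid, v in items.items() if v > med]
    lo = [pid for pid, v in items.items() if v <= med]
    if not hi:
        warnings.warn("degenerate median split: all values at or below the median")
    return hi, lo


def threshold_split(
    values_by_patient: Mapping[str, float], threshold: float = 0.0
) -> tuple[list[str], list[str]]:
    """Split patients at a fixed covariate threshold (hi strictly above).

    ``threshold=0`` separates patients with zero covariate (e.g. no
    marker-positive cells) from everyone else.
    """
    items = {
        pid: v for pid, v in values_by_patient.items() if v is not None and np.isfinite(v)
    }
    hi = [pid for pid, v in items.items() if v > threshold]
    lo = [pid for pid, v in items.items() if v <= threshold]
    return hi, lo


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(
    times: Sequence[float], events: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit Kaplan-Meier estimate.

    Returns step-function arrays (times, survival) starting at (0, 1).
    At tied times deaths are processed before censorings.
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival sample")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events]) if events.any() else np.array([])
    out_t = [0.0]
    out_s = [1.0]
    s = 1.0
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        out_t.append(float(t))
        out_s.append(float(s))
    return np.asarray(out_t), np.asarray(out_s)


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float, float]:
    """Two-group log-rank (Mantel-Cox) test.

    Returns (chi2, p, observed_minus_expected_a); the last term's sign
    says whether group a had more (+) or fewer (-) deaths than expected.
    If there are no events at all, chi2 is 0 and p is NaN (undefined).
    """
    ta = np.asarray(list(times_a), dtype=float)
    ea = np.asarray(list(events_a), dtype=bool)
    tb = np.asarray(list(times_b), dtype=float)
    eb = np.asarray(list(events_b), dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("empty group")
    all_event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    if all_event_times.size == 0:
        return 0.0, float("nan"), 0.0
    o_minus_e = 0.0
    var = 0.0
    for t in all_event_times:
        n_a = np.sum(ta >= t)
        n_b = np.sum(tb >= t)
        n = n_a + n_b
        d_a = np.sum((ta == t) & ea)
        d_b = np.sum((tb == t) & eb)
        d = d_a + d_b
        if n == 0 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, float("nan") if o_minus_e == 0 else 1.0, float(o_minus_e)
    chi2 = o_minus_e**2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p, float(o_minus_e)


@dataclass
class SurvivalSplit:
    """Result of a hi/lo survival comparison at one distance band."""

    band_center: float
    covariate: str
    hi_ids: list[str]
    lo_ids: list[str]
    logrank_chi2: float
    p: float
    o_minus_e_hi: float
    km_hi: tuple[np.ndarray, np.ndarray]
    km_lo: tuple[np.ndarray, np.ndarray]
    degenerate: bool = False

    def km_dataframe(self) -> pd.DataFrame:
        frames = []
        for group, (t, s) in (("hi", self.km_hi), ("lo", self.km_lo)):
            frames.append(
                pd.DataFrame({"group": group, "time_months": t, "survival": s})
            )
        return pd.concat(frames, ignore_index=True)


def km_logrank(
    survival: Sequence[SurvivalRecord],
    hi_ids: Sequence[str],
    lo_ids: Sequence[str],
    band_center: float = float("nan"),
    covariate: str = "",
) -> SurvivalSplit:
    """Kaplan-Meier curves and log-rank test for a hi/lo patient split."""
    by_id = {r.patient_id: r for r in survival}
    hi = [by_id[p] for p in hi_ids if p in by_id]
    lo = [by_id[p] for p in lo_ids if p in by_id]
    if not hi or not lo:
        raise ValueError("both groups must be nonempty")
    t_hi = [r.time for r in hi]
    e_hi = [r.event for r in hi]
    t_lo = [r.time for r in lo]
    e_lo = [r.event for r in lo]
    chi2, p, ome = logrank(t_hi, e_hi, t_lo, e_lo)
    return SurvivalSplit(
        band_center=band_center,
        covariate=covariate,
        hi_ids=list(hi_ids),
        lo_ids=list(lo_ids),
        logrank_chi2=chi2,
        p=p,
        o_minus_e_hi=ome,
        km_hi=km_curve(t_hi, e_hi),
        km_lo=km_curve(t_lo, e_lo),
        degenerate=not np.isfinite(p),
    )


def band_covariate(
    profile_by_patient: Mapping[str, DistanceProfile],
    band_center: float,
    use_mean: bool = False,
) -> dict[str, float | None]:
    """Each patient's cell density in the bin centered at ``band_center``.

    Patients whose profile lacks that bin (or whose bin has zero band
    area) map to None.  Raises listing the available centers when
    ``band_center`` is not on the bin grid of any profile.
    """
    out: dict[str, float | None] = {}
    seen_centers: set[float] = set()
    matched = False
    for pid, prof in profile_by_patient.items():
        centers = prof.bin_centers
        seen_centers.update(np.round(centers, 9).tolist())
        hits = np.nonzero(np.isclose(centers, band_center))[0]
        if hits.size == 0:
            out[pid] = None
            continue
        matched = True
        value = prof.mean_density[hits[0]] if use_mean else prof.density[hits[0]]
        out[pid] = None if not np.isfinite(value) else float(value)
    if not matched:
        raise ValueError(
            f"band center {band_center} not on the bin grid; available: "
            f"{sorted(seen_centers)}"
        )
    return out
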