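"""Region-wise statistical comparison of the sampled hemodynamic records.

Per-point parameters (normalized pressure, normalized WSS, TAWSS, OSI) in
the bleb-formation area are compared against the rest of the dome with the
Mann-Whitney U test; the per-region counts of divergence centers are
compared with Fisher's exact test. Group summaries are mean +/- sample SD.
Significance threshold is p < 0.05, with no multiple-testing correction,
matching the reference protocol.

Two constructions of the 2x2 center table are provided. ``as_printed``
uses columns (center count, total point count) per region — the
construction that reproduces the published p-values from the published
counts; ``conventional`` uses (center count, non-center count), the
statistically standard table. ``as_printed`` is the default.

Points on a surface are spatially correlated; like the reference protocol,
the tests here treat them as independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import BlebpointError
from .mesh_io import BLEB, NONBLEB
from .sampling import SamplePointSet

PARAMETERS = ("normalized_pressure", "normalized_wss", "tawss", "osi")

PARAMETER_TITLES = {
    "normalized_pressure": "Normalized Pressure",
    "normalized_wss": "Normalized WSS",
    "tawss": "TAWSS (Pa)",
    "osi": "OSI",
}

#: exact Mann-Whitney enumeration cap (number of group assignments)
EXACT_MWU_MAX_COMBINATIONS = 100_000


# -- Mann-Whitney U -------------------------------------------------------


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(group_a, group_b, mode: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U statistic of ``group_a`` and two-sided p-value.

    ``exact`` enumerates the permutation distribution of U over all
    C(n, n_a) group assignments (ties handled by the 1/2 convention) and
    returns p = P(|U - n_a n_b / 2| >= |U_obs - n_a n_b / 2|). ``normal_approx``
    uses the normal approximation with continuity and tie correction.
    ``auto`` picks exact when the enumeration is small enough.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise BlebpointError("Mann-Whitney requires two non-empty groups")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    mu = n_a * n_b / 2.0

    if mode == "auto":
        mode = (
            "exact"
            if math.comb(n_a + n_b, n_a) <= EXACT_MWU_MAX_COMBINATIONS
            else "normal_approx"
        )
    if mode == "exact":
        pooled = np.concatenate([a, b])
        n = n_a + n_b
        # M[i, j] = 1 if pooled[i] beats pooled[j], 1/2 on ties, diag 0;
        # U of an assignment A is then sum_{i in A} rowtot_i - k(k-1)/2.
        m = (pooled[:, None] > pooled[None, :]) + 0.5 * (
            pooled[:, None] == pooled[None, :]
        )
        np.fill_diagonal(m, 0.0)
        rowtot = m.sum(axis=1)
        combs = np.array(list(combinations(range(n), n_a)), dtype=np.intp)
        u_all = rowtot[combs].sum(axis=1) - n_a * (n_a - 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))
        return u_obs, p
    if mode == "normal_approx":
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            return u_obs, 1.0
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return u_obs, float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


# -- Fisher's exact test --------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    p is the sum of hypergeometric probabilities (margins fixed) of all
    tables no more likely than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise BlebpointError("Fisher test requires a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_f = np.asarray(table, dtype=float)
        if np.any(t_f < 0) or np.any(t_f != np.round(t_f)):
            raise BlebpointError("counts must be non-negative integers")
        t = t_f.astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0 or row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        return 1.0
    k_min = max(0, col1 - (n_total - row1))
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n_total, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n_total, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


# -- contingency construction --------------------------------------------


def build_center_contingency(
    points: SamplePointSet, mode: str = "as_printed"
) -> np.ndarray:
    """2x2 divergence-center table, rows = (bleb, nonbleb).

    ``as_printed``: columns (center count, total point count).
    ``conventional``: columns (center count, non-center count).
    """
    if points.region is None:
        raise BlebpointError("points carry no region labels")
    is_center = points.is_center
    counts = {}
    for region in (BLEB, NONBLEB):
        sel = points.region == region
        counts[region] = (int(is_center[sel].sum()), int(sel.sum()))
    return contingency_from_counts(
        counts[BLEB][0], counts[BLEB][1], counts[NONBLEB][0], counts[NONBLEB][1], mode
    )


def contingency_from_counts(
    centers_bleb: int,
    n_bleb: int,
    centers_nonbleb: int,
    n_nonbleb: int,
    mode: str = "as_printed",
) -> np.ndarray:
    if mode == "as_printed":
        return np.array(
            [[centers_bleb, n_bleb], [centers_nonbleb, n_nonbleb]], dtype=np.int64
        )
    if mode == "conventional":
        return np.array(
            [
                [centers_bleb, n_bleb - centers_bleb],
                [centers_nonbleb, n_nonbleb - centers_nonbleb],
            ],
            dtype=np.int64,
        )
    raise ValueError(f"unknown contingency mode {mode!r}")


# -- report ---------------------------------------------------------------


@dataclass
class ParameterComparison:
    """Bleb vs non-bleb comparison of one hemodynamic parameter."""

    parameter: str
    n_bleb: int
    n_nonbleb: int
    mean_bleb: float
    sd_bleb: float
    mean_nonbleb: float
    sd_nonbleb: float
    u_statistic: float
    p_value: float
    n_excluded: int = 0

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class CenterComparison:
    """Per-region divergence-center counts with Fisher's exact test."""

    centers_bleb: int
    n_bleb: int
    centers_nonbleb: int
    n_nonbleb: int
    mode: str
    p_value: float

    @property
    def table(self) -> np.ndarray:
        return contingency_from_counts(
            self.centers_bleb,
            self.n_bleb,
            self.centers_nonbleb,
            self.n_nonbleb,
            self.mode,
        )

    @property
    def prevalence_bleb_pct(self) -> float:
        return 100.0 * self.centers_bleb / self.n_bleb if self.n_bleb else float("nan")

    @property
    def prevalence_nonbleb_pct(self) -> float:
        return (
            100.0 * self.centers_nonbleb / self.n_nonbleb
            if self.n_nonbleb
            else float("nan")
        )

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class CaseReport:
    """One column-block of the comparison table (one case, or pooled)."""

    label: str
    n_bleb: int
    n_nonbleb: int
    parameters: list[ParameterComparison] = field(default_factory=list)
    centers: CenterComparison | None = None


@dataclass
class ComparisonReport:
    """Per-case and pooled bleb vs non-bleb comparison."""

    cases: dict[str, CaseReport]

    @property
    def pooled(self) -> CaseReport:
        return self.cases["total"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, case in self.cases.items():
            for p in case.parameters:
                rows.append(
                    {
                        "case": label,
                        "parameter": PARAMETER_TITLES.get(p.parameter, p.parameter),
                        "n_bleb": p.n_bleb,
                        "n_nonbleb": p.n_nonbleb,
                        "bleb_mean": p.mean_bleb,
                        "bleb_sd": p.sd_bleb,
                        "nonbleb_mean": p.mean_nonbleb,
                        "nonbleb_sd": p.sd_nonbleb,
                        "statistic": p.u_statistic,
                        "test": "mann-whitney",
                        "p_value": p.p_value,
                        "significant": p.significant,
                    }
                )
            c = case.centers
            if c is not None:
                rows.append(
                    {
                        "case": label,
                        "parameter": "Center of divergent WSS vectors, N (%)",
                        "n_bleb": c.n_bleb,
                        "n_nonbleb": c.n_nonbleb,
                        "bleb_mean": c.centers_bleb,
                        "bleb_sd": c.prevalence_bleb_pct,
                        "nonbleb_mean": c.centers_nonbleb,
                        "nonbleb_sd": c.prevalence_nonbleb_pct,
                        "statistic": float("nan"),
                        "test": f"fisher ({c.mode})",
                        "p_value": c.p_value,
                        "significant": c.significant,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        out = {}
        for label, case in self.cases.items():
            entry: dict = {"n_bleb": case.n_bleb, "n_nonbleb": case.n_nonbleb}
            for p in case.parameters:
                entry[p.parameter] = {
                    "bleb_mean": p.mean_bleb,
                    "bleb_sd": p.sd_bleb,
                    "nonbleb_mean": p.mean_nonbleb,
                    "nonbleb_sd": p.sd_nonbleb,
                    "U": p.u_statistic,
                    "p": p.p_value,
                    "n_excluded": p.n_excluded,
                }
            if case.centers is not None:
                c = case.centers
                entry["divergence_centers"] = {
                    "bleb": [c.centers_bleb, c.n_bleb],
                    "nonbleb": [c.centers_nonbleb, c.n_nonbleb],
                    "prevalence_bleb_pct": c.prevalence_bleb_pct,
                    "prevalence_nonbleb_pct": c.prevalence_nonbleb_pct,
                    "mode": c.mode,
                    "fisher_p": c.p_value,
                }
            out[label] = entry
        return json.dumps(out, indent=1, sort_keys=True, allow_nan=True)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan")


def _compare_case(
    label: str,
    values: dict[str, np.ndarray],
    regions: np.ndarray,
    is_center: np.ndarray,
    contingency_mode: str,
    mwu_mode: str,
) -> CaseReport:
    bleb_sel = regions == BLEB
    nonbleb_sel = regions == NONBLEB
    report = CaseReport(
        label=label,
        n_bleb=int(bleb_sel.sum()),
        n_nonbleb=int(nonbleb_sel.sum()),
    )
    for name in PARAMETERS:
        va = values[name][bleb_sel]
        vb = values[name][nonbleb_sel]
        ok_a, ok_b = ~np.isnan(va), ~np.isnan(vb)
        n_excluded = int((~ok_a).sum() + (~ok_b).sum())
        va, vb = va[ok_a], vb[ok_b]
        if len(va) == 0 or len(vb) == 0:
            continue
        u, p = mann_whitney_u(va, vb, mode=mwu_mode)
        report.parameters.append(
            ParameterComparison(
                parameter=name,
                n_bleb=len(va),
                n_nonbleb=len(vb),
                mean_bleb=float(va.mean()),
                sd_bleb=_sd(va),
                mean_nonbleb=float(vb.mean()),
                sd_nonbleb=_sd(vb),
                u_statistic=u,
                p_value=p,
                n_excluded=n_excluded,
            )
        )
    cb = int(is_center[bleb_sel].sum())
    cn = int(is_center[nonbleb_sel].sum())
    table = contingency_from_counts(
        cb, int(bleb_sel.sum()), cn, int(nonbleb_sel.sum()), contingency_mode
    )
    report.centers = CenterComparison(
        centers_bleb=cb,
        n_bleb=int(bleb_sel.sum()),
        centers_nonbleb=cn,
        n_nonbleb=int(nonbleb_sel.sum()),
        mode=contingency_mode,
        p_value=fisher_exact_2x2(table),
    )
    return report


def summarize(
    points: SamplePointSet,
    per_case_ids=None,
    contingency_mode: str = "as_printed",
    mwu_mode: str = "auto",
) -> ComparisonReport:
    """Build the comparison report from labelled, measured sample points.

    ``per_case_ids`` optionally assigns each point to a case label; the
    report then contains one block per case plus the pooled ``total``
    block. Points with undefined OSI are excluded from the OSI comparison
    with their count recorded.
    """
    if points.region is None:
        raise BlebpointError("points must be labelled before summarizing")
    values = {
        name: np.array([getattr(r, name) for r in points.records])
        for name in PARAMETERS
    }
    regions = points.region
    is_center = points.is_center
    cases: dict[str, CaseReport] = {}
    if per_case_ids is not None:
        per_case_ids = np.asarray(per_case_ids)
        for label in pd.unique(per_case_ids):
            sel = per_case_ids == label
            cases[str(label)] = _compare_case(
                str(label),
                {k: v[sel] for k, v in values.items()},
                regions[sel],
                is_center[sel],
                contingency_mode,
                mwu_mode,
            )
    cases["total"] = _compare_case(
        "total", values, regions, is_center, contingency_mode, mwu_mode
    )
    return ComparisonReport(cases=cases)


def summarize_counts(
    counts: dict[str, tuple[int, int, int, int]],
    contingency_mode: str = "as_printed",
) -> ComparisonReport:
    """Fisher-only report from per-case center counts.

    ``counts`` maps a case label to (centers_bleb, n_bleb,
    centers_nonbleb, n_nonbleb); a pooled ``total`` block is added by
    summing the per-case counts.
    """
    cases: dict[str, CaseReport] = {}
    agg = np.zeros(4, dtype=np.int64)
    for label, (cb, nb, cn, nn) in counts.items():
        agg += (cb, nb, cn, nn)
        table = contingency_from_counts(cb, nb, cn, nn, contingency_mode)
        cases[label] = CaseReport(
            label=label,
            n_bleb=nb,
            n_nonbleb=nn,
            centers=CenterComparison(
                cb, nb, cn, nn, contingency_mode, fisher_exact_2x2(table)
            ),
        )
    cb, nb, cn, nn = (int(v) for v in agg)
    table = contingency_from_counts(cb, nb, cn, nn, contingency_mode)
    cases["total"] = CaseReport(
        label="total",
        n_bleb=nb,
        n_nonbleb=nn,
        centers=CenterComparison(
            cb, nb, cn, nn, contingency_mode, fisher_exact_2x2(table)
        ),
    )
    return ComparisonReport(cases=cases)
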