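"""Tissue-modulus back-calculation and paired statistics.

The micro-FE model is run with a reference tissue modulus (10 GPa); the
actual tissue modulus of a specimen follows from the ratio of the
experimentally measured bending stiffness to the FE-predicted one:

    E_tissue = (k_exp / k_FE) * E_ref

Paired treated-vs-control comparisons use the Wilcoxon signed-rank test.
The default is the normal approximation without continuity correction and
with tie-corrected variance — the convention whose n = 3 p-values are
0.109, 0.285, 0.593 for rank sums T = 0, 1, 2 — with an exact
enumeration mode for honest small-sample inference. Across-timepoint
comparisons of treated/control ratios use the two-sided t test
(pooled-variance by default, Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TissueModulusResult",
    "PairedComparison",
    "back_calculate_tissue_modulus",
    "wilcoxon_signed_rank",
    "two_sided_t_test",
    "cohort_report",
]


@dataclass(frozen=True)
class TissueModulusResult:
    k_exp_n_per_mm: float
    k_fe_n_per_mm: float
    e_ref_gpa: float
    e_tissue_gpa: float


def back_calculate_tissue_modulus(
    k_exp_n_per_mm: float, k_fe_n_per_mm: float, e_ref_gpa: float = 10.0
) -> TissueModulusResult:
    """Back-calculate the specimen's tissue Young's modulus.

    Exact ratio formula — no fitting. ``k_fe`` must come from an FE run with
    tissue modulus ``e_ref_gpa``.
    """
    if not (k_exp_n_per_mm > 0 and k_fe_n_per_mm > 0 and e_ref_gpa > 0):
        raise ValueError("stiffnesses and reference modulus must be positive")
    return TissueModulusResult(
        k_exp_n_per_mm=k_exp_n_per_mm,
        k_fe_n_per_mm=k_fe_n_per_mm,
        e_ref_gpa=e_ref_gpa,
        e_tissue_gpa=(k_exp_n_per_mm / k_fe_n_per_mm) * e_ref_gpa,
    )


@dataclass
class PairedComparison:
    """Result of one paired treated-vs-control test."""

    pairs: list[tuple[float, float]]     # (treated, control)
    differences: np.ndarray
    ratios: np.ndarray                   # treated / control
    statistic: float                     # smaller signed-rank sum T
    z: float | None
    p: float
    method: str                          # "asymptotic" | "exact"
    n_used: int                          # nonzero differences


def _signed_ranks(diff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero differences, average-rank the absolute values."""
    d = diff[diff != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: test undefined")
    ranks = sps.rankdata(np.abs(d))
    return d, ranks


def wilcoxon_signed_rank(
    pairs, mode: str = "asymptotic"
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on (treated, control) pairs.

    ``mode="asymptotic"``: z = (T - n(n+1)/4) / sqrt(var), with
    var = n(n+1)(2n+1)/24 - sum(t^3 - t)/48 over tie groups, no continuity
    correction; T is the smaller of the two signed-rank sums.
    ``mode="exact"``: enumerates all 2^n sign patterns of the observed
    absolute ranks.
    """
    pairs = [(float(t), float(c)) for t, c in pairs]
    diff = np.array([t - c for t, c in pairs])
    ratios = np.array(
        [t / c if c != 0 else np.nan for t, c in pairs]
    )
    d, ranks = _signed_ranks(diff)
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    T = min(w_plus, w_minus)

    if mode == "asymptotic":
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(((counts**3 - counts) / 48.0)[counts > 1].sum())
        if var <= 0:
            raise ValueError("zero variance: all ranks tied away")
        z = (T - mean) / np.sqrt(var)
        p = float(min(2.0 * sps.norm.cdf(-abs(z)), 1.0))
        return PairedComparison(pairs, diff, ratios, T, float(z), p, "asymptotic", n)
    if mode == "exact":
        # distribution of W+ over all 2^n sign patterns by convolution
        # (doubled ranks so tied average ranks stay integral)
        r2 = np.round(2 * ranks).astype(np.int64)
        total2 = int(r2.sum())
        dist = np.zeros(total2 + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total2 + 1 - r]
            dist = dist + shifted
        t2 = int(round(2 * T))
        count = dist[: t2 + 1].sum() + dist[total2 - t2 :].sum()
        p = float(count) / 2.0**n
        return PairedComparison(pairs, diff, ratios, T, None, min(p, 1.0), "exact", n)
    raise ValueError(f"unknown mode {mode!r}")


def two_sided_t_test(
    sample_a, sample_b, paired: bool = False, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sided t test; returns (t, df, p).

    Unpaired defaults to the pooled-variance (equal-variances) form; pass
    ``welch=True`` for the unequal-variance correction. Paired mode tests the
    differences.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d, 0):
                return 0.0, float(a.size - 1), 1.0
            raise ValueError("zero variance of differences")
        res = sps.ttest_rel(a, b)
        return float(res.statistic), float(a.size - 1), float(res.pvalue)
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        df = sps.ttest_ind(a, b, equal_var=False).df
    else:
        df = a.size + b.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


_PROPERTIES = ("elastic_stiffness_n_per_mm", "yield_load_n", "ultimate_load_n")


def cohort_report(
    summaries: pd.DataFrame,
    fe_results: pd.DataFrame | None = None,
    e_ref_gpa: float = 10.0,
    wilcoxon_mode: str = "asymptotic",
    alpha: float = 0.05,
) -> dict:
    """Group-level report of a paired treated/control cohort.

    ``summaries`` needs columns ``animal``, ``timepoint``, ``side``
    ("treated"/"control") plus the mechanical properties; ``fe_results``
    (optional) needs ``animal``, ``timepoint``, ``side``,
    ``fe_stiffness_n_per_mm`` and enables tissue-modulus calibration. The
    report gives, per timepoint and property, the mean +- sd percent
    difference of treated/control ratios and the Wilcoxon p, plus the
    across-timepoint ratio t test.
    """
    df = summaries.copy()
    required = {"animal", "timepoint", "side"}
    if not required.issubset(df.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    props = [p for p in _PROPERTIES if p in df.columns]

    if fe_results is not None:
        fe = fe_results.rename(
            columns={"fe_stiffness_n_per_mm": "_kfe"}
        )[["animal", "timepoint", "side", "_kfe"]]
        df = df.merge(fe, on=["animal", "timepoint", "side"], how="left")
        if df["_kfe"].isna().any():
            missing = df.loc[df["_kfe"].isna(), ["animal", "timepoint", "side"]]
            raise ValueError(f"missing FE stiffness for: {missing.to_dict('records')}")
        df["tissue_modulus_gpa"] = [
            back_calculate_tissue_modulus(k, kfe, e_ref_gpa).e_tissue_gpa
            for k, kfe in zip(df["elastic_stiffness_n_per_mm"], df["_kfe"])
        ]
        props = props + ["_kfe", "tissue_modulus_gpa"]

    report: dict = {"alpha": alpha, "timepoints": {}, "across_timepoints": {}}
    ratio_tables: dict[str, dict] = {p: {} for p in props}
    for tp, g in df.groupby("timepoint"):
        treated = g[g["side"] == "treated"].set_index("animal")
        control = g[g["side"] == "control"].set_index("animal")
        unmatched = set(treated.index) ^ set(control.index)
        if unmatched:
            raise ValueError(
                f"unmatched treated/control pairs at timepoint {tp!r}: "
                f"{sorted(unmatched)}"
            )
        animals = sorted(treated.index)
        entry = {}
        for prop in props:
            t = treated.loc[animals, prop].to_numpy(dtype=float)
            c = control.loc[animals, prop].to_numpy(dtype=float)
            ratios = t / c
            ratio_tables[prop][tp] = ratios
            cmp = wilcoxon_signed_rank(list(zip(t, c)), mode=wilcoxon_mode)
            name = "fe_stiffness_n_per_mm" if prop == "_kfe" else prop
            entry[name] = {
                "n_pairs": len(animals),
                "percent_difference_mean": float((ratios.mean() - 1.0) * 100.0),
                "percent_difference_sd": float(ratios.std(ddof=1) * 100.0)
                if len(ratios) > 1
                else 0.0,
                "wilcoxon_T": cmp.statistic,
                "wilcoxon_z": cmp.z,
                "p": cmp.p,
                "significant": bool(cmp.p < alpha),
            }
        report["timepoints"][str(tp)] = entry

    tps = sorted(ratio_tables[props[0]]) if props else []
    if len(tps) == 2:
        for prop in props:
            a, b = ratio_tables[prop][tps[0]], ratio_tables[prop][tps[1]]
            try:
                t, dfree, p = two_sided_t_test(a, b)
            except ValueError:
                continue
            name = "fe_stiffness_n_per_mm" if prop == "_kfe" else prop
            report["across_timepoints"][name] = {
                "timepoints": [str(tps[0]), str(tps[1])],
                "t": t,
                "df": dfree,
                "p": p,
                "significant": bool(p < alpha),
            }
    return report
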