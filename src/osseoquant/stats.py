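"""Group statistics for bone-to-implant contact studies.

Small-sample comparisons: per-group mean ± SD, homogeneity of variance
(Levene), pairwise Mann-Whitney U with an exact permutation p-value at the
sample sizes typical of implant studies (n = 4-6 per group), and the
correlation between the 2D (histomorphometry) and 3D (µCT) measurements of
the same specimens.
"""

from __future__ import annotations

import itertools
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_COLUMNS = ["specimen", "group", "method", "bic"]


def group_summary(values) -> tuple[int, float, float]:
    """(n, mean, SD) with the n−1 denominator for SD."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("SD undefined for fewer than 2 values")
    return int(v.size), float(v.mean()), float(v.std(ddof=1))


def pooled_mean(groups) -> float:
    """Sample-size-weighted mean of group means, to 1 decimal.

    ``groups`` is a list of ``(n, mean)`` pairs — the form printed in study
    summary tables, letting an overall row be recomputed without raw data.
    """
    ns = np.array([g[0] for g in groups], dtype=float)
    ms = np.array([g[1] for g in groups], dtype=float)
    if np.any(ns < 1):
        raise ValueError("all group sizes must be >= 1")
    return round(float((ns * ms).sum() / ns.sum()), 1)


def _u_statistics(ranks: np.ndarray, n1: int, n2: int, idx) -> float:
    """min(U1, U2) from midrank sums of group-1 indices."""
    r1 = float(ranks[list(idx)].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return min(u1, n1 * n2 - u1)


def mann_whitney(a, b, exact_max_n: int = 20) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    For combined sample sizes up to ``exact_max_n`` the p-value is exact:
    all C(n1+n2, n1) group assignments are enumerated and
    ``p = P(min(U, U') <= observed min(U, U'))`` under the permutation null
    (midranks handle ties; the statistic returned is the minimum of the two
    group U's). Larger samples use the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))
    u_obs = _u_statistics(ranks, n1, n2, range(n1))
    if n1 + n2 <= exact_max_n:
        total = 0
        hits = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            total += 1
            if _u_statistics(ranks, n1, n2, idx) <= u_obs + 1e-12:
                hits += 1
        return float(u_obs), hits / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u1 = float(res.statistic)
    return min(u1, n1 * n2 - u1), float(res.pvalue)


def levene(groups) -> tuple[float, float]:
    """Levene's W (group means as centers) and its F-distribution p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    with np.errstate(invalid="ignore"):
        w, p = sps.levene(*arrays, center="mean")
    if np.isnan(w):  # all absolute deviations identical: 0/0 → no inhomogeneity
        return 0.0, 1.0
    return float(w), float(p)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Paired correlation (Pearson by default, Spearman via ``method``)
    with a two-sided p-value from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def load_group_table(path) -> pd.DataFrame:
    """Read a study table CSV (columns specimen, group, method, bic)."""
    df = pd.read_csv(path)
    return validate_group_table(df)


def validate_group_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"group table missing columns {missing}")
    if df.duplicated(subset=["specimen", "method"]).any():
        raise ValueError("(specimen, method) pairs must be unique")
    if ((df["bic"] < 0) | (df["bic"] > 100)).any():
        raise ValueError("bic values must lie in [0, 100]")
    return df


def study_report(
    table: pd.DataFrame, correlation: str = "pearson", holm: bool = False
) -> dict:
    """Full comparison report from a per-specimen BIC table.

    Per group × method mean ± SD; pooled (overall) mean per method; all
    pairwise Mann-Whitney p-values within each method; Levene's test across
    groups per method; and the between-method correlation over specimens
    measured by both.  ``holm`` applies a Holm step-down correction to the
    pairwise p-values (off by default).
    """
    table = validate_group_table(table)
    report: dict = {"groups": {}, "pairwise": {}, "levene": {}, "pooled": {}}
    methods = sorted(table["method"].unique())
    groups = sorted(table["group"].unique())
    for m in methods:
        sub = table[table["method"] == m]
        report["pooled"][m] = round(float(sub["bic"].mean()), 1)
        gvals = {}
        for g in groups:
            v = sub.loc[sub["group"] == g, "bic"].to_numpy()
            if v.size == 0:
                continue
            gvals[g] = v
            n, mean, sd = (v.size, float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else float("nan"))
            report["groups"].setdefault(g, {})[m] = {"n": int(n), "mean": mean, "sd": sd}
        pairs = []
        for g1, g2 in itertools.combinations(sorted(gvals), 2):
            u, p = mann_whitney(gvals[g1], gvals[g2])
            pairs.append((f"{g1} vs {g2}", u, p))
        if holm and pairs:
            order = np.argsort([p for _, _, p in pairs])
            k = len(pairs)
            adj = {}
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, min(1.0, (k - rank) * pairs[i][2]))
                adj[i] = running
            pairs = [(name, u, adj[i]) for i, (name, u, _) in enumerate(pairs)]
        report["pairwise"][m] = {name: {"U": u, "p": p} for name, u, p in pairs}
        if len(gvals) >= 2 and all(v.size >= 2 for v in gvals.values()):
            w, p = levene(list(gvals.values()))
            report["levene"][m] = {"W": w, "p": p}
    if len(methods) == 2:
        wide = table.pivot(index="specimen", columns="method", values="bic").dropna()
        if len(wide) >= 3:
            try:
                r, p = correlate(wide[methods[0]], wide[methods[1]], method=correlation)
                report["correlation"] = {
                    "methods": methods,
                    "n": int(len(wide)),
                    "r": r,
                    "p": p,
                    "type": correlation,
                }
            except ValueError as e:
                report["correlation_warning"] = str(e)
        else:
            report["correlation_warning"] = "fewer than 3 specimens measured by both methods"
    return report


def write_report(report: dict, outdir) -> None:
    """Write the report as JSON plus a summary-table-shaped CSV
    (rows: groups + overall; columns: n and mean ± SD per method)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    methods = sorted({m for g in report["groups"].values() for m in g})
    rows = []
    for g, per_method in report["groups"].items():
        row = {"group": g}
        for m in methods:
            if m in per_method:
                st = per_method[m]
                row[f"n_{m}"] = st["n"]
                row[f"bic_{m}"] = f"{st['mean']:.1f} ± {st['sd']:.1f}"
        rows.append(row)
    overall = {"group": "overall"}
    for m in methods:
        ns = [g[m]["n"] for g in report["groups"].values() if m in g]
        overall[f"n_{m}"] = sum(ns)
        overall[f"bic_{m}"] = f"{report['pooled'][m]:.1f}"
    rows.append(overall)
    pd.DataFrame(rows).to_csv(outdir / "report.csv", index=False)
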