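"""Population-level statistics and reporting for temperature experiments.

Per-temperature summaries (mean, SD, 2-SD error bars), an F-test for a
non-zero slope of the linear regression of a per-cell metric on
temperature, and the two-sample Kolmogorov-Smirnov test used to compare
fluctuation amplitudes between conditions. A report bundle writes summary
CSVs, a machine-readable JSON of all test results, and trend/box-plot
figures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "group_summary",
    "slope_f_test",
    "ks_two_sample",
    "experiment_report",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    groups: tuple[str, ...] = ()
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def group_summary(
    table: pd.DataFrame, metric: str, group: str = "temperature_c"
) -> pd.DataFrame:
    """Per-group mean, sample SD and 2-SD error-bar half-width."""
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} missing")
    g = table.groupby(group)[metric]
    out = pd.DataFrame(
        {"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0), "n": g.size()}
    )
    out["err_2sd"] = 2.0 * out["sd"]
    return out.reset_index()


def slope_f_test(x, y, alpha: float = 0.05) -> TestResult:
    """F-test that the OLS regression slope of y on x differs from zero.

    F = SS_regression / (SS_residual / (n - 2)) with 1 and n-2 degrees of
    freedom. An exact linear relation returns p = 0; constant y returns
    F = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3 or np.unique(x).size < 2:
        raise ValueError("need >= 3 points with >= 2 distinct x values")
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    fitted = y.mean() + slope * xc
    ss_reg = float(np.sum((fitted - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = ss_reg + ss_res
    if ss_tot == 0.0:
        return TestResult("slope_f", 0.0, 1.0, (n,), alpha=alpha)
    if ss_res <= 1e-30 * ss_tot:
        return TestResult("slope_f", float("inf"), 0.0, (n,), alpha=alpha)
    f_stat = ss_reg / (ss_res / (n - 2))
    p = float(sps.f.sf(f_stat, 1, n - 2))
    return TestResult("slope_f", float(f_stat), p, (n,), alpha=alpha)


def ks_two_sample(
    a, b, alpha: float = 0.05, method: str = "asymp", groups: tuple[str, str] = ("a", "b")
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_a - ECDF_b|.

    The p-value uses the asymptotic Kolmogorov distribution with the
    standard effective-sample-size correction by default (``method='exact'``
    for small samples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs >= 5 observations")
    res = sps.ks_2samp(a, b, method=method)
    return TestResult(
        "ks_two_sample",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        (a.size, b.size),
        groups=groups,
        alpha=alpha,
    )


def _trend_figure(summary: pd.DataFrame, metric: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(
        summary["temperature_c"], summary["mean"], yerr=summary["err_2sd"],
        fmt="o-", capsize=3,
    )
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _box_figure(table: pd.DataFrame, metric: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    temps = sorted(table["temperature_c"].unique())
    data = [table.loc[table["temperature_c"] == t, metric].values for t in temps]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot(data, tick_labels=[f"{t:g}" for t in temps])
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def experiment_report(
    cell_records: pd.DataFrame,
    out_dir: str | Path,
    cmf_records: pd.DataFrame | None = None,
    metrics: tuple[str, ...] = ("psa_um2", "mch_pg", "sphericity_k"),
    alpha: float = 0.05,
    make_figures: bool = True,
) -> dict:
    """Summaries, slope tests and KS comparisons; deterministic given inputs.

    Writes ``summary.csv``, ``tests.json`` (byte-identical on rerun) and
    PNG figures under ``out_dir``. Slope tests run on per-cell values with
    temperature as a numeric covariate; KS tests compare the CMF amplitude
    between the extreme temperatures and between ring and dimple regions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cell_records["temperature_c"].nunique() < 2:
        raise ValueError("need >= 2 temperature groups")

    summaries = []
    tests: dict[str, dict] = {}
    for metric in metrics:
        summ = group_summary(cell_records, metric)
        summ.insert(0, "metric", metric)
        summaries.append(summ)
        res = slope_f_test(
            cell_records["temperature_c"].values, cell_records[metric].values,
            alpha=alpha,
        )
        tests[f"slope_{metric}"] = res.to_dict()

    if cmf_records is not None and len(cmf_records):
        summ = group_summary(cmf_records, "cmf_amplitude_nm")
        summ.insert(0, "metric", "cmf_amplitude_nm")
        summaries.append(summ)
        temps = sorted(cmf_records["temperature_c"].unique())
        lo = cmf_records.loc[
            cmf_records["temperature_c"] == temps[0], "cmf_amplitude_nm"
        ].values
        hi = cmf_records.loc[
            cmf_records["temperature_c"] == temps[-1], "cmf_amplitude_nm"
        ].values
        if lo.size >= 5 and hi.size >= 5:
            tests["ks_cmf_extreme_temps"] = ks_two_sample(
                lo, hi, alpha=alpha, groups=(f"{temps[0]:g}C", f"{temps[-1]:g}C")
            ).to_dict()
        ring = cmf_records["cmf_ring_nm"].values
        dimple = cmf_records["cmf_dimple_nm"].values
        if ring.size >= 5:
            tests["ks_ring_vs_dimple"] = ks_two_sample(
                ring, dimple, alpha=alpha, groups=("ring", "dimple")
            ).to_dict()

    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out_dir / "summary.csv", index=False)
    with open(out_dir / "tests.json", "w") as fh:
        json.dump(tests, fh, indent=2, sort_keys=True)
        fh.write("\n")

    if make_figures:
        for metric in metrics:
            _trend_figure(
                summary.loc[summary["metric"] == metric], metric,
                out_dir / f"trend_{metric}.png",
            )
        if cmf_records is not None and len(cmf_records):
            _box_figure(cmf_records, "cmf_amplitude_nm", out_dir / "cmf_boxplot.png")

    return {"summary": summary, "tests": tests, "out_dir": str(out_dir)}
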