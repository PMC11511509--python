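"""Agreement statistics: reliability, concurrent validity, Bland-Altman.

Paired tables of per-participant mean peak ROM (two trials of one system, or
the two systems) are compared with:

* an intraclass correlation coefficient from the two-way ANOVA decomposition
  (default ICC(2,1): two-way random effects, absolute agreement, single
  measurement), with an exact F-distribution 95% CI and the conventional
  bands poor (<0.5) / moderate (0.50-0.75) / good (0.75-0.90) /
  excellent (>0.90);
* RMSE over participants;
* Bland-Altman mean bias and SD of the per-participant differences
  (system A - system B), with outliers flagged beyond 2 sample SDs from the
  mean bias (strict inequality, no iterative re-flagging);
* an adjusted RMSE recomputed on the outlier-free subset.

Negative ICCs and CI bounds are reported as computed, never truncated.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .config import MOVEMENTS, SEGMENTS, PipelineConfig
from .errors import InvalidInputError

log = logging.getLogger(__name__)

ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.90, "good"))


def icc_band(icc_value: float) -> str:
    """Band per the conventional cutoffs; 0.50/0.75 are 'moderate', 0.90 'good'."""
    if not np.isfinite(icc_value):
        return "undefined"
    if icc_value < 0.5:
        return "poor"
    if icc_value <= 0.75:
        return "moderate"
    if icc_value <= 0.90:
        return "good"
    return "excellent"


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(
    table: np.ndarray | pd.DataFrame,
    model: str = "ICC2_1",
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """ICC and exact F-based confidence interval for an (n x k) paired table.

    Models: ``ICC2_1`` two-way random, absolute agreement, single rater;
    ``ICC3_1`` two-way mixed, consistency; ``ICC2_k`` absolute agreement of
    the k-rater mean.  Requires >= 3 complete rows; rows with missing values
    are dropped pairwise with their ids logged.
    """
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
        ids = list(table.index)
    else:
        arr = np.asarray(table, dtype=float)
        ids = list(range(arr.shape[0]))
    complete = np.all(np.isfinite(arr), axis=1)
    if not complete.all():
        dropped = [ids[i] for i in np.flatnonzero(~complete)]
        log.info("icc: dropping incomplete rows %s", dropped)
    arr = arr[complete]
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 2:
        raise InvalidInputError("need >= 3 complete rows and >= 2 columns for ICC")
    msr, msc, mse, n, k = _anova_mean_squares(arr)
    alpha = 1.0 - ci

    if msr <= 0 and mse <= 0:
        warnings.warn("zero between-subject variance: ICC undefined", RuntimeWarning)
        return float("nan"), float("nan"), float("nan")

    if model == "ICC3_1":
        denom = msr + (k - 1) * mse
        val = (msr - mse) / denom if denom > 0 else float("nan")
        F = msr / mse if mse > 0 else np.inf
        fl = F / f_dist.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = F * f_dist.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return float(val), float(lo), float(hi)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        warnings.warn("degenerate variance decomposition: ICC set to 0", RuntimeWarning)
        return 0.0, float("nan"), float("nan")
    icc2 = (msr - mse) / denom

    # McGraw & Wong exact interval for ICC(2,1)
    a = (k * icc2) / (n * (1 - icc2)) if icc2 < 1 else np.inf
    b = 1 + (k * icc2 * (n - 1)) / (n * (1 - icc2)) if icc2 < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f2 = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lo = hi = 1.0

    if model == "ICC2_1":
        return float(icc2), float(lo), float(hi)
    if model == "ICC2_k":
        sb = lambda r: r * k / (1 + (k - 1) * r) if np.isfinite(r) and (1 + (k - 1) * r) != 0 else float("nan")
        return float(sb(icc2)), float(sb(lo)), float(sb(hi))
    raise InvalidInputError(f"unknown ICC model {model!r}")


def rmse(table: np.ndarray | pd.DataFrame) -> float:
    """Root-mean-squared difference between the two columns, over rows."""
    arr = np.asarray(table, dtype=float)
    arr = arr[np.all(np.isfinite(arr), axis=1)]
    if arr.shape[0] < 1:
        raise InvalidInputError("need at least one complete pair for RMSE")
    d = arr[:, 0] - arr[:, 1]
    return float(np.sqrt(np.mean(d**2)))


@dataclass
class BlandAltman:
    bias_mean: float
    bias_sd: float  # sample SD (ddof=1)
    differences: np.ndarray  # signed, column 0 - column 1
    means: np.ndarray
    ids: list = field(default_factory=list)


def bland_altman(table: np.ndarray | pd.DataFrame) -> BlandAltman:
    """Per-subject differences (A - B), mean bias and sample SD."""
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
        ids = list(table.index)
    else:
        arr = np.asarray(table, dtype=float)
        ids = list(range(arr.shape[0]))
    keep = np.all(np.isfinite(arr), axis=1)
    arr = arr[keep]
    ids = [i for i, k in zip(ids, keep) if k]
    if arr.shape[0] < 3:
        raise InvalidInputError("need >= 3 complete pairs for Bland-Altman")
    d = arr[:, 0] - arr[:, 1]
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return BlandAltman(
        bias_mean=float(np.mean(d)),
        bias_sd=sd,
        differences=d,
        means=arr.mean(axis=1),
        ids=ids,
    )


def flag_outliers(
    differences: np.ndarray, ids: list | None = None, sd_threshold: float = 2.0
) -> list:
    """Ids whose difference lies strictly beyond ``sd_threshold`` sample SDs
    from the mean difference.  Mean/SD are computed once on the full set."""
    d = np.asarray(differences, dtype=float)
    if d.size < 4:
        raise InvalidInputError("need >= 4 differences to flag outliers")
    if ids is None:
        ids = list(range(d.size))
    mu = d.mean()
    sd = np.std(d, ddof=1)
    if sd == 0:
        return []
    mask = np.abs(d - mu) > sd_threshold * sd
    return [i for i, m in zip(ids, mask) if m]


def adjusted_rmse(table: np.ndarray | pd.DataFrame, outlier_ids: list) -> float:
    """RMSE recomputed on the outlier-free subset."""
    if isinstance(table, pd.DataFrame):
        keep = [i for i in table.index if i not in set(outlier_ids)]
        sub = table.loc[keep]
        if len(sub) == 0:
            raise InvalidInputError("all rows flagged as outliers; adjusted RMSE undefined")
        return rmse(sub)
    arr = np.asarray(table, dtype=float)
    keep = [i for i in range(arr.shape[0]) if i not in set(outlier_ids)]
    if not keep:
        raise InvalidInputError("all rows flagged as outliers; adjusted RMSE undefined")
    return rmse(arr[keep])


@dataclass
class AgreementResult:
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_band: str
    rmse: float
    adjusted_rmse: float
    bias_mean: float
    bias_sd: float
    outlier_ids: list
    n: int


def agreement(
    table: pd.DataFrame, model: str = "ICC2_1", sd_threshold: float = 2.0
) -> AgreementResult:
    """Full validity panel for one paired table (ICC, RMSE, bias, outliers)."""
    val, lo, hi = icc(table, model=model)
    ba = bland_altman(table)
    out = flag_outliers(ba.differences, ba.ids, sd_threshold) if len(ba.differences) >= 4 else []
    return AgreementResult(
        icc=val,
        icc_ci_low=lo,
        icc_ci_high=hi,
        icc_band=icc_band(val),
        rmse=rmse(table),
        adjusted_rmse=adjusted_rmse(table, out),
        bias_mean=ba.bias_mean,
        bias_sd=ba.bias_sd,
        outlier_ids=out,
        n=len(ba.differences),
    )


# ---------------------------------------------------------------------------
# report builder
# ---------------------------------------------------------------------------

_PLANE_VALUE = {
    "primary": "mean_peak_primary",
    "secondary": "excursion_secondary",
    "tertiary": "excursion_tertiary",
}


def _pivot(summaries: pd.DataFrame, segment: str, movement: str, plane: str,
           index: str, columns: str, column_values: tuple) -> pd.DataFrame:
    """Participant x 2 table of one plane's value for one segment movement."""
    value = _PLANE_VALUE[plane]
    sub = summaries[(summaries.segment == segment) & (summaries.movement == movement)]
    piv = sub.pivot_table(index=index, columns=columns, values=value, aggfunc="mean")
    piv = piv.reindex(columns=list(column_values))
    return piv.dropna(how="all")


def _fmt_ci(lo: float, hi: float) -> str:
    return f"({lo:.2f}-{hi:.2f})" if np.isfinite(lo) and np.isfinite(hi) else "(-)"


def build_report(
    summaries: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Reliability / validity / bias / outlier tables for a cohort.

    ``summaries`` is the tidy table from the ROM stage (one row per
    participant/trial/system/segment/movement).  Returns a dict of tidy
    DataFrames: ``reliability`` (18 segment movements x 3 planes),
    ``validity_primary`` (18 rows: ICC, RMSE, adjusted RMSE),
    ``validity_nonprimary`` (18 rows x 2 planes), ``bias`` (6 movements x 3
    segments) and ``outliers``.  Per-row N reflects pairwise-complete
    participants after any exclusions.  When ``out_dir`` is given, tables are
    written as CSV and a Bland-Altman plot per segment movement (primary
    plane only) as PNG.
    """
    cfg = config or PipelineConfig()
    n_participants = summaries["participant"].nunique()
    if n_participants < 3:
        raise InvalidInputError(
            f"cohort has {n_participants} participants; at least 3 required"
        )
    trials = sorted(summaries["trial"].unique())

    # validity compares the two systems on first-trial values, so a missing
    # first-trial measurement (e.g. cluster occlusion) drops the participant
    # for that segment movement while a missing *second* trial does not
    imu = summaries[summaries.system == "IMU"]
    validity_wide = summaries[summaries.trial == trials[0]]

    rel_rows, valp_rows, valnp_rows, bias_rows, outlier_rows = [], [], [], [], []
    ba_payload = {}
    for movement in MOVEMENTS:
        for segment in SEGMENTS:
            # reliability: IMU trial 1 vs trial 2, all three planes
            row = {"movement": movement, "segment": segment}
            for plane in ("primary", "secondary", "tertiary"):
                tab = _pivot(imu, segment, movement, plane, "participant", "trial",
                             tuple(trials[:2]))
                tab = tab.dropna()
                try:
                    v, lo, hi = icc(tab, model=cfg.icc_model, ci=cfg.icc_ci)
                except InvalidInputError:
                    v = lo = hi = float("nan")
                row[f"{plane}_icc"] = v
                row[f"{plane}_ci"] = _fmt_ci(lo, hi)
                row[f"{plane}_band"] = icc_band(v)
                if plane == "primary":
                    row["n"] = len(tab)
            rel_rows.append(row)

            # validity: IMU vs OMC on trial-averaged values
            for plane in ("primary", "secondary", "tertiary"):
                tab = _pivot(validity_wide, segment, movement, plane,
                             "participant", "system", ("IMU", "OMC"))
                tab = tab.dropna()
                try:
                    res = agreement(tab, model=cfg.icc_model,
                                    sd_threshold=cfg.outlier_sd_threshold)
                except InvalidInputError:
                    continue
                if plane == "primary":
                    valp_rows.append({
                        "movement": movement, "segment": segment, "n": res.n,
                        "icc": res.icc, "icc_ci": _fmt_ci(res.icc_ci_low, res.icc_ci_high),
                        "band": res.icc_band, "rmse": res.rmse,
                        "adjusted_rmse": res.adjusted_rmse,
                    })
                    bias_rows.append({
                        "movement": movement, "segment": segment, "n": res.n,
                        "bias_mean": res.bias_mean, "bias_sd": res.bias_sd,
                    })
                    for oid in res.outlier_ids:
                        outlier_rows.append({
                            "movement": movement, "segment": segment,
                            "participant": oid,
                        })
                    ba = bland_altman(tab)
                    ba_payload[(movement, segment)] = ba
                else:
                    valnp_rows.append({
                        "movement": movement, "segment": segment, "plane": plane,
                        "n": res.n, "icc": res.icc,
                        "icc_ci": _fmt_ci(res.icc_ci_low, res.icc_ci_high),
                        "band": res.icc_band, "rmse": res.rmse,
                    })

    report = {
        "reliability": pd.DataFrame(rel_rows),
        "validity_primary": pd.DataFrame(valp_rows),
        "validity_nonprimary": pd.DataFrame(valnp_rows),
        "bias": pd.DataFrame(bias_rows),
        "outliers": pd.DataFrame(outlier_rows, columns=["movement", "segment", "participant"]),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in report.items():
            df.to_csv(out / f"{name}.csv", index=False)
        _write_bland_altman_plots(ba_payload, out)
    return report


def _write_bland_altman_plots(payload: dict, out: Path) -> None:
    """One difference-vs-mean plot per segment movement, primary plane only.

    Reference lines at +-2 SD about the line of equality (y = 0)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out / "bland_altman"
    plot_dir.mkdir(exist_ok=True)
    for (movement, segment), ba in payload.items():
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(ba.means, ba.differences, s=18, color="k")
        ax.axhline(0.0, color="gray", lw=1)
        for s in (2 * ba.bias_sd, -2 * ba.bias_sd):
            ax.axhline(s, color="gray", lw=1, ls=":")
        ax.set_xlabel("mean of systems (deg)")
        ax.set_ylabel("IMU - OMC (deg)")
        ax.set_title(f"{movement} {segment}")
        fig.tight_layout()
        fig.savefig(plot_dir / f"{movement}_{segment}.png", dpi=100)
        plt.close(fig)
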