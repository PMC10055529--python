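"""Group statistics: cross-signal correlations, tests, multiple comparisons,
and the machine-readable report bundle.

The temporal-correlation analysis asks how closely the cellular Ca²⁺ time
courses track the vascular response.  Correlations are zero-lag Pearson
coefficients over a post-injection window; under the default
``flow_negated`` convention a flow/diameter trace is negated before
correlating, so a Ca²⁺-increase / flow-decrease pairing yields a *positive*
r (both conventions are computed and stored).

Multiple comparisons use the Holm–Šidák step-down procedure: p-values are
sorted ascending and the i-th (1-based) hypothesis is tested at
``1 - (1-alpha)^(1/(k-i+1))``, stopping at the first failure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

import flodm


class UsageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

FLOW_LIKE = ("CBFv", "diameter")


def xcorr_pair(
    x: np.ndarray,
    y: np.ndarray,
    sign_convention: str = "flow_negated",
    y_is_flow: bool = True,
) -> Optional[float]:
    """Zero-lag Pearson correlation between two traces on a common grid.

    Returns None when either trace has zero variance (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 10:
        raise ValueError("traces must share a common grid with >= 10 samples")
    if sign_convention == "flow_negated" and y_is_flow:
        y = -y
    elif sign_convention not in ("raw", "flow_negated"):
        raise ValueError(f"unknown sign convention '{sign_convention}'")
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def correlation_table(
    traces: pd.DataFrame,
    pairs: Sequence[Tuple[str, str]] = (("Ca_A", "CBFv"), ("Ca_N", "CBFv")),
    window: Tuple[float, float] = (0.0, 60.0),
) -> pd.DataFrame:
    """Per-animal correlations (both sign conventions) for signal pairs.

    Each animal's m ROI traces are first averaged into one curve per signal;
    correlations are computed on the window's common grid.
    """
    mean = (
        traces.groupby(["animal", "signal", "t_min"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    sel = (mean.t_min >= window[0]) & (mean.t_min <= window[1])
    mean = mean[sel]
    rows = []
    for animal, sub in mean.groupby("animal"):
        piv = sub.pivot_table(index="t_min", columns="signal", values="value",
                              sort=True)
        for sx, sy in pairs:
            if sx not in piv or sy not in piv:
                continue
            for convention in ("flow_negated", "raw"):
                r = xcorr_pair(
                    piv[sx].to_numpy(), piv[sy].to_numpy(),
                    sign_convention=convention,
                    y_is_flow=sy in FLOW_LIKE,
                )
                rows.append(
                    {
                        "animal": animal,
                        "signal_x": sx,
                        "signal_y": sy,
                        "sign_convention": convention,
                        "window_lo": window[0],
                        "window_hi": window[1],
                        "r": np.nan if r is None else r,
                    }
                )
    return pd.DataFrame(rows)


def correlation_rollup(corr: pd.DataFrame) -> pd.DataFrame:
    """Mean ± s.e.m. of r across animals per pair and convention."""
    rows = []
    keys = ["signal_x", "signal_y", "sign_convention"]
    for key_vals, sub in corr.groupby(keys, sort=True):
        vals = sub.r.dropna()
        rec = dict(zip(keys, key_vals))
        rec.update(
            n=len(vals),
            r_mean=float(vals.mean()) if len(vals) else np.nan,
            r_sem=float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1
            else np.nan,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    mean_diff: float
    sem_diff: float
    n: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "mean_diff": self.mean_diff,
            "sem_diff": self.sem_diff,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def paired_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided paired Student's t-test with mean difference ± s.e.m."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise UsageError("paired test requires equal-length paired vectors")
    if a.size < 3:
        raise UsageError("paired test requires >= 3 pairs")
    d = a - b
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    sem = sd / np.sqrt(d.size)
    if sd == 0.0:
        # constant differences: zero-variance guard, not an infinite t
        return TestResult(
            statistic=0.0 if mean == 0 else np.nan,
            pvalue=1.0 if mean == 0 else np.nan,
            mean_diff=mean, sem_diff=0.0, n=d.size, degenerate=True,
        )
    res = sps.ttest_rel(a, b)
    return TestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        mean_diff=mean, sem_diff=float(sem), n=int(d.size),
    )


def one_sample_test(x: np.ndarray, popmean: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test against ``popmean``."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise UsageError("one-sample test requires >= 3 observations")
    sd = float(np.std(x, ddof=1))
    mean = float(np.mean(x) - popmean)
    if sd == 0.0:
        return TestResult(
            statistic=0.0 if mean == 0 else np.nan,
            pvalue=1.0 if mean == 0 else np.nan,
            mean_diff=mean, sem_diff=0.0, n=x.size, degenerate=True,
        )
    res = sps.ttest_1samp(x, popmean)
    return TestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        mean_diff=mean, sem_diff=sd / np.sqrt(x.size), n=int(x.size),
    )


def holm_sidak(pvalues: Sequence[float], alpha: float = 0.05) -> pd.DataFrame:
    """Holm–Šidák step-down multiple-comparison procedure.

    Sorts p-values ascending; the i-th (1-based) is tested at threshold
    ``1 - (1-alpha)^(1/(k-i+1))`` and testing stops at the first failure.
    Returns a frame in the original order with per-hypothesis reject flags
    and adjusted alpha thresholds.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    thresholds = np.array([1 - (1 - alpha) ** (1.0 / (k - i)) for i in range(k)])
    reject_sorted = np.zeros(k, dtype=bool)
    for i in range(k):
        if p[order[i]] <= thresholds[i]:
            reject_sorted[i] = True
        else:
            break  # step-down: stop at first failure
    reject = np.zeros(k, dtype=bool)
    reject[order] = reject_sorted
    adj_alpha = np.empty(k)
    adj_alpha[order] = thresholds
    return pd.DataFrame(
        {"pvalue": p, "reject": reject, "adjusted_alpha": adj_alpha}
    )


def anova_oneway(values: np.ndarray, groups: np.ndarray) -> TestResult:
    """Thin wrapper over the standard one-way ANOVA (scipy.stats.f_oneway)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    res = sps.f_oneway(*samples)
    return TestResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        mean_diff=np.nan, sem_diff=np.nan, n=int(values.size),
    )


def repeated_measures_anova(
    df: pd.DataFrame, dv: str, within: str, subject: str = "animal"
) -> pd.DataFrame:
    """Thin wrapper over statsmodels' repeated-measures ANOVA."""
    from statsmodels.stats.anova import AnovaRM

    return AnovaRM(df, depvar=dv, subject=subject, within=[within]).fit().anova_table


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def build_report(
    outdir,
    metrics: pd.DataFrame,
    rollup: pd.DataFrame,
    correlations: pd.DataFrame,
    config: dict,
    tests: Optional[Dict[str, TestResult]] = None,
    truth: Optional[dict] = None,
) -> dict:
    """Write the machine-readable report bundle (JSON + CSVs).

    ``config`` must carry provenance — at least ``seed`` and
    ``preset_hash`` — or the report is refused.  The report embeds all
    tables as records so re-reading round-trips to identical values, plus a
    content hash over the canonical serialization.
    """
    for key in ("seed", "preset_hash"):
        if key not in config:
            raise UsageError(f"refusing to write report without provenance '{key}'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = {
        "provenance": {
            "seed": config["seed"],
            "preset_hash": config["preset_hash"],
            "preset_name": config.get("preset_name"),
            "software_version": flodm.__version__,
            "config": _plain(config),
        },
        "metrics": _records(metrics),
        "group_rollup": _records(rollup),
        "correlations": _records(correlations),
        "tests": {k: v.as_dict() for k, v in (tests or {}).items()},
    }
    if truth is not None:
        report["ground_truth"] = {
            k: (_records(v) if isinstance(v, pd.DataFrame) else _plain(v))
            for k, v in truth.items()
        }
    canonical = json.dumps(report, sort_keys=True, separators=(",", ":"),
                           allow_nan=True)
    report["content_hash"] = hashlib.sha256(canonical.encode()).hexdigest()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")
    rollup.to_csv(outdir / "group_rollup.csv", index=False, float_format="%.6f")
    correlations.to_csv(outdir / "correlations.csv", index=False,
                        float_format="%.6f")
    return report


def load_report(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "report.json"
    with open(path) as fh:
        return json.load(fh)


def _records(df: pd.DataFrame) -> list:
    out = []
    for rec in df.to_dict(orient="records"):
        out.append({k: _plain(v) for k, v in rec.items()})
    return out


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _records(obj)
    return obj
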