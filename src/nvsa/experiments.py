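"""Experiment orchestration and nonparametric comparison statistics.

Results live in a long-format table (algorithm, scenario, run, metric, value).
Algorithms are compared with Friedman mean ranks across scenarios, pairwise
two-tailed Wilcoxon signed-rank tests (normal approximation, no continuity
correction) and Bonferroni-adjusted significance.  A transcribed reference
table of six optimizers' NMI/RMSE over 41 CT-MR registration scenarios ships
as a fixture for the statistics code.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .optimizers import OptimizerConfig
from .phantoms import make_tier_pair
from .registration import RegistrationConfig, register

__all__ = [
    "RankSummary", "WilcoxonResult", "ExperimentConfig", "load_table6",
    "friedman_mean_ranks", "wilcoxon_signed_rank", "bonferroni_adjust",
    "summarize", "pairwise_wilcoxon", "run_experiment",
]

RESULT_COLUMNS = ("algorithm", "scenario", "run", "metric", "value")


def load_table6() -> pd.DataFrame:
    """The transcribed six-algorithm NMI/RMSE reference table, long format."""
    frames = []
    for metric in ("NMI", "RMSE"):
        ref = importlib.resources.files("nvsa.data") \
            .joinpath(f"table6_{metric.lower()}.csv")
        with importlib.resources.as_file(ref) as path:
            wide = pd.read_csv(path)
        long = wide.melt(id_vars="scenario", var_name="algorithm",
                         value_name="value")
        long["metric"] = metric
        long["run"] = 0
        frames.append(long)
    return pd.concat(frames, ignore_index=True)[list(RESULT_COLUMNS)]


def _pivot(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """scenario x algorithm matrix of per-cell means over runs."""
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no records for metric {metric!r}")
    pivot = (sub.groupby(["scenario", "algorithm"], sort=False)["value"]
             .mean().unstack("algorithm"))
    if pivot.isna().any().any():
        missing = pivot.stack(future_stack=True)
        missing = missing[missing.isna()].index.tolist()
        raise ValueError(f"missing (scenario, algorithm) cells: {missing}")
    return pivot


@dataclass
class RankSummary:
    """Friedman mean ranks and the resulting ordinal standing (1 = best)."""

    mean_rank: pd.Series
    ordinal: pd.Series
    direction: str


def friedman_mean_ranks(table: pd.DataFrame, metric: str,
                        direction: str = "higher_better") -> RankSummary:
    """Friedman mean ranks of the algorithms over scenarios.

    Within each scenario algorithms are ranked 1..k ascending in value (ties
    get average ranks), so under ``higher_better`` the best value receives
    rank k and a larger mean rank is better, while under ``lower_better``
    rank 1 marks the best value and a smaller mean rank is better -- the two
    conventions used for NMI and RMSE respectively.  The ordinal standing is
    derived accordingly (competition ranking on the mean ranks).
    """
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    pivot = _pivot(table, metric)
    ranks = pivot.rank(axis=1, method="average", ascending=True)
    mean_rank = ranks.mean(axis=0)
    if direction == "higher_better":
        ordinal = pd.Series(stats.rankdata(-mean_rank.values, method="min"),
                            index=mean_rank.index, dtype=int)
    else:
        ordinal = pd.Series(stats.rankdata(mean_rank.values, method="min"),
                            index=mean_rank.index, dtype=int)
    return RankSummary(mean_rank=mean_rank, ordinal=ordinal,
                       direction=direction)


@dataclass
class WilcoxonResult:
    p: float
    r_plus: float
    r_minus: float
    z: float
    n_nonzero: int


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Paired two-tailed Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped; ties in |x - y| get average ranks;
    ``r_plus`` sums the ranks of positive differences ``x - y``.  The z score
    is ``(min(R+, R-) - m(m+1)/4) / sqrt(m(m+1)(2m+1)/24)`` without continuity
    correction, matching the reference convention where n=30 one-signed
    differences give p = 1.73e-6.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D paired samples of equal length")
    if x.size < 6:
        raise ValueError("need at least 6 pairs")
    d = x - y
    d = d[d != 0]
    m = d.size
    if m == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    w = min(r_plus, r_minus)
    mean = m * (m + 1) / 4.0
    sd = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    z = (w - mean) / sd
    p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return WilcoxonResult(p=p, r_plus=r_plus, r_minus=r_minus, z=float(z),
                          n_nonzero=m)


def bonferroni_adjust(p: float, m: int) -> float:
    """``min(1, m * p)``; the 6-algorithm pairwise family has m = C(6,2) = 15."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def summarize(table: pd.DataFrame, metric: str) -> pd.Series:
    """Per-algorithm arithmetic mean of the metric across scenarios."""
    return _pivot(table, metric).mean(axis=0)


def pairwise_wilcoxon(table: pd.DataFrame, metric: str,
                      m_family: int | None = None) -> pd.DataFrame:
    """All-pairs Wilcoxon tests over scenarios with Bonferroni adjustment."""
    pivot = _pivot(table, metric)
    algos = list(pivot.columns)
    m_family = m_family or len(algos) * (len(algos) - 1) // 2
    rows = []
    for i, a in enumerate(algos):
        for b in algos[i + 1:]:
            try:
                res = wilcoxon_signed_rank(pivot[a].values, pivot[b].values)
            except ValueError:
                rows.append({"pair": f"{a}-{b}", "p": np.nan,
                             "adj_p": np.nan, "r_plus": np.nan,
                             "r_minus": np.nan, "z": np.nan})
                continue
            rows.append({"pair": f"{a}-{b}", "p": res.p,
                         "adj_p": bonferroni_adjust(res.p, m_family),
                         "r_plus": res.r_plus, "r_minus": res.r_minus,
                         "z": res.z})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    tiers: tuple = ("easy",)
    algorithms: tuple = ("nvsa", "bsd")
    runs: int = 20
    seed: int = 0
    size: tuple = (128, 128)
    model: str = "similarity"
    histogram_bins: int = 64
    N: int = 30
    epochs: int = 100

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("tiers", "algorithms", "size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_experiment(config: ExperimentConfig,
                   out_csv=None) -> pd.DataFrame:
    """Register every (phantom tier x algorithm x run) and tabulate NMI/RMSE.

    One phantom pair per tier (seeded from ``config.seed``); each registration
    run gets its own derived seed, so reruns with the same config produce an
    identical table.
    """
    rows = []
    for t_idx, tier in enumerate(config.tiers):
        fixed, moving, _gt = make_tier_pair(tier, seed=config.seed + t_idx,
                                            size=config.size)
        for algorithm in config.algorithms:
            reg_cfg = RegistrationConfig(
                model=config.model,
                optimizer=OptimizerConfig(N=config.N, epochs=config.epochs,
                                          algorithm=algorithm),
                histogram_bins=config.histogram_bins)
            for run in range(config.runs):
                seed = config.seed + 1000 * (t_idx + 1) + run
                res = register(fixed, moving, reg_cfg, seed=seed)
                for metric, value in (("NMI", res.nmi), ("RMSE", res.rmse)):
                    rows.append({"algorithm": algorithm, "scenario": tier,
                                 "run": run, "metric": metric,
                                 "value": value})
    table = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table


def write_stats(table: pd.DataFrame, out_csv) -> pd.DataFrame:
    """Rank/significance report: Friedman mean ranks plus pairwise Wilcoxon.

    One row per (metric, kind, name): mean ranks per algorithm and, when at
    least six scenarios are available, pairwise p / Bonferroni-adjusted p.
    """
    rows = []
    for metric, direction in (("NMI", "higher_better"),
                              ("RMSE", "lower_better")):
        if not (table["metric"] == metric).any():
            continue
        ranks = friedman_mean_ranks(table, metric, direction)
        for algo, mr in ranks.mean_rank.items():
            rows.append({"metric": metric, "kind": "friedman_mean_rank",
                         "name": algo, "value": mr})
        n_scenarios = table.loc[table["metric"] == metric,
                                "scenario"].nunique()
        if n_scenarios >= 6:
            for _, r in pairwise_wilcoxon(table, metric).iterrows():
                rows.append({"metric": metric, "kind": "wilcoxon_p",
                             "name": r["pair"], "value": r["p"]})
                rows.append({"metric": metric, "kind": "wilcoxon_adj_p",
                             "name": r["pair"], "value": r["adj_p"]})
    stats_df = pd.DataFrame(rows)
    stats_df.to_csv(out_csv, index=False)
    return stats_df
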