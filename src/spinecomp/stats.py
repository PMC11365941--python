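"""Normalisation, goodness-of-fit metrics, and bootstrap statistics for
spine-trajectory cohorts.

Spine fluorescence is a volume proxy; every trajectory is normalised by the
mean of its pre-stimulation snapshots so that sizes are dimensionless with
baseline 1.  Model quality is summarised by two complementary metrics:

* **NMSE** — the mean-squared model-data error at each snapshot divided by
  that snapshot's observed variance, averaged over snapshots.  The
  per-snapshot-mean predictor attains the minimum value 1, so values near 1
  indicate the fit tracks the mean dynamics.
* **weighted R²** — an inverse-variance-weighted coefficient of determination
  comparing the prediction to the per-snapshot means against the pooled mean,
  accounting for heteroscedasticity across time points.

The transient decay of potentiation is quantified by fitting
``f(t) = a * exp(-b t) + c`` to cohort-mean trajectories, with uncertainty
from a resampling bootstrap over experiments, and paradigms are compared by
Kruskal-Wallis / Dunn tests with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpineTrajectoryDataset",
    "GoodnessOfFit",
    "ExpDecayFit",
    "normalise",
    "nmse",
    "r2w",
    "goodness_of_fit",
    "welch_fdr",
    "studentised_bootstrap_ci",
    "fit_exp_decay",
    "bootstrap_exp_decay",
    "kruskal_dunn_fdr",
]

DATA_COLUMNS = ("experiment_id", "spine_id", "position_um", "stimulated",
                "paradigm", "time_min", "fluorescence")


@dataclass
class SpineTrajectoryDataset:
    """Long-format per-spine trajectory table.

    Columns: experiment_id, spine_id, position_um, stimulated (0/1), paradigm,
    time_min (negative = pre-stimulation), fluorescence (raw J) and, after
    :func:`normalise`, size_norm (J-hat).  Optional column ``label``
    (edge/middle).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = set(DATA_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")

    @property
    def is_normalised(self) -> bool:
        return "size_norm" in self.df.columns

    @property
    def experiments(self) -> list:
        return list(self.df["experiment_id"].unique())

    def snapshot_times(self, post_only: bool = False) -> np.ndarray:
        t = np.unique(self.df["time_min"].to_numpy(float))
        return t[t >= 0] if post_only else t

    def mean_trajectory(self, stimulated_only: bool = True,
                        post_only: bool = True):
        """Cohort-mean normalised size per snapshot (times, values)."""
        df = self.df
        if stimulated_only:
            df = df[df["stimulated"].astype(bool)]
        if post_only:
            df = df[df["time_min"] >= 0]
        g = df.groupby("time_min")["size_norm"].mean()
        return g.index.to_numpy(float), g.to_numpy(float)

    def per_experiment_means(self, post_only: bool = True) -> pd.DataFrame:
        """Mean stimulated-spine trajectory of each experiment (times as columns)."""
        df = self.df[self.df["stimulated"].astype(bool)]
        if post_only:
            df = df[df["time_min"] >= 0]
        return df.pivot_table(index="experiment_id", columns="time_min",
                              values="size_norm", aggfunc="mean")

    def observations_by_snapshot(self, times) -> list:
        df = self.df[(self.df["stimulated"].astype(bool))
                     & (self.df["time_min"] >= 0)]
        return [df[np.isclose(df["time_min"], t)]["size_norm"].to_numpy(float)
                for t in times]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpineTrajectoryDataset":
        return cls(pd.read_csv(path))


def normalise(dataset, n_pre: int = 3) -> SpineTrajectoryDataset:
    """Normalise each spine's fluorescence by its pre-stimulation mean.

    Every spine must have exactly ``n_pre`` snapshots at negative times with a
    positive mean; the resulting ``size_norm`` column has per-spine
    pre-stimulation mean 1 (to floating-point precision).
    """
    df = (dataset.df if isinstance(dataset, SpineTrajectoryDataset)
          else dataset).copy()
    pre = df[df["time_min"] < 0]
    base = pre.groupby(["experiment_id", "spine_id"])["fluorescence"].agg(["mean", "count"])
    bad_count = base[base["count"] != n_pre]
    if len(bad_count):
        key = bad_count.index[0]
        raise ValueError(
            f"spine {key} has {int(bad_count['count'].iloc[0])} pre-stimulation "
            f"snapshots, expected {n_pre}")
    bad_mean = base[base["mean"] <= 0]
    if len(bad_mean):
        raise ValueError(
            f"spine {bad_mean.index[0]} has non-positive pre-stimulation mean")
    idx = pd.MultiIndex.from_frame(df[["experiment_id", "spine_id"]])
    df["size_norm"] = df["fluorescence"].to_numpy() / base["mean"].reindex(idx).to_numpy()
    return SpineTrajectoryDataset(df)


# ---------------------------------------------------------------------------
# Goodness of fit


@dataclass
class GoodnessOfFit:
    nmse: float
    r2w: float
    per_snapshot_nmse: np.ndarray
    weights: np.ndarray


def _check_obs(pred, obs):
    pred = np.asarray(pred, dtype=float)
    if pred.ndim != 1 or len(obs) != pred.size:
        raise ValueError("pred and obs must align snapshot-wise")
    obs = [np.asarray(o, dtype=float) for o in obs]
    if any(o.size < 2 for o in obs):
        raise ValueError("need >= 2 observations per snapshot")
    return pred, obs


def _drop_degenerate(pred, obs, variances):
    keep = variances > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance snapshot(s) "
                      "from goodness-of-fit sums")
    if not keep.any():
        raise ValueError("all snapshots have zero variance; metric undefined")
    return keep


def nmse(pred, obs) -> float:
    """Snapshot-averaged normalised mean squared error.

    For each snapshot j: sum_i (pred_j - obs_ji)^2 / sum_i (obs_ji - mean_j)^2,
    averaged over snapshots.  Equals exactly 1 when pred_j = mean_j for all j.
    """
    pred, obs = _check_obs(pred, obs)
    means = np.array([o.mean() for o in obs])
    ss = np.array([np.sum((o - m) ** 2) for o, m in zip(obs, means)])
    keep = _drop_degenerate(pred, obs, ss)
    comp = np.array([np.sum((pred[j] - obs[j]) ** 2) / ss[j]
                     for j in np.flatnonzero(keep)])
    return float(comp.mean())


def per_snapshot_nmse(pred, obs) -> np.ndarray:
    pred, obs = _check_obs(pred, obs)
    means = np.array([o.mean() for o in obs])
    ss = np.array([np.sum((o - m) ** 2) for o, m in zip(obs, means)])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.array([np.sum((pred[j] - obs[j]) ** 2) / ss[j]
                         for j in range(pred.size)])


def r2w(pred, obs) -> float:
    """Inverse-variance-weighted R² of the prediction against snapshot means.

    1 - sum_j w_j (pred_j - mean_j)^2 / sum_j w_j (mean_j - pooled_mean)^2
    with w_j = 1/var_j; <= 1, and 0 for the pooled-mean predictor.
    """
    pred, obs = _check_obs(pred, obs)
    means = np.array([o.mean() for o in obs])
    var = np.array([o.var(ddof=1) for o in obs])
    keep = _drop_degenerate(pred, obs, var)
    pooled = np.concatenate(obs).mean()
    w = 1.0 / var[keep]
    denom = np.sum(w * (means[keep] - pooled) ** 2)
    if denom == 0:
        raise ValueError("all snapshot means equal; weighted R^2 undefined")
    num = np.sum(w * (pred[keep] - means[keep]) ** 2)
    return float(1.0 - num / denom)


def goodness_of_fit(pred, obs) -> GoodnessOfFit:
    pred_a, obs_a = _check_obs(pred, obs)
    var = np.array([o.var(ddof=1) for o in obs_a])
    with np.errstate(divide="ignore"):
        w = np.where(var > 0, 1.0 / var, np.nan)
    return GoodnessOfFit(nmse=nmse(pred, obs), r2w=r2w(pred, obs),
                         per_snapshot_nmse=per_snapshot_nmse(pred, obs),
                         weights=w)


# ---------------------------------------------------------------------------
# Hypothesis tests


def welch_fdr(groups: dict, comparisons=None, alpha: float = 0.05) -> pd.DataFrame:
    """Welch's unequal-variance t tests with Benjamini-Hochberg adjustment.

    ``groups`` maps label -> 1-D samples; ``comparisons`` is a list of label
    pairs (defaults to all unordered pairs).  Returns a table with raw and
    adjusted two-sided p values and a significance flag at ``alpha``.
    """
    for name, vals in groups.items():
        if len(np.asarray(vals)) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    if comparisons is None:
        names = list(groups)
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in comparisons:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.array_equal(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(x, y, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table["p_raw"], alpha=alpha, method="fdr_bh")
    table["p_adj"] = p_adj
    table["significant"] = reject
    return table


def studentised_bootstrap_ci(values, n_boot: int = 1000, seed: int = 0,
                             alpha: float = 0.05) -> dict:
    """Studentised (bootstrap-t) confidence interval for the mean.

    Each replicate's mean is studentised by its own standard error; the
    resulting t* quantiles calibrate the interval around the sample mean.
    Deterministic for a given seed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 for a studentised bootstrap interval")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    sem = sd / np.sqrt(x.size)
    if sd == 0:
        warnings.warn("constant sample: zero-width interval")
        return {"mean": mean, "sem": 0.0, "ci": (mean, mean), "n_boot": n_boot}
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    bs = x[idx]
    bmean = bs.mean(axis=1)
    bsem = bs.std(ddof=1, axis=1) / np.sqrt(x.size)
    ok = bsem > 0
    tstar = (bmean[ok] - mean) / bsem[ok]
    lo_q, hi_q = np.quantile(tstar, [alpha / 2, 1 - alpha / 2])
    return {"mean": mean, "sem": sem,
            "ci": (mean - hi_q * sem, mean - lo_q * sem), "n_boot": n_boot}


# ---------------------------------------------------------------------------
# Exponential decay analysis


@dataclass
class ExpDecayFit:
    """f(t) = a exp(-b t) + c with b >= 0; optionally bootstrap distributions."""

    a: float
    b: float
    c: float
    identifiable: bool = True
    flags: list = field(default_factory=list)
    samples: np.ndarray | None = None      # (n_ok, 3) bootstrap (a, b, c)
    n_boot: int = 0
    n_failed: int = 0
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        if self.samples is None:
            raise ValueError("no bootstrap samples")
        out = []
        for j, name in enumerate(("a", "b", "c")):
            s = self.samples[:, j]
            q1, med, q3 = np.percentile(s, [25, 50, 75])
            lo, hi = np.percentile(s, [2.5, 97.5])
            out.append({"parameter": name, "mean": s.mean(), "median": med,
                        "iqr_low": q1, "iqr_high": q3, "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(out)


def fit_exp_decay(times, values) -> ExpDecayFit:
    """Least-squares fit of a exp(-b t) + c to post-stimulation means.

    Flags non-identifiability: near-constant data (b meaningless) and b ~ 0
    (a and c confounded, only a + c determined).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ValueError("need >= 3 (time, value) points")
    flags = []
    spread = y.max() - y.min()
    if spread < 1e-12:
        return ExpDecayFit(a=0.0, b=0.0, c=float(y.mean()), identifiable=False,
                           flags=["constant data: b unidentifiable"])
    a0 = y[0] - y[-1]
    b0 = 1.0 / max(t[-1] - t[0], 1e-9)
    c0 = y[-1]
    p0 = [a0 if abs(a0) > 1e-6 else spread, max(b0, 1e-4), c0]
    popt, _ = curve_fit(lambda tt, a, b, c: a * np.exp(-b * tt) + c, t, y,
                        p0=p0, bounds=([-np.inf, 0.0, -np.inf], np.inf),
                        maxfev=20000)
    a, b, c = map(float, popt)
    ident = True
    # the exponential term is unconstrained when its dynamic range over the
    # observation window is negligible (b ~ 0, or vanishing amplitude): only
    # a + c (the overall level) is then determined
    exp_range = abs(a) * abs(np.exp(-b * t[0]) - np.exp(-b * t[-1]))
    if b * (t[-1] - t[0]) < 1e-3 or exp_range < 1e-6 * max(np.abs(y).max(), 1e-12):
        flags.append("degenerate exponential: a, b, c confounded "
                     "(a + c determined)")
        ident = False
    return ExpDecayFit(a=a, b=b, c=c, identifiable=ident, flags=flags)


def bootstrap_exp_decay(cohort, n_boot: int = 1000, seed: int = 0) -> ExpDecayFit:
    """Bootstrap the exponential-decay parameters over experiments.

    ``cohort`` is a DataFrame of per-experiment mean trajectories (rows =
    experiments, columns = post-stimulation times; see
    ``SpineTrajectoryDataset.per_experiment_means``) or a
    SpineTrajectoryDataset.  Each replicate draws ceil(n/2) experiments with
    replacement, averages their trajectories, and refits; 1000 replicates by
    default.  Failed replicate fits are excluded and counted.
    """
    if isinstance(cohort, SpineTrajectoryDataset):
        cohort = cohort.per_experiment_means()
    mat = cohort.to_numpy(dtype=float)
    times = cohort.columns.to_numpy(dtype=float)
    n_exp = mat.shape[0]
    if n_exp < 2:
        raise ValueError("need >= 2 experiments to bootstrap")
    point = fit_exp_decay(times, mat.mean(axis=0))
    rng = np.random.default_rng(seed)
    m = int(np.ceil(n_exp / 2))
    samples, n_failed = [], 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_exp, size=m)
        try:
            f = fit_exp_decay(times, mat[pick].mean(axis=0))
            samples.append((f.a, f.b, f.c))
        except (ValueError, RuntimeError):
            n_failed += 1
    return ExpDecayFit(a=point.a, b=point.b, c=point.c,
                       identifiable=point.identifiable, flags=point.flags,
                       samples=np.asarray(samples), n_boot=n_boot,
                       n_failed=n_failed, seed=seed)


def kruskal_dunn_fdr(groups: dict, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise comparisons.

    Dunn's z statistics use pooled mid-ranks with tie correction; pairwise
    two-sided p values are Benjamini-Hochberg adjusted.  If all values are
    tied across groups the omnibus p is 1 and pairwise tests are skipped.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return {"omnibus_p": 1.0, "omnibus_h": 0.0, "pairwise": None}
    h, p_omni = sps.kruskal(*arrays)

    ranks = sps.rankdata(pooled)
    sizes = np.array([a.size for a in arrays])
    stops = np.cumsum(sizes)
    starts = stops - sizes
    mean_ranks = np.array([ranks[s:e].mean() for s, e in zip(starts, stops)])
    n_tot = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = np.sum(counts ** 3 - counts) / (12.0 * (n_tot - 1))
    var_unit = n_tot * (n_tot + 1) / 12.0 - tie_corr

    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_a": names[i], "group_b": names[j],
                         "z": float(z), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(table["p_raw"], alpha=alpha,
                                        method="fdr_bh")
    table["p_adj"] = p_adj
    table["significant"] = reject
    return {"omnibus_p": float(p_omni), "omnibus_h": float(h),
            "pairwise": table}
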