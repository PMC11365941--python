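"""Synthetic spine-trajectory cohorts with the structure of multi-spine
uncaging experiments.

Each experiment draws a dendritic layout whose cluster-span statistics match
the published paradigm geometry, runs the reaction-diffusion model at
ground-truth parameters, and wraps the noiseless trajectories in a
measurement model:

    J(spine, t) = baseline_spine * S(spine, t) * exp(eps),   eps ~ N(0, sigma^2)

i.e. multiplicative log-normal noise on a positive fluorescence baseline,
with three pre-stimulation snapshots at S = 1.  Spine-to-spine parameter
heterogeneity is deliberately absent: the model is an effective description
of the average spine, and only measurement noise and baseline variability
are simulated.

Cluster-span distributions (spans in μm between outermost stimulated spines):

* three — triangular(2.2, 3.2, 4.2): printed min/mean/max.
* seven — Beta(0.694, 2.452) scaled to [4.0, 33.9]: reproduces the printed
  quartiles (5.6, 14.1) and mean (10.6) exactly.
* fifteen — Beta(4.7, 1.3) scaled to [20, 30.6]: printed min/max support
  with mean 28.3.
* seven_distributed — 3x the clustered seven-spine span (the distributed
  experiments tripled the average inter-spine distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import SpineLayout
from .rdmodel import ModelParameters, REFERENCE_PARAMS, simulate
from .stats import SpineTrajectoryDataset, normalise

__all__ = [
    "CohortSpec",
    "TABLE1_COHORTS",
    "make_layout",
    "reference_layout",
    "sample_span",
    "simulate_experiment",
    "generate_cohort",
]

N_STIM = {"single": 1, "three": 3, "seven": 7, "seven_distributed": 7,
          "fifteen": 15}

#: Mean cluster spans (μm) used for reference/representative layouts.
MEAN_SPANS = {"single": 0.0, "three": 3.2, "seven": 10.6,
              "seven_distributed": 31.8, "fifteen": 28.3}

#: Cohort sizes of the experimental dataset: condition -> (paradigm, sham,
#: n_experiments, total stimulated spines entering analysis).
TABLE1_COHORTS = {
    "single": ("single", False, 13, 13),
    "single_sham": ("single", True, 13, 13),
    "single_aip": ("single", False, 6, 6),
    "single_fk506": ("single", False, 6, 6),
    "three": ("three", False, 7, 21),
    "three_sham": ("three", True, 10, 30),
    "seven": ("seven", False, 25, 174),
    "seven_sham": ("seven", True, 7, 49),
    "seven_distributed": ("seven_distributed", False, 10, 68),
    "fifteen": ("fifteen", False, 13, 181),
    "fifteen_sham": ("fifteen", True, 7, 102),
}

DEFAULT_PRE_TIMES = (-6.0, -4.0, -2.0)
DEFAULT_POST_TIMES = tuple(np.arange(2.0, 41.0, 2.0))

# frozen span-distribution constants (see module docstring)
_SEVEN_BETA = (0.6936, 2.4523, 4.0, 33.9348)
_FIFTEEN_BETA = (4.7, 1.3, 20.0, 30.6)


def sample_span(paradigm: str, rng: np.random.Generator) -> float:
    """Draw a cluster span (μm) matching the printed paradigm statistics."""
    if paradigm == "single":
        return 0.0
    if paradigm == "three":
        return float(rng.triangular(2.2, 3.2, 4.2))
    if paradigm in ("seven", "seven_distributed"):
        a, b, lo, hi = _SEVEN_BETA
        span = lo + (hi - lo) * rng.beta(a, b)
        return float(3.0 * span if paradigm == "seven_distributed" else span)
    if paradigm == "fifteen":
        a, b, lo, hi = _FIFTEEN_BETA
        return float(lo + (hi - lo) * rng.beta(a, b))
    raise ValueError(f"unknown paradigm {paradigm!r}")


def make_layout(paradigm: str, rng: np.random.Generator,
                unstim_density: float = 0.5, sham: bool = False,
                jitter: float = 0.2) -> SpineLayout:
    """Draw a layout: stimulated cluster plus interleaved unstimulated spines.

    Stimulated spines are evenly spaced across the drawn span with uniform
    jitter on interior positions (endpoints pinned, preserving the span);
    unstimulated spines are a Poisson scatter at ``unstim_density`` per μm
    over the cluster plus a 3 μm margin.  ``sham=True`` marks the same
    targeted positions but labels the layout sham (zero initial resources
    downstream).
    """
    n = N_STIM[paradigm]
    span = sample_span(paradigm, rng)
    if n == 1:
        stim = np.array([0.0])
    else:
        stim = np.linspace(0.0, span, n)
        spacing = span / (n - 1)
        stim[1:-1] += rng.uniform(-jitter, jitter, n - 2) * spacing
        stim = np.sort(stim)
    lo, hi = stim.min() - 3.0, stim.max() + 3.0
    n_unstim = rng.poisson(unstim_density * (hi - lo))
    unstim = rng.uniform(lo, hi, n_unstim)
    pos = np.concatenate([stim, unstim])
    flags = np.zeros(pos.size, dtype=bool)
    flags[:n] = True
    order = np.argsort(pos, kind="stable")
    return SpineLayout(position=pos[order], stimulated=flags[order],
                       spine_id=np.arange(pos.size),
                       paradigm="sham" if sham else paradigm)


def reference_layout(paradigm: str, span: float | None = None) -> SpineLayout:
    """Deterministic evenly-spaced stimulated cluster at the mean span."""
    n = N_STIM[paradigm]
    span = MEAN_SPANS[paradigm] if span is None else span
    pos = np.linspace(0.0, span, n) if n > 1 else np.array([0.0])
    return SpineLayout(pos, np.ones(n, dtype=bool), paradigm=paradigm)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    paradigm: str = "three"
    n_experiments: int = 7
    sham: bool = False
    noise_sigma: float = 0.05
    baseline_median: float = 100.0
    baseline_log_sd: float = 0.3
    pre_times: tuple = DEFAULT_PRE_TIMES
    post_times: tuple = DEFAULT_POST_TIMES
    params: ModelParameters = REFERENCE_PARAMS
    unstim_density: float = 0.5
    n_stim_total: int | None = None    # cap on analysed stimulated spines
    seed: int = 0
    dt: float = 0.05
    dx: float = 0.125

    def __post_init__(self):
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if len(self.pre_times) != 3:
            raise ValueError("three pre-stimulation snapshots expected")

    @classmethod
    def from_condition(cls, condition: str, **kw) -> "CohortSpec":
        """Cohort spec mirroring the experimental dataset's cohort sizes."""
        paradigm, sham, n_exp, n_spines = TABLE1_COHORTS[condition]
        return cls(paradigm=paradigm, n_experiments=n_exp, sham=sham,
                   n_stim_total=n_spines, **kw)


def simulate_experiment(layout: SpineLayout, params: ModelParameters,
                        spec: CohortSpec, rng: np.random.Generator,
                        experiment_id: str = "exp0"):
    """One experiment: model trajectories plus measurement noise.

    Returns (rows DataFrame with raw fluorescence, noiseless sizes array).
    """
    post = np.asarray(spec.post_times, dtype=float)
    sim = simulate(layout, params, post, dt=spec.dt, dx=spec.dx)
    n_sp = layout.n_spines
    all_times = np.concatenate([spec.pre_times, post])
    S = np.concatenate([np.ones((n_sp, len(spec.pre_times))), sim.sizes], axis=1)
    baseline = spec.baseline_median * np.exp(
        rng.normal(0.0, spec.baseline_log_sd, n_sp))
    eps = rng.normal(0.0, spec.noise_sigma, S.shape) if spec.noise_sigma > 0 \
        else np.zeros_like(S)
    J = baseline[:, None] * S * np.exp(eps)
    rows = pd.DataFrame({
        "experiment_id": np.repeat(experiment_id, n_sp * all_times.size),
        "spine_id": np.repeat(layout.spine_id, all_times.size),
        "position_um": np.repeat(layout.position, all_times.size),
        "stimulated": np.repeat(layout.stimulated.astype(int), all_times.size),
        "paradigm": layout.paradigm,
        "time_min": np.tile(all_times, n_sp),
        "fluorescence": J.ravel(),
    })
    return rows, S


def generate_cohort(spec: CohortSpec):
    """Generate a multi-experiment cohort and its ground-truth sidecar.

    Returns (normalised SpineTrajectoryDataset, truth dict).  The truth dict
    carries the generating parameters, per-experiment layouts, and noiseless
    trajectories for recovery tests.  If ``n_stim_total`` is below the
    nominal count, a seeded random subset of stimulated-spine observations is
    dropped, mimicking spines excluded from image analysis.
    """
    rng = np.random.default_rng(spec.seed)
    frames, truth_traj, layouts = [], {}, {}
    for k in range(spec.n_experiments):
        exp_id = f"{spec.paradigm}{'_sham' if spec.sham else ''}_{k:02d}"
        lay = make_layout(spec.paradigm, rng, spec.unstim_density, sham=spec.sham)
        rows, S = simulate_experiment(lay, spec.params, spec, rng, exp_id)
        frames.append(rows)
        layouts[exp_id] = lay
        truth_traj[exp_id] = {
            "times": np.concatenate([spec.pre_times, spec.post_times]).tolist(),
            "sizes": S.tolist(),
        }
    df = pd.concat(frames, ignore_index=True)

    if spec.n_stim_total is not None:
        stim_keys = df[df["stimulated"] == 1][["experiment_id", "spine_id"]] \
            .drop_duplicates().reset_index(drop=True)
        excess = len(stim_keys) - spec.n_stim_total
        if excess < 0:
            raise ValueError(
                f"cannot reach {spec.n_stim_total} stimulated spines; "
                f"cohort only has {len(stim_keys)}")
        if excess > 0:
            drop = stim_keys.iloc[rng.choice(len(stim_keys), excess,
                                             replace=False)]
            mask = ~(df.set_index(["experiment_id", "spine_id"]).index
                     .isin(drop.set_index(["experiment_id", "spine_id"]).index)
                     & (df["stimulated"] == 1).to_numpy())
            df = df[mask].reset_index(drop=True)

    dataset = normalise(SpineTrajectoryDataset(df))
    truth = {
        "params": spec.params.to_dict(),
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "layouts": layouts,
        "trajectories": truth_traj,
    }
    return dataset, truth
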