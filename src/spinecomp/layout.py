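"""Spine geometry along a dendrite and resource-competition factors.

A stimulation paradigm is described by the 1-D positions of spines on a
dendritic segment and a flag marking which spines were stimulated.  When
``n_stim`` spines are stimulated quasi-simultaneously they compete for the
shared dendritic pool of the fast potentiating resource.  Each stimulated
spine *i* receives a dimensionless share

    D_i = (1 + d_i) / (n_stim + n_hat)

where ``d_i`` sums saturating distance terms ``(r/(1+r))**lam`` over the
other stimulation sites (``r`` in μm), so that ``d_i -> 0`` for tight
clusters (pure 1/N competition) and ``d_i -> n_stim - 1`` for widely
separated sites (no competition, ``D_i -> 1`` when ``n_hat = 0``), and
``n_hat`` counts unstimulated neighbours close enough to at least two
stimulation sites to compete for the same resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PARADIGMS",
    "EDGE_PER_SIDE",
    "SpineLayout",
    "CompetitionFactors",
    "compute_d",
    "count_nhat",
    "compute_competition",
    "classify_edge_middle",
    "read_layout_csv",
    "write_layout_csv",
]

PARADIGMS = ("single", "three", "seven", "seven_distributed", "fifteen", "sham")

#: Published edge/middle split: number of edge spines on *each* side of the
#: sorted stimulated cluster (3-spine: 1, 7-spine: 2, 15-spine: 4).
EDGE_PER_SIDE = {"three": 1, "seven": 2, "fifteen": 4}

#: Default interaction radius (μm) within which an unstimulated spine is
#: considered "close" to a stimulation site.
DEFAULT_NHAT_RADIUS = 2.0


@dataclass(frozen=True)
class SpineLayout:
    """Spine positions (μm) along a dendrite with stimulation flags."""

    position: np.ndarray
    stimulated: np.ndarray
    spine_id: np.ndarray = None
    paradigm: str = "single"

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        stim = np.asarray(self.stimulated, dtype=bool)
        if pos.ndim != 1 or stim.shape != pos.shape:
            raise ValueError("position and stimulated must be equal-length 1-D arrays")
        if not np.all(np.isfinite(pos)):
            raise ValueError("spine positions must be finite")
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.paradigm != "sham" and not stim.any():
            raise ValueError(f"paradigm {self.paradigm!r} requires >=1 stimulated spine")
        sid = self.spine_id
        if sid is None:
            sid = np.arange(pos.size)
        sid = np.asarray(sid)
        if sid.shape != pos.shape:
            raise ValueError("spine_id must match position length")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "stimulated", stim)
        object.__setattr__(self, "spine_id", sid)

    @property
    def n_spines(self) -> int:
        return self.position.size

    @property
    def n_stim(self) -> int:
        return int(self.stimulated.sum())

    @property
    def stim_positions(self) -> np.ndarray:
        return self.position[self.stimulated]

    @property
    def cluster_span(self) -> float:
        """max - min position over stimulated spines (μm); 0 for a single spine."""
        p = self.stim_positions
        if p.size == 0:
            return 0.0
        return float(p.max() - p.min())

    def reflected(self, about: float = 0.0) -> "SpineLayout":
        """Mirror all positions about a point (the model is reflection-symmetric)."""
        return SpineLayout(2.0 * about - self.position, self.stimulated,
                           self.spine_id, self.paradigm)


@dataclass(frozen=True)
class CompetitionFactors:
    """Per-stimulated-spine allocation factors D_i and proximity sums d_i."""

    d: np.ndarray
    D: np.ndarray
    n_stim: int
    n_hat: int

    def __post_init__(self):
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))


def compute_d(layout: SpineLayout, lam: float, i: int) -> float:
    """Proximity sum d_i for stimulated spine ``i`` (index into the layout).

    d_i = sum_{j != i, j stimulated} (|x_i - x_j| / (1 + |x_i - x_j|)) ** lam

    Each summand lies in [0, 1), so 0 <= d_i < n_stim - 1.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not layout.stimulated[i]:
        raise ValueError(f"spine index {i} is not a stimulated spine")
    xi = layout.position[i]
    others = np.flatnonzero(layout.stimulated)
    others = others[others != i]
    r = np.abs(xi - layout.position[others])
    return float(np.sum((r / (1.0 + r)) ** lam))


def count_nhat(layout: SpineLayout, radius: float = DEFAULT_NHAT_RADIUS) -> int:
    """Number of unstimulated spines within ``radius`` μm of >=2 stimulation sites.

    A single global count entering every D_i identically.  "Close to multiple
    stimulation sites" requires at least two distinct sites; an unstimulated
    spine near only one site does not compete for the shared pool.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    stim_x = layout.stim_positions
    unstim_x = layout.position[~layout.stimulated]
    if stim_x.size < 2 or unstim_x.size == 0:
        return 0
    dist = np.abs(unstim_x[:, None] - stim_x[None, :])
    return int(np.count_nonzero((dist <= radius).sum(axis=1) >= 2))


def compute_competition(
    layout: SpineLayout,
    lam: float,
    radius: float = DEFAULT_NHAT_RADIUS,
    n_hat: int | None = None,
) -> CompetitionFactors:
    """Allocation factors D_i = (1 + d_i) / (n_stim + n_hat) per stimulated spine.

    ``n_hat`` overrides the counted number of competing unstimulated spines
    (useful when a layout omits unstimulated positions but an estimate of the
    heterosynaptic competitor count exists).
    """
    n = layout.n_stim
    if n == 0:
        raise ValueError("layout has no stimulated spines")
    if n_hat is None:
        n_hat = count_nhat(layout, radius)
    if n_hat < 0:
        raise ValueError("n_hat must be >= 0")
    idx = np.flatnonzero(layout.stimulated)
    d = np.array([compute_d(layout, lam, i) for i in idx])
    D = (1.0 + d) / (n + n_hat)
    return CompetitionFactors(d=d, D=D, n_stim=n, n_hat=int(n_hat))


def classify_edge_middle(
    layout: SpineLayout, edge_per_side: int | None = None
) -> np.ndarray:
    """Label each stimulated spine ``"edge"`` or ``"middle"`` by sorted position.

    The outermost ``edge_per_side`` spines on each side of the cluster are
    edges.  Defaults follow the published splits (3-spine: 1/side, 7-spine:
    2/side, 15-spine: 4/side); other paradigms need an explicit count.
    Returns labels aligned with the stimulated spines in layout order.
    Position ties are broken by spine_id order, deterministically.
    """
    if edge_per_side is None:
        try:
            edge_per_side = EDGE_PER_SIDE[layout.paradigm]
        except KeyError:
            raise ValueError(
                f"no published edge/middle split for paradigm {layout.paradigm!r}; "
                "pass edge_per_side explicitly"
            ) from None
    idx = np.flatnonzero(layout.stimulated)
    if 2 * edge_per_side >= idx.size:
        raise ValueError("edge_per_side too large for the number of stimulated spines")
    order = np.lexsort((layout.spine_id[idx], layout.position[idx]))
    labels_sorted = np.full(idx.size, "middle", dtype=object)
    labels_sorted[:edge_per_side] = "edge"
    labels_sorted[idx.size - edge_per_side:] = "edge"
    labels = np.empty(idx.size, dtype=object)
    labels[order] = labels_sorted
    return labels.astype(str)


# ---------------------------------------------------------------------------
# CSV round-tripping


def layouts_to_frame(layouts: dict[str, SpineLayout]) -> pd.DataFrame:
    rows = []
    for exp_id, lay in layouts.items():
        for k in range(lay.n_spines):
            rows.append(
                dict(
                    experiment_id=exp_id,
                    spine_id=lay.spine_id[k],
                    position_um=lay.position[k],
                    stimulated=int(lay.stimulated[k]),
                    paradigm=lay.paradigm,
                )
            )
    return pd.DataFrame(rows)


def frame_to_layouts(df: pd.DataFrame) -> dict[str, SpineLayout]:
    required = {"experiment_id", "spine_id", "position_um", "stimulated", "paradigm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"layout table missing columns: {sorted(missing)}")
    out = {}
    for exp_id, g in df.groupby("experiment_id", sort=False):
        paradigms = g["paradigm"].unique()
        if len(paradigms) != 1:
            raise ValueError(f"experiment {exp_id!r} mixes paradigms {paradigms}")
        out[exp_id] = SpineLayout(
            position=g["position_um"].to_numpy(float),
            stimulated=g["stimulated"].to_numpy().astype(bool),
            spine_id=g["spine_id"].to_numpy(),
            paradigm=str(paradigms[0]),
        )
    return out


def read_layout_csv(path) -> dict[str, SpineLayout]:
    return frame_to_layouts(pd.read_csv(path))


def write_layout_csv(layouts: dict[str, SpineLayout], path) -> None:
    layouts_to_frame(layouts).to_csv(path, index=False)
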