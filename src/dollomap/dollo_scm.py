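"""Dollo stochastic character mapping of binary family gains and losses.

Under the Dollo assumption each family is gained exactly once — on the
terminal branch for singletons, otherwise on the branch subtending the least
inclusive clade of taxa possessing it — and can only be lost thereafter.
Because irreversibility forces every internal state (a node carries the
family iff any descendant tip does), the branch placement of the gain and of
every loss is deterministic; only the position of each event *along* its
branch is stochastic.  Mapping therefore decomposes into a deterministic
placement stage and a stochastic timing stage, replicated many times to
propagate timing uncertainty into downstream rate estimates.

The model-object entry point is :class:`DolloCharacterMapping`, whose
``fit`` returns a :class:`DolloMappingResults` carrying the replicated event
maps and the derived rate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .treeio import PresenceMatrix, TimeTree

__all__ = [
    "GainPlacement",
    "LossPlacement",
    "LossBounds",
    "TimedEventMap",
    "DolloEventMaps",
    "infer_gain_branch",
    "infer_loss_branches",
    "sample_event_times",
    "run_dollo_scm",
    "loss_bounds",
    "DolloCharacterMapping",
    "DolloMappingResults",
]


@dataclass(frozen=True)
class GainPlacement:
    """The single gain of a family: the branch above ``branch`` (child id)."""

    family: str
    branch: int  # child node id; tree.branch(branch) gives the interval


@dataclass(frozen=True)
class LossPlacement:
    """Stem branches of the maximal all-absent subtrees inside the gain clade."""

    family: str
    branches: tuple[int, ...]

    @property
    def n_losses(self) -> int:
        return len(self.branches)


@dataclass(frozen=True)
class LossBounds:
    """Min/max observable losses for a family given its presence pattern.

    min is always 0.  max is 0 for singletons and for families whose least
    inclusive clade has two tips, else N - 2 where N is the clade's tip
    count (all losses on terminal branches, with two presences needed to
    define the clade).
    """

    family: str
    min_losses: int
    max_losses: int


@dataclass
class TimedEventMap:
    """One replicate's full event history: (family, type, branch, time)."""

    replicate: int
    seed: int
    events: pd.DataFrame  # columns family, type, branch, time

    def total(self, kind: str) -> int:
        return int((self.events["type"] == kind).sum())


def _presence_tips(family: pd.Series, tree: TimeTree) -> np.ndarray:
    vec = family.reindex(tree.tip_labels)
    if vec.isna().any():
        missing = list(vec.index[vec.isna()])
        raise KeyError(f"family {family.name!r} lacks states for tips {missing}")
    return vec.to_numpy(dtype=bool)


def infer_gain_branch(family: pd.Series, tree: TimeTree) -> GainPlacement:
    """Place the family's single gain.

    Singletons gain on their terminal branch; otherwise the gain sits on the
    branch subtending the MRCA of all presence tips.  Families present on
    both sides of the root require a root stem to host the gain.
    """
    present = _presence_tips(family, tree)
    if not present.any():
        raise ValueError(f"family {family.name!r} is absent from every tip")
    tip_ids = tree.tip_ids[present]
    if len(tip_ids) == 1:
        return GainPlacement(str(family.name), int(tip_ids[0]))
    node = tree.mrca(tip_ids)
    if node == tree.root and not tree.has_stem:
        raise ValueError(
            f"family {family.name!r} spans the root but the tree has no root stem; "
            "supply stem_age (e.g. the analysis horizon) when reading the tree"
        )
    return GainPlacement(str(family.name), node)


def infer_loss_branches(
    family: pd.Series, tree: TimeTree, gain: GainPlacement | None = None
) -> LossPlacement:
    """Deterministic loss placement inside the gain clade.

    With presence fixed at the gain node and only 1->0 transitions allowed,
    a node is present iff any descendant tip is present; the losses are the
    stem branches of the maximal all-absent subtrees.  This is the unique
    minimum-loss irreversible history.
    """
    if gain is None:
        gain = infer_gain_branch(family, tree)
    present = _presence_tips(family, tree)
    tipdesc = tree.tip_descendants()
    if not (present <= tipdesc[gain.branch]).all():
        raise ValueError(
            f"gain clade for family {family.name!r} does not contain all presence tips"
        )
    state = (tipdesc & present).any(axis=1)  # per-node: any present tip below
    clade = tree.subtree_nodes(gain.branch)
    in_clade = np.zeros(tree.n_nodes, dtype=bool)
    in_clade[clade] = True
    losses = [
        int(v)
        for v in clade
        if v != gain.branch and not state[v] and state[tree.parent[v]]
    ]
    return LossPlacement(str(family.name), tuple(sorted(losses)))


def loss_bounds(matrix: PresenceMatrix, tree: TimeTree) -> pd.DataFrame:
    """Per-family (min, max) observable losses, plus the N-2 rule inputs.

    Returns a DataFrame indexed by family with columns ``clade_tips``,
    ``min_losses``, ``max_losses``; the summed maximum is
    ``out['max_losses'].sum()``.
    """
    matrix = matrix.bind(tree)
    tipdesc = tree.tip_descendants()
    rows = {}
    for fam in matrix.families:
        gain = infer_gain_branch(matrix.family(fam), tree)
        n = int(tipdesc[gain.branch].sum())
        rows[fam] = (n, 0, 0 if n <= 2 else n - 2)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["clade_tips", "min_losses", "max_losses"]
    ).rename_axis("family")


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------


def _branch_interval(tree: TimeTree, child: int) -> tuple[float, float]:
    b = tree.branch(child)
    return b.end, b.start


def sample_event_times(
    placements: pd.DataFrame,
    tree: TimeTree,
    rng: np.random.Generator | int | None = None,
    loss_timing: str = "uniform",
    loss_rate: float | None = None,
) -> pd.DataFrame:
    """Draw one replicate of event times for a placement table.

    ``placements`` has columns family, type, branch.  Gain times are uniform
    on their branch interval; loss times are uniform by default, or
    truncated-exponential (clock running tipward from the branch's older
    end, rate ``loss_rate`` per Myr) when ``loss_timing='exponential'``.
    Zero-length branches yield the shared endpoint exactly.  Within each
    family the gain always precedes its losses because a loss branch is a
    strict descendant of the gain branch, so their age intervals are
    disjoint; this is asserted, not conditioned on.
    """
    rng = np.random.default_rng(rng)
    lo = np.empty(len(placements))
    hi = np.empty(len(placements))
    for k, br in enumerate(placements["branch"].to_numpy()):
        lo[k], hi[k] = _branch_interval(tree, int(br))
    u = rng.uniform(size=len(placements))
    is_loss = (placements["type"] == "loss").to_numpy()
    if loss_timing == "uniform":
        t = lo + u * (hi - lo)
    elif loss_timing == "exponential":
        if loss_rate is None or loss_rate <= 0:
            raise ValueError("loss_timing='exponential' requires a positive loss_rate")
        t = lo + u * (hi - lo)
        span = hi - lo
        with np.errstate(divide="ignore", invalid="ignore"):
            # inverse CDF of Exp(loss_rate) truncated to [0, span], measured from hi
            z = -np.log1p(-u * (1.0 - np.exp(-loss_rate * span))) / loss_rate
        t_exp = hi - z
        t = np.where(is_loss & (span > 0), t_exp, t)
    else:
        raise ValueError(f"unknown loss_timing {loss_timing!r}")
    out = placements.copy()
    out["time"] = t
    _assert_gain_precedes_losses(out)
    return out


def _assert_gain_precedes_losses(events: pd.DataFrame) -> None:
    gains = events.loc[events["type"] == "gain"].set_index("family")["time"]
    losses = events.loc[events["type"] == "loss"]
    if len(losses):
        gt = gains.reindex(losses["family"]).to_numpy()
        if not (losses["time"].to_numpy() <= gt + 1e-9).all():
            raise AssertionError("a loss time precedes its family's gain time")


@dataclass
class DolloEventMaps:
    """Replicated event maps with shared placements and per-replicate times.

    ``placements`` has one row per event (family, type, branch, start, end);
    ``times`` is (n_events, n_reps).  Branch assignments — and hence all
    counts — are identical across replicates; only times differ.
    """

    placements: pd.DataFrame
    times: np.ndarray
    seed: int | None
    tree: TimeTree = field(repr=False)
    n_families: int
    loss_timing: str = "uniform"

    @property
    def n_reps(self) -> int:
        return self.times.shape[1]

    def replicate(self, r: int) -> TimedEventMap:
        ev = self.placements[["family", "type", "branch"]].copy()
        ev["time"] = self.times[:, r]
        return TimedEventMap(replicate=r, seed=self.seed, events=ev)

    def __iter__(self) -> Iterator[TimedEventMap]:
        for r in range(self.n_reps):
            yield self.replicate(r)

    def to_long_frame(self) -> pd.DataFrame:
        """One row per (replicate, event); suitable for treeio.write_events."""
        frames = []
        for r in range(self.n_reps):
            ev = self.replicate(r).events.copy()
            ev.insert(0, "replicate", r)
            frames.append(ev)
        return pd.concat(frames, ignore_index=True)

    def loss_counts(self) -> pd.Series:
        """Per-family loss count (replicate-invariant)."""
        losses = self.placements[self.placements["type"] == "loss"]
        counts = losses.groupby("family").size()
        fams = self.placements.loc[self.placements["type"] == "gain", "family"]
        return counts.reindex(fams, fill_value=0).astype(int).rename("n_losses")


def _build_placements(matrix: PresenceMatrix, tree: TimeTree) -> pd.DataFrame:
    rows = []
    for fam in matrix.families:
        col = matrix.family(fam)
        gain = infer_gain_branch(col, tree)
        b = tree.branch(gain.branch)
        rows.append((fam, "gain", gain.branch, b.start, b.end))
        loss = infer_loss_branches(col, tree, gain)
        for v in loss.branches:
            bb = tree.branch(v)
            rows.append((fam, "loss", v, bb.start, bb.end))
    return pd.DataFrame(rows, columns=["family", "type", "branch", "start", "end"])


def run_dollo_scm(
    matrix: PresenceMatrix,
    tree: TimeTree,
    n_reps: int = 1000,
    seed: int | None = None,
    loss_timing: str = "uniform",
    loss_rate: float | None = None,
) -> DolloEventMaps:
    """Run replicated Dollo stochastic character mapping.

    Placements are computed once; replicate ``r`` draws its times from an
    independent RNG stream spawned from the master seed, so each replicate
    is individually reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    matrix = matrix.bind(tree)
    placements = _build_placements(matrix, tree)
    lo = placements["end"].to_numpy()
    hi = placements["start"].to_numpy()
    is_loss = (placements["type"] == "loss").to_numpy()
    span = hi - lo
    times = np.empty((len(placements), n_reps))
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        u = rng.uniform(size=len(placements))
        t = lo + u * span
        if loss_timing == "exponential":
            if loss_rate is None or loss_rate <= 0:
                raise ValueError("loss_timing='exponential' requires a positive loss_rate")
            with np.errstate(divide="ignore", invalid="ignore"):
                z = -np.log1p(-u * (1.0 - np.exp(-loss_rate * span))) / loss_rate
            t = np.where(is_loss & (span > 0), hi - z, t)
        elif loss_timing != "uniform":
            raise ValueError(f"unknown loss_timing {loss_timing!r}")
        times[:, r] = t
    out = DolloEventMaps(
        placements=placements,
        times=times,
        seed=seed,
        tree=tree,
        n_families=matrix.shape[0],
        loss_timing=loss_timing,
    )
    _assert_gain_precedes_losses(out.replicate(0).events)
    return out


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class DolloCharacterMapping:
    """Dollo stochastic character mapping model for a matrix bound to a timetree.

    Parameters
    ----------
    matrix : PresenceMatrix
        Binary families x taxa matrix; taxa must equal the tree's tips.
    tree : TimeTree
        Rooted timetree in Ma/Myr.

    ``fit(n_reps, seed)`` performs the replicated mapping and returns a
    :class:`DolloMappingResults`.
    """

    def __init__(self, matrix: PresenceMatrix, tree: TimeTree):
        self.tree = tree
        self.matrix = matrix.bind(tree)

    @classmethod
    def from_files(cls, matrix_path, tree_path, **kw) -> "DolloCharacterMapping":
        from .treeio import read_matrix, read_timetree

        stem_age = kw.pop("stem_age", None)
        tree = read_timetree(tree_path, stem_age=stem_age)
        matrix = read_matrix(matrix_path, **kw)
        return cls(matrix, tree)

    def fit(
        self,
        n_reps: int = 1000,
        seed: int | None = None,
        loss_timing: str = "uniform",
        loss_rate: float | None = None,
    ) -> "DolloMappingResults":
        maps = run_dollo_scm(
            self.matrix, self.tree, n_reps=n_reps, seed=seed,
            loss_timing=loss_timing, loss_rate=loss_rate,
        )
        return DolloMappingResults(self, maps)


class DolloMappingResults:
    """Results of a replicated Dollo mapping run.

    Exposes the standard summaries: per-branch rates, per-time-bin rate
    series with Monte-Carlo CIs, root-to-tip lineage summaries, the
    loss-count histogram and the min/max loss bounds.
    """

    def __init__(self, model: DolloCharacterMapping, event_maps: DolloEventMaps):
        self.model = model
        self.event_maps = event_maps

    @property
    def tree(self) -> TimeTree:
        return self.model.tree

    @property
    def n_reps(self) -> int:
        return self.event_maps.n_reps

    def total_gains(self) -> int:
        return int((self.event_maps.placements["type"] == "gain").sum())

    def total_losses(self) -> int:
        return int((self.event_maps.placements["type"] == "loss").sum())

    def branch_rates(self) -> pd.DataFrame:
        from .rates import per_branch_rates

        return per_branch_rates(self.event_maps, self.tree)

    def rate_series(self, bin_width: float = 10.0, horizon: float = 720.0):
        from .rates import binned_rate_series

        return binned_rate_series(self.event_maps, bin_width=bin_width, horizon=horizon)

    def lineage_summaries(self) -> pd.DataFrame:
        from .rates import lineage_summary_table

        return lineage_summary_table(self.event_maps, self.tree)

    def loss_histogram(self) -> pd.Series:
        from .rates import loss_count_distribution

        return loss_count_distribution(self.event_maps)

    def loss_bounds(self) -> pd.DataFrame:
        return loss_bounds(self.model.matrix, self.tree)

    def plot_rate_series(self, bin_width: float = 10.0, horizon: float = 720.0, ax=None):
        """Mean per-bin gain/loss counts with the 95% Monte-Carlo band."""
        import matplotlib.pyplot as plt

        series = self.rate_series(bin_width=bin_width, horizon=horizon)
        if ax is None:
            _, ax = plt.subplots()
        for kind, color in (("gain", "tab:blue"), ("loss", "tab:red")):
            s = series[kind].summary
            ax.plot(s["bin_old"], s["mean"], color=color, label=f"{kind}s")
            ax.fill_between(s["bin_old"], s["lo"], s["hi"], color=color, alpha=0.2)
        ax.set_xlabel("age (Ma)")
        ax.set_ylabel(f"events per {bin_width:g}-Myr bin")
        ax.invert_xaxis()
        ax.legend()
        return ax

    def summary(self) -> str:
        hist = self.loss_histogram()
        bounds = self.loss_bounds()
        n_fam = self.event_maps.n_families
        zero = int(hist.get(0, 0))
        lines = [
            "Dollo stochastic character mapping",
            "=" * 50,
            f"families:            {n_fam}",
            f"taxa:                {self.tree.n_tips}",
            f"replicates:          {self.n_reps}",
            f"loss timing:         {self.event_maps.loss_timing}",
            f"total gains:         {self.total_gains()}",
            f"total losses:        {self.total_losses()}",
            f"families w/o loss:   {zero} ({100.0 * zero / n_fam:.1f}%)",
            f"summed max losses:   {int(bounds['max_losses'].sum())}",
            "loss-count histogram: "
            + ", ".join(f"{k}:{v}" for k, v in hist.items()),
        ]
        return "\n".join(lines)
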