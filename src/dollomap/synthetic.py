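"""Synthetic presence/absence data with ground truth, and annotation noise.

The generator realizes the irreversible birth/death process the mapping
stages assume: family origins arrive as a Poisson process along branch time
(optionally time-varying and with per-branch burst multipliers), and each
family, once gained, is lost independently on each descendant lineage at a
constant exponential rate, never to be regained.  Families that end with no
surviving presences are retained in the ground truth but excluded from the
emitted matrix, mimicking real ascertainment (an all-absent family cannot
be observed).

An annotation-noise injector corrupts a matrix the way poorly annotated
repertoires do: false negatives (a present family recorded absent in a tip,
as with low-coverage genomes) and false-positive spurious singleton
families (misannotated sequences present in one tip only).  Every
corruption is recorded in a manifest.

A reversible 2-state chain simulator is also provided for checking the ML
rate model against data generated under exactly its own assumptions.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treeio import PresenceMatrix, TimeTree

__all__ = [
    "SimConfig",
    "SimTruth",
    "NoiseConfig",
    "simulate_matrix",
    "inject_noise",
    "simulate_markov_matrix",
    "pure_birth_tree",
    "load_fixture_timetree",
    "study_scale_config",
    "minimal_history_families",
    "recovery_experiment",
]

# step function: list of (older edge, younger edge, families per Myr)
Intensity = float | list[tuple[float, float, float]]


@dataclass
class SimConfig:
    """Configuration of the irreversible gain/loss simulator.

    gain_intensity : families per Myr of branch time — a constant, or a
        step function as (older, younger, rate) intervals in Ma.
    loss_rate : per-family per-lineage loss rate, per Myr (irreversible).
    burst_branches : branch child-id -> gain-intensity multiplier, for
        programming bursts on specific branches.
    """

    tree: TimeTree
    gain_intensity: Intensity
    loss_rate: float
    seed: int | None = None
    burst_branches: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.loss_rate < 0:
            raise ValueError("loss_rate must be >= 0")
        for rate in self._steps():
            if rate[2] < 0:
                raise ValueError("gain intensities must be >= 0")
        for mult in self.burst_branches.values():
            if mult <= 0:
                raise ValueError("burst multipliers must be > 0")

    def _steps(self) -> list[tuple[float, float, float]]:
        if isinstance(self.gain_intensity, (int, float)):
            return [(np.inf, -np.inf, float(self.gain_intensity))]
        return list(self.gain_intensity)

    def intensity_mass(self, start: float, end: float) -> float:
        """Integral of the gain intensity over the age interval [end, start]."""
        total = 0.0
        for old, young, rate in self._steps():
            lo = max(end, min(young, start))
            hi = min(start, max(old, end))
            o = min(start, old)
            y = max(end, young)
            if o > y:
                total += rate * (o - y)
        return total


@dataclass
class SimTruth:
    """Ground-truth event log of one simulation.

    ``gains``/``losses`` are event tables (family, branch, time); ``tip_states``
    covers every simulated family, including families lost everywhere
    (``observable`` False) which the emitted matrix omits.
    """

    gains: pd.DataFrame
    losses: pd.DataFrame
    tip_states: pd.DataFrame
    observable: pd.Series

    def loss_counts(self, observable_only: bool = True) -> pd.Series:
        fams = self.tip_states.index[self.observable] if observable_only else self.tip_states.index
        counts = self.losses.groupby("family").size()
        return counts.reindex(fams, fill_value=0).astype(int).rename("n_losses")


def _sample_gain_times(config: SimConfig, start: float, end: float, n: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Times of n gains on a branch, density proportional to the intensity."""
    segs = []
    for old, young, rate in config._steps():
        o = min(start, old)
        y = max(end, young)
        if o > y and rate > 0:
            segs.append((o, y, rate * (o - y)))
    if not segs:
        return np.full(n, np.nan)
    w = np.array([s[2] for s in segs])
    pick = rng.choice(len(segs), size=n, p=w / w.sum())
    out = np.empty(n)
    for k, i in enumerate(pick):
        o, y, _ = segs[i]
        out[k] = rng.uniform(y, o)
    return out


def simulate_matrix(config: SimConfig) -> tuple[PresenceMatrix, SimTruth]:
    """Simulate a presence/absence matrix with its ground-truth event log."""
    tree = config.tree
    rng = np.random.default_rng(config.seed)
    branches = tree.branches(include_stem=tree.has_stem)
    masses = []
    for b in branches:
        m = config.intensity_mass(b.start, b.end)
        m *= config.burst_branches.get(b.child, 1.0)
        masses.append(m)
    if tree.total_branch_time(include_stem=tree.has_stem) <= 0:
        raise ValueError("tree has zero total branch time")

    gain_rows, loss_rows, state_rows, fam_ids = [], [], [], []
    fam_no = 0
    for b, mass in zip(branches, masses):
        n_gain = rng.poisson(mass)
        if n_gain == 0:
            continue
        t_gains = _sample_gain_times(config, b.start, b.end, n_gain, rng)
        for t0 in sorted(t_gains, reverse=True):
            fam_no += 1
            fam = f"fam{fam_no:05d}"
            fam_ids.append(fam)
            gain_rows.append((fam, b.child, float(t0)))
            present = dict.fromkeys(tree.tip_labels, 0)
            _propagate_losses(tree, b.child, float(t0), config.loss_rate, rng,
                              fam, loss_rows, present)
            state_rows.append(present)

    if fam_no == 0:
        warnings.warn("simulation produced no families (gain intensity too low?)")
        tip_states = pd.DataFrame(columns=tree.tip_labels, dtype=np.int8)
        truth = SimTruth(
            gains=pd.DataFrame(columns=["family", "branch", "time"]),
            losses=pd.DataFrame(columns=["family", "branch", "time"]),
            tip_states=tip_states,
            observable=pd.Series(dtype=bool),
        )
        return PresenceMatrix(tip_states), truth

    tip_states = pd.DataFrame(state_rows, index=fam_ids, columns=tree.tip_labels, dtype=np.int8)
    observable = tip_states.sum(axis=1) > 0
    truth = SimTruth(
        gains=pd.DataFrame(gain_rows, columns=["family", "branch", "time"]),
        losses=pd.DataFrame(loss_rows, columns=["family", "branch", "time"]),
        tip_states=tip_states,
        observable=observable.rename("observable"),
    )
    if not observable.any():
        raise ValueError("every simulated family was lost before the tips; lower loss_rate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = PresenceMatrix(tip_states.loc[observable])
    return matrix, truth


def _propagate_losses(tree, node, t_from, loss_rate, rng, fam, loss_rows, present):
    """Run the lineage from age t_from down the branch above ``node`` and below."""
    end = float(tree.age[node])
    span = t_from - end
    if loss_rate > 0 and span > 0:
        w = rng.exponential(1.0 / loss_rate)
        if w < span:
            loss_rows.append((fam, node, t_from - w))
            return
    if not tree.children[node]:
        present[tree.labels[node]] = 1
        return
    for c in tree.children[node]:
        _propagate_losses(tree, c, end, loss_rate, rng, fam, loss_rows, present)


# ---------------------------------------------------------------------------
# annotation noise
# ---------------------------------------------------------------------------


@dataclass
class NoiseConfig:
    """False-negative masking and false-positive singleton injection.

    fn_rate : probability a present cell is recorded absent — a scalar, or
        a per-taxon dict (unlisted taxa get 0), emulating low-coverage
        genomes.
    fp_singletons : number of spurious families present only in that tip —
        a scalar applied to every taxon, or a per-taxon dict.
    """

    fn_rate: float | dict[str, float] = 0.0
    fp_singletons: int | dict[str, int] = 0
    seed: int | None = None

    def fn_for(self, taxon: str) -> float:
        r = self.fn_rate.get(taxon, 0.0) if isinstance(self.fn_rate, dict) else self.fn_rate
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"false-negative rate {r} outside [0, 1]")
        return float(r)

    def fp_for(self, taxon: str) -> int:
        c = self.fp_singletons.get(taxon, 0) if isinstance(self.fp_singletons, dict) else self.fp_singletons
        if c < 0:
            raise ValueError("false-positive counts must be >= 0")
        return int(c)


def inject_noise(matrix: PresenceMatrix, config: NoiseConfig) -> tuple[PresenceMatrix, dict]:
    """Corrupt a matrix per the noise config; return it with a manifest.

    The manifest lists every masked (family, taxon) cell, every appended
    spurious family, and any family dropped because masking removed its
    last presence; it exactly explains the difference between input and
    output.
    """
    rng = np.random.default_rng(config.seed)
    data = matrix.data.copy()
    masked: list[tuple[str, str]] = []
    for taxon in data.columns:
        r = config.fn_for(taxon)
        if r <= 0:
            continue
        present = data.index[data[taxon] == 1]
        hits = present[rng.uniform(size=len(present)) < r]
        data.loc[hits, taxon] = 0
        masked.extend((fam, taxon) for fam in hits)
    added: list[str] = []
    fp_blocks = []
    for taxon in data.columns:
        k = config.fp_for(taxon)
        for i in range(k):
            fam = f"fp_{taxon}_{i + 1}"
            row = pd.Series(0, index=data.columns, name=fam, dtype=np.int8)
            row[taxon] = 1
            fp_blocks.append(row)
            added.append(fam)
    if fp_blocks:
        data = pd.concat([data, pd.DataFrame(fp_blocks)])
    dropped = list(data.index[data.sum(axis=1) == 0])
    data = data.loc[data.sum(axis=1) > 0]
    manifest = {
        "masked_cells": masked,
        "added_singletons": added,
        "dropped_all_absent": dropped,
        "seed": config.seed,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PresenceMatrix(data), manifest


# ---------------------------------------------------------------------------
# reversible-chain simulation (for the ML model)
# ---------------------------------------------------------------------------


def simulate_markov_matrix(
    tree: TimeTree,
    gain_rate: float,
    loss_rate: float,
    n_families: int,
    seed: int | None = None,
) -> tuple[PresenceMatrix, int]:
    """Simulate families under the reversible 2-state chain, root absent.

    Matches the ML model exactly (regain allowed).  All-absent families are
    dropped, mirroring ascertainment; returns the matrix and the number of
    unobservable families dropped.
    """
    from .mlmodel import transition_matrix

    rng = np.random.default_rng(seed)
    order = tree.postorder[::-1]  # preorder
    P = {int(c): transition_matrix(gain_rate, loss_rate, tree.branch(int(c)).duration)
         for c in order if tree.parent[int(c)] >= 0}
    states = np.zeros((tree.n_nodes, n_families), dtype=np.int8)
    for nd in order:
        nd = int(nd)
        if tree.parent[nd] < 0:
            continue  # root stays absent
        p = states[int(tree.parent[nd])]
        p1 = np.where(p == 1, P[nd][1, 1], P[nd][0, 1])
        states[nd] = rng.uniform(size=n_families) < p1
    tips = tree.tip_ids
    df = pd.DataFrame(
        states[tips].T,
        index=[f"fam{i + 1:05d}" for i in range(n_families)],
        columns=[tree.labels[int(t)] for t in tips],
        dtype=np.int8,
    )
    keep = df.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PresenceMatrix(df.loc[keep]), n_dropped


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def pure_birth_tree(
    n_tips: int,
    root_age: float,
    seed: int | None = None,
    stem_age: float | None = None,
) -> TimeTree:
    """Random bifurcating timetree: uniform split ages, uniform lineage choice.

    A lightweight convenience (not an exact Yule sample): n_tips - 2 split
    ages are drawn uniformly on (0, root_age) and attached to random open
    lineages, tips sit at 0 Ma.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    parent: list[int] = [-1]
    children: list[list[int]] = [[]]
    age: list[float] = [float(root_age)]
    labels: list[str | None] = [None]

    def new_node(p: int, a: float) -> int:
        parent.append(p)
        children.append([])
        children[p].append(len(parent) - 1)
        age.append(a)
        labels.append(None)
        return len(parent) - 1

    open_nodes = [new_node(0, root_age), new_node(0, root_age)]
    # placeholder ages for open nodes are overwritten on split or at tip time
    for t in sorted(rng.uniform(0, root_age, size=n_tips - 2), reverse=True):
        i = rng.integers(len(open_nodes))
        nd = open_nodes.pop(int(i))
        age[nd] = float(t)
        open_nodes.extend([new_node(nd, t), new_node(nd, t)])
    width = len(str(n_tips))
    for k, nd in enumerate(open_nodes):
        age[nd] = 0.0
        labels[nd] = f"T{k + 1:0{width}d}"
    return TimeTree(parent, children, age, labels, stem_age=stem_age)


_FIXTURE_NAME = "timetree35_synthetic.nwk"


def load_fixture_timetree() -> TimeTree:
    """The committed synthetic 35-taxon, 720-Ma fixture timetree.

    A seeded random timetree (root 693 Ma, stem to 720 Ma) standing in for
    a real metazoan constraint timetree in tests and examples; it is
    synthetic, not a published topology.
    """
    ref = importlib.resources.files("dollomap.data").joinpath(_FIXTURE_NAME)
    return TimeTree.from_newick(ref.read_text())


def study_scale_config(
    tree: TimeTree,
    n_families: float = 1139.0,
    loss_rate: float = 5e-4,
    seed: int | None = None,
) -> SimConfig:
    """Simulator defaults emulating a curated metazoan-scale data set.

    Gain intensity is set so the expected number of simulated families
    equals ``n_families`` over the tree's total branch time; the default
    loss rate (5e-4 per family per lineage-Myr) is calibrated so that on
    the 35-taxon fixture tree ~92% of families are never lost (~0.13
    losses per family), the rare-loss regime of well-curated repertoires.
    """
    total = tree.total_branch_time(include_stem=tree.has_stem)
    return SimConfig(tree=tree, gain_intensity=n_families / total, loss_rate=loss_rate, seed=seed)


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------


def minimal_history_families(truth: SimTruth, tree: TimeTree) -> list[str]:
    """Observable families whose true event log is already the minimal
    irreversible history, judged from the truth alone.

    True losses are recoverable exactly when (a) the MRCA of the surviving
    presence tips is the gain node itself (no early loss pruned one flank)
    and (b) every loss branch's parent retains at least one present
    descendant tip (no two sibling subtrees both lost).  For such families
    parsimony must recover the true loss count; for the rest it undercounts.
    """
    tipdesc = tree.tip_descendants()
    gains = truth.gains.set_index("family")["branch"]
    loss_by_fam = truth.losses.groupby("family")["branch"].apply(list)
    out = []
    for fam in truth.tip_states.index[truth.observable]:
        present = truth.tip_states.loc[fam].reindex(tree.tip_labels).to_numpy(dtype=bool)
        tip_ids = tree.tip_ids[present]
        gain_node = int(gains[fam])
        if len(tip_ids) == 1:
            mrca = int(tip_ids[0])
        else:
            mrca = tree.mrca(tip_ids)
        if mrca != gain_node:
            continue
        state = (tipdesc & present).any(axis=1)
        ok = True
        for lb in loss_by_fam.get(fam, []):
            p = int(tree.parent[lb])
            if p < 0 or not state[p]:
                ok = False
                break
        if ok:
            out.append(fam)
    return out


def recovery_experiment(
    sim_config: SimConfig,
    noise_config: NoiseConfig | None = None,
    markov_truth: tuple[float, float, int] | None = None,
    n_reps: int = 100,
    bin_width: float = 10.0,
    horizon: float = 720.0,
    recent_window: float = 100.0,
    seed: int | None = None,
) -> dict:
    """End-to-end simulate -> map -> rates -> fit recovery report.

    Returns a dict with the true vs Dollo-inferred loss histograms, the ML
    rate recovery (when ``markov_truth = (g*, l*, n_families)`` is given),
    and the clean-vs-noisy contrast in recent (youngest ``recent_window``
    Myr) gain and loss counts.
    """
    from .dollo_scm import DolloCharacterMapping
    from .mlmodel import GainLossMarkovModel
    from .rates import loss_count_distribution

    tree = sim_config.tree
    matrix, truth = simulate_matrix(sim_config)
    res = DolloCharacterMapping(matrix, tree).fit(n_reps=n_reps, seed=seed)
    inferred = res.event_maps.loss_counts()
    true_counts = truth.loss_counts(observable_only=True)
    report: dict = {
        "n_families_observable": int(matrix.shape[0]),
        "n_families_simulated": int(truth.tip_states.shape[0]),
        "true_loss_histogram": true_counts.value_counts().sort_index().to_dict(),
        "inferred_loss_histogram": loss_count_distribution(res.event_maps).to_dict(),
        "total_true_losses": int(true_counts.sum()),
        "total_inferred_losses": int(inferred.sum()),
        "minimal_history_families": len(minimal_history_families(truth, tree)),
    }
    if markov_truth is not None:
        g_true, l_true, n_fam = markov_truth
        mmat, n_dropped = simulate_markov_matrix(tree, g_true, l_true, n_fam, seed=seed)
        fit = GainLossMarkovModel(mmat, tree).fit()
        report["markov"] = {
            "g_true": g_true,
            "l_true": l_true,
            "g_hat": fit.estimate.gain_rate,
            "l_hat": fit.estimate.loss_rate,
            "n_families": n_fam,
            "n_unobservable_dropped": n_dropped,
            "converged": fit.estimate.converged,
        }
    if noise_config is not None:
        noisy, manifest = inject_noise(matrix, noise_config)
        res_noisy = DolloCharacterMapping(noisy, tree).fit(n_reps=n_reps, seed=seed)
        report["noise"] = {
            "manifest_masked": len(manifest["masked_cells"]),
            "manifest_added": len(manifest["added_singletons"]),
            "clean_recent_losses": _recent_mean(res, "loss", recent_window, bin_width, horizon),
            "noisy_recent_losses": _recent_mean(res_noisy, "loss", recent_window, bin_width, horizon),
            "clean_recent_gains": _recent_mean(res, "gain", recent_window, bin_width, horizon),
            "noisy_recent_gains": _recent_mean(res_noisy, "gain", recent_window, bin_width, horizon),
        }
    return report


def _recent_mean(results, kind: str, window: float, bin_width: float, horizon: float) -> float:
    series = results.rate_series(bin_width=bin_width, horizon=horizon)[kind]
    s = series.summary
    recent = s[s["bin_old"] <= window]
    return float(recent["mean"].sum())
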