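"""Altruism metrics for learned reward functions.

The central quantity is the Average Reward of a Trajectory,

    ART(tau, rf) = (1/n_tau) * sum_t norm(rf(t)),

the mean of the per-step rewards after min-max normalization within the
trajectory, so ART always lies in [0, 1] and is invariant to affine
rescaling of the reward function.  When all step rewards are equal the
normalization is degenerate and every step maps to the neutral midpoint
0.5.

The Sharing Ratio of a reward model is mean ART over sharing
trajectories divided by mean ART over cooking trajectories: values above
one mean the model finds carrying an onion to the cooperation bridge
more rewarding than carrying it to the pot, i.e. it has internalized an
altruistic valuation.  Because "min-max normalization applied per
trajectory step" admits two readings, both are implemented: the default
pools the min-max over all steps of the compared trajectory sets (so the
ratio compares reward *levels* between sharing and cooking), while
``normalization="per_trajectory"`` rescales each trajectory in
isolation (making ART a pure shape statistic, blind to which trajectory
sits higher — retained for sensitivity analysis).  Canonical
shortest-path sharing/cooking trajectory pairs are built per layout,
which makes Sharing Ratios deterministic and lets a reward learned on
the original kitchen be evaluated on the six spatial variants without
retraining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import environment as env
from .demos import Trace
from .features import (BINARY_FEATURES, FeatureExtractor, StateCore,
                       core_from_state)
from .irl import RewardNet

_DEGENERATE_SPAN = 1e-12


@dataclass(frozen=True)
class ARTResult:
    trajectory_id: str
    n_steps: int
    art: float


@dataclass(frozen=True)
class SRReport:
    model_id: str
    art_sharing: float
    art_cooking: float

    @property
    def sharing_ratio(self) -> float:
        return self.art_sharing / self.art_cooking


def normalize_rewards(rewards: np.ndarray) -> np.ndarray:
    """Per-trajectory min-max normalization; degenerate spans map to 0.5."""
    r = np.asarray(rewards, dtype=float)
    if r.size == 0:
        raise ValueError("empty trajectory")
    span = r.max() - r.min()
    if span < _DEGENERATE_SPAN:
        return np.full_like(r, 0.5)
    return (r - r.min()) / span


def average_trajectory_reward(step_rewards: Sequence[float],
                              trajectory_id: str = "") -> ARTResult:
    """ART from raw per-step rewards."""
    r = np.asarray(list(step_rewards), dtype=float)
    if r.size == 0:
        raise ValueError("empty trajectory")
    return ARTResult(trajectory_id=trajectory_id, n_steps=int(r.size),
                     art=float(normalize_rewards(r).mean()))


def trajectory_rewards(cores: Sequence[StateCore], model: RewardNet,
                       extractor: FeatureExtractor) -> np.ndarray:
    F = np.array([extractor.extract_core(c) for c in cores])
    return model.forward(F)


def trace_art(trace: Trace, model: RewardNet, extractor: FeatureExtractor) -> ARTResult:
    """ART of a demonstration trace under a learned reward model."""
    if not trace.steps:
        raise ValueError("empty trajectory")
    cores = [core_from_state(s, extractor.layout) for s, _ in trace.steps]
    r = trajectory_rewards(cores, model, extractor)
    return average_trajectory_reward(r, trajectory_id=f"p{trace.participant_id}")


# ---------------------------------------------------------------------------
# Canonical evaluation trajectories
# ---------------------------------------------------------------------------

def _walk_cores(layout: env.Layout, path: Sequence[env.Coord], target: env.Coord,
                deposit: str) -> list[StateCore]:
    """State cores along a carry path ending with the deposit at ``target``."""
    cores: list[StateCore] = []
    for i, pos in enumerate(path):
        if i + 1 < len(path):
            nxt = path[i + 1]
            delta = (nxt[0] - pos[0], nxt[1] - pos[1])
        else:
            delta = (target[0] - pos[0], target[1] - pos[1])
        orient = env.MOVE_TO_ORIENT[env.DELTA_TO_MOVE[delta]]
        cores.append(StateCore(pos=pos, orient=orient, holding=1,
                               pot_nonempty=0, bridge_onion=0, other_has_onion=0))
    last = cores[-1]
    if deposit == "bridge":
        cores.append(last._replace(holding=0, bridge_onion=1))
    else:
        cores.append(last._replace(holding=0, pot_nonempty=1))
    return cores


def canonical_trajectories(layout: env.Layout
                           ) -> tuple[list[StateCore], list[StateCore]]:
    """The layout's canonical (sharing, cooking) trajectory pair.

    Both start with the onion freshly picked up at the store front and
    follow the lexicographically-smallest shortest path to the bridge
    front or the stove front, ending with the deposit.
    """
    extractor = FeatureExtractor.for_layout(layout)
    store_fronts = layout.adjacent_floors(extractor.onion_store, "left")
    if not store_fronts:
        raise env.LayoutError("onion store has no front cell")
    start = store_fronts[0]

    def path_to(obj: env.Coord) -> tuple[env.Coord, ...]:
        fronts = layout.adjacent_floors(obj, "left")
        if not fronts:
            raise env.LayoutError(f"{obj} unreachable from the left kitchen")
        best = None
        for f in fronts:
            d = env.shortest_path_steps(layout, start, f)
            if d is not env.UNREACHABLE and (best is None or (d, f) < best):
                best = (d, f)
        if best is None:
            raise env.LayoutError(f"{obj} unreachable from the left kitchen")
        return env.shortest_path_cells(layout, start, best[1])

    sharing = _walk_cores(layout, path_to(layout.bridge), layout.bridge, "bridge")
    cooking = _walk_cores(layout, path_to(extractor.stove), extractor.stove, "pot")
    return sharing, cooking


def sharing_ratio(model: RewardNet,
                  sharing_trajs: Sequence[Sequence[StateCore]],
                  cooking_trajs: Sequence[Sequence[StateCore]],
                  extractor: FeatureExtractor,
                  model_id: str = "model",
                  normalization: str = "pooled") -> SRReport:
    """Sharing Ratio = mean sharing ART / mean cooking ART.

    With ``normalization="pooled"`` (default) a single min-max over all
    steps of both trajectory sets is used, so the ratio reflects which
    behavior the reward model values more highly; with
    ``"per_trajectory"`` each trajectory is normalized in isolation.
    Both keep every normalized step reward in [0, 1] and are invariant to
    affine rescaling of the reward output.
    """
    if not sharing_trajs or not cooking_trajs:
        raise ValueError("both trajectory sets must be non-empty")
    if normalization not in ("pooled", "per_trajectory"):
        raise ValueError("normalization must be 'pooled' or 'per_trajectory'")
    rs = [trajectory_rewards(tr, model, extractor) for tr in sharing_trajs]
    rc = [trajectory_rewards(tr, model, extractor) for tr in cooking_trajs]
    if normalization == "pooled":
        allr = np.concatenate(rs + rc)
        lo, hi = allr.min(), allr.max()
        span = hi - lo
        if span < _DEGENERATE_SPAN:
            norm = lambda r: np.full_like(r, 0.5)
        else:
            norm = lambda r: (r - lo) / span
        art_s = float(np.mean([norm(r).mean() for r in rs]))
        art_c = float(np.mean([norm(r).mean() for r in rc]))
    else:
        art_s = float(np.mean([average_trajectory_reward(r).art for r in rs]))
        art_c = float(np.mean([average_trajectory_reward(r).art for r in rc]))
    if art_c <= 0:
        raise ZeroDivisionError("cooking ART is zero; sharing ratio undefined")
    return SRReport(model_id=model_id, art_sharing=art_s, art_cooking=art_c)


def layout_sharing_ratio(model: RewardNet, layout: env.Layout,
                         model_id: str = "model",
                         normalization: str = "pooled") -> SRReport:
    sharing, cooking = canonical_trajectories(layout)
    extractor = FeatureExtractor.for_layout(layout)
    return sharing_ratio(model, [sharing], [cooking], extractor,
                         model_id=model_id, normalization=normalization)


def layout_generalization_sweep(models: Mapping[str, RewardNet],
                                layouts: Mapping[str, env.Layout],
                                normalization: str = "pooled") -> pd.DataFrame:
    """Sharing Ratio of each (frozen) model on each layout, no retraining.

    Rows are layouts, columns are model ids.
    """
    table = {}
    for mname, model in models.items():
        col = {}
        for lname, layout in layouts.items():
            col[lname] = layout_sharing_ratio(
                model, layout, model_id=mname,
                normalization=normalization).sharing_ratio
        table[mname] = col
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# Feature attribution
# ---------------------------------------------------------------------------

def feature_attribution(model: RewardNet, feature: str,
                        reference_features: np.ndarray) -> float:
    """Ablation attribution of one binary feature.

    Mean over the reference states of reward(feature := 1) minus
    reward(feature := 0).  Only the four Table-style binary flags are
    attributable this way.
    """
    if feature not in BINARY_FEATURES:
        raise ValueError(
            f"{feature!r} is not a binary feature; choose from {sorted(BINARY_FEATURES)}")
    col = BINARY_FEATURES[feature]
    F1 = np.array(reference_features, dtype=float)
    F0 = F1.copy()
    F1[:, col] = 1.0
    F0[:, col] = 0.0
    return float((model.forward(F1) - model.forward(F0)).mean())


DEFAULT_ATTRIBUTION_FEATURES = ("onion_on_bridge", "onions_in_pot",
                                "other_agent_has_onion")


def scaled_attributions(model: RewardNet, reference_features: np.ndarray,
                        features: Sequence[str] = DEFAULT_ATTRIBUTION_FEATURES
                        ) -> dict[str, float]:
    """Attributions min-max scaled so the largest magnitude equals 1."""
    raw = {f: feature_attribution(model, f, reference_features) for f in features}
    top = max(abs(v) for v in raw.values())
    if top < _DEGENERATE_SPAN:
        return {f: 0.0 for f in features}
    return {f: v / top for f, v in raw.items()}


# ---------------------------------------------------------------------------
# Behavioral metric
# ---------------------------------------------------------------------------

def onions_per_soup(manifest: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-participant and per-group onions shared per delivered soup.

    Participants with zero delivered soups have an undefined ratio and are
    excluded from the group means.
    """
    per = manifest.set_index("participant_id")["onions_per_soup"]
    ok = manifest.dropna(subset=["onions_per_soup"])
    g = ok.groupby("group")["onions_per_soup"]
    stats = g.agg(["mean", "std", "count"]).rename(columns={"count": "n"})
    stats["se"] = stats["std"] / np.sqrt(stats["n"])
    return per, stats
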