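"""Metrics for predicted maps: confusion statistics and atom inclusion.

A grid point is a positive prediction when its value is > 0 — after
overlap averaging and re-interpolation any point touched by at least one
positive cube vote stays positive.  Atom inclusion is the percentage of a
group's atoms whose position interpolates to positive predicted density;
because truth labels mark everything within 1.5 Å of a group atom, the
truth map used as its own prediction scores 100% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import AtomicModel, DensityMap, OrthoGrid
from .training import GROUPS, TargetMap, group_atoms, make_target_map

POSITIVE_THRESHOLD = 0.0  # predictions are positive when value > this


@dataclass
class MetricsReport:
    group: str
    tp: int
    tn: int
    fp: int
    fn: int
    positive_threshold: float = POSITIVE_THRESHOLD
    undefined_rates: bool = False

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def precision_pct(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def recall_pct(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def f1_pct(self) -> float:
        p, r = self.precision_pct, self.recall_pct
        if np.isnan(p) or np.isnan(r) or (p + r) == 0:
            return float("nan")
        return 2.0 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {"group": self.group, "TP": self.tp, "TN": self.tn,
                "FP": self.fp, "FN": self.fn,
                "accuracy_pct": self.accuracy_pct,
                "precision_pct": self.precision_pct,
                "recall_pct": self.recall_pct, "f1_pct": self.f1_pct}


def confusion_metrics(pred, truth: TargetMap,
                      threshold: float = POSITIVE_THRESHOLD
                      ) -> MetricsReport:
    """Point-wise confusion counts of a prediction against a target map.

    ``pred`` may be a DensityMap or OrthoGrid; it must share the truth
    map's grid shape (the truth is expected to have been generated on the
    prediction's grid).
    """
    pv = pred.values
    tv = truth.values.values
    if pv.shape != tv.shape:
        raise ValueError("prediction and truth must share a grid; "
                         "regenerate the target map on the prediction grid")
    p = pv > threshold
    t = tv > 0.5
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    undefined = (tp + fp == 0) or (tp + fn == 0)
    return MetricsReport(group=truth.group, tp=tp, tn=tn, fp=fp, fn=fn,
                         positive_threshold=threshold,
                         undefined_rates=undefined)


def atom_inclusion(pred, model: AtomicModel, group: str,
                   threshold: float = POSITIVE_THRESHOLD,
                   method: str = "interpolate") -> float:
    """Percentage of group atoms sitting in positive predicted density."""
    atoms = group_atoms(model, group)
    if len(atoms) == 0:
        raise ValueError(f"model has no atoms in group {group!r}")
    pos = atoms.positions()
    if method == "interpolate":
        vals = pred.sample(pos)
    elif method == "nearest":
        if isinstance(pred, OrthoGrid):
            idx = np.rint((pos - pred.origin) / pred.spacing).astype(int)
        else:
            idx = np.rint(pred.index_of(pos)).astype(int)
        idx = np.clip(idx, 0, np.array(pred.shape) - 1)
        vals = pred.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    else:
        raise ValueError("method must be 'interpolate' or 'nearest'")
    return float(np.mean(vals > threshold) * 100.0)


def evaluate_prediction(pred, model: AtomicModel, group: str,
                        label_radius: float = 1.5) -> MetricsReport:
    """Confusion metrics with the truth labelled on the prediction's grid."""
    truth = make_target_map(model, pred, group, radius=label_radius)
    return confusion_metrics(pred, truth)


def resolution_sweep(blur_levels, networks, model: AtomicModel,
                     density_factory, out_csv=None) -> pd.DataFrame:
    """Atom inclusion as map quality degrades.

    ``density_factory(blur) -> DensityMap`` generates the input map at one
    degradation setting; ``networks`` maps group name to its trained
    network (a single network is treated as a phosphate model).  The same
    networks predict every map and inclusion is tabulated per group.
    """
    from .inference import predict
    if not isinstance(networks, dict):
        networks = {"phosphate": networks}
    rows = []
    for blur in blur_levels:
        dmap = density_factory(blur)
        for group, net in networks.items():
            pred = predict(dmap, net)
            rows.append({"blur": blur, "group": group,
                         "atom_inclusion_pct":
                             atom_inclusion(pred, model, group)})
    df = pd.DataFrame(rows, columns=["blur", "group", "atom_inclusion_pct"])
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
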