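"""Decoy-set evaluation: RMSD16, sampling/scoring metrics, labels, cluster report.

RMSD16 makes loop RMSDs comparable across lengths by rescaling the
Carugo-Pongor logarithmic length normalization to a reference length of 16
residues: rmsd16 = rmsd / (1 + ln sqrt(L/16)). It is the identity at L = 16,
inflates the RMSD of shorter loops and deflates longer ones. Loop RMSD is
the Calpha RMSD over the loop after superposing the model onto the native on
framework Calpha atoms (all residues outside the loop), without re-fitting
on the loop itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .antibody_io import ChainBackbone
from .clustering import Cluster
from .geometry import rmsd_no_fit, superpose


@dataclass(frozen=True)
class DecoyRecord:
    model_id: str
    score: float  # HCDR3 score, REU
    rmsd: float  # loop Calpha RMSD, A
    rmsd16: float
    loop_length: int

    def __post_init__(self):
        if self.rmsd < 0 or self.rmsd16 < 0:
            raise ValueError("RMSD values must be non-negative")
        if self.loop_length < 1:
            raise ValueError("loop length must be >= 1")


@dataclass(frozen=True)
class EvalReport:
    n_models: int
    n_below_2A: int
    best_rmsd16: float
    avg_rmsd16_best10_by_rmsd: float
    rmsd16_of_top_scoring: float | None = None
    avg_rmsd16_top10_by_score: float | None = None
    rank_of_first_below_2A: int | None = None
    labels: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ClusterRow:
    representative: str
    size: int
    size_rank: int
    avg_score: float
    avg_rmsd16: float
    rmsd_rank: int
    correct: bool


@dataclass(frozen=True)
class ClusterReport:
    rows: tuple[ClusterRow, ...]
    single_cluster: bool  # Fig-style "1*" flag
    not_available: bool  # no cluster survived the size filter

    @property
    def correct(self) -> ClusterRow | None:
        for row in self.rows:
            if row.correct:
                return row
        return None


def rmsd16(rmsd: float, loop_length: int) -> float:
    """Length-normalized loop RMSD referenced to a 16-residue loop."""
    if rmsd < 0:
        raise ValueError(f"rmsd must be non-negative, got {rmsd}")
    if loop_length < 4:
        raise ValueError(f"loop length {loop_length} < 4: normalization meaningless")
    return rmsd / (1.0 + math.log(math.sqrt(loop_length / 16.0)))


def loop_rmsd(
    model: ChainBackbone, native: ChainBackbone, loop: tuple[int, int]
) -> float:
    """Loop Calpha RMSD after framework superposition.

    ``loop`` is the (start, end) 1-based inclusive sequential range of the
    HCDR3 in both chains; superposition uses all Calpha atoms outside it.
    """
    start, end = loop
    if not (1 <= start <= end <= len(model)) or end > len(native):
        raise ValueError(f"loop range {loop} invalid for supplied chains")
    if len(model) != len(native):
        raise ValueError(
            f"model ({len(model)}) and native ({len(native)}) lengths differ"
        )
    fw_idx = [i for i in range(1, len(native) + 1) if not (start <= i <= end)]
    if len(fw_idx) < 3:
        raise ValueError("fewer than 3 framework residues to superpose on")
    fw_model = np.array([model.residue(i).ca for i in fw_idx])
    fw_native = np.array([native.residue(i).ca for i in fw_idx])
    _, rot, trans = superpose(fw_model, fw_native)
    loop_model = np.array([model.residue(i).ca for i in range(start, end + 1)])
    loop_native = np.array([native.residue(i).ca for i in range(start, end + 1)])
    moved = loop_model @ rot.T + trans
    return rmsd_no_fit(moved, loop_native)


def sampling_metrics(decoys: list[DecoyRecord]) -> EvalReport:
    """Conformational-sampling metrics: count < 2 A, best, average of best 10.

    The count uses a strict "below 2 A" threshold; the average is over the
    10 lowest RMSD16 values (all of them when fewer than 10 decoys exist).
    """
    if not decoys:
        raise ValueError("no decoys supplied")
    values = sorted(d.rmsd16 for d in decoys)
    best10 = values[:10]
    return EvalReport(
        n_models=len(decoys),
        n_below_2A=sum(v < 2.0 for v in values),
        best_rmsd16=values[0],
        avg_rmsd16_best10_by_rmsd=float(np.mean(best10)),
    )


def scoring_metrics(decoys: list[DecoyRecord]) -> EvalReport:
    """Score-ranked recovery metrics; score ties broken by model id."""
    if not decoys:
        raise ValueError("no decoys supplied")
    ranked = sorted(decoys, key=lambda d: (d.score, d.model_id))
    base = sampling_metrics(decoys)
    top10 = [d.rmsd16 for d in ranked[:10]]
    rank = None
    for i, d in enumerate(ranked, start=1):
        if d.rmsd16 < 2.0:
            rank = i
            break
    return EvalReport(
        n_models=base.n_models,
        n_below_2A=base.n_below_2A,
        best_rmsd16=base.best_rmsd16,
        avg_rmsd16_best10_by_rmsd=base.avg_rmsd16_best10_by_rmsd,
        rmsd16_of_top_scoring=ranked[0].rmsd16,
        avg_rmsd16_top10_by_score=float(np.mean(top10)),
        rank_of_first_below_2A=rank,
    )


def label_models(decoys: list[DecoyRecord]) -> dict[str, str]:
    """Funnel-plot labels: blue / red / gray.

    Blue: score in the top 10% (lowest scores; cut at ceil(0.10 N)) and
    RMSD16 <= 2 A. Red: score outside the top 10% and RMSD16 > 2 A.
    Everything else gray. Rank-based, so invariant under monotone score
    transforms.
    """
    ranked = sorted(decoys, key=lambda d: (d.score, d.model_id))
    cut = math.ceil(0.10 * len(decoys))
    labels = {}
    for i, d in enumerate(ranked, start=1):
        in_top = i <= cut
        if in_top and d.rmsd16 <= 2.0:
            labels[d.model_id] = "blue"
        elif not in_top and d.rmsd16 > 2.0:
            labels[d.model_id] = "red"
        else:
            labels[d.model_id] = "gray"
    return labels


def _dense_rank(values: list[float], reverse: bool = False) -> list[int]:
    """1-based dense ranks; equal values share a rank."""
    order = sorted(set(values), reverse=reverse)
    lookup = {v: i + 1 for i, v in enumerate(order)}
    return [lookup[v] for v in values]


def cluster_report(
    decoys: list[DecoyRecord], clusters: list[Cluster]
) -> ClusterReport:
    """Per-cluster size/score/RMSD16 averages with dense ranks.

    The "correct" cluster is the one with the lowest average score (the
    operational pick when no native structure is available). Size rank 1 is
    the largest cluster; RMSD rank 1 the lowest average RMSD16.
    """
    if not clusters:
        return ClusterReport(rows=(), single_cluster=False, not_available=True)
    by_id = {d.model_id: d for d in decoys}
    sizes, scores, rmsds = [], [], []
    for c in clusters:
        missing = [m for m in c.members if m not in by_id]
        if missing:
            raise ValueError(f"cluster members without decoy records: {missing}")
        members = [by_id[m] for m in c.members]
        sizes.append(c.size)
        scores.append(float(np.mean([m.score for m in members])))
        rmsds.append(float(np.mean([m.rmsd16 for m in members])))
    size_ranks = _dense_rank(sizes, reverse=True)
    rmsd_ranks = _dense_rank(rmsds)
    correct_idx = int(np.argmin(scores))
    rows = tuple(
        ClusterRow(
            representative=c.representative,
            size=sizes[i],
            size_rank=size_ranks[i],
            avg_score=scores[i],
            avg_rmsd16=rmsds[i],
            rmsd_rank=rmsd_ranks[i],
            correct=(i == correct_idx),
        )
        for i, c in enumerate(clusters)
    )
    return ClusterReport(
        rows=rows, single_cluster=(len(clusters) == 1), not_available=False
    )
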