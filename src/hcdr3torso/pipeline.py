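"""The two end-to-end workflows: derive restraints, evaluate decoy sets.

The derive pipeline mirrors how the reference profiles were built: read
backbones, extract torsos per a definitions table, cluster the concatenated
torso backbones at 2 A, summarize each cluster's dihedrals with circular
statistics, and emit circular-harmonic restraints plus motif statistics for
the largest cluster. The evaluate pipeline consumes the decoy output of an
external modelling engine: loop RMSD against the native, RMSD16
normalization, sampling/scoring metrics, funnel labels and a Calibur-style
cluster report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import antibody_io, classify, clustering, evalmetrics, restraints
from .circstats import AngleSample, UndefinedMeanError, summarize
from .profiles import DEFAULT_EXCLUDED, POSITIONS, TorsoProfile, profile_from_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paper-default parameters for both workflows."""

    cluster_radius: float = 2.0  # A, fragment clustering
    decoy_threshold: float = 2.0  # A, decoy clustering
    min_cluster_fraction: float = 0.01
    sigma_mult: float = 3.0
    min_sigma: float = 1.0  # degrees, restraint width floor
    seed: int = 0
    reference_bulged_psi_t6: tuple[float, float] | None = (-30.0, 26.0)

    def __post_init__(self):
        for name in ("cluster_radius", "decoy_threshold", "sigma_mult", "min_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DerivedCluster:
    label: str
    size: int
    profile: TorsoProfile
    motif: classify.MotifReport
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class DeriveResult:
    clusters: tuple[DerivedCluster, ...]
    restraint_sets: dict[str, restraints.RestraintSet]
    counts: dict[str, int] = field(default_factory=dict)


def profile_from_fragments(
    fragments: list[antibody_io.TorsoFragment],
    label: str,
    excluded=DEFAULT_EXCLUDED,
) -> TorsoProfile:
    """Circular mean/std per torso position over a set of fragments."""
    measured = [antibody_io.torso_dihedrals(f) for f in fragments]
    rows = {}
    for pos in POSITIONS:
        stats = {}
        for angle in ("phi", "psi"):
            values = [m[pos][angle] for m in measured if m[pos][angle] is not None]
            if not values:
                raise ValueError(f"{label}: no measurable {angle} at {pos}")
            try:
                summ = summarize(AngleSample(f"{label}/{pos}/{angle}", tuple(values)))
            except UndefinedMeanError:
                raise ValueError(f"{label}: {pos} {angle} has no mean direction")
            stats[angle] = summ
        rows[pos] = (
            stats["phi"].mean, stats["phi"].std, stats["psi"].mean, stats["psi"].std,
        )
    return profile_from_table(label, rows, n=len(fragments), excluded=excluded)


def run_derive_pipeline(
    pdb_dir: str | Path,
    definitions_csv: str,
    config: RunConfig = RunConfig(),
    restraint_start: int = 100,
    restraint_length: int = 16,
) -> DeriveResult:
    """Extract torsos, cluster them, summarize each cluster, emit restraints.

    Cluster labels: a cluster whose mean psi(T6) lies within ``sigma_mult``
    std of the reference bulged psi(T6) is labeled "bulged", one within the
    window around the antipodal non-bulged regime "non-bulged"; otherwise
    clusters are labeled cluster-1, cluster-2, ... in decreasing size.
    """
    pdb_dir = Path(pdb_dir)
    definitions = antibody_io.read_definitions(definitions_csv)
    if not definitions:
        raise ValueError("derive pipeline: definitions table is empty")
    logger.info("derive: %d definitions", len(definitions))
    fragments = []
    for defn in definitions:
        chain = antibody_io.read_backbone(
            str(pdb_dir / defn.pdb_file), defn.chain_id,
            source_id=Path(defn.pdb_file).stem,
        )
        fragments.append(antibody_io.extract_torso(chain, defn))
    logger.info("derive: %d torsos extracted", len(fragments))

    coords = [antibody_io.torso_coordinates(f) for f in fragments]
    ids = [str(i) for i in range(len(fragments))]
    clusters = clustering.greedy_cluster(coords, config.cluster_radius, ids=ids)
    logger.info("derive: %d clusters, sizes %s",
                len(clusters), [c.size for c in clusters])

    derived = []
    restraint_sets = {}
    used_labels: dict[str, int] = {}
    for rank, cl in enumerate(clusters, start=1):
        members = [fragments[int(i)] for i in cl.members]
        label = f"cluster-{rank}"
        profile = profile_from_fragments(members, label)
        if config.reference_bulged_psi_t6 is not None:
            ref_mean, ref_std = config.reference_bulged_psi_t6
            from .geometry import wrap_degrees

            dev = abs(wrap_degrees(profile.psi["T6"].mean - ref_mean))
            if dev <= config.sigma_mult * ref_std:
                label = "bulged"
            elif abs(wrap_degrees(profile.psi["T6"].mean - ref_mean - 180.0)) <= 90.0:
                label = "non-bulged"
            # sub-conformations (e.g. the two psi(T4) modes) can yield several
            # clusters of the same class; suffix duplicates for uniqueness
            used_labels[label] = used_labels.get(label, 0) + 1
            if used_labels[label] > 1:
                label = f"{label}-{used_labels[label]}"
            profile = profile_from_table(
                label,
                {p: (profile.phi[p].mean, profile.phi[p].std,
                     profile.psi[p].mean, profile.psi[p].std) for p in POSITIONS},
                n=len(members),
            )
        motif = classify.motif_stats([f.sequence for f in members])
        derived.append(DerivedCluster(
            label=label, size=cl.size, profile=profile, motif=motif,
            member_ids=tuple(fragments[int(i)].source_id for i in cl.members),
        ))
        restraint_sets[label] = restraints.derive_restraints(
            profile, restraint_start, restraint_length, min_sigma=config.min_sigma,
        )
    return DeriveResult(
        clusters=tuple(derived),
        restraint_sets=restraint_sets,
        counts={"definitions": len(definitions), "torsos": len(fragments),
                "clusters": len(clusters)},
    )


@dataclass(frozen=True)
class EvaluateResult:
    records: tuple[evalmetrics.DecoyRecord, ...]
    sampling: evalmetrics.EvalReport
    scoring: evalmetrics.EvalReport
    labels: dict[str, str]
    cluster_report: evalmetrics.ClusterReport


def run_evaluate_pipeline(
    native: antibody_io.ChainBackbone,
    decoys: list[antibody_io.ChainBackbone],
    scores: pd.DataFrame,
    loop: tuple[int, int],
    config: RunConfig = RunConfig(),
) -> EvaluateResult:
    """Score decoys against the native: RMSD16 metrics, labels, clusters."""
    score_map = dict(zip(scores["model_id"].astype(str), scores["score"].astype(float)))
    missing = [d.source_id for d in decoys if d.source_id not in score_map]
    if missing:
        raise ValueError(f"decoys without scores: {missing}")
    start, end = loop
    loop_len = end - start + 1
    records = []
    loop_coords = []
    for decoy in decoys:
        r = evalmetrics.loop_rmsd(decoy, native, loop)
        records.append(evalmetrics.DecoyRecord(
            model_id=decoy.source_id,
            score=score_map[decoy.source_id],
            rmsd=r,
            rmsd16=evalmetrics.rmsd16(r, loop_len),
            loop_length=loop_len,
        ))
        loop_coords.append((
            decoy.source_id,
            np.array([decoy.residue(i).ca for i in range(start, end + 1)]),
        ))
    sampling = evalmetrics.sampling_metrics(records)
    scoring = evalmetrics.scoring_metrics(records)
    labels = evalmetrics.label_models(records)
    clusters = clustering.cluster_decoys(
        loop_coords, threshold=config.decoy_threshold,
        min_fraction=config.min_cluster_fraction,
    )
    report = evalmetrics.cluster_report(records, clusters)
    logger.info("evaluate: %d decoys, %d below 2 A, %d surviving clusters",
                len(records), sampling.n_below_2A, len(report.rows))
    return EvaluateResult(
        records=tuple(records), sampling=sampling, scoring=scoring,
        labels=labels, cluster_report=report,
    )


def provenance_block(config: RunConfig, inputs: dict) -> str:
    """Machine-readable provenance: inputs, parameters, versions."""
    from . import __version__

    payload = {
        "package": "hcdr3torso",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {
            "cluster_radius": config.cluster_radius,
            "decoy_threshold": config.decoy_threshold,
            "min_cluster_fraction": config.min_cluster_fraction,
            "sigma_mult": config.sigma_mult,
            "min_sigma": config.min_sigma,
            "seed": config.seed,
        },
        "inputs": inputs,
    }
    return json.dumps(payload, indent=2, sort_keys=True)
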