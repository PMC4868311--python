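"""RMSD16 normalization, loop RMSD, sampling/scoring metrics, labels, clusters."""

import math

import numpy as np
import pytest

from hcdr3torso.clustering import Cluster
from hcdr3torso.evalmetrics import (
    DecoyRecord,
    cluster_report,
    label_models,
    loop_rmsd,
    rmsd16,
    sampling_metrics,
    scoring_metrics,
)
from hcdr3torso.fixtures import BackboneSpec, ResidueSpec, build_backbone
from hcdr3torso.antibody_io import BackboneResidue, ChainBackbone


def _records(pairs):
    return [
        DecoyRecord(model_id=f"m{i}", score=s, rmsd=r, rmsd16=r, loop_length=16)
        for i, (s, r) in enumerate(pairs)
    ]


def test_rmsd16_identity_at_reference_length():
    assert rmsd16(2.0, 16) == pytest.approx(2.0)
    assert rmsd16(0.0, 22) == 0.0


def test_rmsd16_logarithmic_normalization():
    assert rmsd16(2.0, 26) == pytest.approx(
        2.0 / (1.0 + 0.5 * math.log(26 / 16)), abs=1e-9
    )
    # longer loops deflate, shorter loops inflate
    assert rmsd16(2.0, 26) < 2.0 < rmsd16(2.0, 11)


def test_rmsd16_strictly_increasing_in_rmsd():
    values = [rmsd16(r, 20) for r in np.linspace(0, 5, 20)]
    assert all(b > a for a, b in zip(values, values[1:]))


def test_rmsd16_domain_errors():
    with pytest.raises(ValueError):
        rmsd16(1.0, 3)
    with pytest.raises(ValueError):
        rmsd16(-0.1, 16)


def test_loop_rmsd_zero_for_identical_and_rotated():
    chain = build_backbone(
        BackboneSpec(residues=tuple(ResidueSpec() for _ in range(20)))
    )
    loop = (8, 13)
    assert loop_rmsd(chain, chain, loop) == pytest.approx(0.0, abs=1e-9)
    theta = 0.7
    rot = np.array([
        [math.cos(theta), -math.sin(theta), 0.0],
        [math.sin(theta), math.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    moved = ChainBackbone(
        source_id="rot", chain_id="A",
        residues=tuple(
            BackboneResidue(aa=r.aa, index=r.index, n=rot @ r.n + 3.0,
                            ca=rot @ r.ca + 3.0, c=rot @ r.c + 3.0)
            for r in chain.residues
        ),
    )
    assert loop_rmsd(moved, chain, loop) == pytest.approx(0.0, abs=1e-8)


def test_loop_rmsd_detects_uniform_loop_shift():
    chain = build_backbone(
        BackboneSpec(residues=tuple(ResidueSpec() for _ in range(20)))
    )
    loop = (8, 13)
    shift = np.array([0.0, 0.0, 1.0])
    shifted = ChainBackbone(
        source_id="shift", chain_id="A",
        residues=tuple(
            BackboneResidue(
                aa=r.aa, index=r.index,
                n=r.n + (shift if loop[0] <= r.index <= loop[1] else 0.0),
                ca=r.ca + (shift if loop[0] <= r.index <= loop[1] else 0.0),
                c=r.c + (shift if loop[0] <= r.index <= loop[1] else 0.0),
            )
            for r in chain.residues
        ),
    )
    assert loop_rmsd(shifted, chain, loop) == pytest.approx(1.0, abs=1e-9)


def test_sampling_metrics_hand_example():
    report = sampling_metrics(_records([(0, 0.5), (0, 1.5), (0, 2.5), (0, 3.0)]))
    assert report.n_below_2A == 2
    assert report.best_rmsd16 == 0.5
    assert report.avg_rmsd16_best10_by_rmsd == pytest.approx(1.875)


def test_sampling_metrics_boundaries():
    single = sampling_metrics(_records([(0, 1.0)]))
    assert (single.n_below_2A, single.best_rmsd16) == (1, 1.0)
    # exactly 2.0 does not count as "below 2"
    report = sampling_metrics(_records([(0, 2.0), (0, 2.5)]))
    assert report.n_below_2A == 0
    with pytest.raises(ValueError):
        sampling_metrics([])


def test_scoring_metrics_hand_example():
    report = scoring_metrics(_records([(-10, 3.0), (-9, 1.0), (-8, 0.5)]))
    assert report.rmsd16_of_top_scoring == 3.0
    assert report.rank_of_first_below_2A == 2
    assert report.avg_rmsd16_top10_by_score == pytest.approx((3.0 + 1.0 + 0.5) / 3)


def test_scoring_metrics_rank_sentinel():
    all_below = scoring_metrics(_records([(-5, 1.0), (-4, 1.5)]))
    assert all_below.rank_of_first_below_2A == 1
    none_below = scoring_metrics(_records([(-5, 3.0), (-4, 2.5)]))
    assert none_below.rank_of_first_below_2A is None


def test_metrics_agree_with_brute_force_oracle_over_seeds():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        records = _records(zip(rng.normal(size=n), rng.uniform(0, 4, size=n)))
        s = sampling_metrics(records)
        sc = scoring_metrics(records)
        rmsds = sorted(r.rmsd16 for r in records)
        assert s.n_below_2A == sum(1 for r in rmsds if r < 2.0)
        assert s.best_rmsd16 == rmsds[0]
        assert s.avg_rmsd16_best10_by_rmsd == pytest.approx(
            sum(rmsds[:10]) / min(10, n)
        )
        by_score = sorted(records, key=lambda r: (r.score, r.model_id))
        assert sc.rmsd16_of_top_scoring == by_score[0].rmsd16
        expected_rank = next(
            (i + 1 for i, r in enumerate(by_score) if r.rmsd16 < 2.0), None
        )
        assert sc.rank_of_first_below_2A == expected_rank


def test_label_models_reference_cases():
    # N=10: cut = 1 model
    best_good = _records([(-10, 1.0)] + [(i, 3.0) for i in range(9)])
    labels = label_models(best_good)
    assert labels["m0"] == "blue"
    worst = max(best_good, key=lambda r: r.score)
    assert labels[worst.model_id] == "red"
    best_bad = _records([(-10, 3.0)] + [(i, 1.0) for i in range(9)])
    labels2 = label_models(best_bad)
    assert labels2["m0"] == "gray"  # top score but poor RMSD
    assert labels2["m5"] == "gray"  # good RMSD but below the cut


def test_labels_partition_and_monotone_invariance():
    rng = np.random.default_rng(12)
    records = _records(zip(rng.normal(size=40), rng.uniform(0, 4, size=40)))
    labels = label_models(records)
    transformed = [
        DecoyRecord(model_id=r.model_id, score=math.exp(r.score / 5.0),
                    rmsd=r.rmsd, rmsd16=r.rmsd16, loop_length=r.loop_length)
        for r in records
    ]
    assert label_models(transformed) == labels
    assert set(labels.values()) <= {"blue", "red", "gray"}


def test_cluster_report_hand_fixture():
    records = _records([(-12, 1.2)] * 0)  # placeholder, built below
    members_a = [f"a{i}" for i in range(60)]
    members_b = [f"b{i}" for i in range(40)]
    records = [
        DecoyRecord(model_id=m, score=-12.0, rmsd=1.2, rmsd16=1.2, loop_length=16)
        for m in members_a
    ] + [
        DecoyRecord(model_id=m, score=-8.0, rmsd=3.5, rmsd16=3.5, loop_length=16)
        for m in members_b
    ]
    clusters = [
        Cluster(representative="a0", members=tuple(members_a),
                avg_rmsd_to_representative=0.5),
        Cluster(representative="b0", members=tuple(members_b),
                avg_rmsd_to_representative=0.5),
    ]
    report = cluster_report(records, clusters)
    correct = report.correct
    assert correct.representative == "a0"
    assert correct.size_rank == 1 and correct.rmsd_rank == 1
    assert not report.single_cluster and not report.not_available


def test_cluster_report_single_and_empty():
    records = [DecoyRecord(model_id="x", score=-1.0, rmsd=1.0, rmsd16=1.0,
                           loop_length=16)]
    single = cluster_report(
        records, [Cluster(representative="x", members=("x",),
                          avg_rmsd_to_representative=0.0)]
    )
    assert single.single_cluster and single.correct.size_rank == 1
    empty = cluster_report(records, [])
    assert empty.not_available and empty.correct is None


def test_cluster_report_missing_record_errors():
    with pytest.raises(ValueError):
        cluster_report([], [Cluster(representative="x", members=("x",),
                                    avg_rmsd_to_representative=0.0)])
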