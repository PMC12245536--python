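"""Protein-cluster-saturation selection and its stopping criteria."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from derepkit.derep_saturation import (
    SaturationParams,
    incremental_augment,
    saturation_dereplicate,
    write_saturation_trace,
)
from derepkit.io_formats import ClusterMembership


def membership_of(mapping: dict[str, set[str]]) -> ClusterMembership:
    m = ClusterMembership()
    m.genome_to_clusters = {g: set(c) for g, c in mapping.items()}
    return m


def oracle_select(mapping, x=0, y=90.0, z=100.0):
    """From-scratch greedy max-coverage reference: recompute every
    genome's gain each round, apply the three stop criteria literally."""
    all_clusters = set().union(*mapping.values()) if mapping else set()
    counts: dict[str, int] = {}
    for clusters in mapping.values():
        for c in clusters:
            counts[c] = counts.get(c, 0) + 1
    multi = {c for c, k in counts.items() if k >= 2}
    covered: set[str] = set()
    reps: list[str] = []
    remaining = set(mapping)

    def frac(cov, tot):
        return Fraction(cov, tot) if tot else Fraction(1)

    while remaining:
        gains = {g: len(mapping[g] - covered) for g in remaining}
        best = min(
            remaining,
            key=lambda g: (-gains[g], -len(mapping[g]), g),
        )
        if reps and gains[best] < x:
            break
        reps.append(best)
        remaining.discard(best)
        covered |= mapping[best]
        if frac(len(covered), len(all_clusters)) > Fraction(str(y)) / 100:
            break
        if frac(len(covered & multi), len(multi)) > Fraction(str(z)) / 100:
            break
    return reps


def random_membership(rng, max_genomes=10, max_clusters=30):
    n_genomes = int(rng.integers(1, max_genomes + 1))
    n_clusters = int(rng.integers(1, max_clusters + 1))
    clusters = [f"c{j}" for j in range(n_clusters)]
    mapping = {}
    for i in range(n_genomes):
        keep = rng.random(n_clusters) < rng.uniform(0.1, 0.8)
        chosen = {c for c, k in zip(clusters, keep) if k}
        if not chosen:
            chosen = {clusters[int(rng.integers(0, n_clusters))]}
        mapping[f"g{i:02d}"] = chosen
    return mapping


class TestSaturationDereplicate:
    def test_three_genome_hand_trace(self):
        # g1 covers 5/8 (62.5%); g2 adds {c6,c7} (gain 2 beats g3's 1)
        # for 7/8 = 87.5%, still <= 90; g3 adds c8 reaching 8/8 = 100%
        # > 90% -> criterion ii
        m = membership_of(
            {
                "g1": {"c1", "c2", "c3", "c4", "c5"},
                "g2": {"c4", "c5", "c6", "c7"},
                "g3": {"c1", "c8"},
            }
        )
        res, trace = saturation_dereplicate(m)
        assert res.representatives == ["g1", "g2", "g3"]
        assert trace.stop_criterion == "ii"
        assert [s.marginal_gain for s in trace.steps] == [5, 2, 1]
        assert [s.coverage_pct for s in trace.steps] == [62.5, 87.5, 100.0]
        assert trace.steps[-1].cumulative_clusters == 8

    def test_single_genome(self):
        res, trace = saturation_dereplicate(membership_of({"g": {"c1"}}))
        assert res.representatives == ["g"]
        assert trace.steps[-1].coverage_pct == 100.0
        assert trace.stop_criterion == "ii"

    def test_identical_genomes_single_representative(self):
        m = membership_of({"g1": {"c1", "c2"}, "g2": {"c1", "c2"}})
        res, trace = saturation_dereplicate(m)
        # coverage is 100% > 90% after the first pick; the zero-gain
        # twin is never added
        assert res.representatives == ["g1"]
        assert trace.stop_criterion == "ii"

    def test_empty_membership_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            saturation_dereplicate(membership_of({}))

    def test_criterion_i_fires_before_adding(self):
        # with X=2 the third genome's gain of 1 stops selection before
        # it is added
        m = membership_of(
            {
                "g1": {"c1", "c2", "c3"},
                "g2": {"c4", "c5"},
                "g3": {"c6"},
            }
        )
        params = SaturationParams(min_new_clusters=2, saturation_pct=100.0)
        res, trace = saturation_dereplicate(m, params)
        assert res.representatives == ["g1", "g2"]
        assert trace.stop_criterion == "i"

    def test_criterion_iii_on_multigenome_clusters(self):
        # multi-genome clusters: c1 (g1,g2) and c2 (g2,g3); g2 alone
        # covers both -> criterion iii at Z=50 after the first pick
        m = membership_of(
            {
                "g1": {"c1", "u1", "u2"},
                "g2": {"c1", "c2", "u3", "u4"},
                "g3": {"c2", "u5"},
            }
        )
        params = SaturationParams(
            saturation_pct=100.0, multigenome_saturation_pct=50.0
        )
        res, trace = saturation_dereplicate(m, params)
        assert res.representatives == ["g2"]
        assert trace.stop_criterion == "iii"

    def test_exhaustion_when_y_unreachable(self):
        m = membership_of({"g1": {"c1"}, "g2": {"c2"}, "g3": {"c3"}})
        params = SaturationParams(saturation_pct=100.0)
        res, trace = saturation_dereplicate(m, params)
        assert set(res.representatives) == {"g1", "g2", "g3"}
        assert trace.stop_criterion == "exhausted"

    def test_matches_oracle_on_random_memberships(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            mapping = random_membership(rng)
            res, _ = saturation_dereplicate(membership_of(mapping))
            assert res.representatives == oracle_select(mapping)

    def test_marginal_gains_non_increasing(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            mapping = random_membership(rng, max_genomes=15, max_clusters=40)
            _, trace = saturation_dereplicate(
                membership_of(mapping), SaturationParams(saturation_pct=100.0)
            )
            gains = [s.marginal_gain for s in trace.steps]
            assert gains == sorted(gains, reverse=True)

    def test_final_cumulative_equals_union_of_rep_clusters(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mapping = random_membership(rng)
            res, trace = saturation_dereplicate(membership_of(mapping))
            union = set().union(
                *(mapping[g] for g in res.representatives)
            )
            assert trace.steps[-1].cumulative_clusters == len(union)

    def test_termination_contract_under_defaults(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            mapping = random_membership(rng)
            res, trace = saturation_dereplicate(membership_of(mapping))
            covered = trace.steps[-1].cumulative_clusters
            total = trace.total_clusters
            assert (
                Fraction(covered, total) > Fraction(90, 100)
                or set(res.representatives) == set(mapping)
            )


class TestIncrementalAugment:
    def test_fully_overlapping_nonrep_not_promoted(self):
        m = membership_of(
            {"rep": {"c1", "c2", "c3"}, "sub": {"c1", "c2"}}
        )
        res, _ = saturation_dereplicate(m)
        out = incremental_augment(res, m)
        assert out.representatives == res.representatives

    def test_disjoint_nonrep_promoted(self):
        m = membership_of(
            {
                "g1": {f"c{j}" for j in range(20)},
                "odd": {"x1", "x2"},
            }
        )
        params = SaturationParams(saturation_pct=89.0)
        res, _ = saturation_dereplicate(m, params)
        assert res.representatives == ["g1"]  # 20/22 = 90.9% > 89%
        out = incremental_augment(res, m, params)
        assert out.representatives == ["g1", "odd"]

    def test_rounds_promote_disjoint_pool_in_size_order(self):
        m = membership_of(
            {
                "g1": {f"c{j}" for j in range(30)},
                "p1": {"a1", "a2", "a3"},
                "p2": {"b1", "b2"},
                "p3": {"d1"},
            }
        )
        params = SaturationParams(saturation_pct=80.0)
        res, _ = saturation_dereplicate(m, params)
        assert res.representatives == ["g1"]  # 30/36 = 83.3% > 80%
        out = incremental_augment(res, m, params)
        assert out.representatives == ["g1", "p1", "p2", "p3"]

    def test_growing_set_absorbs_later_candidates(self):
        # q overlaps p1 fully; once p1 is promoted, q no longer
        # qualifies against the grown representative set
        m = membership_of(
            {
                "g1": {f"c{j}" for j in range(30)},
                "p1": {"a1", "a2", "a3"},
                "q": {"a1", "a2"},
            }
        )
        params = SaturationParams(saturation_pct=80.0)
        res, _ = saturation_dereplicate(m, params)
        out = incremental_augment(res, m, params)
        assert out.representatives == ["g1", "p1"]
        assert "q" in out.nonrepresentatives


def test_trace_tsv_columns(tmp_path):
    m = membership_of({"g1": {"c1", "c2"}, "g2": {"c3"}})
    _, trace = saturation_dereplicate(m, SaturationParams(saturation_pct=100.0))
    p = tmp_path / "trace.tsv"
    write_saturation_trace(trace, p)
    lines = p.read_text().splitlines()
    assert lines[0].startswith("#genome_id\tmarginal_gain")
    assert len(lines) == 1 + len(trace.steps)
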