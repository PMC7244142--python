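"""Locus assembly: filters, clustering oracles, the diploid ML caller."""

import numpy as np
import pandas as pd
import pytest

from migpipe._align import identity_ungapped
from migpipe.assembly import (
    AssemblyParams,
    Cluster,
    assemble_dataset,
    call_consensus,
    cluster_across_samples,
    cluster_within_sample,
    compare_groups,
    correlogram,
    estimate_het_error,
    filter_loci,
    filter_min_taxa,
    quality_filter_reads,
    _pattern_loglik,
    _site_patterns,
)
from migpipe.core import LocusAlignment, Read, ReadSet


def _read(name, seq, q=40):
    return Read(name, seq, [q] * len(seq))


class TestQualityFilter:
    def test_51_low_quality_bases_removed(self):
        seq = "A" * 100
        quals = [2] * 51 + [40] * 49
        rs = ReadSet("s", [Read("bad", seq, quals)])
        kept, counts = quality_filter_reads(rs, AssemblyParams())
        assert counts == {"reads_raw": 1, "reads_passed_filter": 0}
        assert len(kept) == 0

    def test_high_quality_kept(self):
        rs = ReadSet("s", [_read("good", "ACGT" * 30)])
        kept, _ = quality_filter_reads(rs, AssemblyParams())
        assert len(kept) == 1

    def test_matches_brute_force_recount(self, rng):
        params = AssemblyParams()
        reads = []
        for i in range(1000):
            n = int(rng.integers(60, 150))
            seq = "".join(rng.choice(list("ACGT"), n))
            quals = rng.choice([2, 15, 25, 40], size=n).tolist()
            reads.append(Read(f"r{i}", seq, quals))
        kept, counts = quality_filter_reads(ReadSet("s", reads), params)
        expect = {
            r.name
            for r in reads
            if sum(q < params.low_quality_threshold for q in r.qualities)
            <= params.max_low_quality_bases
        }
        assert {r.name for r in kept.reads} == expect
        assert counts["reads_passed_filter"] == len(expect)


def _greedy_oracle(seqs, identity):
    """All-pairs greedy clustering oracle, O(n^2)."""
    from collections import Counter

    counts = Counter(seqs)
    order = sorted(counts, key=lambda s: (-counts[s], s))
    centroids, members = [], []
    for s in order:
        for k, c in enumerate(centroids):
            n = min(len(s), len(c))
            ident = sum(a == b for a, b in zip(s[:n], c[:n])) / n
            if ident >= identity:
                members[k].extend([s] * counts[s])
                break
        else:
            centroids.append(s)
            members.append([s] * counts[s])
    return centroids, members


class TestWithinSampleClustering:
    def test_identical_reads_one_cluster(self):
        rs = ReadSet("s", [_read(f"r{i}", "ACGT" * 25) for i in range(10)])
        clusters = cluster_within_sample(rs)
        assert len(clusters) == 1
        assert clusters[0].depth == 10

    def test_divergent_groups_split(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for i in rng.choice(100, 30, replace=False):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        rs = ReadSet("s", [_read(f"a{i}", a) for i in range(5)]
                     + [_read(f"b{i}", b) for i in range(5)])
        assert len(cluster_within_sample(rs, 0.85)) == 2

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            base = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(6)]
            seqs = []
            for _ in range(80):
                s = list(base[int(rng.integers(6))])
                for i in rng.choice(60, int(rng.integers(0, 12)), replace=False):
                    s[i] = "ACGT"[int(rng.integers(4))]
                seqs.append("".join(s))
            rs = ReadSet("s", [_read(f"r{i}", s) for i, s in enumerate(seqs)])
            clusters = cluster_within_sample(rs, 0.85)
            centroids, members = _greedy_oracle(seqs, 0.85)
            assert [c.centroid for c in clusters] == centroids
            assert [sorted(r.sequence for r in c.reads) for c in clusters] == [
                sorted(m) for m in members
            ]


def _simulate_clusters(rng, n_clusters, depth, length, h, eps):
    clusters = []
    for k in range(n_clusters):
        truth = rng.integers(0, 4, size=length)
        het = rng.random(length) < h
        alt = (truth + rng.integers(1, 4, size=length)) % 4
        reads = []
        for d in range(depth):
            allele = np.where(
                het & (rng.random(length) < 0.5), alt, truth
            )
            err = rng.random(length) < eps
            read = np.where(err, (allele + rng.integers(1, 4, size=length)) % 4, allele)
            reads.append(_read(f"c{k}r{d}", "".join("ACGT"[b] for b in read)))
        clusters.append(Cluster("s", reads[0].sequence, reads))
    return clusters


class TestHetErrorEstimation:
    def test_unanimous_sites_estimates_at_lower_bound(self):
        reads = [_read(f"r{i}", "ACGT" * 25) for i in range(10)]
        h, e = estimate_het_error([Cluster("s", reads[0].sequence, reads)])
        assert h < 1e-4 and e < 1e-4

    def test_recovers_truth_within_25_percent(self, rng):
        clusters = _simulate_clusters(rng, 200, 30, 80, h=0.01, eps=0.005)
        h, e = estimate_het_error(clusters)
        assert abs(h - 0.01) / 0.01 < 0.25
        assert abs(e - 0.005) / 0.005 < 0.25

    def test_matches_grid_search_oracle(self, rng):
        clusters = _simulate_clusters(rng, 40, 20, 50, h=0.02, eps=0.01)
        h, e = estimate_het_error(clusters)
        counts, weights = _site_patterns(clusters, 5)
        hs = np.linspace(0.001, 0.1, 60)
        es = np.linspace(0.001, 0.05, 60)
        grid = np.array(
            [[_pattern_loglik(hh, ee, counts, weights) for ee in es] for hh in hs]
        )
        ih, ie = np.unravel_index(grid.argmax(), grid.shape)
        assert abs(h - hs[ih]) <= (hs[1] - hs[0])
        assert abs(e - es[ie]) <= (es[1] - es[0])

    def test_balanced_site_called_heterozygous(self):
        # exact 15:15 two-base split: het posterior dominates at small eps
        reads = [_read(f"r{i}", "A" * 30) for i in range(15)] + [
            _read(f"r{i+15}", "C" + "A" * 29) for i in range(15)
        ]
        # only site 0 varies: 15 A / 15 C
        cluster = Cluster("s", reads[0].sequence, reads)
        cons = call_consensus(cluster, 0.01, 0.001, AssemblyParams())
        assert cons.sequence[0] == "M"

    def test_no_deep_cluster_errors(self):
        reads = [_read("r0", "ACGT")]
        with pytest.raises(ValueError):
            estimate_het_error([Cluster("s", "ACGT", reads)])


class TestConsensus:
    def test_depth_below_minimum_rejected(self):
        reads = [_read(f"r{i}", "ACGT" * 10) for i in range(4)]
        cons = call_consensus(Cluster("s", reads[0].sequence, reads), 0.01, 0.005,
                              AssemblyParams())
        assert cons.rejection == "low_depth"

    def test_even_split_calls_iupac(self):
        reads = [_read(f"r{i}", "AAAA") for i in range(10)] + [
            _read(f"r{i+10}", "CAAA") for i in range(10)
        ]
        cons = call_consensus(Cluster("s", "AAAA", reads), 0.01, 0.005,
                              AssemblyParams())
        assert cons.sequence == "MAAA"
        assert cons.het_sites == 1
        assert cons.n_alleles == 2

    def test_three_phased_alleles_detected(self):
        # three haplotypes over two het sites -> 3 resolved alleles
        reads = (
            [_read(f"a{i}", "AATT") for i in range(8)]
            + [_read(f"b{i}", "CATT") for i in range(8)]
            + [_read(f"c{i}", "CGTT") for i in range(8)]
        )
        cons = call_consensus(Cluster("s", "AATT", reads), 0.02, 0.005,
                              AssemblyParams())
        assert cons.n_alleles == 3


class TestAcrossSamples:
    def _cons(self, sample, seq, depth=10):
        from migpipe.assembly import ConsensusSequence

        return ConsensusSequence(sample, 0, seq, depth, 0, 0, 1)

    def test_identical_consensus_one_locus(self):
        seq = "ACGT" * 30
        consensi = [self._cons(f"s{i}", seq) for i in range(5)]
        loci = cluster_across_samples(consensi, AssemblyParams())
        assert len(loci) == 1
        assert len(loci[0].members) == 5

    def test_divergent_consensus_two_loci(self, rng):
        a = "".join(rng.choice(list("ACGT"), 100))
        b = list(a)
        for i in rng.choice(100, 30, replace=False):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        consensi = [self._cons("s1", a), self._cons("s2", "".join(b))]
        assert len(cluster_across_samples(consensi, AssemblyParams())) == 2

    def test_matches_brute_force_oracle(self, rng):
        base = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(4)]
        consensi = []
        k = 0
        for s in range(6):
            for b in base:
                seq = list(b)
                for i in rng.choice(80, int(rng.integers(0, 8)), replace=False):
                    seq[i] = "ACGT"[int(rng.integers(4))]
                consensi.append(self._cons(f"s{s}", "".join(seq), depth=int(rng.integers(5, 30))))
                k += 1
        got = cluster_across_samples(consensi, AssemblyParams())
        # oracle: same greedy rule, all-pairs identities
        order = sorted([c for c in consensi], key=lambda c: (-c.depth, c.sequence))
        centroids, assign = [], []
        for c in order:
            for j, cent in enumerate(centroids):
                n = min(len(c.sequence), len(cent))
                ident = sum(x == y for x, y in zip(c.sequence[:n], cent[:n])) / n
                if ident >= 0.85:
                    assign[j].append(c)
                    break
            else:
                centroids.append(c.sequence)
                assign.append([c])
        assert len(got) == len(centroids)
        for locus, members in zip(got, assign):
            best = {}
            for m in members:
                if m.sample_id not in best or m.depth > best[m.sample_id].depth:
                    best[m.sample_id] = m
            assert {m.sample_id for m in locus.members} == set(best)


class TestFilterCascade:
    def test_min_taxa_boundary(self):
        loci = [
            LocusAlignment("l3", {f"s{i}": "ACGT" for i in range(3)}),
            LocusAlignment("l4", {f"s{i}": "ACGT" for i in range(4)}),
        ]
        retained, report = filter_min_taxa(loci, min_taxa=4)
        assert [l.locus_id for l in retained] == ["l4"]
        assert report.removal_counts["low_taxa"] == 1

    def test_idempotent_on_retained(self, small_dataset):
        result = assemble_dataset(small_dataset.readsets)
        retained, report = filter_min_taxa(result.loci, 4)
        assert report.removed == 0
        assert len(retained) == len(result.loci)

    def test_report_invariant(self, small_dataset):
        report = assemble_dataset(small_dataset.readsets).report
        assert report.retained + report.removed == report.input_loci

    def test_amplicon_clean_recovery(self):
        """Zero-error amplicon simulation: every true locus with enough
        depth and taxa is recovered with a consensus equal to the truth."""
        from migpipe.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_species=6, n_loci=10, read_depth=8, error_rate=0.0, seed=21
        )
        ds = simulate_dataset(cfg)
        result = assemble_dataset(ds.readsets)
        assert len(result.loci) == 10
        truth_by_seqs = {
            frozenset(l.sequences.values()): l for l in ds.truth.loci
        }
        for locus in result.loci:
            key = frozenset(locus.sequences.values())
            match = truth_by_seqs.get(key)
            assert match is not None
            assert locus.sequences == {
                s: match.sequences[s] for s in locus.sequences
            }


class TestStatsAndComparisons:
    def test_stats_consistency(self, small_dataset):
        result = assemble_dataset(small_dataset.readsets)
        stats = result.stats
        assert (stats["reads_passed_filter"] <= stats["reads_raw"]).all()
        assert (stats["clusters_hidepth"] <= stats["clusters_total"]).all()
        assert (stats["loci_in_assembly"] <= stats["clusters_hidepth"]).all()
        # loci_in_assembly equals a recount from the retained loci
        for sample in stats.index:
            recount = sum(sample in l.sequences for l in result.loci)
            assert stats.loc[sample, "loci_in_assembly"] == recount

    def test_identical_groups_p_near_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 1, 2, 3]}, index=list("abcdef"))
        groups = {"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g2", "f": "g2"}
        res = compare_groups(df, groups)
        assert res.loc["x", "p_value"] > 0.9

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(3, 1, 15)
        df = pd.DataFrame({"x": np.concatenate([a, b])},
                          index=[f"s{i}" for i in range(30)])
        groups = {f"s{i}": ("g1" if i < 15 else "g2") for i in range(30)}
        assert compare_groups(df, groups).loc["x", "p_value"] < 0.01

    def test_small_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4]}, index=list("abcd"))
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        with pytest.raises(ValueError):
            compare_groups(df, groups)

    def test_permutation_null_test_size(self, rng):
        rejections = 0
        n_reps = 200
        x = rng.normal(0, 1, 30)
        df = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(30)])
        for _ in range(n_reps):
            perm = rng.permutation(30)
            groups = {
                f"s{i}": ("g1" if j < 15 else "g2") for j, i in enumerate(perm)
            }
            p = compare_groups(df, groups).loc["x", "p_value"]
            rejections += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rejections / n_reps - 0.05) < 3 * se

    def test_correlogram_properties(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=20), "flat": np.ones(20)},
            index=[f"s{i}" for i in range(20)],
        )
        df["b"] = 2 * df["a"]
        corr = correlogram(df)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(corr.loc["a", "flat"])
        assert (corr.fillna(0).to_numpy() == corr.fillna(0).to_numpy().T).all()
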