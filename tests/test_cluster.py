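"""Clustering: validity filter, single linkage, splitting, region filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dmrkit.cluster import (
    BISEQ_PRESET,
    ClusterParams,
    build_regions,
    filter_valid_sites,
    join_samples,
    single_linkage,
    split_matrix,
    split_oversized,
)
from dmrkit.extract import SiteCount

site_sets = st.lists(
    st.integers(min_value=1, max_value=50_000), min_size=1, max_size=500
).map(lambda xs: sorted(set(xs)))


def slc_oracle(positions, d):
    """Independent O(n^2) transitive closure over pairs within d."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(positions)
    for i, p in enumerate(positions):
        for q in positions[i + 1 :]:
            if q - p <= d:
                g.add_edge(p, q)
    return sorted(sorted(c) for c in nx.connected_components(g))


class TestSingleLinkage:
    def test_gap_cut_example(self):
        assert single_linkage([100, 150, 260], 100) == [[100, 150], [260]]

    def test_singleton(self):
        assert single_linkage([42], 10) == [[42]]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            single_linkage([5, 3], 10)

    @given(positions=site_sets, d=st.integers(min_value=1, max_value=1000))
    def test_matches_transitive_closure_oracle(self, positions, d):
        assert sorted(single_linkage(positions, d)) == slc_oracle(positions, d)

    @given(positions=site_sets, d=st.integers(min_value=1, max_value=500))
    def test_increasing_distance_never_adds_clusters(self, positions, d):
        assert len(single_linkage(positions, d + 50)) <= len(
            single_linkage(positions, d)
        )


class TestSplitOversized:
    def test_no_op_when_within_span(self):
        sites = [100, 200, 300, 500]
        assert split_oversized(sites, 500) == [sites]

    def test_hand_traced_recursive_largest_gap(self):
        # three dense blocks of sites joined by two large gaps; span 1400
        sites = (
            list(range(1000, 1400, 25))  # 16 sites, span 375
            + list(range(1600, 1900, 25))  # 12 sites, span 275
            + list(range(2100, 2400, 25))  # 12 sites, span 275
        )
        assert len(sites) == 40 and sites[-1] - sites[0] == 1375
        pieces = split_oversized(sites, 500)
        assert len(pieces) == 3
        assert all(p[-1] - p[0] <= 500 for p in pieces)
        assert [len(p) for p in pieces] == [16, 12, 12]

    def test_leftmost_tie_break(self):
        # two equal internal gaps of 300: split at the first
        sites = [0, 300, 600]
        assert split_oversized(sites, 500) == [[0], [300, 600]]

    @given(positions=site_sets, x=st.integers(min_value=1, max_value=2000))
    def test_span_bound_and_membership_preserved(self, positions, x):
        pieces = split_oversized(positions, x)
        assert [p for piece in pieces for p in piece] == positions
        assert all(len(p) == 1 or p[-1] - p[0] <= x for p in pieces)

    @given(positions=site_sets, d=st.integers(min_value=1, max_value=1000))
    def test_infinite_cap_reduces_to_single_linkage(self, positions, d):
        clusters = single_linkage(positions, d)
        assert [
            piece for c in clusters for piece in split_oversized(c, 10**9)
        ] == clusters


def counts(sample_sites):
    """{(chrom,pos): (meth, unmeth)} -> sorted SiteCount list."""
    return [
        SiteCount(chrom, pos, m, u)
        for (chrom, pos), (m, u) in sorted(sample_sites.items())
    ]


class TestJoin:
    def test_outer_join_keeps_disjoint_rows(self):
        m = join_samples(
            {
                "a": counts({("chr1", 10): (1, 1), ("chr1", 20): (2, 0)}),
                "b": counts({("chr1", 20): (0, 3), ("chr1", 30): (1, 0)}),
            }
        )
        assert list(m.frame.index) == [("chr1", 10), ("chr1", 20), ("chr1", 30)]
        assert np.isnan(m.frame.loc[("chr1", 30), "a:meth"])

    def test_single_table_identity_roundtrip(self):
        table = counts({("chr1", 5): (2, 3), ("chr2", 8): (1, 0)})
        m = join_samples({"a": table})
        assert split_matrix(m)["a"] == table

    def test_join_split_roundtrip_two_samples(self):
        tables = {
            "a": counts({("chr1", 10): (1, 1), ("chr1", 25): (4, 2)}),
            "b": counts({("chr1", 10): (0, 5)}),
        }
        assert split_matrix(join_samples(tables)) == tables

    def test_unsorted_input_rejected(self):
        bad = [SiteCount("chr1", 20, 1, 0), SiteCount("chr1", 10, 1, 0)]
        with pytest.raises(ValueError):
            join_samples({"a": bad})

    def test_duplicate_site_rejected(self):
        bad = [SiteCount("chr1", 10, 1, 0), SiteCount("chr1", 10, 2, 0)]
        with pytest.raises(ValueError):
            join_samples({"a": bad})


class TestValidSites:
    def params(self, **kw):
        defaults = dict(min_reads=3, min_samples=1, max_dist=100, min_cpg=1,
                        max_len=500, min_total=1)
        defaults.update(kw)
        return ClusterParams(**defaults)

    def test_coverage_below_r_removed(self):
        m = join_samples({"a": counts({("chr1", 10): (1, 1)})})
        got = filter_valid_sites(m, self.params(min_reads=3))
        assert len(got.frame) == 0

    def test_one_of_four_samples_suffices_when_s_is_one(self):
        tables = {"a": counts({("chr1", 10): (3, 0)})}
        for name in "bcd":
            tables[name] = counts({("chr1", 10): (1, 0)})
        got = filter_valid_sites(join_samples(tables), self.params())
        assert len(got.frame) == 1

    def test_blind_to_methylation_split(self):
        """Permuting each cell's meth/unmeth split at fixed coverage leaves
        validity decisions identical."""
        rng = np.random.default_rng(0)
        pos = sorted(rng.choice(10_000, size=60, replace=False))
        cov = rng.integers(1, 10, size=(60, 2))
        tabs = {}
        tabs_perm = {}
        for j, name in enumerate(["a", "b"]):
            meth = rng.binomial(cov[:, j], 0.5)
            meth2 = rng.binomial(cov[:, j], 0.1)  # different split, same coverage
            tabs[name] = [
                SiteCount("chr1", int(p), int(m), int(c - m))
                for p, c, m in zip(pos, cov[:, j], meth)
            ]
            tabs_perm[name] = [
                SiteCount("chr1", int(p), int(m), int(c - m))
                for p, c, m in zip(pos, cov[:, j], meth2)
            ]
        p = self.params(min_reads=4, min_samples=2)
        keep1 = filter_valid_sites(join_samples(tabs), p).frame.index
        keep2 = filter_valid_sites(join_samples(tabs_perm), p).frame.index
        assert list(keep1) == list(keep2)


def reference_build_regions(matrix, params):
    """Straight-line re-implementation of the clustering rules (oracle)."""
    out = []
    rows = [
        (chrom, int(pos), row)
        for (chrom, pos), row in matrix.frame.iterrows()
    ]
    by_chrom: dict = {}
    for chrom, pos, row in rows:
        by_chrom.setdefault(chrom, []).append((pos, row))
    for chrom in matrix.chrom_order:
        sites = by_chrom.get(chrom, [])
        # greedy chain: new cluster when gap > d
        clusters, cur = [], []
        for pos, row in sites:
            if cur and pos - cur[-1][0] > params.max_dist:
                clusters.append(cur)
                cur = []
            cur.append((pos, row))
        if cur:
            clusters.append(cur)
        # recursive largest-gap split
        def split(c):
            if len(c) <= 1 or c[-1][0] - c[0][0] <= params.max_len:
                return [c]
            gaps = [c[i + 1][0] - c[i][0] for i in range(len(c) - 1)]
            i = gaps.index(max(gaps)) + 1
            return split(c[:i]) + split(c[i:])

        for cluster in clusters:
            for piece in split(cluster):
                if len(piece) < params.min_cpg:
                    continue
                agg = {}
                ok = True
                for s in matrix.samples:
                    X = sum(
                        0 if np.isnan(row[f"{s}:meth"]) else row[f"{s}:meth"]
                        for _, row in piece
                    )
                    N = X + sum(
                        0 if np.isnan(row[f"{s}:unmeth"]) else row[f"{s}:unmeth"]
                        for _, row in piece
                    )
                    agg[s] = (int(X), int(N))
                    if N < params.min_total:
                        ok = False
                if ok:
                    out.append(
                        (chrom, tuple(p for p, _ in piece), agg)
                    )
    return out


class TestBuildRegions:
    def make_matrix(self, seed=0, n=120, samples=("a", "b")):
        rng = np.random.default_rng(seed)
        pos = np.unique(rng.integers(1, 20_000, size=n))
        tabs = {}
        for j, s in enumerate(samples):
            cov = rng.integers(1, 15, size=pos.size)
            meth = rng.binomial(cov, 0.5)
            present = rng.random(pos.size) > 0.15
            tabs[s] = [
                SiteCount("chr1", int(p), int(m), int(c - m))
                for p, c, m, keep in zip(pos, cov, meth, present)
                if keep
            ]
        return join_samples(tabs)

    def test_min_total_applies_to_every_sample(self):
        tabs = {
            "a": counts({("chr1", 10): (20, 5), ("chr1", 20): (0, 0 + 1)}),
            "b": counts({("chr1", 10): (10, 5), ("chr1", 20): (4, 0)}),
        }
        params = ClusterParams(min_reads=1, min_samples=1, max_dist=100,
                               min_cpg=2, max_len=500, min_total=20)
        # N: a = 26, b = 19 -> dropped
        assert build_regions(join_samples(tabs), params) == []

    def test_min_cpg_filter(self):
        tabs = {"a": counts({("chr1", 10): (30, 0), ("chr1", 20): (30, 0)})}
        params = ClusterParams(min_reads=1, min_samples=1, max_dist=100,
                               min_cpg=3, max_len=500, min_total=1)
        assert build_regions(join_samples(tabs), params) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize(
        "params",
        [
            ClusterParams(min_reads=1, min_samples=1, max_dist=100, min_cpg=1,
                          max_len=500, min_total=1),
            ClusterParams(min_reads=3, min_samples=2, max_dist=50, min_cpg=3,
                          max_len=200, min_total=10),
            BISEQ_PRESET,
        ],
    )
    def test_matches_straight_line_oracle(self, seed, params):
        matrix = self.make_matrix(seed=seed)
        valid = filter_valid_sites(matrix, params)
        got = [
            (r.chrom, r.sites, {s: (r.X[s], r.N[s]) for s in matrix.samples})
            for r in build_regions(valid, params)
        ]
        assert got == reference_build_regions(valid, params)

    def test_emitted_spans_bounded(self):
        matrix = self.make_matrix(seed=7, n=300)
        params = ClusterParams(min_reads=1, min_samples=1, max_dist=100,
                               min_cpg=1, max_len=150, min_total=1)
        for r in build_regions(matrix, params):
            assert r.span <= 150

    def test_methylation_blindness_of_regions(self):
        """Redistributing meth vs unmeth at fixed coverage yields identical
        region structure and per-sample N."""
        m1 = self.make_matrix(seed=11)
        # rebuild with a different split, same coverage pattern
        frame = m1.frame.copy()
        for s in m1.samples:
            cov = frame[f"{s}:meth"] + frame[f"{s}:unmeth"]
            new_meth = (cov * 0).where(cov.isna(), other=cov // 2)
            frame[f"{s}:meth"] = new_meth
            frame[f"{s}:unmeth"] = cov - new_meth
        m2 = type(m1)(frame, m1.samples, m1.chrom_order)
        params = ClusterParams(min_reads=2, min_samples=1, max_dist=80,
                               min_cpg=2, max_len=300, min_total=5)
        r1 = build_regions(filter_valid_sites(m1, params), params)
        r2 = build_regions(filter_valid_sites(m2, params), params)
        assert [(r.chrom, r.sites, r.N) for r in r1] == [
            (r.chrom, r.sites, r.N) for r in r2
        ]

    def test_empty_matrix(self):
        m = join_samples({"a": []})
        assert build_regions(m, ClusterParams()) == []
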