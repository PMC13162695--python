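"""Sweep-scan statistics: pi, Weir-Cockerham Fst, XP-EHH, intersections."""

import itertools

import numpy as np
import pandas as pd
import pytest

from suspop.introgression import WindowTrack
from suspop.simgen import DemographicModel, Event, make_fixture, simulate
from suspop.sweeps import (
    aggregate_to_grid,
    intersect_top,
    map_regions_to_genes,
    pi_ratio,
    windowed_fst,
    windowed_pi,
    xpehh,
)
from tests.conftest import toy_matrix


class TestWindowedPi:
    def test_monomorphic_zero(self):
        m = toy_matrix(np.zeros((4, 5), dtype=np.int8), ["A", "A"])
        track = windowed_pi(m, "A", window_bp=1000, step_bp=1000)
        assert np.all(track.values == 0)

    def test_hand_arithmetic(self):
        # 4 haplotypes, one site at p = 0.5, 1 kb window
        m = toy_matrix([[1], [1], [0], [0]], ["A", "A"])
        track = windowed_pi(m, "A", window_bp=1000, step_bp=1000)
        assert track.values[0] == pytest.approx(2 * 0.25 * (4 / 3) / 1000)

    def test_matches_pairwise_difference_oracle(self, rng):
        alleles = (rng.random((8, 100)) < 0.3).astype(np.int8)
        m = toy_matrix(alleles, ["A"] * 4, positions=rng.choice(5000, 100, False))
        m = m.take_sites(np.argsort(m.positions))
        track = windowed_pi(m, "A", window_bp=1000, step_bp=1000)
        for c, s, e, v in zip(track.chrom, track.start, track.end, track.values):
            sel = (m.positions >= s) & (m.positions < e)
            sub = m.alleles[:, sel]
            diffs = sum(
                (sub[i] != sub[j]).sum()
                for i, j in itertools.combinations(range(8), 2)
            )
            assert v == pytest.approx(diffs / (8 * 7 / 2) / 1000, abs=1e-12)

    def test_window_validation(self):
        m = toy_matrix([[0], [1]], ["A"])
        with pytest.raises(ValueError, match="window_bp"):
            windowed_pi(m, "A", window_bp=0)


def _wc_fst_oracle(ga, gb):
    """Independent scalar Weir-Cockerham (1984) two-deme Fst on genotype lists."""
    a_sum = d_sum = 0.0
    n_sites = len(ga[0][0])
    for j in range(n_sites):
        stats = []
        for g in (ga, gb):
            n = len(g)
            p = sum(h1[j] + h2[j] for h1, h2 in g) / (2 * n)
            h = sum(h1[j] != h2[j] for h1, h2 in g) / n
            stats.append((n, p, h))
        (n1, p1, h1), (n2, p2, h2) = stats
        r = 2
        nbar = (n1 + n2) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        d_sum += a + b + c
    return a_sum / d_sum if d_sum else np.nan


class TestWindowedFst:
    def test_fixed_difference_is_one(self):
        alleles = np.array([[1] * 4, [1] * 4, [1] * 4, [1] * 4,
                            [0] * 4, [0] * 4, [0] * 4, [0] * 4], dtype=np.int8)
        m = toy_matrix(alleles, ["A", "A", "B", "B"])
        track = windowed_fst(m, "A", "B", window_bp=1000, step_bp=1000)
        assert track.values[0] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self, rng):
        base = (rng.random(60) < 0.5).astype(np.int8)
        alleles = np.tile(base, (40, 1))  # both pops identical and monomorphic-free
        alleles[1::2] = 1 - alleles[1::2]  # p = 0.5 in every pop at every site
        m = toy_matrix(alleles, ["A"] * 10 + ["B"] * 10)
        track = windowed_fst(m, "A", "B", window_bp=600, step_bp=600)
        assert abs(track.values[0]) < 0.02

    def test_matches_scalar_oracle(self, rng):
        alleles = (rng.random((12, 40)) < 0.35).astype(np.int8)
        m = toy_matrix(alleles, ["A"] * 3 + ["B"] * 3, positions=np.arange(40))
        track = windowed_fst(m, "A", "B", window_bp=100, step_bp=100)
        ga = [(alleles[2 * i], alleles[2 * i + 1]) for i in range(3)]
        gb = [(alleles[2 * i], alleles[2 * i + 1]) for i in range(3, 6)]
        assert track.values[0] == pytest.approx(_wc_fst_oracle(ga, gb), abs=1e-12)

    def test_fst_increases_with_split_time(self):
        vals = []
        for t in (500.0, 2000.0, 8000.0):
            model = DemographicModel(
                populations={"A": 5000.0, "B": 5000.0},
                events=[Event(time=t, kind="split", derived="B", ancestral="A")],
            )
            mat, _ = simulate(model, {"A": 6, "B": 6}, 120, 20_000, seed=21,
                              return_genealogies=False)
            track = windowed_fst(mat, "A", "B", window_bp=20_000, step_bp=20_000)
            vals.append(float(np.mean(track.values)))
        assert vals[0] < vals[1] < vals[2]

    def test_single_diploid_per_pop_gives_no_defined_window(self):
        # one fully heterozygous sample per deme: every per-site denominator
        # is zero, so all windows are dropped rather than reported as 0/0
        m = toy_matrix([[0, 0], [1, 1], [0, 1], [1, 0]], ["A", "B"])
        track = windowed_fst(m, "A", "B", window_bp=100, step_bp=100)
        assert len(track) == 0


class TestPiRatio:
    def _track(self, values, start=None):
        n = len(values)
        start = np.arange(n, dtype=np.int64) * 100 if start is None else np.asarray(start)
        return WindowTrack("pi", np.full(n, "1", dtype="U32"), start, start + 100,
                           np.asarray(values, float), np.ones(n, dtype=np.int64))

    def test_equal_and_tenfold(self):
        wild = self._track([1e-3, 1e-3])
        target = self._track([1e-3, 1e-4])
        out = pi_ratio(wild, target)
        assert out.values[0] == pytest.approx(0.0)
        assert out.values[1] == pytest.approx(1.0)

    def test_zero_windows_dropped(self):
        out = pi_ratio(self._track([1e-3, 0.0]), self._track([1e-3, 1e-3]))
        assert len(out) == 1

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="grid"):
            pi_ratio(self._track([1.0]), self._track([1.0, 2.0]))


def _ehh_oracle(haps, core, x):
    """Fraction of haplotype pairs identical at all sites in (core, x]."""
    n = haps.shape[0]
    lo, hi = (core + 1, x + 1) if x >= core else (x, core)
    seg = haps[:, lo:hi]
    pairs = n * (n - 1) / 2
    same = sum(
        (seg[i] == seg[j]).all()
        for i, j in itertools.combinations(range(n), 2)
    )
    return same / pairs


class TestXpehh:
    def test_sign_contract(self):
        # pop A shares one haplotype across a focal region, pop B is diverse:
        # standardized scores inside the region are positive
        rng = np.random.default_rng(5)
        a = (rng.random((8, 200)) < 0.5).astype(np.int8)
        b = (rng.random((8, 200)) < 0.5).astype(np.int8)
        region = slice(80, 120)
        a[:, region] = a[0, region]
        m = toy_matrix(np.vstack([a, b]), ["A"] * 4 + ["B"] * 4,
                       positions=np.arange(200) * 100)
        track = xpehh(m, "A", "B")
        inside = (track.start >= 80 * 100) & (track.start < 120 * 100)
        assert track.values[inside].mean() > 0.5

    def test_standardization(self, quartet_fixture):
        track = xpehh(quartet_fixture.matrix, "P1", "P3")
        assert abs(track.values.mean()) < 1e-9
        assert abs(track.values.std() - 1.0) < 1e-9

    def test_ehh_matches_pair_counting_oracle(self, rng):
        from suspop.sweeps import _ehh_profile

        haps = (rng.random((6, 10)) < 0.5).astype(np.int8)
        pos = np.arange(10, dtype=float) * 50
        rows = np.arange(6)
        core = 4
        for direction in (1, -1):
            xs, ea, _ = _ehh_profile(haps, rows, rows, core, direction, pos,
                                     min_ehh=0.0, max_gap_bp=10_000)
            assert ea[0] == 1.0  # EHH at the core itself
            for step in range(1, len(xs)):
                x = core + direction * step
                assert ea[step] == pytest.approx(_ehh_oracle(haps, core, x), abs=1e-12)

    def test_missing_rejected(self):
        m = toy_matrix([[0, -1], [1, 0], [0, 0], [1, 1]], ["A", "B"])
        with pytest.raises(ValueError, match="genotyped"):
            xpehh(m, "A", "B")


class TestIntersectTop:
    def _track(self, values, chrom="1"):
        n = len(values)
        start = np.arange(n, dtype=np.int64) * 100
        return WindowTrack("t", np.full(n, chrom, dtype="U32"), start, start + 100,
                           np.asarray(values, float), np.ones(n, dtype=np.int64))

    def test_q_one_returns_everything_merged(self):
        tracks = {"a": self._track([1, 2, 3]), "b": self._track([3, 2, 1]),
                  "c": self._track([2, 2, 2])}
        calls = intersect_top(tracks, q=1.0)
        assert calls.regions == [("1", 0, 300)]

    def test_order_independent(self):
        rng = np.random.default_rng(3)
        tracks = {k: self._track(rng.random(50)) for k in ("fst", "pi", "xp")}
        a = intersect_top(dict(sorted(tracks.items())), q=0.1)
        b = intersect_top(dict(sorted(tracks.items(), reverse=True)), q=0.1)
        assert a.regions == b.regions

    def test_requires_common_peak(self):
        a = self._track([0, 0, 9, 0, 0])
        b = self._track([0, 0, 8, 0, 1])
        c = self._track([1, 0, 7, 0, 0])
        calls = intersect_top({"a": a, "b": b, "c": c}, q=0.2)
        assert calls.regions == [("1", 200, 300)]
        calls2 = intersect_top({"a": a, "b": b, "c": self._track([0, 9, 0, 0, 1])}, q=0.2)
        assert calls2.regions == []

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            intersect_top({"a": self._track([])}, q=0.5)

    def test_aggregate_to_grid_max(self):
        site = WindowTrack("xp", np.full(3, "1", dtype="U32"),
                           np.array([10, 20, 150], dtype=np.int64),
                           np.array([11, 21, 151], dtype=np.int64),
                           np.array([0.5, 2.0, -1.0]), np.ones(3, dtype=np.int64))
        grid = self._track([0.0, 0.0, 0.0])
        agg = aggregate_to_grid(site, grid)
        assert list(agg.values) == [2.0, -1.0]
        assert list(agg.start) == [0, 100]


class TestGeneMapping:
    annotation = pd.DataFrame(
        [("1", 50, 150, "geneA"), ("1", 300, 400, "geneB"),
         ("1", 100, 120, "geneA"), ("2", 0, 100, "geneC")],
        columns=["chrom", "start", "end", "gene_id"],
    )

    def test_overlap_and_dedup(self):
        genes = map_regions_to_genes([("1", 0, 200)], self.annotation)
        assert genes == ["geneA"]

    def test_abutting_halfopen_excluded(self):
        assert map_regions_to_genes([("1", 150, 300)], self.annotation) == []
        assert map_regions_to_genes([("1", 149, 300)], self.annotation) == ["geneA"]

    def test_file_parsing(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t50\t150\tgeneA\n")
        assert map_regions_to_genes([("1", 0, 60)], str(bed)) == ["geneA"]
        gff = tmp_path / "genes.gff3"
        gff.write_text("1\tsrc\tgene\t51\t150\t.\t+\t.\tID=geneA;Name=x\n")
        assert map_regions_to_genes([("1", 0, 60)], str(gff)) == ["geneA"]
        bad = tmp_path / "bad.txt"
        bad.write_text("1\t50\n")
        with pytest.raises(ValueError, match="malformed"):
            map_regions_to_genes([("1", 0, 60)], str(bad))


def test_hard_sweep_signal_visible():
    fx = make_fixture("hard_sweep", seed=11, n_loci=40)
    m = fx.matrix
    lo, hi = fx.metadata["region"]
    pi_t = windowed_pi(m, "TBT")
    inside = (pi_t.start >= lo) & (pi_t.end <= hi)
    assert pi_t.values[inside].mean() < np.median(pi_t.values[~inside])
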