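"""Three-statistic selective-sweep scan.

Candidate sweep regions are the intersection of the top-q (default 5%)
windows of three signals computed between a target population (e.g. pooled
Tibetan pigs) and a reference population (e.g. pooled Asian wild boars):

* windowed nucleotide diversity pi and the log10 pi-ratio
  (reference / target; elevated where the target lost diversity),
* windowed Weir-Cockerham Fst,
* XP-EHH, the log-ratio of integrated extended-haplotype-homozygosity
  (positive = unusually long haplotypes in the target), standardized
  genome-wide and aggregated to the window grid by maximum.

Windows are anchored at position 0 per chromosome, half-open, 50 kb wide with
a 20 kb step by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from suspop.introgression import WindowTrack, top_fraction_windows
from suspop.simgen import MISSING, GenotypeMatrix


@dataclass
class SweepCallSet:
    regions: list[tuple[str, int, int]]
    statistics: list[str]
    genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# window grid helpers
# ---------------------------------------------------------------------------

def _window_grid(matrix: GenotypeMatrix, window_bp: int, step_bp: int):
    """(chrom, start, end, site-index-array) per window, grid anchored at 0."""
    out = []
    for c in dict.fromkeys(matrix.chrom.tolist()):
        on_c = np.flatnonzero(matrix.chrom == c)
        pos = matrix.positions[on_c]
        last = int(pos.max()) if len(pos) else 0
        start = 0
        while start <= last:
            end = start + window_bp
            sel = on_c[(pos >= start) & (pos < end)]
            out.append((c, start, end, sel))
            start += step_bp
    return out


def _track(stat, rows) -> WindowTrack:
    chrom, start, end, vals, ns = zip(*rows) if rows else ((), (), (), (), ())
    return WindowTrack(
        stat,
        np.asarray(chrom, dtype="U32"),
        np.asarray(start, dtype=np.int64),
        np.asarray(end, dtype=np.int64),
        np.asarray(vals, dtype=float),
        np.asarray(ns, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# diversity and differentiation
# ---------------------------------------------------------------------------

def windowed_pi(
    matrix: GenotypeMatrix, pop: str, window_bp: int = 50_000, step_bp: int = 20_000
) -> WindowTrack:
    """Mean pairwise diversity per bp: sum over sites of 2 p (1-p) n/(n-1)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    haps = matrix.haps_for(pop)
    sub = matrix.alleles[haps]
    called = (sub != MISSING).sum(axis=0)
    p = matrix.derived_freq(pop)
    with np.errstate(invalid="ignore"):
        per_site = np.where(
            called > 1, 2.0 * p * (1 - p) * called / np.maximum(called - 1, 1), 0.0
        )
    rows = []
    for c, s, e, sel in _window_grid(matrix, window_bp, step_bp):
        rows.append((c, s, e, float(per_site[sel].sum()) / window_bp, len(sel)))
    return _track("pi", rows)


def _wc_components(matrix: GenotypeMatrix, pop_a: str, pop_b: str):
    """Per-site Weir-Cockerham (1984) variance components a, b, c for 2 demes."""
    comps = []
    for pop in (pop_a, pop_b):
        haps = matrix.haps_for(pop)
        if haps.size < 2:
            raise ValueError(f"population {pop} needs >= 2 haplotypes")
        g = matrix.alleles[haps].reshape(-1, 2, matrix.n_sites)
        ok = (g != MISSING).all(axis=1)
        n_i = ok.sum(axis=0).astype(float)
        # allele-1 frequency and het proportion among fully-called diploids
        cnt = np.where(ok, (g == 1).sum(axis=1), 0).sum(axis=0)
        het = np.where(ok, (g[:, 0, :] != g[:, 1, :]), False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, cnt / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0, het / n_i, np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    n_bar = (n1 + n2) / r
    valid = (n1 > 0) & (n2 > 0) & (n_bar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / nc) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    a = np.where(valid & (nc > 0), a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return np.nan_to_num(a), np.nan_to_num(b), np.nan_to_num(c)


def windowed_fst(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    window_bp: int = 50_000,
    step_bp: int = 20_000,
) -> WindowTrack:
    """Windowed Weir-Cockerham Fst: sum(a) / sum(a + b + c); undefined windows dropped."""
    a, b, c = _wc_components(matrix, pop_a, pop_b)
    rows = []
    for ch, s, e, sel in _window_grid(matrix, window_bp, step_bp):
        den = (a[sel] + b[sel] + c[sel]).sum()
        if den == 0:
            continue
        rows.append((ch, s, e, float(a[sel].sum() / den), len(sel)))
    return _track("fst", rows)


def pi_ratio(track_wild: WindowTrack, track_target: WindowTrack) -> WindowTrack:
    """log10(pi_wild / pi_target) per window; zero-diversity windows dropped."""
    same_grid = (
        len(track_wild) == len(track_target)
        and np.array_equal(track_wild.start, track_target.start)
        and np.array_equal(track_wild.chrom, track_target.chrom)
    )
    if not same_grid:
        raise ValueError("pi tracks must share an identical window grid")
    ok = (track_wild.values > 0) & (track_target.values > 0)
    idx = np.flatnonzero(ok)
    out = track_wild.take(idx)
    return WindowTrack(
        "pi_ratio", out.chrom, out.start, out.end,
        np.log10(track_wild.values[idx] / track_target.values[idx]),
        np.minimum(track_wild.n_sites[idx], track_target.n_sites[idx]),
    )


# ---------------------------------------------------------------------------
# XP-EHH
# ---------------------------------------------------------------------------

def _ehh_profile(hap_pool, rows_a, rows_b, core, direction, positions,
                 min_ehh, max_gap_bp):
    """EHH decay outward from ``core``; identity over sites beyond the core.

    Returns (positions, ehh_a, ehh_b) including the core point (EHH = 1);
    extension stops when the pooled-sample EHH drops below ``min_ehh``, at a
    gap larger than ``max_gap_bp`` or at the chromosome edge.
    """
    n = hap_pool.shape[0]
    ids = np.zeros(n, dtype=np.int64)
    xs = [positions[core]]
    ea, eb = [1.0], [1.0]

    def homozygosity(labels, m):
        if len(labels) < 2:
            return 0.0
        counts = np.bincount(labels, minlength=m)
        return float((counts * (counts - 1)).sum() / (len(labels) * (len(labels) - 1)))

    j = core
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= hap_pool.shape[1]:
            break
        if abs(positions[j_next] - positions[j]) > max_gap_bp:
            break
        # refine clusters by the next site's allele, relabelling compactly
        raw = ids * 2 + hap_pool[:, j_next]
        seen = np.bincount(raw, minlength=2 * n)
        remap = np.cumsum(seen > 0) - 1
        ids = remap[raw]
        m = int(ids.max()) + 1
        pooled = homozygosity(ids, m)
        xs.append(positions[j_next])
        ea.append(homozygosity(ids[rows_a], m))
        eb.append(homozygosity(ids[rows_b], m))
        if pooled < min_ehh:
            break
        j = j_next
    return np.asarray(xs, float), np.asarray(ea), np.asarray(eb)


def xpehh(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    min_ehh: float = 0.05,
    max_gap_bp: int = 200_000,
) -> WindowTrack:
    """Per-site standardized XP-EHH; positive = longer haplotypes in ``pop_a``.

    Physical distance stands in for genetic distance in the iHH trapezoid
    integration.  Scores are standardized to mean 0, sd 1 genome-wide.
    """
    haps_a = matrix.haps_for(pop_a)
    haps_b = matrix.haps_for(pop_b)
    pool = matrix.alleles[np.concatenate([haps_a, haps_b])]
    if (pool == MISSING).any():
        raise ValueError("XP-EHH requires fully genotyped, phased haplotypes")
    rows_a = np.arange(haps_a.size)
    rows_b = np.arange(haps_a.size, haps_a.size + haps_b.size)

    chroms, starts, scores = [], [], []
    for c in dict.fromkeys(matrix.chrom.tolist()):
        on_c = np.flatnonzero(matrix.chrom == c)
        sub = pool[:, on_c]
        pos = matrix.positions[on_c].astype(float)
        freq = sub.mean(axis=0)
        for ci in range(len(on_c)):
            if freq[ci] == 0 or freq[ci] == 1:  # monomorphic in both pops
                continue
            ihh_a = ihh_b = 0.0
            for direction in (-1, 1):
                xs, ea, eb = _ehh_profile(
                    sub, rows_a, rows_b, ci, direction, pos, min_ehh, max_gap_bp
                )
                d = np.abs(np.diff(xs))
                ihh_a += float(np.sum(d * (ea[:-1] + ea[1:]) / 2))
                ihh_b += float(np.sum(d * (eb[:-1] + eb[1:]) / 2))
            if ihh_a > 0 and ihh_b > 0:
                chroms.append(c)
                starts.append(int(pos[ci]))
                scores.append(math.log(ihh_a / ihh_b))
    scores = np.asarray(scores, dtype=float)
    if len(scores) == 0:
        raise ValueError("no scorable core sites")
    sd = scores.std()
    std = (scores - scores.mean()) / (sd if sd > 0 else 1.0)
    starts = np.asarray(starts, dtype=np.int64)
    return WindowTrack(
        "xpehh",
        np.asarray(chroms, dtype="U32"),
        starts,
        starts + 1,
        std,
        np.ones(len(std), dtype=np.int64),
    )


def aggregate_to_grid(site_track: WindowTrack, grid_track: WindowTrack) -> WindowTrack:
    """Window maximum of site-resolution scores over another track's grid."""
    vals = np.full(len(grid_track), -np.inf)
    ns = np.zeros(len(grid_track), dtype=np.int64)
    for i in range(len(grid_track)):
        sel = (
            (site_track.chrom == grid_track.chrom[i])
            & (site_track.start >= grid_track.start[i])
            & (site_track.start < grid_track.end[i])
        )
        if sel.any():
            vals[i] = site_track.values[sel].max()
            ns[i] = int(sel.sum())
    keep = np.flatnonzero(np.isfinite(vals))
    return WindowTrack(
        site_track.statistic,
        grid_track.chrom[keep], grid_track.start[keep], grid_track.end[keep],
        vals[keep], ns[keep],
    )


# ---------------------------------------------------------------------------
# intersection and gene mapping
# ---------------------------------------------------------------------------

def _merge_intervals(iv: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out = []
    for c, s, e in sorted(iv):
        if out and out[-1][0] == c and s <= out[-1][2]:
            out[-1] = (c, out[-1][1], max(out[-1][2], e))
        else:
            out.append((c, s, e))
    return out


def _intersect_two(a, b):
    out = []
    for c, s, e in a:
        for c2, s2, e2 in b:
            if c == c2 and s < e2 and s2 < e:
                out.append((c, max(s, s2), min(e, e2)))
    return _merge_intervals(out)


def intersect_top(tracks: dict[str, WindowTrack], q: float = 0.05) -> SweepCallSet:
    """Regions in the top-q tail of every supplied statistic, merged.

    Per-statistic top-q window sets are merged into interval unions whose
    common intersection (>= 1 bp) defines the candidate sweep regions;
    the result does not depend on the order of the tracks.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    for name, t in tracks.items():
        if len(t) == 0:
            raise ValueError(f"track {name} is empty")
    sets = [
        _merge_intervals(top_fraction_windows(t, q)) for _, t in sorted(tracks.items())
    ]
    regions = sets[0]
    for s in sets[1:]:
        regions = _intersect_two(regions, s)
    return SweepCallSet(regions=regions, statistics=sorted(tracks))


def map_regions_to_genes(
    regions: list[tuple[str, int, int]], annotation
) -> list[str]:
    """Genes overlapping any region by >= 1 bp (half-open), de-duplicated.

    ``annotation`` is a DataFrame with columns chrom/start/end/gene_id, or a
    path to a BED file (4 columns) or GFF3 subset (ID= attribute).
    """
    if isinstance(annotation, (str,)):
        annotation = _read_annotation(annotation)
    required = {"chrom", "start", "end", "gene_id"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    hits = []
    for _, g in annotation.iterrows():
        for c, s, e in regions:
            if str(g["chrom"]) == str(c) and g["start"] < e and s < g["end"]:
                hits.append(str(g["gene_id"]))
                break
    return sorted(dict.fromkeys(hits))


def _read_annotation(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) >= 9:  # GFF3: 1-based closed -> 0-based half-open
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                rows.append((f[0], int(f[3]) - 1, int(f[4]), attrs.get("ID", f[8])))
            elif len(f) >= 4:  # BED
                rows.append((f[0], int(f[1]), int(f[2]), f[3]))
            else:
                raise ValueError(f"malformed annotation line: {line!r}")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
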