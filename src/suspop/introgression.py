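"""Allele-frequency introgression statistics and topology weighting.

D (ABBA-BABA) and f_d use the frequency-based estimators with the outgroup
fixing the ancestral state: at each usable site the outgroup must be
monomorphic among its called haplotypes; its allele is taken as ancestral and
derived frequencies p1, p2, p3 are computed in the three test populations.

    ABBA = (1 - p1) p2 p3        BABA = p1 (1 - p2) p3
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

A positive D marks excess allele sharing between P2 and P3, negative between
P1 and P3; |Z| > 3 (delete-one block jackknife) is called significant.

f_d divides the same numerator by its donor-maximized version, substituting
p_D = max(p2, p3) in both donor roles, giving a window-level admixture
fraction estimate; windows with negative D or non-positive denominator are 0.

Topology weighting samples one haplotype per group from each true genealogy
and counts which rooted quartet topology it shows; weights average to 1 per
locus and are combined genome-wide with locus-length weighting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from suspop.simgen import MISSING, Genealogy, GenotypeMatrix

Z_SIGNIFICANT = 3.0


@dataclass
class WindowTrack:
    """Per-window values of one statistic over sorted genomic intervals."""

    statistic: str
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    values: np.ndarray
    n_sites: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (str(c), int(s), int(e))
            for c, s, e in zip(self.chrom, self.start, self.end)
        ]

    def take(self, idx) -> "WindowTrack":
        return WindowTrack(
            self.statistic, self.chrom[idx], self.start[idx], self.end[idx],
            self.values[idx], self.n_sites[idx],
        )


@dataclass
class DStatResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    abba: float
    baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    @property
    def significant(self) -> bool:
        return np.isfinite(self.z) and abs(self.z) > Z_SIGNIFICANT


@dataclass
class F3Result:
    outgroup: str
    a: str
    b: str
    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int


# ---------------------------------------------------------------------------
# shared site machinery
# ---------------------------------------------------------------------------

def _freq(matrix: GenotypeMatrix, pop: str) -> np.ndarray:
    return matrix.derived_freq(pop)


def _polarized_freqs(matrix: GenotypeMatrix, pops: list[str], outgroup: str):
    """Derived frequencies for ``pops`` at sites usable for D-type statistics.

    Usable: every population and the outgroup have >= 1 called haplotype and
    the outgroup is monomorphic; the outgroup allele defines the ancestral
    state, so its derived frequency is 0 by construction.
    """
    og_haps = matrix.alleles[matrix.haps_for(outgroup)]
    called = og_haps != MISSING
    has0 = ((og_haps == 0) & called).any(axis=0)
    has1 = ((og_haps == 1) & called).any(axis=0)
    usable = called.any(axis=0) & ~(has0 & has1)
    freqs = []
    for p in pops:
        f = _freq(matrix, p)
        usable &= ~np.isnan(f)
        freqs.append(f)
    idx = np.flatnonzero(usable)
    out = []
    anc_is_one = has1[idx]
    for f in freqs:
        fi = f[idx]
        out.append(np.where(anc_is_one, 1.0 - fi, fi))
    return idx, out


def _block_ids(matrix: GenotypeMatrix, idx: np.ndarray, block_size_bp: float) -> np.ndarray:
    """Contiguous-block index per used site (per chromosome)."""
    pairs = [
        (str(matrix.chrom[i]), int(matrix.positions[i] // block_size_bp)) for i in idx
    ]
    uniq = {p: j for j, p in enumerate(dict.fromkeys(pairs))}
    return np.array([uniq[p] for p in pairs], dtype=np.int64)


def _jackknife(num_blocks: np.ndarray, den_blocks: np.ndarray):
    """Delete-one jackknife of a ratio statistic over block sums."""
    tot_n, tot_d = num_blocks.sum(), den_blocks.sum()
    keep = den_blocks != 0
    loo_n = tot_n - num_blocks
    loo_d = tot_d - den_blocks
    est = np.where(loo_d != 0, loo_n / np.where(loo_d != 0, loo_d, 1.0), np.nan)
    est = est[np.isfinite(est)]
    b = len(est)
    if b < 3:
        raise ValueError("fewer than 3 non-empty jackknife blocks")
    se = math.sqrt((b - 1) / b * np.sum((est - est.mean()) ** 2))
    return se, b


# ---------------------------------------------------------------------------
# D and f3
# ---------------------------------------------------------------------------

def dstat(
    matrix: GenotypeMatrix,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    block_size_bp: float = 5e6,
) -> DStatResult:
    """Frequency-based ABBA-BABA test with block-jackknife Z score."""
    if len({p1, p2, p3, outgroup}) != 4:
        raise ValueError("P1, P2, P3 and outgroup must be four distinct labels")
    idx, (f1, f2, f3_) = _polarized_freqs(matrix, [p1, p2, p3], outgroup)
    abba = (1 - f1) * f2 * f3_
    baba = f1 * (1 - f2) * f3_
    blocks = _block_ids(matrix, idx, block_size_bp)
    nb = blocks.max() + 1 if len(blocks) else 0
    num = np.bincount(blocks, weights=abba - baba, minlength=nb)
    den = np.bincount(blocks, weights=abba + baba, minlength=nb)
    a_sum, b_sum = float(abba.sum()), float(baba.sum())
    if a_sum + b_sum == 0:
        return DStatResult(p1, p2, p3, outgroup, a_sum, b_sum,
                           np.nan, np.nan, np.nan, int(nb), len(idx))
    d = (a_sum - b_sum) / (a_sum + b_sum)
    se, nb_eff = _jackknife(num, den)
    z = d / se if se > 0 else np.nan
    return DStatResult(p1, p2, p3, outgroup, a_sum, b_sum,
                       float(d), float(se), float(z), int(nb_eff), len(idx))


def f3_outgroup(
    matrix: GenotypeMatrix,
    a: str,
    b: str,
    outgroup: str,
    block_size_bp: float = 5e6,
) -> F3Result:
    """Outgroup f3(O; A, B): mean (pO - pA)(pO - pB); higher = more shared drift."""
    fo = _freq(matrix, outgroup)
    fa = _freq(matrix, a)
    fb = _freq(matrix, b)
    usable = ~(np.isnan(fo) | np.isnan(fa) | np.isnan(fb))
    idx = np.flatnonzero(usable)
    prod = (fo[idx] - fa[idx]) * (fo[idx] - fb[idx])
    blocks = _block_ids(matrix, idx, block_size_bp)
    nb = blocks.max() + 1 if len(blocks) else 0
    num = np.bincount(blocks, weights=prod, minlength=nb)
    den = np.bincount(blocks, minlength=nb).astype(float)
    f3 = float(prod.mean())
    se, nb_eff = _jackknife(num, den)
    z = f3 / se if se > 0 else np.nan
    return F3Result(outgroup, a, b, f3, float(se), float(z), int(nb_eff), len(idx))


# ---------------------------------------------------------------------------
# windowed f_d
# ---------------------------------------------------------------------------

def fd_windows(
    matrix: GenotypeMatrix,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    window_snps: int = 100,
    step_snps: int = 50,
) -> WindowTrack:
    """Sliding-window f_d over usable SNPs (window/step in SNP counts)."""
    idx, (f1, f2, f3_) = _polarized_freqs(matrix, [p1, p2, p3], outgroup)
    if len(idx) < window_snps:
        raise ValueError("no complete window of usable sites")
    abba = (1 - f1) * f2 * f3_
    baba = f1 * (1 - f2) * f3_
    fd_don = np.maximum(f2, f3_)
    abba_d = (1 - f1) * fd_don * fd_don
    baba_d = f1 * (1 - fd_don) * fd_don

    chroms, starts, ends, vals, nsites = [], [], [], [], []
    chrom_arr = matrix.chrom[idx]
    pos_arr = matrix.positions[idx]
    for c in dict.fromkeys(chrom_arr.tolist()):
        w = np.flatnonzero(chrom_arr == c)
        for s in range(0, len(w) - window_snps + 1, step_snps):
            sel = w[s : s + window_snps]
            num = abba[sel].sum() - baba[sel].sum()
            den = abba_d[sel].sum() - baba_d[sel].sum()
            fd = 0.0 if (den <= 0 or num < 0) else min(num / den, 1.0)
            chroms.append(c)
            starts.append(int(pos_arr[sel[0]]))
            ends.append(int(pos_arr[sel[-1]]) + 1)
            vals.append(fd)
            nsites.append(window_snps)
    if not vals:
        raise ValueError("no complete window of usable sites")
    return WindowTrack(
        "fd",
        np.asarray(chroms, dtype="U32"),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(vals, dtype=float),
        np.asarray(nsites, dtype=np.int64),
    )


def top_fraction_windows(track: WindowTrack, q: float = 0.01) -> list[tuple[str, int, int]]:
    """The top ceil(q * N) windows by value, as (chrom, start, end) intervals."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    if len(track) == 0:
        raise ValueError("empty track")
    n_top = math.ceil(q * len(track))
    order = np.argsort(-track.values, kind="stable")[:n_top]
    return track.take(np.sort(order)).intervals()


def window_overlap(
    set_a: list[tuple[str, int, int]], set_b: list[tuple[str, int, int]]
) -> float:
    """Fraction of A's windows sharing >= 1 bp with any window in B."""
    if not set_a:
        raise ValueError("empty interval set A")
    hit = 0
    for c, s, e in set_a:
        for c2, s2, e2 in set_b:
            if c == c2 and s < e2 and s2 < e:
                hit += 1
                break
    return hit / len(set_a)


# ---------------------------------------------------------------------------
# topology weighting
# ---------------------------------------------------------------------------

def topology_weights(
    genealogies: list[Genealogy],
    groups: dict[str, np.ndarray],
    outgroup: str,
    subsamples_per_locus: int = 20,
    seed: int = 1,
) -> tuple[dict[str, float], np.ndarray]:
    """Quartet topology weights from true genealogies.

    ``groups`` maps four group names to haplotype indices (leaves of the
    genealogies); the ingroup topology is decided by which ingroup pair has
    the most recent common ancestor.  Returns genome-wide weights (locus mean
    weighted by locus length) and the per-locus weight matrix, both over the
    three rooted topologies in a fixed label order.
    """
    if outgroup not in groups:
        raise ValueError("outgroup must be one of the groups")
    for g, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {g} has no haplotypes")
    ingroup = sorted(g for g in groups if g != outgroup)
    if len(ingroup) != 3:
        raise ValueError("topology weighting needs exactly 4 groups")
    pairs = list(itertools.combinations(range(3), 2))
    labels = []
    for i, j in pairs:
        k = ({0, 1, 2} - {i, j}).pop()
        labels.append(f"((({ingroup[i]},{ingroup[j]}),{ingroup[k]}),{outgroup})")

    rng = np.random.default_rng(seed)
    per_locus = np.zeros((len(genealogies), 3))
    spans = np.array([g.span for g in genealogies], dtype=float)
    for li, gen in enumerate(genealogies):
        counts = np.zeros(3)
        for _ in range(subsamples_per_locus):
            tips = [int(rng.choice(groups[g])) for g in ingroup]
            tm = [gen.mrca_time(tips[i], tips[j]) for i, j in pairs]
            counts[int(np.argmin(tm))] += 1
        per_locus[li] = counts / subsamples_per_locus
    genome = (per_locus * spans[:, None]).sum(axis=0) / spans.sum()
    return dict(zip(labels, genome)), per_locus
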