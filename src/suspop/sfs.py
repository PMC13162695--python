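"""Site-frequency spectra with outgroup polarization and SNP ascertainment filters.

The observed multidimensional SFS is built after four site filters (intergenic,
outside CpG islands, no missing genotypes, >= 2 kb apart) and outgroup
polarization: a site's ancestral allele is the one carried by every non-missing
outgroup haplotype; sites with a polymorphic (or fully missing) outgroup are
discarded as unpolarizable.  Monomorphic corners of the spectrum are masked —
all likelihood work conditions on polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from suspop.simgen import MISSING, GenotypeMatrix


@dataclass
class SfsTensor:
    """Joint allele-count spectrum over an ordered list of populations.

    ``counts[i1, ..., ik]`` is the number of sites whose derived-allele
    (or minor-allele when folded) count is ``i_j`` in population j.  ``mask``
    marks entries excluded from likelihoods (monomorphic corners; for folded
    spectra also the major-allele half).
    """

    pop_order: list[str]
    counts: np.ndarray
    folded: bool
    mask: np.ndarray

    @property
    def dims(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        """Haploid sample size per population."""
        return tuple(d - 1 for d in self.counts.shape)

    @property
    def n_unmasked(self) -> float:
        return float(self.counts[~self.mask].sum())

    def unmasked_values(self) -> np.ndarray:
        return self.counts[~self.mask]

    def copy_with(self, counts: np.ndarray) -> "SfsTensor":
        return SfsTensor(list(self.pop_order), counts, self.folded, self.mask.copy())


def _corner_mask(dims: tuple[int, ...]) -> np.ndarray:
    mask = np.zeros(dims, dtype=bool)
    mask[(0,) * len(dims)] = True
    mask[tuple(d - 1 for d in dims)] = True
    return mask


def _folded_mask(dims: tuple[int, ...]) -> np.ndarray:
    """Mask corners plus every entry in the major-allele half of the tensor."""
    mask = _corner_mask(dims)
    n_tot = sum(d - 1 for d in dims)
    grid = np.indices(dims).reshape(len(dims), -1).sum(axis=0).reshape(dims)
    mask |= grid > n_tot / 2
    # exact-half entries: keep only the lexicographically smaller of each
    # complement pair so each class appears once
    half = np.argwhere(grid * 2 == n_tot)
    for e in half:
        comp = np.array(dims) - 1 - e
        if tuple(e) > tuple(comp):
            mask[tuple(e)] = True
    return mask


# ---------------------------------------------------------------------------
# polarization and filtering
# ---------------------------------------------------------------------------

def polarize(matrix: GenotypeMatrix, outgroup: str) -> GenotypeMatrix:
    """Polarize by the outgroup: its monomorphic allele becomes ancestral (0).

    Sites with a polymorphic or entirely missing outgroup are dropped;
    survivors get ``ancestral_known = True``.
    """
    og = matrix.haps_for(outgroup)
    sub = matrix.alleles[og]
    called = sub != MISSING
    any_called = called.any(axis=0)
    has0 = ((sub == 0) & called).any(axis=0)
    has1 = ((sub == 1) & called).any(axis=0)
    keep = any_called & ~(has0 & has1)
    out = matrix.take_sites(np.flatnonzero(keep))
    flip = has1[keep]  # outgroup fixed for allele 1 -> relabel so ancestral = 0
    alleles = out.alleles.copy()
    cols = np.flatnonzero(flip)
    block = alleles[:, cols]
    alleles[:, cols] = np.where(block == MISSING, MISSING, 1 - block)
    out.alleles = alleles
    out.ancestral_known = np.ones(out.n_sites, dtype=bool)
    return out


def filter_sites(matrix: GenotypeMatrix, min_spacing_bp: int = 2000) -> GenotypeMatrix:
    """Apply the four SNP ascertainment rules.

    Intergenic, non-CpG, fully genotyped sites, thinned greedily left-to-right
    so consecutive kept sites are >= ``min_spacing_bp`` apart per chromosome.
    """
    passing = (
        (matrix.site_class == "intergenic")
        & ~matrix.cpg_flag
        & ~(matrix.alleles == MISSING).any(axis=0)
    )
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for c in np.unique(matrix.chrom):
        idx = np.flatnonzero((matrix.chrom == c) & passing)
        last = -np.inf
        for j in idx:
            if matrix.positions[j] - last >= min_spacing_bp:
                keep[j] = True
                last = matrix.positions[j]
    return matrix.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _per_pop_counts(matrix: GenotypeMatrix, pops: list[str]) -> np.ndarray:
    """(n_sites, n_pops) allele-1 counts; raises on missing genotypes."""
    cols = []
    for p in pops:
        sub = matrix.alleles[matrix.haps_for(p)]
        if (sub == MISSING).any():
            raise ValueError(f"missing genotypes in population {p}; filter first")
        cols.append((sub == 1).sum(axis=0))
    return np.stack(cols, axis=1) if cols else np.zeros((matrix.n_sites, 0), int)


def build_sfs(matrix: GenotypeMatrix, pops: list[str], folded: bool = False) -> SfsTensor:
    """Joint SFS over ``pops``; unfolded mode requires polarized sites."""
    if not folded and not matrix.ancestral_known.all():
        raise ValueError("unfolded SFS requires ancestral_known on every site")
    counts_per_site = _per_pop_counts(matrix, pops)
    sizes = [matrix.haps_for(p).size for p in pops]
    dims = tuple(n + 1 for n in sizes)
    counts = np.zeros(dims, dtype=float)
    if folded:
        n_tot = sum(sizes)
        tot = counts_per_site.sum(axis=1)
        comp = np.asarray(sizes)[None, :] - counts_per_site
        use_comp = (tot * 2 > n_tot) | (
            (tot * 2 == n_tot)
            & np.array([tuple(a) > tuple(b) for a, b in zip(counts_per_site, comp)])
        )
        counts_per_site = np.where(use_comp[:, None], comp, counts_per_site)
    np.add.at(counts, tuple(counts_per_site.T), 1.0)
    mask = _folded_mask(dims) if folded else _corner_mask(dims)
    return SfsTensor(list(pops), counts, folded, mask)


def fold_sfs(sfs: SfsTensor) -> SfsTensor:
    """Fold a derived-allele spectrum onto minor-allele classes.

    Each entry is summed with its complement; complement pairs are assigned to
    the minor-total member (lexicographically smaller one on exact ties), so
    the total site count is conserved.
    """
    if sfs.folded:
        return sfs.copy_with(sfs.counts.copy())
    dims = sfs.dims
    folded = np.zeros(dims, dtype=float)
    mask = _folded_mask(dims)
    rev = sfs.counts[tuple(slice(None, None, -1) for _ in dims)]
    summed = sfs.counts + rev
    n_tot = sum(d - 1 for d in dims)
    grid = np.indices(dims).reshape(len(dims), -1).sum(axis=0).reshape(dims)
    folded[grid * 2 < n_tot] = summed[grid * 2 < n_tot]
    # exact-half classes: entry and complement are distinct cells unless
    # self-complementary; the kept cell receives the pair total once
    half = np.argwhere((grid * 2 == n_tot) & ~mask)
    for e in half:
        comp = tuple(np.array(dims) - 1 - e)
        e = tuple(e)
        folded[e] = sfs.counts[e] + (sfs.counts[comp] if comp != e else 0.0)
    return SfsTensor(list(sfs.pop_order), folded, True, mask)


def _projection_matrix(n: int, m: int) -> np.ndarray:
    """Hypergeometric expectation: P[i, j] = C(i,j) C(n-i, m-j) / C(n,m)."""
    i = np.arange(n + 1)[:, None]
    j = np.arange(m + 1)[None, :]

    def logc(a, b):
        with np.errstate(invalid="ignore"):
            out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
        return out

    logp = logc(i, j) + logc(n - i, m - j) - logc(n, m)
    valid = (j <= i) & (m - j <= n - i) & (j >= 0)
    return np.where(valid, np.exp(logp), 0.0)


def project_sfs(sfs: SfsTensor, new_sizes: list[int]) -> SfsTensor:
    """Project to smaller haploid sample sizes (expected hypergeometric SFS)."""
    if sfs.folded:
        raise ValueError("project unfolded spectra, then fold")
    old = sfs.sample_sizes
    if len(new_sizes) != len(old):
        raise ValueError("one target size per population required")
    if any(m > n for m, n in zip(new_sizes, old)):
        raise ValueError("projection size exceeds sample size")
    counts = sfs.counts
    for axis, (n, m) in enumerate(zip(old, new_sizes)):
        if m == n:
            continue
        proj = _projection_matrix(n, m)
        counts = np.moveaxis(
            np.tensordot(np.moveaxis(counts, axis, -1), proj, axes=([-1], [0])),
            -1, axis,
        )
    dims = tuple(m + 1 for m in new_sizes)
    return SfsTensor(list(sfs.pop_order), counts, False, _corner_mask(dims))


# ---------------------------------------------------------------------------
# flat text serialization (dadi/fastsimcoal style)
# ---------------------------------------------------------------------------

def write_sfs(sfs: SfsTensor, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            " ".join(str(d) for d in sfs.dims)
            + (" folded " if sfs.folded else " unfolded ")
            + " ".join(sfs.pop_order)
            + "\n"
        )
        fh.write(" ".join(f"{x:.10g}" for x in sfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in sfs.mask.ravel()) + "\n")


def read_sfs(path: str) -> SfsTensor:
    with open(path) as fh:
        header = fh.readline().split()
        split_at = header.index("folded") if "folded" in header else header.index("unfolded")
        dims = tuple(int(x) for x in header[:split_at])
        folded = header[split_at] == "folded"
        pops = header[split_at + 1:]
        counts = np.array([float(x) for x in fh.readline().split()]).reshape(dims)
        mask = np.array([x == "1" for x in fh.readline().split()]).reshape(dims)
    return SfsTensor(pops, counts, folded, mask)
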