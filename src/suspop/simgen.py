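"""Seeded coalescent data generator and VCF round-trip I/O.

Genotype data (and the true genealogies underneath) are produced with msprime
under user-specified demographies built from splits, admixture pulses and
population-size changes.  Loci are independent non-recombining blocks laid out
end-to-end on a single synthetic chromosome, so linkage exists at block scale
and sites in different blocks are unlinked — exactly what SFS-based fitting
and window statistics need.

Two output modes:

* ``sequence`` — every infinite-sites mutation on every block is emitted;
  used for window statistics (f_d, Fst, pi, XP-EHH) and topology weighting.
* ``snp`` — exactly one segregating site per retained block (blocks with no
  mutation are resampled), mirroring per-SNP coalescent simulation for SFS
  work where sites must be unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import msprime
import numpy as np

MISSING = -1

#: per-site per-generation mutation rate used throughout (pig resequencing scale)
DEFAULT_MU = 3.6e-9
#: years per generation, reporting only
DEFAULT_GEN_TIME = 3.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """A demographic event, time in generations before present.

    kind:
      * ``split`` — (backward in time) all lineages of ``derived`` move to
        ``ancestral``; forward in time, ``derived`` was founded from
        ``ancestral`` at that moment.
      * ``admixture_pulse`` — fraction ``alpha`` of ``recipient`` lineages is
        reassigned to ``donor`` (backward-time convention).
      * ``size_change`` — ``population`` takes new diploid size ``size`` from
        that time rootward.
    """

    time: float
    kind: str
    derived: str | None = None
    ancestral: str | None = None
    recipient: str | None = None
    donor: str | None = None
    alpha: float | None = None
    population: str | None = None
    size: float | None = None

    def __post_init__(self):
        if self.kind not in ("split", "admixture_pulse", "size_change"):
            raise ValueError(f"unknown event kind: {self.kind}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind == "admixture_pulse":
            if self.alpha is None or not (0.0 <= self.alpha <= 1.0):
                raise ValueError("admixture fraction alpha must be in [0, 1]")
        if self.kind == "size_change" and (self.size is None or self.size <= 0):
            raise ValueError("size_change requires a positive size")


@dataclass
class DemographicModel:
    """Populations plus a time-ordered event list.

    ``populations`` maps name -> present-day diploid effective size Ne.
    Following every split rootward must leave exactly one ancestral
    population.
    """

    populations: dict[str, float]
    events: list[Event]
    mu: float = DEFAULT_MU
    gen_time: float = DEFAULT_GEN_TIME

    def validate(self) -> None:
        for name, ne in self.populations.items():
            if ne <= 0:
                raise ValueError(f"population {name} has non-positive Ne")
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("events must be in non-decreasing time order")
        active = set(self.populations)
        for ev in self.events:
            for attr in ("derived", "ancestral", "recipient", "donor", "population"):
                name = getattr(ev, attr)
                if name is not None and name not in self.populations:
                    raise ValueError(f"event references unknown population {name}")
            if ev.kind == "split":
                if ev.derived not in active:
                    raise ValueError(f"split of inactive population {ev.derived}")
                if ev.ancestral not in active:
                    raise ValueError(f"split into inactive population {ev.ancestral}")
                active.remove(ev.derived)
        if len(active) != 1:
            raise ValueError(
                f"model must coalesce into exactly one ancestral population, got {sorted(active)}"
            )

    def to_msprime(self) -> msprime.Demography:
        self.validate()
        dem = msprime.Demography()
        for name, ne in self.populations.items():
            dem.add_population(name=name, initial_size=ne)
        for ev in self.events:
            if ev.kind == "split":
                dem.add_mass_migration(
                    time=ev.time, source=ev.derived, dest=ev.ancestral, proportion=1.0
                )
            elif ev.kind == "admixture_pulse":
                dem.add_mass_migration(
                    time=ev.time, source=ev.recipient, dest=ev.donor, proportion=ev.alpha
                )
            else:
                dem.add_population_parameters_change(
                    time=ev.time, population=ev.population, initial_size=ev.size
                )
        dem.sort_events()
        return dem


@dataclass
class Genealogy:
    """Rooted binary tree over haplotypes for one non-recombining locus.

    ``parent[u]`` is the parent node of node ``u`` (-1 at the root);
    ``time[u]`` its age in generations; leaves ``0..n_samples-1`` map to the
    haplotype rows of the matrix the locus came from (offset by
    ``hap_offset`` if subset).  ``interval`` is the half-open bp span.
    """

    chrom: str
    interval: tuple[int, int]
    parent: np.ndarray
    time: np.ndarray
    n_samples: int

    @property
    def span(self) -> int:
        return self.interval[1] - self.interval[0]

    def mrca_time(self, u: int, v: int) -> float:
        """Age of the most recent common ancestor of leaves u and v."""
        anc_u = set()
        while u != -1:
            anc_u.add(u)
            u = self.parent[u]
        while v not in anc_u:
            v = self.parent[v]
        return float(self.time[v])


@dataclass
class GenotypeMatrix:
    """Haplotype x site binary matrix with positions and per-site annotations.

    ``alleles`` holds {0, 1, MISSING}; where ``ancestral_known`` is set the
    site is polarized so 1 = derived.  Two consecutive haplotype rows per
    diploid sample.  Positions are 0-based and strictly increasing within a
    chromosome.
    """

    sample_ids: list[str]
    populations: list[str]
    chrom: np.ndarray          # per-site chromosome label
    positions: np.ndarray      # per-site, int64
    alleles: np.ndarray        # (n_haps, n_sites) int8
    ancestral_known: np.ndarray
    site_class: np.ndarray     # 'intergenic' | 'genic'
    cpg_flag: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def hap_populations(self) -> np.ndarray:
        return np.repeat(np.asarray(self.populations, dtype=object), 2)

    def haps_for(self, pop: str) -> np.ndarray:
        """Row indices of the haplotypes belonging to one population."""
        idx = np.flatnonzero(self.hap_populations == pop)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} not present")
        return idx

    def derived_freq(self, pop: str) -> np.ndarray:
        """Per-site derived (allele-1) frequency among non-missing haplotypes.

        Sites where every haplotype of ``pop`` is missing get NaN.
        """
        sub = self.alleles[self.haps_for(pop)]
        called = sub != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, (sub == 1).sum(axis=0) / np.maximum(n, 1), np.nan)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            populations=self.populations,
            chrom=self.chrom[idx],
            positions=self.positions[idx],
            alleles=self.alleles[:, idx],
            ancestral_known=self.ancestral_known[idx],
            site_class=self.site_class[idx],
            cpg_flag=self.cpg_flag[idx],
        )

    def validate(self) -> None:
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("one population label per sample required")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected two haplotype rows per diploid sample")
        for c in np.unique(self.chrom):
            pos = self.positions[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        ok = np.isin(self.alleles, (0, 1, MISSING))
        if not ok.all():
            raise ValueError("allele values must be 0, 1 or missing")


class Fixture(NamedTuple):
    matrix: GenotypeMatrix
    genealogies: list[Genealogy]
    model: DemographicModel
    metadata: dict


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _int_positions(raw: np.ndarray, length: int) -> np.ndarray:
    """Floor continuous infinite-sites positions to distinct ints in [0, length)."""
    pos = np.floor(raw).astype(np.int64)
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    if len(pos) and pos[-1] >= length:          # extremely dense locus: push back
        pos[-1] = length - 1
        for i in range(len(pos) - 2, -1, -1):
            if pos[i] >= pos[i + 1]:
                pos[i] = pos[i + 1] - 1
    return pos


def _tree_mutations(ts, rate: float, length: int, rng: np.random.Generator,
                    one_site: bool = False):
    """Drop infinite-sites mutations on a single-tree sequence.

    Each branch receives Poisson(rate * length * branch_length) mutations;
    every mutation makes one biallelic site (0 ancestral, 1 derived) at a
    uniform continuous position.  With ``one_site`` a single mutation is
    placed, branch chosen proportionally to length (None if the tree carries
    no mutation at all, so the caller can resample the locus).

    Returns (positions ascending, genotypes (n_sites, n_haps) int8) or None.
    """
    tables = ts.tables
    child = tables.edges.child
    parent = tables.edges.parent
    times = tables.nodes.time
    bl = times[parent] - times[child]
    total = bl.sum()
    n_mut = rng.poisson(rate * length * total)
    if n_mut == 0:
        return None
    if one_site:
        n_mut = 1
    p = bl / total
    edges = rng.choice(len(child), size=n_mut, p=p)
    pos = np.sort(rng.random(n_mut)) * length
    # sample-membership masks, children before parents
    n = ts.num_samples
    mask = np.zeros((ts.num_nodes, n), dtype=bool)
    mask[np.arange(n), np.arange(n)] = True
    for e in np.argsort(times[child], kind="stable"):
        mask[parent[e]] |= mask[child[e]]
    geno = mask[child[edges]].astype(np.int8)
    return pos, geno


def _genealogy_from_ts(ts, chrom: str, interval: tuple[int, int]) -> Genealogy:
    tree = ts.first()
    return Genealogy(
        chrom=chrom,
        interval=interval,
        parent=tree.parent_array[: ts.num_nodes].copy(),
        time=ts.tables.nodes.time.copy(),
        n_samples=ts.num_samples,
    )


def _assemble(sample_ids, populations, chrom_labels, positions, allele_blocks,
              model) -> GenotypeMatrix:
    if allele_blocks:
        alleles = np.concatenate(allele_blocks, axis=1).astype(np.int8)
        positions = np.concatenate(positions)
        chrom = np.concatenate(chrom_labels)
    else:
        alleles = np.zeros((2 * len(sample_ids), 0), dtype=np.int8)
        positions = np.zeros(0, dtype=np.int64)
        chrom = np.zeros(0, dtype="U8")
    n = alleles.shape[1]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        populations=populations,
        chrom=chrom,
        positions=positions,
        alleles=alleles,
        ancestral_known=np.ones(n, dtype=bool),
        site_class=np.full(n, "intergenic", dtype="U10"),
        cpg_flag=np.zeros(n, dtype=bool),
    )


def simulate(
    model: DemographicModel,
    samples_per_pop: dict[str, int],
    n_loci: int,
    locus_length: int,
    seed: int,
    mode: str = "sequence",
    chrom: str = "1",
    return_genealogies: bool = True,
) -> tuple[GenotypeMatrix, list[Genealogy]]:
    """Simulate ``n_loci`` independent blocks under ``model``.

    ``samples_per_pop`` gives diploid sample counts.  Identical seeds give
    identical output.  See module docstring for the two modes.
    """
    if mode not in ("sequence", "snp"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_loci < 1 or locus_length < 1:
        raise ValueError("n_loci and locus_length must be >= 1")
    model.validate()
    unknown = set(samples_per_pop) - set(model.populations)
    if unknown:
        raise ValueError(f"unknown population(s) in samples_per_pop: {sorted(unknown)}")
    if sum(samples_per_pop.values()) == 0:
        raise ValueError("zero lineages sampled everywhere")

    demography = model.to_msprime()
    sample_sets = [
        msprime.SampleSet(n, population=p, ploidy=2)
        for p, n in samples_per_pop.items()
        if n > 0
    ]
    sample_ids, populations = [], []
    for p, n in samples_per_pop.items():
        for j in range(n):
            sample_ids.append(f"{p}_{j}")
            populations.append(p)

    rng = np.random.default_rng(seed)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    n_haps = 2 * len(sample_ids)

    blocks, pos_blocks, chrom_blocks, genealogies = [], [], [], []

    if mode == "sequence":
        reps = msprime.sim_ancestry(
            samples=sample_sets,
            demography=demography,
            sequence_length=locus_length,
            ploidy=2,
            num_replicates=n_loci,
            random_seed=anc_seed,
        )
        for i, ts in enumerate(reps):
            offset = i * locus_length
            hit = _tree_mutations(ts, model.mu, locus_length, rng)
            if hit is not None:
                raw_pos, geno = hit
                pos = _int_positions(raw_pos, locus_length)
                blocks.append(geno.T)
                pos_blocks.append(pos + offset)
                chrom_blocks.append(np.full(len(pos), chrom, dtype="U8"))
            if return_genealogies:
                genealogies.append(
                    _genealogy_from_ts(ts, chrom, (offset, offset + locus_length))
                )
    else:  # snp mode: one segregating site per retained locus, empties resampled
        collected = 0
        locus_idx = 0
        while collected < n_loci:
            batch = min(max(n_loci - collected, 64), 4096)
            batch_seed = int(rng.integers(1, 2**31 - 1))
            reps = msprime.sim_ancestry(
                samples=sample_sets,
                demography=demography,
                sequence_length=locus_length,
                ploidy=2,
                num_replicates=batch,
                random_seed=batch_seed,
            )
            for ts in reps:
                if collected >= n_loci:
                    break
                hit = _tree_mutations(ts, model.mu, locus_length, rng, one_site=True)
                if hit is None:
                    continue
                raw_pos, geno = hit
                sitepos = int(min(np.floor(raw_pos[0]), locus_length - 1))
                offset = locus_idx * locus_length
                blocks.append(geno.T)
                pos_blocks.append(np.array([offset + sitepos], dtype=np.int64))
                chrom_blocks.append(np.full(1, chrom, dtype="U8"))
                if return_genealogies:
                    genealogies.append(
                        _genealogy_from_ts(ts, chrom, (offset, offset + locus_length))
                    )
                collected += 1
                locus_idx += 1

    matrix = _assemble(sample_ids, populations, chrom_blocks, pos_blocks, blocks, model)
    assert matrix.n_haps == n_haps
    return matrix, genealogies


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

#: default scaffold parameters shared by the Tibetan-pig style fixtures.
#: Sizes/times are stated desk-scale defaults (the source models give only
#: topologies): wild boar Ne 1e4, Tibetan founding bottleneck Ne 3e3,
#: NAW/SAW divergence 1e4 generations (~30 ky at 3 y/gen), Tibetan founding
#: 3e3 generations, derived-group split 1e3 generations.  The outgroup split
#: is compressed to 5e4 generations so a workable fraction of sites is
#: polymorphic in the ingroup.
SCAFFOLD = dict(
    N_CEB=5000.0,
    N_WEW=5000.0,
    N_NAW=10000.0,
    N_SAW=10000.0,
    N_TT=3000.0,
    N_X=3000.0,
    N_ANC=10000.0,
    T_CEB=50000.0,
    T_WEW=25000.0,
    T_NS=10000.0,
    T_TT=3000.0,
    T_X=1000.0,
    ALPHA_TT=0.5,
)

FIXTURE_SAMPLES = {"CEB": 2, "NAW": 5, "SAW": 5, "TT": 5}

FIXTURE_NAMES = (
    [f"tt_model{i}" for i in range(1, 6)]
    + [f"x_model{i}" for i in range(1, 6)]
    + ["no_geneflow_quartet", "introgressed_tract", "hard_sweep"]
)


def _quartet_model(alpha: float = 0.0, pulse_time: float = 400.0) -> DemographicModel:
    """((P1,P2),P3),OUT quartet; optional recent P3 -> P2 pulse.

    Split times (4e3 / 1.6e4 / 4e4 generations) and Ne (7.5e3) give the
    quartet distinct species structure: incomplete lineage sorting is present
    but does not swamp a strong admixture pulse, so D-type tests are well
    powered at desk scale while staying calibrated under the null.
    """
    events = []
    if alpha > 0:
        events.append(
            Event(time=pulse_time, kind="admixture_pulse",
                  recipient="P2", donor="P3", alpha=alpha)
        )
    events += [
        Event(time=4000.0, kind="split", derived="P2", ancestral="P1"),
        Event(time=16000.0, kind="split", derived="P3", ancestral="P1"),
        Event(time=40000.0, kind="split", derived="OUT", ancestral="P1"),
    ]
    return DemographicModel(
        populations={"P1": 7500.0, "P2": 7500.0, "P3": 7500.0, "OUT": 7500.0},
        events=events,
    )


def _merge_matrices(parts: list[GenotypeMatrix]) -> GenotypeMatrix:
    order = np.argsort(np.concatenate([p.positions for p in parts]), kind="stable")
    merged = GenotypeMatrix(
        sample_ids=parts[0].sample_ids,
        populations=parts[0].populations,
        chrom=np.concatenate([p.chrom for p in parts])[order],
        positions=np.concatenate([p.positions for p in parts])[order],
        alleles=np.concatenate([p.alleles for p in parts], axis=1)[:, order],
        ancestral_known=np.concatenate([p.ancestral_known for p in parts])[order],
        site_class=np.concatenate([p.site_class for p in parts])[order],
        cpg_flag=np.concatenate([p.cpg_flag for p in parts])[order],
    )
    return merged


def make_fixture(
    name: str,
    seed: int,
    n_loci: int | None = None,
    locus_length: int | None = None,
    samples: dict[str, int] | None = None,
) -> Fixture:
    """Build one of the documented synthetic scenarios.

    Every fixture records its true generating parameters in ``metadata``.
    """
    from suspop import demomodels  # deferred: demomodels builds DemographicModels

    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}")

    if name.startswith(("tt_model", "x_model")):
        model_id = name.replace("tt_model", "TT").replace("x_model", "X")
        template = demomodels.get_template(model_id)
        vector = template.default_vector()
        model = template.build(vector)
        samples = samples or dict(FIXTURE_SAMPLES, **({"X": 5} if model_id[0] == "X" else {}))
        n_loci = n_loci or 5000
        locus_length = locus_length or 100_000
        matrix, gens = simulate(
            model, samples, n_loci, locus_length, seed, mode="snp",
            return_genealogies=False,
        )
        meta = {
            "model_id": model_id,
            "true_params": dict(zip(template.param_names, vector)),
            "scaffold": dict(SCAFFOLD),
            "samples": dict(samples),
        }
        return Fixture(matrix, gens, model, meta)

    if name == "no_geneflow_quartet":
        model = _quartet_model(alpha=0.0)
        samples = samples or {"P1": 5, "P2": 5, "P3": 5, "OUT": 2}
        n_loci = n_loci or 200
        locus_length = locus_length or 20_000
        matrix, gens = simulate(model, samples, n_loci, locus_length, seed)
        meta = {"alpha": 0.0, "topology": "((P1,P2),P3),OUT",
                "n_loci": n_loci, "locus_length": locus_length}
        return Fixture(matrix, gens, model, meta)

    if name == "introgressed_tract":
        samples = samples or {"P1": 5, "P2": 5, "P3": 5, "OUT": 2}
        n_loci = n_loci or 300
        locus_length = locus_length or 20_000
        tract_lo, tract_hi = int(n_loci * 0.4), int(n_loci * 0.4) + max(2, n_loci // 10)
        alpha = 0.6
        bg_model = _quartet_model(alpha=0.0)
        fl_model = _quartet_model(alpha=alpha, pulse_time=400.0)
        rng = np.random.default_rng(seed)
        s_bg, s_fl = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
        bg, gens_bg = simulate(bg_model, samples, n_loci, locus_length, s_bg)
        fl, gens_fl = simulate(
            fl_model, samples, tract_hi - tract_lo, locus_length, s_fl
        )
        # move the gene-flow blocks into the tract's coordinates
        shift = tract_lo * locus_length
        fl.positions = fl.positions + shift
        for g in gens_fl:
            g.interval = (g.interval[0] + shift, g.interval[1] + shift)
        keep_bg = (bg.positions < tract_lo * locus_length) | (
            bg.positions >= tract_hi * locus_length
        )
        matrix = _merge_matrices([bg.take_sites(np.flatnonzero(keep_bg)), fl])
        gens = (
            gens_bg[:tract_lo] + gens_fl + gens_bg[tract_hi:]
        )
        meta = {
            "alpha": alpha,
            "tract": (tract_lo * locus_length, tract_hi * locus_length),
            "pulse": "P3->P2 at 400 generations",
            "n_loci": n_loci,
            "locus_length": locus_length,
        }
        return Fixture(matrix, gens, fl_model, meta)

    # hard_sweep: neutral two-population background, then a focal region of the
    # target population overwritten with one core haplotype at high frequency.
    samples = samples or {"WILD": 8, "TBT": 8, "OUT": 2}
    n_loci = n_loci or 100
    locus_length = locus_length or 50_000
    model = DemographicModel(
        populations={"WILD": 10000.0, "TBT": 5000.0, "OUT": 10000.0},
        events=[
            Event(time=3000.0, kind="split", derived="TBT", ancestral="WILD"),
            Event(time=20000.0, kind="split", derived="OUT", ancestral="WILD"),
        ],
    )
    matrix, gens = simulate(model, samples, n_loci, locus_length, seed)
    core_freq = 0.95
    lo = int(n_loci * 0.4)
    region = (lo * locus_length, (lo + 4) * locus_length)
    in_region = (matrix.positions >= region[0]) & (matrix.positions < region[1])
    tbt = matrix.haps_for("TBT")
    rng = np.random.default_rng(seed + 1)
    n_carriers = int(round(core_freq * tbt.size))
    carriers = rng.choice(tbt, size=n_carriers, replace=False)
    core = matrix.alleles[tbt[0], in_region].copy()
    for h in carriers:
        matrix.alleles[h, in_region] = core
    meta = {
        "region": region,
        "core_frequency": core_freq,
        "target": "TBT",
        "reference": "WILD",
        "n_loci": n_loci,
        "locus_length": locus_length,
    }
    return Fixture(matrix, gens, model, meta)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=suspop
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=SITECLASS,Number=1,Type=String,Description="intergenic or genic">
##INFO=<ID=CPG,Number=0,Type=Flag,Description="Site inside a CpG island">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a matrix as phased VCF 4.2 (REF=A, ALT=T; 1-based positions)."""
    matrix.validate()
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in dict.fromkeys(matrix.chrom.tolist()):
            n = int(matrix.positions[matrix.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        code = {0: "0", 1: "1", MISSING: "."}
        for j in range(matrix.n_sites):
            info = [f"SITECLASS={matrix.site_class[j]}"]
            if matrix.ancestral_known[j]:
                info.insert(0, "AA=A")
            if matrix.cpg_flag[j]:
                info.append("CPG")
            gts = [
                code[int(matrix.alleles[2 * i, j])]
                + "|"
                + code[int(matrix.alleles[2 * i + 1, j])]
                for i in range(matrix.n_samples)
            ]
            fh.write(
                f"{matrix.chrom[j]}\t{matrix.positions[j] + 1}\t.\tA\tT\t.\tPASS\t"
                + ";".join(info)
                + "\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str, popmap: dict[str, str] | str) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a GenotypeMatrix.

    ``popmap`` maps sample -> group (or is a path to two-column text).  If
    INFO/AA names the ALT allele, alleles are flipped so 1 = derived.
    """
    from cyvcf2 import VCF

    if isinstance(popmap, str):
        popmap = read_popmap(popmap)

    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = set(popmap) - set(samples)
    if missing:
        raise ValueError(f"popmap samples absent from VCF: {sorted(missing)}")
    keep = [i for i, s in enumerate(samples) if s in popmap]
    sample_ids = [samples[i] for i in keep]
    populations = [popmap[s] for s in sample_ids]

    chroms, positions, rows = [], [], []
    anc_known, site_class, cpg = [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        g = np.asarray(v.genotypes, dtype=np.int16)[keep, :2].reshape(-1)
        g = np.where(g < 0, MISSING, g).astype(np.int8)
        aa = v.INFO.get("AA")
        known = aa in (v.REF, v.ALT[0])
        if aa == v.ALT[0]:  # ancestral is ALT: flip so 1 = derived
            g = np.where(g == MISSING, MISSING, 1 - g).astype(np.int8)
        chroms.append(v.CHROM)
        positions.append(v.POS - 1)
        rows.append(g)
        anc_known.append(bool(known))
        site_class.append(v.INFO.get("SITECLASS") or "intergenic")
        cpg.append(bool(v.INFO.get("CPG")))

    n = len(positions)
    alleles = (
        np.stack(rows, axis=1) if n else np.zeros((2 * len(sample_ids), 0), np.int8)
    )
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        populations=populations,
        chrom=np.asarray(chroms, dtype="U32"),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        ancestral_known=np.asarray(anc_known, dtype=bool),
        site_class=np.asarray(site_class, dtype="U10"),
        cpg_flag=np.asarray(cpg, dtype=bool),
    )
    matrix.validate()
    return matrix


def read_popmap(path: str) -> dict[str, str]:
    """Two-column whitespace text: sample group."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2 and not line.startswith("#"):
                out[parts[0]] = parts[1]
    return out


def write_popmap(matrix: GenotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        for s, p in zip(matrix.sample_ids, matrix.populations):
            fh.write(f"{s}\t{p}\n")
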