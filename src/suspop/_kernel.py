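"""Numba coalescent kernel for Monte-Carlo expected SFS.

The optimizer evaluates expected spectra thousands of times, so the inner
loop is a compiled structured coalescent: lineages carry a vector of
descendant counts per spectrum population plus an outgroup count, coalesce
within populations at rate k(k-1)/(4Ne), and are moved between populations by
split / pulse events (backward-time convention).  Each branch contributes its
length to the spectrum entry indexed by its descendant counts.

Outgroup-aware polarization is modelled exactly as the data path applies it:
a branch also subtending *all* outgroup haplotypes yields a site whose
ancestral state is misassigned, so its contribution is flipped to the
complementary entry; a branch subtending only *some* outgroup haplotypes
yields an outgroup-polymorphic site, which the polarizer drops, so it
contributes nothing.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EV_MOVE = 0   # lineages of pop a move to pop b with probability par
EV_SIZE = 1   # pop a takes new diploid size par


@njit(cache=True, fastmath=True)
def _sfs_branch_lengths(
    seed,
    n_sims,
    init_sizes,      # float64[P] diploid Ne per population
    ev_time,         # float64[E] non-decreasing
    ev_kind,         # int64[E]
    ev_a,            # int64[E]
    ev_b,            # int64[E]
    ev_par,          # float64[E]
    lin_pop0,        # int64[M] initial population per lineage
    lin_desc0,       # int64[M, A] initial descendant unit vectors (spectrum pops)
    lin_og0,         # int64[M] 1 for outgroup lineages
    strides,         # int64[A] flat-index strides of the spectrum tensor
    max_counts,      # int64[A] haploid sample size per spectrum axis
    n_og,            # total outgroup haplotypes
    out_flat,        # float64[prod(dims)] accumulator (modified in place)
):
    np.random.seed(seed)
    P = init_sizes.shape[0]
    M = lin_pop0.shape[0]
    A = strides.shape[0]
    E = ev_time.shape[0]

    pop = np.empty(M, np.int64)
    og = np.empty(M, np.int64)
    birth = np.empty(M, np.float64)
    desc = np.empty((M, A), np.int64)
    inv4n = np.empty(P, np.float64)
    k = np.empty(P, np.int64)
    members = np.empty(M, np.int64)

    for _ in range(n_sims):
        for i in range(M):
            pop[i] = lin_pop0[i]
            og[i] = lin_og0[i]
            birth[i] = 0.0
            for a in range(A):
                desc[i, a] = lin_desc0[i, a]
        for p in range(P):
            inv4n[p] = 1.0 / (4.0 * init_sizes[p])
            k[p] = 0
        for i in range(M):
            k[lin_pop0[i]] += 1
        n = M
        t = 0.0
        e = 0

        while n > 1:
            rate = 0.0
            for p in range(P):
                if k[p] > 1:
                    rate += k[p] * (k[p] - 1) * inv4n[p]

            # fastmath forbids non-finite values: branch explicitly instead of
            # comparing against inf sentinels
            if rate <= 0.0:
                if e >= E:
                    break  # unreachable for validated models
                take_event = True
            else:
                dt = np.random.exponential(1.0 / rate)
                take_event = e < E and t + dt >= ev_time[e]

            if take_event:
                t = ev_time[e]
                if ev_kind[e] == EV_MOVE:
                    src = ev_a[e]
                    dst = ev_b[e]
                    prob = ev_par[e]
                    for i in range(n):
                        if pop[i] == src and (prob >= 1.0 or np.random.random() < prob):
                            pop[i] = dst
                            k[src] -= 1
                            k[dst] += 1
                else:
                    inv4n[ev_a[e]] = 1.0 / (4.0 * ev_par[e])
                e += 1
                continue

            t += dt
            # pick the population in which the coalescence happens
            u = np.random.random() * rate
            chosen = -1
            acc = 0.0
            for p in range(P):
                if k[p] > 1:
                    chosen = p  # fallback: last coalescible pop (fp rounding)
                    acc += k[p] * (k[p] - 1) * inv4n[p]
                    if u < acc:
                        break
            # pick two distinct lineages of that population
            kp = 0
            for i in range(n):
                if pop[i] == chosen:
                    members[kp] = i
                    kp += 1
            ia = np.random.randint(kp)
            ib = np.random.randint(kp - 1)
            if ib >= ia:
                ib += 1
            i = members[ia]
            j = members[ib]

            # record both ending branches
            for child in (i, j):
                w = t - birth[child]
                o = og[child]
                if o == 0:
                    idx = 0
                    for a in range(A):
                        idx += desc[child, a] * strides[a]
                    out_flat[idx] += w
                elif o == n_og:
                    idx = 0
                    for a in range(A):
                        idx += (max_counts[a] - desc[child, a]) * strides[a]
                    out_flat[idx] += w
                # 0 < o < n_og: outgroup-polymorphic site class, dropped

            # merge j into i, swap-remove j
            og[i] += og[j]
            for a in range(A):
                desc[i, a] += desc[j, a]
            birth[i] = t
            k[chosen] -= 1
            last = n - 1
            if j != last:
                pop[j] = pop[last]
                og[j] = og[last]
                birth[j] = birth[last]
                for a in range(A):
                    desc[j, a] = desc[last, a]
            n -= 1


def encode_model(model, sample_sizes: dict[str, int], sfs_pops: list[str],
                 outgroup: str | None):
    """Flatten a DemographicModel and sampling layout into kernel arrays.

    ``sample_sizes`` maps population -> haploid count (spectrum pops plus,
    optionally, the outgroup).
    """
    # prune populations no sampled lineage can ever reach: they only slow the
    # kernel down (their events are no-ops for the sampled genealogy)
    reachable = {p for p, n in sample_sizes.items() if n > 0}
    for ev in sorted(model.events, key=lambda e: e.time):
        if ev.kind == "split" and ev.derived in reachable:
            reachable.add(ev.ancestral)
        elif ev.kind == "admixture_pulse" and ev.recipient in reachable:
            reachable.add(ev.donor)
    pop_names = [p for p in model.populations if p in reachable]
    idx = {name: i for i, name in enumerate(pop_names)}
    init_sizes = np.array([model.populations[n] for n in pop_names], dtype=np.float64)

    def touches(ev):
        names = [ev.derived, ev.ancestral, ev.recipient, ev.donor, ev.population]
        return all(n is None or n in reachable for n in names)

    events = sorted((ev for ev in model.events if touches(ev)), key=lambda ev: ev.time)
    ev_time = np.array([ev.time for ev in events], dtype=np.float64)
    ev_kind = np.empty(len(events), dtype=np.int64)
    ev_a = np.zeros(len(events), dtype=np.int64)
    ev_b = np.zeros(len(events), dtype=np.int64)
    ev_par = np.zeros(len(events), dtype=np.float64)
    for i, ev in enumerate(events):
        if ev.kind == "split":
            ev_kind[i], ev_a[i], ev_b[i], ev_par[i] = EV_MOVE, idx[ev.derived], idx[ev.ancestral], 1.0
        elif ev.kind == "admixture_pulse":
            ev_kind[i], ev_a[i], ev_b[i], ev_par[i] = EV_MOVE, idx[ev.recipient], idx[ev.donor], ev.alpha
        else:
            ev_kind[i], ev_a[i], ev_par[i] = EV_SIZE, idx[ev.population], ev.size

    A = len(sfs_pops)
    lin_pop, lin_og, lin_desc = [], [], []
    for p, nh in sample_sizes.items():
        for _ in range(int(nh)):
            lin_pop.append(idx[p])
            unit = np.zeros(A, dtype=np.int64)
            if p in sfs_pops:
                unit[sfs_pops.index(p)] = 1
                lin_og.append(0)
            elif outgroup is not None and p == outgroup:
                lin_og.append(1)
            else:
                lin_og.append(0)
            lin_desc.append(unit)
    lin_pop = np.asarray(lin_pop, dtype=np.int64)
    lin_og = np.asarray(lin_og, dtype=np.int64)
    lin_desc = np.asarray(lin_desc, dtype=np.int64)

    max_counts = np.array([int(sample_sizes[p]) for p in sfs_pops], dtype=np.int64)
    dims = tuple(int(m) + 1 for m in max_counts)
    strides = np.ones(A, dtype=np.int64)
    for a in range(A - 2, -1, -1):
        strides[a] = strides[a + 1] * dims[a + 1]
    n_og = int(sample_sizes.get(outgroup, 0)) if outgroup else 0

    return dict(
        init_sizes=init_sizes,
        ev_time=ev_time, ev_kind=ev_kind, ev_a=ev_a, ev_b=ev_b, ev_par=ev_par,
        lin_pop0=lin_pop, lin_desc0=lin_desc, lin_og0=lin_og,
        strides=strides, max_counts=max_counts, dims=dims, n_og=n_og,
    )


def branch_length_sfs(model, sample_sizes, sfs_pops, outgroup, n_sims, seed) -> np.ndarray:
    """Total branch length per spectrum entry over n_sims genealogies."""
    enc = encode_model(model, sample_sizes, sfs_pops, outgroup)
    out = np.zeros(int(np.prod(enc["dims"])), dtype=np.float64)
    _sfs_branch_lengths(
        int(seed) % (2**31 - 1) or 1,
        int(n_sims),
        enc["init_sizes"],
        enc["ev_time"], enc["ev_kind"], enc["ev_a"], enc["ev_b"], enc["ev_par"],
        enc["lin_pop0"], enc["lin_desc0"], enc["lin_og0"],
        enc["strides"], enc["max_counts"], enc["n_og"],
        out,
    )
    return out.reshape(enc["dims"])
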