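"""Numba kernels for the multi-deme Kingman coalescent.

Time is measured in units of 2*N0 generations (N0 a reference size); a deme
of relative size N coalesces each lineage pair at rate 1/N.  Backwards-time
migration moves single lineages between demes at the configured per-lineage
rates.  Scheduled demographic events (deme merges, migration-rate changes,
size changes) are applied deterministically at their times.

A simulated genealogy is returned as parent pointers plus node times; nodes
are indexed in coalescence order, so a parent always has a larger index
than its children, which lets descendant counts be accumulated in a single
forward pass.
"""

import numpy as np
from numba import njit

# event type codes
EV_MERGE = 0       # move all lineages from deme a into deme b; zero a's migration
EV_SET_MIG = 1     # set migration rate a -> b to val
EV_SET_SIZE = 2    # set size of deme a to val

_MOD = 2147483647  # 2**31 - 1, keeps derived seeds in int32 range


@njit(cache=False)
def _simulate_tree(lin_deme0, n_demes, sizes0, mig0,
                   ev_time, ev_type, ev_a, ev_b, ev_val, seed):
    """One genealogy. Returns (parent, node_time, ok_flag)."""
    np.random.seed(seed)
    n = lin_deme0.shape[0]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int64)
    node_time = np.zeros(n_nodes)
    act_node = np.empty(n, np.int64)
    act_deme = np.empty(n, np.int64)
    for i in range(n):
        act_node[i] = i
        act_deme[i] = lin_deme0[i]
    n_act = n
    sizes = sizes0.copy()
    mig = mig0.copy()
    k = np.zeros(n_demes, np.int64)
    for i in range(n):
        k[lin_deme0[i]] += 1
    t = 0.0
    next_node = n
    iev = 0
    n_ev = ev_time.shape[0]
    while n_act > 1:
        coal_rate = 0.0
        for d in range(n_demes):
            if k[d] > 1:
                coal_rate += k[d] * (k[d] - 1) * 0.5 / sizes[d]
        mig_rate = 0.0
        for d in range(n_demes):
            if k[d] > 0:
                out = 0.0
                for e in range(n_demes):
                    out += mig[d, e]
                mig_rate += k[d] * out
        total = coal_rate + mig_rate
        if total > 0.0:
            t_next = t + np.random.exponential(1.0 / total)
        else:
            t_next = np.inf
        if iev < n_ev and ev_time[iev] <= t_next:
            t = ev_time[iev]
            typ = ev_type[iev]
            a = ev_a[iev]
            b = ev_b[iev]
            if typ == EV_MERGE:
                for i in range(n_act):
                    if act_deme[i] == a:
                        act_deme[i] = b
                k[b] += k[a]
                k[a] = 0
                for e in range(n_demes):
                    mig[a, e] = 0.0
                    mig[e, a] = 0.0
            elif typ == EV_SET_MIG:
                mig[a, b] = ev_val[iev]
            else:
                sizes[a] = ev_val[iev]
            iev += 1
            continue
        if total <= 0.0:
            return parent, node_time, False  # lineages stranded: invalid scenario
        t = t_next
        u = np.random.random() * total
        if u < coal_rate:
            acc = 0.0
            d = -1
            for dd in range(n_demes):
                if k[dd] > 1:
                    acc += k[dd] * (k[dd] - 1) * 0.5 / sizes[dd]
                    if u < acc:
                        d = dd
                        break
            if d < 0:
                d = n_demes - 1
            i1 = np.random.randint(k[d])
            i2 = np.random.randint(k[d] - 1)
            if i2 >= i1:
                i2 += 1
            c = -1
            a1 = -1
            a2 = -1
            for i in range(n_act):
                if act_deme[i] == d:
                    c += 1
                    if c == i1:
                        a1 = i
                    if c == i2:
                        a2 = i
            node_time[next_node] = t
            parent[act_node[a1]] = next_node
            parent[act_node[a2]] = next_node
            act_node[a1] = next_node
            act_node[a2] = act_node[n_act - 1]
            act_deme[a2] = act_deme[n_act - 1]
            n_act -= 1
            k[d] -= 1
            next_node += 1
        else:
            u -= coal_rate
            acc = 0.0
            src = -1
            dst = -1
            done = False
            for d in range(n_demes):
                if k[d] > 0:
                    for e in range(n_demes):
                        r = k[d] * mig[d, e]
                        if r > 0.0:
                            acc += r
                            if u < acc:
                                src = d
                                dst = e
                                done = True
                                break
                    if done:
                        break
            if not done:
                continue
            i1 = np.random.randint(k[src])
            c = -1
            for i in range(n_act):
                if act_deme[i] == src:
                    c += 1
                    if c == i1:
                        act_deme[i] = dst
                        break
            k[src] -= 1
            k[dst] += 1
    return parent, node_time, True


@njit(cache=False)
def _branch_pop_counts(parent, pop_of_leaf, n_leaves, n_pops):
    """Per-node counts of descendant sampled lineages in each population."""
    n_nodes = parent.shape[0]
    counts = np.zeros((n_nodes, n_pops), np.int64)
    for i in range(n_leaves):
        counts[i, pop_of_leaf[i]] = 1
    for v in range(n_nodes - 1):
        p = parent[v]
        for j in range(n_pops):
            counts[p, j] += counts[v, j]
    return counts


@njit(cache=False)
def _expected_afs_mc(lin_deme, pop_of_leaf, n_demes, n_pops, sizes, mig,
                     ev_time, ev_type, ev_a, ev_b, ev_val,
                     strides, n_reps, seed0, afs_flat):
    """Accumulate branch-length mass per joint derived-count cell."""
    n = lin_deme.shape[0]
    ok_all = True
    for r in range(n_reps):
        seed = (seed0 + 1000003 * (r + 1)) % _MOD
        parent, node_time, ok = _simulate_tree(
            lin_deme, n_demes, sizes, mig,
            ev_time, ev_type, ev_a, ev_b, ev_val, seed)
        if not ok:
            ok_all = False
            break
        counts = _branch_pop_counts(parent, pop_of_leaf, n, n_pops)
        n_nodes = parent.shape[0]
        for v in range(n_nodes - 1):
            blen = node_time[parent[v]] - node_time[v]
            idx = 0
            for j in range(n_pops):
                idx += counts[v, j] * strides[j]
            afs_flat[idx] += blen
    return ok_all


@njit(cache=False)
def _sample_snps_mc(lin_deme, pop_of_leaf, n_demes, n_pops, sizes, mig,
                    ev_time, ev_type, ev_a, ev_b, ev_val,
                    strides, n_snps, seed0, afs_flat):
    """One segregating SNP per genealogy, branch chosen with prob ~ length."""
    n = lin_deme.shape[0]
    ok_all = True
    for r in range(n_snps):
        seed = (seed0 + 1000003 * (r + 1)) % _MOD
        parent, node_time, ok = _simulate_tree(
            lin_deme, n_demes, sizes, mig,
            ev_time, ev_type, ev_a, ev_b, ev_val, seed)
        if not ok:
            ok_all = False
            break
        n_nodes = parent.shape[0]
        total = 0.0
        for v in range(n_nodes - 1):
            total += node_time[parent[v]] - node_time[v]
        u = np.random.random() * total
        acc = 0.0
        pick = n_nodes - 2
        for v in range(n_nodes - 1):
            acc += node_time[parent[v]] - node_time[v]
            if u < acc:
                pick = v
                break
        counts = _branch_pop_counts(parent, pop_of_leaf, n, n_pops)
        idx = 0
        for j in range(n_pops):
            idx += counts[pick, j] * strides[j]
        afs_flat[idx] += 1.0
    return ok_all


@njit(cache=False)
def _mutate_tree(parent, node_time, n_leaves, theta, conditional):
    """Drop infinite-sites mutations on a genealogy.

    Poisson(theta/2 * branch length) mutations per branch; with
    ``conditional`` exactly one mutation is placed on a branch chosen with
    probability proportional to its length.  Returns the per-leaf derived
    state matrix (n_leaves x n_mutations, int8).
    """
    n_nodes = parent.shape[0]
    n_mut = 0
    mut_nodes = np.empty(2 * n_nodes, np.int64)
    if conditional:
        total = 0.0
        for v in range(n_nodes - 1):
            total += node_time[parent[v]] - node_time[v]
        u = np.random.random() * total
        acc = 0.0
        pick = n_nodes - 2
        for v in range(n_nodes - 1):
            acc += node_time[parent[v]] - node_time[v]
            if u < acc:
                pick = v
                break
        mut_nodes[0] = pick
        n_mut = 1
    else:
        for v in range(n_nodes - 1):
            blen = node_time[parent[v]] - node_time[v]
            m = np.random.poisson(0.5 * theta * blen)
            for _ in range(m):
                if n_mut >= mut_nodes.shape[0]:
                    grown = np.empty(mut_nodes.shape[0] * 2, np.int64)
                    grown[: n_mut] = mut_nodes[: n_mut]
                    mut_nodes = grown
                mut_nodes[n_mut] = v
                n_mut += 1
    out = np.zeros((n_leaves, n_mut), np.int8)
    if n_mut == 0:
        return out
    # leaf -> root walks, flagging mutated ancestors
    first = np.full(n_nodes, -1, np.int64)
    nxt = np.full(n_mut, -1, np.int64)
    for j in range(n_mut):
        v = mut_nodes[j]
        nxt[j] = first[v]
        first[v] = j
    for i in range(n_leaves):
        v = i
        while v >= 0:
            j = first[v]
            while j >= 0:
                out[i, j] = 1
                j = nxt[j]
            v = parent[v]
    return out


@njit(cache=False)
def _seed_rng(seed):
    np.random.seed(seed)
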