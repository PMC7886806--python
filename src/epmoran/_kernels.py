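"""Compiled full-sample kernels for both frameworks.

These mirror the pure-Python reference engines in framework1/framework2
exactly (same update rules, same cycle structure); only the random streams
differ.  All randomness inside a kernel comes from numba's global NumPy
RNG, seeded at kernel entry, so a sample is fully reproducible from its
seed.  Outcome codes: 0 = fixation of A, 1 = fixation of B, 2 = undefined.
"""

import numpy as np
from numba import njit

SEED_MOD = 2**31 - 1


@njit(cache=True)
def _weighted_neighbor_f1(indptr, indices, ntype, ep, base, alpha, d):
    total = 0.0
    for k in range(indptr[d], indptr[d + 1]):
        j = indices[k]
        f = base[ntype[j]]
        if ep[j] > 0:
            f += alpha[ntype[j]]
        total += f
    u = np.random.random() * total
    acc = 0.0
    parent = indices[indptr[d + 1] - 1]
    for k in range(indptr[d], indptr[d + 1]):
        j = indices[k]
        f = base[ntype[j]]
        if ep[j] > 0:
            f += alpha[ntype[j]]
        acc += f
        if u < acc:
            parent = j
            break
    return parent


@njit(cache=True)
def _reassign_ep(indptr, indices, ntype, ep, eligible_state, bstate, reuse_ok, d, n):
    """Move the dying node d's EP to an eligible recipient, or destroy it.

    Priority: uniform among eligible neighbors, else uniform among eligible
    nodes anywhere in the graph, else the token vanishes.  Eligibility:
    reuse-capable type, no EP attached, and (when eligible_state >= 0, the
    framework-2 case) currently in that behavioral state.  Returns the
    recipient id or -1.  The timer is carried over unchanged.
    """
    t_left = ep[d]
    ep[d] = 0
    cnt = 0
    for k in range(indptr[d], indptr[d + 1]):
        j = indices[k]
        if reuse_ok[ntype[j]] and ep[j] == 0 and (eligible_state < 0 or bstate[j] == eligible_state):
            cnt += 1
    if cnt > 0:
        pick = np.random.randint(0, cnt)
        c = 0
        for k in range(indptr[d], indptr[d + 1]):
            j = indices[k]
            if reuse_ok[ntype[j]] and ep[j] == 0 and (eligible_state < 0 or bstate[j] == eligible_state):
                if c == pick:
                    ep[j] = t_left
                    return j
                c += 1
    cnt = 0
    for j in range(n):
        if j != d and reuse_ok[ntype[j]] and ep[j] == 0 and (eligible_state < 0 or bstate[j] == eligible_state):
            cnt += 1
    if cnt > 0:
        pick = np.random.randint(0, cnt)
        c = 0
        for j in range(n):
            if j != d and reuse_ok[ntype[j]] and ep[j] == 0 and (eligible_state < 0 or bstate[j] == eligible_state):
                if c == pick:
                    ep[j] = t_left
                    return j
                c += 1
    return -1


@njit(cache=True)
def run_sample_f1(
    indptr,
    indices,
    ntype,
    ep,
    base,
    alpha,
    birth_chance,
    reuse_ok,
    events_per_cycle,
    ep_lifetime,
    cycle_limit,
    seed,
    uniform_parent,
):
    """Run one framework-1 sample to fixation or the cycle limit.

    Mutates ntype/ep in place; returns
    (outcome_code, cycles, count_a, ep_total, ep_total_a).
    """
    np.random.seed(seed % SEED_MOD)
    n = ntype.shape[0]
    dummy_bstate = np.zeros(0, dtype=np.int8)
    count_a = 0
    for i in range(n):
        if ntype[i] == 0:
            count_a += 1
    cycle = 0
    while 0 < count_a < n and cycle < cycle_limit:
        for _ in range(events_per_cycle):
            d = np.random.randint(0, n)
            if uniform_parent:
                parent = indices[np.random.randint(indptr[d], indptr[d + 1])]
            else:
                parent = _weighted_neighbor_f1(indptr, indices, ntype, ep, base, alpha, d)
            new_t = ntype[parent]
            if ep[d] > 0:
                _reassign_ep(indptr, indices, ntype, ep, -1, dummy_bstate, reuse_ok, d, n)
            if ntype[d] != new_t:
                if new_t == 0:
                    count_a += 1
                else:
                    count_a -= 1
                ntype[d] = new_t
            if np.random.random() < birth_chance[new_t]:
                ep[d] = ep_lifetime
        for i in range(n):
            if ep[i] > 0:
                ep[i] -= 1
        cycle += 1
    ep_total = 0
    ep_a = 0
    for i in range(n):
        if ep[i] > 0:
            ep_total += 1
            if ntype[i] == 0:
                ep_a += 1
    if count_a == n:
        code = 0
    elif count_a == 0:
        code = 1
    else:
        code = 2
    return code, cycle, count_a, ep_total, ep_a


@njit(cache=True)
def run_sample_f2(
    indptr,
    indices,
    ntype,
    bstate,
    ep,
    residence,
    base,
    alpha,
    beta,
    gamma,
    produce_ok,
    reuse_ok,
    events_per_cycle,
    ep_lifetime,
    state_time,
    cycle_limit,
    seed,
    uniform_parent,
):
    """Run one framework-2 sample (four behavioral states, timed transitions).

    Mutates the state arrays in place; returns
    (outcome_code, cycles, count_a, ep_total, ep_total_a,
     n_searching, n_producing, n_using_own, n_using_other).
    """
    np.random.seed(seed % SEED_MOD)
    n = ntype.shape[0]
    count_a = 0
    for i in range(n):
        if ntype[i] == 0:
            count_a += 1
    cycle = 0
    while 0 < count_a < n and cycle < cycle_limit:
        for _ in range(events_per_cycle):
            d = np.random.randint(0, n)
            if uniform_parent:
                parent = indices[np.random.randint(indptr[d], indptr[d + 1])]
            else:
                total = 0.0
                for k in range(indptr[d], indptr[d + 1]):
                    j = indices[k]
                    t = ntype[j]
                    s = bstate[j]
                    if s == 0:
                        f = base[t]
                    elif s == 1:
                        f = base[t] - beta[t]
                    elif s == 2:
                        f = base[t] + alpha[t]
                    else:
                        f = base[t] + gamma[t]
                    total += f
                u = np.random.random() * total
                acc = 0.0
                parent = indices[indptr[d + 1] - 1]
                for k in range(indptr[d], indptr[d + 1]):
                    j = indices[k]
                    t = ntype[j]
                    s = bstate[j]
                    if s == 0:
                        f = base[t]
                    elif s == 1:
                        f = base[t] - beta[t]
                    elif s == 2:
                        f = base[t] + alpha[t]
                    else:
                        f = base[t] + gamma[t]
                    acc += f
                    if u < acc:
                        parent = j
                        break
            new_t = ntype[parent]
            if ep[d] > 0:
                r = _reassign_ep(indptr, indices, ntype, ep, 0, bstate, reuse_ok, d, n)
                if r >= 0:
                    bstate[r] = 3  # USING_OTHER
                    residence[r] = 0
            if ntype[d] != new_t:
                if new_t == 0:
                    count_a += 1
                else:
                    count_a -= 1
                ntype[d] = new_t
            bstate[d] = 0  # newborns always start searching, EP-less
            residence[d] = 0
        # end-of-cycle sweep: residence, timed transitions, EP timers/expiry
        for i in range(n):
            residence[i] += 1
            if bstate[i] == 0:
                if produce_ok[ntype[i]] and residence[i] >= state_time:
                    bstate[i] = 1
                    residence[i] = 0
            elif bstate[i] == 1:
                if residence[i] >= state_time:
                    bstate[i] = 2
                    residence[i] = 0
                    ep[i] = ep_lifetime
        for i in range(n):
            if ep[i] > 0:
                ep[i] -= 1
                if ep[i] == 0:
                    bstate[i] = 0
                    residence[i] = 0
        cycle += 1
    ep_total = 0
    ep_a = 0
    sc0 = 0
    sc1 = 0
    sc2 = 0
    sc3 = 0
    for i in range(n):
        if ep[i] > 0:
            ep_total += 1
            if ntype[i] == 0:
                ep_a += 1
        s = bstate[i]
        if s == 0:
            sc0 += 1
        elif s == 1:
            sc1 += 1
        elif s == 2:
            sc2 += 1
        else:
            sc3 += 1
    if count_a == n:
        code = 0
    elif count_a == 0:
        code = 1
    else:
        code = 2
    return code, cycle, count_a, ep_total, ep_a, sc0, sc1, sc2, sc3
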