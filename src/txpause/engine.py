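"""Event-driven compiled simulator for the gene-expression model.

This is the production path for long runs (10^5-10^6 simulated seconds):
a numba-compiled exact stochastic simulator that tracks every RNA
polymerase on the template and every ribosome on every transcript as an
agent, with the same kinetics as the object-level reaction system built
by :func:`txpause.expression_model.build_reaction_system`.  Unlike the
object path, the kernel implements co-transcriptional coupling exactly:
ribonucleotides of the nascent transcript become available as the RNAP
advances, so ribosomes ride the nascent chain and stall where the RNAP
is paused.

The delayed events (open-complex formation, protein folding) live on a
binary-heap waiting list; everything else is Markov.  Sampling follows
the package-wide convention: the sample at time g reflects the state
after all events with event-time <= g.

The RNA observable counts transcripts from promoter clearance onwards
(nascent + completed), matching single-molecule RNA detection during
elongation; the completed-only count is returned as well.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import numpy as np
from numba import njit

from .expression_model import GeneTemplate, ModelParameters

__all__ = ["simulate_expression", "SimulationResult"]

# indices into the packed constant vector
(_KTC, _OCM, _OCS, _KM, _KAR, _IAR, _KED, _IED, _KPRE, _KPYR, _KF, _KDR,
 _KTL, _KTM, _KBT, _KDROP, _KTT, _KTLF, _FOLDM, _FOLDS, _KDP) = range(21)

_HEAP_CAP = 8192
_CHAN_CAP = 8192


@njit(cache=True)
def _heap_push(ht, hk, n, t, kind):
    i = n
    ht[i] = t
    hk[i] = kind
    while i > 0:
        p = (i - 1) >> 1
        if ht[p] <= ht[i]:
            break
        ht[p], ht[i] = ht[i], ht[p]
        hk[p], hk[i] = hk[i], hk[p]
        i = p
    return n + 1


@njit(cache=True)
def _heap_pop(ht, hk, n):
    n -= 1
    ht[0] = ht[n]
    hk[0] = hk[n]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        s = i
        if l < n and ht[l] < ht[s]:
            s = l
        if r < n and ht[r] < ht[s]:
            s = r
        if s == i:
            break
        ht[s], ht[i] = ht[i], ht[s]
        hk[s], hk[i] = hk[i], hk[s]
        i = s
    return n


@njit(cache=True)
def _trunc_normal(mean, sd):
    if sd <= 0.0:
        return mean if mean > 0.0 else 0.0
    while True:
        x = np.random.normal(mean, sd)
        if x >= 0.0:
            return x


@njit(cache=True)
def _kernel(L, dP, dR, ka, kp, krel, cod_rate, const, n_rnap_pool, n_rib_pool,
            t_end, interval, seed, count_nascent):
    np.random.seed(seed)
    n_codons = cod_rate.shape[0]
    last_boundary = 1 + 3 * (n_codons - 1)

    n_samples = int(math.floor(t_end / interval + 1e-9)) + 1
    out_R = np.zeros(n_samples, dtype=np.int64)
    out_Rm = np.zeros(n_samples, dtype=np.int64)
    out_P = np.zeros(n_samples, dtype=np.int64)
    out_E = np.zeros(n_samples, dtype=np.int64)

    MAX_RNAP = L // (2 * dP + 1) + 3
    MAX_TX = 128
    MAX_RIB = n_rib_pool + 1

    # RNAP agents
    r_state = np.full(MAX_RNAP, -1, dtype=np.int8)
    r_pos = np.zeros(MAX_RNAP, dtype=np.int64)
    r_tx = np.full(MAX_RNAP, -1, dtype=np.int64)
    ral = np.zeros(MAX_RNAP, dtype=np.int64)      # active list
    ral_pos = np.zeros(MAX_RNAP, dtype=np.int64)  # index in active list
    ral_n = 0
    rfree = np.empty(MAX_RNAP, dtype=np.int64)
    for i in range(MAX_RNAP):
        rfree[i] = MAX_RNAP - 1 - i
    rfree_n = MAX_RNAP

    occ = np.full(L + 2, -1, dtype=np.int64)      # footprint occupancy
    center = np.full(L + 2, -1, dtype=np.int64)   # RNAP centred at position

    # transcripts
    tx_state = np.zeros(MAX_TX, dtype=np.int8)    # 0 free, 1 nascent, 2 mature
    tx_exposed = np.zeros(MAX_TX, dtype=np.int64)
    tx_nribs = np.zeros(MAX_TX, dtype=np.int64)
    txl = np.zeros(MAX_TX, dtype=np.int64)
    txl_pos = np.zeros(MAX_TX, dtype=np.int64)
    txl_n = 0
    txfree = np.empty(MAX_TX, dtype=np.int64)
    for j in range(MAX_TX):
        txfree[j] = MAX_TX - 1 - j
    txfree_n = MAX_TX
    rna_free = np.zeros((MAX_TX, L + 2), dtype=np.uint8)

    # ribosome agents
    b_state = np.full(MAX_RIB, -1, dtype=np.int8)  # 0 O, 1 A, 2 stage2, 3 stage3
    b_pos = np.zeros(MAX_RIB, dtype=np.int64)
    b_tx = np.full(MAX_RIB, -1, dtype=np.int64)
    b_back = np.zeros(MAX_RIB, dtype=np.int64)
    b_front = np.zeros(MAX_RIB, dtype=np.int64)
    bal = np.zeros(MAX_RIB, dtype=np.int64)
    bal_pos = np.zeros(MAX_RIB, dtype=np.int64)
    bal_n = 0
    bfree = np.empty(MAX_RIB, dtype=np.int64)
    for i in range(MAX_RIB):
        bfree[i] = MAX_RIB - 1 - i
    bfree_n = MAX_RIB

    heap_t = np.empty(_HEAP_CAP, dtype=np.float64)
    heap_k = np.empty(_HEAP_CAP, dtype=np.int64)
    heap_n = 0

    chan_rate = np.empty(_CHAN_CAP, dtype=np.float64)
    chan_code = np.empty(_CHAN_CAP, dtype=np.int64)
    chan_agent = np.empty(_CHAN_CAP, dtype=np.int64)

    promoter_free = 1
    oc_ready = 0
    free_rnap = n_rnap_pool
    free_rib = n_rib_pool
    n_nascent = 0
    n_mature = 0
    P_count = 0
    E_count = 0
    tx_overflow = 0

    t = 0.0
    next_sample = 0
    INF = 1.0e308

    while next_sample < n_samples:
        # ---- enumerate channels -------------------------------------
        nc = 0
        total = 0.0
        if promoter_free == 1 and free_rnap > 0:
            chan_rate[nc] = const[_KTC]; chan_code[nc] = 0; chan_agent[nc] = 0
            total += const[_KTC]; nc += 1
        if oc_ready == 1 and rfree_n > 0 and txfree_n > 0:
            ok = True
            for q in range(1, dP + 2):
                if occ[q] >= 0:
                    ok = False
                    break
            if ok:
                chan_rate[nc] = const[_KM]; chan_code[nc] = 1; chan_agent[nc] = 0
                total += const[_KM]; nc += 1
        if P_count > 0:
            rr = const[_KDP] * P_count
            chan_rate[nc] = rr; chan_code[nc] = 2; chan_agent[nc] = 0
            total += rr; nc += 1
        if n_mature > 0:
            rr = const[_KDR] * n_mature
            chan_rate[nc] = rr; chan_code[nc] = 3; chan_agent[nc] = 0
            total += rr; nc += 1
            if const[_KTT] > 0.0:
                rr = const[_KTT] * n_mature
                chan_rate[nc] = rr; chan_code[nc] = 4; chan_agent[nc] = 0
                total += rr; nc += 1
        # translation initiation per transcript
        if free_rib > 0 and bfree_n > 0:
            for u in range(txl_n):
                j = txl[u]
                ok = True
                for q in range(1, dR + 2):
                    if rna_free[j, q] != 1:
                        ok = False
                        break
                if ok:
                    chan_rate[nc] = const[_KTL]; chan_code[nc] = 5
                    chan_agent[nc] = j
                    total += const[_KTL]; nc += 1
        # RNAP channels
        for u in range(ral_n):
            i = ral[u]
            st = r_state[i]
            pos = r_pos[i]
            if st == 0:  # elongation-competent
                rr = ka[pos]
                chan_rate[nc] = rr; chan_code[nc] = 6; chan_agent[nc] = i
                total += rr; nc += 1
                if kp[pos] > 0.0:
                    chan_rate[nc] = kp[pos]; chan_code[nc] = 7; chan_agent[nc] = i
                    total += kp[pos]; nc += 1
                chan_rate[nc] = const[_KAR]; chan_code[nc] = 8; chan_agent[nc] = i
                total += const[_KAR]; nc += 1
                chan_rate[nc] = const[_KED]; chan_code[nc] = 9; chan_agent[nc] = i
                total += const[_KED]; nc += 1
                chan_rate[nc] = const[_KPRE]; chan_code[nc] = 10; chan_agent[nc] = i
                total += const[_KPRE]; nc += 1
                back_cell = pos - dP - 1
                if back_cell >= 1 and occ[back_cell] < 0 and \
                        rna_free[r_tx[i], back_cell] == 1:
                    chan_rate[nc] = const[_KPYR]; chan_code[nc] = 11
                    chan_agent[nc] = i
                    total += const[_KPYR]; nc += 1
                fpos = pos - (2 * dP + 1)
                if fpos >= 1 and center[fpos] >= 0 and r_state[center[fpos]] == 1:
                    rr = 0.2 * const[_KM]
                    chan_rate[nc] = rr; chan_code[nc] = 12; chan_agent[nc] = i
                    total += rr; nc += 1
            elif st == 1:  # activated
                if pos == L:
                    chan_rate[nc] = const[_KF]; chan_code[nc] = 14
                    chan_agent[nc] = i
                    total += const[_KF]; nc += 1
                else:
                    front_cell = pos + dP + 1
                    if front_cell > L or occ[front_cell] < 0:
                        chan_rate[nc] = const[_KM]; chan_code[nc] = 13
                        chan_agent[nc] = i
                        total += const[_KM]; nc += 1
            elif st == 2:  # paused
                rr = krel[pos]
                fpos = pos - (2 * dP + 1)
                if fpos >= 1 and center[fpos] >= 0 and r_state[center[fpos]] == 1:
                    rr += 0.8 * const[_KM]
                chan_rate[nc] = rr; chan_code[nc] = 15; chan_agent[nc] = i
                total += rr; nc += 1
            elif st == 3:  # arrested
                chan_rate[nc] = const[_IAR]; chan_code[nc] = 17; chan_agent[nc] = i
                total += const[_IAR]; nc += 1
            else:  # editing
                chan_rate[nc] = const[_IED]; chan_code[nc] = 18; chan_agent[nc] = i
                total += const[_IED]; nc += 1
        # ribosome channels
        for u in range(bal_n):
            i = bal[u]
            st = b_state[i]
            if st == 0:  # codon boundary, pre-activation
                m = b_pos[i]
                c = (m - 1) // 3
                rr = cod_rate[c]
                chan_rate[nc] = rr; chan_code[nc] = 20; chan_agent[nc] = i
                total += rr; nc += 1
                if m - dR - 3 >= 1:
                    j = b_tx[i]
                    ok = True
                    for q in range(m - dR - 3, m - dR):
                        if rna_free[j, q] != 1:
                            ok = False
                            break
                    if ok:
                        chan_rate[nc] = const[_KBT]; chan_code[nc] = 21
                        chan_agent[nc] = i
                        total += const[_KBT]; nc += 1
                chan_rate[nc] = const[_KDROP]; chan_code[nc] = 22
                chan_agent[nc] = i
                total += const[_KDROP]; nc += 1
            elif st == 1:  # activated codon
                m = b_pos[i]
                if m == last_boundary:
                    chan_rate[nc] = const[_KTLF]; chan_code[nc] = 24
                    chan_agent[nc] = i
                    total += const[_KTLF]; nc += 1
                else:
                    j = b_tx[i]
                    front = b_front[i]
                    hi = front + 3
                    if hi > L:
                        hi = L
                    ok = True
                    for q in range(front + 1, hi + 1):
                        if rna_free[j, q] != 1:
                            ok = False
                            break
                    if ok:
                        chan_rate[nc] = const[_KTM]; chan_code[nc] = 23
                        chan_agent[nc] = i
                        total += const[_KTM]; nc += 1
            else:  # mid-translocation stages
                chan_rate[nc] = const[_KTM]; chan_code[nc] = 25 + (st - 2)
                chan_agent[nc] = i
                total += const[_KTM]; nc += 1

        # ---- choose the next event ----------------------------------
        t_heap = heap_t[0] if heap_n > 0 else INF
        if total > 0.0:
            t_next = t - math.log(np.random.random()) / total
        else:
            t_next = INF
        release = t_heap <= t_next
        t_event = t_heap if release else t_next

        while next_sample < n_samples and next_sample * interval < t_event:
            R_now = n_nascent + n_mature if count_nascent == 1 else n_mature
            out_R[next_sample] = R_now
            out_Rm[next_sample] = n_mature
            out_P[next_sample] = P_count
            out_E[next_sample] = E_count
            next_sample += 1
        if next_sample >= n_samples or t_event > t_end:
            # everything on the grid recorded, or nothing more before t_end
            while next_sample < n_samples:
                R_now = n_nascent + n_mature if count_nascent == 1 else n_mature
                out_R[next_sample] = R_now
                out_Rm[next_sample] = n_mature
                out_P[next_sample] = P_count
                out_E[next_sample] = E_count
                next_sample += 1
            break
        t = t_event

        # ---- execute ------------------------------------------------
        if release:
            kind = heap_k[0]
            heap_n = _heap_pop(heap_t, heap_k, heap_n)
            if kind == 0:
                P_count += 1
                E_count += 1
            else:
                oc_ready = 1
            continue

        u = np.random.random() * total
        acc = 0.0
        pick = nc - 1
        for q in range(nc):
            acc += chan_rate[q]
            if u < acc:
                pick = q
                break
        code = chan_code[pick]
        agent = chan_agent[pick]

        if code == 0:  # promoter binding; open complex forms after a delay
            promoter_free = 0
            free_rnap -= 1
            heap_n = _heap_push(heap_t, heap_k, heap_n,
                                t + _trunc_normal(const[_OCM], const[_OCS]), 1)
        elif code == 1:  # promoter clearance: new RNAP + nascent transcript
            oc_ready = 0
            promoter_free = 1
            rfree_n -= 1
            i = rfree[rfree_n]
            txfree_n -= 1
            j = txfree[txfree_n]
            r_state[i] = 0
            r_pos[i] = 1
            r_tx[i] = j
            ral[ral_n] = i; ral_pos[i] = ral_n; ral_n += 1
            hi = dP + 1
            if hi > L:
                hi = L
            for q in range(1, hi + 1):
                occ[q] = i
            center[1] = i
            tx_state[j] = 1
            tx_exposed[j] = 0
            tx_nribs[j] = 0
            for q in range(1, L + 1):
                rna_free[j, q] = 0
            txl[txl_n] = j; txl_pos[j] = txl_n; txl_n += 1
            n_nascent += 1
        elif code == 2:
            P_count -= 1
        elif code == 3 or code == 4:  # mRNA degradation / trans-translation
            k = int(np.random.random() * n_mature)
            j = -1
            seen = 0
            for u2 in range(txl_n):
                jj = txl[u2]
                if tx_state[jj] == 2:
                    if seen == k:
                        j = jj
                        break
                    seen += 1
            # release bound ribosomes to the pool
            u2 = 0
            while u2 < bal_n:
                i = bal[u2]
                if b_tx[i] == j:
                    b_state[i] = -1
                    bfree[bfree_n] = i; bfree_n += 1
                    free_rib += 1
                    last = bal[bal_n - 1]
                    bal[u2] = last; bal_pos[last] = u2; bal_n -= 1
                else:
                    u2 += 1
            tx_state[j] = 0
            k2 = txl_pos[j]
            last = txl[txl_n - 1]
            txl[k2] = last; txl_pos[last] = k2; txl_n -= 1
            txfree[txfree_n] = j; txfree_n += 1
            n_mature -= 1
        elif code == 5:  # translation initiation
            j = agent
            bfree_n -= 1
            i = bfree[bfree_n]
            b_state[i] = 0
            b_pos[i] = 1
            b_tx[i] = j
            b_back[i] = 1
            b_front[i] = dR + 1 if dR + 1 <= L else L
            for q in range(1, b_front[i] + 1):
                rna_free[j, q] = 0
            bal[bal_n] = i; bal_pos[i] = bal_n; bal_n += 1
            tx_nribs[j] += 1
            free_rib -= 1
        elif code == 6:
            r_state[agent] = 1
        elif code == 7:
            r_state[agent] = 2
        elif code == 8:
            r_state[agent] = 3
        elif code == 9:
            r_state[agent] = 4
        elif code == 10:  # premature termination: abort the nascent transcript
            i = agent
            pos = r_pos[i]
            lo = pos - dP
            if lo < 1:
                lo = 1
            hi = pos + dP
            if hi > L:
                hi = L
            for q in range(lo, hi + 1):
                occ[q] = -1
            center[pos] = -1
            j = r_tx[i]
            u2 = 0
            while u2 < bal_n:
                ii = bal[u2]
                if b_tx[ii] == j:
                    b_state[ii] = -1
                    bfree[bfree_n] = ii; bfree_n += 1
                    free_rib += 1
                    last = bal[bal_n - 1]
                    bal[u2] = last; bal_pos[last] = u2; bal_n -= 1
                else:
                    u2 += 1
            tx_state[j] = 0
            k2 = txl_pos[j]
            last = txl[txl_n - 1]
            txl[k2] = last; txl_pos[last] = k2; txl_n -= 1
            txfree[txfree_n] = j; txfree_n += 1
            n_nascent -= 1
            r_state[i] = -1
            k2 = ral_pos[i]
            last = ral[ral_n - 1]
            ral[k2] = last; ral_pos[last] = k2; ral_n -= 1
            rfree[rfree_n] = i; rfree_n += 1
            free_rnap += 1
        elif code == 11:  # pyrophosphorolysis: backstep, re-cover one nt
            i = agent
            pos = r_pos[i]
            j = r_tx[i]
            occ[pos - dP - 1] = i
            if pos + dP <= L:
                occ[pos + dP] = -1
            center[pos] = -1
            center[pos - 1] = i
            rna_free[j, pos - dP - 1] = 0
            tx_exposed[j] = pos - dP - 2
            r_pos[i] = pos - 1
        elif code == 12:
            r_state[agent] = 2
        elif code == 13:  # elongation step
            i = agent
            pos = r_pos[i]
            j = r_tx[i]
            newpos = pos + 1
            if newpos + dP <= L:
                occ[newpos + dP] = i
            if pos - dP >= 1:
                occ[pos - dP] = -1
            center[pos] = -1
            center[newpos] = i
            r_pos[i] = newpos
            r_state[i] = 0
            m = newpos - dP - 1
            if m >= 1:
                rna_free[j, m] = 1
                tx_exposed[j] = m
        elif code == 14:  # termination: transcript completes
            i = agent
            j = r_tx[i]
            lo = L - dP
            if lo < 1:
                lo = 1
            for q in range(lo, L + 1):
                occ[q] = -1
            center[L] = -1
            r_state[i] = -1
            k2 = ral_pos[i]
            last = ral[ral_n - 1]
            ral[k2] = last; ral_pos[last] = k2; ral_n -= 1
            rfree[rfree_n] = i; rfree_n += 1
            free_rnap += 1
            for q in range(tx_exposed[j] + 1, L + 1):
                rna_free[j, q] = 1
            tx_exposed[j] = L
            tx_state[j] = 2
            n_nascent -= 1
            n_mature += 1
        elif code == 15:
            r_state[agent] = 0
        elif code == 17:
            r_state[agent] = 0
        elif code == 18:
            r_state[agent] = 0
        elif code == 20:
            b_state[agent] = 1
        elif code == 21:  # back-translocation
            i = agent
            j = b_tx[i]
            m = b_pos[i]
            for q in range(m - dR - 3, m - dR):
                rna_free[j, q] = 0
            b_back[i] = m - dR - 3
            new_front = m - 3 + dR
            if new_front > L:
                new_front = L
            for q in range(new_front + 1, b_front[i] + 1):
                rna_free[j, q] = 1
            b_front[i] = new_front
            b_pos[i] = m - 3
            b_state[i] = 1
        elif code == 22:  # drop-off
            i = agent
            j = b_tx[i]
            for q in range(b_back[i], b_front[i] + 1):
                rna_free[j, q] = 1
            b_state[i] = -1
            k2 = bal_pos[i]
            last = bal[bal_n - 1]
            bal[k2] = last; bal_pos[last] = k2; bal_n -= 1
            bfree[bfree_n] = i; bfree_n += 1
            free_rib += 1
            tx_nribs[j] -= 1
        elif code == 23:  # translocation stage 1: consume ahead
            i = agent
            j = b_tx[i]
            m = b_pos[i]
            new_front = m + 3 + dR
            if new_front > L:
                new_front = L
            for q in range(b_front[i] + 1, new_front + 1):
                rna_free[j, q] = 0
            b_front[i] = new_front
            b_pos[i] = m + 1
            b_state[i] = 2
        elif code == 24:  # completion: protein appears after a folding delay
            i = agent
            j = b_tx[i]
            for q in range(b_back[i], b_front[i] + 1):
                rna_free[j, q] = 1
            b_state[i] = -1
            k2 = bal_pos[i]
            last = bal[bal_n - 1]
            bal[k2] = last; bal_pos[last] = k2; bal_n -= 1
            bfree[bfree_n] = i; bfree_n += 1
            free_rib += 1
            tx_nribs[j] -= 1
            heap_n = _heap_push(heap_t, heap_k, heap_n,
                                t + _trunc_normal(const[_FOLDM], const[_FOLDS]), 0)
        elif code == 25:  # translocation stage 2
            i = agent
            b_pos[i] += 1
            b_state[i] = 3
        else:  # code == 26, translocation stage 3: release behind
            i = agent
            j = b_tx[i]
            m = b_pos[i] + 1  # new boundary position
            new_back = m - dR
            if new_back < 1:
                new_back = 1
            for q in range(b_back[i], new_back):
                rna_free[j, q] = 1
            b_back[i] = new_back
            b_pos[i] = m
            b_state[i] = 0

    return out_R, out_Rm, out_P, out_E, tx_overflow


class SimulationResult(dict):
    """Dict of sampled trajectories with attribute access for convenience."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as err:  # pragma: no cover
            raise AttributeError(name) from err


def simulate_expression(template: GeneTemplate, params: ModelParameters,
                        t_end: float, sample_interval: float = 1.0,
                        seed: int = 0,
                        count_nascent: bool = True) -> SimulationResult:
    """Simulate one replicate of the full expression model.

    Returns a :class:`SimulationResult` with ``times`` and integer series
    ``rna`` (transcripts present; nascent + completed when
    ``count_nascent``), ``rna_completed``, ``protein`` and
    ``protein_cum`` (cumulative proteins produced), plus the seed and
    parameters used.  Identical seed and configuration give bit-identical
    output.
    """
    if t_end <= 0 or sample_interval <= 0:
        raise ValueError("t_end and sample_interval must be > 0")
    L = template.length
    p = params
    ka = np.zeros(L + 2)
    for n in range(1, L + 1):
        ka[n] = p.k_a(n)
    kp = np.zeros(L + 2)
    kp[:L + 1] = template.pause_entry_rates(p)
    krel = np.zeros(L + 2)
    krel[:L + 1] = template.pause_release_rates(p)
    cod_rate = np.array([p.codon_rate(c) for c in template.codon_classes])
    const = np.zeros(21)
    const[_KTC] = p.k_tc
    const[_OCM] = p.tau_oc_mean
    const[_OCS] = p.tau_oc_sd
    const[_KM] = p.k_m
    const[_KAR] = p.k_ar
    const[_IAR] = 1.0 / p.tau_ar
    const[_KED] = p.k_ed
    const[_IED] = 1.0 / p.d_ed
    const[_KPRE] = p.k_pre
    const[_KPYR] = p.k_pyr
    const[_KF] = p.k_f
    const[_KDR] = p.k_dr
    const[_KTL] = p.k_tl
    const[_KTM] = p.k_tm
    const[_KBT] = p.k_bt
    const[_KDROP] = p.k_drop
    const[_KTT] = p.k_tt
    const[_KTLF] = p.k_tlf
    const[_FOLDM] = p.tau_fold_mean
    const[_FOLDS] = p.tau_fold_sd
    const[_KDP] = p.k_dp
    R, Rm, P, E, overflow = _kernel(
        L, p.delta_P, p.delta_R, ka, kp, krel, cod_rate, const,
        p.n_rnap, p.n_rib, float(t_end), float(sample_interval),
        int(seed) % (2**31 - 1), 1 if count_nascent else 0)
    times = np.arange(R.size) * float(sample_interval)
    return SimulationResult(
        times=times, rna=R, rna_completed=Rm, protein=P, protein_cum=E,
        seed=int(seed), t_end=float(t_end),
        sample_interval=float(sample_interval),
        count_nascent=bool(count_nascent),
        params=asdict(params),
        pause_sites=[(s.position, s.efficiency, s.mean_duration)
                     for s in template.pause_sites],
        gene_length=L, tx_slot_overflow=int(overflow))
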