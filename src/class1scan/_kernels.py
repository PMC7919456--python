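"""Numba kernels for exhaustive window scoring and greedy overlap resolution.

These mirror the pure-Python reference operations (`builtin_candidate_score`,
`dedupe_hits`) exactly; equivalence is enforced by tests.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def scan_strand(
    codes,            # int8[L] strand sequence 5'->3'
    pairm,            # uint8[5,5] pairing table
    motif_scores,     # float64[L] PWM score of the motif window starting here
    t5,               # float64[L] matches of codes[p:p+3] to AAG
    t3,               # float64[L+1] matches of codes[q-4:q] to CTGT (index by end)
    mlen,             # motif length
    min_len, max_len,
    max_offset, min_pairs, min_loop, stem_cap, motif_slack,
    stem_w, t5_w, t3_w, len_pen, target_len,
    threshold,
    out_start, out_end, out_score,
):
    """Score every window of length min_len..max_len; record hits >= threshold.

    Returns the total number of hits (which may exceed the output capacity;
    the caller then re-runs with larger buffers).
    """
    L = codes.shape[0]
    cap = out_start.shape[0]
    n = 0
    for p in range(L - min_len + 1):
        wmax = max_len if p + max_len <= L else L - p
        for w in range(min_len, wmax + 1):
            q = p + w
            # best terminal stem: longest run, tie -> smallest i then j
            best_run = 0
            best_i = 0
            for i in range(max_offset + 1):
                for j in range(max_offset + 1):
                    k = 0
                    while True:
                        x = p + i + k
                        y = q - 1 - j - k
                        if y - x <= min_loop:
                            break
                        if pairm[codes[x], codes[y]] == 0:
                            break
                        k += 1
                    if k > best_run:
                        best_run = k
                        best_i = i
            if best_run < min_pairs:
                B = 0.0
                e5 = -1
            else:
                B = float(best_run if best_run < stem_cap else stem_cap)
                e5 = best_i + best_run - 1
            # best motif window within motif_slack nt 3' of the 5' stem arm
            M = 0.0
            for m in range(e5 + 1, e5 + 2 + motif_slack):
                if m < 0 or m + mlen > w:
                    continue
                s = motif_scores[p + m]
                if s > M:
                    M = s
            score = (
                stem_w * B
                + M
                + t5_w * t5[p]
                + t3_w * t3[q]
                - len_pen * abs(w - target_len)
            )
            if score >= threshold:
                if n < cap:
                    out_start[n] = p
                    out_end[n] = q
                    out_score[n] = score
                n += 1
    return n


@njit(cache=True)
def greedy_keep(starts, ends, strands, order, genome_len):
    """Greedy non-overlap resolution: walk hits in ``order``, keep a hit iff
    no already-kept hit on the same strand overlaps it.  Returns a keep mask.
    """
    keep = np.zeros(starts.shape[0], dtype=np.uint8)
    occupied = np.zeros((2, genome_len), dtype=np.uint8)
    for idx in order:
        s = starts[idx]
        e = ends[idx]
        st = strands[idx]
        free = True
        for pos in range(s, e):
            if occupied[st, pos] == 1:
                free = False
                break
        if free:
            keep[idx] = 1
            for pos in range(s, e):
                occupied[st, pos] = 1
    return keep
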