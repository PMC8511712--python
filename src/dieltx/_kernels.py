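"""Numba kernel for the batch permutation null of the umbrella test.

The statistic for a pattern is a sum of pairwise rank-concordance counts
U(a, b) = #{x in group a, y in group b : x < y} + 0.5 * #ties between the
groups named by the pattern's comparison pairs. All counts are kept doubled
(2U) so everything stays in exact integer arithmetic; a tie contributes 1
per tied cross-pair.

Two exact symmetries keep the kernel cheap:

* the permutation null reassigns observations to groups with group sizes
  fixed, realized by shuffling group labels over the *sorted* values (the
  tie-block structure of a series is permutation-invariant, computed once);
* patterns come in complementary (peak, trough) <-> (trough, peak) pairs
  whose comparison pairs are exact mirrors, so S2_complement =
  max2 - S2_base for every labelling (U2[a,b] + U2[b,a] = 2 * n_a * n_b,
  ties included). Only half the patterns are ever evaluated; tail counts
  for the complements read the opposite tail of the same column.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _stats_from_labels(blocks, n_blocks, labels, n_groups, c2, bc, u2, pair_pat, pair_a, pair_b, out):
    """Doubled base-pattern statistics for one labelling of sorted values."""
    for a in range(n_groups):
        c2[a] = 0
        for b in range(n_groups):
            u2[a, b] = 0
    for bi in range(n_blocks):
        s = blocks[bi]
        e = blocks[bi + 1]
        if e == s + 1:  # fast path: untied value
            b = labels[s]
            for a in range(n_groups):
                u2[a, b] += c2[a]
            c2[b] += 2
        else:
            for a in range(n_groups):
                bc[a] = 0
            for k in range(s, e):
                bc[labels[k]] += 1
            for b in range(n_groups):
                if bc[b] > 0:
                    for a in range(n_groups):
                        if c2[a] > 0:
                            u2[a, b] += c2[a] * bc[b]
                        if a != b and bc[a] > 0:
                            u2[a, b] += bc[a] * bc[b]  # doubled half-ties
            for a in range(n_groups):
                c2[a] += 2 * bc[a]
    for p in range(out.shape[0]):
        out[p] = 0
    for k in range(pair_pat.shape[0]):
        out[pair_pat[k]] += u2[pair_a[k], pair_b[k]]


@njit(cache=True)
def batch_permutation_test(
    values,
    group_of,
    n_groups,
    pair_pat,
    pair_a,
    pair_b,
    n_base,
    base_of,
    is_comp,
    max2_base,
    n_perm,
    seed,
    bonferroni,
):
    """Permutation umbrella test for many series sharing one design.

    Parameters
    ----------
    values : (n_series, n_obs) float64
    group_of : (n_obs,) int32 time-of-day group of each observation
    pair_pat, pair_a, pair_b : flattened comparison pairs of the ``n_base``
        evaluated patterns
    base_of, is_comp : (n_patterns,) map each logical pattern to its
        evaluated base column and whether it is the mirrored complement
    max2_base : (n_base,) doubled maxima of the base statistics
    bonferroni : if True combine pattern p-values with a Bonferroni factor,
        otherwise with a max-T statistic (largest standardized pattern
        deviation) calibrated on the same permutations.

    Returns
    -------
    p_raw : (n_series,) combined p-value per series
    counts_obs : (n_series, n_patterns) permutation tail counts
        #{perm : S_perm >= S_obs} per logical pattern
    s2_obs : (n_series, n_patterns) doubled observed statistics
    sd_base : (n_series, n_base) permutation SD of each base statistic
        (complements share it by symmetry); 0 marks a degenerate pattern
    """
    n_series, n_obs = values.shape
    n_patterns = base_of.shape[0]
    # xorshift64* state, initialized by a splitmix64 step so small seeds work
    state = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    state = (state ^ (state >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    state = (state ^ (state >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    state = state ^ (state >> np.uint64(31))
    if state == np.uint64(0):
        state = np.uint64(0x853C49E6748FEA9B)
    p_raw = np.ones(n_series)
    counts_obs = np.zeros((n_series, n_patterns), np.int32)
    s2_obs = np.zeros((n_series, n_patterns), np.int32)
    sd_base = np.zeros((n_series, n_base), np.float64)

    s2_perm = np.empty((n_base, n_perm), np.int32)
    labels = np.empty(n_obs, np.int32)
    blocks = np.empty(n_obs + 1, np.int32)
    c2 = np.empty(n_groups, np.int32)
    bc = np.empty(n_groups, np.int32)
    u2 = np.empty((n_groups, n_groups), np.int32)
    row = np.empty(n_base, np.int32)
    obs_base = np.empty(n_base, np.int32)
    cnt_ge = np.empty(n_base, np.int32)
    cnt_le = np.empty(n_base, np.int32)
    inv_sd = np.empty(n_base, np.float64)
    mean_b = np.empty(n_base, np.float64)

    for si in range(n_series):
        v = values[si]
        vmin = v[0]
        vmax = v[0]
        for i in range(1, n_obs):
            if v[i] < vmin:
                vmin = v[i]
            if v[i] > vmax:
                vmax = v[i]
        if vmax == vmin:  # constant series: no evidence of rhythm
            p_raw[si] = 1.0
            for p in range(n_patterns):
                counts_obs[si, p] = n_perm
                s2_obs[si, p] = max2_base[base_of[p]] // 2
            continue

        order = np.argsort(v)
        n_blocks = 0
        blocks[0] = 0
        for i in range(1, n_obs):
            if v[order[i]] != v[order[i - 1]]:
                n_blocks += 1
                blocks[n_blocks] = i
        n_blocks += 1
        blocks[n_blocks] = n_obs

        for i in range(n_obs):
            labels[i] = group_of[order[i]]

        _stats_from_labels(blocks, n_blocks, labels, n_groups, c2, bc, u2, pair_pat, pair_a, pair_b, obs_base)
        for p in range(n_patterns):
            b = base_of[p]
            s2_obs[si, p] = max2_base[b] - obs_base[b] if is_comp[p] else obs_base[b]

        for b in range(n_base):
            cnt_ge[b] = 0
            cnt_le[b] = 0
        for it in range(n_perm):
            for i in range(n_obs - 1, 0, -1):  # Fisher-Yates, xorshift64* draws
                state ^= state << np.uint64(13)
                state ^= state >> np.uint64(7)
                state ^= state << np.uint64(17)
                out = (state * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(32)
                j = int(out % np.uint64(i + 1))
                t = labels[i]
                labels[i] = labels[j]
                labels[j] = t
            _stats_from_labels(blocks, n_blocks, labels, n_groups, c2, bc, u2, pair_pat, pair_a, pair_b, row)
            for b in range(n_base):
                x = row[b]
                s2_perm[b, it] = x
                if x >= obs_base[b]:
                    cnt_ge[b] += 1
                if x <= obs_base[b]:
                    cnt_le[b] += 1

        min_cnt = n_perm
        for p in range(n_patterns):
            b = base_of[p]
            cnt = cnt_le[b] if is_comp[p] else cnt_ge[b]
            counts_obs[si, p] = cnt
            if cnt < min_cnt:
                min_cnt = cnt

        for b in range(n_base):
            mean_b[b] = max2_base[b] * 0.5
            acc = 0.0
            for it in range(n_perm):
                d = s2_perm[b, it] - mean_b[b]
                acc += d * d
            sd = np.sqrt(acc / n_perm)
            sd_base[si, b] = sd
            inv_sd[b] = 1.0 / sd if sd > 0.0 else 0.0

        if bonferroni:
            pv = n_patterns * (min_cnt + 1.0) / (n_perm + 1.0)
            p_raw[si] = pv if pv < 1.0 else 1.0
        else:
            # max-T combination: standardize every base statistic by its
            # exact permutation mean (max2/2; complements are sign mirrors,
            # so |Z| covers both) and its permutation SD, then calibrate
            # T = max_b |Z_b| against the same permutations. This keeps the
            # p-value floor at 1/(n_perm+1) instead of paying the pattern
            # multiplicity in granularity.
            t_obs = 0.0
            for b in range(n_base):
                z = abs(obs_base[b] - mean_b[b]) * inv_sd[b]
                if z > t_obs:
                    t_obs = z
            hits = 0
            for it in range(n_perm):
                for b in range(n_base):
                    z = abs(s2_perm[b, it] - mean_b[b]) * inv_sd[b]
                    if z >= t_obs:
                        hits += 1
                        break
            p_raw[si] = (hits + 1.0) / (n_perm + 1.0)
    return p_raw, counts_obs, s2_obs, sd_base
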