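"""Nonparametric detection of 24-h rhythmicity with peak-time assignment.

Each (bin, gene family) FPKM series is grouped by time of day (pooling days
and replicates, n = days x replicates per group) and tested against the
family of cyclic *umbrella* alternatives: a monotone rise from a trough
group to a peak group around the cyclic hour axis, followed by a monotone
fall back to the trough. For G groups there are G*(G-1) (peak, trough)
patterns. The statistic for a pattern is a Jonckheere-Terpstra-type sum of
pairwise concordance counts over the pattern's within-chain ordered group
pairs (ties count 1/2); its null distribution comes from permuting
observations across groups with group sizes fixed.

Evidence across the pattern family is combined into a single per-series p
either by a max-T statistic — the largest standardized pattern deviation,
calibrated against its own permutation distribution (default; exact, and
its Monte-Carlo granularity stays at 1/(n_perm+1) instead of paying the
pattern multiplicity) — or by a Bonferroni factor on the smallest pattern
p-value. Discoveries are controlled with Benjamini-Hochberg across all
series, and each discovery is assigned the sampling hour of its
best-supported pattern's peak group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from ._kernels import batch_permutation_test
from .containers import BinAbundance
from .design import SamplingDesign

__all__ = [
    "UmbrellaPattern",
    "enumerate_patterns",
    "umbrella_statistic",
    "pattern_pvalue",
    "rain_test",
    "RainResult",
    "bh_adjust",
    "assign_peak",
    "run_rhythmicity",
]


@dataclass(frozen=True)
class UmbrellaPattern:
    """One cyclic rise/fall alternative.

    ``rising`` walks the cyclic group axis from trough to peak, ``falling``
    from peak back to trough. ``pairs`` are the distinct ordered group
    pairs (low, high) whose concordance the statistic sums: all within-chain
    pairs, with the shared (trough, peak) endpoint pair counted once.
    """

    peak: int
    trough: int
    rising: tuple[int, ...]
    falling: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]


def enumerate_patterns(n_groups: int) -> list[UmbrellaPattern]:
    """All G*(G-1) cyclic (peak, trough) umbrella patterns, peak-major order."""
    if n_groups < 3:
        raise ValueError("need at least 3 groups to define umbrella patterns")
    patterns = []
    for peak in range(n_groups):
        for trough in range(n_groups):
            if trough == peak:
                continue
            rising = [trough]
            while rising[-1] != peak:
                rising.append((rising[-1] + 1) % n_groups)
            falling = [peak]
            while falling[-1] != trough:
                falling.append((falling[-1] + 1) % n_groups)
            pairs: list[tuple[int, int]] = []
            seen = set()
            for i in range(len(rising)):
                for j in range(i + 1, len(rising)):
                    pr = (rising[i], rising[j])
                    if pr not in seen:
                        seen.add(pr)
                        pairs.append(pr)
            for i in range(len(falling)):
                for j in range(i + 1, len(falling)):
                    pr = (falling[j], falling[i])  # later group expected smaller
                    if pr not in seen:
                        seen.add(pr)
                        pairs.append(pr)
            patterns.append(
                UmbrellaPattern(peak, trough, tuple(rising), tuple(falling), tuple(pairs))
            )
    return patterns


def _pair_u(x: np.ndarray, y: np.ndarray) -> float:
    """#{x_i < y_j} + 0.5 #{x_i = y_j}."""
    xs = x[:, None]
    return float((xs < y[None, :]).sum()) + 0.5 * float((xs == y[None, :]).sum())


def umbrella_statistic(
    groups: list[np.ndarray], pattern: UmbrellaPattern
) -> tuple[float, float]:
    """Concordance statistic and its maximum for one pattern."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size == 0:
            raise ValueError("every group needs at least one observation")
    stat = 0.0
    smax = 0.0
    for a, b in pattern.pairs:
        stat += _pair_u(groups[a], groups[b])
        smax += groups[a].size * groups[b].size
    return stat, smax


def _groups_to_arrays(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    group_of = np.concatenate(
        [np.full(len(g), i, dtype=np.int64) for i, g in enumerate(groups)]
    )
    return values, group_of


def n_multiset_permutations(values: np.ndarray) -> int:
    """Number of distinct arrangements of the pooled value multiset."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _exhaustive_stat_matrix(
    values: np.ndarray, group_of: np.ndarray, patterns: list[UmbrellaPattern]
) -> np.ndarray:
    """Statistics (doubled) of every distinct value arrangement x pattern."""
    arrangements = np.array(list(multiset_permutations(list(values))), dtype=float)
    n_all, n_obs = arrangements.shape
    idx_of_group = [np.where(group_of == g)[0] for g in range(group_of.max() + 1)]
    # doubled pairwise U for every needed ordered pair
    needed = sorted({pr for pat in patterns for pr in pat.pairs})
    u2 = {}
    for a, b in needed:
        acc = np.zeros(n_all, dtype=np.int64)
        for i in idx_of_group[a]:
            xi = arrangements[:, i]
            for j in idx_of_group[b]:
                yj = arrangements[:, j]
                acc += 2 * (xi < yj) + (xi == yj)
        u2[(a, b)] = acc
    s2 = np.zeros((n_all, len(patterns)), dtype=np.int64)
    for p, pat in enumerate(patterns):
        for pr in pat.pairs:
            s2[:, p] += u2[pr]
    return s2


def pattern_pvalue(
    groups: list[np.ndarray],
    pattern: UmbrellaPattern,
    null_engine: str = "monte_carlo",
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive_limit: int = 1_000_000,
) -> float:
    """P(statistic >= observed) under random group reassignment.

    ``exhaustive`` enumerates every distinct arrangement of the pooled value
    multiset (only allowed up to ``exhaustive_limit`` arrangements);
    ``monte_carlo`` uses the add-one estimator (r+1)/(n_perm+1).
    """
    values, group_of = _groups_to_arrays(groups)
    if any(len(np.asarray(g)) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    s_obs, _ = umbrella_statistic(groups, pattern)
    if null_engine == "exhaustive":
        total = n_multiset_permutations(values)
        if total > exhaustive_limit:
            raise ValueError(
                f"exhaustive null needs {total} arrangements, above the limit "
                f"of {exhaustive_limit}"
            )
        s2 = _exhaustive_stat_matrix(values, group_of, [pattern])[:, 0]
        return float((s2 >= round(2 * s_obs)).mean())
    if null_engine == "monte_carlo":
        rng = np.random.default_rng(seed)
        labels = group_of.copy()
        sizes = np.bincount(group_of)
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(labels)
            stat = 0.0
            for a, b in pattern.pairs:
                stat += _pair_u(values[labels == a], values[labels == b])
            if stat >= s_obs - 1e-12:
                hits += 1
        del sizes
        return (hits + 1.0) / (n_perm + 1.0)
    raise ValueError(f"unknown null engine {null_engine!r}")


@dataclass
class RainResult:
    statistic: float
    max_statistic: float
    p_raw: float
    best_pattern: UmbrellaPattern | None
    pattern_pvalues: np.ndarray
    pattern_z: np.ndarray
    engine: str
    n_perm: int


def _kernel_inputs(patterns: list[UmbrellaPattern], sizes: np.ndarray):
    """Base/complement bookkeeping for the kernel.

    Complementary patterns (peak, trough) <-> (trough, peak) have mirrored
    comparison pairs, so only one of each pair ("base") is evaluated; the
    complement's statistic is max2 - S2 of the base.
    """
    index_of = {(p.peak, p.trough): i for i, p in enumerate(patterns)}
    base_ids: list[int] = []
    base_col = {}
    base_of = np.empty(len(patterns), dtype=np.int64)
    is_comp = np.zeros(len(patterns), dtype=np.bool_)
    for i, p in enumerate(patterns):
        j = index_of[(p.trough, p.peak)]
        if j < i:  # complement already registered as a base
            base_of[i] = base_col[j]
            is_comp[i] = True
        else:
            base_col[i] = len(base_ids)
            base_of[i] = base_col[i]
            base_ids.append(i)
    pat_idx, pa, pb = [], [], []
    for col, i in enumerate(base_ids):
        for a, b in patterns[i].pairs:
            pat_idx.append(col)
            pa.append(a)
            pb.append(b)
    max2_base = _max2([patterns[i] for i in base_ids], sizes).astype(np.int32)
    return (
        np.array(pat_idx, dtype=np.int64),
        np.array(pa, dtype=np.int64),
        np.array(pb, dtype=np.int64),
        len(base_ids),
        base_of,
        is_comp,
        max2_base,
    )


def _max2(patterns: list[UmbrellaPattern], sizes: np.ndarray) -> np.ndarray:
    return np.array(
        [
            2 * sum(int(sizes[a]) * int(sizes[b]) for a, b in pat.pairs)
            for pat in patterns
        ],
        dtype=np.int64,
    )


def _best_pattern(counts: np.ndarray, z: np.ndarray) -> int:
    """Smallest tail count; ties (common at count 0) broken by largest Z,
    then by enumeration order (smaller peak, then smaller trough)."""
    tied = np.flatnonzero(counts == counts.min())
    return int(tied[np.argmax(np.asarray(z)[tied])])


def rain_test(
    groups: list[np.ndarray],
    design: SamplingDesign | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    engine: str = "auto",
    combine: str = "maxt",
    exhaustive_limit: int = 1_000_000,
) -> RainResult:
    """Test one grouped series against all cyclic umbrella patterns.

    ``combine="maxt"`` (default) calibrates the largest standardized
    pattern deviation against its own permutation distribution;
    ``"bonferroni"`` multiplies the smallest per-pattern p-value by the
    number of patterns. The exhaustive engine is auto-selected when the
    pooled multiset has at most ``exhaustive_limit`` distinct arrangements.
    """
    if combine not in ("maxt", "bonferroni"):
        raise ValueError(f"unknown combine mode {combine!r}")
    if design is not None and len(groups) != len(design.times_of_day):
        raise ValueError("group count does not match the design's times of day")
    values, group_of = _groups_to_arrays(groups)
    n_groups = len(groups)
    patterns = enumerate_patterns(n_groups)
    sizes = np.array([len(g) for g in groups])
    max2 = _max2(patterns, sizes)

    if values.max() == values.min():
        return RainResult(
            statistic=float(max2[0]) / 4.0,
            max_statistic=float(max2[0]) / 2.0,
            p_raw=1.0,
            best_pattern=None,
            pattern_pvalues=np.ones(len(patterns)),
            pattern_z=np.zeros(len(patterns)),
            engine="constant",
            n_perm=0,
        )

    if engine == "auto":
        engine = (
            "exhaustive"
            if n_multiset_permutations(values) <= exhaustive_limit
            else "monte_carlo"
        )

    if engine == "exhaustive":
        total = n_multiset_permutations(values)
        if total > exhaustive_limit:
            raise ValueError(
                f"exhaustive null needs {total} arrangements, above the limit "
                f"of {exhaustive_limit}"
            )
        s2 = _exhaustive_stat_matrix(values, group_of, patterns)
        s2_sorted = np.sort(s2, axis=0)
        n_all = s2.shape[0]
        # observed = identity arrangement (first row order == input order)
        s2_obs = np.empty(len(patterns), dtype=np.int64)
        grouped = [values[group_of == g] for g in range(n_groups)]
        for p, pat in enumerate(patterns):
            st, _ = umbrella_statistic(grouped, pat)
            s2_obs[p] = round(2 * st)
        tails = np.empty((n_all, len(patterns)), dtype=np.int64)
        tails_obs = np.empty(len(patterns), dtype=np.int64)
        for p in range(len(patterns)):
            col = s2_sorted[:, p]
            tails[:, p] = n_all - np.searchsorted(col, s2[:, p], side="left")
            tails_obs[p] = n_all - np.searchsorted(col, s2_obs[p], side="left")
        pattern_p = tails_obs / n_all
        mean2 = max2 / 2.0
        sd2 = s2.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_signed = (s2_obs - mean2) / np.where(sd2 > 0, sd2, np.inf)
        if combine == "bonferroni":
            p_raw = min(1.0, len(patterns) * pattern_p.min())
        else:  # max-T over the exhaustive null; mean is exactly max2/2
            del tails
            with np.errstate(divide="ignore", invalid="ignore"):
                z_all = np.abs(s2 - mean2) / np.where(sd2 > 0, sd2, np.inf)
            p_raw = float((z_all.max(axis=1) >= np.abs(z_signed).max()).mean())
        counts = tails_obs  # on the exhaustive scale
        best = _best_pattern(counts, z_signed)
        return RainResult(
            statistic=float(s2_obs[best]) / 2.0,
            max_statistic=float(max2[best]) / 2.0,
            p_raw=float(p_raw),
            best_pattern=patterns[best],
            pattern_pvalues=pattern_p,
            pattern_z=z_signed,
            engine="exhaustive",
            n_perm=n_all,
        )

    if engine != "monte_carlo":
        raise ValueError(f"unknown engine {engine!r}")
    pat_idx, pa, pb, n_base, base_of, is_comp, max2_base = _kernel_inputs(
        patterns, sizes
    )
    p_raw, counts_obs, s2_obs, sd_base = batch_permutation_test(
        values[None, :],
        group_of.astype(np.int32),
        n_groups,
        pat_idx,
        pa,
        pb,
        n_base,
        base_of,
        is_comp,
        max2_base,
        int(n_perm),
        int(seed) & 0x7FFFFFFF,
        combine == "bonferroni",
    )
    counts = counts_obs[0]
    mean2 = max2_base[base_of] * 0.5
    sd_logical = sd_base[0, base_of]
    with np.errstate(divide="ignore", invalid="ignore"):
        z_mc = (s2_obs[0] - mean2) / np.where(sd_logical > 0, sd_logical, np.inf)
    best = _best_pattern(counts, z_mc)

    return RainResult(
        statistic=float(s2_obs[0, best]) / 2.0,
        max_statistic=float(max2[best]) / 2.0,
        p_raw=float(p_raw[0]),
        best_pattern=patterns[best],
        pattern_pvalues=(counts + 1.0) / (n_perm + 1.0),
        pattern_z=z_mc,
        engine="monte_carlo",
        n_perm=n_perm,
    )


def bh_adjust(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, float]:
    """Benjamini-Hochberg step-up.

    Returns (adjusted p in input order, discovery flags, critical p), where
    critical p = (k/m) * alpha for k discoveries — the largest raw p a
    discovery may have.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    flags = adjusted < alpha
    k = int(flags.sum())
    critical_p = k / m * alpha
    return adjusted, flags, critical_p


def assign_peak(
    pattern_z: np.ndarray,
    group_means: np.ndarray,
    patterns: list[UmbrellaPattern],
    hours: tuple[float, ...],
) -> float:
    """Assign the peak hour from standardized pattern support.

    Each candidate hour is scored by the summed signed standardized
    statistics (Z) of every pattern peaking there, pooling evidence across
    all trough choices; the hour with the largest total support wins.
    Exact ties are broken by the larger group mean abundance, then by hour
    order. Summing over troughs is far more stable than taking the single
    best (peak, trough) pattern, whose trough choice is noise-sensitive.
    """
    z = np.asarray(pattern_z, dtype=float)
    score = np.zeros(len(hours))
    for i, pat in enumerate(patterns):
        score[pat.peak] += z[i]
    tied = np.flatnonzero(score == score.max())
    best = tied[int(np.argmax(np.asarray(group_means)[tied]))]
    return float(hours[best])


def run_rhythmicity(
    abund: BinAbundance,
    design: SamplingDesign,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    combine: str = "maxt",
    scope: str = "global",
) -> pd.DataFrame:
    """Batch umbrella test over every (bin, gene family) series.

    BH correction is applied once across all series pooled
    (``scope="global"``) or within each bin (``scope="per_bin"``).
    Returns one row per series with statistic, p_raw, p_adjusted, is_diel
    and the assigned peak_hour (NaN for non-discoveries).
    """
    if abund.level != "family":
        raise ValueError("rhythmicity runs on family-level abundances")
    if scope not in ("global", "per_bin"):
        raise ValueError(f"unknown BH scope {scope!r}")
    hours = tuple(design.times_of_day)
    hour_of = {str(s): s.hour for s in design.samples}
    cols = list(abund.values.columns)
    group_of = np.array([hours.index(hour_of[c]) for c in cols], dtype=np.int64)
    values = np.ascontiguousarray(abund.values.to_numpy(dtype=float))
    n_groups = len(hours)
    patterns = enumerate_patterns(n_groups)
    sizes = np.bincount(group_of, minlength=n_groups)
    max2 = _max2(patterns, sizes)
    pat_idx, pa, pb, n_base, base_of, is_comp, max2_base = _kernel_inputs(
        patterns, sizes
    )

    p_raw, counts_obs, s2_obs, sd_base = batch_permutation_test(
        values,
        group_of.astype(np.int32),
        n_groups,
        pat_idx,
        pa,
        pb,
        n_base,
        base_of,
        is_comp,
        max2_base,
        int(n_perm),
        int(seed) & 0x7FFFFFFF,
        combine == "bonferroni",
    )

    idx = abund.values.index
    df = pd.DataFrame(
        {
            "taxon_id": idx.get_level_values(0),
            "gene_family_id": idx.get_level_values(1),
            "p_raw": p_raw,
        }
    )
    best = np.argmin(counts_obs, axis=1)
    df["statistic"] = s2_obs[np.arange(len(df)), best] / 2.0
    df["max_statistic"] = max2[best] / 2.0

    if scope == "global":
        adjusted, flags, _ = bh_adjust(p_raw, alpha)
    else:
        adjusted = np.empty(len(df))
        flags = np.zeros(len(df), dtype=bool)
        for _, sub in df.groupby("taxon_id", sort=False):
            a, f, _ = bh_adjust(df.loc[sub.index, "p_raw"].to_numpy(), alpha)
            adjusted[sub.index] = a
            flags[sub.index] = f
    df["p_adjusted"] = adjusted
    df["is_diel"] = flags

    # signed standardized pattern statistics for peak assignment
    means = np.stack(
        [values[:, group_of == g].mean(axis=1) for g in range(n_groups)], axis=1
    )
    mean2 = max2_base[base_of] * 0.5
    sd_logical = sd_base[:, base_of]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (s2_obs - mean2) / np.where(sd_logical > 0, sd_logical, np.inf)
    peak_hour = np.full(len(df), np.nan)
    for i in np.flatnonzero(flags):
        peak_hour[i] = assign_peak(z[i], means[i], patterns, hours)
    df["peak_hour"] = peak_hour
    df["n_perm"] = n_perm
    df["seed"] = seed
    return df[
        [
            "taxon_id",
            "gene_family_id",
            "statistic",
            "max_statistic",
            "p_raw",
            "p_adjusted",
            "is_diel",
            "peak_hour",
            "n_perm",
            "seed",
        ]
    ]
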