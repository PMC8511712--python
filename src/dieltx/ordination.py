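"""Community ordination and temporal profile summaries.

The observation matrix has one row per (bin, day x hour time point) — 1,152
rows for 48 bins on the 6 x 4 design — with gene-family FPKM averaged over
replicates. Features present in strictly more than a prevalence fraction of
the rows are kept, rows are then normalized to sum 1, Bray-Curtis
dissimilarities are computed, and non-metric multidimensional scaling
(Kruskal stress-1, random restarts) embeds the rows. Per-bin ordinations
run the same machinery on each bin's own time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .containers import BinAbundance
from .design import SamplingDesign


@dataclass
class ObservationMatrix:
    """Rows: (taxon_id, day, hour); columns: gene families; row sums 1."""

    values: pd.DataFrame
    zero_rows: list
    prevalence: float
    n_features_before: int

    @property
    def n_rows(self) -> int:
        return len(self.values)


@dataclass
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    k: int
    n_restarts: int
    converged: bool
    seed: int
    row_labels: list


def build_observation_matrix(
    abund: BinAbundance,
    design: SamplingDesign,
    bins: list[str] | None = None,
    prevalence: float = 0.05,
) -> ObservationMatrix:
    """Replicate-averaged, prevalence-filtered, row-normalized matrix.

    Averaging precedes the prevalence filter; the filter keeps features
    with a positive value in strictly more than ``prevalence`` of all rows;
    normalization comes last. All-zero rows are kept (flagged) so the
    bins x timepoints bookkeeping stays intact.
    """
    if bins is None:
        bins = abund.bins
    hour_of = {str(s): s.hour for s in design.samples}
    day_of = {str(s): s.day for s in design.samples}
    cols = list(abund.values.columns)
    key = pd.MultiIndex.from_arrays(
        [[day_of[c] for c in cols], [hour_of[c] for c in cols]], names=["day", "hour"]
    )
    rows = []
    index = []
    for b in bins:
        mat = abund.values.xs(b, level=0)  # families x samples
        mt = mat.T.set_axis(key).groupby(level=["day", "hour"]).mean()
        for (day, hour), r in mt.iterrows():
            rows.append(r)
            index.append((b, day, hour))
    wide = pd.DataFrame(rows)
    wide.index = pd.MultiIndex.from_tuples(index, names=["taxon_id", "day", "hour"])
    wide = wide.fillna(0.0)

    n_before = wide.shape[1]
    frac = (wide.to_numpy() > 0).mean(axis=0)
    wide = wide.loc[:, frac > prevalence]

    sums = wide.sum(axis=1)
    zero_rows = list(wide.index[sums == 0])
    norm = wide.div(sums.replace(0, 1.0), axis=0)
    return ObservationMatrix(
        values=norm,
        zero_rows=zero_rows,
        prevalence=prevalence,
        n_features_before=n_before,
    )


def bray_curtis(obs: ObservationMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = 1 - 2*sum(min)/(sum u + sum v).

    A pair of all-zero rows is defined as distance 0 (scipy leaves it NaN).
    """
    values = obs.values if isinstance(obs, ObservationMatrix) else obs
    x = values.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis needs non-negative values")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    d[np.isnan(d)] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=values.index, columns=values.index)


def nmds(
    dissimilarity: pd.DataFrame,
    k: int = 3,
    trymax: int = 100,
    seed: int = 0,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF with isotonic regression and restarts.

    Returns the centered best-stress configuration with Kruskal stress-1;
    non-convergence yields ``converged=False`` rather than an exception.
    """
    d = dissimilarity.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if k < 1:
        raise ValueError("k must be >= 1")
    if d.shape[0] <= k + 1:
        # trivially embeddable; SMACOF still runs but may not move
        pass
    coords, stress, n_iter = smacof(
        d,
        metric=False,
        n_components=k,
        n_init=trymax,
        max_iter=max_iter,
        random_state=int(seed) & 0x7FFFFFFF,
        normalized_stress=True,
        return_n_iter=True,
    )
    coords = coords - coords.mean(axis=0, keepdims=True)
    return OrdinationResult(
        coordinates=coords,
        stress=float(stress),
        k=k,
        n_restarts=trymax,
        converged=bool(n_iter < max_iter),
        seed=seed,
        row_labels=list(dissimilarity.index),
    )


def per_bin_ordinations(
    abund: BinAbundance,
    design: SamplingDesign,
    bins: list[str] | None = None,
    k: int = 2,
    trymax: int = 100,
    prevalence: float = 0.05,
    seed: int = 0,
) -> dict[str, OrdinationResult]:
    """Independent NMDS of each bin's own timepoints x features matrix."""
    if bins is None:
        bins = abund.bins
    out = {}
    for i, b in enumerate(bins):
        obs = build_observation_matrix(abund, design, [b], prevalence)
        d = bray_curtis(obs)
        out[b] = nmds(d, k=k, trymax=trymax, seed=seed + i)
    return out


def stress_summary(results: dict[str, OrdinationResult]) -> dict:
    stresses = np.array([r.stress for r in results.values()])
    return {
        "mean_stress": float(stresses.mean()),
        "sd_stress": float(stresses.std(ddof=1)) if len(stresses) > 1 else 0.0,
        "n": len(stresses),
    }


def profile_summary(
    abund: BinAbundance,
    design: SamplingDesign,
    bin_id: str,
    gene_family_id: str,
) -> pd.DataFrame:
    """Per-hour mean, standard error and min-max normalized trace.

    Pools the n = days x replicates observations of each sampling hour;
    SE = SD/sqrt(n) (sample SD). The min-max normalization maps the hourly
    means onto [0, 1]; a constant trace maps to 0.5 everywhere (flagged by
    the ``constant`` column).
    """
    try:
        row = abund.values.loc[(bin_id, gene_family_id)]
    except KeyError:
        raise KeyError(f"family {gene_family_id!r} not present in bin {bin_id!r}")
    hour_of = {str(s): s.hour for s in design.samples}
    values = row.to_numpy(dtype=float)
    hours = np.array([hour_of[c] for c in abund.values.columns])
    recs = []
    for h in design.times_of_day:
        obs = values[hours == h]
        n = obs.size
        sd = obs.std(ddof=1) if n > 1 else 0.0
        recs.append({"hour": h, "n": n, "mean": obs.mean(), "se": sd / np.sqrt(n)})
    df = pd.DataFrame(recs)
    lo, hi = df["mean"].min(), df["mean"].max()
    if hi > lo:
        df["minmax"] = (df["mean"] - lo) / (hi - lo)
        df["constant"] = False
    else:
        df["minmax"] = 0.5
        df["constant"] = True
    return df
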