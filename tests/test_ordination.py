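"""Observation matrix, Bray-Curtis, NMDS and temporal profiles."""

import numpy as np
import pandas as pd
import pytest

from dieltx import (
    BinAbundance,
    GenusSpec,
    bray_curtis,
    build_observation_matrix,
    generate_community,
    nmds,
    per_bin_ordinations,
    profile_summary,
    quantify,
)
from dieltx.ordination import stress_summary
from dieltx.taxonomy import TaxonomyTree


def family_abundance(values: pd.DataFrame) -> BinAbundance:
    """Wrap a (bin, family) x sample frame as a family-level BinAbundance."""
    m = values.groupby(level=0).sum()
    return BinAbundance(values=values, m_bin=m, level="family")


def synthetic_abund(design, n_bins, n_fams, seed=0, diel=False):
    rng = np.random.default_rng(seed)
    hours = np.array([s.hour for s in design.samples])
    rows, idx = [], []
    for b in range(n_bins):
        for f in range(n_fams):
            if diel:
                phase = rng.choice(design.times_of_day)
                mu = 10 * (1 + np.cos(2 * np.pi * (hours - phase) / 24.0)) + 0.5
            else:
                mu = np.full(len(hours), 10.0)
            rows.append(rng.poisson(mu).astype(float))
            idx.append((f"b{b:02d}", f"K{f:05d}"))
    values = pd.DataFrame(rows, columns=design.sample_names,
                          index=pd.MultiIndex.from_tuples(idx, names=["taxon_id", "gene_family_id"]))
    return family_abundance(values)


class TestObservationMatrix:
    def test_48_bins_24_timepoints_1152_rows(self, design48):
        abund = synthetic_abund(design48, 48, 5)
        obs = build_observation_matrix(abund, design48)
        assert obs.n_rows == 1152

    def test_replicate_mean_first(self, design48):
        abund = synthetic_abund(design48, 1, 2, seed=3)
        obs = build_observation_matrix(abund, design48, prevalence=0.0)
        # row (b00, day 1, hour 2) feature K00000 = mean of the two replicates
        v = abund.values.loc[("b00", "K00000")]
        expected = (v["d1_h02.00_r1"] + v["d1_h02.00_r2"]) / 2
        raw_row = obs.values.loc[("b00", 1, 2.0)]
        total = sum(
            (abund.values.loc[("b00", k), "d1_h02.00_r1"]
             + abund.values.loc[("b00", k), "d1_h02.00_r2"]) / 2
            for k in ("K00000", "K00001")
        )
        assert raw_row["K00000"] == pytest.approx(expected / total)

    def test_prevalence_strict_boundary(self, design48):
        """A feature in exactly 57/1152 rows (4.9%) drops; 58 (5.03%) stays."""
        abund = synthetic_abund(design48, 48, 2)
        vals = abund.values.copy()
        # add two all-zero features to every bin, then mark cells positive
        extra = [
            pd.DataFrame(
                0.0,
                index=pd.MultiIndex.from_tuples(
                    [(f"b{b:02d}", tag) for b in range(48)],
                    names=["taxon_id", "gene_family_id"],
                ),
                columns=vals.columns,
            )
            for tag in ("Krare57", "Krare58")
        ]
        vals = pd.concat([vals] + extra).sort_index()
        # set positives: Krare57 in the first 57 (bin, timepoint) cells,
        # Krare58 in the first 58; a cell is (bin, day, hour) = both replicates
        cells = [(f"b{b:02d}", d, h) for b in range(48) for d in (1, 2, 3, 4)
                 for h in (2.0, 6.0, 10.0, 14.0, 18.0, 22.0)]
        for tag, n_cells in (("Krare57", 57), ("Krare58", 58)):
            for (b, d, h) in cells[:n_cells]:
                for r in (1, 2):
                    vals.loc[(b, tag), f"d{d}_h{h:05.2f}_r{r}"] = 5.0
        obs = build_observation_matrix(family_abundance(vals), design48, prevalence=0.05)
        assert "Krare57" not in obs.values.columns  # 57/1152 = 4.9% dropped
        assert "Krare58" in obs.values.columns      # 58/1152 = 5.03% kept

    def test_rows_sum_to_one(self, design48):
        abund = synthetic_abund(design48, 4, 6, seed=1)
        obs = build_observation_matrix(abund, design48)
        sums = obs.values.sum(axis=1)
        nonzero = sums[sums > 0]
        assert np.allclose(nonzero, 1.0, atol=1e-9)

    def test_zero_rows_kept_and_flagged(self, design48):
        abund = synthetic_abund(design48, 2, 2, seed=1)
        vals = abund.values.copy()
        vals.loc[("b00",), :] = 0.0
        obs = build_observation_matrix(family_abundance(vals), design48, prevalence=0.0)
        assert obs.n_rows == 48  # 2 bins x 24 timepoints, zeros retained
        assert len(obs.zero_rows) == 24
        assert all(b == "b00" for b, _, _ in obs.zero_rows)

    def test_filter_then_normalize_order(self, design_small):
        """Dropping a column before normalizing changes the sums -- the
        regression guard for the fixed filter-then-normalize order."""
        idx = pd.MultiIndex.from_tuples(
            [("b0", "Kcommon"), ("b0", "Krare")], names=["taxon_id", "gene_family_id"]
        )
        vals = pd.DataFrame(
            [[3.0, 3.0, 3.0], [1.0, 0.0, 0.0]],
            index=idx, columns=design_small.sample_names,
        )
        obs = build_observation_matrix(family_abundance(vals), design_small, prevalence=0.5)
        # Krare present in 1/3 rows (<= 0.5) -> dropped BEFORE normalization,
        # so the common feature carries full weight 1.0 in every row
        assert list(obs.values.columns) == ["Kcommon"]
        assert np.allclose(obs.values.to_numpy(), 1.0)


class TestBrayCurtis:
    def frame(self, rows):
        return pd.DataFrame(rows)

    def test_hand_value(self):
        d = bray_curtis(self.frame([[0.2, 0.8], [0.5, 0.5]]))
        assert d.iloc[0, 1] == pytest.approx(0.3)

    def test_identical_rows_zero(self):
        d = bray_curtis(self.frame([[0.3, 0.7], [0.3, 0.7]]))
        assert d.iloc[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        d = bray_curtis(self.frame([[1.0, 0.0], [0.0, 1.0]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetric_and_in_range(self):
        rng = np.random.default_rng(2)
        x = self.frame(rng.uniform(size=(12, 5)))
        d = bray_curtis(x).to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0.0)

    def test_double_zero_rows_distance_zero(self):
        d = bray_curtis(self.frame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
        assert d.iloc[0, 1] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(self.frame([[1.0, -0.1]]))


class TestNmds:
    def test_two_points_stress_zero(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]])
        res = nmds(d, k=1, trymax=5, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-6)

    def test_embed_recover_planar_points(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        res = nmds(d, k=2, trymax=20, seed=1)
        assert res.stress < 0.05

    def test_k3_stress_le_k2(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(15, 6))
        d = bray_curtis(pd.DataFrame(x))
        s2 = nmds(d, k=2, trymax=20, seed=2).stress
        s3 = nmds(d, k=3, trymax=20, seed=2).stress
        assert s3 <= s2 + 1e-6

    def test_coordinates_centered(self):
        rng = np.random.default_rng(6)
        d = bray_curtis(pd.DataFrame(rng.uniform(size=(8, 4))))
        res = nmds(d, k=2, trymax=5, seed=0)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nmds(pd.DataFrame([[0.0, 0.2], [0.3, 0.0]]), k=1)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            nmds(pd.DataFrame([[0.1, 0.2], [0.2, 0.0]]), k=1)


class TestPerBin:
    @staticmethod
    def circular_ordering_score(coords, hours_of_rows):
        """Mean distance between time-adjacent vs time-opposite rows."""
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        hours = np.asarray(hours_of_rows)
        adj, opp = [], []
        n = len(hours)
        for i in range(n):
            for j in range(i + 1, n):
                gap = abs(hours[i] - hours[j]) % 24
                gap = min(gap, 24 - gap)
                if gap == 4:
                    adj.append(d[i, j])
                elif gap == 12:
                    opp.append(d[i, j])
        return float(np.mean(adj)), float(np.mean(opp))

    def test_diel_bin_shows_clock_layout(self, design48):
        abund = synthetic_abund(design48, 1, 40, seed=9, diel=True)
        res = per_bin_ordinations(abund, design48, k=2, trymax=10, seed=0,
                                  prevalence=0.0)
        coords = res["b00"].coordinates
        hours = [h for (_, _, h) in res["b00"].row_labels]
        adj, opp = self.circular_ordering_score(coords, hours)
        assert adj < opp  # adjacent times closer than opposite times

    def test_null_bin_no_ordering(self, design48):
        abund = synthetic_abund(design48, 1, 40, seed=10, diel=False)
        res = per_bin_ordinations(abund, design48, k=2, trymax=10, seed=0,
                                  prevalence=0.0)
        coords = res["b00"].coordinates
        hours = [h for (_, _, h) in res["b00"].row_labels]
        adj, opp = self.circular_ordering_score(coords, hours)
        assert adj > 0.5 * opp  # no strong clock-like separation

    def test_stress_summary(self, design48):
        abund = synthetic_abund(design48, 3, 10, seed=11)
        res = per_bin_ordinations(abund, design48, k=2, trymax=5, seed=0)
        s = stress_summary(res)
        assert s["n"] == 3 and s["mean_stress"] >= 0


class TestProfileSummary:
    def test_n8_and_se(self, design48):
        abund = synthetic_abund(design48, 1, 3, seed=12)
        df = profile_summary(abund, design48, "b00", "K00001")
        assert (df["n"] == 8).all()
        assert len(df) == 6

    def test_constant_series(self, design48):
        idx = pd.MultiIndex.from_tuples([("b0", "K1")], names=["taxon_id", "gene_family_id"])
        vals = pd.DataFrame([[7.0] * 48], index=idx, columns=design48.sample_names)
        df = profile_summary(family_abundance(vals), design48, "b0", "K1")
        assert (df["se"] == 0).all()
        assert df["constant"].all()
        assert (df["minmax"] == 0.5).all()

    def test_minmax_hand_example(self, design48):
        means = {2.0: 2, 6.0: 4, 10.0: 6, 14.0: 8, 18.0: 6, 22.0: 4}
        idx = pd.MultiIndex.from_tuples([("b0", "K1")], names=["taxon_id", "gene_family_id"])
        row = [float(means[s.hour]) for s in design48.samples]
        vals = pd.DataFrame([row], index=idx, columns=design48.sample_names)
        df = profile_summary(family_abundance(vals), design48, "b0", "K1")
        assert np.allclose(df["minmax"], [0, 1 / 3, 2 / 3, 1, 2 / 3, 1 / 3])

    def test_missing_family_rejected(self, design48):
        abund = synthetic_abund(design48, 1, 2)
        with pytest.raises(KeyError):
            profile_summary(abund, design48, "b00", "Kmissing")
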