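"""Sample/glycan clustering, trajectories, motif ANOVA, time-series fits
and the sulfation-branching test."""

import numpy as np
import pandas as pd
import pytest

import glycolac as gl
from glycolac.tables import CLRMatrix

from conftest import random_structures


def clr_from(arr, meta=None, columns=None):
    df = pd.DataFrame(np.asarray(arr, dtype=float),
                      columns=columns or [f"m{i}" for i in range(np.shape(arr)[1])])
    return CLRMatrix(df, meta=meta)


class TestClusterSamples:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (8, 5)), rng.normal(5, 0.1, (8, 5))])
        res = gl.cluster_samples(clr_from(x), k=2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_duplicated_rows_co_cluster_at_height_zero(self):
        x = np.array([[1.0, 2.0, 3.0]] * 2 + [[9.0, 9.0, 9.0]] * 2)
        res = gl.cluster_samples(clr_from(x), k=2)
        assert res.labels.iloc[0] == res.labels.iloc[1]
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            gl.cluster_samples(clr_from(np.eye(3)), k=5)

    def test_glycan_row_clustering_transposes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 10))
        res = gl.cluster_samples(clr_from(x), k=2, rows="glycans")
        assert len(res.labels) == 10

    def test_timepoint_recovery_on_low_noise_cohort(self, low_noise_cohort):
        table, _ = low_noise_cohort
        m = gl.preprocess(table, gamma=0.0)
        res = gl.cluster_samples(m, k=4)
        score = gl.clustering_scores(res.labels.to_numpy(), table.meta["day"].to_numpy())
        assert score.ari >= 0.9


class TestClusteringScores:
    def test_identical_partitions(self):
        s = gl.clustering_scores([1, 1, 2, 2, 3], [5, 5, 7, 7, 9])
        assert s.ari == pytest.approx(1.0)
        assert s.nmi == pytest.approx(1.0)

    def test_hand_computed_negative_ari(self):
        s = gl.clustering_scores([1, 1, 2, 2], [1, 2, 1, 2])
        assert s.ari == pytest.approx(-0.5)

    def test_random_labelings_center_on_zero(self):
        rng = np.random.default_rng(2)
        aris = [
            gl.clustering_scores(rng.integers(0, 4, 40), rng.integers(0, 4, 40)).ari
            for _ in range(1000)
        ]
        assert abs(np.mean(aris)) < 3 * np.std(aris) / np.sqrt(len(aris)) + 0.005

    def test_bounds_on_random_partition_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            a = rng.integers(0, 5, 25)
            b = rng.integers(0, 5, 25)
            s = gl.clustering_scores(a, b)
            assert -1.0 <= s.ari <= 1.0
            assert 0.0 <= s.nmi <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gl.clustering_scores([1, 2], [1, 2, 3])


class TestTrajectories:
    def test_constant_cluster_is_flat_with_zero_width_ci(self):
        data = pd.DataFrame(
            {"g1": [30.0] * 8, "g2": [70.0] * 8},
            index=[f"s{i}" for i in range(8)],
        )
        meta = pd.DataFrame(
            {"individual": list("AABBCCDD"), "day": [2, 7] * 4}, index=data.index
        )
        t = gl.AbundanceTable(data, meta)
        traj = gl.cluster_trajectories(t, {"g1": "c1", "g2": "c2"})
        c1 = traj[traj.cluster == "c1"]
        assert (c1["mean"] == 30.0).all()
        assert (c1.ci_low == c1.ci_high).all()

    def test_planted_early_cluster_decreases(self, low_noise_cohort):
        table, truth = low_noise_cohort
        traj = gl.cluster_trajectories(table, truth.cluster_assignments)
        early = traj[traj.cluster == "Early"].sort_values("day")
        assert early["mean"].iloc[0] > early["mean"].iloc[-1]
        assert (early["mean"].iloc[1:] < 1e-9).all()  # absent after day 2
        late = traj[traj.cluster == "Late"].sort_values("day")
        assert late["mean"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert late["mean"].is_monotonic_increasing

    def test_cluster_totals_conserve_percentages(self, default_cohort):
        table, truth = default_cohort
        traj = gl.cluster_trajectories(table, truth.cluster_assignments)
        sums = traj.groupby("day")["mean"].sum()
        assert np.allclose(sums, 100.0)

    def test_unassigned_glycan_rejected(self, default_cohort):
        table, truth = default_cohort
        partial = dict(list(truth.cluster_assignments.items())[:-1])
        with pytest.raises(ValueError, match="without cluster"):
            gl.cluster_trajectories(table, partial)


class TestMotifAnova:
    def test_two_identical_groups_give_f_near_zero(self):
        x = np.tile(np.arange(6.0), (2, 1)).T  # same values in both features
        m = clr_from(x)
        rows = gl.motif_anova(m, np.array([0, 1, 0, 1, 0, 1]))
        assert all(r.p > 0.5 for r in rows)

    def test_planted_group_effect_detected_with_tukey(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.1, (18, 10))
        groups = np.repeat([0, 1, 2], 6)
        x[groups == 2, 0] += 10.0
        rows = gl.motif_anova(clr_from(x), groups)
        by_q = sorted(rows, key=lambda r: r.q)
        assert by_q[0].motif == "m0"
        assert by_q[0].tukey is not None
        sig_pairs = by_q[0].tukey[by_q[0].tukey.reject]
        pairs = {tuple(sorted((row.group1, row.group2))) for row in sig_pairs.itertuples()}
        assert pairs == {(0, 2), (1, 2)}

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(100):
            x = rng.normal(size=(18, 5))
            rows = gl.motif_anova(clr_from(x), np.repeat([0, 1, 2], 6))
            ps.extend(r.p for r in rows)
        assert abs(np.mean(ps) - 0.5) < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            gl.motif_anova(clr_from(np.eye(3)), np.array([0, 1, 2]))


class TestTimeSeriesFit:
    def test_constant_series(self):
        meta = pd.DataFrame({"individual": ["A"] * 4, "day": [2, 7, 13, 18]})
        fits = gl.timeseries_fit(clr_from(np.ones((4, 1)), meta=meta))
        assert fits[0].beta == 0.0
        assert fits[0].p == pytest.approx(1.0)

    def test_noise_free_slope_recovered_exactly(self):
        days = np.array([2.0, 7.0, 13.0, 18.0] * 5)
        y = 0.7 * days + 1.0
        fits = gl.timeseries_fit(clr_from(y[:, None]), times=days)
        assert fits[0].beta == pytest.approx(0.7, abs=1e-12)
        assert fits[0].p < 1e-12

    def test_slope_recovery_under_noise(self):
        betas = []
        for rep in range(200):
            df = gl.simulate_motif_timeseries(slope=0.5, noise_sd=0.2, seed=rep)
            fits = gl.timeseries_fit(clr_from(df[["value"]].to_numpy()),
                                     times=df["day"].to_numpy())
            betas.append(fits[0].beta)
        assert np.mean(betas) == pytest.approx(0.5, abs=0.05)

    def test_time_rescaling_equivariance(self):
        rng = np.random.default_rng(6)
        days = np.array([2.0, 7.0, 13.0, 18.0] * 3)
        y = rng.normal(size=len(days))[:, None]
        f1 = gl.timeseries_fit(clr_from(y), times=days)
        f2 = gl.timeseries_fit(clr_from(y), times=days * 2)
        assert f2[0].beta == pytest.approx(f1[0].beta / 2)

    def test_needs_three_distinct_times(self):
        with pytest.raises(ValueError, match="distinct time"):
            gl.timeseries_fit(clr_from(np.ones((4, 1))), times=[1, 1, 2, 2])


class TestSulfationBranching:
    @staticmethod
    def planted(seed, cap, cap_sulf, n=250):
        params = gl.GrammarParams(
            p_extend=0.7, p_branch=0.3, p_sulf6_glcnac=0.4,
            p_cap=cap, p_cap_sulfated=cap_sulf, max_size=20, seed=seed,
        )
        return gl.simulate_structures(n, params)

    def test_extreme_case_detects_negative_direction(self):
        structures = self.planted(seed=0, cap=1.0, cap_sulf=0.0)
        W, p, direction = gl.sulfation_branching_test(structures)
        assert direction == -1
        assert p < 0.05

    def test_identical_rates_report_no_effect(self):
        # hand-built strata with exactly equal extension rates
        s_ext = gl.parse_iupac("Galβ1-4GlcNAc6Sβ1-3Galβ1-4Glc")
        u_ext = gl.parse_iupac("Galβ1-4GlcNAcβ1-3Galβ1-4Glc")
        structures = []
        for k in range(6):  # six size strata via appended LacNAc units
            pad = "Galβ1-4GlcNAcβ1-3" * k
            structures.append(gl.parse_iupac(pad + "Galβ1-4GlcNAc6Sβ1-3Galβ1-4Glc"))
            structures.append(gl.parse_iupac(pad + "Galβ1-4GlcNAcβ1-3Galβ1-4Glc"))
        W, p, direction = gl.sulfation_branching_test(structures)
        assert (W, p, direction) == (0.0, 1.0, 0)

    def test_power_on_planted_extension_gap(self):
        detected = 0
        runs = 60
        for rep in range(runs):
            structures = self.planted(seed=1000 + rep, cap=0.8, cap_sulf=0.2)
            try:
                W, p, direction = gl.sulfation_branching_test(structures)
            except ValueError:
                continue
            detected += direction == -1 and p < 0.05
        assert detected / runs >= 0.95

    def test_swapping_annotations_flips_direction(self):
        structures = self.planted(seed=7, cap=0.9, cap_sulf=0.3)
        W1, p1, d1 = gl.sulfation_branching_test(structures)

        def swap(g):
            out = gl.parse_iupac(gl.write_iupac(g))
            for nid, res in list(out.nodes.items()):
                if res.base == "GlcNAc":
                    mods = set(res.modifications)
                    if (6, "S") in mods:
                        mods.discard((6, "S"))
                    else:
                        mods.add((6, "S"))
                    out.nodes[nid] = gl.Monosaccharide("GlcNAc", frozenset(mods))
            return out

        swapped = [swap(g) for g in structures]
        W2, p2, d2 = gl.sulfation_branching_test(swapped)
        assert d2 == -d1
        assert W1 == pytest.approx(W2)

    def test_insufficient_strata_is_an_error(self):
        structures = [gl.parse_iupac("Galβ1-4GlcNAc6Sβ1-3Galβ1-4Glc"),
                      gl.parse_iupac("Galβ1-4GlcNAcβ1-3Galβ1-4Glc")]
        with pytest.raises(ValueError, match="strata"):
            gl.sulfation_branching_test(structures)
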