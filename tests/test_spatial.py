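"""Normalization, enrichment scores, purity, HMM CN inference, matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scclonal import spatial as sp
from scclonal.containers import STSpotMatrix


def _st(counts, positions=None, chroms=None):
    counts = np.asarray(counts)
    n, m = counts.shape
    spots = pd.DataFrame({"x": np.arange(n), "y": np.zeros(n, int)},
                         index=pd.Index([f"s{i}" for i in range(n)],
                                        name="barcode"))
    genes = pd.DataFrame(
        {"chrom": chroms or ["chr1"] * m,
         "start": positions if positions is not None
         else np.arange(m) * 1_000_000},
        index=pd.Index([f"g{i}" for i in range(m)], name="gene"))
    return STSpotMatrix(spots, genes, counts)


class TestNormalize:
    def test_proportional_spots_identical_after_normalization(self):
        st = _st(np.array([[10, 20, 30], [20, 40, 60]]))
        norm, kept = sp.normalize_counts(st)
        assert np.allclose(norm[0], norm[1])

    def test_global_doubling_invariant(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(10, (4, 6))
        n1, _ = sp.normalize_counts(_st(c))
        n2, _ = sp.normalize_counts(_st(2 * c))
        # scaling to the median depth removes a global factor
        assert np.allclose(n1, n2)

    def test_zero_depth_spot_dropped(self):
        st = _st(np.array([[5, 5], [0, 0]]))
        norm, kept = sp.normalize_counts(st)
        assert list(kept) == ["s0"]

    def test_monotone_in_raw_counts_within_spot(self):
        st = _st(np.array([[1, 5, 25, 125]]))
        norm, _ = sp.normalize_counts(st)
        assert (np.diff(norm[0]) > 0).all()


class TestSsgsea:
    def test_weight_zero_reversal_negates_score(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        in_set = np.zeros(200, bool)
        in_set[rng.choice(200, 20, replace=False)] = True
        s = sp.ssgsea_score(x, in_set, weight=0)
        s_rev = sp.ssgsea_score(-x, in_set, weight=0)
        assert s_rev == pytest.approx(-s, abs=1e-12)

    def test_top_ranked_set_positive(self):
        x = np.arange(100, 0, -1, dtype=float)
        in_set = np.zeros(100, bool)
        in_set[:10] = True              # the top-expressed genes
        assert sp.ssgsea_score(x, in_set) > 0

    def test_random_sets_centered_at_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 300)
        scores = []
        for _ in range(1000):
            in_set = np.zeros(300, bool)
            in_set[rng.choice(300, 20, replace=False)] = True
            scores.append(sp.ssgsea_score(x, in_set, weight=0))
        scores = np.array(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * se + 1e-3

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            sp.ssgsea_score(np.ones(10), np.zeros(10, bool))


class TestPurity:
    def test_synthetic_split_matches_truth(self, small_bundle):
        norm, kept = sp.normalize_counts(small_bundle.st)
        pur = sp.purity_score(norm, small_bundle.st.genes.index,
                              small_bundle.signatures["stromal"],
                              small_bundle.signatures["immune"])
        truth = small_bundle.spot_truth.loc[kept]
        tum = (truth["region"] != "stroma").to_numpy()
        assert (pur["purity"][tum] > 0.7).mean() >= 0.99
        assert (pur["purity"][~tum] <= 0.7).all()

    def test_order_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        norm = rng.normal(2, 1, (6, 120))
        genes = pd.Index([f"g{i}" for i in range(120)])
        sig_a = [f"g{i}" for i in range(10)]
        sig_b = [f"g{i}" for i in range(10, 20)]
        p1 = sp.purity_score(norm, genes, sig_a, sig_b)
        p2 = sp.purity_score(np.exp(norm), genes, sig_a, sig_b)
        assert (p1["purity"].rank() == p2["purity"].rank()).all()

    def test_missing_signature_genes_error(self):
        norm = np.ones((2, 5))
        genes = pd.Index([f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            sp.purity_score(norm, genes, ["absent1"], ["g0"])


class TestViterbi:
    def _exhaustive(self, obs, means, var, stay):
        n_states, n = len(means), len(obs)
        log_emit = (-0.5 * (obs[:, None] - means[None, :]) ** 2 / var
                    - 0.5 * np.log(2 * np.pi * var))
        log_tr = np.full((n_states, n_states),
                         np.log((1 - stay) / (n_states - 1)))
        np.fill_diagonal(log_tr, np.log(stay))
        best, best_ll = None, -np.inf
        for path in itertools.product(range(n_states), repeat=n):
            ll = -np.log(n_states) + log_emit[0, path[0]]
            for t in range(1, n):
                ll += log_tr[path[t - 1], path[t]] + log_emit[t, path[t]]
            if ll > best_ll:
                best, best_ll = path, ll
        return np.array(best)

    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 9), (2, 12)])
    def test_matches_exhaustive_path_search(self, seed, n):
        rng = np.random.default_rng(seed)
        means = np.array([-0.2, 0.0, 0.2])
        obs = rng.normal(0, 0.25, n)
        obs[: n // 3] += 0.2
        states = sp.viterbi_decode(obs, means, 0.04, 0.9)
        expected = self._exhaustive(obs, means, 0.04, 0.9)
        assert (states == expected).all()

    def test_constant_observation_stays_in_one_state(self):
        obs = np.full(20, 0.2)
        states = sp.viterbi_decode(obs, np.array([-0.2, 0.0, 0.2]),
                                   0.01, 1 - 1e-4)
        assert (states == 2).all()


class TestSmoothing:
    def test_shift_equivariance_along_gene_order(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (2, 60))
        chroms = np.array(["chr1"] * 60)
        s1 = sp.smooth_profiles(x, chroms, 7)
        s2 = sp.smooth_profiles(np.roll(x, 10, axis=1), chroms, 7)
        # interior values are shifted copies (edges differ)
        assert np.allclose(s1[:, 15:40], s2[:, 25:50])

    def test_window_respects_chromosomes(self):
        x = np.zeros((1, 20))
        x[0, 10:] = 1.0
        chroms = np.array(["chr1"] * 10 + ["chr2"] * 10)
        s = sp.smooth_profiles(x, chroms, 5)
        assert (s[0, :10] == 0).all() and (s[0, 10:] == 1).all()


class TestInference:
    def test_dosage_free_simulation_all_neutral(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(8, (60, 400))
        st = _st(counts, positions=np.arange(400) * 100_000)
        norm, kept = sp.normalize_counts(st)
        spots = list(kept)
        inf = sp.infer_cn_profiles(norm, kept, st.genes, spots[:30],
                                   spots[30:], window=21, seed=0)
        for p in inf.profiles:
            assert (p.states == 0).all()

    def test_two_clones_recovered_with_segment_overlap(self, small_bundle):
        cfg = small_bundle.config
        norm, kept = sp.normalize_counts(small_bundle.st)
        pur = sp.purity_score(norm, small_bundle.st.genes.index,
                              small_bundle.signatures["stromal"],
                              small_bundle.signatures["immune"])
        tumor = list(kept[pur["is_tumor"].to_numpy()])
        ref = list(kept[~pur["is_tumor"].to_numpy()])
        inf = sp.infer_cn_profiles(norm, kept, small_bundle.st.genes,
                                   tumor, ref, window=21, seed=0)
        assert len(inf.profiles) >= cfg.n_clones
        # per-subgroup gain/loss calls overlap the planted segments
        genes = inf.gene_table
        fine = np.minimum(
            (genes["chrom"].str[3:].astype(int).to_numpy() - 1)
            * cfg.bins_per_chromosome
            + genes["start"].to_numpy() // 20_000, cfg.n_bins - 1)
        truth = small_bundle.spot_truth
        for p in inf.profiles:
            clone_votes = truth.loc[p.spots, "clone"]
            c = int(clone_votes.mode()[0])
            if c < 0:
                continue
            cn = small_bundle.panel.total(
                small_bundle.panel.base_key(c))[fine]
            ts = np.sign(cn.astype(int) - 2)
            for state in (-1, 1):
                want = ts == state
                got = p.states == state
                if want.any():
                    j = (want & got).sum() / (want | got).sum()
                    assert j >= 0.7

    def test_clone_specific_deletion_called_only_in_matching_subgroup(
            self, small_bundle):
        cfg = small_bundle.config
        panel = small_bundle.panel
        norm, kept = sp.normalize_counts(small_bundle.st)
        pur = sp.purity_score(norm, small_bundle.st.genes.index,
                              small_bundle.signatures["stromal"],
                              small_bundle.signatures["immune"])
        tumor = list(kept[pur["is_tumor"].to_numpy()])
        ref = list(kept[~pur["is_tumor"].to_numpy()])
        inf = sp.infer_cn_profiles(norm, kept, small_bundle.st.genes,
                                   tumor, ref, window=21, seed=0)
        genes = inf.gene_table
        fine = np.minimum(
            (genes["chrom"].str[3:].astype(int).to_numpy() - 1)
            * cfg.bins_per_chromosome
            + genes["start"].to_numpy() // 20_000, cfg.n_bins - 1)
        cn0 = panel.total(panel.base_key(0))[fine]
        cn1 = panel.total(panel.base_key(1))[fine]
        private_loss = (cn1 < 2) & (cn0 == 2)
        if not private_loss.any():
            pytest.skip("no clone-1-private loss planted on gene panel")
        truth = small_bundle.spot_truth
        for p in inf.profiles:
            c = int(truth.loc[p.spots, "clone"].mode()[0])
            frac_loss = (p.states[private_loss] == -1).mean()
            if c == 1:
                assert frac_loss >= 0.5
            elif c == 0:
                assert frac_loss <= 0.2


class TestMatching:
    def test_shuffled_gene_positions_degrade_matching(self, small_bundle):
        from scclonal.simulate import aggregate_profile, make_coarse_bins
        from scclonal.containers import CloneProfile
        cfg = small_bundle.config
        norm, kept = sp.normalize_counts(small_bundle.st)
        pur = sp.purity_score(norm, small_bundle.st.genes.index,
                              small_bundle.signatures["stromal"],
                              small_bundle.signatures["immune"])
        tumor = list(kept[pur["is_tumor"].to_numpy()])
        ref = list(kept[~pur["is_tumor"].to_numpy()])
        profs = {}
        for c in range(cfg.n_clones):
            m = aggregate_profile(
                cfg, small_bundle.panel.total(small_bundle.panel.base_key(c)))
            profs[f"clone{c}"] = CloneProfile(f"clone{c}", m, np.round(m),
                                              np.zeros_like(m), 10)
        coarse = make_coarse_bins(cfg)
        inf = sp.infer_cn_profiles(norm, kept, small_bundle.st.genes,
                                   tumor, ref, window=21, seed=0)
        good = sp.match_st_to_scdna(inf, profs, coarse)
        cors_good = good[[c for c in good.columns
                          if c.startswith("cor_")]].max(axis=1)
        rng = np.random.default_rng(9)
        shuffled = small_bundle.st.genes.copy()
        perm = rng.permutation(len(shuffled))
        shuffled["chrom"] = shuffled["chrom"].to_numpy()[perm]
        shuffled["start"] = shuffled["start"].to_numpy()[perm]
        inf_s = sp.infer_cn_profiles(norm, kept, shuffled, tumor, ref,
                                     window=21, seed=0)
        bad = sp.match_st_to_scdna(inf_s, profs, coarse)
        cors_bad = bad[[c for c in bad.columns
                        if c.startswith("cor_")]].max(axis=1)
        assert cors_good.min() > 0.8
        assert cors_bad.max() < 0.5


class TestPositional:
    def _setup(self):
        rng = np.random.default_rng(10)
        n_genes = 300
        base = rng.lognormal(1.5, 0.4, n_genes)
        set_a = [f"g{i}" for i in range(20)]
        set_b = [f"g{i}" for i in range(20, 40)]
        rows = []
        kinds = []
        for kind, boost_a, boost_b in (("a", 3.0, 1.0), ("b", 1.0, 3.0),
                                       ("stroma", 1.0, 1.0)):
            for _ in range(15):
                mean = base.copy()
                mean[:20] *= boost_a
                mean[20:40] *= boost_b
                rows.append(rng.poisson(mean))
                kinds.append(kind)
        st = _st(np.array(rows))
        norm, kept = sp.normalize_counts(st)
        return norm, kept, st.genes.index, set_a, set_b, kinds

    def test_planted_spots_assigned_with_bonferroni(self):
        norm, kept, genes, set_a, set_b, kinds = self._setup()
        res = sp.positional_enrichment(norm, kept, genes,
                                       {"A": set_a, "B": set_b}, seed=0)
        kinds = pd.Series(kinds, index=res.index)
        got_a = res.loc[kinds == "a", "assigned"]
        got_b = res.loc[kinds == "b", "assigned"]
        # no cross-assignment, and nearly all planted spots significant
        assert not (got_a == "B").any() and not (got_b == "A").any()
        assert (got_a == "A").mean() >= 0.9
        assert (got_b == "B").mean() >= 0.9

    def test_stromal_spots_unassigned(self):
        norm, kept, genes, set_a, set_b, kinds = self._setup()
        res = sp.positional_enrichment(norm, kept, genes,
                                       {"A": set_a, "B": set_b}, seed=0)
        stroma = [s for s, k in zip(res.index, kinds) if k == "stroma"]
        assert (res.loc[stroma, "assigned"] == "unassigned").mean() >= 0.9

    def test_swapping_sets_swaps_assignments(self):
        norm, kept, genes, set_a, set_b, kinds = self._setup()
        r1 = sp.positional_enrichment(norm, kept, genes,
                                      {"A": set_a, "B": set_b}, seed=0)
        r2 = sp.positional_enrichment(norm, kept, genes,
                                      {"A": set_b, "B": set_a}, seed=0)
        swap = {"A": "B", "B": "A", "unassigned": "unassigned"}
        assert (r1["assigned"].map(swap) == r2["assigned"]).all()

    def test_bonferroni_never_below_raw(self):
        norm, kept, genes, set_a, set_b, _ = self._setup()
        res = sp.positional_enrichment(norm, kept, genes,
                                       {"A": set_a, "B": set_b}, seed=0)
        assert (res["p_bonferroni"] >= res["p"] - 1e-15).all()


class TestCellCycle:
    def test_no_elevation_all_g1(self):
        rng = np.random.default_rng(11)
        norm = rng.normal(2, 0.1, (20, 200))
        genes = pd.Index([f"g{i}" for i in range(200)])
        s_genes = [f"g{i}" for i in range(10)]
        g2m = [f"g{i}" for i in range(10, 20)]
        df = sp.cell_cycle_score(norm, pd.Index(range(20)), genes,
                                 s_genes, g2m, seed=0)
        assert (df["phase"] == "G1").mean() >= 0.9

    def test_planted_g2m_spots_detected(self):
        rng = np.random.default_rng(12)
        norm = rng.normal(2, 0.1, (40, 200))
        norm[:20, 10:20] += 1.5          # G2M genes elevated
        genes = pd.Index([f"g{i}" for i in range(200)])
        s_genes = [f"g{i}" for i in range(10)]
        g2m = [f"g{i}" for i in range(10, 20)]
        df = sp.cell_cycle_score(norm, pd.Index(range(40)), genes,
                                 s_genes, g2m, seed=0)
        assert (df["phase"][:20] == "G2M").mean() >= 0.9

    def test_phase_proportions_partition(self):
        rng = np.random.default_rng(13)
        norm = rng.normal(2, 0.3, (30, 200))
        genes = pd.Index([f"g{i}" for i in range(200)])
        df = sp.cell_cycle_score(norm, pd.Index(range(30)), genes,
                                 [f"g{i}" for i in range(8)],
                                 [f"g{i}" for i in range(8, 16)], seed=0)
        props = df["phase"].value_counts(normalize=True)
        assert props.sum() == pytest.approx(1.0)

    def test_too_few_genes_for_binning_raises(self):
        norm = np.ones((5, 20))
        genes = pd.Index([f"g{i}" for i in range(20)])
        with pytest.raises(ValueError):
            sp.cell_cycle_score(norm, pd.Index(range(5)), genes,
                                ["g0"], ["g1"], n_bins=24)
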