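import subprocess
import textwrap

import numpy as np
import pytest

from tipchron.phylo import (
    Alignment,
    PruningEngine,
    SubstModel,
    coalescent_log_density,
    distance_matrix,
    empirical_base_freqs,
    f84_distance,
    hky_transition_matrix,
    log_likelihood,
)
from tipchron.simulate import simulate_coalescent_tree, simulate_sequences
from tipchron.tree import TimeTree

from .oracles import enumeration_log_likelihood, k80_distance, pmatrix_expm


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, model):
        np.testing.assert_allclose(
            hky_transition_matrix(model, 0.0), np.eye(4), atol=1e-12
        )

    def test_negative_time_rejected(self, model):
        with pytest.raises(ValueError, match="negative"):
            hky_transition_matrix(model, -1.0)

    def test_jc69_reduction(self):
        # kappa=1 with uniform frequencies collapses HKY to Jukes-Cantor
        m = SubstModel(kappa=1.0, base_freqs=np.full(4, 0.25), alpha=1.0, rate=1.0)
        for d in (0.01, 0.1, 0.75, 2.0):
            P = m.transition_matrices(np.array([d]))[0]
            diag = 0.25 + 0.75 * np.exp(-4 * d / 3)
            off = 0.25 - 0.25 * np.exp(-4 * d / 3)
            expected = np.full((4, 4), off)
            np.fill_diagonal(expected, diag)
            np.testing.assert_allclose(P, expected, atol=1e-12)

    @pytest.mark.parametrize("kappa,d", [(2.0, 0.05), (8.0, 0.5), (20.0, 3.0)])
    def test_matches_matrix_exponential(self, freqs, kappa, d):
        m = SubstModel(kappa=kappa, base_freqs=freqs, alpha=0.5, rate=1.0)
        P = m.transition_matrices(np.array([d]))[0]
        np.testing.assert_allclose(P, pmatrix_expm(kappa, freqs, d), atol=1e-10)

    def test_rows_sum_to_one_and_detailed_balance(self, model, freqs):
        P = hky_transition_matrix(model, 5e5, category_rate=1.7)
        np.testing.assert_allclose(P.sum(axis=1), np.ones(4), atol=1e-10)
        flux = freqs[:, None] * P
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    def test_long_time_limit_is_stationary(self, freqs):
        m = SubstModel(kappa=8.0, base_freqs=freqs, alpha=0.5, rate=1.0)
        P = m.transition_matrices(np.array([100.0]))[0]
        np.testing.assert_allclose(P, np.tile(freqs, (4, 1)), atol=1e-9)


class TestLikelihood:
    def test_matches_enumeration_on_four_taxa(self, four_taxon_tree, freqs):
        m = SubstModel(kappa=5.0, base_freqs=freqs, alpha=0.7, rate=3e-8)
        aln = simulate_sequences(four_taxon_tree, 3e-8, 5.0, 0.7, freqs, 200, seed=9)
        ll = log_likelihood(four_taxon_tree, aln, m)
        pats, wts = aln.site_patterns()
        order = [aln.ids.index(l) for l in four_taxon_tree.labels]
        ll_enum, _ = enumeration_log_likelihood(
            four_taxon_tree, pats[order], wts.astype(float), m
        )
        assert ll == pytest.approx(ll_enum, abs=1e-8)

    def test_all_missing_alignment_has_zero_loglik(self, four_taxon_tree, model):
        aln = Alignment(list(four_taxon_tree.labels), ["NNN-N"] * 4)
        # likelihood 1 per site, up to rounding of the frequency simplex
        assert log_likelihood(four_taxon_tree, aln, model) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_zero_divergence_limit_is_log_base_freq(self, freqs):
        tree = TimeTree(
            ["a", "b"],
            parent=[2, 2, -1],
            children=[[-1, -1], [-1, -1], [0, 1]],
            ages=[0.0, 0.0, 1e-9],
        )
        m = SubstModel(kappa=8.0, base_freqs=freqs, alpha=0.5, rate=3e-8)
        aln = Alignment(["a", "b"], ["C", "C"])
        assert log_likelihood(tree, aln, m) == pytest.approx(np.log(freqs[1]), abs=1e-6)

    def test_invariant_to_tip_order(self, serial_tree, small_alignment, model):
        ll1 = log_likelihood(serial_tree, small_alignment, model)
        rev = Alignment(small_alignment.ids[::-1], small_alignment.rows[::-1])
        ll2 = log_likelihood(serial_tree, rev, model)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_label_mismatch_rejected(self, serial_tree, model):
        aln = Alignment(["nope"], ["ACGT"])
        with pytest.raises(ValueError, match="absent"):
            log_likelihood(serial_tree, aln, model)

    def test_incremental_updates_match_fresh_engine(self, serial_tree, model, freqs):
        aln = simulate_sequences(serial_tree, 3e-8, 8.0, 0.5, freqs, 1_000, seed=3)
        tree = serial_tree.copy()
        eng = PruningEngine(tree, aln, model)
        rng = np.random.default_rng(12)
        ll = eng.log_likelihood()
        for _ in range(100):
            node = int(rng.integers(0, tree.n_nodes))
            par = int(tree.parent[node])
            if node >= tree.n_tips:
                lo = max(tree.ages[int(c)] for c in tree.children[node])
                hi = tree.ages[par] if par != -1 else tree.ages[node] * 1.2 + 1.0
            else:
                lo, hi = 0.0, tree.ages[par]
            if hi <= lo:
                continue
            tree.ages[node] = rng.uniform(lo, hi)
            ll = eng.node_age_changed(node)
        fresh = PruningEngine(tree, aln, model).log_likelihood()
        assert ll == pytest.approx(fresh, abs=1e-9)

    def test_scaled_engine_agrees_with_unscaled(self, serial_tree, model, freqs):
        aln = simulate_sequences(serial_tree, 3e-8, 8.0, 0.5, freqs, 500, seed=4)
        plain = PruningEngine(serial_tree, aln, model, scaling=False).log_likelihood()
        scaled = PruningEngine(serial_tree, aln, model, scaling=True).log_likelihood()
        assert plain == pytest.approx(scaled, rel=1e-12)


class TestCoalescentDensity:
    def test_two_tip_closed_form(self, two_tip_tree):
        N = 5e4
        expected = -np.log(N) - 12_345.0 / N
        assert coalescent_log_density(two_tip_tree, N) == pytest.approx(expected)

    def test_serial_density_matches_interval_sum(self, serial_tree):
        # independent re-derivation: explicit python loop over intervals
        N = 7e4
        events = sorted(
            [(a, +1) for a in serial_tree.tip_ages()]
            + [(float(serial_tree.ages[n]), -1)
               for n in range(serial_tree.n_tips, serial_tree.n_nodes)],
            key=lambda e: (e[0], -e[1]),
        )
        logp, k, t_prev = 0.0, 0, events[0][0]
        for t, kind in events:
            logp -= k * (k - 1) / 2 * (t - t_prev) / N
            t_prev = t
            if kind > 0:
                k += 1
            else:
                logp -= np.log(N)
                k -= 1
        assert coalescent_log_density(serial_tree, N) == pytest.approx(logp)

    def test_density_decreases_with_pop_size_for_short_tree(self, two_tip_tree):
        # for a recent coalescence the density peaks at small N
        vals = [
            coalescent_log_density(two_tip_tree, N) for N in (2e4, 4e4, 8e4, 1.6e5)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_pop_size(self, two_tip_tree):
        with pytest.raises(ValueError):
            coalescent_log_density(two_tip_tree, 0.0)


class TestF84:
    def test_identical_sequences_zero(self):
        s = "ACGT" * 250
        assert f84_distance(s, s) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            f84_distance("ACGT", "ACG")

    def test_pairwise_deletion(self):
        # differing site is masked in one sequence -> distance 0
        assert f84_distance("ACGTN" * 200, "ACGTA" * 200) == 0.0

    def test_k80_closed_form_with_equal_freqs(self):
        # one transition (A<->G) and one transversion (C<->A) in 1000 sites
        a = list("ACGT" * 250)
        b = list(a)
        b[0] = "G"   # transition
        b[1] = "A"   # transversion
        d = f84_distance("".join(a), "".join(b), freqs=np.full(4, 0.25))
        assert d == pytest.approx(k80_distance(1 / 1000, 1 / 1000), abs=1e-10)

    def test_saturation_flagged_not_clamped(self):
        # maximally divergent pair drives the log argument non-positive
        a = "A" * 400 + "C" * 400
        b = "G" * 400 + "T" * 400
        assert np.isnan(f84_distance(a, b))

    def test_simulation_consistency(self, freqs):
        # estimator is consistent: mean over replicates near true divergence
        est = []
        true_d = 0.05
        for rep in range(40):
            tree = TimeTree(
                ["a", "b"],
                parent=[2, 2, -1],
                children=[[-1, -1], [-1, -1], [0, 1]],
                ages=[0.0, 0.0, true_d / 2 / 1e-8],
            )
            aln = simulate_sequences(
                tree, 1e-8, 8.0, 1e7, freqs, 5_000, seed=100 + rep
            )
            est.append(f84_distance(aln.rows[0], aln.rows[1]))
        assert np.mean(est) == pytest.approx(true_d, rel=0.05)

    def test_matches_ape_dist_dna(self, serial_tree, freqs, tmp_path):
        """Independent oracle: ape's dist.dna(F84, pairwise deletion)."""
        aln = simulate_sequences(serial_tree, 3e-8, 8.0, 0.5, freqs, 3_000,
                                 seed=21, missing_frac=0.05)
        sub = aln.subset(aln.ids[:4])
        fasta = tmp_path / "aln.fa"
        fasta.write_text(
            "".join(f">{i}\n{r}\n" for i, r in zip(sub.ids, sub.rows))
        )
        out = tmp_path / "d.csv"
        script = textwrap.dedent(f"""
            library(ape)
            x <- read.dna("{fasta}", format="fasta")
            d <- dist.dna(x, model="F84", pairwise.deletion=TRUE)
            write.csv(as.matrix(d), "{out}")
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        import csv

        with open(out) as fh:
            rows = list(csv.reader(fh))
        labels = rows[0][1:]
        ape = {
            (labels[i], labels[j]): float(rows[i + 1][j + 1])
            for i in range(len(labels))
            for j in range(len(labels))
        }
        gf = empirical_base_freqs(sub)
        for i in range(len(sub.ids)):
            for j in range(i + 1, len(sub.ids)):
                mine = f84_distance(sub.rows[i], sub.rows[j], freqs=gf)
                assert mine == pytest.approx(ape[(sub.ids[i], sub.ids[j])], abs=1e-9)


class TestDistanceMatrix:
    def test_single_sequence(self):
        dm = distance_matrix(Alignment(["x"], ["ACGT"]))
        assert dm.values.shape == (1, 1) and dm.values[0, 0] == 0.0

    def test_consistent_with_pairwise_calls(self, small_alignment):
        sub = small_alignment.subset(small_alignment.ids[:3])
        dm = distance_matrix(sub, freq_mode="pair")
        for i in range(3):
            for j in range(3):
                expected = (
                    0.0 if i == j else f84_distance(sub.rows[i], sub.rows[j])
                )
                assert dm.values[i, j] == pytest.approx(expected)

    def test_permutation_invariance(self, small_alignment):
        sub = small_alignment.subset(small_alignment.ids[:4])
        perm = Alignment(sub.ids[::-1], sub.rows[::-1])
        d1 = distance_matrix(sub)
        d2 = distance_matrix(perm)
        for a in sub.ids:
            for b in sub.ids:
                i1, j1 = d1.labels.index(a), d1.labels.index(b)
                i2, j2 = d2.labels.index(a), d2.labels.index(b)
                assert d1.values[i1, j1] == pytest.approx(d2.values[i2, j2])
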