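"""Coalescent network simulator: validation, statistics, read channel."""

import math

import numpy as np
import pytest

import heliopipe as hp
from heliopipe import error_model as em
from heliopipe import synthetic_data as sd


def one_pop(theta=0.01):
    return sd.SpeciesNetwork.from_parents({"A": None}, {"A": 0.0}, theta=theta)


def three_species(delta_tau, theta, tau_ab=0.004):
    return sd.SpeciesNetwork.from_parents(
        {"A": "ab", "B": "ab", "ab": "r", "C": "r", "r": None},
        {"ab": tau_ab, "r": tau_ab + delta_tau},
        theta=theta,
    )


class TestValidation:
    def test_default_network_is_valid(self, default_net):
        assert sd.validate_network(default_net) == []

    def test_event_outside_branch_lifespan(self, default_net):
        bad = sd.SpeciesNetwork(
            populations=default_net.populations,
            events=[sd.IntrogressionEvent(time=0.05, donor="Era", recipient="Him", gamma=0.1)],
            root=default_net.root,
        )
        assert any("outside lifespan" in v for v in sd.validate_network(bad))

    def test_gamma_out_of_range(self, default_net):
        bad = sd.SpeciesNetwork(
            populations=default_net.populations,
            events=[sd.IntrogressionEvent(time=0.001, donor="Era", recipient="Him", gamma=1.2)],
            root=default_net.root,
        )
        assert any("gamma" in v for v in sd.validate_network(bad))

    def test_parent_younger_than_child_detected(self):
        net = sd.SpeciesNetwork.from_parents(
            {"A": "r", "B": "r", "r": None}, {"r": 0.01}, theta=0.01
        )
        net.populations["A"].t_lower = 0.02
        assert sd.validate_network(net)


class TestGeneTreeStatistics:
    def test_pairwise_coalescent_time_mean_and_variance(self, rng):
        theta = 0.01
        net = one_pop(theta)
        reps = 10_000
        ages = np.array([sd.simulate_gene_tree(net, {"A": 2}, rng).root.age for _ in range(reps)])
        mean, var = theta / 2, (theta / 2) ** 2
        assert abs(ages.mean() - mean) <= 3 * math.sqrt(var / reps)
        # exponential: sd of the sample variance ~ var * sqrt(8/reps)
        assert abs(ages.var() - var) <= 4 * var * math.sqrt(8 / reps)

    def test_triplet_discordance_matches_closed_form(self, rng):
        delta_tau, theta = 0.002, 0.01
        net = three_species(delta_tau, theta)
        reps = 8000
        trees = [sd.simulate_gene_tree(net, {"A": 1, "B": 1, "C": 1}, rng) for _ in range(reps)]
        table = hp.summaries.topology_frequencies(trees, ["A_0", "B_0", "C_0"])
        p_con, p_d1, _ = hp.summaries.triplet_topology_probs(delta_tau, theta)
        freq = table.frequencies()
        se = math.sqrt(p_con * (1 - p_con) / reps)
        assert abs(freq["((A_0,B_0),C_0)"] - p_con) <= 3 * se

    def test_zero_gamma_reduces_to_backbone(self, rng):
        delta_tau, theta = 0.003, 0.01
        plain = three_species(delta_tau, theta)
        with_null_event = sd.SpeciesNetwork.from_parents(
            {"A": "ab", "B": "ab", "ab": "r", "C": "r", "r": None},
            {"ab": 0.004, "r": 0.004 + delta_tau},
            theta=theta,
            events=[sd.IntrogressionEvent(time=0.001, donor="B", recipient="A", gamma=0.0)],
        )
        reps = 4000
        f1 = hp.summaries.topology_frequencies(
            [sd.simulate_gene_tree(plain, {"A": 1, "B": 1, "C": 1}, rng) for _ in range(reps)],
            ["A_0", "B_0", "C_0"],
        ).frequencies()
        f2 = hp.summaries.topology_frequencies(
            [sd.simulate_gene_tree(with_null_event, {"A": 1, "B": 1, "C": 1}, rng) for _ in range(reps)],
            ["A_0", "B_0", "C_0"],
        ).frequencies()
        for label in f1:
            assert abs(f1[label] - f2.get(label, 0.0)) < 0.05

    def test_introgression_path_frequency_matches_gamma(self, rng):
        gamma = 0.3
        net = sd.SpeciesNetwork.from_parents(
            {"A": "r", "B": "r", "r": None},
            {"r": 0.01},
            theta=0.01,
            events=[sd.IntrogressionEvent(time=0.002, donor="B", recipient="A", gamma=gamma, label="x")],
        )
        reps = 10_000
        used = sum(
            sd.simulate_gene_tree(net, {"A": 1, "B": 1}, rng).edge_uses.get("x", 0)
            for _ in range(reps)
        )
        se = math.sqrt(gamma * (1 - gamma) / reps)
        assert abs(used / reps - gamma) <= 3 * se

    def test_ultrametric_and_contained_coalescences(self, default_net, rng):
        tree = sd.simulate_gene_tree(default_net, {s: 2 for s in default_net.tips}, rng)

        def check(node, parent_age=math.inf):
            assert node.age <= parent_age + 1e-15
            for child in node.children:
                check(child, node.age)

        check(tree.root)
        assert len(tree.tip_names) == 12

    def test_msprime_oracle_pairwise_divergence(self, rng):
        """Two-sample coalescent ages agree in distribution with an
        independent coalescent engine on the same one-population model."""
        msprime = pytest.importorskip("msprime")
        from scipy.stats import ks_2samp

        theta = 0.01
        reps = 3000
        ours = np.array([sd.simulate_gene_tree(one_pop(theta), {"A": 2}, rng).root.age
                         for _ in range(reps)])
        ts_ages = []
        # msprime time unit: generations with Ne; mutational time tau = t * (theta/2)
        # when Ne = 0.5 "generations" units scale directly by theta/2
        for seed in range(1, reps + 1):
            ts = msprime.sim_ancestry(
                samples=1, population_size=0.5, ploidy=2, random_seed=seed
            )
            ts_ages.append(ts.max_root_time * theta / 2)
        stat, pvalue = ks_2samp(ours, np.array(ts_ages))
        assert pvalue > 1e-3


class TestSequenceEvolution:
    def test_zero_branch_lengths_identical_sequences(self, rng):
        root = sd.TreeNode("root", 0.0, [sd.TreeNode("a", 0.0), sd.TreeNode("b", 0.0)])
        seqs = sd.simulate_alignment(sd.GeneTree(root=root), 500, rng)
        assert np.array_equal(seqs["a"], seqs["b"])

    def test_jc69_divergence_closed_form(self, rng):
        t = 0.05
        root = sd.TreeNode("root", t, [sd.TreeNode("a", 0.0), sd.TreeNode("b", 0.0)])
        length = 200_000
        seqs = sd.simulate_alignment(sd.GeneTree(root=root), length, rng)
        p_obs = float(np.mean(seqs["a"] != seqs["b"]))
        p_exp = 0.75 * (1.0 - math.exp(-4 * (2 * t) / 3))
        se = math.sqrt(p_exp * (1 - p_exp) / length)
        assert abs(p_obs - p_exp) <= 3 * se


class TestReadChannel:
    def run_channel(self, h1, h2, ref, depth, eps, rng, **kw):
        return sd.diploidize_and_genotype([(h1, h2)], ref, depth, eps, rng, **kw)

    def test_error_free_high_depth_recovers_truth(self, rng):
        length = 2000
        ref = rng.integers(0, 4, length)
        h1 = ref.copy()
        h2 = np.where(rng.random(length) < 0.05, (ref + 1) % 4, ref)
        calls = self.run_channel(h1, h2, ref, sd.DepthModel("fixed", 40), 0.0, rng)
        from heliopipe._iupac import diploid_code

        truth = [
            diploid_code("ACGT"[a], "ACGT"[b]) for a, b in zip(h1, h2)
        ]
        assert list(calls.called[0]) == truth

    def test_het_discordance_matches_analytic_rate(self, rng):
        """True heterozygotes at depth 20, eps = 0.001: miscall rate ~ 4.0e-4."""
        length = 1_000_000
        ref = np.zeros(length, dtype=np.int64)
        h1 = ref.copy()
        h2 = np.ones(length, dtype=np.int64)  # every site heterozygous
        calls = self.run_channel(h1, h2, ref, sd.DepthModel("fixed", 20), 0.001, rng)
        wrong = np.mean(calls.called[0] != "M")  # A/C het is IUPAC M
        analytic = em.genotype_error_rate(em.GenotypeClass.HET, 20, 0.001)
        se = math.sqrt(analytic * (1 - analytic) / length)
        assert abs(wrong - analytic) <= 3 * se

    def test_zero_depth_is_missing(self, rng):
        ref = np.zeros(50, dtype=np.int64)
        calls = self.run_channel(ref, ref, ref, sd.DepthModel("fixed", 0), 0.001, rng)
        assert set(calls.called[0]) == {"N"}


class TestGenerateDataset:
    def test_same_seed_byte_identical(self, tmp_path, default_net):
        cfg = sd.SimConfig(n_loci=5, locus_length=80)
        a = sd.generate_dataset(default_net, cfg, str(tmp_path / "a"), seed=3)
        b = sd.generate_dataset(default_net, cfg, str(tmp_path / "b"), seed=3)
        for key in a.paths:
            with open(a.paths[key], "rb") as fa, open(b.paths[key], "rb") as fb:
                assert fa.read() == fb.read(), key

    def test_different_seed_differs(self, tmp_path, default_net):
        cfg = sd.SimConfig(n_loci=5, locus_length=80)
        a = sd.generate_dataset(default_net, cfg, str(tmp_path / "a"), seed=3)
        c = sd.generate_dataset(default_net, cfg, str(tmp_path / "c"), seed=4)
        with open(a.paths["vcf"]) as fa, open(c.paths["vcf"]) as fc:
            assert fa.read() != fc.read()

    def test_planted_repeat_rejects_locus_downstream(self, tmp_path, default_net):
        cfg = sd.SimConfig(
            n_loci=6, locus_length=120, repeat_loci={2: (0.0, 0.95)}
        )
        ds = sd.generate_dataset(default_net, cfg, str(tmp_path / "rep"), seed=5)
        result = hp.pipeline.extract_from_vcf(
            ds.paths["vcf"], ds.paths["gff"], ds.paths["repeats"], locus_class="noncoding"
        )
        rejected_spans = {(r.spec.start, r.spec.end) for r in result.rejections}
        target = ds.planted[2]
        assert (target.start, target.end) in rejected_spans
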