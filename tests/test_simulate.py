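import numpy as np
import pytest

from methylselex import (
    BindingModel,
    SimConfig,
    count_kmers,
    default_binding_model,
    enrichment_trajectory,
    ligand_affinity,
    run_selex_cycle,
    simulate_selex,
)
from methylselex.simulate import initial_library, affinities


def sharp_monomer_model(mw=10.0, gamma=None):
    """Sharp CAATCA-preferring model with optional gamma map."""
    e = np.full((6, 4), -4.0)
    for i, b in enumerate("CAATCA"):
        e[i, "ACGT".index(b)] = 0.0
    return BindingModel(
        half_site="YAATYA", monomer_energy=e, gamma=gamma or {},
        monomer_weight=mw,
    )


def flat_model():
    return BindingModel(half_site="YAATYA", monomer_energy=np.zeros((6, 4)))


class TestBindingModel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            BindingModel(half_site="YAATYA", monomer_energy=np.zeros((5, 4)))
        with pytest.raises(ValueError):
            BindingModel(half_site="YAATYA", gamma={("XX", 0): 1.0})
        with pytest.raises(ValueError):
            BindingModel(half_site="YAATYA", gamma={("ER", 0): -1.0})
        with pytest.raises(ValueError):
            BindingModel(half_site="YAATYA", methyl_delta={9: 1.0})

    def test_json_roundtrip(self):
        m = default_binding_model()
        back = BindingModel.from_json(m.to_json())
        assert back.half_site == m.half_site
        assert np.allclose(back.monomer_energy, m.monomer_energy)
        assert back.gamma == m.gamma
        assert back.gamma_methylated == m.gamma_methylated
        assert back.methyl_delta == m.methyl_delta


class TestLigandAffinity:
    def test_consensus_is_maximal_for_a_monomer_model(self):
        m = sharp_monomer_model(mw=1.0)
        w_cons = ligand_affinity(m, "CAATCA")
        assert w_cons == pytest.approx(1.0, rel=1e-3)
        for i, alt in enumerate("GAATCA CCATCA CAGTCA".split()):
            assert ligand_affinity(m, alt) < w_cons

    def test_er_cooperativity_prefers_its_spacing(self):
        m = sharp_monomer_model(mw=0.0, gamma={("ER", 1): 50.0})
        gap1 = "GG" + "TGATTG" + "A" + "CAATCA" + "GG"
        gap5 = "GG" + "TGATTG" + "AAAAA" + "CAATCA" + "GG"
        assert ligand_affinity(m, gap1) > ligand_affinity(m, gap5)

    def test_methyl_delta_is_monotone(self):
        m = sharp_monomer_model(mw=1.0)
        m.methyl_delta = {0: -1.0}
        read = "GGCAATCAGG"
        assert ligand_affinity(m, read, methylated=True) < ligand_affinity(m, read)

    def test_flanking_deltas_reward_cg_next_to_the_site(self):
        m = sharp_monomer_model(mw=1.0)
        m.methyl_delta = {-1: 1.0, 6: 1.0}
        with_cg = "GCAATCAC"
        without = "ACAATCAT"
        assert ligand_affinity(m, with_cg, methylated=True) > ligand_affinity(
            m, without, methylated=True
        )
        # unmethylated: flanks are inert
        assert ligand_affinity(m, with_cg) == pytest.approx(
            ligand_affinity(m, without), rel=1e-6
        )

    def test_read_shorter_than_half_site(self):
        with pytest.raises(ValueError):
            ligand_affinity(sharp_monomer_model(), "CAAT")

    def test_weight_is_always_positive(self):
        m = sharp_monomer_model(mw=1.0)
        assert ligand_affinity(m, "GGGGGGGG") > 0


class TestSelexCycle:
    def test_same_seed_reproduces(self):
        m = default_binding_model()
        cfg = SimConfig(library_size=500, random_len=20, seed=3)
        lib = initial_library(cfg, np.random.default_rng(3))
        a = run_selex_cycle(lib, m, cfg, np.random.default_rng(7))
        b = run_selex_cycle(lib, m, cfg, np.random.default_rng(7))
        assert a.reads == b.reads
        assert a.cycle == lib.cycle + 1

    def test_neutral_selection_is_a_uniform_resample(self):
        """Flat energies: planted k-mer frequency drifts but does not trend."""
        m = flat_model()
        deltas = []
        for s in range(20):
            cfg = SimConfig(library_size=800, random_len=20, seed=s)
            lib = initial_library(cfg, np.random.default_rng(s))
            t0 = count_kmers(lib, 5).frequency("ACGTA")
            out = run_selex_cycle(lib, m, cfg, np.random.default_rng(100 + s))
            t1 = count_kmers(out, 5).frequency("ACGTA")
            deltas.append(t1 - t0)
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se + 1e-12

    def test_selection_increases_planted_consensus_frequency(self):
        """One-sided sign test over 20 seeds at 1% planted consensus."""
        from scipy import stats

        m = sharp_monomer_model(mw=50.0)
        ups = 0
        for s in range(20):
            cfg = SimConfig(
                library_size=600, random_len=20, seed=s,
                plant="CAATCA", plant_frac=0.01,
            )
            lib = initial_library(cfg, np.random.default_rng(s))
            t0 = count_kmers(lib, 6).frequency("CAATCA")
            out = run_selex_cycle(lib, m, cfg, np.random.default_rng(200 + s))
            t1 = count_kmers(out, 6).frequency("CAATCA")
            ups += t1 > t0
        assert stats.binomtest(ups, 20, 0.5, alternative="greater").pvalue < 0.05

    def test_two_class_expected_ratio(self):
        """Post-selection class ratio matches (n1 w1)/(n2 w2) in expectation."""
        m = sharp_monomer_model(mw=10.0)
        r1 = "GG" + "CAATCA" + "G" * 14  # consensus class
        r2 = "GG" + "CAGTCA" + "G" * 14  # one-mismatch class
        w1 = ligand_affinity(m, r1)
        w2 = ligand_affinity(m, r2)
        n1, n2 = 200, 600
        from methylselex import LigandLibrary

        lib = LigandLibrary(reads=[r1] * n1 + [r2] * n2, random_region=(2, 20))
        cfg = SimConfig(library_size=n1 + n2, random_len=20, selection_fraction=0.5)
        ratios = []
        for s in range(40):
            out = run_selex_cycle(lib, m, cfg, np.random.default_rng(s))
            c1 = out.reads.count(r1)
            c2 = out.reads.count(r2)
            ratios.append(c1 / c2)
        expected = (n1 * w1) / (n2 * w2)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.1)

    def test_all_weights_at_floor_is_an_error(self):
        m = BindingModel(
            half_site="YAATYA", monomer_energy=np.full((6, 4), -50.0)
        )
        cfg = SimConfig(library_size=100, random_len=20)
        lib = initial_library(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="no binders"):
            run_selex_cycle(lib, m, cfg, np.random.default_rng(0))


class TestSimulateSelex:
    def test_cycle_count_and_flags(self):
        cfg = SimConfig(library_size=300, random_len=20, cycles=5, seed=1,
                        methylated=True)
        libs = simulate_selex(cfg, default_binding_model())
        assert len(libs) == 6
        assert [l.cycle for l in libs] == list(range(6))
        assert all(l.methylated for l in libs)
        assert all(len(l) == 300 for l in libs)

    def test_selection_preserves_length_and_alphabet(self):
        cfg = SimConfig(library_size=300, random_len=20, cycles=2, seed=2)
        libs = simulate_selex(cfg, default_binding_model())
        for lib in libs:
            assert {len(r) for r in lib.reads} == {20 + 16}
            assert set("".join(lib.reads)) <= set("ACGT")

    def test_planted_exponential_enrichment(self):
        """Log2 frequency of a planted consensus 10-mer is near-linear in the
        cycle index under a strong monomeric model."""
        plant = "TGATTGCAAT"
        e = np.full((10, 4), -0.8)
        for i, b in enumerate(plant):
            e[i, "ACGT".index(b)] = 0.0
        model = BindingModel(half_site=plant, monomer_energy=e, monomer_weight=5.0)
        cfg = SimConfig(
            library_size=5000, cycles=5, seed=11, plant=plant, plant_frac=0.005
        )
        libs = simulate_selex(cfg, model)
        tables = [count_kmers(lib, 10) for lib in libs]
        traj = enrichment_trajectory(tables, plant)
        from methylselex import fit_log_linear

        slope, _, r2 = fit_log_linear(traj, pseudo=0.5 / tables[0].total)
        assert slope > 0.5
        assert r2 > 0.9
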