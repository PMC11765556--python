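import numpy as np
import pytest

from methylselex import (
    LigandLibrary,
    PWMModel,
    build_pwm_from_seed,
    compare_methyl_pwms,
    information_content,
    match_motif,
    motif_enrichment,
    score_threshold_for_pvalue,
    shuffle_library,
)
from methylselex.motifs import count_seed_matches, lattice_scores, score_distribution, seed_pwm
from methylselex._seq import revcomp

from conftest import planted_library, random_library


def pwm_of(cols, **kw):
    return PWMModel(matrix=np.array(cols).T, **kw)


class TestInformationContent:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([1.0, 0.0, 0.0, 0.0], 2.0),
            ([0.5, 0.5, 0.0, 0.0], 1.0),
        ],
    )
    def test_closed_forms(self, col, expected):
        ic, mean = information_content(pwm_of([col]))
        assert ic[0] == pytest.approx(expected)
        assert mean == pytest.approx(expected)

    def test_column_normalization_enforced(self):
        with pytest.raises(ValueError):
            pwm_of([[0.5, 0.2, 0.2, 0.2]])


class TestBuildPwm:
    def test_degenerate_library_gives_near_deterministic_pwm(self):
        lib = LigandLibrary(reads=["CAATCA"] * 500)
        m = build_pwm_from_seed(lib, "CAATCA")
        assert m.consensus() == "CAATCA"
        assert m.mean_ic > 1.8

    def test_uniform_library_gives_flat_columns(self):
        lib = random_library(n=10_000, L=30, seed=2)
        m = build_pwm_from_seed(lib, "NNNNNN")
        assert np.abs(m.matrix - 0.25).max() < 0.02
        assert m.mean_ic < 0.05

    def test_mixture_recovery(self):
        # 70% CAATCA / 30% CTATCA planted at a fixed offset
        rng = np.random.default_rng(4)
        reads = []
        for i in range(4000):
            var = "CAATCA" if rng.random() < 0.7 else "CTATCA"
            flank = "".join("ACGT"[c] for c in rng.integers(0, 4, 8))
            reads.append(flank[:4] + var + flank[4:])
        lib = LigandLibrary(reads=reads)
        m = build_pwm_from_seed(lib, "CAATCA")
        # column 2 is the all-but-one counting column for the A/T mixture
        assert m.matrix[0, 1] == pytest.approx(0.7, abs=0.05)
        assert m.matrix[3, 1] == pytest.approx(0.3, abs=0.05)

    def test_reverse_strand_windows_contribute_complemented(self):
        lib = LigandLibrary(reads=["TGATTG"] * 200)  # revcomp of CAATCA
        m = build_pwm_from_seed(lib, "CAATCA")
        assert m.consensus() == "CAATCA"

    def test_zero_matches_names_the_seed(self):
        lib = LigandLibrary(reads=["GGGGGGGG"] * 10)
        with pytest.raises(ValueError, match="CAATCA"):
            build_pwm_from_seed(lib, "CAATCA")

    def test_background_correction_flattens_composition_bias(self):
        lib = random_library(n=3000, L=20, seed=7)
        m_raw = build_pwm_from_seed(lib, "NNNNN")
        m_corr = build_pwm_from_seed(lib, "NNNNN", background=lib)
        assert m_corr.mean_ic <= m_raw.mean_ic + 1e-12


class TestThreshold:
    def test_p_of_one_admits_everything(self):
        m = seed_pwm("ACGT")
        thr = score_threshold_for_pvalue(m, p=1.0)
        assert thr.p_actual == pytest.approx(1.0)
        assert len(match_motif(m, ["TTTT"], thr)) == 2  # both strands

    def test_dp_matches_brute_force_w6(self):
        rng = np.random.default_rng(1)
        m = PWMModel(matrix=rng.dirichlet([1] * 4, size=6).T)
        s_int, _ = lattice_scores(m)
        offset, pmf = score_distribution(s_int, np.full(4, 0.25))
        codes = np.array(np.meshgrid(*[range(4)] * 6, indexing="ij")).reshape(6, -1).T
        scores = s_int[np.arange(6)[None, :], codes].sum(axis=1)
        brute = np.bincount(scores - offset, minlength=len(pmf)) / 4**6
        assert np.abs(pmf - brute).max() < 1e-12

    def test_consensus_threshold_admits_exactly_the_consensus(self):
        m = pwm_of([[1, 0, 0, 0]] * 4)  # AAAA
        thr = score_threshold_for_pvalue(m, p=0.25**4)
        assert thr.p_actual == pytest.approx(0.25**4)
        hits = match_motif(m, ["AAAA", "CAAA", "AAAC"], thr)
        assert set(hits["seq_index"]) == {0}

    def test_p_below_attainable_tail_returns_max_score(self):
        m = pwm_of([[1, 0, 0, 0]] * 3)
        thr = score_threshold_for_pvalue(m, p=1e-12)
        assert thr.p_actual == pytest.approx(0.25**3)


class TestMatch:
    def test_planted_consensus_matches_once_per_read(self):
        lib = planted_library("TGATTGCAATCA", n=200, L=30, seed=3)
        m = seed_pwm("TRATTRYAATYA")
        thr = score_threshold_for_pvalue(m, p=1e-6)
        hits = match_motif(m, lib, thr)
        assert len(set(hits["seq_index"])) == 200

    def test_match_count_invariant_under_revcomp(self):
        lib = planted_library("TGATTGACAATCA", n=100, L=30, seed=5)
        m = seed_pwm("TRATTRNYAATYA")
        thr = score_threshold_for_pvalue(m, p=1e-6)
        fwd = match_motif(m, lib.regions(), thr)
        rc = match_motif(m, [revcomp(s) for s in lib.regions()], thr)
        assert len(fwd) == len(rc)
        assert sorted(fwd["strand"]) == sorted(
            {"+": "-", "-": "+"}[s] for s in rc["strand"]
        )

    def test_threshold_above_max_score_matches_nothing(self):
        m = seed_pwm("CAATCA")
        assert len(match_motif(m, ["CAATCA"], 1e6)) == 0

    def test_count_seed_matches(self):
        assert count_seed_matches(["GGCAATCAGG"], "CAATCA") == 1
        assert count_seed_matches(["GGTGATTGGG"], "CAATCA") == 1  # minus strand
        assert count_seed_matches(["GGCAGTCAGG"], "CAATCA", max_mismatch=1) == 1


class TestShuffle:
    def test_composition_preserved_and_flanks_untouched(self):
        lib = LigandLibrary(
            reads=["GGACGTACGTCC", "GGAAAATTTTCC"], random_region=(2, 8)
        )
        shuf = shuffle_library(lib, seed=1)
        for orig, s in zip(lib.reads, shuf.reads):
            assert s[:2] == "GG" and s[-2:] == "CC"
            assert sorted(s[2:10]) == sorted(orig[2:10])

    def test_homopolymer_region_is_unchanged(self):
        lib = LigandLibrary(reads=["AAAA"])
        assert shuffle_library(lib, seed=3).reads == ["AAAA"]

    def test_same_seed_is_reproducible(self):
        lib = random_library(n=50, L=20, seed=8)
        assert shuffle_library(lib, 42).reads == shuffle_library(lib, 42).reads


class TestEnrichment:
    def test_library_against_itself_is_about_one(self):
        lib = random_library(n=2000, L=30, seed=9)
        m = seed_pwm("YAATYA")
        thr = score_threshold_for_pvalue(m, p=1e-3)
        ratio = motif_enrichment(m, lib, lib, threshold=thr)
        assert ratio == pytest.approx(1.0, abs=0.05)
        assert m.enrichment == ratio

    def test_planted_library_is_strongly_enriched(self):
        lib = planted_library("TGATTGCAATCA", n=1000, L=30, seed=10, frac=0.5)
        m = seed_pwm("TRATTRYAATYA")
        shuf = shuffle_library(lib, seed=0)
        assert motif_enrichment(m, lib, shuf, p=1e-5) > 2

    def test_size_mismatch_is_an_error(self):
        a = random_library(n=100, L=20, seed=1)
        b = random_library(n=50, L=20, seed=2)
        with pytest.raises(ValueError):
            motif_enrichment(seed_pwm("YAATYA"), a, b)


class TestMethylComparison:
    def test_identical_models_all_neutral(self):
        m = seed_pwm("TRATTRYAATYA")
        cmp_ = compare_methyl_pwms(m, m)
        assert set(cmp_.calls()) == {"."}

    def test_cg_gain_is_called_plus(self):
        normal = pwm_of([[0.5, 0.3, 0.1, 0.1]])
        methyl = pwm_of([[0.1, 0.8, 0.05, 0.05]])
        cmp_ = compare_methyl_pwms(normal, methyl)
        assert cmp_.calls() == "+"

    def test_preferred_base_switch_is_recorded(self):
        normal = pwm_of([[0.1, 0.1, 0.7, 0.1]])  # prefers G
        methyl = pwm_of([[0.7, 0.1, 0.1, 0.1]])  # prefers A
        row = compare_methyl_pwms(normal, methyl).table.iloc[0]
        assert row["preferred_base_normal"] == "G"
        assert row["preferred_base_methyl"] == "A"
        assert row["call"] == "-"
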