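import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import entropy

from gchap import (
    FrequencySpectrum,
    diversity_table,
    fst_haplotype,
    nei_identity,
    shannon_equitability,
    spectrum_from_counts,
)
from gchap.diversity import population_spectrum
from util import simple_gene, sites_from_matrix, two_class_panel
from gchap import call_gchaps


def spec(freqs, n=100, gene="g", pop="Xian"):
    return FrequencySpectrum(gene_id=gene, population=pop,
                             freqs={f"Hap{i+1}": f for i, f in enumerate(freqs)},
                             n=n)


random_freqs = st.lists(
    st.floats(0.01, 1.0), min_size=2, max_size=8
).map(lambda w: [x / sum(w) for x in w])


class TestShannonEquitability:
    def test_uniform_spectrum_is_maximally_even(self):
        assert shannon_equitability(spec([0.25] * 4)) == pytest.approx(1.0)

    def test_monomorphic_convention_is_zero(self):
        assert shannon_equitability(spec([1.0])) == 0.0

    def test_hand_computed_value(self):
        # -(0.7 ln 0.7 + 0.2 ln 0.2 + 0.1 ln 0.1) = 0.80182, / ln 3
        eh = shannon_equitability(spec([0.7, 0.2, 0.1]))
        assert eh == pytest.approx(0.8018186 / np.log(3), abs=1e-6)
        assert round(eh, 4) == 0.7298

    def test_empty_spectrum_signalled(self):
        with pytest.raises(ValueError):
            shannon_equitability(spec([], n=0))

    @settings(deadline=None, max_examples=50)
    @given(random_freqs)
    def test_matches_entropy_oracle_and_ignores_zero_entries(self, freqs):
        s = spec(freqs)
        expected = entropy(freqs) / np.log(len(freqs))
        assert shannon_equitability(s) == pytest.approx(expected, abs=1e-12)
        padded = spec(freqs + [0.0])  # zero-frequency entry changes nothing
        assert shannon_equitability(padded) == pytest.approx(expected, abs=1e-12)

    def test_replication_invariance(self):
        # E_H depends only on frequencies, not on sample size
        a = spectrum_from_counts("g", "Xian", {"Hap1": 7, "Hap2": 2, "Hap3": 1})
        b = spectrum_from_counts("g", "Xian",
                                 {"Hap1": 70, "Hap2": 20, "Hap3": 10})
        assert shannon_equitability(a) == pytest.approx(
            shannon_equitability(b), abs=1e-12)


class TestNeiIdentity:
    def test_identical_spectra(self):
        a = spec([0.5, 0.3, 0.2])
        assert nei_identity(a, spec([0.5, 0.3, 0.2])) == pytest.approx(1.0)

    def test_disjoint_haplotype_sets(self):
        a = FrequencySpectrum("g", "Xian", {"Hap1": 1.0}, 50)
        b = FrequencySpectrum("g", "Geng", {"Hap2": 1.0}, 50)
        assert nei_identity(a, b) == 0.0

    def test_hand_computed_value(self):
        # 0.8*0.2 + 0.2*0.8 = 0.32; sqrt(0.68 * 0.68) = 0.68
        assert nei_identity(spec([0.8, 0.2]), spec([0.2, 0.8])) == pytest.approx(
            0.32 / 0.68, abs=1e-12)
        assert round(nei_identity(spec([0.8, 0.2]), spec([0.2, 0.8])), 4) == 0.4706

    def test_empty_population_signalled(self):
        with pytest.raises(ValueError):
            nei_identity(spec([1.0]), spec([], n=0))

    @settings(deadline=None, max_examples=50)
    @given(random_freqs, random_freqs)
    def test_symmetric_and_bounded(self, fx, fy):
        x, y = spec(fx), spec(fy)
        i_xy, i_yx = nei_identity(x, y), nei_identity(y, x)
        assert i_xy == pytest.approx(i_yx, abs=1e-12)
        assert -1e-12 <= i_xy <= 1 + 1e-12


class TestFstHaplotype:
    def test_identical_populations_have_zero_fst(self):
        assert fst_haplotype([spec([0.5, 0.5]), spec([0.5, 0.5])]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_fixed_disjoint_populations_have_fst_one(self):
        a = FrequencySpectrum("g", "Xian", {"Hap1": 1.0}, 100)
        b = FrequencySpectrum("g", "Geng", {"Hap2": 1.0}, 100)
        assert fst_haplotype([a, b]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # H_S = 1 - (0.49 + 0.09) = 0.42, H_T = 0.5 -> Fst = 0.16
        assert fst_haplotype([spec([0.7, 0.3]), spec([0.3, 0.7])]) == \
            pytest.approx(0.16, abs=1e-12)

    def test_single_population_is_an_error(self):
        with pytest.raises(ValueError):
            fst_haplotype([spec([1.0])])

    def test_monomorphic_total_returns_zero(self):
        assert fst_haplotype([spec([1.0]), spec([1.0])]) == 0.0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(random_freqs, min_size=2, max_size=4))
    def test_bounded_for_random_spectra(self, freq_sets):
        spectra = [spec(f, n=50 + 10 * i) for i, f in enumerate(freq_sets)]
        fst = fst_haplotype(spectra)
        assert -1e-9 <= fst <= 1 + 1e-9

    def test_monotone_in_population_divergence(self):
        # moving two equal-size spectra apart along a line raises Fst
        values = [
            fst_haplotype([spec([0.5 + d, 0.5 - d]), spec([0.5 - d, 0.5 + d])])
            for d in np.linspace(0.0, 0.5, 11)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestDiversityTable:
    @pytest.fixture()
    def monomorphic_setup(self):
        panel = two_class_panel(6, 4)
        gene = simple_gene([(100, 200)])
        sites = sites_from_matrix(np.zeros((10, 2)), positions=[110, 120])
        table = call_gchaps(gene, sites, panel)
        return [table], panel

    def test_monomorphic_gene_rows(self, monomorphic_setup):
        tables, panel = monomorphic_setup
        df = diversity_table(tables, panel, ["Xian"])
        gene_rows = df[df.gene != "Mean"]
        assert (gene_rows.EH == 0).all()
        assert (gene_rows.gcHapN == 1).all()

    def test_mean_row_is_arithmetic_mean(self, sim_tables, sim_loaded):
        _, _, panel = sim_loaded
        df = diversity_table(sim_tables, panel, ["Xian", "Geng"])
        for pop in ("Xian", "Geng"):
            genes = df[(df.population == pop) & (df.gene != "Mean")]
            mean = df[(df.population == pop) & (df.gene == "Mean")].iloc[0]
            assert mean.EH == pytest.approx(genes.EH.mean(), abs=1e-12)
            assert mean.gcHapN == pytest.approx(genes.gcHapN.mean(), abs=1e-12)

    def test_matches_per_population_brute_force_recount(self, sim_tables,
                                                        sim_loaded):
        _, _, panel = sim_loaded
        df = diversity_table(sim_tables, panel, ["Xian", "Geng"])
        table = sim_tables[0]
        for pop in ("Xian", "Geng"):
            counts = {}
            for acc, hap in table.assignment.items():
                if panel.population[acc] == pop:
                    counts[hap] = counts.get(hap, 0) + 1
            n = sum(counts.values())
            p = np.array([c / n for c in counts.values()])
            expected_eh = (
                0.0 if len(p) == 1 else float(-(p * np.log(p)).sum() / np.log(len(p)))
            )
            row = df[(df.gene == table.gene_id) & (df.population == pop)].iloc[0]
            assert row.EH == pytest.approx(expected_eh, abs=1e-12)
            assert row.gcHapN == len(counts)

    def test_absent_population_is_an_error(self, sim_tables, sim_loaded):
        _, _, panel = sim_loaded
        with pytest.raises(ValueError, match="Bas"):
            diversity_table(sim_tables, panel, ["Xian", "Bas"])

    def test_major_count_restricted_to_population_members(self):
        from gchap import AccessionPanel

        # 100 accessions: Hap3 (5% globally, major) occurs only in Xian
        hap_of = [0] * 60 + [1] * 35 + [2] * 5
        ids = [f"A{i:03d}" for i in range(100)]
        pops = {a: ("Geng" if i in (60, 61) else "Xian")
                for i, a in enumerate(ids)}
        panel = AccessionPanel(
            accession_ids=ids, population=pops,
            variety_class={a: "LAN" for a in ids})
        mat = [[1 if j == k else 0 for j in range(3)] for k in hap_of]
        gene = simple_gene([(100, 200)])
        table = call_gchaps(gene, sites_from_matrix(mat, positions=[110, 120, 130]),
                            panel)
        df = diversity_table([table], panel, ["Xian", "Geng"])
        xian = df[(df.population == "Xian") & (df.gene != "Mean")].iloc[0]
        geng = df[(df.population == "Geng") & (df.gene != "Mean")].iloc[0]
        assert xian.major_gcHapN == 3
        # Geng holds only two Hap2 carriers, so one global major is present
        assert geng.gcHapN == 1
        assert geng.major_gcHapN == 1
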