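"""Fragment ions, isotope clusters, transition lists."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import glycotarget as gt
from glycotarget.chem import PROTON, WATER, AMINO_ACID_RESIDUE_MASSES, C13_MINUS_C12
from glycotarget.fragments import _AVERAGINE_C_PER_DA, _P13C

from conftest import AA_FORMULAS


def _labels(ions):
    return {i.label: i.mz for i in ions}


class TestOxonium:
    def test_sialic_acid_ions(self):
        ions = _labels(gt.oxonium_ions(gt.GlycanComposition.from_dict({"NeuAc": 1})))
        assert ions["NeuAc"] == pytest.approx(292.1027, abs=1e-3)
        assert ions["NeuAc-H2O"] == pytest.approx(274.0921, abs=1e-3)
        # published two-decimal values
        assert ions["NeuAc"] == pytest.approx(292.10, abs=0.01)
        assert ions["NeuAc-H2O"] == pytest.approx(274.09, abs=0.01)

    def test_disaccharide(self):
        ions = _labels(gt.oxonium_ions(gt.GlycanComposition.from_dict({"HexNAc": 1, "Hex": 1})))
        assert ions["HexNAc+Hex"] == pytest.approx(366.139, abs=1e-3)

    def test_empty_composition(self):
        assert gt.oxonium_ions(gt.GlycanComposition.from_dict({})) == []

    def test_full_target_set(self, target_glycopeptide):
        ions = _labels(gt.oxonium_ions(target_glycopeptide.glycan))
        assert ions["HexNAc"] == pytest.approx(204.0866, abs=1e-3)
        assert ions["HexNAc+Hex+NeuAc"] == pytest.approx(657.2349, abs=1e-3)
        assert "Hex" in ions and "Fuc" in ions  # present classes all covered


class TestBackbone:
    def test_y1_lysine(self):
        pep = gt.Peptide(sequence="HCSLNENITVPDTK")
        y = {i.label: i.mz for i in gt.backbone_ions(pep, "y")}
        assert y["y1"] == pytest.approx(147.1128, abs=1e-3)

    def test_y6_of_target(self):
        # TVPDTK: the nominal y6 computes to 660.36, not the published
        # 658.23 (whose identity is ambiguous)
        pep = gt.Peptide(sequence="HCSLNENITVPDTK")
        y = {i.label: i.mz for i in gt.backbone_ions(pep, "y")}
        assert y["y6"] == pytest.approx(660.3563, abs=1e-3)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            gt.backbone_ions(gt.Peptide(sequence="AAK"), "c")

    @given(st.text(alphabet=sorted(AA_FORMULAS), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_by_complementarity(self, seq):
        """b_i + y_(n-i) = M + 2 protons at z=1, for every cleavage point."""
        pep = gt.Peptide(sequence=seq)
        m = gt.peptide_monoisotopic_mass(pep)
        b = {i.index: i.mz for i in gt.backbone_ions(pep, "b")}
        y = {i.index: i.mz for i in gt.backbone_ions(pep, "y")}
        n = len(seq)
        for i in range(1, n):
            assert b[i] + y[n - i] == pytest.approx(m + 2 * PROTON, abs=1e-8)


class TestYLadder:
    def test_bare_glycan_single_entry(self):
        pep = gt.Peptide(sequence="HCSLNENITVPDTK")
        gp = gt.Glycopeptide(pep, gt.GlycanComposition.from_dict({}))
        ladder = gt.y_ladder(gp)
        assert len(ladder) == 1
        assert ladder[0].mz == pytest.approx(gt.peptide_monoisotopic_mass(pep) + PROTON, abs=1e-6)

    def test_target_ladder_head_and_first_step(self, target_glycopeptide):
        ladder = gt.y_ladder(target_glycopeptide)
        assert ladder[0].mz == pytest.approx(1627.7745, abs=1e-3)
        # first glycan residue added to the bare peptide is the core GlcNAc
        assert ladder[1].mz - ladder[0].mz == pytest.approx(203.0794, abs=1e-3)

    def test_ladder_length_is_residue_count_plus_one(self, target_glycopeptide):
        ladder = gt.y_ladder(target_glycopeptide)
        assert len(ladder) == target_glycopeptide.glycan.total_residues() + 1

    def test_mz_recomputable_from_composition(self, target_glycopeptide):
        pep_mass = gt.peptide_monoisotopic_mass(target_glycopeptide.peptide)
        for ion in gt.y_ladder(target_glycopeptide):
            expect = pep_mass + gt.glycan_mass(ion.composition) + PROTON
            assert ion.mz == pytest.approx(expect, abs=1e-4)


class TestIsotopeCluster:
    def test_target_cluster_start_and_spacing(self, target_glycopeptide):
        mass = gt.glycopeptide_mass(target_glycopeptide)
        cluster = gt.isotope_cluster(mass, 4, 5)
        mzs = [mz for mz, _ in cluster]
        assert mzs[0] == pytest.approx(1323.5205, abs=1e-3)
        assert np.diff(mzs) == pytest.approx(C13_MINUS_C12 / 4, abs=1e-9)

    def test_z1_spacing(self):
        cluster = gt.isotope_cluster(1000.0, 1, 3)
        assert cluster[1][0] - cluster[0][0] == pytest.approx(C13_MINUS_C12, abs=1e-12)

    @pytest.mark.parametrize("mass,min_mode", [(75.03, 0), (5290.05, 2)])
    def test_most_intense_isotopologue_grows_with_mass(self, mass, min_mode):
        """Cross-check the binomial model against scipy's binomial pmf."""
        cluster = gt.isotope_cluster(mass, 1, 6)
        intensities = [rel for _, rel in cluster]
        mode = int(np.argmax(intensities))
        n_c = max(1, round(mass * _AVERAGINE_C_PER_DA))
        oracle = stats.binom.pmf(range(6), n_c, _P13C)
        assert mode == int(np.argmax(oracle))
        assert mode >= min_mode
        # normalized shape agrees with the scipy oracle
        assert np.allclose(intensities, oracle / oracle.max(), atol=1e-9)

    def test_intensities_normalized_nonnegative(self):
        cluster = gt.isotope_cluster(2500.0, 3, 8)
        rel = [r for _, r in cluster]
        assert max(rel) == 1.0
        assert all(r >= 0 for r in rel)
        assert sum(rel) < math.inf


class TestTransitionList:
    def test_target_entry_matches_published_values(self, target_glycopeptide):
        entries = gt.build_transition_list([target_glycopeptide], charge=4,
                                           monitored_isotopologue=2)
        (entry,) = entries
        assert entry.precursor_mz == pytest.approx(1324.02, abs=0.01)
        got = sorted(p.mz for p in entry.products)
        for published, computed in zip([204.09, 274.09, 292.10, 366.14, 657.23], got):
            assert computed == pytest.approx(published, abs=0.01)

    def test_extra_658_optional(self, target_glycopeptide):
        entry = gt.build_transition_list([target_glycopeptide], include_extra_658=True)[0]
        assert any(abs(p.mz - 658.23) < 1e-9 for p in entry.products)

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            gt.build_transition_list([])

    def test_duplicates_collapse_with_warning(self, target_glycopeptide):
        with pytest.warns(UserWarning, match="duplicate"):
            entries = gt.build_transition_list([target_glycopeptide, target_glycopeptide])
        assert len(entries) == 1

    def test_csv_round_trip(self, target_glycopeptide, tmp_path):
        entries = gt.build_transition_list([target_glycopeptide], rt_window=(10.0, 14.0))
        path = tmp_path / "transitions.csv"
        gt.write_transition_csv(entries, path)
        back = gt.read_transition_csv(path)
        assert len(back) == 1
        e0, e1 = entries[0], back[0]
        assert e1.precursor_mz == e0.precursor_mz  # bit-exact
        assert e1.glycopeptide.name == e0.glycopeptide.name
        assert e1.glycopeptide.site == e0.glycopeptide.site
        assert [p.mz for p in e1.products] == [p.mz for p in e0.products]
        assert [p.label for p in e1.products] == [p.label for p in e0.products]
        assert e1.rt_window == e0.rt_window
        # write -> read -> write is byte-stable
        path2 = tmp_path / "transitions2.csv"
        gt.write_transition_csv(back, path2)
        assert path.read_bytes() == path2.read_bytes()
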