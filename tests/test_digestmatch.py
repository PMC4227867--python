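import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pmass

from xlms import digestmatch as dm
from xlms import linkerchem
from xlms.digestmatch import (
    GLUC,
    PROTON,
    TRYPSIN,
    Peptide,
    XLCandidate,
    digest,
    fragment_ions,
    match_precursors,
    pair_mass,
    peptide_mass,
)


def seqs(peptides):
    return sorted(p.sequence for p in peptides)


class TestDigest:
    def test_trypsin_no_missed_cleavage(self):
        assert seqs(digest("AKRGYE", [TRYPSIN], shared_max_missed=0)) == ["AK", "GYE", "R"]

    def test_trypsin_one_missed_cleavage(self):
        got = seqs(digest("AKRGYE", [TRYPSIN], shared_max_missed=1))
        assert got == sorted(["AK", "R", "GYE", "AKR", "RGYE"])

    def test_no_cleavage_sites_returns_full_sequence(self):
        assert seqs(digest("GGAGG", [TRYPSIN])) == ["GGAGG"]

    def test_proline_blocks_cleavage(self):
        assert seqs(digest("AKPG", [TRYPSIN], shared_max_missed=0)) == ["AKPG"]
        assert seqs(
            digest("AKPG", [TRYPSIN], shared_max_missed=0, no_cleave_before_pro=False)
        ) == ["AK", "PG"]

    def test_combined_enzymes_use_union_of_sites(self):
        # trypsin (K/R) + GluC (E): cuts after K and E
        assert seqs(digest("AKGEGG", [TRYPSIN, GLUC], shared_max_missed=0)) == [
            "AK", "GE", "GG",
        ]

    def test_per_enzyme_budget_mode(self):
        # "KAKAEAEAK": shared budget 2 forbids spanning 3 internal sites,
        # but per-enzyme budgets (2 each) allow 2 tryptic + 2 GluC sites
        pep_shared = digest("KAKAEAEAK", [TRYPSIN, GLUC], shared_max_missed=2)
        pep_per = digest("KAKAEAEAK", [TRYPSIN, GLUC], missed_budget="per_enzyme")
        assert "KAKAEAEAK" not in seqs(pep_shared)
        assert "KAKAEAE" in seqs(pep_per)

    def test_photo_codes_cleave_like_parent_residues(self):
        # 'z'/'o' behave as Leu/Met: no new cleavage sites appear
        assert seqs(digest("AzKoG", [TRYPSIN], shared_max_missed=0)) == ["AzK", "oG"]

    def test_empty_sequence_rejected(self):
        with pytest.raises(dm.DigestError):
            digest("", [TRYPSIN])

    @given(m=st.integers(0, 3))
    @settings(deadline=None)
    def test_missed_cleavage_superset_property(self, m):
        seq = "AKRGYEKLMKR"
        smaller = set(seqs(digest(seq, [TRYPSIN], shared_max_missed=m)))
        larger = set(seqs(digest(seq, [TRYPSIN], shared_max_missed=m + 1)))
        assert smaller <= larger


class TestPeptideMass:
    def test_glycine(self):
        assert peptide_mass(Peptide("p", 1, 1, "G")) == pytest.approx(75.03203, abs=1e-5)

    def test_diglycine(self):
        assert peptide_mass(Peptide("p", 1, 2, "GG")) == pytest.approx(132.05349, abs=1e-5)

    def test_matches_pyteomics_for_standard_peptide(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        p = Peptide("p", 1, len(seq), seq)
        # independent oracle; Cys carbamidomethylation added separately
        expected = pmass.calculate_mass(sequence=seq) + dm.CARBAMIDOMETHYL
        assert peptide_mass(p) == pytest.approx(expected, abs=1e-9)

    def test_met_oxidation_adds_one_oxygen(self):
        plain = Peptide("p", 1, 3, "AMA")
        ox = Peptide("p", 1, 3, "AMA", var_mods=((2, "ox"),))
        assert peptide_mass(ox) - peptide_mass(plain) == pytest.approx(
            15.99491, abs=1e-5
        )

    def test_unknown_residue_rejected(self):
        with pytest.raises(dm.MassError):
            peptide_mass(Peptide("p", 1, 1, "B"))


class TestPairMass:
    def make_pair(self, linker="BS2G"):
        alpha = Peptide("a", 1, 4, "GKGG")
        beta = Peptide("b", 10, 13, "AKGA")
        return XLCandidate(alpha, beta, 2, 11, linker)

    def test_bs2g_pair_adds_bridge(self):
        c = self.make_pair()
        expected = (
            peptide_mass(c.alpha) + peptide_mass(c.beta) + linkerchem.bridge_mass("BS2G")
        )
        assert pair_mass(c) == pytest.approx(expected, abs=1e-9)

    def test_photo_pair_loses_n2(self):
        alpha = Peptide("a", 1, 3, "GzG")
        beta = Peptide("b", 10, 12, "AGA")
        c = XLCandidate(alpha, beta, 2, 11, "photo-Leu")
        assert pair_mass(c) == pytest.approx(
            peptide_mass(alpha) + peptide_mass(beta) - 28.00615, abs=1e-5
        )

    def test_symmetric_under_alpha_beta_exchange(self):
        c = self.make_pair()
        swapped = XLCandidate(c.beta, c.alpha, c.link_pos_beta, c.link_pos_alpha, "BS2G")
        assert pair_mass(c) == pair_mass(swapped)

    def test_chemistry_violation_rejected(self):
        alpha = Peptide("a", 1, 4, "GGGG")
        beta = Peptide("b", 10, 13, "AKGA")
        c = XLCandidate(alpha, beta, 2, 11, "BS2G")  # G is not an amine site
        with pytest.raises(linkerchem.ChemistryError):
            pair_mass(c)

    def test_n_terminal_amine_is_valid_site(self):
        alpha = Peptide("a", 1, 4, "GGGG")  # link at the protein N-terminus
        beta = Peptide("b", 10, 13, "AKGA")
        c = XLCandidate(alpha, beta, 1, 11, "BS2G")
        assert pair_mass(c) > 0


class TestMatchPrecursors:
    def make_candidates(self):
        peps = [Peptide("p", 1, 4, s) for s in ("GKGG", "AKGA", "KGGL", "GKLM")]
        return [
            XLCandidate(peps[i], peps[j], peps[i].start + peps[i].sequence.index("K"),
                        peps[j].start + peps[j].sequence.index("K"), "BS2G")
            for i, j in [(0, 1), (0, 2), (1, 3)]
        ]

    def test_exact_mass_matches_at_zero_ppm(self):
        cands = self.make_candidates()
        m0 = pair_mass(cands[0])
        obs = [((m0 + 2 * PROTON) / 2, 2)]
        matches = match_precursors(obs, cands, ppm_max=3.0)
        assert matches[0].candidate is cands[0]
        assert matches[0].ppm == pytest.approx(0.0, abs=1e-9)

    def test_3p5_ppm_off_is_rejected_at_3ppm(self):
        cands = self.make_candidates()
        m0 = pair_mass(cands[0]) * (1 + 3.5e-6)
        obs = [((m0 + 2 * PROTON) / 2, 2)]
        assert match_precursors(obs, cands, ppm_max=3.0) == []

    def test_boundary_inclusive(self):
        cands = self.make_candidates()
        m0 = pair_mass(cands[0]) * (1 + 3.0e-6)
        obs = [((m0 + 3 * PROTON) / 3, 3)]
        matches = match_precursors(obs, cands, ppm_max=3.0)
        assert len(matches) == 1

    def test_infinite_tolerance_returns_all(self):
        cands = self.make_candidates()
        obs = [((pair_mass(cands[0]) + PROTON), 1)]
        assert len(match_precursors(obs, cands, ppm_max=np.inf)) == len(cands)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError):
            dm.neutral_mass(500.0, 0)


class TestFragmentIons:
    def make_candidate(self):
        alpha = Peptide("a", 1, 5, "GAKLG")
        beta = Peptide("b", 20, 23, "AKGA")
        return XLCandidate(alpha, beta, 3, 21, "BS2G")

    def test_y1_of_lysine_terminated_peptide(self):
        alpha = Peptide("a", 1, 3, "GGK")
        beta = Peptide("b", 10, 13, "AKGA")
        c = XLCandidate(alpha, beta, 3, 11, "BS2G")
        ions = fragment_ions(c)
        y1 = next(
            i for i in ions if i.peptide == "alpha" and i.series == "y" and i.index == 1
        )
        assert y1.contains_link  # C-terminal K carries the link here
        expected = (
            dm.RESIDUE_MASSES["K"] + dm.WATER + PROTON
            + peptide_mass(beta) + linkerchem.bridge_mass("BS2G")
        )
        assert y1.mz == pytest.approx(expected, abs=1e-9)

    def test_b1_excluded_y1_included(self):
        ions = fragment_ions(self.make_candidate())
        assert not any(i.series == "b" and i.index == 1 for i in ions)
        assert any(i.series == "y" and i.index == 1 for i in ions)

    def test_link_containing_b_ion_additivity(self):
        c = self.make_candidate()
        ions = {(i.peptide, i.series, i.index): i for i in fragment_ions(c)}
        b3 = ions[("alpha", "b", 3)]  # spans the link at position 3
        assert b3.contains_link
        plain_b3 = sum(dm.RESIDUE_MASSES[aa] for aa in "GAK") + PROTON
        assert b3.mz == pytest.approx(
            plain_b3 + peptide_mass(c.beta) + linkerchem.bridge_mass("BS2G"), abs=1e-9
        )

    def test_complementary_b_y_sum_constant(self):
        # b_i and y_(n-i) partition the peptide, so exactly one of the two
        # carries the link and their sum is constant across i
        alpha = Peptide("a", 1, 6, "GAKLGA")
        beta = Peptide("b", 20, 23, "AKGA")
        c = XLCandidate(alpha, beta, 3, 21, "BS2G")
        ions = {(i.series, i.index): i for i in fragment_ions(c) if i.peptide == "alpha"}
        n = 6
        sums = {
            round(ions[("b", i)].mz + ions[("y", n - i)].mz, 6) for i in range(2, n)
        }
        assert len(sums) == 1

    def test_neutral_loss_variants(self):
        ions = fragment_ions(self.make_candidate(), neutral_losses=True)
        losses = {i.neutral_loss for i in ions}
        assert losses == {"", "-H2O", "-NH3"}


class TestEnumerateCandidates:
    def test_only_chemically_valid_sites(self):
        peps_a = [Peptide("a", 1, 3, "GKG")]
        peps_b = [Peptide("b", 10, 12, "AKA")]
        cands = dm.enumerate_candidates(peps_a, peps_b, "BS2G")
        # K2 x K11, plus the protein N-terminus of peptide a (position 1)
        sites = {(c.link_pos_alpha, c.link_pos_beta) for c in cands}
        assert sites == {(2, 11), (1, 11)}
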