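"""PSSM/MSA profiles and Jensen-Shannon conservation scores."""

import math

import numpy as np
import pytest

from consite.conservation import (
    AA_INDEX, AA_ORDER, MappingError, PSSMFormatError, conservation_for_chain,
    jensen_shannon, load_background, parse_pssm, profile_from_msa,
)

from tests.conftest import build_structure

ONE_TO_THREE = {"A": "ALA", "G": "GLY", "W": "TRP", "C": "CYS", "L": "LEU"}


def write_pssm(tmp_path, rows):
    """rows: list of (letter, 20 percentages)."""
    head = "  ".join(AA_ORDER)
    lines = ["", "Last position-specific scoring matrix computed",
             "            " + head + "   " + head]
    for i, (letter, pct) in enumerate(rows, start=1):
        lines.append(
            f"{i:>5d} {letter} " + " ".join("0" for _ in range(20))
            + "  " + " ".join(str(int(v)) for v in pct) + "  0.40 0.90"
        )
    p = tmp_path / "test.pssm"
    p.write_text("\n".join(lines) + "\n")
    return p


def delta(letter):
    pct = [0] * 20
    pct[AA_INDEX[letter]] = 100
    return pct


class TestParsePSSM:
    def test_single_letter_position(self, tmp_path):
        path = write_pssm(tmp_path, [("A", delta("A")), ("G", delta("G")),
                                     ("W", [5] * 20)])
        prof = parse_pssm(path)
        assert prof.query == "AGW"
        expect = np.zeros(20)
        expect[AA_INDEX["A"]] = 1.0
        assert np.allclose(prof.frequencies[0], expect)
        assert np.allclose(prof.frequencies[2], np.full(20, 1 / 20))

    def test_zero_row_falls_back_to_background(self, tmp_path):
        path = write_pssm(tmp_path, [("A", [0] * 20)])
        bg = load_background()
        prof = parse_pssm(path, bg)
        assert np.allclose(prof.frequencies[0], bg.frequencies)

    def test_query_readback(self, tmp_path):
        letters = "AGWCL"
        path = write_pssm(tmp_path, [(l, delta(l)) for l in letters])
        assert parse_pssm(path).query == letters

    def test_malformed_row_reports_line(self, tmp_path):
        path = write_pssm(tmp_path, [("A", delta("A"))])
        text = path.read_text().splitlines()
        text[3] = "    1 A 1 2 3"  # truncated row
        path.write_text("\n".join(text))
        with pytest.raises(PSSMFormatError, match=":4"):
            parse_pssm(path)


class TestProfileFromMSA:
    def _write(self, tmp_path, seqs):
        p = tmp_path / "aln.fasta"
        p.write_text("".join(f">s{i}\n{s}\n" for i, s in enumerate(seqs)))
        return p

    def test_identical_sequences(self, tmp_path):
        prof = profile_from_msa(self._write(tmp_path, ["AG", "AG", "AG", "AG"]))
        assert prof.query == "AG"
        assert prof.frequencies[0][AA_INDEX["A"]] == 1.0
        assert prof.frequencies[1][AA_INDEX["G"]] == 1.0

    def test_even_split_column(self, tmp_path):
        prof = profile_from_msa(self._write(tmp_path, ["A", "A", "C", "C"]))
        assert prof.frequencies[0][AA_INDEX["A"]] == pytest.approx(0.5)
        assert prof.frequencies[0][AA_INDEX["C"]] == pytest.approx(0.5)

    def test_gaps_excluded(self, tmp_path):
        prof = profile_from_msa(self._write(tmp_path, ["A", "-", "A", "-"]))
        assert prof.frequencies[0][AA_INDEX["A"]] == 1.0

    def test_ragged_alignment_rejected(self, tmp_path):
        with pytest.raises(PSSMFormatError, match="ragged"):
            profile_from_msa(self._write(tmp_path, ["AG", "A"]))


class TestJensenShannon:
    def test_identity_zero(self):
        bg = load_background().frequencies
        assert jensen_shannon(bg, bg) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_support_is_one(self):
        p = np.zeros(20)
        q = np.zeros(20)
        p[:10] = 0.1
        q[10:] = 0.1
        assert jensen_shannon(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_scalar_oracle(self):
        p = np.full(20, 1 / 20)
        q = np.array([0.5] + [0.5 / 19] * 19)
        # frozen value from an independent term-by-term summation
        assert jensen_shannon(p, q) == pytest.approx(0.2053496997366378, rel=1e-12)

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            p = rng.dirichlet(np.full(20, rng.uniform(0.05, 2.0)))
            q = rng.dirichlet(np.full(20, rng.uniform(0.05, 2.0)))
            d = jensen_shannon(p, q)
            assert abs(d - jensen_shannon(q, p)) < 1e-12
            assert -1e-12 <= d <= 1.0 + 1e-12

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            jensen_shannon(np.full(20, 0.1), np.full(20, 1 / 20))


class TestConservationForChain:
    def _chain(self, letters):
        names = [ONE_TO_THREE[l] for l in letters]
        pos = [[3.8 * i, 0.0, 0.0] for i in range(len(letters))]
        return build_structure(pos, residue_names=names)

    def test_fully_conserved_position_scores_delta(self):
        st = self._chain("AGW")
        bg = load_background()
        freqs = np.zeros((3, 20))
        for i, l in enumerate("AGW"):
            freqs[i][AA_INDEX[l]] = 1.0
        from consite.conservation import SequenceProfile
        prof = SequenceProfile("AGW", freqs)
        out = conservation_for_chain(prof, bg, st, "A")
        for i, l in enumerate("AGW"):
            d = np.zeros(20)
            d[AA_INDEX[l]] = 1.0
            assert out.c_scores[(i + 1, "")] == pytest.approx(
                jensen_shannon(d, bg.frequencies))

    def test_background_profile_scores_zero(self):
        st = self._chain("AG")
        bg = load_background()
        from consite.conservation import SequenceProfile
        prof = SequenceProfile("AG", np.tile(bg.frequencies, (2, 1)))
        out = conservation_for_chain(prof, bg, st, "A")
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in out.c_scores.values())

    def test_unresolved_residue_gets_median_and_flag(self):
        # chain has an extra residue (G) absent from the profile query
        st = self._chain("AAGAA")
        bg = load_background()
        freqs = np.zeros((4, 20))
        freqs[:, AA_INDEX["A"]] = 1.0
        from consite.conservation import SequenceProfile
        prof = SequenceProfile("AAAA", freqs)
        out = conservation_for_chain(prof, bg, st, "A")
        assert out.unaligned == {(3, "")}
        aligned = [v for k, v in out.c_scores.items() if k != (3, "")]
        assert out.c_scores[(3, "")] == pytest.approx(np.median(aligned))

    def test_low_identity_rejected(self):
        st = self._chain("WWWWWWWWWW")
        bg = load_background()
        freqs = np.tile(bg.frequencies, (10, 1))
        from consite.conservation import SequenceProfile
        prof = SequenceProfile("AAAAAAAAAA", freqs)
        with pytest.raises(MappingError, match="identity"):
            conservation_for_chain(prof, bg, st, "A")

    def test_many_identical_homologs_converge_to_delta_score(self, tmp_path):
        """Appending many query-identical sequences drives every position's
        C_score to the fully conserved (single-letter) value."""
        rng = np.random.default_rng(4)
        letters = np.array(list(AA_ORDER))
        query = "".join(rng.choice(letters, 8))
        others = ["".join(rng.choice(letters, 8)) for _ in range(5)]
        deep = [query] * 500
        p1 = tmp_path / "a.fasta"
        p1.write_text("".join(f">s{i}\n{s}\n" for i, s in
                              enumerate([query] + others + deep)))
        prof = profile_from_msa(p1)
        bg = load_background()
        for i, l in enumerate(query):
            d = np.zeros(20)
            d[AA_INDEX[l]] = 1.0
            target = jensen_shannon(d, bg.frequencies)
            assert jensen_shannon(prof.frequencies[i], bg.frequencies) == \
                pytest.approx(target, abs=0.05)


def test_pssm_and_msa_routes_agree(pocket_files):
    """Conservation computed from the emitted PSSM matches the MSA route
    within the tolerance set by percentage rounding."""
    from consite.structure_io import parse_structure

    st, _ = parse_structure(pocket_files["pdb"])
    bg = load_background()
    via_pssm = conservation_for_chain(parse_pssm(pocket_files["pssm"], bg),
                                      bg, st, "A")
    via_msa = conservation_for_chain(profile_from_msa(pocket_files["msa"]),
                                     bg, st, "A")
    for key, v in via_pssm.c_scores.items():
        assert v == pytest.approx(via_msa.c_scores[key], abs=0.02)
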