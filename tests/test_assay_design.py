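"""Tryptic digestion, peptide mass, and PRM assay-rule tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prmpanel import assay_design as ad
from prmpanel.assay_design import (
    LibraryFragment,
    Peptide,
    digest,
    fragment_mz,
    gravy,
    heuristic_predictor,
    peptide_mass,
    select_precursor,
    select_transitions,
)

SEQ = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


class TestDigest:
    @pytest.mark.parametrize(
        "sequence, expected",
        [
            ("MAGICKEYSRPELLK", ["MAGICK", "EYSRPELLK"]),  # KR-not-before-P rule
            ("AAAQQQ", ["AAAQQQ"]),  # no cleavage site
            ("AKPRPG", ["AKPRPG"]),  # both sites suppressed by a following P
            ("AKRG", ["AK", "R", "G"]),
        ],
    )
    def test_fully_cleaved_products(self, sequence, expected):
        assert [p.sequence for p in digest(sequence, 0)] == expected

    @given(SEQ)
    @settings(max_examples=200, derandomize=True)
    def test_products_partition_the_input(self, sequence):
        products = [p.sequence for p in digest(sequence, 0)]
        assert "".join(products) == sequence

    @given(SEQ)
    @settings(max_examples=100, derandomize=True)
    def test_digestion_is_idempotent_on_products(self, sequence):
        for prod in digest(sequence, 0):
            assert [p.sequence for p in digest(prod.sequence, 0)] == [prod.sequence]

    def test_missed_cleavage_products(self):
        peps = digest("AKRG", 1)
        assert {(p.sequence, p.missed_cleavages) for p in peps} == {
            ("AK", 0), ("R", 0), ("G", 0), ("AKR", 1), ("RG", 1),
        }

    def test_non_standard_residue_names_offender(self):
        with pytest.raises(ad.SequenceFormatError, match="X"):
            digest("AKXR", 0)


class TestPeptideMass:
    def test_known_masses(self):
        assert peptide_mass("PEPTIDE") == pytest.approx(799.3600, abs=5e-4)
        assert peptide_mass("G") == pytest.approx(75.0320, abs=5e-4)

    @given(SEQ, SEQ)
    @settings(max_examples=100, derandomize=True)
    def test_additive_over_concatenation_minus_water(self, a, b):
        assert peptide_mass(a + b) == pytest.approx(
            peptide_mass(a) + peptide_mass(b) - 18.010565, abs=1e-9
        )

    @given(SEQ)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_pyteomics(self, sequence):
        from pyteomics import mass as pmass

        assert peptide_mass(sequence) == pytest.approx(
            pmass.calculate_mass(sequence=sequence), abs=1e-3
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("")


class TestPrecursorSelection:
    @pytest.mark.parametrize(
        "mass, expected",
        [
            (2000.0, (2, 1001.007276)),
            (2600.0, (3, 867.673943)),  # 2+ would sit at 1301 > 1250
            (120.0, None),  # every charge state below 350
        ],
    )
    def test_charge_priority_and_scan_range(self, mass, expected):
        got = select_precursor(mass)
        if expected is None:
            assert got is None
        else:
            z, mz = got
            assert z == expected[0]
            assert mz == pytest.approx(expected[1], abs=1e-3)

    def test_all_in_range_prefers_doubly_charged(self):
        z, _ = select_precursor(900.0)
        assert z == 2


class TestTransitionSelection:
    def test_top3_excluding_short_fragments(self):
        lib = [
            LibraryFragment("y", 4, 100), LibraryFragment("y", 3, 90),
            LibraryFragment("b", 2, 80), LibraryFragment("y", 7, 70),
            LibraryFragment("b", 5, 60), LibraryFragment("y", 1, 50),
        ]
        chosen = select_transitions("ELVISLIVESK", lib, k=3)
        assert [(t.series, t.ordinal) for t in chosen] == [("y", 4), ("y", 7), ("b", 5)]
        assert [t.rank for t in chosen] == [1, 2, 3]

    def test_exclusion_can_empty_the_library(self):
        lib = [LibraryFragment("y", 2, 100), LibraryFragment("b", 1, 90)]
        assert select_transitions("ELVISLIVESK", lib, k=3) is None

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError):
            select_transitions("ELVISLIVESK", [], k=3)

    def test_top_k_matches_brute_force(self):
        rng = np.random.default_rng(11)
        seq = "ELVISLIVESK"
        combos = [(s, o) for s in "by" for o in range(1, len(seq))]
        for _ in range(50):
            picks = rng.choice(len(combos), size=10, replace=False)
            lib = [
                LibraryFragment(*combos[i], float(rng.integers(1, 1000)))
                for i in picks
            ]
            intensity_of = {(f.series, f.ordinal): f.intensity for f in lib}
            eligible = sorted(
                (f.intensity for f in lib if f.ordinal >= 4), reverse=True
            )
            chosen = select_transitions(seq, lib, k=3)
            if len(eligible) < 3:
                assert chosen is None
            else:
                chosen_int = sorted(
                    (intensity_of[(t.series, t.ordinal)] for t in chosen), reverse=True
                )
                assert chosen_int == eligible[:3]

    def test_fragment_mz_complementarity(self):
        # b_i + y_(n-i) neutral masses sum to precursor + water + 2 protons on m/z scale
        seq = "SAMPLER"
        for i in range(4, len(seq)):
            b = fragment_mz(seq, "b", i)
            y = fragment_mz(seq, "y", len(seq) - i)
            assert b + y == pytest.approx(
                peptide_mass(seq) + 2 * 1.007276, abs=1e-6
            )


class TestSchedule:
    def test_window_centred_on_rt(self):
        assay = _toy_assay("LSSPATLNSR")
        (a,) = ad.build_schedule([assay], {"LSSPATLNSR": 20.0}, width=3.0)
        assert a.rt_window == (18.5, 21.5)

    def test_window_clipped_at_gradient_start(self):
        assay = _toy_assay("LSSPATLNSR")
        (a,) = ad.build_schedule([assay], {"LSSPATLNSR": 1.0}, width=3.0, gradient=(0, 60))
        assert a.rt_window == (0.0, 2.5)

    def test_missing_rt_is_an_error(self):
        with pytest.raises(ValueError, match="LSSPATLNSR"):
            ad.build_schedule([_toy_assay("LSSPATLNSR")], {})

    def test_max_concurrency_matches_sweep_oracle(self):
        rng = np.random.default_rng(5)
        starts = rng.uniform(0, 50, size=40)
        windows = [(s, s + 3.0) for s in starts]
        # brute-force: count open windows at every event point
        points = sorted(itertools.chain.from_iterable(windows))
        oracle = max(
            sum(s < t < e or (s == t) for s, e in windows) for t in points
        )
        assert ad.max_concurrency(windows) == oracle


class TestHeuristicPredictor:
    def test_deterministic(self):
        a = heuristic_predictor("ELVISLIVESK")
        b = heuristic_predictor("ELVISLIVESK")
        assert a == b

    def test_codomain(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(2000):
            seq = "".join(rng.choice(aas, size=int(rng.integers(5, 30))))
            assert 0.0 <= heuristic_predictor(seq).detectability <= 1.0

    def test_retention_follows_hydropathy(self):
        assert heuristic_predictor("LLLLLLLL").irt > heuristic_predictor("DDDDDDDD").irt
        assert gravy("LLLLLLLL") > gravy("DDDDDDDD")


class TestPtpFilter:
    def _index(self, *seqs, shared=()):
        idx = {s: {f"P{i}"} for i, s in enumerate(seqs)}
        for s in shared:
            idx[s] = {"P1", "P2"}
        return idx

    def test_short_peptide_rejected_for_length(self):
        peps = [Peptide("ACDEFK")]
        _, rej, _ = ad.filter_ptps(peps, heuristic_predictor, self._index("ACDEFK"))
        assert rej[0].reason == "length"

    def test_cysteine_rejected_as_forbidden_residue(self):
        peps = [Peptide("LLVGPCGAGK")]
        _, rej, _ = ad.filter_ptps(peps, heuristic_predictor, self._index("LLVGPCGAGK"))
        assert rej[0].reason == "forbidden_residue"

    def test_shared_peptide_rejected_before_other_rules(self):
        peps = [Peptide("ACDEFK")]  # would also fail length; uniqueness first
        _, rej, _ = ad.filter_ptps(
            peps, heuristic_predictor, self._index(shared=["ACDEFK"])
        )
        assert rej[0].reason == "not_unique"

    def test_clean_unique_peptide_accepted(self):
        pep = Peptide("LLVGAAGSGK")
        acc, rej, _ = ad.filter_ptps([pep], heuristic_predictor, self._index("LLVGAAGSGK"))
        assert [p.sequence for p, _ in acc] == ["LLVGAAGSGK"]
        assert rej == []

    def test_accepted_and_rejected_partition_the_input(self):
        from prmpanel import syndata

        proteome = syndata.generate_proteome(20, seed=4)
        idx = ad.build_uniqueness_index(proteome)
        peps, seen = [], set()
        for acc in sorted(proteome):
            for p in digest(proteome[acc], 0):
                if p.sequence not in seen:
                    seen.add(p.sequence)
                    peps.append(p)
        kept, rejections, uncovered = ad.filter_ptps(peps, heuristic_predictor, idx)
        assert len(kept) + len(rejections) <= len(peps)  # per-protein cap trims kept
        assert {r.reason for r in rejections} <= set(ad.REJECTION_REASONS)
        # nothing both kept and rejected
        kept_seqs = {p.sequence for p, _ in kept}
        assert kept_seqs.isdisjoint({r.peptide.sequence for r in rejections})

    def test_per_protein_cap_is_two(self):
        from prmpanel import syndata

        proteome = syndata.generate_proteome(30, seed=7)
        idx = ad.build_uniqueness_index(proteome)
        peps = [p for a in sorted(proteome) for p in digest(proteome[a], 0)]
        kept, _, _ = ad.filter_ptps(peps, heuristic_predictor, idx)
        per_protein = {}
        for p, _ in kept:
            (parent,) = p.parents
            per_protein[parent] = per_protein.get(parent, 0) + 1
        assert max(per_protein.values()) <= 2


class TestDesignedAssays:
    def test_all_assays_satisfy_invariants(self):
        from prmpanel import syndata

        proteome = syndata.generate_proteome(40, seed=9)
        assays, rejections, _ = ad.design_assays(
            proteome,
            library_for=lambda pep: syndata.generate_spectral_library(pep.sequence, 1),
        )
        assert len(assays) > 0
        for a in assays:
            a.validate(window_width=3.0)  # raises on violation
            assert 350 <= a.precursor_mz <= 1250
            assert len(a.transitions) >= 3
            assert all(t.ordinal >= 4 for t in a.transitions)
        starts = [a.rt_window[0] for a in assays]
        assert starts == sorted(starts)


def _toy_assay(seq: str) -> ad.PeptideAssay:
    pep = Peptide(seq, frozenset({"P1"}))
    z, mz = select_precursor(pep.mass)
    trans = [
        ad.Transition("y", o, 1, fragment_mz(seq, "y", o), r + 1)
        for r, o in enumerate((4, 5, 6))
    ]
    return ad.PeptideAssay(pep, z, mz, trans)
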