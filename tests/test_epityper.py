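"""In-silico mass-spec contracts: fragmentation, mass shifts, unit QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methsig.epityper import (
    RIBONUCLEOTIDE_MASS,
    TERMINAL_WATER,
    AmpliconAssay,
    Fragment,
    Primer,
    assign_cpg_units,
    bisulfite_and_fragment,
    check_assay_design,
    process_unit_matrix,
)

PRIMER_F = Primer("ATTGGTTATTGGAGGTGGATTAGGTT")
PRIMER_R = Primer("AAACCCTAAAACTAAACCAATACCAA")


def _assay(seq, reaction="T_reverse"):
    return AmpliconAssay("amp", seq, PRIMER_F, PRIMER_R, reaction=reaction)


def oracle_fragments(seq, reaction="T_reverse"):
    """Independent re-derivation: character loop, split at U, mass lookup."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if reaction == "T_forward":
        seq = "".join(comp[c] for c in reversed(seq))
    converted = "".join("T" if c == "C" else c for c in seq)
    rna = {"A": "U", "T": "A", "G": "C", "C": "G"}
    transcript = ""
    for c in reversed(converted):
        transcript += rna[c]
    frags, cur = [], ""
    for c in transcript:
        cur += c
        if c == "U":
            frags.append(cur)
            cur = ""
    if cur:
        frags.append(cur)
    masses = []
    for f in frags:
        m = TERMINAL_WATER
        for c in f:
            m += RIBONUCLEOTIDE_MASS[c]
        masses.append(round(m, 6))
    return sorted(zip(frags, masses))


@st.composite
def dna(draw, min_size=50, max_size=300):
    return "".join(
        draw(st.lists(st.sampled_from("ACGT"), min_size=min_size,
                      max_size=max_size))
    )


class TestFragmentation:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seq=dna(), reaction=st.sampled_from(["T_forward", "T_reverse"]))
    def test_matches_bruteforce_oracle(self, seq, reaction):
        frags = bisulfite_and_fragment(_assay(seq, reaction))
        got = sorted((f.sequence, round(f.base_mass, 6)) for f in frags)
        assert got == oracle_fragments(seq, reaction)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seq=dna(), data=st.data())
    def test_methylation_shift_is_16_per_cpg(self, seq, data):
        frags = bisulfite_and_fragment(_assay(seq))
        for f in frags:
            if f.n_cpg == 0:
                continue
            k = data.draw(st.integers(0, f.n_cpg))
            assert f.mass(k) - f.mass(0) == pytest.approx(16.0 * k, abs=1e-9)

    def test_no_u_transcript_single_fragment(self):
        # transcript U comes from A in the converted strand; A arises from
        # genomic A or (via conversion) C, so a G/T amplicon has no U
        frags = bisulfite_and_fragment(_assay("GT" * 60))
        assert len(frags) == 1
        assert frags[0].sequence == bisulfite_and_fragment(_assay("GT" * 60))[0].sequence

    def test_cpg_members_tracked(self):
        seq = "ATTACGGTTAAATTTACGTTTAAA"
        frags = bisulfite_and_fragment(_assay(seq))
        members = sorted(p for f in frags for p in f.cpg_genomic_positions)
        assert members == [i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"]

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            _assay("ACGTN")


class TestUnitAssignment:
    def _frag(self, idx, mass, n_cpg):
        return Fragment(
            index=idx, start=0, sequence="A", base_mass=mass,
            cpg_transcript_positions=list(range(n_cpg)),
            cpg_genomic_positions=list(range(n_cpg)),
        )

    def test_cpg_free_fragment_yields_no_unit(self):
        units = assign_cpg_units([self._frag(0, 2000.0, 0)])
        assert units == []

    def test_identical_base_masses_collide(self):
        frags = [self._frag(0, 2000.0, 1), self._frag(1, 2000.0, 1)]
        units = assign_cpg_units(frags)
        assert len(units) == 2
        assert all(not u.informative for u in units)
        assert all("mass_collision" in u.reasons for u in units)

    def test_collision_via_methylated_state(self):
        # 2016 = 2000 + 16: fragment B's base collides with A's +1CH3 state
        frags = [self._frag(0, 2000.0, 1), self._frag(1, 2016.0, 0)]
        units = assign_cpg_units(frags)
        assert not units[0].informative

    def test_mass_window(self):
        low = assign_cpg_units([self._frag(0, 900.0, 1)])
        high = assign_cpg_units([self._frag(0, 6995.0, 2)])  # +32 exits window
        ok = assign_cpg_units([self._frag(0, 3000.0, 2)])
        assert not low[0].informative and "mass_outside_window" in low[0].reasons
        assert not high[0].informative
        assert ok[0].informative

    def test_oracle_bruteforce_collision_enumeration(self, rng):
        # brute-force mass enumeration agrees with the collision flag
        for _ in range(20):
            frags = [
                self._frag(i, float(rng.integers(1600, 2600)),
                           int(rng.integers(0, 3)))
                for i in range(5)
            ]
            units = assign_cpg_units(frags)
            states = {f.index: [f.base_mass + 16.0 * k for k in range(f.n_cpg + 1)]
                      for f in frags}
            for u in units:
                expect = any(
                    abs(a - b) <= 1.0
                    for i, ss in states.items()
                    if i != u.fragment_index
                    for a in states[u.fragment_index]
                    for b in ss
                )
                window_ok = all(1500 <= s <= 7000
                                for s in states[u.fragment_index])
                assert u.informative == (window_ok and not expect)


class TestDesignChecks:
    def test_oversized_amplicon_fails(self):
        report = check_assay_design(_assay("ACGT" * 150))  # 600 bp
        assert not report.passed
        assert any("amplicon_length" in v for v in report.violations)

    def test_primer_with_cpg_fails(self):
        bad = Primer("ATTGGTTATTGGAGGTGGATCGGT")
        assay = AmpliconAssay("amp", "ACGT" * 75, PRIMER_F, bad)
        report = check_assay_design(assay)
        assert "primer_rev_contains_CpG" in report.violations

    def test_tm_difference_gate(self):
        short = Primer("ATTGGT")  # Tm far below a 26-mer's
        assay = AmpliconAssay("amp", "ACGT" * 75, PRIMER_F, short)
        report = check_assay_design(assay)
        assert "tm_difference_exceeds_tolerance" in report.violations

    def test_low_informative_ratio_fails(self):
        # CGA repeats cleave into tiny sub-window fragments: ratio ~ 0
        report = check_assay_design(_assay("CGA" * 80))
        assert report.informative_ratio < 0.7
        assert "informative_cpg_ratio_below_threshold" in report.violations


class TestUnitMatrixQc:
    def test_missingness_boundary(self):
        vals = np.tile(np.linspace(0.2, 0.8, 100), (3, 1))
        units = pd.DataFrame(vals, index=["u_ok", "u_20", "u_21"],
                             columns=[f"s{i}" for i in range(100)])
        units.iloc[1, :20] = np.nan  # exactly 20%: kept
        units.iloc[2, :21] = np.nan  # 21%: dropped
        clean, _ = process_unit_matrix(units, k_neighbors=1)
        assert list(clean.index) == ["u_ok", "u_20"]
        assert not clean.isna().to_numpy().any()

    def test_imputed_value_is_neighbor_mean(self):
        samples = [f"s{i}" for i in range(10)]
        base = np.linspace(0.1, 0.9, 10)
        rows = {"target": base.copy()}
        for i in range(5):
            rows[f"near{i}"] = base.copy()
            rows[f"near{i}"][0] = 0.7
        rows["far"] = np.zeros(10)
        units = pd.DataFrame(rows, index=samples).T
        units.loc["target", "s0"] = np.nan
        clean, _ = process_unit_matrix(units, k_neighbors=5)
        assert clean.loc["target", "s0"] == pytest.approx(0.7)

    def test_observed_entries_untouched(self, rng):
        units = pd.DataFrame(rng.random((20, 12)),
                             index=[f"u{i}" for i in range(20)],
                             columns=[f"s{i}" for i in range(12)])
        mask = rng.random(units.shape) < 0.1
        holed = units.mask(mask)
        clean, _ = process_unit_matrix(holed, k_neighbors=3)
        surviving = holed.loc[clean.index]
        observed = ~surviving.isna()
        np.testing.assert_allclose(clean.to_numpy()[observed.to_numpy()],
                                   surviving.to_numpy()[observed.to_numpy()])
        assert not clean.isna().to_numpy().any()

    def test_probe_aggregation_mean(self):
        units = pd.DataFrame(
            {"s0": [0.4, 0.6, 0.5]}, index=["p1_u0", "p1_u1", "p2_u0"]
        )
        mapping = pd.Series(["p1", "p1", "p2"],
                            index=["p1_u0", "p1_u1", "p2_u0"])
        _, probes = process_unit_matrix(units, mapping, k_neighbors=1)
        assert probes.loc["p1", "s0"] == pytest.approx(0.5)
        assert probes.loc["p2", "s0"] == pytest.approx(0.5)

    def test_k_larger_than_units_warns(self):
        units = pd.DataFrame(
            [[0.1, np.nan, 0.3, 0.2, 0.3],
             [0.2, 0.4, 0.2, 0.25, 0.3],
             [0.15, 0.35, 0.25, 0.2, 0.3]],
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(5)],
        )
        with pytest.warns(UserWarning, match="exceeds available"):
            process_unit_matrix(units, k_neighbors=50)

    def test_rejects_out_of_range_values(self):
        units = pd.DataFrame([[1.5, 0.2]], index=["u"], columns=["a", "b"])
        with pytest.raises(ValueError):
            process_unit_matrix(units)
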