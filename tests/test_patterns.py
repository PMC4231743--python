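"""Pattern dialect parsing, registry and scanning behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimscreen.patterns import (
    PXDLS_FAMILY,
    STANDARD_AA,
    MotifPattern,
    PatternSyntaxError,
    builtin_registry,
    parse_pattern,
    read_patterns_file,
    registry_pattern,
    scan_proteome,
    scan_sequence,
    write_patterns_file,
)
from slimscreen.proteome import ProteinRecord, Proteome

from .conftest import brute_force_hits, random_pattern, random_sequence


class TestParsing:
    @pytest.mark.parametrize(
        "raw,n_elements,min_len,max_len",
        [
            ("PX[NDS]LSX(1,2)[KR]", 7, 7, 8),
            ("[WFY]RP[WFY]", 4, 4, 4),
            ("[∧P]L[∧P][∧P]LL[∧P]", 7, 7, 7),
            ("RGD", 3, 3, 3),
            ("X(2,4)", 1, 2, 4),
            ("[ILV]QXXXRXXXX[RK]XX[FILVWY]", 14, 14, 14),
        ],
    )
    def test_element_counts_and_lengths(self, raw, n_elements, min_len, max_len):
        pat = parse_pattern(raw)
        assert len(pat.elements) == n_elements
        assert (pat.min_len, pat.max_len) == (min_len, max_len)

    def test_wedge_negation_normalized(self):
        pat = parse_pattern("[∧P]L[∧P][∧P]LL[∧P]")
        negated = [e for e in pat.elements if e.kind == "negated"]
        assert len(negated) == 4
        assert all(e.residues == ("P",) for e in negated)
        assert pat.raw == "[^P]L[^P][^P]LL[^P]"

    @pytest.mark.parametrize(
        "raw",
        [
            "",  # empty
            "P[NDS",  # unbalanced bracket
            "PX]",  # stray close
            "[KR](1,2)",  # repeat attached to a class
            "P(1,2)",  # repeat attached to a letter
            "[]LS",  # empty class
            "[^]LS",  # empty negated class
            "PXB",  # nonstandard residue letter
            "[NDB]",  # nonstandard residue inside class
            "X(2,1)",  # inverted repeat range
            "X(0,2)",  # zero repeat
            "X(1,2",  # unbalanced parenthesis
            "pxdls",  # lowercase is not part of the dialect
        ],
    )
    def test_parse_errors(self, raw):
        with pytest.raises(PatternSyntaxError):
            parse_pattern(raw)

    def test_repeat_after_wildcard_is_legal(self):
        pat = parse_pattern("PX(1,2)")
        assert (pat.min_len, pat.max_len) == (2, 3)

    def test_roundtrip_canonical(self):
        for pat in builtin_registry():
            assert pat.canonical == pat.raw
            again = parse_pattern(pat.canonical, pat.name)
            assert again.elements == pat.elements


class TestRegistry:
    def test_size_and_unique_names(self):
        reg = builtin_registry()
        assert len(reg) == 17
        assert len({p.name for p in reg}) == 17

    def test_contains_named_entries(self):
        reg = {p.name: p.raw for p in builtin_registry()}
        assert reg["RGD"] == "RGD"
        assert reg["PXDLS_strict"] == "PXDLSX(1,2)[KR]"
        assert reg["PXDLS_screen"] == "PX[NDS]LSX(1,2)[KR]"

    def test_family_cascade_names_exist(self):
        names = {p.name for p in builtin_registry()}
        assert set(PXDLS_FAMILY) <= names

    def test_registry_lookup_unknown(self):
        with pytest.raises(KeyError):
            registry_pattern("NOPE")

    def test_patterns_file_roundtrip(self, tmp_path):
        path = tmp_path / "patterns.tsv"
        write_patterns_file(builtin_registry(), path)
        back = read_patterns_file(path)
        assert [(p.name, p.raw) for p in back] == [
            (p.name, p.raw) for p in builtin_registry()
        ]


class TestScanning:
    def test_single_variable_length_hit(self):
        hits = scan_sequence(registry_pattern("PXDLS_strict"), "PADLSGK")
        assert [(h.start, h.end, h.peptide) for h in hits] == [(1, 7, "PADLSGK")]

    def test_mutant_control_never_matches(self):
        pat = registry_pattern("PXDLS_screen")
        assert scan_sequence(pat, "ASASA" * 3) == []

    def test_boundary_wildcard_requires_residue(self):
        pat = registry_pattern("NPF")  # XNPFX
        assert scan_sequence(pat, "NPFA") == []
        assert len(scan_sequence(pat, "ANPFA")) == 1

    def test_named_variant_peptide(self):
        hits = scan_sequence(registry_pattern("PXDLS_screen"), "PLNLSAAR")
        assert [(h.start, h.end) for h in hits] == [(1, 8)]

    def test_both_repeat_spans_reported(self):
        # X(1,2) followed by a class both satisfiable -> two ends, one start
        hits = scan_sequence(registry_pattern("PXDLS_strict"), "PADLSKKK")
        assert [(h.start, h.end) for h in hits] == [(1, 7), (1, 8)]

    def test_trailing_stop_and_case_normalized(self):
        hits = scan_sequence(registry_pattern("RGD"), "aaRGDaa*")
        assert [(h.start, h.end, h.peptide) for h in hits] == [(3, 5, "RGD")]

    def test_empty_sequence(self):
        assert scan_sequence(registry_pattern("RGD"), "") == []

    def test_negated_class_alphabet_sweep(self):
        hits = scan_sequence(parse_pattern("[^P]"), STANDARD_AA)
        assert len(hits) == 19
        assert all(h.peptide != "P" for h in hits)

    def test_hit_lengths_within_pattern_bounds(self):
        rng = np.random.default_rng(7)
        pat = registry_pattern("PXDLS_broad")
        seq = random_sequence(rng, 500)
        for h in scan_sequence(pat, seq):
            assert pat.min_len <= h.end - h.start + 1 <= pat.max_len
            assert h.peptide == seq.upper()[h.start - 1 : h.end]

    def test_shift_equivariance(self):
        pat = registry_pattern("PXDLS_screen")
        base = "PLNLSAARGG"
        shifted = "GGGG" + base
        h0 = [(h.start, h.end) for h in scan_sequence(pat, base)]
        h1 = [(h.start, h.end) for h in scan_sequence(pat, shifted)]
        assert h1 == [(s + 4, e + 4) for s, e in h0]


class TestOracleEquivalence:
    def test_seeded_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            pat = random_pattern(rng)
            seq = random_sequence(rng)
            got = {(h.start, h.end) for h in scan_sequence(pat, seq)}
            assert got == brute_force_hits(pat, seq)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_property_random_pattern_sequence(self, seed):
        rng = np.random.default_rng(seed)
        pat = random_pattern(rng, max_elements=6)
        seq = random_sequence(rng, 120)
        got = {(h.start, h.end) for h in scan_sequence(pat, seq)}
        assert got == brute_force_hits(pat, seq)

    def test_fixed_length_patterns_have_fixed_hits(self):
        rng = np.random.default_rng(11)
        pat = registry_pattern("WRPW")
        for _ in range(50):
            seq = random_sequence(rng, 150)
            for h in scan_sequence(pat, seq):
                assert h.end - h.start + 1 == pat.min_len


class TestProteomeScan:
    def test_empty_proteome(self):
        df = scan_proteome(builtin_registry(), Proteome([]))
        assert len(df) == 0
        assert df.attrs["patterns"][0] == "WRPW"

    def test_identical_isoforms_two_rows(self):
        prot = Proteome(
            [
                ProteinRecord("A.1", "GA", "AAPIDLSLKAA"),
                ProteinRecord("A.2", "GA", "AAPIDLSLKAA"),
            ]
        )
        df = scan_proteome([registry_pattern("PXDLS_screen")], prot)
        assert len(df) == 2
        assert df["gene"].nunique() == 1

    def test_scan_deterministic(self, toy_proteome):
        pats = builtin_registry()
        a = scan_proteome(pats, toy_proteome).to_csv(sep="\t", index=False)
        b = scan_proteome(pats, toy_proteome).to_csv(sep="\t", index=False)
        assert a == b
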