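"""Architecture calling, functionality prediction and lineage assignment."""

import random

import pytest

from pncc.catalog import scan_catalog
from pncc.classify import (
    Architecture,
    FunctionalCall,
    call_architecture,
    call_functionality,
    classify_sequence,
    classify_sequences,
)
from pncc.synth import (
    TRUTH_ARCHITECTURE,
    GeneratorConfig,
    generate_lineage_sequences,
)

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


def _classify_panel(panel, catalog):
    hints = dict(zip(panel.truth["id"], panel.truth["taxonomy_hint"]))
    return classify_sequences(panel.records, catalog, taxonomy=hints)


class TestArchitecture:
    @pytest.mark.parametrize(
        "lineage,expected",
        [
            ("1.2", Architecture.MOCF_CINA),
            ("2.2.2.1", Architecture.CINA_ONLY),
            ("1.3", Architecture.MOCF_ONLY),
            ("2.2.3.2", Architecture.CINA_NEXT_SHORT),
            ("2.2.3.3", Architecture.CINA_NEXT_LONG),
            ("2.2.3.4", Architecture.SPLIT_CINA),
        ],
    )
    def test_lineage_panels_get_their_architecture(
        self, catalog, clean_panels, lineage, expected
    ):
        for rid, seq in clean_panels[lineage].records:
            matches = scan_catalog(seq, catalog)
            arch = call_architecture(seq, matches, catalog)
            assert arch.call is expected, rid

    def test_short_sequence_is_unknown_with_warning(self, catalog):
        with pytest.warns(UserWarning, match="shorter"):
            arch = call_architecture("ACDEFGHIKL", {}, catalog)
        assert arch.call is Architecture.UNKNOWN

    def test_invariant_under_short_random_tail(self, catalog, clean_panels):
        rng = random.Random(13)
        for lineage in ("1.3", "2.2.3.1", "1.2"):
            rid, seq = clean_panels[lineage].records[0]
            base = call_architecture(seq, scan_catalog(seq, catalog), catalog).call
            tail = "".join(rng.choice(AA) for _ in range(10))
            extended = seq + tail
            again = call_architecture(
                extended, scan_catalog(extended, catalog), catalog
            ).call
            assert again is base

    def test_mocf_downstream_of_cina_is_not_a_fusion(self, catalog, clean_panels):
        # swap the domains of a clean two-domain sequence: CinA first
        panel = clean_panels["1.2"]
        rid, seq = panel.records[0]
        segs = panel.segments[rid]
        cina_start = min(s.start for s in segs if s.domain_tag == "cina")
        swapped = seq[cina_start:] + seq[:cina_start]
        arch = call_architecture(swapped, scan_catalog(swapped, catalog), catalog)
        assert arch.call is not Architecture.MOCF_CINA


class TestFunctionality:
    def test_active_sequence_passes_all_ten_checks(self, catalog, clean_panels):
        rid, seq = clean_panels["2.2.3.1"].records[0]
        matches = scan_catalog(seq, catalog)
        arch = call_architecture(seq, matches, catalog)
        func = call_functionality(seq, matches, catalog, arch)
        assert func.verdict == "active"
        assert len(func.checks) == 10
        assert all(v == "pass" for v in func.checks.values())

    def test_ydej_sequence_is_inactive_by_signature(self, catalog, clean_panels):
        rid, seq = clean_panels["2.2.2.2"].records[0]
        matches = scan_catalog(seq, catalog)
        arch = call_architecture(seq, matches, catalog)
        func = call_functionality(seq, matches, catalog, arch)
        assert func.verdict == "inactive"
        assert "YdeJ-like" in func.fired_signatures

    def test_unresolved_x_at_catalytic_lysine_is_indeterminate(
        self, catalog, clean_panels
    ):
        panel = clean_panels["2.2.3.1"]
        rid, seq = panel.records[0]
        p3 = next(s for s in panel.segments[rid] if s.entry_id == "P-III")
        mutated = seq[: p3.start + 5] + "X" + seq[p3.start + 6 :]
        matches = scan_catalog(mutated, catalog)
        arch = call_architecture(mutated, matches, catalog)
        func = call_functionality(mutated, matches, catalog, arch)
        assert func.verdict == "indeterminate"
        assert func.checks["P-III:2A9S:K63"] == "absent"

    def test_no_cina_domain_is_indeterminate(self, catalog, clean_panels):
        rid, seq = clean_panels["1.3"].records[0]
        matches = scan_catalog(seq, catalog)
        arch = call_architecture(seq, matches, catalog)
        func = call_functionality(seq, matches, catalog, arch)
        assert func.verdict == "indeterminate"
        assert func.reason == "no CinA domain"

    def test_active_with_fired_signature_is_rejected_at_construction(self):
        with pytest.raises(ValueError):
            FunctionalCall(verdict="active", fired_signatures=["YdeJ-like"])


class TestLineage:
    @pytest.mark.parametrize(
        "lineage",
        ["1.3", "2.2.1.2", "2.2.2.2", "2.2.3.2", "2.2.3.3", "2.2.3.4"],
    )
    def test_architecture_determined_lineages(self, catalog, clean_panels, lineage):
        # these labels follow from architecture/functionality alone (no hint)
        for rid, seq in clean_panels[lineage].records:
            rec = classify_sequence(rid, seq, catalog)
            assert rec.lineage == lineage

    def test_fingerprint_degenerate_set_needs_hint(self, catalog, clean_panels):
        rid, seq = clean_panels["1.2"].records[0]
        without = classify_sequence(rid, seq, catalog)
        assert without.lineage == "unassigned"
        assert without.confidence == 0.0
        with_hint = classify_sequence(rid, seq, catalog, taxonomy_hint="firmicutes")
        assert with_hint.lineage == "1.2"
        assert with_hint.taxonomy_hint_used

    def test_exemplar_tie_break(self, catalog, clean_panels):
        rid, seq = clean_panels["2.2.3.1"].records[0]
        other = clean_panels["2.2.3.1"].records[1][1]
        unrelated = clean_panels["2.2.2.1"].records[0][1]
        rec = classify_sequence(
            rid, seq, catalog,
            exemplars={"2.2.3.1": other, "2.2.2.1": unrelated[::-1]},
        )
        assert rec.lineage == "2.2.3.1"

    def test_zero_noise_confusion_matrix_is_diagonal(self, catalog, clean_panels):
        for lineage, panel in clean_panels.items():
            for rec, (_, row) in zip(
                _classify_panel(panel, catalog), panel.truth.iterrows()
            ):
                assert rec.lineage == row["lineage"]
                assert rec.functional_call.verdict == row["functionality"]
                assert rec.architecture.call.value == row["architecture"]

    def test_recovery_at_five_percent_noise(self, catalog):
        total = lineage_ok = functionality_ok = 0
        for lin in TRUTH_ARCHITECTURE:
            panel = generate_lineage_sequences(
                GeneratorConfig(lineage=lin, n=10, seed=7, substitution_rate=0.05),
                catalog,
            )
            for rec, (_, row) in zip(
                _classify_panel(panel, catalog), panel.truth.iterrows()
            ):
                total += 1
                lineage_ok += rec.lineage == row["lineage"]
                functionality_ok += rec.functional_call.verdict == row["functionality"]
        assert lineage_ok / total >= 0.95
        assert functionality_ok / total >= 0.95
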