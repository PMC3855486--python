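"""Information content, block detection and consensus rendering."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pncc.conservation import (
    LOG2_20,
    Alignment,
    ConservedBlock,
    column_information,
    consensus_string,
    detect_blocks,
    label_blocks,
)
from pncc.motif import parse_pattern, render_pattern
from pncc.synth import (
    GeneratorConfig,
    generate_lineage_sequences,
    generate_truth_alignment,
    truth_block_columns,
)

AA = sorted("ACDEFGHIKLMNPQRSTVWY")


class TestColumnInformation:
    def test_invariant_column_is_full_information(self):
        assert column_information(["G"] * 20) == pytest.approx(math.log2(20))

    def test_two_state_column(self):
        assert column_information(["A"] * 10 + ["G"] * 10) == pytest.approx(
            math.log2(20) - 1.0
        )

    def test_uniform_four_residues(self):
        assert column_information(list("ACDE")) == pytest.approx(math.log2(20) - 2.0)

    def test_small_sample_correction_subtracts_and_floors(self):
        n = 4
        expected = math.log2(20) - 2.0 - 19 / (2 * math.log(2) * n)
        assert column_information(list("ACDE"), correction=True) == pytest.approx(
            max(expected, 0.0)
        )
        # highly entropic small column would go negative without the floor
        assert column_information(list("ACDEFGHIKL"), correction=True) >= 0.0

    def test_gap_handling(self):
        assert column_information(["-"] * 5) == 0.0
        # more than half gaps scores zero
        assert column_information(["G", "G", "-", "-", "-"]) == 0.0
        # gaps excluded from the denominator otherwise
        assert column_information(["G", "G", "G", "-", "-"]) == pytest.approx(
            math.log2(20)
        )

    def test_empty_column_is_error(self):
        with pytest.raises(ValueError):
            column_information([])

    @given(
        st.lists(st.sampled_from(AA + ["-"]), min_size=1, max_size=40),
        st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_zero_to_log2_twenty(self, column, correction):
        r = column_information(column, correction=correction)
        assert 0.0 <= r <= LOG2_20 + 1e-12


class TestDetectBlocks:
    def test_single_constructed_block(self):
        rng = random.Random(3)
        rows = []
        for _ in range(20):
            row = [rng.choice(AA) for _ in range(20)]
            row[5:12] = list("GGLGPTW")
            rows.append("".join(row))
        aln = Alignment(ids=tuple(f"s{i}" for i in range(20)), rows=tuple(rows))
        blocks = detect_blocks(aln)
        assert [(b.start_col, b.end_col) for b in blocks] == [(5, 12)]

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError):
            Alignment(ids=("a",), rows=("ACDE",))

    def test_zero_noise_boundaries_equal_generator_truth(self, catalog):
        panel = generate_lineage_sequences(
            GeneratorConfig(lineage="2.2.3.1", n=20, seed=5, substitution_rate=0.0),
            catalog,
        )
        aln = generate_truth_alignment(panel, domain="cina")
        got = [(b.start_col, b.end_col) for b in detect_blocks(aln)]
        want = [(s, e) for _, s, e in truth_block_columns(panel, domain="cina")]
        assert got == want

    def test_row_shuffle_invariance(self, catalog):
        panel = generate_lineage_sequences(
            GeneratorConfig(lineage="1.3", n=12, seed=9), catalog
        )
        aln = generate_truth_alignment(panel, domain="mocf")
        order = list(range(aln.n_rows))
        random.Random(0).shuffle(order)
        shuffled = Alignment(
            ids=tuple(aln.ids[i] for i in order),
            rows=tuple(aln.rows[i] for i in order),
        )
        a = [(b.start_col, b.end_col) for b in detect_blocks(aln)]
        b = [(b.start_col, b.end_col) for b in detect_blocks(shuffled)]
        assert a == b


class TestConsensus:
    def _single_column(self, residues):
        aln = Alignment(
            ids=tuple(f"s{i}" for i in range(len(residues))),
            rows=tuple(residues),
        )
        return render_pattern(consensus_string(aln, (0, 1)))

    def test_invariant_column_is_strict(self):
        assert self._single_column(["G"] * 20) == "G!"

    def test_two_residue_bracket(self):
        # 55% T / 40% D: jointly above majority, singly below
        # (bracket sets render with residues in alphabetical order)
        col = ["T"] * 11 + ["D"] * 8 + ["A"]
        assert self._single_column(col) == "[DT]"

    def test_hydrophobic_class_column(self):
        col = ["A"] * 6 + ["V"] * 5 + ["L"] * 5 + ["I"] * 4
        assert self._single_column(col) == "h"

    def test_majority_literal(self):
        col = ["G"] * 14 + list("ACDEFH")
        assert self._single_column(col) == "G"

    def test_threshold_ordering_enforced(self):
        aln = Alignment(ids=("a", "b"), rows=("G", "G"))
        with pytest.raises(ValueError):
            consensus_string(aln, (0, 1), strict_threshold=0.5, majority_threshold=0.6)


class TestLabelBlocks:
    def _block(self, consensus, start=0):
        pat = parse_pattern(consensus, id="det")
        return ConservedBlock(
            start_col=start, end_col=start + len(pat), mean_information=4.0,
            consensus=pat,
        )

    def test_m3_consensus_labelled(self, catalog):
        [blk] = label_blocks([self._block("GGLGPTxDDxT")], catalog, domain_tag="mocf")
        assert blk.assigned_label == "M-III"

    def test_unrelated_consensus_unlabelled(self, catalog):
        [blk] = label_blocks([self._block("QQQQQ")], catalog, domain_tag="mocf")
        assert blk.assigned_label is None

    def test_tie_respects_canonical_order(self, catalog):
        # an all-wildcard consensus agrees fully with every pattern it can
        # cover; two such blocks must be labelled in increasing canonical order
        blocks = [self._block("xxxxxxxx", 0), self._block("xxxxxxxx", 10)]
        labelled = label_blocks(blocks, catalog, domain_tag="mocf", min_agreement=0.0)
        by_id = {e.id: e.canonical_order_index for e in catalog}
        orders = [by_id[b.assigned_label] for b in labelled]
        assert orders == sorted(orders) and len(set(orders)) == 2
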