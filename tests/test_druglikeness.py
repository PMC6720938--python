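"""Rule-of-five descriptors and the strict oral drug-likeness filter."""

import io
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import chain
from phytonet.chem_io import MolecularGraph
from phytonet.druglikeness import (
    LOGP_CONTRIBUTIONS,
    CompoundDescriptors,
    count_hba,
    count_hbd,
    count_rotatable_bonds,
    logp,
    molecular_weight,
    read_descriptor_table,
    ro5_pass,
    summarize_descriptors,
    write_descriptor_table,
)


class TestMolecularWeight:
    def test_ethanol(self, ethanol):
        assert molecular_weight(ethanol) == pytest.approx(46.07, abs=0.01)

    def test_methane(self):
        g = MolecularGraph(atoms=[("C", 0)], bonds=[])
        assert molecular_weight(g) == pytest.approx(16.04, abs=0.01)

    def test_glycine(self, glycine):
        assert molecular_weight(glycine) == pytest.approx(75.07, abs=0.01)


class TestHBondCounts:
    def test_hba(self, ethanol, glycine):
        assert count_hba(ethanol) == 1
        assert count_hba(chain(["C", "C", "C"])) == 0
        assert count_hba(glycine) == 3

    def test_hbd(self, ethanol, glycine):
        assert count_hbd(ethanol) == 1  # the OH
        assert count_hbd(chain(["C", "O", "C"])) == 0  # dimethyl ether
        # acetamide C-C(=O)-N: two NH hydrogens
        acetamide = MolecularGraph(
            atoms=[("C", 0), ("C", 0), ("O", 0), ("N", 0)],
            bonds=[(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0)],
        )
        assert count_hbd(acetamide) == 2
        assert count_hbd(glycine) == 3  # NH2 + OH


class TestRotatableBonds:
    def test_ethane_terminal(self):
        assert count_rotatable_bonds(chain(["C", "C"])) == 0

    def test_n_butane(self):
        assert count_rotatable_bonds(chain(["C"] * 4)) == 1

    def test_n_hexane(self):
        assert count_rotatable_bonds(chain(["C"] * 6)) == 3

    def test_ring_bonds_excluded(self, benzene):
        assert count_rotatable_bonds(benzene) == 0

    def test_amide_toggle(self):
        # CH3-C(=O)-N(H)-CH3: the C-N bond is rotatable by default only
        g = MolecularGraph(
            atoms=[("C", 0), ("C", 0), ("O", 0), ("N", 0), ("C", 0)],
            bonds=[(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0), (3, 4, 1.0)],
        )
        assert count_rotatable_bonds(g) == 1
        assert count_rotatable_bonds(g, exclude_amide=True) == 0


class TestLogP:
    def test_supplied_wins(self, ethanol):
        value, source = logp(ethanol, supplied=3.72)
        assert value == 3.72 and source == "supplied"

    def test_single_carbon_is_one_term(self):
        g = MolecularGraph(atoms=[("C", 0)], bonds=[])
        value, source = logp(g)
        expected = LOGP_CONTRIBUTIONS[("C", False, False)] + 4 * LOGP_CONTRIBUTIONS[("H", "on_C")]
        assert source == "computed"
        assert value == pytest.approx(expected)

    def test_matches_explicit_per_atom_loop(self, default_molecules):
        """Oracle: recompute contributions with an independent explicit loop."""
        from phytonet.chem_io import AROMATIC
        from phytonet.druglikeness import HETEROATOMS

        for rec in default_molecules[:10]:
            g = rec.graph
            adj = g.adjacency()
            arom = set()
            carbonyl_o = set()
            for i, j, o in g.bonds:
                if o == AROMATIC:
                    arom |= {i, j}
                if o == 2.0:
                    for a, b in ((i, j), (j, i)):
                        if g.atoms[a][0] == "O" and g.atoms[b][0] == "C":
                            carbonyl_o.add(a)
            expected = 0.0
            for idx, ((el, _), h) in enumerate(zip(g.atoms, g.implicit_h)):
                if idx in carbonyl_o:
                    key = ("=O", False, False)
                else:
                    het = any(g.atoms[v][0] in HETEROATOMS for v in adj[idx])
                    for key in [(el, idx in arom, het), (el, idx in arom, False),
                                (el, False, False)]:
                        if key in LOGP_CONTRIBUTIONS:
                            break
                expected += LOGP_CONTRIBUTIONS[key]
                expected += h * LOGP_CONTRIBUTIONS[("H", "on_het" if el in HETEROATOMS else "on_C")]
            assert logp(g)[0] == pytest.approx(expected)


class TestRo5:
    def test_study_median_compound_passes(self):
        d = CompoundDescriptors("median", 354.36, 5, 3, 3, 3.72)
        assert ro5_pass(d)

    def test_strict_boundary_fails(self):
        assert not ro5_pass(CompoundDescriptors("x", 500.0, 0, 0, 0, 0.0))

    def test_just_under_every_threshold_passes(self):
        assert ro5_pass(CompoundDescriptors("x", 499.9, 9, 4, 9, 4.9))

    @given(
        weight=st.floats(1.0, 499.99),
        a_acc=st.integers(0, 9),
        a_don=st.integers(0, 4),
        b_rotn=st.integers(0, 9),
        logp_v=st.floats(-5.0, 4.99),
        shrink=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_monotone_in_every_descriptor(self, weight, a_acc, a_don, b_rotn, logp_v, shrink):
        """Decreasing any descriptor of a passing compound never causes failure."""
        d = CompoundDescriptors("x", weight, a_acc, a_don, b_rotn, logp_v)
        assert ro5_pass(d)
        smaller = CompoundDescriptors(
            "y", max(1e-6, weight * shrink), int(a_acc * shrink),
            int(a_don * shrink), int(b_rotn * shrink), logp_v - (1 - shrink),
        )
        assert ro5_pass(smaller)

    def test_dropping_a_rule_never_shrinks_the_passing_set(self):
        rng = random.Random(3)
        table = [
            CompoundDescriptors(f"c{i}", rng.uniform(100, 700), rng.randrange(15),
                                rng.randrange(8), rng.randrange(15), rng.uniform(-2, 8))
            for i in range(200)
        ]
        full = {d.compound_id for d in table if ro5_pass(d)}
        without_weight = {d.compound_id for d in table
                          if d.a_don < 5 and d.a_acc < 10 and d.b_rotN < 10 and d.logP < 5}
        assert full <= without_weight

    def test_descriptors_invariant_under_reindexing(self, glycine):
        perm = [2, 0, 4, 1, 3]
        inv = {old: new for new, old in enumerate(perm)}
        relabeled = MolecularGraph(
            atoms=[glycine.atoms[i] for i in perm],
            bonds=[(inv[i], inv[j], o) for i, j, o in glycine.bonds],
        )
        assert molecular_weight(relabeled) == pytest.approx(molecular_weight(glycine))
        assert count_hba(relabeled) == count_hba(glycine)
        assert count_hbd(relabeled) == count_hbd(glycine)
        assert count_rotatable_bonds(relabeled) == count_rotatable_bonds(glycine)
        assert logp(relabeled)[0] == pytest.approx(logp(glycine)[0])


class TestSummary:
    def _row(self, cid, v):
        return CompoundDescriptors(cid, v, int(v) % 10, int(v) % 5, int(v) % 10, v / 100)

    def test_single_row_degenerate(self):
        s = summarize_descriptors([self._row("a", 10.0)])
        assert s.median["weight"] == s.mean["weight"] == 10.0
        assert s.std["weight"] == 0.0

    def test_three_values(self):
        s = summarize_descriptors([self._row("a", 1.0), self._row("b", 2.0), self._row("c", 3.0)])
        assert s.median["weight"] == 2.0
        assert s.mean["weight"] == 2.0
        assert s.std["weight"] == pytest.approx(1.0)

    def test_lower_middle_median_for_even_n(self):
        s = summarize_descriptors([self._row(str(i), float(v)) for i, v in enumerate([1, 2, 3, 4])])
        assert s.median["weight"] == 2.0

    def test_matches_numpy_oracle(self):
        rng = random.Random(9)
        table = [self._row(str(i), rng.uniform(50, 600)) for i in range(100)]
        s = summarize_descriptors(table)
        weights = np.array([d.weight for d in table])
        assert s.mean["weight"] == pytest.approx(weights.mean())
        assert s.std["weight"] == pytest.approx(weights.std(ddof=1))
        assert s.median["weight"] == pytest.approx(np.sort(weights)[49])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_descriptors([])


def test_descriptor_table_roundtrip():
    table = [CompoundDescriptors("a", 100.0, 2, 1, 3, 1.5, "supplied"),
             CompoundDescriptors("b", 350.5, 5, 3, 3, 3.72, "computed")]
    text = write_descriptor_table(table)
    back = read_descriptor_table(io.StringIO(text))
    assert [(d.compound_id, d.weight, d.a_acc, d.logP) for d in back] == [
        ("a", 100.0, 2, 1.5), ("b", 350.5, 5, 3.72)]


def test_invalid_descriptor_values_rejected():
    with pytest.raises(ValueError):
        CompoundDescriptors("x", -1.0, 0, 0, 0, 0.0)
    with pytest.raises(ValueError):
        CompoundDescriptors("x", 100.0, -2, 0, 0, 0.0)
    with pytest.raises(ValueError):
        CompoundDescriptors("x", 100.0, 0, 0, 0, math.inf)
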