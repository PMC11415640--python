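import itertools

import networkx as nx
import pytest

from npfrag.chem import (
    ElementComposition,
    get_adduct,
    monoisotopic_mass,
    parse_molecule,
)
from npfrag.errors import ConfigurationError, RuleDefinitionError
from npfrag.fragmenter import (
    FLAVONOID_13_ELIMINATION,
    FragmenterConfig,
    MolGraph,
    ReconstructionRule,
    apply_reconstruction_rules,
    enumerate_cleavage_sets,
    fragment_molecule,
    h_rearrangement_options,
    precursor_ion,
    _reconstruct,
)
from npfrag.knowledge import RANK_VALUES


class TestHRearrangementOptions:
    @pytest.mark.parametrize(
        "e1,e2,n,expected",
        [
            ("C", "O", 1, {-1, 0}),
            ("O", "C", 1, {0, 1}),
            ("C", "C", 1, {-1, 0, 1}),
            ("C", "O", 2, {-2, 0}),
            ("C", "N", 1, {-1, 0}),
            ("N", "O", 1, {-1, 0}),
            ("P", "S", 2, {-2, 0, 2}),
        ],
    )
    def test_rank_value_rule(self, e1, e2, n, expected):
        assert set(h_rearrangement_options(e1, e2, n)) == expected

    def test_invalid_bond_order(self):
        with pytest.raises(ConfigurationError):
            h_rearrangement_options("C", "C", 3)


# ---------------------------------------------------------------------------
# Cleavage-set enumeration vs a brute-force oracle


def _oracle_sets(rdmol, max_acyclic=2, max_ring_pairs=2):
    """Independent enumeration: all bond subsets that are either <=2 bridges
    or unions of 1-2 two-edge ring cuts, and that split the graph with every
    cut bond straddling two components."""
    g = nx.Graph()
    for atom in rdmol.GetAtoms():
        g.add_node(atom.GetIdx())
    for bi, bond in enumerate(rdmol.GetBonds()):
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), index=bi)
    bridges = set()
    for u, v in nx.bridges(g):
        bridges.add(g.edges[u, v]["index"])
    all_bonds = {g.edges[e]["index"]: e for e in g.edges}
    ring_bonds = [bi for bi in all_bonds if bi not in bridges]

    def valid(bond_set):
        h = g.copy()
        for bi in bond_set:
            h.remove_edge(*all_bonds[bi])
        comps = list(nx.connected_components(h))
        if len(comps) < 2:
            return False
        comp_of = {}
        for ci, comp in enumerate(comps):
            for a in comp:
                comp_of[a] = ci
        return all(
            comp_of[all_bonds[bi][0]] != comp_of[all_bonds[bi][1]]
            for bi in bond_set
        )

    out = set()
    for r in range(1, max_acyclic + 1):
        for sub in itertools.combinations(sorted(bridges), r):
            if valid(sub):
                out.add(frozenset(sub))
    cuts = [
        pair
        for pair in itertools.combinations(sorted(ring_bonds), 2)
        if valid(pair)
    ]
    if max_ring_pairs >= 1:
        out.update(frozenset(p) for p in cuts)
    if max_ring_pairs >= 2:
        for p1, p2 in itertools.combinations(cuts, 2):
            union = frozenset(p1) | frozenset(p2)
            if len(union) == 4 and valid(tuple(union)):
                out.add(union)
    return out


class TestEnumerateCleavageSets:
    def test_ethanol_has_two_single_bond_cleavages(self):
        mol = parse_molecule("CCO")
        sets = enumerate_cleavage_sets(mol)
        singles = [cs for cs in sets if len(cs.bonds) == 1]
        assert len(singles) == 2

    def test_benzene_ring_pairs(self):
        mol = parse_molecule("c1ccccc1")
        sets = enumerate_cleavage_sets(mol)
        assert sum(1 for cs in sets if len(cs.bonds) == 1) == 0
        assert sum(1 for cs in sets if len(cs.bonds) == 2) == 15

    def test_single_atom_molecule(self):
        assert enumerate_cleavage_sets(parse_molecule("C")) == []

    @pytest.mark.parametrize(
        "smiles",
        [
            "CCO",
            "CC(C)C(=O)O",
            "c1ccccc1",
            "c1ccncc1",
            "Cc1ccco1",
            "OC1CCCCC1",
            "C1CC2CCC1C2",  # fused bicyclic
            "CC(=O)Oc1ccccc1",
        ],
    )
    def test_matches_brute_force_oracle(self, smiles):
        mol = parse_molecule(smiles)
        got = {frozenset(cs.bonds) for cs in enumerate_cleavage_sets(mol)}
        assert got == _oracle_sets(mol.rdmol)

    def test_every_set_disconnects(self):
        mol = parse_molecule("COc1ccc(CC(=O)O)cc1")
        for cs in enumerate_cleavage_sets(mol):
            assert len(cs.components) >= 2


# ---------------------------------------------------------------------------
# Depth-1 fragment compositions vs a brute-force oracle


def _oracle_depth1_compositions(mol, polarity):
    """Re-derive all depth-1 ion compositions independently of the engine."""
    rdmol = mol.rdmol
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    n_h = [a.GetTotalNumHs() for a in rdmol.GetAtoms()]
    bonds = []
    for b in rdmol.GetBonds():
        order = 2 if (b.GetIsAromatic() or b.GetBondTypeAsDouble() >= 2) else 1
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    h_delta = 1 if polarity == "positive" else -1
    charge = 1 if polarity == "positive" else -1
    results = set()
    for bond_set in _oracle_sets(rdmol):
        g = nx.Graph()
        g.add_nodes_from(range(len(symbols)))
        for bi, (i, j, _o) in enumerate(bonds):
            if bi not in bond_set:
                g.add_edge(i, j)
        comps = [frozenset(c) for c in nx.connected_components(g)]
        # bare-atom excision rule: no interior lone atom
        cut_count = {ci: 0 for ci in range(len(comps))}
        comp_of = {}
        for ci, comp in enumerate(comps):
            for a in comp:
                comp_of[a] = ci
        for bi in bond_set:
            cut_count[comp_of[bonds[bi][0]]] += 1
            cut_count[comp_of[bonds[bi][1]]] += 1
        if any(len(c) == 1 and cut_count[ci] >= 2 for ci, c in enumerate(comps)):
            continue
        opts = []
        for bi in sorted(bond_set):
            i, j, order = bonds[bi]
            r1, r2 = RANK_VALUES[symbols[i]], RANK_VALUES[symbols[j]]
            if r1 == r2:
                o = (-order, 0, order)
            elif r1 > r2:
                o = (0, order)
            else:
                o = (-order, 0)
            opts.append((i, j, o))
        for combo in itertools.product(*(o for _, _, o in opts)):
            deltas = {ci: 0 for ci in range(len(comps))}
            for (i, j, _), hx in zip(opts, combo):
                deltas[comp_of[i]] += hx
                deltas[comp_of[j]] -= hx
            base_h = {
                ci: sum(n_h[a] for a in comp) for ci, comp in enumerate(comps)
            }
            if any(base_h[ci] + deltas[ci] < 0 for ci in deltas):
                continue
            for ci, comp in enumerate(comps):
                counts = {}
                for a in comp:
                    counts[symbols[a]] = counts.get(symbols[a], 0) + 1
                h = base_h[ci] + deltas[ci] + h_delta
                if h < 0:
                    continue
                counts["H"] = h
                comp_obj = ElementComposition.from_dict(
                    {k: v for k, v in counts.items() if v}, charge=charge
                )
                if polarity == "negative" and comp_obj.carbon_only:
                    continue
                results.add((comp_obj.counts, charge))
    return results


class TestFragmentMolecule:
    @pytest.mark.parametrize(
        "smiles,polarity",
        [
            ("CCO", "positive"),
            ("CC(=O)O", "negative"),
            ("Cc1ccc(O)cc1", "negative"),
            ("c1ccncc1", "positive"),
            ("OCC1OC(O)C(O)C1O", "negative"),
        ],
    )
    def test_depth1_composition_oracle(self, smiles, polarity):
        mol = parse_molecule(smiles)
        ions = fragment_molecule(mol, polarity, max_depth=1, rules=[])
        got = {(f.composition.counts, f.composition.charge) for f in ions}
        assert got == _oracle_depth1_compositions(mol, polarity)

    def test_syringic_acid_sequential_loss_chain(self, syringic_fragments_d3):
        """The printed negative-mode peak chain (CH3•, 2xCH3, +CO2, +CO) is
        reproduced within 5 mDa."""
        mzs = [f.theoretical_mz for f in syringic_fragments_d3]
        for printed in (182.0217, 166.9999, 123.0072, 95.0131):
            assert min(abs(mz - printed) for mz in mzs) < 0.005

    def test_toluene_negative_mode_is_empty(self):
        # all fragments would be carbon-only, which negative mode forbids
        ions = fragment_molecule(parse_molecule("Cc1ccccc1"), "negative")
        assert ions == []

    def test_mass_balance(self, syringic, syringic_fragments_d3):
        prec = precursor_ion(syringic, "[M-H]-")
        prec_mz = monoisotopic_mass(prec)
        for f in syringic_fragments_d3:
            assert f.theoretical_mz + monoisotopic_mass(f.neutral_loss) == pytest.approx(
                prec_mz, abs=1e-4
            )
            # exact count-level conservation
            total = [
                a + b
                for a, b in zip(f.composition.counts, f.neutral_loss.counts)
            ]
            assert tuple(total) == prec.counts

    def test_h_shift_bounded_by_bond_orders(self, syringic_fragments_d3):
        for f in syringic_fragments_d3:
            assert abs(f.h_shift_total) <= 2 * max(f.n_bonds_cleaved, 1)

    def test_depth_monotonicity(self, syringic):
        sets = []
        for depth in (1, 2, 3):
            ions = fragment_molecule(syringic, "negative", max_depth=depth)
            sets.append({f.composition.counts for f in ions})
        assert sets[0] <= sets[1] <= sets[2]

    def test_radical_flag_tracks_electron_parity(self, syringic_fragments_d3):
        for f in syringic_fragments_d3:
            assert f.radical == f.composition.odd_electron

    def test_polarity_adduct_mismatch(self, syringic):
        with pytest.raises(ConfigurationError):
            fragment_molecule(syringic, "positive", "[M-H]-")

    def test_non_hydrogen_adduct_rejected(self, syringic):
        with pytest.raises(ConfigurationError):
            fragment_molecule(syringic, "negative", "[M+Cl]-")

    def test_deduplication_keeps_lowest_depth(self, syringic):
        ions = fragment_molecule(syringic, "negative", max_depth=3)
        seen = {}
        for f in ions:
            key = (f.composition.counts, f.composition.charge)
            assert key not in seen
            seen[key] = f


class TestReconstructionRules:
    def test_acacetin_positive_peak(self, acacetin):
        """1,3-elimination explains the printed positive-mode acacetin peak."""
        ions = apply_reconstruction_rules(
            acacetin, "positive", "[M+H]+", max_depth=3,
            config=FragmenterConfig(max_depth=3),
        )
        assert any(abs(f.theoretical_mz - 139.0559) < 0.005 for f in ions)
        assert all(f.via_reconstruction for f in ions)

    def test_acacetin_second_reconstruction_peak(self, acacetin):
        ions = apply_reconstruction_rules(
            acacetin, "positive", "[M+H]+", config=FragmenterConfig(max_depth=2)
        )
        assert any(abs(f.theoretical_mz - 168.057) < 0.005 for f in ions)

    def test_formononetin_negative_peaks(self, formononetin):
        ions = apply_reconstruction_rules(
            formononetin, "negative", "[M-H]-",
            config=FragmenterConfig(max_depth=3),
        )
        mzs = [f.theoretical_mz for f in ions]
        assert min(abs(mz - 167.0491) for mz in mzs) < 0.005
        assert min(abs(mz - 179.0459) for mz in mzs) < 0.005

    def test_peak_absent_without_rules_at_depth2(self, acacetin):
        ions = fragment_molecule(
            acacetin, "positive", "[M+H]+", max_depth=2, rules=[]
        )
        assert all(abs(f.theoretical_mz - 139.0559) >= 0.005 for f in ions)

    def test_no_trigger_no_products(self, syringic):
        assert apply_reconstruction_rules(syringic, "negative", "[M-H]-") == []

    def test_product_conserves_atoms(self, acacetin):
        graph = MolGraph.from_rdmol(acacetin.rdmol)
        parent_vec = graph.comp_vector(frozenset(range(graph.n_atoms())))
        for product, rule in _reconstruct(
            graph, acacetin.rdmol, FLAVONOID_13_ELIMINATION
        ):
            prod_vec = product.comp_vector(frozenset(range(product.n_atoms())))
            piece = [a - b for a, b in zip(parent_vec, prod_vec)]
            assert piece == list(rule.neutral_piece.counts)

    def test_nonconserving_rule_rejected(self, acacetin):
        bad = ReconstructionRule(
            name="broken",
            smarts=FLAVONOID_13_ELIMINATION.smarts,
            remove_positions=FLAVONOID_13_ELIMINATION.remove_positions,
            add_bonds=FLAVONOID_13_ELIMINATION.add_bonds,
            neutral_piece=ElementComposition.from_formula("CO"),
        )
        with pytest.raises(RuleDefinitionError):
            fragment_molecule(acacetin, "positive", "[M+H]+", rules=[bad])
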