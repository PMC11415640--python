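"""Knowledge-based combinatorial fragment generation.

The generator enumerates bond-cleavage events on the molecular graph —
either up to two acyclic (bridge) bonds or ring-opening events that cleave
two bonds of the same ring — applies the rank-value H-rearrangement rule to
every cleaved bond, lets either side of each cleavage retain the charge,
and emits theoretical fragment ions.  Charged products are fragmented
recursively up to a configurable depth, so sequential neutral-loss chains
(e.g. CH3• then CO2 then CO) emerge naturally.

Charge bookkeeping is composition-level: the precursor ion of an [M+H]+ /
[M-H]- measurement carries a hydrogen delta of +1/-1 relative to the
neutral structure, and that delta travels with whichever fragment keeps
the charge, adjusted by the per-bond H shifts.  In negative mode fragment
ions must contain at least one heteroatom (carbon-only anions are
essentially never observed).

A registry of cleavage-reconstruction rules covers rearrangement reactions
that plain bond cleavage cannot reach; the default registry ships the
flavonoid "1,3 elimination": loss of CO2 from the C-ring of a (iso)flavone
with reformation of a four-membered ring, whose products are then
fragmented like any other precursor.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

from rdkit import Chem

from .chem import (
    ELEMENTS,
    ElementComposition,
    Molecule,
    AdductType,
    get_adduct,
    monoisotopic_mass,
)
from .errors import ConfigurationError, RuleDefinitionError
from .knowledge import RANK_VALUES

_E_INDEX = {e: i for i, e in enumerate(ELEMENTS)}
_H = _E_INDEX["H"]


# ---------------------------------------------------------------------------
# Lightweight molecular graph (heavy atoms + per-atom H counts)


class MolGraph:
    """Heavy-atom graph with per-atom hydrogen counts and 1/2 bond orders.

    Aromatic (and triple) bonds are treated as order 2 for the purpose of
    H-rearrangement limits; everything else is order 1.
    """

    __slots__ = ("symbols", "n_h", "bonds", "adj", "atom_vecs")

    def __init__(self, symbols, n_h, bonds):
        self.symbols = tuple(symbols)
        self.n_h = tuple(n_h)
        self.bonds = tuple(bonds)  # (i, j, order)
        adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(symbols))}
        for bi, (i, j, _o) in enumerate(self.bonds):
            adj[i].append((j, bi))
            adj[j].append((i, bi))
        self.adj = {k: tuple(v) for k, v in adj.items()}
        # per-atom element count vectors (element + its hydrogens)
        vecs = []
        for sym, nh in zip(self.symbols, self.n_h):
            v = [0] * len(ELEMENTS)
            v[_E_INDEX[sym]] += 1
            v[_H] += nh
            vecs.append(tuple(v))
        self.atom_vecs = tuple(vecs)

    @classmethod
    def from_rdmol(cls, rdmol: Chem.Mol) -> "MolGraph":
        symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
        n_h = [a.GetTotalNumHs() for a in rdmol.GetAtoms()]
        bonds = []
        for b in rdmol.GetBonds():
            order = 2 if (b.GetIsAromatic() or b.GetBondTypeAsDouble() >= 2) else 1
            bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return cls(symbols, n_h, bonds)

    def n_atoms(self) -> int:
        return len(self.symbols)

    def comp_vector(self, atoms) -> list[int]:
        vec = [0] * len(ELEMENTS)
        for a in atoms:
            av = self.atom_vecs[a]
            for k in range(len(ELEMENTS)):
                vec[k] += av[k]
        return vec

    def components(self, atoms: frozenset, removed_bonds: frozenset):
        """Connected components of the induced subgraph minus removed bonds."""
        seen = set()
        comps = []
        for start in sorted(atoms):
            if start in seen:
                continue
            stack = [start]
            seen.add(start)
            comp = [start]
            while stack:
                u = stack.pop()
                for v, bi in self.adj[u]:
                    if v in atoms and v not in seen and bi not in removed_bonds:
                        seen.add(v)
                        stack.append(v)
                        comp.append(v)
            comps.append(frozenset(comp))
        return comps


def _graph_from_molecule(mol: Molecule | Chem.Mol | MolGraph) -> MolGraph:
    if isinstance(mol, MolGraph):
        return mol
    if isinstance(mol, Molecule):
        return MolGraph.from_rdmol(mol.rdmol)
    return MolGraph.from_rdmol(mol)


# ---------------------------------------------------------------------------
# H-rearrangement options


def h_rearrangement_options(
    elem1: str,
    elem2: str,
    bond_order: int,
    rank_values: dict[str, int] | None = None,
) -> tuple[int, ...]:
    """Allowed H shifts ``Hx`` for cleaving an ``elem1–elem2`` bond.

    ``Hx > 0`` means the elem1-side fragment gains hydrogens; ``Hx = 0`` is
    homolytic cleavage into two radicals.  With ranks R: equal ranks allow
    ``n*{-1,0,+1}``; R1 > R2 allows ``n*{0,+1}``; R1 < R2 allows
    ``n*{-1,0}``, where ``n`` is 1 for single bonds and 2 for double or
    aromatic bonds.
    """
    if bond_order not in (1, 2):
        raise ConfigurationError(f"bond order must be 1 or 2, got {bond_order}")
    rv = rank_values or RANK_VALUES
    r1, r2 = rv.get(elem1, 0), rv.get(elem2, 0)
    n = bond_order
    if r1 == r2:
        return (-n, 0, n)
    if r1 > r2:
        return (0, n)
    return (-n, 0)


# ---------------------------------------------------------------------------
# Cleavage-set enumeration


@dataclass(frozen=True)
class CleavageSet:
    """A set of simultaneously cleaved bonds that disconnects the graph."""

    bonds: tuple[int, ...]  # bond indices in the parent graph
    kind: str  # "acyclic" | "ring-opening"
    n_acyclic: int
    n_ring_pairs: int
    components: tuple[frozenset, ...] = field(compare=False, default=())


def _find_bridges(graph: MolGraph, atoms: frozenset, live_set: set[int]) -> set[int]:
    """Bridge bonds of the induced subgraph (iterative Tarjan low-link)."""
    disc: dict[int, int] = {}
    low: dict[int, int] = {}
    bridges: set[int] = set()
    counter = 0
    for root in sorted(atoms):
        if root in disc:
            continue
        stack = [(root, -1, iter(graph.adj[root]))]
        disc[root] = low[root] = counter
        counter += 1
        while stack:
            u, parent_bond, it = stack[-1]
            advanced = False
            for v, bi in it:
                if v not in atoms or bi not in live_set:
                    continue
                if v not in disc:
                    disc[v] = low[v] = counter
                    counter += 1
                    stack.append((v, bi, iter(graph.adj[v])))
                    advanced = True
                    break
                elif bi != parent_bond:
                    low[u] = min(low[u], disc[v])
            if not advanced:
                stack.pop()
                if stack:
                    pu = stack[-1][0]
                    low[pu] = min(low[pu], low[u])
                    if low[u] > disc[pu]:
                        bridges.add(parent_bond)
    return bridges


def _validated(graph: MolGraph, atoms, bonds, kind, n_ac, n_rp):
    removed = frozenset(bonds)
    comps = graph.components(atoms, removed)
    if len(comps) < 2:
        return None
    comp_of = {}
    for ci, comp in enumerate(comps):
        for a in comp:
            comp_of[a] = ci
    # every cleaved bond must straddle two distinct components
    if any(comp_of[graph.bonds[bi][0]] == comp_of[graph.bonds[bi][1]] for bi in bonds):
        return None
    return CleavageSet(tuple(bonds), kind, n_ac, n_rp, tuple(comps))


def _enumerate_sets(
    graph: MolGraph,
    atoms: frozenset,
    max_acyclic: int,
    max_ring_pairs: int,
) -> list[CleavageSet]:
    live = [
        bi for bi, (i, j, _o) in enumerate(graph.bonds) if i in atoms and j in atoms
    ]
    if len(atoms) < 2 or not live:
        return []
    bridges = _find_bridges(graph, atoms, set(live))
    acyclic = sorted(bi for bi in live if bi in bridges)
    ring_bonds = sorted(bi for bi in live if bi not in bridges)

    out: list[CleavageSet] = []
    for r in range(1, max_acyclic + 1):
        for sub in itertools.combinations(acyclic, r):
            cs = _validated(graph, atoms, sub, "acyclic", r, 0)
            if cs is not None:
                out.append(cs)

    # a ring-opening pair is any 2-edge cut of the ring system
    pairs: list[CleavageSet] = []
    if max_ring_pairs >= 1:
        for pair in itertools.combinations(ring_bonds, 2):
            cs = _validated(graph, atoms, pair, "ring-opening", 0, 1)
            if cs is not None:
                pairs.append(cs)
        out.extend(pairs)
    if max_ring_pairs >= 2:
        seen_unions = set()
        for c1, c2 in itertools.combinations(pairs, 2):
            union = frozenset(c1.bonds) | frozenset(c2.bonds)
            if len(union) < 4 or union in seen_unions:
                continue
            seen_unions.add(union)
            cs = _validated(
                graph, atoms, tuple(sorted(union)), "ring-opening", 0, 2
            )
            if cs is not None:
                out.append(cs)
    return out


def enumerate_cleavage_sets(
    mol: Molecule | Chem.Mol | MolGraph,
    max_acyclic: int = 2,
    max_ring_pairs: int = 2,
) -> list[CleavageSet]:
    """All deduplicated cleavage sets that disconnect the molecular graph.

    A set is either up to ``max_acyclic`` bridge bonds or up to
    ``max_ring_pairs`` within-ring bond pairs (a single ring bond alone
    never disconnects a graph).
    """
    if max_acyclic < 0 or max_ring_pairs < 0:
        raise ConfigurationError("cleavage limits must be non-negative")
    graph = _graph_from_molecule(mol)
    atoms = frozenset(range(graph.n_atoms()))
    return _enumerate_sets(graph, atoms, max_acyclic, max_ring_pairs)


# ---------------------------------------------------------------------------
# Reconstruction rules

_CO2 = ElementComposition.from_formula("CO2")


@dataclass(frozen=True)
class ReconstructionRule:
    """A cleave-then-reform rearrangement triggered by a substructure.

    ``remove_positions`` are indices into the SMARTS match that leave as
    the neutral piece; ``add_bonds`` are pairs of match indices joined by
    new single bonds to reform the ring.
    """

    name: str
    smarts: str
    remove_positions: tuple[int, ...]
    add_bonds: tuple[tuple[int, int], ...]
    neutral_piece: ElementComposition
    applicable_classes: tuple[str, ...] = ()

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise RuleDefinitionError(f"bad SMARTS in rule {self.name!r}")
        return patt


#: Flavonoid/isoflavonoid C-ring CO2 loss with four-membered-ring reformation
#: ("1,3 elimination").  Match order: carbonyl O, C4, C3, C2, O1, C8a,
#: four benzo carbons, C4a.
FLAVONOID_13_ELIMINATION = ReconstructionRule(
    name="flavonoid-13-elimination-CO2",
    smarts="[#8;X1]=[#6;R]1[#6;R]~[#6;R][#8;R][#6;R]2[#6;R][#6;R][#6;R][#6;R][#6;R]12",
    remove_positions=(0, 1, 4),
    add_bonds=((3, 5), (2, 10)),
    neutral_piece=_CO2,
)


def default_rules() -> list[ReconstructionRule]:
    return [FLAVONOID_13_ELIMINATION]


def _reconstruct(graph: MolGraph, rdmol: Chem.Mol, rule: ReconstructionRule):
    """Yield (product MolGraph, neutral piece) for each trigger match."""
    patt = rule.pattern()
    parent_vec = graph.comp_vector(frozenset(range(graph.n_atoms())))
    seen = set()
    for match in rdmol.GetSubstructMatches(patt):
        removed = frozenset(match[p] for p in rule.remove_positions)
        key = removed
        if key in seen:
            continue
        seen.add(key)
        keep = [a for a in range(graph.n_atoms()) if a not in removed]
        old2new = {a: k for k, a in enumerate(keep)}
        bonds = [
            (old2new[i], old2new[j], o)
            for (i, j, o) in graph.bonds
            if i not in removed and j not in removed
        ]
        for p, q in rule.add_bonds:
            bonds.append((old2new[match[p]], old2new[match[q]], 1))
        product = MolGraph(
            [graph.symbols[a] for a in keep],
            [graph.n_h[a] for a in keep],
            bonds,
        )
        prod_vec = product.comp_vector(frozenset(range(product.n_atoms())))
        piece = [a - b for a, b in zip(parent_vec, prod_vec)]
        if piece != list(rule.neutral_piece.counts):
            raise RuleDefinitionError(
                f"rule {rule.name!r} does not conserve atoms: "
                f"removed {piece}, declared {rule.neutral_piece.counts}"
            )
        yield product, rule


# ---------------------------------------------------------------------------
# Fragment ions


@dataclass(frozen=True)
class FragmentIon:
    """A charged fragment hypothesis with theoretical m/z."""

    composition: ElementComposition  # charged; radical flag set from parity
    theoretical_mz: float
    polarity: str
    h_shift_total: int
    neutral_loss: ElementComposition
    depth: int
    parent_id: str = ""
    via_reconstruction: bool = False
    rule_name: str = ""
    n_bonds_cleaved: int = 0
    cleavage: CleavageSet | None = field(compare=False, default=None)

    @property
    def radical(self) -> bool:
        return self.composition.odd_electron


@dataclass
class FragmenterConfig:
    """Tunable limits of the fragment generator.

    ``max_ring_pairs`` applies when cleaving a root structure (the
    precursor or a reconstruction product); deeper sequential steps use
    ``deep_max_ring_pairs`` — fragmentation deeper in a cascade is
    dominated by small sequential losses, and this keeps enumeration
    tractable.

    ``allow_bare_atom_excision`` controls whether a cleavage event may cut
    a single heavy atom out of the interior of the graph (two or more cut
    bonds around one atom, e.g. excising a ring oxygen as atomic O).  Such
    events are not plausible one-step CID processes and are rejected by
    default; single-atom fragments from one cut (CH3•, OH, ...) are always
    allowed.
    """

    max_depth: int = 2
    max_acyclic: int = 2
    max_ring_pairs: int = 2
    deep_max_ring_pairs: int = 1
    apply_reconstruction: bool = True
    allow_bare_atom_excision: bool = False
    max_states: int = 20000


def _make_ion_comp(vec, charge) -> ElementComposition:
    comp = ElementComposition(tuple(vec), charge)
    if comp.odd_electron:
        comp = ElementComposition(tuple(vec), charge, radical=True)
    return comp


def _check_adduct(polarity: str, adduct: AdductType | str | None) -> AdductType:
    if adduct is None:
        adduct = "[M+H]+" if polarity == "positive" else "[M-H]-"
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if adduct.mode != polarity:
        raise ConfigurationError(
            f"adduct {adduct.name} does not match polarity {polarity!r}"
        )
    if adduct.hydrogen_delta is None:
        raise ConfigurationError(
            f"adduct {adduct.name} is supported for precursor m/z arithmetic "
            "but not for fragment generation (only ±H species are followed)"
        )
    return adduct


def _cleavage_events(graph, atoms, max_acyclic, max_rp, cfg, rank_values):
    """Flattened cleavage outcomes for one subgraph.

    Returns a dict ``(component_atoms, dH) -> (n_bonds, CleavageSet)``
    where ``dH`` is the net H shift gained by that component; every
    H-shift combination of every valid cleavage set is folded in, keeping
    the fewest-bonds provenance.  States that differ only in accumulated
    hydrogen delta share this computation.
    """
    events: dict[tuple, tuple] = {}
    for cs in _enumerate_sets(graph, atoms, max_acyclic, max_rp):
        comps = cs.components
        comp_of = {}
        for ci, comp in enumerate(comps):
            for a in comp:
                comp_of[a] = ci
        if not cfg.allow_bare_atom_excision:
            # reject events that cut a lone heavy atom out of the interior
            cuts = [0] * len(comps)
            for bi in cs.bonds:
                cuts[comp_of[graph.bonds[bi][0]]] += 1
                cuts[comp_of[graph.bonds[bi][1]]] += 1
            if any(len(c) == 1 and k >= 2 for c, k in zip(comps, cuts)):
                continue
        base_h = [sum(graph.n_h[a] for a in c) for c in comps]
        bond_opts = []
        for bi in cs.bonds:
            i, j, order = graph.bonds[bi]
            opts = h_rearrangement_options(
                graph.symbols[i], graph.symbols[j], order, rank_values
            )
            bond_opts.append((comp_of[i], comp_of[j], opts))
        n_bonds = len(cs.bonds)
        for combo in itertools.product(*(o for _, _, o in bond_opts)):
            deltas = [0] * len(comps)
            for (ci_x, ci_y, _), hx in zip(bond_opts, combo):
                deltas[ci_x] += hx
                deltas[ci_y] -= hx
            if any(b + d < 0 for b, d in zip(base_h, deltas)):
                continue
            for ci, comp_atoms in enumerate(comps):
                key = (comp_atoms, deltas[ci])
                old = events.get(key)
                if old is None or n_bonds < old[0]:
                    events[key] = (n_bonds, cs)
    return sorted(
        events.items(), key=lambda kv: (-len(kv[0][0]), sorted(kv[0][0]), kv[0][1])
    )


def _engine(
    roots,  # list of (MolGraph, h_delta, depth, via_recon, rule_name)
    precursor_vec,
    polarity: str,
    charge: int,
    cfg: FragmenterConfig,
    rank_values: dict[str, int],
    parent_id: str,
) -> list[FragmentIon]:
    emitted: dict[tuple, FragmentIon] = {}
    negative = polarity == "negative"

    def emit(vec, h_shift_total, depth, via, rule_name, n_bonds, cleavage):
        if vec[_H] < 0 or not any(vec):
            return False
        key = tuple(vec)
        old = emitted.get(key)
        if old is not None and (old.depth, old.n_bonds_cleaved) <= (depth, n_bonds):
            return True
        comp = _make_ion_comp(vec, charge)
        if negative and comp.carbon_only:
            return False
        loss_vec = [p - v for p, v in zip(precursor_vec, vec)]
        if any(x < 0 for x in loss_vec):
            return False
        emitted[key] = FragmentIon(
            composition=comp,
            theoretical_mz=monoisotopic_mass(comp),
            polarity=polarity,
            h_shift_total=h_shift_total,
            neutral_loss=ElementComposition(tuple(loss_vec)),
            depth=depth,
            parent_id=parent_id,
            via_reconstruction=via,
            rule_name=rule_name,
            n_bonds_cleaved=n_bonds,
            cleavage=cleavage,
        )
        return True

    # state: (graph, atoms, h_delta, depth, via_recon, rule_name, is_root)
    queue: deque = deque()
    visited: set = set()
    for graph, h_delta, depth, via, rule_name in roots:
        atoms = frozenset(range(graph.n_atoms()))
        if via:
            # a reconstruction product is itself an observable ion
            vec = graph.comp_vector(atoms)
            vec[_H] += h_delta
            emit(vec, 0, depth, True, rule_name, 0, None)
        state_key = (id(graph), atoms, h_delta)
        if state_key not in visited:
            visited.add(state_key)
            queue.append((graph, atoms, h_delta, depth, via, rule_name, True))

    event_cache: dict[tuple, list] = {}
    vec_cache: dict[tuple, tuple] = {}

    while queue:
        graph, atoms, h_delta, depth, via, rule_name, is_root = queue.popleft()
        if depth >= cfg.max_depth:
            continue
        max_rp = cfg.max_ring_pairs if is_root else cfg.deep_max_ring_pairs
        cache_key = (id(graph), atoms, max_rp)
        events = event_cache.get(cache_key)
        if events is None:
            events = _cleavage_events(
                graph, atoms, cfg.max_acyclic, max_rp, cfg, rank_values
            )
            event_cache[cache_key] = events
        for (comp_atoms, d_h), (n_bonds, cs) in events:
            vkey = (id(graph), comp_atoms)
            base = vec_cache.get(vkey)
            if base is None:
                base = tuple(graph.comp_vector(comp_atoms))
                vec_cache[vkey] = base
            vec = list(base)
            vec[_H] += d_h + h_delta
            if not emit(vec, d_h, depth + 1, via, rule_name, n_bonds, cs):
                continue
            if depth + 1 >= cfg.max_depth or len(comp_atoms) < 2:
                continue
            child_key = (id(graph), comp_atoms, h_delta + d_h)
            if child_key not in visited and len(visited) < cfg.max_states:
                visited.add(child_key)
                queue.append(
                    (
                        graph,
                        comp_atoms,
                        h_delta + d_h,
                        depth + 1,
                        via,
                        rule_name,
                        False,
                    )
                )

    ions = sorted(
        emitted.values(), key=lambda f: (-f.theoretical_mz, f.composition.counts)
    )
    return ions


def fragment_molecule(
    mol: Molecule,
    polarity: str,
    adduct: AdductType | str | None = None,
    max_depth: int | None = None,
    rules: list[ReconstructionRule] | None = None,
    config: FragmenterConfig | None = None,
    rank_values: dict[str, int] | None = None,
) -> list[FragmentIon]:
    """Generate theoretical fragment ions for a molecule.

    ``rules=None`` uses the default reconstruction registry; pass ``[]``
    to disable reconstruction.  Fragments are deduplicated by charged
    composition, keeping the lowest-depth, fewest-bonds provenance.
    """
    cfg = config or FragmenterConfig()
    if max_depth is not None:
        cfg = FragmenterConfig(**{**cfg.__dict__, "max_depth": max_depth})
    adduct = _check_adduct(polarity, adduct)
    rdmol = mol.rdmol
    graph = MolGraph.from_rdmol(rdmol)
    h_delta = adduct.hydrogen_delta
    atoms = frozenset(range(graph.n_atoms()))
    precursor_vec = graph.comp_vector(atoms)
    precursor_vec[_H] += h_delta

    roots = [(graph, h_delta, 0, False, "")]
    if cfg.apply_reconstruction and rules is None:
        rules = default_rules()
    for rule in rules or []:
        for product, r in _reconstruct(graph, rdmol, rule):
            roots.append((product, h_delta, 1, True, r.name))

    rv = rank_values or RANK_VALUES
    return _engine(
        roots,
        precursor_vec,
        polarity,
        adduct.charge,
        cfg,
        rv,
        mol.meta.source_id or mol.canonical_smiles,
    )


def apply_reconstruction_rules(
    mol: Molecule,
    polarity: str,
    adduct: AdductType | str | None = None,
    rules: list[ReconstructionRule] | None = None,
    max_depth: int = 2,
    config: FragmenterConfig | None = None,
) -> list[FragmentIon]:
    """Fragment ions reachable only through reconstruction rules.

    Emits each triggered rule's rearranged product ion plus the product's
    own fragmentation cascade; returns an empty list when no rule triggers.
    """
    cfg = config or FragmenterConfig(max_depth=max_depth)
    adduct = _check_adduct(polarity, adduct)
    rdmol = mol.rdmol
    graph = MolGraph.from_rdmol(rdmol)
    h_delta = adduct.hydrogen_delta
    atoms = frozenset(range(graph.n_atoms()))
    precursor_vec = graph.comp_vector(atoms)
    precursor_vec[_H] += h_delta
    roots = []
    for rule in rules if rules is not None else default_rules():
        for product, r in _reconstruct(graph, rdmol, rule):
            roots.append((product, h_delta, 1, True, r.name))
    if not roots:
        return []
    return _engine(
        roots,
        precursor_vec,
        polarity,
        adduct.charge,
        cfg,
        RANK_VALUES,
        mol.meta.source_id or mol.canonical_smiles,
    )


def precursor_ion(mol: Molecule, adduct: AdductType | str) -> ElementComposition:
    """Charged composition of the intact precursor ion (±H adducts only)."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    if adduct.hydrogen_delta is None:
        raise ConfigurationError(
            f"adduct {adduct.name} has no defined hydrogen bookkeeping"
        )
    comp = mol.composition.add_hydrogen(adduct.hydrogen_delta)
    return _make_ion_comp(comp.counts, adduct.charge)


def fragments_to_table(ions: list[FragmentIon], path) -> None:
    """Serialize fragments as TSV: parent, m/z, formula, loss, depth, flags."""
    with open(path, "w") as fh:
        fh.write("parent_id\tmz\tformula\tloss\tdepth\tradical\treconstruction\n")
        for f in ions:
            fh.write(
                f"{f.parent_id}\t{f.theoretical_mz:.6f}\t{f.composition.formula()}\t"
                f"{f.neutral_loss.formula()}\t{f.depth}\t"
                f"{int(f.radical)}\t{int(f.via_reconstruction)}\n"
            )
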