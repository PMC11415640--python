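"""Batch in silico fragment library with precursor-indexed retrieval.

A :class:`FragmentLibrary` maps candidate ids to (molecule, per-polarity
fragment sets) and keeps a sorted precursor index of (ion m/z, adduct,
candidate id) rows for fast m/z window queries.  Libraries are built in
deterministic chunked order, so building twice yields identical results,
and persist as a plain-text directory: a JSON manifest, a molecule table
and per-chunk fragment TSVs.
"""

from __future__ import annotations

import bisect
import json
import os
from dataclasses import dataclass, field

from .chem import (
    ADDUCTS,
    Molecule,
    MoleculeMeta,
    adducts_for_mode,
    get_adduct,
    ion_mz,
    parse_molecule,
)
from .errors import ConfigurationError, NpfragError
from .formulas import effective_tolerance, mass_error_score
from .fragmenter import FragmenterConfig, FragmentIon, fragment_molecule

#: Adducts indexed by default for each polarity (all supported ones).
DEFAULT_INDEX_ADDUCTS = {
    "positive": [a.name for a in adducts_for_mode("positive")],
    "negative": [a.name for a in adducts_for_mode("negative")],
}

#: Adducts whose fragments are generated (±H species only).
DEFAULT_FRAGMENT_ADDUCTS = {"positive": "[M+H]+", "negative": "[M-H]-"}


@dataclass
class LibraryEntry:
    molecule: Molecule
    fragments: dict[str, list[FragmentIon]]  # polarity -> fragments
    provenance: str = "known"  # "known" | "generated"


@dataclass
class QueryHit:
    candidate_id: str
    molecule: Molecule
    adduct_name: str
    ion_mz: float
    mass_error_score: float
    fragments: list[FragmentIon] = field(default_factory=list)


class FragmentLibrary:
    def __init__(self):
        self.entries: dict[str, LibraryEntry] = {}
        # parallel sorted arrays for the precursor index
        self._index_mz: list[float] = []
        self._index_rows: list[tuple[float, str, str]] = []  # (mz, adduct, id)
        self.n_failed: int = 0

    # -- construction ------------------------------------------------------
    def add(self, molecule: Molecule, fragments: dict[str, list[FragmentIon]],
            provenance: str = "known") -> None:
        cid = molecule.meta.source_id or molecule.canonical_smiles
        self.entries[cid] = LibraryEntry(molecule, fragments, provenance)

    def build_index(self, index_adducts: dict[str, list[str]] | None = None) -> None:
        adduct_map = index_adducts or DEFAULT_INDEX_ADDUCTS
        rows = []
        for cid, entry in sorted(self.entries.items()):
            for polarity, names in adduct_map.items():
                if polarity not in entry.fragments:
                    continue
                for name in names:
                    mz = ion_mz(entry.molecule.monoisotopic_mass, get_adduct(name))
                    rows.append((mz, name, cid))
        rows.sort()
        self._index_rows = rows
        self._index_mz = [r[0] for r in rows]

    # -- queries -----------------------------------------------------------
    def query_window(self, lo: float, hi: float) -> list[tuple[float, str, str]]:
        """Index rows with ion m/z in [lo, hi]."""
        i = bisect.bisect_left(self._index_mz, lo)
        j = bisect.bisect_right(self._index_mz, hi)
        return self._index_rows[i:j]

    def query_precursor(
        self,
        mz: float,
        mode: str,
        tol_mda: float = 5.0,
        tol_ppm: float | None = 10.0,
    ) -> list[QueryHit]:
        """Candidates with any supported adduct ion within tolerance.

        Each hit is tagged with its adduct hypothesis; a neutral mass
        reachable through two adducts yields two hits.
        """
        tol = effective_tolerance(mz, tol_mda, tol_ppm)
        hits = []
        for row_mz, adduct_name, cid in self.query_window(mz - tol, mz + tol):
            adduct = get_adduct(adduct_name)
            if adduct.mode != mode:
                continue
            entry = self.entries[cid]
            hits.append(
                QueryHit(
                    candidate_id=cid,
                    molecule=entry.molecule,
                    adduct_name=adduct_name,
                    ion_mz=row_mz,
                    mass_error_score=mass_error_score(mz, row_mz, tol),
                    fragments=entry.fragments.get(mode, []),
                )
            )
        hits.sort(key=lambda h: (-h.mass_error_score, h.candidate_id, h.adduct_name))
        return hits


def query_precursor(lib: FragmentLibrary, mz: float, mode: str,
                    tol_mda: float = 5.0, tol_ppm: float | None = 10.0):
    return lib.query_precursor(mz, mode, tol_mda, tol_ppm)


def build_library(
    molecules: list[Molecule],
    polarities: tuple[str, ...] = ("positive", "negative"),
    fragmenter_config: FragmenterConfig | None = None,
    provenance: str = "known",
    chunk_size: int = 100,
) -> FragmentLibrary:
    """Fragment a structure collection into a searchable library.

    Per-molecule failures are logged and counted, not fatal.  Molecules
    are processed in deterministic chunked order so repeated builds are
    identical.
    """
    lib = FragmentLibrary()
    cfg = fragmenter_config or FragmenterConfig()
    ordered = sorted(
        molecules, key=lambda m: (m.meta.source_id or m.canonical_smiles)
    )
    for start in range(0, len(ordered), chunk_size):
        for mol in ordered[start : start + chunk_size]:
            frags: dict[str, list[FragmentIon]] = {}
            try:
                for polarity in polarities:
                    frags[polarity] = fragment_molecule(
                        mol,
                        polarity,
                        DEFAULT_FRAGMENT_ADDUCTS[polarity],
                        config=cfg,
                    )
                lib.add(mol, frags, provenance)
            except NpfragError:
                lib.n_failed += 1
    lib.build_index()
    return lib


# ---------------------------------------------------------------------------
# On-disk layout: manifest.json + molecules.tsv + chunk_XXXX.tsv


def save_library(lib: FragmentLibrary, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    ids = sorted(lib.entries)
    manifest = {
        "n_entries": len(ids),
        "chunks": [],
        "adducts": sorted(ADDUCTS),
    }
    with open(os.path.join(directory, "molecules.tsv"), "w") as fh:
        for cid in ids:
            e = lib.entries[cid]
            fh.write(
                "\t".join(
                    [
                        cid,
                        e.molecule.canonical_smiles,
                        str(e.molecule.meta.annotation_level),
                        e.molecule.meta.chemical_class or "",
                        e.provenance,
                    ]
                )
                + "\n"
            )
    chunk_size = 100
    for ci, start in enumerate(range(0, len(ids), chunk_size)):
        name = f"chunk_{ci:04d}.tsv"
        manifest["chunks"].append(name)
        with open(os.path.join(directory, name), "w") as fh:
            for cid in ids[start : start + chunk_size]:
                for polarity, frags in sorted(lib.entries[cid].fragments.items()):
                    for f in frags:
                        fh.write(
                            "\t".join(
                                [
                                    cid,
                                    polarity,
                                    f"{f.theoretical_mz:.6f}",
                                    f.composition.formula(),
                                    str(f.composition.charge),
                                    f.neutral_loss.formula(),
                                    str(f.depth),
                                    str(int(f.via_reconstruction)),
                                ]
                            )
                            + "\n"
                        )
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_library(directory) -> FragmentLibrary:
    """Reload a saved library (fragment m/z and formulas, not provenance)."""
    from .chem import ElementComposition, monoisotopic_mass

    manifest_path = os.path.join(directory, "manifest.json")
    if not os.path.exists(manifest_path):
        raise ConfigurationError(f"no library manifest under {directory!r}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lib = FragmentLibrary()
    meta_rows = {}
    with open(os.path.join(directory, "molecules.tsv")) as fh:
        for line in fh:
            cid, smiles, level, cls, provenance = line.rstrip("\n").split("\t")
            mol = parse_molecule(
                smiles, MoleculeMeta(cid, int(level), cls or None)
            )
            meta_rows[cid] = (mol, provenance)
            lib.add(mol, {}, provenance)
    for chunk in manifest["chunks"]:
        with open(os.path.join(directory, chunk)) as fh:
            for line in fh:
                cid, polarity, _mz, formula, charge, loss, depth, recon = (
                    line.rstrip("\n").split("\t")
                )
                comp = ElementComposition.from_formula(formula, int(charge))
                if comp.odd_electron:
                    comp = ElementComposition(comp.counts, comp.charge, radical=True)
                ion = FragmentIon(
                    composition=comp,
                    theoretical_mz=monoisotopic_mass(comp),
                    polarity=polarity,
                    h_shift_total=0,
                    neutral_loss=ElementComposition.from_formula(loss)
                    if loss != "[]"
                    else ElementComposition(),
                    depth=int(depth),
                    parent_id=cid,
                    via_reconstruction=bool(int(recon)),
                )
                lib.entries[cid].fragments.setdefault(polarity, []).append(ion)
    lib.build_index()
    return lib
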