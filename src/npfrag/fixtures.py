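"""Built-in fixture molecules, simulated spectra and synthetic libraries.

The fixture set spans the chemical classes the annotation pipeline is
aimed at — flavonoids/isoflavonoids, phenolic acids, terpenoids and
sugars — and includes the worked-example structures (syringic acid,
acacetin, formononetin).  Simulated spectra are built from a molecule's
own theoretical fragments with seeded m/z jitter and optional decoy
peaks, giving reproducible ground-truth inputs for ranking tests without
any external download.
"""

from __future__ import annotations

import numpy as np

from .chem import Molecule, MoleculeMeta, parse_molecule
from .errors import DegenerateSpectrumError
from .fragmenter import FragmenterConfig, fragment_molecule
from .knowledge import AnnotatedFragmentRecord
from .spectra import Spectrum, normalize_spectrum

#: name -> (SMILES, chemical class)
FIXTURE_SMILES: dict[str, tuple[str, str]] = {
    "syringic_acid": ("COc1cc(C(=O)O)cc(OC)c1O", "benzoic_acid"),
    "acacetin": ("COc1ccc(-c2cc(=O)c3c(O)cc(O)cc3o2)cc1", "flavonoid"),
    "formononetin": ("COc1ccc(C2=COc3cc(O)ccc3C2=O)cc1", "isoflavonoid"),
    "apigenin": ("O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", "flavonoid"),
    "chrysin": ("O=c1cc(-c2ccccc2)oc2cc(O)cc(O)c12", "flavonoid"),
    "kaempferol": ("O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12", "flavonoid"),
    "luteolin": ("O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", "flavonoid"),
    "quercetin": ("O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12", "flavonoid"),
    "naringenin": ("O=C1CC(c2ccc(O)cc2)Oc2cc(O)cc(O)c21", "flavonoid"),
    "daidzein": ("O=c1c(-c2ccc(O)cc2)coc2cc(O)ccc12", "isoflavonoid"),
    "genistein": ("O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12", "isoflavonoid"),
    "vanillic_acid": ("COc1cc(C(=O)O)ccc1O", "benzoic_acid"),
    "gallic_acid": ("O=C(O)c1cc(O)c(O)c(O)c1", "benzoic_acid"),
    "salicylic_acid": ("O=C(O)c1ccccc1O", "benzoic_acid"),
    "ferulic_acid": ("COc1cc(/C=C/C(=O)O)ccc1O", "cinnamic_acid"),
    "caffeic_acid": ("O=C(O)/C=C/c1ccc(O)c(O)c1", "cinnamic_acid"),
    "p_coumaric_acid": ("O=C(O)/C=C/c1ccc(O)cc1", "cinnamic_acid"),
    "glucose": ("OCC1OC(O)C(O)C(O)C1O", "sugar"),
    "fructose": ("OCC1(O)OCC(O)C(O)C1O", "sugar"),
    "citric_acid": ("OC(=O)CC(O)(C(=O)O)CC(=O)O", "organic_acid"),
    "menthol": ("CC(C)C1CCC(C)CC1O", "terpenoid"),
    "carvone": ("CC(=C)C1CC=C(C)C(=O)C1", "terpenoid"),
    "camphor": ("CC1(C)C2CCC1(C)C(=O)C2", "terpenoid"),
    "tyrosine": ("NC(Cc1ccc(O)cc1)C(=O)O", "amino_acid"),
}


def fixture_molecule(name: str, annotation_level: int = 5) -> Molecule:
    smiles, cls = FIXTURE_SMILES[name]
    return parse_molecule(
        smiles, MoleculeMeta(source_id=name, annotation_level=annotation_level,
                             chemical_class=cls)
    )


def fixture_molecules(annotation_level: int = 5) -> list[Molecule]:
    """All fixture molecules, parsed, in deterministic name order."""
    return [fixture_molecule(name, annotation_level) for name in sorted(FIXTURE_SMILES)]


def simulate_spectrum(
    mol: Molecule,
    polarity: str,
    adduct: str | None = None,
    n_peaks: int = 8,
    noise_sd_mda: float = 0.0,
    n_decoy_peaks: int = 0,
    seed: int = 0,
    max_depth: int = 1,
    fragmenter_config: FragmenterConfig | None = None,
    bde_model=None,
) -> Spectrum:
    """Simulate an MS² spectrum from a molecule's theoretical fragments.

    The ``n_peaks`` highest-mass fragments become peaks; intensities come
    from the BDE-proxy intensity model when one is given (emulating the
    tendency of weak bonds to yield strong fragments), otherwise they
    decay smoothly with seeded jitter.  Peak m/z values get Gaussian
    noise of ``noise_sd_mda`` (mDa); ``n_decoy_peaks`` uniform random
    unexplainable peaks can be added.  Deterministic under ``seed``.
    """
    from .chem import get_adduct, ion_mz

    rng = np.random.default_rng(seed)
    cfg = fragmenter_config or FragmenterConfig(max_depth=max_depth)
    fragments = fragment_molecule(mol, polarity, adduct, config=cfg)
    if not fragments:
        raise DegenerateSpectrumError(
            f"molecule {mol.meta.source_id or mol.canonical_smiles} "
            f"yields no fragments in {polarity} mode"
        )
    if bde_model is not None:
        from .scoring import predict_spectrum

        predicted = predict_spectrum(mol, fragments, bde_model)
        # the strongest predicted peaks are the ones observed
        base = dict(sorted(predicted, key=lambda p: -p[1])[:n_peaks])
    else:
        chosen = sorted(fragments, key=lambda f: -f.theoretical_mz)[:n_peaks]
        base = {f.theoretical_mz: 0.75**k for k, f in enumerate(chosen)}
    peaks = []
    for mz0, b in sorted(base.items()):
        mz = mz0 + rng.normal(0.0, noise_sd_mda * 1e-3)
        intensity = b * (0.9 + 0.2 * rng.random())
        if intensity > 0:
            peaks.append((mz, intensity))
    adduct_obj = get_adduct(
        adduct or ("[M+H]+" if polarity == "positive" else "[M-H]-")
    )
    precursor_mz = ion_mz(mol.monoisotopic_mass, adduct_obj)
    for _ in range(n_decoy_peaks):
        peaks.append(
            (50.0 + rng.random() * (precursor_mz - 60.0), 0.05 + 0.1 * rng.random())
        )
    spectrum = Spectrum(
        id=f"sim_{mol.meta.source_id or 'mol'}_{polarity}_{seed}",
        precursor_mz=precursor_mz,
        ion_mode=polarity,
        peaks=tuple(peaks),
        adduct_hint=adduct_obj,
    )
    return normalize_spectrum(spectrum)


def synthesize_annotated_library(
    n_events: int,
    pattern_probs: tuple[float, float, float] = (0.7, 0.2, 0.1),
    polarity: str = "positive",
    bond: tuple[str, str, int] = ("C", "O", 1),
    carbon_only_fraction: float = 0.0,
    seed: int = 0,
) -> list[AnnotatedFragmentRecord]:
    """Draw annotated cleavage events with a known H-pattern mixture.

    Pattern 1 (H to the atom2 side) maps to h_shift = -n, Pattern 2 to 0,
    Pattern 3 to +n; used to test that knowledge extraction recovers the
    generating proportions.
    """
    rng = np.random.default_rng(seed)
    e1, e2, order = bond
    shifts = (-order, 0, order)
    out = []
    for _ in range(n_events):
        pattern = rng.choice(3, p=pattern_probs)
        out.append(
            AnnotatedFragmentRecord(
                parent=None,
                polarity=polarity,
                cleaved_bond=(e1, e2, order, False),
                h_shift=int(shifts[pattern]),
                fragment_is_carbon_only=bool(rng.random() < carbon_only_fraction),
            )
        )
    return out


def toy_smiles_corpus(n: int = 500, seed: int = 0) -> list[str]:
    """A small programmatic corpus of valid, simple SMILES strings.

    Linear/branched alcohols, acids, amines, esters and phenols —
    deliberately low-complexity so a desk-scale language model can learn
    the grammar in a few epochs.
    """
    rng = np.random.default_rng(seed)
    heads = ["C", "CC", "CCC", "CCCC", "CC(C)", "CCCCC"]
    tails = ["O", "N", "C(=O)O", "C(=O)OC", "C(=O)N", "CO", ""]
    rings = ["c1ccccc1", "c1ccc(O)cc1", "c1ccc(C)cc1", "C1CCCCC1", "c1ccncc1"]
    out = []
    while len(out) < n:
        r = rng.random()
        if r < 0.6:
            smi = heads[rng.integers(len(heads))] + tails[rng.integers(len(tails))]
        elif r < 0.85:
            smi = heads[rng.integers(len(heads))] + rings[rng.integers(len(rings))]
        else:
            smi = rings[rng.integers(len(rings))]
        out.append(smi)
    return out
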