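"""Candidate scoring and ranking against experimental MS² spectra.

A candidate structure is scored against a spectrum with six terms:

* S0 — formula score: Gaussian mass-error score of the precursor m/z plus
  the frequent-neutral-loss score of the spectrum (each capped at 1);
* S1 — structure score: summed normalized intensity of matched peaks;
* S2 — mean Gaussian mass-error score over matched peaks;
* S3 — greedy cosine similarity between the experimental spectrum and a
  predicted spectrum whose fragment intensities are inversely
  proportional to a regression proxy of bond dissociation energy (BDE);
* S4 — meta score, annotation level / 5 of the candidate's database entry;
* S5 — retention-time score 1 / (1 + exp(|RTexp - RTpred| / theta - 1)).

Final score = S0 + alpha*S1 + beta*S2 + gamma*S3 + S4 + S5 with default
weights alpha = 0.1, beta = 0.2, gamma = 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matchms import Spectrum as MatchmsSpectrum
from matchms.similarity import CosineGreedy
from rdkit.Chem import MACCSkeys
from sklearn.ensemble import RandomForestRegressor

from .chem import Molecule, adducts_for_mode, ion_mz
from .errors import ConfigurationError
from .formulas import (
    effective_tolerance,
    mass_error_score,
    neutral_loss_score,
)
from .fragmenter import FragmentIon, MolGraph
from .spectra import Spectrum, normalize_spectrum


@dataclass
class ScoringConfig:
    """Tolerances, weights and flags of the ranking function."""

    ms1_tol_mda: float = 5.0
    ms1_tol_ppm: float = 10.0
    ms2_tol_mda: float = 20.0
    ms2_tol_ppm: float = 20.0
    alpha: float = 0.1
    beta: float = 0.2
    gamma: float = 0.1
    theta: float = 0.1  # RT score width, minutes
    use_meta: bool = True  # disable for novel-discovery mode
    use_rt: bool = False  # RT models are LC-condition specific
    cap_s0: bool = True


@dataclass(frozen=True)
class PeakMatch:
    peak_index: int
    fragment: FragmentIon
    mass_error: float
    mes: float
    intensity: float


@dataclass(frozen=True)
class CandidateScore:
    s0: float
    s1: float
    s2: float
    s3: float
    s4: float
    s5: float
    alpha: float = 0.1
    beta: float = 0.2
    gamma: float = 0.1

    @property
    def final(self) -> float:
        return (
            self.s0
            + self.alpha * self.s1
            + self.beta * self.s2
            + self.gamma * self.s3
            + self.s4
            + self.s5
        )


def match_peaks(
    spectrum: Spectrum,
    fragments: list[FragmentIon],
    tol_mda: float = 20.0,
    tol_ppm: float | None = 20.0,
) -> list[PeakMatch]:
    """Match each peak to its nearest theoretical fragment within tolerance.

    One peak matches at most one fragment; one fragment may explain
    several peaks.  The Gaussian MES of each match uses the tolerance as
    width.
    """
    if not spectrum.normalized:
        raise ConfigurationError("spectrum must be normalized before matching")
    out = []
    frag_mz = [(f.theoretical_mz, f) for f in fragments]
    for idx, (mz, intensity) in enumerate(spectrum.peaks):
        tol = effective_tolerance(mz, tol_mda, tol_ppm)
        best = None
        best_err = tol
        for fmz, frag in frag_mz:
            err = abs(fmz - mz)
            if err <= best_err:
                best_err = err
                best = frag
        if best is not None:
            out.append(
                PeakMatch(
                    peak_index=idx,
                    fragment=best,
                    mass_error=mz - best.theoretical_mz,
                    mes=mass_error_score(mz, best.theoretical_mz, tol),
                    intensity=intensity,
                )
            )
    return out


def structure_score(matches: list[PeakMatch]) -> float:
    """S1: summed normalized intensity of matched peaks (0 when none)."""
    return float(sum(m.intensity for m in matches))


def fragment_mes(matches: list[PeakMatch]) -> float:
    """S2: mean mass-error score over matched peaks (0 when none)."""
    if not matches:
        return 0.0
    return float(sum(m.mes for m in matches) / len(matches))


def explained_intensity(
    spectrum: Spectrum,
    fragments: list[FragmentIon],
    tol_mda: float = 20.0,
    tol_ppm: float | None = 20.0,
) -> float:
    """Fraction of total normalized intensity explained by the fragments."""
    return structure_score(match_peaks(spectrum, fragments, tol_mda, tol_ppm))


def meta_score(level: int) -> float:
    """S4 = annotation level / 5, values in {0, 0.2, 0.4, 0.6, 0.8, 1}."""
    if not isinstance(level, int) or not (0 <= level <= 5):
        raise ConfigurationError("annotation level must be an integer in 0..5")
    return level / 5


def rt_score(rt_exp: float, rt_pred: float, theta: float = 0.1) -> float:
    """S5 = 1 / (1 + exp(|RTexp - RTpred| / theta - 1)), in (0, 1)."""
    if theta <= 0:
        raise ConfigurationError("theta must be positive")
    return 1.0 / (1.0 + math.exp(abs(rt_exp - rt_pred) / theta - 1.0))


def final_score(
    s0: float,
    s1: float,
    s2: float,
    s3: float,
    s4: float,
    s5: float,
    alpha: float = 0.1,
    beta: float = 0.2,
    gamma: float = 0.1,
) -> float:
    return s0 + alpha * s1 + beta * s2 + gamma * s3 + s4 + s5


# ---------------------------------------------------------------------------
# BDE-proxy intensity model


def _bond_features(graph: MolGraph, bond_index: int) -> list[float]:
    i, j, order = graph.bonds[bond_index]
    e1, e2 = sorted((graph.symbols[i], graph.symbols[j]))
    onehot = []
    for sym in ("C", "N", "O", "P", "S"):
        onehot.append(float(e1 == sym))
    for sym in ("C", "N", "O", "P", "S"):
        onehot.append(float(e2 == sym))
    deg_i = len(graph.adj[i])
    deg_j = len(graph.adj[j])
    return [
        float(order),
        float(deg_i + deg_j),
        float(abs(deg_i - deg_j)),
        float(graph.n_h[i] + graph.n_h[j]),
        *onehot,
    ]


def candidate_bond_features(mol: Molecule) -> tuple[MolGraph, np.ndarray]:
    """Feature matrix (MACCS keys of the parent ‖ bond features) per bond."""
    rdmol = mol.rdmol
    graph = MolGraph.from_rdmol(rdmol)
    maccs = np.array(MACCSkeys.GenMACCSKeys(rdmol))[1:]  # 166 structural keys
    rows = [
        np.concatenate([maccs, np.array(_bond_features(graph, bi))])
        for bi in range(len(graph.bonds))
    ]
    return graph, np.array(rows) if rows else np.empty((0, 166 + 14))


class BdeIntensityModel:
    """Random-forest regression proxy for bond dissociation energy.

    Trained on (parent fingerprint ‖ bond features) → BDE-like target;
    predicted fragment intensities are proportional to the inverse of the
    summed bond predictions of each fragment's cleavage.
    """

    def __init__(self, n_estimators: int = 50, seed: int = 0):
        self._rf = RandomForestRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        self._trained = False

    def fit(self, features: np.ndarray, targets: np.ndarray) -> "BdeIntensityModel":
        self._rf.fit(features, targets)
        self._trained = True
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        if not self._trained:
            raise ConfigurationError(
                "BDE model is untrained; fit it or use train_default_bde_model()"
            )
        return np.clip(self._rf.predict(features), 1e-6, None)


def synthetic_bde_target(features_row: np.ndarray) -> float:
    """Transparent synthetic BDE label used by the fixture trainer.

    Encodes textbook trends: higher order and aromatic delocalization
    strengthen a bond; heteroatom termini weaken homolysis relative to
    C–C; crowding (high degree sum) weakens it slightly.
    """
    order = features_row[166]
    degsum = features_row[167]
    nh = features_row[169]
    het = features_row[171:175].sum() + features_row[176:180].sum()
    return float(280.0 + 90.0 * (order - 1) - 25.0 * het - 6.0 * degsum + 4.0 * nh)


def train_default_bde_model(
    molecules: list[Molecule], seed: int = 0, noise_sd: float = 10.0
) -> BdeIntensityModel:
    """Fit the BDE proxy on synthetic bond labels over fixture molecules."""
    rng = np.random.default_rng(seed)
    rows, targets = [], []
    for mol in molecules:
        _graph, feats = candidate_bond_features(mol)
        for row in feats:
            rows.append(row)
            targets.append(synthetic_bde_target(row) + rng.normal(0.0, noise_sd))
    if not rows:
        raise ConfigurationError("no bonds to train on")
    return BdeIntensityModel(seed=seed).fit(np.array(rows), np.array(targets))


def predict_spectrum(
    candidate: Molecule,
    fragments: list[FragmentIon],
    model: BdeIntensityModel,
) -> list[tuple[float, float]]:
    """Predicted peak list: intensity ∝ 1 / predicted BDE of the cleavage.

    Multi-bond cleavages use the sum of per-bond predictions; fragments
    without bond provenance (reconstruction products) get the median
    predicted energy.  Intensities are normalized to sum 1.
    """
    if not fragments:
        return []
    graph, feats = candidate_bond_features(candidate)
    if len(feats) == 0:
        return []
    bond_bde = model.predict(feats)
    median = float(np.median(bond_bde))
    peaks = []
    for f in fragments:
        if f.cleavage is not None and f.cleavage.bonds:
            energy = float(sum(bond_bde[bi] for bi in f.cleavage.bonds))
        else:
            energy = median
        peaks.append((f.theoretical_mz, 1.0 / max(energy, 1e-6)))
    total = sum(i for _, i in peaks)
    return sorted((m, i / total) for m, i in peaks)


def cosine_score(
    experimental: Spectrum,
    predicted: list[tuple[float, float]],
    tolerance: float = 0.02,
) -> float:
    """S3: greedy cosine similarity between experimental and predicted peaks."""
    if not predicted or not experimental.peaks:
        return 0.0
    exp = MatchmsSpectrum(
        mz=experimental.mz.astype(float),
        intensities=experimental.intensities.astype(float),
        metadata={"precursor_mz": experimental.precursor_mz},
        metadata_harmonization=False,
    )
    pred_sorted = sorted(predicted)
    pred = MatchmsSpectrum(
        mz=np.array([p[0] for p in pred_sorted], dtype=float),
        intensities=np.array([p[1] for p in pred_sorted], dtype=float),
        metadata={"precursor_mz": experimental.precursor_mz},
        metadata_harmonization=False,
    )
    result = CosineGreedy(tolerance=tolerance).pair(exp, pred)
    return float(result["score"])


# ---------------------------------------------------------------------------
# Ranking


@dataclass
class RankedCandidate:
    molecule: Molecule
    score: CandidateScore
    matches: list[PeakMatch] = field(default_factory=list)

    @property
    def final(self) -> float:
        return self.score.final


def rank_candidates(
    spectrum: Spectrum,
    candidates: list[tuple[Molecule, list[FragmentIon]]],
    config: ScoringConfig | None = None,
    bde_model: BdeIntensityModel | None = None,
    rt_predictions: dict[str, float] | None = None,
) -> list[RankedCandidate]:
    """Score and rank candidate structures against one spectrum.

    ``candidates`` pairs each structure with its theoretical fragments.
    Ties are broken deterministically by (S1, S2, candidate id), so the
    ranking is invariant to input order.
    """
    cfg = config or ScoringConfig()
    if not spectrum.normalized:
        spectrum = normalize_spectrum(spectrum)
    ms1_tol = effective_tolerance(
        spectrum.precursor_mz, cfg.ms1_tol_mda, cfg.ms1_tol_ppm
    )
    nl_score = min(1.0, neutral_loss_score(spectrum, tolerance=ms1_tol))
    out = []
    for mol, fragments in candidates:
        best_prec_mes = 0.0
        adduct_hints = (
            [spectrum.adduct_hint]
            if spectrum.adduct_hint is not None
            else adducts_for_mode(spectrum.ion_mode)
        )
        for adduct in adduct_hints:
            theor = ion_mz(mol.monoisotopic_mass, adduct)
            if abs(theor - spectrum.precursor_mz) <= ms1_tol:
                best_prec_mes = max(
                    best_prec_mes,
                    mass_error_score(spectrum.precursor_mz, theor, ms1_tol),
                )
        s0 = best_prec_mes + nl_score
        if cfg.cap_s0:
            s0 = min(1.0, best_prec_mes) + min(1.0, nl_score)
        matches = match_peaks(spectrum, fragments, cfg.ms2_tol_mda, cfg.ms2_tol_ppm)
        s1 = structure_score(matches)
        s2 = fragment_mes(matches)
        s3 = 0.0
        if bde_model is not None and fragments:
            predicted = predict_spectrum(mol, fragments, bde_model)
            s3 = cosine_score(
                spectrum, predicted, tolerance=cfg.ms2_tol_mda * 1e-3
            )
        s4 = meta_score(mol.meta.annotation_level) if cfg.use_meta else 0.0
        s5 = 0.0
        if (
            cfg.use_rt
            and rt_predictions is not None
            and spectrum.retention_time is not None
            and mol.meta.source_id in rt_predictions
        ):
            s5 = rt_score(
                spectrum.retention_time,
                rt_predictions[mol.meta.source_id],
                cfg.theta,
            )
        out.append(
            RankedCandidate(
                molecule=mol,
                score=CandidateScore(
                    s0, s1, s2, s3, s4, s5, cfg.alpha, cfg.beta, cfg.gamma
                ),
                matches=matches,
            )
        )
    out.sort(
        key=lambda rc: (
            -rc.final,
            -rc.score.s1,
            -rc.score.s2,
            rc.molecule.meta.source_id or rc.molecule.canonical_smiles,
        )
    )
    return out
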