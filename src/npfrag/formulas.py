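"""Molecular-formula inference from precursor m/z.

Candidate formulas for an observed precursor m/z are found either by
lookup in a reference formula library or by bounded de novo integer
decomposition over C,H,N,O,P,S, then scored with a Gaussian mass-error
score

    MES = exp(-0.5 * ((m_exp - m_theor) / delta)**2)

where ``delta`` (default 5 mDa) is the user tolerance, i.e. the Gaussian
width: an error of exactly ``delta`` scores e^-0.5.  A complementary
neutral-loss score rewards spectra whose peak pairs differ by frequently
observed neutral losses (H2O, CO, CO2, sugar residues, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

from .chem import (
    ELEMENTS,
    AdductType,
    ElementComposition,
    MONOISOTOPIC_MASS,
    adducts_for_mode,
    get_adduct,
    ion_mz,
    monoisotopic_mass,
    neutral_mass_from_mz,
)
from .errors import ConfigurationError

#: De novo decomposition bounds per element, covering the natural-product
#: mass range up to ~1500 Da.
ELEMENT_BOUNDS: dict[str, int] = {"C": 100, "H": 160, "N": 10, "O": 40, "P": 4, "S": 4}


def mass_error_score(mass_exp: float, mass_theor: float, delta: float = 0.005) -> float:
    """Gaussian mass-error score in (0, 1]; ``delta`` is the width in Da."""
    if delta <= 0:
        raise ConfigurationError("delta must be positive")
    z = (mass_exp - mass_theor) / delta
    return math.exp(-0.5 * z * z)


def effective_tolerance(mz: float, tol_mda: float | None, tol_ppm: float | None) -> float:
    """Absolute tolerance window in Da; the larger of the two wins."""
    cands = []
    if tol_mda is not None:
        cands.append(tol_mda * 1e-3)
    if tol_ppm is not None:
        cands.append(mz * tol_ppm * 1e-6)
    if not cands:
        raise ConfigurationError("no tolerance given")
    return max(cands)


def rdbe(comp: ElementComposition) -> float:
    """Ring-plus-double-bond equivalents of a neutral CHNOPS composition."""
    return comp["C"] - comp["H"] / 2 + comp["N"] / 2 + comp["P"] / 2 + 1


@dataclass(frozen=True)
class FormulaCandidate:
    composition: ElementComposition
    adduct: AdductType
    mass_theor: float  # theoretical ion m/z
    mass_exp: float  # observed precursor m/z
    delta_tolerance: float
    mass_error_score: float

    @property
    def error_mda(self) -> float:
        return (self.mass_exp - self.mass_theor) * 1e3


def decompose_mass(
    neutral_mass: float,
    tolerance: float,
    bounds: dict[str, int] | None = None,
    require_integer_rdbe: bool = True,
) -> list[ElementComposition]:
    """All CHNOPS compositions whose neutral mass falls within tolerance.

    Bounded exhaustive search over the heavy elements; the hydrogen count
    is solved from the residual mass.  Compositions with negative or
    non-integer ring-plus-double-bond equivalents are rejected (an even-
    electron neutral molecule must have integer RDBE >= 0).
    """
    b = {**ELEMENT_BOUNDS, **(bounds or {})}
    mC, mH, mN, mO, mP, mS = (MONOISOTOPIC_MASS[e] for e in ("C", "H", "N", "O", "P", "S"))
    out = []
    for s in range(min(b["S"], int(neutral_mass / mS)) + 1):
        ms = s * mS
        if ms > neutral_mass + tolerance:
            break
        for p in range(min(b["P"], int((neutral_mass - ms) / mP)) + 1):
            mp = ms + p * mP
            if mp > neutral_mass + tolerance:
                break
            for n in range(min(b["N"], int((neutral_mass - mp) / mN)) + 1):
                mn = mp + n * mN
                if mn > neutral_mass + tolerance:
                    break
                for o in range(min(b["O"], int((neutral_mass - mn) / mO)) + 1):
                    mo = mn + o * mO
                    if mo > neutral_mass + tolerance:
                        break
                    for c in range(min(b["C"], int((neutral_mass - mo) / mC)) + 1):
                        rem = neutral_mass - mo - c * mC
                        if rem < -tolerance:
                            break
                        h = round(rem / mH)
                        if h < 0 or h > b["H"]:
                            continue
                        if abs(rem - h * mH) > tolerance:
                            continue
                        comp = ElementComposition.from_dict(
                            {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s}
                        )
                        if comp.is_empty:
                            continue
                        r = rdbe(comp)
                        if require_integer_rdbe and (
                            r < 0 or abs(r - round(r)) > 1e-9
                        ):
                            continue
                        out.append(comp)
    return out


def infer_formulas(
    mass_exp: float,
    mode: str,
    adducts: list[AdductType | str] | None = None,
    tol_mda: float | None = 5.0,
    tol_ppm: float | None = None,
    reference: list[tuple[ElementComposition, float]] | None = None,
) -> list[FormulaCandidate]:
    """Ranked formula candidates for an observed precursor m/z.

    For each adduct hypothesis the neutral mass is back-calculated and
    matched against the reference library when given, otherwise de novo
    decomposition is used.  Candidates are scored by the Gaussian mass
    error of their theoretical ion m/z and returned in descending score
    order.
    """
    if mass_exp <= 0:
        raise ConfigurationError("precursor m/z must be positive")
    adduct_list = (
        [get_adduct(a) if isinstance(a, str) else a for a in adducts]
        if adducts
        else adducts_for_mode(mode)
    )
    tol = effective_tolerance(mass_exp, tol_mda, tol_ppm)
    out: list[FormulaCandidate] = []
    seen = set()
    for adduct in adduct_list:
        if adduct.mode != mode:
            continue
        neutral = neutral_mass_from_mz(mass_exp, adduct)
        if neutral <= 0:
            continue
        if reference is not None:
            comps = [
                comp
                for comp, mass in reference
                if abs(mass - neutral) <= tol / adduct.multiplicity
            ]
        else:
            comps = decompose_mass(neutral, tol / adduct.multiplicity)
        for comp in comps:
            theor = ion_mz(monoisotopic_mass(comp), adduct)
            if abs(theor - mass_exp) > tol:
                continue
            key = (comp.counts, adduct.name)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                FormulaCandidate(
                    composition=comp,
                    adduct=adduct,
                    mass_theor=theor,
                    mass_exp=mass_exp,
                    delta_tolerance=tol,
                    mass_error_score=mass_error_score(mass_exp, theor, tol),
                )
            )
    out.sort(key=lambda c: (-c.mass_error_score, c.composition.formula(), c.adduct.name))
    return out


# ---------------------------------------------------------------------------
# Neutral-loss score


@dataclass(frozen=True)
class NeutralLossEntry:
    formula: ElementComposition
    mass: float
    label: str


def _builtin_losses() -> list[NeutralLossEntry]:
    entries = []
    text = resources.files("npfrag.data").joinpath("neutral_losses.tsv").read_text()
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        label, formula = line.split("\t")
        comp = ElementComposition.from_formula(formula)
        entries.append(NeutralLossEntry(comp, monoisotopic_mass(comp), label))
    return entries


_DEFAULT_LOSSES: list[NeutralLossEntry] | None = None


def default_neutral_losses() -> list[NeutralLossEntry]:
    """The frequent-neutral-loss table shipped with the package."""
    global _DEFAULT_LOSSES
    if _DEFAULT_LOSSES is None:
        _DEFAULT_LOSSES = _builtin_losses()
    return _DEFAULT_LOSSES


def read_neutral_losses(path) -> list[NeutralLossEntry]:
    """Read a user neutral-loss table (TSV: label, formula)."""
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            label, formula = line.split("\t")
            comp = ElementComposition.from_formula(formula)
            entries.append(NeutralLossEntry(comp, monoisotopic_mass(comp), label))
    return entries


def neutral_loss_score(
    spectrum,
    loss_table: list[NeutralLossEntry] | None = None,
    tolerance: float = 0.005,
) -> float:
    """Score the presence of frequent neutral-loss peak pairs in a spectrum.

    For every ordered peak pair (source S above target T) whose m/z
    difference matches a table loss within tolerance, the source and
    target contribute ``intensity * MES`` terms:

        score = 0.5 * (sum_S I_S * MES_S + sum_T I_T * MES_T), capped at 1

    The spectrum must be normalized to summed intensity 1.
    """
    losses = loss_table if loss_table is not None else default_neutral_losses()
    peaks = spectrum.peaks
    s_term = 0.0
    t_term = 0.0
    n = len(peaks)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = peaks[i][0] - peaks[j][0]
            if diff <= 0:
                continue
            best = None
            for entry in losses:
                err = abs(diff - entry.mass)
                if err <= tolerance and (best is None or err < best):
                    best = err
            if best is not None:
                mes = mass_error_score(best, 0.0, tolerance)
                s_term += peaks[i][1] * mes
                t_term += peaks[j][1] * mes
    return min(1.0, 0.5 * (s_term + t_term))
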