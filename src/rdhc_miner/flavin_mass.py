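"""Mass arithmetic for covalent flavinylation.

Covalent FMN attachment to a threonine proceeds with loss of one water, so
the net adduct on the protein is FMN - H2O (average +438.33 Da,
monoisotopic +438.0940 Da, from the FMN formula C17H21N4O9P).  This module
computes intact proteoform masses (including N-terminal methionine
excision), modified tryptic peptide masses, the diagnostic flavin fragment
ions seen in MS/MS spectra of flavinylated peptides, and tolerance-based
annotation of peak lists against theoretical b/y series.

Intact proteoforms are reported on the average-mass scale (the scale of
deconvoluted intact-protein spectra); peptides and fragments are
monoisotopic (the scale of the 0.05 Da fragment / 10 ppm parent search
tolerances).  The mode is always explicit.

All elemental arithmetic is delegated to :mod:`pyteomics.mass`; every table
value is reproducible from atomic composition.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .motifs import BUILTIN_MOTIFS, scan_sequence
from .seqio import STANDARD_AA, RdhcError
from .surfaceome import Peptide

PROTON = 1.00728  # Da

_WATER = _pmass.Composition(formula="H2O")
WATER_AVERAGE = _WATER.mass(average=True)  # 18.015
WATER_MONO = _WATER.mass()  # 18.0106

_FMN = _pmass.Composition(formula="C17H21N4O9P")
FMN_AVERAGE = _FMN.mass(average=True)  # 456.34
FMN_MONO = _FMN.mass()  # 456.1046

#: Net mass added to a protein per covalent FMN (water released on attachment).
FMN_ADDUCT_AVERAGE = FMN_AVERAGE - WATER_AVERAGE  # +438.33
FMN_ADDUCT_MONO = FMN_MONO - WATER_MONO  # +438.0940

#: Per-residue masses, reproducible from atomic composition to 4 decimals.
RESIDUE_AVERAGE = {aa: _pmass.std_aa_comp[aa].mass(average=True) for aa in STANDARD_AA}
RESIDUE_MONO = {aa: _pmass.std_aa_comp[aa].mass() for aa in STANDARD_AA}

#: Residues small enough for methionine aminopeptidase to act on position 1.
MET_EXCISION_SECOND_RESIDUES = frozenset("ACGPSTV")


class MassError(RdhcError):
    """Invalid sequence, modification or tolerance in a mass computation."""


@dataclass(frozen=True)
class Modification:
    """A named residue modification with per-mode mass deltas."""

    name: str
    targets: frozenset  # residues the modification can sit on
    mono_delta: float
    average_delta: float
    n_term_only: bool = False


def _delta(formula: str) -> tuple[float, float]:
    comp = _pmass.Composition(formula=formula)
    return comp.mass(), comp.mass(average=True)


_CAM = _delta("C2H3NO")
_OX = _delta("O")
_NH3 = _delta("NH3")
_PHOS = _delta("HPO3")

#: Standard search modifications; FMN-T is the covalent flavin adduct.
MODIFICATIONS: dict[str, Modification] = {
    "carbamidomethyl-C": Modification(
        "carbamidomethyl-C", frozenset("C"), _CAM[0], _CAM[1]
    ),
    "oxidation-M": Modification("oxidation-M", frozenset("M"), _OX[0], _OX[1]),
    "pyro-glu-Q": Modification(
        "pyro-glu-Q", frozenset("Q"), -_NH3[0], -_NH3[1], n_term_only=True
    ),
    "phospho-STY": Modification("phospho-STY", frozenset("STY"), _PHOS[0], _PHOS[1]),
    "fmn-T": Modification(
        "fmn-T", frozenset("T"), FMN_ADDUCT_MONO, FMN_ADDUCT_AVERAGE
    ),
}


def _residue_table(mode: str) -> Mapping[str, float]:
    if mode == "average":
        return RESIDUE_AVERAGE
    if mode == "monoisotopic":
        return RESIDUE_MONO
    raise MassError(f"mode must be 'average' or 'monoisotopic', got {mode!r}")


def _water(mode: str) -> float:
    return WATER_AVERAGE if mode == "average" else WATER_MONO


def protein_mass(sequence: str, mode: str = "average") -> float:
    """Neutral mass of an unmodified chain: sum of residue masses plus water."""
    table = _residue_table(mode)
    if not sequence:
        raise MassError("empty sequence")
    total = _water(mode)
    for pos, ch in enumerate(sequence, start=1):
        if ch not in table:
            raise MassError(f"non-standard residue {ch!r} at position {pos}")
        total += table[ch]
    return total


def apply_met_excision(sequence: str, rule: str = "auto") -> str:
    """Remove the initiator methionine when the second residue is small.

    ``rule``: ``auto`` (default, excise iff residue 2 is one of A/C/G/P/S/T/V,
    the methionine-aminopeptidase specificity), ``always``, or ``never``.
    """
    if not sequence:
        raise MassError("empty sequence")
    if rule == "never" or sequence[0] != "M" or len(sequence) < 2:
        return sequence
    if rule == "always":
        return sequence[1:]
    if rule == "auto":
        return sequence[1:] if sequence[1] in MET_EXCISION_SECOND_RESIDUES else sequence
    raise MassError(f"unknown met-excision rule {rule!r}")


def flavinylate(mass_da: float, n_fmn: int = 1, mode: str = "average") -> float:
    """Add ``n_fmn`` covalent FMN adducts (FMN - H2O each) to a neutral mass."""
    if n_fmn < 0:
        raise MassError(f"n_fmn must be >= 0, got {n_fmn}")
    _residue_table(mode)  # validates mode
    adduct = FMN_ADDUCT_AVERAGE if mode == "average" else FMN_ADDUCT_MONO
    return mass_da + n_fmn * adduct


@dataclass(frozen=True)
class ProteoformMass:
    """A (modified) peptide or protein with its modification ledger.

    ``modifications`` holds (site, name, delta) triples; the total mass is
    the unmodified chain mass plus the sum of deltas (strict additivity).
    """

    sequence: str
    modifications: tuple  # of (site: int 1-based, name: str, delta: float)
    mode: str
    mass: float


def _resolve_mods(names: Iterable[str]) -> list[Modification]:
    out = []
    for name in names:
        if name not in MODIFICATIONS:
            raise MassError(
                f"unknown modification {name!r}; known: {sorted(MODIFICATIONS)}"
            )
        out.append(MODIFICATIONS[name])
    return out


def peptide_masses(
    peptides: Sequence[Peptide | str],
    fixed_mods: Sequence[str] = ("carbamidomethyl-C",),
    variable_mods: Sequence[str] = (),
    max_var: int = 3,
    mode: str = "monoisotopic",
) -> list[ProteoformMass]:
    """Enumerate proteoform masses for digested peptides.

    Fixed modifications are applied to every eligible site; all
    combinations of at most ``max_var`` variable modifications over
    eligible sites are enumerated (one modification per site).
    """
    fixed = _resolve_mods(fixed_mods)
    variable = _resolve_mods(variable_mods)
    table = _residue_table(mode)
    out: list[ProteoformMass] = []
    for pep in peptides:
        seq = pep.sequence if isinstance(pep, Peptide) else pep
        base = protein_mass(seq, mode)
        fixed_ledger = []
        for mod in fixed:
            delta = mod.average_delta if mode == "average" else mod.mono_delta
            for pos, ch in enumerate(seq, start=1):
                if ch in mod.targets and (not mod.n_term_only or pos == 1):
                    fixed_ledger.append((pos, mod.name, delta))
        base += sum(d for _, _, d in fixed_ledger)
        # every (site, variable mod) pairing, at most one mod per site
        var_sites: list[tuple[int, str, float]] = []
        for mod in variable:
            delta = mod.average_delta if mode == "average" else mod.mono_delta
            for pos, ch in enumerate(seq, start=1):
                if ch in mod.targets and (not mod.n_term_only or pos == 1):
                    var_sites.append((pos, mod.name, delta))
        for k in range(min(max_var, len(var_sites)) + 1):
            for combo in itertools.combinations(var_sites, k):
                if len({site for site, _, _ in combo}) != len(combo):
                    continue  # one modification per site
                out.append(
                    ProteoformMass(
                        sequence=seq,
                        modifications=tuple(fixed_ledger) + combo,
                        mode=mode,
                        mass=base + sum(d for _, _, d in combo),
                    )
                )
    return out


def make_proteoform(
    sequence: str,
    modifications: Sequence[tuple[int, str]] = (),
    mode: str = "monoisotopic",
) -> ProteoformMass:
    """Build a proteoform with named modifications at explicit 1-based sites."""
    total = protein_mass(sequence, mode)
    ledger = []
    for site, name in modifications:
        mod = _resolve_mods([name])[0]
        if not (1 <= site <= len(sequence)):
            raise MassError(f"modification site {site} outside 1..{len(sequence)}")
        if sequence[site - 1] not in mod.targets:
            raise MassError(
                f"{name} cannot sit on {sequence[site - 1]!r} at position {site}"
            )
        delta = mod.average_delta if mode == "average" else mod.mono_delta
        ledger.append((site, name, delta))
        total += delta
    return ProteoformMass(
        sequence=sequence, modifications=tuple(ledger), mode=mode, mass=total
    )


def diagnostic_ions(
    mode: str = "monoisotopic",
    custom: Sequence[tuple[str, float]] | None = None,
) -> list[tuple[str, float]]:
    """Diagnostic flavin ions for MS/MS annotation, as (name, m/z) pairs.

    Defaults cover the protonated flavin and its classic neutral losses:
    FMN+H (457.1119), FMN+H - H2O (439.1013), FMN+H - HPO3 (377.1456).
    Passing ``custom`` replaces the table entirely (an empty sequence
    disables diagnostic matching).
    """
    if custom is not None:
        return list(custom)
    fmn = FMN_AVERAGE if mode == "average" else FMN_MONO
    water = _water(mode)
    phos = _PHOS[1] if mode == "average" else _PHOS[0]
    fmn_h = fmn + PROTON
    return [
        ("FMN+H", fmn_h),
        ("FMN+H-H2O", fmn_h - water),
        ("FMN+H-HPO3", fmn_h - phos),
    ]


def fragment_ions(proteoform: ProteoformMass, charge: int = 1) -> list[tuple[str, float]]:
    """Theoretical b/y fragment series of a proteoform, as (name, m/z).

    Modification deltas are carried by whichever fragment contains the
    modified site.  Default is singly charged; higher charges use
    m/z = (M + z * proton) / z.
    """
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    seq = proteoform.sequence
    table = _residue_table(proteoform.mode)
    water = _water(proteoform.mode)
    n = len(seq)
    prefix = np.zeros(n + 1)
    for i, ch in enumerate(seq, start=1):
        prefix[i] = prefix[i - 1] + table[ch]
    mod_prefix = np.zeros(n + 1)
    for site, _, delta in proteoform.modifications:
        mod_prefix[site:] += delta
    ions = []
    for i in range(1, n):  # b1..b(n-1), y1..y(n-1)
        b_neutral = prefix[i] + mod_prefix[i]
        y_neutral = (prefix[n] - prefix[i]) + (mod_prefix[n] - mod_prefix[i]) + water
        suffix = f"^{charge}+" if charge > 1 else ""
        ions.append((f"b{i}{suffix}", (b_neutral + charge * PROTON) / charge))
        ions.append((f"y{n - i}{suffix}", (y_neutral + charge * PROTON) / charge))
    return ions


@dataclass(frozen=True)
class IonMatch:
    ion_name: str
    theoretical_mz: float
    observed_mz: float
    error_da: float


@dataclass(frozen=True)
class AnnotatedSpectrum:
    """A peak list with its matched theoretical ions and the parent verdict."""

    peaks: np.ndarray  # (n, 2) m/z, intensity
    matches: tuple  # of IonMatch
    frag_tol_da: float
    parent_tol_ppm: float
    parent_error_ppm: float | None
    parent_ok: bool | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ion": m.ion_name,
                    "theoretical_mz": round(m.theoretical_mz, 5),
                    "observed_mz": round(m.observed_mz, 5),
                    "error_da": round(m.error_da, 5),
                }
                for m in self.matches
            ],
            columns=["ion", "theoretical_mz", "observed_mz", "error_da"],
        )


def annotate_spectrum(
    peaks: Sequence[Sequence[float]],
    proteoform: ProteoformMass,
    frag_tol_da: float = 0.05,
    parent_tol_ppm: float = 10.0,
    parent_mz: float | None = None,
    charge: int = 1,
    diagnostics: Sequence[tuple[str, float]] | None = None,
) -> AnnotatedSpectrum:
    """Match an observed peak list against the proteoform's b/y series and
    the diagnostic flavin ions.

    Peaks must be sorted by m/z.  Each observed peak is assigned to at most
    one theoretical ion — the closest within ``frag_tol_da``.  When
    ``parent_mz`` is given, the deconvoluted parent mass is checked against
    the proteoform mass within ``parent_tol_ppm``.
    """
    if frag_tol_da <= 0 or parent_tol_ppm <= 0:
        raise MassError("tolerances must be positive")
    arr = np.asarray(peaks, dtype=float).reshape(-1, 2)
    if arr.shape[0] > 1 and np.any(np.diff(arr[:, 0]) < 0):
        raise MassError("peaks must be sorted by m/z")
    theoretical = fragment_ions(proteoform, charge=1)
    theoretical += diagnostic_ions(proteoform.mode) if diagnostics is None else list(diagnostics)
    matches = []
    for mz, _intensity in arr:
        best = None
        for name, theo in theoretical:
            err = mz - theo
            if abs(err) <= frag_tol_da and (best is None or abs(err) < abs(best[2])):
                best = (name, theo, err)
        if best is not None:
            matches.append(
                IonMatch(
                    ion_name=best[0],
                    theoretical_mz=best[1],
                    observed_mz=float(mz),
                    error_da=float(best[2]),
                )
            )
    parent_error = None
    parent_ok = None
    if parent_mz is not None:
        if charge < 1:
            raise MassError("charge must be >= 1")
        observed_mass = parent_mz * charge - charge * PROTON
        parent_error = (observed_mass - proteoform.mass) / proteoform.mass * 1e6
        parent_ok = abs(parent_error) <= parent_tol_ppm
    return AnnotatedSpectrum(
        peaks=arr,
        matches=tuple(matches),
        frag_tol_da=frag_tol_da,
        parent_tol_ppm=parent_tol_ppm,
        parent_error_ppm=parent_error,
        parent_ok=parent_ok,
    )


_SUBSTITUTION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantReport:
    """Effect of a point substitution on flavinylation competence."""

    substitution: str
    original_sequence: str
    variant_sequence: str
    hits_before: int
    hits_after: int
    flavinylatable: bool


def variant_effect(sequence: str, substitution: str) -> VariantReport:
    """Apply a substitution like ``"T168V"`` and re-scan the FMN consensus.

    The stated original residue is checked against the sequence.  The
    variant is flavinylatable when at least one consensus hit with an
    acceptor threonine survives the substitution.
    """
    m = _SUBSTITUTION_RE.match(substitution.strip())
    if not m:
        raise MassError(f"substitution {substitution!r} not of the form T168V")
    orig, pos, new = m.group(1), int(m.group(2)), m.group(3)
    if not (1 <= pos <= len(sequence)):
        raise MassError(f"substitution position {pos} outside 1..{len(sequence)}")
    if sequence[pos - 1] != orig:
        raise MassError(
            f"sequence has {sequence[pos - 1]!r} at position {pos}, not {orig!r}"
        )
    if new not in STANDARD_AA:
        raise MassError(f"replacement residue {new!r} is not a standard residue")
    variant = sequence[:pos - 1] + new + sequence[pos:]
    motif = BUILTIN_MOTIFS["FMN_CONSENSUS"]
    before = scan_sequence(sequence, motif)
    after = scan_sequence(variant, motif)
    flavinylatable = any(
        h.acceptor_position is not None
        and variant[h.acceptor_position - 1] == "T"
        for h in after
    )
    return VariantReport(
        substitution=substitution,
        original_sequence=sequence,
        variant_sequence=variant,
        hits_before=len(before),
        hits_after=len(after),
        flavinylatable=flavinylatable,
    )
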