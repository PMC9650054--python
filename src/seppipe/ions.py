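"""Fragment-ion arithmetic: peptide masses, theoretical b/y ladders,
spectrum matching at fixed tolerances and ppm-error computation.

Only singly-charged b/y ions are generated by default.  Neutral losses,
a/c/x/z ions and isotope peaks are deliberately not modelled.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MONOISOTOPIC",
    "WATER",
    "PROTON",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "ModifiedPeptide",
    "Spectrum",
    "IonAnnotation",
    "Tolerances",
    "peptide_mass",
    "precursor_mz",
    "theoretical_ions",
    "match_spectrum",
    "precursor_ppm_error",
    "longest_consecutive_run",
    "read_mgf",
    "write_mgf",
]

#: Monoisotopic residue masses (Da) for the 20 standard amino acids.
MONOISOTOPIC: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.0105646863
PROTON = 1.00727646688

#: Fixed cysteine carbamidomethylation delta (Da).
CARBAMIDOMETHYL = 57.02146
#: Variable methionine oxidation delta (Da).
OXIDATION = 15.99491


@dataclass(frozen=True)
class ModifiedPeptide:
    """An amino-acid sequence plus a list of (0-based position, delta Da) mods."""

    sequence: str
    mods: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        for ch in self.sequence:
            if ch not in MONOISOTOPIC:
                raise ValueError(f"unknown residue {ch!r} in peptide {self.sequence!r}")
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for pos, _ in self.mods:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"mod position {pos} outside peptide of length {len(self.sequence)}")

    @classmethod
    def create(
        cls,
        sequence: str,
        variable_mods: Iterable[tuple[int, float]] = (),
        fixed_cam: bool = True,
    ) -> "ModifiedPeptide":
        """Build a peptide, applying fixed carbamidomethyl to every C when
        ``fixed_cam`` (the default search configuration)."""
        mods = list(variable_mods)
        if fixed_cam:
            mods.extend((i, CARBAMIDOMETHYL) for i, aa in enumerate(sequence) if aa == "C")
        return cls(sequence, tuple(sorted(mods)))

    def __len__(self) -> int:
        return len(self.sequence)

    def mods_string(self) -> str:
        """Serialize mods as ``pos:delta;...`` (``-`` when unmodified)."""
        if not self.mods:
            return "-"
        return ";".join(f"{p}:{d:.5f}" for p, d in self.mods)

    @classmethod
    def from_strings(cls, sequence: str, mods: str = "-") -> "ModifiedPeptide":
        if mods in ("", "-", None):
            return cls(sequence)
        parsed = []
        for item in mods.split(";"):
            pos, delta = item.split(":")
            parsed.append((int(pos), float(delta)))
        return cls(sequence, tuple(sorted(parsed)))


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum; peaks are kept sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class IonAnnotation:
    """One b/y ion: theoretical m/z plus the matched observed peak, if any."""

    series: str              # 'b' or 'y'
    index: int               # 1 .. len(peptide)-1
    theoretical_mz: float
    observed_mz: float | None = None
    delta_da: float | None = None


@dataclass(frozen=True)
class Tolerances:
    precursor_ppm: float = 10.0
    fragment_da: float = 0.02
    curation_ppm: float = 2.0

    def __post_init__(self) -> None:
        if min(self.precursor_ppm, self.fragment_da, self.curation_ppm) <= 0:
            raise ValueError("tolerances must be positive")


def _residue_masses(p: ModifiedPeptide) -> np.ndarray:
    masses = np.array([MONOISOTOPIC[aa] for aa in p.sequence], dtype=float)
    for pos, delta in p.mods:
        masses[pos] += delta
    return masses


def peptide_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: sum of residues + mod deltas + water."""
    return float(_residue_masses(p).sum() + WATER)


def precursor_mz(p: ModifiedPeptide, charge: int) -> float:
    """Theoretical precursor m/z at the given positive charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(p) + charge * PROTON) / charge


def theoretical_ions(p: ModifiedPeptide, max_index: int | None = None) -> list[IonAnnotation]:
    """Singly-charged b/y ladder for a peptide of length n: 2*(n-1) ions.

    b_i = sum of the first i residues (+mods) + proton;
    y_i = sum of the last i residues (+mods) + water + proton.
    """
    n = len(p)
    if n < 2:
        raise ValueError("peptide must have length >= 2 for fragmentation")
    masses = _residue_masses(p)
    prefix = np.cumsum(masses)
    suffix = np.cumsum(masses[::-1])
    limit = n - 1 if max_index is None else min(max_index, n - 1)
    out: list[IonAnnotation] = []
    for i in range(1, limit + 1):
        out.append(IonAnnotation("b", i, float(prefix[i - 1] + PROTON)))
    for i in range(1, limit + 1):
        out.append(IonAnnotation("y", i, float(suffix[i - 1] + WATER + PROTON)))
    return out


def match_spectrum(p: ModifiedPeptide, s: Spectrum, tol: Tolerances = Tolerances()) -> list[IonAnnotation]:
    """Match the theoretical b/y ladder against a spectrum.

    Each theoretical ion is assigned the nearest peak within
    ``tol.fragment_da``; exact distance ties go to the more intense peak.
    Returns only the annotations with an observed peak.
    """
    ions = theoretical_ions(p)
    mz = s.mz
    matched: list[IonAnnotation] = []
    for ion in ions:
        j = bisect.bisect_left(mz, ion.theoretical_mz)
        best = None
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(mz):
                d = abs(mz[k] - ion.theoretical_mz)
                if d <= tol.fragment_da:
                    key = (d, -s.intensity[k])
                    if best is None or key < best[0]:
                        best = (key, k)
        if best is not None:
            k = best[1]
            ion.observed_mz = float(mz[k])
            ion.delta_da = float(mz[k] - ion.theoretical_mz)
            matched.append(ion)
    return matched


def precursor_ppm_error(p: ModifiedPeptide, s: Spectrum) -> float:
    """Signed precursor mass error in ppm.

    observed_neutral = precursor_mz * z - z * proton;
    ppm = (observed_neutral - theoretical) / theoretical * 1e6.
    """
    z = s.precursor_charge
    if z < 1:
        raise ValueError("precursor charge must be >= 1")
    theo = peptide_mass(p)
    obs = s.precursor_mz * z - z * PROTON
    return (obs - theo) / theo * 1e6


def longest_consecutive_run(
    annotations: Sequence[IonAnnotation],
    combined: bool = False,
    peptide_length: int | None = None,
) -> int:
    """Longest run of consecutive matched ion indices.

    By default runs are counted within each series (b or y) separately and
    the maximum over the two is returned.  ``combined=True`` merges both
    series onto backbone-bond positions counted from the N terminus (y_i
    breaks the same bond as b_{n-i}); this merged-ladder interpretation
    needs ``peptide_length``.
    """
    observed = [a for a in annotations if a.observed_mz is not None]
    if not observed:
        return 0
    if combined:
        if peptide_length is None:
            raise ValueError("combined mode requires peptide_length")
        bonds = set()
        for a in observed:
            bonds.add(a.index if a.series == "b" else peptide_length - a.index)
        return _longest_run(bonds)
    best = 0
    for series in ("b", "y"):
        idx = {a.index for a in observed if a.series == series}
        best = max(best, _longest_run(idx))
    return best


def _longest_run(indices: set[int]) -> int:
    best = 0
    for i in indices:
        if i - 1 not in indices:
            j = i
            while j + 1 in indices:
                j += 1
            best = max(best, j - i + 1)
    return best


# ---------------------------------------------------------------------------
# MGF input/output (TITLE/PEPMASS/CHARGE conventions).


def write_mgf(spectra: Iterable[Spectrum], path: str) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def read_mgf(path: str) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    title = None
    pepmass = None
    charge = 1
    mzs: list[float] = []
    ints: list[float] = []
    in_block = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block = True
                title, pepmass, charge = None, None, 1
                mzs, ints = [], []
            elif line == "END IONS":
                if title is None or pepmass is None:
                    raise ValueError("MGF block missing TITLE or PEPMASS")
                spectra.append(Spectrum(title, pepmass, charge, np.array(mzs), np.array(ints)))
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    title = line[6:]
                elif line.startswith("PEPMASS="):
                    pepmass = float(line[8:].split()[0])
                elif line.startswith("CHARGE="):
                    charge = int(line[7:].rstrip("+").lstrip("-") or 1)
                elif "=" not in line:
                    parts = line.split()
                    mzs.append(float(parts[0]))
                    ints.append(float(parts[1]) if len(parts) > 1 else 0.0)
    return spectra
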