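"""Peptide methylation mass arithmetic and XIC-based stoichiometry.

Monoisotopic residue masses plus the proton mass 1.007276 Da reproduce, at
2-decimal rounding, the selective-ion m/z grids used to monitor the Me0-Me3
states of the two eEF1A marker peptides (the Glu-C peptide spanning Lys55 and
the chymotryptic iMet-less N-terminal peptide).  Each methyl group adds one
CH2 = 14.015650 Da; the methylated amine (alpha vs epsilon) does not change
the mass, so the site is annotation only.

Stoichiometry of the Me0-Me3 species is approximated as the relative signal
intensity of each species' extracted ion chromatogram (XIC), integrated by
the trapezoid rule after constant-baseline subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: monoisotopic residue (amino-acid minus water) masses, Da
RESIDUE_MASSES = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

WATER = 18.010565
PROTON = 1.007276
METHYL = 14.015650  # CH2
C13_MINUS_C12 = 1.003355
N15_MINUS_N14 = 0.997035

#: chymotryptic iMet-less N-terminal peptide of eEF1A, Gly2-Tyr29
EEF1A_NTERM_PEPTIDE = "GKEKTHINIVVIGHVDSGKSTTTGHLIY"
#: Glu-C peptide of eEF1A spanning Lys55, Met49-Glu68
EEF1A_LYS55_PEPTIDE = "MGKGSFKYAWVLDKLKAERE"


@dataclass
class MethylPeptideSpec:
    """A peptide analyte: sequence, methylation state and charge.

    ``site_label`` (e.g. "N-terminus" or "Lys55") is annotation only —
    methylation site does not affect the mass.
    """

    sequence: str
    n_methyl: int = 0
    charge: int = 1
    site_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for letter in self.sequence:
            if letter not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue letter {letter!r} in {self.sequence!r}")
        if not 0 <= self.n_methyl <= 3:
            raise ValueError(f"n_methyl must be in [0, 3], got {self.n_methyl}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


@dataclass
class MethylStoichiometry:
    """Fractions of the Me0..Me3 species; sums to 1 when signal is present."""

    fractions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    @property
    def dominant_state(self) -> int:
        return int(np.argmax(self.fractions))


def monoisotopic_mass(spec: MethylPeptideSpec | str, n_methyl: int | None = None) -> float:
    """Monoisotopic peptide mass in Da: residue masses + water + n*CH2."""
    if isinstance(spec, str):
        spec = MethylPeptideSpec(spec, n_methyl=n_methyl or 0)
    elif n_methyl is not None:
        raise TypeError("pass n_methyl inside the spec or with a bare sequence")
    mass = WATER + spec.n_methyl * METHYL
    for letter in spec.sequence:
        mass += RESIDUE_MASSES[letter]
    return mass


def mz(spec: MethylPeptideSpec) -> float:
    """m/z = (M + z * proton) / z, full precision."""
    return (monoisotopic_mass(spec) + spec.charge * PROTON) / spec.charge


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero — how selective-ion settings are printed."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def selective_ion_grid(sequence: str, charges: tuple[int, ...], site_label: str = "") -> pd.DataFrame:
    """Printed-style m/z grid over Me0..Me3 and the given charge states."""
    rows = []
    for z in charges:
        for n in range(4):
            value = mz(MethylPeptideSpec(sequence, n_methyl=n, charge=z, site_label=site_label))
            rows.append({"charge": z, "n_methyl": n, "mz": value, "mz_2dp": round_half_away(value)})
    return pd.DataFrame(rows)


def ppm_window(center_mz: float, ppm: float) -> tuple[float, float]:
    """Symmetric relative window: center * (1 +/- ppm * 1e-6)."""
    if ppm < 0:
        raise ValueError("ppm tolerance must be >= 0")
    return center_mz * (1 - ppm * 1e-6), center_mz * (1 + ppm * 1e-6)


def extract_xic(chromatogram: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    """Sum intensity of points with m/z inside the window, per retention time.

    Returns a trace over the chromatogram's full retention-time grid (zero
    where nothing falls in the window), columns rt_min and intensity.
    """
    low, high = window
    grid = np.unique(chromatogram["rt_min"].to_numpy())
    inside = chromatogram[(chromatogram["mz"] >= low) & (chromatogram["mz"] <= high)]
    summed = inside.groupby("rt_min")["intensity"].sum()
    trace = pd.DataFrame({"rt_min": grid})
    trace["intensity"] = trace["rt_min"].map(summed).fillna(0.0)
    return trace


def _baseline(trace: pd.DataFrame, edge_fraction: float = 0.05) -> float:
    """Constant baseline: median intensity of the first and last 5% of time
    points, floored at 0."""
    n = len(trace)
    k = max(1, int(n * edge_fraction))
    edges = np.concatenate([trace["intensity"].to_numpy()[:k], trace["intensity"].to_numpy()[-k:]])
    return max(0.0, float(np.median(edges)))


def methyl_stoichiometry(xics: list[pd.DataFrame]) -> MethylStoichiometry:
    """Me0..Me3 site occupancy as relative integrated XIC signal.

    Expects four traces (Me0..Me3) on a common time grid; each is integrated
    by the trapezoid rule after constant-baseline subtraction.
    """
    if len(xics) != 4:
        raise ValueError(f"expected four XIC traces (Me0..Me3), got {len(xics)}")
    areas = []
    for trace in xics:
        y = np.maximum(trace["intensity"].to_numpy() - _baseline(trace), 0.0)
        areas.append(float(np.trapezoid(y, trace["rt_min"].to_numpy())))
    total = sum(areas)
    if total <= 0:
        raise ValueError("no signal: all XIC areas are zero after baseline subtraction")
    return MethylStoichiometry(tuple(a / total for a in areas))


SILAC_SHIFTS = {
    "K8": 6 * C13_MINUS_C12 + 2 * N15_MINUS_N14,   # Lys(13C6, 15N2)
    "R10": 6 * C13_MINUS_C12 + 4 * N15_MINUS_N14,  # Arg(13C6, 15N4)
}


def silac_shift(label: str) -> tuple[float, int]:
    """Mass shift of a heavy SILAC label: (full precision Da, nominal Da)."""
    if label not in SILAC_SHIFTS:
        raise ValueError(f"unknown SILAC label {label!r}; known: {sorted(SILAC_SHIFTS)}")
    delta = SILAC_SHIFTS[label]
    return delta, round(delta)


def adomet_concentration(activity_uCi: float, specific_activity_Ci_per_mmol: float,
                         volume_ul: float) -> float:
    """Total AdoMet concentration (uM) in a radiolabelled methylation reaction.

    amount = activity / specific activity; concentration = amount / volume.
    uCi / (Ci/mmol) = 1e-6 mmol*Ci/Ci ... propagated so the result is in uM.
    """
    if activity_uCi <= 0 or specific_activity_Ci_per_mmol <= 0:
        raise ValueError("activity and specific activity must be > 0")
    if volume_ul <= 0:
        raise ValueError("reaction volume must be > 0")
    mol = activity_uCi * 1e-6 / specific_activity_Ci_per_mmol * 1e-3  # Ci/(Ci/mmol) -> mmol -> mol
    litres = volume_ul * 1e-6
    return mol / litres * 1e6  # mol/l -> uM
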