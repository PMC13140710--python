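"""Scalar biochemical quantifications.

Molar extinction coefficients at 280 nm from sequence composition
(5500 per Trp, 1490 per Tyr, 125 per cystine when oxidized), degree of
labeling of a dye-protein conjugate, dilute-phase concentration and
fraction after pelleting condensates (Beer-Lambert), and the total
turbidity change of a light-scattering time course.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .io import TurbiditySeries

EXT_TRP = 5500.0
EXT_TYR = 1490.0
EXT_CYSTINE = 125.0

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def extinction_coefficient(sequence: str, cystines: str = "reduced") -> float:
    """Composition-rule molar extinction coefficient at 280 nm (M^-1 cm^-1).

    eps = 5500*nTrp + 1490*nTyr (+ 125 per cystine when ``cystines`` is
    "oxidized"; every cysteine is assumed disulfide-engaged, so an odd
    residue still contributes a half-cystine's full 125). Whitespace is
    ignored; any other non-standard letter is rejected by position.
    """
    if cystines not in ("reduced", "oxidized"):
        raise ValueError("cystines must be 'reduced' or 'oxidized'")
    seq = "".join(sequence.split()).upper()
    for pos, aa in enumerate(seq, start=1):
        if aa not in _AA:
            raise ValueError(f"invalid residue {aa!r} at position {pos}")
    eps = EXT_TRP * seq.count("W") + EXT_TYR * seq.count("Y")
    if cystines == "oxidized":
        eps += EXT_CYSTINE * ceil(seq.count("C") / 2)
    return eps


@dataclass
class LabelingInputs:
    """Absorbances and constants for a degree-of-labeling calculation.

    ``cf`` is the dye's 280 nm correction factor (0.08 for Cy5);
    ``mw_protein`` is accepted as metadata but does not enter the molar-ratio
    formula.
    """

    a280: float
    a_dye: float
    eps_protein: float
    eps_dye: float
    cf: float = 0.08
    mw_protein: float | None = None

    def __post_init__(self) -> None:
        if self.a280 < 0 or self.a_dye < 0 or self.cf < 0:
            raise ValueError("absorbances and cf must be non-negative")
        if self.eps_protein <= 0 or self.eps_dye <= 0:
            raise ValueError("extinction coefficients must be > 0")


def degree_of_labeling(inputs: LabelingInputs) -> float:
    """Molar dye:protein ratio of a conjugate, as a percentage.

    DOL = 100 * (A_dye/eps_dye) / ((A280 - cf*A_dye)/eps_protein). The dye
    also absorbs at 280 nm, hence the correction; values above 100% mean
    more than one dye per protein on average.
    """
    corrected = inputs.a280 - inputs.cf * inputs.a_dye
    if corrected <= 0:
        raise ValueError("corrected protein absorbance (A280 - cf*A_dye) must be > 0")
    protein_molar = corrected / inputs.eps_protein
    dye_molar = inputs.a_dye / inputs.eps_dye
    return 100.0 * dye_molar / protein_molar


@dataclass
class CondensationQuant:
    total_conc_uM: float
    dilute_conc_uM: float
    dilute_fraction: float
    over_unity: bool = False
    delta_od: dict[str, float] | None = None


def dilute_phase_fraction(a280_supernatant: float, eps: float, path_cm: float,
                          total_uM: float) -> CondensationQuant:
    """Dilute-phase (supernatant) concentration and fraction after pelleting
    condensed material, via Beer-Lambert A = eps*c*l.

    A fraction above 1.05 (supernatant apparently more concentrated than the
    input) is flagged, not clipped.
    """
    if a280_supernatant < 0:
        raise ValueError("negative absorbance")
    if total_uM <= 0 or path_cm <= 0 or eps <= 0:
        raise ValueError("total_uM, path_cm and eps must be > 0")
    dilute_uM = a280_supernatant / (eps * path_cm) * 1e6
    frac = dilute_uM / total_uM
    return CondensationQuant(
        total_conc_uM=total_uM, dilute_conc_uM=dilute_uM,
        dilute_fraction=frac, over_unity=frac > 1.05)


def delta_od(series: TurbiditySeries, wavelength: str,
             literal_endpoint: bool = False) -> float:
    """Total turbidity change of one wavelength's time course.

    Default: mean of the final 3 points minus mean of the first 3 (robust to
    last-cycle noise). ``literal_endpoint`` uses the single final and first
    points instead.
    """
    wavelength = str(wavelength)
    if wavelength not in series.od:
        raise KeyError(
            f"wavelength {wavelength} not in series (has {sorted(series.od)})")
    vals = series.od[wavelength]
    if len(vals) < 2:
        raise ValueError("need >= 2 points")
    if literal_endpoint:
        return float(vals[-1] - vals[0])
    m = min(3, len(vals) // 2) or 1
    return float(np.mean(vals[-m:]) - np.mean(vals[:m]))
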