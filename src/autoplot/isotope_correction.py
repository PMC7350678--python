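"""Natural-abundance and tracer-purity correction of isotopologue intensities.

Stable heavy isotopes occur in nature — carbon-13 at roughly 1.1%, plus the
heavy isotopes of H, N, O and S — so the measured M+n signals of a tracing
experiment mix tracer-derived labelling with this natural background. For a
3-carbon molecule such as pyruvate the natural M+1 species is only about 3% of
the pool, but for a 10-carbon molecule such as ATP it reaches 10% and cannot
be neglected.

The correction is classical low-resolution matrix deconvolution. Column j of
the correction matrix is the mass-shift distribution of a molecule with
exactly j tracer atoms labelled:

* each nominally labelled position is heavy with probability equal to the
  tracer purity (impurity moves mass down);
* the remaining tracer-element atoms carry heavy isotopes binomially at
  natural abundance;
* unless ``carbon_only`` (the default, appropriate for high-resolution
  instruments that mass-resolve non-tracer isotopes away), the other
  elements' heavy isotopes are convolved in as independent contributions,
  with +2 Da species (18-O, 34-S) handled by exact polynomial convolution.

The measured intensity vector m then satisfies m = A x where x holds the true
intensities per labelled-atom count; x is recovered by non-negative least
squares, which guarantees a physically meaningful (non-negative) result.

Elements are restricted to C, H, N, O, P and S. Phosphorus has no stable
heavy isotope and contributes nothing; Si, Cl and Br are rejected.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import nnls

from .errors import ValidationError

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "P", "S")

#: Natural-abundance table: element -> ((mass shift in Da, abundance fraction), ...).
#: Carbon is pinned at 1.1%; the rest follow standard IUPAC values. The
#: remainder to 1 per element is the light isotope. User-overridable.
DEFAULT_ISOTOPES: dict[str, tuple[tuple[int, float], ...]] = {
    "C": ((1, 0.011),),
    "H": ((1, 0.000115),),
    "N": ((1, 0.00364),),
    "O": ((1, 0.00038), (2, 0.00205)),
    "S": ((1, 0.0075), (2, 0.0421)),
    "P": (),
}

#: Tracer-element aliases accepted in configs.
TRACER_ELEMENTS = {
    "C13": "C", "13C": "C", "C": "C",
    "N15": "N", "15N": "N", "N": "N",
    "H2": "H", "2H": "H", "D": "H", "H": "H",
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class TracerSpec:
    """The tracer fed in the experiment: its element and isotopic purity
    (fraction of nominally labelled positions that are actually heavy)."""

    element: str = "C13"
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.element not in TRACER_ELEMENTS:
            raise ValidationError(
                f"unknown tracer {self.element!r}; expected one of C13, N15, H2"
            )
        if not 0 < self.purity <= 1:
            raise ValidationError("tracer purity must be in (0, 1]")

    @property
    def symbol(self) -> str:
        return TRACER_ELEMENTS[self.element]


def parse_formula(text: str) -> dict[str, int]:
    """Parse a molecular sum formula like ``"C10H16N5O13P3"`` into an
    element -> count map. Counts default to 1; unsupported elements (Si, Cl,
    Br, ...) are hard errors."""
    text = str(text).strip()
    if not text:
        raise ValidationError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos or not match.group(0):
            break
        element = match.group(1)
        if element not in SUPPORTED_ELEMENTS:
            raise ValidationError(
                f"element {element!r} in formula {text!r} is not supported "
                f"(allowed: {', '.join(SUPPORTED_ELEMENTS)})"
            )
        counts[element] = counts.get(element, 0) + (int(match.group(2)) if match.group(2) else 1)
        pos = match.end()
    if pos != len(text):
        raise ValidationError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def _atom_poly(isotopes: tuple[tuple[int, float], ...]) -> np.ndarray:
    """Single-atom mass-shift distribution as a polynomial coefficient vector."""
    if not isotopes:
        return np.array([1.0])
    max_shift = max(s for s, _ in isotopes)
    poly = np.zeros(max_shift + 1)
    heavy = 0.0
    for shift, abundance in isotopes:
        if shift < 1 or not 0 <= abundance < 1:
            raise ValidationError(f"bad isotope entry ({shift}, {abundance})")
        poly[shift] += abundance
        heavy += abundance
    if heavy >= 1:
        raise ValidationError("isotope abundances of one element must sum to < 1")
    poly[0] = 1.0 - heavy
    return poly


def _poly_power(poly: np.ndarray, n: int) -> np.ndarray:
    """poly ** n under convolution (distribution of a sum of n iid atoms)."""
    result = np.array([1.0])
    base = poly.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def natural_distribution(
    formula: Mapping[str, int] | str,
    tracer: TracerSpec | None = None,
    labelled: int = 0,
    isotopes: Mapping[str, tuple] | None = None,
    carbon_only: bool = True,
) -> np.ndarray:
    """Mass-shift probability distribution of a molecule with ``labelled``
    tracer atoms nominally heavy.

    Returns a vector p where p[k] is the probability of a total mass shift of
    k Da. The vector sums to 1 (the full support is returned, no truncation).
    With zero natural abundance and purity 1 it is a delta at ``labelled``.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    tracer = tracer or TracerSpec()
    isotopes = dict(DEFAULT_ISOTOPES) | (dict(isotopes) if isotopes else {})
    symbol = tracer.symbol
    n_tracer = int(formula.get(symbol, 0))
    if labelled < 0 or labelled > n_tracer:
        raise ValidationError(
            f"labelled count {labelled} exceeds the {n_tracer} {symbol} atoms "
            "in the formula"
        )
    # labelled positions: heavy with probability = purity
    dist = _poly_power(np.array([1.0 - tracer.purity, tracer.purity]), labelled)
    # remaining tracer atoms at natural abundance
    dist = np.convolve(dist, _poly_power(_atom_poly(tuple(isotopes[symbol])),
                                         n_tracer - labelled))
    if not carbon_only:
        for element, count in formula.items():
            if element == symbol or count == 0:
                continue
            dist = np.convolve(dist, _poly_power(_atom_poly(tuple(isotopes[element])),
                                                 int(count)))
    return dist


@dataclass
class CorrectionMatrix:
    """Linear map from true labelled-atom counts to observed mass shifts.

    ``matrix`` has shape (max_shift + 1, n_tracer_atoms + 1): column j is the
    natural distribution for j labelled atoms truncated to the observed
    shifts, so each column sums to at most 1 (shifts beyond the truncation
    carry the remainder).
    """

    matrix: np.ndarray
    tracer: TracerSpec

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_labelled(self) -> int:
        return self.matrix.shape[1]


def build_correction_matrix(
    formula: Mapping[str, int] | str,
    tracer: TracerSpec | None = None,
    max_shift: int | None = None,
    isotopes: Mapping[str, tuple] | None = None,
    carbon_only: bool = True,
) -> CorrectionMatrix:
    """Assemble the correction matrix for one compound.

    ``max_shift`` defaults to the tracer atom count (the highest shift a pure
    tracer signal can produce).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    tracer = tracer or TracerSpec()
    n_tracer = int(formula.get(tracer.symbol, 0))
    if max_shift is None:
        max_shift = n_tracer
    matrix = np.zeros((max_shift + 1, n_tracer + 1))
    for j in range(n_tracer + 1):
        col = natural_distribution(formula, tracer, labelled=j,
                                   isotopes=isotopes, carbon_only=carbon_only)
        take = min(len(col), max_shift + 1)
        matrix[:take, j] = col[:take]
    return CorrectionMatrix(matrix, tracer)


def correct_mid(measured: np.ndarray, matrix: CorrectionMatrix
                ) -> tuple[np.ndarray, float]:
    """Recover tracer-derived intensities from a measured isotopologue vector.

    Solves measured ~= A @ corrected by non-negative least squares and returns
    (corrected, residual norm). Missing (NaN) entries are replaced by 0 with a
    warning; an all-zero vector corrects to all zeros.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 1 or len(measured) != matrix.n_rows:
        raise ValidationError(
            f"measured vector length {measured.shape} does not match the "
            f"{matrix.n_rows} matrix rows"
        )
    if np.isnan(measured).any():
        warnings.warn(
            "missing isotopologue intensities enter the correction as 0",
            stacklevel=2,
        )
        measured = np.nan_to_num(measured, nan=0.0)
    if not measured.any():
        return np.zeros(matrix.n_labelled), 0.0
    corrected, residual = nnls(matrix.matrix, measured)
    return corrected, float(residual)


def correct_group(group, formula, tracer: TracerSpec | None = None,
                  isotopes=None, carbon_only: bool = True):
    """Correct every sample of an IsotopologueGroup, returning a new group
    whose intensities are the tracer-derived ones (shifts 0..n_tracer).

    The measured vector spans shifts 0..max(observed shift, tracer atoms);
    samples with any missing isotopologue are corrected with those entries as
    zero (warned once by correct_mid) and the group's exported table flags
    them via the ``had_missing`` column.
    """
    import pandas as pd

    from .tracing import IsotopologueGroup

    if isinstance(formula, str):
        formula = parse_formula(formula)
    tracer = tracer or TracerSpec()
    n_tracer = int(formula.get(tracer.symbol, 0))
    if n_tracer < group.max_shift:
        raise ValidationError(
            f"{group.base_compound!r}: observed shift M+{group.max_shift} exceeds "
            f"the {n_tracer} tracer atoms in the formula"
        )
    length = n_tracer + 1
    cm = build_correction_matrix(formula, tracer, max_shift=length - 1,
                                 isotopes=isotopes, carbon_only=carbon_only)
    rows = []
    for sample in group.samples:
        vec = group.vector(sample, length=length)
        had_missing = bool(np.isnan(vec[np.array(group.shifts)]).any())
        vec = np.where(np.isnan(vec), 0.0, vec)
        corrected, _ = correct_mid(vec, cm)
        for shift in range(length):
            rows.append((sample, shift, corrected[shift], had_missing))
    frame = pd.DataFrame(rows, columns=["sample_id", "shift", "intensity",
                                        "had_missing"])
    return IsotopologueGroup(group.base_compound,
                             frame[["sample_id", "shift", "intensity"]]), frame
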