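"""Closed-form crystallographic and electron-optics arithmetic.

Everything here is exact algebra on acquisition parameters: relativistic
electron wavelength, unit-cell volume, oscillation per frame, resolution-ring
radii and formula weights.  Angles are degrees in the public interface;
radians appear only inside the formulas.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import gemmi
from scipy import constants

__all__ = [
    "UnitCell",
    "OpticsParams",
    "electron_wavelength",
    "cell_volume",
    "oscillation_per_frame",
    "resolution_ring_radius",
    "formula_weight",
]


class DomainError(ValueError):
    """An input violates a physical or geometric precondition."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Å, angles in degrees.

    The triclinic metric discriminant
    ``1 - cos²α - cos²β - cos²γ + 2·cosα·cosβ·cosγ`` must be positive for
    the six parameters to describe a realizable cell.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise DomainError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise DomainError(f"cell angle {name} must lie in (0, 180) degrees")
        if self._discriminant() <= 0:
            raise DomainError(
                "cell angles alpha, beta, gamma do not define a valid metric "
                "(non-positive discriminant)"
            )

    def _discriminant(self) -> float:
        ca, cb, cg = (
            math.cos(math.radians(self.alpha)),
            math.cos(math.radians(self.beta)),
            math.cos(math.radians(self.gamma)),
        )
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return self.a * self.b * self.c * math.sqrt(self._discriminant())


@dataclass(frozen=True)
class OpticsParams:
    """Electron-optical state relevant to diffraction geometry.

    ``accelerating_voltage`` in kV, ``wavelength`` in Å, ``camera_length``
    in mm, ``pixel_size`` (detector pitch) in mm.  When both voltage and
    wavelength are given they must agree to 3 significant figures.
    """

    accelerating_voltage: float | None = None
    wavelength: float | None = None
    camera_length: float | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        if self.accelerating_voltage is not None and self.accelerating_voltage <= 0:
            raise DomainError("accelerating_voltage must be > 0")
        if self.wavelength is not None and self.wavelength <= 0:
            raise DomainError("wavelength must be > 0")
        if self.accelerating_voltage is not None and self.wavelength is not None:
            lam = electron_wavelength(self.accelerating_voltage)
            # agreement to 3 significant figures
            if abs(lam - self.wavelength) > 0.5 * 10 ** (math.floor(math.log10(lam)) - 2):
                raise DomainError(
                    f"wavelength {self.wavelength} Å inconsistent with "
                    f"{self.accelerating_voltage} kV (expected {lam:.4g} Å)"
                )

    def resolved_wavelength(self) -> float:
        if self.wavelength is not None:
            return self.wavelength
        if self.accelerating_voltage is not None:
            return electron_wavelength(self.accelerating_voltage)
        raise DomainError("neither wavelength nor accelerating_voltage set")


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength, in Å, of electrons at ``voltage_kv``.

    λ = h / sqrt(2 m₀ e V (1 + eV / (2 m₀ c²))) with CODATA constants.
    At 120 kV this evaluates to 0.0335 Å (4 dp), the standard microED
    operating wavelength of a 120 kV instrument.
    """
    if voltage_kv <= 0:
        raise DomainError("accelerating voltage must be > 0 kV")
    v = voltage_kv * 1e3
    h, m0, e, c = constants.h, constants.m_e, constants.e, constants.c
    lam_m = h / math.sqrt(2.0 * m0 * e * v * (1.0 + e * v / (2.0 * m0 * c * c)))
    return lam_m * 1e10


def cell_volume(cell: UnitCell) -> float:
    """Triclinic cell volume V = abc·sqrt(1 − Σcos² + 2·cosα·cosβ·cosγ), Å³."""
    return cell.volume


def oscillation_per_frame(tilt_range: float, n_frames: int) -> float:
    """Tilt angle swept per detector frame (°/frame), at full precision.

    Presentation rounding (the conventional 2 dp) is the caller's concern.
    """
    if tilt_range <= 0:
        raise DomainError("tilt_range must be > 0")
    if n_frames < 1:
        raise DomainError("n_frames must be >= 1")
    return tilt_range / n_frames


def resolution_ring_radius(d: float, optics: OpticsParams) -> float:
    """Radius in detector pixels of the resolution ring at d-spacing ``d`` (Å).

    Small-angle approximation r = L·λ / (d·p) with camera length L and
    pixel pitch p, both in mm.
    """
    if d <= 0:
        raise DomainError("d-spacing must be > 0")
    if optics.camera_length is None or optics.pixel_size is None:
        raise DomainError("optics must define camera_length and pixel_size")
    lam = optics.resolved_wavelength()
    return optics.camera_length * lam / (d * optics.pixel_size)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?|\.\d+)?")


def formula_weight(formula: str) -> float:
    """Molecular weight (g/mol) of a chemical formula with possibly
    fractional element counts, e.g. ``"C21H9O13.6727Zn4"``.

    Uses the standard atomic weights shipped with gemmi.
    """
    if not formula or not formula.strip():
        raise DomainError("empty chemical formula")
    pos = 0
    total = 0.0
    s = formula.strip()
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None:
            raise DomainError(f"cannot parse formula at {s[pos:]!r}")
        symbol, count = m.group(1), m.group(2)
        el = gemmi.Element(symbol)
        # gemmi maps unknown symbols onto the dummy element 'X'
        if el.name != symbol or el.atomic_number == 0:
            raise DomainError(f"unknown element symbol {symbol!r}")
        total += el.weight * (float(count) if count else 1.0)
        pos = m.end()
    return total
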