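"""Scalar field specifications for phantom thickness and strain.

Fields are evaluated on normalized anatomical coordinates of an articular
surface patch: ``ap_n`` runs -1 (posterior edge) to +1 (anterior edge),
``si_n`` runs -1 (inferior edge) to +1 (superior edge).  The same classes
describe cartilage thickness (mm) and imposed compressive strain
(dimensionless fraction in [0, 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ScalarField:
    """Base class: a scalar function of normalized (ap, si) coordinates."""

    def bind(self, ap_n: np.ndarray, si_n: np.ndarray) -> None:
        """Attach a footprint coordinate sample (used by quantile-based fields)."""

    def __call__(self, ap_n: np.ndarray, si_n: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class ConstantField(ScalarField):
    value: float

    def __call__(self, ap_n, si_n):
        ap_n = np.asarray(ap_n, dtype=float)
        return np.full(ap_n.shape, float(self.value))


@dataclass
class LinearField(ScalarField):
    """base + slope_ap * ap_n + slope_si * si_n (slopes per unit normalized coord)."""

    base: float
    slope_ap: float = 0.0
    slope_si: float = 0.0

    def __call__(self, ap_n, si_n):
        ap_n = np.asarray(ap_n, dtype=float)
        si_n = np.asarray(si_n, dtype=float)
        return self.base + self.slope_ap * ap_n + self.slope_si * si_n


@dataclass
class RadialField(ScalarField):
    """Center-to-periphery quadratic ramp with optional directional bias.

    value = center + (edge - center) * rho^2 * (iso + (1-iso) * max(d.b, weight floor))

    where rho = min(1, sqrt(ap_n^2 + si_n^2)), d is the in-plane unit
    direction and b the bias direction (ap, si).  With the defaults of the
    glenoid thickness pattern (center 1.2, edge 1.5, bias anteroinferior)
    the periphery is everywhere thicker than the center and thickest at the
    anteroinferior rim.
    """

    center: float
    edge: float
    bias_ap: float = 0.0
    bias_si: float = 0.0
    iso_weight: float = 1.0  # 1.0 -> purely radial, no directional bias

    def __call__(self, ap_n, si_n):
        ap_n = np.asarray(ap_n, dtype=float)
        si_n = np.asarray(si_n, dtype=float)
        rho = np.sqrt(ap_n**2 + si_n**2)
        rho_c = np.minimum(rho, 1.0)
        out = np.full(ap_n.shape, float(self.center))
        b = np.hypot(self.bias_ap, self.bias_si)
        if b > 0 and self.iso_weight < 1.0:
            with np.errstate(invalid="ignore", divide="ignore"):
                dhat_ap = np.where(rho > 1e-12, ap_n / rho, 0.0)
                dhat_si = np.where(rho > 1e-12, si_n / rho, 0.0)
            align = (dhat_ap * self.bias_ap + dhat_si * self.bias_si) / b
            w = self.iso_weight + (1.0 - self.iso_weight) * 0.5 * (1.0 + align)
        else:
            w = 1.0
        return out + (self.edge - self.center) * rho_c**2 * w


@dataclass
class RegionalField(ScalarField):
    """Piecewise-constant per-third field from a target table.

    ``table`` is indexed ``[si_row][ap_col]`` with rows ordered
    superior -> inferior and columns anterior -> posterior (3x3 for the
    glenoid).  For the humeral head a ``(2, 3, 3)`` nested table gives
    ``[band][si_row][ap_col]`` with band 0 = superior.  Third boundaries sit
    at the 35% / 65% coordinate quantiles of the bound footprint sample, so
    2-mm sampling disks centered at the 20/50/80% quantiles never straddle
    a boundary.
    """

    table: Sequence
    _ap_cuts: np.ndarray | None = field(default=None, repr=False)
    _si_cuts: np.ndarray | None = field(default=None, repr=False)
    _band_cut: float | None = field(default=None, repr=False)
    _band_si_cuts: np.ndarray | None = field(default=None, repr=False)

    @property
    def banded(self) -> bool:
        arr = np.asarray(self.table, dtype=float)
        return arr.ndim == 3

    def bind(self, ap_n, si_n):
        ap_n = np.asarray(ap_n, dtype=float)
        si_n = np.asarray(si_n, dtype=float)
        self._ap_cuts = np.quantile(ap_n, [0.35, 0.65])
        if self.banded:
            self._band_cut = float(np.median(si_n))
            cuts = []
            for band_mask in (si_n >= self._band_cut, si_n < self._band_cut):
                cuts.append(np.quantile(si_n[band_mask], [0.35, 0.65]))
            self._band_si_cuts = np.asarray(cuts)
        else:
            self._si_cuts = np.quantile(si_n, [0.35, 0.65])

    def __call__(self, ap_n, si_n):
        if self._ap_cuts is None:
            raise RuntimeError("RegionalField must be bound to a footprint sample first")
        ap_n = np.asarray(ap_n, dtype=float)
        si_n = np.asarray(si_n, dtype=float)
        arr = np.asarray(self.table, dtype=float)
        # column 0 = anterior (high ap), column 2 = posterior (low ap)
        ap_col = np.where(ap_n > self._ap_cuts[1], 0, np.where(ap_n > self._ap_cuts[0], 1, 2))
        if self.banded:
            if arr.shape != (2, 3, 3):
                raise ValueError(f"banded table must be (2, 3, 3), got {arr.shape}")
            band = np.where(si_n >= self._band_cut, 0, 1)
            lo = self._band_si_cuts[band, 0]
            hi = self._band_si_cuts[band, 1]
            si_row = np.where(si_n > hi, 0, np.where(si_n > lo, 1, 2))
            return arr[band, si_row, ap_col]
        if arr.shape != (3, 3):
            raise ValueError(f"table must be (3, 3), got {arr.shape}")
        si_row = np.where(si_n > self._si_cuts[1], 0, np.where(si_n > self._si_cuts[0], 1, 2))
        return arr[si_row, ap_col]


def field_from_spec(spec) -> ScalarField:
    """Build a field from a number, a ScalarField, or a dict (YAML-friendly)."""
    if isinstance(spec, ScalarField):
        return spec
    if isinstance(spec, (int, float)):
        return ConstantField(float(spec))
    if isinstance(spec, dict):
        kind = spec.get("kind")
        params = {k: v for k, v in spec.items() if k != "kind"}
        kinds = {
            "constant": ConstantField,
            "linear": LinearField,
            "radial": RadialField,
            "regional": RegionalField,
        }
        if kind not in kinds:
            raise ValueError(f"unknown field kind {kind!r}; expected one of {sorted(kinds)}")
        return kinds[kind](**params)
    raise TypeError(f"cannot build a scalar field from {type(spec).__name__}")
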