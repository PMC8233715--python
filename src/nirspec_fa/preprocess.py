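"""Spectral pretreatment operators and chain parsing.

The catalog covers the corrections in routine chemometric use for diffuse
reflectance spectra: offset baseline subtraction, total-area (L1)
normalization, standard normal variate (SNV), quadratic detrending,
multiplicative scatter correction (MSC) and its extended form (EMSC),
Savitzky-Golay derivatives and Norris gap derivatives.

A :class:`PretreatmentChain` is an ordered list of these operators parsed
from a compact string grammar, e.g. ``"Offset|Area|SNV+D|SG-1-2-3"``.
Reference-dependent steps (MSC/EMSC use the mean calibration spectrum) are
fitted on calibration spectra only and then applied unchanged to new data,
so no validation statistic ever leaks into the transform.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    ChainParseError,
    ConfigurationError,
    DegenerateInputError,
    NotFittedError,
    ScatterFitError,
)
from .spectra_io import WavelengthGrid


def _as2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _restore(x: np.ndarray, was_1d: bool) -> np.ndarray:
    return x[0] if was_1d else x


def offset_baseline(x: np.ndarray) -> np.ndarray:
    """Subtract each spectrum's minimum so that min(output) = 0."""
    x, squeeze = _as2d(x)
    out = x - x.min(axis=1, keepdims=True)
    return _restore(out, squeeze)


def area_normalize(x: np.ndarray) -> np.ndarray:
    """Divide each spectrum by its L1 norm so that sum(|output|) = 1."""
    x, squeeze = _as2d(x)
    norm = np.abs(x).sum(axis=1, keepdims=True)
    if np.any(norm == 0):
        raise DegenerateInputError("area normalization of an all-zero spectrum")
    return _restore(x / norm, squeeze)


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and scaling.

    Uses the sample (n-1) standard deviation, so every output spectrum has
    mean 0 and sample SD exactly 1.  Invariant under affine transforms
    a*x + b (a > 0) of the input.
    """
    x, squeeze = _as2d(x)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("SNV of a constant spectrum")
    return _restore((x - x.mean(axis=1, keepdims=True)) / sd, squeeze)


def detrend(x: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """Remove the least-squares quadratic trend in wavelength.

    Residuals are orthogonal to {1, lambda, lambda^2}; an exactly quadratic
    spectrum maps to zero.
    """
    x, squeeze = _as2d(x)
    lam = grid.normalized()
    # Legendre-like design on [-1, 1] keeps the normal equations well
    # conditioned across the 3001-point grid.
    design = np.vander(lam, 3, increasing=True)
    q, _ = np.linalg.qr(design)
    out = x - (x @ q) @ q.T
    return _restore(out, squeeze)


def msc(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed as ``x = a + b * reference`` by least squares
    and the correction ``(x - a) / b`` is returned, inverting additive and
    multiplicative scatter distortions of the reference shape exactly.
    """
    x, squeeze = _as2d(x)
    ref = np.asarray(reference, dtype=float)
    if ref.std() == 0:
        raise DegenerateInputError("MSC reference spectrum has zero variance")
    design = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    a, b = coef[0], coef[1]
    if np.any(np.abs(b) < 1e-12):
        raise ScatterFitError("MSC multiplicative coefficient is numerically zero")
    return _restore(((x - a[:, None]) / b[:, None]), squeeze)


def emsc(x: np.ndarray, reference: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    """Extended MSC: also removes linear and quadratic wavelength baselines.

    Model: ``x = a + b*reference + c1*lam + c2*lam^2`` with lam the
    wavelength mapped to [-1, 1]; output is ``(x - a - c1*lam - c2*lam^2)/b``.
    """
    x, squeeze = _as2d(x)
    ref = np.asarray(reference, dtype=float)
    if ref.std() == 0:
        raise DegenerateInputError("EMSC reference spectrum has zero variance")
    lam = grid.normalized()
    design = np.column_stack([np.ones_like(ref), ref, lam, lam**2])
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    a, b, c1, c2 = coef
    if np.any(np.abs(b) < 1e-12):
        raise ScatterFitError("EMSC multiplicative coefficient is numerically zero")
    baseline = a[:, None] + np.outer(c1, lam) + np.outer(c2, lam**2)
    return _restore((x - baseline) / b[:, None], squeeze)


def savgol_derivative(
    x: np.ndarray,
    deriv_order: int,
    poly_order: int,
    window_points: int,
    grid: WavelengthGrid,
) -> np.ndarray:
    """Savitzky-Golay smoothing derivative.

    Convolves each spectrum with the local least-squares polynomial filter;
    derivatives are scaled by the grid step so units are absorbance * nm^-d.
    Edges are handled by evaluating the one-sided local polynomial fit, which
    keeps the grid length constant (exact on polynomials up to *poly_order*
    everywhere, including edges).
    """
    if window_points % 2 == 0 or window_points < 1:
        raise ConfigurationError(f"window_points must be odd, got {window_points}")
    if deriv_order > poly_order:
        raise ConfigurationError("deriv_order must not exceed poly_order")
    if window_points == 1:
        if deriv_order == 0:
            return np.asarray(x, dtype=float).copy()
        raise ConfigurationError("window of 1 point cannot take a derivative")
    if window_points <= poly_order:
        raise ConfigurationError("window_points must exceed poly_order")
    x, squeeze = _as2d(x)
    out = savgol_filter(
        x, window_length=window_points, polyorder=poly_order,
        deriv=deriv_order, delta=grid.step_nm, axis=1, mode="interp",
    )
    return _restore(out, squeeze)


def norris_gap_derivative(
    x: np.ndarray, deriv_order: int, gap_points: int, grid: WavelengthGrid
) -> np.ndarray:
    """Norris gap first derivative: symmetric difference across a gap.

    At interior point i the derivative is
    ``(x[i+g] - x[i-g]) / (2 * g * step_nm)``; edge points copy the nearest
    valid interior value.  Large gaps act as a combined smoother and
    differentiator for broad bands.
    """
    if deriv_order != 1:
        raise ConfigurationError("Norris gap derivative supports deriv_order=1 only")
    if gap_points < 1:
        raise ConfigurationError("gap_points must be >= 1")
    x, squeeze = _as2d(x)
    n = x.shape[1]
    if n <= 2 * gap_points:
        raise ConfigurationError(
            f"gap of {gap_points} points too large for {n}-point grid"
        )
    g = gap_points
    out = np.empty_like(x)
    out[:, g:n - g] = (x[:, 2 * g:] - x[:, :n - 2 * g]) / (2 * g * grid.step_nm)
    out[:, :g] = out[:, [g]]
    out[:, n - g:] = out[:, [n - g - 1]]
    return _restore(out, squeeze)


# ---------------------------------------------------------------------------
# Chain steps


@dataclass
class _Step:
    """One chain element; subclasses may hold fitted state."""

    def fit(self, x: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        return self.transform(x, grid)

    def transform(self, x: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        raise NotImplementedError

    def spec(self) -> str:
        raise NotImplementedError


@dataclass
class OffsetBaseline(_Step):
    def transform(self, x, grid):
        return offset_baseline(x)

    def spec(self):
        return "Offset"


@dataclass
class AreaNormalize(_Step):
    def transform(self, x, grid):
        return area_normalize(x)

    def spec(self):
        return "Area"


@dataclass
class SNV(_Step):
    def transform(self, x, grid):
        return snv(x)

    def spec(self):
        return "SNV"


@dataclass
class Detrend(_Step):
    def transform(self, x, grid):
        return detrend(x, grid)

    def spec(self):
        return "D"


@dataclass
class MSC(_Step):
    """Scatter correction against the mean calibration spectrum at this stage."""

    reference: np.ndarray | None = None

    def fit(self, x, grid):
        x2, _ = _as2d(x)
        self.reference = x2.mean(axis=0)
        return self.transform(x, grid)

    def transform(self, x, grid):
        if self.reference is None:
            raise NotFittedError("MSC applied before fitting on calibration spectra")
        return msc(x, self.reference)

    def spec(self):
        return "MSC"


@dataclass
class EMSC(_Step):
    reference: np.ndarray | None = None

    def fit(self, x, grid):
        x2, _ = _as2d(x)
        self.reference = x2.mean(axis=0)
        return self.transform(x, grid)

    def transform(self, x, grid):
        if self.reference is None:
            raise NotFittedError("EMSC applied before fitting on calibration spectra")
        return emsc(x, self.reference, grid)

    def spec(self):
        return "EMSC"


@dataclass
class SGDerivative(_Step):
    deriv_order: int
    poly_order: int
    window_points: int

    def transform(self, x, grid):
        return savgol_derivative(
            x, self.deriv_order, self.poly_order, self.window_points, grid
        )

    def spec(self):
        return f"SG-{self.deriv_order}-{self.poly_order}-{self.window_points}"


@dataclass
class NorrisGap(_Step):
    deriv_order: int
    gap_points: int

    def transform(self, x, grid):
        return norris_gap_derivative(x, self.deriv_order, self.gap_points, grid)

    def spec(self):
        return f"NG-{self.deriv_order}-{self.gap_points}"


@dataclass
class PretreatmentChain:
    """Ordered, fittable sequence of pretreatment steps.

    ``fit_transform`` fits reference-dependent steps (MSC/EMSC mean spectra)
    stage by stage on calibration spectra; ``transform`` then applies the
    identical frozen transform to any spectra.  An empty chain is the
    identity.
    """

    steps: list[_Step] = field(default_factory=list)
    fitted: bool = False

    def fit_transform(self, x: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for step in self.steps:
            out = step.fit(out, grid)
        self.fitted = True
        return out

    def transform(self, x: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("chain must be fitted on calibration spectra first")
        out = np.asarray(x, dtype=float)
        for step in self.steps:
            out = step.transform(out, grid)
        return out

    def spec(self) -> str:
        return "|".join(s.spec() for s in self.steps) if self.steps else "None"


_SG_RE = re.compile(r"^SG-(\d+)-(\d+)-(\d+)$")
# Irregular smoothing tokens of the form SG<d>-<p>-<w> (no hyphen after SG)
# are read as zeroth-derivative smoothing passes; see parse_chain.
_SG_SMOOTH_RE = re.compile(r"^SG(\d+)-(\d+)-(\d+)$")
_NG_RE = re.compile(r"^NG-(\d+)-(\d+)$")


def _smallest_valid_window(window: int, poly: int) -> int:
    """Smallest odd window >= requested that exceeds the polynomial order."""
    w = max(window, poly + 1)
    if w % 2 == 0:
        w += 1
    return w


def parse_token(token: str) -> list[_Step]:
    t = token.strip()
    if t in ("", "None"):
        return []
    if t == "Offset":
        return [OffsetBaseline()]
    if t == "Area":
        return [AreaNormalize()]
    if t == "SNV":
        return [SNV()]
    if t == "SNV+D":
        return [SNV(), Detrend()]
    if t == "D":
        return [Detrend()]
    if t == "MSC":
        return [MSC()]
    if t == "EMSC":
        return [EMSC()]
    if t == "EMSC+D":
        return [EMSC(), Detrend()]
    m = _SG_RE.match(t)
    if m:
        d, p, w = (int(g) for g in m.groups())
        if w % 2 == 0 or w <= p or d > p:
            raise ChainParseError(f"invalid Savitzky-Golay parameters in {t!r}")
        return [SGDerivative(d, p, w)]
    m = _SG_SMOOTH_RE.match(t)
    if m:
        # Smoothing-pass shorthand: interpreted as derivative order 0 with the
        # stated polynomial order and window, the window widened to the
        # smallest valid odd size.  Low confidence; near-identity in practice.
        _, p, w = (int(g) for g in m.groups())
        return [SGDerivative(0, p, _smallest_valid_window(w, p))]
    m = _NG_RE.match(t)
    if m:
        d, g = (int(x) for x in m.groups())
        if d != 1 or g < 1:
            raise ChainParseError(f"invalid Norris gap parameters in {t!r}")
        return [NorrisGap(d, g)]
    raise ChainParseError(f"unknown pretreatment token {t!r}")


def parse_chain(spec: str) -> PretreatmentChain:
    """Parse a ``|``-separated chain specification into a PretreatmentChain.

    Tokens: ``Offset``, ``Area``, ``SNV``, ``SNV+D``, ``MSC``, ``EMSC``,
    ``EMSC+D``, ``SG-d-p-w``, ``NG-d-g`` and ``None`` (dropped).  The stored
    order is the application order: baseline, normalization, scatter
    correction, smoothing, derivative.
    """
    steps: list[_Step] = []
    for token in spec.split("|"):
        steps.extend(parse_token(token))
    return PretreatmentChain(steps=steps)
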