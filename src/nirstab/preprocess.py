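"""Spectral preprocessing: Savitzky-Golay filtering and multiplicative
scatter correction (MSC).

The standard chain applied before any distance computation is

1. Savitzky-Golay smoothing (local least-squares polynomial, derivative 0),
2. MSC — per-spectrum ordinary least-squares regression on a reference
   spectrum followed by inversion ``(x - a) / b``, removing scatter-induced
   offset and gain,
3. Savitzky-Golay first derivative with a second-order polynomial.

Savitzky-Golay boundary handling: each edge point is the same-degree
polynomial fit over the window truncated at the array boundary (grown
inward when the truncation leaves fewer than ``polyorder + 1`` points), so
output length always equals input length and grids stay aligned across the
pipeline.  The derivative is per index point by default (filter
coefficients only); ``per_wavenumber`` divides by ``step ** deriv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy.signal import savgol_filter

from .errors import ConfigError, NumericalError, ValidationError
from .spectra import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "MscFit",
    "sg_filter",
    "msc_fit",
    "msc_apply",
    "preprocess_pipeline",
    "smoothed_reference",
]

#: a fitted |slope| below this is treated as degenerate in MSC
_MSC_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the three-step chain.

    Window sizes are odd point counts; defaults (17 points at 8 cm^-1
    resolution, i.e. a 128 cm^-1 span) follow common chemometrics practice.
    ``msc_reference`` is either the mean of the set being corrected
    (``set_mean``) or an ``explicit`` spectrum, e.g. the smoothed
    standard-set mean when scoring products against a reference model.
    """

    sg_smooth_window: int = 17
    sg_smooth_polyorder: int = 2
    sg_deriv_window: int = 17
    sg_deriv_polyorder: int = 2
    msc_reference: str = "set_mean"  # "set_mean" | "explicit"
    derivative_scale: str = "per_point"  # "per_point" | "per_wavenumber"

    def __post_init__(self) -> None:
        for name, window, polyorder in (
            ("smooth", self.sg_smooth_window, self.sg_smooth_polyorder),
            ("deriv", self.sg_deriv_window, self.sg_deriv_polyorder),
        ):
            _check_window(window, polyorder, context=f"sg_{name}")
        if self.sg_deriv_polyorder < 1:
            raise ConfigError("derivative polyorder must be >= 1")
        if self.msc_reference not in ("set_mean", "explicit"):
            raise ConfigError(f"unknown msc_reference {self.msc_reference!r}")
        if self.derivative_scale not in ("per_point", "per_wavenumber"):
            raise ConfigError(f"unknown derivative_scale {self.derivative_scale!r}")

    def to_dict(self) -> dict:
        return {
            "sg_smooth_window": self.sg_smooth_window,
            "sg_smooth_polyorder": self.sg_smooth_polyorder,
            "sg_deriv_window": self.sg_deriv_window,
            "sg_deriv_polyorder": self.sg_deriv_polyorder,
            "msc_reference": self.msc_reference,
            "derivative_scale": self.derivative_scale,
        }


def _check_window(window: int, polyorder: int, context: str = "sg") -> None:
    if window % 2 == 0:
        raise ConfigError(f"{context}: window must be odd, got {window}")
    if window < polyorder + 1:
        raise ConfigError(
            f"{context}: window {window} must be >= polyorder + 1 = {polyorder + 1}"
        )


def _sg_values(
    values: np.ndarray, window: int, polyorder: int, deriv: int
) -> np.ndarray:
    """SG filter on a raw vector, derivative per index point."""
    n = values.shape[0]
    if window > n:
        raise ConfigError(f"window {window} exceeds spectrum length {n}")
    out = savgol_filter(values, window, polyorder, deriv=deriv, delta=1.0, mode="interp")
    # replace edges with truncated-window fits
    half = window // 2
    idx = np.arange(n, dtype=float)
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        while hi - lo + 1 < polyorder + 1:  # grow inward for tiny windows
            if lo > 0:
                lo -= 1
            elif hi < n - 1:
                hi += 1
            else:
                break
        p = Polynomial.fit(idx[lo : hi + 1], values[lo : hi + 1], polyorder)
        out[i] = p.deriv(deriv)(idx[i]) if deriv else p(idx[i])
    return out


def sg_filter(
    spectrum: Spectrum,
    window: int,
    polyorder: int,
    deriv: int = 0,
    derivative_scale: str = "per_point",
) -> Spectrum:
    """Savitzky-Golay smoothing (``deriv=0``) or differentiation of one spectrum.

    Each output point is the ``deriv``-th derivative, at the window centre,
    of the least-squares polynomial of degree ``polyorder`` fit over the
    window (truncated at the boundaries).
    """
    _check_window(window, polyorder)
    if deriv > polyorder:
        raise ConfigError(f"deriv {deriv} exceeds polyorder {polyorder}")
    out = _sg_values(spectrum.values, window, polyorder, deriv)
    if derivative_scale == "per_wavenumber" and deriv:
        out = out / spectrum.grid.step**deriv
    elif derivative_scale not in ("per_point", "per_wavenumber"):
        raise ConfigError(f"unknown derivative_scale {derivative_scale!r}")
    return spectrum.with_values(out)


@dataclass
class MscFit:
    """Per-spectrum affine scatter coefficients against one reference.

    ``coefficients[sample_id] = (a, b)`` with correction ``(x - a) / b``.
    """

    reference: Spectrum
    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)


def msc_fit(spectrum_set: SpectrumSet, reference: Spectrum) -> MscFit:
    """OLS intercept/slope of each spectrum regressed on the reference."""
    if reference.grid != spectrum_set.grid:
        raise ValidationError("MSC reference is on a different grid than the set")
    r = reference.values
    r_mean = r.mean()
    r_var = float(np.dot(r - r_mean, r - r_mean))
    if r_var <= 0:
        raise NumericalError("MSC reference has zero variance (constant spectrum)")
    fit = MscFit(reference=reference)
    for s in spectrum_set:
        x = s.values
        b = float(np.dot(r - r_mean, x - x.mean()) / r_var)
        a = float(x.mean() - b * r_mean)
        if abs(b) < _MSC_SLOPE_TOL:
            raise NumericalError(
                f"degenerate MSC slope for sample {s.meta.sample_id!r} (|b| < {_MSC_SLOPE_TOL})"
            )
        fit.coefficients[s.meta.sample_id] = (a, b)
    return fit


def msc_apply(spectrum_set: SpectrumSet, fit: MscFit) -> SpectrumSet:
    """Apply the scatter correction ``(x - a) / b`` spectrum by spectrum."""
    missing = [sid for sid in spectrum_set.sample_ids if sid not in fit.coefficients]
    if missing:
        raise ValidationError(f"MscFit lacks coefficients for samples {missing}")

    def correct(s: Spectrum) -> np.ndarray:
        a, b = fit.coefficients[s.meta.sample_id]
        return (s.values - a) / b

    return spectrum_set.map_values(correct)


def smoothed_reference(
    spectrum_set: SpectrumSet, config: PreprocessConfig
) -> Spectrum:
    """Mean spectrum of the set after the smoothing step — the MSC reference
    the pipeline uses in ``set_mean`` mode, exposed so a standard set's
    reference can be reused to correct product sets."""
    smoothed = spectrum_set.map_values(
        lambda s: _sg_values(
            s.values, config.sg_smooth_window, config.sg_smooth_polyorder, 0
        )
    )
    return smoothed.mean_spectrum(sample_id="msc_reference")


def preprocess_pipeline(
    spectrum_set: SpectrumSet,
    config: PreprocessConfig | None = None,
    explicit_reference: Spectrum | None = None,
) -> SpectrumSet:
    """Run the full chain: smooth, MSC, first derivative.

    In ``set_mean`` mode the MSC reference is the mean of the set computed
    *after* smoothing; in ``explicit`` mode ``explicit_reference`` (already
    on the smoothed scale) is used, which makes the result for one spectrum
    independent of whatever else is in the set.  Metadata passes through
    untouched and the operation is deterministic.
    """
    config = config or PreprocessConfig()
    smoothed = spectrum_set.map_values(
        lambda s: _sg_values(
            s.values, config.sg_smooth_window, config.sg_smooth_polyorder, 0
        )
    )
    if config.msc_reference == "explicit" or explicit_reference is not None:
        if explicit_reference is None:
            raise ConfigError(
                "msc_reference='explicit' requires an explicit_reference spectrum"
            )
        reference = explicit_reference
    else:
        reference = smoothed.mean_spectrum(sample_id="msc_reference")
    corrected = msc_apply(smoothed, msc_fit(smoothed, reference))
    return corrected.map_values(
        lambda s: _sg_values(s.values, config.sg_deriv_window, config.sg_deriv_polyorder, 1)
        / (
            s.grid.step
            if config.derivative_scale == "per_wavenumber"
            else 1.0
        )
    )
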