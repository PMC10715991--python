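"""Synthetic NIR study generator.

Emulates the statistical structure of a two-brand smoking-machine study:
each brand has a distinct band signature; product batches arrive on a
timeline with a batch-level random effect shared by the batch's pads; each
pad adds its own effect and a common empty-filter-pad background; every
measurement then passes through a multiplicative scatter transform
``b * x + a`` and additive detector noise.  Half of each batch's pads are
measured in the classical cup and half in the self-made cup; paired
measurements share one underlying pad signal and are linked by ``pair_id``,
with a small systematic spectral shift (offset band + gain) applied to the
self-made-cup member.  Separate standard batches provide the
reference-distribution spectra, and empty-pad spectra carry background
only.

Randomness is one global stream per study, split deterministically by
(role, brand, batch, pad), so adding a batch never changes earlier
batches' spectra and the same seed reproduces the study bit for bit.

The generator emulates structure, not chemistry: band positions are
NIR-plausible but arbitrary, and effect sizes are chosen so the distance
populations reproduce the qualitative ordering seen on real data
(inter-brand >> intra-brand sample-to-standard > paired-cup).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .spectra import (
    CANONICAL_GRID,
    Cup,
    Role,
    Spectrum,
    SpectrumMeta,
    SpectrumSet,
    WavenumberGrid,
)

__all__ = [
    "BrandProfile",
    "StudyConfig",
    "render_profile",
    "simulate_study",
    "simulate_empty_pads",
    "default_study_config",
    "scaled_study_config",
    "study_config_to_dict",
    "study_config_from_dict",
]


@dataclass(frozen=True)
class BrandProfile:
    """Sum-of-Gaussian-bands spectral signature plus polynomial baseline.

    ``peaks`` is a tuple of (center cm^-1, width cm^-1, amplitude) triples;
    ``baseline`` are polynomial coefficients (low order first) in the
    normalized wavenumber t in [0, 1].
    """

    peaks: tuple[tuple[float, float, float], ...]
    baseline: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ConfigError("BrandProfile needs at least one peak")
        for c, w, a in self.peaks:
            if w <= 0:
                raise ConfigError(f"peak width must be > 0, got {w}")
            if a < 0:
                raise ConfigError(f"peak amplitude must be >= 0, got {a}")


def render_profile(profile: BrandProfile, grid: WavenumberGrid) -> np.ndarray:
    """Evaluate the profile on the grid (deterministic)."""
    w = grid.values
    t = (w - grid.start) / (grid.stop - grid.start)
    out = np.polynomial.polynomial.polyval(t, np.asarray(profile.baseline, dtype=float))
    out = np.broadcast_to(out, w.shape).astype(float).copy()
    for center, width, amp in profile.peaks:
        out += amp * np.exp(-0.5 * ((w - center) / width) ** 2)
    return out


# Two brands sharing most bands; they differ in three band amplitudes and
# one band position — enough for clean PCA separation without pretending
# chemical realism.
_TT_PROFILE = BrandProfile(
    peaks=(
        (4350.0, 120.0, 0.55),
        (4700.0, 180.0, 0.35),
        (5200.0, 160.0, 0.60),
        (5800.0, 200.0, 0.40),
        (6900.0, 260.0, 0.50),
        (8400.0, 320.0, 0.20),
    ),
    baseline=(0.25, -0.12, 0.04),
)
_AA_PROFILE = BrandProfile(
    peaks=(
        (4350.0, 120.0, 0.45),
        (4700.0, 180.0, 0.35),
        (5230.0, 160.0, 0.70),
        (5800.0, 200.0, 0.40),
        (6900.0, 260.0, 0.62),
        (8400.0, 320.0, 0.20),
    ),
    baseline=(0.25, -0.12, 0.04),
)
# Empty-pad background: broad, low-amplitude bands whose first derivative is
# slight relative to the tobacco bands, so a background common to a
# measurement pair perturbs paired distances only marginally.
_EMPTY_PAD_PROFILE = BrandProfile(
    peaks=((5150.0, 400.0, 0.008), (7000.0, 600.0, 0.005)),
    baseline=(0.010, 0.005),
)
#: spectral shape of the systematic self-made-cup offset (unit amplitude)
_CUP_SHIFT_PROFILE = BrandProfile(peaks=((6200.0, 300.0, 1.0),))
_ANOMALY_PROFILE = BrandProfile(peaks=((5000.0, 200.0, 1.0),))


@dataclass(frozen=True)
class StudyConfig:
    """Full description of one synthetic study.

    Scale parameters are in absorbance units.  ``between_batch_sd`` and
    ``within_batch_sd`` are standard deviations of the coefficients on a
    fixed smooth bump basis (see ``n_effect_basis``); ``noise_sd`` is
    per-point white detector noise.  ``cup_shift_amplitude`` scales the
    fixed shift band and ``cup_shift_gain`` the multiplicative gain applied
    to self-made-cup measurements.  ``anomaly_amplitude`` adds an
    exponentially decaying drift to the earliest product batches.
    """

    grid: WavenumberGrid = CANONICAL_GRID
    brands: dict[str, BrandProfile] = field(
        default_factory=lambda: {"TT": _TT_PROFILE, "AA": _AA_PROFILE}
    )
    n_batches: dict[str, int] = field(default_factory=lambda: {"TT": 62, "AA": 66})
    pads_per_batch: int = 24
    n_standard_batches: dict[str, int] = field(
        default_factory=lambda: {"TT": 11, "AA": 11}
    )
    standard_pads_per_batch: dict[str, int] = field(
        default_factory=lambda: {"TT": 4, "AA": 5}
    )
    between_batch_sd: float = 0.004
    within_batch_sd: float = 0.002
    noise_sd: float = 2e-4
    scatter_slope_sd: float = 0.02
    scatter_offset_sd: float = 0.01
    empty_pad_profile: BrandProfile = _EMPTY_PAD_PROFILE
    cup_shift_amplitude: float = 1e-3
    cup_shift_gain: float = 2e-3
    n_empty_pads: int = 12
    anomaly_amplitude: float = 0.0
    anomaly_batches: int = 4
    n_effect_basis: int = 12
    seed: int = 0

    def validate(self) -> None:
        if not self.brands:
            raise ConfigError("study needs at least one brand")
        for name, n in self.n_batches.items():
            if n < 1:
                raise ConfigError(f"brand {name!r}: n_batches must be >= 1, got {n}")
        if set(self.n_batches) != set(self.brands):
            raise ConfigError("n_batches keys must match brand names")
        if self.pads_per_batch < 2 or self.pads_per_batch % 2:
            raise ConfigError(
                f"pads_per_batch must be even and >= 2 for pairing, got {self.pads_per_batch}"
            )
        for field_name in (
            "between_batch_sd",
            "within_batch_sd",
            "noise_sd",
            "scatter_slope_sd",
            "scatter_offset_sd",
        ):
            if getattr(self, field_name) < 0:
                raise ConfigError(f"{field_name} must be >= 0")
        if self.n_empty_pads < 0:
            raise ConfigError("n_empty_pads must be >= 0")

    def with_(self, **kwargs) -> "StudyConfig":
        return replace(self, **kwargs)


def default_study_config(seed: int = 0) -> StudyConfig:
    """Full-scale study: 62 TT / 66 AA batches of 24 pads, 44 + 55 standards."""
    return StudyConfig(seed=seed)


def scaled_study_config(seed: int = 0) -> StudyConfig:
    """Desk-scale study preserving the full design's structure:
    20 batches x 8 pads per brand, 5 standard batches x 4 pads (20 standards
    per brand), same effect sizes."""
    return StudyConfig(
        n_batches={"TT": 20, "AA": 20},
        pads_per_batch=8,
        n_standard_batches={"TT": 5, "AA": 5},
        standard_pads_per_batch={"TT": 4, "AA": 4},
        seed=seed,
    )


def _rng(config: StudyConfig, *key: int) -> np.random.Generator:
    """Deterministic substream keyed by (namespace, brand, batch, pad, ...)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def _effect_basis(grid: WavenumberGrid, n_basis: int) -> np.ndarray:
    """(n_basis, d) matrix of unit-amplitude smooth Gaussian bumps spanning the grid."""
    w = grid.values
    centers = np.linspace(grid.start, grid.stop, n_basis)
    width = (grid.stop - grid.start) / (n_basis * 0.9)
    return np.exp(-0.5 * ((w[None, :] - centers[:, None]) / width) ** 2)


def _smooth_effect(rng: np.random.Generator, basis: np.ndarray, sd: float) -> np.ndarray:
    return rng.normal(0.0, sd, size=basis.shape[0]) @ basis if sd > 0 else np.zeros(basis.shape[1])


# namespaces for the deterministic stream split
_NS_BATCH, _NS_PAD, _NS_MEAS, _NS_EMPTY = 1, 2, 3, 6
_ROLE_PRODUCT, _ROLE_STANDARD = 0, 1


def _measure(
    core: np.ndarray,
    rng: np.random.Generator,
    config: StudyConfig,
    shift: np.ndarray | None,
) -> np.ndarray:
    """One instrument measurement of a pad signal: optional cup shift, then
    multiplicative scatter b*x + a, then white noise."""
    x = core
    if shift is not None:
        x = x * (1.0 + config.cup_shift_gain) + shift
    b = rng.normal(1.0, config.scatter_slope_sd)
    a = rng.normal(0.0, config.scatter_offset_sd)
    noise = rng.normal(0.0, config.noise_sd, size=x.shape[0])
    return b * x + a + noise


def _simulate_brand_block(
    config: StudyConfig,
    brand_idx: int,
    brand: str,
    role_tag: int,
    n_batches: int,
    pads_per_batch: int,
    basis: np.ndarray,
    cup_shift: np.ndarray,
    background: np.ndarray,
) -> list[Spectrum]:
    """Batches for one brand, either product (paired, two cups) or standard
    (classical cup only, one spectrum per pad)."""
    profile = render_profile(config.brands[brand], config.grid)
    is_std = role_tag == _ROLE_STANDARD
    spectra: list[Spectrum] = []
    for j in range(1, n_batches + 1):
        batch_rng = _rng(config, _NS_BATCH, brand_idx, role_tag, j)
        batch_effect = _smooth_effect(batch_rng, basis, config.between_batch_sd)
        anomaly = np.zeros_like(profile)
        if not is_std and config.anomaly_amplitude > 0:
            decay = np.exp(-(j - 1) / max(config.anomaly_batches, 1))
            anomaly = (
                config.anomaly_amplitude
                * decay
                * render_profile(_ANOMALY_PROFILE, config.grid)
            )
        batch_id = f"{brand}-{'S' if is_std else 'B'}{j:03d}"
        date_index = 0 if is_std else j
        n_sources = pads_per_batch if is_std else pads_per_batch // 2
        for p in range(1, n_sources + 1):
            pad_rng = _rng(config, _NS_PAD, brand_idx, role_tag, j, p)
            pad_effect = _smooth_effect(pad_rng, basis, config.within_batch_sd)
            core = profile + batch_effect + pad_effect + background + anomaly
            if is_std:
                rng = _rng(config, _NS_MEAS, brand_idx, role_tag, j, p, 0)
                meta = SpectrumMeta(
                    sample_id=f"{batch_id}-p{p:02d}",
                    brand=brand,
                    batch_id=batch_id,
                    role=Role.STANDARD,
                    cup=Cup.CLASSICAL,
                    date_index=date_index,
                )
                spectra.append(
                    Spectrum(meta=meta, grid=config.grid,
                             values=_measure(core, rng, config, None))
                )
            else:
                pair_id = f"{batch_id}-p{p:02d}"
                for cup_idx, cup in enumerate((Cup.CLASSICAL, Cup.SELFMADE)):
                    rng = _rng(config, _NS_MEAS, brand_idx, role_tag, j, p, cup_idx)
                    shift = cup_shift if cup is Cup.SELFMADE else None
                    meta = SpectrumMeta(
                        sample_id=f"{pair_id}-{cup.value}",
                        brand=brand,
                        batch_id=batch_id,
                        role=Role.PRODUCT,
                        cup=cup,
                        pair_id=pair_id,
                        date_index=date_index,
                    )
                    spectra.append(
                        Spectrum(meta=meta, grid=config.grid,
                                 values=_measure(core, rng, config, shift))
                    )
    return spectra


def simulate_study(config: StudyConfig | None = None) -> SpectrumSet:
    """Generate a full study: products, standards and empty-pad spectra.

    Product counts follow the config arithmetic: per brand,
    ``n_batches * pads_per_batch`` product spectra (half per cup, paired),
    plus ``n_standard_batches * standard_pads_per_batch`` standard spectra
    and ``n_empty_pads`` shared empty-pad spectra.  Same seed, same output,
    bit for bit.
    """
    config = config or StudyConfig()
    config.validate()
    basis = _effect_basis(config.grid, config.n_effect_basis)
    background = render_profile(config.empty_pad_profile, config.grid)
    cup_shift = config.cup_shift_amplitude * render_profile(_CUP_SHIFT_PROFILE, config.grid)
    spectra: list[Spectrum] = []
    for brand_idx, brand in enumerate(sorted(config.brands)):
        spectra.extend(
            _simulate_brand_block(
                config, brand_idx, brand, _ROLE_PRODUCT,
                config.n_batches[brand], config.pads_per_batch,
                basis, cup_shift, background,
            )
        )
        spectra.extend(
            _simulate_brand_block(
                config, brand_idx, brand, _ROLE_STANDARD,
                config.n_standard_batches.get(brand, 0),
                config.standard_pads_per_batch.get(brand, 0),
                basis, cup_shift, background,
            )
        )
    if config.n_empty_pads:
        spectra.extend(simulate_empty_pads(config).spectra)
    return SpectrumSet(grid=config.grid, spectra=spectra)


def simulate_empty_pads(config: StudyConfig, n: int | None = None) -> SpectrumSet:
    """Empty Cambridge-filter-pad spectra: background profile plus noise only."""
    config.validate()
    n = config.n_empty_pads if n is None else n
    if n < 1:
        raise ConfigError(f"need n >= 1 empty pads, got {n}")
    background = render_profile(config.empty_pad_profile, config.grid)
    spectra = []
    for i in range(1, n + 1):
        rng = _rng(config, _NS_EMPTY, i)
        values = background + rng.normal(0.0, config.noise_sd, size=background.shape[0])
        meta = SpectrumMeta(sample_id=f"empty-e{i:02d}", role=Role.EMPTY_PAD)
        spectra.append(Spectrum(meta=meta, grid=config.grid, values=values))
    return SpectrumSet(grid=config.grid, spectra=spectra)


# --- config (de)serialization for YAML/JSON configs and manifests ----------

def _profile_to_dict(profile: BrandProfile) -> dict:
    return {
        "peaks": [list(p) for p in profile.peaks],
        "baseline": list(profile.baseline),
    }


def _profile_from_dict(data: dict) -> BrandProfile:
    return BrandProfile(
        peaks=tuple(tuple(float(x) for x in p) for p in data["peaks"]),
        baseline=tuple(float(x) for x in data.get("baseline", (0.0,))),
    )


def study_config_to_dict(config: StudyConfig) -> dict:
    """Plain-JSON/YAML representation of a StudyConfig."""
    return {
        "grid": {
            "start": config.grid.start,
            "step": config.grid.step,
            "n_points": config.grid.n_points,
        },
        "brands": {name: _profile_to_dict(p) for name, p in config.brands.items()},
        "n_batches": dict(config.n_batches),
        "pads_per_batch": config.pads_per_batch,
        "n_standard_batches": dict(config.n_standard_batches),
        "standard_pads_per_batch": dict(config.standard_pads_per_batch),
        "between_batch_sd": config.between_batch_sd,
        "within_batch_sd": config.within_batch_sd,
        "noise_sd": config.noise_sd,
        "scatter_slope_sd": config.scatter_slope_sd,
        "scatter_offset_sd": config.scatter_offset_sd,
        "empty_pad_profile": _profile_to_dict(config.empty_pad_profile),
        "cup_shift_amplitude": config.cup_shift_amplitude,
        "cup_shift_gain": config.cup_shift_gain,
        "n_empty_pads": config.n_empty_pads,
        "anomaly_amplitude": config.anomaly_amplitude,
        "anomaly_batches": config.anomaly_batches,
        "n_effect_basis": config.n_effect_basis,
        "seed": config.seed,
    }


def study_config_from_dict(data: dict) -> StudyConfig:
    """Inverse of :func:`study_config_to_dict`; missing keys take defaults."""
    kwargs = dict(data)
    if "grid" in kwargs:
        g = kwargs["grid"]
        kwargs["grid"] = WavenumberGrid(
            start=float(g["start"]), step=float(g["step"]), n_points=int(g["n_points"])
        )
    if "brands" in kwargs:
        kwargs["brands"] = {
            name: _profile_from_dict(p) for name, p in kwargs["brands"].items()
        }
    if "empty_pad_profile" in kwargs:
        kwargs["empty_pad_profile"] = _profile_from_dict(kwargs["empty_pad_profile"])
    unknown = set(kwargs) - {f.name for f in __import__("dataclasses").fields(StudyConfig)}
    if unknown:
        raise ConfigError(f"unknown study config keys: {sorted(unknown)}")
    return StudyConfig(**kwargs)
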