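"""Reference model fitting and Mahalanobis-distance stability scoring.

The product-stability statistic is the quadratic form

    D = (x - mu) C^{-1} (x - mu)^T

where ``mu`` and ``C`` are the mean and covariance of the preprocessed
standard-sample spectra of one brand.  As printed this is the *squared*
Mahalanobis distance; it is reported as such (``sqrt_D`` is offered for
display).  With tens of standards and ~1000 wavenumber points the sample
covariance is singular, so three covariance treatments are provided:

``pca_subspace`` (default)
    Eigendecomposition of the sample covariance (divisor ``n_ref - 1``);
    the smallest number of leading components whose eigenvalue sum reaches
    ``variance_retained`` of the total is kept and D is evaluated inside
    that subspace: ``D = sum_j (v_j . (x - mu))^2 / lambda_j``.
``shrinkage``
    Ledoit-Wolf shrinkage toward the scaled identity,
    ``C_lambda = (1 - lambda) S + lambda (tr S / d) I``.
``classical``
    The plain sample covariance; only valid when ``n_ref - 1 >= d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.decomposition import PCA

from .errors import ConfigError, NumericalError, ValidationError
from .preprocess import PreprocessConfig
from .spectra import Cup, Role, Spectrum, SpectrumMeta, SpectrumSet, WavenumberGrid

__all__ = [
    "ReferenceModel",
    "StabilityResult",
    "fit_reference",
    "mahalanobis_D",
    "batch_average",
    "stability_timeline",
    "pca_scores",
]

#: eigenvalues below this fraction of the largest are always dropped
_EIG_REL_TOL = 1e-12


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: each row's largest-|.| element positive."""
    out = basis.copy()
    for j in range(out.shape[0]):
        k = int(np.argmax(np.abs(out[j])))
        if out[j, k] < 0:
            out[j] = -out[j]
    return out


@dataclass
class ReferenceModel:
    """Mean and covariance representation of a brand's standard spectra.

    ``basis``/``eigenvalues`` hold the retained subspace in ``pca_subspace``
    mode; ``covariance`` holds the full (shrunk or plain) matrix otherwise.
    ``msc_reference`` and ``preprocess`` record the preprocessing provenance
    so new product spectra can be transformed identically before scoring.
    """

    mu: np.ndarray
    grid: WavenumberGrid
    brand: str
    method: str  # "pca_subspace" | "shrinkage" | "classical"
    n_ref: int
    variance_retained: float = 0.99
    basis: np.ndarray | None = None  # (k, d)
    eigenvalues: np.ndarray | None = None  # (k,)
    covariance: np.ndarray | None = None  # (d, d)
    shrinkage_intensity: float | None = None
    shrinkage_rule: str | None = None
    msc_reference: np.ndarray | None = None
    preprocess: dict | None = None
    _cho: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def d(self) -> int:
        return int(self.mu.shape[0])

    @property
    def k(self) -> int | None:
        return None if self.eigenvalues is None else int(self.eigenvalues.shape[0])

    def _factor(self):
        if self._cho is None:
            try:
                self._cho = linalg.cho_factor(self.covariance)
            except linalg.LinAlgError as exc:
                raise NumericalError(f"covariance not positive definite: {exc}") from exc
        return self._cho

    def quadratic_form(self, delta: np.ndarray) -> float:
        """``delta C^{-1} delta^T`` under this model's covariance representation."""
        delta = np.asarray(delta, dtype=float)
        if delta.shape != (self.d,):
            raise ValidationError(
                f"vector of length {delta.shape} does not match model dimension {self.d}"
            )
        if self.method == "pca_subspace":
            z = self.basis @ delta
            return float(np.sum(z * z / self.eigenvalues))
        if self.d <= 50:
            return float(delta @ np.linalg.inv(self.covariance) @ delta)
        return float(delta @ linalg.cho_solve(self._factor(), delta))

    def to_json_dict(self) -> dict:
        out = {
            "brand": self.brand,
            "method": self.method,
            "n_ref": self.n_ref,
            "variance_retained": self.variance_retained,
            "grid": {"start": self.grid.start, "step": self.grid.step,
                     "n_points": self.grid.n_points},
            "mu": self.mu.tolist(),
        }
        if self.basis is not None:
            out["basis"] = self.basis.tolist()
            out["eigenvalues"] = self.eigenvalues.tolist()
        if self.covariance is not None:
            out["covariance"] = self.covariance.tolist()
        if self.shrinkage_intensity is not None:
            out["shrinkage_intensity"] = self.shrinkage_intensity
            out["shrinkage_rule"] = self.shrinkage_rule
        if self.msc_reference is not None:
            out["msc_reference"] = self.msc_reference.tolist()
        if self.preprocess is not None:
            out["preprocess"] = self.preprocess
        return out

    @classmethod
    def from_json_dict(cls, data: dict) -> "ReferenceModel":
        grid = WavenumberGrid(**data["grid"])
        return cls(
            mu=np.asarray(data["mu"]),
            grid=grid,
            brand=data["brand"],
            method=data["method"],
            n_ref=int(data["n_ref"]),
            variance_retained=float(data.get("variance_retained", 0.99)),
            basis=np.asarray(data["basis"]) if "basis" in data else None,
            eigenvalues=np.asarray(data["eigenvalues"]) if "eigenvalues" in data else None,
            covariance=np.asarray(data["covariance"]) if "covariance" in data else None,
            shrinkage_intensity=data.get("shrinkage_intensity"),
            shrinkage_rule=data.get("shrinkage_rule"),
            msc_reference=(
                np.asarray(data["msc_reference"]) if "msc_reference" in data else None
            ),
            preprocess=data.get("preprocess"),
        )


def fit_reference(
    standards: SpectrumSet,
    method: str = "pca_subspace",
    variance_retained: float = 0.99,
    msc_reference: Spectrum | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> ReferenceModel:
    """Fit the (mu, C) reference model on preprocessed standard spectra.

    ``standards`` must share one brand and carry role=standard.  The
    optional ``msc_reference``/``preprocess_config`` are stored as
    provenance only; pass them when the model will be serialized and later
    used to score raw product spectra.
    """
    brands = {s.meta.brand for s in standards}
    roles = {s.meta.role for s in standards}
    if len(brands) != 1:
        raise ValidationError(f"standards mix brands {sorted(b or '?' for b in brands)}")
    if roles != {Role.STANDARD}:
        raise ValidationError("all reference spectra must have role=standard")
    n = len(standards)
    if n < 3:
        raise ValidationError(f"need at least 3 standard spectra, got {n}")
    if method not in ("pca_subspace", "shrinkage", "classical"):
        raise ConfigError(f"unknown covariance method {method!r}")
    if not 0 < variance_retained <= 1:
        raise ConfigError("variance_retained must lie in (0, 1]")

    X = standards.values
    d = X.shape[1]
    mu = X.mean(axis=0)
    Xc = X - mu
    model = ReferenceModel(
        mu=mu,
        grid=standards.grid,
        brand=brands.pop(),
        method=method,
        n_ref=n,
        variance_retained=variance_retained,
        msc_reference=None if msc_reference is None else msc_reference.values,
        preprocess=None if preprocess_config is None else preprocess_config.to_dict(),
    )

    if method == "pca_subspace":
        # eigenpairs of S = Xc^T Xc / (n-1) via SVD of the centered data
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        eig = s**2 / (n - 1)
        keep = eig > _EIG_REL_TOL * eig[0]
        eig, vt = eig[keep], vt[keep]
        total = eig.sum()
        k = int(np.searchsorted(np.cumsum(eig), variance_retained * total - 1e-15) + 1)
        k = min(k, eig.shape[0])
        model.eigenvalues = eig[:k]
        model.basis = _fix_signs(vt[:k])
    else:
        S = Xc.T @ Xc / (n - 1)
        if method == "classical":
            if n - 1 < d:
                raise NumericalError(
                    f"classical covariance needs n_ref-1 >= d ({n - 1} < {d}); "
                    "use method='pca_subspace' or 'shrinkage'"
                )
            model.covariance = S
        else:
            lam = float(ledoit_wolf_shrinkage(X))
            model.covariance = (1 - lam) * S + lam * (np.trace(S) / d) * np.eye(d)
            model.shrinkage_intensity = lam
            model.shrinkage_rule = "ledoit_wolf"
    return model


def mahalanobis_D(x: Spectrum, model: ReferenceModel) -> float:
    """The stability statistic ``D = (x - mu) C^{-1} (x - mu)^T`` (squared form)."""
    if x.grid != model.grid:
        raise ValidationError(
            f"spectrum {x.meta.sample_id!r} grid {x.grid} != model grid {model.grid}"
        )
    return model.quadratic_form(x.values - model.mu)


@dataclass
class StabilityResult:
    """Per-sample and batch-averaged distances along the production timeline."""

    per_sample: pd.DataFrame  # sample_id, batch_id, date_index, D
    per_batch: pd.DataFrame | None  # batch_id, date_index, D
    reference_brand: str
    method: str
    k: int | None


def batch_average(spectrum_set: SpectrumSet, by_cup: bool = False) -> SpectrumSet:
    """Elementwise mean spectrum per (brand, batch_id[, cup]) group.

    The averaged spectrum takes the batch's date_index and a synthesized
    deterministic sample_id; every input spectrum must carry a batch_id.
    """
    groups: dict[tuple, list[Spectrum]] = {}
    order: list[tuple] = []
    for s in spectrum_set:
        if not s.meta.batch_id:
            raise ValidationError(f"spectrum {s.meta.sample_id!r} lacks batch_id")
        key = (s.meta.brand, s.meta.batch_id) + ((s.meta.cup,) if by_cup else ())
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    out: list[Spectrum] = []
    for key in order:
        members = groups[key]
        vals = np.mean([m.values for m in members], axis=0)
        cup = key[2] if by_cup else members[0].meta.cup
        sid = ":".join(str(k.value if isinstance(k, Cup) else k) for k in key) + ":mean"
        meta = SpectrumMeta(
            sample_id=sid,
            brand=key[0],
            batch_id=key[1],
            role=members[0].meta.role,
            cup=cup,
            date_index=min(m.meta.date_index for m in members),
        )
        out.append(Spectrum(meta=meta, grid=spectrum_set.grid, values=vals))
    return SpectrumSet(grid=spectrum_set.grid, spectra=out)


def stability_timeline(
    products: SpectrumSet,
    model: ReferenceModel,
    average_batches: bool = True,
) -> StabilityResult:
    """Score every product spectrum (and, optionally, every batch mean)
    against the reference model, ordered by date_index.

    ``products`` must have been preprocessed identically to the model's
    training standards."""
    rows = [
        {
            "sample_id": s.meta.sample_id,
            "batch_id": s.meta.batch_id,
            "date_index": s.meta.date_index,
            "D": mahalanobis_D(s, model),
        }
        for s in products
    ]
    per_sample = (
        pd.DataFrame(rows)
        .sort_values(["date_index", "sample_id"], kind="stable")
        .reset_index(drop=True)
    )
    per_batch = None
    if average_batches:
        means = batch_average(products)
        batch_rows = [
            {
                "batch_id": s.meta.batch_id,
                "date_index": s.meta.date_index,
                "D": mahalanobis_D(s, model),
            }
            for s in means
        ]
        per_batch = (
            pd.DataFrame(batch_rows)
            .sort_values(["date_index", "batch_id"], kind="stable")
            .reset_index(drop=True)
        )
    return StabilityResult(
        per_sample=per_sample,
        per_batch=per_batch,
        reference_brand=model.brand,
        method=model.method,
        k=model.k,
    )


def pca_scores(all_spectra: SpectrumSet, n_components: int = 2) -> pd.DataFrame:
    """Centered PCA scores of a set, with deterministic component signs.

    Signs follow the convention that each loading's largest-magnitude
    element is positive.  Returns a frame with sample_id, brand, cup and
    PC1..PCn columns, rows in set order.
    """
    X = all_spectra.values
    n, d = X.shape
    if not 1 <= n_components <= min(n - 1, d):
        raise ConfigError(
            f"n_components={n_components} must be in [1, min(n-1, d)] = "
            f"[1, {min(n - 1, d)}]"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    flip = np.array(
        [
            -1.0 if comp[int(np.argmax(np.abs(comp)))] < 0 else 1.0
            for comp in pca.components_
        ]
    )
    scores = scores * flip
    frame = all_spectra.metadata_frame()[["sample_id", "brand", "cup"]]
    for j in range(n_components):
        frame[f"PC{j + 1}"] = scores[:, j]
    frame.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return frame
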