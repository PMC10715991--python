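"""Container-cup equivalence analysis.

The cup change is judged by comparing two distance populations under one
reference-model metric: the distance between the two members of each
measurement pair (same sample source, classical vs self-made cup), and the
distance of product samples to the brand's standard reference.  If the
paired distances sit far below the sample-to-standard distances, the cup
change is negligible relative to ordinary product variability.

A Wilcoxon rank-sum location comparison is attached to the descriptive
summary as a convenience decision statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .similarity import ReferenceModel
from .spectra import Cup, Spectrum, SpectrumSet

__all__ = ["SpectrumPair", "EquivalenceResult", "pair_up", "paired_distance", "compare_groups"]


@dataclass(frozen=True)
class SpectrumPair:
    pair_id: str
    classical: Spectrum
    selfmade: Spectrum


def pair_up(spectrum_set: SpectrumSet) -> tuple[list[SpectrumPair], list[Spectrum]]:
    """Group spectra by pair_id into (classical, selfmade) pairs.

    Returns ``(pairs, remainder)``; spectra without a pair_id or whose
    partner is missing go to the remainder rather than being dropped
    silently.  A pair_id carried by two same-cup spectra (or more than two
    spectra) is a validation error naming the pair.
    """
    by_pair: dict[str, list[Spectrum]] = {}
    remainder: list[Spectrum] = []
    order: list[str] = []
    for s in spectrum_set:
        pid = s.meta.pair_id
        if pid is None:
            remainder.append(s)
            continue
        if pid not in by_pair:
            by_pair[pid] = []
            order.append(pid)
        by_pair[pid].append(s)
    pairs: list[SpectrumPair] = []
    for pid in order:
        members = by_pair[pid]
        if len(members) == 1:
            remainder.append(members[0])
            continue
        if len(members) > 2:
            raise ValidationError(f"pair {pid!r} has {len(members)} members, expected 2")
        cups = {m.meta.cup for m in members}
        if cups != {Cup.CLASSICAL, Cup.SELFMADE}:
            raise ValidationError(
                f"pair {pid!r} members share cup {members[0].meta.cup.value!r}"
            )
        classical = next(m for m in members if m.meta.cup == Cup.CLASSICAL)
        selfmade = next(m for m in members if m.meta.cup == Cup.SELFMADE)
        pairs.append(SpectrumPair(pair_id=pid, classical=classical, selfmade=selfmade))
    return pairs, remainder


def paired_distance(pair: SpectrumPair, model: ReferenceModel) -> float:
    """D of the pair's difference vector under the model metric.

    ``D = (x_old - x_new) C^{-1} (x_old - x_new)^T`` — the reference mean
    cancels, so this isolates the cup effect in the same units as the
    sample-to-standard distances.  Symmetric in the two members.
    """
    if pair.classical.grid != model.grid or pair.selfmade.grid != model.grid:
        raise ValidationError(f"pair {pair.pair_id!r} not on the model grid")
    return model.quadratic_form(pair.classical.values - pair.selfmade.values)


@dataclass
class EquivalenceResult:
    """Paired-cup vs sample-to-standard distance populations.

    ``separation_ratio = median_sample / median_paired``; a large ratio
    means the cup change is small relative to product variability.
    ``rank_sum_p`` is the two-sided Wilcoxon rank-sum p-value for a
    location difference between the two populations.
    """

    paired_D: pd.DataFrame  # pair_id, D
    sample_D: pd.DataFrame  # sample_id, D
    summary: dict
    bin_edges: np.ndarray
    paired_counts: np.ndarray
    sample_counts: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "summary": self.summary,
            "paired_D": self.paired_D.to_dict(orient="records"),
            "sample_D": self.sample_D.to_dict(orient="records"),
            "histogram": {
                "bin_edges": self.bin_edges.tolist(),
                "paired_counts": self.paired_counts.tolist(),
                "sample_counts": self.sample_counts.tolist(),
            },
        }


def compare_groups(
    paired_D: list[tuple[str, float]],
    sample_D: list[tuple[str, float]],
    n_bins: int = 30,
) -> EquivalenceResult:
    """Summarize the two distance populations over shared equal-width bins."""
    if n_bins < 2:
        raise ConfigError(f"n_bins must be >= 2, got {n_bins}")
    if not paired_D or not sample_D:
        raise ValidationError("both distance lists must be non-empty")
    p_vals = np.array([d for _, d in paired_D], dtype=float)
    s_vals = np.array([d for _, d in sample_D], dtype=float)
    pooled_lo = min(p_vals.min(), s_vals.min())
    pooled_hi = max(p_vals.max(), s_vals.max())
    if pooled_hi == pooled_lo:  # all-identical degenerate case
        pooled_hi = pooled_lo + 1.0
    edges = np.linspace(pooled_lo, pooled_hi, n_bins + 1)
    paired_counts, _ = np.histogram(p_vals, bins=edges)
    sample_counts, _ = np.histogram(s_vals, bins=edges)
    median_paired = float(np.median(p_vals))
    median_sample = float(np.median(s_vals))
    rank_p = float(stats.ranksums(s_vals, p_vals).pvalue)
    summary = {
        "median_paired": median_paired,
        "median_sample": median_sample,
        "separation_ratio": median_sample / median_paired if median_paired > 0 else np.inf,
        "range_paired": (float(p_vals.min()), float(p_vals.max())),
        "range_sample": (float(s_vals.min()), float(s_vals.max())),
        "n_paired": int(p_vals.size),
        "n_sample": int(s_vals.size),
        "rank_sum_p": rank_p,
    }
    return EquivalenceResult(
        paired_D=pd.DataFrame(paired_D, columns=["pair_id", "D"]),
        sample_D=pd.DataFrame(sample_D, columns=["sample_id", "D"]),
        summary=summary,
        bin_edges=edges,
        paired_counts=paired_counts,
        sample_counts=sample_counts,
    )
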