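"""Condition contrasts of band-averaged DTF values.

Per-segment DTF spectra are summarised as the arithmetic mean over a
frequency band (default 3–40 Hz), compared across conditions with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test, and corrected for
multiple comparisons across the full family of direction × modality
contrasts with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError
from .mvar import DTFSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionContrast",
    "band_average_dtf",
    "ranksum_test",
    "fdr_bh",
    "compare_conditions",
]


@dataclass
class ConditionContrast:
    """One direction × modality contrast of band-averaged DTF values."""

    direction: tuple[str, str]  # (from_label, to_label)
    modality: str
    band: tuple[float, float]
    values_W: np.ndarray
    values_A: np.ndarray
    statistic: float  # rank-sum W of the first (wakefulness) sample
    p_raw: float
    p_fdr: float = np.nan
    significant: bool = False
    effect_sign: float = 0.0  # median(A) − median(W)
    family_size: int = 1


def band_average_dtf(
    dtf: DTFSpectrum, band: tuple[float, float], direction: tuple[int, int]
) -> float:
    """Mean DTF over grid frequencies in ``[f_lo, f_hi]`` (inclusive).

    ``direction`` is ``(j, i)``: flow from channel ``j`` into channel ``i``.
    """
    f_lo, f_hi = band
    if f_lo >= f_hi:
        raise InvalidParameterError(f"band must satisfy f_lo < f_hi, got {band}")
    sel = (dtf.freqs >= f_lo) & (dtf.freqs <= f_hi)
    if not np.any(sel):
        raise InvalidParameterError(f"no grid frequencies inside band {band}")
    j, i = direction
    return float(dtf.values[sel, i, j].mean())


def ranksum_test(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Uses exact enumeration for small samples (n_x + n_y ≤ 12, no ties);
    otherwise the normal approximation with tie and continuity corrections.
    Returns ``(W, p)`` where W is the rank-sum of ``xs``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    pooled = np.concatenate([xs, ys])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (xs.size + ys.size <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(
        xs, ys, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + xs.size * (xs.size + 1) / 2.0  # U → rank-sum W
    return w, float(res.pvalue)


def fdr_bh(p_raw: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR adjustment.

    Returns ``(p_adjusted, reject)`` with adjusted p-values monotone in the
    raw ones and capped at 1; rejection where ``p_adjusted ≤ q``.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if p_raw.size == 0:
        return p_raw.copy(), np.zeros(0, dtype=bool)
    _, p_adj, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def compare_conditions(
    dtf_W,
    dtf_A,
    band: tuple[float, float],
    directions: list[tuple[int, int]],
    q: float = 0.05,
    labels: list[str] | None = None,
    modality: str = "ECOG",
) -> list[ConditionContrast]:
    """Contrast per-segment band-averaged DTFs between conditions.

    ``dtf_W`` / ``dtf_A`` are lists of per-segment :class:`DTFSpectrum`
    (one modality), or dicts ``{modality: list}`` to test several
    modalities in one family. FDR is applied jointly across every
    direction × modality contrast in the call; the effect sign reported is
    ``median(values_A) − median(values_W)``.
    """
    if not isinstance(dtf_W, dict):
        dtf_W = {modality: dtf_W}
        dtf_A = {modality: dtf_A}
    contrasts: list[ConditionContrast] = []
    for mod, spectra_w in dtf_W.items():
        spectra_a = dtf_A[mod]
        if len(spectra_w) != len(spectra_a):
            raise InvalidParameterError(
                f"{mod}: {len(spectra_w)} W segments vs {len(spectra_a)} A segments"
            )
        chan = labels or (spectra_w[0].channel_labels or None)
        for j, i in directions:
            vw = np.array([band_average_dtf(d, band, (j, i)) for d in spectra_w])
            va = np.array([band_average_dtf(d, band, (j, i)) for d in spectra_a])
            stat, p = ranksum_test(vw, va)
            name = (
                (chan[j], chan[i])
                if chan
                else (f"ch{j}", f"ch{i}")
            )
            contrasts.append(
                ConditionContrast(
                    direction=name,
                    modality=mod,
                    band=tuple(band),
                    values_W=vw,
                    values_A=va,
                    statistic=stat,
                    p_raw=p,
                    effect_sign=float(np.median(va) - np.median(vw)),
                )
            )
    p_adj, reject = fdr_bh(np.array([c.p_raw for c in contrasts]), q=q)
    for c, pa, r in zip(contrasts, p_adj, reject):
        c.p_fdr = float(pa)
        c.significant = bool(r)
        c.family_size = len(contrasts)
    logger.info(
        "compare_conditions: family of %d contrasts, %d rejected at q=%g",
        len(contrasts),
        int(reject.sum()),
        q,
    )
    return contrasts
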