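"""End-to-end analysis tracks over a two-condition, two-modality study.

The data-driven track segments each recording (15 × 2 s by default), fits
an MVAR model per segment, computes normalized DTFs on the analysis grid,
band-averages them over 3–40 Hz and contrasts conditions with the
rank-sum test under joint FDR correction.

Note on referencing: the common-average reference and detrending stages of
:mod:`dirconn.preprocess` are meant for full multichannel arrays; once the
analysis is restricted to a two-source pair they are deliberately not
re-applied (averaging two analysis channels would mix the very sources
whose directed coupling is under test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import DTFSpectrum, compute_dtf, default_freq_grid, fit_mvar, transfer_matrix
from .preprocess import segment_recording
from .recording import MultichannelRecording, SegmentSet
from .stats import ConditionContrast, compare_conditions

__all__ = ["DTFTrackConfig", "dtf_per_segment", "run_dtf_track"]


@dataclass
class DTFTrackConfig:
    order: int = 7
    seg_duration_s: float = 2.0
    n_segments: int = 15
    band: tuple[float, float] = (3.0, 40.0)
    q: float = 0.05
    freqs: np.ndarray = field(default_factory=default_freq_grid)


def dtf_per_segment(
    segments: SegmentSet, order: int = 7, freqs: np.ndarray | None = None
) -> list[DTFSpectrum]:
    """One normalized DTF spectrum per analysis segment."""
    if freqs is None:
        freqs = default_freq_grid()
    out = []
    for seg in segments.segments:
        single = SegmentSet(
            segments=[seg],
            fs=segments.fs,
            seg_duration_s=segments.seg_duration_s,
            condition=segments.condition,
            modality=segments.modality,
            channel_labels=segments.channel_labels,
        )
        model = fit_mvar(single, order)
        dtf = compute_dtf(
            transfer_matrix(model, freqs), channel_labels=segments.channel_labels
        )
        out.append(dtf)
    return out


def run_dtf_track(
    recordings: dict[str, dict[str, MultichannelRecording]],
    config: DTFTrackConfig | None = None,
) -> list[ConditionContrast]:
    """Full data-driven track on ``{condition: {modality: recording}}``.

    Tests both cross-directions for every modality present, with FDR
    applied jointly over the whole direction × modality family (4
    contrasts in the standard two-modality design).
    """
    cfg = config or DTFTrackConfig()
    dtf_w: dict[str, list[DTFSpectrum]] = {}
    dtf_a: dict[str, list[DTFSpectrum]] = {}
    labels = None
    for cond, per_mod in recordings.items():
        for mod, rec in per_mod.items():
            segs = segment_recording(rec, cfg.seg_duration_s, cfg.n_segments)
            spectra = dtf_per_segment(segs, cfg.order, cfg.freqs)
            (dtf_w if cond == "W" else dtf_a)[mod] = spectra
            labels = labels or rec.channel_labels
    directions = [(0, 1), (1, 0)]  # ch0→ch1 and ch1→ch0
    return compare_conditions(
        dtf_w, dtf_a, band=cfg.band, directions=directions, q=cfg.q, labels=labels
    )
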