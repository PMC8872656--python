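"""End-to-end analysis: filter -> beats -> MRPW -> APV features."""

from __future__ import annotations

import logging

import pandas as pd

from .apv import extract_apv_features, reference_channel
from .beats import Waveform, compute_apw, segment_beats, select_mrpw
from .config import PipelineConfig
from .errors import PipelineError
from .model import N_CHANNELS, ArrayRecording
from .preprocess import apply_filter, design_bandpass

log = logging.getLogger("arraypulse")


def analyze_recording(
    recording: ArrayRecording,
    config: PipelineConfig | None = None,
    subject_id: str = "",
    group_label: str = "unknown",
) -> pd.DataFrame:
    """Run the full pipeline on one recording and return the feature table.

    Steps: band-pass each channel; segment beats per channel; choose the
    reference channel (largest median beat amplitude); average its beats
    into the APW and select the MRPW by correlation; the MRPW window then
    delimits the beat over which APV features are extracted for every
    channel group.
    """
    config = config or PipelineConfig()
    spec = design_bandpass(
        recording.fs,
        config.filter_low_hz,
        config.filter_high_hz,
        config.filter_order,
        config.filter_ripple_db,
        config.filter_zero_phase,
    )
    filtered = apply_filter(recording, spec)
    segs = [
        segment_beats(
            Waveform(filtered.channel(ch), filtered.fs),
            config.min_hr_bpm,
            config.max_hr_bpm,
        )
        for ch in range(N_CHANNELS)
    ]
    ref = reference_channel(filtered, segs)
    seg = segs[ref]
    if seg.n_beats < 2:
        raise PipelineError(f"reference channel {ref} has fewer than 2 beats")
    ref_wave = Waveform(filtered.channel(ref), filtered.fs)
    apw = compute_apw(ref_wave, seg)
    mrpw = select_mrpw(ref_wave, seg, apw)
    log.info(
        "subject=%s ref_channel=%d beats=%d mrpw_cc=%.4f",
        subject_id, ref, seg.n_beats, mrpw.cc,
    )
    return extract_apv_features(
        filtered,
        mrpw.window,
        n_grid=config.n_grid,
        footprint=config.footprint,
        subject_id=subject_id,
        group_label=group_label,
    )


def analyze_cohort(subjects, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Analyze a list of SubjectRecording objects into one feature table."""
    frames = []
    for sub in subjects:
        frames.append(
            analyze_recording(
                sub.recording, config, subject_id=sub.subject_id, group_label=sub.group
            )
        )
    return pd.concat(frames, ignore_index=True)
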