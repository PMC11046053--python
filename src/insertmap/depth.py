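"""Read-depth copy-number estimation and qPCR relative quantification.

Depth normalization follows the c/4 convention: per-window depth is divided
by twice the genome-wide modal window depth, so against a two-copy (diploid)
background a region present at c copies sits at c/4 — one-copy regions at
0.25, the background at 0.50, three copies at 0.75, and so on.  Integer copy
calls are then ``round(4 x normalized depth)``.

Only primary alignments should be supplied; reads whose placement is
ambiguous between references (shared sequence such as a selection-marker
homolog) are assigned deterministically and the affected windows are not
meaningful — restrict feature estimates to unique sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import Alignment
from .records import CtTable, Feature, SequenceRecord


@dataclass
class DepthProfile:
    """Windowed depth over one reference, with per-base resolution retained."""

    ref_id: str
    window: int
    starts: np.ndarray  # window start coordinates
    depth: np.ndarray  # per-window mean depth
    per_base: np.ndarray  # per-base depth (float32)
    modal_depth: float | None = None  # genome-wide modal window depth
    normalized: np.ndarray | None = None  # depth / (2 * modal)

    def to_frame(self) -> pd.DataFrame:
        data = {"reference": self.ref_id, "start": self.starts, "depth": self.depth}
        if self.normalized is not None:
            data["normalized"] = self.normalized
        return pd.DataFrame(data)


@dataclass
class CopyNumberEstimate:
    label: str
    mean_normalized_depth: float
    copies: int
    normalization_constant: float


def depth_profile(
    alignments: Iterable[Alignment],
    reference: SequenceRecord,
    window: int = 500,
) -> DepthProfile:
    """Per-window mean of per-base coverage from the M/D blocks of primary
    alignments on one reference."""
    if window < 100:
        raise ValueError("window must be >= 100")
    L = len(reference)
    per_base = np.zeros(L + 1, dtype=np.float64)
    n = 0
    for aln in alignments:
        if aln.ref_id != reference.id:
            continue
        pos = aln.pos
        for op, length in aln.cigar:
            if op in "MD":
                per_base[max(pos, 0)] += 1
                per_base[min(pos + length, L)] -= 1
                pos += length
        n += 1
    if n == 0:
        warnings.warn(f"no alignments on {reference.id}; depth profile is all zero")
    per_base = np.cumsum(per_base)[:L]
    starts = np.arange(0, L, window)
    sums = np.add.reduceat(per_base, starts)
    widths = np.minimum(starts + window, L) - starts
    depth = sums / widths
    return DepthProfile(reference.id, window, starts, depth, per_base.astype(np.float32))


def mean_shift_mode(values: np.ndarray, half_width: float = 0.2, iters: int = 10) -> float:
    """Mode of a positive-valued sample by mean-shift refinement.

    A raw histogram argmax is noisy at desk scale (a few hundred windows), so
    starting from the median the estimate is repeatedly replaced by the mean
    of the values within a relative ``half_width`` band around it, converging
    onto the dominant peak while secondary peaks (at half or 1.5x the
    background, say) stay outside the band."""
    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size == 0:
        raise ValueError("no positive values; cannot find a mode")
    mode = float(np.median(values))
    for _ in range(iters):
        band = values[(values > (1 - half_width) * mode) & (values < (1 + half_width) * mode)]
        if band.size == 0:
            break
        new = float(band.mean())
        if abs(new - mode) < 1e-9:
            break
        mode = new
    return mode


def modal_window_depth(profiles: Sequence[DepthProfile]) -> float:
    """Genome-wide modal window depth (mean-shift mode over all windows).

    With a mostly two-copy genome this is the background depth peak."""
    depths = np.concatenate([p.depth for p in profiles])
    return mean_shift_mode(depths)


def normalize_depth(
    profiles: Sequence[DepthProfile], modal: float | None = None
) -> list[DepthProfile]:
    """Divide window depths by twice the genome-wide modal depth (c/4 scale)."""
    if modal is None:
        modal = modal_window_depth(profiles)
    if modal <= 0:
        raise ValueError("modal depth must be positive")
    out = []
    for p in profiles:
        out.append(
            DepthProfile(
                p.ref_id,
                p.window,
                p.starts,
                p.depth,
                p.per_base,
                modal_depth=modal,
                normalized=p.depth / (2.0 * modal),
            )
        )
    return out


def estimate_feature_copies(
    profiles: Sequence[DepthProfile], feature: Feature
) -> CopyNumberEstimate:
    """Integer copy call for a feature interval: round(4 x mean normalized
    per-base depth over the interval)."""
    profile = next((p for p in profiles if p.ref_id == feature.record_id), None)
    if profile is None:
        raise ValueError(f"feature {feature.label!r} is outside the profiled references")
    if profile.modal_depth is None:
        raise ValueError("profiles must be normalized first")
    base = profile.per_base[feature.start : feature.end]
    if base.size == 0:
        raise ValueError(f"feature {feature.label!r} overlaps no profiled base")
    mean_norm = float(base.mean() / (2.0 * profile.modal_depth))
    return CopyNumberEstimate(
        feature.label, mean_norm, int(round(4.0 * mean_norm)), 2.0 * profile.modal_depth
    )


def copy_table(
    profiles: Sequence[DepthProfile], features: Sequence[Feature]
) -> pd.DataFrame:
    rows = []
    for f in features:
        est = estimate_feature_copies(profiles, f)
        rows.append((f.label, f.record_id, f.start, f.end, est.mean_normalized_depth, est.copies))
    return pd.DataFrame(
        rows, columns=["label", "reference", "start", "end", "normalized_depth", "copies"]
    )


def ddct(ct: CtTable, sample_id: str, control_id: str) -> float:
    """Relative copy number by the delta-delta-Ct method.

    dCt = mean Ct(target) - mean Ct(reference) per sample; the fold change of
    sample over control is 2^-(dCt_sample - dCt_control), assuming 100%
    amplification efficiency."""
    d_sample = ct.mean_ct(sample_id, "target") - ct.mean_ct(sample_id, "reference")
    d_control = ct.mean_ct(control_id, "target") - ct.mean_ct(control_id, "reference")
    return float(2.0 ** (-(d_sample - d_control)))
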