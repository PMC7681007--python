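"""Spike-in (HMD-style) normalization arithmetic, for comparison with alpha.

Spike-in calibration divides the raw IP/input ratio track by a normalizer
computed from the spike-in reads alone -- the number of IP reads of the
target spike-in over the number of input reads of the target spike-in --
and multiplies by the mean fragment length <L> to report a "histone
modification density" (HMD) per fragment. The normalizer only reflects
the spike-in's own capture efficiency; it is blind to the composition of
the captured chromatin and saturates whenever antibody is in excess of
the spike-in, which makes the resulting scale insensitive to exactly the
perturbations it is meant to quantify. A spike-in scale is physically
meaningful only when the normalizer happens to equal 1/alpha, a condition
:func:`compare_normalizers` checks directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .alpha import AlphaResult
from .tracks import EfficiencyTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeCounts",
    "hmd_factor",
    "hmd_track",
    "compare_normalizers",
    "compare_conditions",
]


@dataclass
class SpikeCounts:
    """Read counts mapped to the spike-in species in IP and input samples."""

    ip_target_reads: float
    input_target_reads: float
    off_target: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ip_target_reads < 0 or self.input_target_reads < 0:
            raise ValueError("spike-in read counts must be >= 0")


def hmd_factor(counts: SpikeCounts) -> float:
    """The HMD normalizer: spike-in IP reads / spike-in input reads."""
    if counts.input_target_reads <= 0:
        raise ValueError("HMD normalizer undefined: zero spike-in input reads")
    if counts.ip_target_reads == 0:
        logger.warning("spike-in captured no IP reads; HMD factor is 0 and "
                       "the normalized track will be undefined")
    return counts.ip_target_reads / counts.input_target_reads


def hmd_track(raw_ratio_track: EfficiencyTrack, factor: float,
              mean_length: float) -> EfficiencyTrack:
    """Spike-in-normalized track: raw IP/input ratio / factor * <L>.

    Values may exceed 100% -- the normalizer carries no guarantee of
    staying on a physical efficiency scale.
    """
    if factor <= 0:
        raise ValueError("HMD factor must be > 0")
    scale = mean_length / factor
    return EfficiencyTrack(
        interval_width=raw_ratio_track.interval_width,
        values={c: v * scale for c, v in raw_ratio_track.values.items()},
        unit="hmd-per-fragment",
        mean_length=float(mean_length),
        weights={c: w.copy() for c, w in raw_ratio_track.weights.items()},
        flags={c: f.copy() for c, f in raw_ratio_track.flags.items()},
    )


def compare_normalizers(hmd: float, alpha: AlphaResult) -> dict:
    """Compare a spike-in normalizer with 1/alpha for the same experiment.

    The two agree (discrepancy 1) exactly when the spike-in scale is
    quantitative; any other value measures how far the spike-in scale is
    from the physical one.
    """
    return {
        "hmd_factor": hmd,
        "alpha_inverse": alpha.alpha_inverse,
        "discrepancy": alpha.alpha_inverse / hmd,
    }


def compare_conditions(hmd_a: float, hmd_b: float,
                       alpha_a: AlphaResult, alpha_b: AlphaResult,
                       labels: Optional[tuple] = None) -> dict:
    """Two-condition comparison of the implied material-difference ratios.

    The ratio of alphas between conditions is, by construction, the true
    material difference between the samples at the sequencer; the ratio of
    spike-in normalizers is what spike-in calibration *implies* that
    difference to be. Disagreement between the two ratios quantifies the
    spike-in sensitivity failure.
    """
    a, b = labels if labels else ("a", "b")
    report = {
        f"hmd_{a}": hmd_a,
        f"hmd_{b}": hmd_b,
        f"alpha_inverse_{a}": alpha_a.alpha_inverse,
        f"alpha_inverse_{b}": alpha_b.alpha_inverse,
        "hmd_ratio": hmd_b / hmd_a,
        "inverse_alpha_ratio": alpha_b.alpha_inverse / alpha_a.alpha_inverse,
        "alpha_ratio": alpha_b.alpha / alpha_a.alpha,
    }
    report["normalizer_disagreement"] = (report["hmd_ratio"]
                                         / report["inverse_alpha_ratio"])
    return report
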