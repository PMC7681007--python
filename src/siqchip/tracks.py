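"""Quantitative capture-efficiency genome tracks from fragment files.

The pipeline is: read paired-end fragments (BED-like intervals) for IP and
input, bin them in two dimensions over (genomic start-interval x, fragment
length L), form the 2D efficiency

    e(x, L) = alpha * IP(x, L) / input(x, L)

with a zero rule -- a bin is evaluated to 0 whenever either sample has no
fragments there (and flagged when IP has counts but input does not, the
symptom of a too-small interval) -- then project over L to a 1D browser
track. The projection is the input-count-weighted mean over length bins,
which preserves the per-base interpretation, collapses exactly to the
plain 1D count ratio, and reduces to the scalar ratio when all fragments
share one length. Multiplying by the mean fragment length <L> converts
per-base efficiency to per-fragment units.

Coordinates are 0-based half-open throughout (BED/bedGraph dialect); a
fragment is assigned to an x-bin by its start only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alpha import AlphaResult

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "Track2D",
    "Efficiency2D",
    "EfficiencyTrack",
    "GeometryError",
    "read_fragments",
    "bin2d",
    "efficiency2d",
    "project1d",
    "efficiency_profile",
    "stabilize_width",
    "StabilizeResult",
    "differential",
    "write_bedgraph",
    "read_bedgraph",
]


class GeometryError(ValueError):
    """Two tracks do not share binning geometry."""


@dataclass
class FragmentSet:
    """Mapped fragments: chromosome, 0-based start, length in bp."""

    chroms: np.ndarray
    starts: np.ndarray
    lengths: np.ndarray
    skipped: int = 0

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.lengths)):
            raise ValueError("chroms/starts/lengths must be aligned")
        if len(self.starts) and (self.starts.min() < 0 or self.lengths.min() <= 0):
            raise ValueError("starts must be >= 0 and lengths > 0")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def mean_length(self) -> float:
        """<L>, the mean fragment length of this sample."""
        if len(self) == 0:
            raise ValueError("mean length of an empty fragment set")
        return float(self.lengths.mean())

    def chromosomes(self) -> list:
        return sorted(set(self.chroms.tolist()))


def read_fragments(path, constant_length: Optional[int] = None) -> FragmentSet:
    """Read a 3+-column BED-like fragment file.

    Each line is ``chrom start end`` (0-based half-open); fragment length
    is ``end - start``. For single-end data pass ``constant_length`` and
    every fragment is assigned that length regardless of its end
    coordinate. Lines with ``end <= start`` are skipped and counted;
    structurally malformed lines raise with their line number.
    """
    chroms, starts, lengths = [], [], []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            if constant_length is None and end <= start:
                skipped += 1
                continue
            chroms.append(fields[0])
            starts.append(start)
            lengths.append(constant_length if constant_length is not None
                           else end - start)
    if skipped:
        logger.warning("%s: skipped %d fragments with end <= start", path, skipped)
    if not chroms:
        logger.warning("%s: no fragments read", path)
    return FragmentSet(np.array(chroms, dtype=object),
                       np.array(starts, dtype=np.int64),
                       np.array(lengths, dtype=np.int64),
                       skipped=skipped)


@dataclass
class Track2D:
    """Counts binned over (x-interval, fragment-length) per chromosome.

    ``data[chrom]`` has shape (n x-bins, n L-bins); the L-bin axis is
    shared across chromosomes.
    """

    interval_width: int
    length_bin_width: int
    data: dict = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def marginal_x(self, chrom: str) -> np.ndarray:
        return self.data[chrom].sum(axis=1)


def bin2d(fragments: FragmentSet, interval_width: int,
          length_bin_width: int) -> Track2D:
    """Histogram fragments into (x-bin, L-bin) counts.

    A fragment lands in x-bin floor(start / interval_width) on its
    chromosome and L-bin floor(L / length_bin_width). Total count is
    conserved exactly.
    """
    if interval_width <= 0 or length_bin_width <= 0:
        raise ValueError("bin widths must be positive")
    track = Track2D(interval_width=int(interval_width),
                    length_bin_width=int(length_bin_width))
    if len(fragments) == 0:
        return track
    n_l = int(fragments.lengths.max() // length_bin_width) + 1
    lbins = fragments.lengths // length_bin_width
    xbins = fragments.starts // interval_width
    for chrom in fragments.chromosomes():
        sel = fragments.chroms == chrom
        xb = xbins[sel]
        arr = np.zeros((int(xb.max()) + 1, n_l), dtype=np.int64)
        np.add.at(arr, (xb, lbins[sel]), 1)
        track.data[chrom] = arr
    return track


def _pad(arr: np.ndarray, nx: int, nl: int) -> np.ndarray:
    out = np.zeros((nx, nl), dtype=arr.dtype)
    out[: arr.shape[0], : arr.shape[1]] = arr
    return out


@dataclass
class Efficiency2D:
    """2D efficiency e(x, L) with the count tracks it was built from.

    ``flags`` marks bins where the IP had fragments but the input had
    none -- the diagnostic symptom of a too-small interval width. The
    input counts are retained because the 1D projection weights by them.
    """

    interval_width: int
    length_bin_width: int
    values: dict = field(default_factory=dict)
    ip_counts: dict = field(default_factory=dict)
    input_counts: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def _alpha_scale(alpha) -> float:
    if isinstance(alpha, AlphaResult):
        return alpha.alpha
    return float(alpha)


def efficiency2d(ip: Track2D, input: Track2D, alpha) -> Efficiency2D:
    """e(x, L) = alpha * IP(x, L) / input(x, L), zero where either is empty.

    The chromosome universe is the union of both samples; bins absent
    from one sample are zero-filled (and therefore evaluate to 0 under
    the zero rule). ``alpha`` may be an :class:`AlphaResult` or a bare
    scale.
    """
    if (ip.interval_width != input.interval_width
            or ip.length_bin_width != input.length_bin_width):
        raise GeometryError(
            f"mismatched binning: IP ({ip.interval_width}, {ip.length_bin_width})"
            f" vs input ({input.interval_width}, {input.length_bin_width})")
    a = _alpha_scale(alpha)
    out = Efficiency2D(interval_width=ip.interval_width,
                       length_bin_width=ip.length_bin_width)
    chroms = sorted(set(ip.data) | set(input.data))
    n_l = max([arr.shape[1] for t in (ip, input) for arr in t.data.values()],
              default=1)
    for chrom in chroms:
        shapes = [t.data[chrom].shape[0] for t in (ip, input) if chrom in t.data]
        nx = max(shapes)
        ipc = _pad(ip.data.get(chrom, np.zeros((0, n_l), dtype=np.int64)), nx, n_l)
        inc = _pad(input.data.get(chrom, np.zeros((0, n_l), dtype=np.int64)),
                   nx, n_l)
        both = (ipc > 0) & (inc > 0)
        vals = np.zeros((nx, n_l), dtype=float)
        np.divide(a * ipc, inc, out=vals, where=both)
        out.values[chrom] = vals
        out.ip_counts[chrom] = ipc
        out.input_counts[chrom] = inc
        out.flags[chrom] = (ipc > 0) & (inc == 0)
    return out


@dataclass
class EfficiencyTrack:
    """1D siQ efficiency track e(x), per-base or per-fragment units.

    ``weights`` holds the per-bin input fragment counts used in the L
    projection; ``flags`` marks bins where one sample had coverage and the
    other did not.
    """

    interval_width: int
    values: dict = field(default_factory=dict)
    unit: str = "per-base"
    mean_length: Optional[float] = None
    weights: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def per_fragment(self, mean_length: Optional[float] = None) -> "EfficiencyTrack":
        """Convert per-base efficiency to per-fragment units: e(x) * <L>."""
        if self.unit != "per-base":
            raise ValueError(f"cannot rescale a {self.unit!r} track")
        L = mean_length if mean_length is not None else self.mean_length
        if L is None:
            raise ValueError("mean fragment length <L> is required")
        return EfficiencyTrack(
            interval_width=self.interval_width,
            values={c: v * L for c, v in self.values.items()},
            unit="per-fragment",
            mean_length=float(L),
            weights={c: w.copy() for c, w in self.weights.items()},
            flags={c: f.copy() for c, f in self.flags.items()},
        )


def project1d(e2d: Efficiency2D, unit: str = "per-base",
              mean_length: Optional[float] = None) -> EfficiencyTrack:
    """Collapse the L axis by input-count-weighted mean of e(x, L).

    With weights equal to the input counts the projection collapses to
    alpha * IP(x) / input(x) over bins obeying the zero rule, so no extra
    estimator bias is introduced. ``unit='per-fragment'`` additionally
    multiplies by ``mean_length`` (<L>, conventionally taken from the IP
    sample).
    """
    track = EfficiencyTrack(interval_width=e2d.interval_width,
                            mean_length=mean_length)
    for chrom, vals in e2d.values.items():
        w = e2d.input_counts[chrom].astype(float)
        wsum = w.sum(axis=1)
        num = (vals * w).sum(axis=1)
        out = np.divide(num, wsum, out=np.zeros_like(num), where=wsum > 0)
        track.values[chrom] = out
        track.weights[chrom] = wsum
        ip1 = e2d.ip_counts[chrom].sum(axis=1)
        track.flags[chrom] = (ip1 > 0) != (wsum > 0)
    if unit == "per-fragment":
        return track.per_fragment(mean_length)
    if unit != "per-base":
        raise ValueError(f"unknown unit {unit!r}")
    return track


def efficiency_profile(ip: FragmentSet, input: FragmentSet, alpha,
                       interval_width: int,
                       length_bin_width: int = 10) -> EfficiencyTrack:
    """Full fragment-to-track path at one interval width (per-base units)."""
    e2d = efficiency2d(bin2d(ip, interval_width, length_bin_width),
                       bin2d(input, interval_width, length_bin_width), alpha)
    track = project1d(e2d)
    if len(ip):
        track.mean_length = ip.mean_length
    return track


@dataclass
class StabilizeResult:
    """Chosen interval width plus per-width convergence diagnostics."""

    width: int
    converged: bool
    diagnostics: pd.DataFrame


def _zero_flag_fraction(track: EfficiencyTrack) -> float:
    flagged = occupied = 0
    for chrom in track.values:
        w = track.weights[chrom]
        f = track.flags[chrom]
        occ = (w > 0) | f
        occupied += int(occ.sum())
        flagged += int(f.sum())
    return flagged / occupied if occupied else 0.0


def _coarsen(track: EfficiencyTrack, width: int) -> dict:
    """Resample a fine track onto a coarser grid.

    A fine bin is assigned to the coarse bin containing its start (the
    same start rule used for fragments) and the coarse value is the plain
    mean over data-bearing fine bins. Weighting by counts would make the
    comparison telescope to an exact identity; the unweighted mean keeps
    it sensitive to the zero-evaluated bins and ratio scatter that signal
    a too-small interval.
    """
    out = {}
    for chrom, vals in track.values.items():
        occupied = (track.weights[chrom] > 0) | track.flags[chrom]
        idx = (np.arange(len(vals)) * track.interval_width) // width
        n = int(idx.max()) + 1 if len(vals) else 0
        num = np.bincount(idx, weights=vals * occupied, minlength=n)
        den = np.bincount(idx, weights=occupied.astype(float), minlength=n)
        out[chrom] = (np.divide(num, den, out=np.zeros_like(num),
                                where=den > 0), den)
    return out


def _dissimilarity(fine: EfficiencyTrack, coarse: EfficiencyTrack) -> float:
    """Mean absolute relative difference after resampling to the coarse grid."""
    resampled = _coarsen(fine, coarse.interval_width)
    diffs = []
    for chrom, (rv, rn) in resampled.items():
        if chrom not in coarse.values:
            continue
        cv = coarse.values[chrom]
        n = min(len(rv), len(cv))
        a, b = rv[:n], cv[:n]
        ok = (rn[:n] > 0) & (b > 0)
        if ok.any():
            diffs.append(np.abs(a[ok] - b[ok]) / (0.5 * (a[ok] + b[ok])))
    if not diffs:
        return math.nan
    return float(np.mean(np.concatenate(diffs)))


def stabilize_width(ip: FragmentSet, input: FragmentSet, alpha,
                    widths: Sequence[int], criterion: float = 0.05,
                    length_bin_width: int = 10) -> StabilizeResult:
    """Find the smallest interval width at which the track stops changing.

    Tracks are built at each width of the increasing grid; consecutive
    widths are compared after resampling the finer track onto the coarser
    grid. The chosen width is the smallest one whose dissimilarity to the
    next width is <= ``criterion``; if none converges the largest width is
    returned with ``converged=False``. The fraction of zero-flagged bins
    at each width is reported as a sparsity diagnostic.
    """
    widths = list(widths)
    if len(widths) < 2 or any(b <= a for a, b in zip(widths, widths[1:])):
        raise ValueError("widths must be an increasing list with >= 2 entries")
    tracks = [efficiency_profile(ip, input, alpha, w, length_bin_width)
              for w in widths]
    rows = []
    chosen, converged = None, False
    for i, w in enumerate(widths):
        d = (_dissimilarity(tracks[i], tracks[i + 1])
             if i + 1 < len(widths) else math.nan)
        rows.append({"width": w,
                     "zero_flag_fraction": _zero_flag_fraction(tracks[i]),
                     "dissimilarity_to_next": d})
        if chosen is None and not math.isnan(d) and d <= criterion:
            chosen, converged = w, True
    if chosen is None:
        chosen = widths[-1]
        logger.warning("no interval width converged at criterion %.3g; "
                       "returning largest width %d", criterion, chosen)
    return StabilizeResult(width=chosen, converged=converged,
                           diagnostics=pd.DataFrame(rows))


def differential(treatment: EfficiencyTrack,
                 control: EfficiencyTrack) -> EfficiencyTrack:
    """Per-bin treatment/control efficiency ratio.

    Bins where either track is zero are emitted as missing (NaN), never 0
    or infinity, so genome browsers do not render false depletion.
    """
    if treatment.interval_width != control.interval_width:
        raise GeometryError(
            f"mismatched interval widths: {treatment.interval_width} vs "
            f"{control.interval_width}")
    out = EfficiencyTrack(interval_width=treatment.interval_width, unit="ratio")
    for chrom in sorted(set(treatment.values) | set(control.values)):
        t = treatment.values.get(chrom)
        c = control.values.get(chrom)
        if t is None or c is None:
            n = len(t) if t is not None else len(c)
            out.values[chrom] = np.full(n, np.nan)
            continue
        n = max(len(t), len(c))
        tv = np.zeros(n); tv[: len(t)] = t
        cv = np.zeros(n); cv[: len(c)] = c
        vals = np.full(n, np.nan)
        ok = (tv > 0) & (cv > 0)
        vals[ok] = tv[ok] / cv[ok]
        out.values[chrom] = vals
    return out


def write_bedgraph(track: EfficiencyTrack, path, merge: bool = False) -> None:
    """Write a 4-column bedGraph (chrom, start, end, value), 0-based half-open.

    Zero and missing (NaN) bins are omitted, which keeps sparse genome
    tracks compact; with ``merge=True`` runs of adjacent equal-valued bins
    are collapsed into single records.
    """
    w = track.interval_width
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            run_start, run_val = None, None
            for b, v in enumerate(vals):
                keep = np.isfinite(v) and v != 0
                text = f"{v:.6g}" if keep else None
                if merge and text is not None and text == run_val:
                    continue
                if merge and run_val is not None:
                    fh.write(f"{chrom}\t{run_start}\t{b * w}\t{run_val}\n")
                    run_start = run_val = None
                if not keep:
                    continue
                if merge:
                    run_start, run_val = b * w, text
                else:
                    fh.write(f"{chrom}\t{b * w}\t{(b + 1) * w}\t{text}\n")
            if merge and run_val is not None:
                fh.write(f"{chrom}\t{run_start}\t{len(vals) * w}\t{run_val}\n")


def read_bedgraph(path, interval_width: Optional[int] = None) -> EfficiencyTrack:
    """Read a bedGraph written by :func:`write_bedgraph` back into a track."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            records.append((chrom, int(start), int(end), float(value)))
    if interval_width is None:
        if not records:
            raise ValueError(f"{path}: empty bedGraph and no interval_width given")
        interval_width = min(end - start for _, start, end, _ in records)
    track = EfficiencyTrack(interval_width=interval_width)
    by_chrom: dict = {}
    for chrom, start, end, value in records:
        by_chrom.setdefault(chrom, []).append((start, end, value))
    for chrom, recs in by_chrom.items():
        n = max(end for _, end, _ in recs) // interval_width
        vals = np.zeros(n)
        for start, end, value in recs:
            vals[start // interval_width: -(-end // interval_width)] = value
        track.values[chrom] = vals
    return track
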