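"""Read-depth copy-number pipeline: depth, diploid normalization, smoothing,
integer-level segmentation.

Depth is computed on the collapsed haploid reference, so a locus present at
``c`` copies across both homologues (plus any episomes) shows ``c/2`` times
the diploid depth.  Copy number is normalized so that the mean over the
un-masked genome equals 2, then smoothed with a centered sliding window
(default 1,500 nt; 5,000 nt for coarser views) and segmented into maximal
runs of constant integer level.

Because the normalizing mean includes the amplified material itself, the
raw normalized level is biased low whenever the amplified fraction of the
genome is non-negligible (on small simulated genomes it always is).  The
segmenter therefore re-anchors the diploid baseline on the genome-wide
*median* copy number before integer rounding — the usual CNV-caller
re-centering step — which makes integer-level recovery independent of the
amplified fraction as long as most of the genome is unamplified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mapping import (
    STATUS_AMBIGUOUS,
    STATUS_CLIPPED,
    STATUS_UNIQUE,
    AlignmentSet,
    ReferenceIndex,
)

DEFAULT_WINDOW = 1500
COARSE_WINDOW = 5000


@dataclass
class CoverageProfile:
    """Per-chromosome depth and normalized copy-number arrays."""

    index: ReferenceIndex
    depth: dict[str, np.ndarray]
    cn: dict[str, np.ndarray] | None = None
    cn_smooth: dict[str, np.ndarray] | None = None
    mask: dict[str, np.ndarray] | None = None  # True = masked (repeat regions)
    mean_depth: float = 0.0
    window: int = 1

    @property
    def chroms(self) -> list[str]:
        return list(self.depth)

    def masked_fraction(self) -> float:
        if self.mask is None:
            return 0.0
        total = sum(arr.size for arr in self.depth.values())
        masked = sum(int(m.sum()) for m in self.mask.values())
        return masked / total


@dataclass(frozen=True)
class SegmentCall:
    """A maximal constant-integer-copy-level interval."""

    chrom: str
    start: int
    end: int
    level: int
    mean_cn: float
    boundary_uncertainty: int

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("copy level must be >= 0")
        if not self.start < self.end:
            raise ValueError("empty segment")

    @property
    def extra(self) -> int:
        return self.level - 2

    @property
    def length(self) -> int:
        return self.end - self.start


def compute_depth(alignments: AlignmentSet, index: ReferenceIndex | None = None) -> CoverageProfile:
    """Per-position depth from unique + ambiguous + clipped alignments.

    Ambiguous reads count once at their lowest-coordinate placement;
    clipped reads contribute over their mapped span only.
    """
    index = index or alignments.index
    total_len = int(index.chrom_starts[-1])
    diff = np.zeros(total_len + 1, dtype=np.int64)
    keep = (
        (alignments.status == STATUS_UNIQUE)
        | (alignments.status == STATUS_AMBIGUOUS)
        | (alignments.status == STATUS_CLIPPED)
    )
    starts = alignments.gpos[keep]
    ends = starts + alignments.span[keep]
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends, -1)
    flat = np.cumsum(diff[:-1]).astype(np.float64)
    depth = {}
    for ci, c in enumerate(index.chroms):
        depth[c] = flat[index.chrom_starts[ci] : index.chrom_starts[ci + 1]]
    mean_depth = float(flat.mean()) if total_len else 0.0
    return CoverageProfile(index=index, depth=depth, mean_depth=mean_depth)


def normalize_cn(
    profile: CoverageProfile, mask: dict[str, list[tuple[int, int]]] | None = None
) -> CoverageProfile:
    """cn(x) = 2 d(x) / m with m the mean depth over un-masked positions.

    Masked positions keep their cn value but are flagged; the mean of cn
    over the un-masked genome is exactly 2 afterwards.
    """
    masks = {}
    for c, d in profile.depth.items():
        m = np.zeros(d.size, dtype=bool)
        if mask and c in mask:
            for s, e in mask[c]:
                m[s:e] = True
        masks[c] = m
    n_unmasked = sum(int((~m).sum()) for m in masks.values())
    if n_unmasked == 0:
        raise ValueError("entire genome is masked; cannot normalize")
    total = sum(float(d[~masks[c]].sum()) for c, d in profile.depth.items())
    mean = total / n_unmasked
    if mean <= 0:
        raise ValueError("mean depth over the un-masked genome is zero")
    cn = {c: 2.0 * d / mean for c, d in profile.depth.items()}
    return replace(profile, cn=cn, mask=masks, mean_depth=mean)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    # centered, with edge truncation (shorter effective windows at the ends)
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def smooth_profile(profile: CoverageProfile, window: int = DEFAULT_WINDOW) -> CoverageProfile:
    """Centered moving average of cn; the window is odd-ized internally."""
    if profile.cn is None:
        raise ValueError("normalize before smoothing")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    for c, arr in profile.cn.items():
        if window > arr.size:
            raise ValueError(f"window {window} exceeds chromosome {c} length {arr.size}")
    sm = {c: _moving_average(arr, window) for c, arr in profile.cn.items()}
    return replace(profile, cn_smooth=sm, window=window)


def _runs(levels: np.ndarray) -> list[list[int]]:
    """[start, end, level] runs of a piecewise-constant integer array."""
    if levels.size == 0:
        return []
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [levels.size]])
    return [[int(s), int(e), int(levels[s])] for s, e in zip(starts, ends)]


def _absorb_short_runs(runs: list[list[int]], min_segment: int) -> list[list[int]]:
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        lengths = [r[1] - r[0] for r in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= min_segment:
            break
        # merge into the neighbour with the closer level (longer one on ties)
        cands = []
        if shortest > 0:
            cands.append(shortest - 1)
        if shortest < len(runs) - 1:
            cands.append(shortest + 1)
        lvl = runs[shortest][2]
        best = min(
            cands,
            key=lambda j: (abs(runs[j][2] - lvl), -(runs[j][1] - runs[j][0])),
        )
        a, b = sorted((shortest, best))
        runs[a] = [runs[a][0], runs[b][1], runs[best][2]]
        del runs[b]
        # merge equal-level neighbours created by the absorption
        merged = [runs[0]]
        for r in runs[1:]:
            if r[2] == merged[-1][2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        runs = merged
    return runs


def _refine_boundary(raw: np.ndarray, pos: int, window: int) -> int:
    """Step-position estimate: split point minimizing two-means SSE near pos."""
    lo = max(pos - window, 1)
    hi = min(pos + window, raw.size - 1)
    if hi <= lo:
        return pos
    x = raw[lo - 1 : hi + 1].astype(np.float64)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    n = x.size
    best_k, best_sse = None, np.inf
    for k in range(1, n):
        sl, sl2 = cs[k], cs2[k]
        sr, sr2 = cs[n] - cs[k], cs2[n] - cs2[k]
        sse = (sl2 - sl * sl / k) + (sr2 - sr * sr / (n - k))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return lo - 1 + best_k


def segment_cn(
    profile: CoverageProfile,
    min_segment: int = 5000,
    recenter: bool = True,
) -> list[SegmentCall]:
    """Integer-level run-length segmentation with median refinement.

    Smoothed cn is rounded to the nearest integer level; runs shorter than
    ``min_segment`` are absorbed into their closest-level neighbour (this
    also removes the sub-window ramps smoothing creates at step edges, so
    same-level runs separated by less than ~2 windows coalesce); boundaries
    are refined to the raw-profile step position within one window; each
    segment's level is recomputed as the rounded median of raw cn.
    """
    if profile.cn_smooth is None:
        raise ValueError("smooth before segmenting")
    factor = 1.0
    if recenter:
        # two-pass diploid re-anchoring: a plain median over the genome sits
        # at a shifted quantile of the baseline when a large fraction is
        # amplified, so refine against the modal integer level
        smoothed = np.concatenate(
            [
                profile.cn_smooth[c][~profile.mask[c]]
                if profile.mask
                else profile.cn_smooth[c]
                for c in profile.chroms
            ]
        )
        med = float(np.median(smoothed))
        if med > 0:
            f1 = 2.0 / med
            levels0 = np.rint(smoothed * f1)
            vals, counts = np.unique(levels0, return_counts=True)
            mode = vals[int(np.argmax(counts))]
            # the modal level is the diploid baseline; pin its median at 2
            baseline = smoothed[levels0 == mode]
            base_med = float(np.median(baseline))
            factor = 2.0 / base_med if base_med > 0 else f1
    calls: list[SegmentCall] = []
    for c in profile.chroms:
        raw = profile.cn[c] * factor
        sm = profile.cn_smooth[c] * factor
        levels = np.rint(sm).astype(np.int64)
        levels[levels < 0] = 0
        runs = _absorb_short_runs(_runs(levels), min_segment)
        # refine interior boundaries on the raw profile
        bounds = [0]
        for left, right in zip(runs, runs[1:]):
            bounds.append(_refine_boundary(raw, left[1], profile.window))
        bounds.append(raw.size)
        refined = []
        for (s, e), run in zip(zip(bounds, bounds[1:]), runs):
            if e <= s:
                continue
            level = int(np.rint(np.median(raw[s:e])))
            refined.append([s, e, max(level, 0)])
        # medians may re-merge neighbours
        merged = [refined[0]]
        for r in refined[1:]:
            if r[2] == merged[-1][2]:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        for s, e, lvl in merged:
            calls.append(
                SegmentCall(
                    chrom=c,
                    start=s,
                    end=e,
                    level=lvl,
                    mean_cn=float(np.mean(raw[s:e])),
                    boundary_uncertainty=profile.window,
                )
            )
    return calls
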