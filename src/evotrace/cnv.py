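"""Copy-number calling from binned read-depth tracks.

Reads are accumulated in 500-bp bins, bins with fewer than 10 reads are
rejected, per-bin log2 ratios are taken against the genome-wide median bin
count (the diploid expectation), and chromosomes are segmented by recursive
binary splitting with a Welch t-test at a very conservative significance
threshold (circular-binary-segmentation style), with 5% of the most extreme
bins per chromosome excluded from breakpoint evidence. Segments are called
gain/loss at mean log2 ratio +/-0.25 and additionally labelled against the
display bands (0.23..0.58 gain, -1..-0.23 loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthTrack", "Log2Track", "CNVSegment",
    "bin_and_mask", "log2_ratio", "segment", "call_segments",
    "summarize_recurrence", "segments_to_bed",
    "GAIN_LIMIT", "LOSS_LIMIT", "GAIN_BAND", "LOSS_BAND",
]

GAIN_LIMIT = 0.25
LOSS_LIMIT = -0.25
GAIN_BAND = (0.23, 0.58)
LOSS_BAND = (-1.0, -0.23)


@dataclass
class DepthTrack:
    """Binned read counts for one sample; bins 0-based half-open."""
    bins: pd.DataFrame   # chromosome, start, end, count, masked
    bin_size: int
    sample: str = ""
    ploidy: int = 2


@dataclass
class Log2Track:
    """Per-bin log2(observed/expected-diploid); masked bins carry NaN."""
    bins: pd.DataFrame   # chromosome, start, end, count, masked, log2
    baseline: float
    bin_size: int
    sample: str = ""


@dataclass
class CNVSegment:
    chromosome: str
    start: int
    end: int
    n_bins: int
    mean_log2: float
    call: str = "neutral"        # gain | loss | neutral
    band: str = "outside"        # within-gain-band | within-loss-band | outside


def bin_and_mask(depths: pd.DataFrame, bin_size: int = 500,
                 min_reads: int = 10, sample: str = "",
                 ploidy: int = 2) -> DepthTrack:
    """Aggregate counts to fixed bins and mask bins with < ``min_reads``.

    ``depths`` carries ``chromosome, start, end, count`` (0-based half-open);
    rows may be per-base (end = start+1) or pre-binned. Pre-binned rows must
    not overlap.
    """
    d = depths.sort_values(["chromosome", "start"]).reset_index(drop=True)
    for chrom, sub in d.groupby("chromosome", sort=False):
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping input bins on {chrom}")
    frames = []
    for chrom, sub in d.groupby("chromosome", sort=False):
        b = (sub["start"] // bin_size).to_numpy()
        counts = sub.groupby(b)["count"].sum()
        idx = np.arange(counts.index.min(), counts.index.max() + 1)
        counts = counts.reindex(idx, fill_value=0)
        frames.append(pd.DataFrame({
            "chromosome": chrom,
            "start": idx * bin_size,
            "end": (idx + 1) * bin_size,
            "count": counts.to_numpy(),
        }))
    bins = pd.concat(frames, ignore_index=True)
    bins["masked"] = bins["count"] < min_reads
    return DepthTrack(bins=bins, bin_size=bin_size, sample=sample, ploidy=ploidy)


def log2_ratio(track: DepthTrack, baseline: float | None = None) -> Log2Track:
    """log2 of each unmasked bin count over the diploid-expected baseline
    (genome-wide median of unmasked bins by default, rescaled by
    ploidy/2 when the assumed ploidy differs from diploid)."""
    bins = track.bins.copy()
    unmasked = bins.loc[~bins["masked"], "count"]
    if unmasked.empty:
        raise ValueError("all bins are masked")
    if baseline is None:
        baseline = float(np.median(unmasked)) * track.ploidy / 2.0
    bins["log2"] = np.where(~bins["masked"] & (bins["count"] > 0),
                            np.log2(bins["count"] / baseline), np.nan)
    bins.loc[bins["masked"], "log2"] = np.nan
    return Log2Track(bins=bins, baseline=baseline, bin_size=track.bin_size,
                     sample=track.sample)


def _welch_stat(n1, s1, q1, n2, s2, q2):
    """Welch t and df from group counts, sums and sums of squares."""
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum(0.0, (q1 - n1 * m1 ** 2) / (n1 - 1))
    v2 = np.maximum(0.0, (q2 - n2 * m2 ** 2) / (n2 - 1))
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se2 > 0, (m1 - m2) / np.sqrt(np.where(se2 > 0, se2, 1.0)),
                     np.where(np.isclose(m1, m2, rtol=0.0, atol=1e-10),
                              0.0, np.inf) * np.sign(m1 - m2 + 0.0))
        df = np.where(se2 > 0,
                      se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                                  + (v2 / n2) ** 2 / (n2 - 1)), 1.0)
    return t, df


def _cbs_best(x: np.ndarray, evidence: np.ndarray,
              min_bins: int) -> tuple[int, int, float]:
    """Most significant interior segment [i, j) against the rest of the
    window (circular-binary-segmentation scan). Every candidate pair is
    scored by its Welch p-value over evidence bins; returns (i, j, p), or
    (0, len(x), 1.0) when nothing is testable."""
    n = len(x)
    xe = np.where(evidence, x, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(xe)])
    cs2 = np.concatenate([[0.0], np.cumsum(xe ** 2)])
    cn = np.concatenate([[0], np.cumsum(evidence.astype(np.int64))])
    tot_s, tot_s2, tot_n = cs[n], cs2[n], cn[n]
    best = (0, n, 1.0)
    buf_i, buf_j, buf_t, buf_df = [], [], [], []

    def flush():
        nonlocal best
        if not buf_i:
            return
        t = np.abs(np.concatenate(buf_t))
        df = np.concatenate(buf_df)
        ii = np.concatenate(buf_i)
        jj = np.concatenate(buf_j)
        buf_i.clear(); buf_j.clear(); buf_t.clear(); buf_df.clear()
        with np.errstate(invalid="ignore"):
            p = np.where(np.isinf(t), 0.0,
                         2.0 * stats.t.sf(np.where(np.isinf(t), 1.0, t), df))
        p = np.nan_to_num(p, nan=1.0)
        k = int(np.argmin(p))
        if p[k] < best[2]:
            best = (int(ii[k]), int(jj[k]), float(p[k]))

    # left flank is empty or >= min_bins; same for the right flank
    for i in [0] + list(range(min_bins, n - min_bins + 1)):
        j = np.arange(i + min_bins, n + 1)
        j = j[(j == n) | (j <= n - min_bins)]
        if i == 0:
            j = j[j < n]          # (0, n) is not a split
        if len(j) == 0:
            continue
        n1 = (cn[j] - cn[i]).astype(float)
        n2 = tot_n - n1
        ok = (n1 >= 2) & (n2 >= 2)
        if not ok.any():
            continue
        j, n1, n2 = j[ok], n1[ok], n2[ok]
        s1 = cs[j] - cs[i]
        q1 = cs2[j] - cs2[i]
        t, df = _welch_stat(n1, s1, q1, n2, tot_s - s1, tot_s2 - q1)
        buf_i.append(np.full(len(j), i))
        buf_j.append(j)
        buf_t.append(t)
        buf_df.append(df)
        if sum(len(b) for b in buf_t) >= 1 << 16:
            flush()
    flush()
    return best


def _segment_chromosome(values: np.ndarray, evidence: np.ndarray,
                        min_bins: int, alpha: float) -> list[tuple[int, int]]:
    """Recursive segmentation via the CBS scan; returns half-open ranges."""
    segs: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2 * min_bins:
            segs.append((lo, hi))
            return
        i, j, p = _cbs_best(values[lo:hi], evidence[lo:hi], min_bins)
        if p >= alpha or (i == 0 and j == hi - lo):
            segs.append((lo, hi))
            return
        for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
            if b > a:
                recurse(a, b)

    recurse(0, len(values))
    segs.sort()
    segs = _merge_segments(values, evidence, segs, alpha)
    return _refine_boundaries(values, segs, min_bins)


def _merge_segments(values: np.ndarray, evidence: np.ndarray,
                    segs: list[tuple[int, int]],
                    alpha: float) -> list[tuple[int, int]]:
    """Merge adjacent segments whose means do not differ at ``alpha``:
    the recursive scan can carve one event into several pieces."""
    segs = list(segs)
    while len(segs) > 1:
        worst_p, worst_k = -1.0, None
        for k in range(len(segs) - 1):
            (a, b), (c, d) = segs[k], segs[k + 1]
            g1 = values[a:b][evidence[a:b]]
            g2 = values[c:d][evidence[c:d]]
            if len(g1) < 2 or len(g2) < 2:
                p = 1.0
            else:
                t, df = _welch_stat(
                    np.array(float(len(g1))), g1.sum(), (g1 ** 2).sum(),
                    np.array(float(len(g2))), g2.sum(), (g2 ** 2).sum())
                p = (0.0 if np.isinf(t) else
                     float(2.0 * stats.t.sf(abs(float(t)), float(df))))
            if p > worst_p:
                worst_p, worst_k = p, k
        if worst_p < alpha:
            break
        a, _ = segs[worst_k]
        _, d = segs.pop(worst_k + 1)
        segs[worst_k] = (a, d)
    return segs


def _refine_boundaries(values: np.ndarray, segs: list[tuple[int, int]],
                       min_bins: int, n_passes: int = 2) -> list[tuple[int, int]]:
    """Re-locate each breakpoint at the least-squares optimum of the local
    two-mean model; recursion can misplace boundaries by a few bins when the
    initial split lands inside an event."""
    segs = list(segs)
    for _ in range(n_passes):
        moved = False
        for j in range(len(segs) - 1):
            lo, _ = segs[j]
            _, hi = segs[j + 1]
            x = values[lo:hi]
            n = len(x)
            if n < 2 * min_bins:
                continue
            cs = np.cumsum(x)
            cs2 = np.cumsum(x ** 2)
            idx = np.arange(min_bins, n - min_bins + 1)
            nl = idx.astype(float)
            nr = n - nl
            sl = cs[idx - 1]
            sse = ((cs2[-1] - 0)                       # total sum of squares
                   - sl ** 2 / nl - (cs[-1] - sl) ** 2 / nr)
            best = int(idx[np.argmin(sse)]) + lo
            if best != segs[j][1]:
                segs[j] = (segs[j][0], best)
                segs[j + 1] = (best, segs[j + 1][1])
                moved = True
        if not moved:
            break
    return segs


def segment(track: Log2Track, min_bins: int = 5, alpha: float = 1e-9,
            outlier_pct: float = 5.0) -> list[CNVSegment]:
    """Segment each chromosome's unmasked log2 track.

    The most extreme ``outlier_pct`` of bins per chromosome (half per tail)
    are excluded from breakpoint evidence but still belong to, and are
    averaged into, their segment. Chromosomes with fewer than ``2*min_bins``
    unmasked bins come back as a single neutral segment.
    """
    out: list[CNVSegment] = []
    for chrom, sub in track.bins.groupby("chromosome", sort=False):
        sub = sub[~sub["masked"] & sub["log2"].notna()]
        if sub.empty:
            continue
        x = sub["log2"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(x) < 2 * min_bins:
            out.append(CNVSegment(chrom, int(starts[0]), int(ends[-1]),
                                  len(x), float(np.mean(x))))
            continue
        lo_q, hi_q = np.percentile(x, [outlier_pct / 2, 100 - outlier_pct / 2])
        evidence = (x >= lo_q) & (x <= hi_q)
        for lo, hi in _segment_chromosome(x, evidence, min_bins, alpha):
            out.append(CNVSegment(chrom, int(starts[lo]), int(ends[hi - 1]),
                                  hi - lo, float(np.mean(x[lo:hi]))))
    return out


def call_segments(segments: list[CNVSegment], gain: float = GAIN_LIMIT,
                  loss: float = LOSS_LIMIT,
                  gain_band: tuple[float, float] = GAIN_BAND,
                  loss_band: tuple[float, float] = LOSS_BAND,
                  min_bins: int = 5) -> list[CNVSegment]:
    """Assign gain/loss calls at the mean-log2 limits and, independently,
    the display-band labels."""
    for seg in segments:
        if seg.n_bins >= min_bins and seg.mean_log2 >= gain:
            seg.call = "gain"
        elif seg.n_bins >= min_bins and seg.mean_log2 <= loss:
            seg.call = "loss"
        else:
            seg.call = "neutral"
        if gain_band[0] <= seg.mean_log2 <= gain_band[1]:
            seg.band = "within-gain-band"
        elif loss_band[0] <= seg.mean_log2 <= loss_band[1]:
            seg.band = "within-loss-band"
        else:
            seg.band = "outside"
    return segments


def summarize_recurrence(per_clone: dict[str, list[CNVSegment]],
                         chrom_lengths: dict[str, int],
                         bin_size: int = 500,
                         aneuploidy_fraction: float = 0.9) -> pd.DataFrame:
    """Per-bin fraction of clones carrying a non-neutral call, plus a
    whole-chromosome aneuploidy flag per clone when >= ``aneuploidy_fraction``
    of a chromosome's bins share one non-neutral call."""
    if not per_clone:
        raise ValueError("need at least one clone")
    n_clones = len(per_clone)
    frames = []
    for chrom, length in chrom_lengths.items():
        n_bins = length // bin_size
        starts = np.arange(n_bins) * bin_size
        hit = np.zeros(n_bins)
        gain_frac = {c: 0.0 for c in per_clone}
        loss_frac = {c: 0.0 for c in per_clone}
        for clone, segs in per_clone.items():
            cov = np.zeros(n_bins, dtype=bool)
            gains = np.zeros(n_bins, dtype=bool)
            losses = np.zeros(n_bins, dtype=bool)
            for s in segs:
                if s.chromosome != chrom or s.call == "neutral":
                    continue
                sel = (starts >= s.start) & (starts < s.end)
                cov |= sel
                (gains if s.call == "gain" else losses)[sel] = True
            hit += cov
            gain_frac[clone] = gains.mean() if n_bins else 0.0
            loss_frac[clone] = losses.mean() if n_bins else 0.0
        aneuploid = sorted(c for c in per_clone
                           if gain_frac[c] >= aneuploidy_fraction
                           or loss_frac[c] >= aneuploidy_fraction)
        frames.append(pd.DataFrame({
            "chromosome": chrom, "start": starts, "end": starts + bin_size,
            "recurrence": hit / n_clones,
            "aneuploid_clones": ",".join(aneuploid),
        }))
    return pd.concat(frames, ignore_index=True)


def segments_to_bed(segments: list[CNVSegment], path: str) -> None:
    pd.DataFrame([{
        "chromosome": s.chromosome, "start": s.start, "end": s.end,
        "n_bins": s.n_bins, "mean_log2": round(s.mean_log2, 4),
        "call": s.call, "band": s.band,
    } for s in segments]).to_csv(path, sep="\t", index=False, header=False)
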