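"""Genome-wide nick statistics: peak calling, shuffle-null enrichment,
metagene profiles, closest-gene assignment and expression resampling.

The central test mirrors common interval-permutation practice: observed
nucleotide overlap between peaks and an annotation category is compared with
the mean overlap of randomized peak sets that preserve, per chromosome, the
multiset of peak lengths.  Fold change is observed/null-mean; significance
comes from a two-tailed pooled two-proportion z-test of overlap proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests

from ._rng import as_rng
from .synthetic_data import Genome

PEAK_COLUMNS = ["chrom", "start", "end", "score"]


@dataclass
class EnrichmentResult:
    category: str
    observed: float  # nucleotides of peak-category overlap
    null_mean: float
    null_sd: float
    fold_change: float
    z: float
    p_two_tailed: float
    n_perm: int


# ---------------------------------------------------------------------------
# peak calling (robust z on tiled log-ratio signal)
# ---------------------------------------------------------------------------

def call_peaks(
    signal: pd.DataFrame,
    z_threshold: float = 4.0,
    min_probes: int = 1,
    merge_gap: int = 300,
) -> pd.DataFrame:
    """Call peaks on tiled array signal (columns chrom/position/value).

    Probes whose robust z-score (median/MAD per chromosome) reaches
    ``z_threshold`` are kept; runs of at least ``min_probes`` significant
    probes, merged across gaps of at most ``merge_gap`` bp, become peaks
    scored by their mean z.  Probe intervals are taken as +-half the local
    probe spacing around each midpoint.
    """
    peaks = []
    for chrom, sub in signal.groupby("chrom", sort=False):
        sub = sub.sort_values("position")
        v = sub["value"].to_numpy(dtype=float)
        pos = sub["position"].to_numpy(dtype=np.int64)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            raise ValueError(
                f"constant signal on {chrom} (MAD=0); add a noise floor before calling"
            )
        z = (v - med) / (1.4826 * mad)
        sig = np.nonzero(z >= z_threshold)[0]
        if not len(sig):
            continue
        spacing = int(np.median(np.diff(pos))) if len(pos) > 1 else 1
        half = max(spacing // 2, 1)
        run = [sig[0]]
        runs = []
        for i in sig[1:]:
            if pos[i] - pos[run[-1]] <= merge_gap:
                run.append(i)
            else:
                runs.append(run)
                run = [i]
        runs.append(run)
        for r in runs:
            if len(r) < min_probes:
                continue
            peaks.append(
                (chrom, int(pos[r[0]] - half), int(pos[r[-1]] + half), float(np.mean(z[r])))
            )
    return pd.DataFrame(peaks, columns=PEAK_COLUMNS)


# ---------------------------------------------------------------------------
# shuffle null
# ---------------------------------------------------------------------------

def _place_nonoverlapping(
    lengths: np.ndarray, chrom_len: int, rng: np.random.Generator, max_iter: int = 1000
) -> np.ndarray:
    """Uniform non-overlapping starts for the given interval lengths."""
    if len(lengths) and lengths.max() == 1:
        # 1-bp intervals (nick positions): non-overlap = distinct starts
        if chrom_len < len(lengths):
            raise ValueError("more 1-bp intervals than positions on chromosome")
        starts = rng.integers(0, chrom_len, len(lengths))
        for _ in range(max_iter):
            uniq, first = np.unique(starts, return_index=True)
            if len(uniq) == len(starts):
                return starts
            dup = np.ones(len(starts), dtype=bool)
            dup[first] = False
            starts[dup] = rng.integers(0, chrom_len, int(dup.sum()))
        raise RuntimeError("could not draw distinct 1-bp placements")
    order = np.argsort(lengths)[::-1]  # place long intervals first
    starts = np.empty(len(lengths), dtype=np.int64)
    placed: list[tuple[int, int]] = []
    for i in order:
        L = int(lengths[i])
        if L > chrom_len:
            raise ValueError(f"interval of {L} bp exceeds chromosome of {chrom_len} bp")
        for attempt in range(max_iter):
            s = int(rng.integers(0, chrom_len - L + 1))
            if all(s + L <= a or s >= b for a, b in placed):
                placed.append((s, s + L))
                starts[i] = s
                break
        else:
            raise RuntimeError(
                f"could not place {L} bp interval without overlap in {max_iter} tries"
            )
    return starts


def shuffle_intervals(
    peaks: pd.DataFrame,
    genome: Genome,
    n_perm: int,
    rng_or_seed=0,
):
    """Yield randomized peak sets preserving per-chromosome length multisets.

    Placements are uniform and non-overlapping within each randomized set
    (rejection sampling with an iteration cap).
    """
    rng = as_rng(rng_or_seed)
    lengths = {
        chrom: (sub["end"] - sub["start"]).to_numpy(dtype=np.int64)
        for chrom, sub in peaks.groupby("chrom", sort=False)
    }
    sizes = genome.lengths
    for chrom in lengths:
        if chrom not in sizes:
            raise ValueError(f"peak chromosome {chrom!r} not in genome")
    for _ in range(n_perm):
        frames = []
        for chrom, ls in lengths.items():
            starts = _place_nonoverlapping(ls, sizes[chrom], rng)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": starts + ls, "score": 0.0}
                )
            )
        yield pd.concat(frames, ignore_index=True)


def _merge_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chromosome merged sorted intervals as an (n, 2) array."""
    merged = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
        iv = iv[np.argsort(iv[:, 0])]
        out = []
        for s, e in iv:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def overlap_nucleotides(peaks: pd.DataFrame, category: pd.DataFrame) -> int:
    """Total nucleotides of peak-category intersection."""
    cat = _merge_intervals(category)
    total = 0
    for chrom, sub in peaks.groupby("chrom", sort=False):
        if chrom not in cat:
            continue
        iv = cat[chrom]
        starts, ends = iv[:, 0], iv[:, 1]
        # prefix sums of category coverage for O(log n) per peak
        cum = np.concatenate([[0], np.cumsum(ends - starts)])
        ps = sub["start"].to_numpy(dtype=np.int64)
        pe = sub["end"].to_numpy(dtype=np.int64)
        i = np.searchsorted(ends, ps, side="right")
        j = np.searchsorted(starts, pe, side="left")
        valid = i < j
        if not valid.any():
            continue
        i, j, ps, pe = i[valid], j[valid], ps[valid], pe[valid]
        inside = cum[j] - cum[i]
        inside -= np.clip(ps - starts[i], 0, None)
        inside -= np.clip(ends[j - 1] - pe, 0, None)
        total += int(inside.sum())
    return total


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-tailed pooled two-proportion z-test.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with pooled p; a degenerate
    pooled proportion (0 or 1) yields z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def enrichment_test(
    peaks: pd.DataFrame,
    category_intervals: pd.DataFrame,
    genome: Genome,
    n_perm: int = 1000,
    rng_or_seed=0,
    category: str = "category",
) -> EnrichmentResult:
    """Shuffle-null enrichment of peaks within an annotation category.

    Observed overlap (nt) is divided by the mean overlap of ``n_perm``
    size- and chromosome-preserving randomized peak sets to give the fold
    change; the p-value compares the observed overlap proportion against the
    pooled null proportion (all permutations pooled) with the two-tailed
    two-proportion z-test.
    """
    total_nt = int((peaks["end"] - peaks["start"]).sum())
    if total_nt <= 0:
        raise ValueError("peak set has zero total nucleotides")
    observed = overlap_nucleotides(peaks, category_intervals)
    null = np.array(
        [
            overlap_nucleotides(p, category_intervals)
            for p in shuffle_intervals(peaks, genome, n_perm, rng_or_seed)
        ],
        dtype=float,
    )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    fold = observed / null_mean if null_mean > 0 else np.inf
    z, p = two_proportion_test(
        observed, total_nt, int(null.sum()), n_perm * total_nt
    )
    return EnrichmentResult(
        category=category,
        observed=float(observed),
        null_mean=null_mean,
        null_sd=null_sd,
        fold_change=float(fold),
        z=z,
        p_two_tailed=p,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# metagene profiles and smoothing
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    bin_edges: np.ndarray  # offsets relative to anchor, len = n_bins + 1
    mean: np.ndarray
    n_anchors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean": self.mean,
                "n": self.n_anchors,
            }
        )


def metagene_profile(
    signal: pd.DataFrame,
    anchors: pd.DataFrame,
    window: int = 1500,
    bin_size: int = 100,
    strand_aware: bool = True,
) -> Profile:
    """Mean binned signal around anchors (+-``window`` bp).

    ``anchors`` needs columns chrom/position and, when ``strand_aware``, a
    strand column ('+'/'-'); minus-strand anchors are flipped so bins read
    5'->3'.  Each bin averages the probe values falling in it, then bins are
    averaged over anchors that contained data.
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin_size")
    if len(anchors) == 0:
        raise ValueError("no anchors given")
    n_bins = 2 * window // bin_size
    edges = np.arange(-window, window + 1, bin_size)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    by_chrom = {
        chrom: sub.sort_values("position")
        for chrom, sub in signal.groupby("chrom", sort=False)
    }
    for _, a in anchors.iterrows():
        sub = by_chrom.get(a["chrom"])
        if sub is None:
            continue
        pos = sub["position"].to_numpy(dtype=np.int64)
        val = sub["value"].to_numpy(dtype=float)
        lo = np.searchsorted(pos, a["position"] - window, side="left")
        hi = np.searchsorted(pos, a["position"] + window, side="right")
        if lo == hi:
            continue
        off = pos[lo:hi] - int(a["position"])
        if strand_aware and a.get("strand", "+") == "-":
            off = -off
        idx = np.clip((off + window) // bin_size, 0, n_bins - 1)
        np.add.at(sums, idx, val[lo:hi])
        np.add.at(counts, idx, 1.0)
    mean = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    return Profile(bin_edges=edges, mean=mean, n_anchors=len(anchors))


def loess_smooth(x, y, span: float = 0.3):
    """Loess (locally weighted linear regression, tricube weights) at input x.

    Thin wrapper around the statsmodels lowess smoother; local linear fits
    reproduce exactly linear inputs to numerical precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 points to smooth")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if span * len(x) < 2:
        raise ValueError("span too small for local linear fits")
    return _sm_lowess(y, x, frac=span, it=0, return_sorted=False)


# ---------------------------------------------------------------------------
# closest gene and expression resampling
# ---------------------------------------------------------------------------

def assign_closest_gene(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Closest gene per peak with signed edge-to-edge distance.

    Distance is 0 for overlap, positive when the gene lies downstream
    (higher coordinates) of the peak, negative when upstream.  Ties break
    toward the gene with the 5'-most (smallest) start.
    """
    if len(genes) == 0:
        raise ValueError("gene table is empty")
    rows = []
    gene_by_chrom = {c: sub.reset_index() for c, sub in genes.groupby("chrom", sort=False)}
    for pi, p in peaks.iterrows():
        sub = gene_by_chrom.get(p["chrom"])
        if sub is None:
            continue
        gs = sub["start"].to_numpy(dtype=np.int64)
        ge = sub["end"].to_numpy(dtype=np.int64)
        gap_right = gs - p["end"]  # >0 when gene downstream of peak
        gap_left = p["start"] - ge  # >0 when gene upstream of peak
        dist = np.maximum(np.maximum(gap_right, gap_left), 0)
        best = np.min(dist)
        cand = np.nonzero(dist == best)[0]
        win = cand[np.argmin(gs[cand])]
        signed = 0 if best == 0 else (int(best) if gap_right[win] > 0 else -int(best))
        rows.append(
            {
                "peak_index": pi,
                "chrom": p["chrom"],
                "peak_start": p["start"],
                "peak_end": p["end"],
                "gene_id": sub.loc[win, "gene_id"],
                "rpkm": sub.loc[win, "rpkm"],
                "distance": signed,
            }
        )
    return pd.DataFrame(rows)


def expression_resample_test(
    nick_genes: pd.DataFrame,
    all_genes: pd.DataFrame,
    n_resample: int = 1000,
    rng_or_seed=0,
    alpha: float = 0.05,
) -> dict:
    """Compare expression of nick-associated genes with random gene samples.

    The nick-gene RPKM distribution is tested (Mann-Whitney rank sum, normal
    approximation with tie correction) against ``n_resample`` random
    samples of the same size drawn from the total gene pool; p-values are
    Benjamini-Hochberg adjusted across resamples.  Returns the two medians,
    the p-value arrays, and the fractions of resamples rejected at ``alpha``
    before and after adjustment.
    """
    if len(nick_genes) < 2:
        raise ValueError("need at least 2 nick-associated genes")
    if not set(nick_genes["gene_id"]).issubset(set(all_genes["gene_id"])):
        raise ValueError("nick_genes must be a subset of all_genes")
    rng = as_rng(rng_or_seed)
    nick_expr = nick_genes["rpkm"].to_numpy(dtype=float)
    pool = all_genes["rpkm"].to_numpy(dtype=float)
    k = len(nick_expr)
    pvals = np.empty(n_resample)
    for i in range(n_resample):
        sample = pool[rng.choice(len(pool), k, replace=False)]
        pvals[i] = stats.mannwhitneyu(
            nick_expr, sample, alternative="two-sided", method="asymptotic"
        ).pvalue
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return {
        "median_nick": float(np.median(nick_expr)),
        "median_genome": float(np.median(pool)),
        "p_values": pvals,
        "p_adjusted": p_adj,
        "rejection_fraction_raw": float(np.mean(pvals < alpha)),
        "rejection_fraction_adjusted": float(np.mean(reject)),
        "n_resample": n_resample,
    }


def chrom_correlation(nick_counts, chrom_lengths) -> float:
    """Pearson r between per-chromosome nick counts and chromosome lengths."""
    counts = np.asarray(nick_counts, dtype=float)
    lengths = np.asarray(chrom_lengths, dtype=float)
    if len(counts) < 3:
        raise ValueError("need at least 3 chromosomes")
    if counts.std() == 0 or lengths.std() == 0:
        raise ValueError("zero variance in counts or lengths")
    return float(stats.pearsonr(counts, lengths).statistic)


def profile_comparison_tests(observed: np.ndarray, randomized: np.ndarray) -> dict:
    """K-S and t-test comparison of observed vs randomized profile values."""
    ks = stats.ks_2samp(observed, randomized)
    tt = stats.ttest_ind(observed, randomized, equal_var=False)
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "t_statistic": float(tt.statistic),
        "t_p": float(tt.pvalue),
    }
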