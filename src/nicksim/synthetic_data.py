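"""Synthetic genomes, gene annotations, nicks, R-loops, rDNA arrays and tiled
array signal.

The generator emulates the statistical structure that the downstream analyses
assume for a budding-yeast-like genome:

* a multi-chromosome genome whose lengths span the yeast karyotype scale
  (~230 kb to ~1.5 Mb), so that nick-count vs chromosome-length correlation is
  testable;
* per-strand nick positions from a background Poisson process (default one
  nick per 140 kb per strand, i.e. a combined duplex spacing of ~70 kb) of
  which a configurable share is placed in windows around transcription start
  sites of genes sampled proportionally to expression;
* R-loop intervals biased toward transcription termination sites;
* a tandem rDNA array of identical 9.1 kb units in which roughly every 10th
  unit carries a nick at weighted named sites;
* tiled two-color array signal (log IP/input ratio) elevated near labeled
  nicks.

No real S. cerevisiae sequence or coordinates are used; everything is
generated from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import as_rng, rng_for
from .fragmentation import Molecule

NICK_COLUMNS = ["chrom", "position", "strand"]
GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "rpkm"]
RLOOP_COLUMNS = ["chrom", "start", "end", "strand"]

#: default chromosome length span, yeast karyotype scale (bp)
DEFAULT_CHROM_MIN = 230_000
DEFAULT_CHROM_MAX = 1_530_000


@dataclass(frozen=True)
class Genome:
    """Ordered chromosomes as (name, length-in-bp) pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class SimConfig:
    """All rates, thresholds and windows of the synthetic-data generator.

    background_rate
        Nicks per bp per strand (default 1/140 000, i.e. ~70 kb combined
        duplex spacing).
    promoter_fraction
        Share of nicks placed uniformly within ``tss_window`` of a TSS of a
        gene sampled with probability proportional to expression.
    nickase_efficiency
        Probability that a recognition site of an exogenous nicking enzyme is
        actually nicked and detected (default 0.07).
    """

    seed: int = 0
    background_rate: float = 1.0 / 140_000
    promoter_fraction: float = 0.5
    tss_window: int = 500
    rloop_rate: float = 0.1  # expected R-loops per gene
    tts_bias: float = 0.9
    tts_window: int = 500
    rloop_length: int = 300
    nickase_sites: tuple = ()
    nickase_efficiency: float = 0.07
    probe_spacing: int = 250
    signal_noise_sd: float = 0.3
    signal_amplitude: float = 2.0
    label_reach: int = 200  # bp a limiting label tract can extend from a nick
    expr_mu: float = math.log(10.0)  # log-normal location: median 10 RPKM
    expr_sigma: float = 1.2

    def __post_init__(self) -> None:
        for name in ("background_rate", "rloop_rate", "signal_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("promoter_fraction", "tts_bias", "nickase_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")


def empty_nicks() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "position": pd.Series(dtype=np.int64),
                         "strand": pd.Series(dtype=str)})


def _default_lengths(n_chrom: int) -> np.ndarray:
    # geometric progression across the karyotype span (>=5-fold variation)
    if n_chrom == 1:
        return np.array([DEFAULT_CHROM_MAX], dtype=np.int64)
    return np.geomspace(DEFAULT_CHROM_MIN, DEFAULT_CHROM_MAX, n_chrom).astype(np.int64)


def make_genome(
    n_chrom: int = 16,
    length_spec=None,
    n_genes: int = 6664,
    expr_spec: tuple[float, float] | None = None,
    seed: int = 0,
    gene_length_mean: float = 1200.0,
    gene_length_sigma: float = 0.5,
) -> tuple[Genome, pd.DataFrame]:
    """Generate a genome and a non-overlapping gene annotation.

    ``length_spec`` may be an explicit list of lengths, a ``(min, max)`` pair
    (log-spaced), or None for the default karyotype-scale progression.  Gene
    counts per chromosome are proportional to length; gene intervals are
    placed uniformly at random without overlap; expression is log-normal RPKM
    (``expr_spec = (mu, sigma)`` of the underlying normal).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    rng = rng_for(seed, "genome")
    if length_spec is None:
        lengths = _default_lengths(n_chrom)
    elif isinstance(length_spec, tuple) and len(length_spec) == 2 and np.isscalar(length_spec[0]):
        lengths = np.geomspace(length_spec[0], length_spec[1], n_chrom).astype(np.int64)
    else:
        lengths = np.asarray(list(length_spec), dtype=np.int64)
        if len(lengths) != n_chrom:
            raise ValueError("length_spec length does not match n_chrom")
    genome = Genome(tuple((f"chr{i+1:02d}", int(l)) for i, l in enumerate(lengths)))

    mu, sigma = expr_spec if expr_spec is not None else (math.log(10.0), 1.2)
    records = []
    total = genome.total_length
    remaining = n_genes
    for i, (name, length) in enumerate(genome.chromosomes):
        if i == n_chrom - 1:
            n_c = remaining
        else:
            n_c = int(round(n_genes * length / total))
            n_c = min(n_c, remaining)
        remaining -= n_c
        if n_c == 0:
            continue
        glen = np.clip(
            rng.lognormal(math.log(gene_length_mean), gene_length_sigma, n_c), 200, None
        ).astype(np.int64)
        slack = length - int(glen.sum())
        if slack < 0:
            raise ValueError(
                f"cannot place {n_c} non-overlapping genes on {name} "
                f"({length} bp < {int(glen.sum())} bp of gene sequence)"
            )
        # uniform non-overlapping placement: scatter the slack between genes
        gaps = np.sort(rng.integers(0, slack + 1, n_c))
        starts = gaps + np.concatenate([[0], np.cumsum(glen[:-1])])
        strands = rng.choice(["+", "-"], n_c)
        rpkm = rng.lognormal(mu, sigma, n_c)
        for j in range(n_c):
            records.append(
                (name, int(starts[j]), int(starts[j] + glen[j]), strands[j],
                 f"{name}_g{j+1:04d}", float(rpkm[j]))
            )
    genes = pd.DataFrame(records, columns=GENE_COLUMNS)
    return genome, genes


def tss_positions(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware 5' ends (TSS) of a gene table."""
    return np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)


def tts_positions(genes: pd.DataFrame) -> np.ndarray:
    """Strand-aware 3' ends (TTS) of a gene table."""
    return np.where(genes["strand"] == "+", genes["end"] - 1, genes["start"])


def place_nicks(
    genome: Genome,
    genes: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-strand nick positions: Poisson background plus TSS component.

    Per chromosome the total nick count is Poisson with mean
    ``2 * background_rate * length`` (both strands).  Each nick is placed, with
    probability ``promoter_fraction``, uniformly within ``tss_window`` of the
    TSS of a gene on that chromosome sampled proportionally to expression;
    otherwise uniformly on the chromosome.  Strands are assigned
    independently with probability 1/2.  Duplicate positions on a strand are
    dropped.
    """
    rng = rng if rng is not None else rng_for(config.seed, "nicks")
    out = []
    for name, length in genome.chromosomes:
        n = rng.poisson(2.0 * config.background_rate * length)
        if n == 0:
            continue
        pos = rng.integers(1, length, n)
        sub = genes[genes["chrom"] == name]
        if config.promoter_fraction > 0 and len(sub):
            promo = rng.random(n) < config.promoter_fraction
            k = int(promo.sum())
            if k:
                w = sub["rpkm"].to_numpy(dtype=float)
                w = w / w.sum()
                gi = rng.choice(len(sub), size=k, p=w)
                tss = tss_positions(sub)[gi]
                offs = rng.integers(-config.tss_window, config.tss_window + 1, k)
                pos[promo] = np.clip(tss + offs, 1, length - 1)
        strand = rng.choice(["top", "bottom"], n)
        out.append(pd.DataFrame({"chrom": name, "position": pos, "strand": strand}))
    if not out:
        return empty_nicks()
    nicks = pd.concat(out, ignore_index=True)
    nicks = nicks.drop_duplicates(subset=NICK_COLUMNS, ignore_index=True)
    return nicks.sort_values(["chrom", "position"], ignore_index=True)


def place_rloops(
    genes: pd.DataFrame,
    config: SimConfig,
    genome: Genome | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Place R-loop intervals, biased toward TTSs.

    The number of R-loops is Poisson with mean ``rloop_rate * n_genes``; each
    attaches to a gene sampled proportionally to expression.  With probability
    ``tts_bias`` the midpoint is uniform within ``tts_window`` of the TTS,
    otherwise uniform in the gene body.  The interval strand is the gene
    strand.
    """
    rng = rng if rng is not None else rng_for(config.seed, "rloops")
    if len(genes) == 0 or config.rloop_rate == 0:
        return pd.DataFrame(columns=RLOOP_COLUMNS)
    n = rng.poisson(config.rloop_rate * len(genes))
    if n == 0:
        return pd.DataFrame(columns=RLOOP_COLUMNS)
    w = genes["rpkm"].to_numpy(dtype=float)
    w = w / w.sum()
    gi = rng.choice(len(genes), size=n, p=w)
    tts = tts_positions(genes)[gi]
    gstart = genes["start"].to_numpy()[gi]
    gend = genes["end"].to_numpy()[gi]
    at_tts = rng.random(n) < config.tts_bias
    mid = np.where(
        at_tts,
        tts + rng.integers(-config.tts_window, config.tts_window + 1, n),
        gstart + (rng.random(n) * (gend - gstart)).astype(np.int64),
    )
    half = config.rloop_length // 2
    start = mid - half
    end = start + config.rloop_length
    chroms = genes["chrom"].to_numpy()[gi]
    if genome is not None:
        lims = np.array([genome.lengths[c] for c in chroms])
        start = np.clip(start, 0, lims - config.rloop_length)
        end = start + config.rloop_length
    else:
        start = np.maximum(start, 0)
        end = start + config.rloop_length
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "strand": genes["strand"].to_numpy()[gi],
        }
    ).sort_values(["chrom", "start"], ignore_index=True)


def apply_nickase(
    nicks: pd.DataFrame,
    nickase_sites: pd.DataFrame,
    efficiency: float,
    rng_or_seed=0,
) -> pd.DataFrame:
    """Add exogenous nicking-enzyme cuts to an endogenous nick table.

    Each recognition site (rows of chrom/position/strand) is nicked
    independently with probability ``efficiency``; the result is the union
    with the input nicks.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    rng = as_rng(rng_or_seed)
    if len(nickase_sites) == 0 or efficiency == 0.0:
        added = nickase_sites.iloc[:0]
    else:
        keep = rng.random(len(nickase_sites)) < efficiency
        added = nickase_sites[keep]
    merged = pd.concat([nicks, added[NICK_COLUMNS]], ignore_index=True)
    merged = merged.drop_duplicates(subset=NICK_COLUMNS, ignore_index=True)
    return merged.sort_values(["chrom", "position"], ignore_index=True)


# ---------------------------------------------------------------------------
# rDNA unit map and tandem array
# ---------------------------------------------------------------------------

# StuI cut sites chosen so single-unit digestion yields the 3983/2419/1686/1029
# bp fragments; PvuII sites so the StuI+PvuII double digest contains the
# 757/2061/1165/982/1029 bp fragments.  The two sub-fragments not fixed by
# those sizes absorb the residual 3123 bp as 1437 + 1686 (an unconstrained
# choice, configurable via cut_sites).
_DEFAULT_CUT_SITES = {
    "SfiI": (0,),
    "StuI": (3983, 6402, 8088),
    "PvuII": (757, 2818, 5420),
}

# Named in-unit features.  Only fragment membership is meaningful: C-PRO in
# fragment a, the ARS/IGS2 region in fragment b, E-PRO in fragment c, the
# RFB/IGS1 in fragment d, the TAR1 promoter in fragment e.  Absolute
# coordinates are synthetic placeholders.
_DEFAULT_FEATURES = {
    "C-PRO": (350, 550),
    "ARS/IGS2": (1400, 1700),
    "E-PRO": (2900, 3100),
    "RFB/IGS1": (4000, 4150),
    "5S": (4600, 4720),
    "TAR1-promoter": (5800, 6000),
    "5.8S": (6500, 6660),
    "18S": (6800, 7600),
    "25S": (8200, 9000),
}

# Nick sites b..i: positions, fixed strand, and relative weights.  The
# promoter-bearing double-digest fragments a (C-PRO), c (E-PRO) and e (TAR1)
# carry the highest weight; no site falls in the ARS-containing fragment
# [757, 2818), whose weight is therefore zero.  Positions are chosen so that
# every nick-derived fragment size, and every composite size involving the
# default off-target incision site, stays >2% (gel-resolution tolerance)
# away from all sizes of the other origin class, keeping band-origin
# classification exact.
_DEFAULT_NICK_SITES = {
    "b": (120, "top"),
    "c": (3070, "top"),
    "d": (3310, "bottom"),
    "e": (5910, "top"),
    "f": (5080, "bottom"),
    "g": (6680, "top"),
    "h": (8380, "bottom"),
    "i": (8940, "top"),
}
_DEFAULT_NICK_WEIGHTS = {
    "b": 3.0, "c": 3.0, "d": 2.0, "e": 3.0, "f": 1.0, "g": 1.0, "h": 1.0, "i": 1.0,
}


@dataclass
class RdnaUnitMap:
    """The 9.1 kb tandem ribosomal repeat unit: enzyme sites, named features,
    weighted nick sites and the Southern probe.

    Unit coordinates are registered on the SfiI cut site (position 0)."""

    unit_length: int = 9117
    cut_sites: dict = field(default_factory=lambda: dict(_DEFAULT_CUT_SITES))
    features: dict = field(default_factory=lambda: dict(_DEFAULT_FEATURES))
    nick_sites: dict = field(default_factory=lambda: dict(_DEFAULT_NICK_SITES))
    nick_site_weights: dict = field(default_factory=lambda: dict(_DEFAULT_NICK_WEIGHTS))
    probe: tuple = ((4100, 5100), "top")  # interval, strand of probe sequence

    def __post_init__(self) -> None:
        for enz, sites in self.cut_sites.items():
            for s in sites:
                if not 0 <= s < self.unit_length:
                    raise ValueError(f"{enz} site {s} outside unit")
        for name, (pos, strand) in self.nick_sites.items():
            if not 0 < pos < self.unit_length:
                raise ValueError(f"nick site {name} at {pos} outside unit")
            if strand not in ("top", "bottom"):
                raise ValueError(f"nick site {name} has invalid strand {strand}")

    def digest_fragment_sizes(self, enzymes) -> list[int]:
        """Fragment sizes of one clean unit cut by the given enzyme(s)."""
        if isinstance(enzymes, str):
            enzymes = [enzymes]
        cuts = sorted(
            {s for e in enzymes for s in self.cut_sites[e] if 0 < s < self.unit_length}
        )
        edges = [0] + cuts + [self.unit_length]
        return [b - a for a, b in zip(edges[:-1], edges[1:])]

    def double_digest_intervals(self) -> dict[str, tuple[int, int]]:
        """Named StuI+PvuII double-digest fragments a..g, in map order."""
        cuts = sorted(
            set(self.cut_sites["StuI"]) | {s for s in self.cut_sites["PvuII"] if s > 0}
        )
        edges = [0] + cuts + [self.unit_length]
        names = "abcdefghijklm"
        return {
            names[i]: (edges[i], edges[i + 1]) for i in range(len(edges) - 1)
        }

    def ars_fragment(self) -> str:
        """Name of the double-digest fragment containing the ARS."""
        a, b = self.features["ARS/IGS2"]
        for name, (s, e) in self.double_digest_intervals().items():
            if s <= a and b <= e:
                return name
        raise ValueError("ARS feature spans a double-digest boundary")


def build_rdna_array(
    unit_map: RdnaUnitMap,
    n_units: int = 150,
    nicked_unit_fraction: float = 0.1,
    per_unit_nicks: int = 1,
    rng_or_seed=0,
) -> tuple[Molecule, pd.DataFrame]:
    """A single linear molecule of ``n_units`` tandem repeats with nicks.

    Units are independently nicked with probability ``nicked_unit_fraction``
    (every ~10th unit at the default 0.1).  Within a nicked unit,
    ``per_unit_nicks`` sites are drawn (without replacement) from the weighted
    named sites; each site's strand is fixed by the map.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if not 0.0 <= nicked_unit_fraction <= 1.0:
        raise ValueError("nicked_unit_fraction must be in [0, 1]")
    rng = as_rng(rng_or_seed)
    names = list(unit_map.nick_sites)
    weights = np.array([unit_map.nick_site_weights.get(n, 0.0) for n in names])
    if nicked_unit_fraction > 0 and (not names or weights.sum() <= 0):
        raise ValueError("all nick-site weights are zero but nicked_unit_fraction > 0")
    top, bottom, rows = [], [], []
    if nicked_unit_fraction > 0:
        p = weights / weights.sum()
        nicked = rng.random(n_units) < nicked_unit_fraction
        k = min(per_unit_nicks, int((p > 0).sum()))
        for u in np.nonzero(nicked)[0]:
            chosen = rng.choice(len(names), size=k, replace=False, p=p)
            for ci in chosen:
                pos, strand = unit_map.nick_sites[names[ci]]
                abs_pos = int(u) * unit_map.unit_length + pos
                (top if strand == "top" else bottom).append(abs_pos)
                rows.append(("rDNA_array", abs_pos, strand, names[ci], int(u)))
    mol = Molecule(
        length=n_units * unit_map.unit_length,
        nicks_top=np.array(sorted(top), dtype=np.int64),
        nicks_bottom=np.array(sorted(bottom), dtype=np.int64),
        origin="rDNA_array",
    )
    nicks = pd.DataFrame(rows, columns=["chrom", "position", "strand", "site", "unit"])
    return mol, nicks


def simulate_array_signal(
    genome: Genome,
    nicks: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Tiled IP/input log-ratio signal: probes every ``probe_spacing`` bp,
    elevated by ``signal_amplitude`` within ``label_reach`` of a nick on
    either strand, plus Gaussian noise of sd ``signal_noise_sd``."""
    rng = rng if rng is not None else rng_for(config.seed, "signal")
    frames = []
    for name, length in genome.chromosomes:
        mids = np.arange(config.probe_spacing // 2, length, config.probe_spacing)
        value = np.zeros(len(mids))
        pos = np.sort(
            nicks.loc[nicks["chrom"] == name, "position"].to_numpy(dtype=np.int64)
        )
        if len(pos):
            idx = np.searchsorted(pos, mids)
            left = np.where(idx > 0, mids - pos[np.maximum(idx - 1, 0)], np.inf)
            right = np.where(idx < len(pos), pos[np.minimum(idx, len(pos) - 1)] - mids, np.inf)
            near = np.minimum(left, right) <= config.label_reach
            value[near] += config.signal_amplitude
        if config.signal_noise_sd > 0:
            value += rng.normal(0.0, config.signal_noise_sd, len(mids))
        frames.append(pd.DataFrame({"chrom": name, "position": mids, "value": value}))
    return pd.concat(frames, ignore_index=True)
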