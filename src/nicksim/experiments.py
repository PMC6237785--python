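"""End-to-end in-silico experiments at fixed study conditions.

These functions wire the generator, the fragmentation physics and the
statistics into the headline analyses: null calibration of the shuffle
enrichment test, detection power under TSS-enriched nick placement,
expression-resampling calibration, parameter recovery from fragment sizes,
rDNA periodicity, treatment-order agreement and band-origin classification
accuracy.  Problem sizes are chosen so each experiment runs in seconds to a
few minutes on one core; see docs/methods.md for the rationale behind each
scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import rng_for
from .combing import (
    FragPhysicsParams,
    LabelParams,
    comb_and_measure,
    coloc_stats,
    label_3prime_ends,
    plant_rloop_labels,
)
from .enrichment import (
    call_peaks,
    chrom_correlation,
    enrichment_test,
    expression_resample_test,
    overlap_nucleotides,
    _merge_intervals,
)
from .fragmentation import Molecule, denature, ds_break
from .rdna import TreatmentPlan, classify_band_origin, default_enzymes, run_plan
from .synthetic_data import (
    Genome,
    RdnaUnitMap,
    SimConfig,
    build_rdna_array,
    make_genome,
    place_nicks,
    simulate_array_signal,
    tss_positions,
)


def _nicks_as_point_peaks(nicks: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": nicks["chrom"],
            "start": nicks["position"],
            "end": nicks["position"] + 1,
            "score": 0.0,
        }
    )


def _tss_category(genes: pd.DataFrame, window: int) -> pd.DataFrame:
    tss = tss_positions(genes)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(tss - window, 0),
            "end": tss + window,
        }
    )


def _ars_like_category(genome: Genome, width: int = 500, spacing: int = 10_000) -> pd.DataFrame:
    """Replication-origin-like intervals laid down independently of nicks."""
    rows = []
    for name, length in genome.chromosomes:
        for s in range(spacing // 2, length - width, spacing):
            rows.append((name, s, s + width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# statistical calibration and power
# ---------------------------------------------------------------------------

def type_i_calibration(
    n_genomes: int = 500,
    n_perm: int = 60,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the shuffle enrichment test under uniform nicks.

    Small two-chromosome genomes (100 kb) with a fixed 10%-coverage
    annotation; ~400 uniformly placed nicks act as 1-bp peaks (enough that
    the normal approximation of the proportion test is accurate).
    """
    genome = Genome((("chr01", 60_000), ("chr02", 40_000)))
    category = pd.DataFrame(
        [
            (name, s, s + 500)
            for name, length in genome.chromosomes
            for s in range(2_000, length - 500, 5_000)
        ],
        columns=["chrom", "start", "end"],
    )
    cfg = SimConfig(seed=seed, background_rate=2e-3, promoter_fraction=0.0)
    genes = pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id", "rpkm"])
    rng = rng_for(seed, "nicks")
    shuffle_rng = rng_for(seed, "shuffle")
    rejections = 0
    used = 0
    for _ in range(n_genomes):
        nicks = place_nicks(genome, genes, cfg, rng)
        if len(nicks) < 10:
            continue
        res = enrichment_test(
            _nicks_as_point_peaks(nicks), category, genome, n_perm, shuffle_rng
        )
        rejections += res.p_two_tailed < alpha
        used += 1
    return {"rejection_rate": rejections / used, "n_genomes": used, "alpha": alpha}


POWER_GENOME_SPEC = dict(n_chrom=10, length_spec=(150_000, 600_000), n_genes=600)


def tss_power_experiment(
    n_reps: int = 60,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Detection power for TSS enrichment under default nick placement.

    Each replicate draws a ~3.3 Mb ten-chromosome genome with 600 genes
    (TSS +-500 windows cover ~18% of it), places nicks with the default
    configuration (promoter_fraction 0.5), and tests the nick positions
    against the TSS category and an origin-like control category.
    """
    shuffle_rng = rng_for(seed, "shuffle")
    tss_detected = fold_gt2 = ars_rejected = 0
    tss_folds, ars_folds = [], []
    for rep in range(n_reps):
        rep_seed = (seed * 100_003 + rep) % (2**31 - 1)
        genome, genes = make_genome(seed=rep_seed, **POWER_GENOME_SPEC)
        cfg = SimConfig(seed=rep_seed)
        nicks = place_nicks(genome, genes, cfg)
        peaks = _nicks_as_point_peaks(nicks)
        tss = enrichment_test(peaks, _tss_category(genes, cfg.tss_window), genome,
                              n_perm, shuffle_rng, category="TSS")
        ars = enrichment_test(peaks, _ars_like_category(genome), genome,
                              n_perm, shuffle_rng, category="ARS")
        tss_detected += tss.p_two_tailed < alpha and tss.fold_change > 1
        fold_gt2 += tss.fold_change > 2
        ars_rejected += ars.p_two_tailed < alpha
        tss_folds.append(tss.fold_change)
        ars_folds.append(ars.fold_change)
    return {
        "power": tss_detected / n_reps,
        "fold_gt2_fraction": fold_gt2 / n_reps,
        "tss_fold_mean": float(np.mean(tss_folds)),
        "ars_fold_mean": float(np.mean(ars_folds)),
        "ars_rejection_rate": ars_rejected / n_reps,
        "n_reps": n_reps,
    }


def chrom_length_correlation_experiment(n_reps: int = 10, seed: int = 0) -> dict:
    """Pearson r between pooled per-chromosome nick counts and lengths on the
    default 16-chromosome karyotype."""
    genome, genes = make_genome(16, None, 2000, seed=seed)
    cfg = SimConfig(seed=seed)
    rng = rng_for(seed, "nicks")
    counts = np.zeros(16)
    for _ in range(n_reps):
        nicks = place_nicks(genome, genes, cfg, rng)
        counts += nicks["chrom"].value_counts().reindex(genome.names).fillna(0).to_numpy()
    lengths = [l for _, l in genome.chromosomes]
    return {"pearson_r": chrom_correlation(counts, lengths), "n_nicks": int(counts.sum())}


def expression_calibration_experiment(
    seed: int = 0,
    n_reps: int = 12,
    n_resample: int = 150,
    pool_size: int = 6664,
    k: int = 215,
) -> dict:
    """Null and top-decile behaviour of the expression resampling test at the
    gene-pool proportions of the genome-wide analysis (215 of 6664)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
    pool = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(pool_size)],
            "rpkm": rng.lognormal(np.log(10.0), 1.2, pool_size),
        }
    )
    null_fracs = []
    for _ in range(n_reps):
        nick = pool.iloc[rng.choice(pool_size, k, replace=False)]
        out = expression_resample_test(nick, pool, n_resample, rng)
        null_fracs.append(out["rejection_fraction_raw"])
    top = pool.nlargest(int(pool_size * 0.1), "rpkm").head(k)
    alt = expression_resample_test(top, pool, n_resample, rng)
    return {
        "null_rejection_rate": float(np.mean(null_fracs)),
        "alt_rejection_rate": alt["rejection_fraction_adjusted"],
        "alt_median_ratio": alt["median_nick"] / alt["median_genome"],
    }


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def nick_rate_recovery(seed: int = 0, length: int = 50_000_000) -> dict:
    """Recover the per-strand nick rate from denatured fragment sizes.

    Under per-strand Poisson placement the ss fragment sizes are
    exponential; the maximum-likelihood rate is 1/mean.
    """
    cfg = SimConfig(seed=seed, promoter_fraction=0.0)
    genome = Genome((("chr01", length),))
    genes = pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id", "rpkm"])
    nicks = place_nicks(genome, genes, cfg, rng_for(seed, "nicks"))
    mol = Molecule(
        length,
        nicks_top=nicks.loc[nicks["strand"] == "top", "position"].to_numpy(),
        nicks_bottom=nicks.loc[nicks["strand"] == "bottom", "position"].to_numpy(),
    )
    sizes = denature(mol).lengths()
    est = 1.0 / float(np.mean(sizes))
    true = cfg.background_rate
    return {
        "true_rate": true,
        "estimated_rate": est,
        "relative_error_pct": abs(est - true) / true * 100.0,
        "n_fragments": len(sizes),
    }


def rdna_periodicity(seed: int = 0, n_units: int = 150, n_reps: int = 100) -> dict:
    """Inter-break spacing in the rDNA array at the every-~10th-unit rate."""
    um = RdnaUnitMap()
    rng = rng_for(seed, "rdna")
    sizes = []
    for _ in range(n_reps):
        mol, _ = build_rdna_array(um, n_units, 0.1, 1, rng)
        sizes.extend(ds_break(mol, "s1").lengths())
    sizes = np.array(sizes, dtype=float)
    return {
        "mean_fragment_kb": float(sizes.mean() / 1000.0),
        "median_fragment_kb": float(np.median(sizes) / 1000.0),
        "mean_units_between_breaks": float(sizes.mean() / um.unit_length),
        "n_fragments": len(sizes),
    }


def mutant_scaling_recovery(seed: int = 0, n_reps: int = 10, n_units: int = 2000) -> dict:
    """Recover a global x0.5 reduction of rDNA nicking from rSW ratios."""
    from .rdna import compare_strains, rsw_fragment_profile

    rng = rng_for(seed, "bootstrap")

    def reps(scale, offset):
        rows = []
        for r in range(n_reps):
            prof = rsw_fragment_profile(RdnaUnitMap(), n_units, 0.1, scale, rng)
            for _, row in prof.iterrows():
                rows.append({"band": row["fragment"], "replicate": offset + r,
                             "ratio": row["ratio"]})
        return pd.DataFrame(rows)

    wt = reps(1.0, 0)
    mut = reps(0.5, 100)
    out = compare_strains(wt, mut, n_boot=400, rng_or_seed=rng, ci=0.99)
    covered = ((out["ci_low"] <= 0.5) & (0.5 <= out["ci_high"])).mean()
    return {
        "mean_fold_change": float(out["fold_change"].mean()),
        "ci_coverage_of_half": float(covered),
        "n_bands": len(out),
    }


# ---------------------------------------------------------------------------
# rDNA order-invariance and classification
# ---------------------------------------------------------------------------

def order_invariance_agreement(n_arrays: int = 100, seed: int = 0) -> dict:
    """Fraction of arrays where [S1, digest] and [digest, S1] band multisets
    agree exactly (no off-target nicking)."""
    um = RdnaUnitMap()
    rng = rng_for(seed, "rdna")
    agree = 0
    for trial in range(n_arrays):
        n_units = int(rng.integers(3, 7))
        mol, _ = build_rdna_array(um, n_units, 0.5, 1, rng)
        enzyme = "SfiI" if trial % 2 == 0 else "StuI"
        key = []
        for steps in (["s1", f"digest:{enzyme}"], [f"digest:{enzyme}", "s1"]):
            t = run_plan(mol, TreatmentPlan.parse(steps), um, 0, comigration_tol=0.0)
            key.append(sorted((r["size_bp"], r["intensity"]) for _, r in t.bands.iterrows()))
        agree += key[0] == key[1]
    return {"agreement_fraction": agree / n_arrays, "n_arrays": n_arrays}


def band_origin_accuracy(n_trials: int = 100, seed: int = 0, n_units: int = 8) -> dict:
    """Classification accuracy against the known plant: endogenous nicks vs
    an always-on off-target incision site (probability 1)."""
    um = RdnaUnitMap()
    off_site = 1200
    enz = default_enzymes(um, smai_off_target_p=1.0)
    rng = rng_for(seed, "plan")
    correct_trials = 0
    for trial in range(n_trials):
        mol, nicks = build_rdna_array(um, n_units, 0.4, 1, rng)
        if len(nicks) == 0:
            mol, nicks = build_rdna_array(um, n_units, 0.9, 1, rng)
        re_first = run_plan(mol, TreatmentPlan.parse(["digest:SmaI", "s1"]),
                            um, rng, enzymes=enz, comigration_tol=0.0)
        s1_first = run_plan(mol, TreatmentPlan.parse(["s1", "digest:SmaI"]),
                            um, rng, enzymes=enz, comigration_tol=0.0)
        denat = run_plan(mol, TreatmentPlan.parse(["digest:SfiI", "denature"]),
                         um, rng, enzymes=enz, comigration_tol=0.0)
        result = classify_band_origin(s1_first, re_first, denat)
        # truth from the plant: any fragment end at the off-target incision
        # marks the band as artefactual
        off_sizes = set()
        endo_sizes = set()
        rel = {u: [] for u in range(n_units)}
        for _, row in nicks.iterrows():
            rel[int(row["unit"])].append(int(row["position"]) % um.unit_length)
        for u in range(n_units):
            edges = [0] + sorted(set(rel[u]) | {off_site}) + [um.unit_length]
            for a, b in zip(edges[:-1], edges[1:]):
                (off_sizes if off_site in (a, b) else endo_sizes).add(b - a)
        ok = True
        for _, row in result.iterrows():
            if row["strandedness"] == "unmatched":
                continue
            want = "off_target" if row["size_bp"] in off_sizes else "endogenous"
            ok = ok and (row["origin"] == want)
        correct_trials += ok
    return {"accuracy": correct_trials / n_trials, "n_trials": n_trials}


# ---------------------------------------------------------------------------
# combing and array-signal recovery
# ---------------------------------------------------------------------------

def coloc_experiment(seed: int = 0, n_molecules: int = 40, fraction: float = 0.10) -> dict:
    """Recover a planted nick/R-loop co-localization fraction on combed
    fibers at 1 kb optical resolution."""
    rng = rng_for(seed, "combing")
    mols = []
    for _ in range(n_molecules):
        top = np.sort(rng.choice(np.arange(1, 300_000), 8, replace=False))
        bottom = np.sort(rng.choice(np.arange(1, 300_000), 7, replace=False))
        mols.append(Molecule(300_000, top, bottom))
    mols = [label_3prime_ends(m, LabelParams(), rng) for m in mols]
    mols = plant_rloop_labels(mols, fraction, rng_or_seed=rng)
    fibers = comb_and_measure(
        mols, FragPhysicsParams(p_break=0.0), LabelParams(min_detect_length=0), rng
    )
    out = coloc_stats(fibers, 1000)
    return {
        "coloc_fraction": float(out.loc[0, "coloc_fraction"]),
        "n_labels": int(out.loc[0, "n_nick_labels"]),
    }


def signal_recovery_experiment(seed: int = 0, n_nicks: int = 40) -> dict:
    """Sensitivity of peak calling for nicks planted in tiled array signal."""
    genome = Genome((("chr01", 2_000_000),))
    rng = rng_for(seed, "signal")
    pos = np.sort(rng.choice(np.arange(5_000, 1_995_000), n_nicks, replace=False))
    nicks = pd.DataFrame({"chrom": "chr01", "position": pos, "strand": "top"})
    cfg = SimConfig(seed=seed)
    sig = simulate_array_signal(genome, nicks, cfg, rng)
    peaks = call_peaks(sig)
    recovered = sum(
        bool(((peaks["start"] - 300 <= p) & (p <= peaks["end"] + 300)).any())
        for p in pos
    )
    return {"sensitivity": recovered / n_nicks, "n_planted": n_nicks,
            "n_peaks": len(peaks)}


def tss_window_coverage(genes: pd.DataFrame, genome: Genome, window: int) -> float:
    """Fraction of the genome covered by TSS windows (merged)."""
    cat = _tss_category(genes, window)
    nt = sum((iv[:, 1] - iv[:, 0]).sum() for iv in _merge_intervals(cat).values())
    return nt / genome.total_length
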