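"""Forward models of the rDNA Southern and reverse-Southwestern experiments.

The tandem rDNA array (identical 9.1 kb units) is digested, S1-treated,
denatured and/or 3'OH-labeled in a configurable order; fragments are
aggregated into gel bands, detected with strand-specific probes, and
quantified as biotin/EBr ratios.  Off-target nicking by restriction enzymes
(single-strand incisions at near-cognate sites) is modeled as stochastic
nicks added during the digestion step — the basis of the treatment-order
logic that separates genuine endogenous nicks from enzyme artefacts: a nick
converted to a ds break by S1 *before* the enzyme ever touched the DNA must
be endogenous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import as_rng
from .combing import LabelParams, label_3prime_ends
from .fragmentation import Fragment, FragmentSet, Molecule, gel_migrate
from .synthetic_data import RdnaUnitMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnzymeModel:
    """A restriction enzyme acting on the rDNA unit.

    ``off_target_nick_sites`` is a list of ``(unit_position, strand,
    probability)`` triples: during a digest each such site, in each unit, is
    nicked (not cut) with the given probability.  SfiI generates no
    artefactual nicks; an off-target-prone enzyme (e.g. SmaI) carries a
    nonzero entry.
    """

    name: str
    sites: tuple[int, ...] = ()
    off_target_nick_sites: tuple[tuple[int, str, float], ...] = ()

    def __post_init__(self) -> None:
        for pos, strand, p in self.off_target_nick_sites:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: off-target probability {p} not in [0,1]")
            if strand not in ("top", "bottom"):
                raise ValueError(f"{self.name}: invalid off-target strand {strand}")


def default_enzymes(unit_map: RdnaUnitMap, smai_off_target_p: float = 0.0) -> dict:
    """Enzyme registry for a unit map.

    Canonical sites come from the map.  SmaI is modeled with one potential
    off-target single-strand incision site per unit (probability
    ``smai_off_target_p``, default 0); its canonical ds site coincides with
    the unit registration point so that band sizes are directly comparable
    across enzymes in this synthetic map.
    """
    enz = {
        name: EnzymeModel(name, tuple(sites))
        for name, sites in unit_map.cut_sites.items()
    }
    enz["SmaI"] = EnzymeModel(
        "SmaI", (0,), ((1200, "top", smai_off_target_p),)
    )
    return enz


@dataclass
class TreatmentPlan:
    """Ordered in-silico treatments: ``digest(<enzyme>)``, ``s1``,
    ``denature``, ``label``.  At most one denature, and nothing but the gel
    may follow it."""

    steps: tuple

    def __post_init__(self) -> None:
        seen_denature = False
        for step in self.steps:
            kind = step[0]
            if kind not in ("digest", "s1", "denature", "label"):
                raise ValueError(f"unknown treatment step {kind!r}")
            if seen_denature:
                raise ValueError("no treatment may follow denaturation")
            if kind == "denature":
                seen_denature = True

    @classmethod
    def parse(cls, names) -> "TreatmentPlan":
        """Build from strings like ``["digest:SfiI", "s1", "denature"]``."""
        steps = []
        for n in names:
            if n.startswith("digest:"):
                steps.append(("digest", n.split(":", 1)[1]))
            elif n in ("s1", "denature", "label"):
                steps.append((n,))
            else:
                raise ValueError(f"cannot parse treatment step {n!r}")
        return cls(tuple(steps))


@dataclass
class BandTable:
    """Gel bands plus the underlying fragment set (parent coordinates)."""

    bands: pd.DataFrame  # size_bp, strandedness, intensity, members, probe_detected
    fragments: FragmentSet


def _split_ds_fragment(frag: Fragment, cuts: np.ndarray) -> list[Fragment]:
    """Partition a ds fragment at absolute cut coordinates inside it."""
    cuts = np.unique(np.asarray(cuts, dtype=np.int64))
    cuts = cuts[(cuts > frag.start) & (cuts < frag.end)]
    if not len(cuts):
        return [frag]
    edges = np.concatenate([[frag.start], cuts, [frag.end]])
    pieces = []
    for s, e in zip(edges[:-1], edges[1:]):
        nt = frag.nicks_top[(frag.nicks_top > s) & (frag.nicks_top < e)]
        nb = frag.nicks_bottom[(frag.nicks_bottom > s) & (frag.nicks_bottom < e)]
        pieces.append(Fragment(frag.parent, int(s), int(e), "ds", nt, nb, []))
    for tract in frag.labels:
        anchor = min(max(tract.five_prime_base(), frag.start), frag.end - 1)
        idx = int(np.searchsorted(edges, anchor, side="right") - 1)
        idx = min(idx, len(pieces) - 1)
        piece = pieces[idx]
        piece.labels.append(
            replace(tract, start=max(tract.start, piece.start), end=min(tract.end, piece.end))
        )
    return pieces


def _denature_fragments(frags: list[Fragment]) -> list[Fragment]:
    out = []
    for frag in frags:
        for strand in ("top", "bottom"):
            own = frag.nicks_top if strand == "top" else frag.nicks_bottom
            edges = np.concatenate([[frag.start], own, [frag.end]])
            pieces = [
                Fragment(frag.parent, int(s), int(e), strand)
                for s, e in zip(edges[:-1], edges[1:])
            ]
            for tract in frag.labels:
                if tract.strand != strand:
                    continue
                anchor = min(max(tract.five_prime_base(), frag.start), frag.end - 1)
                idx = int(np.searchsorted(edges, anchor, side="right") - 1)
                idx = min(idx, len(pieces) - 1)
                piece = pieces[idx]
                piece.labels.append(
                    replace(tract, start=max(tract.start, piece.start),
                            end=min(tract.end, piece.end))
                )
            out.extend(pieces)
    return out


def run_plan(
    array_molecule: Molecule,
    plan: TreatmentPlan,
    unit_map: RdnaUnitMap,
    rng_or_seed=0,
    enzymes: dict | None = None,
    label_params: LabelParams | None = None,
    comigration_tol: float = 0.1,
) -> BandTable:
    """Apply an ordered treatment plan to an rDNA array molecule.

    Step semantics: ``digest`` makes ds cuts at every canonical site of every
    unit and stochastically adds off-target *nicks*; ``s1`` converts every
    current nick into a ds break; ``denature`` separates strands, each
    splitting at its own nicks; ``label`` appends a 3'OH label tract at every
    current nick.  Fragment sizes are aggregated into gel bands per
    strandedness via log-mobility co-migration merging.
    """
    rng = as_rng(rng_or_seed)
    enzymes = enzymes if enzymes is not None else default_enzymes(unit_map)
    n_units = array_molecule.length // unit_map.unit_length
    frags: list[Fragment] = [
        Fragment(
            array_molecule.origin,
            0,
            array_molecule.length,
            "ds",
            array_molecule.nicks_top.copy(),
            array_molecule.nicks_bottom.copy(),
            list(array_molecule.labels),
        )
    ]
    denatured = False
    for step in plan.steps:
        kind = step[0]
        if kind == "digest":
            enzyme_name = step[1]
            if enzyme_name not in enzymes:
                raise ValueError(f"enzyme {enzyme_name!r} not in registry")
            enzyme = enzymes[enzyme_name]
            cuts = np.unique(
                np.array(
                    [
                        u * unit_map.unit_length + s
                        for u in range(n_units)
                        for s in enzyme.sites
                    ],
                    dtype=np.int64,
                )
            )
            new_frags: list[Fragment] = []
            for f in frags:
                lo = np.searchsorted(cuts, f.start, side="right")
                hi = np.searchsorted(cuts, f.end, side="left")
                new_frags.extend(_split_ds_fragment(f, cuts[lo:hi]))
            frags = new_frags
            # stochastic off-target nicking, per unit and site
            for pos, strand, p in enzyme.off_target_nick_sites:
                if p <= 0:
                    continue
                hits = np.nonzero(rng.random(n_units) < p)[0]
                abs_pos = hits * unit_map.unit_length + pos
                for ap in abs_pos:
                    for f in frags:
                        if f.start < ap < f.end:
                            arr = f.nicks_top if strand == "top" else f.nicks_bottom
                            merged = np.unique(np.append(arr, ap))
                            if strand == "top":
                                f.nicks_top = merged
                            else:
                                f.nicks_bottom = merged
                            break
        elif kind == "s1":
            frags = [
                p
                for f in frags
                for p in _split_ds_fragment(
                    f, np.concatenate([f.nicks_top, f.nicks_bottom])
                )
            ]
        elif kind == "denature":
            frags = _denature_fragments(frags)
            denatured = True
        elif kind == "label":
            lp = label_params or LabelParams()
            new = []
            for f in frags:
                mol = f.as_molecule()
                labeled = label_3prime_ends(mol, lp, rng)
                tracts = [
                    replace(t, start=t.start + f.start, end=t.end + f.start)
                    for t in labeled.labels
                ]
                new.append(replace(f, labels=tracts))
            frags = new
    fset = FragmentSet(frags)
    bands = []
    for strandedness in ("ds", "top", "bottom"):
        idx = [i for i, f in enumerate(frags) if f.strandedness == strandedness]
        if not idx:
            continue
        sizes = [frags[i].length for i in idx]
        tab = gel_migrate(
            sizes,
            comigration_tol=comigration_tol,
            members=[[i] for i in idx],
        )
        tab["strandedness"] = strandedness
        bands.append(tab)
    table = pd.concat(bands, ignore_index=True)
    table["probe_detected"] = pd.NA
    del denatured
    return BandTable(table[["size_bp", "strandedness", "intensity", "members",
                            "probe_detected", "mobility"]], fset)


def probe_detect(
    band_table: BandTable,
    unit_map: RdnaUnitMap,
    probe: tuple | None = None,
    min_overlap: int = 50,
    cross_detection_p: float = 0.0,
    rng_or_seed=0,
) -> BandTable:
    """Flag bands detected by a strand-specific probe.

    A ds band is detected when any member fragment overlaps the probe
    interval (in unit coordinates, any repeat copy) by at least
    ``min_overlap`` bp.  An ss band additionally requires the fragment strand
    to be complementary to the probe strand (a sense/top probe hybridizes to
    bottom-strand fragments), with an optional small cross-detection
    probability modeling contaminating complementary strand in the probe
    preparation.
    """
    (pstart, pend), pstrand = probe if probe is not None else unit_map.probe
    complementary = "bottom" if pstrand == "top" else "top"
    rng = as_rng(rng_or_seed)
    U = unit_map.unit_length

    def frag_overlap(f: Fragment) -> int:
        best = 0
        u0 = f.start // U
        u1 = (f.end - 1) // U
        for u in range(u0, u1 + 1):
            s, e = u * U + pstart, u * U + pend
            best = max(best, min(f.end, e) - max(f.start, s))
        return best

    flags = []
    for _, row in band_table.bands.iterrows():
        members = [band_table.fragments.fragments[i] for i in row["members"]]
        hit = any(frag_overlap(f) >= min_overlap for f in members)
        if hit and row["strandedness"] != "ds":
            if row["strandedness"] != complementary:
                hit = bool(cross_detection_p > 0 and rng.random() < cross_detection_p)
        flags.append(hit)
    bands = band_table.bands.copy()
    bands["probe_detected"] = flags
    return BandTable(bands, band_table.fragments)


def _sizes(table: BandTable, strandedness) -> np.ndarray:
    sel = table.bands["strandedness"].isin(
        [strandedness] if isinstance(strandedness, str) else strandedness
    )
    return table.bands.loc[sel, "size_bp"].to_numpy(dtype=float)


def _present(size: float, pool: np.ndarray, tol: float) -> bool:
    if not len(pool):
        return False
    return bool(np.min(np.abs(pool - size) / np.minimum(pool, size)) <= tol)


def classify_band_origin(
    bands_s1_first: BandTable,
    bands_re_first: BandTable,
    bands_denat: BandTable,
    size_tol: float = 0.02,
) -> pd.DataFrame:
    """Label each band of the enzyme-first experiment by its origin.

    A band of the RE-first (digest-then-S1) table is ``endogenous`` when a
    band of matching size (relative tolerance ``size_tol``, gel-resolution
    scale) appears in the S1-first table or among the single-strand bands of
    the denaturing experiment; it is ``off_target`` when it appears in
    neither — the signature of a nick introduced by the restriction enzyme
    itself, which the S1-first ordering could not have converted.  Bands seen
    only outside the RE-first table are ``ambiguous``.
    """
    if size_tol <= 0:
        raise ValueError("size_tol must be > 0")
    s1_sizes = _sizes(bands_s1_first, ["ds", "top", "bottom"])
    denat_sizes = _sizes(bands_denat, ["top", "bottom"])
    rows = []
    for _, row in bands_re_first.bands.iterrows():
        size = float(row["size_bp"])
        in_s1 = _present(size, s1_sizes, size_tol)
        in_denat = _present(size, denat_sizes, size_tol)
        label = "endogenous" if (in_s1 or in_denat) else "off_target"
        rows.append(
            {
                "size_bp": size,
                "strandedness": row["strandedness"],
                "in_s1_first": in_s1,
                "in_denaturing": in_denat,
                "origin": label,
            }
        )
    re_sizes = _sizes(bands_re_first, ["ds", "top", "bottom"])
    for extra in np.concatenate([s1_sizes, denat_sizes]):
        if not _present(float(extra), re_sizes, size_tol) and not any(
            _present(float(extra), np.array([r["size_bp"]]), size_tol) for r in rows
        ):
            rows.append(
                {
                    "size_bp": float(extra),
                    "strandedness": "unmatched",
                    "in_s1_first": True,
                    "in_denaturing": False,
                    "origin": "ambiguous",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reverse Southwestern quantification
# ---------------------------------------------------------------------------

def rsw_quantify(band_table: BandTable, noise_sd: float = 0.0, rng_or_seed=0) -> pd.DataFrame:
    """Biotin/EBr quantification of a labeled digest.

    Per band: biotin intensity is the number of 3'OH label tracts carried by
    the member fragments; EBr intensity is proportional to fragment size
    times copy number (total nucleotides in the band); the ratio is
    normalized so the band with the highest ratio is 1.0.
    """
    frags = band_table.fragments.fragments
    rows = []
    for _, row in band_table.bands.iterrows():
        members = [frags[i] for i in row["members"]]
        biotin = float(sum(len(f.labels) for f in members))
        ebr = float(sum(f.length for f in members))
        rows.append(
            {
                "size_bp": row["size_bp"],
                "strandedness": row["strandedness"],
                "biotin_intensity": biotin,
                "ebr_intensity": ebr,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or (df["ebr_intensity"] <= 0).all():
        raise ValueError("rsw_quantify needs at least one band with positive EBr signal")
    if noise_sd > 0:
        rng = as_rng(rng_or_seed)
        df["biotin_intensity"] *= np.exp(rng.normal(0.0, noise_sd, len(df)))
    df["ratio"] = df["biotin_intensity"] / df["ebr_intensity"]
    peak = df["ratio"].max()
    if peak <= 0:
        logger.info("rsw_quantify: no biotin signal on the gel; ratios all zero")
        df["normalized_ratio"] = 0.0
    else:
        df["normalized_ratio"] = df["ratio"] / peak
    return df


def rsw_fragment_profile(
    unit_map: RdnaUnitMap,
    n_units: int = 150,
    nicked_unit_fraction: float = 0.1,
    weight_scale: float = 1.0,
    rng_or_seed=0,
    label_params: LabelParams | None = None,
) -> pd.DataFrame:
    """One full in-silico rSW experiment on a fresh array realization.

    Builds an array (site weights globally scaled by ``weight_scale`` acting
    on the per-unit nicking probability, modeling silencing mutants), labels
    3'OH ends, performs the SfiI + StuI + PvuII triple digest, and returns
    per named double-digest fragment (a..g): nick count, biotin, EBr, raw and
    max-normalized ratios.
    """
    from .synthetic_data import build_rdna_array  # local import to avoid cycle

    rng = as_rng(rng_or_seed)
    fraction = min(1.0, nicked_unit_fraction * weight_scale)
    mol, _ = build_rdna_array(unit_map, n_units, fraction, 1, rng)
    labeled = label_3prime_ends(mol, label_params or LabelParams(), rng)
    plan = TreatmentPlan.parse(["digest:SfiI", "digest:StuI", "digest:PvuII"])
    table = run_plan(labeled, plan, unit_map, rng, comigration_tol=0.0)
    intervals = unit_map.double_digest_intervals()
    U = unit_map.unit_length
    rows = []
    for name, (s, e) in intervals.items():
        members = [
            f
            for f in table.fragments
            if f.start % U == s and (f.length == e - s)
        ]
        biotin = float(sum(len(f.labels) for f in members))
        ebr = float(sum(f.length for f in members))
        rows.append(
            {
                "fragment": name,
                "size_bp": e - s,
                "n_copies": len(members),
                "biotin_intensity": biotin,
                "ebr_intensity": ebr,
                "ratio": biotin / ebr if ebr else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    peak = df["ratio"].max()
    df["normalized_ratio"] = df["ratio"] / peak if peak > 0 else 0.0
    return df


def compare_strains(
    ratios_wt: pd.DataFrame,
    ratios_mut: pd.DataFrame,
    n_boot: int = 1000,
    rng_or_seed=0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-band fold change (mutant / wild type) with a bootstrap CI.

    Inputs are long tables with columns ``band``, ``replicate`` and
    ``ratio`` (raw biotin/EBr, *not* max-normalized, so a global scaling of
    nicking survives).  Bands with zero signal in both strains are excluded
    with a note; mismatched band sets raise an error naming the bands.
    """
    rng = as_rng(rng_or_seed)
    bw = set(ratios_wt["band"])
    bm = set(ratios_mut["band"])
    if bw != bm:
        raise ValueError(f"band sets differ; unmatched: {sorted(bw ^ bm)}")
    rows = []
    alpha = (1.0 - ci) / 2.0
    for band in sorted(bw):
        wt = ratios_wt.loc[ratios_wt["band"] == band, "ratio"].to_numpy(dtype=float)
        mut = ratios_mut.loc[ratios_mut["band"] == band, "ratio"].to_numpy(dtype=float)
        if wt.mean() == 0 and mut.mean() == 0:
            logger.info("compare_strains: band %s has no signal in either strain", band)
            continue
        fold = mut.mean() / wt.mean() if wt.mean() > 0 else np.inf
        boots = np.empty(n_boot)
        for b in range(n_boot):
            w = rng.choice(wt, len(wt))
            m = rng.choice(mut, len(mut))
            boots[b] = m.mean() / w.mean() if w.mean() > 0 else np.inf
        rows.append(
            {
                "band": band,
                "fold_change": fold,
                "ci_low": float(np.quantile(boots, alpha)),
                "ci_high": float(np.quantile(boots, 1.0 - alpha)),
                "n_wt": len(wt),
                "n_mut": len(mut),
            }
        )
    return pd.DataFrame(rows)
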