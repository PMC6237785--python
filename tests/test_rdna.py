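"""rDNA unit map, treatment plans, band-origin classification and rSW
quantification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nicksim.fragmentation import Fragment, FragmentSet, LabelTract
from nicksim.rdna import (
    BandTable,
    TreatmentPlan,
    classify_band_origin,
    compare_strains,
    default_enzymes,
    probe_detect,
    rsw_fragment_profile,
    rsw_quantify,
    run_plan,
)
from nicksim.synthetic_data import RdnaUnitMap, build_rdna_array

UM = RdnaUnitMap()
U = UM.unit_length


class TestUnitMap:
    def test_stui_digest_prints_published_sizes(self):
        assert UM.digest_fragment_sizes("StuI") == [3983, 2419, 1686, 1029]
        assert sum(UM.digest_fragment_sizes("StuI")) == 9117

    def test_double_digest_contains_printed_fragments(self):
        sizes = sorted(UM.digest_fragment_sizes(["StuI", "PvuII"]))
        for printed in (757, 2061, 1165, 982, 1029):
            assert printed in sizes
        assert sum(sizes) == 9117

    def test_named_fragments_partition_unit(self):
        iv = UM.double_digest_intervals()
        edges = sorted(s for s, _ in iv.values()) + [U]
        assert edges[0] == 0
        spans = [iv[n][1] - iv[n][0] for n in sorted(iv)]
        assert sum(spans) == U

    def test_ars_fragment_carries_no_nick_sites(self):
        ars = UM.ars_fragment()
        s, e = UM.double_digest_intervals()[ars]
        for name, (pos, _) in UM.nick_sites.items():
            assert not (s <= pos < e), f"site {name} inside ARS fragment"

    def test_promoter_fragments_carry_highest_weight_density(self):
        iv = UM.double_digest_intervals()
        density = {}
        for frag, (s, e) in iv.items():
            w = sum(
                UM.nick_site_weights[n]
                for n, (pos, _) in UM.nick_sites.items()
                if s <= pos < e
            )
            density[frag] = w / (e - s)
        top3 = sorted(density, key=density.get, reverse=True)[:3]
        assert set(top3) == {"a", "c", "e"}


class TestRunPlan:
    def test_sfii_on_clean_array_single_91kb_band(self):
        mol, _ = build_rdna_array(UM, 5, 0.0, 1, 0)
        table = run_plan(mol, TreatmentPlan.parse(["digest:SfiI"]), UM, 0)
        assert len(table.bands) == 1
        row = table.bands.iloc[0]
        assert row["size_bp"] == 9117 and row["intensity"] == 5

    def test_ds_length_conservation_through_any_plan(self):
        mol, _ = build_rdna_array(UM, 6, 0.5, 1, 3)
        for steps in (["digest:StuI"], ["s1", "digest:SfiI"], ["digest:SfiI", "s1"]):
            table = run_plan(mol, TreatmentPlan.parse(steps), UM, 0, comigration_tol=0.0)
            assert table.fragments.lengths("ds").sum() == mol.length

    def test_denature_conserves_each_strand(self):
        mol, _ = build_rdna_array(UM, 4, 0.5, 1, 9)
        table = run_plan(mol, TreatmentPlan.parse(["digest:SfiI", "denature"]), UM, 0)
        assert table.fragments.lengths("top").sum() == mol.length
        assert table.fragments.lengths("bottom").sum() == mol.length

    def test_step_after_denature_rejected(self):
        with pytest.raises(ValueError, match="denatur"):
            TreatmentPlan.parse(["digest:SfiI", "denature", "s1"])

    def test_unknown_enzyme_rejected(self):
        mol, _ = build_rdna_array(UM, 2, 0.0, 1, 0)
        with pytest.raises(ValueError, match="EcoRI"):
            run_plan(mol, TreatmentPlan(((("digest"), "EcoRI"),)), UM, 0)

    def test_order_invariance_without_off_target(self):
        """[S1, digest] and [digest, S1] give identical band multisets when
        the enzyme makes no artefactual nicks — 100 random small arrays."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n_units = int(rng.integers(3, 7))
            mol, _ = build_rdna_array(UM, n_units, 0.5, 1, rng)
            enzyme = "SfiI" if trial % 2 == 0 else "StuI"
            a = run_plan(mol, TreatmentPlan.parse(["s1", f"digest:{enzyme}"]),
                         UM, 0, comigration_tol=0.0)
            b = run_plan(mol, TreatmentPlan.parse([f"digest:{enzyme}", "s1"]),
                         UM, 0, comigration_tol=0.0)
            key = lambda t: sorted(
                (r["size_bp"], r["intensity"]) for _, r in t.bands.iterrows()
            )
            assert key(a) == key(b)

    def test_off_target_adds_band_pair_only_when_enzyme_first(self):
        mol, _ = build_rdna_array(UM, 5, 0.0, 1, 0)  # no endogenous nicks
        enz = default_enzymes(UM, smai_off_target_p=1.0)
        re_first = run_plan(mol, TreatmentPlan.parse(["digest:SmaI", "s1"]),
                            UM, 0, enzymes=enz, comigration_tol=0.0)
        s1_first = run_plan(mol, TreatmentPlan.parse(["s1", "digest:SmaI"]),
                            UM, 0, enzymes=enz, comigration_tol=0.0)
        re_sizes = sorted(re_first.bands["size_bp"])
        assert re_sizes == [1200, 7917]
        assert sorted(s1_first.bands["size_bp"]) == [9117]


class TestProbeDetect:
    def test_strand_complementarity_rule(self):
        mol, _ = build_rdna_array(UM, 1, 0.0, 1, 0)
        mol.nicks_bottom = np.array([5080])  # site f, bottom strand
        table = run_plan(mol, TreatmentPlan.parse(["denature"]), UM, 0,
                         comigration_tol=0.0)
        # sense/top probe over (4100, 5100) hybridizes to bottom-strand pieces
        out = probe_detect(table, UM, probe=((4100, 5100), "top"), min_overlap=50)
        detected = out.bands[out.bands["probe_detected"]]
        assert set(detected["strandedness"]) == {"bottom"}
        assert sorted(detected["size_bp"]) == [5080]

    def test_full_unit_ds_band_always_detected(self):
        mol, _ = build_rdna_array(UM, 3, 0.0, 1, 0)
        table = run_plan(mol, TreatmentPlan.parse(["digest:SfiI"]), UM, 0)
        out = probe_detect(table, UM)
        assert out.bands["probe_detected"].all()

    def test_non_overlapping_band_undetected(self):
        mol, _ = build_rdna_array(UM, 1, 0.0, 1, 0)
        table = run_plan(mol, TreatmentPlan.parse(["digest:StuI"]), UM, 0,
                         comigration_tol=0.0)
        out = probe_detect(table, UM, probe=((4100, 5100), "top"))
        det = {row["size_bp"]: row["probe_detected"] for _, row in out.bands.iterrows()}
        assert det[2419]  # [3983, 6402) spans the probe
        assert not det[1029] and not det[1686] and not det[3983]


def _expected_origin_classes(nicks: pd.DataFrame, off_site: int, n_units: int):
    """Oracle: per-unit enumeration of the digest+S1 fragment sizes, each
    size classed by whether an off-target incision forms one of its ends."""
    endo_sizes, off_sizes = set(), set()
    rel = {int(u): [] for u in range(n_units)}
    for _, row in nicks.iterrows():
        rel[int(row["unit"])].append(int(row["position"]) % U)
    for u in range(n_units):
        cuts = sorted(set(rel[u]) | {off_site})
        edges = [0] + cuts + [U]
        for a, b in zip(edges[:-1], edges[1:]):
            if a == off_site or b == off_site:
                off_sizes.add(b - a)
            else:
                endo_sizes.add(b - a)
    return endo_sizes, off_sizes


class TestClassifyBandOrigin:
    def test_planted_labels_recovered_in_100_trials(self):
        """Endogenous nicks stay 'endogenous', enzyme artefacts become
        'off_target', against the known plant, in 100/100 random arrays."""
        enz = default_enzymes(UM, smai_off_target_p=1.0)
        n_units = 8
        successes = 0
        for trial in range(100):
            mol, nicks = build_rdna_array(UM, n_units, 0.4, 1, 1000 + trial)
            if len(nicks) == 0:
                mol, nicks = build_rdna_array(UM, n_units, 0.9, 1, 5000 + trial)
            re_first = run_plan(mol, TreatmentPlan.parse(["digest:SmaI", "s1"]),
                                UM, 0, enzymes=enz, comigration_tol=0.0)
            s1_first = run_plan(mol, TreatmentPlan.parse(["s1", "digest:SmaI"]),
                                UM, 0, enzymes=enz, comigration_tol=0.0)
            denat = run_plan(mol, TreatmentPlan.parse(["digest:SfiI", "denature"]),
                             UM, 0, enzymes=enz, comigration_tol=0.0)
            result = classify_band_origin(s1_first, re_first, denat)
            endo_sizes, off_sizes = _expected_origin_classes(nicks, 1200, n_units)
            ok = True
            for _, row in result.iterrows():
                if row["strandedness"] == "unmatched":
                    continue
                size = row["size_bp"]
                expected = (
                    "off_target"
                    if any(abs(size - o) / min(size, o) <= 0.02 for o in off_sizes)
                    else "endogenous"
                )
                assert size in off_sizes or size in endo_sizes
                ok = ok and (row["origin"] == expected)
            successes += ok
        assert successes == 100

    def test_no_nicks_all_canonical_bands_endogenous(self):
        mol, _ = build_rdna_array(UM, 4, 0.0, 1, 0)
        tabs = {
            name: run_plan(mol, TreatmentPlan.parse(steps), UM, 0, comigration_tol=0.0)
            for name, steps in {
                "s1": ["s1", "digest:SfiI"],
                "re": ["digest:SfiI", "s1"],
                "den": ["digest:SfiI", "denature"],
            }.items()
        }
        out = classify_band_origin(tabs["s1"], tabs["re"], tabs["den"])
        assert (out["origin"] == "endogenous").all()

    def test_zero_tolerance_rejected(self):
        mol, _ = build_rdna_array(UM, 2, 0.0, 1, 0)
        t = run_plan(mol, TreatmentPlan.parse(["digest:SfiI"]), UM, 0)
        with pytest.raises(ValueError):
            classify_band_origin(t, t, t, size_tol=0.0)


def _band_table_with_label_counts(counts, length=1000):
    frags = []
    for i, c in enumerate(counts):
        labels = [
            LabelTract("top", j * 10, j * 10 + 5, "nick") for j in range(c)
        ]
        frags.append(Fragment("synthetic", 0, length, "ds", labels=labels))
    bands = pd.DataFrame(
        {
            "size_bp": [float(length)] * len(counts),
            "strandedness": "ds",
            "intensity": 1.0,
            "members": [[i] for i in range(len(counts))],
            "probe_detected": pd.NA,
            "mobility": 1.0,
        }
    )
    return BandTable(bands, FragmentSet(frags))


class TestRswQuantify:
    def test_label_counts_four_one_zero(self):
        table = _band_table_with_label_counts([4, 1, 0])
        out = rsw_quantify(table)
        assert list(out["normalized_ratio"]) == [1.0, 0.25, 0.0]

    def test_single_labeled_band_normalizes_to_one(self):
        out = rsw_quantify(_band_table_with_label_counts([2]))
        assert list(out["normalized_ratio"]) == [1.0]

    def test_all_zero_biotin_gives_zero_ratios(self, caplog):
        with caplog.at_level("INFO"):
            out = rsw_quantify(_band_table_with_label_counts([0, 0]))
        assert (out["normalized_ratio"] == 0.0).all()

    def test_ars_fragment_ratio_zero_with_default_weights(self):
        prof = rsw_fragment_profile(UM, 400, 0.1, 1.0, 17)
        ars = UM.ars_fragment()
        assert prof.loc[prof["fragment"] == ars, "ratio"].iloc[0] == 0.0
        assert prof["normalized_ratio"].max() == 1.0

    def test_promoter_fragments_rank_highest(self):
        prof = rsw_fragment_profile(UM, 6000, 0.1, 1.0, 23)
        ranked = prof.sort_values("normalized_ratio", ascending=False)
        assert set(ranked["fragment"].head(3)) == {"a", "c", "e"}


class TestCompareStrains:
    @staticmethod
    def _replicates(scale, seeds, n_units=2000):
        rows = []
        for s in seeds:
            prof = rsw_fragment_profile(UM, n_units, 0.1, scale, s)
            for _, r in prof.iterrows():
                rows.append({"band": r["fragment"], "replicate": s, "ratio": r["ratio"]})
        return pd.DataFrame(rows)

    def test_identical_inputs_fold_one(self):
        wt = self._replicates(1.0, range(4))
        out = compare_strains(wt, wt, n_boot=100, rng_or_seed=0)
        assert (out["fold_change"] == 1.0).all()

    def test_halved_nicking_recovered(self):
        wt = self._replicates(1.0, range(10))
        mut = self._replicates(0.5, range(100, 110))
        out = compare_strains(wt, mut, n_boot=400, rng_or_seed=1, ci=0.99)
        # joint statement over six bands, hence the wider per-band interval
        assert ((out["ci_low"] <= 0.5) & (0.5 <= out["ci_high"])).all()
        assert abs(out["fold_change"].mean() - 0.5) < 0.15

    def test_zero_band_excluded_and_mismatch_reported(self):
        wt = self._replicates(1.0, range(3))
        out = compare_strains(wt, wt, n_boot=50, rng_or_seed=0)
        ars = UM.ars_fragment()
        assert ars not in set(out["band"])  # no signal in either strain
        with pytest.raises(ValueError, match="unmatched"):
            compare_strains(wt, wt[wt["band"] != "a"], n_boot=10)
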