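"""Filtering, rarefaction, first detection, attribution, and vertical patterns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

import planktrace as pt
from planktrace.tracking import first_detection, presence, shared_unique

from conftest import make_table, make_taxonomy


class TestFilterPhytoplankton:
    LINEAGES = {
        "SVa": "Eukaryota;Archaeplastida;Chlorophyta;Mamiellophyceae",
        "SVd": "Eukaryota;Alveolata;Dinoflagellata;Dinophyceae",
        "SVh": "Eukaryota;Stramenopiles;Heterokontophyta;Chrysophyceae",
        "SVx": "Eukaryota;Opisthokonta;Fungi;Ascomycota",
    }

    def table(self):
        return make_table({"s1": [5, 5, 5, 5]}, self.LINEAGES)

    def test_include_exclude_rules(self):
        tax = make_taxonomy(self.LINEAGES, {"SVh": "heterotroph"})
        out = pt.filter_phytoplankton(self.table(), tax)
        # Archaeplastida retained; dinoflagellate, heterotroph, and
        # non-target fungus all removed; samples unchanged
        assert out.sv_ids == ["SVa"]
        assert out.sample_ids == ["s1"]

    def test_heterotroph_retained_if_not_excluded(self):
        tax = make_taxonomy(self.LINEAGES, {"SVh": "heterotroph"})
        out = pt.filter_phytoplankton(self.table(), tax, exclude_heterotrophs=False)
        assert set(out.sv_ids) == {"SVa", "SVh"}

    def test_missing_taxonomy_named(self):
        tax = make_taxonomy({k: v for k, v in self.LINEAGES.items() if k != "SVx"})
        with pytest.raises(ValueError, match="SVx"):
            pt.filter_phytoplankton(self.table(), tax)

    def test_empty_include_rejected(self):
        tax = make_taxonomy(self.LINEAGES)
        with pytest.raises(ValueError, match="include"):
            pt.filter_phytoplankton(self.table(), tax, include_groups=frozenset())


class TestRarefy:
    def test_whole_sample_unchanged(self):
        t = make_table({"s1": [40, 30, 30]}, ["A", "B", "C"])
        out = pt.rarefy(t, 100, seed=0)
        assert out.counts.equals(t.counts)

    def test_column_sums_and_bounds(self, random_table):
        depth = int(random_table.sample_totals().min())
        out = pt.rarefy(random_table, depth, seed=1)
        assert (out.sample_totals() == depth).all()
        assert (out.counts.to_numpy() <= random_table.counts.to_numpy()).all()
        assert (out.counts.to_numpy() >= 0).all()

    def test_depth_validation(self, random_table):
        with pytest.raises(ValueError):
            pt.rarefy(random_table, 0, seed=0)
        with pytest.raises(ValueError, match="below"):
            pt.rarefy(random_table, 10**9, seed=0)
        with pytest.raises(ValueError, match="all samples"):
            pt.rarefy(random_table, 10**9, seed=0, drop_below=True)

    def test_drop_below_removes_shallow_samples(self):
        t = make_table({"deep": [5000, 5000], "shallow": [10, 10]}, ["A", "B"])
        out = pt.rarefy(t, 100, seed=0, drop_below=True)
        assert out.sample_ids == ["deep"]

    def test_mean_matches_hypergeometric_expectation(self):
        # {A: 50, B: 50} rarefied to 10: E[A] = 10 * 50/100 = 5
        t = make_table({f"s{i}": [50, 50] for i in range(4000)}, ["A", "B"])
        out = pt.rarefy(t, 10, seed=2)
        a = out.counts.loc["A"].to_numpy()
        sd = hypergeom(100, 50, 10).std()
        assert abs(a.mean() - 5.0) <= 3 * sd / np.sqrt(len(a))


class TestFirstDetection:
    def test_earliest_presence(self):
        t = make_table({"g1": [0, 0, 4], "g2": [3, 0, 0], "g3": [5, 2, 1]}, ["X", "Y", "Z"])
        sel = {"l1": ["g1"], "l2": ["g2"], "l3": ["g3"]}
        origin = first_detection(t, ["l1", "l2", "l3"], sel)
        # X first present in l2; Y only in l3; Z in l1 and l3 -> l1
        assert origin == {"X": "l2", "Y": "l3", "Z": "l1"}

    def test_brute_force_enumeration(self, rng):
        t = make_table(
            {f"g{i}": rng.integers(0, 3, 8) for i in range(5)},
            [f"SV{i}" for i in range(8)],
        )
        order = [f"l{i}" for i in range(5)]
        sel = {f"l{i}": [f"g{i}"] for i in range(5)}
        origin = first_detection(t, order, sel)
        for sv in t.sv_ids:
            present = [lab for lab in order if t.counts.loc[sv, sel[lab][0]] > 0]
            if present:
                assert origin[sv] == present[0]
            else:
                assert sv not in origin

    def test_empty_order_rejected(self, random_table):
        with pytest.raises(ValueError):
            first_detection(random_table, [], {})

    def test_overlapping_groups_rejected(self, random_table):
        with pytest.raises(ValueError, match="disjoint"):
            first_detection(
                random_table, ["a", "b"], {"a": ["samp0"], "b": ["samp0", "samp1"]}
            )


def two_month_meta():
    frame = pd.DataFrame(
        {"month": ["m1", "m2"], "depth_m": [10.0, 10.0], "fraction": ["large"] * 2},
        index=["s1", "s2"],
    ).rename_axis("sample_id")
    return pt.SampleMetadata(frame)


class TestAttributeTemporal:
    def test_first_month_is_its_own_origin(self, monthly_meta):
        t = make_table({"s1": [3], "s2": [1], "s3": [2], "s3deep": [0]}, ["A"])
        res = pt.attribute_temporal(t, monthly_meta, ["m1", "m2", "m3"])
        assert res[0].origins == {"m1": 1.0}

    def test_two_sv_hand_enumeration(self):
        # month-2 community: A 30 reads (first seen m1), B 70 reads (new in m2)
        t = make_table({"s1": [10, 0], "s2": [30, 70]}, ["A", "B"])
        meta = two_month_meta()
        reads = pt.attribute_temporal(t, meta, ["m1", "m2"], "reads")
        assert reads[1].origins == pytest.approx({"m1": 0.3, "m2": 0.7})
        rich = pt.attribute_temporal(t, meta, ["m1", "m2"], "richness")
        assert rich[1].origins == pytest.approx({"m1": 0.5, "m2": 0.5})

    def test_subset_month_fully_attributed_to_predecessor(self):
        t = make_table({"s1": [10, 5], "s2": [3, 7]}, ["A", "B"])
        res = pt.attribute_temporal(t, two_month_meta(), ["m1", "m2"])
        assert res[1].origins == pytest.approx({"m1": 1.0})

    def test_single_month_identity(self):
        t = make_table({"s1": [10, 5]}, ["A", "B"])
        frame = pd.DataFrame(
            {"month": ["m1"], "depth_m": [10.0], "fraction": ["large"]}, index=["s1"]
        ).rename_axis("sample_id")
        res = pt.attribute_temporal(t, pt.SampleMetadata(frame), ["m1"])
        assert len(res) == 1 and res[0].status == "ok"
        assert res[0].origins == pytest.approx({"m1": 1.0})

    def test_empty_target_reported_as_empty(self):
        t = make_table({"s1": [10], "s2": [0]}, ["A"])
        res = pt.attribute_temporal(t, two_month_meta(), ["m1", "m2"])
        assert res[1].status == "empty" and res[1].origins == {}

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n_sv, n_month = rng.integers(1, 8), rng.integers(1, 5)
        t = make_table(
            {f"s{j}": rng.integers(0, 5, n_sv) for j in range(n_month)},
            [f"SV{i}" for i in range(n_sv)],
        )
        frame = pd.DataFrame(
            {
                "month": [f"m{j}" for j in range(n_month)],
                "depth_m": 10.0,
                "fraction": "large",
            },
            index=[f"s{j}" for j in range(n_month)],
        ).rename_axis("sample_id")
        meta = pt.SampleMetadata(frame)
        for basis in ("reads", "richness"):
            for r in pt.attribute_temporal(t, meta, [f"m{j}" for j in range(n_month)], basis):
                if r.status == "ok":
                    assert sum(r.origins.values()) == pytest.approx(1.0, abs=1e-9)
                    # origins never postdate the target
                    assert all(int(o[1:]) <= int(r.target[1:]) for o in r.origins)

    def test_monotonicity_in_earlier_origin_reads(self):
        # adding target-month reads to an SV of earlier origin never lowers
        # that origin's attributed fraction
        base = make_table({"s1": [10, 0], "s2": [30, 70]}, ["A", "B"])
        more = make_table({"s1": [10, 0], "s2": [45, 70]}, ["A", "B"])
        meta = two_month_meta()
        f0 = pt.attribute_temporal(base, meta, ["m1", "m2"])[1].fraction("m1")
        f1 = pt.attribute_temporal(more, meta, ["m1", "m2"])[1].fraction("m1")
        assert f1 >= f0


class TestAttributeVertical:
    def zone_meta(self):
        frame = pd.DataFrame(
            {
                "month": "m1",
                "depth_m": [10.0, 500.0, 1000.0, 5000.0],
                "fraction": "large",
            },
            index=["surf", "meso", "bathy", "abyss"],
        ).rename_axis("sample_id")
        return pt.SampleMetadata(frame)

    def test_all_deep_svs_from_surface(self):
        t = make_table(
            {"surf": [5, 5], "meso": [1, 2], "bathy": [1, 0], "abyss": [0, 3]},
            ["A", "B"],
        )
        res = pt.attribute_vertical(t, self.zone_meta(), month="m1")
        assert all(r.origins == pytest.approx({"surface": 1.0}) for r in res)

    def test_surface_zone_is_its_own_origin(self):
        t = make_table(
            {"surf": [5, 0], "meso": [0, 0], "bathy": [0, 0], "abyss": [0, 1]},
            ["A", "B"],
        )
        res = pt.attribute_vertical(t, self.zone_meta(), month="m1")
        assert res[0].origins == {"surface": 1.0}

    def test_half_new_in_abyssopelagic(self):
        # abyssal community: X 10 reads (surface origin), Y 10 reads (abyssal first)
        t = make_table(
            {"surf": [5, 0], "meso": [0, 0], "bathy": [0, 0], "abyss": [10, 10]},
            ["X", "Y"],
        )
        res = pt.attribute_vertical(t, self.zone_meta(), month="m1")
        assert res[3].origins == pytest.approx({"surface": 0.5, "abyssopelagic": 0.5})

    def test_representative_substitution(self):
        # a 300 m epipelagic bottle stands in for a lost 500 m sample
        frame = pd.DataFrame(
            {"month": "m1", "depth_m": [10.0, 300.0, 5000.0], "fraction": "large"},
            index=["surf", "sub300", "abyss"],
        ).rename_axis("sample_id")
        meta = pt.SampleMetadata(frame)
        t = make_table({"surf": [5, 0], "sub300": [2, 4], "abyss": [1, 1]}, ["A", "B"])
        res = pt.attribute_vertical(
            t,
            meta,
            zones=("surface", "mesopelagic", "abyssopelagic"),
            representative={
                "surface": ["surf"],
                "mesopelagic": ["sub300"],
                "abyssopelagic": ["abyss"],
            },
        )
        assert res[1].origins == pytest.approx({"surface": 1 / 3, "mesopelagic": 2 / 3})
        assert res[2].origins == pytest.approx({"surface": 0.5, "mesopelagic": 0.5})


class TestRepresentativeSVs:
    def table(self):
        return make_table({"s1": [6, 5, 89], "s2": [4, 5, 91]}, ["A", "B", "C"])

    def test_above_threshold_included(self):
        hits = pt.representative_svs(self.table(), 0.05)
        assert "A" in hits.index  # 6% in s1

    def test_exact_threshold_included(self):
        hits = pt.representative_svs(self.table(), 0.05)
        assert "B" in hits.index  # exactly 5.0%
        assert hits.loc["B", "max_relative_abundance"] == pytest.approx(0.05)

    def test_below_threshold_excluded(self):
        t = make_table({"s1": [49, 951], "s2": [49, 951]}, ["A", "B"])
        hits = pt.representative_svs(t, 0.05)
        assert "A" not in hits.index  # 4.9% everywhere

    def test_scope_and_threshold_validation(self):
        with pytest.raises(ValueError):
            pt.representative_svs(self.table(), 0.0)
        with pytest.raises(ValueError, match="scope"):
            pt.representative_svs(self.table(), 0.05, scope=[])


class TestVerticalPatterns:
    def meta(self):
        frame = pd.DataFrame(
            {
                "month": "m1",
                "depth_m": [10.0, 200.0, 500.0, 1000.0, 5000.0],
                "fraction": "large",
            },
            index=["surf", "epi", "meso", "bathy", "abyss"],
        ).rename_axis("sample_id")
        return pt.SampleMetadata(frame)

    def table(self):
        # rows: epi+abysso (P1), epi only (P2), bathy only (P3),
        # epi+meso (P2 extended), absent everywhere
        return make_table(
            {
                "surf": [2, 3, 0, 1, 0],
                "epi": [0, 1, 0, 0, 0],
                "meso": [0, 0, 0, 4, 0],
                "bathy": [0, 0, 7, 0, 0],
                "abyss": [9, 0, 0, 0, 0],
            },
            ["P1sv", "P2sv", "P3sv", "EMsv", "NOsv"],
        )

    def test_three_patterns(self):
        pats = {p.sv_id: p.pattern for p in pt.classify_vertical_patterns(self.table(), self.meta())}
        assert pats["P1sv"] == "P1_surface_to_deep"
        assert pats["P2sv"] == "P2_epipelagic_only"
        assert pats["P3sv"] == "P3_deep_only"
        assert pats["EMsv"] == "P2_epipelagic_only"  # epi+meso convention

    def test_partitions_present_svs_exactly(self):
        pats = pt.classify_vertical_patterns(self.table(), self.meta())
        ids = [p.sv_id for p in pats]
        assert sorted(ids) == ["EMsv", "P1sv", "P2sv", "P3sv"]  # NOsv absent
        assert len(set(ids)) == len(ids)

    def test_zone_profile_recorded(self):
        pats = {p.sv_id: p for p in pt.classify_vertical_patterns(self.table(), self.meta())}
        assert pats["EMsv"].zones_present == ("surface", "mesopelagic")


class TestSharedUnique:
    def test_membership_classes(self):
        t = make_table({"g1": [1, 0, 2, 0], "g2": [0, 3, 1, 0]}, ["A", "B", "C", "D"])
        classes = shared_unique(t, {"g1": ["g1"], "g2": ["g2"]})
        assert classes[frozenset({"g1"})] == ["A"]
        assert classes[frozenset({"g2"})] == ["B"]
        assert classes[frozenset({"g1", "g2"})] == ["C"]
        assert sum(len(v) for v in classes.values()) == 3  # D absent everywhere

    def test_needs_two_groups(self, random_table):
        with pytest.raises(ValueError):
            shared_unique(random_table, {"only": ["samp0"]})
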