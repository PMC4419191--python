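import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pathsea.core import OmicsDataSet
from pathsea.enrichment import (
    EnrichmentConfig,
    esea,
    hypergeom_tail,
    ks_top_statistic,
    msea_iga,
    msea_ks,
    msea_ranksum,
    msea_static,
    run_enrichment,
    ssea,
)
from pathsea.adduct import group_features
from pathsea.pathway_db import (
    PathwayDatabase,
    map_features,
    mass_cluster_entries,
)
from pathsea.ranking import SignalSpec, rank_and_filter, snr_scores
from pathsea.synth import StudySpec, generate_study

from .conftest import make_design


def hypergeom_tail_oracle(k, K, n, N):
    """Exhaustive tail by enumerating counts of success draws."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / total


class TestHypergeomTail:
    def test_matches_enumeration_for_all_small_configurations(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_tail(k, K, n, N) == pytest.approx(
                            hypergeom_tail_oracle(k, K, n, N), abs=1e-12
                        )

    def test_worked_examples(self):
        assert hypergeom_tail(0, 3, 2, 10) == 1.0
        assert hypergeom_tail(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)
        assert hypergeom_tail(2, 2, 2, 4) == pytest.approx(1 / 6, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 5, 2, 4)


def _entry_db(masses, pathway_members):
    entries = pd.DataFrame(
        [
            {
                "entry_id": e,
                "entry_name": e,
                "entry_type": "compound",
                "formula": "",
                "mass": m,
            }
            for e, m in masses.items()
        ]
    )
    pw = pd.DataFrame(
        [
            {"pathway_id": pid, "pathway_name": pid, "database_label": "d"}
            for pid in pathway_members
        ]
    )
    mem = pd.DataFrame(
        [
            {"pathway_id": pid, "entry_id": e}
            for pid, ents in pathway_members.items()
            for e in ents
        ]
    )
    return PathwayDatabase(entries=entries, pathways=pw, memberships=mem)


class TestEsea:
    def _setup(self):
        # ten well-separated compounds, each matched by exactly one feature
        masses = {f"e{i}": 100.0 + 10 * i for i in range(10)}
        db = _entry_db(masses, {"pw": ["e0", "e1", "e2"]})
        corrected = {f"f{i}": 100.0 + 10 * i for i in range(10)}
        mapping = map_features(db, corrected=corrected)
        clusters = mass_cluster_entries(db)
        return db, mapping, clusters

    def test_enumeration_example(self):
        db, mapping, clusters = self._setup()
        p = esea({"f0", "f1", "f2", "f3"}, mapping, db, clusters)
        # N=10 units, K=4 selected, pathway n=3 k=3 -> C(4,3)/C(10,3)
        assert p["pw"] == pytest.approx(4 / 120, abs=1e-12)

    def test_no_selected_member_gives_one(self):
        db, mapping, clusters = self._setup()
        assert esea({"f9"}, mapping, db, clusters)["pw"] == 1.0

    def test_isobaric_compounds_collapse_to_one_unit(self):
        masses = {"a": 180.0634, "b": 180.0639, "c": 300.0, "d": 400.0}
        db = _entry_db(masses, {"pw": ["a", "b"], "bg": ["c", "d"]})
        mapping = map_features(
            db, corrected={"f1": 180.0636, "f2": 300.0, "f3": 400.0}
        )
        clusters = mass_cluster_entries(db)
        p = esea({"f1"}, mapping, db, clusters)
        # universe has 3 units (one isobaric pair + 2 singletons), K=1, n=1, k=1
        assert p["pw"] == pytest.approx(1 / 3, abs=1e-12)

    def test_invariant_to_member_list_order(self):
        db, mapping, clusters = self._setup()
        db2 = PathwayDatabase(
            entries=db.entries,
            pathways=db.pathways,
            memberships=db.memberships.iloc[::-1].reset_index(drop=True),
        )
        sel = {"f0", "f2", "f5"}
        assert esea(sel, mapping, db, clusters) == esea(sel, mapping, db2, clusters)

    def test_empty_mapping_rejected(self):
        db, _, clusters = self._setup()
        empty = map_features(db, corrected={})
        with pytest.raises(ValueError, match="matchable"):
            esea(set(), empty, db, clusters)


class TestMarkerStatistics:
    def test_static_hypergeometric_example(self):
        assert msea_static([1, 3], 10, 3) == pytest.approx(8 / 120, abs=1e-12)
        assert msea_static([], 10, 3) == 1.0
        assert msea_static([2, 7], 10, 10) == 1.0  # everything selected

    def test_iga_prefix_minimum_examples(self):
        assert msea_iga([1, 3], 10) == pytest.approx(8 / 120, abs=1e-12)
        assert msea_iga([1], 10) == pytest.approx(0.1, abs=1e-12)
        assert msea_iga([9, 10], 10) > 0.9

    def test_iga_matches_brute_force_on_random_rank_sets(self, rng):
        for _ in range(50):
            F = int(rng.integers(3, 31))
            m = int(rng.integers(1, F))
            ranks = sorted(rng.choice(np.arange(1, F + 1), m, replace=False))
            brute = min(
                hypergeom_tail_oracle(j, m, r, F)
                for j, r in enumerate(ranks, start=1)
            )
            assert msea_iga(ranks, F) == pytest.approx(brute, abs=1e-12)

    def test_ranksum_matches_enumeration_for_four_features(self):
        # all C(4,2) member placements; p = fraction with rank sum <= observed
        def exact(members):
            obs = sum(members)
            sums = [
                sum(c) for c in itertools.combinations(range(1, 5), 2)
            ]
            return sum(s <= obs for s in sums) / len(sums)

        assert msea_ranksum([1, 2], 4) == pytest.approx(exact([1, 2]), abs=1e-12)
        assert msea_ranksum([1, 2], 4) == pytest.approx(1 / 6, abs=1e-12)
        assert msea_ranksum([3, 4], 4) == pytest.approx(1.0, abs=1e-12)
        assert msea_ranksum([2, 3], 4) == pytest.approx(exact([2, 3]), abs=1e-12)

    def test_ranksum_invariant_to_member_order(self):
        assert msea_ranksum([7, 2, 5], 12) == msea_ranksum([5, 7, 2], 12)

    def test_ranksum_degenerate_member_counts_rejected(self):
        with pytest.raises(ValueError):
            msea_ranksum([], 4)
        with pytest.raises(ValueError):
            msea_ranksum([1, 2, 3, 4], 4)

    def test_ks_complete_separation(self):
        d, p = msea_ks([1, 2], 4)
        assert d == pytest.approx(1.0)
        assert p < 0.5

    def test_ks_interleaved_members_small_statistic(self):
        d, _ = msea_ks([2, 4, 6, 8], 8)
        assert 0 <= d <= 0.25

    def test_ks_statistic_bounded(self, rng):
        for _ in range(30):
            F = int(rng.integers(3, 40))
            m = int(rng.integers(1, F))
            ranks = sorted(rng.choice(np.arange(1, F + 1), m, replace=False))
            assert 0.0 <= ks_top_statistic(ranks, F) <= 1.0


def _small_dataset(x, design, label="D"):
    return OmicsDataSet(
        label=label,
        kind="other",
        feature_ids=tuple(f"f{i}" for i in range(x.shape[0])),
        intensities=x,
        design=design,
    )


class TestSsea:
    def test_matches_exhaustive_enumeration_on_four_units(self, rng):
        # 2 conditions × 2 units: only 6 distinct label assignments
        design = make_design(n_conditions=2, units_per_condition=2)
        x = rng.uniform(1, 10, (8, 4))
        x[:3, 2:] *= 4.0  # members respond to condition 2
        ds = _small_dataset(x, design)
        members = {"pw": {"D": {"f0", "f1", "f2"}}}

        def stat(des):
            ranks = np.empty(8)
            order = np.argsort(-snr_scores(x, des, None), kind="stable")
            ranks[order] = np.arange(1, 9)
            m = 3
            rs = np.sort(ranks[:3])
            j = np.arange(1, 4)
            return np.max(j / m - (rs - j) / (8 - m))

        units = design.units
        t_obs = stat(design)
        t_all = [
            stat(design.with_unit_conditions(dict(zip(units, labels))))
            for labels in set(itertools.permutations(["c1", "c1", "c2", "c2"]))
        ]
        exact = np.mean([t >= t_obs for t in t_all])
        p = ssea([ds], members, statistic="ks", permutations=3000, seed=0)
        assert p.loc["pw", "D"] == pytest.approx(exact, abs=0.03)

    def test_null_pvalues_cover_their_range(self, rng):
        design = make_design(n_conditions=2, units_per_condition=3)
        x = rng.uniform(1, 2, (30, 6))
        ds = _small_dataset(x, design)
        members = {f"pw{i}": {"D": {f"f{i}", f"f{i+10}"}} for i in range(10)}
        P = 200
        p = ssea([ds], members, statistic="ranksum", permutations=P, seed=1)
        vals = p["D"].to_numpy()
        assert np.all(vals >= 1 / (1 + P))
        assert 0.15 < vals.mean() < 0.85

    def test_smoothing_lower_bound_for_extreme_member_sets(self, rng):
        design = make_design(n_conditions=2, units_per_condition=3)
        x = rng.uniform(1, 2, (10, 6))
        x[0, 3:] *= 50.0
        ds = _small_dataset(x, design)
        P = 50
        p = ssea(
            [ds], {"pw": {"D": {"f0"}}}, statistic="ks", permutations=P, seed=2
        )
        assert p.loc["pw", "D"] >= 1 / (1 + P)


@pytest.fixture(scope="module")
def study():
    datasets, db, truth = generate_study(StudySpec(seed=1))
    ms, tr = datasets
    corr = group_features(ms)
    rankings = {
        "MS1": rank_and_filter(ms, permutations=100, seed=2),
        "T1": rank_and_filter(tr, permutations=100, seed=3),
    }
    return datasets, db, truth, corr, rankings


class TestRunEnrichment:

    def test_oversized_pathway_excluded(self, study):
        datasets, db, truth, corr, rankings = study
        big = pd.DataFrame(
            [{"pathway_id": "huge", "entry_id": e} for e in db.entries["entry_id"]]
        )
        db_big = PathwayDatabase(
            entries=db.entries,
            pathways=pd.concat(
                [
                    db.pathways,
                    pd.DataFrame(
                        [
                            {
                                "pathway_id": "huge",
                                "pathway_name": "global",
                                "database_label": "synthetic",
                            }
                        ]
                    ),
                ],
                ignore_index=True,
            ),
            memberships=pd.concat([db.memberships, big], ignore_index=True),
        )
        cfg = EnrichmentConfig(mode="entry", max_pathway_entries=db_big.entry_count("huge") - 1)
        table = run_enrichment(
            cfg, datasets, db_big, rankings=rankings, corrections={"MS1": corr}
        )
        assert "huge" not in set(table["pathway_id"])

    def test_counts_match_generator_truth(self, study):
        datasets, db, truth, corr, rankings = study
        cfg = EnrichmentConfig(mode="entry")
        table = run_enrichment(
            cfg, datasets, db, rankings=rankings, corrections={"MS1": corr}
        ).set_index("pathway_id")
        enriched = truth.enriched_pathways().pop()
        row = table.loc[enriched]
        # independent bookkeeping from ground truth
        members = set(db.members(enriched))
        sel_ms = set(rankings["MS1"].passed_ids())
        sel_tr = set(rankings["T1"].passed_ids())
        parent = truth.true_groups("MS1")
        f_expect = sum(1 for f in sel_ms if parent.get(f) in members) + sum(
            1 for f in sel_tr if f in members
        )
        # mass matching may add coincidental hits, never lose true ones
        assert row["F"] >= f_expect * 0.9
        assert row["M"] <= len([m for m in members if m.startswith("M")])
        assert row["G"] == len([g for g in members if g in sel_tr])

    def test_output_sorted_by_fdr_then_meta_p(self, study):
        datasets, db, truth, corr, rankings = study
        cfg = EnrichmentConfig(mode="marker", statistic="ranksum")
        table = run_enrichment(
            cfg, datasets, db, rankings=rankings, corrections={"MS1": corr}
        )
        assert list(table["fdr"]) == sorted(table["fdr"])
        assert table.iloc[0]["pathway_id"] in truth.enriched_pathways()

    def test_sample_mode_config_validation(self):
        with pytest.raises(ValueError, match="ranksum or ks"):
            EnrichmentConfig(mode="sample", statistic="hypergeom_static")
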