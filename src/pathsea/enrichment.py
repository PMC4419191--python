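"""Pathway set-enrichment analysis in three modes.

*Entry-based* (E-SEA): over-representation of matched database entries
among the entries matched by the selected features, tested with an exact
hypergeometric upper tail.  For MS data the compound entries are collapsed
into isobaric mass clusters beforehand so that a single accurate-mass hit
cannot count several indistinguishable compounds.

*Marker/feature-based* (M-SEA): the ranks of the features matching a
pathway (as ranked by the SNR filter) are tested against a uniform draw
from all feature ranks, assuming independent features.  Available
statistics: a static hypergeometric test on the top-``n_selected`` cut, the
iterative hypergeometric (minimum prefix p, Breitling's iGA), a one-sided
rank-sum test, and a one-sided Kolmogorov-Smirnov statistic.

*Sample-based* (S-SEA): the rank statistic is recomputed under random
permutations of sample condition labels (biological units move as blocks,
linked data sets are relabeled together) and the p-value is the smoothed
fraction of permutation statistics at least as extreme as the observed
one.  This mode assumes neither independent features nor independent
entries, at the price of needing replicates and far more computation.

Unspecific "global" pathways with more than ``max_pathway_entries``
associated entries are excluded before any testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adduct import FeatureCorrection
from .core import OmicsDataSet
from .defaults import ALPHA, MASS_TOL, MAX_PATHWAY_ENTRIES, PERMUTATIONS
from .meta import bh_fdr, meta_fisher, meta_stouffer, perm_meta_fdr
from .pathway_db import (
    EntryMassCluster,
    FeatureEntryMap,
    PathwayDatabase,
    map_features,
    mass_cluster_entries,
)
from .ranking import RankingResult, SignalSpec, permute_designs, snr_scores

__all__ = [
    "EnrichmentConfig",
    "hypergeom_tail",
    "esea",
    "msea_static",
    "msea_iga",
    "msea_ranksum",
    "msea_ks",
    "ssea",
    "run_enrichment",
]

_STATISTICS = ("hypergeom_static", "hypergeom_iterative", "ranksum", "ks")


@dataclass
class EnrichmentConfig:
    """Mode, statistic, and thresholds for one enrichment run."""

    mode: str = "entry"
    statistic: str = "hypergeom_static"
    permutations: int = PERMUTATIONS
    max_pathway_entries: int = MAX_PATHWAY_ENTRIES
    mass_tol: float = MASS_TOL
    alpha: float = ALPHA
    meta_method: str = "fisher"
    fdr_method: str = "auto"  # bh | permutation | auto (permutation in sample mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("entry", "marker", "sample"):
            raise ValueError(f"unknown enrichment mode {self.mode!r}")
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.mode == "sample":
            if self.statistic not in ("ranksum", "ks"):
                raise ValueError("sample mode requires a ranksum or ks statistic")
            if self.permutations < 1:
                raise ValueError("sample mode requires at least one permutation")
        if self.meta_method not in ("fisher", "stouffer"):
            raise ValueError(f"unknown meta method {self.meta_method!r}")
        if self.fdr_method not in ("auto", "bh", "permutation"):
            raise ValueError(f"unknown FDR method {self.fdr_method!r}")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) <= N and K <= N and n <= N):
        raise ValueError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# entry-based SEA


def _unit_of_entry(
    db: PathwayDatabase, clusters: Sequence[EntryMassCluster]
) -> dict[str, str]:
    """Counting unit per entry: mass-cluster id for compounds, own id for genes."""
    unit: dict[str, str] = {}
    for cl in clusters:
        for eid in cl.entry_ids:
            unit[eid] = f"mc{cl.cluster_id}"
    for gid in db.gene_ids():
        unit[gid] = f"g:{gid}"
    return unit


def esea(
    selected: Iterable[str],
    mapping: FeatureEntryMap,
    db: PathwayDatabase,
    clusters: Sequence[EntryMassCluster],
) -> dict[str, float]:
    """Entry-based hypergeometric enrichment per pathway.

    The population is the set of counting units (isobaric mass clusters
    plus individual genes) matchable by *any* feature in the mapping; the
    successes are the units matched by the ``selected`` features.
    """
    unit_of = _unit_of_entry(db, clusters)
    selected = set(selected)
    matchable: set[str] = set()
    hit: set[str] = set()
    for fid, eid in zip(mapping.table["feature_id"], mapping.table["entry_id"]):
        u = unit_of.get(eid)
        if u is None:
            continue
        matchable.add(u)
        if fid in selected:
            hit.add(u)
    N = len(matchable)
    if N == 0:
        raise ValueError("no database entry is matchable by any feature")
    K = len(hit)
    out: dict[str, float] = {}
    for pid in db.pathway_ids:
        units = {unit_of[e] for e in db.members(pid) if e in unit_of}
        n = len(units & matchable)
        k = len(units & hit)
        out[pid] = hypergeom_tail(k, K, n, N)
    return out


# ---------------------------------------------------------------------------
# marker/feature-based SEA


def msea_static(ranks: Sequence[int], F: int, n_selected: int) -> float:
    """Static hypergeometric test: members falling in the top-``n_selected`` ranks."""
    ranks = sorted(ranks)
    if any(r < 1 or r > F for r in ranks):
        raise ValueError("ranks must lie in 1..F")
    m = len(ranks)
    if m == 0:
        return 1.0
    k = sum(1 for r in ranks if r <= n_selected)
    return hypergeom_tail(k, m, n_selected, F)


def msea_iga(ranks: Sequence[int], F: int) -> float:
    """Iterative hypergeometric score: minimum prefix p over the sorted member ranks.

    Returns min_j P(X >= j) with X ~ Hypergeometric(F, m, r_j) where r_j is
    the j-th smallest member rank.  This is a ranking *score* (the minimum
    is not corrected for the number of prefixes tried); it is treated like
    a p-value by the downstream meta/FDR machinery.
    """
    ranks = sorted(ranks)
    m = len(ranks)
    if m < 1:
        raise ValueError("need at least one member rank")
    if ranks[0] < 1 or ranks[-1] > F:
        raise ValueError("ranks must lie in 1..F")
    return min(hypergeom_tail(j, m, r, F) for j, r in enumerate(ranks, start=1))


def msea_ranksum(ranks: Sequence[int], F: int) -> float:
    """One-sided Mann-Whitney p that members rank higher (smaller rank numbers).

    Exact when m*(F-m) <= 1e6 (ranks are untied by construction), otherwise
    the normal approximation with continuity correction.
    """
    ranks = sorted(ranks)
    m = len(ranks)
    if m == 0 or m >= F:
        raise ValueError("member count must satisfy 1 <= m < F")
    if ranks[0] < 1 or ranks[-1] > F or len(set(ranks)) != m:
        raise ValueError("ranks must be distinct integers in 1..F")
    members = np.asarray(ranks, dtype=float)
    others = np.setdiff1d(np.arange(1, F + 1, dtype=float), members)
    method = "exact" if m * (F - m) <= 1_000_000 else "asymptotic"
    res = stats.mannwhitneyu(members, others, alternative="less", method=method)
    return float(res.pvalue)


def ks_top_statistic(ranks: Sequence[int], F: int) -> float:
    """One-sided two-sample KS statistic D+ toward top (small) ranks.

    D+ = max_j ( j/m - (r_j - j)/(F - m) ) over the sorted member ranks;
    it is the largest lead of the member rank ECDF over the non-member
    ECDF, in [0, 1], with 1 meaning complete separation at the top.
    """
    ranks = sorted(ranks)
    m = len(ranks)
    if m == 0 or m >= F:
        raise ValueError("member count must satisfy 1 <= m < F")
    d = 0.0
    for j, r in enumerate(ranks, start=1):
        d = max(d, j / m - (r - j) / (F - m))
    return max(d, 0.0)


def msea_ks(ranks: Sequence[int], F: int) -> tuple[float, float]:
    """One-sided KS statistic toward top ranks with its asymptotic p-value."""
    m = len(ranks)
    d = ks_top_statistic(ranks, F)
    n_eff = m * (F - m) / F
    p = float(np.exp(-2.0 * n_eff * d * d))
    return d, min(p, 1.0)


# ---------------------------------------------------------------------------
# sample-based SEA


def _rank_stat(member_idx: np.ndarray, ranks: np.ndarray, statistic: str) -> float:
    """Enrichment statistic from member indices and a full rank vector.

    Larger = more enriched toward top ranks.  Degenerate member sets
    (empty, or the whole data set) score -inf so that their p-value is 1.
    """
    F = ranks.size
    m = member_idx.size
    if m == 0 or m == F:
        return -np.inf
    r = ranks[member_idx]
    if statistic == "ks":
        rs = np.sort(r)
        j = np.arange(1, m + 1)
        return float(np.max(j / m - (rs - j) / (F - m)))
    # rank-sum, oriented: count of (member, non-member) pairs the member wins
    R = float(r.sum())
    return m * (F - m) + m * (m + 1) / 2.0 - R


def _ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(scores.size, dtype=float)
    ranks[order] = np.arange(1, scores.size + 1)
    return ranks


def ssea(
    datasets: Sequence[OmicsDataSet],
    member_features: Mapping[str, Mapping[str, Iterable[str]]],
    signal_spec: SignalSpec | None = None,
    statistic: str = "ks",
    permutations: int = 100,
    links: Iterable[Iterable[str]] | None = None,
    seed: int | np.random.Generator = 0,
    return_null: bool = False,
):
    """Sample-based SEA: permutation p-values per pathway and data set.

    ``member_features`` maps pathway id -> data-set label -> member feature
    ids; the member sets are fixed from the observed mapping and only the
    feature ranking is recomputed per permutation.  All data sets are
    relabeled together (biological units with the same id are linked, plus
    any explicit ``links``), so one permutation round yields one coherent
    null ranking per data set.

    Returns a DataFrame of observed p-values (pathways × data sets); with
    ``return_null`` also a P×npath×ndata array of per-round null p-values
    (each round ranked within the permutation distribution) for use in a
    permutation FDR.
    """
    if statistic not in ("ranksum", "ks"):
        raise ValueError("sample-based SEA requires a ranksum or ks statistic")
    if permutations < 1:
        raise ValueError("need at least one permutation")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    spec = signal_spec or SignalSpec()
    pathway_ids = list(member_features)
    labels = [ds.label for ds in datasets]
    fid_index = [
        {f: i for i, f in enumerate(ds.feature_ids)} for ds in datasets
    ]
    member_idx = [
        [
            np.array(
                sorted(
                    fid_index[d][f]
                    for f in member_features[pid].get(labels[d], ())
                    if f in fid_index[d]
                ),
                dtype=int,
            )
            for d in range(len(datasets))
        ]
        for pid in pathway_ids
    ]

    def all_stats(designs) -> np.ndarray:
        out = np.empty((len(pathway_ids), len(datasets)))
        for d, ds in enumerate(datasets):
            ranks = _ranks_from_scores(snr_scores(ds.intensities, designs[d], spec))
            for pi in range(len(pathway_ids)):
                out[pi, d] = _rank_stat(member_idx[pi][d], ranks, statistic)
        return out

    t_obs = all_stats([ds.design for ds in datasets])
    t_perm = np.empty((permutations, len(pathway_ids), len(datasets)))
    for p in range(permutations):
        designs = permute_designs([ds.design for ds in datasets], rng, links=links)
        t_perm[p] = all_stats(designs)

    with np.errstate(invalid="ignore"):
        p_obs = (1 + (t_perm >= t_obs[None]).sum(axis=0)) / (1 + permutations)
    obs_df = pd.DataFrame(p_obs, index=pathway_ids, columns=labels)
    if not return_null:
        return obs_df
    # per-round null p, exchangeable with the observed p: each round is
    # ranked against the other P-1 rounds plus the observed statistic, with
    # the same +1/(P+1) smoothing
    null_p = np.empty_like(t_perm)
    for pi in range(len(pathway_ids)):
        for d in range(len(datasets)):
            col = t_perm[:, pi, d]
            srt = np.sort(col)
            ge_others = (
                permutations - np.searchsorted(srt, col, side="left") - 1
            )  # rounds != self with statistic >= this round's
            ge_obs = (t_obs[pi, d] >= col).astype(int)
            null_p[:, pi, d] = (1 + ge_others + ge_obs) / (1 + permutations)
    return obs_df, null_p


# ---------------------------------------------------------------------------
# orchestration


def _pathway_member_features(
    db: PathwayDatabase,
    mapping: FeatureEntryMap,
    correction: FeatureCorrection | None,
    priority: Mapping[str, float],
) -> dict[str, set[str]]:
    """Member feature set per pathway with adduct-group deduplication.

    Features in the same adduct group that match the same entry are
    redundant ion species of one putative metabolite: only the
    representative with the lowest ``priority`` value is kept per
    (group, entry).  Marker mode uses the observed rank as priority;
    sample mode must use a rank-independent priority (the strongest ion)
    because its member sets are fixed before the permutation test.
    """
    group_of = correction.group_of() if correction is not None else {}
    by_entry: dict[str, list[str]] = {}
    for fid, eid in zip(mapping.table["feature_id"], mapping.table["entry_id"]):
        by_entry.setdefault(eid, []).append(fid)
    dedup_by_entry: dict[str, set[str]] = {}
    for eid, fids in by_entry.items():
        if group_of:
            best: dict[int, str] = {}
            for f in sorted(fids):
                g = group_of.get(f, -1)
                cur = best.get(g)
                if cur is None or priority.get(f, np.inf) < priority.get(cur, np.inf):
                    best[g] = f
            dedup_by_entry[eid] = set(best.values())
        else:
            dedup_by_entry[eid] = set(fids)
    out: dict[str, set[str]] = {}
    for pid in db.pathway_ids:
        members: set[str] = set()
        for eid in db.members(pid):
            members |= dedup_by_entry.get(eid, set())
        out[pid] = members
    return out


def run_enrichment(
    config: EnrichmentConfig,
    datasets: Sequence[OmicsDataSet],
    db: PathwayDatabase,
    rankings: Mapping[str, RankingResult] | None = None,
    corrections: Mapping[str, FeatureCorrection] | None = None,
    selection: Mapping[str, Iterable[str]] | None = None,
    signal_spec: SignalSpec | None = None,
    links: Iterable[Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Full per-pathway enrichment table across data sets, with meta-p and FDR.

    ``rankings`` supply feature ranks and the default selection (features
    passing the SNR filter); ``corrections`` supply corrected masses and
    adduct groups for metabolomics data sets; an explicit ``selection``
    (feature ids per data-set label) overrides the default.

    Output columns: database, pathway_id, pathway, F (selected features
    matched over all data sets), M (matched metabolite entries), G
    (matched gene entries), p_<label> per data set, meta_p, fdr; sorted by
    fdr, then meta_p, then pathway name.
    """
    corrections = corrections or {}
    rankings = rankings or {}
    labels = [ds.label for ds in datasets]

    # pathway-size exclusion happens before any universe or test computation
    keep = [
        pid
        for pid in db.pathway_ids
        if db.entry_count(pid) <= config.max_pathway_entries
    ]
    if not keep:
        warnings.warn("no pathway survives the size filter", UserWarning, stacklevel=2)
        return pd.DataFrame(
            columns=["database", "pathway_id", "pathway", "F", "M", "G", "meta_p", "fdr"]
        )
    db = db.restrict_pathways(keep)
    clusters = mass_cluster_entries(db, config.mass_tol)

    mappings: dict[str, FeatureEntryMap] = {}
    for ds in datasets:
        if ds.kind == "metabolomics":
            corr = corrections.get(ds.label)
            if corr is None:
                raise ValueError(
                    f"metabolomics data set {ds.label!r} needs an adduct correction"
                )
            mappings[ds.label] = map_features(
                db, corrected=corr, mass_tol=config.mass_tol
            )
        else:
            mappings[ds.label] = map_features(db, gene_features=list(ds.feature_ids))

    def selected_of(label: str) -> set[str]:
        if selection is not None and label in selection:
            return set(selection[label])
        if label in rankings:
            return set(rankings[label].passed_ids())
        return set()

    pvals = pd.DataFrame(1.0, index=db.pathway_ids, columns=labels)
    null_meta = None

    if config.mode == "entry":
        for ds in datasets:
            try:
                p = esea(selected_of(ds.label), mappings[ds.label], db, clusters)
            except ValueError:
                continue  # nothing matchable in this data set: contribute p=1
            for pid, v in p.items():
                pvals.loc[pid, ds.label] = v
    elif config.mode == "marker":
        for ds in datasets:
            ranking = rankings.get(ds.label)
            if ranking is None:
                raise ValueError(
                    f"marker mode requires a ranking for data set {ds.label!r}"
                )
            rank_of = ranking.ranks()
            members = _pathway_member_features(
                db, mappings[ds.label], corrections.get(ds.label), rank_of
            )
            F = len(ds.feature_ids)
            n_sel = len(selected_of(ds.label))
            for pid in db.pathway_ids:
                ranks = sorted(rank_of[f] for f in members[pid])
                if not ranks:
                    continue
                if config.statistic == "hypergeom_static":
                    p = msea_static(ranks, F, n_sel)
                elif config.statistic == "hypergeom_iterative":
                    p = msea_iga(ranks, F)
                elif config.statistic == "ranksum":
                    p = msea_ranksum(ranks, F) if len(ranks) < F else 1.0
                else:
                    p = msea_ks(ranks, F)[1] if len(ranks) < F else 1.0
                pvals.loc[pid, ds.label] = p
    else:  # sample mode
        member_features = {
            pid: {} for pid in db.pathway_ids
        }  # type: dict[str, dict[str, set[str]]]
        for ds in datasets:
            # rank-free priority: the strongest ion represents its adduct group
            strength = dict(
                zip(ds.feature_ids, -ds.intensities.max(axis=1))
            )
            members = _pathway_member_features(
                db, mappings[ds.label], corrections.get(ds.label), strength
            )
            for pid in db.pathway_ids:
                member_features[pid][ds.label] = members[pid]
        obs_df, null_p = ssea(
            datasets,
            member_features,
            signal_spec=signal_spec,
            statistic=config.statistic,
            permutations=config.permutations,
            links=links,
            seed=config.seed,
            return_null=True,
        )
        pvals.loc[obs_df.index, obs_df.columns] = obs_df
        combine = meta_fisher if config.meta_method == "fisher" else meta_stouffer
        null_meta = np.array(
            [
                [combine(np.clip(null_p[r, pi], 1e-300, 1.0)) for pi in range(null_p.shape[1])]
                for r in range(null_p.shape[0])
            ]
        )

    combine = meta_fisher if config.meta_method == "fisher" else meta_stouffer
    meta_p = np.array([combine(pvals.loc[pid].to_numpy()) for pid in db.pathway_ids])

    fdr_method = config.fdr_method
    if fdr_method == "auto":
        fdr_method = "permutation" if config.mode == "sample" else "bh"
    if fdr_method == "permutation":
        if null_meta is None:
            raise ValueError("permutation FDR requires sample-mode null meta-p-values")
        fdr = perm_meta_fdr(meta_p, null_meta)
    else:
        fdr = bh_fdr(meta_p)

    # F/M/G bookkeeping over all data sets, counting selected features only
    rows = []
    pw = db.pathways.set_index("pathway_id")
    for i, pid in enumerate(db.pathway_ids):
        members = set(db.members(pid))
        f_count = 0
        matched_entries: set[str] = set()
        for ds in datasets:
            sel = selected_of(ds.label)
            t = mappings[ds.label].table
            hit = t[t["entry_id"].isin(members) & t["feature_id"].isin(sel)]
            f_count += hit["feature_id"].nunique()
            matched_entries |= set(hit["entry_id"])
        types = db.entries.set_index("entry_id")["entry_type"]
        m_count = sum(1 for e in matched_entries if types.get(e) == "compound")
        g_count = sum(1 for e in matched_entries if types.get(e) == "gene")
        row = {
            "database": pw.loc[pid, "database_label"],
            "pathway_id": pid,
            "pathway": pw.loc[pid, "pathway_name"],
            "F": f_count,
            "M": m_count,
            "G": g_count,
        }
        for label in labels:
            row[f"p_{label}"] = pvals.loc[pid, label]
        row["meta_p"] = meta_p[i]
        row["fdr"] = fdr[i]
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["fdr", "meta_p", "pathway"], kind="stable"
    ).reset_index(drop=True)
    if out.empty:
        warnings.warn("enrichment produced no testable pathway", UserWarning, stacklevel=2)
    return out
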