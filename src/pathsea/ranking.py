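"""Signal-to-noise ranking with replicate-linked permutation FDR.

Each feature is scored by a signal-to-noise ratio (SNR): the signal is a
difference of aggregated condition-mean intensities and the noise is the
pooled within-condition sample standard deviation,

    noise = sqrt( sum_c sum_{j in c} (x_cj - m_c)^2 / (N - C) ).

With the default ``full_range`` signal the numerator is the difference
between the largest and smallest condition mean; a ``subset_contrast``
signal compares the max/min/mean of condition means over two disjoint
condition subsets, which turns the ratio into a targeted pattern search
(e.g. "induced in conditions 2-3 relative to everything else").

No distributional assumption is made about the intensities.  Significance
is assessed by permuting condition labels over *biological units* — all
technical replicates of a biological sample move together, and linked data
sets measured on the same biological material are relabeled identically —
and converting the permuted score distribution into SAM-style q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import OmicsDataSet, SampleDesign
from .defaults import ALPHA, LABEL_RATIO, PERMUTATIONS

__all__ = [
    "SignalSpec",
    "RankingResult",
    "snr",
    "snr_scores",
    "permute_design",
    "permute_designs",
    "permutation_fdr",
    "rank_and_filter",
    "label_by_ratio",
]

_AGGS = {"max": np.max, "min": np.min, "mean": np.mean}


@dataclass(frozen=True)
class SignalSpec:
    """Definition of the SNR numerator.

    ``full_range``: max minus min over all condition means.
    ``subset_contrast``: ``agg_a`` over the condition means of ``subset_a``
    minus ``agg_b`` over those of ``subset_b``; the subsets must be disjoint
    and non-empty.
    """

    mode: str = "full_range"
    subset_a: tuple[str, ...] = ()
    subset_b: tuple[str, ...] = ()
    agg_a: str = "max"
    agg_b: str = "max"

    def __post_init__(self) -> None:
        if self.mode not in ("full_range", "subset_contrast"):
            raise ValueError(f"unknown signal mode {self.mode!r}")
        if self.mode == "subset_contrast":
            if not self.subset_a or not self.subset_b:
                raise ValueError("subset_contrast requires two non-empty subsets")
            if set(self.subset_a) & set(self.subset_b):
                raise ValueError("condition subsets must be disjoint")
            for agg in (self.agg_a, self.agg_b):
                if agg not in _AGGS:
                    raise ValueError(f"unknown aggregator {agg!r}")

    @classmethod
    def full_range(cls) -> "SignalSpec":
        return cls()

    @classmethod
    def contrast(
        cls,
        subset_a: Sequence[str],
        subset_b: Sequence[str],
        agg_a: str = "max",
        agg_b: str = "max",
    ) -> "SignalSpec":
        return cls(
            mode="subset_contrast",
            subset_a=tuple(subset_a),
            subset_b=tuple(subset_b),
            agg_a=agg_a,
            agg_b=agg_b,
        )


@dataclass
class RankingResult:
    """Per-feature score, rank, permutation q-value, pass flag, and label.

    ``table`` columns: feature_id, score, rank, qvalue, passed, label.
    """

    table: pd.DataFrame
    spec: SignalSpec
    alpha: float = ALPHA

    def passed_ids(self) -> tuple[str, ...]:
        return tuple(self.table.loc[self.table["passed"], "feature_id"])

    def labeled_ids(self, label: str) -> tuple[str, ...]:
        return tuple(self.table.loc[self.table["label"] == label, "feature_id"])

    def ranks(self) -> dict[str, int]:
        return dict(zip(self.table["feature_id"], self.table["rank"]))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _condition_columns(design: SampleDesign) -> list[np.ndarray]:
    conds = design.conditions
    return [
        np.array(
            [j for j, s in enumerate(design.sample_ids) if design.condition_of[s] == c]
        )
        for c in conds
    ]


def snr_scores(
    intensities: np.ndarray, design: SampleDesign, spec: SignalSpec | None = None
) -> np.ndarray:
    """Vectorized SNR over the rows of an F×S intensity matrix."""
    spec = spec or SignalSpec()
    x = np.atleast_2d(np.asarray(intensities, dtype=float))
    N = x.shape[1]
    conds = design.conditions
    C = len(conds)
    if N <= C:
        raise ValueError(
            f"noise undefined: {N} samples for {C} conditions (need N > C)"
        )
    cols = _condition_columns(design)
    means = np.column_stack([x[:, idx].mean(axis=1) for idx in cols])
    ss_within = sum(
        ((x[:, idx] - means[:, [k]]) ** 2).sum(axis=1) for k, idx in enumerate(cols)
    )
    noise = np.sqrt(ss_within / (N - C))

    if spec.mode == "full_range":
        signal = means.max(axis=1) - means.min(axis=1)
    else:
        pos = {c: k for k, c in enumerate(conds)}
        missing = [c for c in spec.subset_a + spec.subset_b if c not in pos]
        if missing:
            raise ValueError(f"unknown condition in signal subsets: {missing[0]!r}")
        ia = [pos[c] for c in spec.subset_a]
        ib = [pos[c] for c in spec.subset_b]
        signal = _AGGS[spec.agg_a](means[:, ia], axis=1) - _AGGS[spec.agg_b](
            means[:, ib], axis=1
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        score = signal / noise
    zero_noise = noise == 0
    score[zero_noise & (signal > 0)] = np.inf
    score[zero_noise & (signal < 0)] = -np.inf
    score[zero_noise & (signal == 0)] = 0.0
    return score


def snr(
    values: Sequence[float], design: SampleDesign, spec: SignalSpec | None = None
) -> float:
    """SNR score of a single feature's per-sample intensity vector."""
    return float(snr_scores(np.asarray(values, dtype=float)[None, :], design, spec)[0])


def _linked_groups(
    designs: Sequence[SampleDesign],
    links: Iterable[Iterable[str]] | None,
) -> tuple[list[list[tuple[int, str]]], list[str]]:
    """Group biological units that must receive the same permuted label.

    By default units with the same id in different designs are linked (they
    are the same biological sample measured on several platforms).  Explicit
    ``links`` (iterables of unit ids) merge further units; a link naming an
    unknown unit is an error.
    """
    unit_home: dict[str, list[int]] = {}
    for di, d in enumerate(designs):
        for u in d.units:
            unit_home.setdefault(u, []).append(di)
    group_of: dict[str, str] = {u: u for u in unit_home}
    if links is not None:
        for link in links:
            link = list(link)
            for u in link:
                if u not in unit_home:
                    raise ValueError(f"link references unknown unit {u!r}")
            root = group_of[link[0]]
            for u in link:
                old = group_of[u]
                for v, g in list(group_of.items()):
                    if g == old:
                        group_of[v] = root
    groups: dict[str, list[tuple[int, str]]] = {}
    order: list[str] = []
    for di, d in enumerate(designs):
        for u in d.units:
            g = group_of[u]
            if g not in groups:
                groups[g] = []
                order.append(g)
            groups[g].append((di, u))
    conds = []
    for g in order:
        cs = {designs[di].condition_of_unit(u) for di, u in groups[g]}
        if len(cs) != 1:
            raise ValueError(
                f"linked units {groups[g]} carry different conditions {sorted(cs)}"
            )
        conds.append(cs.pop())
    return [groups[g] for g in order], conds


def permute_designs(
    designs: Sequence[SampleDesign],
    rng: np.random.Generator,
    links: Iterable[Iterable[str]] | None = None,
) -> list[SampleDesign]:
    """Permute condition labels jointly over the biological units of linked designs.

    Labels are permuted uniformly over unit groups (preserving the condition
    multiset); all technical replicates of a unit, and all occurrences of a
    linked unit across data sets, receive the same new label.
    """
    groups, conds = _linked_groups(designs, links)
    perm = rng.permutation(len(groups))
    new_cond_per_design: list[dict[str, str]] = [dict() for _ in designs]
    for gi, members in enumerate(groups):
        c = conds[perm[gi]]
        for di, u in members:
            new_cond_per_design[di][u] = c
    return [
        d.with_unit_conditions(new_cond_per_design[di])
        for di, d in enumerate(designs)
    ]


def permute_design(
    design: SampleDesign, rng: np.random.Generator
) -> SampleDesign:
    """Permute condition labels over the biological units of one design."""
    return permute_designs([design], rng)[0]


def permutation_fdr(
    observed: np.ndarray, permuted: np.ndarray, monotonize: bool = True
) -> np.ndarray:
    """SAM-style q-values from observed scores and a P×F permuted score matrix.

    For each observed score t the raw FDR is the mean permutation count of
    scores >= t divided by the observed count of scores >= t, capped at 1.
    With ``monotonize`` the q-values are made non-increasing in the score
    (each q becomes the minimum raw FDR over all thresholds at or below it).
    """
    obs = np.asarray(observed, dtype=float)
    perm = np.atleast_2d(np.asarray(permuted, dtype=float))
    P = perm.shape[0]
    if P < 1:
        raise ValueError("need at least one permutation")
    F = obs.size
    order = np.argsort(-obs, kind="stable")
    sorted_obs = obs[order]
    pooled = np.sort(perm.ravel())
    n_ge_perm = pooled.size - np.searchsorted(pooled, sorted_obs, side="left")
    obs_sorted_asc = np.sort(obs)
    n_ge_obs = F - np.searchsorted(obs_sorted_asc, sorted_obs, side="left")
    q = np.minimum(1.0, (n_ge_perm / P) / n_ge_obs)
    if monotonize:
        q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(F)
    out[order] = q
    return out


def rank_and_filter(
    ds: OmicsDataSet,
    spec: SignalSpec | None = None,
    permutations: int = PERMUTATIONS,
    alpha: float = ALPHA,
    seed: int | np.random.Generator = 0,
    monotonize: bool = True,
) -> RankingResult:
    """Score, rank, and filter one data set by SNR with a permutation FDR.

    Ranks are 1..F with 1 the largest score; ties keep input order.
    ``passed`` is ``qvalue < alpha``.
    """
    spec = spec or SignalSpec()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    obs = snr_scores(ds.intensities, ds.design, spec)
    perm = np.empty((permutations, ds.n_features))
    for p in range(permutations):
        d = permute_design(ds.design, rng)
        perm[p] = snr_scores(ds.intensities, d, spec)
    q = permutation_fdr(obs, perm, monotonize=monotonize)
    order = np.argsort(-obs, kind="stable")
    ranks = np.empty(len(obs), dtype=int)
    ranks[order] = np.arange(1, len(obs) + 1)
    table = pd.DataFrame(
        {
            "feature_id": list(ds.feature_ids),
            "score": obs,
            "rank": ranks,
            "qvalue": q,
            "passed": q < alpha,
            "label": [""] * len(obs),
        }
    )
    return RankingResult(table=table, spec=spec, alpha=alpha)


def label_by_ratio(
    result: RankingResult,
    tau: float = LABEL_RATIO,
    label: str = "wt",
) -> RankingResult:
    """Attach ``label`` to every feature whose SNR score strictly exceeds ``tau``."""
    table = result.table.copy()
    table.loc[table["score"] > tau, "label"] = label
    return replace(result, table=table)
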