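"""Adduct/isotope correction and grouping of co-eluting MS features.

In electrospray ionization one neutral metabolite typically appears as
several ion features: protonated/deprotonated species, alkali adducts,
and heavier isotopologues.  Each correction rule maps an observed m/z back
to a putative neutral monoisotopic mass::

    M = m/z - delta - k * 1.003355

where ``delta`` is the adduct mass shift (for singly charged species) and
``k`` counts extra neutrons (1.003355 Da apiece).  Features whose corrected
masses agree within a mass tolerance and that co-elute within a
retention-time tolerance are grouped into one putative metabolite; the
group's representative mass is the intensity-weighted mean of the member
corrected masses.

The grouping heuristic is deterministic: features are processed in a
canonical order (descending maximum intensity, ties by feature id), the
strongest unassigned feature seeds a group under its mode's default rule
([M+H]+ or [M-H]-), and unassigned features with any rule candidate within
``mass_tol`` of the running representative mass and ``rt_tol`` of the seed's
retention time are absorbed greedily.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import OmicsDataSet
from .defaults import MASS_TOL, RT_TOL

__all__ = [
    "ISOTOPE_SPACING",
    "CorrectionRule",
    "default_rules",
    "read_rules",
    "write_rules",
    "correct_mass",
    "FeatureCorrection",
    "group_features",
]

ISOTOPE_SPACING = 1.003355  # Da per extra neutron (13C - 12C)

_POSITIVE_BASE = (
    ("[M+H]+", 1.007276),
    ("[M+Na]+", 22.989218),
    ("[M+K]+", 38.963158),
    ("[M+NH4]+", 18.033823),
)
_NEGATIVE_BASE = (
    ("[M-H]-", -1.007276),
    ("[M+Cl]-", 34.969402),
    ("[M+HCOO]-", 44.998201),
)
DEFAULT_RULE_NAMES = {"positive": "[M+H]+", "negative": "[M-H]-"}


@dataclass(frozen=True)
class CorrectionRule:
    """One m/z correction rule: ``M = mz - delta - isotope_offset * 1.003355``."""

    name: str
    mode: str
    delta: float
    isotope_offset: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown ionization mode {self.mode!r}")
        if not np.isfinite(self.delta):
            raise ValueError("rule delta must be finite")
        if self.isotope_offset < 0:
            raise ValueError("isotope offset must be non-negative")

    @property
    def label(self) -> str:
        if self.isotope_offset == 0:
            return self.name
        return f"{self.name}+{self.isotope_offset}n"


def default_rules(mode: str, max_isotope: int = 2) -> tuple[CorrectionRule, ...]:
    """Common ESI adduct rules for one mode, with isotope offsets 0..max_isotope."""
    base = {"positive": _POSITIVE_BASE, "negative": _NEGATIVE_BASE}.get(mode)
    if base is None:
        raise ValueError(f"unknown ionization mode {mode!r}")
    return tuple(
        CorrectionRule(name=n, mode=mode, delta=d, isotope_offset=k)
        for n, d in base
        for k in range(max_isotope + 1)
    )


def read_rules(path: str | Path) -> tuple[CorrectionRule, ...]:
    """Read a rules CSV with columns name, mode, delta, isotope_offset."""
    df = pd.read_csv(path)
    return tuple(
        CorrectionRule(
            name=str(r["name"]),
            mode=str(r["mode"]),
            delta=float(r["delta"]),
            isotope_offset=int(r.get("isotope_offset", 0)),
        )
        for _, r in df.iterrows()
    )


def write_rules(rules: Iterable[CorrectionRule], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "mode": r.mode,
                "delta": r.delta,
                "isotope_offset": r.isotope_offset,
            }
            for r in rules
        ]
    ).to_csv(path, index=False)


def correct_mass(mz: float, rule: CorrectionRule) -> float:
    """Neutral monoisotopic mass for one observed m/z under one rule."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    mass = mz - rule.delta - rule.isotope_offset * ISOTOPE_SPACING
    if mass <= 0:
        raise ValueError(
            f"rule {rule.label} yields non-positive neutral mass for m/z {mz}"
        )
    return mass


@dataclass
class FeatureCorrection:
    """Per-feature rule assignment and putative-metabolite grouping.

    ``table`` columns: feature_id, rule, corrected_mass, group_id,
    representative_mass.
    """

    table: pd.DataFrame

    def corrected_masses(self) -> dict[str, float]:
        return dict(zip(self.table["feature_id"], self.table["corrected_mass"]))

    def group_of(self) -> dict[str, int]:
        return dict(zip(self.table["feature_id"], self.table["group_id"]))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _default_rule(rules: Sequence[CorrectionRule], mode: str) -> CorrectionRule:
    want = DEFAULT_RULE_NAMES[mode]
    for r in rules:
        if r.name == want and r.isotope_offset == 0:
            return r
    return rules[0]


def group_features(
    ds: OmicsDataSet,
    rules: Sequence[CorrectionRule] | None = None,
    mass_tol: float = MASS_TOL,
    rt_tol: float = RT_TOL,
) -> FeatureCorrection:
    """Assign correction rules and group co-eluting adducts of one MS data set."""
    if ds.kind != "metabolomics":
        raise ValueError("adduct grouping requires a metabolomics data set")
    if rules is None:
        rules = default_rules(ds.ionization_mode)
    rules = tuple(rules)
    if not rules:
        raise ValueError("empty rule set")
    for r in rules:
        if r.mode != ds.ionization_mode:
            raise ValueError(
                f"rule {r.label} is for {r.mode} mode but data set is "
                f"{ds.ionization_mode}"
            )
    fallback = _default_rule(rules, ds.ionization_mode)

    F = ds.n_features
    mz = ds.mz
    rt = ds.rt
    weight = ds.intensities.max(axis=1)
    # canonical processing order: strongest first, ties by feature id
    order = sorted(range(F), key=lambda i: (-weight[i], ds.feature_ids[i]))

    # candidate (rule_index, corrected_mass) lists, invalid corrections dropped
    candidates: list[list[tuple[int, float]]] = []
    for i in range(F):
        cand = []
        for ri, r in enumerate(rules):
            m = mz[i] - r.delta - r.isotope_offset * ISOTOPE_SPACING
            if m > 0:
                cand.append((ri, m))
        candidates.append(cand)

    assigned_rule = np.full(F, -1, dtype=int)
    assigned_mass = np.zeros(F)
    group_id = np.full(F, -1, dtype=int)
    rep_mass = np.zeros(F)

    next_gid = 0
    for seed in order:
        if group_id[seed] >= 0:
            continue
        gid = next_gid
        next_gid += 1
        # seed under the mode-default rule if it yields a valid mass
        try:
            seed_mass = correct_mass(mz[seed], fallback)
            seed_rule = rules.index(fallback)
        except ValueError:
            if not candidates[seed]:
                raise ValueError(
                    f"no rule yields a valid mass for feature "
                    f"{ds.feature_ids[seed]!r}"
                )
            seed_rule, seed_mass = candidates[seed][0]
        group_id[seed] = gid
        assigned_rule[seed] = seed_rule
        assigned_mass[seed] = seed_mass
        members = [seed]
        rep = seed_mass
        seed_rt = rt[seed]
        changed = True
        while changed:
            changed = False
            for f in order:
                if group_id[f] >= 0 or abs(rt[f] - seed_rt) > rt_tol:
                    continue
                best = None
                for ri, m in candidates[f]:
                    err = abs(m - rep)
                    if err > mass_tol:
                        continue
                    key = (err, abs(rules[ri].isotope_offset), ri)
                    if best is None or key < best[0]:
                        best = (key, ri, m)
                if best is not None:
                    _, ri, m = best
                    group_id[f] = gid
                    assigned_rule[f] = ri
                    assigned_mass[f] = m
                    members.append(f)
                    w = weight[members]
                    tot = w.sum()
                    rep = (
                        float(np.dot(w, assigned_mass[members]) / tot)
                        if tot > 0
                        else float(np.mean(assigned_mass[members]))
                    )
                    changed = True
        rep_mass[members] = rep

    table = pd.DataFrame(
        {
            "feature_id": list(ds.feature_ids),
            "rule": [rules[r].label for r in assigned_rule],
            "corrected_mass": assigned_mass,
            "group_id": group_id,
            "representative_mass": rep_mass,
        }
    )
    return FeatureCorrection(table=table)
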