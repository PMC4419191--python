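"""End-to-end workflow: filter -> annotate -> combine -> cluster -> enrich.

The pipeline mirrors the interactive analysis sequence as a batch run over
a single configuration mapping: each data set is SNR-ranked and filtered
with a permutation FDR on the full feature table, MS features are
adduct-corrected and grouped, the filtered tables are concatenated and
clustered with a 1D-SOM, features are mapped to a pathway database, and a
per-pathway enrichment table with meta-analysis FDRs is produced.  Every
stage writes its artifact as CSV into the output directory, and a run log
records parameters and seeds.

Enrichment is computed on the full ranked data sets with the
FDR-passing features as the selection, so the universe of
matchable entries and the feature ranks reflect the whole measurement,
not just the filtered subset.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import defaults
from .adduct import group_features, read_rules
from .core import (
    combine_datasets,
    normalize_profiles,
    read_design,
    read_feature_table,
)
from .enrichment import EnrichmentConfig, run_enrichment
from .pathway_db import read_custom_db
from .ranking import SignalSpec, label_by_ratio, rank_and_filter
from .som import cluster_composition, train_1dsom

__all__ = ["StageError", "run_all"]


class StageError(RuntimeError):
    """Failure inside a named pipeline stage; partial outputs are retained."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _signal_spec(cfg: Mapping[str, Any] | None) -> SignalSpec:
    if not cfg or cfg.get("signal", "full") in ("full", "full_range"):
        return SignalSpec.full_range()
    return SignalSpec.contrast(
        subset_a=cfg["subset_a"],
        subset_b=cfg["subset_b"],
        agg_a=cfg.get("agg_a", "max"),
        agg_b=cfg.get("agg_b", "max"),
    )


def run_all(config: Mapping[str, Any]) -> Path:
    """Execute the full workflow described by ``config``; returns the result dir.

    Config keys (all stage parameters default to the package defaults):
    ``design``, ``datasets`` (list of {features, kind, ionization_mode,
    label}), ``database``, optional ``rules``, ``out_dir``, ``seed``, and
    per-stage mappings ``filter``, ``label``, ``annotate``, ``cluster``,
    ``enrich``.
    """
    out_dir = Path(config.get("out_dir", "pathsea_results"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: dict[str, Any] = {
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "defaults": {
            k: getattr(defaults, k)
            for k in dir(defaults)
            if k.isupper()
        },
        "config": {k: v for k, v in config.items()},
        "stages": [],
    }

    def log_stage(name: str, **params: Any) -> None:
        log["stages"].append({"stage": name, **params})
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    # ---- filter: import, SNR ranking, permutation FDR -------------------
    fcfg = dict(config.get("filter", {}))
    try:
        design = read_design(config["design"])
        datasets = []
        for i, dcfg in enumerate(config["datasets"]):
            datasets.append(
                read_feature_table(
                    dcfg["features"],
                    design,
                    kind=dcfg.get("kind", "other"),
                    ionization_mode=dcfg.get("ionization_mode"),
                    label=dcfg.get("label"),
                )
            )
        spec = _signal_spec(fcfg)
        permutations = int(fcfg.get("permutations", defaults.PERMUTATIONS))
        alpha = float(fcfg.get("alpha", defaults.ALPHA))
        rng = np.random.default_rng(seed)
        rankings = {}
        for ds in datasets:
            rankings[ds.label] = rank_and_filter(
                ds, spec, permutations=permutations, alpha=alpha, seed=rng
            )
    except KeyError as e:
        raise StageError("filter", e)
    except (OSError, ValueError) as e:
        raise StageError("filter", e)

    # optional profile labeling with a customized signal
    lcfg = config.get("label")
    if lcfg:
        try:
            lspec = _signal_spec(lcfg)
            tau = float(lcfg.get("tau", defaults.LABEL_RATIO))
            name = lcfg.get("name", "wt")
            for ds in datasets:
                scored = rank_and_filter(
                    ds, lspec, permutations=1, alpha=1.0, seed=seed
                )
                labeled = label_by_ratio(scored, tau=tau, label=name)
                rankings[ds.label].table["label"] = labeled.table["label"].to_numpy()
        except (ValueError, KeyError) as e:
            raise StageError("label", e)
    for label, rr in rankings.items():
        rr.write_csv(out_dir / f"ranking_{label}.csv")
    log_stage(
        "filter",
        permutations=int(fcfg.get("permutations", defaults.PERMUTATIONS)),
        alpha=float(fcfg.get("alpha", defaults.ALPHA)),
        filtered={label: int(rr.table["passed"].sum()) for label, rr in rankings.items()},
    )

    # ---- annotate: adduct correction + database load --------------------
    acfg = dict(config.get("annotate", {}))
    try:
        if "database" not in config:
            raise ValueError("missing database path")
        db = read_custom_db(config["database"])
        rules = read_rules(config["rules"]) if config.get("rules") else None
        mass_tol = float(acfg.get("mass_tol", defaults.MASS_TOL))
        rt_tol = float(acfg.get("rt_tol", defaults.RT_TOL))
        corrections = {}
        for ds in datasets:
            if ds.kind == "metabolomics":
                corrections[ds.label] = group_features(
                    ds, rules=rules, mass_tol=mass_tol, rt_tol=rt_tol
                )
                corrections[ds.label].write_csv(out_dir / f"adducts_{ds.label}.csv")
    except (OSError, ValueError) as e:
        raise StageError("annotate", e)
    log_stage("annotate", mass_tol=mass_tol, rt_tol=rt_tol)

    # ---- combine + cluster on the filtered tables -----------------------
    ccfg = dict(config.get("cluster", {}))
    try:
        filtered = [
            ds.subset_features(
                np.asarray(rankings[ds.label].table["passed"], dtype=bool)
            )
            for ds in datasets
            if rankings[ds.label].table["passed"].any()
        ]
        combined = combine_datasets(filtered) if filtered else None
        if combined is not None:
            combined.rows.to_csv(out_dir / "combined_rows.csv", index=False)
            profiles, excluded = normalize_profiles(combined.profiles)
            kept = combined.rows.drop(index=excluded).reset_index(drop=True)
            k = int(ccfg.get("k", defaults.SOM_K))
            model = train_1dsom(
                profiles,
                k=k,
                epochs=int(ccfg.get("epochs", 50)),
                seed=seed,
            )
            pd.DataFrame(
                model.prototypes,
                index=[f"cluster{i + 1}" for i in range(model.k)],
                columns=list(combined.conditions),
            ).to_csv(out_dir / "som_prototypes.csv")
            assign = kept.copy()
            assign["cluster"] = model.assignment
            assign.to_csv(out_dir / "som_assignment.csv", index=False)
            cluster_composition(model.assignment, list(kept["kind"]), k=model.k).to_csv(
                out_dir / "som_composition.csv", index=False
            )
    except (OSError, ValueError) as e:
        raise StageError("cluster", e)
    log_stage("cluster", k=int(ccfg.get("k", defaults.SOM_K)))

    # ---- enrichment + meta-analysis --------------------------------------
    ecfg = dict(config.get("enrich", {}))
    try:
        enrich_config = EnrichmentConfig(
            mode=ecfg.get("mode", "entry"),
            statistic=ecfg.get("statistic", "hypergeom_static"),
            permutations=int(ecfg.get("permutations", defaults.PERMUTATIONS)),
            max_pathway_entries=int(
                ecfg.get("max_pathway_entries", defaults.MAX_PATHWAY_ENTRIES)
            ),
            mass_tol=float(ecfg.get("mass_tol", defaults.MASS_TOL)),
            alpha=float(ecfg.get("alpha", defaults.ALPHA)),
            meta_method=ecfg.get("meta_method", "fisher"),
            fdr_method=ecfg.get("fdr_method", "auto"),
            seed=seed,
        )
        table = run_enrichment(
            enrich_config,
            datasets,
            db,
            rankings=rankings,
            corrections=corrections,
            signal_spec=_signal_spec(fcfg),
        )
        table.to_csv(out_dir / "enrichment.csv", index=False)
    except (OSError, ValueError) as e:
        raise StageError("enrich", e)
    log_stage("enrich", **{k: v for k, v in asdict(enrich_config).items()})
    return out_dir
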