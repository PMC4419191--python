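"""Seeded generator of synthetic multi-omics studies with ground truth.

The generator emulates a wound-response-style cross-omics design: six
experimental conditions, three biological replicates each, metabolomics
data sets with two technical replicates per biological sample (so six
intensity columns per condition) and a transcriptomics data set measured
once per biological sample.  Each metabolite is expanded into several
adduct features with Gaussian m/z error and a shared retention time;
each gene maps one-to-one to a transcript feature.

Intensities are multiplicative: a feature's base level times a
condition-specific multiplier (non-unity only for members of enriched
pathways) times log-normal biological noise, with technical replicates
adding a smaller log-normal technical factor on top of the biological
value.  Null features are therefore exchangeable across conditions, which
is the basis of every calibration test downstream.

The generated pathway database contains the enriched pathways (members
drawn exclusively, so null pathways stay null) plus null pathways sampled
from the remaining metabolite and gene pools.  Everything is reproducible
bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .adduct import CorrectionRule, default_rules
from .core import OmicsDataSet, SampleDesign
from .pathway_db import PathwayDatabase

__all__ = ["StudySpec", "GroundTruth", "generate_study", "write_study"]

#: Relative ion yields per adduct rule name (protonated species dominate).
_ADDUCT_ABUNDANCE = {
    "[M+H]+": 1.0,
    "[M+Na]+": 0.4,
    "[M+K]+": 0.2,
    "[M+NH4]+": 0.3,
    "[M-H]-": 1.0,
    "[M+Cl]-": 0.4,
    "[M+HCOO]-": 0.3,
}


@dataclass
class StudySpec:
    """Design of a synthetic study.

    Defaults mirror the emulated cross-omics design: 6 conditions × 3
    biological replicates, MS data with 2 technical replicates per sample,
    transcript data measured once per sample; log-normal noise with
    sigma 0.3 biological and 0.1 technical; m/z error sigma 0.002 Da; and
    an induction-at-conditions-2-and-3 effect template (multipliers
    [1, e, e, 1, 1, 1] with e = 5) for enriched-pathway members.
    """

    n_conditions: int = 6
    units_per_condition: int = 3
    tech_reps_ms: int = 2
    tech_reps_transcript: int = 1
    n_metabolites: int = 60
    n_genes: int = 150
    n_pathways: int = 21
    pathway_n_compounds: int = 8
    pathway_n_genes: int = 8
    n_enriched: int = 1
    enriched_n_compounds: int = 10
    enriched_n_genes: int = 10
    effect_multipliers: tuple[float, ...] | None = None  # default [1,e,e,1,1,1]
    effect_size: float = 5.0
    sigma_bio: float = 0.3
    sigma_tech: float = 0.1
    mz_sigma: float = 0.002
    rt_min: float = 1.0
    rt_max: float = 12.0
    rt_sigma: float = 0.01
    mass_min: float = 100.0
    mass_max: float = 900.0
    adduct_rules: tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M+K]+")
    ionization_mode: str = "positive"
    seed: int = 0

    def multipliers(self) -> np.ndarray:
        if self.effect_multipliers is not None:
            mult = np.asarray(self.effect_multipliers, dtype=float)
            if mult.size != self.n_conditions:
                raise ValueError("effect multipliers must cover every condition")
        else:
            mult = np.ones(self.n_conditions)
            if self.n_conditions >= 3:
                mult[1] = mult[2] = self.effect_size
        if np.any(mult <= 0):
            raise ValueError("effect multipliers must be positive")
        return mult

    def rules(self) -> tuple[CorrectionRule, ...]:
        table = {r.name: r for r in default_rules(self.ionization_mode, max_isotope=0)}
        out = []
        for name in self.adduct_rules:
            if name not in table:
                raise ValueError(f"unknown adduct rule {name!r} for {self.ionization_mode} mode")
            out.append(table[name])
        return tuple(out)


@dataclass
class GroundTruth:
    """What the generator actually planted.

    ``features`` columns: feature_id, dataset, parent_id, parent_type,
    rule, group_id, parent_mass (neutral monoisotopic mass, MS features
    only), perturbed.  ``pathways`` columns: pathway_id, enriched.
    """

    features: pd.DataFrame
    pathways: pd.DataFrame

    def perturbed_features(self, dataset: str | None = None) -> set[str]:
        t = self.features
        if dataset is not None:
            t = t[t["dataset"] == dataset]
        return set(t.loc[t["perturbed"], "feature_id"])

    def true_groups(self, dataset: str) -> dict[str, str]:
        """feature id -> parent metabolite id (the true adduct group)."""
        t = self.features[self.features["dataset"] == dataset]
        return dict(zip(t["feature_id"], t["parent_id"]))

    def enriched_pathways(self) -> set[str]:
        return set(self.pathways.loc[self.pathways["enriched"], "pathway_id"])


def _make_design(
    label: str,
    conditions: list[str],
    units_per_condition: int,
    tech_reps: int,
) -> SampleDesign:
    sample_ids, cond_of, unit_of, ds_of = [], {}, {}, {}
    for ci, c in enumerate(conditions):
        for b in range(units_per_condition):
            unit = f"u{ci + 1}_{b + 1}"
            for t in range(tech_reps):
                s = f"{label}_{unit}_t{t + 1}"
                sample_ids.append(s)
                cond_of[s] = c
                unit_of[s] = unit
                ds_of[s] = label
    return SampleDesign(
        sample_ids=tuple(sample_ids),
        condition_of=cond_of,
        biounit_of=unit_of,
        dataset_of=ds_of,
    )


def generate_study(
    spec: StudySpec,
) -> tuple[list[OmicsDataSet], PathwayDatabase, GroundTruth]:
    """Generate (data sets, pathway database, ground truth) from a study spec."""
    rng = np.random.default_rng(spec.seed)
    conditions = [f"cond{i + 1}" for i in range(spec.n_conditions)]
    mult = spec.multipliers()
    rules = spec.rules()

    n_enr_cpd = spec.n_enriched * spec.enriched_n_compounds
    n_enr_gene = spec.n_enriched * spec.enriched_n_genes
    if n_enr_cpd > spec.n_metabolites or n_enr_gene > spec.n_genes:
        raise ValueError("enriched pathways larger than the metabolite/gene universe")
    if spec.n_pathways < spec.n_enriched:
        raise ValueError("more enriched pathways than pathways")
    null_pool_cpd = spec.n_metabolites - n_enr_cpd
    null_pool_gene = spec.n_genes - n_enr_gene
    if spec.n_pathways > spec.n_enriched and (
        spec.pathway_n_compounds > null_pool_cpd
        or spec.pathway_n_genes > null_pool_gene
    ):
        raise ValueError("null pathway larger than the remaining entry pool")

    met_ids = [f"M{i + 1:04d}" for i in range(spec.n_metabolites)]
    gene_ids = [f"G{i + 1:04d}" for i in range(spec.n_genes)]

    # metabolite masses on a jittered grid: pairwise separation far above
    # the matching tolerance so mass identities are unambiguous by design
    slots = rng.choice(
        int((spec.mass_max - spec.mass_min) / 0.5),
        size=spec.n_metabolites,
        replace=False,
    )
    masses = spec.mass_min + slots * 0.5 + rng.uniform(0.0, 0.1, spec.n_metabolites)
    rt = rng.uniform(spec.rt_min, spec.rt_max, spec.n_metabolites)

    # pathway memberships: enriched pathways take exclusive members first
    perturbed_mets: set[str] = set()
    perturbed_genes: set[str] = set()
    pw_rows = []
    pw_truth = []
    cpd_cursor = 0
    gene_cursor = 0
    for pi in range(spec.n_pathways):
        pid = f"pw{pi + 1:03d}"
        enriched = pi < spec.n_enriched
        if enriched:
            cpds = met_ids[cpd_cursor : cpd_cursor + spec.enriched_n_compounds]
            genes = gene_ids[gene_cursor : gene_cursor + spec.enriched_n_genes]
            cpd_cursor += spec.enriched_n_compounds
            gene_cursor += spec.enriched_n_genes
            perturbed_mets |= set(cpds)
            perturbed_genes |= set(genes)
        else:
            cpds = list(
                rng.choice(met_ids[n_enr_cpd:], spec.pathway_n_compounds, replace=False)
            )
            genes = list(
                rng.choice(gene_ids[n_enr_gene:], spec.pathway_n_genes, replace=False)
            )
        pw_truth.append({"pathway_id": pid, "enriched": enriched})
        for eid in cpds + genes:
            pw_rows.append((pid, eid))

    mass_of = dict(zip(met_ids, masses))
    ent_rows = [
        {
            "entry_id": m,
            "entry_name": f"metabolite {m}",
            "entry_type": "compound",
            "formula": "",
            "mass": mass_of[m],
        }
        for m in sorted({e for _, e in pw_rows if e.startswith("M")})
    ] + [
        {
            "entry_id": g,
            "entry_name": f"gene {g}",
            "entry_type": "gene",
            "formula": "",
            "mass": np.nan,
        }
        for g in sorted({e for _, e in pw_rows if e.startswith("G")})
    ]
    db = PathwayDatabase(
        entries=pd.DataFrame(ent_rows),
        pathways=pd.DataFrame(
            [
                {
                    "pathway_id": t["pathway_id"],
                    "pathway_name": f"pathway {t['pathway_id']}"
                    + (" (enriched)" if t["enriched"] else ""),
                    "database_label": "synthetic",
                }
                for t in pw_truth
            ]
        ),
        memberships=pd.DataFrame(pw_rows, columns=["pathway_id", "entry_id"]),
    )

    def intensity_matrix(
        n_feat: int,
        design: SampleDesign,
        base: np.ndarray,
        perturbed: np.ndarray,
    ) -> np.ndarray:
        """Base × condition multiplier × biological × technical log-normal noise."""
        units = design.units
        unit_idx = {u: i for i, u in enumerate(units)}
        cond_idx = {c: i for i, c in enumerate(conditions)}
        bio = np.exp(rng.normal(0.0, spec.sigma_bio, (n_feat, len(units))))
        out = np.empty((n_feat, len(design.sample_ids)))
        for j, s in enumerate(design.sample_ids):
            u = unit_idx[design.biounit_of[s]]
            c = cond_idx[design.condition_of[s]]
            m = np.where(perturbed, mult[c], 1.0)
            tech = np.exp(rng.normal(0.0, spec.sigma_tech, n_feat))
            out[:, j] = base * m * bio[:, u] * tech
        return out

    datasets: list[OmicsDataSet] = []
    truth_rows = []

    # --- MS data set: every metabolite expanded over the adduct rules
    ms_label = "MS1"
    ms_design = _make_design(
        ms_label, conditions, spec.units_per_condition, spec.tech_reps_ms
    )
    fids, fmz, frt, fbase, fpert = [], [], [], [], []
    met_base = 10 ** rng.uniform(3.0, 5.0, spec.n_metabolites)
    for mi, m in enumerate(met_ids):
        for rule in rules:
            fid = f"{ms_label}_{m}_{rule.name}"
            mz = mass_of[m] + rule.delta + rng.normal(0.0, spec.mz_sigma)
            fids.append(fid)
            fmz.append(mz)
            frt.append(rt[mi] + rng.normal(0.0, spec.rt_sigma))
            yield_factor = _ADDUCT_ABUNDANCE.get(rule.name, 0.3) * np.exp(
                rng.normal(0.0, 0.2)
            )
            fbase.append(met_base[mi] * yield_factor)
            fpert.append(m in perturbed_mets)
            truth_rows.append(
                {
                    "feature_id": fid,
                    "dataset": ms_label,
                    "parent_id": m,
                    "parent_type": "metabolite",
                    "rule": rule.name,
                    "group_id": mi,
                    "parent_mass": mass_of[m],
                    "perturbed": m in perturbed_mets,
                }
            )
    ms_intens = intensity_matrix(
        len(fids), ms_design, np.asarray(fbase), np.asarray(fpert)
    )
    datasets.append(
        OmicsDataSet(
            label=ms_label,
            kind="metabolomics",
            feature_ids=tuple(fids),
            intensities=ms_intens,
            design=ms_design,
            mz=np.asarray(fmz),
            rt=np.clip(np.asarray(frt), 0.0, None),
            ionization_mode=spec.ionization_mode,
        )
    )

    # --- transcript data set: features are the gene ids themselves
    tr_label = "T1"
    tr_design = _make_design(
        tr_label, conditions, spec.units_per_condition, spec.tech_reps_transcript
    )
    g_base = 10 ** rng.uniform(2.0, 4.0, spec.n_genes)
    g_pert = np.array([g in perturbed_genes for g in gene_ids])
    tr_intens = intensity_matrix(spec.n_genes, tr_design, g_base, g_pert)
    for gi, g in enumerate(gene_ids):
        truth_rows.append(
            {
                "feature_id": g,
                "dataset": tr_label,
                "parent_id": g,
                "parent_type": "gene",
                "rule": "",
                "group_id": -1,
                "parent_mass": np.nan,
                "perturbed": bool(g_pert[gi]),
            }
        )
    datasets.append(
        OmicsDataSet(
            label=tr_label,
            kind="transcriptomics",
            feature_ids=tuple(gene_ids),
            intensities=tr_intens,
            design=tr_design,
        )
    )

    truth = GroundTruth(
        features=pd.DataFrame(truth_rows), pathways=pd.DataFrame(pw_truth)
    )
    return datasets, db, truth


def write_study(
    datasets: list[OmicsDataSet],
    db: PathwayDatabase,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the study as plain CSV files; returns the paths written."""
    from .core import write_feature_table
    from .pathway_db import write_custom_db

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    design_frames = []
    for ds in datasets:
        p = out / f"features_{ds.label}.csv"
        write_feature_table(ds, p)
        paths[f"features_{ds.label}"] = p
        design_frames.append(ds.design.to_frame())
    design = pd.concat(design_frames, ignore_index=True)
    paths["design"] = out / "design.csv"
    design.to_csv(paths["design"], index=False)
    paths["database"] = out / "database.csv"
    write_custom_db(db, paths["database"])
    paths["truth_features"] = out / "truth_features.csv"
    truth.features.to_csv(paths["truth_features"], index=False)
    paths["truth_pathways"] = out / "truth_pathways.csv"
    truth.pathways.to_csv(paths["truth_pathways"], index=False)
    return paths
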