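"""End-to-end pipeline: chain filtering, phylogeny/ITH, SCNA, WGD, timing
and dominance into per-patient and cohort reports.

Inputs come either from files (variant TSVs, SEG + purity tables, feature
tables, driver lists) or from the built-in simulator; every stage writes
into one JSON report per patient plus flat TSV twins, and a Newick tree per
patient.  Reports are deterministic given the config and seed: per-patient
randomness is re-seeded from the master seed and the patient id.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import dominance as dom
from . import filters, io, phylo, scna, wgd_timing
from .simulate import SimConfig, SimulatedTumor, patient_seed, simulate_cohort
from .types import (
    DriverCatalog,
    SectorProfile,
    VariantRecord,
    group_by_patient,
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, patient: Optional[str], cause: Exception):
        self.stage = stage
        self.patient = patient
        where = f"stage {stage!r}" + (f", patient {patient}" if patient else "")
        super().__init__(f"{where}: {cause}")


@dataclass
class PipelineConfig:
    out_dir: str = "clonarch_out"
    seed: int = 0
    # file inputs (all optional; simulate used when exome/deepseq are absent)
    exome_variants: Optional[str] = None
    deepseq_variants: Optional[str] = None
    segments: Optional[str] = None
    purity: Optional[str] = None
    cytobands: Optional[str] = None
    genes_bed: Optional[str] = None
    luad_drivers: Optional[str] = None
    extended_drivers: Optional[str] = None
    # simulator conditions (used when no variant files are given)
    simulate: Optional[SimConfig] = None
    # stage parameters (defaults follow the emulated study)
    subsample_k: int = 3
    subsample_iters: int = 20
    wgd_nsim: int = 10000
    min_carriers: int = 5
    scna_ith_min_sectors: int = 3
    gene_set: str = "luad"

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimConfig(**sim) if isinstance(sim, dict) else sim
        return cfg


# ---------------------------------------------------------------------------


@dataclass
class PatientInputs:
    patient_id: str
    exome: list[VariantRecord]
    deepseq: list[VariantRecord]
    profiles: dict[str, SectorProfile] = field(default_factory=dict)
    truth: Optional[Any] = None


def _load_inputs(cfg: PipelineConfig) -> tuple[list[PatientInputs], Optional[DriverCatalog]]:
    catalog = None
    if cfg.luad_drivers:
        catalog = io.read_driver_catalog(cfg.luad_drivers, cfg.extended_drivers)
    if cfg.exome_variants or cfg.deepseq_variants:
        exome = io.read_variants(cfg.exome_variants, "exome") if cfg.exome_variants else []
        deepseq = (
            io.read_variants(cfg.deepseq_variants, "deepseq")
            if cfg.deepseq_variants
            else []
        )
        profiles = (
            io.read_segments(cfg.segments, cfg.purity) if cfg.segments else {}
        )
        by_patient_ex = group_by_patient(exome)
        by_patient_ds = group_by_patient(deepseq)
        patients = sorted(set(by_patient_ex) | set(by_patient_ds))
        inputs = []
        for pid in patients:
            sectors = {v.sector_id for v in by_patient_ds.get(pid, [])}
            inputs.append(
                PatientInputs(
                    patient_id=pid,
                    exome=by_patient_ex.get(pid, []),
                    deepseq=by_patient_ds.get(pid, []),
                    profiles={s: p for s, p in profiles.items() if s in sectors},
                )
            )
        return inputs, catalog
    sim_cfg = cfg.simulate or SimConfig()
    cohort: list[SimulatedTumor] = simulate_cohort(sim_cfg, cfg.seed)
    inputs = [
        PatientInputs(
            patient_id=t.patient_id,
            exome=t.exome_variants,
            deepseq=t.deepseq_variants,
            profiles=t.profiles,
            truth=t.truth,
        )
        for t in cohort
    ]
    if catalog is None:
        planted = sorted({g for t in cohort for g in t.truth.driver_genes})
        if planted:
            catalog = DriverCatalog(frozenset(planted), frozenset(planted))
    return inputs, catalog


# ---------------------------------------------------------------------------
# per-patient stages


def _run_filters(p: PatientInputs) -> dict[str, Any]:
    exome_decisions = [filters.apply_filters(v) for v in p.exome]
    exome_called = {
        d.key for d in exome_decisions if d.passed
    }
    deepseq_decisions = {}
    for v in p.deepseq:
        deepseq_decisions[(v.key, v.sector_id)] = filters.apply_filters(
            v, exome_called=v.key in exome_called
        )
    passed_exome = [v for v, d in zip(p.exome, exome_decisions) if d.passed]
    rates = filters.validation_rate(passed_exome, deepseq_decisions)
    return {
        "exome_called": exome_called,
        "deepseq_decisions": deepseq_decisions,
        "validation_rate": rates,
    }


def _run_phylo(
    p: PatientInputs, decisions: dict, cfg: PipelineConfig, rng: np.random.Generator
) -> tuple[Optional[phylo.PresenceMatrix], dict[str, Any]]:
    sectors = sorted({v.sector_id for v in p.deepseq})
    matrix = phylo.build_presence_matrix(
        p.deepseq,
        sectors=sectors,
        present=lambda v: decisions[(v.key, v.sector_id)].passed,
    )
    cls = phylo.classify_mutations(matrix)
    pith = phylo.compute_pith(cls)
    tree = phylo.build_tree(matrix) if matrix.n_mutations else None
    k = min(cfg.subsample_k, len(sectors))
    report = {
        "n_sectors": len(sectors),
        "n_mutations": int(matrix.n_mutations),
        "n_trunk": cls.n_trunk,
        "n_branch": cls.n_branch,
        "n_private": cls.n_private,
        "pith_percent": pith,
        "trunk_percent": None if pith is None else 100.0 - pith,
        "subsample_k": k,
        "subsample_trunk_ratio": (
            phylo.subsample_trunk_ratio(matrix, k, cfg.subsample_iters, rng=rng)
            if matrix.n_mutations and k >= 2
            else None
        ),
        "burden_gain_percent": (
            phylo.burden_gain(matrix, k, cfg.subsample_iters, rng=rng)
            if matrix.n_mutations
            else None
        ),
        "newick": io.write_newick(tree) if tree is not None else None,
        "trunk_length": phylo.trunk_length(tree) if tree is not None else None,
    }
    return matrix, report


def _run_scna(
    p: PatientInputs, features, cfg: PipelineConfig
) -> dict[str, Any]:
    if not p.profiles:
        return {"available": False}
    sectors = {}
    feature_cn = {}
    for sid, profile in sorted(p.profiles.items()):
        scores = scna.instability_scores(profile)
        loh = scna.detect_loh(profile)
        sectors[sid] = {
            "ploidy": profile.ploidy,
            "purity": profile.purity,
            "gii": scores.gii,
            "adgii": scores.adgii,
            "loh_fraction": loh.genome_fraction,
        }
        if features:
            feature_cn[sid] = scna.map_to_features(profile, features)
    out: dict[str, Any] = {"available": True, "sectors": sectors}
    if features and len(p.profiles) >= cfg.scna_ith_min_sectors:
        ith = scna.scna_ith(
            feature_cn,
            {s: p.profiles[s].ploidy for s in feature_cn},
            min_sectors=cfg.scna_ith_min_sectors,
        )
        out["scna_ith_late_fraction"] = ith.late_fraction
        out["scna_ith_n_features"] = len(ith.labels)
    return out


def _run_wgd(
    p: PatientInputs, cfg: PipelineConfig, rng: np.random.Generator
) -> dict[str, Any]:
    if not p.profiles:
        return {"available": False}
    sectors = {}
    doubled_votes = 0
    for sid, profile in sorted(p.profiles.items()):
        res = wgd_timing.wgd_test(profile, n_sim=cfg.wgd_nsim, rng=rng)
        sectors[sid] = {
            "t_obs": res.t_obs,
            "p_value": res.p_value,
            "ploidy": res.ploidy,
            "doubled": res.doubled,
        }
        doubled_votes += int(res.doubled)
    return {
        "available": True,
        "sectors": sectors,
        "tumor_doubled": doubled_votes * 2 >= len(sectors),
    }


def _run_timing(
    p: PatientInputs, matrix: Optional[phylo.PresenceMatrix], decisions: dict
) -> dict[str, Any]:
    if not p.profiles or matrix is None:
        return {"available": False}
    rows = []
    by_key_sector = {(v.key, v.sector_id): v for v in p.deepseq}
    for key_str in matrix.matrix.index:
        chrom, pos, ref, alt = key_str.split(":")
        key = (chrom, int(pos), ref, alt)
        for sid in matrix.sectors:
            if not matrix.matrix.at[key_str, sid]:
                continue
            profile = p.profiles.get(sid)
            v = by_key_sector.get((key, sid))
            if profile is None or v is None:
                continue
            seg = profile.segment_at(chrom, int(pos))
            if seg is None:
                continue
            est = wgd_timing.ccf_and_timing(v, profile.purity, seg)
            rows.append(
                {
                    "mutation": key_str,
                    "sector": sid,
                    "n_mut": est.n_mut,
                    "multiplicity": est.multiplicity,
                    "ccf": est.ccf,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "clonal": est.clonal,
                    "timing": est.timing,
                }
            )
    counts = {"early": 0, "late": 0, "not_evaluable": 0}
    for r in rows:
        counts[r["timing"]] += 1
    return {"available": True, "mutations": rows, "timing_counts": counts}


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run all stages and write the report bundle; returns the cohort report."""
    out_dir = Path(cfg.out_dir)
    (out_dir / "patients").mkdir(parents=True, exist_ok=True)

    inputs, catalog = _load_inputs(cfg)
    features = []
    if cfg.cytobands:
        features += io.read_cytobands(cfg.cytobands)
    if cfg.genes_bed:
        features += io.read_bed(cfg.genes_bed)

    patient_reports: dict[str, dict[str, Any]] = {}
    all_validated: list[VariantRecord] = []
    for p in inputs:
        rng = np.random.default_rng(patient_seed(cfg.seed, p.patient_id))
        report: dict[str, Any] = {"patient_id": p.patient_id}
        try:
            filt = _run_filters(p)
        except Exception as exc:  # noqa: BLE001 - stage name must propagate
            raise PipelineStageError("filter", p.patient_id, exc) from exc
        report["validation_rate"] = _jsonable(filt["validation_rate"])
        try:
            matrix, report["phylo"] = _run_phylo(p, filt["deepseq_decisions"], cfg, rng)
        except Exception as exc:
            raise PipelineStageError("phylo", p.patient_id, exc) from exc
        try:
            report["scna"] = _run_scna(p, features, cfg)
        except Exception as exc:
            raise PipelineStageError("scna", p.patient_id, exc) from exc
        try:
            report["wgd"] = _run_wgd(p, cfg, rng)
        except Exception as exc:
            raise PipelineStageError("wgd", p.patient_id, exc) from exc
        try:
            report["timing"] = _run_timing(p, matrix, filt["deepseq_decisions"])
        except Exception as exc:
            raise PipelineStageError("timing", p.patient_id, exc) from exc

        all_validated += [
            v
            for v in p.deepseq
            if filt["deepseq_decisions"][(v.key, v.sector_id)].passed
        ]
        patient_reports[p.patient_id] = report
        if report["phylo"]["newick"]:
            (out_dir / "patients" / f"{p.patient_id}.tree.nwk").write_text(
                report["phylo"]["newick"] + "\n"
            )

    cohort: dict[str, Any] = {
        "seed": cfg.seed,
        "n_patients": len(inputs),
        "patients": patient_reports,
    }
    if catalog is not None:
        try:
            table = dom.dominance_table(
                all_validated, catalog, cfg.gene_set, cfg.min_carriers
            )
            cohort["dominance"] = table.to_dict(orient="records")
        except Exception as exc:
            raise PipelineStageError("dominance", None, exc) from exc

    piths = [
        r["phylo"]["pith_percent"]
        for r in patient_reports.values()
        if r["phylo"]["pith_percent"] is not None
    ]
    cohort["pith_median_percent"] = float(np.median(piths)) if piths else None

    _write_reports(out_dir, cohort)
    return cohort


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if f != f else f  # NaN -> null for valid JSON
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_reports(out_dir: Path, cohort: dict[str, Any]) -> None:
    payload = _jsonable(cohort)
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    # flat TSV twin: one row per patient
    lines = [
        "patient_id\tn_sectors\tn_mutations\tn_trunk\tn_branch\tn_private\t"
        "pith_percent\tburden_gain_percent\ttumor_doubled"
    ]
    for pid in sorted(payload["patients"]):
        r = payload["patients"][pid]
        ph = r["phylo"]
        lines.append(
            "\t".join(
                str(x)
                for x in [
                    pid,
                    ph["n_sectors"],
                    ph["n_mutations"],
                    ph["n_trunk"],
                    ph["n_branch"],
                    ph["n_private"],
                    ph["pith_percent"],
                    ph["burden_gain_percent"],
                    r["wgd"].get("tumor_doubled") if r["wgd"]["available"] else "NA",
                ]
            )
        )
    (out_dir / "cohort.tsv").write_text("\n".join(lines) + "\n")
    for pid, r in payload["patients"].items():
        with open(out_dir / "patients" / f"{pid}.json", "w") as fh:
            json.dump(r, fh, indent=2, sort_keys=True)
            fh.write("\n")
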