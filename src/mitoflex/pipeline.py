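"""End-to-end pipeline: synth -> parameterize -> simulate/fcc -> fit-ogtt ->
lipidiff -> report, driven by a YAML configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .betaox.params_io import write_parameters
from .betaox.solve import default_substrate_grid
from .errors import ConfigurationError
from .mca import CohortMember, cohort_simulation
from .ogtt import fit_ogtt, homa_ir, misi
from .omics import (
    correlate_with_index,
    diet_response_scatter,
    differential,
    factorial_screen,
    normalize_to_class_standard,
)
from .parameterization import parameterize_cohort
from .synth import (
    CohortConfig,
    generate_lipidomics,
    generate_ogtt,
    generate_proteomics,
    sample_sheet,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("synth", "parameterize", "simulate", "fcc", "ogtt", "lipidiff")


@dataclass
class PipelineConfig:
    """Serializable pipeline settings; unknown keys are rejected on load."""

    seed: int = 0
    out_dir: str = "results"
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    # inputs (None -> produced by the synth stage)
    proteomics_path: Optional[str] = None
    lipidomics_path: Optional[str] = None
    standards_path: Optional[str] = None
    classes_path: Optional[str] = None
    ogtt_path: Optional[str] = None
    samples_path: Optional[str] = None
    parameters_path: Optional[str] = None
    # analysis settings
    substrate_min: float = 0.1
    substrate_max: float = 10.0
    substrate_points: int = 9
    malonyl_levels: List[float] = field(default_factory=lambda: [0.0, 0.2])
    fcc_enzymes: List[str] = field(default_factory=lambda: ["CPT1B", "MCKAT"])
    fdr_method: str = "bh"
    insulin_conversion: float = 25.0
    synth: Dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stage(s) {sorted(unknown)}")
        for key in ("proteomics_path", "lipidomics_path", "standards_path",
                    "classes_path", "ogtt_path", "samples_path",
                    "parameters_path"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{key} does not exist: {value}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Execute the enabled stages in dependency order; returns a mapping of
    artifact name -> path.  Any stage failure aborts with the stage name;
    artifacts of completed stages are left in place."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}
    stage = "init"
    cohort_cfg = CohortConfig(seed=config.seed, **config.synth)
    try:
        # ---------------- synth ----------------
        if "synth" in config.stages:
            stage = "synth"
            log.info("stage=%s seed=%d config=%s", stage, config.seed, config.digest())
            sheet = sample_sheet(cohort_cfg)
            io.write_table(sheet.reset_index(), out / "samples.tsv", index=False)
            prot = generate_proteomics(cohort_cfg)
            io.write_matrix(prot.values, out / "proteomics.tsv",
                            units={"values": "fmol per ug total protein"})
            lip, standards = generate_lipidomics(cohort_cfg)
            io.write_matrix(lip.values, out / "lipidomics.tsv",
                            units={"values": "raw intensity"})
            io.write_table(
                lip.classes.rename("class").reset_index(),
                out / "lipid_classes.tsv", index=False,
            )
            io.write_standards(standards, out / "lipid_standards.tsv")
            io.write_ogtt(generate_ogtt(cohort_cfg), out / "ogtt.tsv")
            for name in ("samples", "proteomics", "lipidomics", "lipid_classes",
                         "lipid_standards", "ogtt"):
                artifacts[name] = out / f"{name}.tsv"

        def _path(key: str, default_name: str) -> Path:
            configured = getattr(config, key)
            if configured is not None:
                return Path(configured)
            candidate = out / default_name
            if not candidate.exists():
                raise ConfigurationError(
                    f"stage input {default_name} not found; enable the synth "
                    f"stage or set {key}"
                )
            return candidate

        cohort: Optional[List[CohortMember]] = None
        if {"parameterize", "simulate", "fcc"} & set(config.stages):
            stage = "parameterize"
            sheet = io.read_sample_sheet(_path("samples_path", "samples.tsv"))
            prot_values = io.read_matrix(_path("proteomics_path", "proteomics.tsv"),
                                         index_name="protein")
            params_by_animal = parameterize_cohort(prot_values)
            cohort = [
                CohortMember(animal=a, age=sheet.loc[a, "age"],
                             diet=sheet.loc[a, "diet"], params=p)
                for a, p in params_by_animal.items()
            ]
        if "parameterize" in config.stages:
            pdir = out / "params"
            pdir.mkdir(exist_ok=True)
            rows = []
            for member in cohort:
                write_parameters(member.params, pdir / f"{member.animal}.ini")
                row = {"animal": member.animal, "age": member.age,
                       "diet": member.diet}
                row.update({f"vmax_{e}": v for e, v in member.params.vmax.items()})
                rows.append(row)
            io.write_table(pd.DataFrame(rows), out / "cohort_parameters.tsv",
                           index=False,
                           units={"vmax_*": "umol min^-1 mg^-1"})
            artifacts["cohort_parameters"] = out / "cohort_parameters.tsv"

        if {"simulate", "fcc"} & set(config.stages):
            stage = "simulate"
            grid = default_substrate_grid(config.substrate_min,
                                          config.substrate_max,
                                          config.substrate_points)
            sim = cohort_simulation(
                cohort, grid, malonyl_levels=config.malonyl_levels,
                enzymes=config.fcc_enzymes,
            )
            if "simulate" in config.stages:
                flux = sim.table.drop_duplicates(
                    subset=["animal", "s_cyt_uM", "malonyl_uM"]
                )[["animal", "age", "diet", "s_cyt_uM", "malonyl_uM", "flux",
                   "acylcarnitine_c16_uM"]]
                io.write_table(flux, out / "fluxes.tsv", index=False,
                               units={"flux": "umol min^-1 mg^-1",
                                      "s_cyt_uM": "uM"})
                artifacts["fluxes"] = out / "fluxes.tsv"
            if "fcc" in config.stages:
                stage = "fcc"
                io.write_table(sim.table, out / "fcc.tsv", index=False)
                io.write_table(sim.summary, out / "fcc_summary.tsv", index=False)
                artifacts["fcc"] = out / "fcc.tsv"
                artifacts["fcc_summary"] = out / "fcc_summary.tsv"

        if "ogtt" in config.stages:
            stage = "ogtt"
            series = io.read_ogtt(_path("ogtt_path", "ogtt.tsv"))
            rows = []
            for s in series:
                gfit = fit_ogtt(s, "glucose")
                ifit = fit_ogtt(s.insulin_times,
                                s.insulin_mU_per_L(config.insulin_conversion))
                row = {"animal": s.animal}
                for name, value in zip(
                    ("c_b", "c_1", "c_2", "k_a", "k_e1", "k_e2"), gfit.params
                ):
                    row[f"glucose_{name}"] = value
                row["glucose_rss"] = gfit.rss
                row["misi"] = misi(gfit, ifit) if gfit.converged else np.nan
                row["homa_ir"] = homa_ir(
                    s.glucose[0],
                    s.insulin_mU_per_L(config.insulin_conversion)[0],
                )
                rows.append(row)
            io.write_table(pd.DataFrame(rows), out / "insulin_indices.tsv",
                           index=False,
                           units={"misi": "mM min^-1 per mU L^-1"})
            artifacts["insulin_indices"] = out / "insulin_indices.tsv"

        if "lipidiff" in config.stages:
            stage = "lipidiff"
            table = io.read_omics(
                _path("lipidomics_path", "lipidomics.tsv"),
                _path("samples_path", "samples.tsv"),
                _path("classes_path", "lipid_classes.tsv"),
            )
            standards = io.read_standards(
                _path("standards_path", "lipid_standards.tsv")
            )
            normalized = normalize_to_class_standard(table, standards)
            for age in ("young", "old"):
                result = differential(normalized, age, fdr=config.fdr_method)
                io.write_table(result.reset_index(names="analyte"),
                               out / f"differential_{age}.tsv", index=False)
                artifacts[f"differential_{age}"] = out / f"differential_{age}.tsv"
            io.write_table(diet_response_scatter(normalized),
                           out / "diet_response_scatter.tsv", index=False)
            artifacts["diet_response_scatter"] = out / "diet_response_scatter.tsv"
            screen = factorial_screen(normalized, tukey=False)
            io.write_table(screen.reset_index(names="analyte"),
                           out / "factorial_screen.tsv", index=False)
            artifacts["factorial_screen"] = out / "factorial_screen.tsv"
            indices_path = out / "insulin_indices.tsv"
            if indices_path.exists():
                indices = io.read_table(indices_path, required_columns=("animal", "misi"),
                                        index_column="animal")
                corr = correlate_with_index(normalized, indices["misi"])
                io.write_table(corr.reset_index(names="analyte"),
                               out / "misi_correlations.tsv", index=False)
                artifacts["misi_correlations"] = out / "misi_correlations.tsv"
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config.digest(),
        "stages": list(config.stages),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
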