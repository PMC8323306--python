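"""Synthetic age x diet cohort generator.

Produces proteomics, lipidomics and OGTT data with the statistical structure
the downstream analyses assume: a 2x2 cohort (young/old x LFD/HFD), planted
group effects (generator knobs, labelled synthetic — not estimates of any
real dataset), multiplicative log-normal noise, and fully seed-deterministic
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .ogtt import GLUCOSE_TIMES, INSULIN_TIMES, OGTTSeries, curve
from .omics import OmicsTable
from .parameterization import DEFAULT_LIVER_PROTEOMICS, ENZYME_PROTEIN

# ---------------------------------------------------------------------------
# protein panels
# ---------------------------------------------------------------------------

#: 16 beta-oxidation proteins (stable mouse gene-style identifiers)
BETAOX_PROTEINS: Tuple[str, ...] = (
    "Cpt1b", "Cpt2", "Slc25a20", "Acadvl", "Acadl", "Acadm", "Acads",
    "Echs1", "Hadha", "Hadhb", "Hadh", "Acaa2", "Eci1", "Decr1", "Etfa",
    "Etfb",
)

#: 31 glucose-metabolism proteins (glycolysis, glycogen, PPP, PDH)
GLYCO_PROTEINS: Tuple[str, ...] = (
    "Hk2", "Gpi1", "Pfkm", "Aldoa", "Tpi1", "Gapdh", "Pgk1", "Pgam2",
    "Eno1", "Eno3", "Pkm", "Ldha", "Ldhb", "Pgm1", "Pgm2", "Ugp2", "Gys1",
    "Pygm", "Agl", "Gbe1", "Pdha1", "Pdhb", "Dlat", "Dld", "Pdk4", "G6pdx",
    "Pgd", "Tkt", "Taldo1", "Slc2a4", "Mpc1",
)

#: proteins whose HFD upregulation is planted in both age groups (14 of 16;
#: Cpt1b follows its own age-dependent pattern, Etfb is left diet-neutral)
HFD_RESPONSIVE_BETAOX: Tuple[str, ...] = tuple(
    p for p in BETAOX_PROTEINS if p not in ("Cpt1b", "Etfb")
)

#: lower-glycolysis proteins planted as diet-responsive only in young mice
FLEXIBLE_GLYCO: Tuple[str, ...] = ("Eno3", "Pgk1", "Pgam2", "Pgm1", "Pkm")

# ---------------------------------------------------------------------------
# lipid class composition (443 species)
# ---------------------------------------------------------------------------

LIPID_CLASS_COUNTS: Dict[str, int] = {
    "TG": 85, "PC": 70, "LPC": 25, "PL": 35, "PE": 45, "LPE": 15, "SM": 25,
    "DG": 40, "CER": 25, "FA": 20, "PR": 5, "CL": 12, "MG": 6, "LPI": 8,
    "CAR": 27,
}

#: named exemplar species (replace the auto-generated name at that class slot)
EXEMPLAR_SPECIES: Dict[str, str] = {
    "TG": "TG(18:0_18:0_18:1)",
    "CER": "Cer(d18:1/18:0)",
    "DG": "DG(16:0_18:0)",
}
ACYLCARNITINE_SPECIES: Tuple[str, ...] = (
    "CAR(14:0)", "CAR(16:0)", "CAR(18:0)", "CAR(20:0)",
    "CAR(16:0-OH)", "CAR(18:0-OH)", "CAR(18:1-OH)",
)


def _default_ogtt_params() -> Dict[str, Dict[str, Tuple[float, ...]]]:
    # (C_b, C_1, C_2, k_a, k_e1, k_e2); glucose in mM, insulin in ng/mL.
    # Chosen so group-mean MISI orders yLFD > yHFD > oLFD > oHFD and
    # HOMA-IR the reverse.
    return {
        "young_LFD": {
            "glucose": (4.6, 9.0, 0.30, 0.20, 0.035, 0.008),
            "insulin": (0.40, 0.90, 0.10, 0.12, 0.030, 0.010),
        },
        "young_HFD": {
            "glucose": (5.2, 11.0, 0.35, 0.17, 0.028, 0.008),
            "insulin": (0.80, 1.60, 0.20, 0.12, 0.030, 0.010),
        },
        "old_LFD": {
            "glucose": (5.4, 10.0, 0.40, 0.15, 0.022, 0.008),
            "insulin": (1.00, 1.80, 0.30, 0.12, 0.030, 0.010),
        },
        "old_HFD": {
            "glucose": (6.2, 12.0, 0.50, 0.13, 0.017, 0.008),
            "insulin": (2.00, 3.50, 0.60, 0.12, 0.030, 0.010),
        },
    }


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort.  All effect sizes are generator inputs,
    not estimates of any measured dataset."""

    seed: int = 0
    n_young: int = 6
    n_old: int = 10

    # proteomics effects (multiplicative)
    cpt1b_age_mult: float = 0.6          # old vs young baseline
    cpt1b_hfd_mult_young: float = 1.5
    cpt1b_hfd_mult_old: float = 1.3      # reduced diet flexibility with age
    betaox_hfd_mult: float = 1.5         # applied to HFD_RESPONSIVE_BETAOX
    betaox_age_mult: float = 1.2         # most beta-ox proteins higher in old
    glycolysis_age_mult: float = 0.8
    lower_glyco_hfd_mult_young: float = 0.75
    cv_proteomics: float = 0.15

    # lipidomics planted blocks
    n_lipid_species: int = 443
    lipid_up_old: int = 58
    lipid_up_old_mult: float = 2.5
    lipid_down_old: int = 3
    lipid_down_old_mult: float = 0.4
    lipid_up_young: int = 7
    lipid_up_young_mult: float = 2.6
    lipid_down_young: int = 2
    lipid_down_young_mult: float = 0.45
    tg_exemplar_mult: float = 7.7
    cv_lipidomics: float = 0.25

    # OGTT
    ogtt_params: Dict[str, Dict[str, Tuple[float, ...]]] = field(
        default_factory=_default_ogtt_params
    )
    cv_ogtt_params: float = 0.10
    cv_glucose: float = 0.05
    cv_insulin: float = 0.15

    def __post_init__(self):
        if self.n_young < 2 or self.n_old < 2:
            raise DomainError("need >= 2 animals per group")
        for name in (
            "cpt1b_age_mult", "cpt1b_hfd_mult_young", "cpt1b_hfd_mult_old",
            "betaox_hfd_mult", "betaox_age_mult", "glycolysis_age_mult",
            "lower_glyco_hfd_mult_young", "lipid_up_old_mult",
            "lipid_down_old_mult", "lipid_up_young_mult",
            "lipid_down_young_mult", "tg_exemplar_mult",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        for name in ("cv_proteomics", "cv_lipidomics", "cv_ogtt_params",
                     "cv_glucose", "cv_insulin"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    def with_null_young_lipids(self) -> "CohortConfig":
        return replace(self, lipid_up_young=0, lipid_down_young=0)


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return np.exp(rng.normal(0.0, sigma, shape))


def sample_sheet(config: CohortConfig) -> pd.DataFrame:
    """Animal identifiers with age and diet labels (the single source of
    group membership for all generated tables)."""
    rows = []
    for age, n in (("young", config.n_young), ("old", config.n_old)):
        for diet in ("LFD", "HFD"):
            prefix = f"{'Y' if age == 'young' else 'O'}{'L' if diet == 'LFD' else 'H'}"
            for i in range(n):
                rows.append({"sample": f"{prefix}{i + 1:02d}", "age": age, "diet": diet})
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

def generate_proteomics(config: CohortConfig) -> OmicsTable:
    """16 beta-oxidation + 31 glucose-metabolism proteins x all animals,
    fmol per ug total protein, with the planted age/diet pattern."""
    rng = _rng(config, stage=1)
    sheet = sample_sheet(config)
    proteins = list(BETAOX_PROTEINS) + list(GLYCO_PROTEINS)

    # baselines: model-mapped enzymes anchor to the liver reference scale so
    # that a young-LFD animal lands near the default kinetic model
    protein_baseline: Dict[str, float] = {}
    for enzyme, protein in ENZYME_PROTEIN.items():
        protein_baseline[protein] = DEFAULT_LIVER_PROTEOMICS[enzyme]
    for p in proteins:
        if p not in protein_baseline:
            protein_baseline[p] = float(np.exp(rng.uniform(np.log(0.5), np.log(50.0))))

    values = np.empty((len(proteins), len(sheet)))
    for j, (sample, row) in enumerate(sheet.iterrows()):
        age, diet = row["age"], row["diet"]
        for i, p in enumerate(proteins):
            v = protein_baseline[p]
            if p == "Cpt1b":
                if age == "old":
                    v *= config.cpt1b_age_mult
                    if diet == "HFD":
                        v *= config.cpt1b_hfd_mult_old
                elif diet == "HFD":
                    v *= config.cpt1b_hfd_mult_young
            elif p in BETAOX_PROTEINS:
                if age == "old":
                    v *= config.betaox_age_mult
                if diet == "HFD" and p in HFD_RESPONSIVE_BETAOX:
                    v *= config.betaox_hfd_mult
            else:  # glucose metabolism
                if age == "old":
                    v *= config.glycolysis_age_mult
                if (diet == "HFD" and age == "young"
                        and p in FLEXIBLE_GLYCO):
                    v *= config.lower_glyco_hfd_mult_young
            values[i, j] = v
    values *= _noise(rng, config.cv_proteomics, values.shape)
    frame = pd.DataFrame(values, index=pd.Index(proteins, name="protein"),
                         columns=sheet.index)
    pathway = pd.Series(
        ["betaox"] * len(BETAOX_PROTEINS) + ["glucose"] * len(GLYCO_PROTEINS),
        index=frame.index, name="class",
    )
    return OmicsTable(values=frame, samples=sheet, classes=pathway)


# ---------------------------------------------------------------------------
# lipidomics
# ---------------------------------------------------------------------------

def lipid_catalogue(config: CohortConfig) -> pd.Series:
    """Species -> class annotation for the synthetic lipidome."""
    names: List[str] = []
    classes: List[str] = []
    counts = dict(LIPID_CLASS_COUNTS)
    total = sum(counts.values())
    if config.n_lipid_species != total:
        # rescale the TG bucket to absorb the difference
        counts["TG"] += config.n_lipid_species - total
        if counts["TG"] < 1:
            raise DomainError("n_lipid_species too small for the class layout")
    for cls, count in counts.items():
        for i in range(count):
            if cls in EXEMPLAR_SPECIES and i == 0:
                names.append(EXEMPLAR_SPECIES[cls])
            elif cls == "CAR" and i < len(ACYLCARNITINE_SPECIES):
                names.append(ACYLCARNITINE_SPECIES[i])
            else:
                names.append(f"{cls}({i + 1:03d})")
            classes.append(cls)
    return pd.Series(classes, index=pd.Index(names, name="analyte"), name="class")


def planted_lipid_blocks(config: CohortConfig) -> Dict[str, List[str]]:
    """Deterministic species membership of the planted effect blocks."""
    catalogue = lipid_catalogue(config)
    rng = _rng(config, stage=2)
    # the old-HFD accumulation block: the named exemplars, the long-chain
    # acylcarnitines, and a deterministic draw of TG/DG/CER/SM species
    up_old: List[str] = [
        EXEMPLAR_SPECIES["TG"], EXEMPLAR_SPECIES["CER"], EXEMPLAR_SPECIES["DG"],
        *ACYLCARNITINE_SPECIES,
    ]
    pool = [
        s for s in catalogue.index
        if catalogue[s] in ("TG", "DG", "CER", "SM", "PC") and s not in up_old
    ]
    n_extra = config.lipid_up_old - len(up_old)
    if n_extra < 0:
        up_old = up_old[: config.lipid_up_old]
        n_extra = 0
    up_old += list(rng.choice(pool, size=n_extra, replace=False))
    remaining = [s for s in catalogue.index if s not in set(up_old)]
    picks = list(rng.choice(remaining, size=(config.lipid_down_old
                                             + config.lipid_up_young
                                             + config.lipid_down_young),
                            replace=False))
    down_old = picks[: config.lipid_down_old]
    up_young = picks[config.lipid_down_old:
                     config.lipid_down_old + config.lipid_up_young]
    down_young = picks[config.lipid_down_old + config.lipid_up_young:]
    return {
        "up_old": up_old,
        "down_old": down_old,
        "up_young": up_young,
        "down_young": down_young,
    }


def generate_lipidomics(
    config: CohortConfig,
) -> Tuple[OmicsTable, Dict[str, float]]:
    """Raw-intensity lipidomics table plus per-class standard intensities.

    The returned table is on the raw scale (class standards multiplied in),
    so the class-standard normalization stage reconstructs comparable
    abundances.  Planted blocks act multiplicatively on single age x diet
    cells (old-HFD accumulation etc.).
    """
    catalogue = lipid_catalogue(config)
    blocks = planted_lipid_blocks(config)
    rng = _rng(config, stage=3)
    sheet = sample_sheet(config)

    baseline = pd.Series(
        np.exp(rng.uniform(np.log(1e4), np.log(1e7), size=len(catalogue))),
        index=catalogue.index,
    )
    standards = {cls: float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                 for cls in sorted(set(catalogue))}

    up_old = set(blocks["up_old"])
    down_old = set(blocks["down_old"])
    up_young = set(blocks["up_young"])
    down_young = set(blocks["down_young"])

    values = np.empty((len(catalogue), len(sheet)))
    for j, (sample, row) in enumerate(sheet.iterrows()):
        age, diet = row["age"], row["diet"]
        mult = np.ones(len(catalogue))
        if age == "old" and diet == "HFD":
            for i, s in enumerate(catalogue.index):
                if s in up_old:
                    mult[i] = (config.tg_exemplar_mult
                               if s == EXEMPLAR_SPECIES["TG"]
                               else config.lipid_up_old_mult)
                elif s in down_old:
                    mult[i] = config.lipid_down_old_mult
        elif age == "young" and diet == "HFD":
            for i, s in enumerate(catalogue.index):
                if s in up_young:
                    mult[i] = config.lipid_up_young_mult
                elif s in down_young:
                    mult[i] = config.lipid_down_young_mult
        values[:, j] = baseline.to_numpy() * mult
    values *= _noise(rng, config.cv_lipidomics, values.shape)
    # move to the raw scale: multiply each class by its standard's intensity
    class_factor = catalogue.map(standards).to_numpy(dtype=float)
    values = values * class_factor[:, None]
    frame = pd.DataFrame(values, index=catalogue.index, columns=sheet.index)
    return OmicsTable(values=frame, samples=sheet, classes=catalogue), standards


# ---------------------------------------------------------------------------
# OGTT
# ---------------------------------------------------------------------------

def generate_ogtt(
    config: CohortConfig, return_params: bool = False
):
    """Per-animal OGTT series sampled from the double-exponential family.

    Glucose at the 8 standard times, insulin (ng/mL) at its 6 times.
    Animal-level parameters jitter around group means; measurement noise is
    multiplicative at the configured CVs.  All concentrations are > 0.
    """
    rng = _rng(config, stage=4)
    sheet = sample_sheet(config)
    g_times = np.array(GLUCOSE_TIMES)
    i_times = np.array(INSULIN_TIMES)
    series: List[OGTTSeries] = []
    truth: Dict[str, Dict[str, Tuple[float, ...]]] = {}
    for sample, row in sheet.iterrows():
        group = f"{row['age']}_{row['diet']}"
        params = config.ogtt_params[group]
        animal_params = {}
        for which in ("glucose", "insulin"):
            base = np.asarray(params[which], dtype=float)
            jitter = _noise(rng, config.cv_ogtt_params, base.shape)
            animal_params[which] = tuple(base * jitter)
        g = curve(g_times, *animal_params["glucose"])
        g = np.maximum(g * _noise(rng, config.cv_glucose, g.shape), 1e-6)
        ins = curve(i_times, *animal_params["insulin"])
        ins = np.maximum(ins * _noise(rng, config.cv_insulin, ins.shape), 1e-6)
        series.append(
            OGTTSeries(
                animal=str(sample),
                glucose_times=g_times,
                glucose=g,
                insulin_times=i_times,
                insulin=ins,
                insulin_unit="ng/mL",
            )
        )
        truth[str(sample)] = animal_params
    if return_params:
        return series, truth
    return series
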