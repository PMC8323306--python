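"""Proteomics-anchored parameterization of the beta-oxidation model.

Catalytic constants are anchored on a liver reference (published Vmax and
protein concentrations), ``k_cat_e = Vmax_e / E_e``, then applied to each
muscle sample, ``Vmax_e,sample = k_cat_e * E_e,sample`` — one parameter
overlay per animal.  Also provides peptide-to-protein quantification from
paired endogenous/standard transition areas and the mitochondrial
enrichment-ratio correction ``rate / (CS_mito / CS_homog)``.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Mapping, Optional

import pandas as pd

from .betaox.model import ENZYMES, ParameterSet
from .errors import ConfigurationError, DomainError

log = logging.getLogger(__name__)

#: model enzyme -> proteomics identifier carrying its abundance.
#: Lumped steps are represented by one protein (IMPORT by Cpt2; the lumped
#: hydratase+HAD step by Hadha, the MTP alpha subunit which hosts both
#: activities; the MTP thiolase by Hadhb).
ENZYME_PROTEIN: Dict[str, str] = {
    "CPT1B": "Cpt1b",
    "IMPORT": "Cpt2",
    "VLCAD": "Acadvl",
    "LCAD": "Acadl",
    "MCAD": "Acadm",
    "SCAD": "Acads",
    "HYD_HAD": "Hadha",
    "MCKAT": "Acaa2",
    "MTP": "Hadhb",
}

#: Liver-anchored reference used to derive default k_cat values.  These are
#: order-of-magnitude plausible placeholders, NOT published liver data
#: (which the package cannot ship); supply your own reference tables to
#: reproduce a published parameterization.
DEFAULT_LIVER_VMAX: Dict[str, float] = {   # umol min^-1 mg^-1
    "CPT1B": 0.0020,
    "IMPORT": 0.0030,
    "VLCAD": 0.0080,
    "LCAD": 0.0050,
    "MCAD": 0.0100,
    "SCAD": 0.0080,
    "HYD_HAD": 0.0400,
    "MCKAT": 0.0026,
    "MTP": 0.0080,
}
DEFAULT_LIVER_PROTEOMICS: Dict[str, float] = {  # fmol (ug total protein)^-1
    "CPT1B": 2.0,
    "IMPORT": 4.0,
    "VLCAD": 10.0,
    "LCAD": 8.0,
    "MCAD": 20.0,
    "SCAD": 12.0,
    "HYD_HAD": 30.0,
    "MCKAT": 15.0,
    "MTP": 25.0,
}


def estimate_kcats(
    liver_vmax: Mapping[str, float], liver_proteomics: Mapping[str, float]
) -> Dict[str, float]:
    """k_cat per enzyme from a liver reference: ``Vmax / concentration``.

    Units: (umol min^-1 mg^-1) per (fmol ug^-1).  A zero reference Vmax
    yields k_cat 0 with a warning (the enzyme is effectively absent).
    """
    missing = set(liver_vmax) ^ set(liver_proteomics)
    if missing:
        raise ConfigurationError(
            f"enzyme sets of liver Vmax and proteomics differ: {sorted(missing)}"
        )
    kcats: Dict[str, float] = {}
    for enzyme, vmax in liver_vmax.items():
        conc = liver_proteomics[enzyme]
        if conc <= 0:
            raise DomainError(
                f"non-positive liver concentration for enzyme {enzyme!r}"
            )
        if vmax < 0:
            raise DomainError(f"negative liver Vmax for enzyme {enzyme!r}")
        if vmax == 0:
            warnings.warn(
                f"liver Vmax for {enzyme!r} is 0; enzyme treated as absent",
                stacklevel=2,
            )
        kcats[enzyme] = vmax / conc
    return kcats


def default_kcats() -> Dict[str, float]:
    return estimate_kcats(DEFAULT_LIVER_VMAX, DEFAULT_LIVER_PROTEOMICS)


def compute_vmax(
    kcats: Mapping[str, float],
    sample: Mapping[str, float],
    protein_map: Mapping[str, str] = ENZYME_PROTEIN,
    impute: Optional[Mapping[str, float]] = None,
) -> Dict[str, float]:
    """Per-enzyme Vmax for one animal: ``k_cat * measured concentration``.

    ``sample`` maps protein identifiers to fmol/ug concentrations (one
    proteomics table column).  A protein missing from the sample is a hard
    configuration error unless an explicit ``impute`` mapping (e.g. cohort
    means) provides a value, in which case the imputation is logged.
    """
    vmax: Dict[str, float] = {}
    for enzyme, kcat in kcats.items():
        protein = protein_map.get(enzyme, enzyme)
        if protein in sample and pd.notna(sample[protein]):
            conc = float(sample[protein])
        elif impute is not None and protein in impute:
            conc = float(impute[protein])
            log.warning("imputing %s (%s) with %g", enzyme, protein, conc)
        else:
            raise ConfigurationError(
                f"no measured concentration for enzyme {enzyme!r} "
                f"(protein {protein!r}) and no imputation rule engaged"
            )
        if conc < 0:
            raise DomainError(f"negative concentration for protein {protein!r}")
        vmax[enzyme] = kcat * conc
    return vmax


def parameterize_cohort(
    proteomics: pd.DataFrame,
    kcats: Optional[Mapping[str, float]] = None,
    base: Optional[ParameterSet] = None,
    protein_map: Mapping[str, str] = ENZYME_PROTEIN,
) -> Dict[str, ParameterSet]:
    """One ParameterSet per sample column of a protein x sample table."""
    if kcats is None:
        kcats = default_kcats()
    if base is None:
        base = ParameterSet()
    if proteomics.index.duplicated().any():
        dupes = proteomics.index[proteomics.index.duplicated()].unique().tolist()
        raise ConfigurationError(f"duplicate protein identifiers: {dupes}")
    out: Dict[str, ParameterSet] = {}
    for sample in proteomics.columns:
        overlay = compute_vmax(kcats, proteomics[sample].to_dict(), protein_map)
        missing = [e for e in ENZYMES if e not in overlay]
        if missing:
            raise ConfigurationError(f"k_cat table lacks enzymes {missing}")
        out[str(sample)] = base.with_vmax(overlay)
    return out


def peptide_to_protein(
    peptide_areas: pd.DataFrame,
    standard_amounts: Mapping[str, float],
) -> pd.DataFrame:
    """Protein x sample concentration table from transition peak areas.

    ``peptide_areas`` is long format with columns ``sample``, ``protein``,
    ``peptide``, ``area_endogenous``, ``area_standard``.  Peptide
    concentration = (endogenous/standard area ratio) x standard amount
    (fmol per ug injected); protein value = unweighted mean over its
    surviving peptides.  Peptides with a zero standard area are dropped with
    a warning; a protein with no surviving peptide gets a missing value.
    """
    required = {"sample", "protein", "peptide", "area_endogenous", "area_standard"}
    missing = required - set(peptide_areas.columns)
    if missing:
        raise ConfigurationError(f"peptide table lacks columns {sorted(missing)}")
    df = peptide_areas.copy()
    unknown = set(df["peptide"]) - set(standard_amounts)
    if unknown:
        raise ConfigurationError(
            f"no standard amount for peptide(s) {sorted(unknown)}"
        )
    if (df["area_endogenous"] < 0).any() or (df["area_standard"] < 0).any():
        raise DomainError("negative peak area")
    dropped = df["area_standard"] == 0
    if dropped.any():
        for _, row in df[dropped].iterrows():
            log.warning(
                "dropping peptide %s of %s in sample %s: zero standard area",
                row["peptide"], row["protein"], row["sample"],
            )
        df = df[~dropped]
    df = df.assign(
        conc=df["area_endogenous"]
        / df["area_standard"]
        * df["peptide"].map(standard_amounts)
    )
    wide = (
        df.groupby(["protein", "sample"], sort=True)["conc"]
        .mean()
        .unstack("sample")
    )
    # reinstate proteins/samples whose every peptide was dropped, as missing
    all_proteins = pd.Index(sorted(set(peptide_areas["protein"])), name="protein")
    all_samples = pd.Index(sorted(set(peptide_areas["sample"])), name="sample")
    return wide.reindex(index=all_proteins, columns=all_samples)


def enrichment_correct(rate_mito: float, cs_mito: float, cs_homog: float) -> float:
    """Convert a per-mg-mitochondrial-protein rate to per-mg-tissue-protein
    using the citrate-synthase enrichment ratio R = CS_mito / CS_homog."""
    if cs_mito <= 0 or cs_homog <= 0:
        raise DomainError("citrate synthase activities must be > 0")
    return rate_mito * cs_homog / cs_mito
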