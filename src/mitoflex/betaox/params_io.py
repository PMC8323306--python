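"""Flat key-value parameter files for the beta-oxidation model.

Format (INI-style, units fixed by convention):

    [vmax]              # umol min^-1 (mg total protein)^-1
    CPT1B = 0.002
    ...
    [km]                # uM; either "ENZYME = x" (broadcast over its chains)
    VLCAD = 2.0         # or "ENZYME.C16 = x" per chain length
    CPT1B.C16 = 2.0
    KI_MALONYL = 0.05
    CARNITINE = 500
    COA = 15
    [conserved]         # uM
    COA_TOTAL = 2500
    CARNITINE_TOTAL = 2000
    [chains]            # optional chain-specificity overrides
    MCKAT = 12,10,8,6,4
    [options]
    K_SINK = 10000      # min^-1
    VOLUME_FACTOR = 1.0 # uL matrix water per mg total protein
    CARNITINE_CYTOSOLIC = 2000
"""

from __future__ import annotations

import configparser
from pathlib import Path
from typing import Dict, Union

from ..errors import ConfigurationError
from .model import DEFAULT_CHAINS, ENZYMES, ParameterSet


def read_parameters(path: Union[str, Path]) -> ParameterSet:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"parameter file not found: {path}")
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep enzyme-name case
    cp.read(path)

    kwargs: Dict[str, object] = {}
    if cp.has_section("vmax"):
        kwargs["vmax"] = {k: float(v) for k, v in cp.items("vmax")}
    km: Dict[str, Dict[int, float]] = {}
    chains = dict(DEFAULT_CHAINS)
    if cp.has_section("chains"):
        for enzyme, spec in cp.items("chains"):
            chains[enzyme] = tuple(int(t.strip().lstrip("Cc")) for t in spec.split(","))
    kwargs["chains"] = chains
    if cp.has_section("km"):
        for key, value in cp.items("km"):
            if key == "KI_MALONYL":
                kwargs["ki_malonyl"] = float(value)
            elif key == "CARNITINE":
                kwargs["km_carnitine"] = float(value)
            elif key == "COA":
                kwargs["km_coa"] = float(value)
            elif "." in key:
                enzyme, chain = key.split(".", 1)
                km.setdefault(enzyme, {})[int(chain.lstrip("Cc"))] = float(value)
            else:
                # scalar: broadcast over the enzyme's chain mask
                km[key] = {l: float(value) for l in chains[key]}
    if km:
        kwargs["km"] = km
    if cp.has_section("conserved"):
        for key, value in cp.items("conserved"):
            if key == "COA_TOTAL":
                kwargs["coa_total"] = float(value)
            elif key == "CARNITINE_TOTAL":
                kwargs["carnitine_total"] = float(value)
            else:
                raise ConfigurationError(f"unknown conserved-pool key {key!r}")
    if cp.has_section("options"):
        mapping = {
            "K_SINK": "k_sink",
            "VOLUME_FACTOR": "volume_factor",
            "CARNITINE_CYTOSOLIC": "carnitine_cytosolic",
        }
        for key, value in cp.items("options"):
            if key not in mapping:
                raise ConfigurationError(f"unknown option {key!r} in {path}")
            kwargs[mapping[key]] = float(value)
    return ParameterSet(**kwargs)  # type: ignore[arg-type]


def write_parameters(params: ParameterSet, path: Union[str, Path]) -> None:
    path = Path(path)
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp["vmax"] = {e: repr(params.vmax[e]) for e in ENZYMES}
    km_section: Dict[str, str] = {}
    for e in ENZYMES:
        values = params.km[e]
        if len(set(values.values())) == 1:
            km_section[e] = repr(next(iter(values.values())))
        else:
            for l, v in values.items():
                km_section[f"{e}.C{l}"] = repr(v)
    km_section["KI_MALONYL"] = repr(params.ki_malonyl)
    km_section["CARNITINE"] = repr(params.km_carnitine)
    km_section["COA"] = repr(params.km_coa)
    cp["km"] = km_section
    cp["conserved"] = {
        "COA_TOTAL": repr(params.coa_total),
        "CARNITINE_TOTAL": repr(params.carnitine_total),
    }
    cp["chains"] = {
        e: ",".join(str(l) for l in params.chains[e]) for e in ENZYMES
    }
    cp["options"] = {
        "K_SINK": repr(params.k_sink),
        "VOLUME_FACTOR": repr(params.volume_factor),
        "CARNITINE_CYTOSOLIC": repr(params.carnitine_cytosolic),
    }
    with open(path, "w") as fh:
        fh.write("# beta-oxidation model parameters; units per section docs\n")
        cp.write(fh)
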