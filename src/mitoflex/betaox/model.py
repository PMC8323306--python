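"""Deterministic kinetic model of mitochondrial long-chain fatty-acid
beta-oxidation.

The pathway is resolved per acyl chain length l in {16, 14, 12, 10, 8, 6, 4}
with three intra-cycle species per length (acyl-CoA ``A_l``, enoyl-CoA
``E_l``, 3-ketoacyl-CoA ``K_l``; the hydratase and the 3-hydroxyacyl-CoA
dehydrogenase are lumped, so the 3-hydroxy intermediate is not tracked).

Steps and their chain specificity (the mask is data, not code, and can be
overridden per :class:`ParameterSet`):

* ``CPT1B``        cytosolic palmitoyl-CoA + carnitine -> C16-acylcarnitine;
                   competitive malonyl-CoA inhibition (M/Ki enters the
                   acyl-CoA binding denominator).
* ``IMPORT``       lumped CACT/CPT2: C16-acylcarnitine + free CoA ->
                   matrix palmitoyl-CoA + free carnitine.
* ``VLCAD/LCAD/MCAD/SCAD``  acyl-CoA dehydrogenases, A_l -> E_l.
* ``HYD_HAD``      lumped enoyl-CoA hydratase + 3-hydroxyacyl-CoA
                   dehydrogenase, E_l -> K_l.
* ``MTP``/``MCKAT`` thiolases, K_l + CoA -> A_{l-2} + acetyl-CoA
                   (K_4 + CoA -> 2 acetyl-CoA).
* ``SINK``         first-order acetyl-CoA drain regenerating free CoA.

Each multi-substrate enzyme uses a single shared competitive denominator
``1 + sum_l S_l/Km_{e,l}`` over its active chain lengths.

Two moieties are conserved: total CoA (free CoA + all CoA esters) and total
carnitine (free carnitine + C16-acylcarnitine).  Cytosolic palmitoyl-CoA,
cytosolic carnitine and malonyl-CoA are clamped boundary species.

Units: concentrations are uM; maximal rates are supplied per mg total
protein (umol min^-1 mg^-1) and converted to uM min^-1 through a fixed
matrix-volume factor (uL matrix water per mg total protein).  The factor
rescales time only and cancels in control coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np

from ..errors import ConfigurationError, DomainError

#: tracked acyl chain lengths, longest first
CHAIN_LENGTHS: Tuple[int, ...] = (16, 14, 12, 10, 8, 6, 4)

#: acyl-CoA dehydrogenases
ACADS: Tuple[str, ...] = ("VLCAD", "LCAD", "MCAD", "SCAD")

#: thiolases
THIOLASES: Tuple[str, ...] = ("MTP", "MCKAT")

#: every Vmax-bearing enzyme except the acetyl-CoA sink
ENZYMES: Tuple[str, ...] = ("CPT1B", "IMPORT") + ACADS + ("HYD_HAD",) + THIOLASES

#: all flux-scaling steps (used for the MCA summation theorem)
ALL_STEPS: Tuple[str, ...] = ENZYMES + ("SINK",)

#: default chain-specificity mask
DEFAULT_CHAINS: Dict[str, Tuple[int, ...]] = {
    "CPT1B": (16,),
    "IMPORT": (16,),
    "VLCAD": (16, 14, 12),
    "LCAD": (16, 14, 12, 10, 8),
    "MCAD": (12, 10, 8, 6),
    "SCAD": (6, 4),
    "HYD_HAD": CHAIN_LENGTHS,
    "MTP": (16, 14, 12, 10, 8),
    "MCKAT": (12, 10, 8, 6, 4),
}

#: default Michaelis constants, uM (one value per enzyme, broadcast over its
#: active chain lengths; replacements for the unavailable published set)
DEFAULT_KM: Dict[str, float] = {
    "CPT1B": 2.0,
    "IMPORT": 10.0,
    "VLCAD": 2.0,
    "LCAD": 5.0,
    "MCAD": 5.0,
    "SCAD": 5.0,
    "HYD_HAD": 5.0,
    "MTP": 2.0,
    "MCKAT": 200.0,
}

#: default maximal rates, umol min^-1 (mg total protein)^-1.  Chosen so that
#: CPT1B holds nearly all flux control at low substrate while, without
#: malonyl-CoA, control shifts towards MCKAT under palmitoyl-CoA overload
#: (mediated by ketoacyl-CoA accumulation sequestering the CoA pool).
DEFAULT_VMAX: Dict[str, float] = {
    "CPT1B": 0.0020,
    "IMPORT": 0.0030,
    "VLCAD": 0.0080,
    "LCAD": 0.0050,
    "MCAD": 0.0100,
    "SCAD": 0.0080,
    "HYD_HAD": 0.0400,
    "MTP": 0.0080,
    "MCKAT": 0.0026,
}

#: acetyl-CoA molecules released per imported C16 (7 thiolytic cleavages, the
#: terminal C4 cleavage yields two)
ACETYL_PER_C16 = 8


@dataclass(frozen=True)
class ParameterSet:
    """Per-sample kinetic parameterization of the beta-oxidation model.

    ``vmax`` entries are umol min^-1 mg^-1 (per mg total protein); ``km``
    maps enzyme -> {chain length -> uM}; ``k_sink`` is the first-order
    acetyl-CoA drain constant (min^-1); ``volume_factor`` is the
    matrix-volume bridge (uL per mg total protein).
    """

    vmax: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VMAX))
    km: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    chains: Mapping[str, Tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CHAINS)
    )
    ki_malonyl: float = 0.05
    km_carnitine: float = 100.0
    km_coa: float = 300.0
    coa_total: float = 500.0
    carnitine_total: float = 150.0
    carnitine_cytosolic: float = 2000.0
    k_sink: float = 1.0e4
    volume_factor: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "vmax", dict(self.vmax))
        object.__setattr__(self, "chains", {k: tuple(v) for k, v in self.chains.items()})
        # broadcast scalar or partial Km specs over the chain mask
        km_full: Dict[str, Dict[int, float]] = {}
        for enzyme in ENZYMES:
            chains = self.chains.get(enzyme)
            if chains is None:
                raise ConfigurationError(f"no chain mask for enzyme {enzyme!r}")
            spec = self.km.get(enzyme, DEFAULT_KM[enzyme]) if self.km else DEFAULT_KM[enzyme]
            if isinstance(spec, (int, float)):
                km_full[enzyme] = {l: float(spec) for l in chains}
            else:
                missing = [l for l in chains if l not in spec]
                if missing:
                    raise ConfigurationError(
                        f"missing Km for enzyme {enzyme!r} at chain length(s) {missing}"
                    )
                km_full[enzyme] = {l: float(spec[l]) for l in chains}
        object.__setattr__(self, "km", km_full)
        self.validate()

    def validate(self) -> None:
        for enzyme in ENZYMES:
            if enzyme not in self.vmax:
                raise ConfigurationError(f"missing Vmax for enzyme {enzyme!r}")
            if self.vmax[enzyme] < 0:
                raise DomainError(f"negative Vmax for enzyme {enzyme!r}")
            for l, v in self.km[enzyme].items():
                if v <= 0:
                    raise DomainError(f"non-positive Km for ({enzyme!r}, C{l})")
        if self.ki_malonyl <= 0:
            raise DomainError("ki_malonyl must be > 0")
        for name in ("km_carnitine", "km_coa", "coa_total", "carnitine_total",
                     "carnitine_cytosolic", "volume_factor"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        if self.k_sink < 0:
            raise DomainError("k_sink must be >= 0")

    # -- convenience -------------------------------------------------------
    def with_vmax(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Return a copy with some (or all) Vmax entries replaced."""
        new = dict(self.vmax)
        new.update(overrides)
        return replace(self, vmax=new)

    def scaled(self, factor: float) -> "ParameterSet":
        """Scale every flux-bearing step (all Vmax and the sink) by ``factor``."""
        return replace(
            self,
            vmax={k: v * factor for k, v in self.vmax.items()},
            k_sink=self.k_sink * factor,
        )


def default_parameters() -> ParameterSet:
    return ParameterSet()


def random_parameters(
    rng: np.random.Generator,
    vmax_range: Tuple[float, float] = (0.3, 3.0),
    km_range: Tuple[float, float] = (0.5, 2.0),
) -> ParameterSet:
    """Draw a random ParameterSet: log-uniform multipliers around the defaults."""
    lo, hi = np.log(vmax_range[0]), np.log(vmax_range[1])
    vmax = {e: DEFAULT_VMAX[e] * float(np.exp(rng.uniform(lo, hi))) for e in ENZYMES}
    klo, khi = np.log(km_range[0]), np.log(km_range[1])
    km = {e: DEFAULT_KM[e] * float(np.exp(rng.uniform(klo, khi))) for e in ENZYMES}
    return ParameterSet(vmax=vmax, km=km)


# ---------------------------------------------------------------------------
# state container
# ---------------------------------------------------------------------------

N_CHAINS = len(CHAIN_LENGTHS)
#: reduced (independent) state dimension: AC16, A(7), E(7), K(7), acetyl-CoA
N_STATE = 1 + 3 * N_CHAINS + 1
_I_AC16 = 0
_I_A = slice(1, 1 + N_CHAINS)
_I_E = slice(1 + N_CHAINS, 1 + 2 * N_CHAINS)
_I_K = slice(1 + 2 * N_CHAINS, 1 + 3 * N_CHAINS)
_I_AC = N_STATE - 1


@dataclass
class ModelState:
    """Concentrations of all model species (uM).

    ``s_cyt`` (cytosolic palmitoyl-CoA), ``carnitine_cyt`` and ``malonyl``
    are clamped boundary species.  ``coa_free`` and ``carnitine_free`` are
    determined by the conserved moieties.
    """

    s_cyt: float
    malonyl: float
    carnitine_cyt: float
    acylcarnitine_c16: float
    acyl_coa: np.ndarray       # shape (7,), chain lengths 16..4
    enoyl_coa: np.ndarray
    ketoacyl_coa: np.ndarray
    acetyl_coa: float
    coa_free: float
    carnitine_free: float

    @classmethod
    def from_vector(
        cls, x: np.ndarray, params: ParameterSet, s_cyt: float, malonyl: float
    ) -> "ModelState":
        x = np.asarray(x, dtype=float)
        esters = float(x[_I_A].sum() + x[_I_E].sum() + x[_I_K].sum() + x[_I_AC])
        return cls(
            s_cyt=float(s_cyt),
            malonyl=float(malonyl),
            carnitine_cyt=params.carnitine_cytosolic,
            acylcarnitine_c16=float(x[_I_AC16]),
            acyl_coa=x[_I_A].copy(),
            enoyl_coa=x[_I_E].copy(),
            ketoacyl_coa=x[_I_K].copy(),
            acetyl_coa=float(x[_I_AC]),
            coa_free=params.coa_total - esters,
            carnitine_free=params.carnitine_total - float(x[_I_AC16]),
        )

    def to_vector(self) -> np.ndarray:
        x = np.empty(N_STATE)
        x[_I_AC16] = self.acylcarnitine_c16
        x[_I_A] = self.acyl_coa
        x[_I_E] = self.enoyl_coa
        x[_I_K] = self.ketoacyl_coa
        x[_I_AC] = self.acetyl_coa
        return x

    @classmethod
    def zero(cls, params: ParameterSet, s_cyt: float = 0.0, malonyl: float = 0.0) -> "ModelState":
        return cls.from_vector(np.zeros(N_STATE), params, s_cyt, malonyl)

    def validate(self) -> None:
        concs = np.concatenate(
            [
                [self.s_cyt, self.malonyl, self.carnitine_cyt, self.acylcarnitine_c16,
                 self.acetyl_coa, self.coa_free, self.carnitine_free],
                self.acyl_coa, self.enoyl_coa, self.ketoacyl_coa,
            ]
        )
        if np.any(concs < -1e-9):
            raise DomainError("negative concentration in ModelState")


# ---------------------------------------------------------------------------
# compiled kinetics
# ---------------------------------------------------------------------------

class CompiledModel:
    """Numeric form of (ParameterSet, clamps) optimised for repeated solves."""

    __slots__ = (
        "params", "vm_uM", "ki", "km_cpt1", "km_imp", "km_carn", "km_coa",
        "coa_tot", "carn_tot", "k_sink", "vol",
        "acad_inv_km", "hyd_inv_km", "thio_inv_km", "vm_acad", "vm_hyd", "vm_thio",
    )

    def __init__(self, params: ParameterSet):
        self.params = params
        vol = params.volume_factor
        self.vol = vol
        # umol min^-1 mg^-1  ->  uM min^-1  (divide by matrix litres per mg)
        to_uM = 1.0e6 / vol
        self.vm_uM = {e: params.vmax[e] * to_uM for e in ENZYMES}
        self.ki = params.ki_malonyl
        self.km_cpt1 = params.km["CPT1B"][16]
        self.km_imp = params.km["IMPORT"][16]
        self.km_carn = params.km_carnitine
        self.km_coa = params.km_coa
        self.coa_tot = params.coa_total
        self.carn_tot = params.carnitine_total
        self.k_sink = params.k_sink

        len_index = {l: i for i, l in enumerate(CHAIN_LENGTHS)}
        self.acad_inv_km = np.zeros((len(ACADS), N_CHAINS))
        for i, e in enumerate(ACADS):
            for l in params.chains[e]:
                self.acad_inv_km[i, len_index[l]] = 1.0 / params.km[e][l]
        self.hyd_inv_km = np.zeros(N_CHAINS)
        for l in params.chains["HYD_HAD"]:
            self.hyd_inv_km[len_index[l]] = 1.0 / params.km["HYD_HAD"][l]
        self.thio_inv_km = np.zeros((len(THIOLASES), N_CHAINS))
        for i, e in enumerate(THIOLASES):
            for l in params.chains[e]:
                self.thio_inv_km[i, len_index[l]] = 1.0 / params.km[e][l]
        self.vm_acad = np.array([self.vm_uM[e] for e in ACADS])
        self.vm_hyd = self.vm_uM["HYD_HAD"]
        self.vm_thio = np.array([self.vm_uM[e] for e in THIOLASES])

    # -- kinetics ----------------------------------------------------------
    def rate_arrays(self, x: np.ndarray, s_cyt: float, malonyl: float):
        """All reaction rates (uM min^-1) at reduced state ``x``.

        Returns (v_cpt1, v_imp, v_acad (4,7), v_hyd (7,), v_thio (2,7), v_sink).
        Negative concentrations are treated as zero so that every rate vanishes
        with its substrate.
        """
        ac16 = max(x[_I_AC16], 0.0)
        A = np.maximum(x[_I_A], 0.0)
        E = np.maximum(x[_I_E], 0.0)
        K = np.maximum(x[_I_K], 0.0)
        ac = max(x[_I_AC], 0.0)
        coa = max(self.coa_tot - (A.sum() + E.sum() + K.sum() + ac), 0.0)
        carn = max(self.carn_tot - ac16, 0.0)

        s = max(s_cyt, 0.0)
        f_carn = carn / (self.km_carn + carn) if carn > 0 else 0.0
        f_coa = coa / (self.km_coa + coa) if coa > 0 else 0.0

        v_cpt1 = (
            self.vm_uM["CPT1B"]
            * (s / self.km_cpt1)
            / (1.0 + s / self.km_cpt1 + malonyl / self.ki)
            * f_carn
        )
        v_imp = (
            self.vm_uM["IMPORT"]
            * (ac16 / self.km_imp) / (1.0 + ac16 / self.km_imp)
            * f_coa
        )

        sat_a = self.acad_inv_km * A[None, :]
        v_acad = self.vm_acad[:, None] * sat_a / (1.0 + sat_a.sum(axis=1))[:, None]

        sat_e = self.hyd_inv_km * E
        v_hyd = self.vm_hyd * sat_e / (1.0 + sat_e.sum())

        # thiolase CoA site treated as high-affinity (no CoA saturation factor);
        # CoA consumption is stoichiometric, the kinetic CoA feedback acts on
        # the import step only, which keeps the conserved-pool feedback stabilising
        sat_k = self.thio_inv_km * K
        v_thio = self.vm_thio[:, None] * sat_k / (1.0 + sat_k.sum(axis=1))[:, None]

        v_sink = self.k_sink * ac
        return v_cpt1, v_imp, v_acad, v_hyd, v_thio, v_sink

    def rhs(self, x: np.ndarray, s_cyt: float, malonyl: float) -> np.ndarray:
        """Time derivative of the reduced state (uM min^-1)."""
        v_cpt1, v_imp, v_acad, v_hyd, v_thio, v_sink = self.rate_arrays(x, s_cyt, malonyl)
        dx = np.empty(N_STATE)
        dx[_I_AC16] = v_cpt1 - v_imp
        acad_tot = v_acad.sum(axis=0)
        thio_tot = v_thio.sum(axis=0)
        dA = -acad_tot
        dA[0] += v_imp
        dA[1:] += thio_tot[:-1]          # K_l + CoA -> A_{l-2}
        dx[_I_A] = dA
        dx[_I_E] = acad_tot - v_hyd
        dx[_I_K] = v_hyd - thio_tot
        # one acetyl-CoA per cleavage, plus one extra from the terminal C4 step
        dx[_I_AC] = thio_tot.sum() + thio_tot[-1] - v_sink
        return dx

    def cpt1_rate(self, x: np.ndarray, s_cyt: float, malonyl: float) -> float:
        return self.rate_arrays(x, s_cyt, malonyl)[0]


# ---------------------------------------------------------------------------
# public kinetics API
# ---------------------------------------------------------------------------

def reaction_rates(
    state: ModelState, params: ParameterSet
) -> Dict[Tuple[str, int], float]:
    """Reaction rate (uM min^-1) for every (enzyme, chain length) pair.

    The acetyl-CoA sink is reported under ``("SINK", 2)``.
    """
    state.validate()
    cm = CompiledModel(params)
    x = state.to_vector()
    v_cpt1, v_imp, v_acad, v_hyd, v_thio, v_sink = cm.rate_arrays(
        x, state.s_cyt, state.malonyl
    )
    rates: Dict[Tuple[str, int], float] = {
        ("CPT1B", 16): float(v_cpt1),
        ("IMPORT", 16): float(v_imp),
        ("SINK", 2): float(v_sink),
    }
    for i, e in enumerate(ACADS):
        for j, l in enumerate(CHAIN_LENGTHS):
            if cm.acad_inv_km[i, j] > 0:
                rates[(e, l)] = float(v_acad[i, j])
    for j, l in enumerate(CHAIN_LENGTHS):
        if cm.hyd_inv_km[j] > 0:
            rates[("HYD_HAD", l)] = float(v_hyd[j])
    for i, e in enumerate(THIOLASES):
        for j, l in enumerate(CHAIN_LENGTHS):
            if cm.thio_inv_km[i, j] > 0:
                rates[(e, l)] = float(v_thio[i, j])
    return rates


def time_derivatives(state: ModelState, params: ParameterSet) -> Dict[str, float]:
    """Per-species time derivative (uM min^-1), clamped species included (0)."""
    state.validate()
    cm = CompiledModel(params)
    x = state.to_vector()
    dx = cm.rhs(x, state.s_cyt, state.malonyl)
    out: Dict[str, float] = {
        "s_cyt": 0.0,
        "malonyl": 0.0,
        "carnitine_cyt": 0.0,
        "acylcarnitine_c16": float(dx[_I_AC16]),
        "acetyl_coa": float(dx[_I_AC]),
    }
    for j, l in enumerate(CHAIN_LENGTHS):
        out[f"acyl_coa_c{l}"] = float(dx[_I_A][j])
        out[f"enoyl_coa_c{l}"] = float(dx[_I_E][j])
        out[f"ketoacyl_coa_c{l}"] = float(dx[_I_K][j])
    # moiety closures
    ester_rate = (
        float(dx[_I_A].sum() + dx[_I_E].sum() + dx[_I_K].sum()) + out["acetyl_coa"]
    )
    out["coa_free"] = -ester_rate
    out["carnitine_free"] = -out["acylcarnitine_c16"]
    return out


def cpt1_closed_form(params: ParameterSet, s_cyt: float, malonyl: float) -> float:
    """CPT1 rate (umol min^-1 mg^-1) when nothing downstream limits: the
    inhibited Michaelis-Menten closed form at a full free-carnitine pool."""
    if s_cyt < 0 or malonyl < 0:
        raise DomainError("concentrations must be >= 0")
    km = params.km["CPT1B"][16]
    carn = params.carnitine_total
    f_carn = carn / (params.km_carnitine + carn)
    return (
        params.vmax["CPT1B"]
        * (s_cyt / km)
        / (1.0 + s_cyt / km + malonyl / params.ki_malonyl)
        * f_carn
    )
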