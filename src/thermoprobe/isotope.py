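"""13CO2 headspace calculus and position-specific carbon-fate accounting.

Covers the arithmetic of a stable-isotope probing experiment in sealed serum
bottles: converting headspace CO2 mixing ratios to moles with the ideal gas
law, converting delta-13C (permil vs VPDB) to 13C atom fractions, accumulating
excess 13C with corrections for repeated headspace sampling, partitioning
excess into biotic and abiotic sources by mass balance against sterile
controls, and a steady-state bookkeeping model of which labeled carbon
positions of glucose, pyruvate, and acetate are released as CO2 under on/off
states of the central carbon pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: 13C/12C isotope ratio of the VPDB standard.
R_VPDB = 0.0111802

#: Ideal gas constant in L·atm·mol^-1·K^-1.
GAS_CONSTANT_L_ATM = 0.082057

#: Default incubation temperature (75 degC) in kelvin.
INCUBATION_TEMPERATURE_K = 348.15


@dataclass(frozen=True)
class GasConditions:
    """Physical state of the bottle headspace.

    Parameters
    ----------
    pressure_atm : total headspace pressure in atmospheres.
    headspace_volume_L : gas volume of the bottle (bottle minus medium), L.
    temperature_K : incubation temperature in kelvin (default 348.15 K, 75 degC).
    """

    pressure_atm: float
    headspace_volume_L: float
    temperature_K: float = INCUBATION_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.pressure_atm <= 0 or self.headspace_volume_L <= 0 or self.temperature_K <= 0:
            raise ValueError("pressure, volume, and temperature must all be positive")

    @property
    def total_moles_gas(self) -> float:
        """Total moles of headspace gas, n = PV/RT."""
        return (
            self.pressure_atm
            * self.headspace_volume_L
            / (GAS_CONSTANT_L_ATM * self.temperature_K)
        )


@dataclass(frozen=True)
class PartitionResult:
    """Mass-balance split of excess 13CO2 into biotic and abiotic sources."""

    excess_total: float
    excess_abiotic: float
    excess_biotic: float
    biotic_fraction: float


@dataclass(frozen=True)
class PathwayState:
    """On/off switches for the central carbon pathway steps that release CO2.

    ``glycolysis`` routes glucose carbons onto pyruvate carbons;
    ``oxidative_ppp`` decarboxylates glucose C1 at 6-phosphogluconate
    dehydrogenase; ``pyruvate_decarboxylation`` releases pyruvate C1 at the
    pyruvate-ferredoxin oxidoreductase / pyruvate dehydrogenase step;
    ``tca_oxidation`` oxidizes the acetyl carbons (pyruvate C2/C3, acetate
    C1/C2); ``acetate_oxidation`` activates exogenous acetate for oxidation.
    A disabled pathway retains its positions (label stays in biomass or
    excreted products, never in CO2).
    """

    glycolysis: bool = False
    oxidative_ppp: bool = False
    pyruvate_decarboxylation: bool = False
    tca_oxidation: bool = False
    acetate_oxidation: bool = False


#: Valid labeled positions per substrate.
SUBSTRATE_POSITIONS = {
    "glucose": (1, 2, 3, 4, 5, 6),
    "pyruvate": (1, 2, 3),
    "acetate": (1, 2),
}

#: Glycolytic mapping of glucose carbons onto pyruvate carbons
#: (cleavage of fructose-1,6-bisphosphate and triose-phosphate isomerisation):
#: glucose C1/C6 -> pyruvate C3 (methyl), C2/C5 -> C2, C3/C4 -> C1 (carboxyl).
GLUCOSE_TO_PYRUVATE = {1: 3, 6: 3, 2: 2, 5: 2, 3: 1, 4: 1}


def delta_to_atom_fraction(delta_permil: float) -> float:
    """Convert delta-13C (permil vs VPDB) to the 13C atom fraction.

    R = R_VPDB * (delta/1000 + 1); AF = R / (1 + R).
    """
    if delta_permil < -1000:
        raise ValueError(f"delta13C {delta_permil} permil is below -1000 (unphysical)")
    r = R_VPDB * (delta_permil / 1000.0 + 1.0)
    return r / (1.0 + r)


def atom_fraction_to_delta(atom_fraction: float) -> float:
    """Exact algebraic inverse of :func:`delta_to_atom_fraction`."""
    if not 0.0 <= atom_fraction < 1.0:
        raise ValueError(f"atom fraction must be in [0, 1); got {atom_fraction}")
    r = atom_fraction / (1.0 - atom_fraction)
    return (r / R_VPDB - 1.0) * 1000.0


def headspace_moles(mixing_ratio_umol_per_mol: float, conditions: GasConditions) -> float:
    """Moles of CO2 in the headspace from its mixing ratio (umol CO2 / mol gas)."""
    if mixing_ratio_umol_per_mol < 0:
        raise ValueError("mixing ratio must be non-negative")
    return conditions.total_moles_gas * mixing_ratio_umol_per_mol * 1e-6


def excess_13co2(n_co2_mol: float, af_sample: float, af_baseline: float) -> float:
    """Excess 13C above baseline, in umol.

    ``n_co2 * (AF_sample - AF_baseline) * 1e6``; negative values are returned
    as-is (sampling noise can push a difference slightly negative).
    """
    if n_co2_mol < 0:
        raise ValueError("moles of CO2 must be non-negative")
    return n_co2_mol * (af_sample - af_baseline) * 1e6


def correct_for_sampling(
    series: pd.DataFrame,
    conditions: GasConditions,
    baseline_delta_permil: float | None = None,
) -> pd.DataFrame:
    """Cumulative CO2 and excess-13C production, adding back sampled moles.

    Each headspace sample permanently removes gas from the bottle; cumulative
    production at a time point must therefore include the CO2 (and its excess
    13C) carried away by every *prior* sample, computed from the headspace
    concentration at the instant each sample was drawn.

    Parameters
    ----------
    series : DataFrame with columns ``time_h``, ``delta13C_permil``,
        ``co2_umol_per_mol``, ``sample_volume_mL`` (volume withdrawn at that
        time point, after the measurement).
    conditions : headspace gas state.
    baseline_delta_permil : natural-abundance baseline; defaults to the first
        time point's delta.

    Returns
    -------
    DataFrame with ``time_h``, ``n_co2_mol`` (cumulative, sampling-corrected)
    and ``excess_13c_umol`` (cumulative excess above baseline).
    """
    df = series.sort_values("time_h").reset_index(drop=True)
    if baseline_delta_permil is None:
        baseline_delta_permil = float(df["delta13C_permil"].iloc[0])
    af_base = delta_to_atom_fraction(baseline_delta_permil)

    v_head_mL = conditions.headspace_volume_L * 1000.0
    removed_mol = 0.0
    removed_excess = 0.0
    out_n, out_ex = [], []
    for row in df.itertuples(index=False):
        n_i = headspace_moles(row.co2_umol_per_mol, conditions)
        af_i = delta_to_atom_fraction(row.delta13C_permil)
        ex_i = excess_13co2(n_i, af_i, af_base)
        out_n.append(n_i + removed_mol)
        out_ex.append(ex_i + removed_excess)
        v = float(row.sample_volume_mL)
        if v >= v_head_mL:
            raise ValueError(
                f"sample volume {v} mL must be smaller than headspace {v_head_mL} mL"
            )
        frac = v / v_head_mL
        removed_mol += frac * n_i
        removed_excess += frac * ex_i
    return pd.DataFrame(
        {"time_h": df["time_h"], "n_co2_mol": out_n, "excess_13c_umol": out_ex}
    )


def partition_biotic_abiotic(
    excess_culture_umol: float, excess_sterile_umol: float
) -> PartitionResult:
    """Two-end-member mass balance against the sterile labeled control.

    The sterile control captures abiotic (thermal) label release; the biotic
    share is whatever the live culture released above that. A small negative
    difference (sterile exceeding culture within noise) floors to zero with a
    warning rather than erroring.
    """
    if not (np.isfinite(excess_culture_umol) and np.isfinite(excess_sterile_umol)):
        raise ValueError("excess values must be finite")
    excess_abiotic = excess_sterile_umol
    excess_biotic = excess_culture_umol - excess_sterile_umol
    if excess_biotic < 0:
        warnings.warn(
            "sterile excess exceeds culture excess; biotic excess floored at 0",
            stacklevel=2,
        )
        excess_biotic = 0.0
    if excess_culture_umol > 0:
        biotic_fraction = excess_biotic / excess_culture_umol
    else:
        biotic_fraction = float("nan")
    return PartitionResult(
        excess_total=excess_culture_umol,
        excess_abiotic=excess_abiotic,
        excess_biotic=excess_biotic,
        biotic_fraction=biotic_fraction,
    )


def _position_released(substrate: str, position: int, state: PathwayState) -> bool:
    if substrate == "pyruvate":
        if position == 1:
            return state.pyruvate_decarboxylation
        return state.tca_oxidation
    if substrate == "acetate":
        # Acetate carbons are the acetyl carbons; either route to oxidation
        # (activation to acetyl-CoA followed by TCA turns) releases them.
        return state.tca_oxidation or state.acetate_oxidation
    if substrate == "glucose":
        if position == 1 and state.oxidative_ppp:
            return True
        if state.glycolysis:
            return _position_released("pyruvate", GLUCOSE_TO_PYRUVATE[position], state)
        return False
    raise ValueError(f"unknown substrate {substrate!r}")


def carbon_fate_yield(
    substrate: str, labeled_positions: list[int] | tuple[int, ...], state: PathwayState
) -> float:
    """Fraction of labeled atoms of an isotopomer released as CO2.

    Every labeled position maps to exactly one fate (released or retained)
    under the given pathway state; the yield is the released share of the
    labeled positions.
    """
    if substrate not in SUBSTRATE_POSITIONS:
        raise ValueError(f"unknown substrate {substrate!r}")
    positions = list(labeled_positions)
    if not positions:
        raise ValueError("at least one labeled position is required")
    valid = SUBSTRATE_POSITIONS[substrate]
    for p in positions:
        if p not in valid:
            raise ValueError(f"invalid position C{p} for {substrate} (valid: {valid})")
    released = sum(_position_released(substrate, p, state) for p in positions)
    return released / len(positions)


#: Pathway state of the organism inferred from the isotopomer experiments:
#: glycolysis and pyruvate decarboxylation active, TCA oxidation of the acetyl
#: carbons uncoupled (no release from 2,3-13C pyruvate).
UNCOUPLED_TCA_STATE = PathwayState(
    glycolysis=True,
    oxidative_ppp=True,
    pyruvate_decarboxylation=True,
    tca_oxidation=False,
    acetate_oxidation=False,
)


def glucose_label_signals(
    glycolysis_flux: float, oxppp_flux: float, state: PathwayState = UNCOUPLED_TCA_STATE
) -> tuple[float, float]:
    """Forward model: 13CO2 signals from U-13C and 1-13C glucose.

    With glucose flux G through glycolysis and P through the oxidative PPP,
    the released label (atoms per unit time) is::

        U-13C:  6 * G * yield(U | glycolysis route) + 6 * P * yield(U | PPP route)
        1-13C:      G * yield(C1 | glycolysis route) +    P * yield(C1 | PPP route)

    Under the uncoupled-TCA state the glycolysis route releases only the
    carbons arriving at pyruvate C1 (glucose C3/C4) and the PPP route releases
    only glucose C1, so the signals reduce to ``(2G + P, P)``.
    """
    glyc_only = PathwayState(
        glycolysis=state.glycolysis,
        oxidative_ppp=False,
        pyruvate_decarboxylation=state.pyruvate_decarboxylation,
        tca_oxidation=state.tca_oxidation,
        acetate_oxidation=state.acetate_oxidation,
    )
    ppp_only = PathwayState(oxidative_ppp=state.oxidative_ppp)
    u_positions = SUBSTRATE_POSITIONS["glucose"]
    # integer released-atom counts per mole of glucose keep the signals exact
    atoms_glyc = sum(_position_released("glucose", p, glyc_only) for p in u_positions)
    atoms_ppp = sum(_position_released("glucose", p, ppp_only) for p in u_positions)
    u_signal = glycolysis_flux * atoms_glyc + oxppp_flux * atoms_ppp
    c1_signal = glycolysis_flux * _position_released(
        "glucose", 1, glyc_only
    ) + oxppp_flux * _position_released("glucose", 1, ppp_only)
    return u_signal, c1_signal


def infer_flux_ratio_glycolysis_ppp(ratio_u_to_c1: float) -> float:
    """Invert the observed U-13C : 1-13C glucose 13CO2 ratio to G/P.

    Under the uncoupled-TCA fate model the U signal is 2G + P label units and
    the C1 signal is P, so G/P = (ratio - 1) / 2. An observed ratio of ~25
    therefore implies glycolysis runs more than ten-fold faster than the
    oxidative PPP.
    """
    if ratio_u_to_c1 < 1:
        raise ValueError(
            "U:C1 ratio below 1 is inconsistent with the fate model "
            "(the C1 signal is a component of the U signal)"
        )
    return (ratio_u_to_c1 - 1.0) / 2.0


def production_rate(
    times_h: np.ndarray | list[float], cumulative_excess_umol: np.ndarray | list[float]
) -> tuple[float, float]:
    """OLS slope (umol/h) and its standard error for a cumulative-excess series."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(cumulative_excess_umol, dtype=float)
    if t.size < 2:
        raise ValueError("at least two time points are required")
    res = stats.linregress(t, y)
    return float(res.slope), float(res.stderr)
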