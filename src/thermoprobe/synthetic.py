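"""Seeded generators for every input the downstream analyses consume.

The generators plant known ground truth so that each estimator can be tested
as a round trip: multiplicative (log-normal) replicate noise on peak heights
with planted consumed/produced/thermally-altered compounds over the
three-treatment design; headspace delta-13CO2 traces produced by exact
algebraic inversion of the isotope arithmetic in :mod:`thermoprobe.isotope`
from stated biotic and abiotic label-release rates; peptidase annotation
tables with planted family counts; and KO sets targeting a requested module
completeness. All randomness flows through explicit integer seeds; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome as genome_mod
from . import isotope

EFFECT_CLASSES = (
    "none",
    "biological_consumption",
    "biological_production",
    "thermal_degradation",
    "thermal_production",
)

#: Replicate layout of the cultivation experiment: sterile starting medium
#: stored cold (n=4), sterile incubated control (n=5), incubated culture (n=5).
DEFAULT_DESIGN: dict[str, int] = {"start": 4, "incubated_control": 5, "culture": 5}


@dataclass(frozen=True)
class TruthSpec:
    """Planted ground truth for one compound."""

    compound_id: str
    effect_class: str = "none"
    fold_change: float = 1.0
    baseline_intensity: float = 2e5

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(
                f"unknown effect class {self.effect_class!r}; "
                f"expected one of {EFFECT_CLASSES}"
            )
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.baseline_intensity < 0:
            raise ValueError("baseline_intensity must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal multiplicative replicate noise.

    ``cv`` is the coefficient of variation of the replicate values; the
    underlying normal has sigma = sqrt(ln(1 + cv^2)) and the multiplier is
    mean-one, so treatment means are unbiased. ``cv = 0`` is noiseless.
    """

    cv: float = 0.1
    seed: int = 0
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.distribution != "lognormal":
            raise ValueError("only log-normal noise is supported")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log1p(self.cv**2))


def _treatment_means(truth: TruthSpec) -> dict[str, float]:
    """Apply the planted effect multiplicatively to the right treatments.

    Biological effects act on the culture only; thermal effects act on both
    incubated treatments (the culture was incubated too), so a thermal and a
    biological effect would compose multiplicatively.
    """
    base = truth.baseline_intensity
    means = {"start": base, "incubated_control": base, "culture": base}
    fc = truth.fold_change
    if truth.effect_class == "biological_consumption":
        means["culture"] /= fc
    elif truth.effect_class == "biological_production":
        means["culture"] *= fc
    elif truth.effect_class == "thermal_degradation":
        means["incubated_control"] /= fc
        means["culture"] /= fc
    elif truth.effect_class == "thermal_production":
        means["incubated_control"] *= fc
        means["culture"] *= fc
    return means


def generate_peak_table(
    design: dict[str, int] | None = None,
    truths: list[TruthSpec] = (),
    noise: NoiseModel = NoiseModel(),
    mode: str = "pos",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a compound x replicate peak-height table with planted effects.

    Returns the peak table (columns ``compound_id, treatment, replicate, mode,
    peak_height``) and the truth-label table (``compound_id, effect_class,
    fold_change, baseline_intensity``).
    """
    design = dict(DEFAULT_DESIGN if design is None else design)
    for t, n in design.items():
        if n < 1:
            raise ValueError(f"treatment {t!r} needs at least one replicate")
    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma
    rows = []
    for truth in truths:
        means = _treatment_means(truth)
        for treatment, n_rep in design.items():
            mean = means.get(treatment, truth.baseline_intensity)
            if sigma > 0:
                mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, n_rep))
            else:
                mult = np.ones(n_rep)
            for r, m in enumerate(mult, start=1):
                rows.append(
                    (truth.compound_id, treatment, r, mode, mean * float(m))
                )
    peaks = pd.DataFrame(
        rows, columns=["compound_id", "treatment", "replicate", "mode", "peak_height"]
    )
    truth_df = pd.DataFrame(
        [
            (t.compound_id, t.effect_class, t.fold_change, t.baseline_intensity)
            for t in truths
        ],
        columns=["compound_id", "effect_class", "fold_change", "baseline_intensity"],
    )
    return peaks, truth_df


def standard_benchmark(
    seed: int,
    n_planted: int = 200,
    n_null: int = 200,
    fold_change: float = 8.0,
    cv: float = 0.1,
    baseline: float = 2e5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The planted-effect recovery benchmark for the exometabolome pipeline.

    ``n_planted`` compounds carry one of the four effect classes in rotation
    at the stated fold change; ``n_null`` compounds are unaffected. Replicate
    layout follows :data:`DEFAULT_DESIGN`.
    """
    effects = [c for c in EFFECT_CLASSES if c != "none"]
    truths = [
        TruthSpec(f"planted_{i:04d}", effects[i % len(effects)], fold_change, baseline)
        for i in range(n_planted)
    ]
    truths += [
        TruthSpec(f"null_{i:04d}", "none", 1.0, baseline) for i in range(n_null)
    ]
    return generate_peak_table(None, truths, NoiseModel(cv=cv, seed=seed))


# --------------------------------------------------------------------------
# Headspace series
# --------------------------------------------------------------------------

#: Wheaton-bottle scale gas conditions used by the probing simulations.
DEFAULT_CONDITIONS = isotope.GasConditions(
    pressure_atm=1.0, headspace_volume_L=0.5, temperature_K=348.15
)

HEADSPACE_COLUMNS = [
    "time_h",
    "treatment",
    "delta13C_permil",
    "co2_umol_per_mol",
    "sample_volume_mL",
]


def _simulate_series(
    rate_umol_13c_per_h: float,
    conditions: isotope.GasConditions,
    times_h: np.ndarray,
    treatment: str,
    baseline_delta_permil: float,
    baseline_co2_umol_per_mol: float,
    sample_volume_mL: float,
    noise_sd_permil: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Track headspace 13C/12C pools forward in time.

    Label release is modeled as addition of pure 13CO2, scaled by
    1/(1 - AF_baseline) so that the excess-13C estimator recovers exactly
    rate x time (the generator is the algebraic inverse of the estimator).
    Each sampling event removes ``sample_volume_mL`` of well-mixed headspace
    after the measurement, which :func:`thermoprobe.isotope.
    correct_for_sampling` adds back.
    """
    n_gas = conditions.total_moles_gas
    af0 = isotope.delta_to_atom_fraction(baseline_delta_permil)
    n_co2 = n_gas * baseline_co2_umol_per_mol * 1e-6
    n13 = af0 * n_co2
    n12 = n_co2 - n13
    v_head_mL = conditions.headspace_volume_L * 1000.0
    if sample_volume_mL >= v_head_mL:
        raise ValueError("sample volume must be smaller than the headspace volume")

    rows = []
    prev_t = times_h[0]
    for i, t in enumerate(times_h):
        dt = t - prev_t
        n13 += rate_umol_13c_per_h * dt * 1e-6 / (1.0 - af0)
        prev_t = t
        af = n13 / (n13 + n12)
        delta = isotope.atom_fraction_to_delta(af)
        if noise_sd_permil > 0:
            delta += rng.normal(0.0, noise_sd_permil)
        mixing_ratio = (n13 + n12) / n_gas * 1e6
        rows.append((float(t), treatment, float(delta), float(mixing_ratio),
                     float(sample_volume_mL)))
        frac = sample_volume_mL / v_head_mL
        n13 *= 1.0 - frac
        n12 *= 1.0 - frac
    return pd.DataFrame(rows, columns=HEADSPACE_COLUMNS)


def generate_headspace_series(
    biotic_rate_umol_per_h: float,
    abiotic_rate_umol_per_h: float,
    conditions: isotope.GasConditions = DEFAULT_CONDITIONS,
    times_h=(0, 12, 24, 48, 72, 96, 120, 144, 168, 180),
    noise_sd_permil: float = 0.0,
    seed: int = 0,
    baseline_delta_permil: float = -10.0,
    baseline_co2_umol_per_mol: float = 1000.0,
    sample_volume_mL: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired culture and sterile-control delta-13CO2 series.

    The culture embeds biotic + abiotic label release; the sterile control
    embeds the abiotic release only. Rates are in umol 13C per hour.
    """
    if biotic_rate_umol_per_h < 0 or abiotic_rate_umol_per_h < 0:
        raise ValueError("release rates must be non-negative")
    times = np.asarray(times_h, dtype=float)
    if times.size < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    culture = _simulate_series(
        biotic_rate_umol_per_h + abiotic_rate_umol_per_h, conditions, times,
        "culture", baseline_delta_permil, baseline_co2_umol_per_mol,
        sample_volume_mL, noise_sd_permil, rng,
    )
    sterile = _simulate_series(
        abiotic_rate_umol_per_h, conditions, times,
        "sterile_control", baseline_delta_permil, baseline_co2_umol_per_mol,
        sample_volume_mL, noise_sd_permil, rng,
    )
    return culture, sterile


# --------------------------------------------------------------------------
# Annotation tables
# --------------------------------------------------------------------------

LOCALITIES = ("cytoplasmic", "membrane", "extracellular", "lipoprotein")
LOCALITY_WEIGHTS = (0.80, 0.10, 0.05, 0.05)


def generate_annotation_table(
    n_genes: int,
    family_spec: dict[str, int],
    seed: int = 0,
    genome_id: str = "genome",
) -> pd.DataFrame:
    """Gene annotation table with exactly the requested per-family counts.

    Families are assigned to randomly chosen genes; remaining genes are
    unannotated (empty family). Localities are drawn with a cytoplasm-heavy
    weighting. Over-subscribed specs (more assigned genes than genes) raise.
    """
    total_assigned = sum(family_spec.values())
    if any(c < 0 for c in family_spec.values()):
        raise ValueError("family counts must be non-negative")
    if total_assigned > n_genes:
        raise ValueError(
            f"family spec assigns {total_assigned} genes but only {n_genes} exist"
        )
    rng = np.random.default_rng(seed)
    gene_ids = [f"{genome_id}_g{i:05d}" for i in range(1, n_genes + 1)]
    families = [""] * n_genes
    localities = [
        LOCALITIES[k]
        for k in rng.choice(len(LOCALITIES), size=n_genes, p=LOCALITY_WEIGHTS)
    ]
    chosen = rng.choice(n_genes, size=total_assigned, replace=False)
    idx = 0
    for fam in sorted(family_spec):
        for _ in range(family_spec[fam]):
            families[chosen[idx]] = fam
            idx += 1
    return pd.DataFrame(
        {"gene_id": gene_ids, "family": families, "locality": localities}
    )


# --------------------------------------------------------------------------
# KO profiles
# --------------------------------------------------------------------------


def _satisfying_kos(node, rng: np.random.Generator) -> set[str]:
    """A minimal-ish KO set satisfying one step-expression node."""
    kind = node[0]
    if kind == "ko":
        return {node[1]}
    if kind == "and":
        out: set[str] = set()
        for child in node[1]:
            out |= _satisfying_kos(child, rng)
        return out
    if kind == "or":
        child = node[1][int(rng.integers(len(node[1])))]
        return _satisfying_kos(child, rng)
    if kind == "optional":
        return set()
    if kind == "gap":
        return set()  # unsatisfiable; nothing helps
    raise ValueError(f"unknown node kind {kind!r}")


def generate_ko_profile(
    modules: list[genome_mod.ModuleDefinition],
    completeness: float,
    seed: int = 0,
) -> set[str]:
    """KO set whose per-module completion approximates ``completeness``.

    Each step of each module is independently satisfied with probability
    ``completeness`` (one random alternative of the step is added). With
    completeness 1 every satisfiable step is satisfied; with 0 the set is
    empty. Because modules can share KOs, realized MCRs can exceed the target
    slightly.
    """
    if not 0.0 <= completeness <= 1.0:
        raise ValueError("completeness must be in [0, 1]")
    rng = np.random.default_rng(seed)
    kos: set[str] = set()
    for module in modules:
        for step in module.steps:
            if completeness >= 1.0 or rng.random() < completeness:
                kos |= _satisfying_kos(step, rng)
    return kos
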