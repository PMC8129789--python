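"""Three-treatment exometabolite classification.

A compound measured in a sterile starting medium (stored cold), a sterile
incubated control, and an incubated culture can change in abundance for two
reasons: high-temperature incubation (thermal degradation/production, read
from the start vs incubated-control contrast) or microbial activity
(biological consumption/production, read from the incubated-control vs
culture contrast). A compound is labeled only when it passes three criteria:

(i)   at least two of the three treatment groups are normally distributed
      (Shapiro-Wilk p > 0.05);
(ii)  at least one of the two treatment contrasts is significant under a
      Tukey-Kramer HSD test (adjusted p < 0.05);
(iii) at least one treatment has a mean peak height above 1e5 au (strict).

Compounds whose peak heights are at or below the intensity threshold in some
but not all treatments are flagged for manual chromatogram inspection rather
than excluded automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TREATMENTS = ("start", "incubated_control", "culture")

BIOLOGICAL_LABELS = frozenset({"biological_consumption", "biological_production"})
THERMAL_LABELS = frozenset({"thermal_degradation", "thermal_production"})


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the significance screen, as printed inequalities.

    Normality passes when Shapiro-Wilk p is strictly above ``alpha_normality``;
    a Tukey contrast is significant when the adjusted p is strictly below
    ``alpha_tukey``; the intensity screen requires some treatment mean strictly
    above ``intensity_threshold`` (au).
    """

    alpha_normality: float = 0.05
    alpha_tukey: float = 0.05
    intensity_threshold: float = 1e5
    mode_preference: str = "pos"
    manual_exclusions: frozenset[str] = frozenset()


@dataclass
class CompoundClassification:
    compound_id: str
    mode: str
    passed_normality: bool
    tukey_p_thermal: float
    tukey_p_biological: float
    anova_f: float
    anova_p: float
    passed_intensity: bool
    labels: frozenset[str]
    log2fc_biological: float
    log2fc_thermal: float
    manual_inspection_flag: bool
    treatment_means: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.labels)


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one replicate group.

    Groups with fewer than three values or zero variance are untestable and
    raise; callers that use this as a screen treat the error as non-normal.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError(f"Shapiro-Wilk requires n >= 3; got n = {arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant values")
    w, p = stats.shapiro(arr)
    return float(w), float(p)


def normality_screen(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[bool, dict[str, float]]:
    """Criterion (i): at least two of the three treatments normal (p > alpha).

    Returns the flag and the per-treatment p-values (NaN where the test was
    untestable; such groups count as non-normal).
    """
    missing = set(TREATMENTS) - set(groups)
    if missing:
        raise ValueError(f"missing treatment groups: {sorted(missing)}")
    pvals: dict[str, float] = {}
    n_normal = 0
    for t in TREATMENTS:
        try:
            _, p = shapiro_wilk(groups[t])
        except ValueError:
            pvals[t] = float("nan")
            continue
        pvals[t] = p
        if p > alpha:
            n_normal += 1
    return n_normal >= 2, pvals


def tukey_hsd(
    groups: dict[str, np.ndarray],
) -> tuple[dict[frozenset[str], float], float, float]:
    """Tukey-Kramer HSD adjusted p-values for all pairs, plus the omnibus ANOVA.

    Handles unequal group sizes (Tukey-Kramer). Returns a mapping keyed by the
    unordered pair of group names, and the one-way ANOVA F and p.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("at least two groups are required")
    arrays = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        arrays.append(arr)
    res = stats.tukey_hsd(*arrays)
    pairs: dict[frozenset[str], float] = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            pairs[frozenset((a, names[j]))] = float(res.pvalue[i, j])
    f_stat, f_p = stats.f_oneway(*arrays)
    return pairs, float(f_stat), float(f_p)


def intensity_screen(means: dict[str, float], threshold: float = 1e5) -> bool:
    """Criterion (iii): some treatment mean strictly above the threshold."""
    missing = set(TREATMENTS) - set(means)
    if missing:
        raise ValueError(f"missing treatment means: {sorted(missing)}")
    return any(means[t] > threshold for t in TREATMENTS)


def log2_fold_change(mean_b: float, mean_a: float) -> float:
    """log2(mean_b / mean_a); both means must be positive."""
    if mean_b <= 0 or mean_a <= 0:
        raise ValueError("fold changes require strictly positive means")
    return math.log2(mean_b / mean_a)


def classify_compound(
    slice_: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> CompoundClassification:
    """Run criteria (i)-(iii) and attribute direction for one compound/mode.

    ``slice_`` holds the replicate rows of a single compound in a single
    ionization mode (columns ``compound_id``, ``treatment``, ``peak_height``,
    optionally ``mode``). Direction of a significant contrast follows the sign
    of the mean difference: culture below the incubated control means
    consumption, above means production; the incubated control below the
    start means thermal degradation, above means thermal production. A
    compound may carry one biological and one thermal label at once.
    """
    compound_id = str(slice_["compound_id"].iloc[0])
    mode = str(slice_["mode"].iloc[0]) if "mode" in slice_.columns else "pos"
    groups = {
        t: slice_.loc[slice_["treatment"] == t, "peak_height"].to_numpy(dtype=float)
        for t in TREATMENTS
    }
    for t, arr in groups.items():
        if arr.size == 0:
            raise ValueError(f"compound {compound_id}: treatment {t!r} missing")
    means = {t: float(np.mean(v)) for t, v in groups.items()}

    passed_normality, _ = normality_screen(groups, config.alpha_normality)
    pairs, anova_f, anova_p = tukey_hsd(groups)
    p_thermal = pairs[frozenset(("start", "incubated_control"))]
    p_biological = pairs[frozenset(("incubated_control", "culture"))]
    passed_intensity = intensity_screen(means, config.intensity_threshold)

    any_significant = (
        p_thermal < config.alpha_tukey or p_biological < config.alpha_tukey
    )
    labels: set[str] = set()
    if passed_normality and any_significant and passed_intensity:
        if p_biological < config.alpha_tukey:
            if means["culture"] < means["incubated_control"]:
                labels.add("biological_consumption")
            elif means["culture"] > means["incubated_control"]:
                labels.add("biological_production")
        if p_thermal < config.alpha_tukey:
            if means["incubated_control"] < means["start"]:
                labels.add("thermal_degradation")
            elif means["incubated_control"] > means["start"]:
                labels.add("thermal_production")

    low = [means[t] <= config.intensity_threshold for t in TREATMENTS]
    manual_flag = any(low) and not all(low)

    def safe_log2fc(b: float, a: float) -> float:
        try:
            return log2_fold_change(b, a)
        except ValueError:
            return float("nan")

    return CompoundClassification(
        compound_id=compound_id,
        mode=mode,
        passed_normality=passed_normality,
        tukey_p_thermal=p_thermal,
        tukey_p_biological=p_biological,
        anova_f=anova_f,
        anova_p=anova_p,
        passed_intensity=passed_intensity,
        labels=frozenset(labels),
        log2fc_biological=safe_log2fc(means["culture"], means["incubated_control"]),
        log2fc_thermal=safe_log2fc(means["incubated_control"], means["start"]),
        manual_inspection_flag=manual_flag,
        treatment_means=means,
    )


def run_exometabolome_pipeline(
    table: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Classify every compound in a peak table and assemble the report.

    One row per reported compound. A compound significant in both ionization
    modes is reported once, preferring the configured mode; compounds whose
    treatment means are all at or below the intensity threshold are dropped;
    compounds listed in ``config.manual_exclusions`` (the manual-inspection
    override) are dropped.
    """
    columns = [
        "compound_id", "mode", "passed_normality", "tukey_p_thermal",
        "tukey_p_biological", "anova_f", "anova_p", "passed_intensity",
        "labels", "log2fc_biological", "log2fc_thermal",
        "manual_inspection_flag", "mean_start", "mean_incubated_control",
        "mean_culture",
    ]
    if table.empty:
        return pd.DataFrame(columns=columns)
    work = table.copy()
    if "mode" not in work.columns:
        work["mode"] = "pos"

    per_compound: dict[str, dict[str, CompoundClassification]] = {}
    for (cid, mode), slice_ in work.groupby(["compound_id", "mode"], sort=True):
        per_compound.setdefault(str(cid), {})[str(mode)] = classify_compound(
            slice_, config
        )

    rows = []
    for cid in sorted(per_compound):
        by_mode = per_compound[cid]
        if cid in config.manual_exclusions:
            continue
        # prefer the configured mode; among the rest prefer a significant mode
        order = sorted(
            by_mode,
            key=lambda m: (m != config.mode_preference, not by_mode[m].significant),
        )
        chosen = by_mode[order[0]]
        if not chosen.significant:
            significant = [m for m in by_mode if by_mode[m].significant]
            if significant:
                chosen = by_mode[
                    min(significant, key=lambda m: m != config.mode_preference)
                ]
        means = chosen.treatment_means
        if all(means[t] <= config.intensity_threshold for t in TREATMENTS):
            continue
        rows.append(
            {
                "compound_id": chosen.compound_id,
                "mode": chosen.mode,
                "passed_normality": chosen.passed_normality,
                "tukey_p_thermal": chosen.tukey_p_thermal,
                "tukey_p_biological": chosen.tukey_p_biological,
                "anova_f": chosen.anova_f,
                "anova_p": chosen.anova_p,
                "passed_intensity": chosen.passed_intensity,
                "labels": ";".join(sorted(chosen.labels)),
                "log2fc_biological": chosen.log2fc_biological,
                "log2fc_thermal": chosen.log2fc_thermal,
                "manual_inspection_flag": chosen.manual_inspection_flag,
                "mean_start": means["start"],
                "mean_incubated_control": means["incubated_control"],
                "mean_culture": means["culture"],
            }
        )
    return pd.DataFrame(rows, columns=columns)


def estimate_cell_density(
    filament_lengths_um,
    counted_chamber_volume_mL: float,
    concentration_factor: float,
    cell_length_um: float = 4.0,
) -> float:
    """Cells per mL of original culture from filament-length measurements.

    Filamentous cells are counted by total filament length divided by the
    average individual cell length (4.0 um). ``concentration_factor`` is the
    factor dividing the chamber density to recover the original culture
    density (the volume ratio of the concentration step).
    """
    if cell_length_um <= 0:
        raise ValueError("cell length must be positive")
    if counted_chamber_volume_mL <= 0 or concentration_factor <= 0:
        raise ValueError("chamber volume and concentration factor must be positive")
    lengths = np.asarray(list(filament_lengths_um), dtype=float)
    if lengths.size and (lengths <= 0).any():
        raise ValueError("filament lengths must be positive")
    n_cells = float(lengths.sum()) / cell_length_um
    return n_cells / counted_chamber_volume_mL / concentration_factor
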