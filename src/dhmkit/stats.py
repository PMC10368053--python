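"""Group comparisons, sensitivity analyses and dosimetry arithmetic.

Group comparisons follow a normality-gated two-branch scheme: Shapiro-Wilk
on each group, unpaired two-sided t-test if both pass, Mann-Whitney U
otherwise.  Multi-group comparisons use one-way ANOVA with Tukey HSD and
compact-letter grouping.  Sensitivity operations re-run the RI inversion
under perturbed analysis radius or added smooth background distortion and
report the relative change of the mean valid RI.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .optics import OpticalConfig, PhaseMap
from .ri import CircularROI, background_subtract, compute_ri

__all__ = [
    "GroupSeries",
    "TestResult",
    "choose_and_compare",
    "compare_across_stages",
    "radius_sensitivity",
    "background_sensitivity",
    "energy_density",
]

DEFAULT_ALPHA = 0.05


@dataclass
class GroupSeries:
    """Per-specimen summary RI values for one (stage, lipid) group."""

    stage: str
    lipid: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def label(self) -> str:
        return f"{self.stage}/{self.lipid}"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    warnings: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)


def _is_degenerate(v: np.ndarray) -> bool:
    return np.ptp(v) == 0


def choose_and_compare(a: GroupSeries, b: GroupSeries,
                       alpha: float = DEFAULT_ALPHA,
                       force: str | None = None) -> TestResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at ``alpha`` → two-sided unpaired t-test; otherwise
    (or on degenerate zero-variance input, where Shapiro-Wilk is undefined)
    a two-sided Mann-Whitney U.  ``force`` ∈ {"ttest", "mannwhitney"} skips
    the gate for auditing.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs at least 2 specimens")
    warnings: list[str] = []
    details: dict = {}

    if force is None:
        degenerate = _is_degenerate(a.values) or _is_degenerate(b.values)
        if degenerate:
            warnings.append("zero-variance group: normality check skipped, "
                            "falling back to Mann-Whitney")
            branch = "mannwhitney"
            details["normality_p"] = (math.nan, math.nan)
        else:
            pa = sps.shapiro(a.values).pvalue
            pb = sps.shapiro(b.values).pvalue
            details["normality_p"] = (float(pa), float(pb))
            branch = "ttest" if (pa >= alpha and pb >= alpha) else "mannwhitney"
    else:
        if force not in ("ttest", "mannwhitney"):
            raise ValueError("force must be 'ttest' or 'mannwhitney'")
        branch = force

    if branch == "ttest":
        res = sps.ttest_ind(a.values, b.values, alternative="two-sided")
        name = "unpaired t-test"
    else:
        res = sps.mannwhitneyu(a.values, b.values, alternative="two-sided")
        name = "Mann-Whitney U"
    p = float(res.pvalue)
    return TestResult(test_name=name, statistic=float(res.statistic),
                      p_value=p, alpha=alpha, significant=bool(p < alpha),
                      warnings=warnings, details=details)


def _compact_letters(labels: list[str], sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different (insert-and-absorb construction)."""
    letter_sets: list[set[str]] = [set(labels)]
    for (g1, g2), is_sig in sig.items():
        if not is_sig:
            continue
        for s in list(letter_sets):
            if g1 in s and g2 in s:
                letter_sets.remove(s)
                s1, s2 = s - {g1}, s - {g2}
                for cand in (s1, s2):
                    if not any(cand <= other for other in letter_sets):
                        letter_sets.append(cand)
    letter_sets = [s for s in letter_sets if s]
    letter_sets.sort(key=lambda s: sorted(labels.index(g) for g in s))
    out = {g: "" for g in labels}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", letter_sets):
        for g in sorted(s, key=labels.index):
            out[g] += letter
    return out


def compare_across_stages(groups: list[GroupSeries],
                          alpha: float = DEFAULT_ALPHA) -> dict:
    """One-way ANOVA across ≥3 groups plus Tukey HSD pairwise comparisons.

    Returns the ANOVA F and p, a tidy pairwise table with Tukey-adjusted
    p-values, and letter-style group labels (groups sharing a letter are not
    significantly different).
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for ANOVA + Tukey")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label} has fewer than 2 specimens")

    samples = [g.values for g in groups]
    labels = [g.label for g in groups]
    f_stat, f_p = sps.f_oneway(*samples)
    tukey = sps.tukey_hsd(*samples)

    rows = []
    sig: dict[tuple[str, str], bool] = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append({
                "group_1": labels[i],
                "group_2": labels[j],
                "mean_diff": float(samples[i].mean() - samples[j].mean()),
                "p_adj": p_adj,
                "significant": bool(p_adj < alpha),
            })
            sig[(labels[i], labels[j])] = bool(p_adj < alpha)

    return {
        "anova": {"F": float(f_stat), "p_value": float(f_p),
                  "significant": bool(f_p < alpha)},
        "pairwise": pd.DataFrame(rows),
        "letters": _compact_letters(labels, sig),
        "alpha": alpha,
    }


def _mean_ri(phase: PhaseMap, roi: CircularROI, config: OpticalConfig,
             h_min_frac: float) -> float:
    corrected = background_subtract(phase, roi, config)
    return compute_ri(corrected, roi, config, h_min_frac=h_min_frac).summary["mean"]


def radius_sensitivity(phase: PhaseMap, roi: CircularROI,
                       config: OpticalConfig,
                       perturb_fracs: list[float] = (-0.15, 0.0, 0.15),
                       h_min_frac: float = 0.1) -> pd.DataFrame:
    """Mean-RI response to perturbing the analysis radius by fractions f.

    For each f the full ring subtraction + RI inversion is re-run with
    radius R*(1+f); the relative change is reported against the nominal
    (f=0) reconstruction.
    """
    nominal = _mean_ri(phase, roi, config, h_min_frac)
    rows = []
    for f in perturb_fracs:
        if f == 0.0:
            mean = nominal
        else:
            mean = _mean_ri(phase, roi.scaled(1.0 + f), config, h_min_frac)
        rows.append({
            "perturb_frac": f,
            "radius": roi.radius * (1.0 + f),
            "mean_ri": mean,
            "relative_change": (mean - nominal) / nominal,
        })
    return pd.DataFrame(rows)


def background_distortion_field(roi: CircularROI, config: OpticalConfig,
                                amplitude_rad: float) -> np.ndarray:
    """Tilt-plus-curvature background phase, scaled to the requested
    peak-to-peak amplitude over the ROI disk plus its ring."""
    x, y = config.pixel_coords()
    extent = roi.radius + roi.ring_width
    u = (x - roi.center_x) / extent
    v = (y - roi.center_y) / extent
    raw = u + v + (u ** 2 + v ** 2)  # first- plus second-order terms
    region = roi.radial_distance(config) <= extent
    ptp = np.ptp(raw[region])
    if ptp == 0:
        return np.zeros_like(raw)
    return raw * (amplitude_rad / ptp)


def background_sensitivity(phase: PhaseMap, roi: CircularROI,
                           config: OpticalConfig,
                           distortion_amplitude_rad: float = 0.2,
                           h_min_frac: float = 0.1) -> dict:
    """Mean-RI response to a smooth background distortion.

    Adds a tilt-plus-curvature polynomial with the stated peak-to-peak
    amplitude across the ROI before ring subtraction, re-runs the inversion
    and reports the relative mean-RI change.
    """
    if distortion_amplitude_rad < 0:
        raise ValueError("distortion amplitude must be >= 0")
    nominal = _mean_ri(phase, roi, config, h_min_frac)
    distortion = background_distortion_field(roi, config,
                                             distortion_amplitude_rad)
    distorted = PhaseMap(phase.values + distortion, wrapped=False)
    perturbed = _mean_ri(distorted, roi, config, h_min_frac)
    return {
        "amplitude_rad": distortion_amplitude_rad,
        "mean_ri_nominal": nominal,
        "mean_ri_distorted": perturbed,
        "relative_change": (perturbed - nominal) / nominal,
    }


def energy_density(power_W: float, exposure_s: float,
                   spot_diameter_m: float) -> float:
    """Delivered energy density in J/cm²: power × time over the spot area.

    The spot is a circle of the given diameter; the result is expressed per
    square centimetre.
    """
    if power_W <= 0 or exposure_s <= 0 or spot_diameter_m <= 0:
        raise ValueError("power, exposure and spot diameter must be positive")
    radius_cm = spot_diameter_m * 100.0 / 2.0
    area_cm2 = math.pi * radius_cm ** 2
    return power_W * exposure_s / area_cm2
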