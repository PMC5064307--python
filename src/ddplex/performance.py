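"""Method-performance rules for droplet digital PCR validation.

Implements the rule set used to validate quantitative GMO methods:

* repeatability as relative standard deviation (RSD, percent);
* absolute limit of quantification (aLOQ): lowest level with RSD <= 25%,
  optionally after removing 1.5 x IQR outliers;
* absolute limit of detection (aLOD): lowest level where at most one
  replicate fails the >= 3-positive-droplets rule (generalising the
  14-of-15 design to any replicate count);
* signed percent bias against a reference value (|bias| <= 25% trueness
  criterion);
* proficiency-test z-scores with the |Z| < 2 pass rule;
* linearity of measured vs assigned copies (OLS, R^2);
* mass-fraction <-> copy-number-ratio conversion factors (consensus 0.5,
  ~0.4 / ~0.6 when the GM parent was male / female);
* rain-induced false-positive rate relative to the co-channel
  high-amplitude target, and the 0.9% / 0.1% GM-content labelling flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Literal, Sequence

import numpy as np
from scipy import stats

from .simulate import DilutionLevel

__all__ = [
    "ConversionFactor",
    "PerformanceReport",
    "rsd",
    "iqr_outliers",
    "determine_aloq",
    "determine_alod",
    "percent_bias",
    "z_score",
    "linearity",
    "convert_units",
    "false_positive_rate",
    "labelling_flags",
    "evaluate_dilution_series",
]

logger = logging.getLogger(__name__)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 x sd(n-1) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def iqr_outliers(values: Sequence[float]) -> np.ndarray:
    """Flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation at position (n-1) x q, numpy's
    default convention. Returns a boolean mask parallel to ``values``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("outlier detection needs at least 4 values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    low, high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (x < low) | (x > high)


def _level_values(level: DilutionLevel, remove_outliers: bool) -> np.ndarray:
    x = np.asarray(level.replicate_values, dtype=float)
    if remove_outliers and x.size >= 4:
        keep = ~iqr_outliers(x)
        if keep.sum() >= 2:
            x = x[keep]
    return x


def determine_aloq(
    levels: Sequence[DilutionLevel],
    max_rsd: float = 25.0,
    remove_outliers: bool = False,
) -> float | None:
    """Absolute limit of quantification.

    The lowest mean measured copy number among levels whose replicate RSD is
    at or below ``max_rsd`` percent; ``None`` when no level qualifies (each
    level's RSD is logged as a diagnostic). With ``remove_outliers``, the
    1.5 x IQR rule is applied per level before the RSD.
    """
    if not levels:
        raise ValueError("no dilution levels given")
    passing: list[float] = []
    diagnostics: list[str] = []
    for level in levels:
        x = _level_values(level, remove_outliers)
        level_rsd = rsd(x)
        diagnostics.append(f"{level.level_id}: RSD {level_rsd:.1f}%")
        if level_rsd <= max_rsd:
            passing.append(float(x.mean()))
    if not passing:
        logger.info(
            "no level meets RSD <= %.1f%% (%s); aLOQ undefined",
            max_rsd,
            "; ".join(diagnostics),
        )
        return None
    return min(passing)


def determine_alod(
    levels: Sequence[DilutionLevel],
    min_positive_droplets: int = 3,
    max_negative_replicates: int = 1,
) -> float | None:
    """Absolute limit of detection.

    A replicate is positive when it has at least ``min_positive_droplets``
    positive droplets; a level detects when at most
    ``max_negative_replicates`` replicates are negative (the default, 1,
    generalises the 14-of-15-replicates design). Returns the lowest mean
    measured copy number among detecting levels, ``None`` if no level
    detects.
    """
    if not levels:
        raise ValueError("no dilution levels given")
    detecting: list[float] = []
    for level in levels:
        droplets = level.replicate_positive_droplets
        if not droplets:
            raise ValueError(f"{level.level_id}: missing positive-droplet counts")
        negatives = sum(1 for d in droplets if d < min_positive_droplets)
        if negatives <= max_negative_replicates:
            detecting.append(float(np.mean(level.replicate_values)))
    if not detecting:
        return None
    return min(detecting)


def percent_bias(reference: float, measured: float) -> float:
    """Signed percent deviation of a measured value from a reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (measured - reference) / reference


def z_score(measured: float, assigned: float, sigma: float) -> tuple[float, bool]:
    """Proficiency-test z-score and its pass flag (pass iff |Z| < 2, strict).

    The strict boundary is evaluated to a relative 1e-9, so a z-score that is
    exactly 2 up to floating-point representation fails as intended.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (measured - assigned) / sigma
    return z, abs(z) < 2.0 * (1.0 - 1e-9)


def linearity(
    assigned: Sequence[float],
    measured: Sequence[float],
    scale: Literal["linear", "log10"] = "linear",
) -> tuple[float, float, float]:
    """Least-squares fit of measured on assigned copies: (slope, intercept, R^2).

    ``scale="log10"`` fits on log10-transformed values (all inputs must then
    be positive).
    """
    x = np.asarray(assigned, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("linearity needs at least 3 paired points")
    if np.all(x == x[0]):
        raise ValueError("assigned values are all equal; fit is degenerate")
    if scale == "log10":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log10 scale requires positive values")
        x, y = np.log10(x), np.log10(y)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


@dataclass(frozen=True)
class ConversionFactor:
    """Dimensionless factor relating copy-number ratio to mass fraction.

    The consensus value is 0.5; experimentally the factor is around 0.4 when
    the GM parent was male and around 0.6 when female, because parental DNA
    contributes unevenly to endosperm, embryo and aleurone.
    """

    value: float
    origin: str = "custom"

    _KNOWN = {
        "consensus_0.5": 0.5,
        "male_parent_0.4": 0.4,
        "female_parent_0.6": 0.6,
    }

    def __post_init__(self) -> None:
        if not 0 < self.value <= 1:
            raise ValueError("conversion factor must lie in (0, 1]")
        if self.origin != "custom" and self.origin not in self._KNOWN:
            raise ValueError(f"unknown origin {self.origin!r}")

    @classmethod
    def consensus(cls) -> "ConversionFactor":
        return cls(0.5, "consensus_0.5")

    @classmethod
    def male_parent(cls) -> "ConversionFactor":
        return cls(0.4, "male_parent_0.4")

    @classmethod
    def female_parent(cls) -> "ConversionFactor":
        return cls(0.6, "female_parent_0.6")


def convert_units(
    value: float,
    factor: ConversionFactor,
    direction: Literal["mass_to_copies", "copies_to_mass"],
) -> float:
    """Convert GM content between mass-fraction % and copy-number-ratio %.

    Convention: copy% = mass% x factor, mass% = copy% / factor, so the two
    directions are exact inverses for any factor.
    """
    if direction == "mass_to_copies":
        return value * factor.value
    if direction == "copies_to_mass":
        return value / factor.value
    raise ValueError(f"unknown direction {direction!r}")


def false_positive_rate(fp_positives: int, paired_high_positives: int) -> float:
    """False positives for an absent target, as percent of the co-channel
    high-amplitude target's positive droplets (the rain metric)."""
    if paired_high_positives < 1:
        raise ValueError("paired high-target positive count must be >= 1")
    if fp_positives < 0:
        raise ValueError("false-positive count must be >= 0")
    return 100.0 * fp_positives / paired_high_positives


def labelling_flags(gm_percent: float) -> dict[str, bool]:
    """EU reporting flags for a GM content in percent.

    ``above_labelling_threshold``: content >= 0.9% (product must be
    labelled); ``above_screening_threshold``: content >= 0.1% (relevant for
    unauthorised-event screening). Flags only — no regulatory logic.
    """
    return {
        "above_labelling_threshold": gm_percent >= 0.9,
        "above_screening_threshold": gm_percent >= 0.1,
    }


@dataclass(frozen=True)
class LevelStats:
    level_id: str
    assigned_copies: float
    mean_measured: float
    rsd_percent: float
    n_replicates: int
    outlier_flags: tuple[bool, ...]


@dataclass(frozen=True)
class PerformanceReport:
    """Validation summary for one target's dilution series."""

    target_name: str
    levels: tuple[LevelStats, ...]
    aloq_copies: float | None
    alod_copies: float | None
    linearity_fit: tuple[float, float, float] | None
    bias_entries: tuple[tuple[str, float], ...] = ()
    z_entries: tuple[tuple[str, float, bool], ...] = ()

    @property
    def alod_exceeds_aloq(self) -> bool:
        """Flag (not an error): noisy input can invert the expected order."""
        if self.aloq_copies is None or self.alod_copies is None:
            return False
        return self.alod_copies > self.aloq_copies

    def write(self, stream: IO[str], *, digits: int = 4) -> None:
        def f(x: float | None) -> str:
            return "undefined" if x is None else f"{x:.{digits}g}"

        stream.write(f"# performance report\ttarget={self.target_name}\n")
        stream.write("level\tassigned_copies\tmean_measured\trsd_percent\tn\toutliers\n")
        for lv in self.levels:
            n_out = sum(lv.outlier_flags)
            stream.write(
                f"{lv.level_id}\t{f(lv.assigned_copies)}\t{f(lv.mean_measured)}\t"
                f"{f(lv.rsd_percent)}\t{lv.n_replicates}\t{n_out}\n"
            )
        stream.write(f"aLOQ_copies\t{f(self.aloq_copies)}\n")
        stream.write(f"aLOD_copies\t{f(self.alod_copies)}\n")
        if self.alod_exceeds_aloq:
            stream.write("flag\taLOD exceeds aLOQ (noisy input)\n")
        if self.linearity_fit is not None:
            slope, intercept, r2 = self.linearity_fit
            stream.write(
                f"linearity\tslope={f(slope)}\tintercept={f(intercept)}\tR2={f(r2)}\n"
            )
        for label, bias in self.bias_entries:
            stream.write(f"bias\t{label}\t{f(bias)}%\n")
        for label, z, ok in self.z_entries:
            stream.write(f"z_score\t{label}\t{f(z)}\t{'pass' if ok else 'fail'}\n")


def evaluate_dilution_series(
    levels: Sequence[DilutionLevel],
    target_name: str = "target",
    *,
    max_rsd: float = 25.0,
    remove_outliers: bool = False,
    min_positive_droplets: int = 3,
    max_negative_replicates: int = 1,
    linearity_scale: Literal["linear", "log10"] = "linear",
    bias_entries: Sequence[tuple[str, float]] = (),
    z_entries: Sequence[tuple[str, float, bool]] = (),
) -> PerformanceReport:
    """Apply the full rule set to one target's dilution series."""
    if not levels:
        raise ValueError("no dilution levels given")
    stats_rows = []
    for level in levels:
        x = np.asarray(level.replicate_values, dtype=float)
        flags = tuple(bool(b) for b in iqr_outliers(x)) if x.size >= 4 else tuple(
            False for _ in x
        )
        stats_rows.append(
            LevelStats(
                level_id=level.level_id,
                assigned_copies=level.assigned_copies,
                mean_measured=float(x.mean()),
                rsd_percent=rsd(x) if x.size >= 2 else float("nan"),
                n_replicates=int(x.size),
                outlier_flags=flags,
            )
        )
    aloq = determine_aloq(levels, max_rsd=max_rsd, remove_outliers=remove_outliers)
    alod = determine_alod(
        levels,
        min_positive_droplets=min_positive_droplets,
        max_negative_replicates=max_negative_replicates,
    )
    fit = None
    assigned = [lv.assigned_copies for lv in levels]
    means = [float(np.mean(lv.replicate_values)) for lv in levels]
    if len(levels) >= 3 and len(set(assigned)) > 1:
        fit = linearity(assigned, means, scale=linearity_scale)
    return PerformanceReport(
        target_name=target_name,
        levels=tuple(stats_rows),
        aloq_copies=aloq,
        alod_copies=alod,
        linearity_fit=fit,
        bias_entries=tuple(bias_entries),
        z_entries=tuple(z_entries),
    )
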